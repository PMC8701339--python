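"""Downstream statistics for grader CDR measures.

Two analyses are provided:

* Spearman rank correlation between grader vertical CDR and the
  clinician's slit-lamp VCDR, with a 95% CI from the Fisher
  z-transform using the rank-correlation variance 1.06/(n-3).
* A per-SNP allele-count trend test on a grader outcome (VCDR or
  cup/disc area ratio): an identity-link linear mean model
  ``outcome ~ allele_count + age + gender`` fitted by generalized
  estimating equations with an exchangeable working correlation across
  the (up to two) eyes of each subject and robust sandwich standard
  errors.  The trend p-value is the Wald test on the allele-count
  coefficient treated as a continuous predictor; adjusted means are
  model predictions at each allele count with age and gender held at
  their sample means.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = ["CorrelationResult", "TrendTestResult", "spearman_with_ci",
           "gee_trend_test", "nearest_date_join"]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    ci_low: float
    ci_high: float


def spearman_with_ci(x, y, *, ci_method: str = "fisher", n_boot: int = 2000,
                     seed: int | None = None) -> CorrelationResult:
    """Spearman rho of paired samples with a 95% confidence interval.

    Ties receive average ranks.  ``fisher`` (default) transforms rho to
    z = atanh(rho) with SE sqrt(1.06/(n-3)); ``bootstrap`` resamples
    pairs (percentile interval).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d vectors")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    r = float(sps.spearmanr(x, y).statistic)
    if ci_method == "fisher":
        if abs(r) >= 1.0:
            lo = hi = r
        else:
            z = np.arctanh(r)
            se = np.sqrt(1.06 / (n - 3))
            zc = sps.norm.ppf(0.975)
            lo, hi = np.tanh(z - zc * se), np.tanh(z + zc * se)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            xb, yb = x[idx], y[idx]
            if np.ptp(xb) == 0 or np.ptp(yb) == 0:
                reps[b] = np.nan
                continue
            reps[b] = sps.spearmanr(xb, yb).statistic
        lo, hi = np.nanpercentile(reps, [2.5, 97.5])
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return CorrelationResult(r=r, n=n, ci_low=float(lo), ci_high=float(hi))


def nearest_date_join(
    clinical: pd.DataFrame,
    images: pd.DataFrame,
    *,
    on: tuple[str, str] = ("subject_id", "eye"),
    clinical_date: str = "exam_date",
    image_date: str = "image_date",
) -> pd.DataFrame:
    """Pair each image with the clinical record nearest in time.

    For every (subject, eye) image row, attaches the clinical row whose
    exam date is closest to the image date (ties to the earlier exam).
    """
    cl = clinical.copy()
    im = images.copy()
    cl[clinical_date] = pd.to_datetime(cl[clinical_date])
    im[image_date] = pd.to_datetime(im[image_date])
    rows = []
    grouped = cl.groupby(list(on))
    for row in im.itertuples(index=False):
        d = row._asdict()
        key = tuple(d[k] for k in on)
        try:
            cand = grouped.get_group(key)
        except KeyError:
            continue
        delta = (cand[clinical_date] - d[image_date]).abs()
        best = cand.loc[delta.sort_values(kind="stable").index[0]]
        merged = {**d, **{f"clinical_{k}" if k in d else k: v for k, v in best.items()}}
        rows.append(merged)
    return pd.DataFrame(rows)


@dataclass
class TrendTestResult:
    snp_id: str
    p_trend: float
    coef: float
    coef_se: float
    levels: list[int] = field(default_factory=list)
    adjusted_means: dict[int, float] = field(default_factory=dict)
    adjusted_ses: dict[int, float] = field(default_factory=dict)
    n_eyes: dict[int, int] = field(default_factory=dict)
    exchangeable_corr: float = float("nan")
    warnings: list[str] = field(default_factory=list)


def gee_trend_test(
    eyes: pd.DataFrame,
    *,
    outcome: str = "outcome",
    snp_id: str = "snp",
) -> TrendTestResult:
    """Allele-count trend test on a per-eye outcome via GEE.

    ``eyes`` needs columns subject_id, eye, the outcome, allele_count,
    age, gender.  Eyes are the analysis rows; the two eyes of one
    subject form a cluster with exchangeable working correlation.  When
    every subject contributes a single eye the fit degenerates to an
    independence model (OLS point estimates with robust SEs) and a
    warning is recorded.
    """
    required = {"subject_id", "eye", outcome, "allele_count", "age", "gender"}
    missing = required - set(eyes.columns)
    if missing:
        raise ValueError(f"missing columns: {', '.join(sorted(missing))}")
    df = eyes.dropna(subset=[outcome, "allele_count", "age", "gender"]).copy()
    if not df["allele_count"].isin([0, 1, 2]).all():
        raise ValueError("allele_count must be 0, 1 or 2")
    levels = sorted(int(v) for v in df["allele_count"].unique())
    for lv in levels:
        n_subj = df.loc[df["allele_count"] == lv, "subject_id"].nunique()
        if n_subj < 2:
            raise ValueError(f"allele level {lv} represented by fewer than 2 subjects")
    warnings_out: list[str] = []

    # Sort by cluster so statsmodels sees contiguous groups.
    df = df.sort_values(["subject_id", "eye"], kind="stable").reset_index(drop=True)
    gender_levels = sorted(df["gender"].astype(str).unique())
    if len(gender_levels) > 2:
        raise ValueError("gender must be binary-coded")
    df["_gender_ind"] = (df["gender"].astype(str) == gender_levels[-1]).astype(float)
    age_mean = float(df["age"].mean())
    df["_age_c"] = df["age"] - age_mean
    X = sm.add_constant(
        df[["allele_count", "_age_c", "_gender_ind"]].astype(float), has_constant="add"
    )
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("singular design matrix")
    y = df[outcome].astype(float)
    multi_eye = (df.groupby("subject_id").size() > 1).any()
    cov = sm.cov_struct.Exchangeable() if multi_eye else sm.cov_struct.Independence()
    if not multi_eye:
        warnings_out.append("all subjects single-eyed; independence model (OLS with robust SE)")
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        model = sm.GEE(y, X, groups=df["subject_id"].to_numpy(),
                       family=sm.families.Gaussian(), cov_struct=cov)
        fit = model.fit()
    coef = float(fit.params["allele_count"])
    se = float(fit.bse["allele_count"])
    p = float(fit.pvalues["allele_count"])
    covb = np.asarray(fit.cov_params())
    gender_mean = float(df["_gender_ind"].mean())
    adj_means, adj_ses, n_eyes = {}, {}, {}
    cols = list(X.columns)
    for lv in levels:
        L = np.zeros(len(cols))
        L[cols.index("const")] = 1.0
        L[cols.index("allele_count")] = lv
        L[cols.index("_age_c")] = 0.0  # age at sample mean (centered)
        L[cols.index("_gender_ind")] = gender_mean
        adj_means[lv] = float(L @ fit.params.to_numpy())
        adj_ses[lv] = float(np.sqrt(L @ covb @ L))
        n_eyes[lv] = int((df["allele_count"] == lv).sum())
    rho = float(cov.dep_params) if multi_eye else 0.0
    return TrendTestResult(
        snp_id=snp_id,
        p_trend=p,
        coef=coef,
        coef_se=se,
        levels=levels,
        adjusted_means=adj_means,
        adjusted_ses=adj_ses,
        n_eyes=n_eyes,
        exchangeable_corr=rho,
        warnings=warnings_out,
    )


def trend_results_to_csv(results, path) -> None:
    """Table-style CSV: one row per (SNP, allele level) plus the p-trend."""
    rows = []
    for r in results:
        for lv in r.levels:
            rows.append(
                {
                    "snp_id": r.snp_id,
                    "allele_count": lv,
                    "n_eyes": r.n_eyes[lv],
                    "adjusted_mean": r.adjusted_means[lv],
                    "adjusted_se": r.adjusted_ses[lv],
                    "p_trend": r.p_trend,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")
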