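"""Synthetic optic nerve head generator with known ground truth.

Cup and disc boundaries are modelled as star-shaped radial functions in
the clock-angle frame: a rotated ellipse base radius modulated by a
low-order cosine waviness, the cup nested inside the disc with a
controllable base CDR and centroid offset (eccentric cupping), and an
optional *notch* — a localized outward bulge of the cup boundary over a
smooth raised-cosine angular window, mimicking focal rim loss.

Two graders observe each boundary through smooth multiplicative radial
noise (low-order random Fourier series on the circle, so neighbouring
degrees are correlated as in hand tracing) plus an optional systematic
per-grader bias.  Identical seeds give identical outlines.

Ground truth (per-degree half CDR about the true disc centroid, VCDR,
HCDR, area ratio) is evaluated on densely sampled noiseless boundaries
(default 3600 vertices), which approximates the continuous model far
below any tolerance used in testing.

`generate_cohort` builds a whole case/control cohort — subjects with up
to two correlated eyes, clinician VCDR re-reads, ages, genders and SNP
allele counts with an optional additive allele effect on VCDR — and can
emit the same ROI zip + manifest + clinical CSV files the real pipeline
consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import polygon_area, polygon_centroid, half_cut_throughs, close_gaps
from .roi_io import (
    Eye,
    GradedImage,
    Outline,
    Structure,
    write_roi_zip,
)

__all__ = ["NotchSpec", "GraderNoise", "SyntheticEyeSpec", "GroundTruth",
           "generate_eye", "CohortData", "generate_cohort", "simulate_gee_dataset"]

_TRUTH_VERTICES = 3600


@dataclass(frozen=True)
class NotchSpec:
    center_degree: float = 225.0
    width_degree: float = 30.0
    depth: float = 0.2  # fractional outward extension of the cup radius


@dataclass(frozen=True)
class GraderNoise:
    jitter_sd: float = 0.02          # SD of the multiplicative radial error
    corr_length_degree: float = 60.0  # angular scale of the error
    bias: tuple[float, float] = (0.0, 0.0)  # systematic per-grader radius scaling


@dataclass(frozen=True)
class SyntheticEyeSpec:
    """Generative parameters for one synthetic eye."""

    disc_center: tuple[float, float] = (300.0, 300.0)
    disc_axes: tuple[float, float] = (100.0, 90.0)   # semi-axes, px
    disc_rotation: float = 0.0                        # deg, clockwise from 12
    disc_waviness_amp: float = 0.03                   # fraction of radius
    disc_waviness_order: int = 5
    cup_cdr: float = 0.5                              # base cup/disc radial ratio
    cup_offset: tuple[float, float] = (0.0, 0.0)      # px, cup center - disc center
    cup_waviness_amp: float = 0.03
    cup_waviness_order: int = 4
    notch: NotchSpec | None = None
    grader_noise: GraderNoise = field(default_factory=GraderNoise)
    vertex_count: int = 120
    eye: Eye = Eye.OD
    image_id: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.cup_cdr < 1.0):
            raise ValueError("cup_cdr must lie in (0, 1)")
        depth = self.notch.depth if self.notch else 0.0
        # Cup and disc share the ellipse shape, so their radial ratio is
        # cup_cdr before waviness/notch/offset; bound the worst case.
        min_disc = min(self.disc_axes) * (1 - self.disc_waviness_amp)
        worst_ratio = (
            self.cup_cdr * (1 + self.cup_waviness_amp) * (1 + depth)
            / (1 - self.disc_waviness_amp)
            + float(np.hypot(*self.cup_offset)) / min_disc
        )
        if worst_ratio >= 1.0:
            raise ValueError(
                "cup (with offset/waviness/notch) would not nest inside the disc"
            )


def _ellipse_radius(theta_deg: np.ndarray, a: float, b: float, rot_deg: float) -> np.ndarray:
    t = np.radians(theta_deg - rot_deg)
    return a * b / np.sqrt((b * np.cos(t)) ** 2 + (a * np.sin(t)) ** 2)


def _raised_cosine(theta_deg: np.ndarray, center: float, width: float) -> np.ndarray:
    """Smooth bump: 1 at center, 0 outside +/- width/2, circular."""
    d = (theta_deg - center + 180.0) % 360.0 - 180.0
    w = np.zeros_like(theta_deg, dtype=float)
    half = width / 2.0
    inside = np.abs(d) <= half
    w[inside] = 0.5 * (1 + np.cos(np.pi * d[inside] / half))
    return w


def _disc_radius(spec: SyntheticEyeSpec, theta: np.ndarray) -> np.ndarray:
    r = _ellipse_radius(theta, *spec.disc_axes, spec.disc_rotation)
    return r * (1 + spec.disc_waviness_amp * np.cos(np.radians(spec.disc_waviness_order * theta)))


def _cup_radius(spec: SyntheticEyeSpec, theta: np.ndarray) -> np.ndarray:
    r = _ellipse_radius(theta, spec.disc_axes[0] * spec.cup_cdr,
                        spec.disc_axes[1] * spec.cup_cdr, spec.disc_rotation)
    r = r * (1 + spec.cup_waviness_amp * np.cos(np.radians(spec.cup_waviness_order * theta + 40.0)))
    if spec.notch is not None:
        r = r * (1 + spec.notch.depth
                 * _raised_cosine(theta, spec.notch.center_degree, spec.notch.width_degree))
    return r


def _polar_polygon(center: tuple[float, float], radius_fn, n: int,
                   noise: np.ndarray | None = None) -> np.ndarray:
    theta = np.arange(n) * (360.0 / n)
    r = radius_fn(theta)
    if noise is not None:
        r = r * noise
    u = np.column_stack([np.sin(np.radians(theta)), -np.cos(np.radians(theta))])
    return np.asarray(center, dtype=float) + r[:, None] * u


def _fourier_noise(rng: np.random.Generator, n: int, sd: float,
                   corr_length_degree: float) -> np.ndarray:
    """Smooth multiplicative noise 1 + eps(theta) with SD(eps) = sd."""
    if sd == 0:
        return np.ones(n)
    k_max = max(1, int(round(360.0 / corr_length_degree)))
    theta = np.arange(n) * (2 * np.pi / n)
    eps = np.zeros(n)
    scale = sd / np.sqrt(k_max)
    for k in range(1, k_max + 1):
        a, b = rng.normal(0.0, scale, 2)
        eps += a * np.cos(k * theta) + b * np.sin(k * theta)
    return 1.0 + eps


@dataclass
class GroundTruth:
    half_cdr: np.ndarray          # (360,) about the true disc centroid
    vcdr: float
    hcdr: float
    area_ratio: float
    notch_center_degree: float | None
    disc_centroid: tuple[float, float]


def _ground_truth(spec: SyntheticEyeSpec) -> GroundTruth:
    disc = close_gaps(_polar_polygon(spec.disc_center, lambda t: _disc_radius(spec, t),
                                     _TRUTH_VERTICES))
    cup_center = (spec.disc_center[0] + spec.cup_offset[0],
                  spec.disc_center[1] + spec.cup_offset[1])
    cup = close_gaps(_polar_polygon(cup_center, lambda t: _cup_radius(spec, t),
                                    _TRUTH_VERTICES))
    origin = polygon_centroid(disc)
    disc_prof = half_cut_throughs(disc, origin, "disc")
    cup_prof = half_cut_throughs(cup, origin, "cup")
    hc = cup_prof.radii / disc_prof.radii
    full_cup = cup_prof.radii + np.roll(cup_prof.radii, -180)
    full_disc = disc_prof.radii + np.roll(disc_prof.radii, -180)
    full = full_cup / full_disc
    return GroundTruth(
        half_cdr=hc,
        vcdr=float(full[0]),
        hcdr=float(full[90]),
        area_ratio=polygon_area(cup) / polygon_area(disc),
        notch_center_degree=spec.notch.center_degree if spec.notch else None,
        disc_centroid=(origin.x, origin.y),
    )


def generate_eye(spec: SyntheticEyeSpec) -> tuple[GradedImage, GroundTruth]:
    """Generate the two graders' cup/disc outlines plus ground truth."""
    rng = np.random.default_rng(spec.seed)
    truth = _ground_truth(spec)
    cup_center = (spec.disc_center[0] + spec.cup_offset[0],
                  spec.disc_center[1] + spec.cup_offset[1])
    image = GradedImage(image_id=spec.image_id, eye=spec.eye)
    gn = spec.grader_noise
    for gi, grader in enumerate(("g1", "g2")):
        bias = 1.0 + gn.bias[gi]
        for structure, center, rfn in (
            (Structure.DISC, spec.disc_center, lambda t: _disc_radius(spec, t)),
            (Structure.CUP, cup_center, lambda t: _cup_radius(spec, t)),
        ):
            noise = _fourier_noise(rng, spec.vertex_count, gn.jitter_sd,
                                   gn.corr_length_degree) * bias
            verts = _polar_polygon(center, rfn, spec.vertex_count, noise)
            image.add(Outline(image_id=spec.image_id, eye=spec.eye,
                              structure=structure, grader_id=grader, vertices=verts))
    return image, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortData:
    images: list[GradedImage]
    truths: dict[str, GroundTruth]
    clinical: pd.DataFrame       # per-eye table incl. clinical_vcdr, alleles
    notch_labels: dict[str, bool]

    def to_files(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit ROI zip + manifest CSV + clinical CSV (the real input formats)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        entries, manifest_rows = [], []
        for img in self.images:
            for o in img.outlines:
                fname = f"{o.image_id}_{o.eye.value}_{o.structure.value}_{o.grader_id}.roi"
                entries.append((fname, o.vertices))
                manifest_rows.append(
                    {"filename": fname, "image_id": o.image_id, "eye": o.eye.value,
                     "structure": o.structure.value, "grader_id": o.grader_id}
                )
        paths = {
            "roi_zip": out / "outlines.zip",
            "manifest": out / "manifest.csv",
            "clinical": out / "clinical.csv",
        }
        write_roi_zip(entries, paths["roi_zip"])
        pd.DataFrame(manifest_rows).to_csv(paths["manifest"], index=False)
        self.clinical.to_csv(paths["clinical"], index=False, float_format="%.6g")
        return paths


_DEFAULT_SNPS = {"snp_a": 0.41, "snp_b": 0.10, "snp_c": 0.42}


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    x = rng.normal(mean, sd, size)
    return np.clip(x, lo, hi)


def generate_cohort(
    n_eyes: int,
    seed: int = 0,
    *,
    case_fraction: float = 0.6,
    case_cdr: tuple[float, float] = (0.65, 0.12),
    control_cdr: tuple[float, float] = (0.40, 0.10),
    clinical_noise_sd: float = 0.05,
    within_subject_sd: float = 0.03,
    notch_fraction: float = 0.15,
    allele_freqs: dict[str, float] | None = None,
    allele_effects: dict[str, float] | None = None,
    grader_noise: GraderNoise = GraderNoise(),
    vertex_count: int = 120,
) -> CohortData:
    """Simulate a graded case/control cohort with clinical re-reads.

    Subjects contribute up to two eyes whose base CDRs share a subject
    latent value (inter-eye correlation); cases draw higher base CDRs
    than controls.  ``clinical_vcdr`` is the true VCDR plus truncated
    Gaussian reader noise.  Allele counts are binomial(2, freq) per
    subject, with any ``allele_effects`` added to the base CDR before
    generation.  A ``notch_fraction`` of eyes receives a notch at a
    random temporal-ish location and a has_notch label.
    """
    if n_eyes < 1:
        raise ValueError("n_eyes must be >= 1")
    if allele_freqs is None:
        allele_freqs = dict(_DEFAULT_SNPS)
    if allele_effects is None:
        allele_effects = {}
    rng = np.random.default_rng(seed)
    images: list[GradedImage] = []
    truths: dict[str, GroundTruth] = {}
    clin_rows = []
    notch_labels: dict[str, bool] = {}
    eye_i = 0
    subj_i = 0
    while eye_i < n_eyes:
        subj_i += 1
        subject_id = f"S{subj_i:04d}"
        status = "case" if rng.random() < case_fraction else "control"
        mean, sd = case_cdr if status == "case" else control_cdr
        subj_base = _truncated_normal(rng, mean, sd, 0.1, 0.85)
        alleles = {s: int(rng.binomial(2, f)) for s, f in allele_freqs.items()}
        shift = sum(allele_effects.get(s, 0.0) * alleles[s] for s in alleles)
        age = float(np.round(_truncated_normal(rng, 62.0, 10.0, 35.0, 90.0), 1))
        gender = "F" if rng.random() < 0.55 else "M"
        n_sub_eyes = 2 if (rng.random() < 0.8 and eye_i + 1 < n_eyes) else 1
        for k in range(n_sub_eyes):
            eye = Eye.OD if k == 0 else Eye.OS
            base = float(np.clip(subj_base + shift + rng.normal(0, within_subject_sd),
                                 0.08, 0.88))
            has_notch = bool(rng.random() < notch_fraction)
            notch = None
            if has_notch:
                center = float(rng.uniform(180.0, 300.0))
                notch = NotchSpec(center_degree=center, width_degree=40.0,
                                  depth=min(0.18, (0.92 - base) / base * 0.5))
            axes_a = float(rng.uniform(90.0, 110.0))
            axes_b = axes_a * float(rng.uniform(0.85, 1.0))
            # eccentricity bounded both by the rim margin and by the cup
            # radius itself, so the disc centroid stays inside the cup
            max_off = min(axes_b * (1 - base) * 0.3, 0.5 * base * axes_b)
            off_ang = rng.uniform(0, 2 * np.pi)
            off_mag = rng.uniform(0, max_off)
            image_id = f"I{eye_i:04d}"
            spec = SyntheticEyeSpec(
                disc_center=(300.0, 300.0),
                disc_axes=(axes_a, axes_b),
                disc_rotation=float(rng.uniform(0, 180)),
                cup_cdr=base,
                cup_offset=(off_mag * np.cos(off_ang), off_mag * np.sin(off_ang)),
                notch=notch,
                grader_noise=grader_noise,
                vertex_count=vertex_count,
                eye=eye,
                image_id=image_id,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            img, truth = generate_eye(spec)
            images.append(img)
            truths[image_id] = truth
            notch_labels[image_id] = has_notch
            clin_rows.append(
                {
                    "subject_id": subject_id,
                    "image_id": image_id,
                    "eye": eye.value,
                    "clinical_vcdr": float(
                        _truncated_normal(rng, truth.vcdr, clinical_noise_sd, 0.0, 1.0)
                    ),
                    "age": age,
                    "gender": gender,
                    "status": status,
                    "has_notch": has_notch,
                    **{s: alleles[s] for s in alleles},
                }
            )
            eye_i += 1
            if eye_i >= n_eyes:
                break
    return CohortData(
        images=images,
        truths=truths,
        clinical=pd.DataFrame(clin_rows),
        notch_labels=notch_labels,
    )


def simulate_gee_dataset(
    n_subjects: int,
    seed: int,
    *,
    allele_freq: float = 0.3,
    allele_effect: float = 0.0,
    intercept: float = 0.5,
    age_effect: float = 0.002,
    gender_effect: float = 0.02,
    subject_sd: float = 0.07,
    eye_sd: float = 0.07,
    two_eye_fraction: float = 1.0,
) -> pd.DataFrame:
    """Per-eye outcome table from a shared-subject-effect linear model.

    With equal subject and eye SDs the implied within-subject (inter-
    eye) outcome correlation is subject_sd^2/(subject_sd^2 + eye_sd^2)
    = 0.5.  Used for Monte-Carlo calibration of the trend test without
    running the geometry pipeline.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        allele = int(rng.binomial(2, allele_freq))
        age = float(rng.normal(62, 10))
        gender = "F" if rng.random() < 0.5 else "M"
        u = rng.normal(0, subject_sd)
        n_eyes = 2 if rng.random() < two_eye_fraction else 1
        for k in range(n_eyes):
            mu = (intercept + allele_effect * allele + age_effect * (age - 62)
                  + gender_effect * (gender == "F") + u)
            rows.append(
                {
                    "subject_id": f"S{i:04d}",
                    "eye": "OD" if k == 0 else "OS",
                    "outcome": mu + rng.normal(0, eye_sd),
                    "allele_count": allele,
                    "age": age,
                    "gender": gender,
                }
            )
    return pd.DataFrame(rows)
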