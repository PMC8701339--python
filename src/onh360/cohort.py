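"""Cohort-level structure: VCDR decile bins, per-degree summaries, notches.

Images are binned by their vertical CDR in 0.1 increments: bin k covers
[(k-1)/10, k/10), with bin 10 closed above so a VCDR of exactly 1.0 is
representable.  Per bin (optionally split by case/control status) the
per-degree mean and sample SD of the half and full cut-through CDRs are
summarized, together with the mean cup/disc boundary radii used to
reconstruct averaged polar plots.

Notch analysis: the degree of the maximum half CDR is located for each
eye and the CDR examined over the 50 degrees surrounding it (25 either
side, circular).  Eyes with a clinically identified notch show a
steeper drop away from the peak than eyes without.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .profiles import CdrProfile, invert_os
from .roi_io import Eye

__all__ = [
    "NOTCH_HALF_WINDOW",
    "BinSummary",
    "NotchProfile",
    "assign_bin",
    "bin_summaries",
    "notch_window",
    "notch_contrast",
    "bin_summaries_to_csv",
    "notch_report_to_csv",
]

NOTCH_HALF_WINDOW = 25  # degrees either side of the peak


def assign_bin(vcdr: float) -> int:
    """Decile bin of a vertical CDR: k with (k-1)/10 <= vcdr < k/10.

    vcdr = 1.0 maps to bin 10 (right-closed top bin).  Values outside
    [0, 1] raise; upstream flags exclude such profiles with a warning.
    """
    if not np.isfinite(vcdr) or not (0.0 <= vcdr <= 1.0):
        raise ValueError(f"vcdr {vcdr!r} outside [0, 1]")
    return min(int(np.floor(vcdr * 10.0)) + 1, 10)


@dataclass
class BinSummary:
    bin_index: int                  # 1..10
    status: str | None              # case/control/... or None when ungrouped
    n_images: int
    mean_half_cdr: np.ndarray       # (360,)
    sd_half_cdr: np.ndarray
    mean_full_cdr: np.ndarray
    sd_full_cdr: np.ndarray
    mean_cup_radii: np.ndarray      # px, for polar-plot reconstruction
    mean_disc_radii: np.ndarray


def _nan360() -> np.ndarray:
    return np.full(360, np.nan)


def bin_summaries(
    profiles: Sequence[CdrProfile],
    *,
    statuses: Sequence[str] | None = None,
    group_by_status: bool = False,
    os_policy: str = "invert",
) -> list[BinSummary]:
    """Per-degree mean/SD summaries per VCDR bin (and optionally status).

    Profiles must already be resolved (adjudication applied).  With
    ``os_policy='invert'`` every OS profile is mirrored into the OD
    nasal/temporal frame before pooling; ``'asis'`` pools raw profiles.
    SD uses the n-1 denominator.  Empty bins yield n=0 summaries with
    undefined (NaN) moments rather than an exception.
    """
    if os_policy not in ("invert", "asis"):
        raise ValueError(f"unknown os_policy {os_policy!r}")
    if statuses is not None and len(statuses) != len(profiles):
        raise ValueError("statuses must align with profiles")
    if group_by_status and statuses is None:
        raise ValueError("group_by_status requires statuses")

    prepped: list[tuple[int, str | None, CdrProfile]] = []
    for i, p in enumerate(profiles):
        if os_policy == "invert" and p.eye is Eye.OS and not p.inverted:
            p = invert_os(p)
        b = assign_bin(p.vcdr)
        st = statuses[i] if group_by_status else None
        prepped.append((b, st, p))

    status_levels: list[str | None]
    if group_by_status:
        status_levels = sorted({st for _, st, _ in prepped})  # type: ignore[arg-type]
    else:
        status_levels = [None]

    out: list[BinSummary] = []
    for b in range(1, 11):
        for st in status_levels:
            members = [p for bb, ss, p in prepped if bb == b and ss == st]
            n = len(members)
            if n == 0:
                out.append(
                    BinSummary(b, st, 0, _nan360(), _nan360(), _nan360(), _nan360(),
                               _nan360(), _nan360())
                )
                continue
            half = np.stack([p.half_cdr for p in members])
            full = np.stack([p.full_cdr for p in members])
            cupr = np.stack([p.half_cut_cup for p in members])
            discr = np.stack([p.half_cut_disc for p in members])
            sd_kw = {"axis": 0, "ddof": 1} if n > 1 else {"axis": 0, "ddof": 0}
            out.append(
                BinSummary(
                    bin_index=b,
                    status=st,
                    n_images=n,
                    mean_half_cdr=half.mean(axis=0),
                    sd_half_cdr=half.std(**sd_kw) if n > 1 else np.zeros(360),
                    mean_full_cdr=full.mean(axis=0),
                    sd_full_cdr=full.std(**sd_kw) if n > 1 else np.zeros(360),
                    mean_cup_radii=cupr.mean(axis=0),
                    mean_disc_radii=discr.mean(axis=0),
                )
            )
    return out


@dataclass
class NotchProfile:
    image_id: str
    has_notch: bool
    peak_degree: int
    offsets: np.ndarray        # -25..+25
    window_half_cdr: np.ndarray  # (51,) half CDR re-indexed by offset

    @property
    def drop_statistic(self) -> float:
        """Peak CDR minus the mean CDR at the window edges (+/-25 deg)."""
        center = self.window_half_cdr[len(self.offsets) // 2]
        edges = (self.window_half_cdr[0] + self.window_half_cdr[-1]) / 2.0
        return float(center - edges)


def notch_window(
    profile: CdrProfile,
    has_notch: bool,
    *,
    half_window: int = NOTCH_HALF_WINDOW,
    on: str = "half_cdr",
) -> NotchProfile:
    """Locate the peak half CDR and extract the surrounding window.

    ``on='half_cdr'`` peaks on the per-degree cup/disc ratio (the CDR
    examined around the peak); ``on='cup_radius'`` peaks on the raw cup
    half cut-through instead.  Argmax ties break to the smallest
    degree; the window wraps circularly at 0/359.
    """
    if on == "half_cdr":
        signal = profile.half_cdr
    elif on == "cup_radius":
        signal = profile.half_cut_cup
    else:
        raise ValueError(f"unknown peak signal {on!r}")
    peak = int(np.argmax(signal))
    offsets = np.arange(-half_window, half_window + 1)
    window = profile.half_cdr[(peak + offsets) % 360]
    return NotchProfile(
        image_id=profile.image_id,
        has_notch=bool(has_notch),
        peak_degree=peak,
        offsets=offsets,
        window_half_cdr=window,
    )


def notch_contrast(
    notched: Sequence[NotchProfile],
    plain: Sequence[NotchProfile],
) -> pd.DataFrame:
    """Per-offset mean window curves and drop statistics for both groups.

    Returns a tidy frame with columns group, offset, mean_half_cdr plus
    a ``drop_statistic`` attribute per group in ``DataFrame.attrs``.
    """
    frames = []
    drops = {}
    for name, group in (("notched", notched), ("plain", plain)):
        if len(group) == 0:
            continue
        curves = np.stack([n.window_half_cdr for n in group])
        offsets = group[0].offsets
        frames.append(
            pd.DataFrame(
                {"group": name, "offset": offsets, "mean_half_cdr": curves.mean(axis=0)}
            )
        )
        drops[name] = float(np.mean([n.drop_statistic for n in group]))
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["group", "offset", "mean_half_cdr"]
    )
    df.attrs["drop_statistic"] = drops
    return df


def bin_summaries_to_csv(summaries: Sequence[BinSummary], path: str | Path) -> Path:
    frames = []
    for s in summaries:
        if s.n_images == 0:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "bin": s.bin_index,
                    "status": s.status if s.status is not None else "all",
                    "degree": np.arange(360),
                    "n": s.n_images,
                    "mean_half_cdr": s.mean_half_cdr,
                    "sd_half_cdr": s.sd_half_cdr,
                    "mean_full_cdr": s.mean_full_cdr,
                    "sd_full_cdr": s.sd_full_cdr,
                    "mean_cup_radius": s.mean_cup_radii,
                    "mean_disc_radius": s.mean_disc_radii,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    df.to_csv(path, index=False, float_format="%.6g")
    return Path(path)


def notch_report_to_csv(notches: Sequence[NotchProfile], path: str | Path) -> Path:
    rows = [
        {
            "image_id": n.image_id,
            "has_notch": n.has_notch,
            "peak_degree": n.peak_degree,
            "drop_statistic": n.drop_statistic,
        }
        for n in notches
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")
    return Path(path)
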