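"""Cortical-depth profiles, CBVvO2 normalization and participant-wise depth slopes.

A DepthProfile holds one quantity per subject per depth bin (deep to
superficial: L1..L6 plus the pial-vein bin). Group summaries follow the
missing-value convention of the analysis: mean +- SD when complete, median
with a 95% CI when any subject is missing, and missing entries are flagged,
never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fir import laminar_average
from .synth import DEPTH_BINS, DepthProbabilityMap

__all__ = ["DepthProfile", "build_profile", "normalize_by_cbvvo2", "DepthSlopeModel", "SlopeFit"]


@dataclass
class DepthProfile:
    """Per-subject depth profile of one quantity.

    ``values`` is (n_subjects, n_bins) with NaN marking missing cells.
    """

    quantity: str
    values: np.ndarray
    units: str = ""
    bins: tuple[str, ...] = DEPTH_BINS

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.bins):
            raise ValueError(f"values must have {len(self.bins)} columns")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    @property
    def complete(self) -> bool:
        return not self.missing.any()

    def group_center(self) -> np.ndarray:
        """Per-bin group mean, or median when any value is missing."""
        if self.complete:
            return self.values.mean(axis=0)
        return np.nanmedian(self.values, axis=0)

    def group_dispersion(self) -> np.ndarray:
        """Per-bin SD when complete, else a bootstrap-free 95% CI half-width
        from the normal approximation to the median."""
        if self.complete:
            return self.values.std(axis=0, ddof=1)
        out = np.full(len(self.bins), np.nan)
        for b in range(len(self.bins)):
            col = self.values[:, b]
            col = col[np.isfinite(col)]
            if len(col) >= 2:
                out[b] = 1.2533 * 1.96 * col.std(ddof=1) / np.sqrt(len(col))
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.bins))
        df.insert(0, "subject", np.arange(1, self.n_subjects + 1))
        df.insert(1, "quantity", self.quantity)
        return df

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": list(self.bins),
                "center": self.group_center(),
                "dispersion": self.group_dispersion(),
                "n_missing": self.missing.sum(axis=0),
            }
        )


def build_profile(
    voxel_values: np.ndarray,
    depth_probs: DepthProbabilityMap,
    selection: np.ndarray | None = None,
    quantity: str = "",
    units: str = "",
) -> DepthProfile:
    """Single-subject profile of a per-voxel map quantity (probability-weighted mean).

    HRF descriptors do not pass through here: they are quantified from the
    bin-level averaged curves (average the voxel HRFs per bin, then fit and
    quantify), matching the aggregation order of the laminar analysis.
    """
    if selection is not None and not np.any(selection):
        raise ValueError("empty voxel selection: every bin would be undefined")
    per_bin, _ = laminar_average(voxel_values, depth_probs, selection)
    return DepthProfile(quantity=quantity, values=per_bin[None, :], units=units)


def normalize_by_cbvvo2(amp_profile: DepthProfile, cbvvo2_profile: DepthProfile) -> DepthProfile:
    """Divide HRF amplitudes by the CBVvO2 profile, subject-wise and bin-wise.

    The ratio removes the venous blood-volume weighting from the amplitude
    profile (a.u. output). Cells where either input is missing or CBVvO2 is
    non-positive become missing.
    """
    a, c = amp_profile.values, cbvvo2_profile.values
    if a.shape != c.shape:
        raise ValueError("profiles must share subjects and bins")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(np.isfinite(a) & np.isfinite(c) & (c > 0), a / c, np.nan)
    if not np.isfinite(out).any():
        raise ValueError("normalization produced no defined cells (CBVvO2 <= 0 everywhere?)")
    return DepthProfile(
        quantity=f"{amp_profile.quantity}_over_cbvvo2",
        values=out,
        units="a.u.",
        bins=amp_profile.bins,
    )


@dataclass
class SlopeFit:
    """Participant-wise depth-slope estimates and the group-level test."""

    slopes: np.ndarray          # per-subject slope, NaN where undefined
    mean_slope: float
    ci95: tuple[float, float]
    tstat: float
    pvalue: float
    n_subjects: int
    quantity: str = ""

    def summary(self) -> str:
        lo, hi = self.ci95
        return (
            f"Depth slope [{self.quantity}]: mean {self.mean_slope:.4g} per lamina "
            f"(95% CI {lo:.4g} to {hi:.4g}), t({self.n_subjects - 1}) = {self.tstat:.3g}, "
            f"p = {self.pvalue:.3g}, n = {self.n_subjects}"
        )


class DepthSlopeModel:
    """Per-subject OLS slope of a depth profile against bin index 1..7.

    Subjects need >= 3 defined bins to contribute; the group inference is a
    one-sample t-test of the subject slopes against zero. The pial-vein bin is
    included by default (``include_vein=False`` drops it).
    """

    def __init__(self, profile: DepthProfile, include_vein: bool = True):
        self.profile = profile
        self.include_vein = include_vein

    def fit(self) -> SlopeFit:
        vals = self.profile.values
        bins = np.arange(1, vals.shape[1] + 1, dtype=float)
        if not self.include_vein:
            keep = [i for i, b in enumerate(self.profile.bins) if b != "pial_vein"]
            vals = vals[:, keep]
            bins = bins[keep]
        slopes = np.full(vals.shape[0], np.nan)
        for s in range(vals.shape[0]):
            ok = np.isfinite(vals[s])
            if ok.sum() >= 3:
                slopes[s] = np.polyfit(bins[ok], vals[s, ok], 1)[0]
        valid = slopes[np.isfinite(slopes)]
        if len(valid) < 3:
            return SlopeFit(slopes, np.nan, (np.nan, np.nan), np.nan, np.nan, len(valid), self.profile.quantity)
        mean = float(valid.mean())
        if np.ptp(valid) == 0:
            # identical slopes: degenerate SE, CI collapses to the point
            return SlopeFit(slopes, mean, (mean, mean), np.inf if mean != 0 else 0.0,
                            0.0 if mean != 0 else 1.0, len(valid), self.profile.quantity)
        se = valid.std(ddof=1) / np.sqrt(len(valid))
        tcrit = stats.t.ppf(0.975, len(valid) - 1)
        res = stats.ttest_1samp(valid, 0.0)
        return SlopeFit(
            slopes=slopes,
            mean_slope=mean,
            ci95=(mean - tcrit * se, mean + tcrit * se),
            tstat=float(res.statistic),
            pvalue=float(res.pvalue),
            n_subjects=len(valid),
            quantity=self.profile.quantity,
        )
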