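"""FIR deconvolution of condition-specific HRFs and laminar aggregation.

The FIR model assigns one free coefficient to each post-stimulus lag on the TR
grid (24 lags for a 20 s window at TR 0.85 s) separately for each gas
condition, so overlapping responses are resolved by linear superposition
without any shape assumption. Lag coefficients are scaled to %BOLD with the
localizer-GLM baseline so amplitudes share one scale across stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import FIRDesign
from .synth import DEPTH_BINS, DepthProbabilityMap

__all__ = ["FIRModel", "FIRResults", "laminar_average"]


@dataclass
class FIRResults:
    """Per-voxel deconvolved HRFs: ``hrf[condition]`` is (n_voxels, n_lags) in %BOLD."""

    hrf: dict[str, np.ndarray]
    lag_times: np.ndarray
    conditions: list[str]
    baseline: np.ndarray
    resid_var: np.ndarray
    df_resid: int

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: voxel, condition, lag_s, value_pct."""
        rows = []
        for cond in self.conditions:
            H = self.hrf[cond]
            for v in range(H.shape[0]):
                for ell, lag in enumerate(self.lag_times):
                    rows.append((v, cond, lag, H[v, ell]))
        return pd.DataFrame(rows, columns=["voxel", "condition", "lag_s", "value_pct"])


class FIRModel:
    """Finite-impulse-response model of cleaned BOLD against a lagged-event design.

    Fit jointly with the design's confound columns (high-pass cosines, gas
    traces, nuisance), which equals residualizing both sides against them.

    Parameters
    ----------
    bold
        (n_voxels, n_volumes) raw or cleaned time series.
    design
        A :class:`~laminarhrf.design.FIRDesign`.
    baseline
        Per-voxel baseline signal for %BOLD scaling (the localizer-GLM
        constant beta); pass 100.0 * ones to keep raw units.
    """

    def __init__(self, bold: np.ndarray, design: FIRDesign, baseline: np.ndarray):
        bold = np.atleast_2d(np.asarray(bold, dtype=float))
        if bold.shape[1] != design.interest.shape[0]:
            raise ValueError("bold and design disagree on the number of volumes")
        baseline = np.broadcast_to(np.asarray(baseline, dtype=float), (bold.shape[0],))
        if np.any(baseline <= 0):
            raise ValueError("baseline must be positive for %BOLD scaling")
        self.bold = bold
        self.design = design
        self.baseline = baseline

    def fit(self) -> FIRResults:
        X = self.design.matrix
        n, p = X.shape
        if np.linalg.matrix_rank(X) < p:
            raise ValueError(
                "FIR design is rank deficient (degenerate event schedule); re-seed the schedule"
            )
        Y = self.bold.T
        beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
        df = n - p
        sigma2 = (resid**2).sum(axis=0) / max(df, 1)
        L = self.design.n_lags
        hrf = {}
        for cond in self.design.conditions:
            block = beta[self.design.lag_block(cond)]  # (L, V)
            hrf[cond] = 100.0 * block.T / self.baseline[:, None]
        return FIRResults(
            hrf=hrf,
            lag_times=self.design.lag_times,
            conditions=list(self.design.conditions),
            baseline=self.baseline,
            resid_var=sigma2,
            df_resid=df,
        )


def laminar_average(
    values: np.ndarray,
    depth_probs: DepthProbabilityMap,
    selection: np.ndarray | None = None,
    exclude_veins_from_laminae: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Probability-weighted laminar average of a per-voxel quantity.

    ``values`` is (n_voxels,) or (n_voxels, k) (e.g. FIR curves); the bin
    value is sum_v p_vb * y_v / sum_v p_vb over selected voxels. Voxels in the
    vein mask are excluded from the six laminae bins and pooled into the
    pial-vein bin (and vice versa) when ``exclude_veins_from_laminae``.

    Returns ``(per_bin, weights)`` where ``per_bin`` is (7,) or (7, k) with
    NaN for bins of zero total weight, and ``weights`` the per-bin weight sums.
    """
    P = depth_probs.probs
    y = np.asarray(values, dtype=float)
    squeeze = y.ndim == 1
    Y = y[:, None] if squeeze else y
    if Y.shape[0] != P.shape[0]:
        raise ValueError("values and depth probabilities disagree on voxel count")
    sel = np.ones(P.shape[0], bool) if selection is None else np.asarray(selection, bool)
    vein = depth_probs.vein_mask
    nb = P.shape[1]
    vein_col = depth_probs.bins.index("pial_vein")
    out = np.full((nb, Y.shape[1]), np.nan)
    wsum = np.zeros(nb)
    for b in range(nb):
        use = sel.copy()
        if exclude_veins_from_laminae:
            use &= vein if b == vein_col else ~vein
        w = P[use, b]
        total = w.sum()
        wsum[b] = total
        if total > 0:
            ok = np.isfinite(Y[use]).all(axis=1)
            if ok.any():
                ww = w[ok]
                if ww.sum() > 0:
                    out[b] = ww @ Y[use][ok] / ww.sum()
                    wsum[b] = ww.sum()
    return (out[:, 0] if squeeze else out), wsum
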