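"""Localizer GLM: OLS fit, t-statistics, FDR voxel selection and reactivity maps.

CVR and CBVvO2 are the regression coefficients of %BOLD change on the
end-tidal CO2 and O2 traces in Delta-mmHg. The %BOLD scaling uses the
constant-column beta as the voxel baseline, which with baseline-referenced
(room-air-zero) gas regressors is the drift-free resting signal estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import DesignMatrix

__all__ = [
    "LocalizerGLM",
    "GLMResults",
    "ReactivityMap",
    "compute_reactivity",
    "fdr_bh",
    "select_voxels",
]


@dataclass
class GLMResults:
    """OLS estimates for every voxel: betas, standard errors, t-values."""

    params: np.ndarray    # (n_regressors, n_voxels)
    bse: np.ndarray
    tvalues: np.ndarray
    df_resid: int
    resid_var: np.ndarray  # (n_voxels,)
    names: list[str]
    model: "LocalizerGLM | None" = None

    def beta(self, name: str) -> np.ndarray:
        return self.params[self.names.index(name)]

    def tstat(self, name: str) -> np.ndarray:
        return self.tvalues[self.names.index(name)]

    def pvalues(self, name: str, alternative: str = "two-sided") -> np.ndarray:
        t = self.tstat(name)
        sf = stats.t.sf(t, self.df_resid)
        if alternative == "two-sided":
            return 2.0 * stats.t.sf(np.abs(t), self.df_resid)
        if alternative == "greater":
            return sf
        if alternative == "less":
            return 1.0 - sf
        raise ValueError(f"unknown alternative {alternative!r}")

    def summary(self) -> pd.DataFrame:
        """Per-regressor summary of voxel-wise estimates."""
        return pd.DataFrame(
            {
                "mean_beta": self.params.mean(axis=1),
                "mean_t": self.tvalues.mean(axis=1),
                "frac_t_gt_1": (self.tvalues > 1).mean(axis=1),
            },
            index=self.names,
        )


class LocalizerGLM:
    """Voxel-wise ordinary-least-squares model of a run against a named design.

    Parameters
    ----------
    bold
        (n_voxels, n_volumes) time series; data and design are assumed
        detrended identically (the design carries its own drift columns).
    design
        A :class:`~laminarhrf.design.DesignMatrix`.
    """

    def __init__(self, bold: np.ndarray, design: DesignMatrix):
        bold = np.atleast_2d(np.asarray(bold, dtype=float))
        X = design.matrix
        if bold.shape[1] != X.shape[0]:
            raise ValueError("bold and design disagree on the number of volumes")
        self.bold = bold
        self.design = design

    def fit(self) -> GLMResults:
        X = self.design.matrix
        Y = self.bold.T  # (n, V)
        n, p = X.shape
        XtX = X.T @ X
        XtX_inv = np.linalg.pinv(XtX)  # tolerates all-zero columns
        beta = XtX_inv @ X.T @ Y
        resid = Y - X @ beta
        df = n - p
        if df <= 0:
            raise ValueError("no residual degrees of freedom")
        sigma2 = (resid**2).sum(axis=0) / df
        se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        return GLMResults(
            params=beta,
            bse=se,
            tvalues=t,
            df_resid=df,
            resid_var=sigma2,
            names=self.design.names,
            model=self,
        )


@dataclass
class ReactivityMap:
    """Voxel-wise CVR and CBVvO2 (%BOLD per mmHg) with validity and selection masks."""

    cvr: np.ndarray
    cbvvo2: np.ndarray
    baseline: np.ndarray
    valid: np.ndarray
    selection: np.ndarray | None = None


def compute_reactivity(
    results: GLMResults,
    co2_name: str = "dpetco2",
    o2_name: str = "dpeto2",
    baseline_name: str = "constant",
) -> ReactivityMap:
    """CVR = 100 * beta_CO2 / baseline and CBVvO2 = 100 * beta_O2 / baseline.

    Voxels with non-positive baseline estimate are flagged invalid (NaN).
    """
    baseline = results.beta(baseline_name)
    valid = baseline > 0
    cvr = np.full_like(baseline, np.nan)
    cbv = np.full_like(baseline, np.nan)
    cvr[valid] = 100.0 * results.beta(co2_name)[valid] / baseline[valid]
    cbv[valid] = 100.0 * results.beta(o2_name)[valid] / baseline[valid]
    return ReactivityMap(cvr=cvr, cbvvo2=cbv, baseline=baseline, valid=valid)


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def select_voxels(
    t_co2: np.ndarray,
    t_o2: np.ndarray,
    t_visual: np.ndarray,
    df: int,
    q: float = 0.05,
    t_thresh: float = 1.0,
    mode: str = "intersect-visual",
) -> np.ndarray:
    """Voxel selection combining FDR-corrected gas responses and a loose visual cut.

    Gas t-maps are converted to two-sided p-values and BH-corrected at ``q``;
    the visual map is thresholded one-sided at ``t_thresh`` (no correction).
    ``intersect-visual`` (default) keeps voxels FDR-significant for CO2 or O2
    AND visually responsive — the commonly-responsive reading; ``union-all``
    takes the union of all three maps.
    """
    p_co2 = 2.0 * stats.t.sf(np.abs(t_co2), df)
    p_o2 = 2.0 * stats.t.sf(np.abs(t_o2), df)
    gas = fdr_bh(p_co2, q) | fdr_bh(p_o2, q)
    vis = np.asarray(t_visual) > t_thresh
    if mode == "intersect-visual":
        return gas & vis
    if mode == "union-all":
        return gas | vis
    raise ValueError(f"unknown selection mode {mode!r}")
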