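"""Design-matrix construction: drift bases, canonical HRF, localizer and FIR designs.

Two discrete-cosine cutoffs matter downstream: the localizer GLM detrends with a
7e-4 Hz set (which for a 697 s run contributes zero cosines beyond the constant)
and the FIR stage high-passes at 0.01 Hz (13 cosines for 697 s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "dct_basis",
    "double_gamma",
    "canonical_hrf",
    "DesignMatrix",
    "FIRDesign",
    "build_localizer_design",
    "build_fir_design",
    "highpass_remove_gas",
]


def dct_basis(n_volumes: int, tr: float, cutoff: float) -> np.ndarray:
    """Discrete cosine drift regressors with frequencies below ``cutoff`` (Hz).

    Returns the K = floor(2 * T * cutoff) unit-norm DCT-II cosines with
    frequency k / (2T) < cutoff, T = n_volumes * tr; the constant term is
    handled separately by callers. ``cutoff = 0`` returns an empty basis.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    if n_volumes < 1 or tr <= 0:
        raise ValueError("need n_volumes >= 1 and tr > 0")
    T = n_volumes * tr
    K = int(math.floor(2.0 * T * cutoff))
    K = min(K, n_volumes - 1)
    i = np.arange(n_volumes)
    cols = [np.cos(np.pi * k * (2 * i + 1) / (2 * n_volumes)) for k in range(1, K + 1)]
    if not cols:
        return np.empty((n_volumes, 0))
    X = np.column_stack(cols)
    return X / np.linalg.norm(X, axis=0)


def double_gamma(
    t: np.ndarray,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    dispersion: float = 1.0,
    u_dispersion: float = 1.0,
    ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Field-standard double-gamma impulse response, zero for t < 0, unit dense peak.

    The positive lobe is a gamma density with shape ``peak_delay`` and the
    undershoot a gamma with shape ``undershoot_delay``, subtracted at ``ratio``.
    With defaults the peak sits near 5 s.
    """
    from scipy.stats import gamma as gamma_dist

    t = np.asarray(t, dtype=float)
    h = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    h[pos] = gamma_dist.pdf(tp, peak_delay / dispersion, scale=dispersion) - ratio * gamma_dist.pdf(
        tp, undershoot_delay / u_dispersion, scale=u_dispersion
    )
    # normalize by the dense-grid maximum so the analytic shape has unit peak
    tt = np.arange(0.0, 50.0, 0.001)
    hh = gamma_dist.pdf(tt, peak_delay / dispersion, scale=dispersion) - ratio * gamma_dist.pdf(
        tt, undershoot_delay / u_dispersion, scale=u_dispersion
    )
    return h / hh.max()


def canonical_hrf(tr: float, duration: float = 32.0, **shape) -> np.ndarray:
    """Canonical double-gamma kernel sampled at TR, normalized to unit sampled peak."""
    if tr <= 0 or duration <= 0:
        raise ValueError("tr and duration must be > 0")
    t = np.arange(0.0, duration, tr)
    h = double_gamma(t, **shape)
    m = np.abs(h).max()
    if m == 0:
        return h
    return h / h.max()


@dataclass
class DesignMatrix:
    """Named regressor matrix for the localizer GLM."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        X = self.frame.to_numpy(dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("design contains non-finite values")
        # all-zero columns (e.g. the visual regressor of an empty schedule)
        # carry no information but are not an error; rank is checked on the rest
        nonzero = X.any(axis=0)
        if np.linalg.matrix_rank(X[:, nonzero]) < int(nonzero.sum()):
            raise ValueError("design matrix is rank deficient")

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def names(self) -> list[str]:
        return list(self.frame.columns)


def _detrend_columns(cols: np.ndarray, drift: np.ndarray) -> np.ndarray:
    """Residualize columns against [constant + drift] (same DCT set as the data)."""
    n = cols.shape[0]
    Z = np.column_stack([np.ones(n), drift]) if drift.size else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(Z, cols, rcond=None)
    return cols - Z @ beta


def event_regressor(onsets: np.ndarray, n_volumes: int, tr: float, kernel: np.ndarray) -> np.ndarray:
    """Convolve a TR-grid impulse train (onsets rounded to the grid) with ``kernel``."""
    train = np.zeros(n_volumes)
    idx = np.round(np.asarray(onsets, dtype=float) / tr).astype(int)
    if np.any(idx < 0) or np.any(idx >= n_volumes):
        raise ValueError("event onset outside the run")
    np.add.at(train, idx, 1.0)
    return np.convolve(train, kernel)[:n_volumes]


def build_localizer_design(
    trace,
    schedule,
    nuisance=None,
    *,
    tr: float,
    n_volumes: int,
    dct_cutoff: float = 7e-4,
    hrf_kernel: np.ndarray | None = None,
) -> DesignMatrix:
    """Assemble the localizer GLM design.

    Regressors of interest are the end-tidal traces in Delta-mmHg relative to
    baseline (unconvolved, not de-meaned, so the constant column keeps its
    room-air-baseline interpretation) and the visual event train convolved with
    the canonical HRF. Drift cosines below ``dct_cutoff`` plus motion/RVT/BPM
    nuisance series (detrended with the same cosine set, unconvolved) complete
    the design.

    ``trace`` needs ``dpetco2``/``dpeto2`` arrays on the TR grid, ``schedule``
    an ``onsets`` array (s), ``nuisance`` optionally ``motion`` (n x 6),
    ``rvt`` and ``bpm``.
    """
    dpetco2 = np.asarray(trace.dpetco2, dtype=float)
    dpeto2 = np.asarray(trace.dpeto2, dtype=float)
    if len(dpetco2) != n_volumes or len(dpeto2) != n_volumes:
        raise ValueError("trace length does not match n_volumes")
    if hrf_kernel is None:
        hrf_kernel = canonical_hrf(tr)
    visual = event_regressor(schedule.onsets, n_volumes, tr, hrf_kernel) if len(schedule.onsets) else np.zeros(n_volumes)

    drift = dct_basis(n_volumes, tr, dct_cutoff)
    cols: dict[str, np.ndarray] = {
        "constant": np.ones(n_volumes),
        "dpetco2": dpetco2,
        "dpeto2": dpeto2,
        "visual": visual,
    }
    for k in range(drift.shape[1]):
        cols[f"drift_{k + 1}"] = drift[:, k]
    if nuisance is not None:
        raw = [np.asarray(nuisance.motion, dtype=float)[:, j] for j in range(6)]
        raw += [np.asarray(nuisance.rvt, dtype=float), np.asarray(nuisance.bpm, dtype=float)]
        names = [f"motion_{j + 1}" for j in range(6)] + ["rvt", "bpm"]
        stacked = _detrend_columns(np.column_stack(raw), drift)
        for name, col in zip(names, stacked.T):
            if np.std(col) > 0:  # drop constant nuisance (e.g. amplitude-0 series)
                cols[name] = col
    return DesignMatrix(pd.DataFrame(cols))


@dataclass
class FIRDesign:
    """FIR design: per-condition lag indicator blocks plus confound columns.

    ``interest`` holds the lag columns (n_volumes x n_conditions*L), ``confounds``
    the high-pass cosines, constant, gas traces, and high-passed nuisance
    series. Fitting the two jointly is the Frisch-Waugh equivalent of
    residualizing data and lag columns against the confounds.
    """

    interest: np.ndarray
    confounds: np.ndarray
    conditions: list[str]
    n_lags: int
    tr: float
    confound_names: list[str] = field(default_factory=list)

    @property
    def lag_times(self) -> np.ndarray:
        return np.arange(self.n_lags) * self.tr

    @property
    def matrix(self) -> np.ndarray:
        return np.hstack([self.interest, self.confounds])

    def lag_block(self, condition: str) -> slice:
        j = self.conditions.index(condition)
        return slice(j * self.n_lags, (j + 1) * self.n_lags)


def build_fir_design(
    schedule,
    trace=None,
    nuisance=None,
    *,
    tr: float,
    n_volumes: int,
    window: float = 20.0,
    hp_cutoff: float = 0.01,
    conditions: list[str] | None = None,
) -> FIRDesign:
    """Build the condition-specific FIR design with L = ceil(window / tr) lags.

    Each event contributes indicator columns only to its own gas condition
    (taken from ``schedule.conditions``, i.e. the block containing its onset).
    Confounds are the 0.01 Hz cosine set, the constant, the end-tidal traces
    (when given) and high-passed nuisance series.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    L = int(math.ceil(window / tr))
    onsets = np.asarray(schedule.onsets, dtype=float)
    labels = np.asarray(schedule.conditions)
    if conditions is None:
        seen = []
        for lab in labels:
            if lab not in seen:
                seen.append(lab)
        conditions = seen
    unknown = set(labels) - set(conditions)
    if unknown:
        raise ValueError(f"events carry labels outside the condition set: {sorted(unknown)}")

    interest = np.zeros((n_volumes, len(conditions) * L))
    for onset, lab in zip(onsets, labels):
        j0 = int(round(onset / tr))
        if j0 < 0 or j0 >= n_volumes:
            raise ValueError("event onset outside the run")
        c = conditions.index(lab)
        for lag in range(L):
            if j0 + lag < n_volumes:
                interest[j0 + lag, c * L + lag] += 1.0

    drift = dct_basis(n_volumes, tr, hp_cutoff)
    conf_cols = [np.ones(n_volumes)] + [drift[:, k] for k in range(drift.shape[1])]
    conf_names = ["constant"] + [f"hp_{k + 1}" for k in range(drift.shape[1])]
    if trace is not None:
        conf_cols += [np.asarray(trace.dpetco2, float), np.asarray(trace.dpeto2, float)]
        conf_names += ["dpetco2", "dpeto2"]
    if nuisance is not None:
        raw = np.column_stack(
            [np.asarray(nuisance.motion, float)[:, j] for j in range(6)]
            + [np.asarray(nuisance.rvt, float), np.asarray(nuisance.bpm, float)]
        )
        hp = _detrend_columns(raw, drift)
        keep = np.std(hp, axis=0) > 0
        conf_cols += [hp[:, j] for j in range(hp.shape[1]) if keep[j]]
        base = [f"motion_{j + 1}" for j in range(6)] + ["rvt", "bpm"]
        conf_names += [n for n, k in zip(base, keep) if k]
    confounds = np.column_stack(conf_cols)
    return FIRDesign(
        interest=interest,
        confounds=confounds,
        conditions=list(conditions),
        n_lags=L,
        tr=tr,
        confound_names=conf_names,
    )


def highpass_remove_gas(bold: np.ndarray, trace, *, tr: float, cutoff: float = 0.01) -> np.ndarray:
    """Residualize time series against [constant + DCT(cutoff) + end-tidal traces].

    ``bold`` is (n_voxels, n_volumes); the projection span is the one the FIR
    stage also controls for.
    """
    bold = np.atleast_2d(np.asarray(bold, dtype=float))
    n = bold.shape[1]
    drift = dct_basis(n, tr, cutoff)
    Z = np.column_stack(
        [np.ones(n)]
        + [drift[:, k] for k in range(drift.shape[1])]
        + [np.asarray(trace.dpetco2, float), np.asarray(trace.dpeto2, float)]
    )
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("projection basis is rank deficient")
    beta, *_ = np.linalg.lstsq(Z, bold.T, rcond=None)
    return bold - (Z @ beta).T
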