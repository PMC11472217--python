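"""Synthetic laminar gas-challenge experiments with planted ground truth.

The generator emulates a single 697 s run (820 volumes, TR 0.85 s): end-tidal
CO2/O2 traces stepping through hypercapnic and hyperoxic blocks, 71 brief
(200 ms) visual events with right-skewed-exponential inter-stimulus intervals,
per-voxel cortical-depth probability vectors over six laminae plus a pial-vein
bin, and voxel-wise BOLD built from planted laminar CVR, CBVvO2 and HRF
descriptors, with drift, physiological nuisance coupling and AR(1) thermal
noise on top. Every planted quantity is recoverable by the analysis stages, so
the whole pipeline is testable without scanner data.

Forward model per voxel v with baseline signal S0_v::

    S_v(t) = S0_v * [1 + cvr_v/100 * dPetCO2(t) + cbvvo2_v/100 * dPetO2(t)
                       + sum_k h_{v,cond(k)}(t - t_k)/100] + drift + coupling + noise

where cvr_v etc. are the depth-probability mixtures of the per-bin truth and
h is the planted HRF (in %BOLD) for the gas condition of event k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .protocol import GasProtocol, default_protocol

__all__ = [
    "CONDITIONS",
    "DEPTH_BINS",
    "EndTidalTrace",
    "StimulusSchedule",
    "DepthProbabilityMap",
    "NuisanceSeries",
    "LaminarGroundTruth",
    "NoiseSpec",
    "SyntheticDataset",
    "make_end_tidal_traces",
    "make_stimulus_schedule",
    "make_depth_probability_maps",
    "make_nuisance_series",
    "calibrated_hrf",
    "linear_profile",
    "simulate_dataset",
]

#: gas conditions during which visual events can occur, in protocol order
CONDITIONS = ("room_air", "hc5", "hc10", "ho")

#: cortical-depth bins, deep (GM/WM border) to superficial, plus the pial-vein bin
DEPTH_BINS = ("L1", "L2", "L3", "L4", "L5", "L6", "pial_vein")
N_BINS = len(DEPTH_BINS)


# --------------------------------------------------------------------------- traces


@dataclass
class EndTidalTrace:
    """Sampled end-tidal pressures on the TR grid with per-sample block labels."""

    t: np.ndarray
    petco2: np.ndarray
    peto2: np.ndarray
    block_labels: np.ndarray
    baseline_petco2: float
    baseline_peto2: float

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.petco2) == len(self.peto2) == len(self.block_labels) == n):
            raise ValueError("trace arrays must share one length")
        if np.any(self.petco2 <= 0) or np.any(self.peto2 <= 0):
            raise ValueError("end-tidal pressures must stay positive")

    @property
    def dpetco2(self) -> np.ndarray:
        """CO2 trace in Delta-mmHg relative to baseline (the GLM regressor)."""
        return self.petco2 - self.baseline_petco2

    @property
    def dpeto2(self) -> np.ndarray:
        return self.peto2 - self.baseline_peto2

    def __len__(self) -> int:
        return len(self.t)


def make_end_tidal_traces(
    protocol: GasProtocol,
    tr: float,
    jitter_sd: float = 0.0,
    seed: int | None = None,
) -> EndTidalTrace:
    """Generate end-tidal CO2/O2 traces for a gas protocol.

    Levels approach each block's target by a first-order exponential with the
    protocol's ``transition_tau`` (per-sample recursion
    ``x[n+1] = target + (x[n] - target) * exp(-tr / tau)``; ``tau = 0`` steps
    instantly). Optional breath-to-breath jitter is white Gaussian noise of SD
    ``jitter_sd`` mmHg on CO2 and ``10 * jitter_sd`` on O2, whose end-tidal
    plateau fluctuates about an order of magnitude more in absolute terms.
    """
    if tr <= 0:
        raise ValueError("tr must be > 0")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    duration = protocol.duration
    n = round(duration / tr)
    if abs(n * tr - duration) > 1e-6:
        raise ValueError(
            f"protocol duration {duration} s is not a multiple of tr {tr} s"
        )
    t = np.arange(n) * tr
    labels = protocol.labels_at(t)
    co2_target = np.empty(n)
    o2_target = np.empty(n)
    edges = protocol.boundaries
    idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(protocol.blocks) - 1)
    for i, b in enumerate(protocol.blocks):
        sel = idx == i
        co2_target[sel] = protocol.baseline_petco2 + b.dpetco2
        o2_target[sel] = protocol.baseline_peto2 + b.dpeto2

    tau = protocol.transition_tau
    if tau <= 1e-12:
        co2, o2 = co2_target.copy(), o2_target.copy()
    else:
        decay = math.exp(-tr / tau)
        co2 = np.empty(n)
        o2 = np.empty(n)
        co2[0], o2[0] = co2_target[0], o2_target[0]
        for i in range(1, n):
            co2[i] = co2_target[i] + (co2[i - 1] - co2_target[i]) * decay
            o2[i] = o2_target[i] + (o2[i - 1] - o2_target[i]) * decay

    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        co2 = co2 + rng.normal(0.0, jitter_sd, n)
        o2 = o2 + rng.normal(0.0, 10.0 * jitter_sd, n)
        co2 = np.maximum(co2, 1e-3)
        o2 = np.maximum(o2, 1e-3)

    return EndTidalTrace(
        t=t,
        petco2=co2,
        peto2=o2,
        block_labels=labels,
        baseline_petco2=protocol.baseline_petco2,
        baseline_peto2=protocol.baseline_peto2,
    )


# ------------------------------------------------------------------------- schedule


@dataclass
class StimulusSchedule:
    """Visual event onsets (s) with their gas-condition labels."""

    onsets: np.ndarray
    conditions: np.ndarray
    duration: float = 0.2  # stimulus presentation length, s

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.conditions = np.asarray(self.conditions)
        if len(self.onsets) != len(self.conditions):
            raise ValueError("onsets and conditions must align")
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.onsets)


def make_stimulus_schedule(
    n_events: int = 71,
    isi_min: float = 3.0,
    isi_max: float = 28.0,
    skew: float = 7.0,
    lead_in: float = 30.0,
    duration: float = 697.0,
    hrf_window: float = 20.0,
    protocol: GasProtocol | None = None,
    seed: int | None = None,
    snap_to_grid: bool = False,
    tr: float = 0.85,
    max_attempts: int = 2000,
) -> StimulusSchedule:
    """Draw a pseudorandom event schedule with right-skewed-exponential ISIs.

    ISIs are ``isi_min`` plus an exponential of scale ``skew`` truncated at
    ``isi_max - isi_min``; whole schedules are rejection-sampled until every
    onset fits in ``[lead_in, duration - hrf_window]``. The first event is at
    ``lead_in`` (task onset after the rest baseline). Gas-condition labels are
    taken from the protocol block containing each onset. ``snap_to_grid``
    rounds ISIs to TR multiples while respecting the ISI bounds, so events
    coincide exactly with acquisition samples (used for exactness checks).
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if not (0 < isi_min < isi_max):
        raise ValueError("need 0 < isi_min < isi_max")
    if lead_in < 0 or skew <= 0:
        raise ValueError("lead_in must be >= 0 and skew > 0")
    budget = duration - hrf_window - lead_in
    if (n_events - 1) * isi_min > budget:
        raise ValueError(
            f"infeasible schedule: {n_events} events at ISI >= {isi_min} s need "
            f"{(n_events - 1) * isi_min:.1f} s but only {budget:.1f} s are available"
        )
    if protocol is None:
        protocol = default_protocol()
    rng = np.random.default_rng(seed)
    width = isi_max - isi_min
    start = math.ceil(lead_in / tr - 1e-9) * tr if snap_to_grid else lead_in
    for _ in range(max_attempts):
        # inverse-CDF draw from Exp(skew) truncated to [0, width]
        u = rng.random(n_events - 1)
        isis = isi_min - skew * np.log1p(-u * (1.0 - math.exp(-width / skew)))
        if snap_to_grid:
            lo = math.ceil(isi_min / tr)
            hi = math.floor(isi_max / tr)
            isis = np.clip(np.round(isis / tr), lo, hi) * tr
        onsets = start + np.concatenate([[0.0], np.cumsum(isis)])
        if onsets[-1] <= duration - hrf_window:
            labels = protocol.labels_at(onsets)
            if np.any(labels == "baseline"):
                continue  # event inside the rest baseline; redraw
            return StimulusSchedule(onsets=onsets, conditions=labels)
    raise RuntimeError(
        f"no feasible schedule in {max_attempts} attempts; ISI scale {skew} is "
        f"likely too long for {n_events} events in {budget:.0f} s"
    )


# -------------------------------------------------------------------- depth maps


@dataclass
class DepthProbabilityMap:
    """Per-voxel membership probabilities over the 7 depth bins (rows sum to 1)."""

    probs: np.ndarray  # (n_voxels, 7)
    bins: tuple[str, ...] = DEPTH_BINS

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != len(self.bins):
            raise ValueError(f"probs must be (n_voxels, {len(self.bins)})")
        if np.any(self.probs < -1e-12):
            raise ValueError("probabilities must be non-negative")
        if np.any(np.abs(self.probs.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("probability rows must sum to 1")

    @property
    def n_voxels(self) -> int:
        return self.probs.shape[0]

    @property
    def vein_mask(self) -> np.ndarray:
        """Voxels whose pial-vein probability exceeds 0.5."""
        return self.probs[:, self.bins.index("pial_vein")] > 0.5

    def mix(self, per_bin: np.ndarray) -> np.ndarray:
        """Per-voxel expectation of a per-bin quantity (probs @ values)."""
        return self.probs @ np.asarray(per_bin, dtype=float)


def make_depth_probability_maps(
    n_voxels_per_bin: int = 60,
    mixing: float = 0.25,
    seed: int | None = None,
) -> DepthProbabilityMap:
    """Voxel depth-probability vectors with partial-volume spread to neighbours.

    Each voxel has a home bin receiving probability ``1 - m`` and its adjacent
    bins ``m / 2`` each, where ``m`` is the ``mixing`` level jittered by
    +-20% per voxel; at the edge bins the spill toward the missing neighbour is
    folded back into the home bin. ``mixing = 0`` gives one-hot vectors.
    """
    if not 0.0 <= mixing <= 1.0:
        raise ValueError("mixing must be in [0, 1]")
    if n_voxels_per_bin < 1:
        raise ValueError("n_voxels_per_bin must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for home in range(N_BINS):
        if mixing == 0:
            m = np.zeros(n_voxels_per_bin)
        else:
            m = np.clip(mixing * rng.uniform(0.8, 1.2, n_voxels_per_bin), 0.0, 0.6)
        block = np.zeros((n_voxels_per_bin, N_BINS))
        block[:, home] = 1.0 - m
        for nb in (home - 1, home + 1):
            if 0 <= nb < N_BINS:
                block[:, nb] += m / 2.0
            else:
                block[:, home] += m / 2.0  # fold edge spill back inward
        rows.append(block)
    return DepthProbabilityMap(probs=np.vstack(rows))


# ---------------------------------------------------------------------- nuisance


@dataclass
class NuisanceSeries:
    """Slow smooth stochastic nuisance series: 6 motion traces, RVT and BPM."""

    motion: np.ndarray  # (n_volumes, 6)
    rvt: np.ndarray
    bpm: np.ndarray


def make_nuisance_series(
    n_volumes: int,
    tr: float,
    seed: int | None = None,
    amplitude: float = 1.0,
    smooth_s: float = 8.0,
) -> NuisanceSeries:
    """Gaussian-smoothed noise series standardized to SD = ``amplitude``."""
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n_volumes, 8))
    if amplitude == 0:
        z = np.zeros_like(raw)
    else:
        sigma = max(smooth_s / tr, 1e-6)
        half = int(4 * sigma) + 1
        k = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
        k /= k.sum()
        sm = np.column_stack(
            [np.convolve(raw[:, j], k, mode="same") for j in range(raw.shape[1])]
        )
        sm -= sm.mean(axis=0)
        sd = sm.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        z = amplitude * sm / sd
    return NuisanceSeries(motion=z[:, :6], rvt=z[:, 6], bpm=z[:, 7])


# ------------------------------------------------------------------ planted HRFs

_TEMPLATE_CACHE: dict[str, float] = {}


def _template_descriptors() -> tuple[float, float]:
    """Dense-grid TTP and FWHM of the unit-peak double-gamma template."""
    if not _TEMPLATE_CACHE:
        from .design import double_gamma

        t = np.arange(0.0, 40.0, 0.001)
        h = double_gamma(t)
        i_peak = int(np.argmax(h))
        half = 0.5 * h[i_peak]
        above = h >= half
        left = i_peak
        while left > 0 and above[left - 1]:
            left -= 1
        right = i_peak
        while right < len(h) - 1 and above[right + 1]:
            right += 1
        _TEMPLATE_CACHE["ttp"] = t[i_peak]
        _TEMPLATE_CACHE["fwhm"] = t[right] - t[left]
    return _TEMPLATE_CACHE["ttp"], _TEMPLATE_CACHE["fwhm"]


def calibrated_hrf(amplitude: float, ttp: float, fwhm: float):
    """Planted HRF: double-gamma template affinely calibrated to descriptors.

    The template is time-scaled so its FWHM equals ``fwhm``, time-shifted so
    its dense-grid peak lands at ``ttp`` and amplitude-scaled to peak
    ``amplitude`` (%BOLD). Onset (20-80% rising-edge rule) is then implied by
    the shape; an affine time map cannot set it independently. Returns a
    vectorized callable h(t) that is the planted %BOLD impulse response.
    """
    if amplitude == 0:
        return lambda t: np.zeros_like(np.asarray(t, dtype=float))
    if ttp <= 0 or fwhm <= 0:
        raise ValueError("ttp and fwhm must be > 0 for a nonzero HRF")
    from .design import double_gamma

    ttp0, fwhm0 = _template_descriptors()
    s = fwhm / fwhm0
    delta = ttp - s * ttp0

    def h(t):
        t = np.asarray(t, dtype=float)
        return amplitude * double_gamma((t - delta) / s)

    return h


def linear_profile(center: float, slope: float, n_bins: int = N_BINS) -> np.ndarray:
    """Linear depth profile ``center + slope * (i - mid)`` over bins i = 1..n."""
    i = np.arange(1, n_bins + 1, dtype=float)
    return center + slope * (i - (n_bins + 1) / 2.0)


@dataclass
class LaminarGroundTruth:
    """Planted per-bin CVR, CBVvO2 and HRF descriptors for one contrast.

    ``amplitude``, ``ttp`` and ``fwhm`` map each gas condition to a per-bin
    array; ``onset`` holds the rising-edge onset implied by the calibrated
    shape (filled in automatically). ``contrast`` distinguishes GE-like
    (all-vessel) from SE-like (microvascular) planted regimes.
    """

    cvr: np.ndarray
    cbvvo2: np.ndarray
    amplitude: dict[str, np.ndarray]
    ttp: dict[str, np.ndarray]
    fwhm: dict[str, np.ndarray]
    contrast: str = "GE"
    bins: tuple[str, ...] = DEPTH_BINS
    onset: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cvr = np.asarray(self.cvr, dtype=float)
        self.cbvvo2 = np.asarray(self.cbvvo2, dtype=float)
        nb = len(self.bins)
        if self.cvr.shape != (nb,) or self.cbvvo2.shape != (nb,):
            raise ValueError(f"cvr and cbvvo2 must have shape ({nb},)")
        if np.any(self.cvr < 0) or np.any(self.cbvvo2 < 0):
            raise ValueError("cvr and cbvvo2 must be >= 0")
        for name, d in (("amplitude", self.amplitude), ("ttp", self.ttp), ("fwhm", self.fwhm)):
            for cond, arr in d.items():
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (nb,):
                    raise ValueError(f"{name}[{cond}] must have shape ({nb},)")
                d[cond] = arr
        for cond, arr in self.ttp.items():
            amp = self.amplitude[cond]
            if np.any((amp != 0) & (arr <= 0)):
                raise ValueError("ttp must be > 0 where amplitude is nonzero")
        if not self.onset:
            self.onset = {c: self._implied_onsets(c) for c in self.amplitude}

    def _implied_onsets(self, cond: str) -> np.ndarray:
        from .hrfmodel import quantify_curve

        t = np.arange(0.0, 24.0, 0.01)
        out = np.full(len(self.bins), np.nan)
        for b in range(len(self.bins)):
            a = self.amplitude[cond][b]
            if a == 0:
                continue
            h = calibrated_hrf(a, self.ttp[cond][b], self.fwhm[cond][b])
            q = quantify_curve(t, h(t))
            out[b] = q["onset"]
        return out

    @property
    def conditions(self) -> list[str]:
        return list(self.amplitude)

    def hrf(self, bin_index: int, cond: str):
        """Planted %BOLD impulse-response callable for one bin and condition."""
        return calibrated_hrf(
            self.amplitude[cond][bin_index],
            self.ttp[cond][bin_index],
            self.fwhm[cond][bin_index],
        )

    @classmethod
    def from_profiles(
        cls,
        cvr: np.ndarray,
        cbvvo2: np.ndarray,
        amplitude: dict[str, np.ndarray],
        ttp: float | dict[str, np.ndarray] = 4.09,
        fwhm: float | dict[str, np.ndarray] = 3.66,
        contrast: str = "GE",
    ) -> "LaminarGroundTruth":
        """Convenience constructor broadcasting scalar TTP/FWHM over bins."""
        nb = N_BINS
        amplitude = {c: np.broadcast_to(np.asarray(v, float), (nb,)).copy() for c, v in amplitude.items()}
        if not isinstance(ttp, dict):
            ttp = {c: np.full(nb, float(ttp)) for c in amplitude}
        if not isinstance(fwhm, dict):
            fwhm = {c: np.full(nb, float(fwhm)) for c in amplitude}
        return cls(
            cvr=np.broadcast_to(np.asarray(cvr, float), (nb,)).copy(),
            cbvvo2=np.broadcast_to(np.asarray(cbvvo2, float), (nb,)).copy(),
            amplitude=amplitude,
            ttp=ttp,
            fwhm=fwhm,
            contrast=contrast,
        )


# -------------------------------------------------------------------- simulation


@dataclass
class NoiseSpec:
    """Noise model: baseline tSNR, AR(1) coefficient, drift and nuisance coupling.

    ``tsnr`` is S0 / noise-SD at baseline (``inf`` disables noise); ``ar1`` the
    lag-one autocorrelation of the thermal noise; ``drift_pct`` the RMS of the
    slow scanner drift in percent of S0; ``nuisance_pct`` the per-series RMS
    coupling of motion/RVT/BPM into the signal, in percent of S0.
    """

    tsnr: float = 40.0
    ar1: float = 0.3
    drift_pct: float = 0.2
    nuisance_pct: float = 0.1

    def __post_init__(self) -> None:
        if self.tsnr <= 0:
            raise ValueError("tsnr must be > 0 (use inf for noiseless)")
        if not -1 < self.ar1 < 1:
            raise ValueError("ar1 must be in (-1, 1)")
        if self.drift_pct < 0 or self.nuisance_pct < 0:
            raise ValueError("drift_pct and nuisance_pct must be >= 0")


@dataclass
class SyntheticDataset:
    """Complete synthetic run: BOLD, geometry, traces, events and the truth."""

    bold: np.ndarray  # (n_voxels, n_volumes), scanner units
    tr: float
    depth_probs: DepthProbabilityMap
    trace: EndTidalTrace
    schedule: StimulusSchedule
    nuisance: NuisanceSeries | None
    truth: LaminarGroundTruth
    seed: int | None
    s0: np.ndarray  # planted per-voxel baseline signal

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.bold)):
            raise ValueError("bold must be finite")
        if self.bold.shape != (self.depth_probs.n_voxels, len(self.trace)):
            raise ValueError("bold shape must be (n_voxels, n_volumes)")

    @property
    def vein_mask(self) -> np.ndarray:
        return self.depth_probs.vein_mask

    @property
    def n_volumes(self) -> int:
        return self.bold.shape[1]


def simulate_dataset(
    truth: LaminarGroundTruth,
    trace: EndTidalTrace,
    schedule: StimulusSchedule,
    depth_probs: DepthProbabilityMap,
    noise_spec: NoiseSpec | None = None,
    seed: int | None = None,
    *,
    tr: float = 0.85,
    nuisance: NuisanceSeries | None = None,
    s0_mean: float = 1000.0,
    s0_sd_frac: float = 0.05,
) -> SyntheticDataset:
    """Simulate one run from planted laminar truth (forward model in module docstring).

    Per-voxel generative parameters are the depth-probability mixtures of the
    per-bin truth. With ``noise_spec.tsnr = inf`` and drift/nuisance coupling
    zero, the analysis stages recover every planted quantity to numerical
    precision (given grid-aligned events and a model-matched HRF shape).
    """
    if noise_spec is None:
        noise_spec = NoiseSpec()
    n = len(trace)
    t_grid = trace.t
    if len(schedule) and schedule.onsets[-1] > t_grid[-1] + tr:
        raise ValueError("schedule extends past the sampled trace")
    P = depth_probs.probs
    V = depth_probs.n_voxels

    # per-bin visual responses (%BOLD), mixed into voxels through P
    bin_visual = np.zeros((N_BINS, n))
    for cond in truth.conditions:
        ons = schedule.onsets[schedule.conditions == cond]
        if len(ons) == 0:
            continue
        lags = t_grid[None, :] - ons[:, None]  # (events, n)
        for b in range(N_BINS):
            if truth.amplitude[cond][b] == 0:
                continue
            h = truth.hrf(b, cond)
            bin_visual[b] += h(lags).sum(axis=0)
    voxel_visual = P @ bin_visual
    voxel_cvr = depth_probs.mix(truth.cvr)
    voxel_cbv = depth_probs.mix(truth.cbvvo2)

    ss = np.random.SeedSequence(seed if seed is not None else 0)
    rng_s0, rng_drift, rng_coup, rng_noise = [np.random.default_rng(s) for s in ss.spawn(4)]

    s0 = s0_mean * (1.0 + s0_sd_frac * rng_s0.standard_normal(V))
    s0 = np.maximum(s0, 0.2 * s0_mean)

    pct = (
        voxel_cvr[:, None] * trace.dpetco2[None, :]
        + voxel_cbv[:, None] * trace.dpeto2[None, :]
        + voxel_visual
    ) / 100.0
    bold = s0[:, None] * (1.0 + pct)

    if noise_spec.drift_pct > 0:
        x = (t_grid - t_grid.mean()) / np.ptp(t_grid)
        shapes = np.stack([2.0 * x, np.cos(np.pi * (x + 0.5)), np.cos(2 * np.pi * (x + 0.5))])
        shapes /= np.sqrt((shapes**2).mean(axis=1, keepdims=True))
        w = rng_drift.standard_normal((V, shapes.shape[0])) / math.sqrt(shapes.shape[0])
        bold += (s0[:, None] * noise_spec.drift_pct / 100.0) * (w @ shapes)

    if nuisance is not None and noise_spec.nuisance_pct > 0:
        series = np.column_stack(
            [nuisance.motion, nuisance.rvt[:, None], nuisance.bpm[:, None]]
        ).T  # (8, n)
        sd = series.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        series = series / sd
        coefs = rng_coup.standard_normal((V, series.shape[0])) * noise_spec.nuisance_pct
        bold += s0[:, None] / 100.0 * (coefs @ series)

    if np.isfinite(noise_spec.tsnr):
        rho = noise_spec.ar1
        w = rng_noise.standard_normal((V, n))
        innov_sd = math.sqrt(1.0 - rho**2) if rho != 0 else 1.0
        e = lfilter([1.0], [1.0, -rho], w * innov_sd, axis=1)
        bold = bold + (s0 / noise_spec.tsnr)[:, None] * e

    return SyntheticDataset(
        bold=bold,
        tr=tr,
        depth_probs=depth_probs,
        trace=trace,
        schedule=schedule,
        nuisance=nuisance,
        truth=truth,
        seed=seed,
        s0=s0,
    )
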