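"""End-to-end experiment runner: simulate -> GLM -> FIR -> quantify -> profiles -> stats.

A RunConfig collects every protocol, geometry, noise and estimator parameter
(defaults are the study conditions the package emulates: 820 volumes at TR
0.85 s, the four-block gas protocol, 71 events, detrend cutoff 7e-4 Hz,
high-pass 0.01 Hz, 20 s FIR window, FDR q = 0.05, visual t > 1). A single
global seed fans out into per-subject, per-stage substreams so any subject
can be re-simulated in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import synth
from .protocol import default_protocol
from .synth import (
    CONDITIONS,
    DEPTH_BINS,
    LaminarGroundTruth,
    NoiseSpec,
    SyntheticDataset,
    linear_profile,
    make_depth_probability_maps,
    make_end_tidal_traces,
    make_nuisance_series,
    make_stimulus_schedule,
    simulate_dataset,
)
from .design import build_localizer_design, build_fir_design
from .glm import LocalizerGLM, compute_reactivity, select_voxels
from .fir import FIRModel, laminar_average
from .hrfmodel import InverseLogitHRF, quantify_hrf
from .profiles import DepthProfile, DepthSlopeModel, normalize_by_cbvvo2
from .groupstats import friedman, skillings_mack

logger = logging.getLogger("laminarhrf")

__all__ = [
    "TruthConfig",
    "RunConfig",
    "SubjectResult",
    "ExperimentReport",
    "simulate_subject",
    "analyze_subject",
    "run_experiment",
    "validate_against_truth",
]

# paper-reported GE/SE group values used as default planted truths
_GE_AMPLITUDES = {"room_air": 2.17, "hc5": 1.77, "hc10": 1.20, "ho": 2.35}
_SE_AMPLITUDES = {"room_air": 0.90, "hc5": 0.90, "hc10": 0.90, "ho": 1.26}


@dataclass
class TruthConfig:
    """Planted laminar truth, parameterized as center + per-lamina slope.

    Profiles over the 7 depth bins are ``center + slope * (bin - 4)``; zero
    slopes plant spatially uniform quantities. Amplitude centers are per gas
    condition; TTP and FWHM are shared across bins and conditions.
    """

    contrast: str = "GE"
    cvr_center: float = 1.01          # %BOLD / mmHg CO2
    cvr_slope: float = 0.0
    cbvvo2_center: float = 0.013      # %BOLD / mmHg O2
    cbvvo2_slope: float = 0.0
    amplitude_center: dict = field(default_factory=lambda: dict(_GE_AMPLITUDES))
    amplitude_slope: float = 0.0      # %BOLD per lamina, applied to every condition
    ttp: float = 4.09                 # s
    fwhm: float = 3.66                # s

    @classmethod
    def se_defaults(cls) -> "TruthConfig":
        return cls(
            contrast="SE",
            cvr_center=0.55,
            cbvvo2_center=0.010,
            amplitude_center=dict(_SE_AMPLITUDES),
        )

    def build(self) -> LaminarGroundTruth:
        amp = {
            c: np.maximum(linear_profile(v, self.amplitude_slope), 0.0)
            for c, v in self.amplitude_center.items()
        }
        return LaminarGroundTruth.from_profiles(
            cvr=np.maximum(linear_profile(self.cvr_center, self.cvr_slope), 0.0),
            cbvvo2=np.maximum(linear_profile(self.cbvvo2_center, self.cbvvo2_slope), 0.0),
            amplitude=amp,
            ttp=self.ttp,
            fwhm=self.fwhm,
            contrast=self.contrast,
        )


@dataclass
class RunConfig:
    """Full experiment configuration; defaults are the emulated study conditions."""

    # acquisition grid
    tr: float = 0.85
    n_volumes: int = 820
    # gas protocol
    tail_duration: float = 107.0
    baseline_petco2: float = 38.0
    baseline_peto2: float = 100.0
    transition_tau: float = 10.0
    jitter_sd: float = 0.5            # mmHg breath-to-breath CO2 jitter
    # visual task
    n_events: int = 71
    isi_min: float = 3.0
    isi_max: float = 28.0
    isi_skew: float = 7.0             # exponential ISI scale, s (events span the run)
    lead_in: float = 30.0
    snap_to_grid: bool = False
    # geometry and noise
    n_voxels_per_bin: int = 60
    mixing: float = 0.25
    tsnr: float = 40.0
    ar1: float = 0.3
    drift_pct: float = 0.2
    nuisance_pct: float = 0.1
    nuisance_amplitude: float = 1.0
    # estimator options
    detrend_cutoff: float = 7e-4      # Hz, localizer GLM
    hrf_kernel_duration: float = 32.0  # s, canonical-kernel truncation
    hp_cutoff: float = 0.01           # Hz, FIR stage
    fir_window: float = 20.0          # s
    fdr_q: float = 0.05
    t_visual: float = 1.0
    selection_mode: str = "intersect-visual"
    k_detect: float = 2.0
    n_starts: int = 8
    include_vein_in_slope: bool = True
    # cohort
    n_subjects: int = 9
    seed: int = 1
    truth: TruthConfig = field(default_factory=TruthConfig)

    @property
    def duration(self) -> float:
        return self.n_volumes * self.tr

    def noise_spec(self) -> NoiseSpec:
        return NoiseSpec(
            tsnr=self.tsnr, ar1=self.ar1, drift_pct=self.drift_pct, nuisance_pct=self.nuisance_pct
        )

    def protocol(self):
        return default_protocol(
            tail_duration=self.tail_duration,
            baseline_petco2=self.baseline_petco2,
            baseline_peto2=self.baseline_peto2,
            transition_tau=self.transition_tau,
        )

    # --- round-trippable serialization -------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["tsnr"] = "inf" if np.isinf(self.tsnr) else self.tsnr
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("tsnr") == "inf":
            d["tsnr"] = float("inf")
        if "truth" in d and isinstance(d["truth"], dict):
            d["truth"] = TruthConfig(**d["truth"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _subject_seeds(config: RunConfig) -> np.ndarray:
    """Per-subject, per-stage integer seeds (< 2**31) fanned out from the run seed."""
    rng = np.random.default_rng(config.seed)
    return rng.integers(0, 2**31 - 1, size=(config.n_subjects, 5))


def simulate_subject(config: RunConfig, subject: int) -> SyntheticDataset:
    """Simulate subject ``subject`` (0-based) of the configured cohort."""
    seeds = _subject_seeds(config)[subject]
    protocol = config.protocol()
    trace = make_end_tidal_traces(protocol, config.tr, config.jitter_sd, seed=int(seeds[0]))
    schedule = make_stimulus_schedule(
        n_events=config.n_events,
        isi_min=config.isi_min,
        isi_max=config.isi_max,
        skew=config.isi_skew,
        lead_in=config.lead_in,
        duration=config.duration,
        hrf_window=config.fir_window,
        protocol=protocol,
        seed=int(seeds[1]),
        snap_to_grid=config.snap_to_grid,
        tr=config.tr,
    )
    depth = make_depth_probability_maps(config.n_voxels_per_bin, config.mixing, seed=int(seeds[2]))
    nuis = make_nuisance_series(
        config.n_volumes, config.tr, seed=int(seeds[3]), amplitude=config.nuisance_amplitude
    )
    return simulate_dataset(
        config.truth.build(),
        trace,
        schedule,
        depth,
        config.noise_spec(),
        seed=int(seeds[4]),
        tr=config.tr,
        nuisance=nuis,
    )


@dataclass
class SubjectResult:
    """All per-subject estimates the group stage consumes."""

    mean_cvr: float                   # over selected voxels, %BOLD/mmHg
    mean_cbvvo2: float
    cvr_profile: np.ndarray           # (7,)
    cbvvo2_profile: np.ndarray
    amplitude: dict                   # cond -> (7,)
    ttp: dict
    onset: dict
    fwhm: dict
    detectable: dict
    n_selected: int
    n_voxels: int
    il5_seed: int


def analyze_subject(ds: SyntheticDataset, config: RunConfig, il5_seed: int = 0) -> SubjectResult:
    """Run the full estimation chain on one dataset."""
    from .design import canonical_hrf

    design = build_localizer_design(
        ds.trace,
        ds.schedule,
        ds.nuisance,
        tr=ds.tr,
        n_volumes=ds.n_volumes,
        dct_cutoff=config.detrend_cutoff,
        hrf_kernel=canonical_hrf(ds.tr, duration=config.hrf_kernel_duration),
    )
    glm_res = LocalizerGLM(ds.bold, design).fit()
    react = compute_reactivity(glm_res)
    sel = (
        select_voxels(
            glm_res.tstat("dpetco2"),
            glm_res.tstat("dpeto2"),
            glm_res.tstat("visual"),
            glm_res.df_resid,
            q=config.fdr_q,
            t_thresh=config.t_visual,
            mode=config.selection_mode,
        )
        & react.valid
    )
    logger.info("selection: %d / %d voxels survive", int(sel.sum()), len(sel))
    if not sel.any():
        raise RuntimeError("no voxels survived selection; cannot build laminar profiles")

    cvr_profile, _ = laminar_average(react.cvr, ds.depth_probs, sel)
    cbv_profile, _ = laminar_average(react.cbvvo2, ds.depth_probs, sel)

    conditions = [c for c in CONDITIONS if c in set(ds.schedule.conditions)]
    fir_design = build_fir_design(
        ds.schedule,
        ds.trace,
        ds.nuisance,
        tr=ds.tr,
        n_volumes=ds.n_volumes,
        window=config.fir_window,
        hp_cutoff=config.hp_cutoff,
        conditions=conditions,
    )
    baseline = np.where(react.valid, react.baseline, 1.0)
    fir_res = FIRModel(ds.bold, fir_design, baseline).fit()

    amp = {c: np.full(len(DEPTH_BINS), np.nan) for c in conditions}
    ttp = {c: np.full(len(DEPTH_BINS), np.nan) for c in conditions}
    onset = {c: np.full(len(DEPTH_BINS), np.nan) for c in conditions}
    fwhm = {c: np.full(len(DEPTH_BINS), np.nan) for c in conditions}
    detect = {c: np.zeros(len(DEPTH_BINS), bool) for c in conditions}
    for cond in conditions:
        curves, weights = laminar_average(fir_res.hrf[cond], ds.depth_probs, sel)
        for b in range(len(DEPTH_BINS)):
            if weights[b] == 0 or not np.all(np.isfinite(curves[b])):
                continue
            model = InverseLogitHRF(fir_res.lag_times, curves[b], window=config.fir_window)
            fit = model.fit(n_starts=config.n_starts, seed=il5_seed + 97 * b)
            q = quantify_hrf(fit, k_detect=config.k_detect)
            amp[cond][b] = q.amplitude
            ttp[cond][b] = q.ttp
            onset[cond][b] = q.onset
            fwhm[cond][b] = q.fwhm
            detect[cond][b] = q.detectable
    n_missing = int(sum(np.isnan(a).sum() for a in amp.values()))
    logger.info("laminar HRFs: %d bins, %d missing descriptor cells", len(DEPTH_BINS), n_missing)

    return SubjectResult(
        mean_cvr=float(np.nanmean(react.cvr[sel])),
        mean_cbvvo2=float(np.nanmean(react.cbvvo2[sel])),
        cvr_profile=cvr_profile,
        cbvvo2_profile=cbv_profile,
        amplitude=amp,
        ttp=ttp,
        onset=onset,
        fwhm=fwhm,
        detectable=detect,
        n_selected=int(sel.sum()),
        n_voxels=len(sel),
        il5_seed=il5_seed,
    )


@dataclass
class ExperimentReport:
    """Cohort-level results: profiles, slopes, omnibus tests, truth comparison."""

    config: RunConfig
    config_hash: str
    profiles: dict          # name -> DepthProfile
    slopes: dict            # name -> SlopeFit
    tests: dict             # name -> RankTestResult
    headline: dict          # scalar summaries (group means/medians)
    subjects: list          # SubjectResult
    truth_comparison: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        def _clean(x):
            if isinstance(x, float) and not np.isfinite(x):
                return None
            return x

        out = {
            "config": self.config.to_dict(),
            "config_hash": self.config_hash,
            "seed": self.config.seed,
            "headline": {k: _clean(v) for k, v in self.headline.items()},
            "profiles": {
                name: {
                    "units": p.units,
                    "bins": list(p.bins),
                    "values": [[_clean(float(v)) for v in row] for row in p.values],
                }
                for name, p in self.profiles.items()
            },
            "slopes": {
                name: {
                    "mean_slope": _clean(s.mean_slope),
                    "ci95": [_clean(s.ci95[0]), _clean(s.ci95[1])],
                    "tstat": _clean(s.tstat),
                    "pvalue": _clean(s.pvalue),
                    "n_subjects": s.n_subjects,
                    "subject_slopes": [_clean(float(v)) for v in s.slopes],
                }
                for name, s in self.slopes.items()
            },
            "tests": {
                name: {
                    "statistic": _clean(t.statistic),
                    "df": t.df,
                    "pvalue": _clean(t.pvalue),
                    "method": t.method,
                    "n_blocks": t.n_blocks,
                }
                for name, t in self.tests.items()
            },
        }
        if self.truth_comparison is not None:
            out["truth_comparison"] = json.loads(
                self.truth_comparison.to_json(orient="records")
            )
        return out

    def to_json(self, path=None) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(blob)
        return blob

    def summary(self) -> str:
        lines = [f"Experiment report (seed {self.config.seed}, config {self.config_hash})"]
        for k, v in sorted(self.headline.items()):
            lines.append(f"  {k}: {v:.4g}" if isinstance(v, float) and np.isfinite(v) else f"  {k}: {v}")
        for name, s in self.slopes.items():
            lines.append("  " + s.summary())
        for name, t in self.tests.items():
            lines.append(f"  {name}: " + t.summary())
        return "\n".join(lines)


def _profile(name: str, rows: list[np.ndarray], units: str) -> DepthProfile:
    return DepthProfile(quantity=name, values=np.vstack([r[None, :] for r in rows]), units=units)


def run_experiment(config: RunConfig) -> ExperimentReport:
    """Simulate and analyze the configured cohort and assemble the group report."""
    subjects: list[SubjectResult] = []
    truth = config.truth.build()
    for i in range(config.n_subjects):
        logger.info("subject %d / %d", i + 1, config.n_subjects)
        ds = simulate_subject(config, i)
        subjects.append(analyze_subject(ds, config, il5_seed=1000 * (i + 1) + config.seed))

    conditions = list(subjects[0].amplitude)
    profiles: dict[str, DepthProfile] = {
        "cvr": _profile("cvr", [s.cvr_profile for s in subjects], "%BOLD/mmHg CO2"),
        "cbvvo2": _profile("cbvvo2", [s.cbvvo2_profile for s in subjects], "%BOLD/mmHg O2"),
    }
    for cond in conditions:
        profiles[f"amplitude_{cond}"] = _profile(
            f"amplitude_{cond}", [s.amplitude[cond] for s in subjects], "%BOLD"
        )
        profiles[f"ttp_{cond}"] = _profile(f"ttp_{cond}", [s.ttp[cond] for s in subjects], "s")
        profiles[f"onset_{cond}"] = _profile(f"onset_{cond}", [s.onset[cond] for s in subjects], "s")
        profiles[f"fwhm_{cond}"] = _profile(f"fwhm_{cond}", [s.fwhm[cond] for s in subjects], "s")
        profiles[f"norm_amplitude_{cond}"] = normalize_by_cbvvo2(
            profiles[f"amplitude_{cond}"], profiles["cbvvo2"]
        )

    slope_targets = ["cvr", "cbvvo2", "amplitude_room_air", "norm_amplitude_room_air",
                     "ttp_room_air", "onset_room_air"]
    slopes = {
        name: DepthSlopeModel(profiles[name], include_vein=config.include_vein_in_slope).fit()
        for name in slope_targets
        if name in profiles
    }

    tests = {}
    amp_table = np.vstack(
        [
            np.column_stack([s.amplitude[c] for c in conditions])
            for s in subjects
        ]
    )  # (subjects * bins, conditions)
    tests["amplitude_condition_effect"] = (
        friedman(amp_table) if np.all(np.isfinite(amp_table)) else skillings_mack(amp_table)
    )
    ttp_table = np.vstack([np.column_stack([s.ttp[c] for c in conditions]) for s in subjects])
    ok_rows = np.isfinite(ttp_table).sum(axis=1) >= 2
    if ok_rows.sum() >= 2 and np.all(np.isfinite(ttp_table[ok_rows]).sum(axis=0) >= 1):
        tests["ttp_condition_effect"] = skillings_mack(ttp_table[ok_rows])

    amp_room = profiles["amplitude_room_air"].values
    headline = {
        "group_mean_cvr": float(np.mean([s.mean_cvr for s in subjects])),
        "group_mean_cbvvo2": float(np.mean([s.mean_cbvvo2 for s in subjects])),
        "n_subjects": config.n_subjects,
        "mean_selected_voxels": float(np.mean([s.n_selected for s in subjects])),
    }
    for cond in conditions:
        vals = profiles[f"amplitude_{cond}"].values
        headline[f"group_mean_amplitude_{cond}"] = float(np.nanmean(vals))
        headline[f"group_median_ttp_{cond}"] = float(np.nanmedian(profiles[f"ttp_{cond}"].values))
    if "amplitude_room_air" in slopes:
        headline["amplitude_room_air_slope"] = slopes["amplitude_room_air"].mean_slope
    headline["cvr_slope"] = slopes["cvr"].mean_slope

    report = ExperimentReport(
        config=config,
        config_hash=config.hash(),
        profiles=profiles,
        slopes=slopes,
        tests=tests,
        headline=headline,
        subjects=subjects,
    )
    report.truth_comparison = validate_against_truth(report, truth)
    return report


def validate_against_truth(report: ExperimentReport, truth: LaminarGroundTruth) -> pd.DataFrame:
    """Planted-versus-recovered comparison table (bias and relative bias)."""
    rows = []

    def add(name, planted, recovered):
        if planted is None or recovered is None or not np.isfinite(recovered):
            return
        bias = recovered - planted
        rel = bias / planted if planted != 0 else np.nan
        rows.append((name, planted, recovered, bias, rel))

    add("mean_cvr", float(truth.cvr.mean()), report.headline.get("group_mean_cvr"))
    add("mean_cbvvo2", float(truth.cbvvo2.mean()), report.headline.get("group_mean_cbvvo2"))
    for cond in truth.conditions:
        key = f"group_mean_amplitude_{cond}"
        if key in report.headline:
            add(f"amplitude_{cond}", float(truth.amplitude[cond].mean()), report.headline[key])
        keyt = f"group_median_ttp_{cond}"
        if keyt in report.headline:
            add(f"ttp_{cond}", float(np.median(truth.ttp[cond])), report.headline[keyt])
    # planted slopes from the per-bin truth
    bins = np.arange(1, len(truth.bins) + 1, dtype=float)
    add("cvr_slope", float(np.polyfit(bins, truth.cvr, 1)[0]), report.slopes["cvr"].mean_slope)
    if "amplitude_room_air" in report.slopes:
        add(
            "amplitude_room_air_slope",
            float(np.polyfit(bins, truth.amplitude["room_air"], 1)[0]),
            report.slopes["amplitude_room_air"].mean_slope,
        )
    return pd.DataFrame(rows, columns=["quantity", "planted", "recovered", "bias", "rel_bias"])
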