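"""Plain-format readers and writers: NIfTI-1 volumes, BIDS-style TSVs, JSON sidecars.

A synthetic dataset round-trips through: ``bold.nii`` (4D, voxels unraveled on
the first axis), ``depth_probs.nii`` (one volume per depth bin),
``vein_mask.nii``, ``events.tsv`` (onset, duration, trial_type),
``physio.tsv`` (time, petco2, peto2, rvt, bpm, motion_1..6) and
``truth.json``. The laminar HRF travels as a tidy TSV
(subject, contrast, condition, bin, lag_s, value_pct), the package's central
intermediate format.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .protocol import default_protocol
from .synth import (
    DEPTH_BINS,
    DepthProbabilityMap,
    EndTidalTrace,
    LaminarGroundTruth,
    NuisanceSeries,
    StimulusSchedule,
    SyntheticDataset,
)

__all__ = ["save_dataset", "load_dataset", "save_laminar_hrf", "load_laminar_hrf", "save_hrf_params"]


def _write_nifti(path: Path, data: np.ndarray, tr: float | None = None) -> None:
    arr = np.asarray(data, dtype=np.float32)
    while arr.ndim < 4:
        arr = arr[:, None]
    img = nib.Nifti1Image(arr, affine=np.eye(4))
    if tr is not None:
        img.header["pixdim"][4] = tr
    nib.save(img, str(path))


def save_dataset(ds: SyntheticDataset, outdir) -> Path:
    """Write one synthetic run to ``outdir`` in plain interchange formats."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _write_nifti(out / "bold.nii", ds.bold[:, None, None, :], tr=ds.tr)
    _write_nifti(out / "depth_probs.nii", ds.depth_probs.probs[:, None, None, :])
    _write_nifti(out / "vein_mask.nii", ds.vein_mask.astype(np.float32)[:, None, None, None])
    pd.DataFrame(
        {
            "onset": ds.schedule.onsets,
            "duration": np.full(len(ds.schedule), ds.schedule.duration),
            "trial_type": ds.schedule.conditions,
        }
    ).to_csv(out / "events.tsv", sep="\t", index=False)
    physio = pd.DataFrame(
        {
            "time": ds.trace.t,
            "petco2": ds.trace.petco2,
            "peto2": ds.trace.peto2,
            "block": ds.trace.block_labels,
        }
    )
    if ds.nuisance is not None:
        physio["rvt"] = ds.nuisance.rvt
        physio["bpm"] = ds.nuisance.bpm
        for j in range(6):
            physio[f"motion_{j + 1}"] = ds.nuisance.motion[:, j]
    physio.to_csv(out / "physio.tsv", sep="\t", index=False, float_format="%.6f")
    truth = ds.truth
    sidecar = {
        "tr": ds.tr,
        "seed": ds.seed,
        "baseline_petco2": ds.trace.baseline_petco2,
        "baseline_peto2": ds.trace.baseline_peto2,
        "contrast": truth.contrast,
        "bins": list(truth.bins),
        "cvr": truth.cvr.tolist(),
        "cbvvo2": truth.cbvvo2.tolist(),
        "amplitude": {c: v.tolist() for c, v in truth.amplitude.items()},
        "ttp": {c: v.tolist() for c, v in truth.ttp.items()},
        "fwhm": {c: v.tolist() for c, v in truth.fwhm.items()},
        "onset": {c: v.tolist() for c, v in truth.onset.items()},
        "s0": ds.s0.tolist(),
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
    return out


def load_dataset(indir) -> SyntheticDataset:
    """Reload a dataset written by :func:`save_dataset`."""
    d = Path(indir)
    with open(d / "truth.json") as fh:
        meta = json.load(fh)
    bold = np.asarray(nib.load(str(d / "bold.nii")).dataobj, dtype=float)[:, 0, 0, :]
    probs = np.asarray(nib.load(str(d / "depth_probs.nii")).dataobj, dtype=float)[:, 0, 0, :]
    probs /= probs.sum(axis=1, keepdims=True)  # undo float32 rounding
    events = pd.read_csv(d / "events.tsv", sep="\t")
    physio = pd.read_csv(d / "physio.tsv", sep="\t")
    trace = EndTidalTrace(
        t=physio["time"].to_numpy(),
        petco2=physio["petco2"].to_numpy(),
        peto2=physio["peto2"].to_numpy(),
        block_labels=physio["block"].to_numpy(),
        baseline_petco2=meta["baseline_petco2"],
        baseline_peto2=meta["baseline_peto2"],
    )
    schedule = StimulusSchedule(
        onsets=events["onset"].to_numpy(),
        conditions=events["trial_type"].to_numpy(),
        duration=float(events["duration"].iloc[0]) if len(events) else 0.2,
    )
    nuisance = None
    if "rvt" in physio:
        nuisance = NuisanceSeries(
            motion=physio[[f"motion_{j + 1}" for j in range(6)]].to_numpy(),
            rvt=physio["rvt"].to_numpy(),
            bpm=physio["bpm"].to_numpy(),
        )
    truth = LaminarGroundTruth(
        cvr=np.array(meta["cvr"]),
        cbvvo2=np.array(meta["cbvvo2"]),
        amplitude={c: np.array(v) for c, v in meta["amplitude"].items()},
        ttp={c: np.array(v) for c, v in meta["ttp"].items()},
        fwhm={c: np.array(v) for c, v in meta["fwhm"].items()},
        onset={c: np.array(v) for c, v in meta["onset"].items()},
        contrast=meta["contrast"],
        bins=tuple(meta["bins"]),
    )
    return SyntheticDataset(
        bold=bold,
        tr=meta["tr"],
        depth_probs=DepthProbabilityMap(probs=probs, bins=tuple(meta["bins"])),
        trace=trace,
        schedule=schedule,
        nuisance=nuisance,
        truth=truth,
        seed=meta["seed"],
        s0=np.array(meta["s0"]),
    )


def save_laminar_hrf(
    curves: dict, lag_times: np.ndarray, path, subject: int = 1, contrast: str = "GE"
) -> None:
    """Write per-bin HRFs as the tidy TSV (condition -> (7, L) array)."""
    rows = []
    for cond, arr in curves.items():
        for b, label in enumerate(DEPTH_BINS):
            for ell, lag in enumerate(lag_times):
                rows.append((subject, contrast, cond, label, lag, arr[b, ell]))
    pd.DataFrame(
        rows, columns=["subject", "contrast", "condition", "bin", "lag_s", "value_pct"]
    ).to_csv(path, sep="\t", index=False, float_format="%.8g")


def load_laminar_hrf(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"subject", "contrast", "condition", "bin", "lag_s", "value_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"laminar HRF TSV lacks columns: {sorted(missing)}")
    return df


def save_hrf_params(records: list[dict], path) -> None:
    """Write HRF descriptor rows (subject, contrast, condition, bin, ...) as TSV."""
    pd.DataFrame.from_records(records).to_csv(path, sep="\t", index=False, float_format="%.8g")
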