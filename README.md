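# laminarhrf

Laminar BOLD analysis of combined visual-task and respiratory gas-challenge
fMRI runs — cerebrovascular reactivity and venous blood-volume mapping from
end-tidal gas regressors, condition-specific FIR deconvolution of the
hemodynamic response, inverse-logit HRF quantification, probability-weighted
cortical-depth profiles, and nonparametric group statistics — plus a
synthetic-experiment generator with planted laminar ground truth so the
entire pipeline is testable without scanner data.

## The problem

At ultrahigh field, BOLD fMRI can resolve responses across cortical depth,
but the signal is shaped as much by the venous vascular architecture —
blood volume, vessel size and reactivity all increase toward the pial
surface — as by neuronal activity. A run that combines brief visual stimuli
with controlled hypercapnia (+5, +10 mmHg end-tidal CO2) and hyperoxia
(+350 mmHg end-tidal O2) lets the two be separated:

* **CVR** (cerebrovascular reactivity) and **CBVvO2** (a hyperoxia-derived
  proxy for venous blood volume) are the regression coefficients of %BOLD
  on the end-tidal traces:
  `CVR = 100·β_CO2/β_0 [%BOLD/mmHg]`, `CBVvO2 = 100·β_O2/β_0`.
* The **HRF** to each 200 ms stimulus is deconvolved per gas condition with
  a 24-lag FIR basis (20 s window at TR 0.85 s), averaged into depth bins by
  membership probability, smoothed with a five-inverse-logit fit
  `h(t) = Σᵢ aᵢ σ((t−Tᵢ)/Dᵢ)`, and summarized by amplitude, time-to-peak,
  rising-edge onset and FWHM.
* Amplitude profiles normalized by CBVvO2 remove the venous-volume
  weighting; participant-wise OLS slopes across depth bins and
  Friedman / Skillings–Mack rank tests with Holm-corrected Wilcoxon post
  hocs provide the group inference.

The intended user is an fMRI methods researcher who wants a tested,
seed-reproducible reference implementation of this analysis chain, or a
validated harness for planting and recovering laminar effects.

## Worked example

Simulate a 9-subject cohort with a spatially uniform GE-like truth
(CVR 1.01 %/mmHg, CBVvO2 0.013 %/mmHg, HRF amplitude 2.17 %BOLD) at
tSNR 40 and recover it:

```python
from laminarhrf.experiments import reactivity_cohort
from laminarhrf.pipeline import run_experiment

report = run_experiment(reactivity_cohort("GE", seed=1, n_subjects=9))
print(report.headline["group_mean_cvr"])            # 1.0086
print(report.headline["group_mean_cbvvo2"])         # 0.012987
print(report.headline["group_mean_amplitude_room_air"])  # 2.1654
print(report.truth_comparison[["quantity", "planted", "recovered", "rel_bias"]])
```

The recovered group-mean CVR (1.0086 %BOLD/mmHg CO2) sits within 0.2% of
the planted 1.01; the hyperoxia coefficient (0.012987 %BOLD/mmHg O2) and
the room-air HRF amplitude (2.1654 %BOLD) are recovered within 0.1% and
0.3%. `report.profiles` holds per-subject depth profiles (6 laminae plus
the pial-vein bin, deep → superficial), `report.slopes` the
participant-wise depth-slope fits with CIs, and `report.tests` the omnibus
rank tests; `report.to_json(path)` writes everything.

The same machinery is available from the shell:

```bash
laminarhrf simulate --seed 1 --out run01/        # NIfTI + TSV + truth.json
laminarhrf glm --data run01 --out glm01/         # CVR/CBVvO2 maps, selection
laminarhrf fir --data run01 --glm-dir glm01 --out fir01/
laminarhrf quantify --hrf fir01/laminar_hrf.tsv --out params01.tsv
laminarhrf run-all --seed 1 --out exp01/         # full cohort report
```

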