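# laminarmeg

Laminar MEG source analysis on synthetic sensor data: a two-surface
(pial / white-matter) empirical Bayesian beamformer, frequency-band power
extraction, and an ROI-based laminar discrimination statistic with its
perturbation controls.

## The problem

MEG measures magnetic fields a few centimeters from the cortex; whether a
frequency-specific signal originates from deep (infragranular,
white-matter boundary) or superficial (supragranular, pial) cortical
laminae is a ~2–4 mm distinction that standard source analyses do not
attempt.  The approach implemented here builds a generative model whose
source space contains *both* surfaces with a one-to-one vertex
correspondence, inverts the sensor data onto the combined space with an
empirical Bayesian beamformer, and asks, per frequency band and time
window, on which surface the unsigned fractional power change from
baseline is larger.

For each signal with band `f`, window of interest `WOI` and baseline `B`:

- source prior (fixed orientation, per source `i` with lead field `Lᵢ`):
  `Q(i) = (LᵢᵀLᵢ)⁻¹ (Lᵢᵀ(YYᵀ)⁻¹Lᵢ + λ̃)⁻¹`
- noise/source scales by ReML on
  `F = −N/2 (log det C + tr C⁻¹S)`, `C = h_ε Qε + h_Q L Q Lᵀ`
- MAP currents `Ĵ = Q̂Lᵀ(Q̂ε + LQ̂Lᵀ)⁻¹Y`
- statistic: paired t over trials of the ROI-averaged
  `|P_WOI − P_B| / P_B` between surfaces (positive t → pial/superficial,
  negative → white/deep), with an exact Wilcoxon signed-rank test over
  participants at the group level.

Everything runs on simulated sessions with exported ground truth — a
wrinkled two-layer spherical cortex, a synthetic axial-gradiometer helmet,
a factorial task schedule (70% congruent, 3 coherence levels), and
band-limited induced responses placed on either surface.  The package is
for methodologists who want a tested, self-contained laminar-inference
pipeline to probe (when does laminar discrimination survive noise,
co-registration error, lead-field shuffling?) rather than a tool for
analyzing raw recordings.

## Worked example

```python
from laminarmeg.pipeline import (
    ALPHA_SIGNAL, GAMMA_SIGNAL, default_session_config,
    fit_session, laminar_analysis)
from laminarmeg.synthetic import simulate_session

cfg = default_session_config(seed=1, snr_db=0.0, subdivisions=3,
                             trials_per_block=120)
session = simulate_session(cfg)      # deep alpha + superficial gamma
fitted = fit_session(session)
for sig in (ALPHA_SIGNAL, GAMMA_SIGNAL):
    r = laminar_analysis(fitted, sig, metric="functional")
    print(sig.name, f"t={r.t:+.2f}", r.classification)
```

prints

```
visual_alpha_rdk t=-7.70 deep
visual_gamma_rdk t=+8.56 superficial
```

The alpha decrease (planted on the white surface) yields a negative
laminar t — classified deep; the gamma burst (planted on the pial surface)
a positive t — superficial.  Both match the exported ground truth in
`session.truth`.  Across 8 simulated participants
(`laminarmeg.pipeline.run_group`), the group Wilcoxon tests give
`W(8)=0, p=0.008` for alpha (8/8 deep) and `W(8)=36, p=0.008` for gamma
(8/8 superficial) — opposite-signed laminar effects for the two bands.

The `examples/` directory has one narrative script per capability:
session simulation, single-participant laminar analysis, the group run,
the perturbation controls, and sensor-level time-frequency summaries.
A thin CLI mirrors the pipeline stages:

```bash
laminarmeg simulate --seed 1 --out run/
laminarmeg invert run/
laminarmeg laminar run/ --metric functional
laminarmeg controls run/ --kinds shuffle,noise
laminarmeg report run/
```

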