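# Methods

`laminarmeg` implements a laminar source analysis for MEG: sensor data are
explained by a generative model whose source space is the union of two
cortical surfaces — the white-matter/grey boundary (deep) and the pial
surface (superficial) — and frequency-band power changes are compared
between corresponding vertices of the two surfaces to infer the laminar
origin of a signal.  Because the real multi-session head-cast recordings
that motivate this analysis are not part of the package, every quantity is
exercised on synthetic sessions with known laminar ground truth.

## Generative model and inversion

Sensor data `Y` (channels × time, reduced by SVD to spatial and temporal
modes) follow a two-level Gaussian model

    Y = L J + ε,   ε ~ N(0, h_ε Qε),   J ~ N(0, h_Q Q),

where `L` is the lead field of the combined `[white, pial]` source space
(one source per vertex, oriented along the vertex normal), `Qε` is the
identity by default, and `Q` is diagonal with the empirical Bayesian
beamformer (EBB) prior

    Q(i) = (Liᵀ Li)⁻¹ · (Liᵀ (YYᵀ)⁻¹ Li + λ̃)⁻¹ ,

with `λ` expressed as a percent of the mean eigenvalue of `YYᵀ` (λ = 0 by
default; `multi_reg_invert` scores λ ∈ {0, 5, 10, 50, 100, 1000} by model
evidence).  The hyperparameters `(h_ε, h_Q)` maximize the restricted
Gaussian likelihood

    F = −N/2 (log det C + tr(C⁻¹ S)),   C = h_ε Qε + h_Q L Q Lᵀ,

by Fisher scoring on log-scales with step halving; `F` is reported as the
free energy and is comparable only within a candidate set (no hyperprior
terms are included).  The MAP current estimate is
`Ĵ = Q̂ Lᵀ (Q̂ε + L Q̂ Lᵀ)⁻¹ Y` with the ReML-scaled covariances.

**Reconstruction operator used by the laminar pipeline.**  The pipeline's
per-signal reconstruction uses the *empirical-covariance* form of the same
operator: unit-gain weights `wᵢ = C⁻¹Lᵢ/(LᵢᵀC⁻¹Lᵢ)` with `C` the
band-limited sample covariance (plus λ% mean-eigenvalue regularization).
The reason is a property of the synthetic world, not of the method: the
synthetic sensor noise is spatially white, so ReML — correctly — assigns
almost all broadband variance to `h_ε·I`, and the model-covariance operator
degenerates to a non-adaptive matched filter with no laminar selectivity.
Real MEG data contain spatially structured background activity that loads
`h_Q`, making the fitted model covariance data-like; the sample covariance
is the honest equivalent here and is the standard beamformer convention
(the prior formula itself inverts `YYᵀ`).  `reml_mix`/`invert` implement
and are tested on the model-covariance form.

**Forward model.**  The volume conductor is the analytic homogeneous
sphere (current-dipole closed form; the external field is independent of
the radial conductivity profile), with the sphere fitted to the scalp hull
by least squares.  Axial gradiometers are modeled as the field component
along the coil orientation at the pickup coil minus the same component at
a coil displaced by the baseline (default 0.05 m) along that orientation.
The module interface accepts any channels × sources gain matrix, so a
realistic shell model can be substituted.

**Patch (coherence) prior.**  Columns are smoothed within-surface by a
normalized Gaussian of geodesic distance (graph shortest path along mesh
edges), FWHM 10 mm by default at toy mesh scale; `patch_size_sweep`
compares free energies across FWHM ∈ {2.5, 5, 10, 20} mm relative to their
mean.

## The laminar statistic

For each signal (band × window-of-interest × baseline window):

1. band-pass the epoched sensor data (4th-order Butterworth, zero phase);
2. build the unit-gain beamformer operator from the band-limited covariance;
3. per trial and per vertex, compute power (variance of the projected
   signal) in the WOI and in the baseline window — for band-limited
   signals this equals the mean time-frequency power over the band
   (Parseval), at a fraction of the cost of per-vertex wavelet transforms;
4. ROI: vertices of either surface whose trial-pooled unsigned fractional
   change |ΔP|/P_baseline is at or above the 80th percentile of that
   surface (order-statistic threshold, ties included), expanded to full
   white/pial pairs.  Metrics: `global` (all vertices), `functional`
   (restricted to a 10 mm geodesic neighborhood of the peak vertex),
   `anatomical` (restricted to a label mask);
5. per-trial ROI values per surface: unsigned fractional change of the
   trial's WOI power against the *trial-pooled* frequency-specific
   baseline (the robust-average-across-trials convention used for
   sensor-level baseline correction), averaged over ROI vertices;
6. paired t-test over trials, pial minus white; the paired-difference
   variance is floored at 1% of the squared mean difference so degenerate
   near-zero-variance data cannot produce unbounded t (|t| ≤ 10√n);
   positive t classifies the signal as superficial, negative as deep;
7. group level: exact Wilcoxon signed-rank test on the per-participant
   pial−white differences (all 2ⁿ sign assignments enumerated for n ≤ 25;
   zeros dropped, midranks for ties, two-sided p by doubling the smaller
   tail), optionally against a shifted null taken from the shuffled
   lead-field control.

Two numerical choices in steps 4–5 deserve emphasis.  The ROI map uses
*trial-pooled* power ratios because a per-trial 0.5 s baseline in a 6 Hz
band carries only ~6 degrees of freedom; maps built from per-trial ratios
are dominated by estimator noise at toy mesh scale.  The per-trial
statistic keeps its trial resolution in the numerator (WOI power) but uses
the pooled baseline denominator for the same reason: with a per-trial
denominator, the expected value of the *unsigned* change at a
well-suppressed vertex is the noise offset E|P̂/B̂ − 1| ≈ 0.6, which exceeds
a 30–40% true modulation and systematically inverts deep classifications.

**Silent sources.**  On a spherical conductor a radially oriented dipole
is externally silent.  Lead-field columns whose RMS falls below 10% of the
median (the wrinkled sphere's near-radial critical points) are excluded
from the analysis — their prior variances otherwise blow up as 1/‖L‖⁴ and
dominate `L Q Lᵀ` with patterns unrelated to the data.  Real cortical
meshes in a realistic conductor do not have this degeneracy.

## Spectral machinery

Sensor-level time-frequency power uses seven-cycle complex Morlet wavelets
on a 1 Hz grid (2–45 Hz) and a sliding-window sine-taper estimate (200 ms
windows, 10 ms steps, 3 tapers, 5 Hz grid, 55–115 Hz).  Samples within one
wavelet half-length of the epoch edges are flagged; epochs carry a 250 ms
margin beyond the analysis windows so that band-pass and wavelet
transients stay out of the baselines.  Baseline correction is
frequency-specific per channel: the baseline is an iteratively reweighted
(Tukey bisquare, c = 4.685, MAD scale) average over baseline samples
pooled across trials, and power is expressed as (P − b)/b.  When the MAD
is zero but residuals are not, samples at the median keep weight 1 and the
rest get 0 (the bisquare limit for vanishing scale).  Cross-participant
sensor summaries average a sensor cluster, smooth with a Gaussian kernel
(FWHM 8 Hz × 80 ms) and mask pixels by a one-sample t across participants
with Bonferroni correction — a deliberate simplification of a
random-intercept mixed model, to which it is equivalent for balanced
designs.  Session reproducibility uses ICC(2,k) from two-way
random-effects mean squares.

## Synthetic sessions

The generator produces everything a session needs, with ground truth:

- **Geometry.**  Pial surface = icosphere (radius 0.07 m) with a smooth
  radial "wrinkle" (default amplitude 7 mm, a fixed trigonometric field);
  white surface = pial moved 3 mm along the inward pial normal, so index
  correspondence holds by construction; scalp = convex hull of the pial
  vertices inflated by 10 mm.  The wrinkle exists because a *plain* sphere
  with surface-normal sources is completely silent in a spherical
  conductor; folding is exactly what makes real cortex visible to MEG.
  Amplitude 0 reproduces plain concentric spheres for geometric tests.
- **Sensors.**  A Fibonacci-lattice spherical cap (default 130 axial
  gradiometers, helmet radius 0.105 m, 120° half-angle, radial coils).
- **Task schedule.**  Exact factorial counts per block: at 180 trials,
  126 congruent / 54 incongruent, 60 per coherence level (30 leftward
  each), randomly ordered; block sizes must be multiples of 60 for the
  70/30 × 3 × 2 design to give integer cells.  A correctness flag defaults
  to all-correct (configurable error rate); behavioral responses are not
  modeled.
- **Sources.**  Each source is a Gaussian geodesic patch (default FWHM
  10 mm) on one surface carrying band-limited Gaussian noise (independent
  per trial — induced, not evoked), whose amplitude is scaled by
  √(1 + m) inside the window of interest with 50 ms raised-cosine ramps;
  `m` is the signed fractional power modulation, optionally offset per
  condition (e.g. extra gamma on incongruent trials).  The standard
  condition plants a deep alpha decrease (7–13 Hz, m = −0.4, amplitude 1)
  and a superficial gamma burst (60–90 Hz, m = +0.6, amplitude 0.6); the
  amplitude ratio keeps the two bands' in-band SNRs comparable, as in real
  band-limited analyses.
- **Noise.**  White Gaussian sensor noise scaled so that
  10·log₁₀(P_signal/P_noise) over channels × union-of-WOIs equals the
  target SNR (default 0 dB).  The generator does **not** emulate 1/f
  spatially structured brain noise, head movement, or evoked components —
  which is why the pipeline's reconstruction uses the empirical covariance
  (above), and why passing tests certify the machinery and its directional
  behavior rather than real-data effect sizes.

Problem sizes: group analyses run 8 participants at 2 × 642 vertices and
130 channels with 120 trials; control experiments run at 2 × 162 vertices
and 80 channels.  These sizes keep a full study run in minutes while
leaving all qualitative behavior intact.

## Perturbation controls

Four controls re-run the identical laminar analysis under a degradation,
each a pure function of (session, seeds):

- **Shuffle** — permute lead-field columns (10 repetitions); the mean
  shuffled pial−white difference is exported as a shifted null for the
  group test.  The shuffle control reports the whole-brain (global) ROI by
  default since a "functional peak" of a geometry-free model is
  meaningless.
- **Co-registration** — random rigid transform of the sensor array
  (rotation angle ~ N(10°, 2.5°) about a random axis, translation
  ~ N(10 mm, 2.5 mm)), lead field rebuilt per repetition.
- **Subsampling** — random trial subsets from 10 up to all trials, 10
  repetitions each, t-statistics averaged per count.
- **Noise injection** — white noise at {0, 0.5, 1, 2, 4, 8} × the
  per-channel data SD added to the epoched data before inversion.

On the standard synthetic condition these reproduce, as directional
properties: a shuffled null biased superficially relative to the veridical
deep-alpha t; |t| growing with trial count; added noise driving the deep
alpha bias toward the superficial surface with saturation; and the gamma
bias saturating at lower noise and flipping sign in some sessions.

## Design choices and limitations

- Vertex correspondence is strictly index-based; unequal vertex counts are
  an error (no nearest-neighbor fallback), because silent mismatching
  would corrupt every laminar comparison.
- Head frame: right-handed, origin at the conductor-sphere center, meters
  everywhere.  Combined source ordering `[white, pial]` is fixed; the sign
  convention (positive t = pial) depends on it.
- Decimation is greedy shortest-edge collapse with a manifold (link
  condition) guard; a pair is decimated jointly by collapsing the pial
  surface and carrying the surviving vertex set to the white surface.
- The functional ROI radius (10 mm geodesic) and the anatomical masks
  (label sets over generator patches) are package conventions; at
  2 × 642 vertices the global top-20% ROI contains ~130 pairs of which
  only a handful carry signal, so the global metric is noticeably diluted
  relative to a 30 000-vertex mesh where power maps concentrate on the
  active blob.
- Free energy comparisons between veridical and shuffled forward models
  require the patch smoothing to be applied *after* shuffling (a bare
  column permutation leaves L·diag(q)·Lᵀ invariant for any per-column
  prior) and a low-noise regime: at high sensor noise the diffuse shuffled
  prior genuinely fits a noise-dominated covariance better.
- The variance floor stands in for a corrected noise-variance estimate;
  its contract — attenuating artifactually large t — is what is tested,
  and it can be disabled or set explicitly.
- Wilcoxon: exact for n ≤ 25 non-zero differences, normal approximation
  with tie correction (flagged) beyond; Friedman follow-ups use the
  studentized-range (Tukey–Kramer) distribution on mean rank differences
  with large-sample error degrees of freedom.
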