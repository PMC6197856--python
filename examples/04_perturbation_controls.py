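"""Perturbation controls: what breaks the laminar inference, and how.

Runs lead-field shuffling, trial subsampling and white-noise injection on
one fitted session (test scale: 162 vertex pairs, 80 channels) and prints
the control curves.  Takes a few minutes.
"""

from laminarmeg.controls import (
    ControlSpec,
    run_noise_control,
    run_shuffle_control,
    run_subsample_control,
)
from laminarmeg.pipeline import (
    ALPHA_SIGNAL,
    GAMMA_SIGNAL,
    default_session_config,
    fit_session,
    laminar_analysis,
)
from laminarmeg.synthetic import simulate_session

cfg = default_session_config(seed=1, snr_db=0.0, subdivisions=2,
                             n_sensors=80, trials_per_block=120)
fitted = fit_session(simulate_session(cfg))
signals = [ALPHA_SIGNAL, GAMMA_SIGNAL]

veridical = {s.name: laminar_analysis(fitted, s, metric="functional").t
             for s in signals}
print("veridical laminar t:", {k: round(v, 2) for k, v in veridical.items()})

sh = run_shuffle_control(fitted, [ALPHA_SIGNAL],
                         ControlSpec("shuffle", repetitions=10))
print(f"\nshuffled lead fields (10 permutations): mean alpha t = "
      f"{sh['table']['t'].mean():+.2f} vs veridical "
      f"{veridical[ALPHA_SIGNAL.name]:+.2f}")
print("  → destroying the anatomy/sensor correspondence removes the deep "
      "bias (the shuffled null is superficially biased).")

sub = run_subsample_control(fitted, signals,
                            trial_counts=(10, 20, 40, 80, 120),
                            repetitions=5)
print("\nmean t vs number of trials:")
print(sub["mean_t"].pivot(index="parameter", columns="signal",
                          values="t").round(2))
print("  → |t| grows with the trial count.")

ns = run_noise_control(fitted, signals,
                       noise_sds=(0.0, 0.5, 1.0, 2.0, 4.0, 8.0))
print("\nlaminar t vs added white-noise SD (× data SD):")
print(ns["table"].pivot(index="parameter", columns="signal",
                        values="t").round(2))
print("  → added noise drives the deep alpha bias toward the superficial "
      "surface until it saturates; the gamma bias collapses at lower "
      "noise and can flip sign.")
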