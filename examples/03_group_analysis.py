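"""Group-level laminar inference over 8 simulated participants.

Each participant gets an independent session (deep alpha + superficial
gamma, SNR 0 dB); the per-participant pial−white ROI differences enter an
exact Wilcoxon signed-rank test.  Takes a couple of minutes.
"""

from laminarmeg.pipeline import ALPHA_SIGNAL, GAMMA_SIGNAL, run_group

out = run_group(n_participants=8, base_seed=1, snr_db=0.0, subdivisions=3,
                trials_per_block=120)

print(out["table"][["participant", "signal", "t",
                    "classification"]].to_string(index=False))
for name, g in out["group"].items():
    n = g.wilcoxon.n
    print(f"\n{name}: W({n}) = {g.wilcoxon.W:.0f}, "
          f"exact p = {g.wilcoxon.p:.3f}; "
          f"{g.n_deep}/8 deep, {g.n_superficial}/8 superficial")

print("\nW near 0 means every participant's difference was negative "
      "(deep); W near n(n+1)/2 = 36 means every difference was positive "
      "(superficial). p = 0.008 is the smallest two-sided value "
      "achievable at n = 8.")
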