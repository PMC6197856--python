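"""Run the two-surface beamformer laminar analysis on one participant.

Fits the empirical Bayesian beamformer, then band-passes the data per
signal, reconstructs per-vertex power in the window of interest and
baseline, and compares the unsigned fractional power change between the
pial and white surfaces within the functionally defined ROI.
"""

from laminarmeg.pipeline import (
    ALPHA_SIGNAL,
    GAMMA_SIGNAL,
    default_session_config,
    fit_session,
    laminar_analysis,
)
from laminarmeg.synthetic import simulate_session

cfg = default_session_config(seed=1, snr_db=0.0, subdivisions=3,
                             trials_per_block=120)
session = simulate_session(cfg)
fitted = fit_session(session)
print(f"ReML free energy: {fitted.inversion.free_energy:.1f} "
      f"(h_eps={fitted.inversion.h_eps:.3e}, h_q={fitted.inversion.h_q:.3e})")

for sig in (ALPHA_SIGNAL, GAMMA_SIGNAL):
    r = laminar_analysis(fitted, sig, metric="functional")
    print(f"\n{sig.name} ({sig.band[0]}-{sig.band[1]} Hz, "
          f"WOI {sig.woi}s vs baseline {sig.baseline_woi}s)")
    print(f"  ROI: {len(r.roi)} vertex pair(s)")
    print(f"  laminar t = {r.t:+.2f} (p = {r.p:.2g}) → {r.classification}")
    print(f"  pial−white difference = {r.difference:+.4f}")

print("\nA negative t localizes the signal to the white-matter (deep) "
      "surface, a positive t to the pial (superficial) surface. With the "
      "default generator the alpha decrease is deep and the gamma burst "
      "superficial, so the two t values should have opposite signs.")
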