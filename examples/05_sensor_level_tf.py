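"""Sensor-level time-frequency analysis of a synthetic session.

Morlet wavelets below 45 Hz, sine-taper multitaper above, robust-average
baseline correction, and a cluster-averaged smoothed spectrogram with a
Bonferroni significance mask across participants.
"""

import numpy as np

from laminarmeg.pipeline import default_session_config
from laminarmeg.spectral import baseline_correct, morlet_tf, sensor_tf_summary
from laminarmeg.synthetic import simulate_session

tfs = []
cluster = None
for participant in range(4):
    cfg = default_session_config(seed=participant, snr_db=0.0,
                                 subdivisions=2, n_sensors=40,
                                 trials_per_block=60)
    session = simulate_session(cfg)
    tf = morlet_tf(session.epochs, freqs=np.arange(5.0, 31.0))
    if cluster is None:
        # the sensors "overlying" the alpha source: strongest baseline
        # alpha power (a stand-in for the anatomical occipital cluster)
        base = session.epochs.time_mask(-1.0, -0.5)
        arows = (tf.freqs >= 7) & (tf.freqs <= 13)
        strength = tf.power[:, :, arows][..., base].mean(axis=(0, 2, 3))
        cluster = np.argsort(strength)[-15:]
    tf = baseline_correct(tf, (-1.0, -0.5))
    tfs.append(tf)

summary = sensor_tf_summary(tfs, sensor_cluster=cluster,
                            smooth_fwhm=(8.0, 0.08))
alpha_rows = (summary["freqs"] >= 7) & (summary["freqs"] <= 13)
woi_cols = (summary["times"] >= 0.0) & (summary["times"] <= 2.0)
mean_alpha = summary["mean"][np.ix_(alpha_rows, woi_cols)].mean()
print(f"cluster-mean fractional alpha change in the WOI: {mean_alpha:+.3f}")
print(f"significant pixels (Bonferroni): {summary['significant'].sum()} "
      f"of {summary['significant'].size}")
print("\nThe alpha-band power drops from baseline during the stimulus "
      "window (the generator plants a deep alpha decrease), and the "
      "Bonferroni mask marks where the change is consistent across the "
      "four simulated participants.")
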