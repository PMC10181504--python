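"""Heel-strike detection under added sensor noise.

Degrades the vertical acceleration channel to several signal-to-noise
ratios and reports how detection recall and timing hold up.
"""

import numpy as np

from stridekit import SimConfig, degrade, match_events, run_pipeline, simulate_trial

imu, emg, truth = simulate_trial(SimConfig(seed=3))

print("SNR (dB)  recall  precision  mean |dt| (ms)")
for snr_db in (30, 20, 10, 5):
    noisy = dict(imu)
    noisy["accel_z"] = degrade(imu["accel_z"], snr_db, truth.bout_intervals_s, seed=snr_db)
    result = run_pipeline(noisy, emg)
    detected = (
        np.sort(np.concatenate([e.times_s for e in result.events]))
        if result.events else np.array([])
    )
    r = match_events(detected, truth.all_hs_times_s, tol_s=0.05)
    print(f"{snr_db:8d}  {r.recall:6.3f}  {r.precision:9.3f}  "
          f"{1e3 * r.mean_abs_error_s:13.1f}")

# Recall near 1 down to moderate SNR shows the envelope cascade is doing
# the work; degradation at low SNR marks the detector's operating limit.
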