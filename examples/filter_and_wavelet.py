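"""Split one labelled window into its 9 derived band-limited series.

Each 30 s window is reduced to tremor-band (3.5-7.5 Hz) and voluntary-band
(0.5-3 Hz) series plus a wavelet tremor-energy trace; comparing a tremor
window against a quiet one shows the separation the classifier relies on.
"""

import numpy as np

from tremorkit import SessionConfig, derive_series, extract_windows, simulate_session

cfg = SessionConfig(
    duration_s=1800.0, severity_stationary=(0.5, 0.3, 0.2), mean_bout_s=120.0,
    nodata_prob=0.0, seed=7,
)
rec, events = simulate_session(cfg)
windows = {w.label: w for w in extract_windows(rec, events)}

for label in (0, 2):
    series = derive_series(windows[label])
    trem_rms = np.sqrt(np.mean(series["trem_acc_mag"] ** 2))
    vol_rms = np.sqrt(np.mean(series["vol_acc_mag"] ** 2))
    wave = np.mean(series["wavelet_trem_energy"])
    print(
        f"severity {label}: tremor-band accel RMS {trem_rms:.3f} m/s^2, "
        f"voluntary-band RMS {vol_rms:.3f} m/s^2, mean wavelet energy {wave:.3f}"
    )
print(
    "Tremor-band RMS and wavelet energy rise sharply with severity while the\n"
    "voluntary band stays comparable - the bands isolate the clinical signal."
)
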