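"""Simulate an ECG with known beat times, preprocess it, and score detection.

Builds two minutes of modulated RR intervals, renders a 5 kHz ECG with mains
interference and baseline wander, runs the preprocessing chain and the
R-peak detector, and compares detections against the generator's exact beat
times.
"""

import numpy as np

from hrvcross import (
    EcgSimConfig,
    RrSimConfig,
    detect_rpeaks,
    generate_rr_series,
    preprocess,
    synthesize_ecg,
)

rr = generate_rr_series(RrSimConfig(duration=120.0, seed=1))
ecg, true_peaks = synthesize_ecg(rr, EcgSimConfig(seed=1))
print(f"simulated {len(true_peaks)} beats over {ecg.duration:.0f} s at "
      f"{ecg.sampling_rate:.0f} Hz")

clean = preprocess(ecg)  # detrend, 40 Hz low-pass, 0.5 Hz high-pass, 1 kHz
peaks = detect_rpeaks(clean)

errors = np.array([np.min(np.abs(peaks.peak_times - t)) for t in true_peaks])
matched = (errors < 0.05).sum()
print(f"detected {len(peaks)} peaks: recall {matched / len(true_peaks):.1%}, "
      f"median timing error {1000 * np.median(errors[errors < 0.05]):.2f} ms")
# recall should be 100% and the timing error well under a millisecond: the
# QRS template is symmetric and all filtering is zero-phase.
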