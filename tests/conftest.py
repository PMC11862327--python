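import numpy as np
import pytest

from hrvcross.rpeaks import RRSeries
from hrvcross.simulate import EcgSimConfig, RrSimConfig, generate_rr_series, synthesize_ecg


@pytest.fixture(scope="session")
def steady_rr() -> RRSeries:
    """Five minutes of the default modulated RR process."""
    return generate_rr_series(RrSimConfig(duration=300.0, seed=101))


@pytest.fixture(scope="session")
def clean_ecg():
    """Noise-free synthetic ECG with its exact beat times."""
    rr = generate_rr_series(RrSimConfig(duration=90.0, seed=202))
    rec, peaks = synthesize_ecg(
        rr, EcgSimConfig(seed=202, powerline_amp=0.0, baseline_wander_amp=0.0)
    )
    return rec, peaks


@pytest.fixture(scope="session")
def noisy_ecg():
    """Synthetic ECG with mains interference and baseline wander."""
    rr = generate_rr_series(RrSimConfig(duration=90.0, seed=303))
    rec, peaks = synthesize_ecg(rr, EcgSimConfig(seed=303))
    return rec, peaks


def match_peaks(detected: np.ndarray, truth: np.ndarray, tol_s: float = 0.05):
    """Greedy nearest matching of detected to true peaks within tol_s.

    Returns (recall, precision, median absolute timing error in ms).
    """
    if detected.size == 0 or truth.size == 0:
        return 0.0, 0.0, float("nan")
    errs = []
    used = np.zeros(detected.size, dtype=bool)
    for t in truth:
        d = np.abs(detected - t)
        i = int(np.argmin(d))
        if d[i] <= tol_s and not used[i]:
            used[i] = True
            errs.append(d[i])
    matched = len(errs)
    recall = matched / truth.size
    precision = matched / detected.size
    med = 1000.0 * float(np.median(errs)) if errs else float("nan")
    return recall, precision, med


@pytest.fixture(scope="session")
def peak_scorer():
    return match_peaks
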