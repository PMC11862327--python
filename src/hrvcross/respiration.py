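"""Respiration rate from RR-interval variations (respiratory sinus arrhythmia).

Breathing modulates the heart period, so the respiration frequency appears
as a spectral peak of the tachogram. Each accepted 6-min window contributes
the dominant tachogram frequency within 0.1–0.5 Hz; a window is reliable
only when that peak clearly stands out of the local spectral floor. The
phase estimate is the mean rate over reliable windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = ["RespirationEstimate", "estimate_respiration_rate"]

# Lower edge sits above the ~0.1 Hz baroreflex (LF) rhythm so its spectral
# main lobe cannot masquerade as a breathing peak; 0.12 Hz = 7.2 cpm is still
# below any plausible resting respiration rate.
SEARCH_BAND = (0.12, 0.50)  # Hz
PEAK_DOMINANCE = 5.0  # peak PSD over median in-band PSD
PLAUSIBLE_CPM = (6.0, 30.0)


@dataclass
class RespirationEstimate:
    """Respiration rate estimate for one phase.

    ``rate_cpm`` is the mean over reliable windows (None when no window was
    reliable); ``window_rates`` has one entry per accepted window (NaN where
    unreliable).
    """

    rate_cpm: float | None
    reliable: bool
    window_rates: np.ndarray = field(default_factory=lambda: np.array([]))
    window_reliable: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))


def _window_rate(tachogram: np.ndarray, rate_hz: float) -> tuple[float, bool]:
    x = np.asarray(tachogram, float)
    x = x - x.mean()
    if not np.any(x):
        return float("nan"), False
    nperseg = min(int(120.0 * rate_hz), x.size)
    freqs, psd = signal.welch(
        x, fs=rate_hz, window="hann", nperseg=nperseg, noverlap=nperseg // 2,
        detrend=False,
    )
    mask = (freqs >= SEARCH_BAND[0]) & (freqs <= SEARCH_BAND[1])
    if not mask.any() or psd[mask].max() <= 0:
        return float("nan"), False
    band_f, band_p = freqs[mask], psd[mask]
    i = int(np.argmax(band_p))
    floor = np.median(band_p)
    dominant = floor > 0 and band_p[i] / floor >= PEAK_DOMINANCE
    cpm = 60.0 * band_f[i]
    plausible = PLAUSIBLE_CPM[0] <= cpm <= PLAUSIBLE_CPM[1]
    return cpm, bool(dominant and plausible)


def estimate_respiration_rate(clean, grid) -> RespirationEstimate:
    """Estimate the respiration rate over a graded window grid.

    Parameters
    ----------
    clean : CleanRRSeries
        Artifact-screened RR series of the phase.
    grid : WindowGrid
        Grid whose accepted windows are analyzed (see
        :func:`hrvcross.hrv.grade_windows`).
    """
    from .hrv import interpolate_rr_uniform, INTERP_RATE_HZ

    rates, flags = [], []
    for w in grid.accepted_windows:
        try:
            _, tach = interpolate_rr_uniform(clean, w)
        except ValueError:
            continue
        cpm, ok = _window_rate(tach, INTERP_RATE_HZ)
        rates.append(cpm)
        flags.append(ok)
    rates = np.asarray(rates)
    flags = np.asarray(flags, dtype=bool)
    if rates.size == 0 or not flags.any():
        return RespirationEstimate(None, False, rates, flags)
    return RespirationEstimate(float(np.mean(rates[flags])), True, rates, flags)
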