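"""Time- and frequency-domain HRV on a sliding-window protocol.

Time-domain indices (SDRR, RMSSD, mean HR) are computed over the whole
phase. Spectral indices use 6-min windows advanced in 30-s steps: within
each window the artifact-screened RR series is cubic-spline interpolated to
a uniform 4 Hz tachogram and a Welch periodogram (120-s Hann segments, 50%
overlap) is integrated over the LF (0.04–0.15 Hz) and HF (0.15–0.4 Hz)
bands. A window is rejected when more than 20% of its time was deleted by
artifact screening; per-phase spectral values are arithmetic means over the
accepted windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .rpeaks import CleanRRSeries, mean_heart_rate

__all__ = [
    "LF_BAND",
    "HF_BAND",
    "WindowGrid",
    "HrvPhaseSummary",
    "sdrr",
    "rmssd",
    "build_window_grid",
    "window_usable_fraction",
    "interpolate_rr_uniform",
    "welch_band_power",
    "phase_hrv_summary",
]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

WINDOW_LENGTH_S = 360.0
WINDOW_STEP_S = 30.0
MAX_REJECTED_FRACTION = 0.20
INTERP_RATE_HZ = 4.0
WELCH_SEGMENT_S = 120.0


def sdrr(clean: CleanRRSeries) -> float:
    """Standard deviation (n−1) of the retained RR intervals, ms."""
    kept = clean.clean_intervals
    if kept.size < 2:
        raise ValueError("SDRR needs at least two retained intervals")
    return float(np.std(kept, ddof=1))


def rmssd(clean: CleanRRSeries) -> float:
    """Root mean square of successive differences, ms.

    Differences are formed only between retained intervals adjacent on the
    original beat grid, so no difference spans a deleted interval.
    """
    diffs = clean.successive_diffs()
    if diffs.size == 0:
        raise ValueError("RMSSD needs at least one gap-free successive pair")
    return float(np.sqrt(np.mean(diffs**2)))


@dataclass
class Window:
    start: float
    end: float
    usable_fraction: float = float("nan")
    accepted: bool = False


@dataclass
class WindowGrid:
    """6-min analysis windows stepping by 30 s across one phase."""

    windows: list
    window_length: float = WINDOW_LENGTH_S
    step: float = WINDOW_STEP_S

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def accepted_windows(self) -> list:
        return [w for w in self.windows if w.accepted]


def build_window_grid(
    phase_duration: float,
    window_length: float = WINDOW_LENGTH_S,
    step: float = WINDOW_STEP_S,
    t0: float = 0.0,
) -> WindowGrid:
    """Window starts at t0, t0+step, … while start + window_length ≤ duration."""
    if phase_duration < window_length:
        raise ValueError(
            f"phase duration {phase_duration} s is shorter than one "
            f"{window_length} s analysis window"
        )
    n = int(np.floor((phase_duration - window_length) / step)) + 1
    windows = [Window(t0 + i * step, t0 + i * step + window_length) for i in range(n)]
    return WindowGrid(windows, window_length, step)


def window_usable_fraction(clean: CleanRRSeries, window: Window) -> float:
    """Fraction of the window covered by retained RR intervals.

    Each retained interval [onset, onset + rr) contributes its overlap with
    the window; deleted intervals and uncovered tails count as rejected time.
    """
    starts = clean.clean_onsets
    ends = starts + clean.clean_intervals / 1000.0
    lo = np.maximum(starts, window.start)
    hi = np.minimum(ends, window.end)
    covered = np.clip(hi - lo, 0.0, None).sum()
    return float(covered / (window.end - window.start))


def grade_windows(clean: CleanRRSeries, grid: WindowGrid) -> WindowGrid:
    """Fill usable fractions and accept windows with ≤ 20% rejected time."""
    for w in grid.windows:
        w.usable_fraction = window_usable_fraction(clean, w)
        w.accepted = (1.0 - w.usable_fraction) <= MAX_REJECTED_FRACTION
    return grid


def interpolate_rr_uniform(
    clean: CleanRRSeries, window: Window, rate: float = INTERP_RATE_HZ
):
    """Cubic-spline tachogram of RR(t) at a uniform grid across one window.

    Anchors are the retained beats inside the window plus up to three on each
    flank so the spline does not extrapolate at the edges. Requires an
    accepted window and ≥ 4 anchors.
    """
    if not window.accepted:
        raise ValueError("window was rejected by the 20% quality rule")
    onsets, intervals = clean.clean_onsets, clean.clean_intervals
    inside = (onsets >= window.start) & (onsets < window.end)
    idx = np.flatnonzero(inside)
    if idx.size < 4:
        raise ValueError("need at least four anchor beats inside the window")
    lo = max(idx[0] - 3, 0)
    hi = min(idx[-1] + 4, onsets.size)
    t_anchor, v_anchor = onsets[lo:hi], intervals[lo:hi]
    t_uni = np.arange(window.start, window.end, 1.0 / rate)
    spline = CubicSpline(t_anchor, v_anchor)
    values = spline(np.clip(t_uni, t_anchor[0], t_anchor[-1]))
    return t_uni, values


def welch_band_power(
    tachogram: np.ndarray,
    band: tuple,
    rate: float = INTERP_RATE_HZ,
    segment_s: float = WELCH_SEGMENT_S,
) -> float:
    """Band power (ms²) of a uniform tachogram via mean-removed Welch PSD.

    120-s Hann segments with 50% overlap; the PSD is integrated over the
    half-open band [f_lo, f_hi).
    """
    f_lo, f_hi = band
    if f_lo < 0 or f_hi > rate / 2.0 or f_lo >= f_hi:
        raise ValueError(f"band {band} outside [0, Nyquist={rate / 2}] or empty")
    x = np.asarray(tachogram, dtype=float)
    nperseg = min(int(segment_s * rate), x.size)
    freqs, psd = signal.welch(
        x - x.mean(), fs=rate, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, detrend=False,
    )
    mask = (freqs >= f_lo) & (freqs < f_hi)
    df = freqs[1] - freqs[0]
    return float(psd[mask].sum() * df)


@dataclass
class HrvPhaseSummary:
    """Per-phase cardiovascular indices.

    HR in bpm; SDRR/RMSSD in ms over the whole phase; HF/LF in ms² and the
    LF/HF ratio averaged over accepted 6-min windows; respiration in cycles
    per minute. Spectral fields are None when no window was accepted,
    ``lfhf`` is None when HF is zero.
    """

    hr: float
    sdrr: float
    rmssd: float
    hf: float | None
    lf: float | None
    lfhf: float | None
    resp_cpm: float | None
    resp_reliable: bool
    n_windows_used: int
    retained_fraction: float
    labels: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = dict(self.labels)
        row.update(
            hr=self.hr, sdrr=self.sdrr, rmssd=self.rmssd, hf=self.hf, lf=self.lf,
            lfhf=self.lfhf, resp_cpm=self.resp_cpm, resp_reliable=self.resp_reliable,
            n_windows_used=self.n_windows_used, retained_fraction=self.retained_fraction,
        )
        return row


def phase_hrv_summary(
    clean: CleanRRSeries,
    phase_duration: float | None = None,
    labels: dict | None = None,
    lfhf_ratio_of_means: bool = False,
) -> HrvPhaseSummary:
    """Compute the full per-phase summary.

    Time-domain indices span the whole phase; spectral indices and the
    respiration rate are means over accepted sliding windows. LF/HF is
    computed per window and then averaged; set ``lfhf_ratio_of_means`` to
    take the ratio of the averaged band powers instead.
    """
    from .respiration import estimate_respiration_rate

    if phase_duration is None:
        last = clean.onsets[-1] + clean.intervals[-1] / 1000.0
        phase_duration = float(last - clean.onsets[0])

    hr = mean_heart_rate(clean)
    sd = sdrr(clean)
    rm = rmssd(clean)

    hf_vals, lf_vals, ratio_vals = [], [], []
    n_used = 0
    try:
        grid = grade_windows(clean, build_window_grid(phase_duration, t0=float(clean.onsets[0])))
    except ValueError:
        grid = WindowGrid([])
    for w in grid.accepted_windows:
        try:
            _, tach = interpolate_rr_uniform(clean, w)
        except ValueError:
            w.accepted = False
            continue
        hf = welch_band_power(tach, HF_BAND)
        lf = welch_band_power(tach, LF_BAND)
        hf_vals.append(hf)
        lf_vals.append(lf)
        if hf > 0:
            ratio_vals.append(lf / hf)
        n_used += 1

    resp = estimate_respiration_rate(clean, grid) if n_used else None
    hf_mean = float(np.mean(hf_vals)) if hf_vals else None
    lf_mean = float(np.mean(lf_vals)) if lf_vals else None
    if lfhf_ratio_of_means:
        lfhf = lf_mean / hf_mean if hf_mean else None
    else:
        lfhf = float(np.mean(ratio_vals)) if ratio_vals else None
    return HrvPhaseSummary(
        hr=hr,
        sdrr=sd,
        rmssd=rm,
        hf=hf_mean,
        lf=lf_mean,
        lfhf=lfhf,
        resp_cpm=resp.rate_cpm if resp is not None and resp.reliable else None,
        resp_reliable=bool(resp.reliable) if resp is not None else False,
        n_windows_used=n_used,
        retained_fraction=clean.retained_fraction,
        labels=labels or {},
    )
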