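"""R-peak detection, RR-interval construction, and artifact deletion.

The detector is a Pan–Tompkins-style chain: band-pass around the QRS band,
differentiate, square, moving-window integrate, adaptive threshold with a
200 ms refractory period, then snap each detection to the local extremum of
the band-passed signal.

Artifact screening follows a deviation-deletion rule: any RR interval that
falls outside an absolute physiological range, or deviates by more than a
fraction from a running median, is flagged, and the flagged interval *and the
interval immediately following it* are removed. The retained fraction is
reported as retained time over total time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io import EcgRecording

__all__ = [
    "RPeakSeries",
    "RRSeries",
    "CleanRRSeries",
    "ArtifactRule",
    "detect_rpeaks",
    "rr_from_peaks",
    "reject_rr_artifacts",
    "mean_heart_rate",
]

REFRACTORY_S = 0.200


@dataclass
class RPeakSeries:
    """Detected R-peaks: times in seconds and 0-based sample indices."""

    peak_times: np.ndarray
    peak_indices: np.ndarray
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        if self.peak_times.size and np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return self.peak_times.size


@dataclass
class RRSeries:
    """RR intervals in ms with their onset times (the earlier peak) in seconds."""

    onsets: np.ndarray
    intervals: np.ndarray
    valid_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.onsets.shape != self.intervals.shape:
            raise ValueError("onsets and intervals must have equal length")
        if np.any(self.intervals <= 0):
            raise ValueError("intervals must be positive")
        if self.onsets.size > 1 and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.intervals.size, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)

    def __len__(self) -> int:
        return self.intervals.size

    @property
    def total_time_s(self) -> float:
        return float(self.intervals.sum() / 1000.0)


@dataclass
class CleanRRSeries:
    """An artifact-screened RR series.

    ``onsets``/``intervals`` keep the full original grid; ``valid_mask`` marks
    retained intervals and ``reasons`` carries a code per deleted interval
    ('range', 'median', 'post_deviant'). ``retained_fraction`` is retained
    time / total time.
    """

    onsets: np.ndarray
    intervals: np.ndarray
    valid_mask: np.ndarray
    reasons: dict
    retained_fraction: float
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return int(self.valid_mask.sum())

    @property
    def clean_intervals(self) -> np.ndarray:
        """Retained intervals, ms."""
        return self.intervals[self.valid_mask]

    @property
    def clean_onsets(self) -> np.ndarray:
        return self.onsets[self.valid_mask]

    def successive_diffs(self) -> np.ndarray:
        """Differences between adjacent retained intervals.

        A difference is formed only when both intervals are retained *and*
        adjacent on the original beat grid, so no difference spans a deleted
        interval.
        """
        m = self.valid_mask
        pair = m[:-1] & m[1:]
        return np.diff(self.intervals)[pair]


@dataclass(frozen=True)
class ArtifactRule:
    """Deviation rule: absolute range plus relative running-median criterion."""

    min_rr_ms: float = 300.0
    max_rr_ms: float = 2000.0
    max_rel_dev: float = 0.30
    median_window: int = 11  # beats, odd


def detect_rpeaks(rec: EcgRecording, min_rr_s: float = REFRACTORY_S) -> RPeakSeries:
    """Detect R-peaks on a preprocessed recording.

    Returns an empty series with ``flags['quality'] = 'flat_or_saturated'``
    when the signal carries no usable QRS energy.
    """
    fs = rec.sampling_rate
    x = rec.samples
    if x.size < int(fs):  # under a second of data
        return RPeakSeries(np.array([]), np.array([], int), {"quality": "too_short"})
    if np.ptp(x) == 0:
        return RPeakSeries(np.array([]), np.array([], int), {"quality": "flat_or_saturated"})

    # 1) band-pass to the QRS energy band
    sos = signal.butter(3, [5.0, min(15.0, 0.45 * fs)], btype="band", fs=fs, output="sos")
    bp = signal.sosfiltfilt(sos, x)
    # 2) derivative, 3) squaring, 4) moving-window integration (150 ms)
    deriv = np.gradient(bp)
    sq = deriv * deriv
    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    med = np.median(mwi)
    if med <= 0 or np.ptp(mwi) == 0:
        return RPeakSeries(np.array([]), np.array([], int), {"quality": "flat_or_saturated"})

    # adaptive threshold: blend of global and local (per 10 s block) levels
    thr = np.empty_like(mwi)
    block = int(10 * fs)
    for start in range(0, mwi.size, block):
        seg = mwi[start : start + block]
        thr[start : start + block] = 0.25 * np.max(seg) * 0.5 + 0.5 * np.mean(seg)
    candidates, _ = signal.find_peaks(mwi, height=np.maximum(thr, 1e-12), distance=int(min_rr_s * fs))
    if candidates.size == 0:
        return RPeakSeries(np.array([]), np.array([], int), {"quality": "no_peaks"})

    # snap each candidate to the R apex of the (preprocessed) waveform itself;
    # the integrator output lags the QRS, so search a generous neighbourhood.
    # Polarity comes from the median local extremum over candidate windows,
    # which is immune to filter edge transients.
    half = int(round(0.120 * fs))
    pos, neg = [], []
    for c in candidates:
        lo, hi = max(0, c - half), min(x.size, c + half + 1)
        pos.append(np.max(x[lo:hi]))
        neg.append(np.max(-x[lo:hi]))
    polarity = 1.0 if np.median(pos) >= np.median(neg) else -1.0
    peaks = []
    for c in candidates:
        lo, hi = max(0, c - half), min(x.size, c + half + 1)
        peaks.append(lo + int(np.argmax(polarity * x[lo:hi])))
    peaks = np.unique(peaks)
    # enforce refractory after snapping
    kept = [int(peaks[0])]
    for p in peaks[1:]:
        if (p - kept[-1]) / fs >= min_rr_s:
            kept.append(int(p))
        elif polarity * x[p] > polarity * x[kept[-1]]:
            kept[-1] = int(p)
    idx = np.asarray(kept, dtype=int)
    return RPeakSeries(rec.t0 + idx / fs, idx)


def rr_from_peaks(peaks: RPeakSeries) -> RRSeries:
    """Build the RR-interval series from detected peaks (interval i spans
    peak i to peak i+1; its onset is peak i)."""
    if len(peaks) < 2:
        raise ValueError("need at least two peaks to form RR intervals")
    t = peaks.peak_times
    return RRSeries(onsets=t[:-1], intervals=np.diff(t) * 1000.0)


def reject_rr_artifacts(rr: RRSeries, rule: ArtifactRule | None = None) -> CleanRRSeries:
    """Apply the deviation-deletion rule.

    An interval is deviant if it leaves ``[min_rr_ms, max_rr_ms]`` or deviates
    by more than ``max_rel_dev`` from the running median of the surrounding
    ``median_window`` beats. Every deviant interval and the one immediately
    following it are deleted. Raises when nothing survives.
    """
    rule = rule or ArtifactRule()
    x = rr.intervals
    n = x.size
    half = rule.median_window // 2
    run_med = np.array(
        [np.median(x[max(0, i - half) : min(n, i + half + 1)]) for i in range(n)]
    )
    deviant = (
        (x < rule.min_rr_ms)
        | (x > rule.max_rr_ms)
        | (np.abs(x - run_med) > rule.max_rel_dev * run_med)
    )
    valid = np.ones(n, dtype=bool)
    reasons: dict[int, str] = {}
    for i in np.flatnonzero(deviant):
        valid[i] = False
        reasons[i] = "range" if (x[i] < rule.min_rr_ms or x[i] > rule.max_rr_ms) else "median"
        if i + 1 < n and valid[i + 1]:
            valid[i + 1] = False
            reasons[i + 1] = "post_deviant"
    total = x.sum()
    retained = x[valid].sum() / total if total > 0 else 0.0
    if not valid.any():
        raise ValueError("all RR intervals flagged as artifacts; no data retained")
    out = CleanRRSeries(
        onsets=rr.onsets.copy(),
        intervals=x.copy(),
        valid_mask=valid,
        reasons=reasons,
        retained_fraction=float(retained),
        meta=dict(rr.meta),
    )
    if retained < 0.5:
        out.meta["quality_warning"] = f"retained fraction {retained:.1%} below 50%"
    return out


def mean_heart_rate(clean: CleanRRSeries) -> float:
    """Mean heart rate in bpm, computed as 60000 / mean(retained RR in ms)."""
    kept = clean.clean_intervals
    if kept.size == 0:
        raise ValueError("no retained intervals")
    return 60000.0 / float(kept.mean())
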