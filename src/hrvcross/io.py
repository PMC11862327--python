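"""Reading and writing single-lead ECG recordings.

Supported on-disk formats:

* two-column CSV (``time_s``, ``ecg_uv``) — native text format,
* EDF (read via :mod:`mne`; written by a minimal built-in single-channel
  EDF writer),
* WFDB format-16 single-channel records (minimal built-in reader/writer),
* BrainVision triplets (read via :mod:`mne`).

Samples are held in microvolts throughout the package. Session metadata
(subject, session, condition, side, phase) travels in :attr:`EcgRecording.meta`
and is populated from a sidecar manifest row when the file header cannot
carry it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EcgRecording",
    "read_ecg",
    "write_csv",
    "write_edf",
    "write_wfdb",
    "read_wfdb",
]


@dataclass
class EcgRecording:
    """A uniformly sampled single-lead ECG trace.

    Parameters
    ----------
    samples : ndarray
        Voltage samples in microvolts.
    sampling_rate : float
        Sampling frequency in Hz, > 0.
    t0 : float
        Time of the first sample in seconds.
    meta : dict
        Free-form labels; the study pipeline uses the keys
        ``subject``, ``session``, ``condition``, ``side``, ``phase``.
    """

    samples: np.ndarray
    sampling_rate: float
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.sampling_rate


# ---------------------------------------------------------------------------
# CSV

def _read_csv(path: Path) -> EcgRecording:
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "time_s" not in cols or "ecg_uv" not in cols:
        raise ValueError(f"{path}: CSV must have columns time_s, ecg_uv")
    t = df[cols["time_s"]].to_numpy(dtype=float)
    v = df[cols["ecg_uv"]].to_numpy(dtype=float)
    dt = np.diff(t)
    if t.size < 2 or np.any(dt <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    step = np.median(dt)
    if not np.allclose(dt, step, rtol=1e-3, atol=step * 1e-3):
        raise ValueError(f"{path}: time column is not uniformly sampled")
    return EcgRecording(v, sampling_rate=1.0 / step, t0=float(t[0]))


def write_csv(rec: EcgRecording, path: str | Path) -> Path:
    """Write a recording as a two-column CSV (time_s, ecg_uv)."""
    path = Path(path)
    pd.DataFrame({"time_s": rec.times, "ecg_uv": rec.samples}).to_csv(
        path, index=False
    )
    return path


# ---------------------------------------------------------------------------
# Minimal EDF writer (single channel).  Reading goes through mne.

def write_edf(rec: EcgRecording, path: str | Path) -> Path:
    """Write a single-channel EDF file.

    Uses 1-second data records and int16 quantization over the observed
    physical range, which is the resolution the format affords. The tail of
    the last partial second is zero-padded on disk; the true sample count is
    not recoverable from plain EDF, so round-trips are exact only for whole
    seconds of data.
    """
    path = Path(path)
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_records = int(np.ceil(rec.samples.size / fs))
    padded = np.zeros(n_records * fs)
    padded[: rec.samples.size] = rec.samples

    pmin, pmax = float(padded.min()), float(padded.max())
    if pmax <= pmin:  # flat signal: EDF needs a non-degenerate range
        pmax = pmin + 1.0
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.round((padded - pmin) / scale + dmin).astype("<i2")

    def pad(s: str, n: int) -> bytes:
        b = s.encode("ascii")[:n]
        return b + b" " * (n - len(b))

    header = b"".join(
        [
            pad("0", 8),  # version
            pad("X X X X", 80),  # patient id
            pad("Startdate X X X X", 80),  # recording id
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 + 256), 8),  # header bytes: fixed + 1 signal
            pad("", 44),
            pad(str(n_records), 8),
            pad("1", 8),  # record duration, seconds
            pad("1", 4),  # number of signals
            pad("ECG", 16),  # label
            pad("", 80),  # transducer
            pad("uV", 8),  # physical dimension
            pad(f"{pmin:.6g}", 8),
            pad(f"{pmax:.6g}", 8),
            pad(str(dmin), 8),
            pad(str(dmax), 8),
            pad("", 80),  # prefiltering
            pad(str(fs), 8),  # samples per record
            pad("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())
    return path


def _read_edf(path: Path) -> EcgRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data(picks=[0])[0] * 1e6  # mne holds volts
    return EcgRecording(data, sampling_rate=float(raw.info["sfreq"]))


def _read_brainvision(path: Path) -> EcgRecording:
    import mne

    raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    data = raw.get_data(picks=[0])[0] * 1e6
    return EcgRecording(data, sampling_rate=float(raw.info["sfreq"]))


# ---------------------------------------------------------------------------
# Minimal WFDB (format 16, single signal)

def write_wfdb(rec: EcgRecording, record_path: str | Path, adc_gain: float = 1000.0) -> Path:
    """Write a single-channel WFDB record (.hea + .dat, format 16).

    ``adc_gain`` is in ADC units per millivolt, the WFDB convention.
    Returns the path of the header file.
    """
    record_path = Path(record_path)
    if record_path.suffix:
        record_path = record_path.with_suffix("")
    name = record_path.name
    mv = rec.samples / 1000.0  # uV -> mV
    digital = np.clip(np.round(mv * adc_gain), -32768, 32767).astype("<i2")
    fs = rec.sampling_rate
    fs_str = f"{fs:g}"
    hea = (
        f"{name} 1 {fs_str} {digital.size}\n"
        f"{name}.dat 16 {adc_gain:g}(0)/mV 16 0 {digital[0]} 0 0 ECG\n"
    )
    record_path.parent.mkdir(parents=True, exist_ok=True)
    (record_path.parent / f"{name}.hea").write_text(hea)
    (record_path.parent / f"{name}.dat").write_bytes(digital.tobytes())
    return record_path.parent / f"{name}.hea"


def read_wfdb(path: str | Path) -> EcgRecording:
    """Read a single-channel format-16 WFDB record written by this package."""
    path = Path(path)
    if path.suffix:
        path = path.with_suffix("")
    hea = (path.parent / f"{path.name}.hea").read_text().splitlines()
    rec_line = hea[0].split()
    n_sig = int(rec_line[1])
    if n_sig != 1:
        raise ValueError("only single-signal WFDB records are supported")
    fs = float(rec_line[2])
    n_samp = int(rec_line[3])
    sig_line = hea[1].split()
    fmt = sig_line[1]
    if not fmt.startswith("16"):
        raise ValueError(f"unsupported WFDB format {fmt!r}; only 16 is supported")
    gain_field = sig_line[2]
    gain = float(gain_field.split("(")[0].split("/")[0])
    baseline = 0.0
    if "(" in gain_field:
        baseline = float(gain_field.split("(")[1].split(")")[0])
    raw = (path.parent / f"{path.name}.dat").read_bytes()
    digital = np.frombuffer(raw, dtype="<i2", count=n_samp).astype(float)
    mv = (digital - baseline) / gain
    return EcgRecording(mv * 1000.0, sampling_rate=fs)


# ---------------------------------------------------------------------------

_FORMAT_READERS = {
    "csv": _read_csv,
    "edf": _read_edf,
    "wfdb": read_wfdb,
    "brainvision": _read_brainvision,
}

_SUFFIX_FORMATS = {
    ".csv": "csv",
    ".edf": "edf",
    ".hea": "wfdb",
    ".dat": "wfdb",
    ".vhdr": "brainvision",
}


def read_ecg(
    path: str | Path,
    format: str | None = None,
    meta: dict | None = None,
) -> EcgRecording:
    """Read an ECG recording.

    Parameters
    ----------
    path : path-like
        File to read (for WFDB, either the .hea file or the record stem).
    format : {"csv", "edf", "wfdb", "brainvision"}, optional
        Explicit format; inferred from the suffix when omitted.
    meta : dict, optional
        Metadata (e.g. a manifest row) merged into the recording, filling
        labels the file header cannot carry.
    """
    path = Path(path)
    if format is None:
        format = _SUFFIX_FORMATS.get(path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer format from suffix {path.suffix!r}")
    fmt = format.lower()
    if fmt not in _FORMAT_READERS:
        raise ValueError(f"unknown format {format!r}")
    if fmt != "wfdb" and not path.exists():
        raise FileNotFoundError(path)
    rec = _FORMAT_READERS[fmt](path)
    if meta:
        rec.meta.update(meta)
    return rec
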