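"""Synthetic RR series, ECG waveforms, and full crossover study datasets.

The generator realizes a beat-to-beat RR process with known structure,

    RR(t) = mean_rr + lf_amp*sin(2*pi*lf_freq*t) + hf_amp*sin(2*pi*resp_freq*t) + e,

sampled at each beat onset (e is white Gaussian jitter), renders an ECG by
placing a QRS-like template at every beat, and assembles multi-session
study datasets in which condition effects on heart rate and HRV indices are
injected with known magnitude. Ground truth (beat times, generative
amplitudes, injected effects) is always returned, so detection, HRV
estimation, and inference can be scored exactly.

The LF modulator stands in for baroreflex-band rhythms (~0.1 Hz) and the HF
modulator for respiratory sinus arrhythmia at the respiration frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import EcgRecording
from .rpeaks import RRSeries

__all__ = [
    "RrSimConfig",
    "EcgSimConfig",
    "StudyDesign",
    "StudyDataset",
    "DEFAULT_EFFECTS",
    "generate_rr_series",
    "synthesize_ecg",
    "generate_study_dataset",
    "analytic_indices",
]

CONDITIONS = ("taVNS", "sham")
SIDES = ("left", "right")
PHASES = ("baseline", "stimulation", "caloric_load")


@dataclass(frozen=True)
class RrSimConfig:
    """Generative parameters of the beat-to-beat RR process.

    ``duration`` s of beats; ``mean_rr`` ms; sinusoidal modulation amplitudes
    ``lf_amp``/``hf_amp`` (ms) at ``lf_freq``/``resp_freq`` (Hz); white RR
    jitter ``broadband_sd`` (ms).
    """

    duration: float = 1800.0
    mean_rr: float = 850.0
    lf_amp: float = 30.0
    lf_freq: float = 0.1
    hf_amp: float = 45.0
    resp_freq: float = 0.25
    broadband_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if min(self.lf_amp, self.hf_amp, self.broadband_sd) < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.mean_rr <= 2 * (self.lf_amp + self.hf_amp):
            raise ValueError(
                "mean_rr must exceed 2*(lf_amp + hf_amp) to keep RR positive"
            )
        if not (0.15 <= self.resp_freq <= 0.4):
            raise ValueError("resp_freq must lie within [0.15, 0.4] Hz")


@dataclass(frozen=True)
class EcgSimConfig:
    """Waveform-level parameters: QRS template and additive disturbances."""

    sampling_rate: float = 5000.0
    qrs_amplitude: float = 800.0  # uV
    qrs_width: float = 0.080  # s, total template support
    powerline_amp: float = 20.0  # uV at 50 Hz
    baseline_wander_amp: float = 100.0  # uV below 0.5 Hz
    artifact_rate: float = 0.0  # events per minute
    artifact_amp: float = 1500.0  # uV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate < 250:
            raise ValueError("sampling_rate must be at least 250 Hz to resolve QRS")
        for name in ("qrs_amplitude", "powerline_amp", "baseline_wander_amp",
                     "artifact_rate", "artifact_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# Default injected effects, additive on each index relative to the session
# baseline phase: stimulation lowers HR slightly in both conditions, the
# caloric load raises it, and taVNS (vs. sham) lowers RMSSD/SDRR/HF during
# stimulation and after the load. Magnitudes are in the range reported for
# auricular stimulation crossover studies. Condition "*" applies to both.
DEFAULT_EFFECTS: dict[tuple[str, str, str], float] = {
    ("hr", "*", "stimulation"): -0.8,
    ("hr", "*", "caloric_load"): 3.3,
    ("rmssd", "taVNS", "stimulation"): -4.0,
    ("rmssd", "taVNS", "caloric_load"): -5.0,
    ("sdrr", "taVNS", "stimulation"): -5.0,
    ("sdrr", "taVNS", "caloric_load"): -5.0,
    ("hf", "taVNS", "stimulation"): -175.0,
    ("hf", "taVNS", "caloric_load"): -270.0,
}


@dataclass(frozen=True)
class StudyDesign:
    """2 (condition) x 2 (side) x 3 (phase) within-subject layout.

    Each subject completes 4 sessions (condition x side); the stimulated side
    stays fixed across sessions 1-2 and flips for sessions 3-4, mirroring the
    randomization rule of a counterbalanced crossover. ``effect_table`` maps
    (index, condition, phase) to an additive shift of that index relative to
    the same session's baseline phase; condition "*" matches both conditions.
    Supported indices: "hr" (bpm), "rmssd" (ms), "sdrr" (ms), "hf" (ms^2).
    """

    n_subjects: int = 36
    effect_table: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    between_subject_cv: float = 0.15
    mean_rr_sd: float = 60.0  # ms, between-subject spread of mean RR
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for (index, cond, phase) in self.effect_table:
            if index not in ("hr", "rmssd", "sdrr", "hf"):
                raise ValueError(f"unsupported index {index!r} in effect_table")
            if cond not in CONDITIONS and cond != "*":
                raise ValueError(f"unknown condition {cond!r}")
            if phase not in ("stimulation", "caloric_load"):
                raise ValueError(f"effects apply to post-baseline phases, got {phase!r}")


# ---------------------------------------------------------------------------
# RR realization

def _realize_beats(cfg: RrSimConfig, rng: np.random.Generator):
    """Beat-by-beat realization of the modulated RR process."""
    n_max = int(cfg.duration * 1000.0 / max(cfg.mean_rr - 2 * (cfg.lf_amp + cfg.hf_amp), 1.0)) + 16
    noise = rng.normal(0.0, cfg.broadband_sd, n_max) if cfg.broadband_sd > 0 else np.zeros(n_max)
    w_lf = 2.0 * math.pi * cfg.lf_freq
    w_hf = 2.0 * math.pi * cfg.resp_freq
    mean, a_lf, a_hf = cfg.mean_rr, cfg.lf_amp, cfg.hf_amp
    onsets, intervals = [], []
    t = 0.0
    i = 0
    while t < cfg.duration:
        rr = mean + a_lf * math.sin(w_lf * t) + a_hf * math.sin(w_hf * t) + noise[i]
        if rr <= 0:
            raise ValueError(
                "configuration produced a non-positive RR interval; reduce "
                "modulation amplitudes or broadband_sd"
            )
        onsets.append(t)
        intervals.append(rr)
        t += rr / 1000.0
        i += 1
    if not intervals:
        raise ValueError("duration too short to produce a single beat")
    return np.asarray(onsets), np.asarray(intervals)


_HF_BW = 0.40 - 0.15  # Hz
_LF_BW = 0.15 - 0.04


def analytic_indices(cfg: RrSimConfig) -> dict:
    """Expected HR/SDRR/RMSSD/HF/LF of the generative process.

    SDRR adds the component variances; RMSSD uses the variance of first
    differences of a sinusoid sampled at the mean beat period
    (amplitude 2*A*sin(pi*f*rbar)). Band powers combine the sinusoid power
    A²/2 with the broadband jitter's in-band contribution: white beat-level
    noise of variance σ² spreads a flat tachogram PSD of 2σ²·rbar (ms²/Hz)
    up to the beat Nyquist, contributing 2σ²·rbar·bandwidth to each band.
    """
    rbar = cfg.mean_rr / 1000.0
    k_hf = 2.0 * math.sin(math.pi * cfg.resp_freq * rbar) ** 2
    k_lf = 2.0 * math.sin(math.pi * cfg.lf_freq * rbar) ** 2
    floor = 2.0 * cfg.broadband_sd**2 * rbar  # flat tachogram PSD, ms²/Hz
    return {
        "hr": 60000.0 / cfg.mean_rr,
        "sdrr": math.sqrt(cfg.lf_amp**2 / 2 + cfg.hf_amp**2 / 2 + cfg.broadband_sd**2),
        "rmssd": math.sqrt(
            2 * cfg.broadband_sd**2 + k_hf * cfg.hf_amp**2 + k_lf * cfg.lf_amp**2
        ),
        "hf": cfg.hf_amp**2 / 2 + floor * _HF_BW,
        "lf": cfg.lf_amp**2 / 2 + floor * _LF_BW,
        "resp_cpm": 60.0 * cfg.resp_freq,
    }


def generate_rr_series(config: RrSimConfig) -> RRSeries:
    """Generate a seeded RR-interval series.

    The returned series carries the generative configuration and its analytic
    index values in ``meta['truth']``.
    """
    rng = np.random.default_rng(config.seed)
    onsets, intervals = _realize_beats(config, rng)
    truth = {"config": config, **analytic_indices(config)}
    return RRSeries(onsets=onsets, intervals=intervals, meta={"truth": truth})


# ---------------------------------------------------------------------------
# ECG synthesis

def _qrs_template(fs: float, width: float) -> np.ndarray:
    """Symmetric Mexican-hat (Gaussian second-derivative) QRS stand-in.

    Peaks at its center, with the two negative side lobes playing Q and S.
    """
    sigma = width / 6.0
    t = np.arange(-width / 2, width / 2 + 1.0 / fs, 1.0 / fs)
    return (1.0 - (t / sigma) ** 2) * np.exp(-(t**2) / (2 * sigma**2))


def synthesize_ecg(rr: RRSeries, config: EcgSimConfig | None = None):
    """Render an ECG from an RR series.

    Returns ``(recording, true_peak_times)``; one template per beat, centered
    at the cumulative beat times, plus 50 Hz mains, slow baseline wander, and
    optional 1-3 s saturating artifact segments.
    """
    config = config or EcgSimConfig()
    if len(rr) == 0:
        raise ValueError("RR series has no beats; cannot synthesize a recording")
    fs = config.sampling_rate
    # peak times: every interval onset plus the closing beat of the last interval
    peak_times = np.concatenate([rr.onsets, [rr.onsets[-1] + rr.intervals[-1] / 1000.0]])
    duration = peak_times[-1] + 0.5
    n = int(round(duration * fs))
    x = np.zeros(n)

    template = _qrs_template(fs, config.qrs_width) * config.qrs_amplitude
    half = template.size // 2
    for tp in peak_times:
        c = int(round(tp * fs))
        lo, hi = c - half, c - half + template.size
        s0, s1 = max(lo, 0), min(hi, n)
        x[s0:s1] += template[s0 - lo : template.size - (hi - s1)]

    rng = np.random.default_rng(config.seed)
    t = np.arange(n) / fs
    if config.powerline_amp > 0:
        x += config.powerline_amp * np.sin(2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
    if config.baseline_wander_amp > 0:
        for f_w, a_w in ((rng.uniform(0.05, 0.15), 1.0), (rng.uniform(0.15, 0.33), 0.5)):
            x += a_w * config.baseline_wander_amp * np.sin(
                2 * np.pi * f_w * t + rng.uniform(0, 2 * np.pi)
            )
    if config.artifact_rate > 0 and config.artifact_amp > 0:
        n_events = rng.poisson(config.artifact_rate * duration / 60.0)
        for _ in range(n_events):
            start = rng.uniform(0, max(duration - 3.0, 0.0))
            length = rng.uniform(1.0, 3.0)
            sign = rng.choice([-1.0, 1.0])
            i0, i1 = int(start * fs), min(int((start + length) * fs), n)
            x[i0:i1] = sign * config.artifact_amp  # saturated segment

    rec = EcgRecording(x, sampling_rate=fs, meta={"synthetic": True})
    return rec, peak_times


# ---------------------------------------------------------------------------
# Study-level generation

def _effect(table: dict, index: str, condition: str, phase: str) -> float:
    return table.get((index, condition, phase), 0.0) + table.get((index, "*", phase), 0.0)


def _specified(table: dict, index: str, condition: str, phase: str) -> bool:
    return (index, condition, phase) in table or (index, "*", phase) in table


def _solve_phase_config(
    base: RrSimConfig, design: StudyDesign, condition: str, phase: str, seed: int,
    n_iter: int = 8,
) -> RrSimConfig:
    """Parameters whose analytic indices equal the baseline values plus the
    injected effects for (condition, phase).

    Only parameters tied to indices present in the effect table are touched:
    HR sets the mean beat period, HF band power sets hf_amp, RMSSD sets the
    broadband jitter, SDRR sets lf_amp. Because the equations couple (the
    jitter contributes to the HF band; the amplitudes enter RMSSD/SDRR),
    they are iterated to a joint fixed point.
    """
    table = design.effect_table
    if phase == "baseline":
        return replace(base, seed=seed)
    ref = analytic_indices(base)

    mean_rr = base.mean_rr
    if _specified(table, "hr", condition, phase):
        hr = ref["hr"] + _effect(table, "hr", condition, phase)
        if hr <= 0:
            raise ValueError("HR effect drives heart rate non-positive")
        mean_rr = 60000.0 / hr

    rbar = mean_rr / 1000.0
    k_hf = 2.0 * math.sin(math.pi * base.resp_freq * rbar) ** 2
    k_lf = 2.0 * math.sin(math.pi * base.lf_freq * rbar) ** 2

    do_hf = _specified(table, "hf", condition, phase)
    do_rmssd = _specified(table, "rmssd", condition, phase)
    do_sdrr = _specified(table, "sdrr", condition, phase)
    hf_t = ref["hf"] + _effect(table, "hf", condition, phase)
    rmssd_t = ref["rmssd"] + _effect(table, "rmssd", condition, phase)
    sdrr_t = ref["sdrr"] + _effect(table, "sdrr", condition, phase)
    if (do_hf and hf_t < 0) or (do_rmssd and rmssd_t <= 0) or (do_sdrr and sdrr_t <= 0):
        raise ValueError("effect table drives an index out of range")

    hf_amp, sd, lf_amp = base.hf_amp, base.broadband_sd, base.lf_amp
    for _ in range(n_iter):
        if do_hf:
            hf2 = 2.0 * (hf_t - 2.0 * sd**2 * rbar * _HF_BW)
            if hf2 < 0:
                raise ValueError("HF effect not realizable below the broadband floor")
            hf_amp = math.sqrt(hf2)
        if do_rmssd:
            if do_hf:
                # hf_amp is pinned by the HF target; absorb RMSSD in the jitter
                var2 = rmssd_t**2 - k_hf * hf_amp**2 - k_lf * lf_amp**2
                if var2 < 0:
                    raise ValueError("RMSSD effect not realizable with the current "
                                     "HF/LF amplitudes")
                sd = math.sqrt(var2 / 2.0)
            else:
                # scale all variability sources jointly: RMSSD is homogeneous
                # of degree one in (sd, hf_amp, lf_amp), so this is exact
                cur = math.sqrt(2 * sd**2 + k_hf * hf_amp**2 + k_lf * lf_amp**2)
                gamma = rmssd_t / cur
                sd, hf_amp, lf_amp = gamma * sd, gamma * hf_amp, gamma * lf_amp
        if do_sdrr:
            lf2 = 2.0 * (sdrr_t**2 - sd**2 - hf_amp**2 / 2.0)
            if lf2 < 0:
                raise ValueError("SDRR effect not realizable with the current "
                                 "jitter/HF power")
            lf_amp = math.sqrt(lf2)

    cfg = replace(base, mean_rr=mean_rr, hf_amp=hf_amp, broadband_sd=sd,
                  lf_amp=lf_amp, seed=seed)
    if cfg.mean_rr <= 2 * (cfg.lf_amp + cfg.hf_amp):
        raise ValueError("effect table drives RR non-positive")
    return cfg


@dataclass
class StudyDataset:
    """One generated study: a tidy manifest plus per-phase RR/ECG data.

    ``manifest`` has one row per subject x session x phase with the key
    ``(subject, session, condition, side, phase)``; ``rr`` maps that key to
    the generated :class:`RRSeries`, and when ECG was rendered, ``files``
    maps it to the written record path and ``true_peaks`` to the exact beat
    times. ``ground_truth`` holds the injected effect table and the per-phase
    generative index values.
    """

    manifest: pd.DataFrame
    rr: dict
    ground_truth: dict
    files: dict = field(default_factory=dict)
    true_peaks: dict = field(default_factory=dict)


def _session_plan(design: StudyDesign, rng: np.random.Generator):
    """Four sessions per subject: side fixed across sessions 1-2, flipped for
    3-4; condition order randomized within each side pair."""
    first_side = SIDES[rng.integers(2)]
    other = SIDES[1 - SIDES.index(first_side)]
    plan = []
    for block, side in enumerate((first_side, other)):
        order = list(CONDITIONS) if rng.integers(2) == 0 else list(CONDITIONS[::-1])
        for j, cond in enumerate(order):
            plan.append((2 * block + j + 1, cond, side))
    return plan


def generate_study_dataset(
    design: StudyDesign | None = None,
    rr_cfg: RrSimConfig | None = None,
    ecg_cfg: EcgSimConfig | None = None,
    signal: str = "rr",
    out_dir=None,
    file_format: str = "wfdb",
) -> StudyDataset:
    """Generate a full crossover dataset with known condition effects.

    ``signal="rr"`` keeps RR series in memory (fast; sufficient for HRV and
    inference); ``signal="ecg"`` additionally renders ECG waveforms and, if
    ``out_dir`` is given, writes one record per phase plus ``manifest.csv``
    and ``ground_truth.json``.
    """
    from pathlib import Path

    design = design or StudyDesign()
    rr_cfg = rr_cfg or RrSimConfig()
    ecg_cfg = ecg_cfg or EcgSimConfig()
    if signal not in ("rr", "ecg"):
        raise ValueError("signal must be 'rr' or 'ecg'")

    root = np.random.SeedSequence(design.seed)
    rows, rr_map, files, peaks_map = [], {}, {}, {}
    truth_phases = {}
    subject_seeds = root.spawn(design.n_subjects)

    for s in range(design.n_subjects):
        subj = f"S{s + 1:03d}"
        s_rng = np.random.default_rng(subject_seeds[s])
        cv = design.between_subject_cv
        base = replace(
            rr_cfg,
            mean_rr=float(s_rng.normal(rr_cfg.mean_rr, design.mean_rr_sd)),
            lf_amp=float(rr_cfg.lf_amp * max(0.2, 1 + cv * s_rng.standard_normal())),
            hf_amp=float(rr_cfg.hf_amp * max(0.2, 1 + cv * s_rng.standard_normal())),
            broadband_sd=float(rr_cfg.broadband_sd * max(0.2, 1 + cv * s_rng.standard_normal())),
            resp_freq=float(np.clip(s_rng.normal(rr_cfg.resp_freq, 0.03), 0.15, 0.4)),
        )
        for session, condition, side in _session_plan(design, s_rng):
            for phase in PHASES:
                seed = int(s_rng.integers(2**31 - 1))
                cfg = _solve_phase_config(base, design, condition, phase, seed)
                rr = generate_rr_series(cfg)
                key = (subj, session, condition, side, phase)
                rr_map[key] = rr
                truth_phases[key] = {
                    k: v for k, v in rr.meta["truth"].items() if k != "config"
                }
                row = {
                    "subject": subj, "session": session, "condition": condition,
                    "side": side, "phase": phase, "seed": seed,
                }
                if signal == "ecg":
                    ecg, true_peaks = synthesize_ecg(
                        rr, replace(ecg_cfg, seed=seed)
                    )
                    ecg.meta.update(row)
                    peaks_map[key] = true_peaks
                    if out_dir is not None:
                        out = Path(out_dir)
                        out.mkdir(parents=True, exist_ok=True)
                        stem = out / f"{subj}_ses{session}_{phase}"
                        from . import io as _io

                        if file_format == "wfdb":
                            path = _io.write_wfdb(ecg, stem)
                        elif file_format == "edf":
                            path = _io.write_edf(ecg, stem.with_suffix(".edf"))
                        elif file_format == "csv":
                            path = _io.write_csv(ecg, stem.with_suffix(".csv"))
                        else:
                            raise ValueError(f"unknown file_format {file_format!r}")
                        files[key] = path
                        row["file"] = str(path)
                    else:
                        files[key] = ecg
                rows.append(row)

    manifest = pd.DataFrame(rows)
    ground_truth = {
        "effect_table": {"|".join(k): v for k, v in design.effect_table.items()},
        "phase_indices": {"|".join(map(str, k)): v for k, v in truth_phases.items()},
        "seed": design.seed,
    }
    if signal == "ecg" and out_dir is not None:
        import json

        out = Path(out_dir)
        manifest.to_csv(out / "manifest.csv", index=False)
        (out / "ground_truth.json").write_text(json.dumps(ground_truth, indent=1))
    return StudyDataset(
        manifest=manifest, rr=rr_map, ground_truth=ground_truth,
        files=files, true_peaks=peaks_map,
    )
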