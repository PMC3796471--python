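"""Calibration-referenced sound pressure level measurement.

Recordings are mapped to absolute SPL (dB re 20 μPa) through the embedded
calibration tone of known level (94 dB at 1 kHz): the offset added to digital
dB-full-scale levels is ``reference_spl − 20·log10(RMS_digital)`` of the
calibration segment. Per-segment RMS and peak SPLs, band-matched
signal-to-noise ratios and 15-s background-noise statistics follow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signals import (PlaybackSchedule, Segment, Waveform, label_frequency,
                      label_individual, label_species)

DEFAULT_SNR_THRESHOLD_DB = 6.0
CLIP_LEVEL = 0.999
CLIP_FRACTION = 0.01
EDGE_TRIM_S = 0.005  # skip the 5-ms synthesis ramps
CALL_BAND_HZ = (200.0, 5000.0)
THIRD_OCTAVE = 2.0 ** (1.0 / 6.0)  # half-width factor of a 1/3-octave band


@dataclass
class CalibrationResult:
    offset: float  # dB: digital dBFS -> dB SPL
    cal_segments_used: int
    drift: float  # dB between start and end calibration tones
    drift_warning: bool = False


@dataclass
class MeasurementRecord:
    locality: str
    substrate: str
    distance: float
    signal_id: str
    kind: str
    spl_rms: float
    spl_peak: float
    snr: float
    valid: bool
    flags: str = ""


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x))))


def _trim(x: np.ndarray, fs: int) -> np.ndarray:
    n = int(round(EDGE_TRIM_S * fs))
    return x[n:-n] if len(x) > 2 * n else x


def band_rms(x: np.ndarray, fs: int, f_lo: float, f_hi: float) -> float:
    """RMS of the component of ``x`` within [f_lo, f_hi], via the FFT power
    in the band (Parseval)."""
    n = len(x)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    power = np.abs(spec) ** 2
    # one-sided scaling: interior bins count twice
    scale = np.full(len(power), 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    mask = (freqs >= f_lo) & (freqs <= f_hi)
    return float(np.sqrt(np.sum(power[mask] * scale[mask]) / n**2))


def calibrate(recording: Waveform, schedule: PlaybackSchedule,
              reference_spl: float = 94.0,
              drift_tolerance: float = 1.0) -> CalibrationResult:
    """Offset mapping digital dBFS to dB SPL from the calibration segments.

    With two segments (transect start and end) the two offsets are averaged
    in dB and their difference reported as drift; drift beyond the tolerance
    raises a warning flag but does not fail.
    """
    segs = schedule.by_kind("calibration")
    if not segs:
        raise ValueError("no calibration segment in schedule")
    offsets = []
    for seg in segs:
        x = _trim(recording.segment(seg), recording.sample_rate)
        offsets.append(reference_spl - 20.0 * np.log10(_rms(x)))
    drift = float(max(offsets) - min(offsets)) if len(offsets) > 1 else 0.0
    return CalibrationResult(offset=float(np.mean(offsets)),
                             cal_segments_used=len(offsets),
                             drift=drift,
                             drift_warning=drift > drift_tolerance)


def _noise_band_rms(recording: Waveform, schedule: PlaybackSchedule,
                    f_lo: float, f_hi: float) -> float | None:
    noise_segs = schedule.by_kind("background_noise")
    if not noise_segs:
        return None
    x = recording.segment(noise_segs[0])
    return band_rms(x, recording.sample_rate, f_lo, f_hi)


def measure_spl(recording: Waveform, schedule: PlaybackSchedule,
                calibration: CalibrationResult, segment_label: str,
                *, snr_threshold: float = DEFAULT_SNR_THRESHOLD_DB,
                locality: str = "", substrate: str = "",
                distance: float = float("nan")) -> MeasurementRecord:
    """SPL of one scheduled segment.

    RMS is taken over the segment minus its 5-ms edge ramps. SNR compares
    the segment's band-matched level against the recording's background-noise
    segment: a ±1/3-octave band around the tone frequency for tones, the
    0.2–5 kHz band otherwise. Clipped segments (≥0.1% full scale margin for
    >1% of samples) are flagged invalid.
    """
    seg = schedule.find(segment_label)
    fs = recording.sample_rate
    raw = recording.segment(seg)
    x = _trim(raw, fs)
    spl_rms = 20.0 * np.log10(max(_rms(x), 1e-300)) + calibration.offset
    spl_peak = 20.0 * np.log10(max(np.max(np.abs(x)), 1e-300)) + calibration.offset

    freq = label_frequency(seg.label)
    if freq is not None:
        f_lo, f_hi = freq / THIRD_OCTAVE, freq * THIRD_OCTAVE
    else:
        f_lo, f_hi = CALL_BAND_HZ
    noise_rms = _noise_band_rms(recording, schedule, f_lo, f_hi)
    if noise_rms is None or noise_rms <= 0:
        snr = float("inf")
    else:
        sig_band = band_rms(x, fs, f_lo, f_hi)
        snr = 20.0 * np.log10(max(sig_band, 1e-300) / noise_rms)

    flags = []
    clipped = np.mean(np.abs(raw) >= CLIP_LEVEL) > CLIP_FRACTION
    if clipped:
        flags.append("clipped")
    valid = (snr >= snr_threshold) and not clipped
    if snr < snr_threshold:
        flags.append("low_snr")
    return MeasurementRecord(locality=locality, substrate=substrate,
                             distance=distance, signal_id=seg.label,
                             kind=seg.kind, spl_rms=float(spl_rms),
                             spl_peak=float(spl_peak), snr=float(snr),
                             valid=bool(valid), flags=";".join(flags))


def background_noise_stats(noise: np.ndarray, sample_rate: int,
                           calibration: CalibrationResult,
                           window: float = 15.0):
    """Maximum per-window RMS and peak SPL of a background-noise segment,
    over consecutive windows (default 15 s). A segment shorter than one
    window is evaluated as a single truncated window and flagged."""
    n_win = int(round(window * sample_rate))
    truncated = len(noise) < n_win
    if truncated:
        windows = [noise]
    else:
        n_full = len(noise) // n_win
        windows = [noise[i * n_win:(i + 1) * n_win] for i in range(n_full)]
    rms_spls = [20.0 * np.log10(max(_rms(w), 1e-300)) + calibration.offset
                for w in windows]
    peak_spls = [20.0 * np.log10(max(np.max(np.abs(w)), 1e-300))
                 + calibration.offset for w in windows]
    return {"max_rms_spl": float(max(rms_spls)),
            "max_peak_spl": float(max(peak_spls)),
            "n_windows": len(windows), "truncated": truncated}


def measure_recording(recording: Waveform, schedule: PlaybackSchedule,
                      *, locality: str = "", substrate: str = "",
                      distance: float = float("nan"),
                      reference_spl: float = 94.0,
                      snr_threshold: float = DEFAULT_SNR_THRESHOLD_DB,
                      kinds: tuple[str, ...] = ("tone", "call", "white_noise")
                      ) -> pd.DataFrame:
    """Measure every signal segment of one recording; one row per segment."""
    cal = calibrate(recording, schedule, reference_spl)
    rows = []
    for seg in schedule:
        if seg.kind not in kinds:
            continue
        rec = measure_spl(recording, schedule, cal, seg.label,
                          snr_threshold=snr_threshold, locality=locality,
                          substrate=substrate, distance=distance)
        row = rec.__dict__.copy()
        row["frequency_hz"] = label_frequency(seg.label)
        row["species"] = label_species(seg.label)
        row["individual"] = label_individual(seg.label)
        row["cal_offset"] = cal.offset
        row["cal_drift"] = cal.drift
        rows.append(row)
    return pd.DataFrame(rows)


def measure_transect(dataset, *, reference_spl: float = 94.0,
                     snr_threshold: float = DEFAULT_SNR_THRESHOLD_DB
                     ) -> pd.DataFrame:
    """Measurement table for a full TransectDataset (all distances)."""
    frames = []
    for d, (wav, sched) in sorted(dataset.recordings.items()):
        frames.append(measure_recording(
            wav, sched, locality=dataset.scenario.locality,
            substrate=dataset.scenario.substrate, distance=d,
            reference_spl=reference_spl, snr_threshold=snr_threshold))
    return pd.concat(frames, ignore_index=True)
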