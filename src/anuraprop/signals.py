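"""Playback-stimulus synthesis.

Builds the broadcast program used in the propagation experiments: a series of
29 pure tones (0.2–5 kHz), synthetic advertisement calls for a native and an
invasive ranid frog, a white-noise burst, and a 1-kHz broadcast-level
reference tone, assembled into a single peak-normalized mono waveform with a
segment schedule.

The synthetic calls are stand-ins for field recordings that are not publicly
archived: they reproduce the dominant frequency, duration, harmonic content
and amplitude-modulation envelope of the real calls but make no attempt to
imitate fine pulse structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.io import wavfile

log = logging.getLogger(__name__)

DEFAULT_SAMPLE_RATE = 44100

#: Species parameters for the synthetic advertisement calls: dominant
#: frequency (Hz) and call duration (ms) of the playback calls, and the
#: number of individuals included in the broadcast program.
NATIVE_SPECIES = "Pelophylax perezi"
INVASIVE_SPECIES = "Lithobates catesbeianus"
SPECIES_TAGS = {NATIVE_SPECIES: "Pp", INVASIVE_SPECIES: "Lc"}
TAG_SPECIES = {v: k for k, v in SPECIES_TAGS.items()}


@dataclass(frozen=True)
class ToneSpec:
    """A pure-tone segment of the broadcast program."""

    frequency: float  # Hz, within the 200–5000 Hz probe range
    duration: float = 0.5  # s
    peak_amplitude: float = 1.0  # fraction of digital full scale

    def __post_init__(self) -> None:
        if not 200.0 <= self.frequency <= 5000.0:
            raise ValueError(f"tone frequency {self.frequency} Hz outside [200, 5000]")
        if self.duration <= 0:
            raise ValueError("tone duration must be positive")
        if not 0.0 < self.peak_amplitude <= 1.0:
            raise ValueError("peak_amplitude must be in (0, 1]")


@dataclass(frozen=True)
class CallSpec:
    """Parameters of a synthetic advertisement call.

    ``dominant_frequency`` is realized as the strongest partial of a harmonic
    stack; ``am_rate`` sets the raised-cosine amplitude-modulation envelope
    that gives the call its pulsatile character.
    """

    species_label: str
    dominant_frequency: float  # Hz
    duration_ms: float
    secondary_band: float | None = None  # Hz, optional weaker spectral band
    harmonic_count: int = 5
    am_rate: float = 50.0  # Hz
    n_calls: int = 6  # renditions per individual in the playback

    def __post_init__(self) -> None:
        if self.dominant_frequency <= 0:
            raise ValueError("dominant_frequency must be positive")
        if self.duration_ms <= 0:
            raise ValueError("duration must be positive")
        if self.harmonic_count < 1:
            raise ValueError("harmonic_count must be >= 1")


#: Default call specs for the two study species (mean dominant frequency and
#: mean duration of the broadcast calls).
NATIVE_CALL = CallSpec(NATIVE_SPECIES, dominant_frequency=2678.0, duration_ms=430.0,
                       harmonic_count=4, am_rate=45.0)
INVASIVE_CALL = CallSpec(INVASIVE_SPECIES, dominant_frequency=1405.0, duration_ms=641.0,
                         secondary_band=500.0, harmonic_count=5, am_rate=30.0)

N_NATIVE_INDIVIDUALS = 7
N_INVASIVE_INDIVIDUALS = 6


@dataclass(frozen=True)
class Segment:
    label: str
    onset: float  # s
    duration: float  # s
    kind: str  # tone | call | white_noise | broadcast_ref | calibration | background_noise


@dataclass
class PlaybackSchedule:
    """Ordered, non-overlapping segment index into a recording."""

    segments: list[Segment] = field(default_factory=list)

    def add(self, label: str, onset: float, duration: float, kind: str) -> None:
        self.segments.append(Segment(label, onset, duration, kind))

    def validate(self) -> None:
        last_end = -np.inf
        last_onset = -np.inf
        for seg in self.segments:
            if seg.onset <= last_onset:
                raise ValueError(f"segment onsets not strictly increasing at {seg.label}")
            if seg.onset < last_end - 1e-9:
                raise ValueError(f"segment {seg.label} overlaps its predecessor")
            last_onset = seg.onset
            last_end = seg.onset + seg.duration

    def __iter__(self):
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    def find(self, label: str) -> Segment:
        for seg in self.segments:
            if seg.label == label:
                return seg
        raise KeyError(f"no segment labelled {label!r}")

    def by_kind(self, kind: str) -> list[Segment]:
        return [s for s in self.segments if s.kind == kind]

    def shifted(self, offset: float) -> "PlaybackSchedule":
        return PlaybackSchedule(
            [replace(s, onset=s.onset + offset) for s in self.segments])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"label": s.label, "onset_s": s.onset, "duration_s": s.duration,
              "kind": s.kind} for s in self.segments])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PlaybackSchedule":
        df = pd.read_csv(path)
        return cls([Segment(r.label, float(r.onset_s), float(r.duration_s), r.kind)
                    for r in df.itertuples()])


@dataclass
class Waveform:
    """Mono audio: dimensionless amplitude (|x| <= 1 at full scale) + rate."""

    samples: np.ndarray
    sample_rate: int = DEFAULT_SAMPLE_RATE

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    def segment(self, seg: Segment) -> np.ndarray:
        i0 = int(round(seg.onset * self.sample_rate))
        i1 = int(round((seg.onset + seg.duration) * self.sample_rate))
        return self.samples[i0:i1]

    def write_wav(self, path) -> None:
        """Write PCM 16-bit mono WAV (values clipped to full scale)."""
        x = np.clip(self.samples, -1.0, 1.0)
        wavfile.write(path, self.sample_rate, (x * 32767.0).astype(np.int16))

    @classmethod
    def read_wav(cls, path) -> "Waveform":
        rate, data = wavfile.read(path)
        if data.ndim > 1:
            data = data[:, 0]
        if data.dtype == np.int16:
            x = data.astype(np.float64) / 32767.0
        else:
            x = data.astype(np.float64)
        return cls(x, int(rate))


def _raised_cosine_ramps(n: int, sample_rate: int, ramp: float = 0.005) -> np.ndarray:
    """Unit envelope with raised-cosine onset/offset ramps (default 5 ms)."""
    env = np.ones(n)
    nr = min(int(round(ramp * sample_rate)), n // 2)
    if nr > 0:
        r = 0.5 * (1.0 - np.cos(np.pi * np.arange(nr) / nr))
        env[:nr] = r
        env[-nr:] = r[::-1]
    return env


def generate_tone_schedule() -> list[ToneSpec]:
    """The 29-tone probe series: 200–2400 Hz in 100-Hz steps (23 tones) then
    2500–5000 Hz in 500-Hz steps (6 tones), each 0.5 s."""
    freqs = np.concatenate([np.arange(200, 2500, 100), np.arange(2500, 5001, 500)])
    return [ToneSpec(float(f)) for f in freqs]


def synth_tone(spec: ToneSpec, sample_rate: int = DEFAULT_SAMPLE_RATE) -> Waveform:
    """Sine at ``spec.frequency`` with 5-ms raised-cosine ramps."""
    if spec.frequency >= sample_rate / 2:
        raise ValueError(
            f"tone frequency {spec.frequency} Hz at or above Nyquist "
            f"({sample_rate / 2} Hz)")
    n = int(round(spec.duration * sample_rate))
    t = np.arange(n) / sample_rate
    x = np.sin(2 * np.pi * spec.frequency * t) * _raised_cosine_ramps(n, sample_rate)
    peak = np.max(np.abs(x))
    return Waveform(x / peak * spec.peak_amplitude, sample_rate)


def synth_call(spec: CallSpec, sample_rate: int = DEFAULT_SAMPLE_RATE,
               seed: int = 0) -> Waveform:
    """Synthetic advertisement call: decaying harmonic stack whose strongest
    partial sits at the dominant frequency, amplitude-modulated at
    ``spec.am_rate``; deterministic for a fixed seed (random partial phases
    and a small AM-phase jitter emulate between-call variation)."""
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration_ms / 1000.0 * sample_rate))
    t = np.arange(n) / sample_rate
    nyq = sample_rate / 2
    x = np.zeros(n)
    for k in range(1, spec.harmonic_count + 1):
        f = k * spec.dominant_frequency
        if f >= nyq:
            log.info("dropping partial %d (%.0f Hz) above Nyquist", k, f)
            continue
        x += (1.0 / k) * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    if spec.secondary_band is not None and spec.secondary_band < nyq:
        x += 0.35 * np.sin(2 * np.pi * spec.secondary_band * t
                           + rng.uniform(0, 2 * np.pi))
    am_phase = rng.uniform(0, 2 * np.pi)
    am = 0.6 + 0.4 * np.sin(2 * np.pi * spec.am_rate * t + am_phase)
    x *= am * _raised_cosine_ramps(n, sample_rate, ramp=0.01)
    return Waveform(x / np.max(np.abs(x)), sample_rate)


def synth_white_noise(duration: float = 3.0, sample_rate: int = DEFAULT_SAMPLE_RATE,
                      seed: int = 0, band: tuple[float, float] = (100.0, 10000.0)
                      ) -> Waveform:
    """Gaussian white noise band-limited to ``band`` (default 0.1–10 kHz),
    peak-normalized."""
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    x = rng.standard_normal(n)
    lo, hi = band
    hi = min(hi, 0.999 * sample_rate / 2)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=sample_rate, output="sos")
    x = sps.sosfiltfilt(sos, x)
    return Waveform(x / np.max(np.abs(x)), sample_rate)


def highpass_300(x: np.ndarray, sample_rate: int, cutoff: float = 300.0) -> np.ndarray:
    """4th-order zero-phase Butterworth high-pass (default 300 Hz cutoff),
    used to strip wind/handling rumble from call segments."""
    sos = sps.butter(4, cutoff, btype="highpass", fs=sample_rate, output="sos")
    return sps.sosfiltfilt(sos, x)


def default_call_roster() -> list[tuple[str, CallSpec]]:
    """(individual_id, CallSpec) pairs for the 7 native + 6 invasive
    individuals of the broadcast program. Per-individual dominant-frequency
    offsets are deterministic and stay within each species' reported range."""
    roster: list[tuple[str, CallSpec]] = []
    native_offsets = [-260, -170, -80, 0, 90, 180, 270]  # Hz, spread ~ +-1 SD
    invasive_offsets = [-450, -270, -90, 90, 270, 450]
    for i, off in enumerate(native_offsets, start=1):
        roster.append((f"Pp{i:02d}", replace(
            NATIVE_CALL, dominant_frequency=NATIVE_CALL.dominant_frequency + off)))
    for i, off in enumerate(invasive_offsets, start=1):
        roster.append((f"Lc{i:02d}", replace(
            INVASIVE_CALL, dominant_frequency=INVASIVE_CALL.dominant_frequency + off)))
    return roster


def assemble_playback(tones: list[ToneSpec] | None = None,
                      calls: list[tuple[str, CallSpec]] | None = None,
                      sample_rate: int = DEFAULT_SAMPLE_RATE,
                      *,
                      gap: float = 0.5,
                      white_noise_duration: float = 3.0,
                      level_ref_duration: float = 2.0,
                      highpass_calls: bool = True,
                      highpass_tones: bool = False,
                      seed: int = 0) -> tuple[Waveform, PlaybackSchedule]:
    """Assemble the broadcast program.

    Order: per-individual call blocks (``n_calls`` renditions each), the tone
    series, the white-noise burst, and a 1-kHz broadcast-level reference tone.
    Every segment is 100% peak-normalized before assembly; call segments are
    optionally high-passed at 300 Hz (default on; default off for tones).
    Returns the waveform and a schedule indexing every segment.
    """
    if tones is None:
        tones = generate_tone_schedule()
    if calls is None:
        calls = default_call_roster()
    if not tones and not calls:
        raise ValueError("nothing to assemble: no tones and no calls")

    pieces: list[np.ndarray] = []
    schedule = PlaybackSchedule()
    cursor = 0.0
    gap_n = int(round(gap * sample_rate))

    def push(x: np.ndarray, label: str, kind: str) -> None:
        nonlocal cursor
        x = x / np.max(np.abs(x))  # 100% peak normalization per segment
        pieces.append(x)
        schedule.add(label, cursor, len(x) / sample_rate, kind)
        cursor += len(x) / sample_rate
        pieces.append(np.zeros(gap_n))
        cursor += gap_n / sample_rate

    rng = np.random.default_rng(seed)
    for indiv, spec in calls:
        for k in range(spec.n_calls):
            call_seed = int(rng.integers(0, 2**31 - 1))
            w = synth_call(spec, sample_rate, seed=call_seed)
            x = highpass_300(w.samples, sample_rate) if highpass_calls else w.samples
            tag = SPECIES_TAGS.get(spec.species_label, "Xx")
            push(x, f"call_{tag}_{indiv}_{k + 1:02d}", "call")

    for spec in tones:
        w = synth_tone(spec, sample_rate)
        x = highpass_300(w.samples, sample_rate) if highpass_tones else w.samples
        push(x, f"tone_{int(round(spec.frequency)):04d}", "tone")

    if white_noise_duration > 0:
        noise_seed = int(rng.integers(0, 2**31 - 1))
        push(synth_white_noise(white_noise_duration, sample_rate, seed=noise_seed)
             .samples, "white_noise", "white_noise")

    if level_ref_duration > 0:
        ref = synth_tone(ToneSpec(1000.0, duration=level_ref_duration), sample_rate)
        push(ref.samples, "calibration", "broadcast_ref")

    samples = np.concatenate(pieces)
    schedule.validate()
    return Waveform(samples, sample_rate), schedule


def label_frequency(label: str) -> float | None:
    """Tone frequency encoded in a segment label, or None."""
    if label.startswith("tone_"):
        return float(label.split("_")[1])
    return None


def label_species(label: str) -> str | None:
    """Species name encoded in a call segment label, or None."""
    if label.startswith("call_"):
        return TAG_SPECIES.get(label.split("_")[1])
    return None


def label_individual(label: str) -> str | None:
    if label.startswith("call_"):
        return label.split("_")[2]
    return None
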