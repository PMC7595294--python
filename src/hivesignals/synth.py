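"""Synthetic electrostatic-field (ESF) recordings with exact ground truth.

No raw hive recordings are publicly deposited for this kind of experiment,
so the detector is developed and validated against synthetic multi-channel
recordings that realize the published spectro-temporal signatures:

* waggle run — a body-waggle component at the pulse rate (10–25 Hz) plus a
  190–230 Hz wing-vibration carrier amplitude-modulated by the same pulse
  train;
* fanning — a long, amplitude-stable 90–120 Hz tone;
* stop signal — a short (<0.5 s) windowed pulse with a 250–400 Hz
  fundamental and geometrically decaying harmonics.

Every event gets a 10 ms tapered-cosine (Tukey) onset/offset so energy
stays in-band; broadband white Gaussian noise is added per channel.
Amplitudes are dimensionless — only ratios (SNR) are meaningful.  All
randomness flows from explicit seeds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal.windows import tukey

from .config import BandConfig, ConfigurationError

__all__ = [
    "BEHAVIORS",
    "EventSpec",
    "EventAnnotation",
    "ESFRecording",
    "SchedulingError",
    "synth_waggle_run",
    "synth_fanning",
    "synth_stop_signal",
    "generate_recording",
    "random_schedule",
    "amplitude_for_snr",
    "read_annotations",
    "write_annotations",
]

BEHAVIORS = ("waggle_run", "fanning", "stop_signal")

#: relative amplitude of the body-waggle (low-frequency) component of a run
_WAGGLE_LOW_GAIN = 0.6
#: geometric decay ratio between successive stop-signal harmonics
_HARMONIC_DECAY = 0.5
#: Tukey taper length on each event edge, seconds
_EDGE_TAPER = 0.01


class SchedulingError(ValueError):
    """Raised when events cannot be placed without same-channel overlap."""


@dataclass(frozen=True)
class EventSpec:
    """Prescription for one synthetic event."""

    behavior: str
    channel: int = 0
    t_start: float = 0.0
    duration: float = 1.0
    fundamental_freq: float = 210.0
    amplitude: float = 1.0
    pulse_rate: float = 15.0     # waggle only: body-waggle / AM rate, Hz
    n_harmonics: int = 2         # stop only: harmonics above the fundamental

    def __post_init__(self) -> None:
        if self.behavior not in BEHAVIORS:
            raise ConfigurationError(f"unknown behavior {self.behavior!r}")
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        if self.amplitude < 0:
            raise ConfigurationError("amplitude must be non-negative")
        if self.channel < 0:
            raise ConfigurationError("channel must be non-negative")

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration


@dataclass(frozen=True)
class EventAnnotation:
    """A labeled time interval; half-open [t_start, t_end) in seconds."""

    behavior: str
    channel: int
    t_start: float
    t_end: float
    edge: bool = False          # straddles a recording boundary
    energy: float | None = None  # detector-filled in-band energy (fusion tie-break)

    def __post_init__(self) -> None:
        if self.behavior not in BEHAVIORS:
            raise ConfigurationError(f"unknown behavior {self.behavior!r}")
        if not self.t_end > self.t_start:
            raise ConfigurationError("t_end must exceed t_start")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class ESFRecording:
    """Multi-channel dimensionless ESF waveform."""

    samples: np.ndarray  # shape (n_channels, n_samples)
    sample_rate: float

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples))
        if self.samples.ndim != 2 or self.samples.shape[0] < 1:
            raise ConfigurationError("samples must be a (n_channels, n_samples) matrix")
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def to_wav(self, path: str | Path, split_channels: bool = False) -> list[Path]:
        """Write as float32 WAV; one multi-channel file or one file per channel."""
        path = Path(path)
        data = self.samples.astype(np.float32)
        if not split_channels:
            wavfile.write(path, int(round(self.sample_rate)), data.T.copy())
            return [path]
        paths = []
        for ch in range(self.n_channels):
            p = path.with_name(f"{path.stem}_ch{ch}{path.suffix or '.wav'}")
            wavfile.write(p, int(round(self.sample_rate)), data[ch])
            paths.append(p)
        return paths

    @classmethod
    def from_wav(cls, path: str | Path) -> "ESFRecording":
        rate, data = wavfile.read(path)
        if data.ndim == 1:
            data = data[np.newaxis, :]
        else:
            data = data.T
        if np.issubdtype(data.dtype, np.integer):
            data = data.astype(np.float64) / np.iinfo(data.dtype).max
        return cls(samples=np.ascontiguousarray(data), sample_rate=float(rate))


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator | None:
    if seed is None or isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _edge_window(n: int, sample_rate: float) -> np.ndarray:
    """Tukey window with ~10 ms tapers; falls back to Hann for tiny segments."""
    taper = _EDGE_TAPER * sample_rate
    alpha = min(1.0, 2.0 * taper / max(n, 1))
    return tukey(n, alpha=alpha)


def _require_in_band(value: float, band: tuple[float, float], what: str) -> None:
    if not (band[0] <= value <= band[1]):
        raise ConfigurationError(f"{what} {value} Hz outside band {band}")


def synth_waggle_run(
    spec: EventSpec,
    band_config: BandConfig | None = None,
    rng: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Waveform of one waggle run.

    The segment carries energy in both class bands: the body waggle as a
    direct low-frequency component at ``pulse_rate`` and the wing-vibration
    carrier at ``fundamental_freq``, amplitude-modulated by the raised-cosine
    pulse train ``0.5*(1 - cos(2*pi*pulse_rate*t))`` so the rectified
    high-band envelope peaks at the pulse rate.
    """
    cfg = band_config or BandConfig()
    if spec.behavior != "waggle_run":
        raise ConfigurationError("spec.behavior must be 'waggle_run'")
    _require_in_band(spec.pulse_rate, cfg.waggle_low_band, "pulse_rate")
    _require_in_band(spec.fundamental_freq, cfg.waggle_high_band, "fundamental_freq")
    n = int(round(spec.duration * cfg.sample_rate))
    t = np.arange(n) / cfg.sample_rate
    g = _as_rng(rng)
    phase_c = g.uniform(0, 2 * np.pi) if g is not None else 0.0
    phase_p = g.uniform(0, 2 * np.pi) if g is not None else 0.0
    pulses = 0.5 * (1.0 - np.cos(2 * np.pi * spec.pulse_rate * t + phase_p))
    carrier = np.sin(2 * np.pi * spec.fundamental_freq * t + phase_c)
    body = _WAGGLE_LOW_GAIN * np.sin(2 * np.pi * spec.pulse_rate * t + phase_p)
    seg = spec.amplitude * (pulses * carrier + body)
    return seg * _edge_window(n, cfg.sample_rate)


def synth_fanning(
    spec: EventSpec,
    band_config: BandConfig | None = None,
    rng: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Waveform of one fanning bout: a long amplitude-stable tone.

    A slow multiplicative amplitude jitter (<5% RMS, sub-Hz) is applied when
    an *rng* is given; the envelope's coefficient of variation stays well
    under 0.2 so the signal reads as "stable".
    """
    cfg = band_config or BandConfig()
    if spec.behavior != "fanning":
        raise ConfigurationError("spec.behavior must be 'fanning'")
    if spec.duration <= cfg.fanning_min_duration:
        raise ConfigurationError(
            f"fanning duration must exceed {cfg.fanning_min_duration} s, got {spec.duration}"
        )
    _require_in_band(spec.fundamental_freq, cfg.fanning_band, "fundamental_freq")
    n = int(round(spec.duration * cfg.sample_rate))
    t = np.arange(n) / cfg.sample_rate
    g = _as_rng(rng)
    phase = g.uniform(0, 2 * np.pi) if g is not None else 0.0
    envelope = np.ones(n)
    if g is not None:
        # slow jitter: random walk at ~2 Hz control rate, smoothed, 5% depth
        n_knots = max(4, int(spec.duration * 2))
        knots = g.normal(0.0, 1.0, n_knots)
        jitter = np.interp(np.linspace(0, n_knots - 1, n), np.arange(n_knots), knots)
        jitter = jitter / max(np.abs(jitter).max(), 1e-12)
        envelope = 1.0 + 0.05 * jitter
    seg = spec.amplitude * envelope * np.sin(2 * np.pi * spec.fundamental_freq * t + phase)
    return seg * _edge_window(n, cfg.sample_rate)


def synth_stop_signal(
    spec: EventSpec,
    band_config: BandConfig | None = None,
    rng: int | np.random.Generator | None = None,
    allow_pure_tone: bool = False,
) -> np.ndarray:
    """Waveform of one stop signal: short harmonic pulse.

    Harmonic ``h`` (1 = fundamental) has amplitude ``0.5**(h-1)``.  By
    default ``n_harmonics`` must be >= 1; pass ``allow_pure_tone=True`` to
    accept a harmonic-free pulse (``n_harmonics=0``).
    """
    cfg = band_config or BandConfig()
    if spec.behavior != "stop_signal":
        raise ConfigurationError("spec.behavior must be 'stop_signal'")
    if spec.duration >= cfg.stop_max_duration:
        raise ConfigurationError(
            f"stop-signal duration must be below {cfg.stop_max_duration} s, got {spec.duration}"
        )
    _require_in_band(spec.fundamental_freq, cfg.stop_band, "fundamental_freq")
    if spec.n_harmonics < 1 and not allow_pure_tone:
        raise ConfigurationError("n_harmonics must be >= 1 (or set allow_pure_tone=True)")
    n = int(round(spec.duration * cfg.sample_rate))
    t = np.arange(n) / cfg.sample_rate
    g = _as_rng(rng)
    seg = np.zeros(n)
    for h in range(spec.n_harmonics + 1):
        f = (h + 1) * spec.fundamental_freq
        if f >= cfg.nyquist:
            break
        phase = g.uniform(0, 2 * np.pi) if g is not None else 0.0
        seg += (_HARMONIC_DECAY ** h) * np.sin(2 * np.pi * f * t + phase)
    return spec.amplitude * seg * _edge_window(n, cfg.sample_rate)


_SYNTH = {
    "waggle_run": synth_waggle_run,
    "fanning": synth_fanning,
    "stop_signal": synth_stop_signal,
}


def synth_event(
    spec: EventSpec,
    band_config: BandConfig | None = None,
    rng: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Dispatch to the class-specific waveform synthesizer."""
    return _SYNTH[spec.behavior](spec, band_config, rng)


def amplitude_for_snr(snr_db: float, noise_sigma: float) -> float:
    """Event amplitude giving a nominal in-band RMS SNR against white noise.

    Treats the event as a unit-amplitude tone (RMS = A/sqrt(2)), so
    ``A = sigma * 10**(snr_db/20) * sqrt(2)``.
    """
    return float(noise_sigma * 10 ** (snr_db / 20.0) * np.sqrt(2.0))


def _check_schedule(schedule: list[EventSpec], duration: float) -> None:
    by_channel: dict[int, list[EventSpec]] = {}
    for ev in schedule:
        if ev.t_start < 0 or ev.t_end > duration + 1e-9:
            raise SchedulingError(
                f"event [{ev.t_start:.3f}, {ev.t_end:.3f}) extends outside [0, {duration}]"
            )
        by_channel.setdefault(ev.channel, []).append(ev)
    for ch, evs in by_channel.items():
        evs = sorted(evs, key=lambda e: e.t_start)
        for a, b in zip(evs, evs[1:]):
            if b.t_start < a.t_end:
                raise SchedulingError(
                    f"overlapping events on channel {ch}: "
                    f"[{a.t_start:.3f},{a.t_end:.3f}) and [{b.t_start:.3f},{b.t_end:.3f})"
                )


def generate_recording(
    schedule: list[EventSpec],
    duration: float,
    n_channels: int = 4,
    noise_sigma: float = 1.0,
    seed: int = 0,
    band_config: BandConfig | None = None,
) -> tuple[ESFRecording, list[EventAnnotation]]:
    """Render a schedule into a noisy multi-channel recording.

    Returns the recording and ground-truth annotations that mirror the
    schedule exactly.  Identical ``(schedule, seed)`` produce bit-identical
    output: noise and per-event phase randomness are spawned from one
    :class:`numpy.random.SeedSequence`.
    """
    cfg = band_config or BandConfig()
    if n_channels < 1:
        raise ConfigurationError("n_channels must be >= 1")
    if duration <= 0:
        raise ConfigurationError("duration must be positive")
    if any(ev.channel >= n_channels for ev in schedule):
        raise SchedulingError("event channel index out of range")
    _check_schedule(schedule, duration)

    n = int(round(duration * cfg.sample_rate))
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_channels + len(schedule))
    samples = np.empty((n_channels, n), dtype=np.float32)
    for ch in range(n_channels):
        rng = np.random.default_rng(children[ch])
        if noise_sigma > 0:
            samples[ch] = rng.normal(0.0, noise_sigma, n).astype(np.float32)
        else:
            samples[ch] = 0.0
    annotations: list[EventAnnotation] = []
    for k, ev in enumerate(schedule):
        rng = np.random.default_rng(children[n_channels + k])
        seg = synth_event(ev, cfg, rng).astype(np.float32)
        i0 = int(round(ev.t_start * cfg.sample_rate))
        samples[ev.channel, i0:i0 + seg.size] += seg
        annotations.append(
            EventAnnotation(ev.behavior, ev.channel, ev.t_start, ev.t_end)
        )
    return ESFRecording(samples=samples, sample_rate=cfg.sample_rate), annotations


#: default duration ranges (s) used when drawing random events
_DURATION_RANGES = {
    "waggle_run": (0.5, 1.5),
    "fanning": (10.5, 20.0),
    "stop_signal": (0.1, 0.45),
}


def random_schedule(
    rates: dict[str, float],
    duration: float,
    n_channels: int = 4,
    seed: int = 0,
    band_config: BandConfig | None = None,
    amplitude: float = 1.0,
    min_separation: float = 0.5,
    max_retries: int = 200,
) -> list[EventSpec]:
    """Draw a Poisson schedule of events with legal class parameters.

    *rates* maps behavior name to expected events per hour.  Event counts
    are Poisson with mean ``rate * duration / 3600``; durations and
    frequencies are uniform inside each class's legal range.  Placement is
    rejection-sampled: with a positive ``min_separation`` every pair of
    events keeps that much clearance regardless of channel, so each event
    is individually resolvable after cross-sensor fusion; with
    ``min_separation=0`` only same-channel overlap is forbidden and
    concurrent events on different sensors (distinct bees) may occur.
    """
    cfg = band_config or BandConfig()
    for name, r in rates.items():
        if name not in BEHAVIORS:
            raise ConfigurationError(f"unknown behavior {name!r} in rates")
        if r < 0:
            raise ConfigurationError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    wanted: list[str] = []
    for name in BEHAVIORS:
        rate = rates.get(name, 0.0)
        count = rng.poisson(rate * duration / 3600.0)
        wanted.extend([name] * count)

    placed: list[tuple[int, float, float]] = []
    events: list[EventSpec] = []
    # place longest-duration classes first so fanning bouts find room
    order = sorted(range(len(wanted)), key=lambda i: -_DURATION_RANGES[wanted[i]][1])
    for i in order:
        name = wanted[i]
        dlo, dhi = _DURATION_RANGES[name]
        dhi = min(dhi, duration)
        ev_dur = rng.uniform(dlo, dhi)
        band = cfg.band_for(name)
        f0 = rng.uniform(*band)
        kwargs: dict = {}
        if name == "waggle_run":
            kwargs["pulse_rate"] = rng.uniform(*cfg.waggle_low_band)
        if name == "stop_signal":
            kwargs["n_harmonics"] = int(rng.integers(1, 4))
        for _ in range(max_retries):
            ch = int(rng.integers(0, n_channels))
            t0 = rng.uniform(0.0, duration - ev_dur)
            ok = all(
                t0 >= b + min_separation or t0 + ev_dur <= a - min_separation
                for pch, a, b in placed
                if pch == ch or min_separation > 0
            )
            if ok:
                placed.append((ch, t0, t0 + ev_dur))
                events.append(
                    EventSpec(
                        behavior=name, channel=ch, t_start=t0, duration=ev_dur,
                        fundamental_freq=f0, amplitude=amplitude, **kwargs,
                    )
                )
                break
        else:
            raise SchedulingError(
                f"could not place a {name} event after {max_retries} retries; "
                "rates too dense for the recording"
            )
    events.sort(key=lambda e: (e.t_start, e.channel))
    return events


# ---------------------------------------------------------------------------
# Annotation CSV I/O: header `channel,behavior,t_start_s,t_end_s`

def write_annotations(events: list[EventAnnotation], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "channel": [e.channel for e in events],
            "behavior": [e.behavior for e in events],
            "t_start_s": [round(e.t_start, 6) for e in events],
            "t_end_s": [round(e.t_end, 6) for e in events],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_annotations(path: str | Path) -> list[EventAnnotation]:
    df = pd.read_csv(path)
    required = {"channel", "behavior", "t_start_s", "t_end_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation CSV missing columns: {sorted(missing)}")
    return [
        EventAnnotation(
            behavior=row.behavior, channel=int(row.channel),
            t_start=float(row.t_start_s), t_end=float(row.t_end_s),
        )
        for row in df.itertuples()
    ]
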