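"""Frequency-band and detector configuration.

The three in-hive social signals picked up by electrostatic-field (ESF)
sensors occupy well-separated spectro-temporal niches:

* **waggle run** — rhythmic pulses: body waggle at 10–25 Hz carrying a
  190–230 Hz wing-vibration component, amplitude-modulated at the waggle
  rate; individual runs last well under 10 s.
* **fanning** — long (>10 s), amplitude-stable wing-beat tone at 90–120 Hz.
* **stop signal** — brief (<0.5 s) pulse with a 250–400 Hz fundamental and
  pronounced harmonics.

:class:`BandConfig` is the single source of truth for these criteria;
:class:`DetectionParams` holds every tunable of the detector so nothing is
hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import yaml

__all__ = ["BandConfig", "DetectionParams", "ConfigurationError"]


class ConfigurationError(ValueError):
    """Raised when a band or parameter configuration is inconsistent."""


def _check_band(name: str, band: tuple[float, float]) -> tuple[float, float]:
    lo, hi = float(band[0]), float(band[1])
    if not (0 <= lo < hi):
        raise ConfigurationError(f"{name} must satisfy 0 <= low < high, got {band}")
    return (lo, hi)


@dataclass(frozen=True)
class BandConfig:
    """Class-defining frequency bands and duration gates.

    Frequencies in Hz, durations in seconds.  Defaults are the published
    signatures of the three signal classes.
    """

    waggle_low_band: tuple[float, float] = (10.0, 25.0)
    waggle_high_band: tuple[float, float] = (190.0, 230.0)
    fanning_band: tuple[float, float] = (90.0, 120.0)
    stop_band: tuple[float, float] = (250.0, 400.0)
    fanning_min_duration: float = 10.0
    stop_max_duration: float = 0.5
    sample_rate: float = 44100.0

    def __post_init__(self) -> None:
        for name in ("waggle_low_band", "waggle_high_band", "fanning_band", "stop_band"):
            object.__setattr__(self, name, _check_band(name, getattr(self, name)))
        if self.fanning_min_duration <= 0:
            raise ConfigurationError("fanning_min_duration must be positive")
        if self.stop_max_duration <= 0:
            raise ConfigurationError("stop_max_duration must be positive")
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be positive")

    @property
    def nyquist(self) -> float:
        return self.sample_rate / 2.0

    def band_for(self, behavior: str) -> tuple[float, float]:
        """Fundamental-frequency band of a behavior class."""
        return {
            "waggle_run": self.waggle_high_band,
            "fanning": self.fanning_band,
            "stop_signal": self.stop_band,
        }[behavior]

    def with_sample_rate(self, sample_rate: float) -> "BandConfig":
        return replace(self, sample_rate=sample_rate)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BandConfig":
        kwargs = {k: tuple(v) if isinstance(v, (list, tuple)) else v for k, v in d.items()}
        return cls(**kwargs)


@dataclass(frozen=True)
class DetectionParams:
    """Tunables of the band-energy detector.

    threshold_k
        Segmentation threshold is ``median + threshold_k * MAD`` of the
        band-energy envelope, computed per band per recording (raw,
        unscaled MAD).  Scale-free by construction.
    min_gap_merge
        Above-threshold intervals separated by shorter gaps are merged (s).
    min_event_duration
        Intervals shorter than this are discarded as noise blips (s).
    envelope_smooth
        Moving-average width applied to each envelope before thresholding;
        suppresses single-frame noise spikes (s).
    waggle_run_split_gap
        Waggle intervals closer than this merge into one run; gaps at or
        above it separate runs (the return phase of the dance) (s).
    harmonic_min_ratio
        Minimum (E(2f0)+E(3f0))/E(f0) for a strict stop-signal call; only
        enforced when ``require_harmonics`` is true ("often combined with
        pronounced harmonics" — supporting, not mandatory, evidence).
    fusion_overlap_min
        Temporal intersection-over-union at or above which same-class
        events on different sensors are considered the same bee.
    short_window / short_hop
        STFT resolution used for the 90–120, 190–230 and 250–400 Hz bands (s).
    long_window / long_hop
        STFT resolution for the 10–25 Hz band (only used on the ``stft``
        waggle path) (s).
    waggle_low_path
        ``"modulation"`` (default): verify the 10–25 Hz pulse train as the
        modulation-spectrum peak of the rectified 190–230 Hz envelope.
        ``"stft"``: require concurrent above-threshold 10–25 Hz energy in a
        long-window STFT.
    modulation_tol_hz
        Slack on the pulse-rate band for the modulation peak (finite
        segments have limited rate resolution) (Hz).
    """

    threshold_k: float = 5.0
    min_gap_merge: float = 0.1
    min_event_duration: float = 0.05
    envelope_smooth: float = 0.05
    waggle_run_split_gap: float = 0.3
    harmonic_min_ratio: float = 0.1
    require_harmonics: bool = False
    fusion_overlap_min: float = 0.5
    short_window: float = 0.046
    short_hop: float = 0.023
    long_window: float = 0.5
    long_hop: float = 0.25
    waggle_low_path: str = "modulation"
    modulation_tol_hz: float = 2.0

    def __post_init__(self) -> None:
        positive = (
            "threshold_k", "min_gap_merge", "min_event_duration",
            "waggle_run_split_gap", "harmonic_min_ratio", "short_window",
            "short_hop", "long_window", "long_hop", "envelope_smooth",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if not (0 < self.fusion_overlap_min <= 1):
            raise ConfigurationError("fusion_overlap_min must lie in (0, 1]")
        if self.short_hop > self.short_window or self.long_hop > self.long_window:
            raise ConfigurationError("hop must not exceed window length")
        if self.waggle_low_path not in ("modulation", "stft"):
            raise ConfigurationError("waggle_low_path must be 'modulation' or 'stft'")
        if self.modulation_tol_hz < 0:
            raise ConfigurationError("modulation_tol_hz must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DetectionParams":
        return cls(**d)


def load_config(path: str | Path) -> tuple[BandConfig, DetectionParams]:
    """Read a YAML config with optional ``bands:`` and ``detection:`` sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    bands = BandConfig.from_dict(raw.get("bands", {}))
    params = DetectionParams.from_dict(raw.get("detection", {}))
    return bands, params


def dump_config(bands: BandConfig, params: DetectionParams, path: str | Path | None = None) -> str:
    """Serialize configs to YAML; write to *path* if given."""
    text = yaml.safe_dump(
        {"bands": bands.to_dict(), "detection": params.to_dict()},
        sort_keys=False,
    )
    if path is not None:
        Path(path).write_text(text)
    return text
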