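"""Band-energy detection and classification of in-hive social signals.

The detector reimplements the classic audiogram-style analysis of
electrostatic-field (ESF) recordings: short-time spectra, per-band energy
envelopes, robust adaptive thresholding, duration gates, and a small set
of class rules —

* **stop signal**: < 0.5 s, dominant energy at >= 250 Hz, harmonics at
  2*f0/3*f0 scored (optionally required);
* **fanning**: > 10 s of dominant 90–120 Hz energy;
* **waggle run**: above-threshold 190–230 Hz energy whose amplitude
  modulation (the rectified high-band envelope) peaks at the 10–25 Hz
  body-waggle rate.

Two STFT resolutions are used: a short window (default 46 ms) resolves
stop signals and waggle-run boundaries in the 90–400 Hz bands; a long
window (default 0.5 s, 2 Hz bins) serves the 10–25 Hz band and the
segmentation of long fanning bouts.  Thresholds are ``median + k*MAD`` of
each envelope, so the whole pipeline is invariant to global amplitude
rescaling of the recording.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import ShortTimeFFT, butter, hilbert, sosfiltfilt
from scipy.signal.windows import hann

from .config import BandConfig, DetectionParams
from .synth import ESFRecording, EventAnnotation

__all__ = [
    "Spectrogram",
    "BandEnvelope",
    "DetectionSummary",
    "DetectionResult",
    "compute_spectrogram",
    "band_envelope",
    "mad_threshold",
    "segment_events",
    "classify_event",
    "count_waggle_runs",
    "fuse_channels",
    "summarize",
    "evaluate_detector",
    "detect_recording",
]


@dataclass
class Spectrogram:
    """One-sided magnitude short-time spectrum of one channel."""

    magnitudes: np.ndarray  # (n_freqs, n_frames), >= 0
    freq_axis: np.ndarray   # Hz
    time_axis: np.ndarray   # s, frame centers, strictly increasing
    window_length: float    # s
    hop: float              # s
    sample_rate: float
    _win_sumsq: float = 0.0
    _nfft: int = 0

    def signal_energy(self) -> float:
        """Time-domain-equivalent energy sum(x^2) implied by the magnitudes.

        Uses per-frame Parseval with the window-overlap normalization
        ``hop_samples / (nfft * sum(w^2))``; exact for overlap-add-constant
        squared windows, within a few percent otherwise.
        """
        m2 = self.magnitudes.astype(np.float64) ** 2
        twosided = 2.0 * m2.sum() - m2[0, :].sum()
        if self._nfft % 2 == 0:
            twosided -= m2[-1, :].sum()
        hop_samples = self.hop * self.sample_rate
        return float(twosided * hop_samples / (self._nfft * self._win_sumsq))


@dataclass
class BandEnvelope:
    """Per-frame summed magnitude-squared energy restricted to a band."""

    band: tuple[float, float]
    energy: np.ndarray
    time_axis: np.ndarray
    hop: float
    n_bins: int = 1


@dataclass
class DetectionSummary:
    """The per-recording quantities reported by the study-style analysis."""

    waggle_runs_per_hour: float
    stop_signals_per_hour: float
    fanning_fraction: float
    recording_duration: float
    n_waggle_runs: int = 0
    n_stop_signals: int = 0
    n_fanning_bouts: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fanning_fraction <= 1.0):
            raise ValueError("fanning_fraction must lie in [0, 1]")
        if self.waggle_runs_per_hour < 0 or self.stop_signals_per_hour < 0:
            raise ValueError("rates must be non-negative")

    def to_dict(self) -> dict:
        return {
            "waggle_runs_per_hour": self.waggle_runs_per_hour,
            "stop_signals_per_hour": self.stop_signals_per_hour,
            "fanning_fraction": self.fanning_fraction,
            "recording_duration": self.recording_duration,
            "n_waggle_runs": self.n_waggle_runs,
            "n_stop_signals": self.n_stop_signals,
            "n_fanning_bouts": self.n_fanning_bouts,
        }


def compute_spectrogram(
    recording: ESFRecording,
    channel: int,
    window_length: float,
    hop: float | None = None,
) -> Spectrogram:
    """Magnitude STFT (Hann window) of one channel.

    *window_length* and *hop* in seconds; *hop* defaults to half the
    window.  Frames whose centers fall outside the recording are dropped.
    """
    if not (0 <= channel < recording.n_channels):
        raise IndexError(f"channel {channel} out of range [0, {recording.n_channels})")
    fs = recording.sample_rate
    nperseg = int(round(window_length * fs))
    if nperseg < 2:
        raise ValueError("window_length * sample_rate must be >= 2")
    if hop is None:
        hop = window_length / 2.0
    hop_samples = int(round(hop * fs))
    if hop_samples < 1 or hop_samples > nperseg:
        raise ValueError("hop must be positive and no longer than the window")

    x = np.asarray(recording.samples[channel], dtype=np.float64)
    win = hann(nperseg, sym=False)
    sft = ShortTimeFFT(win, hop=hop_samples, fs=fs, mfft=nperseg, fft_mode="onesided")
    S = sft.stft(x)
    t = sft.t(x.size)
    keep = (t >= 0.0) & (t <= x.size / fs)
    return Spectrogram(
        magnitudes=np.abs(S[:, keep]).astype(np.float32),
        freq_axis=sft.f.copy(),
        time_axis=t[keep],
        window_length=nperseg / fs,
        hop=hop_samples / fs,
        sample_rate=fs,
        _win_sumsq=float(np.sum(win ** 2)),
        _nfft=nperseg,
    )


def band_envelope(spec: Spectrogram, band: tuple[float, float]) -> BandEnvelope:
    """Summed magnitude-squared energy per frame inside *band* (inclusive)."""
    lo, hi = band
    nyq = spec.sample_rate / 2.0
    if not (0 <= lo < hi <= nyq + 1e-9):
        raise ValueError(f"band {band} outside [0, Nyquist={nyq}]")
    idx = (spec.freq_axis >= lo) & (spec.freq_axis <= hi)
    if not idx.any():
        raise ValueError(f"band {band} contains no frequency bins "
                         f"(bin spacing {spec.freq_axis[1] - spec.freq_axis[0]:.2f} Hz)")
    energy = (spec.magnitudes[idx].astype(np.float64) ** 2).sum(axis=0)
    return BandEnvelope(
        band=(lo, hi), energy=energy, time_axis=spec.time_axis,
        hop=spec.hop, n_bins=int(idx.sum()),
    )


def mad_threshold(energy: np.ndarray, threshold_k: float) -> float:
    """Linear-domain threshold ``exp(median + k * MAD)`` of the log-energy.

    Band energies of broadband noise are gamma-distributed with heavy
    right tails when a band spans few bins; on the log scale the tail is
    light, so a robust ``median + k*MAD`` rule set there separates noise
    exceedances from coherent events (which sit orders of magnitude above
    the floor).  The rule stays invariant to amplitude rescaling: scaling
    the recording shifts the log-envelope, moving median and threshold
    together.  A flat envelope has zero spread and the strict ``>``
    comparison then yields no detections.
    """
    energy = np.asarray(energy, dtype=np.float64)
    top = energy.max(initial=0.0)
    if top <= 0:
        return np.inf
    z = np.log(energy + 1e-12 * top)
    med = float(np.median(z))
    mad = float(np.median(np.abs(z - med)))
    # the 1e-12*top offset keeps a flat envelope's threshold strictly above it
    return float(np.exp(med + threshold_k * mad))


def _smooth(energy: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return energy
    kernel = np.ones(n) / n
    return np.convolve(energy, kernel, mode="same")


def _merge_intervals(
    intervals: list[tuple[float, float]], gap: float
) -> list[tuple[float, float]]:
    """Merge sorted intervals separated by gaps strictly below *gap*."""
    merged: list[tuple[float, float]] = []
    for t0, t1 in sorted(intervals):
        if merged and t0 - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], max(merged[-1][1], t1))
        else:
            merged.append((t0, t1))
    return merged


def segment_events(
    env: BandEnvelope, params: DetectionParams
) -> list[tuple[float, float]]:
    """Above-threshold intervals of a band envelope.

    The envelope is lightly smoothed (moving average over
    ``params.envelope_smooth`` seconds) to suppress single-frame noise
    spikes, then thresholded at ``median + k*MAD``; intervals with gaps
    under ``min_gap_merge`` are merged and those shorter than
    ``min_event_duration`` dropped.  A flat envelope has zero spread and
    yields no detections (nothing strictly exceeds the median).
    """
    if env.energy.size == 0:
        raise ValueError("empty envelope")
    n_smooth = max(1, int(round(params.envelope_smooth / env.hop)))
    energy = _smooth(env.energy, n_smooth)
    thr = mad_threshold(energy, params.threshold_k)
    above = energy > thr
    if not above.any():
        return []
    half = env.hop / 2.0
    t = env.time_axis
    idx = np.flatnonzero(above)
    runs: list[tuple[int, int]] = []
    start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            runs.append((start, prev))
            start = i
        prev = i
    runs.append((start, prev))
    intervals = [(t[i] - half, t[j] + half) for i, j in runs]
    intervals = _merge_intervals(intervals, params.min_gap_merge)
    return [iv for iv in intervals if iv[1] - iv[0] >= params.min_event_duration]


def _band_frames(env: BandEnvelope, t0: float, t1: float) -> np.ndarray:
    sel = (env.time_axis >= t0) & (env.time_axis < t1)
    if not sel.any():
        # fall back to the nearest frame for sub-hop candidates
        sel = np.zeros_like(sel)
        sel[np.argmin(np.abs(env.time_axis - 0.5 * (t0 + t1)))] = True
    return sel


def _mean_per_bin(env: BandEnvelope, sel: np.ndarray) -> float:
    return float(env.energy[sel].mean() / env.n_bins)


def harmonic_score(
    spec: Spectrogram, sel: np.ndarray, band: tuple[float, float]
) -> float:
    """(E(2*f0) + E(3*f0)) / E(f0) with f0 the band's peak frequency.

    Energies are magnitude-squared sums over +-1 bin around each harmonic,
    averaged over the selected frames.
    """
    f = spec.freq_axis
    m2 = spec.magnitudes[:, sel].astype(np.float64) ** 2
    prof = m2.mean(axis=1)
    in_band = (f >= band[0]) & (f <= band[1])
    k0 = np.flatnonzero(in_band)[np.argmax(prof[in_band])]
    f0 = f[k0]

    def _energy_at(freq: float) -> float:
        if freq > f[-1]:
            return 0.0
        k = int(np.argmin(np.abs(f - freq)))
        lo, hi = max(0, k - 1), min(f.size, k + 2)
        return float(prof[lo:hi].sum())

    e0 = _energy_at(f0)
    if e0 <= 0:
        return 0.0
    return (_energy_at(2 * f0) + _energy_at(3 * f0)) / e0


def _modulation_peak_hz(
    x: np.ndarray, fs: float, band: tuple[float, float]
) -> float:
    """Peak of the modulation spectrum of the band-filtered envelope.

    Band-pass the segment, take the Hilbert envelope, remove its mean and
    return the frequency (4–60 Hz search range) of the strongest
    modulation component.
    """
    nyq = fs / 2.0
    hi = min(band[1], nyq * 0.95)
    sos = butter(4, [band[0], hi], btype="bandpass", fs=fs, output="sos")
    if x.size < 30:
        return 0.0
    y = sosfiltfilt(sos, x)
    env = np.abs(hilbert(y))
    env = (env - env.mean()) * hann(env.size, sym=False)
    nfft = int(2 ** np.ceil(np.log2(env.size * 4)))
    mag = np.abs(np.fft.rfft(env, nfft))
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    sel = (freqs >= 4.0) & (freqs <= 60.0)
    if not sel.any() or mag[sel].max() <= 0:
        return 0.0
    return float(freqs[sel][np.argmax(mag[sel])])


@dataclass
class _ChannelContext:
    """Everything classify_event needs for one channel."""

    x: np.ndarray
    sample_rate: float
    spec_short: Spectrogram
    spec_long: Spectrogram
    envelopes: dict[str, BandEnvelope]     # keys: fanning, waggle_high, stop (short); fanning_long, low_long
    thresholds: dict[str, float]


def _build_context(
    recording: ESFRecording, channel: int, cfg: BandConfig, params: DetectionParams
) -> _ChannelContext:
    spec_short = compute_spectrogram(recording, channel, params.short_window, params.short_hop)
    spec_long = compute_spectrogram(recording, channel, params.long_window, params.long_hop)
    envs = {
        "fanning": band_envelope(spec_short, cfg.fanning_band),
        "waggle_high": band_envelope(spec_short, cfg.waggle_high_band),
        "stop": band_envelope(spec_short, cfg.stop_band),
        "fanning_long": band_envelope(spec_long, cfg.fanning_band),
    }
    try:
        envs["low_long"] = band_envelope(spec_long, cfg.waggle_low_band)
    except ValueError:
        pass  # low band unresolvable at this window length; modulation path still works
    thresholds = {}
    for name, env in envs.items():
        n_smooth = max(1, int(round(params.envelope_smooth / env.hop)))
        thresholds[name] = mad_threshold(_smooth(env.energy, n_smooth), params.threshold_k)
    return _ChannelContext(
        x=np.asarray(recording.samples[channel], dtype=np.float64),
        sample_rate=recording.sample_rate,
        spec_short=spec_short,
        spec_long=spec_long,
        envelopes=envs,
        thresholds=thresholds,
    )


def classify_event(
    candidate: tuple[float, float],
    ctx: _ChannelContext,
    cfg: BandConfig,
    params: DetectionParams,
) -> str | None:
    """Label a candidate interval, or ``None`` to reject.

    Duration gates apply first, then dominant per-bin band energy, with
    precedence stop > fanning > waggle for pathological inputs.
    """
    t0, t1 = candidate
    dur = t1 - t0
    sel = _band_frames(ctx.envelopes["stop"], t0, t1)
    e_fan = _mean_per_bin(ctx.envelopes["fanning"], sel)
    e_wag = _mean_per_bin(ctx.envelopes["waggle_high"], sel)
    e_stop = _mean_per_bin(ctx.envelopes["stop"], sel)

    # stop signal: short, dominant >= 250 Hz, harmonics support the call
    if dur < cfg.stop_max_duration and e_stop >= max(e_fan, e_wag):
        if ctx.envelopes["stop"].energy[sel].mean() > ctx.thresholds["stop"] * 0.5:
            score = harmonic_score(ctx.spec_short, sel, cfg.stop_band)
            if not params.require_harmonics or score >= params.harmonic_min_ratio:
                return "stop_signal"

    # fanning: long, stable, dominant 90-120 Hz
    if dur > cfg.fanning_min_duration and e_fan >= max(e_wag, e_stop):
        return "fanning"

    # waggle run: above-threshold high band, pulse-rate modulation in the low band
    if dur < cfg.fanning_min_duration and e_wag >= max(e_fan, e_stop):
        if ctx.envelopes["waggle_high"].energy[sel].mean() > ctx.thresholds["waggle_high"] * 0.5:
            lo_band = cfg.waggle_low_band
            tol = params.modulation_tol_hz
            if params.waggle_low_path == "modulation":
                fs = ctx.sample_rate
                pad = 0.05
                i0 = max(0, int((t0 - pad) * fs))
                i1 = min(ctx.x.size, int((t1 + pad) * fs))
                peak = _modulation_peak_hz(ctx.x[i0:i1], fs, cfg.waggle_high_band)
                if lo_band[0] - tol <= peak <= lo_band[1] + tol:
                    return "waggle_run"
            else:
                env_low = ctx.envelopes.get("low_long")
                if env_low is not None:
                    sel_lo = _band_frames(env_low, t0, t1)
                    if env_low.energy[sel_lo].mean() > ctx.thresholds["low_long"]:
                        return "waggle_run"
    return None


def count_waggle_runs(
    intervals: list[tuple[float, float]], params: DetectionParams
) -> int:
    """Number of waggle runs among sorted dual-band-activity intervals.

    Intervals separated by gaps below ``waggle_run_split_gap`` (shorter
    than a dance return phase) are counted as one run.
    """
    return len(_merge_intervals(list(intervals), params.waggle_run_split_gap))


def _interval_iou(a: tuple[float, float], b: tuple[float, float]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union


def fuse_channels(
    events: list[EventAnnotation], params: DetectionParams
) -> list[EventAnnotation]:
    """Merge same-class detections of the same bee seen on several sensors.

    Same-class events whose temporal IoU is at least
    ``fusion_overlap_min`` are merged transitively (union-find); the fused
    event spans their union and is attributed to the channel with the
    greatest in-band energy (lowest channel index if energies are absent).
    """
    parent = list(range(len(events)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    for i in range(len(events)):
        for j in range(i + 1, len(events)):
            a, b = events[i], events[j]
            if a.behavior != b.behavior:
                continue
            if _interval_iou((a.t_start, a.t_end), (b.t_start, b.t_end)) >= params.fusion_overlap_min:
                union(i, j)

    groups: dict[int, list[EventAnnotation]] = {}
    for i, ev in enumerate(events):
        groups.setdefault(find(i), []).append(ev)

    fused = []
    for members in groups.values():
        t0 = min(m.t_start for m in members)
        t1 = max(m.t_end for m in members)
        best = max(
            members,
            key=lambda m: (m.energy if m.energy is not None else -1.0, -m.channel),
        )
        fused.append(
            EventAnnotation(
                behavior=members[0].behavior, channel=best.channel,
                t_start=t0, t_end=t1,
                edge=any(m.edge for m in members),
                energy=best.energy,
            )
        )
    fused.sort(key=lambda e: (e.t_start, e.t_end, e.channel))
    return fused


def _union_length(intervals: list[tuple[float, float]]) -> float:
    return sum(t1 - t0 for t0, t1 in _merge_intervals(intervals, 0.0))


def summarize(
    events: list[EventAnnotation],
    recording_duration: float,
    params: DetectionParams | None = None,
) -> DetectionSummary:
    """Study-style per-recording summary from (fused) events.

    Waggle intervals closer than the run split gap count as one run;
    fanning time is the length of the union of fanning intervals.
    """
    if recording_duration <= 0:
        raise ValueError("recording_duration must be positive")
    params = params or DetectionParams()
    clipped: dict[str, list[tuple[float, float]]] = {b: [] for b in ("waggle_run", "fanning", "stop_signal")}
    for ev in events:
        if ev.t_start >= recording_duration or ev.t_end <= 0:
            raise ValueError(f"event [{ev.t_start}, {ev.t_end}) outside the recording")
        clipped[ev.behavior].append(
            (max(ev.t_start, 0.0), min(ev.t_end, recording_duration))
        )
    n_waggle = count_waggle_runs(sorted(clipped["waggle_run"]), params)
    n_stop = len(clipped["stop_signal"])
    fanning_time = _union_length(clipped["fanning"])
    return DetectionSummary(
        waggle_runs_per_hour=n_waggle * 3600.0 / recording_duration,
        stop_signals_per_hour=n_stop * 3600.0 / recording_duration,
        fanning_fraction=min(1.0, fanning_time / recording_duration),
        recording_duration=recording_duration,
        n_waggle_runs=n_waggle,
        n_stop_signals=n_stop,
        n_fanning_bouts=len(clipped["fanning"]),
    )


@dataclass
class DetectionResult:
    """Fused events plus the per-recording summary."""

    events: list[EventAnnotation]
    per_channel_events: list[EventAnnotation]
    summary: DetectionSummary

    def to_json(self, params: DetectionParams | None = None) -> str:
        payload = self.summary.to_dict()
        if params is not None:
            payload["params"] = params.to_dict()
        return json.dumps(payload, indent=2)


def _detect_channel(
    recording: ESFRecording, channel: int, cfg: BandConfig, params: DetectionParams
) -> list[EventAnnotation]:
    ctx = _build_context(recording, channel, cfg, params)
    duration = recording.duration

    candidates: list[tuple[float, float, float]] = []  # (t0, t1, shrink)
    for name, shrink in (("waggle_high", params.short_hop), ("stop", params.short_hop),
                         ("fanning_long", params.long_hop)):
        for t0, t1 in segment_events(ctx.envelopes[name], params):
            candidates.append((t0, t1, shrink))

    labeled: dict[str, list[tuple[float, float]]] = {}
    for t0, t1, shrink in candidates:
        # the analysis window smears detected intervals outward by roughly
        # one hop per side; pull boundaries back in, keeping >= half the span
        s = min(shrink, (t1 - t0) / 4.0)
        tt0, tt1 = t0 + s, t1 - s
        label = classify_event((tt0, tt1), ctx, cfg, params)
        if label is not None:
            labeled.setdefault(label, []).append((tt0, tt1))

    out: list[EventAnnotation] = []
    for label, ivs in labeled.items():
        # merge cross-band duplicates and sub-gap fragments of one event
        merged = _merge_intervals(ivs, params.min_gap_merge)
        for t0, t1 in (iv for iv in merged if iv[1] - iv[0] >= params.min_event_duration):
            edge = t0 <= params.short_window or t1 >= duration - params.short_window
            env = ctx.envelopes["fanning" if label == "fanning" else
                               "waggle_high" if label == "waggle_run" else "stop"]
            sel = _band_frames(env, t0, t1)
            out.append(
                EventAnnotation(
                    behavior=label, channel=channel,
                    t_start=max(t0, 0.0), t_end=min(t1, duration),
                    edge=edge, energy=_mean_per_bin(env, sel),
                )
            )
    out.sort(key=lambda e: e.t_start)
    return out


def detect_recording(
    recording: ESFRecording,
    band_config: BandConfig | None = None,
    params: DetectionParams | None = None,
) -> DetectionResult:
    """Run the full detector on every channel and fuse the results."""
    cfg = (band_config or BandConfig())
    if cfg.sample_rate != recording.sample_rate:
        cfg = cfg.with_sample_rate(recording.sample_rate)
    params = params or DetectionParams()
    per_channel: list[EventAnnotation] = []
    for ch in range(recording.n_channels):
        per_channel.extend(_detect_channel(recording, ch, cfg, params))
    fused = fuse_channels(per_channel, params)
    summary = summarize(fused, recording.duration, params)
    return DetectionResult(events=fused, per_channel_events=per_channel, summary=summary)


def evaluate_detector(
    truth: list[EventAnnotation],
    detected: list[EventAnnotation],
    match_iou: float = 0.5,
) -> dict[str, dict[str, float]]:
    """Per-class precision/recall/F1 by greedy one-to-one IoU matching.

    Matching is temporal only (fused detections need not preserve the
    ground-truth channel index).  Returns one entry per behavior class
    plus ``"macro"`` with the unweighted mean F1 over classes present in
    the truth.
    """
    results: dict[str, dict[str, float]] = {}
    f1s = []
    for behavior in ("waggle_run", "fanning", "stop_signal"):
        t_ivs = [(e.t_start, e.t_end) for e in truth if e.behavior == behavior]
        d_ivs = [(e.t_start, e.t_end) for e in detected if e.behavior == behavior]
        pairs = [
            (_interval_iou(t, d), i, j)
            for i, t in enumerate(t_ivs) for j, d in enumerate(d_ivs)
        ]
        pairs.sort(key=lambda p: -p[0])
        used_t: set[int] = set()
        used_d: set[int] = set()
        tp = 0
        for iou, i, j in pairs:
            if iou < match_iou:
                break
            if i in used_t or j in used_d:
                continue
            used_t.add(i)
            used_d.add(j)
            tp += 1
        fp = len(d_ivs) - tp
        fn = len(t_ivs) - tp
        precision = tp / (tp + fp) if tp + fp else (1.0 if fn == 0 else 0.0)
        recall = tp / (tp + fn) if tp + fn else 1.0
        f1 = (2 * precision * recall / (precision + recall)) if precision + recall else 0.0
        results[behavior] = {
            "precision": precision, "recall": recall, "f1": f1,
            "tp": tp, "fp": fp, "fn": fn,
        }
        if t_ivs:
            f1s.append(f1)
    results["macro"] = {"f1": float(np.mean(f1s)) if f1s else 1.0}
    return results
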