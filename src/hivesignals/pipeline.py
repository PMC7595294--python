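"""End-to-end campaign simulation: simulate -> detect -> summarize.

A campaign emulates the field design: one recording session per day for
each of two colonies (control and treated), each colony with its own
expected event rates.  Every session is generated, run through the
detector, and summarized; per-colony means and standard errors over days
are reported.  All randomness derives from a single root seed split
deterministically per (day, colony), so campaigns are exactly
reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import BandConfig, DetectionParams, ConfigurationError
from .detect import DetectionResult, detect_recording, evaluate_detector
from .synth import (
    amplitude_for_snr,
    generate_recording,
    random_schedule,
    write_annotations,
)

__all__ = ["CampaignConfig", "CampaignResult", "run_campaign", "export_report"]

logger = logging.getLogger("hivesignals")

COLONIES = ("control", "treated")


@dataclass
class CampaignConfig:
    """Configuration of a simulated two-colony recording campaign.

    Defaults mirror the field design: 22 daily dance-induction sessions of
    two hours, four sensors per comb side, 44.1 kHz sampling.  Rates are
    expected events per hour per colony.
    """

    n_days: int = 22
    session_duration: float = 7200.0
    n_channels: int = 4
    sample_rate: float = 44100.0
    control_rates: dict = field(
        default_factory=lambda: {"waggle_run": 120.0, "fanning": 10.0, "stop_signal": 13.0}
    )
    treated_rates: dict = field(
        default_factory=lambda: {"waggle_run": 64.0, "fanning": 7.0, "stop_signal": 5.0}
    )
    noise_sigma: float = 1.0
    snr_db: float = 20.0
    seed: int = 0
    bands: BandConfig | None = None
    detection: DetectionParams | None = None

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ConfigurationError("n_days must be >= 1")
        if self.session_duration <= 0:
            raise ConfigurationError("session_duration must be positive")
        if self.n_channels < 1:
            raise ConfigurationError("n_channels must be >= 1")
        for rates in (self.control_rates, self.treated_rates):
            if any(v < 0 for v in rates.values()):
                raise ConfigurationError("rates must be non-negative")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CampaignConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "bands" in raw:
            raw["bands"] = BandConfig.from_dict(raw["bands"])
        if "detection" in raw:
            raw["detection"] = DetectionParams.from_dict(raw["detection"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = {k: v for k, v in asdict(self).items() if k not in ("bands", "detection")}
        if self.bands is not None:
            d["bands"] = self.bands.to_dict()
        if self.detection is not None:
            d["detection"] = self.detection.to_dict()
        return d


def _session_seed(root_seed: int, day: int, colony_idx: int) -> int:
    """Deterministic per-session seed below 2**31."""
    ss = np.random.SeedSequence([root_seed, day, colony_idx])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class CampaignResult:
    """Per-day, per-colony detection table plus group means +- SEM."""

    table: pd.DataFrame          # columns: day, colony, waggle_runs_per_hour, ...
    group_stats: pd.DataFrame    # index colony; columns <metric>_mean, <metric>_sem
    config: CampaignConfig
    detections: dict = field(default_factory=dict)  # (day, colony) -> DetectionResult


_METRICS = ["waggle_runs_per_hour", "stop_signals_per_hour", "fanning_fraction"]


def run_campaign(config: CampaignConfig, keep_detections: bool = False) -> CampaignResult:
    """Simulate and analyze every session of a campaign."""
    cfg = (config.bands or BandConfig()).with_sample_rate(config.sample_rate)
    params = config.detection or DetectionParams()
    amplitude = amplitude_for_snr(config.snr_db, config.noise_sigma) if config.noise_sigma > 0 else 1.0
    rows = []
    detections: dict = {}
    for day in range(config.n_days):
        for colony_idx, colony in enumerate(COLONIES):
            rates = config.control_rates if colony == "control" else config.treated_rates
            seed = _session_seed(config.seed, day, colony_idx)
            schedule = random_schedule(
                rates, config.session_duration, config.n_channels,
                seed=seed, band_config=cfg, amplitude=amplitude,
            )
            recording, truth = generate_recording(
                schedule, config.session_duration, config.n_channels,
                noise_sigma=config.noise_sigma, seed=seed, band_config=cfg,
            )
            result = detect_recording(recording, cfg, params)
            logger.info(
                "day %d %s: %d scheduled events, %d detected",
                day, colony, len(schedule), len(result.events),
            )
            row = {"day": day, "colony": colony, "n_true_events": len(truth)}
            row.update({m: getattr(result.summary, m) for m in _METRICS})
            rows.append(row)
            if keep_detections:
                detections[(day, colony)] = (result, truth)
    table = pd.DataFrame(rows)
    stats = {}
    for colony in COLONIES:
        sub = table[table["colony"] == colony]
        entry = {}
        for m in _METRICS:
            vals = sub[m].to_numpy()
            entry[f"{m}_mean"] = float(vals.mean())
            entry[f"{m}_sem"] = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        stats[colony] = entry
    group_stats = pd.DataFrame(stats).T
    group_stats.index.name = "colony"
    return CampaignResult(table=table, group_stats=group_stats,
                          config=config, detections=detections)


REPORT_SCHEMA = {
    "required": ["config", "group_stats", "n_days"],
    "group_stats_keys": [f"{m}_{s}" for m in _METRICS for s in ("mean", "sem")],
}


def export_report(
    result: CampaignResult,
    out_dir: str | Path,
    homing_report: dict | None = None,
    foraging_report: dict | None = None,
    plots: bool = False,
) -> dict[str, Path]:
    """Write the campaign tables: summary.csv, report.json, optional plots.

    Returns the mapping of artifact name to path.  The JSON report always
    contains ``config``, ``n_days`` and per-colony ``group_stats``; homing
    and foraging summaries are attached when given.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    summary_csv = out / "summary.csv"
    result.table.to_csv(summary_csv, index=False)
    paths["summary"] = summary_csv

    for (day, colony), (det, _truth) in result.detections.items():
        p = out / f"events_day{day}_{colony}.csv"
        write_annotations(det.events, p)
        paths[f"events_day{day}_{colony}"] = p

    report = {
        "config": result.config.to_dict(),
        "n_days": int(result.config.n_days),
        "group_stats": {
            colony: {k: float(v) for k, v in result.group_stats.loc[colony].items()}
            for colony in result.group_stats.index
        },
    }
    if homing_report is not None:
        report["homing"] = homing_report
    if foraging_report is not None:
        report["foraging"] = foraging_report
    report_json = out / "report.json"
    report_json.write_text(json.dumps(report, indent=2))
    paths["report"] = report_json

    if plots and not result.table.empty:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
        for ax, metric in zip(axes, _METRICS):
            for colony, marker in (("control", "^"), ("treated", "s")):
                sub = result.table[result.table["colony"] == colony]
                ax.plot(sub["day"], sub[metric], marker=marker, label=colony)
            ax.set_xlabel("day")
            ax.set_ylabel(metric.replace("_", " "))
        axes[0].legend()
        fig.tight_layout()
        plot_path = out / "campaign_metrics.png"
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
        paths["plot"] = plot_path
    return paths
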