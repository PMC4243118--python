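"""Threshold-sweep orchestration: integrate, detect, evaluate, report.

The experiment re-runs the whole pipeline once per confidence threshold:
starting from the *original* network each time, literature records at or
above the threshold are integrated, complexes are detected, and the result is
scored against every gold standard.  A baseline row ("Origin") records the
metrics of the unmodified network; per-threshold deltas are expressed as
relative percent changes against that baseline, and the average delta across
gold standards summarizes each threshold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .clusterone import DetectionParams, get_detector
from .complexes import ComplexSet
from .evaluation import EvaluationResult, evaluate_all
from .literature import IntegrationReport, LiteraturePPI, integrate
from .network import PPINetwork

logger = logging.getLogger(__name__)

__all__ = ["SweepConfig", "SweepResult", "run_sweep", "write_report", "DEFAULT_THRESHOLDS"]

DEFAULT_THRESHOLDS = [0.0] + [round(-0.1 * k, 1) for k in range(1, 10)]  # 0, -0.1, ..., -0.9

ORIGIN = "Origin"
_METRICS = ("acc", "mmr", "sn", "ppv")


@dataclass
class SweepConfig:
    """Configuration of a threshold-sweep experiment."""

    thresholds: Sequence[float] = field(default_factory=lambda: list(DEFAULT_THRESHOLDS))
    detection: DetectionParams = field(default_factory=DetectionParams)
    omega_min: float = 0.25
    detector: str = "clusterone"
    rescale: str = "minmax"

    def __post_init__(self):
        if not self.thresholds:
            raise ValueError("thresholds must be non-empty")
        if not (0 < self.omega_min <= 1):
            raise ValueError("omega_min must lie in (0, 1]")


@dataclass
class SweepResult:
    """Per-threshold integration counts and evaluation metrics, plus deltas."""

    gold_names: list[str]
    rows: list[dict]  # one dict per row: label, integration counts, metrics per gold

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows).set_index("threshold")

    def origin_row(self) -> dict:
        return next(r for r in self.rows if r["threshold"] == ORIGIN)

    def metric(self, gold: str, metric: str) -> dict:
        """Map row label -> metric value for one gold standard."""
        return {r["threshold"]: r[f"{gold}.{metric}"] for r in self.rows}

    def best_threshold(self, metric: str = "mmr") -> tuple[str, float]:
        """Row label with the highest average metric across gold standards."""
        best_label, best_val = None, float("-inf")
        for r in self.rows:
            avg = sum(r[f"{g}.{metric}"] for g in self.gold_names) / len(self.gold_names)
            if avg > best_val:
                best_label, best_val = r["threshold"], avg
        return best_label, best_val


def _relative_delta(value: float, origin: float) -> float:
    """Relative percent change vs the baseline (the Avg-delta convention)."""
    if origin == 0:
        return 0.0 if value == 0 else float("inf")
    return 100.0 * (value - origin) / origin


def run_sweep(
    net: PPINetwork,
    records: Sequence[LiteraturePPI],
    golds: Mapping[str, ComplexSet],
    config: SweepConfig | None = None,
) -> SweepResult:
    """Run the full threshold-sweep experiment.

    ``records`` must already be normalized to the network's identifier space.
    Each threshold restarts the integration from the original network, so the
    per-threshold edge counts are totals, not increments.  Returns a
    :class:`SweepResult` whose rows carry integration counts, every metric
    per gold standard, relative deltas vs the baseline, and the across-gold
    average delta.
    """
    config = config or SweepConfig()
    if not golds:
        raise ValueError("at least one gold standard is required")
    detector = get_detector(config.detector)

    def evaluate_network(network: PPINetwork) -> dict[str, EvaluationResult]:
        pred = detector(network, config.detection)
        return {name: evaluate_all(pred, gold, omega_min=config.omega_min) for name, gold in golds.items()}

    logger.info("sweep: evaluating baseline network (%s)", net)
    origin_metrics = evaluate_network(net)

    rows: list[dict] = []

    def make_row(label, report: IntegrationReport | None, metrics: dict[str, EvaluationResult]) -> dict:
        row: dict = {"threshold": label}
        if report is not None:
            row.update(
                n_candidates=report.n_candidates,
                n_added=report.n_added,
                n_skipped_unknown_protein=report.n_skipped_unknown_protein,
                n_skipped_duplicate=report.n_skipped_duplicate,
            )
        else:
            row.update(n_candidates=0, n_added=0, n_skipped_unknown_protein=0, n_skipped_duplicate=0)
        for gold_name, res in metrics.items():
            for metric in _METRICS:
                row[f"{gold_name}.{metric}"] = getattr(res, metric)
            row[f"{gold_name}.n_clusters"] = res.n_clusters
            row[f"{gold_name}.n_matched"] = res.n_matched
        if report is not None:
            deltas = {}
            for metric in ("acc", "mmr"):
                per_gold = []
                for gold_name, res in metrics.items():
                    d = _relative_delta(getattr(res, metric), getattr(origin_metrics[gold_name], metric))
                    row[f"{gold_name}.delta_{metric}"] = d
                    per_gold.append(d)
                deltas[metric] = sum(per_gold) / len(per_gold)
                row[f"avg_delta_{metric}"] = deltas[metric]
        return row

    rows.append(make_row(ORIGIN, None, origin_metrics))
    for threshold in config.thresholds:
        logger.info("sweep: threshold %.3g", threshold)
        merged, report = integrate(net, records, threshold, rescale=config.rescale)
        metrics = evaluate_network(merged)
        rows.append(make_row(threshold, report, metrics))

    return SweepResult(gold_names=list(golds), rows=rows)


def write_report(result: SweepResult, outdir: str | Path) -> dict[str, Path]:
    """Persist a sweep as sweep.csv, sweep.json and a plain-text summary.

    The summary names, for each gold standard and for the across-gold
    average, the threshold with the best MMR and accuracy.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / "sweep.csv"
    json_path = outdir / "sweep.json"
    txt_path = outdir / "summary.txt"

    df = result.to_dataframe()
    df.to_csv(csv_path)
    with json_path.open("w") as fh:
        json.dump({"gold_standards": result.gold_names, "rows": result.rows}, fh, indent=2)

    lines = ["Threshold sweep summary", "======================="]
    for metric in ("mmr", "acc"):
        label, value = result.best_threshold(metric)
        lines.append(f"best {metric.upper()} (avg over gold standards): threshold={label} value={value:.4f}")
        for gold in result.gold_names:
            series = result.metric(gold, metric)
            best_label = max(series, key=lambda k: series[k])
            lines.append(f"  {gold}: best threshold={best_label} {metric}={series[best_label]:.4f}")
    txt_path.write_text("\n".join(lines) + "\n")
    return {"csv": csv_path, "json": json_path, "summary": txt_path}
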