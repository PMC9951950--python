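"""Evaluation pipeline: subset paired data by diet group, evaluate each subset, write reports."""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .dataset import AnimalRecord, DietComposition, PairedSeries, to_paired
from .errors import ConfigurationError, InsufficientDataError
from .metrics import MetricSet, evaluate

logger = logging.getLogger(__name__)

#: Row labels in report order; percentages get 1 decimal, the rest 3.
ROW_LABELS = (
    "Mean S/O ratio",
    "Slope",
    "Mean bias (%)",
    "Coefficient of variation of S/O ratio (%)",
    "R^2",
    "Model efficiency",
    "Mean square prediction error",
    "Bias (%)",
    "Slope (%)",
    "Random (%)",
    "Concordance correlation coefficient",
    "Ca",
    "R",
)

_ROW_FIELDS = {
    "Mean S/O ratio": ("msor", 3),
    "Slope": ("slope", 3),
    "Mean bias (%)": ("mb_pct", 1),
    "Coefficient of variation of S/O ratio (%)": ("cv_so_pct", 1),
    "R^2": ("r2", 3),
    "Model efficiency": ("me", 3),
    "Mean square prediction error": ("mspe", 3),
    "Bias (%)": ("bias_pct", 1),
    "Slope (%)": ("slope_pct", 1),
    "Random (%)": ("random_pct", 1),
    "Concordance correlation coefficient": ("ccc", 3),
    "Ca": ("ca", 3),
    "R": ("r", 3),
}

ALL_LABEL = "All diets"
NO_GROUP_LABEL = "Without Leucaena"
GROUP_LABEL = "With Leucaena"


@dataclass
class EvaluationReport:
    """One evaluated variable: ordered (subset label, MetricSet) columns plus metadata."""

    variable: str
    columns: list[tuple[str, MetricSet]]
    metadata: dict = field(default_factory=dict)

    def column(self, label: str) -> MetricSet:
        for lab, ms in self.columns:
            if lab == label:
                return ms
        raise KeyError(label)

    def to_json(self) -> str:
        """Full-precision serialization (rounding is display-only)."""
        payload = {
            "variable": self.variable,
            "metadata": self.metadata,
            "columns": [
                {"label": lab, "metrics": ms.to_dict()} for lab, ms in self.columns
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def run_evaluation(
    records: Sequence[AnimalRecord],
    diets: Sequence[DietComposition],
    variable: str,
    split_by_group: bool = False,
    mode: str = "moment",
) -> EvaluationReport:
    """Evaluate all records, optionally also the with/without group subsets.

    With ``split_by_group`` the report has up to three columns (all diets,
    diets without the flagged legume, diets with it); a subset with fewer than
    three records is omitted with a warning rather than failing the run.
    """
    paired = to_paired(records, variable, diets)
    if len(paired) < 3:
        raise InsufficientDataError(
            f"need at least 3 paired records, got {len(paired)}"
        )
    columns: list[tuple[str, MetricSet]] = [(ALL_LABEL, evaluate(paired, mode=mode))]
    if split_by_group:
        for label, mask in (
            (NO_GROUP_LABEL, ~paired.group),
            (GROUP_LABEL, paired.group),
        ):
            n_sub = int(mask.sum())
            if n_sub < 3:
                logger.warning(
                    "subset %r has %d records (< 3); column omitted", label, n_sub
                )
                continue
            columns.append((label, evaluate(paired.subset(mask), mode=mode)))
    meta = {
        "variable": variable,
        "mode": mode,
        "split_by_group": split_by_group,
        "package_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    return EvaluationReport(variable=variable, columns=columns, metadata=meta)


def _fmt(value: float, decimals: int) -> str:
    return f"{value:.{decimals}f}"


def _table_rows(report: EvaluationReport) -> list[tuple[str, list[str]]]:
    rows = [("N", [str(ms.n) for _, ms in report.columns])]
    for label in ROW_LABELS:
        attr, decimals = _ROW_FIELDS[label]
        rows.append(
            (label, [_fmt(getattr(ms, attr), decimals) for _, ms in report.columns])
        )
    return rows


def write_report(
    report: EvaluationReport, path: str | Path, format: str = "markdown"
) -> Path:
    """Write a display-rounded report table (markdown or CSV) to ``path``."""
    if format not in {"markdown", "csv"}:
        raise ConfigurationError(f"format must be 'markdown' or 'csv', got {format!r}")
    path = Path(path)
    headers = [lab for lab, _ in report.columns]
    rows = _table_rows(report)
    lines: list[str] = []
    if format == "markdown":
        lines.append(f"# Evaluation report: {report.variable}")
        lines.append("")
        lines.append("| Descriptor | " + " | ".join(headers) + " |")
        lines.append("|" + "---|" * (len(headers) + 1))
        for label, values in rows:
            lines.append(f"| {label} | " + " | ".join(values) + " |")
    else:
        lines.append("descriptor," + ",".join(f'"{h}"' for h in headers))
        for label, values in rows:
            lines.append(f'"{label}",' + ",".join(values))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
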