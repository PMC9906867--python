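"""Full-analysis composition and report rendering.

``run_full_analysis`` chains the whole pipeline — estimate, factor
adjustments, Monte Carlo and bootstrap intervals, degree sensitivity scan,
demographic tables — into a single :class:`RunReport` that renders to a
machine-readable JSON document and a human-readable Markdown report.  The
JSON output is deterministic for fixed inputs and seed (sorted keys, no
timestamps), so pipelines can diff reruns byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .config import NetworkConfig, load_config
from .estimator import NetworkScaleUp, NsumResults
from .sensitivity import SensitivityRow
from .survey import AlterRecord, read_alters, read_survey, summarize_demographics
from .uncertainty import UncertaintyResult

__all__ = ["RunReport", "run_full_analysis"]

REPORT_SCHEMA_VERSION = 1

RESPONDENT_TABLE_VARS = ("gender", "age_group", "education", "marital_status")
ALTER_TABLE_VARS = (
    "age_group", "education", "marital_status", "n_children",
    "ever_alcohol", "ever_prison", "ever_drug",
)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunReport:
    """Structured result of a full scale-up analysis run."""

    config: NetworkConfig
    results: NsumResults
    intervals: list[UncertaintyResult]
    sensitivity: list[SensitivityRow]
    respondent_table: pd.DataFrame
    alter_table: pd.DataFrame | None
    provenance: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        def table(df: pd.DataFrame) -> list[dict]:
            out = df.reset_index()
            return [
                {
                    "variable": r.variable,
                    "category": r.category,
                    "count": int(r.count),
                    "percent": float(r.percent),
                }
                for r in out.itertuples()
            ]

        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "config": self.config.to_dict(),
            "estimates": self.results.to_dict(),
            "intervals": [iv.to_dict() for iv in self.intervals],
            "sensitivity": [
                {"scale": s.scale, "e_adjusted": s.e_adjusted,
                 "prevalence_per_1000": s.prevalence_per_1000}
                for s in self.sensitivity
            ],
            "demographics": {
                "respondents": table(self.respondent_table),
                "alters": table(self.alter_table) if self.alter_table is not None else None,
            },
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        """Canonical JSON rendering (sorted keys; byte-stable across reruns)."""
        doc = self.to_json_dict()
        _validate_schema(doc)
        return json.dumps(doc, sort_keys=True, indent=2) + "\n"

    def to_markdown(self) -> str:
        """Human-readable Markdown report (counts rounded to integers)."""
        res = self.results
        lines = [
            "# Network scale-up size estimation report",
            "",
            "## Point estimates",
            "",
            "| Quantity | Value |",
            "|---|---|",
            f"| Respondents (male/female) | {res.to_dict()['n_male']}/{res.to_dict()['n_female']} |",
            f"| Reported alters (sum m) | {res.sum_m} |",
            f"| Crude estimate | {round(res.e_crude)} |",
            f"| Adjusted for visibility | {round(res.e_vf)} |",
            f"| Adjusted for popularity | {round(res.e_pf)} |",
            f"| Adjusted for both factors | {round(res.e_adjusted)} |",
            f"| Prevalence per 1000 | {res.prevalence_per_1000:.2f} |",
            "",
            "## Uncertainty intervals",
            "",
            "| Method | Point | Lower | Upper | Percentiles | Replicates |",
            "|---|---|---|---|---|---|",
        ]
        for iv in self.intervals:
            lines.append(
                f"| {iv.method.value} | {round(iv.point)} | {round(iv.lower)} | "
                f"{round(iv.upper)} | {iv.level_low}-{iv.level_high} | {iv.n_replicates} |"
            )
        lines += ["", "## Sensitivity to personal network size", "",
                  "| Degree scale | Adjusted estimate | Prevalence per 1000 |", "|---|---|---|"]
        for s in self.sensitivity:
            lines.append(f"| {s.scale:g} | {round(s.e_adjusted)} | {s.prevalence_per_1000:.2f} |")

        def md_table(df: pd.DataFrame, title: str) -> list[str]:
            out = ["", f"## {title}", "", "| Variable | Category | Count | Percent |",
                   "|---|---|---|---|"]
            for (var, cat), row in df.iterrows():
                out.append(f"| {var} | {cat} | {int(row['count'])} | {row['percent']:.1f} |")
            return out

        lines += md_table(self.respondent_table, "Respondent demographics")
        if self.alter_table is not None:
            lines += md_table(self.alter_table, "Reported alter demographics")
        lines += ["", "## Provenance", ""]
        for key in sorted(self.provenance):
            lines.append(f"- {key}: {self.provenance[key]}")
        return "\n".join(lines) + "\n"

    def sensitivity_tsv(self) -> str:
        rows = ["scale\te_adjusted\tprevalence_per_1000"]
        rows += [f"{s.scale:g}\t{s.e_adjusted:.6f}\t{s.prevalence_per_1000:.6f}"
                 for s in self.sensitivity]
        return "\n".join(rows) + "\n"


_REQUIRED_TOP_KEYS = {
    "schema_version", "config", "estimates", "intervals",
    "sensitivity", "demographics", "provenance",
}


def _validate_schema(doc: dict) -> None:
    missing = _REQUIRED_TOP_KEYS - doc.keys()
    if missing:  # pragma: no cover - internal invariant
        raise ValueError(f"report document missing keys: {sorted(missing)}")
    if doc["schema_version"] != REPORT_SCHEMA_VERSION:  # pragma: no cover
        raise ValueError("unknown report schema version")


def run_full_analysis(
    survey_path: str | Path,
    config_path: str | Path,
    alters_path: str | Path | None = None,
    seed: int = 0,
    mc_replicates: int = 10_000,
    bootstrap_replicates: int = 10_000,
    percentiles: tuple[float, float] = (2.5, 97.5),
    scales: Sequence[float] = (0.9, 1.0, 1.1),
    sample_factors: bool = True,
) -> RunReport:
    """Run the complete analysis over a survey file and configuration.

    Returns a :class:`RunReport`; any I/O or validation failure raises
    before partial output is produced.  The Monte Carlo and bootstrap
    seeds are derived deterministically from ``seed``.
    """
    config = load_config(config_path)
    respondents = read_survey(survey_path)
    alters: list[AlterRecord] | None = None
    if alters_path is not None:
        alters = read_alters(alters_path, respondents=respondents)

    results = NetworkScaleUp(respondents, config).fit()
    mc = results.monte_carlo_interval(
        n_replicates=mc_replicates, percentiles=percentiles,
        sample_factors=sample_factors, seed=seed,
    )
    boot = results.bootstrap_interval(
        n_replicates=bootstrap_replicates, percentiles=percentiles, seed=seed + 1,
    )
    sens = results.sensitivity_scan(scales)

    respondent_table = summarize_demographics(
        respondents, RESPONDENT_TABLE_VARS, percent_denominator=config.percent_denominator
    )
    alter_table = None
    if alters:
        alter_table = summarize_demographics(
            alters, ALTER_TABLE_VARS, percent_denominator=config.percent_denominator
        )

    provenance = {
        "survey_sha256": _sha256(survey_path),
        "config_sha256": _sha256(config_path),
        "alters_sha256": _sha256(alters_path) if alters_path is not None else None,
        "seed": seed,
        "package_version": __version__,
    }
    return RunReport(
        config=config, results=results, intervals=[mc, boot],
        sensitivity=sens, respondent_table=respondent_table,
        alter_table=alter_table, provenance=provenance,
    )
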