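"""JSON report schema and the two-cohort category comparison.

The report mirrors the pipeline's summary/detail presentation: a summary
block with the fourteen Boolean calls plus the overall 'explained' flag,
and a detail block with continuous scores, units, thresholds and the
provenance of each threshold (calibrated vs conventional default).
Reports are pydantic-validated and serialised with a fixed key order so
they are stable for byte-level regression testing.
"""
from __future__ import annotations

import json
from typing import Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict
from scipy import stats

from .config import DEFAULT_CONFIG, AnalysisConfig
from .results import ANALYSIS_NAMES, AnalysisReport

SCHEMA_VERSION = "1"

# which config threshold applies to each analysis (None: count-based rule)
_THRESHOLD_FIELD = {
    "interface": "interface_dsasa_cutoff",
    "binding": "contact_distance",
    "sprotft": None,
    "clash": "clash_energy_cutoff",
    "void": "void_volume_cutoff",
    "cisproline": "cis_omega",
    "glycine": None,   # per-map threshold, echoed from the result
    "proline": None,
    "hbond": "hbond_distance",
    "corephilic": "core_rel_access",
    "surfacephobic": "core_rel_access",
    "buriedcharge": "contact_distance",
    "ssgeometry": "ss_distance",
    "impact": "conservation_cutoff",
}


class MutationBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    structure: str
    chain: str
    resnum: int
    insert_code: str
    native: str
    mutant: str
    mutation_key: str


class SummaryBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    flags: dict
    explained: bool


class AnalysisEntry(BaseModel):
    model_config = ConfigDict(extra="forbid")
    analysis: str
    applicable: bool
    flagged: bool
    score: Optional[float]
    units: str
    detail: str
    threshold: Optional[float]
    threshold_source: Optional[str]
    extras: dict


class ReportModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    schema_version: str
    mutation: MutationBlock
    summary: SummaryBlock
    detail: list[AnalysisEntry]
    parameters: dict


def build_report(report: AnalysisReport,
                 config: AnalysisConfig = DEFAULT_CONFIG) -> ReportModel:
    mut = report.mutation
    entries = []
    for name in ANALYSIS_NAMES:
        r = report.result(name)
        field = _THRESHOLD_FIELD[name]
        if field is not None:
            threshold = getattr(config, field)
            source = config.threshold_provenance.get(field, "default")
        elif name in ("glycine", "proline") and "threshold" in r.extras:
            threshold = float(r.extras["threshold"])
            source = "calibrated"
        else:
            threshold = None
            source = None
        entries.append(AnalysisEntry(
            analysis=name, applicable=r.applicable, flagged=r.flagged,
            score=None if r.score is None else float(r.score),
            units=r.units, detail=r.detail, threshold=threshold,
            threshold_source=source,
            extras={k: (float(v) if not isinstance(v, str) else v)
                    for k, v in r.extras.items()},
        ))
    return ReportModel(
        schema_version=SCHEMA_VERSION,
        mutation=MutationBlock(
            structure=mut.structure_ref, chain=mut.chain_id,
            resnum=mut.seq_num, insert_code=mut.insert_code,
            native=mut.native_aa, mutant=mut.mutant_aa,
            mutation_key=mut.mutation_key),
        summary=SummaryBlock(
            flags={name: report.result(name).flagged for name in ANALYSIS_NAMES},
            explained=report.explained),
        detail=entries,
        parameters={
            "clash_energy_cutoff": config.clash_energy_cutoff,
            "void_volume_cutoff": config.void_volume_cutoff,
            "interface_dsasa_cutoff": config.interface_dsasa_cutoff,
            "contact_distance": config.contact_distance,
            "hbond_distance": config.hbond_distance,
            "ss_distance": config.ss_distance,
            "core_rel_access": config.core_rel_access,
            "conservation_cutoff": config.conservation_cutoff,
            "cis_omega": config.cis_omega,
        },
    )


def report_json(report: AnalysisReport,
                config: AnalysisConfig = DEFAULT_CONFIG) -> str:
    return build_report(report, config).model_dump_json(indent=2)


def validate_report(data) -> ReportModel:
    """Parse/validate a report dict or JSON string against the schema."""
    if isinstance(data, str):
        data = json.loads(data)
    return ReportModel.model_validate(data)


def report_json_schema() -> dict:
    return ReportModel.model_json_schema()


def _flag_table(reports) -> list:
    out = []
    for rep in reports:
        if isinstance(rep, AnalysisReport):
            out.append({n: rep.result(n).flagged for n in ANALYSIS_NAMES})
        elif isinstance(rep, ReportModel):
            out.append(dict(rep.summary.flags))
        else:  # raw dict in report-JSON shape
            out.append(dict(rep["summary"]["flags"]))
    return out


def category_comparison(reports_a, reports_b) -> pd.DataFrame:
    """Per-analysis flagged fractions in two report sets with a
    two-sided Fisher's exact test on the 2x2 counts.

    Stars mark p < 0.05 (*) and p < 0.01 (**).  Fisher's exact test is
    this implementation's choice of significance method and is labelled
    in the output.
    """
    flags_a = _flag_table(reports_a)
    flags_b = _flag_table(reports_b)
    if not flags_a or not flags_b:
        raise ValueError("both report sets must be non-empty")
    rows = []
    for name in ANALYSIS_NAMES:
        ka = sum(f[name] for f in flags_a)
        kb = sum(f[name] for f in flags_b)
        na, nb = len(flags_a), len(flags_b)
        _, p = stats.fisher_exact([[ka, na - ka], [kb, nb - kb]],
                                  alternative="two-sided")
        rows.append({
            "analysis": name,
            "flagged_a": ka, "n_a": na, "frac_a": ka / na,
            "flagged_b": kb, "n_b": nb, "frac_b": kb / nb,
            "p_value": float(p),
            "stars": "**" if p < 0.01 else ("*" if p < 0.05 else ""),
            "test": "fisher_exact_two_sided",
        })
    return pd.DataFrame(rows)
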