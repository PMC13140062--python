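"""Serialization, figure-data exports and the end-to-end pipeline.

All writers are pure functions of their inputs plus configuration: rerunning
a pipeline with identical inputs produces byte-identical tables. Existing
outputs are never silently replaced — overwriting requires an explicit flag.

Delimited-format dialect: comma separator, UTF-8, mandatory header row,
"." decimal mark, the literal ``None`` for an empty isoform set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import config_hash, default_config
from .cyp import (
    CANONICAL_CELLS,
    CELL_COLUMNS,
    CypProbabilityMatrix,
    CypSummary,
    load_probability_matrix,
    summarize,
)
from .descriptors import CompoundRecord, PhysicochemicalProfile, profile_compound
from .errors import ContractError, ValidationError
from .risk import CypInhibitionFlags, RiskAssessment, RiskInput, classify_cohort

__all__ = [
    "PipelineConfig",
    "FigureDataExport",
    "PipelineResult",
    "read_compound_table",
    "read_smiles_file",
    "read_inhibition_flags",
    "read_risk_table",
    "profile_table",
    "risk_table",
    "summary_table",
    "export_figure_data",
    "run_pipeline",
]

PROFILE_COLUMNS = ("Compound", "MW", "cLogP", "GI", "BBB",
                   "LipinskiViolations", "BAScore", "CYPInhibition", "TPSA")


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs, outputs and settings of one end-to-end run."""

    compounds_path: str
    matrix_path: str
    out_dir: str
    flags_path: str | None = None
    threshold: float = 50.0
    seed: int = 0
    overwrite: bool = False
    charge_class: str = "neutral"
    settings: dict = field(default_factory=default_config)


@dataclass(frozen=True)
class FigureDataExport:
    """Plot-ready grids: a compound x cell heatmap and per-compound radar rings."""

    heatmap: pd.DataFrame  # rows: compounds (input order); columns: 10 cells
    radar: pd.DataFrame  # requested compounds only
    reference_level: float  # the configured Active threshold


@dataclass(frozen=True)
class PipelineResult:
    profiles: dict  # compound_id -> PhysicochemicalProfile
    summaries: tuple[CypSummary, ...]
    assessments: tuple[RiskAssessment, ...]
    counts: dict
    output_files: tuple[str, ...]


# -- readers ----------------------------------------------------------------

def read_compound_table(path) -> list[CompoundRecord]:
    """Delimited compound table: compound_id,name,smiles,phytochemical_class."""
    df = pd.read_csv(path)
    required = {"compound_id", "name", "smiles"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise ValidationError([f"missing column: {c}" for c in missing])
    if df.empty:
        raise ValidationError(f"compound table {path!s} contains no rows")
    dupes = df["compound_id"][df["compound_id"].duplicated()].unique()
    if len(dupes):
        raise ValidationError([f"duplicate compound_id: {d}" for d in dupes])
    records = []
    for _, r in df.iterrows():
        cls = r.get("phytochemical_class", "other")
        if pd.isna(cls):
            cls = "other"
        records.append(CompoundRecord(str(r["compound_id"]), str(r["name"]),
                                      str(r["smiles"]), str(cls)))
    return records


def read_smiles_file(path) -> list[CompoundRecord]:
    """SMILES file: one record per line — SMILES, whitespace, identifier."""
    records = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise ValidationError(
                    f"{path!s}:{lineno}: expected 'SMILES identifier', got {line!r}"
                )
            smiles, ident = parts
            records.append(CompoundRecord(ident.strip(), ident.strip(), smiles))
    if not records:
        raise ValidationError(f"SMILES file {path!s} contains no records")
    return records


def read_inhibition_flags(path) -> dict:
    """SwissADME-style boolean flag table -> compound_id to CypInhibitionFlags."""
    df = pd.read_csv(path)
    if "compound_id" not in df.columns:
        raise ValidationError("missing column: compound_id")
    iso_cols = [c for c in df.columns if c.startswith("CYP")]
    if not iso_cols:
        raise ValidationError("flag table names no CYP isoform columns")
    truthy = {"yes", "true", "1", "active", "inhibitor"}
    flags = {}
    for _, r in df.iterrows():
        cid = str(r["compound_id"])
        isoforms = frozenset(
            c for c in iso_cols
            if str(r[c]).strip().lower() in truthy or r[c] is True
        )
        flags[cid] = CypInhibitionFlags(cid, isoforms)
    return flags


def read_risk_table(path) -> list[RiskInput]:
    """Risk-input table matching the published layout (see fixtures)."""
    df = pd.read_csv(path)
    required = {"compound_id", "mean_probability", "cyp_inhibition",
                "gi_absorption", "bbb_permeant", "lipinski_violations"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise ValidationError([f"missing column: {c}" for c in missing])
    return [
        RiskInput(
            compound_id=str(r["compound_id"]),
            mean_probability=float(r["mean_probability"]),
            inhibition=CypInhibitionFlags.from_string(str(r["compound_id"]),
                                                      str(r["cyp_inhibition"])),
            gi_absorption=str(r["gi_absorption"]),
            bbb_permeant=str(r["bbb_permeant"]),
            lipinski_violations=int(r["lipinski_violations"]),
        )
        for _, r in df.iterrows()
    ]


# -- table builders ---------------------------------------------------------

def profile_table(
    profiles: dict,
    flags: dict | None = None,
    cfg: dict | None = None,
) -> pd.DataFrame:
    """ADME-summary-shaped table from computed profiles.

    ``flags`` supplies the CYPInhibition column (ingested, not computed);
    compounds without flags print ``None``.
    """
    cfg = cfg or default_config()
    flags = flags or {}
    rows = []
    for cid, p in profiles.items():
        inh = flags.get(cid)
        rows.append({
            "Compound": cid,
            "MW": round(p.mw, cfg["mw_decimals"]),
            "cLogP": round(p.logp_consensus, cfg["logp_decimals"]),
            "GI": p.gi_absorption,
            "BBB": p.bbb_permeant,
            "LipinskiViolations": p.lipinski_violations,
            "BAScore": p.ba_score,
            "CYPInhibition": inh.to_string() if inh is not None else "None",
            "TPSA": round(p.tpsa, cfg["tpsa_decimals"]),
        })
    return pd.DataFrame(rows, columns=list(PROFILE_COLUMNS))


def summary_table(summaries, cfg: dict | None = None) -> pd.DataFrame:
    cfg = cfg or default_config()
    return pd.DataFrame(
        [
            {
                "compound_id": s.compound_id,
                "mean_probability": round(s.mean_probability, cfg["mean_decimals"]),
                "active_count": s.active_count,
                "primary_target": s.primary_target,
            }
            for s in summaries
        ]
    )


def risk_table(inputs, assessments, cfg: dict | None = None) -> pd.DataFrame:
    cfg = cfg or default_config()
    rows = []
    for inp, a in zip(inputs, assessments):
        rows.append({
            "compound_id": inp.compound_id,
            "mean_probability": round(inp.mean_probability, cfg["mean_decimals"]),
            "cyp_inhibition": inp.inhibition.to_string(),
            "gi_absorption": inp.gi_absorption,
            "bbb_permeant": inp.bbb_permeant,
            "lipinski_violations": inp.lipinski_violations,
            "risk_level": a.level,
            "fired_rule": a.fired_rule,
        })
    return pd.DataFrame(rows)


def export_figure_data(
    summaries,
    matrices,
    radar_compounds=None,
    threshold: float = 50.0,
) -> FigureDataExport:
    """Heatmap and radar grids in canonical cell order.

    Heatmap rows follow the input order of ``matrices``; the radar frame
    contains exactly the requested compounds (default: all).
    """
    by_id = {m.compound_id: m for m in matrices}
    radar_compounds = list(radar_compounds) if radar_compounds is not None else list(by_id)
    missing = [c for c in radar_compounds if c not in by_id]
    if missing:
        raise ContractError(f"requested compounds not in matrices: {missing}")

    def grid_rows(ids):
        rows = []
        for cid in ids:
            m = by_id[cid]
            rows.append({"compound_id": cid,
                         **{col: m.probabilities.get(cell)
                            for cell, col in zip(CANONICAL_CELLS, CELL_COLUMNS)}})
        return pd.DataFrame(rows, columns=["compound_id", *CELL_COLUMNS])

    return FigureDataExport(
        heatmap=grid_rows([m.compound_id for m in matrices]),
        radar=grid_rows(radar_compounds),
        reference_level=threshold,
    )


# -- end-to-end pipeline ----------------------------------------------------

def _write(df: pd.DataFrame, path: Path, overwrite: bool, written: list):
    if path.exists() and not overwrite:
        raise ValidationError(f"refusing to overwrite existing output {path}")
    df.to_csv(path, index=False)
    written.append(str(path))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run structures -> profiles -> CYP summaries -> risk report.

    Validation errors across all inputs are collected and raised together;
    nothing is written unless every input validates.
    """
    cfg = config.settings
    problems = []
    records = matrices = flags = None
    try:
        records = read_compound_table(config.compounds_path)
    except ValidationError as e:
        problems.extend(f"compounds: {p}" for p in e.problems)
    try:
        matrices = load_probability_matrix(config.matrix_path)
    except ValidationError as e:
        problems.extend(f"matrix: {p}" for p in e.problems)
    if config.flags_path is not None:
        try:
            flags = read_inhibition_flags(config.flags_path)
        except ValidationError as e:
            problems.extend(f"flags: {p}" for p in e.problems)
    if problems:
        raise ValidationError(problems)

    profiles = {r.compound_id: profile_compound(r, config.charge_class, cfg) for r in records}
    summaries = tuple(summarize(m, config.threshold) for m in matrices)
    flags = flags or {}

    sum_by_id = {s.compound_id: s for s in summaries}
    inputs = []
    for r in records:
        if r.compound_id not in sum_by_id:
            problems.append(f"no probability matrix for compound {r.compound_id!r}")
            continue
        p = profiles[r.compound_id]
        inputs.append(RiskInput(
            compound_id=r.compound_id,
            mean_probability=sum_by_id[r.compound_id].mean_probability,
            inhibition=flags.get(r.compound_id, CypInhibitionFlags(r.compound_id)),
            gi_absorption=p.gi_absorption,
            bbb_permeant=p.bbb_permeant,
            lipinski_violations=p.lipinski_violations,
        ))
    if problems:
        raise ValidationError(problems)

    cohort = classify_cohort(inputs, cfg)
    fig = export_figure_data(summaries, matrices, threshold=config.threshold)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    _write(profile_table(profiles, flags, cfg), out / "profiles.csv", config.overwrite, written)
    _write(summary_table(summaries, cfg), out / "cyp_summaries.csv", config.overwrite, written)
    _write(risk_table(inputs, cohort.assessments, cfg), out / "risk_report.csv",
           config.overwrite, written)
    _write(fig.heatmap, out / "figure_heatmap.csv", config.overwrite, written)
    _write(fig.radar, out / "figure_radar.csv", config.overwrite, written)

    counts_df = pd.DataFrame(
        [{"risk_level": k, "count": v} for k, v in cohort.counts.items()]
    )
    _write(counts_df, out / "cohort_summary.csv", config.overwrite, written)

    log_path = out / "run_log.txt"
    if log_path.exists() and not config.overwrite:
        raise ValidationError(f"refusing to overwrite existing output {log_path}")
    log_lines = [
        f"herbcyp {__version__}",
        f"config_hash {config_hash(cfg)}",
        f"seed {config.seed}",
        f"threshold {config.threshold}",
        f"charge_class {config.charge_class}",
        f"compounds {config.compounds_path}",
        f"matrix {config.matrix_path}",
        f"flags {config.flags_path}",
        "fixture_snapshot curated literature structures, validated against known formulas",
    ]
    log_path.write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    written.append(str(log_path))

    return PipelineResult(
        profiles=profiles,
        summaries=summaries,
        assessments=cohort.assessments,
        counts=cohort.counts,
        output_files=tuple(written),
    )
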