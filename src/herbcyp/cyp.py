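"""CYP450 interaction-probability matrices.

Each compound carries up to ten interaction probabilities — five isoforms
(CYP1A2, CYP2C9, CYP2C19, CYP2D6, CYP3A4) crossed with two fingerprint
methods (MACCS keys, Morgan circular) — on a percent scale. This module
ingests such matrices from delimited exports, applies the Active/Inactive
threshold call (Active strictly above 50%), aggregates per-compound
summaries and validates a reference-inhibitor benchmark panel.

Probabilities are stored on the percent scale [0, 100] throughout. Files
whose values all lie in [0, 1] are assumed to be on the fraction scale and
are converted once at load time, with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .errors import ContractError, ValidationError

__all__ = [
    "ISOFORMS",
    "FINGERPRINT_METHODS",
    "CANONICAL_CELLS",
    "CELL_COLUMNS",
    "CypProbabilityMatrix",
    "ActivityCall",
    "CypSummary",
    "BenchmarkRow",
    "load_probability_matrix",
    "load_benchmark_panel",
    "classify_activity",
    "summarize",
    "benchmark_validate",
]

ISOFORMS = ("CYP1A2", "CYP2C9", "CYP2C19", "CYP2D6", "CYP3A4")
FINGERPRINT_METHODS = ("MACCS", "Morgan")

#: canonical cell order: isoform order crossed with (MACCS, Morgan)
CANONICAL_CELLS = tuple((iso, m) for iso in ISOFORMS for m in FINGERPRINT_METHODS)
CELL_COLUMNS = tuple(f"{iso}_{m}" for iso, m in CANONICAL_CELLS)

DEFAULT_THRESHOLD = 50.0


@dataclass(frozen=True)
class CypProbabilityMatrix:
    """Per-compound interaction probabilities (percent scale).

    ``probabilities`` holds only the cells present in the source data;
    absent cells are never imputed.
    """

    compound_id: str
    probabilities: dict  # (isoform, method) -> percent

    def __post_init__(self):
        for cell, value in self.probabilities.items():
            if cell not in CANONICAL_CELLS:
                raise ContractError(f"{self.compound_id}: unknown cell {cell!r}")
            if not 0.0 <= value <= 100.0:
                raise ContractError(
                    f"{self.compound_id}: probability {value} for {cell} outside [0, 100]"
                )

    @property
    def completeness_mask(self) -> dict:
        """Which of the ten canonical cells are present."""
        return {cell: cell in self.probabilities for cell in CANONICAL_CELLS}

    @property
    def n_present(self) -> int:
        return len(self.probabilities)

    def values_in_canonical_order(self) -> list:
        """Present cell values, canonical cell order."""
        return [self.probabilities[c] for c in CANONICAL_CELLS if c in self.probabilities]


@dataclass(frozen=True)
class ActivityCall:
    """Threshold classification of one probability cell."""

    probability: float
    call: str  # "Active" | "Inactive"
    cell: tuple | None = None

    @property
    def is_active(self) -> bool:
        return self.call == "Active"


@dataclass(frozen=True)
class CypSummary:
    """Aggregate view of one compound's probability matrix."""

    compound_id: str
    mean_probability: float  # unweighted mean over present cells, percent
    active_count: int
    primary_target: str  # isoform of the maximum cell, canonical-order ties
    per_isoform_max: dict = field(default_factory=dict)


@dataclass(frozen=True)
class BenchmarkRow:
    """One reference inhibitor with its expected primary isoform."""

    name: str
    expected_isoform: str
    probabilities: dict  # (isoform, method) -> percent

    def __post_init__(self):
        if self.expected_isoform not in ISOFORMS:
            raise ContractError(
                f"{self.name}: expected isoform {self.expected_isoform!r} "
                f"is not one of {ISOFORMS}"
            )


def _resolve_scale(df: pd.DataFrame, cols, source: str) -> pd.DataFrame:
    values = df[list(cols)].to_numpy(dtype=float)
    finite = values[~pd.isna(values)]
    if finite.size and finite.max() <= 1.0:
        warnings.warn(
            f"{source}: all probabilities lie in [0, 1]; assuming fraction "
            "scale and converting to percent",
            stacklevel=3,
        )
        df = df.copy()
        df[list(cols)] = df[list(cols)] * 100.0
    return df


def load_probability_matrix(path) -> list[CypProbabilityMatrix]:
    """Read a delimited probability-matrix export.

    The header must name the compound id and the ten canonical cells
    (``CYP1A2_MACCS`` ... ``CYP3A4_Morgan``). Blank cells are recorded as
    missing, never imputed. Values outside [0, 100] after scale resolution
    and duplicate compound ids raise :class:`ValidationError`.
    """
    df = pd.read_csv(path)
    problems = []
    if "compound_id" not in df.columns:
        problems.append("missing column: compound_id")
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    problems.extend(f"missing column: {c}" for c in missing)
    if problems:
        raise ValidationError(problems)

    df = _resolve_scale(df, CELL_COLUMNS, str(path))

    dupes = df["compound_id"][df["compound_id"].duplicated()].unique()
    problems.extend(f"duplicate compound_id: {d}" for d in dupes)

    matrices = []
    for _, row in df.iterrows():
        probs = {}
        for cell, col in zip(CANONICAL_CELLS, CELL_COLUMNS):
            v = row[col]
            if pd.isna(v):
                continue
            if not 0.0 <= float(v) <= 100.0:
                problems.append(
                    f"row {row['compound_id']!r}: value {v} in {col} outside [0, 100]"
                )
                continue
            probs[cell] = float(v)
        if not problems:
            matrices.append(CypProbabilityMatrix(str(row["compound_id"]), probs))
    if problems:
        raise ValidationError(problems)
    return matrices


def load_benchmark_panel(path) -> list[BenchmarkRow]:
    """Read a benchmark panel table (``name,expected_isoform,<cells...>``)."""
    df = pd.read_csv(path)
    required = {"name", "expected_isoform"}
    if not required.issubset(df.columns):
        raise ValidationError([f"missing column: {c}" for c in sorted(required - set(df.columns))])
    cols = [c for c in CELL_COLUMNS if c in df.columns]
    df = _resolve_scale(df, cols, str(path))
    rows = []
    for _, r in df.iterrows():
        probs = {}
        for cell, col in zip(CANONICAL_CELLS, CELL_COLUMNS):
            if col in df.columns and not pd.isna(r[col]):
                probs[cell] = float(r[col])
        rows.append(BenchmarkRow(str(r["name"]), str(r["expected_isoform"]), probs))
    return rows


def classify_activity(
    probability: float,
    threshold: float = DEFAULT_THRESHOLD,
    cell: tuple | None = None,
) -> ActivityCall:
    """Active/Inactive call for one probability (percent scale).

    The inequality is strict: a probability exactly at the threshold is
    Inactive.
    """
    if not 0.0 <= probability <= 100.0:
        raise ContractError(f"probability {probability} outside [0, 100]")
    call = "Active" if probability > threshold else "Inactive"
    return ActivityCall(probability=probability, call=call, cell=cell)


def summarize(matrix: CypProbabilityMatrix, threshold: float = DEFAULT_THRESHOLD) -> CypSummary:
    """Aggregate one probability matrix.

    The mean is the unweighted arithmetic mean over the *present* cells; the
    primary target is the isoform holding the maximum cell, with ties broken
    by canonical isoform order.
    """
    if matrix.n_present == 0:
        raise ContractError(f"{matrix.compound_id}: cannot summarize an empty matrix")
    values = matrix.values_in_canonical_order()
    mean = sum(values) / len(values)
    active = sum(
        classify_activity(matrix.probabilities[c], threshold, cell=c).is_active
        for c in CANONICAL_CELLS
        if c in matrix.probabilities
    )
    per_iso_max = {}
    for (iso, _), v in matrix.probabilities.items():
        per_iso_max[iso] = max(per_iso_max.get(iso, 0.0), v)
    primary = max(
        (iso for iso in ISOFORMS if iso in per_iso_max),
        key=lambda iso: (per_iso_max[iso], -ISOFORMS.index(iso)),
    )
    return CypSummary(
        compound_id=matrix.compound_id,
        mean_probability=mean,
        active_count=active,
        primary_target=primary,
        per_isoform_max=per_iso_max,
    )


def benchmark_validate(
    panel: list[BenchmarkRow],
    threshold: float = DEFAULT_THRESHOLD,
) -> int:
    """Count panel rows whose expected primary isoform is called Active.

    A row validates when at least one fingerprint method's probability for
    the expected isoform exceeds the threshold.
    """
    if not panel:
        warnings.warn("benchmark panel is empty", stacklevel=2)
        return 0
    correct = 0
    for row in panel:
        cells = [
            row.probabilities[(row.expected_isoform, m)]
            for m in FINGERPRINT_METHODS
            if (row.expected_isoform, m) in row.probabilities
        ]
        if not cells:
            raise ContractError(
                f"{row.name}: no probability cell for expected isoform {row.expected_isoform}"
            )
        if any(classify_activity(v, threshold).is_active for v in cells):
            correct += 1
    return correct
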