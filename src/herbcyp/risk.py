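"""Four-level integrated herb-drug interaction risk classifier.

A compound's risk level combines five signals: its mean CYP interaction
probability, the set of isoforms it is independently predicted to inhibit,
its gastrointestinal absorption class, blood-brain-barrier permeation and
rule-of-five violation count. The ruleset is an ordered first-match cascade:

R1  mean > 50% with High GI absorption, confirmed inhibition of at least one
    isoform and zero violations                                     -> HIGH
R2  mean >= 30% with High GI absorption and confirmed inhibition:
    inhibition of >= 4 of the 5 isoforms with zero violations escalates to
    HIGH (breadth escalation); otherwise                            -> MODERATE
R3  mean < 30% with Low GI absorption, no confirmed inhibition and no
    BBB permeation                                                  -> NEGLIGIBLE
R4  everything else                                                 -> LOW

R2 has no upper probability cap: a compound above 50% that misses HIGH only
on drug-likeness stays MODERATE rather than falling through to LOW, which
keeps the level monotone in the mean probability. Every classification
carries a rule trace naming the rules evaluated and the one that fired —
the framework is exploratory, so each call must be auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import default_config
from .cyp import ISOFORMS
from .errors import ContractError

__all__ = [
    "RISK_LEVELS",
    "LEVEL_ORDER",
    "CypInhibitionFlags",
    "RiskInput",
    "RuleEvaluation",
    "RiskAssessment",
    "CohortClassification",
    "classify_risk",
    "classify_cohort",
]

RISK_LEVELS = ("NEGLIGIBLE", "LOW", "MODERATE", "HIGH")
LEVEL_ORDER = {level: i for i, level in enumerate(RISK_LEVELS)}

# short isoform tokens as printed in tables ("1A2", "None", ...)
_SHORT = {iso.replace("CYP", ""): iso for iso in ISOFORMS}


@dataclass(frozen=True)
class CypInhibitionFlags:
    """The isoforms a compound is independently predicted to inhibit."""

    compound_id: str
    inhibited_isoforms: frozenset = frozenset()

    def __post_init__(self):
        bad = set(self.inhibited_isoforms) - set(ISOFORMS)
        if bad:
            raise ContractError(f"{self.compound_id}: unknown isoforms {sorted(bad)}")
        object.__setattr__(self, "inhibited_isoforms", frozenset(self.inhibited_isoforms))

    @classmethod
    def from_string(cls, compound_id: str, text: str) -> "CypInhibitionFlags":
        """Parse a printed isoform list: ``"1A2;2D6"``, ``"1A2, 2D6"`` or ``"None"``."""
        if text is None or isinstance(text, float):  # NaN from a blank cell
            text = ""
        text = str(text).strip()
        if not text or text.lower() in ("none", "nan"):
            return cls(compound_id, frozenset())
        tokens = [t.strip() for t in text.replace(";", ",").split(",") if t.strip()]
        isoforms = set()
        for t in tokens:
            full = t if t in ISOFORMS else _SHORT.get(t)
            if full is None:
                raise ContractError(f"{compound_id}: unknown isoform token {t!r}")
            isoforms.add(full)
        return cls(compound_id, frozenset(isoforms))

    def to_string(self) -> str:
        if not self.inhibited_isoforms:
            return "None"
        ordered = [iso for iso in ISOFORMS if iso in self.inhibited_isoforms]
        return ";".join(iso.replace("CYP", "") for iso in ordered)


@dataclass(frozen=True)
class RiskInput:
    """Everything the classifier looks at for one compound."""

    compound_id: str
    mean_probability: float  # percent
    inhibition: CypInhibitionFlags
    gi_absorption: str  # "High" | "Low"
    bbb_permeant: str  # "Yes" | "No"
    lipinski_violations: int

    def __post_init__(self):
        if not 0.0 <= self.mean_probability <= 100.0:
            raise ContractError(
                f"{self.compound_id}: mean_probability {self.mean_probability} outside [0, 100]"
            )
        if self.gi_absorption not in ("High", "Low"):
            raise ContractError(f"{self.compound_id}: gi_absorption must be High or Low")
        if self.bbb_permeant not in ("Yes", "No"):
            raise ContractError(f"{self.compound_id}: bbb_permeant must be Yes or No")
        if not 0 <= int(self.lipinski_violations) <= 4:
            raise ContractError(
                f"{self.compound_id}: lipinski_violations must lie in 0-4, "
                f"got {self.lipinski_violations}"
            )


@dataclass(frozen=True)
class RuleEvaluation:
    rule_id: str
    fired: bool
    detail: str = ""


@dataclass(frozen=True)
class RiskAssessment:
    compound_id: str
    level: str
    rule_trace: tuple[RuleEvaluation, ...]

    @property
    def fired_rule(self) -> str:
        return next(e.rule_id for e in self.rule_trace if e.fired)


@dataclass(frozen=True)
class CohortClassification:
    assessments: tuple[RiskAssessment, ...]
    counts: dict = field(default_factory=dict)


def classify_risk(inp: RiskInput, cfg: dict | None = None) -> RiskAssessment:
    """Classify one compound; deterministic first-match over R1..R4."""
    cfg = cfg or default_config()
    high_cut = cfg["risk_high_mean_percent"]
    mod_cut = cfg["risk_moderate_mean_percent"]
    breadth = cfg["risk_breadth_escalation_isoforms"]

    inhibited = len(inp.inhibition.inhibited_isoforms)
    gi_high = inp.gi_absorption == "High"
    trace = []

    r1 = inp.mean_probability > high_cut and gi_high and inhibited >= 1 \
        and inp.lipinski_violations == 0
    trace.append(RuleEvaluation("R1", r1, f"mean>{high_cut}, High GI, inhibition, 0 violations"))
    if r1:
        return RiskAssessment(inp.compound_id, "HIGH", tuple(trace))

    r2 = inp.mean_probability >= mod_cut and gi_high and inhibited >= 1
    if r2 and inhibited >= breadth and inp.lipinski_violations == 0:
        trace.append(RuleEvaluation("R2", True, f">={breadth} isoforms inhibited: breadth escalation"))
        return RiskAssessment(inp.compound_id, "HIGH", tuple(trace))
    trace.append(RuleEvaluation("R2", r2, f"mean>={mod_cut}, High GI, inhibition"))
    if r2:
        return RiskAssessment(inp.compound_id, "MODERATE", tuple(trace))

    r3 = inp.mean_probability < mod_cut and not gi_high and inhibited == 0 \
        and inp.bbb_permeant == "No"
    trace.append(RuleEvaluation("R3", r3, f"mean<{mod_cut}, Low GI, no inhibition, BBB No"))
    if r3:
        return RiskAssessment(inp.compound_id, "NEGLIGIBLE", tuple(trace))

    trace.append(RuleEvaluation("R4", True, "default"))
    return RiskAssessment(inp.compound_id, "LOW", tuple(trace))


def classify_cohort(inputs, cfg: dict | None = None) -> CohortClassification:
    """Classify a cohort; per-compound order is preserved.

    Raises on an empty list or duplicate compound ids.
    """
    inputs = list(inputs)
    if not inputs:
        raise ContractError("cannot classify an empty cohort")
    seen, dupes = set(), set()
    for inp in inputs:
        if inp.compound_id in seen:
            dupes.add(inp.compound_id)
        seen.add(inp.compound_id)
    if dupes:
        raise ContractError(f"duplicate compound ids: {sorted(dupes)}")
    assessments = tuple(classify_risk(inp, cfg) for inp in inputs)
    counts = {level: 0 for level in RISK_LEVELS}
    for a in assessments:
        counts[a.level] += 1
    return CohortClassification(assessments=assessments, counts=counts)
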