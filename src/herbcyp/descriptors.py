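"""Physicochemical, drug-likeness and oral-exposure descriptors from SMILES.

One function per descriptor, composed by :func:`profile_compound` into a
:class:`PhysicochemicalProfile` — the per-compound row of an ADME summary
table: molecular weight, lipophilicity estimates, topological polar surface
area (Ertl fragment method, S/P contributions included), H-bond donor and
acceptor counts, rule-of-five violations, the Abbott bioavailability score
and the BOILED-Egg gastrointestinal-absorption / blood-brain-barrier call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import Descriptors, Lipinski

from .config import default_config
from .errors import ContractError, EmptySmilesError, SmilesParseError
from .lipophilicity import LipophilicityEstimates, estimate_logp, has_unparameterized_atoms

__all__ = [
    "PHYTOCHEMICAL_CLASSES",
    "CHARGE_CLASSES",
    "BA_SCORE_VALUES",
    "CompoundRecord",
    "MolecularStructure",
    "PhysicochemicalProfile",
    "BoiledEggParams",
    "parse_structure",
    "compute_molecular_weight",
    "compute_tpsa",
    "compute_logp",
    "count_lipinski_violations",
    "abbott_bioavailability_score",
    "boiled_egg_classify",
    "profile_compound",
]

PHYTOCHEMICAL_CLASSES = (
    "aporphine",
    "benzylisoquinoline",
    "proaporphine",
    "indolizidine",
    "acetogenin",
    "sesquiterpene",
    "other",
)

CHARGE_CLASSES = ("neutral", "anion", "cation", "zwitterion")

#: the five values the Abbott bioavailability score can take
BA_SCORE_VALUES = (0.11, 0.17, 0.55, 0.56, 0.85)


@dataclass(frozen=True)
class CompoundRecord:
    """Identity and structure of one compound."""

    compound_id: str
    name: str
    smiles: str
    phytochemical_class: str = "other"

    def __post_init__(self):
        if not self.compound_id:
            raise ContractError("compound_id must be non-empty")
        if not self.smiles or not self.smiles.strip():
            raise ContractError(f"compound {self.compound_id!r}: smiles must be non-empty")
        if self.phytochemical_class not in PHYTOCHEMICAL_CLASSES:
            raise ContractError(
                f"compound {self.compound_id!r}: unknown phytochemical class "
                f"{self.phytochemical_class!r}"
            )


@dataclass(frozen=True)
class MolecularStructure:
    """A sanitized molecular graph with a consistent implicit-hydrogen model."""

    mol: Chem.Mol
    canonical_smiles: str
    heavy_atom_count: int


@dataclass(frozen=True)
class PhysicochemicalProfile:
    """One row of the ADME descriptor table."""

    mw: float
    logp_consensus: float
    logp_wildman_crippen: float
    logp_lipinski_criterion: float
    tpsa: float
    hbd: int
    hba: int
    lipinski_violations: int
    lipinski_pass: bool
    ba_score: float
    gi_absorption: str  # "High" | "Low"
    bbb_permeant: str  # "Yes" | "No"
    provenance: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if self.mw <= 0:
            raise ContractError(f"mw must be positive, got {self.mw}")
        if self.tpsa < 0:
            raise ContractError(f"tpsa must be non-negative, got {self.tpsa}")
        if self.lipinski_pass != (self.lipinski_violations <= 1):
            raise ContractError("lipinski_pass must equal (violations <= 1)")
        if self.ba_score not in BA_SCORE_VALUES:
            raise ContractError(f"ba_score {self.ba_score} not in {BA_SCORE_VALUES}")


@dataclass(frozen=True)
class BoiledEggParams:
    """The two best-fit ellipses in (TPSA, WLOGP) space.

    ``width``/``height`` are full axis lengths; ``angle_deg`` rotates the
    ellipse counter-clockwise. Membership on the boundary counts as inside.
    """

    white_cx: float
    white_cy: float
    white_width: float
    white_height: float
    white_angle_deg: float
    yolk_cx: float
    yolk_cy: float
    yolk_width: float
    yolk_height: float
    yolk_angle_deg: float

    @classmethod
    def from_config(cls, cfg: dict | None = None) -> "BoiledEggParams":
        cfg = cfg or default_config()
        return cls(
            white_cx=cfg["egg_white_cx"],
            white_cy=cfg["egg_white_cy"],
            white_width=cfg["egg_white_width"],
            white_height=cfg["egg_white_height"],
            white_angle_deg=cfg["egg_white_angle_deg"],
            yolk_cx=cfg["egg_yolk_cx"],
            yolk_cy=cfg["egg_yolk_cy"],
            yolk_width=cfg["egg_yolk_width"],
            yolk_height=cfg["egg_yolk_height"],
            yolk_angle_deg=cfg["egg_yolk_angle_deg"],
        )


def parse_structure(smiles: str) -> MolecularStructure:
    """Parse and sanitize a SMILES string.

    Hydrogens stay implicit throughout; every descriptor operation works on
    the same sanitized graph, so re-profiling the canonical SMILES of a
    molecule reproduces its profile.
    """
    if smiles is None or not str(smiles).strip():
        raise EmptySmilesError()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return MolecularStructure(
        mol=mol,
        canonical_smiles=Chem.MolToSmiles(mol),
        heavy_atom_count=mol.GetNumHeavyAtoms(),
    )


def compute_molecular_weight(struct: MolecularStructure) -> float:
    """Average-isotopic molecular weight in g/mol, implicit hydrogens included."""
    return Descriptors.MolWt(struct.mol)


def compute_tpsa(struct: MolecularStructure) -> float:
    """Ertl fragment-contribution topological polar surface area (S and P
    fragment contributions included). Exactly zero for pure hydrocarbons."""
    return Descriptors.TPSA(struct.mol, includeSandP=True)


def compute_logp(struct: MolecularStructure) -> LipophilicityEstimates:
    """Wildman-Crippen, Moriguchi and consensus lipophilicity estimates."""
    return estimate_logp(struct.mol)


def count_lipinski_violations(
    mw: float,
    logp_lipinski_criterion: float,
    hbd: int,
    hba: int,
    cfg: dict | None = None,
) -> int:
    """Count violated rule-of-five conditions (0-4).

    Conditions: MW > 500, MLOGP > 4.15, H-bond donors > 5, H-bond acceptors
    (N + O count) > 10. Cutoffs come from the configuration.
    """
    for name, v in (("mw", mw), ("logp", logp_lipinski_criterion), ("hbd", hbd), ("hba", hba)):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ContractError(f"lipinski counting requires {name} to be populated")
    cfg = cfg or default_config()
    return sum(
        [
            mw > cfg["mw_lipinski_cutoff"],
            logp_lipinski_criterion > cfg["mlogp_lipinski_cutoff"],
            hbd > cfg["hbd_lipinski_cutoff"],
            hba > cfg["hba_lipinski_cutoff"],
        ]
    )


def abbott_bioavailability_score(
    lipinski_violations: int,
    tpsa: float,
    charge_class: str = "neutral",
    cfg: dict | None = None,
) -> float:
    """Abbott bioavailability score from the published decision tree.

    Anions are scored on polar surface area alone (PSA <= 75 -> 0.85,
    75 < PSA <= 150 -> 0.56, PSA > 150 -> 0.11); everything else is scored on
    rule-of-five status (pass, i.e. at most one violation -> 0.55, fail ->
    0.17). Charge class defaults to neutral — no pKa model is applied.
    """
    if charge_class not in CHARGE_CLASSES:
        raise ContractError(f"unknown charge_class {charge_class!r}; expected one of {CHARGE_CLASSES}")
    if lipinski_violations is None or tpsa is None:
        raise ContractError("abbott scoring requires lipinski_violations and tpsa")
    cfg = cfg or default_config()
    if charge_class == "anion":
        if tpsa <= 75.0:
            return 0.85
        if tpsa <= 150.0:
            return 0.56
        return 0.11
    passes = lipinski_violations <= cfg["lipinski_pass_max_violations"]
    return 0.55 if passes else 0.17


def _inside_ellipse(x, y, cx, cy, width, height, angle_deg) -> bool:
    theta = math.radians(angle_deg)
    dx, dy = x - cx, y - cy
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    return (u / (width / 2.0)) ** 2 + (v / (height / 2.0)) ** 2 <= 1.0


def boiled_egg_classify(
    logp_wildman_crippen: float,
    tpsa: float,
    params: BoiledEggParams | None = None,
) -> tuple[str, str]:
    """BOILED-Egg membership calls.

    Returns ``(gi_absorption, bbb_permeant)``: GI absorption is High iff the
    (TPSA, WLOGP) point lies inside the absorption ("white") ellipse, and the
    compound is predicted BBB-permeant iff the point lies inside the
    brain-penetration ("yolk") ellipse. Boundary points count as inside.
    """
    if not (math.isfinite(logp_wildman_crippen) and math.isfinite(tpsa)):
        raise ContractError("boiled_egg_classify requires finite coordinates")
    p = params or BoiledEggParams.from_config()
    gi = _inside_ellipse(
        tpsa, logp_wildman_crippen, p.white_cx, p.white_cy,
        p.white_width, p.white_height, p.white_angle_deg,
    )
    bbb = _inside_ellipse(
        tpsa, logp_wildman_crippen, p.yolk_cx, p.yolk_cy,
        p.yolk_width, p.yolk_height, p.yolk_angle_deg,
    )
    return ("High" if gi else "Low", "Yes" if bbb else "No")


def profile_compound(
    record: CompoundRecord,
    charge_class: str = "neutral",
    cfg: dict | None = None,
) -> PhysicochemicalProfile:
    """Compute the full descriptor profile of one compound.

    Pure function of the structure, the charge class and the configuration;
    parse failures are re-raised with the compound id attached.
    """
    cfg = cfg or default_config()
    try:
        struct = parse_structure(record.smiles)
    except SmilesParseError as exc:
        raise SmilesParseError(record.smiles, detail=f"compound {record.compound_id!r}") from exc

    mw = compute_molecular_weight(struct)
    tpsa = compute_tpsa(struct)
    logp = compute_logp(struct)
    hbd = Lipinski.NHOHCount(struct.mol)
    hba = Lipinski.NOCount(struct.mol)
    violations = count_lipinski_violations(mw, logp.lipinski_criterion, hbd, hba, cfg)
    ba = abbott_bioavailability_score(violations, tpsa, charge_class, cfg)
    gi, bbb = boiled_egg_classify(logp.wildman_crippen, tpsa, BoiledEggParams.from_config(cfg))

    notes = []
    if has_unparameterized_atoms(struct.mol):
        notes.append("contains atoms outside the Moriguchi contribution tables; "
                     "their MLOGP contribution defaults to zero")
    return PhysicochemicalProfile(
        mw=mw,
        logp_consensus=logp.consensus,
        logp_wildman_crippen=logp.wildman_crippen,
        logp_lipinski_criterion=logp.lipinski_criterion,
        tpsa=tpsa,
        hbd=hbd,
        hba=hba,
        lipinski_violations=violations,
        lipinski_pass=violations <= 1,
        ba_score=ba,
        gi_absorption=gi,
        bbb_permeant=bbb,
        provenance=tuple(notes),
    )
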