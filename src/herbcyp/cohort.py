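"""Synthetic compound cohorts and packaged reference fixtures.

The generator draws descriptor-level compounds (no structures) from
archetype distributions shaped like the phytochemical classes of the study
cohort: aporphine-like compounds with very high CYP2D6 probabilities and
high oral absorption, acetogenin-like compounds with uniformly low
probabilities and poor absorption, apolar terpene-like compounds, and an
inert background class. Each synthetic compound carries its 10-cell
probability matrix, the derived risk-classifier input and a ground-truth
risk level obtained by running the *same* ruleset implementation at
generation time, so classifier and generator can never drift apart.

Archetype parameters are anchored loosely to the reference cohort's summary
statistics (aporphine CYP2D6 MACCS cells 85.7-94.9%, acetogenin means
14.1-15.1%); they exist to exercise code paths, not to simulate chemistry.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .cyp import CANONICAL_CELLS, BenchmarkRow, CypProbabilityMatrix, load_benchmark_panel
from .descriptors import CompoundRecord
from .errors import ContractError, FixtureError
from .risk import CypInhibitionFlags, RiskInput, classify_risk

__all__ = [
    "ArchetypeSpec",
    "SyntheticCompound",
    "DEFAULT_ARCHETYPES",
    "DEFAULT_MIX",
    "generate_cohort",
    "ReferenceFixtures",
    "load_reference_fixtures",
]


@dataclass(frozen=True)
class ArchetypeSpec:
    """Sampling distributions for one compound archetype.

    Probability cells are drawn from normal distributions truncated to
    [0, 100] (location/spread in percent). Rates are Bernoulli parameters;
    ``violation_dist`` gives the probabilities of 0-4 rule-of-five
    violations.
    """

    name: str
    cyp2d6_loc: float
    cyp2d6_spread: float
    other_loc: float
    other_spread: float
    gi_high_rate: float
    bbb_yes_rate: float
    violation_dist: tuple  # probabilities for 0..4 violations
    inhibition_rate: dict  # isoform -> Bernoulli rate

    def __post_init__(self):
        rates = [self.gi_high_rate, self.bbb_yes_rate, *self.inhibition_rate.values()]
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ContractError(f"{self.name}: rates must lie in [0, 1]")
        if abs(sum(self.violation_dist) - 1.0) > 1e-9 or len(self.violation_dist) != 5:
            raise ContractError(f"{self.name}: violation_dist must be 5 probabilities summing to 1")
        for loc in (self.cyp2d6_loc, self.other_loc):
            if not 0.0 <= loc <= 100.0:
                raise ContractError(f"{self.name}: cell locations must lie in [0, 100]")


DEFAULT_ARCHETYPES = {
    "aporphine_like": ArchetypeSpec(
        name="aporphine_like",
        cyp2d6_loc=85.0, cyp2d6_spread=6.0,
        other_loc=40.0, other_spread=12.0,
        gi_high_rate=1.0, bbb_yes_rate=0.9,
        violation_dist=(1.0, 0.0, 0.0, 0.0, 0.0),
        inhibition_rate={"CYP1A2": 0.8, "CYP2C9": 0.1, "CYP2C19": 0.15,
                         "CYP2D6": 0.95, "CYP3A4": 0.15},
    ),
    "benzylisoquinoline_like": ArchetypeSpec(
        name="benzylisoquinoline_like",
        cyp2d6_loc=70.0, cyp2d6_spread=8.0,
        other_loc=25.0, other_spread=8.0,
        gi_high_rate=1.0, bbb_yes_rate=0.9,
        violation_dist=(1.0, 0.0, 0.0, 0.0, 0.0),
        inhibition_rate={"CYP1A2": 0.1, "CYP2C9": 0.05, "CYP2C19": 0.05,
                         "CYP2D6": 0.9, "CYP3A4": 0.05},
    ),
    "acetogenin_like": ArchetypeSpec(
        name="acetogenin_like",
        cyp2d6_loc=15.0, cyp2d6_spread=5.0,
        other_loc=15.0, other_spread=5.0,
        gi_high_rate=0.0, bbb_yes_rate=0.0,
        violation_dist=(0.0, 1.0, 0.0, 0.0, 0.0),
        inhibition_rate={"CYP1A2": 0.05, "CYP2C9": 0.05, "CYP2C19": 0.05,
                         "CYP2D6": 0.05, "CYP3A4": 0.3},
    ),
    "terpene_like": ArchetypeSpec(
        name="terpene_like",
        cyp2d6_loc=18.0, cyp2d6_spread=5.0,
        other_loc=18.0, other_spread=5.0,
        gi_high_rate=0.0, bbb_yes_rate=0.5,
        violation_dist=(0.5, 0.5, 0.0, 0.0, 0.0),
        inhibition_rate={"CYP1A2": 0.05, "CYP2C9": 0.2, "CYP2C19": 0.05,
                         "CYP2D6": 0.05, "CYP3A4": 0.05},
    ),
    "inert": ArchetypeSpec(
        name="inert",
        cyp2d6_loc=10.0, cyp2d6_spread=4.0,
        other_loc=10.0, other_spread=4.0,
        gi_high_rate=0.0, bbb_yes_rate=0.0,
        violation_dist=(1.0, 0.0, 0.0, 0.0, 0.0),
        inhibition_rate={iso: 0.0 for iso in
                         ("CYP1A2", "CYP2C9", "CYP2C19", "CYP2D6", "CYP3A4")},
    ),
}

#: a study-like mixture: alkaloid-heavy with acetogenin and terpene classes
DEFAULT_MIX = {
    "aporphine_like": 0.25,
    "benzylisoquinoline_like": 0.15,
    "acetogenin_like": 0.25,
    "terpene_like": 0.15,
    "inert": 0.20,
}


@dataclass(frozen=True)
class SyntheticCompound:
    """One generated compound: matrix, classifier input and its label."""

    risk_input: RiskInput
    matrix: CypProbabilityMatrix
    ground_truth_level: str


def _truncnorm_sample(rng, loc, spread, n):
    if spread <= 0:
        return np.full(n, float(loc))
    a, b = (0.0 - loc) / spread, (100.0 - loc) / spread
    return stats.truncnorm.rvs(a, b, loc=loc, scale=spread, size=n, random_state=rng)


def _allocate(n: int, mix: dict) -> list:
    """Largest-remainder allocation of n compounds across archetypes."""
    names = sorted(mix)
    exact = {k: n * mix[k] for k in names}
    counts = {k: int(np.floor(exact[k])) for k in names}
    remainder = n - sum(counts.values())
    by_frac = sorted(names, key=lambda k: (-(exact[k] - counts[k]), k))
    for k in by_frac[:remainder]:
        counts[k] += 1
    out = []
    for k in names:
        out.extend([k] * counts[k])
    return out


def generate_cohort(
    n: int,
    mix: dict | None = None,
    seed: int = 0,
    archetypes: dict | None = None,
) -> list[SyntheticCompound]:
    """Generate ``n`` synthetic compounds, deterministically for a fixed seed.

    ``mix`` maps archetype names to proportions summing to one. Each
    compound's ten probability cells are sampled from its archetype's
    truncated-normal distributions; the classifier input's mean probability
    is the exact arithmetic mean of those cells; the ground-truth level is
    the risk ruleset applied to the sampled input at generation time.
    """
    if n < 0:
        raise ContractError(f"n must be non-negative, got {n}")
    archetypes = archetypes or DEFAULT_ARCHETYPES
    mix = dict(mix or DEFAULT_MIX)
    unknown = sorted(set(mix) - set(archetypes))
    if unknown:
        raise ContractError(f"unknown archetypes in mix: {unknown}")
    if any(p < 0 for p in mix.values()) or abs(sum(mix.values()) - 1.0) > 1e-6:
        raise ContractError("mix proportions must be non-negative and sum to 1")
    if n == 0:
        return []

    rng = np.random.default_rng(seed)
    assignment = _allocate(n, mix)
    cohort = []
    for i, arch_name in enumerate(assignment):
        arch = archetypes[arch_name]
        cid = f"syn-{arch_name}-{i:05d}"
        cells = {}
        d6 = _truncnorm_sample(rng, arch.cyp2d6_loc, arch.cyp2d6_spread, 2)
        other = _truncnorm_sample(rng, arch.other_loc, arch.other_spread, 8)
        j = 0
        for iso, method in CANONICAL_CELLS:
            if iso == "CYP2D6":
                cells[(iso, method)] = float(d6[0] if method == "MACCS" else d6[1])
            else:
                cells[(iso, method)] = float(other[j])
                j += 1
        matrix = CypProbabilityMatrix(cid, cells)
        inhibited = frozenset(
            iso for iso, rate in sorted(arch.inhibition_rate.items())
            if rng.random() < rate
        )
        risk_input = RiskInput(
            compound_id=cid,
            mean_probability=float(np.mean(list(cells.values()))),
            inhibition=CypInhibitionFlags(cid, inhibited),
            gi_absorption="High" if rng.random() < arch.gi_high_rate else "Low",
            bbb_permeant="Yes" if rng.random() < arch.bbb_yes_rate else "No",
            lipinski_violations=int(rng.choice(5, p=arch.violation_dist)),
        )
        cohort.append(
            SyntheticCompound(
                risk_input=risk_input,
                matrix=matrix,
                ground_truth_level=classify_risk(risk_input).level,
            )
        )
    return cohort


# ---------------------------------------------------------------------------
# packaged reference fixtures

_FIXTURE_FILES = {
    "compounds": "compounds_curated.csv",
    "adme": "table1_printed.csv",
    "risk": "table2_printed.csv",
    "benchmark": "benchmark_panel.csv",
}


@dataclass(frozen=True)
class ReferenceFixtures:
    """The packaged 12-compound study set and its printed result tables.

    ``compounds`` carries curated literature structures (a hand-validated
    snapshot, since the package ships no network access); ``adme_table`` and
    ``risk_table`` hold the published per-compound values verbatim;
    ``benchmark_panel`` holds the five reference CYP inhibitors with their
    published prediction probabilities.
    """

    compounds: tuple[CompoundRecord, ...]
    adme_table: pd.DataFrame
    risk_table: pd.DataFrame
    benchmark_panel: tuple[BenchmarkRow, ...]

    def risk_inputs(self) -> list[RiskInput]:
        """The published risk table as classifier inputs, row order preserved."""
        out = []
        for _, r in self.risk_table.iterrows():
            out.append(
                RiskInput(
                    compound_id=r["compound_id"],
                    mean_probability=float(r["mean_probability"]),
                    inhibition=CypInhibitionFlags.from_string(
                        r["compound_id"], r["cyp_inhibition"]
                    ),
                    gi_absorption=r["gi_absorption"],
                    bbb_permeant=r["bbb_permeant"],
                    lipinski_violations=int(r["lipinski_violations"]),
                )
            )
        return out

    def published_levels(self) -> dict:
        return dict(zip(self.risk_table["compound_id"], self.risk_table["risk_level"]))


def _read_fixture(name: str) -> str:
    try:
        return resources.files("herbcyp.data").joinpath(name).read_text("utf-8")
    except (FileNotFoundError, OSError) as exc:
        raise FixtureError(f"packaged fixture {name!r} is missing or unreadable") from exc


def load_reference_fixtures() -> ReferenceFixtures:
    """Load the packaged study fixtures (no network access, ever)."""
    comp_df = pd.read_csv(io.StringIO(_read_fixture(_FIXTURE_FILES["compounds"])))
    expected = {"compound_id", "name", "smiles", "phytochemical_class"}
    if set(comp_df.columns) != expected:
        raise FixtureError(
            f"fixture {_FIXTURE_FILES['compounds']!r} has unexpected columns "
            f"{sorted(comp_df.columns)}"
        )
    compounds = tuple(
        CompoundRecord(r["compound_id"], r["name"], r["smiles"], r["phytochemical_class"])
        for _, r in comp_df.iterrows()
    )
    adme = pd.read_csv(io.StringIO(_read_fixture(_FIXTURE_FILES["adme"])))
    risk = pd.read_csv(io.StringIO(_read_fixture(_FIXTURE_FILES["risk"])))

    # go through the shared reader so scale handling and validation stay
    # identical for fixture and user files
    text = _read_fixture(_FIXTURE_FILES["benchmark"])
    panel = tuple(load_benchmark_panel(io.StringIO(text)))
    return ReferenceFixtures(
        compounds=compounds,
        adme_table=adme,
        risk_table=risk,
        benchmark_panel=panel,
    )
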