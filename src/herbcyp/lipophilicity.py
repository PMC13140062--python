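"""Lipophilicity estimators.

Two octanol/water partition estimators are implemented:

* Wildman-Crippen (WLOGP): the atom-contribution method, delegated to RDKit's
  Crippen implementation. This is the lipophilicity axis of the BOILED-Egg
  GI/BBB classifier.
* Moriguchi (MLOGP): the 13-parameter topological regression model built from
  simple structural counts. This is the estimator fed to the rule-of-five
  lipophilicity criterion (conventional cutoff 4.15), matching the behaviour
  of the reference ADME web tool.

The consensus value reported in profiles is the unweighted mean of the
estimators implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem
from rdkit.Chem import Crippen, rdmolops

__all__ = ["LipophilicityEstimates", "wildman_crippen_logp", "moriguchi_logp", "estimate_logp"]

# Moriguchi regression coefficients, in the order the terms appear below.
_MLOGP_COEF = {
    "CX": 1.244,    # (carbons + weighted halogens) ** 0.6
    "NO": -1.017,   # (N + O count) ** 0.9
    "PRX": 0.406,   # N/O proximity effect
    "UB": -0.145,   # (unsaturated bond count) ** 0.8
    "HB": 0.511,    # intramolecular H-bond dummy (not detected; see note)
    "POL": 0.268,   # aromatic polar substituents
    "AMP": -2.215,  # amphoteric (alpha-amino acid) dummy
    "ALK": 0.912,   # pure hydrocarbon with <= 1 double bond
    "RNG": -0.392,  # ring dummy (rings other than benzene)
    "QN": -3.684,   # quaternary N (1.0) / N-oxide (0.5)
    "NO2": 0.474,   # nitro group count
    "NCS": 1.582,   # isothiocyanate (1.0) / thiocyanate (0.5)
    "BLM": 0.773,   # beta-lactam dummy
}
_MLOGP_INTERCEPT = -1.041

_HALOGEN_WEIGHT = {9: 0.5, 17: 1.0, 35: 1.5, 53: 2.0}

# atoms the Moriguchi model parameterizes; anything else contributes nothing
# and is flagged in the profile provenance
_MLOGP_KNOWN_ELEMENTS = frozenset({1, 6, 7, 8, 9, 15, 16, 17, 35, 53})

_SMARTS = {
    "nitro": Chem.MolFromSmarts("[$([NX3](=O)=O),$([NX3+](=O)[O-])]"),
    "carboxamide": Chem.MolFromSmarts("[NX3][CX3](=O)"),
    "sulfonamide": Chem.MolFromSmarts("[NX3][SX4](=O)(=O)"),
    "quat_n": Chem.MolFromSmarts("[NX4,NX4+]"),
    "n_oxide": Chem.MolFromSmarts("[NX3+]-[OX1-]"),
    "isothiocyanate": Chem.MolFromSmarts("N=C=S"),
    "thiocyanate": Chem.MolFromSmarts("SC#N"),
    "beta_lactam": Chem.MolFromSmarts("O=C1CCN1"),
    "alpha_amino_acid": Chem.MolFromSmarts("[NX3;H2,H1][CX4][CX3](=O)[OX2H1,OX1-]"),
}


@dataclass(frozen=True)
class LipophilicityEstimates:
    """The logP values a profile carries."""

    wildman_crippen: float
    moriguchi: float

    @property
    def consensus(self) -> float:
        return (self.wildman_crippen + self.moriguchi) / 2.0

    @property
    def lipinski_criterion(self) -> float:
        """The value the rule-of-five lipophilicity condition is tested on."""
        return self.moriguchi


def wildman_crippen_logp(mol: Chem.Mol) -> float:
    return Crippen.MolLogP(mol)


def moriguchi_logp(mol: Chem.Mol) -> float:
    """Moriguchi topological logP from structural counts.

    The intramolecular hydrogen-bond dummy (HB) is not detected and is left
    at zero; for molecules without rigid donor/acceptor pairs this term does
    not apply, and its omission shifts MLOGP by at most +0.51 elsewhere.
    """
    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)

    cx = sum(
        1.0 if a.GetAtomicNum() == 6 else _HALOGEN_WEIGHT.get(a.GetAtomicNum(), 0.0)
        for a in kek.GetAtoms()
    )
    no_idx = [a.GetIdx() for a in kek.GetAtoms() if a.GetAtomicNum() in (7, 8)]
    no = float(len(no_idx))

    # proximity effect: N/O pairs separated by one bond count 2, by two bonds
    # count 1; each carboxamide / sulfonamide corrects the sum by -1
    prx = 0.0
    if len(no_idx) > 1:
        dm = rdmolops.GetDistanceMatrix(kek)
        for i, ai in enumerate(no_idx):
            for aj in no_idx[i + 1:]:
                d = dm[ai, aj]
                if d == 1:
                    prx += 2.0
                elif d == 2:
                    prx += 1.0
    prx -= len(kek.GetSubstructMatches(_SMARTS["carboxamide"]))
    prx -= len(kek.GetSubstructMatches(_SMARTS["sulfonamide"]))

    nitro_matches = kek.GetSubstructMatches(_SMARTS["nitro"])
    nitro_atoms = {i for m in nitro_matches for i in m}
    ub = 0.0
    for b in kek.GetBonds():
        if b.GetBondTypeAsDouble() >= 2.0:
            if b.GetBeginAtomIdx() in nitro_atoms and b.GetEndAtomIdx() in nitro_atoms:
                continue  # counted by the NO2 term instead
            ub += 1.0

    # aromatic polar substituents: exocyclic N/O attached to an aromatic carbon
    pol = 0.0
    for a in mol.GetAtoms():
        if a.GetAtomicNum() in (7, 8) and not a.GetIsAromatic():
            if any(n.GetIsAromatic() and n.GetAtomicNum() == 6 for n in a.GetNeighbors()):
                pol += 1.0

    is_hydrocarbon = all(a.GetAtomicNum() in (1, 6) for a in kek.GetAtoms())
    alk = 1.0 if is_hydrocarbon and ub <= 1.0 else 0.0

    # ring dummy: any ring that is not a six-membered aromatic carbocycle
    rng = 0.0
    for ring in mol.GetRingInfo().AtomRings():
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        if not (len(ring) == 6 and all(a.GetIsAromatic() and a.GetAtomicNum() == 6 for a in atoms)):
            rng = 1.0
            break

    if kek.GetSubstructMatches(_SMARTS["quat_n"]):
        qn = 1.0
    elif kek.GetSubstructMatches(_SMARTS["n_oxide"]):
        qn = 0.5
    else:
        qn = 0.0

    if kek.GetSubstructMatches(_SMARTS["isothiocyanate"]):
        ncs = 1.0
    elif kek.GetSubstructMatches(_SMARTS["thiocyanate"]):
        ncs = 0.5
    else:
        ncs = 0.0

    terms = {
        "CX": cx ** 0.6,
        "NO": no ** 0.9,
        "PRX": prx,
        "UB": ub ** 0.8,
        "HB": 0.0,
        "POL": pol,
        "AMP": 1.0 if kek.GetSubstructMatches(_SMARTS["alpha_amino_acid"]) else 0.0,
        "ALK": alk,
        "RNG": rng,
        "QN": qn,
        "NO2": float(len(nitro_matches)),
        "NCS": ncs,
        "BLM": 1.0 if kek.GetSubstructMatches(_SMARTS["beta_lactam"]) else 0.0,
    }
    return _MLOGP_INTERCEPT + sum(_MLOGP_COEF[k] * v for k, v in terms.items())


def has_unparameterized_atoms(mol: Chem.Mol) -> bool:
    """True when the molecule contains elements outside the MLOGP tables."""
    return any(a.GetAtomicNum() not in _MLOGP_KNOWN_ELEMENTS for a in mol.GetAtoms())


def estimate_logp(mol: Chem.Mol) -> LipophilicityEstimates:
    return LipophilicityEstimates(
        wildman_crippen=wildman_crippen_logp(mol),
        moriguchi=moriguchi_logp(mol),
    )
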