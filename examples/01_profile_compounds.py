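"""Profile the packaged reference compounds from their structures.

Parses each curated SMILES, computes molecular weight, consensus logP,
Ertl TPSA, rule-of-five violations, the Abbott bioavailability score and
the BOILED-Egg GI/BBB call, and prints the descriptor table.
"""

from herbcyp import load_reference_fixtures, profile_compound
from herbcyp.reports import profile_table
from herbcyp.risk import CypInhibitionFlags

fixtures = load_reference_fixtures()
profiles = {c.compound_id: profile_compound(c) for c in fixtures.compounds}

# the CYP-inhibition column is ingested (here: the published flags), never computed
flags = {
    r["compound_id"]: CypInhibitionFlags.from_string(r["compound_id"], r["cyp_inhibition"])
    for _, r in fixtures.adme_table.iterrows()
}

table = profile_table(profiles, flags)
print(table.to_string(index=False))
print()
print("Each row is one compound: MW in g/mol, TPSA in Angstrom^2; GI High means")
print("the (TPSA, WLOGP) point falls in the absorption ellipse, BBB Yes in the")
print("brain-penetration ellipse. A BAScore of 0.55 marks a neutral molecule")
print("passing the rule of five (at most one violation).")
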