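"""Classify the reference cohort with the four-level integrated risk engine.

Feeds the published per-compound evidence (mean CYP probability, confirmed
inhibition, GI absorption, BBB, rule-of-five status) through the ordered
ruleset and prints each level with the rule that fired.
"""

from herbcyp import classify_cohort, load_reference_fixtures

fixtures = load_reference_fixtures()
result = classify_cohort(fixtures.risk_inputs())

for a in result.assessments:
    print(f"{a.compound_id:16s} {a.level:10s} (rule {a.fired_rule})")
print()
print("cohort:", dict(result.counts))
print("R1 = high probability + absorbed + inhibiting + drug-like; R2 = moderate")
print("band (>=4 inhibited isoforms escalates); R3 = negligible (low everything);")
print("R4 = default LOW. Four HIGH compounds warrant monitoring during therapy.")
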