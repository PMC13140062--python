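# herbcyp

Integrated *in silico* herb–drug-interaction risk profiling for
phytochemicals.

Oncology patients frequently take herbal preparations — soursop (*Annona
muricata*) leaf extracts being a prominent example — alongside chemotherapy,
yet most phytochemicals have never been screened for interference with the
cytochrome P450 (CYP450) enzymes that metabolize the majority of clinical
drugs. `herbcyp` implements the full assessment chain for this problem, for
pharmacologists and cheminformaticians who need a reproducible, auditable
screen:

1. **Descriptor profiling from structures** — molecular weight, Wildman–
   Crippen and Moriguchi logP (plus their consensus), Ertl topological polar
   surface area (TPSA), H-bond donor/acceptor counts, Lipinski rule-of-five
   violations, the Abbott bioavailability score, and the BOILED-Egg
   two-ellipse classifier for gastrointestinal (GI) absorption and
   blood–brain-barrier (BBB) permeation in (TPSA, WLOGP) space.
2. **CYP interaction-probability aggregation** — ingestion of per-compound
   probability matrices (five isoforms CYP1A2/2C9/2C19/2D6/3A4 × two
   fingerprint methods MACCS/Morgan, percent scale), Active/Inactive calls
   (Active ⇔ p > 50%, strict), per-compound means and primary targets, and
   validation against a five-drug reference-inhibitor panel.
3. **Four-level risk stratification** — an ordered ruleset combining the
   mean interaction probability m, the confirmed-inhibition isoform set I,
   GI absorption, BBB permeation and the violation count v:

   | rule | condition | level |
   |------|-----------|-------|
   | R1 | m > 50%, GI High, I ≠ ∅, v = 0 | HIGH |
   | R2 | m ≥ 30%, GI High, I ≠ ∅ (|I| ≥ 4 and v = 0 escalates) | HIGH / MODERATE |
   | R3 | m < 30%, GI Low, I = ∅, BBB No | NEGLIGIBLE |
   | R4 | otherwise | LOW |

   Every assessment carries a rule trace naming the rule that fired.

A seeded synthetic-cohort generator (archetype-structured: aporphine-like
high-CYP2D6 profiles, acetogenin-like low-bioavailability profiles,
apolar terpene-like profiles, an inert background) and a packaged
12-compound soursop reference set make every stage testable offline.

## Worked example

```python
from herbcyp import classify_cohort, load_reference_fixtures

fixtures = load_reference_fixtures()
result = classify_cohort(fixtures.risk_inputs())
for a in result.assessments:
    print(f"{a.compound_id:16s} {a.level:10s} (rule {a.fired_rule})")
print(dict(result.counts))
```

prints

```
isolaureline     HIGH       (rule R1)
xylopine         HIGH       (rule R1)
anonaine         HIGH       (rule R1)
stepharine       HIGH       (rule R2)
coclaurine       MODERATE   (rule R2)
reticuline       MODERATE   (rule R2)
annonacin        LOW        (rule R4)
swainsonine      LOW        (rule R4)
germacrene_d     LOW        (rule R4)
e_caryophyllene  LOW        (rule R4)
bullatacin       NEGLIGIBLE (rule R3)
annomuricin      NEGLIGIBLE (rule R3)
{'NEGLIGIBLE': 2, 'LOW': 4, 'MODERATE': 2, 'HIGH': 4}
```

The three aporphine alkaloids reach HIGH through the direct rule R1 (mean
CYP probability above 50% with high absorption, confirmed inhibition and
clean drug-likeness); stepharine reaches HIGH through breadth escalation
(predicted inhibition of four of the five isoforms); the two
benzylisoquinolines sit in the moderate band; the poorly absorbed
acetogenins and terpenes land in LOW/NEGLIGIBLE.

The `examples/` directory holds one short narrative script per capability
(profiling, CYP summaries, risk classification, synthetic cohorts, the
end-to-end report bundle). A thin CLI mirrors the same stages:

```bash
herbcyp report --input compounds.csv --matrix cyp_matrix.csv \
               --flags flags.csv --out report/
```

## Data notes

The packaged structures are a hand-curated literature snapshot (validated
against each compound's known molecular formula); the reference result
tables are stored verbatim. The published table's (E)-caryophyllene row is
internally inconsistent with the real C15H24 sesquiterpene structure — see
`docs/methods.md` for how the package handles it.
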