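# Methods

This note documents the models the package implements, the numerical and
design choices behind them, what the synthetic-data generator does and does
not emulate, and the known limitations.

## Descriptor profiling

**Parsing.** Structures enter as SMILES and are sanitized once by RDKit;
hydrogens stay implicit throughout, and every descriptor operates on that
same graph, so profiling is a pure function of the canonical structure.

**Molecular weight** is the average-isotopic weight including implicit
hydrogens, reported to 0.1 g/mol in tables.

**TPSA** is Ertl's fragment-contribution topological polar surface area
with sulfur and phosphorus contributions enabled, so TPSA is zero exactly
when the molecule has no N/O/S/P polar fragments. It is additive over
fragments and invariant under atom reordering.

**Lipophilicity.** Two estimators are implemented: Wildman–Crippen WLOGP
(RDKit's atom-contribution implementation) and a Moriguchi MLOGP built from
the published 13-term topological regression (carbon/halogen count, N+O
count, N/O proximity with carboxamide/sulfonamide correction, unsaturated
bonds, aromatic polar substituents, amphoteric/alkane/ring/quaternary-N/
nitro/NCS/β-lactam terms). The reported consensus logP is their unweighted
mean. The intramolecular hydrogen-bond dummy of the Moriguchi model is not
detected (always 0); it can only lower MLOGP by 0.51 and does not affect any
classification in the reference cohort. On the bicyclic C15H24 sesquiterpene
the implementation reproduces the reference web tool's printed MLOGP (4.63)
exactly.

**Rule of five.** Violations are counted among MW > 500, MLOGP > 4.15,
H-bond donors (NH+OH) > 5, H-bond acceptors (N+O) > 10. The topological
estimator with the 4.15 cutoff is deliberately the rule's lipophilicity
criterion: it is what makes a small pure hydrocarbon such as germacrene D
(MW 204) carry exactly one violation, as the reference tool reports.
"Passing" means at most one violation.

**Abbott bioavailability score.** The published decision tree: anions are
scored on polar surface area (PSA ≤ 75 Å² → 0.85; 75 < PSA ≤ 150 → 0.56;
PSA > 150 → 0.11); all other charge classes score 0.55 on a rule-of-five
pass and 0.17 on a fail. The score therefore takes only the five published
values {0.11, 0.17, 0.55, 0.56, 0.85}. Charge class defaults to neutral —
no pKa engine is implemented, and the alkaloids are treated as free bases;
this reproduces the uniform 0.55 column of the reference cohort.

**BOILED-Egg.** GI absorption is High iff the (TPSA, WLOGP) point lies in
the absorption ("white") ellipse; the compound is BBB-permeant iff it lies
in the brain-penetration ("yolk") ellipse. The ellipse constants are pinned
in `data/defaults.yaml` (digitized from the original publication's best-fit
ellipses; rotation angles in degrees) and boundary points count as inside.
With these constants the classifier reproduces the reference cohort's
printed GI/BBB calls for every structure-consistent row, and reproduces the
remaining row from its printed coordinates (see "Reference-data
discrepancies").

## CYP probability handling

Probabilities live on the percent scale [0, 100] internally. The loader
accepts exports whose values all lie in [0, 1] by converting once with a
warning — a single, explicit conversion rule prevents silent double
scaling. Blank cells are recorded as missing and excluded from means, never
imputed (imputing zeros would bias ingestion of partial exports). The
Active call is strict: Active ⇔ p > threshold (default 50%), so exactly
50% is Inactive. The per-compound mean is the unweighted arithmetic mean
over present cells; the primary target is the isoform holding the maximum
cell, ties broken by the canonical isoform order (1A2, 2C9, 2C19, 2D6,
3A4). A benchmark row validates when at least one fingerprint method calls
its expected isoform Active.

## Risk engine

The four-level classifier is an ordered first-match cascade (R1→R4, see
README table) over the mean probability, confirmed-inhibition set, GI
class, BBB class and violation count. Band boundaries follow the stated
"> 50%", "30–50%", "< 30%" wording: the HIGH band is strictly above 50,
the moderate band includes both 30 and 50. Two choices were genuinely open
and are codified as follows:

* **Breadth escalation.** A moderate-band compound predicted to inhibit at
  least four of the five isoforms, with high absorption and zero
  violations, escalates to HIGH. This reproduces the reference assignment
  of the broad-spectrum proaporphine (mean 32.5% yet HIGH) and reflects the
  polypharmacy concern broad inhibition raises.
* **NEGLIGIBLE requires BBB No.** A compound meeting the low-probability /
  low-absorption / no-inhibition conditions but predicted brain-permeant
  stays LOW rather than NEGLIGIBLE, matching the reference assignment of
  the BBB-permeant sesquiterpene.
* **No upper cap on the moderate band.** R2 tests m ≥ 30 only: a compound
  above 50% that misses HIGH solely on drug-likeness demotes to MODERATE,
  not to LOW. The literal "30–50%" band, combined with the HIGH rule's
  zero-violation requirement, would make the level non-monotone in the mean
  (raising a violating compound's mean from 40% to 60% would *lower* its
  level); keeping R2 uncapped restores monotonicity without changing any
  reference assignment, since R1 precedes R2.

Monotonicity (in mean probability and in the inhibition set), totality and
the GI gate (Low absorption excludes HIGH and MODERATE) are verified in the
tests against an independently written enumeration oracle over a
discretized input grid. Every assessment records its rule trace — the
framework is exploratory and not clinically validated, so each
classification must be auditable.

## Synthetic cohorts

The generator samples descriptor-level compounds (no structures) from five
archetypes whose parameters are loosely anchored to the reference cohort's
summary statistics: `aporphine_like` (CYP2D6 cells ~N(85, 6²), other cells
~N(40, 12²), always absorbed, no violations, high 1A2/2D6 inhibition
rates), `benzylisoquinoline_like` (2D6-selective, absorbed),
`acetogenin_like` (all cells ~N(15, 5²), never absorbed, one violation, BBB
No), `terpene_like` (low cells, never absorbed, mixed BBB) and `inert` (low
cells, nothing else). Cells are truncated-normal on [0, 100]; all sampling
flows from an explicit integer seed through one NumPy generator — no global
state. Compound counts per archetype use largest-remainder allocation, so a
mix is honored exactly.

Each synthetic compound's classifier input takes its mean probability as
the exact arithmetic mean of its sampled cells, and its ground-truth label
is produced by running the *same* `classify_risk` implementation at
generation time — generator and classifier cannot drift apart, and the
round-trip (label = fresh classification) is asserted over seeded cohorts
of 2000 in the tests.

What the generator does **not** emulate: real molecular structures (no
SMILES are generated), correlations between descriptors and probabilities
(each field is sampled independently given the archetype), extract-level
compound co-occurrence, and any concentration or potency scale. Passing
tests on synthetic cohorts therefore demonstrate the correctness and
stability of the pipeline's logic, not predictive validity on real
chemistry.

## Reference data and problem sizes

The packaged 12-compound set (soursop leaf phytochemicals: three aporphine
and two benzylisoquinoline alkaloids, a proaporphine, an indolizidine,
three acetogenins, two sesquiterpenes) ships as a hand-curated SMILES
snapshot validated against each compound's known molecular formula, because
the package performs no network access. The published ADME and risk tables
are stored verbatim; the per-cell probability matrices behind the published
means were never published, so the means are ingestion-checked, not
recomputed. The reference-inhibitor panel (ketoconazole/CYP3A4,
quinidine/CYP2D6, fluvoxamine/CYP1A2, fluconazole/CYP2C9,
omeprazole/CYP2C19) stores the published probabilities.

**Reference-data discrepancies.** Several printed MW cells are inconsistent
with the compounds' established formulas (stepharine, annonacin,
bullatacin, germacrene D, (E)-caryophyllene); MW agreement is asserted only
for the structure-consistent rows. The (E)-caryophyllene row is wholly
inconsistent with C15H24 (printed MW 162.3, logP 3.27): computed from the
real structure it classifies BBB No with one violation, while its printed
coordinates (TPSA 0, logP 3.27) reproduce the printed Low/Yes call under
this package's own classifier — the row evidently derives from a different
submitted structure. Structure-derived acceptance checks therefore exclude
that row and verify it from its printed coordinates instead.

Test problem sizes (grid of 1080 rule-engine inputs, synthetic cohorts of
200–2000, 50 random matrices for permutation checks) were chosen to cover
every rule branch and give distributional assertions many standard errors
of margin; the full suite runs in well under a minute.

## Limitations

No pKa/charge-state prediction, no 3D conformers, no P-gp or permeability
models beyond BOILED-Egg, no fingerprint computation or upstream
probability prediction (matrices are ingested, not predicted), no
distinction among inhibition/induction/substrate behavior, and no
clinical-severity or concentration-dependent modelling. The four-level
stratification is a prioritization heuristic for follow-up experiments,
not a validated clinical risk score.
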