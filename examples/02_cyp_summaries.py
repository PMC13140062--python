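"""Summarize CYP interaction-probability matrices.

Builds a small synthetic matrix export, loads it through the validating
reader, and prints per-compound means, Active-call counts and primary
targets, plus the reference-inhibitor benchmark result.
"""

import io

from herbcyp import benchmark_validate, load_probability_matrix, load_reference_fixtures, summarize
from herbcyp.cyp import CELL_COLUMNS

csv = "compound_id," + ",".join(CELL_COLUMNS) + "\n"
csv += "aporphine-like," + ",".join(map(str, [55, 50, 40, 45, 50, 48, 94.9, 80, 52, 53])) + "\n"
csv += "inert-like," + ",".join(["10"] * 10) + "\n"

for m in load_probability_matrix(io.StringIO(csv)):
    s = summarize(m)
    print(f"{s.compound_id:15s} mean={s.mean_probability:5.1f}%  "
          f"active {s.active_count}/10  primary target {s.primary_target}")

panel = list(load_reference_fixtures().benchmark_panel)
print(f"\nbenchmark: {benchmark_validate(panel)}/{len(panel)} reference inhibitors "
      "called Active on their known primary isoform")
print("A cell is Active when its probability exceeds 50% (strict); the mean is")
print("the plain average over the ten isoform-by-fingerprint cells.")
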