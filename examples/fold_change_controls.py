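"""Fold-change truth set: Mix A vs Mix B differential abundance.

Mix B shuffles 50 of the 86 sequins across ladder points (known +/-1, 2, 3
log2 fold changes) and leaves 36 equimolar. Simulated replicate libraries
then give the differential test a built-in positive and negative control
set, from which sensitivity, specificity and ROC are computed.
"""

import pandas as pd

from metaquin import build_ladder, build_mix_pair, compose_sample, expected_lfc
from metaquin.design import SequinRecord
from metaquin.diffnorm import diff_test, roc_curve
from metaquin.simulate import simulate_counts
import numpy as np

rng = np.random.default_rng(0)
sequins = [
    SequinRecord(f"MG_{i + 1:02d}", "", int(rng.integers(1000, 10000)),
                 float(rng.uniform(0.2, 0.71)), f"genome_{i + 1}", (0, 0))
    for i in range(86)
]
mix_a = build_ladder(sequins)
pair = build_mix_pair(mix_a, n_fold_change=50, rng_seed=1)

cols = {}
for r in range(3):
    for label, mix in (("A", mix_a), ("B", pair.mix_b)):
        spec = compose_sample([], mixture=mix)
        # modest depth on purpose: the ladder bottom stays noisy, which is
        # what makes the per-magnitude ROC stratification informative
        cols[f"{label}{r + 1}"] = simulate_counts(spec, 400_000,
                                                  seed=10 * r + (label == "B"))
counts = pd.DataFrame(cols)

result = diff_test(counts, ["A1", "A2", "A3"], ["B1", "B2", "B3"],
                   roles=pair.roles, alpha=0.05)
print(f"fold-change sequins called significant: "
      f"{result.sensitivity:.1%} (sensitivity)")
print(f"equimolar sequins correctly unchanged:  "
      f"{result.specificity:.1%} (specificity)")

roc = roc_curve(result.table["p"].to_numpy(),
                (result.table["role"] == "fold_change").to_numpy(),
                magnitudes=expected_lfc(pair)["expected_lfc"].to_numpy())
print(f"overall AUC = {roc.auc:.3f}")
for mag, sub in sorted(roc.by_magnitude.items()):
    print(f"  |expected LFC| = {mag:.0f}: AUC = {sub.auc:.3f}")
print("Diagnostic power grows with the designed fold change, as the "
      "per-magnitude ROC stratification shows.")
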