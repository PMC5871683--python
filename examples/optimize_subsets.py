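"""Exhaustive feature-subset search with the three-stage selection rule.

A reduced demonstration: 5 features (31 subsets), 10 train/test iterations
on a corpus where the first feature alone determines the labels.  The
selection rule — dominate the full-feature classifier in every iteration,
then maximal summed accuracy, then fewest features — should recover a
small subset containing the decisive feature.
"""

import numpy as np
import pandas as pd

from icfp import LabeledICSet, run_search
from icfp.features import FEATURE_NAMES

rng = np.random.default_rng(123)
rows, labels, ids = [], [], []
for d in range(12):
    for _ in range(18):
        is_artifact = rng.uniform() < 0.2
        x = rng.uniform(0, 0.4, size=5)
        x[0] = rng.uniform(0.75, 1.0) if is_artifact else rng.uniform(0.0, 0.35)
        rows.append(x)
        labels.append(int(is_artifact))
        ids.append(f"d{d}")
fp = pd.DataFrame(rows, columns=list(FEATURE_NAMES[:5]))
fp.insert(0, "dataset_id", ids)
labeled = LabeledICSet(fp, np.array(labels))

report = run_search(labeled, n_iterations=10, n_test=3, seed=1, n_features=5)
full_row = report.accuracy_matrix[-1]
best_row = report.accuracy_matrix[report.subsets.index(report.final_subset)]
print(f"searched {len(report.subsets)} subsets x {report.accuracy_matrix.shape[1]} iterations")
print(f"full-set accuracy per iteration:  {np.round(full_row, 3)}")
print(f"final subset {report.final_subset.names}: {np.round(best_row, 3)}")
print(f"stage-1 survivors: {len(report.stage1)}  full-set fallback: {report.full_set_fallback}")
print("-> the selected subset contains the decisive feature "
      f"({FEATURE_NAMES[0]}) and no more features than needed.")
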