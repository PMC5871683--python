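"""Train the preset eyeblink classifier on a labeled synthetic corpus.

Builds a 12-dataset cued-blink corpus with ground-truth IC labels, trains
the published 4-feature eyeblink RBF-SVM (K, MEV, SAD, PSD_DELTA) on 8
datasets and scores it on the held-out 4.
"""

import warnings

from icfp import SimulationConfig, make_labeled_corpus, predict, preset_classifiers, score, train

cfg = SimulationConfig(montage_size=32, fs=256.0, duration_s=50.0, seed=0)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    labeled, decomps, truths = make_labeled_corpus(12, cfg, seed=5, artifact_type="eyeblink")

ids = list(dict.fromkeys(labeled.dataset_ids))
train_set = labeled.restrict_to(ids[:8])
test_set = labeled.restrict_to(ids[8:])
print(f"corpus: {len(ids)} datasets, {labeled.labels.size} ICs, "
      f"{int(labeled.labels.sum())} blink ICs")

subset = preset_classifiers()["eyeblink"]
model = train(train_set, subset, seed=0)
report = score(predict(model, test_set.fingerprints), test_set.labels)

print(f"features: {', '.join(subset.names)}")
print(f"held-out: accuracy={report.accuracy:.3f}  "
      f"TP={report.tp} TN={report.tn} FP={report.fp} FN={report.fn}")
print("-> accuracy is the fraction of held-out ICs labeled correctly;")
print("   blink ICs are rare, so also check TP/FN for detection quality.")
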