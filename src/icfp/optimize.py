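"""Exhaustive feature-subset search and three-stage optimal-subset selection.

The optimization trains one RBF-SVM per non-empty subset of the fingerprint
features (16,383 subsets for 14 features) on repeated random dataset-level
train/test splits (default 10 iterations, 6 test datasets each) and picks
the final subset by three criteria applied in order:

1. *generalizability* — accuracy at least that of the full-feature
   classifier in **every** iteration (if no subset qualifies, the full set
   is declared optimal);
2. *performance* — greatest accuracy summed over iterations;
3. *efficiency* — fewest features.

Remaining ties trigger additional iterations until unique (bounded by a
configurable cap, after which the first subset in canonical order wins).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import FeatureSubset, LabeledICSet, train, predict

__all__ = [
    "IterationResult",
    "OptimizationReport",
    "enumerate_subsets",
    "split_datasets",
    "run_search",
    "select_optimal",
    "accuracy",
]


def accuracy(tp: int, tn: int, fp: int, fn: int) -> float:
    """Classification accuracy (TP + TN) / (TP + TN + FP + FN)."""
    total = tp + tn + fp + fn
    if total <= 0:
        raise ValueError("confusion counts sum to zero")
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    return (tp + tn) / total


def enumerate_subsets(n_features: int) -> list[FeatureSubset]:
    """All 2**n - 1 non-empty subsets, ordered by size then binary value.

    The order is deterministic and places smaller subsets first, so
    "fewest features" ties can fall back to first-in-order.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    bits = sorted(range(1, 2**n_features), key=lambda b: (bin(b).count("1"), b))
    return [FeatureSubset.from_int(b, n_features) for b in bits]


def split_datasets(dataset_ids, n_test: int = 6, seed: int = 0):
    """Random dataset-level split into (train_ids, test_ids).

    The split is always by dataset, never by IC, so no recording leaks
    between partitions.
    """
    ids = list(dict.fromkeys(dataset_ids))  # unique, order-preserving
    if n_test >= len(ids):
        raise ValueError(f"n_test={n_test} but only {len(ids)} datasets")
    rng = np.random.default_rng(seed)
    test = set(rng.choice(len(ids), size=n_test, replace=False).tolist())
    test_ids = [ids[i] for i in sorted(test)]
    train_ids = [d for i, d in enumerate(ids) if i not in test]
    return train_ids, test_ids


@dataclass
class IterationResult:
    """Per-iteration bookkeeping: the split and per-subset confusion counts."""

    iteration: int
    train_ids: list
    test_ids: list
    counts: np.ndarray  # (n_subsets, 4) TP, TN, FP, FN
    accuracies: np.ndarray  # (n_subsets,)


@dataclass
class OptimizationReport:
    subsets: list[FeatureSubset]
    accuracy_matrix: np.ndarray  # (n_subsets, n_iterations)
    iterations: list[IterationResult] = field(default_factory=list)
    stage1: list[int] = field(default_factory=list)
    stage2: list[int] = field(default_factory=list)
    final_subset: FeatureSubset | None = None
    full_set_fallback: bool = False
    extra_iterations: int = 0


def _score_iteration(
    labeled: LabeledICSet,
    subsets: list[FeatureSubset],
    iteration: int,
    n_test: int,
    seed: int,
    svm_kwargs: dict,
) -> IterationResult:
    train_ids, test_ids = split_datasets(labeled.dataset_ids, n_test=n_test, seed=seed)
    tr = labeled.restrict_to(train_ids)
    te = labeled.restrict_to(test_ids)
    y = te.labels
    counts = np.zeros((len(subsets), 4), dtype=int)
    accs = np.zeros(len(subsets))
    for k, sub in enumerate(subsets):
        model = train(tr, sub, seed=seed, **svm_kwargs)
        pred = predict(model, te.fingerprints)
        tp = int(np.sum((pred == 1) & (y == 1)))
        tn = int(np.sum((pred == 0) & (y == 0)))
        fp = int(np.sum((pred == 1) & (y == 0)))
        fn = int(np.sum((pred == 0) & (y == 1)))
        counts[k] = (tp, tn, fp, fn)
        accs[k] = accuracy(tp, tn, fp, fn)
    return IterationResult(iteration, train_ids, test_ids, counts, accs)


def run_search(
    labeled: LabeledICSet,
    n_iterations: int = 10,
    n_test: int = 6,
    seed: int = 0,
    n_features: int | None = None,
    max_subsets: int | None = None,
    max_extra_rounds: int = 5,
    select: bool = True,
    **svm_kwargs,
) -> OptimizationReport:
    """Exhaustive subset search with iterated random dataset splits.

    One split per iteration is shared by all subsets.  ``n_features``
    restricts the search to the first ``n`` fingerprint columns (useful for
    reduced searches); ``max_subsets`` subsamples the enumeration for smoke
    tests.  When ``select`` is set the three-stage rule is applied, drawing
    additional tie-break iterations from the same stream.
    """
    from .features import FEATURE_NAMES

    n_features = n_features if n_features is not None else len(FEATURE_NAMES)
    subsets = enumerate_subsets(n_features)
    if max_subsets is not None and max_subsets < len(subsets):
        rng = np.random.default_rng(seed)
        keep = sorted(rng.choice(len(subsets) - 1, size=max_subsets - 1, replace=False))
        subsets = [subsets[i] for i in keep] + [subsets[-1]]  # always keep full set
    seed_seq = np.random.SeedSequence(seed)
    iter_seeds = [int(s) for s in seed_seq.generate_state(n_iterations + max_extra_rounds) >> 1]
    results = [
        _score_iteration(labeled, subsets, i, n_test, iter_seeds[i], svm_kwargs)
        for i in range(n_iterations)
    ]
    report = OptimizationReport(
        subsets=subsets,
        accuracy_matrix=np.stack([r.accuracies for r in results], axis=1),
        iterations=results,
    )
    if not select:
        return report

    def extra_iteration(matrix: np.ndarray) -> np.ndarray | None:
        i = matrix.shape[1]
        if i - n_iterations >= max_extra_rounds:
            return None
        res = _score_iteration(labeled, subsets, i, n_test, iter_seeds[i], svm_kwargs)
        report.iterations.append(res)
        report.extra_iterations += 1
        return res.accuracies

    final, info = select_optimal(
        report.accuracy_matrix,
        subsets=subsets,
        extra_iteration=extra_iteration,
    )
    report.final_subset = final
    report.stage1 = info["stage1"]
    report.stage2 = info["stage2"]
    report.full_set_fallback = info["full_set_fallback"]
    if report.extra_iterations:
        report.accuracy_matrix = info["matrix"]
    return report


def select_optimal(
    accuracy_matrix: np.ndarray,
    subsets: list[FeatureSubset] | None = None,
    full_index: int | None = None,
    extra_iteration=None,
):
    """Apply the three-stage optimality rule to a subsets x iterations matrix.

    Stage 1 keeps subsets whose accuracy is >= the full subset's in every
    iteration (the full subset itself is not a candidate); when none
    qualify, the full subset is returned as a declared fallback.  Stage 2
    keeps the maximal summed accuracy; stage 3 the fewest features.  If
    several subsets still tie, ``extra_iteration(matrix)`` is called to
    append a fresh accuracy column and the stages are re-applied; when it
    is exhausted (returns None) the first survivor in enumeration order
    wins.

    Returns ``(final_subset, info)`` where ``info`` holds the survivor index
    lists and the possibly extended matrix.
    """
    matrix = np.asarray(accuracy_matrix, dtype=float)
    n_subsets = matrix.shape[0]
    if subsets is None:
        # infer feature count: enumeration covers all non-empty masks
        n_features = int(np.log2(n_subsets + 1))
        if 2**n_features - 1 != n_subsets:
            raise ValueError("cannot infer subsets; pass them explicitly")
        subsets = enumerate_subsets(n_features)
    if full_index is None:
        sizes = [s.size for s in subsets]
        full_index = int(np.argmax(sizes))

    while True:
        full_row = matrix[full_index]
        dominates = np.all(matrix >= full_row[None, :], axis=1)
        dominates[full_index] = False
        stage1 = np.flatnonzero(dominates)
        if stage1.size == 0:
            info = {
                "stage1": [],
                "stage2": [],
                "full_set_fallback": True,
                "matrix": matrix,
            }
            return subsets[full_index], info
        sums = matrix[stage1].sum(axis=1)
        stage2 = stage1[sums == sums.max()]
        sizes = np.array([subsets[i].size for i in stage2])
        stage3 = stage2[sizes == sizes.min()]
        if stage3.size == 1:
            info = {
                "stage1": stage1.tolist(),
                "stage2": stage2.tolist(),
                "full_set_fallback": False,
                "matrix": matrix,
            }
            return subsets[int(stage3[0])], info
        col = extra_iteration(matrix) if extra_iteration is not None else None
        if col is None:
            info = {
                "stage1": stage1.tolist(),
                "stage2": stage2.tolist(),
                "full_set_fallback": False,
                "matrix": matrix,
            }
            return subsets[int(stage3[0])], info
        matrix = np.concatenate([matrix, np.asarray(col, float)[:, None]], axis=1)
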