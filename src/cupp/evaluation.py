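"""Benchmarking: sensitivity/precision/F-score and cluster-aware N-fold CV.

Scoring is label-set based per protein: a true positive is a predicted
label present in the truth, a false negative a truth label that was
missed, a false positive a predicted label absent from the truth.  Folds
for cross-validation treat high-similarity clusters as atomic units so
that no near-duplicate pair straddles the train/test boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

from .clustering import ClusteringParams, run_incremental
from .family_io import ProteinRecord, RepresentativeMap
from .library import compile_library, finalize_family
from .prediction import annotate_many


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    level: str = "family"

    @property
    def sensitivity(self) -> float | None:
        denom = self.tp + self.fn
        return self.tp / denom if denom else None

    @property
    def precision(self) -> float | None:
        denom = self.tp + self.fp
        return self.tp / denom if denom else None

    @property
    def f_score(self) -> float | None:
        p, s = self.precision, self.sensitivity
        if p is None or s is None or p + s == 0:
            return None
        return 2 * p * s / (p + s)


def score(
    predictions: dict[str, set[str]],
    truth: dict[str, set[str]],
    level: str = "family",
    unknown_ok: dict[str, set[str]] | None = None,
) -> ConfusionCounts:
    """Count tp/fp/fn over proteins keyed by id.

    ``unknown_ok`` lists, per protein, truth labels for which an *absent*
    prediction counts as correct — used at the EC level when every
    carrier of a function was excluded from training, so "unknown" is the
    right answer.
    """
    counts = ConfusionCounts(level=level)
    for pid, true_labels in truth.items():
        pred_labels = predictions.get(pid, set())
        ok_absent = (unknown_ok or {}).get(pid, set())
        for t in true_labels:
            if t in pred_labels:
                counts.tp += 1
            elif t in ok_absent and not pred_labels:
                counts.tp += 1
            else:
                counts.fn += 1
        counts.fp += len(pred_labels - true_labels)
    return counts


def adjusted_rand_index(labels_a: dict[str, object], labels_b: dict[str, object]) -> float:
    """Adjusted Rand agreement between two partitions of the same id set.

    1 for identical partitions, ~0 for independent ones.
    """
    ids = sorted(labels_a)
    if set(ids) != set(labels_b):
        raise ValueError("partitions cover different id sets")
    contingency: dict[tuple[object, object], int] = {}
    a_sizes: dict[object, int] = {}
    b_sizes: dict[object, int] = {}
    for pid in ids:
        a, b = labels_a[pid], labels_b[pid]
        contingency[(a, b)] = contingency.get((a, b), 0) + 1
        a_sizes[a] = a_sizes.get(a, 0) + 1
        b_sizes[b] = b_sizes.get(b, 0) + 1
    n = len(ids)
    sum_cells = sum(comb(c, 2) for c in contingency.values())
    sum_a = sum(comb(c, 2) for c in a_sizes.values())
    sum_b = sum(comb(c, 2) for c in b_sizes.values())
    expected = sum_a * sum_b / comb(n, 2) if n >= 2 else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return (sum_cells - expected) / (max_index - expected)


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class FoldPlan:
    k: int
    assignments: dict[str, int]  # protein id -> fold index

    def fold_ids(self, fold: int) -> set[str]:
        return {pid for pid, f in self.assignments.items() if f == fold}


def make_folds(
    ids: list[str],
    cluster_map: RepresentativeMap | list[set[str]],
    k: int = 10,
) -> FoldPlan:
    """Deal similarity clusters greedily into ``k`` folds.

    Clusters (atomic units) are sorted by size descending and added to the
    current fold until it holds at least 1/k of the proteins, then the
    next fold starts; the final fold takes the remainder.
    """
    if isinstance(cluster_map, RepresentativeMap):
        clusters = list(cluster_map.clusters.values())
    else:
        clusters = [set(c) for c in cluster_map]
    id_set = set(ids)
    covered = {pid for c in clusters for pid in c}
    missing = id_set - covered
    clusters = [c & id_set for c in clusters]
    clusters = [c for c in clusters if c]
    clusters.extend({pid} for pid in missing)
    if k > len(clusters):
        raise ValueError(
            f"cannot make {k} folds from {len(clusters)} atomic clusters"
        )
    clusters.sort(key=lambda c: (-len(c), min(c)))
    total = len(id_set)
    target = total / k
    assignments: dict[str, int] = {}
    fold = 0
    fold_size = 0
    for cluster in clusters:
        if fold_size >= target and fold < k - 1:
            fold += 1
            fold_size = 0
        for pid in sorted(cluster):
            assignments[pid] = fold
        fold_size += len(cluster)
    return FoldPlan(k=k, assignments=assignments)


def _truth_labels(
    records: list[ProteinRecord], level: str
) -> dict[str, set[str]]:
    truth: dict[str, set[str]] = {}
    for r in records:
        labels: set[str] = set()
        for m in r.metas:
            if level == "family":
                labels.add(m.family)
            elif level == "subfamily":
                if m.subfamily is not None:
                    labels.add(f"{m.family}:{m.subfamily}")
            elif level == "ec":
                labels.update(m.ec_functions)
            else:
                raise ValueError(f"unknown level {level!r}")
        if labels:
            truth[r.protein_id] = labels
    return truth


def predicted_labels(annotations, level: str) -> dict[str, set[str]]:
    """Extract per-query label sets from annotations at the given level."""
    out: dict[str, set[str]] = {}
    for ann in annotations:
        labels: set[str] = set()
        for call in ann.calls:
            if level == "family":
                labels.add(call.family)
            elif level == "subfamily":
                if call.subfamily is not None:
                    labels.add(f"{call.family}:{call.subfamily}")
            elif level == "ec":
                if call.ec:
                    labels.add(call.ec.split("-")[0])  # the assigned majority
            else:
                raise ValueError(f"unknown level {level!r}")
        out[ann.query_id] = labels
    return out


def build_family_library(
    records: list[ProteinRecord], params: ClusteringParams
):
    """Cluster each family present in ``records`` and compile one library."""
    by_family: dict[str, list[ProteinRecord]] = {}
    for r in records:
        fam = r.family
        if fam is None:
            raise ValueError(f"record {r.protein_id} lacks family metadata")
        by_family.setdefault(fam, []).append(r)
    all_groups = []
    results = {}
    for fam in sorted(by_family):
        fam_records = by_family[fam]
        sequences = {
            r.protein_id: r.domain_sequence(fam) for r in fam_records
        }
        result = run_incremental(sequences, params)
        metas = {r.protein_id: r.metas for r in fam_records}
        all_groups.extend(
            finalize_family(result, metas, fam, retain=params.retain_conservation)
        )
        results[fam] = result
    lib = compile_library(all_groups, params.peptide_params)
    return lib, results


def holdout_run(
    records: list[ProteinRecord],
    plan: FoldPlan,
    fold: int,
    params: ClusteringParams | None = None,
) -> dict[str, ConfusionCounts]:
    """Train on all folds but one, annotate the held-out fold, and score.

    Returns confusion counts at the family, subfamily, and EC levels.  At
    the EC level an absent prediction counts as correct when none of the
    function's carriers were available for training.
    """
    params = params or ClusteringParams()
    test_ids = plan.fold_ids(fold)
    train = [r for r in records if r.protein_id not in test_ids]
    test = [r for r in records if r.protein_id in test_ids]
    if not train or not test:
        raise ValueError(f"fold {fold} leaves an empty train or test set")
    lib, _ = build_family_library(train, params)
    if not lib.groups:
        raise RuntimeError("degenerate run: training folds yielded zero groups")
    queries = [(r.protein_id, r.sequence) for r in test]
    annotations = annotate_many(queries, lib, mode="full")
    train_ecs = {
        tok for r in train for m in r.metas for tok in m.ec_functions
    }
    unknown_ok = {
        r.protein_id: {
            tok
            for m in r.metas
            for tok in m.ec_functions
            if tok not in train_ecs
        }
        for r in test
    }
    out: dict[str, ConfusionCounts] = {}
    for level in ("family", "subfamily", "ec"):
        preds = predicted_labels(annotations, level)
        truth = _truth_labels(test, level)
        out[level] = score(
            preds,
            truth,
            level=level,
            unknown_ok=unknown_ok if level == "ec" else None,
        )
    return out


def cross_validate(
    records: list[ProteinRecord],
    plan: FoldPlan,
    params: ClusteringParams | None = None,
) -> dict[int, dict[str, ConfusionCounts]]:
    """Run every fold of the plan as a hold-out experiment."""
    return {
        fold: holdout_run(records, plan, fold, params) for fold in range(plan.k)
    }
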