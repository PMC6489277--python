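"""Incremental peptide-based clustering of a protein family.

The engine groups proteins of one family by the degenerate peptides they
share.  Dissimilarity between two proteins is

    score_ij = (1 - shared_positions / (2 * max_positions)) ** c_clust

where ``shared_positions`` counts the distinct start positions of the
shared peptides in both proteins combined and ``max_positions`` is the
larger of the two proteins' distinct conserved-peptide start counts.  The
clustering coefficient ``c_clust`` (default 9) amplifies the separation:
larger values give fewer, tighter groups.

Clustering is *incremental*: five passes with tightening thresholds.  Each
pass prunes peptides to those conserved in the previous pass, removes
poorly covered outliers, clusters the Ward dendrogram of the dissimilarity
matrix at height 1, re-extracts conserved peptides per group, and merges
sister groups whose conserved patterns largely coincide (complete linkage,
cut at 0.7).  Conservation floors rise 10% -> 20% -> 30% -> 40% while the
minimum group size rises 2 -> 3 -> 4 -> 5; a final pass on the 40%
peptides fixes the definitive groups.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .peptides import PeptideParams, PeptidePool, build_pool

logger = logging.getLogger(__name__)


class ClusteringError(RuntimeError):
    """Raised when a family cannot be clustered under the current settings."""


@dataclass(frozen=True)
class ClusteringParams:
    """All tunable knobs of the incremental clustering engine."""

    peptide_params: PeptideParams = PeptideParams()
    c_clust: int = 9
    min_coverage_abs: int = 20
    min_coverage_median_frac: float = 0.10
    conservation_schedule: tuple[float, ...] = (0.10, 0.20, 0.30, 0.40)
    min_group_size_schedule: tuple[int, ...] = (2, 3, 4, 5)
    protein_cluster_threshold: float = 1.0
    group_merge_threshold: float = 0.7
    final_min_group_size: int = 5
    retain_conservation: float = 0.20

    def __post_init__(self) -> None:
        if len(self.conservation_schedule) != len(self.min_group_size_schedule):
            raise ValueError("conservation and group-size schedules differ in length")
        if self.c_clust < 1:
            raise ValueError("c_clust must be a positive integer")
        if not all(0 < f <= 1 for f in self.conservation_schedule):
            raise ValueError("conservation fractions must lie in (0, 1]")

    def reduced(self) -> "ClusteringParams":
        """Relaxed settings for sparse families (minimum group size 3)."""
        return ClusteringParams(
            peptide_params=self.peptide_params,
            c_clust=self.c_clust,
            min_coverage_abs=self.min_coverage_abs,
            min_coverage_median_frac=self.min_coverage_median_frac,
            conservation_schedule=self.conservation_schedule,
            min_group_size_schedule=self.min_group_size_schedule,
            protein_cluster_threshold=self.protein_cluster_threshold,
            group_merge_threshold=self.group_merge_threshold,
            final_min_group_size=3,
            retain_conservation=self.retain_conservation,
        )


@dataclass(frozen=True)
class PairwiseScore:
    shared_positions: int
    max_positions: int
    score: float


@dataclass
class ProvisionalGroup:
    """A protein group with its conserved peptides and their conservation."""

    member_ids: tuple[str, ...]
    conserved: dict[str, float] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class ClusteringResult:
    groups: list[ProvisionalGroup]
    outliers: dict[str, str]  # protein id -> reason removed
    protein_linkage: np.ndarray | None
    protein_linkage_labels: list[str]
    group_linkage: np.ndarray | None
    round_log: list[dict]
    final_pools: dict[str, PeptidePool]
    params: ClusteringParams

    @property
    def grouped_ids(self) -> set[str]:
        out: set[str] = set()
        for g in self.groups:
            out.update(g.member_ids)
        return out


# ---------------------------------------------------------------------------
# Per-step operations


def prune_peptides(
    pools: dict[str, PeptidePool], carried: set[str] | None = None
) -> dict[str, PeptidePool]:
    """Drop uninformative peptides from every pool.

    Peptides found in only a single protein are removed.  When ``carried``
    is given (passes after the first), peptides outside the carried set are
    removed first.  Within-protein multiplicity counts as presence only,
    but the start-position sets are retained for coverage bookkeeping.
    Returns fresh pools; inputs are not mutated.
    """
    n_containing: dict[str, int] = {}
    for pool in pools.values():
        for pep in pool.entries:
            if carried is not None and pep not in carried:
                continue
            n_containing[pep] = n_containing.get(pep, 0) + 1
    keep = {pep for pep, c in n_containing.items() if c >= 2}
    out: dict[str, PeptidePool] = {}
    for pid, pool in pools.items():
        entries = {
            pep: set(starts) for pep, starts in pool.entries.items() if pep in keep
        }
        out[pid] = PeptidePool(
            protein_id=pid, sequence_length=pool.sequence_length, entries=entries
        )
    return out


def remove_outliers(
    pools: dict[str, PeptidePool], params: ClusteringParams
) -> tuple[dict[str, PeptidePool], dict[str, str]]:
    """Remove proteins whose surviving peptides cover too little sequence.

    A protein is an outlier if its covered-position count (union of
    ``[s, s + n)`` windows over surviving peptides) is below the absolute
    floor (default 20 residues) or below 10% of the family median.
    """
    n = params.peptide_params.n
    coverage = {pid: len(pool.covered_positions(n)) for pid, pool in pools.items()}
    med = statistics.median(coverage.values()) if coverage else 0
    removed: dict[str, str] = {}
    kept: dict[str, PeptidePool] = {}
    for pid in sorted(pools):
        cov = coverage[pid]
        if cov < params.min_coverage_abs:
            removed[pid] = f"coverage {cov} < {params.min_coverage_abs}"
        elif cov < params.min_coverage_median_frac * med:
            removed[pid] = (
                f"coverage {cov} < {params.min_coverage_median_frac:.0%} of median {med}"
            )
        else:
            kept[pid] = pools[pid]
    if pools and not kept:
        raise ClusteringError(
            "all proteins were removed as outliers; consider reduced settings"
        )
    return kept, removed


def eq1_distance(
    pool_a: PeptidePool, pool_b: PeptidePool, c_clust: int
) -> PairwiseScore:
    """Pairwise dissimilarity from shared peptide start positions.

    Shared peptides are found by exact string equality of variant strings.
    An empty pool gives maximal dissimilarity 1.
    """
    if not pool_a.entries or not pool_b.entries:
        logger.debug(
            "empty pool in pair (%s, %s); distance 1", pool_a.protein_id,
            pool_b.protein_id,
        )
        return PairwiseScore(0, 0, 1.0)
    shared = pool_a.entries.keys() & pool_b.entries.keys()
    starts_a: set[int] = set()
    starts_b: set[int] = set()
    for pep in shared:
        starts_a.update(pool_a.entries[pep])
        starts_b.update(pool_b.entries[pep])
    shared_positions = len(starts_a) + len(starts_b)
    max_positions = max(len(pool_a.all_starts()), len(pool_b.all_starts()))
    score = (1.0 - shared_positions / (2.0 * max_positions)) ** c_clust
    return PairwiseScore(shared_positions, max_positions, score)


def distance_matrix(
    pools: dict[str, PeptidePool], c_clust: int
) -> tuple[np.ndarray, list[str]]:
    """Symmetric dissimilarity matrix over the pools, ids in sorted order."""
    ids = sorted(pools)
    # cache per-protein distinct start counts to avoid recomputing in the loop
    n_starts = {pid: len(pools[pid].all_starts()) for pid in ids}
    m = len(ids)
    mat = np.zeros((m, m))
    for i in range(m):
        pa = pools[ids[i]]
        for j in range(i + 1, m):
            pb = pools[ids[j]]
            if not pa.entries or not pb.entries:
                score = 1.0
            else:
                shared = pa.entries.keys() & pb.entries.keys()
                sa: set[int] = set()
                sb: set[int] = set()
                for pep in shared:
                    sa.update(pa.entries[pep])
                    sb.update(pb.entries[pep])
                sp = len(sa) + len(sb)
                mp = max(n_starts[ids[i]], n_starts[ids[j]])
                score = (1.0 - sp / (2.0 * mp)) ** c_clust
            mat[i, j] = mat[j, i] = score
    return mat, ids


def cluster_proteins(
    mat: np.ndarray, ids: list[str], threshold: float = 1.0
) -> tuple[list[list[str]], np.ndarray]:
    """Ward-linkage flat clustering of a dissimilarity matrix.

    Returns the flat groups (cut at ``threshold`` cophenetic distance,
    ordered by smallest member id) and the linkage matrix.
    """
    if np.isnan(mat).any():
        raise ValueError("distance matrix contains NaN")
    if len(ids) < 2:
        return [[pid] for pid in ids], None
    z = linkage(squareform(mat, checks=False), method="ward")
    labels = fcluster(z, t=threshold, criterion="distance")
    by_label: dict[int, list[str]] = {}
    for pid, lab in zip(ids, labels):
        by_label.setdefault(int(lab), []).append(pid)
    groups = sorted((sorted(g) for g in by_label.values()), key=lambda g: g[0])
    return groups, z


def extract_conserved(
    member_ids: list[str],
    pools: dict[str, PeptidePool],
    floor: float,
) -> ProvisionalGroup:
    """Collect peptides present in at least ``floor`` of the group's members.

    Conservation is the fraction of members whose pool contains the
    peptide; within-member multiplicity does not matter.  ``floor`` of 0
    keeps every peptide present in at least one member.
    """
    size = len(member_ids)
    counts: dict[str, int] = {}
    for pid in member_ids:
        for pep in pools[pid].entries:
            counts[pep] = counts.get(pep, 0) + 1
    conserved = {
        pep: c / size for pep, c in counts.items() if c / size >= floor and c > 0
    }
    return ProvisionalGroup(member_ids=tuple(sorted(member_ids)), conserved=conserved)


def group_dissimilarity(ga: ProvisionalGroup, gb: ProvisionalGroup) -> float:
    """1 - shared_conservation / individual_conservation between two groups.

    ``shared_conservation`` sums, over peptides conserved in both groups,
    the mean of the two conservation fractions; ``individual_conservation``
    is the larger of the two groups' total conservation sums.  Identical
    groups score 0, groups with disjoint peptides score 1.
    """
    shared = ga.conserved.keys() & gb.conserved.keys()
    shared_conservation = sum(
        (ga.conserved[p] + gb.conserved[p]) / 2.0 for p in shared
    )
    individual = max(sum(ga.conserved.values()), sum(gb.conserved.values()))
    if individual == 0:
        return 1.0
    return 1.0 - shared_conservation / individual


def merge_sister_groups(
    groups: list[ProvisionalGroup],
    pools: dict[str, PeptidePool],
    floor: float,
    threshold: float = 0.7,
) -> tuple[list[ProvisionalGroup], np.ndarray | None]:
    """Merge groups whose conserved peptide patterns largely coincide.

    Complete-linkage clustering of the group dissimilarity matrix, cut at
    ``threshold``; merged groups pool their members and re-extract
    conserved peptides at the current round's floor.
    """
    if len(groups) < 2:
        return list(groups), None
    m = len(groups)
    mat = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            mat[i, j] = mat[j, i] = group_dissimilarity(groups[i], groups[j])
    z = linkage(squareform(mat, checks=False), method="complete")
    labels = fcluster(z, t=threshold, criterion="distance")
    by_label: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        by_label.setdefault(int(lab), []).append(idx)
    merged: list[ProvisionalGroup] = []
    for idxs in by_label.values():
        if len(idxs) == 1:
            merged.append(groups[idxs[0]])
        else:
            members = sorted({pid for i in idxs for pid in groups[i].member_ids})
            merged.append(extract_conserved(members, pools, floor))
    merged.sort(key=lambda g: g.member_ids[0])
    return merged, z


# ---------------------------------------------------------------------------
# The full incremental run


def run_incremental(
    sequences: dict[str, str], params: ClusteringParams | None = None
) -> ClusteringResult:
    """Execute the five-pass incremental clustering on one family.

    ``sequences`` maps protein id to the residue string to cluster on
    (the family-domain region when domain ranges are available, otherwise
    the full-length sequence).
    """
    params = params or ClusteringParams()
    pp = params.peptide_params
    raw_pools = {
        pid: build_pool(pid, sequences[pid], pp) for pid in sorted(sequences)
    }
    outliers: dict[str, str] = {}
    round_log: list[dict] = []
    carried: set[str] | None = None
    active = dict(raw_pools)

    schedule = list(
        zip(params.conservation_schedule, params.min_group_size_schedule)
    )
    # final pass: cluster on the last round's conserved peptides, keep all
    # present peptides per group (the >20% retention happens at finalization)
    schedule.append((0.0, params.final_min_group_size))
    n_rounds = len(schedule)

    groups: list[ProvisionalGroup] = []
    protein_linkage = None
    linkage_ids: list[str] = []
    final_pools: dict[str, PeptidePool] = {}

    for round_no, (floor, min_size) in enumerate(schedule, start=1):
        is_final = round_no == n_rounds
        pruned = prune_peptides(active, carried)
        kept, removed = remove_outliers(pruned, params)
        for pid, reason in removed.items():
            outliers[pid] = f"round {round_no}: {reason}"
        if len(kept) < 2:
            raise ClusteringError(
                f"round {round_no}: fewer than 2 proteins survive "
                f"({len(kept)}); consider reduced settings"
            )
        mat, ids = distance_matrix(kept, params.c_clust)
        flat, z = cluster_proteins(mat, ids, params.protein_cluster_threshold)
        if is_final:
            protein_linkage, linkage_ids = z, ids
        sized = []
        for members in flat:
            if len(members) < min_size:
                for pid in members:
                    outliers[pid] = (
                        f"round {round_no}: group of {len(members)} below "
                        f"minimum size {min_size}"
                    )
            else:
                sized.append(members)
        if not sized:
            raise ClusteringError(
                f"round {round_no}: no group reaches the minimum size "
                f"{min_size}; consider reduced settings"
            )
        groups = [extract_conserved(m, kept, floor) for m in sized]
        if not is_final:
            groups, _ = merge_sister_groups(
                groups, kept, floor, params.group_merge_threshold
            )
        carried = set()
        for g in groups:
            carried.update(g.conserved)
        grouped = {pid for g in groups for pid in g.member_ids}
        active = {pid: kept[pid] for pid in sorted(grouped)}
        round_log.append(
            {
                "round": round_no,
                "conservation_floor": floor,
                "min_group_size": min_size,
                "n_proteins": len(kept),
                "n_grouped": len(grouped),
                "n_groups": len(groups),
                "n_peptides": len({p for pool in kept.values() for p in pool.entries}),
                "n_carried": len(carried),
            }
        )
        if is_final:
            final_pools = {pid: kept[pid] for pid in grouped}

    group_z = None
    if len(groups) >= 2:
        m = len(groups)
        gmat = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                gmat[i, j] = gmat[j, i] = group_dissimilarity(groups[i], groups[j])
        group_z = linkage(squareform(gmat, checks=False), method="complete")

    return ClusteringResult(
        groups=groups,
        outliers=outliers,
        protein_linkage=protein_linkage,
        protein_linkage_labels=linkage_ids,
        group_linkage=group_z,
        round_log=round_log,
        final_pools=final_pools,
        params=params,
    )
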