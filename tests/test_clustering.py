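"""Distance definition, pruning, outlier removal, and the incremental run."""

import numpy as np
import pytest
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import adjusted_rand_score

from cupp.clustering import (
    ClusteringError,
    ClusteringParams,
    cluster_proteins,
    distance_matrix,
    eq1_distance,
    extract_conserved,
    group_dissimilarity,
    merge_sister_groups,
    prune_peptides,
    remove_outliers,
    run_incremental,
    ProvisionalGroup,
)
from cupp.peptides import PeptideParams, build_pool, build_pools


def random_protein(rng, length):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))


def naive_eq1(pool_a, pool_b, c_clust):
    """Independent recomputation of the dissimilarity by set arithmetic."""
    if not pool_a.entries or not pool_b.entries:
        return 1.0
    shared = set(pool_a.entries) & set(pool_b.entries)
    starts_a = set()
    starts_b = set()
    for p in shared:
        starts_a |= pool_a.entries[p]
        starts_b |= pool_b.entries[p]
    all_a = set()
    for s in pool_a.entries.values():
        all_a |= s
    all_b = set()
    for s in pool_b.entries.values():
        all_b |= s
    frac = (len(starts_a) + len(starts_b)) / (2 * max(len(all_a), len(all_b)))
    return (1 - frac) ** c_clust


class TestPrunePeptides:
    params = PeptideParams(8, 2)

    def test_identical_sequences_keep_everything(self):
        seq = "MKLVTAGHWQERTYIPSD"
        pools = build_pools({"a": seq, "b": seq}, self.params)
        pruned = prune_peptides(pools)
        assert pruned["a"].entries == pools["a"].entries

    def test_unrelated_sequences_lose_everything(self):
        pools = build_pools(
            {"a": "MKLVTAGHWQER", "b": "CCDDEEFFNNSS"}, self.params
        )
        pruned = prune_peptides(pools)
        assert len(pruned["a"]) == 0 and len(pruned["b"]) == 0

    def test_survivors_match_brute_force_count(self):
        rng = np.random.default_rng(0)
        seqs = {f"p{i}": random_protein(rng, 30) for i in range(3)}
        # force overlap between p0 and p1
        seqs["p1"] = seqs["p0"][:20] + seqs["p1"][20:]
        pools = build_pools(seqs, self.params)
        pruned = prune_peptides(pools)
        surviving = {p for pool in pruned.values() for p in pool.entries}
        expected = {
            pep
            for pep in {p for pool in pools.values() for p in pool.entries}
            if sum(pep in pool.entries for pool in pools.values()) >= 2
        }
        assert surviving == expected

    def test_carried_set_restricts_first(self):
        seq = "MKLVTAGHWQERTYIPSD"
        pools = build_pools({"a": seq, "b": seq}, self.params)
        carried = set(list(pools["a"].entries)[:5])
        pruned = prune_peptides(pools, carried)
        assert set(pruned["a"].entries) == carried


class TestRemoveOutliers:
    params = ClusteringParams(peptide_params=PeptideParams(8, 2))

    def test_empty_pool_removed(self):
        seq = "MKLVTAGHWQERTYIPSDMKLVTAGHWQERTYIPSD"
        pools = build_pools({"a": seq, "b": seq, "c": "WWYYFFHHKKRR"}, self.params.peptide_params)
        pruned = prune_peptides(pools)
        kept, removed = remove_outliers(pruned, self.params)
        assert set(kept) == {"a", "b"}
        assert "c" in removed and "coverage 0" in removed["c"]

    def test_uniform_family_keeps_all(self):
        seq = "MKLVTAGHWQERTYIPSDMKLVTAGH"
        pools = prune_peptides(
            build_pools({c: seq for c in "abcd"}, self.params.peptide_params)
        )
        kept, removed = remove_outliers(pools, self.params)
        assert not removed and len(kept) == 4

    def test_coverage_floor_is_residue_positions(self):
        # 2 identical short proteins: covered positions = sequence length
        seq = "MKLVTAGHWQERTYIPSDA"  # 19 residues < 20 floor
        pools = prune_peptides(
            build_pools({"a": seq, "b": seq}, self.params.peptide_params)
        )
        with pytest.raises(ClusteringError, match="outliers"):
            remove_outliers(pools, self.params)


class TestEq1Distance:
    params = PeptideParams(8, 2)

    def test_identical_proteins_score_zero(self):
        seq = "MKLVTAGHWQERTYIPSD"
        pools = prune_peptides(build_pools({"a": seq, "b": seq}, self.params))
        score = eq1_distance(pools["a"], pools["b"], 9)
        assert score.score == 0.0
        assert score.shared_positions == 2 * score.max_positions

    def test_disjoint_proteins_score_one(self):
        pools = build_pools(
            {"a": "MKLVTAGHWQER", "b": "CCDDEEFFNNSS"}, self.params
        )
        assert eq1_distance(pools["a"], pools["b"], 9).score == 1.0

    def test_empty_pool_maximal(self):
        pools = build_pools({"a": "MKLVTAGHWQER"}, self.params)
        with pytest.warns(UserWarning, match="shorter than window"):
            empty = build_pool("e", "MKLVTAG", self.params)
        assert eq1_distance(pools["a"], empty, 9).score == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seqs = {}
        base = random_protein(rng, 120)
        for i in range(4):
            chars = list(base)
            for j in rng.choice(len(chars), size=12, replace=False):
                chars[j] = random_protein(rng, 1)
            seqs[f"p{i}"] = "".join(chars)
        pools = prune_peptides(build_pools(seqs, self.params))
        ids = sorted(pools)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                got = eq1_distance(pools[a], pools[b], 9).score
                assert got == pytest.approx(naive_eq1(pools[a], pools[b], 9), abs=1e-12)

    def test_monotone_in_c_clust(self):
        rng = np.random.default_rng(3)
        base = random_protein(rng, 80)
        other = base[:50] + random_protein(rng, 30)
        pools = prune_peptides(build_pools({"a": base, "b": other, "c": base}, self.params))
        scores = [
            eq1_distance(pools["a"], pools["b"], c).score for c in (3, 6, 9, 12)
        ]
        assert scores == sorted(scores, reverse=True)


class TestClusterProteins:
    def test_all_zero_matrix_single_group(self):
        mat = np.zeros((4, 4))
        groups, _ = cluster_proteins(mat, list("abcd"))
        assert groups == [["a", "b", "c", "d"]]

    def test_two_blocks_split(self):
        mat = np.ones((4, 4))
        mat[:2, :2] = 0
        mat[2:, 2:] = 0
        np.fill_diagonal(mat, 0)
        groups, _ = cluster_proteins(mat, list("abcd"))
        assert groups == [["a", "b"], ["c", "d"]]

    def test_nan_rejected(self):
        mat = np.zeros((3, 3))
        mat[0, 1] = mat[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            cluster_proteins(mat, list("abc"))

    def test_matches_reference_ward_implementation(self):
        """Same flat labels as scikit-learn Ward on the underlying points."""
        rng = np.random.default_rng(4)
        pts = np.vstack(
            [rng.normal(0, 0.05, (3, 2)), rng.normal(3, 0.05, (3, 2))]
        )
        mat = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        threshold = 1.0
        groups, _ = cluster_proteins(mat, [f"p{i}" for i in range(6)])
        ours = {}
        for gi, g in enumerate(groups):
            for pid in g:
                ours[int(pid[1:])] = gi
        ref = AgglomerativeClustering(
            n_clusters=None, distance_threshold=threshold, linkage="ward"
        ).fit(pts)
        assert adjusted_rand_score(
            [ours[i] for i in range(6)], ref.labels_
        ) == 1.0


class TestConservedAndMerge:
    params = PeptideParams(8, 2)

    def test_conservation_fractions(self):
        seq = "MKLVTAGHWQERTYIPSDMKLVTAGHWQ"
        other = "WQERTYIPSDMKLVTAGHWQCCDDEEFF"
        pools = build_pools(
            {"a": seq, "b": seq, "c": seq, "d": other}, self.params
        )
        group = extract_conserved(["a", "b", "c", "d"], pools, floor=0.0)
        values = set(group.conserved.values())
        assert values <= {0.25, 0.5, 0.75, 1.0}
        high = extract_conserved(["a", "b", "c", "d"], pools, floor=0.6)
        assert all(v >= 0.6 for v in high.conserved.values())
        brute = {
            pep: sum(pep in pools[x].entries for x in "abcd") / 4
            for pool in pools.values()
            for pep in pool.entries
        }
        assert high.conserved == {p: v for p, v in brute.items() if v >= 0.6}

    def test_group_dissimilarity_hand_computed(self):
        ga = ProvisionalGroup(("a",), {"P1": 1.0, "P2": 0.5})
        gb = ProvisionalGroup(("b",), {"P1": 0.8, "P3": 0.6})
        gc = ProvisionalGroup(("c",), {"Q1": 1.0})
        # shared {P1}: mean 0.9; individual = max(1.5, 1.4) = 1.5
        assert group_dissimilarity(ga, gb) == pytest.approx(1 - 0.9 / 1.5)
        assert group_dissimilarity(ga, gc) == 1.0
        assert group_dissimilarity(ga, ga) == 0.0

    def test_identical_groups_merge_disjoint_do_not(self):
        seq_a = "MKLVTAGHWQERTYIPSDMKLVTAGHWQ"
        seq_b = "CCDDEEFFNNSSRRHHKKCCDDEEFFNN"
        pools = build_pools(
            {"a1": seq_a, "a2": seq_a, "b1": seq_b, "b2": seq_b}, self.params
        )
        g1 = extract_conserved(["a1"], pools, 0.0)
        g2 = extract_conserved(["a2"], pools, 0.0)
        g3 = extract_conserved(["b1", "b2"], pools, 0.0)
        merged, _ = merge_sister_groups([g1, g2, g3], pools, floor=0.0)
        assert sorted(len(g.member_ids) for g in merged) == [2, 2]
        member_sets = {g.member_ids for g in merged}
        assert ("a1", "a2") in member_sets


class TestRunIncremental:
    def test_identical_family_single_group(self):
        seq = "MKLVTAGHWQERTYIPSDMKLVTAGHWQERTYIPSD"
        result = run_incremental({f"p{i}": seq for i in range(5)})
        assert len(result.groups) == 1
        assert result.groups[0].member_ids == tuple(f"p{i}" for i in range(5))
        assert not result.outliers

    def test_too_few_proteins_raises_with_round(self):
        seq = "MKLVTAGHWQERTYIPSDMKLVTAGHWQERTYIPSD"
        with pytest.raises(ClusteringError, match="round"):
            run_incremental({"a": seq, "b": seq})  # group of 2 dies in round 2

    def test_groups_partition_non_outliers(self, family, family_result):
        _, records, _, _ = family
        grouped = family_result.grouped_ids
        outliers = set(family_result.outliers)
        all_ids = {r.protein_id for r in records}
        assert grouped | outliers == all_ids
        assert not grouped & outliers
        sizes = sum(len(g.member_ids) for g in family_result.groups)
        assert sizes == len(grouped)

    def test_peptide_counts_non_increasing_over_rounds(self, family_result):
        counts = [row["n_peptides"] for row in family_result.round_log]
        assert counts == sorted(counts, reverse=True)

    def test_recovers_generative_groups(self, family, family_result):
        _, _, truth, _ = family
        assert len(family_result.groups) == 5
        for g in family_result.groups:
            assert len({truth[pid] for pid in g.member_ids}) == 1

    def test_deterministic_rerun(self, small_family):
        _, records, _, _ = small_family
        seqs = {r.protein_id: r.sequence for r in records}
        r1 = run_incremental(seqs)
        r2 = run_incremental(seqs)
        assert [g.member_ids for g in r1.groups] == [g.member_ids for g in r2.groups]
        assert [g.conserved for g in r1.groups] == [g.conserved for g in r2.groups]
        assert r1.round_log == r2.round_log
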