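"""Distances, neighbor joining, nearest-panel placement, mito mismatch,
clonal clusters and embryo typing."""

import numpy as np
import pytest

from xenopop import lineage_placement as lp
from xenopop.variant_store import IndividualMeta, VariantSite

from conftest import make_cohort


class TestPDistance:
    def test_identical_zero(self):
        assert lp.p_distance("ACGTACGT", "ACGTACGT", min_overlap=1) == (0.0, 8)

    def test_single_mismatch(self):
        d, o = lp.p_distance("ACGT", "ACGA", min_overlap=1)
        assert d == 0.25 and o == 4

    def test_n_positions_excluded_from_denominator(self):
        # hand count: N/gap in either sequence excludes positions 3 and 6;
        # comparable = {1,2,4,5}, mismatches at 4 and 5 -> 2/4
        d, o = lp.p_distance("ACNTG-", "AC-ACN", min_overlap=1)
        assert o == 4 and d == pytest.approx(0.5)

    def test_insufficient_overlap_flagged(self):
        d, o = lp.p_distance("ANNN", "ACGT", min_overlap=2)
        assert np.isnan(d) and o == 1

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            lp.p_distance("ACGT", "ACG")


def additive_matrix(bl):
    """4-taxon tree ((A:bl0,B:bl1):bl4,(C:bl2,D:bl3)); returns the additive
    distance matrix for topology AB|CD."""
    a, b, c, d, m = bl
    D = np.array(
        [
            [0, a + b, a + m + c, a + m + d],
            [a + b, 0, b + m + c, b + m + d],
            [a + m + c, b + m + c, 0, c + d],
            [a + m + d, b + m + d, c + d, 0],
        ],
        dtype=float,
    )
    return lp.DistanceMatrix(["A", "B", "C", "D"], D, np.full((4, 4), 1000))


def newick_splits(newick, taxa):
    """Non-trivial bipartitions of an unrooted tree; each split is stored as
    both its leaf set and the complement so comparisons are root-agnostic."""
    import dendropy

    taxa = set(taxa)
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.encode_bipartitions()
    splits = set()
    for bip in tree.bipartition_encoding:
        side = frozenset(t.label for t in bip.leafset_taxa(tree.taxon_namespace))
        comp = frozenset(taxa - side)
        if 1 < len(side) < len(taxa) - 1:
            splits.add(side)
            splits.add(comp)
    return splits


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 0.3, 0.5], [0.3, 0, 0.4], [0.5, 0.4, 0]])
        dm = lp.DistanceMatrix(["a", "b", "c"], D, np.full((3, 3), 1000))
        nwk = lp.nj_tree(dm)
        # three-point solution: a=0.2, b=0.1, c=0.3
        assert "a:0.2" in nwk and "b:0.1" in nwk and "c:0.3" in nwk

    @pytest.mark.parametrize("pair", [("A", "B"), ("A", "C"), ("A", "D")])
    def test_recovers_each_four_taxon_topology(self, pair):
        """All three labeled topologies, checked by the four-point condition."""
        order = list(pair) + [t for t in "ABCD" if t not in pair]
        bl = [0.11, 0.23, 0.17, 0.08, 0.3]
        D4 = additive_matrix(bl)
        # relabel so the cherry is `pair`
        perm = [order.index(t) for t in "ABCD"]
        vals = D4.values[np.ix_(perm, perm)]
        dm = lp.DistanceMatrix(["A", "B", "C", "D"], vals, np.full((4, 4), 1000))
        nwk = lp.nj_tree(dm)
        splits = newick_splits(nwk, "ABCD")
        assert frozenset(pair) in splits or frozenset(set("ABCD") - set(pair)) in splits

    def test_recovers_additive_branch_lengths(self):
        bl = [0.11, 0.23, 0.17, 0.08, 0.3]
        nwk = lp.nj_tree(additive_matrix(bl))
        import dendropy

        tree = dendropy.Tree.get(data=nwk, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        D = additive_matrix(bl).values
        for i, x in enumerate("ABCD"):
            for j, y in enumerate("ABCD"):
                if i < j:
                    assert pdm.distance(taxa[x], taxa[y]) == pytest.approx(D[i, j], abs=1e-9)

    def test_ultrametric_topology_matches_single_linkage(self):
        # heights: (a,b) at 0.1, +c at 0.2, +(d,e) pair at 0.15, all at 0.4
        labels = list("abcde")
        h = {
            ("a", "b"): 0.1, ("a", "c"): 0.2, ("b", "c"): 0.2,
            ("d", "e"): 0.15,
        }
        D = np.zeros((5, 5))
        for i, x in enumerate(labels):
            for j, y in enumerate(labels):
                if i < j:
                    D[i, j] = D[j, i] = h.get((x, y), h.get((y, x), 0.4))
        dm = lp.DistanceMatrix(labels, D, np.full((5, 5), 1000))
        splits = newick_splits(lp.nj_tree(dm), labels)
        assert frozenset({"a", "b"}) in splits
        assert frozenset({"d", "e"}) in splits

    def test_agrees_with_skbio_on_additive_six_taxon_matrix(self):
        skbio = pytest.importorskip("skbio")
        import dendropy

        nwk = "((t0:0.1,t1:0.2):0.15,((t2:0.05,t3:0.3):0.2,t4:0.25):0.1,t5:0.4);"
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        tns = tree.taxon_namespace
        labels = [t.label for t in tns]
        D = np.array([[pdm.distance(a, b) for b in tns] for a in tns])
        dm = lp.DistanceMatrix(labels, D, np.full((6, 6), 1000))
        ours = newick_splits(lp.nj_tree(dm), labels)
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
        theirs = newick_splits(str(sk_tree), labels)
        assert ours == theirs

    def test_fewer_than_three_taxa_raises(self):
        dm = lp.DistanceMatrix(["a", "b"], np.zeros((2, 2)), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            lp.nj_tree(dm)


class TestNearestPanel:
    def test_query_identical_to_member_full_support(self):
        panels = {"X": ["ACGT" * 50], "Y": ["TTTT" * 50]}
        res = lp.assign_by_nearest_panel("ACGT" * 50, panels, n_bootstrap=50, rng=0)
        assert res.assigned_group == "X" and res.support == 1.0

    def test_equidistant_tie_unassigned(self):
        q = "AAAA" * 50
        panels = {"X": ["AAAC" * 50], "Y": ["AAAG" * 50]}
        res = lp.assign_by_nearest_panel(q, panels, n_bootstrap=0, rng=0)
        assert res.assigned_group == "unassigned"

    def test_all_overlap_too_small_unassigned(self):
        q = "N" * 200
        res = lp.assign_by_nearest_panel(q, {"X": ["A" * 200]}, n_bootstrap=0)
        assert res.assigned_group == "unassigned"

    def test_empty_panel_raises(self):
        with pytest.raises(ValueError):
            lp.assign_by_nearest_panel("ACGT", {"X": []})

    def test_mito_assignment_robust_to_half_masked_query(self):
        rng = np.random.default_rng(3)
        ref_a = "".join(rng.choice(list("ACGT"), 400))
        ref_b = list(ref_a)
        for k in rng.choice(400, 30, replace=False):
            ref_b[k] = "ACGT"[("ACGT".index(ref_b[k]) + 1) % 4]
        ref_b = "".join(ref_b)
        full = lp.assign_mito(ref_a, {"A": ref_a, "B": ref_b}, n_bootstrap=50, rng=1)
        masked = ref_a[:200] + "N" * 200
        half = lp.assign_mito(masked, {"A": ref_a, "B": ref_b}, n_bootstrap=50, rng=1)
        assert full.assigned_group == half.assigned_group == "A"


class TestMismatch:
    def res(self, group):
        return lp.PlacementResult("m1", group, 0.1, 1.0)

    def test_structor_nucleus_with_ibericus_mito_flagged(self):
        flag = lp.detect_mito_nuclear_mismatch(self.res("structor"), self.res("ibericus"))
        assert flag.is_mismatch and not flag.indeterminate

    def test_concordant_not_flagged(self):
        flag = lp.detect_mito_nuclear_mismatch(self.res("ibericus"), self.res("ibericus"))
        assert not flag.is_mismatch

    def test_unassigned_side_indeterminate(self):
        flag = lp.detect_mito_nuclear_mismatch(self.res("unassigned"), self.res("ibericus"))
        assert flag.indeterminate and not flag.is_mismatch

    def test_lineage_labels_mapped_to_species(self):
        flag = lp.detect_mito_nuclear_mismatch(
            self.res("structor_clonal"),
            self.res("ibericus"),
            species_of={"structor_clonal": "structor", "ibericus": "ibericus"},
        )
        assert flag.is_mismatch


class TestClonalCluster:
    def test_identical_set_single_cluster_zero_mean(self):
        seqs = {f"m{k}": "ACGT" * 30 for k in range(4)}
        res = lp.detect_clonal_cluster(seqs, 0.01, min_overlap=10)
        assert len(res.clusters) == 1 and res.mean_distances[0] == 0.0

    def test_two_groups_split_and_clonal_like_is_tight_one(self):
        rng = np.random.default_rng(5)
        base = "".join(rng.choice(list("ACGT"), 300))
        far = list(base)
        for k in rng.choice(300, 40, replace=False):
            far[k] = "ACGT"[("ACGT".index(far[k]) + 1) % 4]
        far = "".join(far)

        def jitter(s, k_mut, seed):
            r = np.random.default_rng(seed)
            out = list(s)
            for k in r.choice(300, k_mut, replace=False):
                out[k] = "ACGT"[("ACGT".index(out[k]) + 1) % 4]
            return "".join(out)

        seqs = {f"c{k}": jitter(base, 1, k) for k in range(4)}
        seqs |= {f"w{k}": jitter(far, 8, 10 + k) for k in range(4)}
        res = lp.detect_clonal_cluster(seqs, 0.05, min_overlap=10)
        parts = {frozenset(c) for c in res.clusters}
        assert parts == {
            frozenset({"c0", "c1", "c2", "c3"}),
            frozenset({"w0", "w1", "w2", "w3"}),
        }
        assert set(res.clusters[res.clonal_like]) == {"c0", "c1", "c2", "c3"}

    def test_degenerate_threshold_single_cluster(self):
        seqs = {"a": "AAAA" * 30, "b": "CCCC" * 30, "c": "GGGG" * 30}
        res = lp.detect_clonal_cluster(seqs, 1.0, min_overlap=10)
        assert len(res.clusters) == 1


class TestClassifyEmbryo:
    def egg_cohort(self, genotype, n_sites=30):
        metas = [
            IndividualMeta("q", "c", "queen", "ibericus", 2),
            IndividualMeta("m", "c", "male", "structor", 1),
            IndividualMeta("egg1", "c", "egg", "ibericus", 2),
        ]
        rows = [[(0, 0), (1, 1), genotype] for _ in range(n_sites)]
        sites = [VariantSite("chr1", i + 1, "A", ("C",)) for i in range(n_sites)]
        return make_cohort(rows, metas=metas, sites=sites)

    def test_androgenetic_egg_paternal_only(self):
        cohort = self.egg_cohort((1, 1))
        diag = lp.diagnostic_sites(cohort, ["q"], ["m"])
        assert len(diag) == 30
        assert lp.classify_embryo(cohort, "egg1", diag) == "paternal_only"

    def test_f1_egg_hybrid(self):
        cohort = self.egg_cohort((0, 1))
        diag = lp.diagnostic_sites(cohort, ["q"], ["m"])
        assert lp.classify_embryo(cohort, "egg1", diag) == "hybrid"

    def test_all_missing_indeterminate(self):
        cohort = self.egg_cohort(None)
        diag = lp.diagnostic_sites(cohort, ["q"], ["m"])
        assert lp.classify_embryo(cohort, "egg1", diag) == "indeterminate"

    def test_too_few_called_sites_indeterminate(self):
        cohort = self.egg_cohort((1, 1), n_sites=10)
        diag = lp.diagnostic_sites(cohort, ["q"], ["m"])
        assert lp.classify_embryo(cohort, "egg1", diag) == "indeterminate"
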