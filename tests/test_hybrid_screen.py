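"""Heterozygosity profiles, the F1 gap classifier, supervised ancestry."""

import itertools

import numpy as np
import pytest

from xenopop import hybrid_screen as hs
from xenopop.variant_store import IndividualMeta

from conftest import make_cohort


def profile(values):
    return [hs.HetProfile(f"i{k}", 0, 1, v) for k, v in enumerate(values)]


class TestHetProportion:
    def test_direct_count_over_full_panel(self):
        # 3 het calls on a 10-site panel -> 0.3 even with missing calls
        rows = [[(0, 1)]] * 3 + [[(0, 0)]] * 5 + [[None]] * 2
        cohort = make_cohort(rows)
        p = hs.het_proportion(cohort, "ind0")
        assert p.het_sites == 3 and p.panel_size == 10 and p.het_proportion == 0.3

    def test_saturation(self):
        cohort = make_cohort([[(0, 1)]] * 10)
        assert hs.het_proportion(cohort, "ind0").het_proportion == 1.0

    def test_called_denominator_mode(self):
        rows = [[(0, 1)]] * 3 + [[(0, 0)]] * 3 + [[None]] * 4
        p = hs.het_proportion(make_cohort(rows), "ind0", denominator="called")
        assert p.het_proportion == 0.5

    def test_haploid_male_forced_zero_with_note(self):
        metas = [IndividualMeta("m1", "c", "male", "structor", 1)]
        cohort = make_cohort([[(0, 1)], [(0, 0)]], metas=metas)
        with pytest.warns(UserWarning, match="ploidy 1"):
            p = hs.het_proportion(cohort, "m1")
        assert p.het_proportion == 0.0 and "haploid" in p.note

    def test_absent_individual_raises(self):
        cohort = make_cohort([[(0, 0)]])
        with pytest.raises(Exception, match="ghost"):
            hs.het_proportion(cohort, "ghost")

    def test_invariant_under_site_order_and_extra_individuals(self, small_sim):
        from xenopop.variant_store import filter_sites

        panel = filter_sites(small_sim.cohort)
        iid = "WC_ib_001"
        base = hs.het_proportion(panel, iid)
        rng = np.random.default_rng(0)
        perm = rng.permutation(panel.n_sites)
        # permute the rows and renumber positions on one contig: same calls,
        # different site order
        from xenopop.variant_store import CohortMatrix, VariantSite

        sites = [
            VariantSite("chr1", k + 1, panel.sites[p].ref_allele, panel.sites[p].alt_alleles)
            for k, p in enumerate(perm)
        ]
        shuffled = CohortMatrix(
            sites=sites,
            individuals=panel.individuals,
            alleles=panel.alleles[perm],
            depth=panel.depth[perm],
            quality=panel.quality[perm],
        )
        p1 = hs.het_proportion(shuffled, iid)
        assert (p1.het_sites, p1.het_proportion) == (base.het_sites, base.het_proportion)
        fewer = type(panel)(
            sites=panel.sites,
            individuals=panel.individuals[: panel.column(iid) + 1],
            alleles=panel.alleles[:, : panel.column(iid) + 1],
            depth=panel.depth[:, : panel.column(iid) + 1],
            quality=panel.quality[:, : panel.column(iid) + 1],
        )
        p2 = hs.het_proportion(fewer, iid)
        assert (p2.het_sites, p2.het_proportion) == (base.het_sites, base.het_proportion)


def oracle_split(values):
    """Exhaustive largest-gap split: try every cut of the sorted values."""
    sv = sorted(values)
    best_cut, best_gap = None, -1.0
    for k in range(1, len(sv)):
        gap = sv[k] - sv[k - 1]
        if gap > best_gap:
            best_gap, best_cut = gap, k
    return set(sv[best_cut:])


class TestClassifyF1:
    def test_matches_exhaustive_split_oracle_on_four_values(self):
        values = [0.80, 0.79, 0.05, 0.04]
        calls = hs.classify_f1(profile(values))
        flagged = {values[int(c.individual_id[1:])] for c in calls if c.is_f1}
        assert flagged == oracle_split(values) == {0.79, 0.80}

    def test_intermediate_hybrid_joins_upper_cluster(self):
        # a 0.58 value among an ~0.8 cluster and an ~0.05 cluster joins the
        # hybrids (the single hybrid worker of the sister species)
        values = [0.82, 0.80, 0.79, 0.58, 0.06, 0.05, 0.04]
        calls = {c.individual_id: c for c in hs.classify_f1(profile(values))}
        assert calls["i3"].is_f1
        assert not calls["i4"].is_f1

    def test_no_separation_no_flags(self):
        with pytest.warns(UserWarning, match="identical"):
            calls = hs.classify_f1(profile([0.05] * 6))
        assert not any(c.is_f1 for c in calls)

    def test_separation_guard_blocks_weak_split(self):
        # continuous spread: upper/lower means differ by < 5x
        calls = hs.classify_f1(profile([0.30, 0.28, 0.26, 0.22, 0.20]))
        assert not any(c.is_f1 for c in calls)

    def test_needs_two_profiles(self):
        with pytest.raises(ValueError):
            hs.classify_f1(profile([0.5]))


class TestEstimateAncestry:
    def two_source_cohort(self, genotypes, n_sites):
        rows = [[genotypes[i]] for i in range(n_sites)]
        return make_cohort(rows)

    def test_pure_maternal_hits_upper_boundary(self):
        cohort = self.two_source_cohort([(0, 0)] * 50, 50)
        p_m = np.tile([1.0, 0.0], (50, 1))
        p_p = np.tile([0.0, 1.0], (50, 1))
        est = hs.estimate_ancestry(cohort, "ind0", (p_m, p_p))
        assert est.q_maternal > 0.999

    def test_f1_symmetry_gives_half(self):
        cohort = self.two_source_cohort([(0, 1)] * 50, 50)
        p_m = np.tile([1.0, 0.0], (50, 1))
        p_p = np.tile([0.0, 1.0], (50, 1))
        est = hs.estimate_ancestry(cohort, "ind0", (p_m, p_p))
        assert est.q_maternal == pytest.approx(0.5, abs=1e-4)

    def test_two_site_toy_matches_grid_search_oracle(self):
        p_m = np.array([[0.9, 0.1], [0.8, 0.2]])
        p_p = np.array([[0.1, 0.9], [0.3, 0.7]])
        cohort = self.two_source_cohort([(0, 1), (0, 0)], 2)
        est = hs.estimate_ancestry(cohort, "ind0", (p_m, p_p))

        def loglik(q):
            total = 0.0
            for (a, b), pm_row, pp_row in zip([(0, 1), (0, 0)], p_m, p_p):
                for al in (a, b):
                    total += np.log(q * pm_row[al] + (1 - q) * pp_row[al])
            return total

        grid = np.linspace(0, 1, 10001)
        q_star = grid[np.argmax([loglik(q) for q in grid])]
        assert est.q_maternal == pytest.approx(q_star, abs=1e-4)

    def test_uninformative_panel_raises(self):
        p = np.tile([0.5, 0.5], (5, 1))
        cohort = self.two_source_cohort([(0, 1)] * 5, 5)
        with pytest.raises(ValueError, match="uninformative"):
            hs.estimate_ancestry(cohort, "ind0", (p, p.copy()))

    @pytest.mark.parametrize("q_true", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_recovers_admixture_on_large_panels(self, q_true):
        """10^4 fixed-difference sites: q recovered within 0.02 (seeded)."""
        rng = np.random.default_rng(int(q_true * 100) + 11)
        n = 10_000
        p_m = np.tile([1.0, 0.0], (n, 1))
        p_p = np.tile([0.0, 1.0], (n, 1))
        copies = rng.random((n, 2)) < q_true  # True -> maternal allele (0)
        genotypes = [tuple(np.sort(np.where(copies[i], 0, 1))) for i in range(n)]
        cohort = self.two_source_cohort(genotypes, n)
        est = hs.estimate_ancestry(cohort, "ind0", (p_m, p_p))
        assert est.q_maternal == pytest.approx(q_true, abs=0.02)


class TestCompareGroups:
    def test_identical_groups_p_near_one(self):
        assert hs.compare_groups([1, 2, 3, 4], [1, 2, 3, 4]) > 0.95

    def test_exact_p_matches_permutation_oracle(self):
        a, b = [1, 2, 3], [4, 5, 6]
        p = hs.compare_groups(a, b)
        # exhaustive oracle: distribution of the rank-sum statistic over all
        # assignments of 3 ranks out of 6
        pooled = sorted(a + b)
        obs = sum(pooled.index(x) + 1 for x in a)
        sums = [sum(c) for c in itertools.combinations(range(1, 7), 3)]
        lo = sum(s <= obs for s in sums) / len(sums)
        hi = sum(s >= obs for s in sums) / len(sums)
        expected = min(1.0, 2 * min(lo, hi))
        assert p == pytest.approx(expected, abs=1e-9)

    def test_fully_separated_groups_tiny_p(self):
        p = hs.compare_groups(range(20), range(100, 120))
        assert p < 1e-9

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            hs.compare_groups([], [1.0])
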