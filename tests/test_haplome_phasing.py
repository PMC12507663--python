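"""The reference-guided phasing rule table and haplome reconstruction."""

import itertools

import pytest

from xenopop import haplome_phasing as hp
from xenopop.haplome_phasing import PhaseRule
from xenopop.variant_store import GenotypeCall, VariantSite, filter_sites
from xenopop.synthetic_colonies import simulate_scenario

from conftest import make_cohort, small_scenario

SITE = VariantSite("g1", 5, "A", ("G", "T"))


def call(a, b, depth=10):
    return GenotypeCall((a, b), depth, 60.0)


def oracle_phase(site, hyb, ref, min_depth=3):
    """Independently coded rule table (straight transcription of the
    published decision text, separate from the implementation)."""
    nts = site.alleles
    if hyb.depth < min_depth or ref.depth < min_depth:
        return ("N", "N", PhaseRule.LOW_DEPTH)
    if hyb.alleles[0] == -1 or ref.alleles[0] == -1:
        return ("N", "N", PhaseRule.MISSING)
    if ref.alleles[0] != ref.alleles[1]:
        return ("N", "N", PhaseRule.MAT_REF_HET)
    r = ref.alleles[0]
    a, b = hyb.alleles
    if a != b:  # hybrid heterozygous
        if r == a:
            return (nts[a], nts[b], PhaseRule.HET_MATCH)
        if r == b:
            return (nts[b], nts[a], PhaseRule.HET_MATCH)
        return ("N", "N", PhaseRule.NO_MATCH)
    if a == r:
        return (nts[a], nts[a], PhaseRule.HOM_SHARED)
    return ("N", "N", PhaseRule.NO_MATCH)


class TestPhaseSite:
    def test_canonical_het_match(self):
        # hybrid A/G with homozygous A/A reference: A maternal, G paternal
        ps = hp.phase_site(SITE, call(0, 1), call(0, 0))
        assert (ps.maternal_allele, ps.paternal_allele) == ("A", "G")
        assert ps.rule_applied == PhaseRule.HET_MATCH

    def test_low_reference_coverage_masks(self):
        ps = hp.phase_site(SITE, call(0, 1), call(0, 0, depth=2))
        assert ps.rule_applied == PhaseRule.LOW_DEPTH
        assert (ps.maternal_allele, ps.paternal_allele) == ("N", "N")

    def test_heterozygous_reference_masks(self):
        ps = hp.phase_site(SITE, call(0, 1), call(0, 1))
        assert ps.rule_applied == PhaseRule.MAT_REF_HET

    def test_shared_homozygous_assigned_to_both(self):
        ps = hp.phase_site(SITE, call(0, 0), call(0, 0))
        assert (ps.maternal_allele, ps.paternal_allele) == ("A", "A")
        assert ps.rule_applied == PhaseRule.HOM_SHARED

    def test_strict_mode_masks_shared_homozygous(self):
        ps = hp.phase_site(SITE, call(0, 0), call(0, 0), strict=True)
        assert ps.rule_applied == PhaseRule.HOM_SHARED
        assert (ps.maternal_allele, ps.paternal_allele) == ("N", "N")

    def test_multiallelic_het_without_reference_allele_no_match(self):
        # hybrid G/T vs reference A/A: conservative mask
        ps = hp.phase_site(SITE, call(1, 2), call(0, 0))
        assert ps.rule_applied == PhaseRule.NO_MATCH

    def test_exhaustive_enumeration_agrees_with_oracle(self):
        genotype_space = list(itertools.product([0, 1, 2], repeat=2)) + [(-1, -1)]
        depth_space = [2, 3, 7]
        n_checked = 0
        for (ha, hb), (ra, rb), dh, dr in itertools.product(
            genotype_space, genotype_space, depth_space, depth_space
        ):
            hyb = GenotypeCall((ha, hb), dh, 60.0)
            ref = GenotypeCall((ra, rb), dr, 60.0)
            got = hp.phase_site(SITE, hyb, ref)
            want = oracle_phase(SITE, hyb, ref)
            assert (got.maternal_allele, got.paternal_allele, got.rule_applied) == want
            n_checked += 1
        assert n_checked == len(genotype_space) ** 2 * len(depth_space) ** 2


@pytest.fixture(scope="module")
def mono_maternal_sim():
    """Maternal species monomorphic: the reference queen is identical to
    every worker's maternal haplotype, the regime in which the rule table
    makes zero phasing errors."""
    sc = small_scenario(
        pi_s_targets={"ibericus": 0.0, "structor_wild": 0.0014, "structor_clonal": 0.00027},
        seed=4242,
    )
    return simulate_scenario(sc)


def phase_panel(sim):
    return filter_sites(sim.cohort, min_maf=0.0, min_called=0.0)


class TestPhaseIndividual:
    def test_zero_paternal_errors_with_monomorphic_reference(self, mono_maternal_sim):
        sim = mono_maternal_sim
        panel = phase_panel(sim)
        workers = sim.truth.ids_where(true_class="F1", caste="worker")
        queens = sim.truth.ids_where(true_class="pure_maternal", caste="queen")
        for w in workers[:4]:
            phased = hp.phase_individual(panel, w, queens[0])
            _, hap_p = sim.truth.haplotypes[w]
            errors = assigned = 0
            for site, ps in zip(panel.sites, phased):
                if ps.paternal_allele == "N":
                    continue
                assigned += 1
                true_nt = "ACGT"[hap_p[site.contig][site.position - 1]]
                errors += ps.paternal_allele != true_nt
            assert assigned > 0
            assert errors == 0

    def test_reconstruction_conserves_genotype_at_het_match(self, small_sim):
        panel = phase_panel(small_sim)
        phased = hp.phase_individual(panel, "WC_ib_001", "Q_ib_001")
        jh = panel.column("WC_ib_001")
        for i, ps in enumerate(phased):
            if ps.rule_applied == PhaseRule.HET_MATCH:
                gt = {panel.sites[i].alleles[a] for a in panel.alleles[i, jh]}
                assert {ps.maternal_allele, ps.paternal_allele} == gt

    def test_self_phasing_yields_no_het_match(self, small_sim):
        panel = phase_panel(small_sim)
        phased = hp.phase_individual(panel, "WC_ib_001", "WC_ib_001")
        counts = hp.rule_counts(phased)
        assert counts["HET_MATCH"] == 0

    def test_f1_reference_rejected(self, small_sim):
        panel = phase_panel(small_sim)
        with pytest.raises(ValueError, match="F1"):
            hp.phase_individual(panel, "WC_ib_001", "WC_ib_002", f1_ids={"WC_ib_002"})

    def test_min_depth_monotonicity(self):
        """Raising min_depth never increases the assigned fraction."""
        sc = small_scenario(depth_mean=4.0, seed=99)
        sim = simulate_scenario(sc)
        panel = phase_panel(sim)
        backbone = sim.reference_backbone
        fracs = []
        for md in (1, 2, 3, 4, 6):
            phased = hp.phase_individual(panel, "WC_ib_001", "Q_ib_001", min_depth=md)
            _, pat = hp.build_haplome_sequences(phased, backbone, "WC_ib_001")
            fracs.append(pat.assigned_fraction)
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))
        assert fracs[0] > fracs[-1]  # depth ~4: masking must actually bite


class TestBuildHaplomes:
    def test_gene_with_excess_gaps_excluded(self):
        backbone = {"g1": "ACGTACGTAC", "g2": "ACGTACGTAC"}
        phased = [
            hp.PhasedSite(VariantSite("g1", p, "A", ("G",)), "N", "N", PhaseRule.NO_MATCH)
            for p in range(1, 8)
        ]  # 7 of 10 positions N in g1
        mat, pat = hp.build_haplome_sequences(phased, backbone, "x")
        assert "g1" not in mat.gene_sequences
        assert mat.gene_sequences["g2"] == backbone["g2"]

    def test_no_phased_sites_backbone_with_panel_ns(self):
        backbone = {"g1": "ACGTACGTAC"}
        phased = [
            hp.PhasedSite(VariantSite("g1", 3, "G", ("C",)), "N", "N", PhaseRule.MISSING)
        ]
        mat, _ = hp.build_haplome_sequences(phased, backbone, "x")
        assert mat.gene_sequences["g1"] == "ACNTACGTAC"

    def test_fully_phased_worker_matches_true_haplotypes(self, mono_maternal_sim):
        sim = mono_maternal_sim
        panel = phase_panel(sim)
        queens = sim.truth.ids_where(true_class="pure_maternal", caste="queen")
        w = sim.truth.ids_where(true_class="F1", caste="worker")[0]
        phased = hp.phase_individual(panel, w, queens[0])
        mat, pat = hp.build_haplome_sequences(phased, sim.reference_backbone, w)
        hap_m, hap_p = sim.truth.haplotypes[w]
        for gene, seq in pat.gene_sequences.items():
            true_p = sim.truth.haplotype_sequence(w, "paternal", gene)
            true_m = sim.truth.haplotype_sequence(w, "maternal", gene)
            for k, (got_p, got_m) in enumerate(zip(seq, mat.gene_sequences[gene])):
                if got_p != "N":
                    assert got_p == true_p[k]
                if got_m != "N":
                    assert got_m == true_m[k]

    def test_site_outside_backbone_counted_and_skipped(self):
        backbone = {"g1": "ACGT"}
        phased = [
            hp.PhasedSite(VariantSite("g9", 1, "A", ("G",)), "A", "G", PhaseRule.HET_MATCH)
        ]
        with pytest.warns(UserWarning, match="outside"):
            hp.build_haplome_sequences(phased, backbone, "x")


class TestConsensus:
    def test_diploid_single_het_site_one_n(self):
        backbone = {"chr1": "A" * 10}
        rows = [[(0, 1)]] + [[(0, 0)]] * 2
        sites = [VariantSite("chr1", p, "A", ("C",)) for p in (2, 5, 9)]
        cohort = make_cohort(rows, sites=sites)
        seq = hp.consensus_sequence(cohort, "ind0", backbone)["chr1"]
        assert seq.count("N") == 1 and seq[1] == "N"

    def test_low_depth_becomes_gap(self):
        backbone = {"chr1": "A" * 4}
        cohort = make_cohort([[(0, 0)]], depth=2, sites=[VariantSite("chr1", 2, "A", ("C",))])
        seq = hp.consensus_sequence(cohort, "ind0", backbone, max_gap_fraction=0.5)
        assert seq["chr1"][1] == "-"

    def test_haploid_male_consensus_equals_true_haplotype(self, small_sim):
        panel = phase_panel(small_sim)
        male = small_sim.truth.ids_where(true_class="pure_paternal", caste="male")[0]
        cons = hp.consensus_sequence(panel, male, small_sim.reference_backbone)
        hap, _ = small_sim.truth.haplotypes[male]
        for gene, seq in cons.items():
            true_seq = "".join("ACGT"[c] for c in hap[gene])
            mismatches = sum(
                1 for a, b in zip(seq, true_seq) if a not in "N-" and a != b
            )
            assert mismatches == 0
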