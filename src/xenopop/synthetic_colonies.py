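"""Synthetic colony cohorts with planted truth.

The generator emulates the statistical structure the downstream analyses
assume: two ant species that diverged long enough ago to carry fixed
nucleotide differences at an appreciable density, within-lineage
polymorphism calibrated to target synonymous diversities, a near-monomorphic
clonal paternal lineage nested inside the paternal species and carrying the
host species' mitochondria, F1 hybrid workers, haploid males, eggs
(biparental or androgenetic) and spermatheca sperm mixtures.

Sites are modeled directly (fixed differences plus frequency-tagged
polymorphic sites) rather than through a coalescent: the analyses consume
only site patterns, and direct placement keeps every expectation
closed-form.  Sequences are codon-structured under the standard genetic code
so synonymous and nonsynonymous diversity targets are enforceable per class.

Lineage labels: ``ibericus`` (maternal/host species), ``structor_wild``
(wild-type paternal species) and ``structor_clonal`` (the clonal male
lineage).  Species labels are ``ibericus`` and ``structor``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator

import numpy as np
import yaml

from . import codons
from .variant_store import (
    CohortMatrix,
    GeneSequenceSet,
    IndividualMeta,
    VariantSite,
    write_cohort,
    write_gene_sequences,
)

__all__ = [
    "CompositionRow",
    "SimScenario",
    "SpeciesPools",
    "TruthRecord",
    "TruthTable",
    "SimulatedCohort",
    "default_scenario",
    "load_scenario",
    "save_scenario",
    "build_species_pools",
    "simulate_individuals",
    "simulate_scenario",
    "write_scenario",
    "expected_pairwise_distance",
]

LINEAGES = ("ibericus", "structor_wild", "structor_clonal")
MATERNAL_SPECIES = "ibericus"
PATERNAL_SPECIES = "structor"

#: number of chromosomes in the notional frequency spectrum used when
#: tagging polymorphic sites with a derived-allele frequency
_SFS_N = 20


def _sfs_frequencies(rng: np.random.Generator, size: int, n: int = _SFS_N) -> np.ndarray:
    """Derived-allele frequencies i/n drawn with the neutral weight 1/i."""
    i = np.arange(1, n)
    w = 1.0 / i
    return rng.choice(i, size=size, p=w / w.sum()) / n


def _carriers_matching_pi(f: float, n: int) -> int:
    """Derived-carrier count whose sample pairwise diversity 2c(n-c)/(n(n-1))
    best matches the population per-site diversity 2f(1-f)."""
    target = 2 * f * (1 - f)

    def pi_of(c: int) -> float:
        return 2 * c * (n - c) / (n * (n - 1))

    disc = n * n - 4 * f * (1 - f) * n * (n - 1)
    c_real = (n - np.sqrt(max(disc, 0.0))) / 2
    cands = {int(np.floor(c_real)), int(np.ceil(c_real))}
    cands = {min(max(c, 0), n) for c in cands}
    return min(cands, key=lambda c: abs(pi_of(c) - target))


def _expected_site_pi(n: int = _SFS_N) -> float:
    """E[2f(1-f)] per polymorphic site under the 1/i frequency spectrum."""
    i = np.arange(1, n)
    w = (1.0 / i) / (1.0 / i).sum()
    f = i / n
    return float((w * 2 * f * (1 - f)).sum())


@dataclass
class CompositionRow:
    """One block of simulated individuals.

    ``father_lineage`` is "clonal", "wild" or "none".  Workers/eggs with a
    father lineage are F1 hybrids (maternal species x that paternal pool);
    males with a father lineage are clones of a sperm haplotype from that
    pool and carry the host species' mitochondria; ``androgenetic`` eggs are
    haploid paternal clones.  Spermatheca rows pool one host-species and one
    paternal sperm genome.
    """

    caste: str
    nominal_species: str
    father_lineage: str = "none"
    count: int = 0
    androgenetic: bool = False

    def __post_init__(self) -> None:
        if self.father_lineage not in ("clonal", "wild", "none"):
            raise ValueError(f"unknown father_lineage {self.father_lineage!r}")
        if self.count < 0:
            raise ValueError("count must be >= 0")


def _default_composition() -> list[CompositionRow]:
    # mirrors the sampled cohort: 164 F1 workers (144 clonal-sired, 20
    # wild-sired), 24 clonal males, 53 wild-type paternal-species males,
    # 127 non-hybrid controls (50 host queens + 24 host males + the 53 wild
    # males), a few eggs and one spermatheca
    return [
        CompositionRow("queen", "ibericus", "none", 50),
        CompositionRow("male", "ibericus", "none", 24),
        CompositionRow("male", "structor", "none", 53),
        CompositionRow("worker", "ibericus", "clonal", 144),
        CompositionRow("worker", "ibericus", "wild", 20),
        CompositionRow("male", "structor", "clonal", 24),
        CompositionRow("egg", "ibericus", "clonal", 6),
        CompositionRow("egg", "ibericus", "clonal", 2, androgenetic=True),
        CompositionRow("spermatheca", "ibericus", "clonal", 1),
    ]


@dataclass
class SimScenario:
    """Generative parameters; a fixed seed makes every output reproducible."""

    n_genes: int = 200
    gene_length_codons: int = 150
    #: per-site probability of an interspecific fixed difference (~5 Myr of
    #: divergence at a density sufficient to saturate hybrid heterozygosity)
    fixed_diff_density: float = 0.01
    #: per-site private divergence of the clonal lineage from the wild-type
    #: paternal pool (the clonal clade must be placeable, but stays within
    #: the species: an order of magnitude below the interspecific density)
    clonal_divergence: float = 0.001
    pi_s_targets: dict[str, float] = field(
        default_factory=lambda: {
            "ibericus": 0.00045,
            "structor_wild": 0.0014,
            "structor_clonal": 0.00027,
        }
    )
    pi_n_over_pi_s_targets: dict[str, float] = field(
        default_factory=lambda: {
            "ibericus": 0.21,
            "structor_wild": 0.21,
            "structor_clonal": 0.43,
        }
    )
    composition: list[CompositionRow] = field(default_factory=_default_composition)
    mito_length: int = 2000
    mito_divergence: float = 0.02
    #: per-site within-species mitochondrial variation
    mito_pi: float = 5e-4
    depth_mean: float = 30.0
    quality_model: dict[str, float] = field(
        default_factory=lambda: {"mean": 60.0, "sd": 15.0}
    )
    #: per-allele-copy symmetric flip probability (0 = error-free)
    genotyping_error: float = 0.0
    seed: int = 20240501

    def __post_init__(self) -> None:
        for p in (self.fixed_diff_density, self.clonal_divergence, self.mito_divergence,
                  self.mito_pi, self.genotyping_error):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        if self.n_genes < 1 or self.gene_length_codons < 1:
            raise ValueError("n_genes and gene_length_codons must be >= 1")

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"gene{str(i + 1).zfill(width)}" for i in range(self.n_genes)]

    @property
    def gene_length(self) -> int:
        return 3 * self.gene_length_codons


def default_scenario(**overrides) -> SimScenario:
    return SimScenario(**overrides)


def save_scenario(scenario: SimScenario, path: str | Path) -> None:
    d = asdict(scenario)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def load_scenario(path: str | Path) -> SimScenario:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    rows = [CompositionRow(**r) for r in d.pop("composition", [])]
    sc = SimScenario(**d)
    if rows:
        sc.composition = rows
    return sc


def expected_pairwise_distance(
    pi_s: float, pi_n_over_pi_s: float, syn_site_fraction: float = 0.24
) -> float:
    """Expected all-sites pairwise distance implied by (pi_s, pi_n/pi_s).

    ``syn_site_fraction`` is the NG synonymous share of sites in typical
    coding sequence (~24% under the standard code).
    """
    return pi_s * syn_site_fraction + pi_s * pi_n_over_pi_s * (1 - syn_site_fraction)


# ---------------------------------------------------------------------------
# Species pools
# ---------------------------------------------------------------------------


@dataclass
class _PolySites:
    """Within-lineage polymorphic sites of one gene: parallel arrays."""

    positions: np.ndarray  # 0-based within gene
    derived: np.ndarray  # nucleotide codes 0..3
    freq: np.ndarray


@dataclass
class SpeciesPools:
    """Lineage base haplotypes plus frequency-tagged polymorphism.

    A haplotype draw copies the lineage base and switches each polymorphic
    site to its derived allele with the site's frequency, so expected
    pairwise diversity per site is ``sum 2f(1-f)``, calibrated to the
    scenario's targets.
    """

    scenario: SimScenario
    bases: dict[str, dict[str, np.ndarray]]  # lineage -> gene -> codes
    poly: dict[str, dict[str, _PolySites]]  # lineage -> gene -> sites
    mito: dict[str, np.ndarray]  # species -> codes

    def draw_haplotype(self, lineage: str, rng: np.random.Generator) -> dict[str, np.ndarray]:
        out = {}
        for gene, base in self.bases[lineage].items():
            hap = base.copy()
            ps = self.poly[lineage][gene]
            if ps.positions.size:
                hit = rng.random(ps.positions.size) < ps.freq
                hap[ps.positions[hit]] = ps.derived[hit]
            out[gene] = hap
        return out

    def draw_mito(self, species: str, rng: np.random.Generator) -> np.ndarray:
        m = self.mito[species].copy()
        k = rng.poisson(self.scenario.mito_pi * m.size)
        if k:
            pos = rng.choice(m.size, size=min(k, m.size), replace=False)
            m[pos] = (m[pos] + rng.integers(1, 4, size=pos.size)) % 4
        return m

    def draw_pool(
        self,
        lineage: str,
        n: int,
        rng: np.random.Generator,
        prefix: str | None = None,
        exact_frequencies: bool = False,
    ) -> list[GeneSequenceSet]:
        """n haplotypes as per-gene alignments (for diversity estimation).

        With ``exact_frequencies`` each polymorphic site gets exactly
        round(f*n) derived carriers, so the sample's allele frequencies equal
        the population's and realized diversity tracks the calibration
        targets instead of fluctuating with binomial sampling.
        """
        prefix = prefix or lineage
        if exact_frequencies:
            haps = [{g: b.copy() for g, b in self.bases[lineage].items()} for _ in range(n)]
            for gene in self.scenario.gene_ids:
                ps = self.poly[lineage][gene]
                for pos, alt, f in zip(ps.positions, ps.derived, ps.freq):
                    c = _carriers_matching_pi(float(f), n)
                    for k in rng.choice(n, size=c, replace=False):
                        haps[k][gene][pos] = alt
        else:
            haps = [self.draw_haplotype(lineage, rng) for _ in range(n)]
        genes = []
        for gene in self.scenario.gene_ids:
            seqs = {f"{prefix}_{i:03d}": codons.decode_seq(h[gene]) for i, h in enumerate(haps)}
            genes.append(GeneSequenceSet.from_sequences(gene, seqs))
        return genes

    def fixed_difference_count(self) -> int:
        """Realized interspecific fixed differences between the base genomes."""
        return int(
            sum(
                (self.bases["ibericus"][g] != self.bases["structor_wild"][g]).sum()
                for g in self.scenario.gene_ids
            )
        )

    def reference_backbone(self) -> dict[str, str]:
        """Host-species reference gene sequences (the VCF REF backbone)."""
        return {g: codons.decode_seq(b) for g, b in self.bases["ibericus"].items()}


def _random_coding_sequence(rng: np.random.Generator, n_codons: int) -> np.ndarray:
    sense = np.array([codons.encode_seq(c) for c in codons.SENSE_CODONS], dtype=np.uint8)
    picks = rng.integers(0, len(sense), size=n_codons)
    return sense[picks].reshape(-1)


def _mutate_no_stop(seq: np.ndarray, pos: int, rng: np.random.Generator) -> bool:
    """Substitute a random different base at pos, rejecting stop-creating changes."""
    old = seq[pos]
    choices = [b for b in range(4) if b != old]
    rng.shuffle(choices)
    c0 = 3 * (pos // 3)
    for b in choices:
        seq[pos] = b
        codon = codons.decode_seq(seq[c0 : c0 + 3])
        if not codons.is_stop(codon):
            return True
    seq[pos] = old
    return False


def _candidate_changes(base: np.ndarray) -> tuple[list, list]:
    """(position, derived_code) pairs that are synonymous / nonsynonymous
    single-base changes of the base sequence (stop-creating changes excluded)."""
    syn, nonsyn = [], []
    seq = codons.decode_seq(base)
    for c0 in range(0, len(seq), 3):
        codon = seq[c0 : c0 + 3]
        aa = codons.AA_OF.get(codon)
        if aa is None:
            continue
        for off in range(3):
            for alt in codons.NUC:
                if alt == codon[off]:
                    continue
                mut = codon[:off] + alt + codon[off + 1 :]
                if codons.is_stop(mut):
                    continue
                pair = (c0 + off, codons.NUC_CODE[alt])
                (syn if codons.AA_OF[mut] == aa else nonsyn).append(pair)
    return syn, nonsyn


def build_species_pools(scenario: SimScenario, rng: np.random.Generator | None = None) -> SpeciesPools:
    """Draw ancestral genes, place fixed differences and calibrated polymorphism.

    Within-lineage synonymous (nonsynonymous) variants are placed only at
    positions where the change is synonymous (nonsynonymous) with respect to
    the lineage base, at stochastically rounded expected counts chosen so the
    expected pairwise diversity per NG synonymous (nonsynonymous) site equals
    the scenario's pi_s (pi_n) target.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence(scenario.seed).spawn(1)[0])
    e_pi = _expected_site_pi()
    tables = codons.codon_tables()

    bases: dict[str, dict[str, np.ndarray]] = {lin: {} for lin in LINEAGES}
    poly: dict[str, dict[str, _PolySites]] = {lin: {} for lin in LINEAGES}

    gene_ids = scenario.gene_ids
    L = scenario.gene_length
    for gene in gene_ids:
        anc = _random_coding_sequence(rng, scenario.gene_length_codons)
        ib = anc  # host species base == reference backbone
        st = anc.copy()
        n_fix = rng.binomial(L, scenario.fixed_diff_density)
        for pos in rng.choice(L, size=n_fix, replace=False):
            _mutate_no_stop(st, int(pos), rng)
        cl = st.copy()
        n_div = rng.binomial(L, scenario.clonal_divergence)
        for pos in rng.choice(L, size=n_div, replace=False):
            _mutate_no_stop(cl, int(pos), rng)
        bases["ibericus"][gene] = ib
        bases["structor_wild"][gene] = st
        bases["structor_clonal"][gene] = cl

    # polymorphism: accept candidate changes genome-wide until the realized
    # sum of 2f(1-f) hits the per-class diversity budget (pi target x NG
    # sites), with a fractional final acceptance, so realized generative
    # diversity tracks the target instead of fluctuating with Poisson counts
    for lin in LINEAGES:
        ng_syn_total = ng_nonsyn_total = 0.0
        syn_cands: list[tuple[str, int, int]] = []
        nonsyn_cands: list[tuple[str, int, int]] = []
        for gene in gene_ids:
            base = bases[lin][gene]
            cod = codons.codon_codes(base)
            ng_syn_total += float(np.nansum(tables["syn_sites"][cod[cod >= 0]]))
            ng_nonsyn_total += float(np.nansum(tables["nonsyn_sites"][cod[cod >= 0]]))
            s_cand, n_cand = _candidate_changes(base)
            syn_cands.extend((gene, pos, alt) for pos, alt in s_cand)
            nonsyn_cands.extend((gene, pos, alt) for pos, alt in n_cand)
        pi_s = scenario.pi_s_targets[lin]
        pi_n = pi_s * scenario.pi_n_over_pi_s_targets[lin]
        used: dict[str, set[int]] = {g: set() for g in gene_ids}
        chosen: dict[str, list[tuple[int, int, float]]] = {g: [] for g in gene_ids}
        for budget, cands in ((pi_s * ng_syn_total, syn_cands), (pi_n * ng_nonsyn_total, nonsyn_cands)):
            if budget <= 0:
                continue
            if budget / e_pi < 1:
                warnings.warn(
                    f"{lin}: diversity target implies < 1 expected variant "
                    "genome-wide; realized diversity will be 0 or far above target"
                )
            acc = 0.0
            for k in rng.permutation(len(cands)):
                gene, pos, alt = cands[k]
                if pos in used[gene]:
                    continue
                f = float(_sfs_frequencies(rng, 1)[0])
                x = 2 * f * (1 - f)
                if acc + x >= budget:
                    if rng.random() < (budget - acc) / x:
                        used[gene].add(pos)
                        chosen[gene].append((pos, alt, f))
                    break
                acc += x
                used[gene].add(pos)
                chosen[gene].append((pos, alt, f))
        for gene in gene_ids:
            sites = sorted(chosen[gene])
            poly[lin][gene] = _PolySites(
                positions=np.array([p for p, _, _ in sites], dtype=np.int64),
                derived=np.array([a for _, a, _ in sites], dtype=np.uint8),
                freq=np.array([f for _, _, f in sites], dtype=float),
            )

    # mitochondria
    mito_ib = rng.integers(0, 4, size=scenario.mito_length).astype(np.uint8)
    mito_st = mito_ib.copy()
    n_m = rng.binomial(scenario.mito_length, scenario.mito_divergence)
    pos = rng.choice(scenario.mito_length, size=n_m, replace=False)
    mito_st[pos] = (mito_st[pos] + rng.integers(1, 4, size=n_m)) % 4

    return SpeciesPools(
        scenario=scenario,
        bases=bases,
        poly=poly,
        mito={"ibericus": mito_ib, "structor": mito_st},
    )


# ---------------------------------------------------------------------------
# Individuals
# ---------------------------------------------------------------------------


@dataclass
class TruthRecord:
    individual_id: str
    true_class: str  # pure_maternal | pure_paternal | F1 | sperm_mixture
    true_father_lineage: str  # clonal | wild | none
    true_mito_species: str
    caste: str
    nominal_species: str


@dataclass
class TruthTable:
    records: list[TruthRecord]
    #: individual -> (maternal, paternal) haplotypes, each gene -> codes;
    #: haploids carry the same haplotype twice
    haplotypes: dict[str, tuple[dict[str, np.ndarray], dict[str, np.ndarray]]]
    mito_sequences: dict[str, np.ndarray]

    def record(self, individual_id: str) -> TruthRecord:
        for r in self.records:
            if r.individual_id == individual_id:
                return r
        raise KeyError(individual_id)

    def ids_where(self, **conds) -> list[str]:
        out = []
        for r in self.records:
            if all(getattr(r, k) == v for k, v in conds.items()):
                out.append(r.individual_id)
        return out

    def haplotype_sequence(self, individual_id: str, role: str, gene: str) -> str:
        m, p = self.haplotypes[individual_id]
        return codons.decode_seq((m if role == "maternal" else p)[gene])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([asdict(r) for r in self.records])


@dataclass
class SimulatedCohort:
    scenario: SimScenario
    pools: SpeciesPools
    cohort: CohortMatrix
    truth: TruthTable
    reference_backbone: dict[str, str]

    @property
    def mito_sequences(self) -> dict[str, str]:
        return {k: codons.decode_seq(v) for k, v in self.truth.mito_sequences.items()}

    def truth_gene_sets(self, ids: list[str] | None = None) -> list[GeneSequenceSet]:
        """Per-gene alignments of true haplotypes (haploids once, diploids
        as <id>__m / <id>__p)."""
        ids = ids or [r.individual_id for r in self.truth.records]
        ploidy = {m.individual_id: m.ploidy for m in self.cohort.individuals}
        genes = []
        for gene in self.scenario.gene_ids:
            seqs = {}
            for iid in ids:
                m, p = self.truth.haplotypes[iid]
                if ploidy[iid] == 1:
                    seqs[iid] = codons.decode_seq(m[gene])
                else:
                    seqs[f"{iid}__m"] = codons.decode_seq(m[gene])
                    seqs[f"{iid}__p"] = codons.decode_seq(p[gene])
            genes.append(GeneSequenceSet.from_sequences(gene, seqs))
        return genes


def _iter_individuals(scenario: SimScenario) -> Iterator[tuple[CompositionRow, str]]:
    tags = {
        ("queen", "none"): "Q",
        ("worker", "clonal"): "WC",
        ("worker", "wild"): "WW",
        ("worker", "none"): "W",
        ("male", "none"): "M",
        ("male", "clonal"): "MC",
        ("male", "wild"): "MW",
        ("egg", "clonal"): "E",
        ("egg", "wild"): "E",
        ("egg", "none"): "E",
        ("spermatheca", "clonal"): "S",
        ("spermatheca", "wild"): "S",
        ("spermatheca", "none"): "S",
    }
    counters: dict[str, int] = {}
    for row in scenario.composition:
        tag = tags[(row.caste, row.father_lineage)]
        sp = "ib" if row.nominal_species == "ibericus" else "st"
        if row.caste == "egg" and row.androgenetic:
            tag = "EA"
        for _ in range(row.count):
            counters[tag + sp] = counters.get(tag + sp, 0) + 1
            yield row, f"{tag}_{sp}_{counters[tag + sp]:03d}"


def simulate_individuals(
    scenario: SimScenario, pools: SpeciesPools, rng: np.random.Generator | None = None
) -> SimulatedCohort:
    """Sample individuals per the composition and emit genotypes over the
    cohort's polymorphic sites.

    Genotypes derive directly from the true haplotypes; depth is
    Poisson(depth_mean) per call, genotype quality is a clipped rounded
    normal draw, and no genotyping error is injected unless
    ``genotyping_error`` > 0.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence(scenario.seed).spawn(2)[1])
    father_pool = {"clonal": "structor_clonal", "wild": "structor_wild"}

    metas: list[IndividualMeta] = []
    records: list[TruthRecord] = []
    haplotypes: dict[str, tuple[dict, dict]] = {}
    mito_seqs: dict[str, np.ndarray] = {}

    for row, iid in _iter_individuals(scenario):
        own_lineage = "ibericus" if row.nominal_species == "ibericus" else "structor_wild"
        own_species = row.nominal_species
        if row.caste == "queen" or (row.caste == "male" and row.father_lineage == "none"):
            ploidy = 2 if row.caste == "queen" else 1
            hap_m = pools.draw_haplotype(own_lineage, rng)
            hap_p = pools.draw_haplotype(own_lineage, rng) if ploidy == 2 else hap_m
            true_class, father, mito_sp = "pure_maternal" if own_species == MATERNAL_SPECIES else "pure_paternal", "none", own_species
            mito = pools.draw_mito(mito_sp, rng)
        elif row.caste == "male":  # clone from stored allospecific sperm
            ploidy = 1
            hap_m = hap_p = pools.draw_haplotype(father_pool[row.father_lineage], rng)
            true_class, father, mito_sp = "pure_paternal", row.father_lineage, MATERNAL_SPECIES
            mito = pools.draw_mito(MATERNAL_SPECIES, rng)
        elif row.caste == "worker" and row.father_lineage != "none":
            ploidy = 2
            hap_m = pools.draw_haplotype("ibericus", rng)
            hap_p = pools.draw_haplotype(father_pool[row.father_lineage], rng)
            true_class, father, mito_sp = "F1", row.father_lineage, MATERNAL_SPECIES
            mito = pools.draw_mito(MATERNAL_SPECIES, rng)
        elif row.caste == "worker":
            ploidy = 2
            hap_m = pools.draw_haplotype(own_lineage, rng)
            hap_p = pools.draw_haplotype(own_lineage, rng)
            true_class, father, mito_sp = (
                "pure_maternal" if own_species == MATERNAL_SPECIES else "pure_paternal",
                "none",
                own_species,
            )
            mito = pools.draw_mito(mito_sp, rng)
        elif row.caste == "egg":
            if row.androgenetic:
                ploidy = 1
                hap_m = hap_p = pools.draw_haplotype(father_pool[row.father_lineage], rng)
                true_class, father = "pure_paternal", row.father_lineage
            else:
                ploidy = 2
                hap_m = pools.draw_haplotype("ibericus", rng)
                hap_p = pools.draw_haplotype(father_pool[row.father_lineage], rng)
                true_class, father = "F1", row.father_lineage
            mito_sp = MATERNAL_SPECIES
            mito = pools.draw_mito(MATERNAL_SPECIES, rng)
        elif row.caste == "spermatheca":
            if row.father_lineage == "none":
                raise ValueError("spermatheca rows need a father_lineage")
            ploidy = 2  # two pooled haploid sperm genomes
            hap_m = pools.draw_haplotype("ibericus", rng)
            hap_p = pools.draw_haplotype(father_pool[row.father_lineage], rng)
            true_class, father, mito_sp = "sperm_mixture", row.father_lineage, MATERNAL_SPECIES
            mito = pools.draw_mito(MATERNAL_SPECIES, rng)
        else:  # pragma: no cover
            raise ValueError(f"unhandled composition row {row}")

        if row.father_lineage != "none" and not pools.bases[father_pool[row.father_lineage]]:
            raise ValueError(f"composition requests {row.father_lineage} father but pool is empty")

        metas.append(
            IndividualMeta(
                individual_id=iid,
                colony_id="colony_ib" if row.nominal_species == "ibericus" or father != "none" else "colony_st",
                caste=row.caste,
                nominal_species=row.nominal_species,
                ploidy=ploidy,
            )
        )
        records.append(TruthRecord(iid, true_class, father, mito_sp, row.caste, row.nominal_species))
        haplotypes[iid] = (hap_m, hap_p)
        mito_seqs[iid] = mito

    if not metas:
        raise ValueError("no individuals: empty composition")

    cohort = _genotype_matrix(scenario, pools, metas, haplotypes, rng)
    truth = TruthTable(records=records, haplotypes=haplotypes, mito_sequences=mito_seqs)
    return SimulatedCohort(
        scenario=scenario,
        pools=pools,
        cohort=cohort,
        truth=truth,
        reference_backbone=pools.reference_backbone(),
    )


def _genotype_matrix(scenario, pools, metas, haplotypes, rng) -> CohortMatrix:
    """Find cohort-polymorphic positions against the host reference and emit calls."""
    n_ind = len(metas)
    ids = [m.individual_id for m in metas]
    sites: list[VariantSite] = []
    allele_rows: list[np.ndarray] = []
    for gene in scenario.gene_ids:
        ref = pools.bases["ibericus"][gene]
        stack = np.empty((2 * n_ind, ref.size), dtype=np.uint8)
        for j, iid in enumerate(ids):
            m, p = haplotypes[iid]
            stack[2 * j] = m[gene]
            stack[2 * j + 1] = p[gene]
        variable = np.flatnonzero((stack != ref[None, :]).any(axis=0))
        for pos in variable:
            col = stack[:, pos]
            ref_nt = codons.NUC[ref[pos]]
            alts = sorted({codons.NUC[c] for c in col if c != ref[pos]})
            site = VariantSite(contig=gene, position=int(pos) + 1, ref_allele=ref_nt, alt_alleles=tuple(alts))
            amap = {nt: k for k, nt in enumerate(site.alleles)}
            idx = np.array([amap[codons.NUC[c]] for c in col], dtype=np.int16)
            sites.append(site)
            allele_rows.append(idx.reshape(n_ind, 2))

    n_sites = len(sites)
    alleles = (
        np.array(allele_rows, dtype=np.int16).reshape(n_sites, n_ind, 2)
        if n_sites
        else np.empty((0, n_ind, 2), dtype=np.int16)
    )
    if scenario.genotyping_error > 0 and n_sites:
        flip = rng.random(alleles.shape) < scenario.genotyping_error
        n_alleles = np.array([len(s.alleles) for s in sites], dtype=np.int16)
        shift = rng.integers(1, np.maximum(n_alleles, 2)[:, None, None], size=alleles.shape)
        alleles = np.where(flip, (alleles + shift) % n_alleles[:, None, None], alleles).astype(np.int16)

    depth = rng.poisson(scenario.depth_mean, size=(n_sites, n_ind)).astype(np.int32)
    qm = scenario.quality_model
    quality = np.clip(
        np.round(rng.normal(qm["mean"], qm["sd"], size=(n_sites, n_ind))), 0, 99
    ).astype(float)
    return CohortMatrix(sites=sites, individuals=metas, alleles=alleles, depth=depth, quality=quality)


def simulate_scenario(scenario: SimScenario) -> SimulatedCohort:
    """Build pools and simulate individuals with streams derived from the seed."""
    ss = np.random.SeedSequence(scenario.seed).spawn(2)
    pools = build_species_pools(scenario, np.random.default_rng(ss[0]))
    return simulate_individuals(scenario, pools, np.random.default_rng(ss[1]))


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------


def write_scenario(
    sim: SimulatedCohort, out_dir: str | Path, include_truth_sequences: bool = False
) -> dict[str, Path]:
    """Write VCF + metadata + reference/mito FASTA + truth TSV, re-readable
    by the variant store."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out_dir / "cohort.vcf",
        "meta": out_dir / "meta.tsv",
        "reference": out_dir / "reference.fa",
        "mito": out_dir / "mito.fa",
        "truth": out_dir / "truth.tsv",
        "scenario": out_dir / "scenario.yaml",
    }
    write_cohort(sim.cohort, paths["vcf"], paths["meta"])
    with open(paths["reference"], "w") as fh:
        for gene, seq in sim.reference_backbone.items():
            fh.write(f">{gene}\n{seq}\n")
    with open(paths["mito"], "w") as fh:
        for iid, seq in sim.mito_sequences.items():
            fh.write(f">{iid}\n{seq}\n")
    sim.truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    save_scenario(sim.scenario, paths["scenario"])
    if include_truth_sequences:
        gene_dir = out_dir / "truth_genes"
        write_gene_sequences(sim.truth_gene_sets(), gene_dir)
        paths["truth_genes"] = gene_dir
    return paths
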