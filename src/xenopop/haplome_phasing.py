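"""Reference-guided separation of maternal and paternal alleles in F1 hybrids.

The maternal species has very low nucleotide diversity, so a single
homozygous conspecific reference genome (the highest-coverage non-hybrid
queen) identifies the maternal allele at almost every heterozygous site of a
hybrid: at a site where the hybrid is heterozygous A/G and the reference is
homozygous A/A, A is assigned maternal and G paternal.  Sites where the
reference is heterozygous, where no allele matches, or where either genome
is covered by fewer than ``min_depth`` reads are masked with N.  Phased
alleles are substituted into the maternal species' reference backbone
gene-by-gene to reconstruct maternal and paternal haplome sequences; genes
that end up mostly masked are dropped.

The rule set is deterministic and site-independent; there is no statistical
or read-backed phasing by design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

from .variant_store import CohortMatrix, GenotypeCall, VariantSite

__all__ = [
    "PhaseRule",
    "PhasedSite",
    "Haplome",
    "phase_site",
    "phase_individual",
    "build_haplome_sequences",
    "consensus_sequence",
]


class PhaseRule(str, Enum):
    HET_MATCH = "HET_MATCH"  # hybrid het, one allele matches homozygous reference
    HOM_SHARED = "HOM_SHARED"  # hybrid and reference homozygous for the same allele
    MAT_REF_HET = "MAT_REF_HET"  # reference heterozygous -> masked
    NO_MATCH = "NO_MATCH"  # no allele shared between hybrid and reference
    LOW_DEPTH = "LOW_DEPTH"  # < min_depth reads in either genome
    MISSING = "MISSING"  # no genotype call in either genome


_MASKED = (PhaseRule.MAT_REF_HET, PhaseRule.NO_MATCH, PhaseRule.LOW_DEPTH, PhaseRule.MISSING)


@dataclass(frozen=True)
class PhasedSite:
    site: VariantSite
    maternal_allele: str  # nucleotide or N
    paternal_allele: str
    rule_applied: PhaseRule

    def __post_init__(self) -> None:
        if self.rule_applied in _MASKED and (self.maternal_allele != "N" or self.paternal_allele != "N"):
            raise ValueError(f"rule {self.rule_applied} requires masked alleles")


@dataclass
class Haplome:
    source_individual_id: str
    role: str  # "maternal" | "paternal"
    gene_sequences: dict[str, str]
    assigned_fraction: float

    def __post_init__(self) -> None:
        if self.role not in ("maternal", "paternal"):
            raise ValueError(f"role must be maternal/paternal, got {self.role!r}")
        if not 0.0 <= self.assigned_fraction <= 1.0:
            raise ValueError("assigned_fraction out of [0,1]")


def phase_site(
    site: VariantSite,
    hybrid_call: GenotypeCall,
    maternal_ref_call: GenotypeCall,
    min_depth: int = 3,
    strict: bool = False,
) -> PhasedSite:
    """Apply the rule table at one site.

    Precedence: low depth, then missing calls, then a heterozygous
    reference, then allele matching.  A shared homozygous genotype is
    assigned to both haplomes (both parents necessarily carry the allele)
    unless ``strict`` is set, which masks it and thereby reproduces the
    literal assign-only-at-heterozygous-sites behavior.
    """
    nts = site.alleles

    def masked(rule: PhaseRule) -> PhasedSite:
        return PhasedSite(site, "N", "N", rule)

    if hybrid_call.depth < min_depth or maternal_ref_call.depth < min_depth:
        return masked(PhaseRule.LOW_DEPTH)
    if hybrid_call.is_missing or maternal_ref_call.is_missing:
        return masked(PhaseRule.MISSING)
    if maternal_ref_call.is_het:
        return masked(PhaseRule.MAT_REF_HET)

    ref_allele = maternal_ref_call.alleles[0]
    h0, h1 = hybrid_call.alleles
    if hybrid_call.is_het:
        if h0 == ref_allele:
            return PhasedSite(site, nts[h0], nts[h1], PhaseRule.HET_MATCH)
        if h1 == ref_allele:
            return PhasedSite(site, nts[h1], nts[h0], PhaseRule.HET_MATCH)
        return masked(PhaseRule.NO_MATCH)
    if h0 == ref_allele:
        if strict:
            return PhasedSite(site, "N", "N", PhaseRule.HOM_SHARED)
        return PhasedSite(site, nts[h0], nts[h0], PhaseRule.HOM_SHARED)
    return masked(PhaseRule.NO_MATCH)


def phase_individual(
    cohort: CohortMatrix,
    hybrid_id: str,
    maternal_ref_id: str,
    min_depth: int = 3,
    strict: bool = False,
    f1_ids: set[str] | None = None,
) -> list[PhasedSite]:
    """Phase every panel site of one hybrid against the maternal reference.

    ``f1_ids`` (when supplied, e.g. from the hybrid screen) guards against
    using a hybrid as the maternal reference.
    """
    if f1_ids is not None and maternal_ref_id in f1_ids:
        raise ValueError(
            f"maternal reference {maternal_ref_id!r} is flagged as an F1 hybrid"
        )
    jh = cohort.column(hybrid_id)
    jr = cohort.column(maternal_ref_id)
    out = []
    alleles, depth = cohort.alleles, cohort.depth
    for i, site in enumerate(cohort.sites):
        hyb = GenotypeCall(
            (int(alleles[i, jh, 0]), int(alleles[i, jh, 1])),
            int(depth[i, jh]),
            float(cohort.quality[i, jh]),
        )
        ref = GenotypeCall(
            (int(alleles[i, jr, 0]), int(alleles[i, jr, 1])),
            int(depth[i, jr]),
            float(cohort.quality[i, jr]),
        )
        out.append(phase_site(site, hyb, ref, min_depth=min_depth, strict=strict))
    return out


def rule_counts(phased: list[PhasedSite]) -> dict[str, int]:
    counts = {r.value: 0 for r in PhaseRule}
    for p in phased:
        counts[p.rule_applied.value] += 1
    return counts


def build_haplome_sequences(
    phased: list[PhasedSite],
    reference_backbone: dict[str, str],
    source_individual_id: str,
    max_gap_fraction: float = 0.5,
) -> tuple[Haplome, Haplome]:
    """Substitute phased alleles into the reference backbone per gene.

    Panel sites map into genes by contig name and 1-based position.  Sites
    masked by the rule table become N; positions outside the panel carry the
    backbone.  Genes whose sequence exceeds ``max_gap_fraction`` N/gaps are
    dropped from both haplomes.  Sites falling outside every backbone gene
    are counted and skipped with a warning.
    """
    seqs_m = {g: list(s) for g, s in reference_backbone.items()}
    seqs_p = {g: list(s) for g, s in reference_backbone.items()}
    assigned = 0
    outside = 0
    for p in phased:
        gene = p.site.contig
        pos = p.site.position - 1
        if gene not in seqs_m or not 0 <= pos < len(seqs_m[gene]):
            outside += 1
            continue
        seqs_m[gene][pos] = p.maternal_allele
        seqs_p[gene][pos] = p.paternal_allele
        if p.maternal_allele != "N":
            assigned += 1
    if outside:
        warnings.warn(f"{outside} phased sites fall outside the reference backbone; skipped")

    def finish(seqs: dict[str, list[str]]) -> dict[str, str]:
        out = {}
        for gene, chars in seqs.items():
            s = "".join(chars)
            bad = (s.count("N") + s.count("-")) / len(s) if s else 1.0
            if bad <= max_gap_fraction:
                out[gene] = s
        return out

    frac = assigned / len(phased) if phased else 0.0
    return (
        Haplome(source_individual_id, "maternal", finish(seqs_m), frac),
        Haplome(source_individual_id, "paternal", finish(seqs_p), frac),
    )


def consensus_sequence(
    cohort: CohortMatrix,
    individual_id: str,
    reference_backbone: dict[str, str],
    min_depth: int = 3,
    max_gap_fraction: float = 0.5,
    f1_ids: set[str] | None = None,
) -> dict[str, str]:
    """Per-gene consensus of a NON-hybrid individual.

    Homozygous calls are written into the backbone; heterozygous positions
    become N (missing data); positions under ``min_depth`` become gaps;
    genes exceeding ``max_gap_fraction`` N/gaps are dropped.
    """
    if f1_ids is not None and individual_id in f1_ids:
        raise ValueError(f"{individual_id!r} is flagged as an F1 hybrid")
    j = cohort.column(individual_id)
    seqs = {g: list(s) for g, s in reference_backbone.items()}
    for i, site in enumerate(cohort.sites):
        gene = site.contig
        pos = site.position - 1
        if gene not in seqs or not 0 <= pos < len(seqs[gene]):
            continue
        a, b = cohort.alleles[i, j]
        if cohort.depth[i, j] < min_depth:
            seqs[gene][pos] = "-"
        elif a == -1:
            seqs[gene][pos] = "N"
        elif a != b:
            seqs[gene][pos] = "N"
        else:
            seqs[gene][pos] = site.alleles[a]
    out = {}
    for gene, chars in seqs.items():
        s = "".join(chars)
        bad = (s.count("N") + s.count("-")) / len(s) if s else 1.0
        if bad <= max_gap_fraction:
            out[gene] = s
    return out
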