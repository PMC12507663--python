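"""Genotype matrices, site panels, gene alignments and individual metadata.

The data model mirrors what a multi-sample VCF plus a sample sheet carry:
biallelic-or-multiallelic sites with per-call genotype, read depth (DP) and
genotype quality (GQ), and per-individual colony/caste/species/ploidy
metadata.  Coordinates are 1-based inclusive throughout, as in VCF.

Haploid individuals (ant males develop from unfertilized eggs) are stored as
homozygous diploid calls, the usual convention of joint callers; their ploidy
lives in the metadata.  Spermatheca records hold pooled haploid sperm and are
excluded from diploid-only statistics by callers that filter on caste.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantSite",
    "GenotypeCall",
    "IndividualMeta",
    "CohortMatrix",
    "GeneSequenceSet",
    "MISSING",
    "read_cohort",
    "write_cohort",
    "filter_sites",
    "read_gene_sequences",
    "write_gene_sequences",
]

#: allele index used for missing calls
MISSING = -1

CASTES = ("queen", "worker", "male", "egg", "spermatheca")


class CohortError(ValueError):
    """Malformed cohort input (VCF/metadata mismatch, bad record, ...)."""


@dataclass(frozen=True)
class VariantSite:
    contig: str
    position: int  # 1-based, VCF convention
    ref_allele: str
    alt_alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if not self.ref_allele or any(not a for a in self.alt_alleles):
            raise ValueError("alleles must be non-empty")

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref_allele, *self.alt_alleles)

    @property
    def is_indel(self) -> bool:
        return any(len(a) != 1 for a in self.alleles)


@dataclass(frozen=True)
class GenotypeCall:
    """One genotype with its depth and quality; alleles are site-allele indices."""

    alleles: tuple[int, int]
    depth: int
    quality: float

    def __post_init__(self) -> None:
        a, b = self.alleles
        if (a == MISSING) != (b == MISSING):
            raise ValueError("half-missing genotypes are not representable")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")

    @property
    def is_missing(self) -> bool:
        return self.alleles[0] == MISSING

    @property
    def is_het(self) -> bool:
        return not self.is_missing and self.alleles[0] != self.alleles[1]


@dataclass(frozen=True)
class IndividualMeta:
    individual_id: str
    colony_id: str
    caste: str
    nominal_species: str
    ploidy: int

    def __post_init__(self) -> None:
        if self.caste not in CASTES:
            raise ValueError(f"unknown caste {self.caste!r}")
        if self.ploidy not in (1, 2):
            raise ValueError(f"ploidy must be 1 or 2, got {self.ploidy}")
        if self.caste == "male" and self.ploidy != 1:
            raise ValueError(f"male {self.individual_id} must have ploidy 1")
        if self.caste in ("queen", "worker") and self.ploidy != 2:
            raise ValueError(f"{self.caste} {self.individual_id} must have ploidy 2")


@dataclass
class CohortMatrix:
    """Site x individual genotype table with per-call depth and quality.

    ``alleles`` has shape (n_sites, n_individuals, 2) holding allele indices
    into each site's allele list, with :data:`MISSING` for no-calls; ``depth``
    and ``quality`` have shape (n_sites, n_individuals).
    """

    sites: list[VariantSite]
    individuals: list[IndividualMeta]
    alleles: np.ndarray
    depth: np.ndarray
    quality: np.ndarray

    def __post_init__(self) -> None:
        n_sites, n_ind = len(self.sites), len(self.individuals)
        if self.alleles.shape != (n_sites, n_ind, 2):
            raise ValueError("alleles array shape does not match sites/individuals")
        if self.depth.shape != (n_sites, n_ind) or self.quality.shape != (n_sites, n_ind):
            raise ValueError("depth/quality shape does not match sites/individuals")
        keys = [(s.contig, s.position) for s in self.sites]
        if any(k2 <= k1 for k1, k2 in zip(keys, keys[1:])):
            raise ValueError("sites must be strictly increasing by (contig, position)")
        self._ind_index = {m.individual_id: i for i, m in enumerate(self.individuals)}
        if len(self._ind_index) != n_ind:
            raise ValueError("duplicate individual ids")

    # -- accessors -------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def individual_ids(self) -> list[str]:
        return [m.individual_id for m in self.individuals]

    def column(self, individual_id: str) -> int:
        try:
            return self._ind_index[individual_id]
        except KeyError:
            raise CohortError(f"individual {individual_id!r} not in cohort") from None

    def meta(self, individual_id: str) -> IndividualMeta:
        return self.individuals[self.column(individual_id)]

    def call(self, site_idx: int, individual_id: str) -> GenotypeCall:
        j = self.column(individual_id)
        a = self.alleles[site_idx, j]
        return GenotypeCall(
            alleles=(int(a[0]), int(a[1])),
            depth=int(self.depth[site_idx, j]),
            quality=float(self.quality[site_idx, j]),
        )

    def subset_sites(self, keep: np.ndarray) -> "CohortMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return CohortMatrix(
            sites=[self.sites[i] for i in idx],
            individuals=list(self.individuals),
            alleles=self.alleles[idx].copy(),
            depth=self.depth[idx].copy(),
            quality=self.quality[idx].copy(),
        )

    def equals(self, other: "CohortMatrix") -> bool:
        return (
            self.sites == other.sites
            and self.individuals == other.individuals
            and np.array_equal(self.alleles, other.alleles)
            and np.array_equal(self.depth, other.depth)
            and np.array_equal(self.quality, other.quality)
        )


@dataclass
class GeneSequenceSet:
    """Aligned nucleotide sequences for one gene over {A,C,G,T,N,-}."""

    gene_id: str
    sequences: dict[str, str]
    codon_frame: bool = field(default=False)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"gene {self.gene_id}: ragged alignment, lengths {sorted(lengths)}")
        self.length = lengths.pop() if lengths else 0

    @classmethod
    def from_sequences(cls, gene_id: str, sequences: Mapping[str, str]) -> "GeneSequenceSet":
        seqs = {k: v.upper() for k, v in sequences.items()}
        gss = cls(gene_id=gene_id, sequences=seqs)
        gss.codon_frame = gss.length % 3 == 0
        return gss


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

META_COLUMNS = ["individual_id", "colony_id", "caste", "nominal_species", "ploidy"]


def read_metadata(meta_path: str | Path) -> list[IndividualMeta]:
    df = pd.read_csv(meta_path, sep="\t", dtype=str)
    missing = set(META_COLUMNS) - set(df.columns)
    if missing:
        raise CohortError(f"metadata missing columns: {sorted(missing)}")
    return [
        IndividualMeta(
            individual_id=r.individual_id,
            colony_id=r.colony_id,
            caste=r.caste,
            nominal_species=r.nominal_species,
            ploidy=int(r.ploidy),
        )
        for r in df.itertuples()
    ]


def write_metadata(individuals: Iterable[IndividualMeta], meta_path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (m.individual_id, m.colony_id, m.caste, m.nominal_species, m.ploidy)
            for m in individuals
        ],
        columns=META_COLUMNS,
    )
    df.to_csv(meta_path, sep="\t", index=False)


def read_cohort(vcf_path: str | Path, meta_path: str | Path) -> CohortMatrix:
    """Load a multi-sample VCF (GT/DP/GQ) plus its sample sheet.

    Every VCF sample must appear in the metadata; metadata-only individuals
    are dropped with a warning.  Missing genotypes are preserved as missing.
    """
    from cyvcf2 import VCF

    meta = {m.individual_id: m for m in read_metadata(meta_path)}
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    absent = [s for s in samples if s not in meta]
    if absent:
        raise CohortError(f"VCF samples absent from metadata: {absent}")
    extra = set(meta) - set(samples)
    if extra:
        warnings.warn(f"{len(extra)} metadata individuals not in VCF; dropped")

    sites: list[VariantSite] = []
    allele_rows, depth_rows, qual_rows = [], [], []
    for lineno, var in enumerate(vcf, start=1):
        try:
            site = VariantSite(
                contig=var.CHROM,
                position=var.POS,
                ref_allele=var.REF,
                alt_alleles=tuple(var.ALT),
            )
        except ValueError as exc:
            raise CohortError(f"malformed VCF record {lineno}: {exc}") from exc
        gts = np.array([g[:2] for g in var.genotypes], dtype=np.int16)
        gts[gts < 0] = MISSING
        # half-missing calls collapse to fully missing
        half = (gts == MISSING).any(axis=1)
        gts[half] = MISSING
        dp = var.format("DP")
        dp = np.zeros(len(samples), dtype=np.int32) if dp is None else np.maximum(
            dp.reshape(-1).astype(np.int32), 0
        )
        gq = var.format("GQ")
        gq = np.zeros(len(samples)) if gq is None else gq.reshape(-1).astype(float)
        gq = np.maximum(np.nan_to_num(gq, nan=0.0), 0.0)
        sites.append(site)
        allele_rows.append(gts)
        depth_rows.append(dp)
        qual_rows.append(gq)
    vcf.close()

    return CohortMatrix(
        sites=sites,
        individuals=[meta[s] for s in samples],
        alleles=np.array(allele_rows, dtype=np.int16).reshape(len(sites), len(samples), 2),
        depth=np.array(depth_rows, dtype=np.int32).reshape(len(sites), len(samples)),
        quality=np.array(qual_rows, dtype=float).reshape(len(sites), len(samples)),
    )


def write_cohort(cohort: CohortMatrix, vcf_path: str | Path, meta_path: str | Path | None = None) -> None:
    """Emit the cohort as uncompressed VCF v4.2 (GT:DP:GQ) and optional sample sheet."""
    contigs = []
    for s in cohort.sites:
        if s.contig not in contigs:
            contigs.append(s.contig)
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=xenopop\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.individual_ids)
            + "\n"
        )
        for i, site in enumerate(cohort.sites):
            cells = []
            for j in range(cohort.n_individuals):
                a, b = cohort.alleles[i, j]
                gt = "./." if a == MISSING else f"{a}/{b}"
                cells.append(f"{gt}:{cohort.depth[i, j]}:{int(round(cohort.quality[i, j]))}")
            fh.write(
                f"{site.contig}\t{site.position}\t.\t{site.ref_allele}\t"
                f"{','.join(site.alt_alleles) or '.'}\t.\tPASS\t.\tGT:DP:GQ\t"
                + "\t".join(cells)
                + "\n"
            )
    if meta_path is not None:
        write_metadata(cohort.individuals, meta_path)


# ---------------------------------------------------------------------------
# Site filtering
# ---------------------------------------------------------------------------


def filter_sites(
    cohort: CohortMatrix,
    min_quality: float = 10.0,
    drop_indels: bool = True,
    min_maf: float = 0.05,
    min_called: float = 0.8,
) -> CohortMatrix:
    """Quality-mask calls and build the polymorphic site panel.

    Calls with genotype quality <= ``min_quality`` are set missing (the
    threshold is strict: a call at exactly the threshold is masked).  Sites
    are then dropped when they are indels, when the minor allele frequency
    among called allele copies falls below ``min_maf``, or when fewer than
    ``min_called`` of individuals have a call.  MAF of a multi-allelic site
    uses its second-most-frequent allele.
    """
    if cohort.n_sites == 0:
        raise CohortError("empty cohort")
    alleles = cohort.alleles.copy()
    masked = cohort.quality <= min_quality
    alleles[masked] = MISSING

    n_ind = cohort.n_individuals
    keep = np.ones(cohort.n_sites, dtype=bool)
    for i, site in enumerate(cohort.sites):
        if drop_indels and site.is_indel:
            keep[i] = False
            continue
        row = alleles[i]
        called = row[:, 0] != MISSING
        if called.sum() / n_ind < min_called:
            keep[i] = False
            continue
        if min_maf > 0:
            copies = row[called].reshape(-1)
            counts = np.bincount(copies, minlength=len(site.alleles))
            counts = np.sort(counts)[::-1]
            second = counts[1] if len(counts) > 1 else 0
            total = copies.size
            if total == 0 or second / total < min_maf:
                keep[i] = False
    if not keep.any():
        raise CohortError(
            "all sites removed by filtering; review min_quality/min_maf/min_called"
        )
    out = CohortMatrix(
        sites=[cohort.sites[i] for i in np.flatnonzero(keep)],
        individuals=list(cohort.individuals),
        alleles=alleles[keep],
        depth=cohort.depth[keep].copy(),
        quality=cohort.quality[keep].copy(),
    )
    return out


# ---------------------------------------------------------------------------
# Gene sequence I/O
# ---------------------------------------------------------------------------


def read_gene_sequences(fasta_dir: str | Path) -> list[GeneSequenceSet]:
    """Read one aligned FASTA per gene from a directory (gene id = file stem)."""
    from Bio import SeqIO

    fasta_dir = Path(fasta_dir)
    paths = sorted(p for p in fasta_dir.iterdir() if p.suffix in (".fa", ".fasta", ".fna"))
    if not paths:
        raise CohortError(f"no FASTA files in {fasta_dir}")
    out = []
    for p in paths:
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(p), "fasta")}
        try:
            out.append(GeneSequenceSet.from_sequences(p.stem, seqs))
        except ValueError as exc:
            raise CohortError(f"gene {p.stem}: {exc}") from exc
    return out


def write_gene_sequences(
    genes: Sequence[GeneSequenceSet], fasta_dir: str | Path, width: int = 80
) -> None:
    fasta_dir = Path(fasta_dir)
    fasta_dir.mkdir(parents=True, exist_ok=True)
    for gene in genes:
        with open(fasta_dir / f"{gene.gene_id}.fa", "w") as fh:
            for name, seq in gene.sequences.items():
                fh.write(f">{name}\n")
                for k in range(0, len(seq), width):
                    fh.write(seq[k : k + width] + "\n")
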