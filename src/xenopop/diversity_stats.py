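"""Synonymous and nonsynonymous nucleotide diversity (pi_s, pi_n, pi_n/pi_s).

Site counting follows the Nei-Gojobori fractional scheme under the standard
genetic code: each codon position contributes the share of its single-base
changes that are synonymous, with changes to stop codons excluded from the
denominator.  Pairwise differences in codons differing at several positions
are averaged over the minimal mutational paths, excluding paths that
traverse a stop codon.  Estimates pool differences and sites over all
unordered sequence pairs and all genes (equal pair weight); confidence
intervals come from a percentile bootstrap over genes, the natural
resampling unit for genome-wide per-lineage panels.

The pi_n/pi_s ratio indexes the efficacy of purifying selection: a small,
recently bottlenecked or clonal lineage accumulates nonsynonymous variants
it cannot purge, inflating the ratio relative to a large wild population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import codons
from .variant_store import GeneSequenceSet

__all__ = [
    "CodonSiteCounts",
    "DiversityEstimate",
    "count_syn_nonsyn_sites",
    "pairwise_pi",
    "pi_with_ci",
]


@dataclass(frozen=True)
class CodonSiteCounts:
    syn_sites: float
    nonsyn_sites: float
    counted: bool = True


@dataclass
class DiversityEstimate:
    pi_s: float
    pi_n: float
    ratio: float  # NaN when pi_s == 0
    n_sequences: int
    n_genes: int
    pi_s_ci: tuple[float, float] = (float("nan"), float("nan"))
    pi_n_ci: tuple[float, float] = (float("nan"), float("nan"))
    ratio_ci: tuple[float, float] = (float("nan"), float("nan"))
    ci_available: bool = False


def count_syn_nonsyn_sites(codon: str) -> CodonSiteCounts:
    """NG site counts for one codon; codons with N are flagged uncounted and
    stop codons are excluded with a warning."""
    codon = codon.upper()
    if len(codon) != 3 or any(c not in codons.NUC for c in codon):
        return CodonSiteCounts(0.0, 0.0, counted=False)
    if codons.is_stop(codon):
        warnings.warn(f"stop codon {codon} excluded from site counting")
        return CodonSiteCounts(0.0, 0.0, counted=False)
    s, n = codons.syn_nonsyn_site_fractions(codon)
    return CodonSiteCounts(s, n)


def _per_gene_components(
    genes: Sequence[GeneSequenceSet],
    ids: Sequence[str] | None,
    max_seq_gap_fraction: float = 0.2,
) -> tuple[np.ndarray, int]:
    """Per-gene (syn_diffs, syn_sites, nonsyn_diffs, nonsyn_sites) summed
    over unordered pairs; sequences exceeding the per-gene N/gap fraction are
    dropped for that gene."""
    t = codons.codon_tables()
    comp = np.zeros((len(genes), 4))
    n_seq_used = 0
    for g_idx, gene in enumerate(genes):
        if not gene.codon_frame:
            raise ValueError(f"gene {gene.gene_id} is not codon-aligned")
        use = ids if ids is not None else list(gene.sequences)
        codes = {}
        for sid in use:
            seq = gene.sequences.get(sid)
            if seq is None:
                continue
            arr = codons.encode_seq(seq)
            if (arr > 3).mean() > max_seq_gap_fraction:
                continue  # too much missing data for this gene
            codes[sid] = codons.codon_codes(arr)
        sids = list(codes)
        n_seq_used = max(n_seq_used, len(sids))
        for i in range(len(sids)):
            ci = codes[sids[i]]
            for j in range(i + 1, len(sids)):
                cj = codes[sids[j]]
                ok = (ci >= 0) & (cj >= 0)
                ok &= ~np.isnan(t["syn_sites"][np.where(ok, ci, 0)]) & ~np.isnan(
                    t["syn_sites"][np.where(ok, cj, 0)]
                )
                if not ok.any():
                    continue
                a, b = ci[ok], cj[ok]
                comp[g_idx, 0] += np.nansum(t["syn_diffs"][a, b])
                comp[g_idx, 1] += 0.5 * (t["syn_sites"][a].sum() + t["syn_sites"][b].sum())
                comp[g_idx, 2] += np.nansum(t["nonsyn_diffs"][a, b])
                comp[g_idx, 3] += 0.5 * (
                    t["nonsyn_sites"][a].sum() + t["nonsyn_sites"][b].sum()
                )
    return comp, n_seq_used


def _point(comp: np.ndarray) -> tuple[float, float, float]:
    syn_d, syn_s = comp[:, 0].sum(), comp[:, 1].sum()
    non_d, non_s = comp[:, 2].sum(), comp[:, 3].sum()
    if syn_s == 0 and non_s == 0:
        raise ValueError("no comparable codons between the requested sequences")
    pi_s = syn_d / syn_s if syn_s else 0.0
    pi_n = non_d / non_s if non_s else 0.0
    ratio = pi_n / pi_s if pi_s > 0 else float("nan")
    return pi_s, pi_n, ratio


def pairwise_pi(
    genes: Sequence[GeneSequenceSet],
    ids: Sequence[str] | None = None,
    max_seq_gap_fraction: float = 0.2,
) -> DiversityEstimate:
    """Point estimates of pi_s, pi_n and their ratio over a sequence panel.

    ``ids`` restricts to a subset of sequence names (default: all names in
    each gene).  Identical panels yield pi_s = pi_n = 0 with an undefined
    (NaN) ratio, never infinity.
    """
    comp, n_seq = _per_gene_components(genes, ids, max_seq_gap_fraction)
    pi_s, pi_n, ratio = _point(comp)
    return DiversityEstimate(pi_s, pi_n, ratio, n_seq, len(genes))


def pi_with_ci(
    genes: Sequence[GeneSequenceSet],
    ids: Sequence[str] | None = None,
    n_bootstrap: int = 1000,
    seed: int | np.random.Generator | None = None,
    max_seq_gap_fraction: float = 0.2,
    ci_level: float = 0.95,
) -> DiversityEstimate:
    """Point estimates plus percentile-bootstrap CIs over genes."""
    comp, n_seq = _per_gene_components(genes, ids, max_seq_gap_fraction)
    pi_s, pi_n, ratio = _point(comp)
    est = DiversityEstimate(pi_s, pi_n, ratio, n_seq, len(genes))
    if len(genes) < 2:
        warnings.warn("single gene: bootstrap CI unavailable")
        return est
    rng = np.random.default_rng(seed)
    n_g = comp.shape[0]
    bs = np.empty((n_bootstrap, 3))
    for b in range(n_bootstrap):
        sel = rng.integers(0, n_g, size=n_g)
        c = comp[sel]
        syn_d, syn_s = c[:, 0].sum(), c[:, 1].sum()
        non_d, non_s = c[:, 2].sum(), c[:, 3].sum()
        ps = syn_d / syn_s if syn_s else 0.0
        pn = non_d / non_s if non_s else 0.0
        bs[b] = (ps, pn, pn / ps if ps > 0 else np.nan)
    lo, hi = 100 * (1 - ci_level) / 2, 100 * (1 + ci_level) / 2
    est.pi_s_ci = tuple(np.percentile(bs[:, 0], [lo, hi]))
    est.pi_n_ci = tuple(np.percentile(bs[:, 1], [lo, hi]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-NaN ratio replicates
        finite = bs[np.isfinite(bs[:, 2]), 2]
    est.ratio_ci = (
        tuple(np.percentile(finite, [lo, hi])) if finite.size else (float("nan"),) * 2
    )
    est.ci_available = True
    return est
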