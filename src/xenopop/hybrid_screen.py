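"""F1 hybrid detection from SNP heterozygosity and supervised two-source
ancestry estimation.

An F1 between two well-diverged species is heterozygous at every
interspecific fixed difference, so its heterozygous-site proportion on a
polymorphic panel sits far above conspecific diploids.  The screen computes
per-individual heterozygosity (heterozygous calls divided by the full panel
size), splits the cohort at the largest gap in sorted values, and flags the
upper cluster when the cluster means are separated by a configurable factor.

Ancestry of a putative hybrid is estimated against two known source pools by
maximizing, over the admixture fraction q, the product over carried allele
copies of q*p_M + (1-q)*p_P, where p_M and p_P are the allele's frequencies
in the maternal and paternal pools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .variant_store import MISSING, CohortMatrix

__all__ = [
    "HetProfile",
    "F1Call",
    "AncestryEstimate",
    "het_proportion",
    "het_profiles",
    "classify_f1",
    "allele_frequencies",
    "estimate_ancestry",
    "compare_groups",
]


@dataclass(frozen=True)
class HetProfile:
    individual_id: str
    het_sites: int
    panel_size: int
    het_proportion: float
    note: str = ""


@dataclass(frozen=True)
class F1Call:
    individual_id: str
    is_f1: bool
    cluster_means: tuple[float, float]  # (lower, upper)
    separation: float


@dataclass(frozen=True)
class AncestryEstimate:
    individual_id: str
    q_maternal: float
    log_likelihood: float


def het_proportion(
    cohort: CohortMatrix, individual_id: str, denominator: str = "panel"
) -> HetProfile:
    """Heterozygous calls over the panel for one individual.

    The default denominator is the full panel size regardless of how many
    sites the individual was called at; ``denominator="called"`` switches to
    the individual's called sites (sensitivity mode).
    """
    j = cohort.column(individual_id)
    col = cohort.alleles[:, j]
    called = col[:, 0] != MISSING
    het = int(((col[:, 0] != col[:, 1]) & called).sum())
    denom = cohort.n_sites if denominator == "panel" else max(int(called.sum()), 1)
    note = ""
    meta = cohort.individuals[j]
    if meta.ploidy == 1:
        if het:
            warnings.warn(
                f"{individual_id}: {het} heterozygous calls at ploidy 1 (artifacts?)"
            )
        note = "haploid: heterozygosity forced to 0"
        het = 0
    return HetProfile(individual_id, het, denom, het / denom if denom else 0.0, note)


def het_profiles(
    cohort: CohortMatrix, ids: list[str] | None = None, denominator: str = "panel"
) -> list[HetProfile]:
    ids = ids or cohort.individual_ids
    return [het_proportion(cohort, i, denominator) for i in ids]


def classify_f1(profiles: list[HetProfile], min_separation: float = 5.0) -> list[F1Call]:
    """Two-cluster split of heterozygosity values at the largest gap.

    The upper cluster is flagged F1 only when the ratio of cluster means
    exceeds ``min_separation``; otherwise nothing is flagged.  All-identical
    values yield no flags with a warning.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to classify")
    values = np.array([p.het_proportion for p in profiles])
    order = np.argsort(values, kind="stable")
    sv = values[order]
    gaps = np.diff(sv)
    if gaps.max() <= 0:
        warnings.warn("all heterozygosity values identical; no F1 flagged")
        return [F1Call(p.individual_id, False, (sv.mean(), sv.mean()), 1.0) for p in profiles]
    cut = int(np.argmax(gaps)) + 1  # first index of the upper cluster
    lower_mean = float(sv[:cut].mean())
    upper_mean = float(sv[cut:].mean())
    separation = np.inf if lower_mean == 0 else upper_mean / lower_mean
    threshold = sv[cut]
    flag_upper = separation > min_separation
    return [
        F1Call(
            p.individual_id,
            bool(flag_upper and p.het_proportion >= threshold),
            (lower_mean, upper_mean),
            float(separation),
        )
        for p in profiles
    ]


def allele_frequencies(cohort: CohortMatrix, ids: list[str]) -> np.ndarray:
    """Per-site allele frequencies among called allele copies of ``ids``.

    Returns shape (n_sites, max_alleles); rows with no called copies are
    uniform.  Haploids stored as homozygous diploid calls contribute both
    stored copies.
    """
    cols = [cohort.column(i) for i in ids]
    max_alleles = max(len(s.alleles) for s in cohort.sites)
    freqs = np.zeros((cohort.n_sites, max_alleles))
    sub = cohort.alleles[:, cols, :]  # (sites, ids, 2)
    for i in range(cohort.n_sites):
        copies = sub[i].reshape(-1)
        copies = copies[copies != MISSING]
        k = len(cohort.sites[i].alleles)
        if copies.size == 0:
            freqs[i, :k] = 1.0 / k
        else:
            freqs[i, :k] = np.bincount(copies, minlength=k)[:k] / copies.size
    return freqs


def estimate_ancestry(
    cohort: CohortMatrix,
    individual_id: str,
    source_freqs: tuple[np.ndarray, np.ndarray],
    freq_floor: float = 1e-3,
    tol: float = 1e-6,
) -> AncestryEstimate:
    """Maximum-likelihood admixture fraction from the maternal-species source.

    ``source_freqs`` are (maternal, paternal) per-site allele-frequency
    matrices as from :func:`allele_frequencies`.  Frequencies are clipped to
    [floor, 1-floor] so fixed differences cannot yield infinite
    log-likelihoods.
    """
    p_mat, p_pat = (np.clip(f, freq_floor, 1 - freq_floor) for f in source_freqs)
    j = cohort.column(individual_id)
    col = cohort.alleles[:, j]
    called = np.flatnonzero(col[:, 0] != MISSING)
    pm_list, pp_list = [], []
    for i in called:
        for a in col[i]:
            pm_list.append(p_mat[i, a])
            pp_list.append(p_pat[i, a])
    pm = np.array(pm_list)
    pp = np.array(pp_list)
    informative = pm != pp
    if not informative.any():
        raise ValueError("panel uninformative: source frequencies identical at all called sites")

    def neg_loglik(q: float) -> float:
        return -float(np.log(q * pm + (1 - q) * pp).sum())

    res = optimize.minimize_scalar(
        neg_loglik, bounds=(0.0, 1.0), method="bounded", options={"xatol": tol}
    )
    return AncestryEstimate(individual_id, float(res.x), -float(res.fun))


def compare_groups(values_a, values_b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value.

    Uses the exact null distribution for small tie-free samples (where the
    normal approximation is off by orders of magnitude in the tails), the
    asymptotic test otherwise.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (tie_free and a.size <= 25 and b.size <= 25) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
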