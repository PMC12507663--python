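"""Species/lineage placement of haplomes and mitochondrial haplotypes.

Placement works at desk scale with p-distances: a query is assigned to the
reference panel with the smallest mean pairwise distance, with support from
a site (alignment-column) bootstrap, replacing full likelihood tree
inference whose only consumed output here is clade membership and support.
Mito-nuclear mismatches -- the signature of cross-species cloned males --
are flagged when the nuclear genome and the mitochondrial haplotype place in
different species.  Clonal clusters of near-identical male genomes are
found by single-linkage clustering at a small distance threshold, and eggs
are typed against a fixed-difference diagnostic panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .codons import encode_seq
from .variant_store import MISSING, CohortMatrix

__all__ = [
    "DistanceMatrix",
    "PlacementResult",
    "MismatchFlag",
    "p_distance",
    "distance_matrix",
    "nj_tree",
    "concatenate_genes",
    "assign_by_nearest_panel",
    "assign_mito",
    "detect_mito_nuclear_mismatch",
    "detect_clonal_cluster",
    "diagnostic_sites",
    "classify_embryo",
]

UNASSIGNED = "unassigned"


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def _as_codes(seq: str | np.ndarray) -> np.ndarray:
    return seq if isinstance(seq, np.ndarray) else encode_seq(seq)


def p_distance(
    seq_a: str | np.ndarray, seq_b: str | np.ndarray, min_overlap: int = 100
) -> tuple[float, int]:
    """Proportion of differing positions among jointly called (non-N,
    non-gap) sites; NaN when the overlap is below ``min_overlap``."""
    a, b = _as_codes(seq_a), _as_codes(seq_b)
    if a.size != b.size:
        raise ValueError(f"sequence length mismatch: {a.size} vs {b.size}")
    valid = (a < 4) & (b < 4)
    overlap = int(valid.sum())
    if overlap < min_overlap:
        return float("nan"), overlap
    mism = int((valid & (a != b)).sum())
    return mism / overlap, overlap


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    pairwise_overlap: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(np.diag(self.values), 0, equal_nan=True):
            raise ValueError("diagonal must be zero")


def distance_matrix(seqs: Mapping[str, str | np.ndarray], min_overlap: int = 100) -> DistanceMatrix:
    labels = list(seqs)
    codes = [_as_codes(seqs[k]) for k in labels]
    n = len(labels)
    values = np.zeros((n, n))
    overlap = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        overlap[i, i] = int((codes[i] < 4).sum())
        for j in range(i + 1, n):
            d, o = p_distance(codes[i], codes[j], min_overlap)
            values[i, j] = values[j, i] = d
            overlap[i, j] = overlap[j, i] = o
    return DistanceMatrix(labels, values, overlap)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label=None, children=None):
        self.label = label
        self.children = children or []  # list of (child, branch_length)

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c.newick()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"


def nj_tree(dm: DistanceMatrix) -> str:
    """Unrooted neighbor-joining tree in newick form.

    Negative branch lengths are clamped to zero with the excess transferred
    to the sister branch at the same join, preserving the pair's summed
    length (the usual correction for slightly non-additive inputs).
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if np.isnan(dm.values).any():
        raise ValueError("distance matrix contains undefined entries")
    D = dm.values.astype(float).copy()
    nodes = [_Node(label=l) for l in dm.labels]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(Q), Q.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        a, b = active[i_], active[j_]
        d_ab = sub[i_, j_]
        bl_a = 0.5 * d_ab + (r[i_] - r[j_]) / (2 * (m - 2))
        bl_b = d_ab - bl_a
        if bl_a < 0:
            bl_b += -bl_a
            bl_a = 0.0
        if bl_b < 0:
            bl_a += -bl_b
            bl_b = 0.0
        new = _Node(children=[(nodes[a], bl_a), (nodes[b], bl_b)])
        # distances from the new node to the remaining taxa
        d_new = 0.5 * (D[a, :] + D[b, :] - d_ab)
        D = np.vstack([D, d_new[None, :]])
        D = np.hstack([D, np.append(d_new, 0.0)[:, None]])
        nodes.append(new)
        active = [k for k in active if k not in (a, b)] + [len(nodes) - 1]

    a, b, c = active
    # three-point formulas for the final star
    bl_a = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    bl_b = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    bl_c = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    bls = [max(x, 0.0) for x in (bl_a, bl_b, bl_c)]
    root = _Node(children=list(zip((nodes[a], nodes[b], nodes[c]), bls)))
    return root.newick() + ";"


# ---------------------------------------------------------------------------
# Nearest-panel assignment with site bootstrap
# ---------------------------------------------------------------------------


def concatenate_genes(
    gene_seqs: Mapping[str, str], gene_lengths: Mapping[str, int]
) -> str:
    """Concatenate per-gene sequences in sorted gene order, filling genes
    absent from ``gene_seqs`` (e.g. dropped for excess gaps) with N."""
    parts = []
    for gene in sorted(gene_lengths):
        parts.append(gene_seqs.get(gene, "N" * gene_lengths[gene]))
    return "".join(parts)


@dataclass(frozen=True)
class PlacementResult:
    query_id: str
    assigned_group: str  # panel label or "unassigned"
    margin: float  # best-vs-second-best mean-distance gap
    support: float  # bootstrap fraction agreeing with the point assignment
    mean_distances: dict[str, float] | None = None


def assign_by_nearest_panel(
    query: str | np.ndarray,
    panels: Mapping[str, Mapping[str, str | np.ndarray] | Sequence[str | np.ndarray]],
    query_id: str = "query",
    n_bootstrap: int = 200,
    min_margin: float = 0.0,
    min_overlap: int = 100,
    rng: np.random.Generator | int | None = None,
) -> PlacementResult:
    """Assign a query sequence to the panel with the smallest mean p-distance.

    Support is the fraction of site-resampled bootstrap replicates in which
    the same panel is nearest.  Distance ties (margin <= ``min_margin``)
    yield "unassigned"; so does a query whose overlap with every panel
    member is below ``min_overlap``.
    """
    if not panels or any(len(p) == 0 for p in panels.values()):
        raise ValueError("every panel must be non-empty")
    rng = np.random.default_rng(rng)
    q = _as_codes(query)

    labels: list[str] = []
    members: list[np.ndarray] = []
    for label, panel in panels.items():
        seqs = panel.values() if isinstance(panel, Mapping) else panel
        for s in seqs:
            arr = _as_codes(s)
            if arr.size != q.size:
                raise ValueError(f"panel {label}: member length {arr.size} != query {q.size}")
            labels.append(label)
            members.append(arr)
    M = np.stack(members)  # (m, L)
    valid = (M < 4) & (q[None, :] < 4)
    mism = valid & (M != q[None, :])

    def panel_means(mism_counts: np.ndarray, valid_counts: np.ndarray) -> dict[str, float]:
        with np.errstate(invalid="ignore", divide="ignore"):
            member_d = np.where(valid_counts >= min_overlap, mism_counts / valid_counts, np.nan)
        out = {}
        for label in panels:
            sel = [k for k, l in enumerate(labels) if l == label]
            vals = member_d[sel]
            out[label] = float(np.nanmean(vals)) if not np.all(np.isnan(vals)) else float("nan")
        return out

    means = panel_means(mism.sum(axis=1), valid.sum(axis=1))
    finite = {l: d for l, d in means.items() if np.isfinite(d)}
    if not finite:
        return PlacementResult(query_id, UNASSIGNED, float("nan"), 0.0, means)
    ranked = sorted(finite, key=finite.get)
    best = ranked[0]
    margin = (finite[ranked[1]] - finite[best]) if len(ranked) > 1 else float("inf")

    support = 0.0
    if n_bootstrap > 0:
        # collapse identical alignment columns so each replicate is a small
        # matrix-vector product over unique (mismatch, validity) patterns;
        # columns that are valid everywhere with no mismatch (the vast
        # majority) collapse to a single pattern without sorting
        pattern = (mism.astype(np.uint8) << 1) | valid.astype(np.uint8)
        interesting = mism.any(axis=0) | ~valid.all(axis=0)
        n_plain = int((~interesting).sum())
        uniq, counts = np.unique(pattern[:, interesting], axis=1, return_counts=True)
        if n_plain:
            uniq = np.hstack([uniq, np.ones((uniq.shape[0], 1), dtype=np.uint8)])
            counts = np.append(counts, n_plain)
        A_mism = (uniq >> 1).astype(np.float64)  # (m, U)
        A_valid = (uniq & 1).astype(np.float64)
        L = q.size
        probs = counts / L
        hits = 0
        for _ in range(n_bootstrap):
            c = rng.multinomial(L, probs).astype(np.float64)
            mm = panel_means(A_mism @ c, A_valid @ c)
            fin = {l: d for l, d in mm.items() if np.isfinite(d)}
            if fin and min(fin, key=fin.get) == best:
                hits += 1
        support = hits / n_bootstrap

    assigned = best if margin > min_margin else UNASSIGNED
    return PlacementResult(query_id, assigned, float(margin), support, means)


def assign_mito(
    query: str | np.ndarray,
    species_refs: Mapping[str, str | np.ndarray],
    query_id: str = "query",
    n_bootstrap: int = 200,
    min_margin: float = 0.0,
    min_overlap: int = 100,
    rng: np.random.Generator | int | None = None,
) -> PlacementResult:
    """Nearest-reference species assignment of a mitochondrial haplotype."""
    panels = {sp: [ref] for sp, ref in species_refs.items()}
    return assign_by_nearest_panel(
        query, panels, query_id=query_id, n_bootstrap=n_bootstrap,
        min_margin=min_margin, min_overlap=min_overlap, rng=rng,
    )


# ---------------------------------------------------------------------------
# Mito-nuclear mismatch
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MismatchFlag:
    individual_id: str
    nuclear_species: str
    mito_species: str
    is_mismatch: bool
    indeterminate: bool = False


def detect_mito_nuclear_mismatch(
    nuclear: PlacementResult,
    mito: PlacementResult,
    species_of: Mapping[str, str] | None = None,
) -> MismatchFlag:
    """Flag when the nuclear genome and the mitochondrial haplotype place in
    different species; either side unassigned yields an indeterminate,
    unflagged record.  ``species_of`` maps panel labels (e.g. lineages) to
    species labels."""
    species_of = species_of or {}
    nuc = species_of.get(nuclear.assigned_group, nuclear.assigned_group)
    mit = species_of.get(mito.assigned_group, mito.assigned_group)
    if UNASSIGNED in (nuc, mit):
        return MismatchFlag(nuclear.query_id, nuc, mit, False, indeterminate=True)
    return MismatchFlag(nuclear.query_id, nuc, mit, nuc != mit)


# ---------------------------------------------------------------------------
# Clonal clusters
# ---------------------------------------------------------------------------


@dataclass
class ClonalClusters:
    clusters: list[list[str]]
    mean_distances: list[float]
    clonal_like: int  # index into clusters, or -1


def detect_clonal_cluster(
    seqs: Mapping[str, str | np.ndarray],
    max_intra_distance: float,
    min_overlap: int = 100,
) -> ClonalClusters:
    """Single-linkage clusters at ``max_intra_distance`` on p-distances.

    The "clonal-like" cluster is the one with the lowest mean pairwise
    distance among clusters of at least two members (near-identical genomes
    are the clonality signal); -1 when no multi-member cluster exists.
    """
    ids = list(seqs)
    if len(ids) < 2:
        raise ValueError("need at least 2 sequences")
    dm = distance_matrix(seqs, min_overlap=min_overlap)
    vals = dm.values.copy()
    if np.isnan(vals).any():
        big = 2.0 * np.nanmax(vals[np.isfinite(vals)]) if np.isfinite(vals).any() else 1.0
        vals[np.isnan(vals)] = max(big, 1.0)
    Z = linkage(squareform(vals, checks=False), method="single")
    assignment = fcluster(Z, t=max_intra_distance, criterion="distance")
    clusters: list[list[str]] = []
    means: list[float] = []
    for c in sorted(set(assignment)):
        sel = np.flatnonzero(assignment == c)
        clusters.append([ids[k] for k in sel])
        if sel.size > 1:
            pair = vals[np.ix_(sel, sel)][np.triu_indices(sel.size, 1)]
            means.append(float(pair.mean()))
        else:
            means.append(0.0)
    multi = [k for k, cl in enumerate(clusters) if len(cl) > 1]
    clonal_like = min(multi, key=lambda k: means[k]) if multi else -1
    return ClonalClusters(clusters, means, clonal_like)


# ---------------------------------------------------------------------------
# Embryo genotype classification
# ---------------------------------------------------------------------------


def diagnostic_sites(
    cohort: CohortMatrix, maternal_ids: list[str], paternal_ids: list[str]
) -> list[tuple[int, int, int]]:
    """(site index, maternal allele, paternal allele) for sites fixed for
    different alleles between the two pure groups."""
    out = []
    jm = [cohort.column(i) for i in maternal_ids]
    jp = [cohort.column(i) for i in paternal_ids]
    for i in range(cohort.n_sites):
        am = cohort.alleles[i, jm].reshape(-1)
        ap = cohort.alleles[i, jp].reshape(-1)
        am = np.unique(am[am != MISSING])
        ap = np.unique(ap[ap != MISSING])
        if am.size == 1 and ap.size == 1 and am[0] != ap[0]:
            out.append((i, int(am[0]), int(ap[0])))
    return out


def classify_embryo(
    cohort: CohortMatrix,
    egg_id: str,
    diag: list[tuple[int, int, int]],
    min_called: int = 20,
    pure_threshold: float = 0.99,
    het_threshold: float = 0.90,
) -> str:
    """Type an egg/embryo on the fixed-difference diagnostic panel.

    "paternal_only" when >= ``pure_threshold`` of called diagnostic sites
    carry only paternal-species alleles (the androgenetic signature),
    "maternal_only" symmetric, "hybrid" when >= ``het_threshold`` are
    heterozygous maternal/paternal, else "indeterminate".
    """
    j = cohort.column(egg_id)
    n_called = n_mat = n_pat = n_het = 0
    for i, a_mat, a_pat in diag:
        a, b = (int(x) for x in cohort.alleles[i, j])
        if a == MISSING:
            continue
        n_called += 1
        carried = {a, b}
        if carried == {a_mat}:
            n_mat += 1
        elif carried == {a_pat}:
            n_pat += 1
        elif carried == {a_mat, a_pat}:
            n_het += 1
    if n_called < min_called:
        return "indeterminate"
    if n_pat / n_called >= pure_threshold:
        return "paternal_only"
    if n_mat / n_called >= pure_threshold:
        return "maternal_only"
    if n_het / n_called >= het_threshold:
        return "hybrid"
    return "indeterminate"
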