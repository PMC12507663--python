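"""Standard-genetic-code codon utilities shared by the simulator and the
diversity estimators.

Nucleotides are encoded 0..3 = A,C,G,T internally; a codon index is the
base-4 integer 16*n1 + 4*n2 + n3.  Codons containing anything outside
{A,C,G,T} get index -1 and are treated as uncountable.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

import numpy as np
from Bio.Data import CodonTable

NUC = "ACGT"
NUC_CODE = {c: i for i, c in enumerate(NUC)}

_table = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_table.stop_codons)
AA_OF = dict(_table.forward_table)  # sense codons only

SENSE_CODONS = tuple(sorted(AA_OF))


def codon_str(idx: int) -> str:
    return NUC[(idx >> 4) & 3] + NUC[(idx >> 2) & 3] + NUC[idx & 3]


def codon_index(codon: str) -> int:
    """Base-4 index of a codon, or -1 if it contains non-ACGT characters."""
    try:
        return (NUC_CODE[codon[0]] << 4) | (NUC_CODE[codon[1]] << 2) | NUC_CODE[codon[2]]
    except (KeyError, IndexError):
        return -1


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def encode_seq(seq: str) -> np.ndarray:
    """Nucleotide string -> uint8 codes; non-ACGT (N, gaps) -> 255."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for i, c in enumerate(NUC):
        out[arr == ord(c)] = i
    return out


def decode_seq(codes: np.ndarray) -> str:
    out = np.full(codes.shape, ord("N"), dtype=np.uint8)
    for i, c in enumerate(NUC):
        out[codes == i] = ord(c)
    return out.tobytes().decode("ascii")


def codon_codes(codes: np.ndarray) -> np.ndarray:
    """Per-codon indices (-1 where any base is non-ACGT); length must be %3==0."""
    tri = codes.reshape(-1, 3).astype(np.int32)
    bad = (tri > 3).any(axis=1)
    idx = (tri[:, 0] << 4) | (tri[:, 1] << 2) | tri[:, 2]
    idx[bad] = -1
    return idx


# ---------------------------------------------------------------------------
# Nei-Gojobori site counting and pairwise path classification
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def syn_nonsyn_site_fractions(codon: str) -> tuple[float, float]:
    """Fractional synonymous/nonsynonymous site counts of one sense codon.

    Per position, the synonymous fraction is the share of the (up to 3)
    single-base changes that preserve the amino acid, after excluding changes
    that create a stop codon; fractions per position sum to 1, so the two
    counts always total 3.
    """
    aa = AA_OF[codon]
    syn = 0.0
    for pos in range(3):
        n_syn = 0
        n_valid = 0
        for alt in NUC:
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            n_valid += 1
            if AA_OF[mut] == aa:
                n_syn += 1
        if n_valid:
            syn += n_syn / n_valid
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _path_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Average (syn, nonsyn) difference counts between two sense codons.

    Multi-difference codons are averaged over the minimal mutational paths
    (orderings of the differing positions); paths traversing a stop codon are
    excluded, falling back to all paths if every one hits a stop.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        cur = c1
        syn = nonsyn = 0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                return None
            if AA_OF[cur] == AA_OF[nxt]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        return syn, nonsyn

    results = [r for r in (walk(o) for o in permutations(diff_pos)) if r is not None]
    if not results:
        results = []
        for order in permutations(diff_pos):
            cur = c1
            syn = nonsyn = 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if cur in STOP_CODONS or nxt in STOP_CODONS or AA_OF.get(cur) != AA_OF.get(nxt):
                    nonsyn += 1
                else:
                    syn += 1
                cur = nxt
            results.append((syn, nonsyn))
    s = sum(r[0] for r in results) / len(results)
    n = sum(r[1] for r in results) / len(results)
    return s, n


@lru_cache(maxsize=1)
def codon_tables() -> dict[str, np.ndarray]:
    """Vectorized lookup tables over codon indices 0..63.

    ``syn_sites``/``nonsyn_sites``: NG site counts (NaN for stop codons);
    ``syn_diffs``/``nonsyn_diffs``: 64x64 path-averaged difference counts
    (NaN where either codon is a stop).
    """
    syn_sites = np.full(64, np.nan)
    nonsyn_sites = np.full(64, np.nan)
    for codon in SENSE_CODONS:
        s, n = syn_nonsyn_site_fractions(codon)
        syn_sites[codon_index(codon)] = s
        nonsyn_sites[codon_index(codon)] = n
    syn_d = np.full((64, 64), np.nan)
    nonsyn_d = np.full((64, 64), np.nan)
    for a in SENSE_CODONS:
        ia = codon_index(a)
        for b in SENSE_CODONS:
            s, n = _path_diffs(a, b)
            syn_d[ia, codon_index(b)] = s
            nonsyn_d[ia, codon_index(b)] = n
    return {
        "syn_sites": syn_sites,
        "nonsyn_sites": nonsyn_sites,
        "syn_diffs": syn_d,
        "nonsyn_diffs": nonsyn_d,
    }
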