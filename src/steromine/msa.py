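"""Progressive multiple alignment: k-mer guide tree plus profile-profile
Needleman-Wunsch, with gap-fraction column trimming.

A light-weight stand-in for a production multiple aligner, sufficient to turn
protein subclusters into trimmed alignments for profile-HMM training and
supermatrix construction: pairwise k-mer (default 3-mer) count distances feed
a UPGMA guide tree; profiles are aligned by global affine-gap DP on expected
substitution scores between column frequency vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from numba import njit
from scipy.cluster.hierarchy import linkage

from .align import ScoringScheme, default_scheme
from .alphabet import X_INDEX, encode
from .errors import InputError

__all__ = ["MultipleAlignment", "progressive_align", "trim_columns", "sum_of_pairs_score"]

GAP = "-"


@dataclass
class MultipleAlignment:
    ids: List[str]
    rows: List[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise InputError("ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise InputError("alignment rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def gap_fractions(self) -> np.ndarray:
        if not self.rows:
            return np.zeros(0)
        arr = np.array([[c == GAP for c in row] for row in self.rows])
        return arr.mean(axis=0)

    def degapped(self, index: int) -> str:
        return self.rows[index].replace(GAP, "")

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)


def _freq_profile(rows: List[str]) -> np.ndarray:
    """Per-column residue frequency vectors (20 residues; gaps and X excluded
    from the mass, columns renormalized over residues present)."""
    n_cols = len(rows[0])
    out = np.zeros((n_cols, 20))
    for row in rows:
        for j, c in enumerate(row):
            if c != GAP:
                i = encode(c)[0]
                if i != X_INDEX:
                    out[j, i] += 1.0
    return out / max(len(rows), 1)


@njit(cache=True)
def _nw_profile_ops(S, gap_open, gap_extend):
    """Global affine-gap DP over a precomputed column-score matrix.

    Returns ops: 0 = match columns, 1 = gap in A (consume B column),
    2 = gap in B (consume A column), emitted alignment-start first.
    """
    n1, n2 = S.shape
    NEG = -1e30
    H = np.full((n1 + 1, n2 + 1), NEG)
    E = np.full((n1 + 1, n2 + 1), NEG)
    F = np.full((n1 + 1, n2 + 1), NEG)
    go = gap_open + gap_extend
    H[0, 0] = 0.0
    for j in range(1, n2 + 1):
        E[0, j] = -(gap_open + gap_extend * j)
        H[0, j] = E[0, j]
    for i in range(1, n1 + 1):
        F[i, 0] = -(gap_open + gap_extend * i)
        H[i, 0] = F[i, 0]
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            E[i, j] = max(H[i, j - 1] - go, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - go, F[i - 1, j] - gap_extend)
            h = H[i - 1, j - 1] + S[i - 1, j - 1]
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            H[i, j] = h
    ops = np.empty(n1 + n2, dtype=np.int8)
    k = n1 + n2
    i, j = n1, n2
    state = 0
    while i > 0 or j > 0:
        if state == 0:
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + S[i - 1, j - 1]:
                k -= 1
                ops[k] = 0
                i -= 1
                j -= 1
            elif j > 0 and H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            k -= 1
            ops[k] = 1
            if j > 1 and E[i, j] == E[i, j - 1] - gap_extend:
                j -= 1
            else:
                j -= 1
                state = 0
        else:
            k -= 1
            ops[k] = 2
            if i > 1 and F[i, j] == F[i - 1, j] - gap_extend:
                i -= 1
            else:
                i -= 1
                state = 0
    return ops[k:]


def _merge(
    a: List[str], b: List[str], sub20: np.ndarray, gap_open: float, gap_extend: float
) -> List[str]:
    fa = _freq_profile(a)
    fb = _freq_profile(b)
    S = fa @ sub20 @ fb.T
    ops = _nw_profile_ops(S, gap_open, gap_extend)
    rows_a = ["" for _ in a]
    rows_b = ["" for _ in b]
    i = j = 0
    for op in ops:
        if op == 0:
            for r in range(len(a)):
                rows_a[r] += a[r][i]
            for r in range(len(b)):
                rows_b[r] += b[r][j]
            i += 1
            j += 1
        elif op == 1:  # gap in A
            for r in range(len(a)):
                rows_a[r] += GAP
            for r in range(len(b)):
                rows_b[r] += b[r][j]
            j += 1
        else:
            for r in range(len(a)):
                rows_a[r] += a[r][i]
            for r in range(len(b)):
                rows_b[r] += GAP
            i += 1
    return rows_a + rows_b


def _kmer_distance_matrix(seqs: List[str], k: int = 3) -> np.ndarray:
    from collections import Counter

    counters = [Counter(s[i : i + k] for i in range(len(s) - k + 1)) for s in seqs]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = sum((counters[i] & counters[j]).values())
            denom = min(
                sum(counters[i].values()), sum(counters[j].values())
            )
            d[i, j] = d[j, i] = 1.0 - (shared / denom if denom else 0.0)
    return d


def progressive_align(
    sequences: Dict[str, str],
    scoring: Optional[ScoringScheme] = None,
    word_size: int = 3,
) -> MultipleAlignment:
    """Align sequences progressively along a UPGMA k-mer-distance guide tree.

    A single sequence is returned unchanged as a one-row alignment.
    """
    if not sequences:
        raise InputError("no sequences to align")
    ids = sorted(sequences)
    if len(ids) == 1:
        return MultipleAlignment(ids=ids, rows=[sequences[ids[0]]])
    scoring = scoring or default_scheme()
    sub20 = scoring.substitution_scores[:20, :20].astype(float)
    seqs = [sequences[i] for i in ids]
    for i, s in enumerate(seqs):
        if not s:
            raise InputError(f"empty sequence {ids[i]!r}")
    d = _kmer_distance_matrix(seqs, word_size)
    condensed = d[np.triu_indices(len(ids), k=1)]
    Z = linkage(condensed, method="average")
    # progressive merge following the guide tree
    nodes: Dict[int, Tuple[List[int], List[str]]] = {
        i: ([i], [seqs[i]]) for i in range(len(ids))
    }
    nxt = len(ids)
    for a_idx, b_idx, _dist, _n in Z:
        ia, rows_a = nodes.pop(int(a_idx))
        ib, rows_b = nodes.pop(int(b_idx))
        merged = _merge(rows_a, rows_b, sub20, scoring.gap_open, scoring.gap_extend)
        nodes[nxt] = (ia + ib, merged)
        nxt += 1
    order, rows = nodes.popitem()[1]
    by_leaf = dict(zip(order, rows))
    out_rows = [by_leaf[i] for i in range(len(ids))]
    aln = MultipleAlignment(ids=ids, rows=out_rows)
    for i in range(len(ids)):
        if aln.degapped(i) != seqs[i]:
            raise AssertionError("alignment does not preserve sequence content")
    return aln


def trim_columns(
    alignment: MultipleAlignment, max_gap_fraction: float = 0.5
) -> MultipleAlignment:
    """Keep exactly the columns whose gap fraction is <= ``max_gap_fraction``,
    preserving order; raises if nothing survives."""
    fracs = alignment.gap_fractions()
    keep = [j for j, f in enumerate(fracs) if f <= max_gap_fraction]
    if not keep:
        raise InputError("trimming removed every column")
    rows = ["".join(row[j] for j in keep) for row in alignment.rows]
    return MultipleAlignment(ids=list(alignment.ids), rows=rows)


def sum_of_pairs_score(
    alignment: MultipleAlignment, scoring: Optional[ScoringScheme] = None
) -> float:
    """Sum over columns and row pairs of substitution scores (gap pairs score
    the affine penalties via simple per-column gap costs)."""
    scoring = scoring or default_scheme()
    sub = scoring.substitution_scores
    total = 0.0
    n = len(alignment.rows)
    enc = [encode(r.replace(GAP, "X")) for r in alignment.rows]
    gaps = [[c == GAP for c in r] for r in alignment.rows]
    for j in range(alignment.n_columns):
        for a in range(n):
            for b in range(a + 1, n):
                ga, gb = gaps[a][j], gaps[b][j]
                if ga and gb:
                    continue
                if ga or gb:
                    total -= scoring.gap_extend
                else:
                    total += sub[enc[a][j], enc[b][j]]
    return total
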