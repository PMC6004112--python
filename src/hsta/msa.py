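"""A small progressive protein aligner.

Protein MSAs are normally produced by a dedicated aligner and handed to
:func:`hsta.backalign.back_align` as input.  For self-contained runs and
tests this module provides a classical progressive scheme: global
Needleman-Wunsch with BLOSUM62 and linear gap cost, guide tree by UPGMA on
k-mer (k=3) distances, profile-profile merging with average-of-pairs column
scores.  It is adequate for the closely related coding sequences this
package handles, not a general-purpose MSA tool.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
from Bio.Align import substitution_matrices

from .backalign import ProteinAlignment

__all__ = ["align_proteins"]

_BLOSUM = substitution_matrices.load("BLOSUM62")
_GAP = -6.0  # linear gap cost per residue-vs-gap column


# dense alphabet for vectorized column scoring: 20 residues + X + gap
_ALPHABET = "ACDEFGHIKLMNPQRSTVWY" + "X-"
_AA_INDEX = {c: i for i, c in enumerate(_ALPHABET)}
_NA = len(_ALPHABET)


def _score_matrix() -> np.ndarray:
    S = np.zeros((_NA, _NA))
    for i, a in enumerate(_ALPHABET[:20]):
        for j, b in enumerate(_ALPHABET[:20]):
            S[i, j] = float(_BLOSUM[a, b])
    S[_AA_INDEX["-"], :] = _GAP
    S[:, _AA_INDEX["-"]] = _GAP
    S[_AA_INDEX["-"], _AA_INDEX["-"]] = 0.0
    # X and other nonstandard residues score neutrally
    return S


_S = _score_matrix()


def _column_counts(rows: list[str]) -> np.ndarray:
    """(ncol, alphabet) residue counts per column."""
    n = len(rows[0]) if rows else 0
    counts = np.zeros((n, _NA))
    for r in rows:
        for i, c in enumerate(r):
            counts[i, _AA_INDEX.get(c, _AA_INDEX["X"])] += 1
    return counts


def _align_profiles(
    a: list[str], b: list[str]
) -> tuple[list[str], list[str]]:
    """Global NW on two profiles (lists of equal-length rows); returns gapped rows."""
    la = len(a[0]) if a else 0
    lb = len(b[0]) if b else 0
    ca = _column_counts(a)
    cb = _column_counts(b)
    # average-of-pairs column score for every column pair at once
    pair = (ca @ _S @ cb.T) / (len(a) * len(b))
    F = np.zeros((la + 1, lb + 1))
    ptr = np.zeros((la + 1, lb + 1), dtype=np.int8)  # 0 diag, 1 up (gap in b), 2 left
    F[1:, 0] = _GAP * np.arange(1, la + 1)
    F[0, 1:] = _GAP * np.arange(1, lb + 1)
    ptr[1:, 0] = 1
    ptr[0, 1:] = 2
    for i in range(1, la + 1):
        diag = F[i - 1, :-1] + pair[i - 1]
        up = F[i - 1, 1:] + _GAP
        row = F[i]
        for j in range(1, lb + 1):
            d = diag[j - 1]
            u = up[j - 1]
            left = row[j - 1] + _GAP
            if d >= u and d >= left:
                row[j] = d
                ptr[i, j] = 0
            elif u >= left:
                row[j] = u
                ptr[i, j] = 1
            else:
                row[j] = left
                ptr[i, j] = 2
    # traceback
    path = []
    i, j = la, lb
    while i > 0 or j > 0:
        p = ptr[i, j]
        path.append(p)
        if p == 0:
            i, j = i - 1, j - 1
        elif p == 1:
            i -= 1
        else:
            j -= 1
    path.reverse()
    out_a = ["" for _ in a]
    out_b = ["" for _ in b]
    i = j = 0
    for p in path:
        if p == 0:
            for r, row in enumerate(a):
                out_a[r] += row[i]
            for r, row in enumerate(b):
                out_b[r] += row[j]
            i += 1
            j += 1
        elif p == 1:
            for r, row in enumerate(a):
                out_a[r] += row[i]
            for r in range(len(b)):
                out_b[r] += "-"
            i += 1
        else:
            for r in range(len(a)):
                out_a[r] += "-"
            for r, row in enumerate(b):
                out_b[r] += row[j]
            j += 1
    return out_a, out_b


def _kmer_distance(seqs: list[str], k: int = 3) -> np.ndarray:
    counts = [Counter(s[i : i + k] for i in range(max(len(s) - k + 1, 0))) for s in seqs]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = sum((counts[i] & counts[j]).values())
            denom = min(sum(counts[i].values()), sum(counts[j].values())) or 1
            d[i, j] = d[j, i] = 1.0 - shared / denom
    return d


def _upgma_order(d: np.ndarray) -> list[tuple[int, int]]:
    """Return merge pairs (cluster indices into a growing list) UPGMA-style."""
    n = d.shape[0]
    active = {i: [i] for i in range(n)}
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    next_id = n
    while len(active) > 1:
        (i, j) = min(dist, key=lambda ij: (dist[ij], ij))
        merges.append((i, j))
        members = active[i] + active[j]
        del active[i], active[j]
        dist = {k: v for k, v in dist.items() if i not in k and j not in k}
        for k in list(active):
            dij = np.mean([d[a, b] for a in members for b in active[k]])
            dist[(min(k, next_id), max(k, next_id))] = dij
        active[next_id] = members
        next_id += 1
    return merges


def align_proteins(ids: list[str], seqs: list[str]) -> ProteinAlignment:
    """Progressively align protein sequences; returns a :class:`ProteinAlignment`."""
    if len(ids) != len(seqs):
        raise ValueError("ids and seqs must have equal length")
    if not seqs:
        raise ValueError("nothing to align")
    if len(seqs) == 1:
        return ProteinAlignment(ids=(ids[0],), rows=(seqs[0],))
    d = _kmer_distance(seqs)
    merges = _upgma_order(d)
    # cluster id -> (ids, rows)
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([ids[i]], [seqs[i]]) for i in range(len(seqs))
    }
    next_id = len(seqs)
    for i, j in merges:
        ids_a, rows_a = clusters.pop(i)
        ids_b, rows_b = clusters.pop(j)
        rows_a, rows_b = _align_profiles(rows_a, rows_b)
        clusters[next_id] = (ids_a + ids_b, rows_a + rows_b)
        next_id += 1
    (final_ids, final_rows), = clusters.values()
    # restore the input order
    order = sorted(range(len(final_ids)), key=lambda r: ids.index(final_ids[r]))
    return ProteinAlignment(
        ids=tuple(final_ids[r] for r in order),
        rows=tuple(final_rows[r] for r in order),
    )
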