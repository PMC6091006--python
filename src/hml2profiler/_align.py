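"""Shared pairwise-alignment primitives.

All sequence comparison in the package funnels through here: scored global
alignment (Bio.Align.PairwiseAligner, affine gaps) for difference counting and
coordinate projection, and a numba-compiled semiglobal edit-distance DP for the
read-assignment inner loop (read fully aligned, reference end gaps free, unit
costs). Distances are plain Levenshtein-style integers so results are exactly
reproducible and oracle-checkable.
"""
from __future__ import annotations

import numpy as np
from Bio import Align
from numba import njit

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: affine scoring used for all scored DNA alignments: match +1, mismatch -1,
#: gap open -5, gap extend -1 (a gap of length L costs 5 + (L-1))
MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1.0, -1.0, -5.0, -1.0


def revcomp(seq: str) -> str:
    """Reverse complement (ACGTN alphabet, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _make_aligner(free_end_gaps: bool = False) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    if free_end_gaps:
        # free end gaps in the query row: the second sequence aligns as a
        # complete query against a substring of the first
        try:
            aligner.end_deletion_score = 0.0
        except AttributeError:  # older biopython naming
            aligner.query_end_gap_score = 0.0
    return aligner


_GLOBAL = _make_aligner()
_SEMIGLOBAL = _make_aligner(free_end_gaps=True)


def align_pair(a: str, b: str, free_end_gaps: bool = False) -> tuple[str, str]:
    """Globally align two sequences; return the two gapped rows.

    With ``free_end_gaps`` the *first* sequence's end gaps are free (``b`` is
    aligned as a complete query against a substring of ``a``).
    """
    aligner = _SEMIGLOBAL if free_end_gaps else _GLOBAL
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def count_differences(a: str, b: str) -> int:
    """Count nucleotide differences between two sequences.

    Differences = substitution columns + indel events in the optimal global
    alignment, where a contiguous gap run of any length counts as ONE event.
    Two identical sequences give 0.
    """
    if a == b:
        return 0
    row_a, row_b = align_pair(a, b)
    return differences_in_rows(row_a, row_b)


def differences_in_rows(row_a: str, row_b: str) -> int:
    """Substitutions + gap runs in a pre-computed pair of gapped rows."""
    subs = 0
    gap_events = 0
    in_gap_a = in_gap_b = False
    for x, y in zip(row_a, row_b):
        if x == "-":
            if not in_gap_a:
                gap_events += 1
            in_gap_a = True
        else:
            in_gap_a = False
        if y == "-":
            if not in_gap_b:
                gap_events += 1
            in_gap_b = True
        else:
            in_gap_b = False
        if x != "-" and y != "-" and x != y:
            subs += 1
    return subs + gap_events


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


@njit(cache=True)
def _semiglobal_edit(read: np.ndarray, ref: np.ndarray) -> int:  # pragma: no cover
    m = read.shape[0]
    n = ref.shape[0]
    prev = np.zeros(n + 1, dtype=np.int32)  # leading ref gap free
    cur = np.empty(n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        cur[0] = i
        ri = read[i - 1]
        for j in range(1, n + 1):
            cost = 0 if ri == ref[j - 1] else 1
            best = prev[j - 1] + cost
            up = prev[j] + 1
            if up < best:
                best = up
            left = cur[j - 1] + 1
            if left < best:
                best = left
            cur[j] = best
        prev, cur = cur, prev
    best = prev[0]
    for j in range(1, n + 1):  # trailing ref gap free
        if prev[j] < best:
            best = prev[j]
    return best


def edit_distance(read: str, ref: str) -> int:
    """Minimum edit distance aligning all of ``read`` to a substring of ``ref``.

    End gaps on ``ref`` are free (Sanger reads may be truncated relative to the
    full per-locus amplicon); gaps on the read are charged. Unit costs.
    """
    if read == ref:
        return 0
    if len(read) == 0:
        return 0
    if len(ref) == 0:
        return len(read)
    return int(_semiglobal_edit(_encode(read), _encode(ref)))


_LOCAL = _make_aligner()
_LOCAL.mode = "local"


def local_alignment_blocks(a: str, b: str) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Aligned (a-interval, b-interval) block pairs of the best local alignment.

    Only genuinely homologous segments are covered; non-homologous flanks are
    excluded (unlike a global alignment, which must place them somewhere).
    """
    aln = _LOCAL.align(a, b)[0]
    a_blocks, b_blocks = aln.aligned
    return [
        ((int(s1), int(e1)), (int(s2), int(e2)))
        for (s1, e1), (s2, e2) in zip(a_blocks, b_blocks)
    ]


def protein_identity(a: str, b: str) -> float:
    """Fraction of identical columns in a global alignment of two proteins."""
    if not a or not b:
        return 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(a, b)[0]
    ra, rb = str(aln[0]), str(aln[1])
    ident = sum(1 for x, y in zip(ra, rb) if x == y and x != "-")
    return ident / max(len(a), len(b))
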