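"""Independent brute-force oracles used by the test suite.

Each oracle re-implements a contract from first principles, sharing no code
with the package's implementation path it checks.
"""
from __future__ import annotations

import numpy as np
from numba import njit

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq.upper()))


@njit(cache=True)
def _edit_full_matrix(read, ref):  # pragma: no cover
    """Full-matrix semiglobal edit distance (read vs any ref substring)."""
    m, n = read.shape[0], ref.shape[0]
    D = np.empty((m + 1, n + 1), dtype=np.int32)
    for j in range(n + 1):
        D[0, j] = 0
    for i in range(1, m + 1):
        D[i, 0] = i
        for j in range(1, n + 1):
            cost = 0 if read[i - 1] == ref[j - 1] else 1
            D[i, j] = min(D[i - 1, j - 1] + cost, D[i - 1, j] + 1, D[i, j - 1] + 1)
    best = D[m, 0]
    for j in range(1, n + 1):
        if D[m, j] < best:
            best = D[m, j]
    return best


def oracle_edit_distance(read: str, ref: str) -> int:
    a = np.frombuffer(read.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(ref.upper().encode(), dtype=np.uint8)
    if len(a) == 0:
        return 0
    if len(b) == 0:
        return len(a)
    return int(_edit_full_matrix(a, b))


def oracle_assign(read: str, sequences: dict[str, str], margin: int, max_distance: float):
    """Exhaustive pairwise-comparison assignment of one read.

    Both orientations of the read are compared against every amplicon; the
    orientation with the smaller minimum distance wins (ties toward forward).
    Returns (status, frozenset(best loci), distance).
    """
    ids = list(sequences)
    d_fwd = {l: oracle_edit_distance(read, sequences[l]) for l in ids}
    read_rc = rc(read)
    d_rev = {l: oracle_edit_distance(read_rc, sequences[l]) for l in ids}
    if min(d_rev.values()) < min(d_fwd.values()):
        dists = d_rev
    else:
        dists = d_fwd
    dmin = min(dists.values())
    best = [l for l in ids if dists[l] <= dmin + margin]
    if dmin > max_distance * len(sequences[best[0]]):
        return "unassigned", frozenset(best), dmin
    return ("unique" if len(best) == 1 else "ambiguous"), frozenset(best), dmin


def gotoh_score(a: str, b: str, match=1.0, mismatch=-1.0, open_=-5.0, extend=-1.0) -> float:
    """Optimal affine-gap global alignment score (Gotoh three-state DP)."""
    m, n = len(a), len(b)
    neg = -1e9
    M = np.full((m + 1, n + 1), neg)
    X = np.full((m + 1, n + 1), neg)  # gap in b (vertical)
    Y = np.full((m + 1, n + 1), neg)  # gap in a (horizontal)
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        X[i, 0] = open_ + extend * (i - 1)
    for j in range(1, n + 1):
        Y[0, j] = open_ + extend * (j - 1)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + open_, X[i - 1, j] + extend)
            Y[i, j] = max(M[i, j - 1] + open_, Y[i, j - 1] + extend)
    return float(max(M[m, n], X[m, n], Y[m, n]))


def oracle_primer_scan(sequence: str, forward: list[str], reverse: list[str], k: int,
                       max_product: int = 5000) -> list[tuple[int, int]]:
    """Naive sliding-window primer-pair scan (early-exit mismatch counting).

    Forward hits pair with the nearest downstream reverse-complemented reverse
    hit; both strands scanned, intervals in forward coordinates, deduplicated.
    """

    def hits(seq: str, primers: list[str]) -> list[int]:
        out = []
        for start in range(len(seq)):
            for p in primers:
                if start + len(p) > len(seq):
                    continue
                mism = 0
                for i, ch in enumerate(p):
                    if seq[start + i] != ch:
                        mism += 1
                        if mism > k:
                            break
                else:
                    out.append(start)
                    break
        return out

    def scan(seq: str) -> list[tuple[int, int]]:
        fwd = hits(seq, forward)
        rev_rc = [rc(p) for p in reverse]
        rev = hits(seq, rev_rc)
        rev_end = max(len(p) for p in reverse)
        f_len = min(len(p) for p in forward)
        out = []
        for f in fwd:
            downstream = [r for r in rev if r >= f + f_len]
            if downstream:
                r = downstream[0]
                if r + rev_end - f <= max_product:
                    out.append((f, r + rev_end))
        return out

    intervals = set(scan(sequence))
    n = len(sequence)
    for s, e in scan(rc(sequence)):
        intervals.add((n - e, n - s))
    return sorted(intervals)


def oracle_splice_boundaries(read: str, genome: str, min_intron: int = 50):
    """Exhaustive single-intron boundary search.

    Enumerates every (junction j, donor d, acceptor a) such that read[:j]
    matches genome ending at d and read[j:] matches genome starting at a with
    a - d >= min_intron; returns the GT..AG solutions.
    """
    out = []
    n = len(read)
    for j in range(20, n - 20 + 1):
        prefix, suffix = read[:j], read[j:]
        d = genome.find(prefix)
        if d < 0:
            continue
        d_end = d + j
        start = d_end + min_intron
        a = genome.find(suffix, start)
        while a >= 0:
            if genome[d_end : d_end + 2] == "GT" and genome[a - 2 : a] == "AG":
                out.append((d_end, a))
            a = genome.find(suffix, a + 1)
    return sorted(set(out))


def permutation_pvalue(a, b, statistic="mean_diff", n_perm: int = 10000, seed: int = 0) -> float:
    """Two-sided permutation p-value for the difference of group means or the
    rank-sum statistic, permuting group labels."""
    rng = np.random.default_rng(seed)
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    na = len(a)

    def stat(x, y):
        if statistic == "mean_diff":
            return x.mean() - y.mean()
        ranks = np.argsort(np.argsort(np.concatenate([x, y]))) + 1
        expected = len(x) * (len(x) + len(y) + 1) / 2.0
        return ranks[: len(x)].sum() - expected

    observed = abs(stat(a, b))
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(stat(perm[:na], perm[na:])) >= observed - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def oracle_translate(nt: str) -> str:
    return "".join(CODON_TABLE[nt[i : i + 3]] for i in range(0, len(nt) - 2, 3))
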