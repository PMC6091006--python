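"""In-silico modelling of the RT-PCR amplicons used for locus profiling.

Three amplicons identify transcribed HML-2 loci: one within gag (~620 nt), one
across the env gene 5' region spanning the 292-bp segment that separates
provirus types 1 and 2 (products ~330 / ~620 nt), and one across the large env
intron of the spliced rec/np9 transcripts. This module extracts per-locus
amplicon sequences with degenerate primer mixes, classifies provirus type from
the 292-bp indel, and computes the pairwise difference matrices and diagnostic
sites that read assignment relies on.

Difference counting convention: substitutions + indel *events* (one contiguous
gap run of any length counts once) in an affine-gap global alignment. A single
long indel therefore cannot drown out the substitution signal.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._align import align_pair, count_differences, revcomp

DEFAULT_MAX_PRODUCT = 5000


@dataclass(frozen=True)
class Primer:
    """A single primer of a (possibly degenerate) mix."""

    sequence: str
    ratio: float = 1.0
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "sequence", self.sequence.upper())
        if self.ratio <= 0:
            raise ValueError("primer mix ratio must be > 0")


@dataclass(frozen=True)
class PrimerSet:
    """Forward/reverse primer mixes with a mismatch tolerance.

    Mix ratios are metadata for the simulator (amplification bias); matching is
    a pure sequence question and ignores them. Matching allows substitutions
    only — no indels inside primer sites.
    """

    name: str
    forward: tuple[Primer, ...]
    reverse: tuple[Primer, ...]
    max_mismatches: int = 1

    def __post_init__(self):
        if not self.forward or not self.reverse:
            raise ValueError(f"primer set {self.name!r} needs >=1 forward and reverse primer")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass(frozen=True)
class AmpliconDefinition:
    """One named amplicon: its primer set and expected product lengths.

    ``expected_lengths`` maps provirus type (1, 2 or "unknown") to an inclusive
    (lo, hi) product-length range; extraction accepts a product inside any of
    the ranges.
    """

    name: str
    primer_set: PrimerSet
    expected_lengths: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.expected_lengths:
            raise ValueError("expected_lengths must be non-empty")

    def length_ok(self, length: int) -> bool:
        return any(lo <= length <= hi for lo, hi in self.expected_lengths.values())


def _hits(sequence: str, primers: tuple[Primer, ...], max_mismatches: int) -> list[int]:
    """Start positions where any mix member matches with <= max_mismatches subs."""
    seq = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    starts: set[int] = set()
    for primer in primers:
        p = np.frombuffer(primer.sequence.encode(), dtype=np.uint8)
        if len(p) > len(seq):
            continue
        windows = np.lib.stride_tricks.sliding_window_view(seq, len(p))
        mismatches = (windows != p).sum(axis=1)
        starts.update(np.flatnonzero(mismatches <= max_mismatches).tolist())
    return sorted(starts)


def _scan_strand(sequence: str, primer_set: PrimerSet, max_product: int) -> list[tuple[int, int]]:
    fwd = _hits(sequence, primer_set.forward, primer_set.max_mismatches)
    rc_reverse = tuple(
        Primer(revcomp(p.sequence), p.ratio, p.name) for p in primer_set.reverse
    )
    rev = _hits(sequence, rc_reverse, primer_set.max_mismatches)
    rev_len = {r: max(len(p.sequence) for p in primer_set.reverse) for r in rev}
    intervals = []
    for f in fwd:
        f_end = f + min(len(p.sequence) for p in primer_set.forward)
        # nearest downstream reverse site: PCR yields the shortest product
        downstream = [r for r in rev if r >= f_end]
        if not downstream:
            continue
        r = downstream[0]
        end = r + rev_len[r]
        if end - f <= max_product:
            intervals.append((f, end))
    return intervals


def match_primers(
    locus_sequence: str,
    primer_set: PrimerSet,
    max_product: int = DEFAULT_MAX_PRODUCT,
) -> list[tuple[int, int]]:
    """Amplicon intervals (0-based half-open, primers included) on a locus.

    Each forward-primer match is paired with the nearest downstream match of a
    reverse-complemented reverse primer; both strands are searched and
    intervals are reported in forward-strand coordinates. An empty list is a
    valid outcome (no product).
    """
    intervals = set(_scan_strand(locus_sequence, primer_set, max_product))
    n = len(locus_sequence)
    for s, e in _scan_strand(revcomp(locus_sequence), primer_set, max_product):
        intervals.add((n - e, n - s))
    return sorted(intervals)


@dataclass
class DiagnosticSite:
    """One alignment column separating at least two loci."""

    column: int
    bases: dict[str, str]
    private: bool = False
    private_locus: Optional[str] = None


@dataclass
class AmpliconProfile:
    """Per-locus in-silico amplicons plus their comparison structures.

    ``sequences`` holds the extracted amplicon per locus; loci without a
    product are recorded in ``absent`` with a reason. The implied multiple
    alignment for diagnostic sites is built progressively against the longest
    amplicon (the anchor): every other amplicon is projected onto anchor
    coordinates via pairwise global alignment, ignoring insertions relative to
    the anchor.
    """

    amplicon: AmpliconDefinition
    sequences: dict[str, str]
    absent: dict[str, str] = field(default_factory=dict)
    _matrix: Optional[pd.DataFrame] = field(default=None, repr=False)
    _rows: Optional[dict] = field(default=None, repr=False)
    _posmaps: Optional[dict] = field(default=None, repr=False)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.sequences)

    @property
    def anchor(self) -> str:
        """Locus id of the alignment anchor (longest amplicon, first wins)."""
        return max(self.sequences, key=lambda k: (len(self.sequences[k]),))

    def length_range(self) -> tuple[int, int]:
        lengths = [len(s) for s in self.sequences.values()]
        return min(lengths), max(lengths)

    @property
    def difference_matrix(self) -> pd.DataFrame:
        if self._matrix is None:
            self._matrix = difference_matrix(self.sequences)
        return self._matrix

    def alignment_rows(self) -> dict[str, str]:
        """Each amplicon projected onto anchor coordinates ('-' = deletion)."""
        if self._rows is None:
            self._build_projection()
        return self._rows

    def position_maps(self) -> dict[str, np.ndarray]:
        """Per locus: anchor column for each amplicon position (-1 if inserted)."""
        if self._posmaps is None:
            self._build_projection()
        return self._posmaps

    def _build_projection(self) -> None:
        anchor_id = self.anchor
        anchor = self.sequences[anchor_id]
        rows, posmaps = {}, {}
        for locus_id, seq in self.sequences.items():
            if locus_id == anchor_id:
                rows[locus_id] = anchor
                posmaps[locus_id] = np.arange(len(anchor))
                continue
            rows[locus_id], posmaps[locus_id] = _project(anchor, seq)
        self._rows = rows
        self._posmaps = posmaps


def _project(anchor: str, seq: str) -> tuple[str, np.ndarray]:
    """Project ``seq`` onto anchor coordinates via global alignment."""
    row_a, row_s = align_pair(anchor, seq)
    projected = []
    posmap = np.full(len(seq), -1, dtype=int)
    a_pos = s_pos = 0
    for x, y in zip(row_a, row_s):
        if x != "-" and y != "-":
            projected.append(y)
            posmap[s_pos] = a_pos
            a_pos += 1
            s_pos += 1
        elif x != "-":  # deletion in seq
            projected.append("-")
            a_pos += 1
        else:  # insertion relative to anchor: ignored in the projection
            s_pos += 1
    return "".join(projected), posmap


def extract_amplicons(registry, amplicon_def: AmpliconDefinition) -> AmpliconProfile:
    """Extract the per-locus amplicon for every locus in a registry.

    Loci where primers find no product (or only products outside the expected
    size ranges) are recorded as absent with a human-readable reason.
    """
    sequences: dict[str, str] = {}
    absent: dict[str, str] = {}
    for rec in registry:
        intervals = match_primers(rec.sequence, amplicon_def.primer_set)
        valid = [iv for iv in intervals if amplicon_def.length_ok(iv[1] - iv[0])]
        if valid:
            s, e = min(valid, key=lambda iv: iv[1] - iv[0])
            sequences[rec.locus_id] = rec.sequence[s:e]
            continue
        if intervals:
            absent[rec.locus_id] = "product outside expected size range"
            continue
        ps = amplicon_def.primer_set
        has_fwd = bool(_hits(rec.sequence, ps.forward, ps.max_mismatches)) or bool(
            _hits(revcomp(rec.sequence), ps.forward, ps.max_mismatches)
        )
        rc_rev = tuple(Primer(revcomp(p.sequence), p.ratio, p.name) for p in ps.reverse)
        has_rev = bool(_hits(rec.sequence, rc_rev, ps.max_mismatches)) or bool(
            _hits(revcomp(rec.sequence), rc_rev, ps.max_mismatches)
        )
        if not has_fwd:
            absent[rec.locus_id] = "no forward primer match"
        elif not has_rev:
            absent[rec.locus_id] = "no reverse primer match"
        else:
            absent[rec.locus_id] = "no forward/reverse primer pairing"
    return AmpliconProfile(amplicon=amplicon_def, sequences=sequences, absent=absent)


def difference_matrix(sequences: dict[str, str]) -> pd.DataFrame:
    """Symmetric matrix of pairwise nucleotide-difference counts.

    Count = substitutions + indel events (a contiguous gap counts once) in the
    optimal global alignment; 0 if and only if the sequences are identical.
    """
    if len(sequences) < 2:
        raise ValueError("difference matrix needs >= 2 amplicon sequences")
    ids = list(sequences)
    n = len(ids)
    mat = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = count_differences(sequences[ids[i]], sequences[ids[j]])
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=ids, columns=ids)


def diagnostic_sites(profile: AmpliconProfile) -> list[DiagnosticSite]:
    """Alignment columns at which at least one locus differs from another.

    A site where exactly one locus carries a base different from the (single)
    state shared by all the others is flagged private.
    """
    rows = profile.alignment_rows()
    ids = list(rows)
    length = len(rows[profile.anchor])
    sites = []
    for col in range(length):
        states = {locus: rows[locus][col] for locus in ids}
        distinct = set(states.values())
        if len(distinct) < 2:
            continue
        private_locus = None
        if len(distinct) == 2 and len(ids) > 2:
            counts = {s: sum(1 for v in states.values() if v == s) for s in distinct}
            rare = [s for s, c in counts.items() if c == 1]
            if len(rare) == 1:
                private_locus = next(k for k, v in states.items() if v == rare[0])
        sites.append(
            DiagnosticSite(
                column=col,
                bases=states,
                private=private_locus is not None,
                private_locus=private_locus,
            )
        )
    return sites


def indistinguishable_groups(profile: AmpliconProfile) -> list[frozenset]:
    """Groups of loci whose amplicons are identical (pairwise difference 0).

    Every 0-difference pair belongs to exactly one group; reads from these loci
    can never be assigned uniquely over this amplicon.
    """
    matrix = profile.difference_matrix
    ids = list(matrix.index)
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in ids:
        for j in ids:
            if i < j and matrix.loc[i, j] == 0:
                parent[find(i)] = find(j)
    groups: dict[str, set] = {}
    for i in ids:
        groups.setdefault(find(i), set()).add(i)
    return [frozenset(g) for g in groups.values() if len(g) > 1]


def load_primer_config(path=None) -> dict[str, AmpliconDefinition]:
    """Amplicon definitions from a YAML primer-config file.

    Without a path, the packaged defaults are loaded: the six published
    env600nt reverse primers verbatim (5:1:1:1:1:1 mix) with empty forward
    slots, since the degenerate forward mixes were published elsewhere and
    must be user-supplied. Primer sets with an empty side are returned as
    None-valued entries so callers can report exactly what is missing.
    """
    import yaml

    if path is None:
        from importlib import resources

        handle = resources.files("hml2profiler").joinpath("data", "primers.yaml").open()
    else:
        handle = open(path)
    with handle:
        config = yaml.safe_load(handle)

    definitions: dict[str, AmpliconDefinition] = {}
    lengths_cfg = config.get("amplicon_definitions", {})
    for name, pset_cfg in config.get("primer_sets", {}).items():
        fwd = tuple(
            Primer(p["sequence"], float(p.get("ratio", 1.0)), p.get("name", ""))
            for p in pset_cfg.get("forward", [])
        )
        rev = tuple(
            Primer(p["sequence"], float(p.get("ratio", 1.0)), p.get("name", ""))
            for p in pset_cfg.get("reverse", [])
        )
        if not fwd or not rev:
            definitions[name] = None  # incomplete set: user must supply primers
            continue
        pset = PrimerSet(
            name=name, forward=fwd, reverse=rev,
            max_mismatches=int(pset_cfg.get("max_mismatches", 1)),
        )
        lengths = {
            (int(k) if str(k) in ("1", "2") else "unknown"): tuple(v)
            for k, v in lengths_cfg.get(name, {}).get("expected_lengths", {}).items()
        } or {"unknown": (1, DEFAULT_MAX_PRODUCT)}
        definitions[name] = AmpliconDefinition(name, pset, lengths)
    return definitions


def classify_provirus_type(
    env_region_sequence: str,
    reference_type2_env5prime: str,
    segment: Optional[tuple[int, int]] = None,
    indel_length: int = 292,
    indel_tolerance: int = 10,
    intact_gap_max: int = 50,
):
    """Classify a locus as provirus type 1 or 2 from the env 5' indel.

    The query is globally aligned to a type-2 reference of the env 5' region.
    Type 2: the 292-bp segment is present (every deletion run inside it is
    shorter than ``intact_gap_max``). Type 1: the segment is absent as one
    deletion of ``indel_length`` +/- ``indel_tolerance`` nt. Anything else is
    "unknown". ``segment`` optionally restricts attention to the segment's
    (start, end) interval on the reference; without it any deletion run is
    considered.
    """
    if len(env_region_sequence) < 100:
        raise ValueError("region too short (< 100 nt) to classify provirus type")
    row_ref, row_q = align_pair(reference_type2_env5prime, env_region_sequence)
    # deletion runs in the query, in reference coordinates
    runs = []
    ref_pos = 0
    run_start = None
    for x, y in zip(row_ref, row_q):
        if x != "-" and y == "-":
            if run_start is None:
                run_start = ref_pos
        elif x != "-":
            if run_start is not None:
                runs.append((run_start, ref_pos))
                run_start = None
        if x != "-":
            ref_pos += 1
    if run_start is not None:
        runs.append((run_start, ref_pos))
    if segment is not None:
        s, e = segment
        runs = [r for r in runs if r[1] > s and r[0] < e]
    lengths = [e - s for s, e in runs]
    longest = max(lengths, default=0)
    if abs(longest - indel_length) <= indel_tolerance:
        return 1
    if longest < intact_gap_max:
        return 2
    return "unknown"
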