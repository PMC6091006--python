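"""Intron inference and transcript classification for rec/np9 amplicon reads.

Type 2 proviruses splice a splice donor (SD2, inside the 292-bp env 5'
segment) to an acceptor (SA2) just upstream of the 3' LTR, producing the rec
transcript; type 1 proviruses lack the segment and use a donor at the deletion
junction to produce np9. Variants occur: an alternative acceptor 260 nt
downstream of SA2 inside the 3' LTR (an np9-like transcript from a type 2
locus, encoding a C-terminally shortened Rec), and an acceptor shifted +7 nt
when the canonical SA2 AG is mutated away.

``spliced_align`` recovers introns by exact-match seeding of collinear exon
blocks and refines ambiguous junction placements to the canonical GT..AG
dinucleotides; ``classify_transcript`` names the transcript class given the
locus splice annotation and provirus type.

Coordinate convention: a splice donor position is the first intronic base (the
G of GT); an acceptor position is the first exonic base after the intron, so
the intron is the half-open interval [donor, acceptor).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

DEFAULT_MIN_INTRON = 50
MIN_EXON_BLOCK = 20
SEED_LENGTH = 20
GT_AG_SEARCH_WINDOW = 10  # nt around the naive boundary searched for GT..AG
NP9_ACCEPTOR_TOLERANCE = 20  # max |offset| from SA2 still called np9 on a type 1 locus

TRANSCRIPT_CLASSES = ("rec", "np9", "np9_like_alternative", "unspliced", "unknown")


@dataclass
class SpliceAnnotation:
    """Known splice sites of one locus (0-based on the locus sequence).

    ``sd2`` is the secondary splice donor (the rec donor on a type 2 locus,
    the np9 donor at the deletion junction on a type 1 locus); ``sa2`` is the
    canonical rec/np9 acceptor (first exonic base after the intron).
    ``env_start`` is the shared Env/Rec/Np9 translational start;
    ``lstart_3ltr`` the first base of the 3' LTR.
    """

    locus_id: str
    sd2: Optional[int] = None
    sa2: Optional[int] = None
    sd1: Optional[int] = None
    sa1: Optional[int] = None
    lstart_3ltr: Optional[int] = None
    env_start: Optional[int] = None

    def __post_init__(self):
        if self.sd2 is not None and self.sa2 is not None and not self.sd2 < self.sa2:
            raise ValueError(f"{self.locus_id}: sd2 must lie upstream of sa2")


@dataclass
class Intron:
    donor: int
    acceptor: int
    donor_dinucleotide: str
    acceptor_dinucleotide: str

    @property
    def length(self) -> int:
        return self.acceptor - self.donor

    @property
    def is_gt_ag(self) -> bool:
        return self.donor_dinucleotide == "GT" and self.acceptor_dinucleotide == "AG"

    def as_tuple(self) -> tuple:
        return (
            self.donor,
            self.acceptor,
            self.donor_dinucleotide,
            self.acceptor_dinucleotide,
        )


@dataclass
class SpliceCall:
    """Classified splice structure of one read against its source locus."""

    read_id: str
    locus_id: str
    introns: list[Intron] = field(default_factory=list)
    transcript_class: str = "unknown"
    acceptor_offset: Optional[int] = None  # nt relative to canonical SA2; 0 = canonical
    reason: str = ""


def _extend_match(read: str, genome: str, r: int, g: int) -> int:
    """Length of the exact common extension from read[r] / genome[g]."""
    n = 0
    while r + n < len(read) and g + n < len(genome) and read[r + n] == genome[g + n]:
        n += 1
    return n


def _find_anchor(
    read: str, genome: str, r_from: int, g_from: int
) -> Optional[tuple[int, int]]:
    """First exact seed of a read k-mer in the genome at/after g_from, trying
    successive read offsets so a stray mismatch cannot kill seeding."""
    for r in range(r_from, min(r_from + 40, len(read) - SEED_LENGTH + 1)):
        g = genome.find(read[r : r + SEED_LENGTH], g_from)
        if g >= 0:
            return r, g
    return None


def spliced_align(
    read: str, locus_sequence: str, min_intron: int = DEFAULT_MIN_INTRON
) -> list[Intron]:
    """Recover the intron chain of a read against its source locus.

    The read is partitioned into collinear exon blocks (each >= 20 nt) by
    exact-match seeding and maximal extension; gaps >= ``min_intron`` between
    consecutive blocks are reported as introns. Where the junction placement is
    ambiguous (read bases compatible with both the donor-side and the
    acceptor-side exon), the placement giving GT..AG boundaries within +/-10 nt
    of the naive boundary is preferred; remaining ties resolve to the smallest
    shift from the naive boundary. Returns [] if the read is a contiguous match
    or if no collinear chain explains it (use :func:`maps_contiguously` to
    separate the two; ``call_splice`` does).
    """
    read = read.upper()
    genome = locus_sequence.upper()
    anchor = _find_anchor(read, genome, 0, 0)
    if anchor is None:
        return []
    r, g = anchor
    while r > 0 and g > 0 and read[r - 1] == genome[g - 1]:
        r -= 1
        g -= 1
    if r > 5:  # unexplained read prefix
        return []
    introns: list[Intron] = []
    while True:
        ext = _extend_match(read, genome, r, g)
        r_end, g_end = r + ext, g + ext
        if len(read) - r_end <= 2:  # read explained (tolerate <3 trailing nt)
            return introns
        nxt = _find_anchor(read, genome, r_end, g_end + min_intron)
        if nxt is None:
            return []
        r2, g2 = nxt
        while r2 > r and g2 > 0 and read[r2 - 1] == genome[g2 - 1]:
            r2 -= 1
            g2 -= 1
        if r2 > r_end:  # unmatched read bases between the blocks
            return []
        intron = _refine_boundary(read, genome, r, g, r_end, r2, g2)
        if intron is None or intron.length < min_intron:
            return []
        junction_r = intron.donor - g + r  # read coordinate of the junction
        if junction_r - r < MIN_EXON_BLOCK:
            return []
        introns.append(intron)
        r, g = junction_r, intron.acceptor
        if len(read) - r < MIN_EXON_BLOCK:
            return introns


def _refine_boundary(
    read: str, genome: str, r: int, g: int, r_end: int, r2: int, g2: int
) -> Optional[Intron]:
    """Pick the junction read-offset j within the ambiguity window [r2, r_end].

    Donor-side exon covers read[r:j) at genome[g:g+(j-r)), so the first
    intronic base is donor = g + (j - r); the acceptor-side exon starts at
    read[j] / genome g2 + (j - r2), so acceptor = g2 + (j - r2).
    """
    candidates = []
    for j in range(max(r2, r), r_end + 1):
        donor = g + (j - r)
        acceptor = g2 + (j - r2)
        if donor >= acceptor or acceptor < 2 or donor + 2 > len(genome):
            continue
        d_dn = genome[donor : donor + 2]
        a_dn = genome[acceptor - 2 : acceptor]
        candidates.append((j, donor, acceptor, d_dn, a_dn))
    if not candidates:
        return None
    gt_ag = [
        c
        for c in candidates
        if c[3] == "GT" and c[4] == "AG" and abs(c[0] - r_end) <= GT_AG_SEARCH_WINDOW
    ]
    pool = gt_ag or candidates
    j, donor, acceptor, d_dn, a_dn = min(pool, key=lambda c: (abs(c[0] - r_end), c[0]))
    return Intron(
        donor=donor,
        acceptor=acceptor,
        donor_dinucleotide=d_dn,
        acceptor_dinucleotide=a_dn,
    )


def maps_contiguously(read: str, locus_sequence: str) -> bool:
    """True if the read is explained by one contiguous exon block."""
    read = read.upper()
    genome = locus_sequence.upper()
    anchor = _find_anchor(read, genome, 0, 0)
    if anchor is None:
        return False
    r, g = anchor
    while r > 0 and g > 0 and read[r - 1] == genome[g - 1]:
        r -= 1
        g -= 1
    ext = _extend_match(read, genome, r, g)
    return r <= 5 and len(read) - (r + ext) <= 2


def classify_transcript(
    introns: list[Intron],
    annotation: Optional[SpliceAnnotation],
    provirus_type,
    read_id: str = "read",
    locus_id: str = "",
) -> SpliceCall:
    """Name the transcript class of an intron chain.

    rec: SD2 -> SA2 on a type 2 locus. np9: the type-1 donor -> SA2 (small
    acceptor shifts, e.g. +7 after an AG->GG mutation of SA2, stay np9 with the
    offset recorded). np9_like_alternative: SD2 donor but a non-canonical
    acceptor (e.g. +260 into the 3' LTR on a type 2 locus). unspliced: no
    introns. Introns violating the GT..AG rule demote the call to unknown.
    Deterministic given (introns, annotation, provirus type).
    """
    locus_id = locus_id or (annotation.locus_id if annotation else "")
    call = SpliceCall(read_id=read_id, locus_id=locus_id, introns=list(introns))
    if not introns:
        call.transcript_class = "unspliced"
        return call
    if annotation is None or annotation.sd2 is None or annotation.sa2 is None:
        call.transcript_class = "unknown"
        call.reason = "annotation missing sd2/sa2"
        return call
    if not all(i.is_gt_ag for i in introns):
        call.transcript_class = "unknown"
        call.reason = "non-canonical intron boundaries"
        return call

    main = next((i for i in introns if i.donor == annotation.sd2), None)
    if main is None:
        call.transcript_class = "unknown"
        call.reason = "donor does not match annotated sd2"
        return call
    offset = main.acceptor - annotation.sa2
    call.acceptor_offset = offset
    if provirus_type == 2:
        call.transcript_class = "rec" if offset == 0 else "np9_like_alternative"
    elif provirus_type == 1:
        if abs(offset) <= NP9_ACCEPTOR_TOLERANCE:
            call.transcript_class = "np9"
        else:
            call.transcript_class = "np9_like_alternative"
    else:
        call.transcript_class = "unknown"
        call.reason = "provirus type unknown"
    return call


def call_splice(
    read: str,
    locus_sequence: str,
    annotation: Optional[SpliceAnnotation],
    provirus_type,
    read_id: str = "read",
    locus_id: str = "",
    min_intron: int = DEFAULT_MIN_INTRON,
) -> SpliceCall:
    """spliced_align + classify_transcript, distinguishing unspliced reads
    (contiguous match) from reads with no collinear chain (unknown)."""
    introns = spliced_align(read, locus_sequence, min_intron=min_intron)
    if not introns and not maps_contiguously(read, locus_sequence):
        call = SpliceCall(read_id=read_id, locus_id=locus_id)
        call.reason = "no collinear chain on locus"
        return call
    return classify_transcript(
        introns, annotation, provirus_type, read_id=read_id, locus_id=locus_id
    )


def splice_calls_to_frame(calls: list[SpliceCall]):
    """Tidy table of splice calls (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "read_id": [c.read_id for c in calls],
            "locus_id": [c.locus_id for c in calls],
            "transcript_class": [c.transcript_class for c in calls],
            "introns": [
                ";".join(f"{i.donor}-{i.acceptor}:{i.donor_dinucleotide}..{i.acceptor_dinucleotide}" for i in c.introns)
                for c in calls
            ],
            "acceptor_offset": [c.acceptor_offset for c in calls],
            "reason": [c.reason for c in calls],
        }
    )
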