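"""Assignment of amplicon cDNA reads to their most likely source locus.

Each read is compared, in both orientations, with every per-locus in-silico
amplicon by edit distance (read fully aligned, amplicon end gaps free, since
Sanger reads may be truncated). The call is

* ``unique``     — a single locus at minimal distance, with the runner-up more
                   than ``margin`` edits away;
* ``ambiguous``  — two or more loci tie within ``margin`` (paralogous loci with
                   too few nucleotide differences over the amplified interval);
* ``unassigned`` — the best distance exceeds ``max_distance`` (a fraction of
                   the amplicon length) or the read length is implausible.

Ambiguous calls are reported as composite categories ("locusA|locusB") and
counted as single rows downstream, never split between members.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._align import edit_distance, revcomp
from .amplicons import AmpliconProfile

#: default ambiguity margin (strict tie) and error ceiling (fraction of
#: amplicon length) absorbing Sanger/PCR error
DEFAULT_MARGIN = 0
DEFAULT_MAX_DISTANCE = 0.05

#: read length plausibility window relative to the amplicon length range
LENGTH_WINDOW = (0.5, 1.5)

UNASSIGNED_LABEL = "unassigned"


@dataclass
class AssignmentParams:
    margin: int = DEFAULT_MARGIN
    max_distance: float = DEFAULT_MAX_DISTANCE

    def __post_init__(self):
        if self.margin < 0:
            raise ValueError("margin must be >= 0")
        if not 0 < self.max_distance <= 1:
            raise ValueError("max_distance is a fraction of amplicon length in (0, 1]")


@dataclass
class ReadAssignment:
    """One read's locus call with explicit ambiguity semantics."""

    read_id: str
    orientation: str = "forward"  # or "reverse_complement"
    best_loci: tuple[str, ...] = ()
    distance: int = -1
    second_distance: int = -1
    status: str = UNASSIGNED_LABEL  # unique | ambiguous | unassigned
    reason: str = ""
    observed_variant_columns: list = field(default_factory=list)

    @property
    def category(self) -> str:
        """Row label for frequency tables: locus, composite group, or unassigned."""
        if self.status == "unique":
            return self.best_loci[0]
        if self.status == "ambiguous":
            return "|".join(sorted(self.best_loci))
        return UNASSIGNED_LABEL


def orient_read(read: str, profile: AmpliconProfile) -> tuple[str, str]:
    """Choose the read orientation minimising distance to any profile amplicon.

    The cDNA strategy is unstranded, so roughly half of all reads arrive
    reverse-complemented. Ties break toward forward. Returns
    ``(oriented_sequence, orientation)``.
    """
    if not profile.sequences:
        raise ValueError("profile has no amplicon sequences")
    rc = revcomp(read)
    d_fwd = min(edit_distance(read, amp) for amp in profile.sequences.values())
    if d_fwd == 0:
        return read, "forward"
    d_rev = min(edit_distance(rc, amp) for amp in profile.sequences.values())
    if d_rev < d_fwd:
        return rc, "reverse_complement"
    return read, "forward"


def assign_read(
    read: str,
    profile: AmpliconProfile,
    params: AssignmentParams | None = None,
    read_id: str = "read",
) -> ReadAssignment:
    """Assign one read by exhaustive pairwise comparison to all amplicons."""
    params = params or AssignmentParams()
    lo, hi = profile.length_range()
    if not (LENGTH_WINDOW[0] * lo <= len(read) <= LENGTH_WINDOW[1] * hi):
        return ReadAssignment(read_id=read_id, status=UNASSIGNED_LABEL, reason="length")

    oriented, orientation = orient_read(read, profile)
    distances = {
        locus: edit_distance(oriented, amp) for locus, amp in profile.sequences.items()
    }
    dmin = min(distances.values())
    best = tuple(l for l in profile.locus_ids if distances[l] <= dmin + params.margin)
    others = [distances[l] for l in profile.locus_ids if l not in best]
    second = min(others) if others else -1

    best_len = len(profile.sequences[best[0]])
    if dmin > params.max_distance * best_len:
        return ReadAssignment(
            read_id=read_id,
            orientation=orientation,
            best_loci=best,
            distance=dmin,
            second_distance=second,
            status=UNASSIGNED_LABEL,
            reason="distance above error ceiling",
        )

    status = "unique" if len(best) == 1 else "ambiguous"
    assignment = ReadAssignment(
        read_id=read_id,
        orientation=orientation,
        best_loci=best,
        distance=dmin,
        second_distance=second,
        status=status,
    )
    if status == "unique":
        assignment.observed_variant_columns = _observed_variants(
            oriented, best[0], profile
        )
    return assignment


def _observed_variants(read: str, locus: str, profile: AmpliconProfile) -> list:
    """Bases the read shows at the profile's diagnostic columns.

    Only computed for unique calls: the read is projected onto its locus
    amplicon, whose positions map onto anchor columns of the implied profile
    alignment. Cheap exact case only (read equal to or substring of the
    amplicon); noisy reads return an empty list rather than a fuzzy projection.
    """
    from .amplicons import diagnostic_sites

    amp = profile.sequences[locus]
    offset = amp.find(read) if len(read) <= len(amp) else -1
    if offset < 0:
        return []
    posmap = profile.position_maps()[locus]
    out = []
    for site in diagnostic_sites(profile):
        hits = [
            i for i in range(len(read)) if posmap[offset + i] == site.column
        ]
        if hits:
            out.append((site.column, read[hits[0]]))
    return out


def assign_batch(
    reads: dict[str, str] | list[tuple[str, str]],
    profile: AmpliconProfile,
    params: AssignmentParams | None = None,
) -> tuple[list[ReadAssignment], pd.DataFrame]:
    """Assign a batch of reads; returns assignments plus summary counts.

    ``reads`` maps read_id -> sequence. The summary has one row per observed
    category (locus, composite ambiguous group, unassigned) with count and
    percentage of all reads.
    """
    params = params or AssignmentParams()
    items = reads.items() if isinstance(reads, dict) else reads
    assignments = [assign_read(seq, profile, params, read_id=rid) for rid, seq in items]
    counts: dict[str, int] = {}
    for a in assignments:
        counts[a.category] = counts.get(a.category, 0) + 1
    total = len(assignments)
    summary = pd.DataFrame(
        {
            "category": list(counts),
            "count": list(counts.values()),
        }
    ).sort_values("count", ascending=False, ignore_index=True)
    summary["percent"] = 100.0 * summary["count"] / total if total else 0.0
    return assignments, summary


def assignments_to_frame(assignments: list[ReadAssignment]) -> pd.DataFrame:
    """Flatten assignments to a tidy table (TSV-ready)."""
    return pd.DataFrame(
        {
            "read_id": [a.read_id for a in assignments],
            "status": [a.status for a in assignments],
            "loci": ["|".join(sorted(a.best_loci)) for a in assignments],
            "distance": [a.distance for a in assignments],
            "second_distance": [a.second_distance for a in assignments],
            "orientation": [a.orientation for a in assignments],
            "reason": [a.reason for a in assignments],
        }
    )
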