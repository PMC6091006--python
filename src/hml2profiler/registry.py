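"""Catalogue of reference and non-reference HERV-K(HML-2) proviral loci.

A registry is the single source of locus sequence and metadata for every
downstream stage: amplicon extraction, read assignment, splice inference and
coding prediction. Reference-genome loci, non-reference polymorphic proviruses
and retrotransposed mRNA copies (retrocopies) are all first-class members,
distinguished only by their ``provenance`` tag.

Coordinates: the public metadata carries a 1-based single anchor position, the
convention used when reporting loci by a representative genomic position. All
internal sequence arithmetic elsewhere in the package is 0-based half-open;
conversion happens only at I/O boundaries.
"""
from __future__ import annotations

import difflib
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_ALPHABET = frozenset("ACGTN")
STRANDS = ("+", "-", "unknown")
PROVENANCES = ("reference", "non_reference", "retrocopy")

METADATA_COLUMNS = [
    "locus_id",
    "assembly",
    "chrom",
    "anchor_pos",
    "strand",
    "provirus_type",
    "provenance",
]


class RegistryError(ValueError):
    """Raised for malformed registry inputs or failed lookups."""


@dataclass
class LocusRecord:
    """One HML-2 locus: sequence plus reporting metadata.

    ``provirus_type`` is 1 or 2 (presence/absence of the 292-bp env 5' region
    segment) or "unknown". ``strand`` may be "unknown" because the cDNA
    strategy the registry serves is unstranded.
    """

    locus_id: str
    sequence: str
    assembly: str = "synthetic"
    chrom: str = "chrU"
    anchor_pos: int = 1
    strand: str = "unknown"
    provirus_type: int | str = "unknown"
    provenance: str = "reference"
    notes: str = ""

    def __post_init__(self) -> None:
        self.sequence = str(self.sequence).strip().upper()
        if not self.locus_id:
            raise RegistryError("locus_id must be non-empty")
        if len(self.sequence) == 0:
            raise RegistryError(f"{self.locus_id}: sequence is empty")
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise RegistryError(
                f"{self.locus_id}: invalid characters in sequence: {sorted(bad)}"
            )
        if self.strand not in STRANDS:
            raise RegistryError(f"{self.locus_id}: invalid strand {self.strand!r}")
        if self.provenance not in PROVENANCES:
            raise RegistryError(
                f"{self.locus_id}: invalid provenance {self.provenance!r}"
            )
        self.provirus_type = _normalise_type(self.provirus_type)
        self.anchor_pos = int(self.anchor_pos)
        if self.anchor_pos < 1:
            raise RegistryError(f"{self.locus_id}: anchor_pos must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)


def _normalise_type(value) -> int | str:
    if value in (1, 2):
        return int(value)
    text = str(value).strip().strip('"')
    if text in ("1", "2"):
        return int(text)
    if text in ("", "unknown", "nan", "None", "del"):
        return "unknown"
    raise RegistryError(f"invalid provirus_type {value!r}")


@dataclass
class LocusRegistry:
    """An ordered collection of :class:`LocusRecord` with unique ids."""

    records: dict[str, LocusRecord] = field(default_factory=dict)
    canonical_env_reference: str = "chr7p22.1_K-6"

    def __post_init__(self) -> None:
        if not self.records:
            raise RegistryError("registry contains no records")

    @classmethod
    def from_records(
        cls, records: Iterable[LocusRecord], canonical_env_reference: str | None = None
    ) -> "LocusRegistry":
        mapping: dict[str, LocusRecord] = {}
        for rec in records:
            if rec.locus_id in mapping:
                raise RegistryError(f"duplicate locus_id {rec.locus_id!r}")
            mapping[rec.locus_id] = rec
        if canonical_env_reference is None:
            canonical_env_reference = (
                "chr7p22.1_K-6" if "chr7p22.1_K-6" in mapping else next(iter(mapping))
            )
        if canonical_env_reference not in mapping:
            raise RegistryError(
                f"canonical_env_reference {canonical_env_reference!r} not in registry"
            )
        return cls(records=mapping, canonical_env_reference=canonical_env_reference)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[LocusRecord]:
        return iter(self.records.values())

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self.records

    @property
    def locus_ids(self) -> list[str]:
        return list(self.records)

    def by_provenance(self, provenance: str) -> list[LocusRecord]:
        return [r for r in self if r.provenance == provenance]


def get_locus(registry: LocusRegistry, locus_id: str) -> LocusRecord:
    """Exact-match lookup; unknown ids raise with near-match suggestions."""
    try:
        return registry.records[locus_id]
    except KeyError:
        near = difflib.get_close_matches(locus_id, registry.locus_ids, n=3, cutoff=0.6)
        hint = f"; did you mean {near}?" if near else ""
        raise RegistryError(f"unknown locus_id {locus_id!r}{hint}") from None


def load_registry(
    sequence_file: str | Path,
    metadata_file: str | Path,
    canonical_env_reference: str | None = None,
) -> LocusRegistry:
    """Load a registry from a multi-FASTA plus a tab-separated metadata table.

    Every FASTA identifier must have a metadata row and vice versa; a missing
    pairing is a hard error naming the identifier. Loaders tolerate CRLF line
    endings and trailing whitespace.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(sequence_file), "fasta"):
        if rec.id in seqs:
            raise RegistryError(f"duplicate FASTA identifier {rec.id!r}")
        seqs[rec.id] = str(rec.seq).strip()
    if not seqs:
        raise RegistryError(f"no records in {sequence_file}")

    meta = pd.read_csv(
        metadata_file, sep="\t", dtype=str, comment="#", skip_blank_lines=True
    )
    meta.columns = [c.strip() for c in meta.columns]
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise RegistryError(f"metadata is missing columns {missing_cols}")
    meta = meta.fillna("")
    meta_ids = [str(x).strip() for x in meta["locus_id"]]

    only_fasta = sorted(set(seqs) - set(meta_ids))
    only_meta = sorted(set(meta_ids) - set(seqs))
    if only_fasta:
        raise RegistryError(f"no metadata row for FASTA identifier(s) {only_fasta}")
    if only_meta:
        raise RegistryError(f"no FASTA sequence for metadata row(s) {only_meta}")

    records = []
    for _, row in meta.iterrows():
        locus_id = str(row["locus_id"]).strip()
        records.append(
            LocusRecord(
                locus_id=locus_id,
                sequence=seqs[locus_id],
                assembly=str(row["assembly"]).strip(),
                chrom=str(row["chrom"]).strip(),
                anchor_pos=int(str(row["anchor_pos"]).strip()),
                strand=str(row["strand"]).strip() or "unknown",
                provirus_type=str(row["provirus_type"]).strip() or "unknown",
                provenance=str(row["provenance"]).strip() or "reference",
                notes=str(row.get("notes", "")).strip(),
            )
        )
    return LocusRegistry.from_records(records, canonical_env_reference)


def write_registry(
    registry: LocusRegistry,
    sequence_file: str | Path,
    metadata_file: str | Path,
) -> None:
    """Write a registry back to multi-FASTA + metadata TSV (round-trip safe)."""
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=rec.locus_id, description="")
        for rec in registry
    ]
    with open(sequence_file, "w") as handle:
        SeqIO.write(seq_records, handle, "fasta")
    rows = [
        {
            "locus_id": rec.locus_id,
            "assembly": rec.assembly,
            "chrom": rec.chrom,
            "anchor_pos": rec.anchor_pos,
            "strand": rec.strand,
            "provirus_type": rec.provirus_type,
            "provenance": rec.provenance,
            "notes": rec.notes,
        }
        for rec in registry
    ]
    pd.DataFrame(rows).to_csv(metadata_file, sep="\t", index=False)


def check_provirus_types(
    registry: LocusRegistry, reference_type2_env5prime: str
) -> dict[str, tuple]:
    """Check declared provirus types against sequence-based classification.

    Loci whose sequence covers the env 5' indel region are re-classified from
    sequence (see :func:`hml2profiler.amplicons.classify_provirus_type`);
    mismatches between the declared and inferred type produce a warning and are
    returned as ``{locus_id: (declared, inferred)}``.
    """
    from ._align import local_alignment_blocks
    from .amplicons import classify_provirus_type

    mismatches: dict[str, tuple] = {}
    for rec in registry:
        if rec.provirus_type == "unknown":
            continue
        blocks = local_alignment_blocks(rec.sequence, reference_type2_env5prime)
        if not blocks:
            continue
        lo = max(0, blocks[0][0][0] - 10)
        hi = min(len(rec.sequence), blocks[-1][0][1] + 10)
        try:
            inferred = classify_provirus_type(rec.sequence[lo:hi], reference_type2_env5prime)
        except ValueError:
            continue
        if inferred != "unknown" and inferred != rec.provirus_type:
            mismatches[rec.locus_id] = (rec.provirus_type, inferred)
    if mismatches:
        warnings.warn(
            f"provirus_type metadata disagrees with sequence for {sorted(mismatches)}",
            stacklevel=2,
        )
    return mismatches


def registry_to_fasta_string(registry: LocusRegistry) -> str:
    buf = io.StringIO()
    for rec in registry:
        buf.write(f">{rec.locus_id}\n{rec.sequence}\n")
    return buf.getvalue()
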