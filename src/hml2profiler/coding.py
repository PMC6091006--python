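"""Prediction of env-region protein products of transcribed loci.

The canonical full-length Env precursor (699 aa, ~79 kDa, encoded by type 2
loci) is processed into a stable signal peptide (SP, N-terminal 96 aa,
~13 kDa on gels), a surface/outer-membrane domain (SU/OM, ~41 kDa) and a
transmembrane domain (TM, ~26 kDa) released by furin cleavage. Most loci do
not encode the full precursor: premature stops, N-terminal truncations
(type 1 loci lack the 292-bp env 5' segment and can only encode an Env variant
starting near the deletion junction), upstream in-frame extensions (Pol-Env
fusions) and spliced products (Rec from type 2, Np9 from type 1, truncated and
chimeric variants) make up the realistic repertoire.

This module scans loci for ORFs overlapping the env region, maps them onto
canonical Env coordinates, annotates cleavage products with average-mass
estimates, and predicts the protein encoded by a classified splice call.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio.Seq import Seq

from ._align import local_alignment_blocks, protein_identity

MIN_ORF_AA = 50
FUSION_MIN_UPSTREAM_AA = 30
PREMATURE_STOP_MAX_CODON = 25

#: average residue masses (Da); protein mass = sum(residues) + one water
WATER_DA = 18.01528
RESIDUE_MASS_DA = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

ORF_CLASSES = (
    "full_length_env",
    "type1_env",
    "SU_OM_fragment",
    "SP_SU_OM_fragment",
    "TM_fragment",
    "pol_env_fusion",
    "other",
)

PROTEIN_CLASSES = (
    "Env_canonical",
    "Env_type1",
    "Rec",
    "Rec_truncated",
    "Np9",
    "chimeric_env_rec_np9",
    "none",
)


@dataclass
class DomainMap:
    """Cleavage architecture of canonical Env (1-based aa coordinates).

    ``sp_end_aa``: last residue of the signal peptide (SPPase site).
    ``furin_site_aa``: last residue of SU/OM (furin cleaves after it); the
    default is derived from the ~41/~26 kDa SU/TM mass split of the 699-aa
    precursor, and is a user-overridable parameter since the exact position is
    not part of the published architecture.
    """

    sp_end_aa: int = 96
    furin_site_aa: int = 463
    tm_cytoplasmic_tail_start_aa: int = 650
    env_length_aa: int = 699

    def __post_init__(self):
        if not 0 < self.sp_end_aa < self.furin_site_aa < self.env_length_aa:
            raise ValueError("require 0 < sp_end_aa < furin_site_aa < env length")


@dataclass
class OrfAnnotation:
    """One ORF overlapping the env region, mapped to canonical Env."""

    locus_id: str
    frame_offset: int
    nt_span: tuple[int, int]  # half-open on the locus
    aa_length: int
    aa_sequence: str
    alignment_to_canonical: tuple[int, int]  # 1-based inclusive aa on canonical Env
    orf_class: str = "other"
    predicted_mass_kDa: float = 0.0
    upstream_extension_aa: int = 0  # residues upstream of the env alignment (fusions)
    env_overlap_aa: int = 0


@dataclass
class ProteinProduct:
    """A cleavage product of an Env(-like) ORF."""

    name: str  # SP | SU_OM | TM
    canonical_span: tuple[int, int]
    aa_sequence: str
    predicted_mass_kDa: float


@dataclass
class ProteinPrediction:
    """Protein predicted from an in-silico spliced transcript."""

    protein_class: str
    aa_sequence: str = ""
    source_transcript_class: str = ""
    domain_hits: dict = field(default_factory=dict)
    truncation_note: str = ""
    stop_position: Optional[int] = None
    reason: str = ""


def protein_mass(aa_sequence: str) -> float:
    """Protein mass in kDa: sum of average residue masses plus one water.

    The empty chain returns the mass of water (0.018 kDa); a single glycine
    0.075 kDa. Unknown residues raise.
    """
    total = WATER_DA
    for residue in aa_sequence.upper():
        try:
            total += RESIDUE_MASS_DA[residue]
        except KeyError:
            raise ValueError(f"unknown residue {residue!r}") from None
    return total / 1000.0


def _cds_position_map(locus_sequence: str, canonical_env_cds: str) -> dict[int, int]:
    """locus position -> canonical CDS position for aligned columns.

    Uses a local alignment so that only the genuinely env-homologous part of
    the locus maps; upstream fusions and flanking sequence stay unmapped.
    """
    mapping: dict[int, int] = {}
    for (ls, le), (cs, _) in local_alignment_blocks(locus_sequence, canonical_env_cds):
        for i in range(le - ls):
            mapping[ls + i] = cs + i
    return mapping


def scan_env_orfs(
    locus_sequence: str,
    canonical_env_cds: str,
    provirus_type="unknown",
    locus_id: str = "locus",
    domain_map: Optional[DomainMap] = None,
    min_aa: int = MIN_ORF_AA,
    indel_aa_interval: Optional[tuple[int, int]] = None,
) -> list[OrfAnnotation]:
    """All ORFs >= ``min_aa`` overlapping the env region of a locus.

    An ORF is a maximal run of non-stop codons bounded by stops or the
    sequence ends (so no reported ORF is extendable), scanned in the three
    forward frames. Each ORF is mapped onto canonical Env coordinates and
    classified: ``full_length_env`` spans aa 1-699 on a type 2 locus;
    ``type1_env`` starts near the 292-bp deletion junction of a type 1 locus
    and reaches the TM region; fusions extend >= 30 aa upstream of the env
    alignment; fragments are classed by the domains their span covers.
    ``indel_aa_interval`` gives the segment's canonical-Env aa interval
    (defaults to ending at the junction implied by a 292-nt deletion being
    absent from type 1 loci — callers with annotated references should pass it).
    """
    dm = domain_map or DomainMap()
    seq = locus_sequence.upper()
    cds_map = _cds_position_map(seq, canonical_env_cds)
    if not cds_map:
        return []
    env_lo, env_hi = min(cds_map), max(cds_map) + 1
    if indel_aa_interval is None:
        indel_aa_interval = (dm.sp_end_aa, dm.sp_end_aa + 98)  # 292 nt ~ 97 codons

    orfs: list[OrfAnnotation] = []
    for frame in range(3):
        n_codons = (len(seq) - frame) // 3
        if n_codons < min_aa:
            continue
        protein = str(Seq(seq[frame : frame + 3 * n_codons]).translate())
        start = 0
        for segment in protein.split("*"):
            if len(segment) >= min_aa:
                nt_start = frame + 3 * start
                nt_end = nt_start + 3 * len(segment)
                if nt_end > env_lo and nt_start < env_hi:
                    orf = _annotate_orf(
                        locus_id, frame, nt_start, nt_end, segment, cds_map,
                        provirus_type, dm, indel_aa_interval,
                    )
                    orfs.append(orf)
            start += len(segment) + 1
    return sorted(orfs, key=lambda o: (o.nt_span[0], o.frame_offset))


def _annotate_orf(
    locus_id, frame, nt_start, nt_end, aa_sequence, cds_map,
    provirus_type, dm: DomainMap, indel_aa,
) -> OrfAnnotation:
    # an ORF codon counts as canonically mapped only when its three bases align
    # to one complete, in-frame canonical codon; off-frame ORFs overlapping the
    # env region are reported but carry no canonical span
    mapped_aa = []
    first_mapped_codon = None
    for k, q in enumerate(range(nt_start, nt_end, 3)):
        cds = [cds_map.get(q + i) for i in range(3)]
        if (
            None not in cds
            and cds[1] == cds[0] + 1
            and cds[2] == cds[0] + 2
            and cds[0] % 3 == 0
        ):
            mapped_aa.append(cds[0] // 3 + 1)
            if first_mapped_codon is None:
                first_mapped_codon = k
    # scattered sub-15-codon alignment islands (random similarity picked up by
    # the free-end-gap CDS alignment) do not constitute a canonical mapping
    if len(mapped_aa) < 15:
        mapped_aa = []
    if mapped_aa:
        start_aa, end_aa = min(mapped_aa), max(mapped_aa)
        upstream_ext = first_mapped_codon
    else:
        start_aa = end_aa = 0
        upstream_ext = 0
    in_span = mapped_aa
    env_overlap = end_aa - start_aa + 1 if mapped_aa else 0

    orf_class = "other"
    if in_span:
        if upstream_ext >= FUSION_MIN_UPSTREAM_AA:
            orf_class = "pol_env_fusion"
        elif provirus_type == 2 and start_aa <= 1 and end_aa >= dm.env_length_aa:
            orf_class = "full_length_env"
        elif (
            provirus_type == 1
            and indel_aa[1] - 2 <= start_aa <= indel_aa[1] + 40
            and end_aa >= dm.furin_site_aa + 30
        ):
            orf_class = "type1_env"
        elif start_aa > dm.furin_site_aa:
            orf_class = "TM_fragment"
        elif end_aa <= dm.furin_site_aa + 30 and end_aa > dm.sp_end_aa:
            orf_class = "SU_OM_fragment"
        elif start_aa <= dm.sp_end_aa and end_aa > dm.furin_site_aa + 30:
            orf_class = "SP_SU_OM_fragment" if end_aa < dm.env_length_aa else "other"

    return OrfAnnotation(
        locus_id=locus_id,
        frame_offset=frame,
        nt_span=(nt_start, nt_end),
        aa_length=len(aa_sequence),
        aa_sequence=aa_sequence,
        alignment_to_canonical=(start_aa, end_aa),
        orf_class=orf_class,
        predicted_mass_kDa=protein_mass(aa_sequence),
        upstream_extension_aa=upstream_ext,
        env_overlap_aa=env_overlap,
    )


def annotate_domains(orf: OrfAnnotation, domain_map: Optional[DomainMap] = None) -> list[ProteinProduct]:
    """Cleavage products (SP, SU/OM, TM) of an ORF, restricted to its span.

    Products are the intersections of the ORF's canonical-Env span with
    SP = aa 1..sp_end, SU/OM = sp_end+1..furin, TM = furin+1..end; each gets a
    predicted average mass. An ORF not reaching a domain yields no product for
    it (e.g. a span of aa 120-436 has no SP).
    """
    dm = domain_map or DomainMap()
    start_aa, end_aa = orf.alignment_to_canonical
    if end_aa == 0:
        return []
    domains = [
        ("SP", 1, dm.sp_end_aa),
        ("SU_OM", dm.sp_end_aa + 1, dm.furin_site_aa),
        ("TM", dm.furin_site_aa + 1, dm.env_length_aa),
    ]
    products = []
    for name, lo, hi in domains:
        s, e = max(start_aa, lo), min(end_aa, hi)
        if s > e:
            continue
        # residue index of canonical aa k within the ORF sequence
        idx0 = orf.upstream_extension_aa + (s - start_aa)
        seq = orf.aa_sequence[idx0 : idx0 + (e - s + 1)]
        products.append(
            ProteinProduct(
                name=name,
                canonical_span=(s, e),
                aa_sequence=seq,
                predicted_mass_kDa=protein_mass(seq),
            )
        )
    return products


def splice_transcript(locus_sequence: str, introns) -> str:
    """Remove introns ([donor, acceptor) intervals) from a locus sequence."""
    seq = locus_sequence
    for intron in sorted(introns, key=lambda i: i.donor, reverse=True):
        seq = seq[: intron.donor] + seq[intron.acceptor :]
    return seq


def predict_spliced_protein(
    locus_sequence: str,
    splice_call,
    annotation,
    references: dict[str, str],
    min_identity: float = 0.95,
    chimera_identity: float = 0.60,
    rec_domains: Optional[dict[str, tuple[int, int]]] = None,
) -> ProteinPrediction:
    """Translate an in-silico spliced transcript and class the protein.

    ``references`` supplies canonical Rec, Np9 and Env amino-acid sequences
    ({"rec": .., "np9": .., "env": ..}). The transcript is spliced according to
    the call's introns and translated from the annotated Env/Rec/Np9 start.
    A premature stop within the first 25 codons yields class "none" with the
    stop codon's position recorded (e.g. a retrotransposed rec mRNA with a stop
    at codon 19 encodes nothing). Rec_truncated must be a proper N-terminal
    prefix of Rec; chimeric calls require both terminal halves to match their
    respective references at >= 60% identity over >= 30 aa.
    """
    if splice_call.transcript_class == "unknown":
        raise ValueError("cannot predict protein from an unknown splice call")
    if annotation is None or annotation.env_start is None:
        return ProteinPrediction(protein_class="none", reason="no env start annotated")

    mrna = splice_transcript(locus_sequence, splice_call.introns)
    start = annotation.env_start - sum(
        i.length for i in splice_call.introns if i.acceptor <= annotation.env_start
    )
    if mrna[start : start + 3] != "ATG":
        return ProteinPrediction(protein_class="none", reason="start codon absent")

    coding = mrna[start:]
    coding = coding[: 3 * (len(coding) // 3)]
    translated = str(Seq(coding).translate())
    stop_at = translated.find("*")
    protein = translated if stop_at < 0 else translated[:stop_at]
    prediction = ProteinPrediction(
        protein_class="none",
        aa_sequence=protein,
        source_transcript_class=splice_call.transcript_class,
    )
    if 0 <= stop_at <= PREMATURE_STOP_MAX_CODON - 1:
        prediction.stop_position = stop_at + 1  # 1-based codon index of the stop
        prediction.reason = f"premature stop at codon {stop_at + 1}"
        return prediction

    rec, np9, env = references.get("rec", ""), references.get("np9", ""), references.get("env", "")
    if env and (protein == env or (abs(len(protein) - len(env)) <= 2 and protein_identity(protein, env) >= min_identity)):
        prediction.protein_class = "Env_canonical"
    elif rec and (protein == rec or (abs(len(protein) - len(rec)) <= 2 and protein_identity(protein, rec) >= min_identity)):
        prediction.protein_class = "Rec"
    elif rec and len(protein) < len(rec) and rec.startswith(protein):
        prediction.protein_class = "Rec_truncated"
        prediction.truncation_note = f"lacks the C-terminal {len(rec) - len(protein)} aa of Rec"
    elif np9 and (protein == np9 or (abs(len(protein) - len(np9)) <= 2 and protein_identity(protein, np9) >= min_identity)):
        prediction.protein_class = "Np9"
    elif _is_chimeric(protein, rec, np9, env, chimera_identity):
        prediction.protein_class = "chimeric_env_rec_np9"
    else:
        prediction.reason = "no reference match"

    if rec_domains and prediction.protein_class in ("Rec", "Rec_truncated"):
        for name, (lo, hi) in rec_domains.items():
            prediction.domain_hits[name] = len(protein) >= hi
    return prediction


def _is_chimeric(protein: str, rec: str, np9: str, env: str, threshold: float) -> bool:
    if len(protein) < 60 or not env:
        return False
    half = len(protein) // 2
    n_half, c_half = protein[:half], protein[half:]
    if len(n_half) < 30 or len(c_half) < 30:
        return False
    n_ok = any(
        protein_identity(n_half, ref[: max(len(n_half), 30)]) >= threshold
        for ref in (rec, np9)
        if ref
    )
    c_ok = protein_identity(c_half, env[-max(len(c_half), 30):]) >= threshold
    return n_ok and c_ok
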