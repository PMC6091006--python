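"""Synthetic paralog families, amplicon read sets, splice fixtures and Ct tables.

Every fixture the pipeline needs is generated here, with known ground truth
and no downloads. The generator emulates the structure of a young
multi-copy provirus group as seen through the three profiling amplicons:

* one ancestral provirus (~3.8 kb here; LTRs, a gag segment carrying the
  ~620-nt gag amplicon, and an env region carrying the 292-bp type 1/2
  segment with the rec splice donor SD2 inside it, the canonical acceptor SA2
  just upstream of the 3' LTR, an alternative acceptor 260 nt downstream
  inside the 3' LTR, a +7 acceptor used when SA2 is mutated, and a complete
  699-codon env ORF);
* ~20 descendant loci with per-locus planted substitutions giving a pairwise
  spread of roughly 1-40 differences over the gag amplicon, optionally
  including one pair with identical amplicons (forced ambiguity) and one
  retrotransposed rec-mRNA locus with a stop at Rec codon 19;
* reads drawn multinomially from skewed mixing proportions (dominant locus
  ~53% of reads, top four ~80%), substitution errors at a Sanger-like
  per-base rate, ~50% reverse-complemented (unstranded cDNA);
* Ct tables consistent with the 2^-ddCt model around a designated
  high-expression reference sample.

Substitutions are placed uniformly at random excluding primer sites and the
planted functional elements (splice dinucleotides, start/stop codons), and are
resampled if they would introduce a stop into the env reading frame, so
fixture loci never lose their amplicons or ORFs by accident. A fixed seed
gives byte-identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from ._align import revcomp
from .amplicons import AmpliconDefinition, AmpliconProfile, Primer, PrimerSet, extract_amplicons
from .coding import DomainMap
from .registry import LocusRecord, LocusRegistry
from .splicing import Intron, SpliceAnnotation
from .quantify import SampleMeta

# ---------------------------------------------------------------------------
# ancestor layout (0-based half-open intervals on the type-2 ancestor)

LTR5 = (0, 300)
SD1 = 345                      # GT at [345, 347)
GAG_F_SITE = (360, 380)
GAG_R_SITE = (960, 980)        # gag product = [360, 980), 620 nt
ENV_STOP_BEFORE = (1247, 1250)  # TAA: the codon before the env start is a stop
ENV_START = 1250               # shared Env/Rec/Np9 ATG; also the forward primer site
ENV_F_SITE = (1250, 1270)
TYPE1_ORF_STOP = (1396, 1399)  # stop bounding the type-1 Env ORF at the junction
SEGMENT = (1400, 1692)         # the 292-bp segment distinguishing type 1/2
SD2 = 1514                     # rec donor, GT at [1514, 1516), inside the segment
NP9_DONOR_ANC = 1692           # GT at [1692, 1694): the type-1 donor at the junction
TYPE1_ENV_ATG = (1694, 1697)
ENV600_R_SITE = (1850, 1870)   # env600nt product = [1250, 1870): 620 nt (type 2)
ENV_CDS = (1250, 3347)         # 699 codons; stop at [3347, 3350)
ENV_STOP = (3347, 3350)
SA2 = 3390                     # first exonic base after the rec intron; AG at [3388, 3390)
K111_AG = (3395, 3397)         # the +7 acceptor used when SA2's AG is mutated
REC_STOP = (3441, 3444)        # rec exon 3: 17 codons after SA2, then TAA
LTR3_START = 3420
ALT_AG = (3648, 3650)          # alternative acceptor 260 nt downstream of SA2
ALT_STOP = (3650, 3653)        # in-frame stop right after the alternative junction
REC_R_SITE = (3690, 3710)
ANCESTOR_LENGTH = 3800

#: planted primer-site sequences (constants, so primer sets are stable)
GAG_F_PRIMER = "ACGTACGGTTCAGACCTAGC"
GAG_R_SITE_SEQ = "TCCGATGGCAATCCTGAACG"
ENV_F_PRIMER = "ATGGCACTTCAGAGGCTTAC"   # starts with the env ATG
ENV600_R_SITE_SEQ = "GGATTCCTGATCAAGTGGCA"
REC_R_SITE_SEQ = "CCTGAGTACGGATCAGTCCA"

_PROTECTED = [
    (SD1, SD1 + 2),
    GAG_F_SITE,
    GAG_R_SITE,
    ENV_STOP_BEFORE,
    ENV_F_SITE,
    (TYPE1_ORF_STOP[0], SEGMENT[0] + 2),
    (SD2 - 3, SD2 + 5),
    (NP9_DONOR_ANC - 3, TYPE1_ENV_ATG[1] + 3),
    ENV600_R_SITE,
    ENV_STOP,
    (SA2 - 5, K111_AG[1] + 3),
    REC_STOP,
    (ALT_AG[0] - 3, ALT_STOP[1] + 3),
    REC_R_SITE,
]

STOP_CODONS = {"TAA", "TAG", "TGA"}
BASES = np.array(list("ACGT"))

DEFAULT_MIXING = (0.53, 0.12, 0.10, 0.05)  # dominant + next three; rest share equally


@dataclass
class SimulationConfig:
    """The stated world of the synthetic fixtures.

    Defaults mirror the published survey: 20 loci, a ~620-nt gag amplicon
    with 0-38 pairwise differences, one identical pair, one retrocopy, a
    dominant locus at 53% of reads with the top four at 80%, 820 reads over
    28 pseudo-samples (about 29 per sample) and a Sanger-like 0.2% per-base
    substitution error.
    """

    n_loci: int = 20
    substitution_rate: float = 0.005  # background per-base rate outside amplicon design
    type2_fraction: float = 0.5
    indel_length: int = 292
    identical_pair: bool = True
    retrocopy: bool = True
    read_error_rate: float = 0.002
    n_reads: int = 820
    reads_per_sample: int = 29
    mixing_proportions: Optional[tuple] = None
    unstranded: bool = True
    primer_bias: Optional[dict] = None
    seed: int = 0

    def __post_init__(self):
        if self.identical_pair and self.n_loci < 2:
            raise ValueError("identical_pair requires n_loci >= 2")
        if not 0 <= self.read_error_rate <= 1:
            raise ValueError("read_error_rate must lie in [0, 1]")
        if not 0 <= self.substitution_rate <= 1:
            raise ValueError("substitution_rate must lie in [0, 1]")
        if self.mixing_proportions is not None:
            p = np.asarray(self.mixing_proportions, dtype=float)
            if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
                raise ValueError("mixing_proportions must be non-negative and sum to 1")

    def proportions(self, n: int) -> np.ndarray:
        if self.mixing_proportions is not None:
            p = np.asarray(self.mixing_proportions, dtype=float)
            if len(p) != n:
                raise ValueError(f"mixing_proportions has {len(p)} entries for {n} loci")
            return p
        head = np.array(DEFAULT_MIXING[: min(len(DEFAULT_MIXING), n)])
        rest = n - len(head)
        if rest <= 0:
            return head[:n] / head[:n].sum()
        tail = np.full(rest, (1.0 - head.sum()) / rest)
        return np.concatenate([head, tail])


@dataclass
class SyntheticFamily:
    """A simulated paralog family plus everything needed to analyse it."""

    registry: LocusRegistry
    truth: pd.DataFrame
    annotations: dict[str, SpliceAnnotation]
    definitions: dict[str, AmpliconDefinition]
    references: dict[str, str]  # env_cds, env, rec, np9 (aa except env_cds)
    domain_map: DomainMap
    indel_aa_interval: tuple[int, int]
    config: SimulationConfig
    ancestor: str = ""

    def profile(self, amplicon: str = "gag") -> AmpliconProfile:
        return extract_amplicons(self.registry, self.definitions[amplicon])


def _random_nonstop_codons(rng: np.random.Generator, n: int) -> str:
    codons = []
    while len(codons) < n:
        c = "".join(rng.choice(BASES, size=3))
        if c not in STOP_CODONS:
            codons.append(c)
    return "".join(codons)


def _plant(seq: list, interval: tuple[int, int], text: str) -> None:
    s, e = interval
    assert e - s == len(text)
    seq[s:e] = list(text)


def build_ancestor(rng: np.random.Generator) -> str:
    """The type-2 ancestral provirus with all functional elements planted."""
    seq = list("".join(rng.choice(BASES, size=ANCESTOR_LENGTH)))
    # env ORF: 699 non-stop codons framed by stops
    _plant(seq, ENV_CDS, _random_nonstop_codons(rng, 699))
    _plant(seq, ENV_STOP_BEFORE, "TAA")
    _plant(seq, ENV_STOP, "TAA")
    # primer sites
    _plant(seq, GAG_F_SITE, GAG_F_PRIMER)
    _plant(seq, GAG_R_SITE, GAG_R_SITE_SEQ)
    _plant(seq, ENV_F_SITE, ENV_F_PRIMER)
    _plant(seq, ENV600_R_SITE, ENV600_R_SITE_SEQ)
    _plant(seq, REC_R_SITE, REC_R_SITE_SEQ)
    # splice sites (rec/np9 biology)
    _plant(seq, (SD1, SD1 + 2), "GT")
    _plant(seq, (SD2, SD2 + 2), "GT")
    _plant(seq, (NP9_DONOR_ANC, NP9_DONOR_ANC + 2), "GT")
    _plant(seq, TYPE1_ENV_ATG, "ATG")
    # in the type-1 reading frame at the junction, a stop immediately upstream
    # bounds the type-1 Env ORF (the planted TAA is not a stop in the env frame)
    _plant(seq, TYPE1_ORF_STOP, "TAA")
    _plant(seq, (SA2 - 2, SA2), "AG")
    _plant(seq, (ALT_AG[0], ALT_AG[1]), "AG")
    _plant(seq, ALT_STOP, "TAA")
    # rec exon 3: 17 non-stop codons after SA2, then a stop; the +7 acceptor AG
    # sits inside the exon and must be planted after it (xxA / Gxx: no stops)
    _plant(seq, (SA2, REC_STOP[0]), _random_nonstop_codons(rng, 17))
    _plant(seq, REC_STOP, "TAA")
    _plant(seq, K111_AG, "AG")
    _fix_env_frame(seq, rng)
    return "".join(seq)


def _fix_env_frame(seq: list, rng: np.random.Generator) -> None:
    """Remove stop codons the planting may have introduced into the env frame."""
    protected = _protected_mask()
    for start in range(ENV_CDS[0], ENV_CDS[1], 3):
        while "".join(seq[start : start + 3]) in STOP_CODONS:
            free = [p for p in range(start, start + 3) if not protected[p]]
            if not free:  # planted elements never form stops by construction
                raise AssertionError("stop codon inside a fully protected interval")
            p = int(rng.choice(free))
            seq[p] = str(rng.choice(BASES))


def _protected_mask() -> np.ndarray:
    mask = np.zeros(ANCESTOR_LENGTH, dtype=bool)
    for s, e in _PROTECTED:
        mask[s:e] = True
    return mask


def _substitute(
    seq: list, rng: np.random.Generator, positions: np.ndarray
) -> list[tuple[int, str, str]]:
    """Apply substitutions at the given ancestor positions; returns the events.

    Substitutions landing in the env frame are re-drawn if they would create a
    stop codon.
    """
    events = []
    for pos in positions:
        pos = int(pos)
        old = seq[pos]
        choices = [b for b in "ACGT" if b != old]
        rng.shuffle(choices)
        placed = None
        for new in choices:
            if ENV_CDS[0] <= pos < ENV_CDS[1]:
                cstart = ENV_CDS[0] + 3 * ((pos - ENV_CDS[0]) // 3)
                codon = seq[cstart : cstart + 3]
                codon[pos - cstart] = new
                if "".join(codon) in STOP_CODONS:
                    continue
            placed = new
            break
        if placed is None:
            continue
        seq[pos] = placed
        events.append((pos, old, placed))
    return events


def _amplicon_regions() -> list[tuple[int, int]]:
    """Ancestor intervals covered by any amplicon (used by the identical pair)."""
    return [
        (GAG_F_SITE[0], GAG_R_SITE[1]),
        (ENV_F_SITE[0], ENV600_R_SITE[1]),
        (SA2, REC_R_SITE[1]),
    ]


def _make_definitions(max_mismatches: int = 1) -> dict[str, AmpliconDefinition]:
    def mix(site: str) -> tuple[Primer, ...]:
        # a two-member degenerate mix: the planted site plus a 1-off variant
        variant = ("A" if site[10] != "A" else "C") + site[11:]
        return (
            Primer(site, ratio=5.0, name="exact"),
            Primer(site[:10] + variant, ratio=1.0, name="variant"),
        )

    gag = PrimerSet(
        name="gag",
        forward=mix(GAG_F_PRIMER),
        reverse=(Primer(revcomp(GAG_R_SITE_SEQ), 1.0, "gagR"),),
        max_mismatches=max_mismatches,
    )
    env600 = PrimerSet(
        name="env600nt",
        forward=mix(ENV_F_PRIMER),
        reverse=(Primer(revcomp(ENV600_R_SITE_SEQ), 1.0, "env600R"),),
        max_mismatches=max_mismatches,
    )
    rec_np9 = PrimerSet(
        name="rec_np9",
        forward=mix(ENV_F_PRIMER),
        reverse=(Primer(revcomp(REC_R_SITE_SEQ), 1.0, "recR"),),
        max_mismatches=max_mismatches,
    )
    return {
        "gag": AmpliconDefinition(
            "gag", gag, {1: (550, 700), 2: (550, 700), "unknown": (550, 700)}
        ),
        "env600nt": AmpliconDefinition("env600nt", env600, {1: (280, 400), 2: (560, 700)}),
        "rec_np9": AmpliconDefinition("rec_np9", rec_np9, {1: (300, 550), 2: (400, 700)}),
    }


def _annotation_for(locus_id: str, provirus_type) -> SpliceAnnotation:
    if provirus_type == 2:
        return SpliceAnnotation(
            locus_id=locus_id, sd2=SD2, sa2=SA2, sd1=SD1,
            lstart_3ltr=LTR3_START, env_start=ENV_START,
        )
    shift = SEGMENT[1] - SEGMENT[0]
    return SpliceAnnotation(
        locus_id=locus_id, sd2=SEGMENT[0], sa2=SA2 - shift, sd1=SD1,
        lstart_3ltr=LTR3_START - shift, env_start=ENV_START,
    )


def simulate_locus_family(config: SimulationConfig) -> SyntheticFamily:
    """Generate a paralog family with planted, fully recorded differences.

    Locus i receives i substitutions inside the gag amplicon (pairwise gag
    differences therefore span ~1 to 2*(n_loci-1)) plus background
    substitutions elsewhere at ``substitution_rate``. Locus 1 is forced to
    type 2 with no substitutions and acts as the canonical full-length
    reference. With ``identical_pair`` the last two loci share all
    substitutions inside amplicon regions and differ only outside them; with
    ``retrocopy`` an extra locus represents a retrotransposed rec mRNA
    (spliced, flanking-promoter driven) carrying a stop at Rec codon 19.
    """
    rng = np.random.default_rng(config.seed)
    ancestor = build_ancestor(rng)
    protected = _protected_mask()
    gag_region = np.arange(GAG_F_SITE[0], GAG_R_SITE[1])
    gag_allowed = gag_region[~protected[gag_region]]
    everywhere = np.arange(ANCESTOR_LENGTH)
    bg_allowed = everywhere[~protected]
    amp_regions = _amplicon_regions()

    types = [2 if rng.random() < config.type2_fraction else 1 for _ in range(config.n_loci)]
    types[0] = 2  # canonical full-length reference
    if config.identical_pair:
        types[-1] = types[-2]

    records: list[LocusRecord] = []
    annotations: dict[str, SpliceAnnotation] = {}
    truth_rows = []
    pair_events: list[tuple[int, str, str]] = []

    for i in range(config.n_loci):
        locus_id = f"locus{i + 1:02d}"
        seq = list(ancestor)
        events: list[tuple[int, str, str]] = []
        if i == 0:
            pass  # canonical reference: no substitutions
        elif config.identical_pair and i == config.n_loci - 1:
            # replay the previous locus's substitutions inside amplicon regions,
            # then add private differences outside them
            inside = [
                ev for ev in pair_events
                if any(s <= ev[0] < e for s, e in amp_regions)
            ]
            for pos, _, new in inside:
                seq[pos] = new
            events.extend(inside)
            outside = bg_allowed[
                ~np.isin(bg_allowed, gag_region)
                & ~np.array([any(s <= p < e for s, e in amp_regions) for p in bg_allowed])
            ]
            extra = rng.choice(outside, size=3, replace=False)
            events.extend(_substitute(seq, rng, extra))
        else:
            n_gag = i
            gag_pos = rng.choice(gag_allowed, size=n_gag, replace=False)
            events.extend(_substitute(seq, rng, np.sort(gag_pos)))
            n_bg = rng.binomial(len(bg_allowed) - len(gag_allowed), config.substitution_rate)
            bg_pool = bg_allowed[~np.isin(bg_allowed, gag_region)]
            bg_pos = rng.choice(bg_pool, size=n_bg, replace=False)
            events.extend(_substitute(seq, rng, np.sort(bg_pos)))
            if config.identical_pair and i == config.n_loci - 2:
                pair_events = list(events)

        if types[i] == 1:
            seq = seq[: SEGMENT[0]] + seq[SEGMENT[1] :]
        records.append(
            LocusRecord(
                locus_id=locus_id,
                sequence="".join(seq),
                assembly="synthetic",
                chrom="chrS",
                anchor_pos=1000 * (i + 1),
                strand="+",
                provirus_type=types[i],
                provenance="reference",
            )
        )
        annotations[locus_id] = _annotation_for(locus_id, types[i])
        truth_rows.append(
            {
                "locus_id": locus_id,
                "provirus_type": types[i],
                "provenance": "reference",
                "n_substitutions": len(events),
                "n_gag_substitutions": sum(
                    1 for ev in events if GAG_F_SITE[0] <= ev[0] < GAG_R_SITE[1]
                ),
                "substitutions": ";".join(f"{p}{o}>{n}" for p, o, n in events),
            }
        )

    if config.retrocopy:
        locus_id = "locus_retro"
        retro = _build_retrocopy(ancestor, rng)
        records.append(
            LocusRecord(
                locus_id=locus_id,
                sequence=retro,
                assembly="synthetic",
                chrom="chrS",
                anchor_pos=1000 * (config.n_loci + 1),
                strand="+",
                provirus_type=2,
                provenance="retrocopy",
                notes="retrotransposed rec mRNA; stop at Rec codon 19",
            )
        )
        exon1 = SD1
        annotations[locus_id] = SpliceAnnotation(
            locus_id=locus_id, env_start=exon1, lstart_3ltr=exon1 + (SD2 - ENV_START) + (LTR3_START - SA2)
        )
        truth_rows.append(
            {
                "locus_id": locus_id,
                "provirus_type": 2,
                "provenance": "retrocopy",
                "n_substitutions": 2,
                "n_gag_substitutions": 0,
                "substitutions": "private exon2 differences",
            }
        )

    registry = LocusRegistry.from_records(records, canonical_env_reference="locus01")
    truth = pd.DataFrame(truth_rows).set_index("locus_id")

    env_cds = ancestor[ENV_CDS[0] : ENV_CDS[1]]
    references = {
        "env_cds": env_cds,
        "env": _translate(env_cds),
        "rec": _translate(ancestor[ENV_START:SD2] + ancestor[SA2 : REC_STOP[0]]),
        "np9": _translate(
            ancestor[ENV_START : SEGMENT[0]] + ancestor[SA2 : REC_STOP[0]]
        ),
    }
    indel_aa = (
        (SEGMENT[0] - ENV_START) // 3 + 1,
        (SEGMENT[1] - 1 - ENV_START) // 3 + 1,
    )
    return SyntheticFamily(
        registry=registry,
        truth=truth,
        annotations=annotations,
        definitions=_make_definitions(),
        references=references,
        domain_map=DomainMap(),
        indel_aa_interval=indel_aa,
        config=config,
        ancestor=ancestor,
    )


def _build_retrocopy(ancestor: str, rng: np.random.Generator) -> str:
    """A retrotransposed rec mRNA: leader exon + rec exons, stop at Rec codon 19,
    plus two private exon-2 differences so its amplicon is uniquely assignable."""
    exon2 = list(ancestor[ENV_START:SD2])
    # stop at Rec codon 19 (codons are 0-based from the env start)
    exon2[54:57] = list("TAA")
    free = [
        p for p in range(30, len(exon2) - 3)
        if not (54 <= p < 57) and not (0 <= p < ENV_F_SITE[1] - ENV_START)
    ]
    for p in rng.choice(np.array(free), size=2, replace=False):
        p = int(p)
        old = exon2[p]
        exon2[p] = str(rng.choice([b for b in "ACGT" if b != old]))
    return ancestor[:SD1] + "".join(exon2) + ancestor[SA2:]


def _translate(nt: str) -> str:
    from Bio.Seq import Seq

    aa = str(Seq(nt[: 3 * (len(nt) // 3)]).translate())
    return aa.split("*")[0]


# ---------------------------------------------------------------------------
# reads


def rec_np9_product(
    locus: LocusRecord,
    annotation: SpliceAnnotation,
    acceptor: Optional[int] = None,
) -> str:
    """The rec/np9 amplicon product of one locus's spliced transcript.

    Splices [sd2, acceptor or sa2) out of the locus and returns the product
    from the forward primer (at the env start) to the end of the reverse
    primer site. For loci without sd2/sa2 (retrocopies) the locus is already
    spliced and the product is the contiguous interval.
    """
    seq = locus.sequence
    start = annotation.env_start
    site = seq.find(REC_R_SITE_SEQ, start)
    if annotation.sd2 is None or annotation.sa2 is None:
        if site < 0:
            raise ValueError(f"{locus.locus_id}: reverse primer site not found")
        return seq[start : site + len(REC_R_SITE_SEQ)]
    acc = annotation.sa2 if acceptor is None else acceptor
    spliced = seq[start : annotation.sd2] + seq[acc:]
    site = spliced.find(REC_R_SITE_SEQ)
    if site < 0:
        raise ValueError(f"{locus.locus_id}: reverse primer site not found after splicing")
    return spliced[: site + len(REC_R_SITE_SEQ)]


def _apply_errors(read: str, rng: np.random.Generator, rate: float) -> tuple[str, int]:
    if rate <= 0:
        return read, 0
    arr = np.frombuffer(read.encode(), dtype="S1").astype("U1")
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for pos in hits:
        arr[pos] = rng.choice([b for b in "ACGT" if b != arr[pos]])
    return "".join(arr), len(hits)


def simulate_amplicon_reads(
    family: SyntheticFamily,
    config: Optional[SimulationConfig] = None,
    amplicon: str = "gag",
    samples: Optional[list[SampleMeta]] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Draw reads from per-locus amplicons with known ground truth.

    Reads are sampled multinomially from the mixing proportions (optionally
    reweighted by per-locus primer bias), carry iid per-base substitution
    errors, are reverse-complemented with probability 0.5 when unstranded, and
    are spread over the given pseudo-samples. Returns the reads plus a truth
    table (read_id, true locus, sample, errors, orientation).
    """
    config = config or family.config
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    profile = family.profile(amplicon)
    loci = profile.locus_ids
    p = config.proportions(len(loci))
    if config.primer_bias:
        w = np.array([config.primer_bias.get(l, 1.0) for l in loci])
        p = p * w
        p = p / p.sum()
    counts = rng.multinomial(config.n_reads, p)
    if samples is None:
        n_samples = max(1, round(config.n_reads / config.reads_per_sample))
        samples = default_samples(n_samples)
    sample_ids = [s.sample_id for s in samples]

    reads: dict[str, str] = {}
    rows = []
    k = 0
    for locus, n in zip(loci, counts):
        for _ in range(n):
            read, n_err = _apply_errors(profile.sequences[locus], rng, config.read_error_rate)
            orientation = "forward"
            if config.unstranded and rng.random() < 0.5:
                read = revcomp(read)
                orientation = "reverse_complement"
            read_id = f"r{k:05d}"
            reads[read_id] = read
            rows.append(
                {
                    "read_id": read_id,
                    "true_locus": locus,
                    "sample_id": sample_ids[int(rng.integers(len(sample_ids)))],
                    "n_errors": n_err,
                    "orientation": orientation,
                }
            )
            k += 1
    truth = pd.DataFrame(rows).set_index("read_id")
    return reads, truth


def default_samples(
    n: int = 28, n_als: Optional[int] = None
) -> list[SampleMeta]:
    """Pseudo-samples named 'patientNumber-Region', split ALS/control ~2:1."""
    if n_als is None:
        n_als = round(n * 19 / 28)
    tissues = ["motor_cortex", "occipital", "spinal_cord"]
    suffix = {"motor_cortex": "Mot", "occipital": "Occ", "spinal_cord": "SC"}
    out = []
    for i in range(n):
        condition = "ALS" if i < n_als else "control"
        tissue = tissues[i % 3]
        out.append(
            SampleMeta(
                sample_id=f"{i + 1}-{suffix[tissue]}",
                donor_id=f"d{i + 1}",
                tissue=tissue,
                condition=condition,
            )
        )
    return out


def spliced_amplicon_profile(family: SyntheticFamily) -> AmpliconProfile:
    """Per-locus rec/np9 *spliced* products as an assignment profile.

    The genomic rec/np9 'amplicon' spans a multi-kb intron, so reads from
    spliced transcripts must be compared against predicted spliced products.
    """
    sequences = {}
    absent = {}
    for rec in family.registry:
        ann = family.annotations.get(rec.locus_id)
        if ann is None or ann.env_start is None:
            absent[rec.locus_id] = "no splice annotation"
            continue
        try:
            sequences[rec.locus_id] = rec_np9_product(rec, ann)
        except ValueError as exc:
            absent[rec.locus_id] = str(exc)
    return AmpliconProfile(
        amplicon=family.definitions["rec_np9"], sequences=sequences, absent=absent
    )


# ---------------------------------------------------------------------------
# splice-variant fixtures


def make_variant_reads(family: SyntheticFamily) -> dict[str, dict]:
    """Error-free splice-variant fixture reads with their expected classes.

    rec (type 2, SD2->SA2), np9 (type 1, junction donor -> SA2), the
    alternative acceptor +260 into the 3' LTR from a type 2 locus
    (np9-like), an unspliced read, and a retrocopy read.
    """
    t2 = family.registry.records[family.registry.canonical_env_reference]
    t1 = pristine_type1(family)
    ann2 = family.annotations[t2.locus_id]
    ann1 = _annotation_for(t1.locus_id, 1)
    out = {
        "rec": {
            "read": rec_np9_product(t2, ann2),
            "locus": t2,
            "annotation": ann2,
            "expected_class": "rec",
            "expected_offset": 0,
        },
        "np9": {
            "read": rec_np9_product(t1, ann1),
            "locus": t1,
            "annotation": ann1,
            "expected_class": "np9",
            "expected_offset": 0,
        },
        "np9_like_alt": {
            "read": rec_np9_product(t2, ann2, acceptor=ann2.sa2 + 260),
            "locus": t2,
            "annotation": ann2,
            "expected_class": "np9_like_alternative",
            "expected_offset": 260,
        },
        "unspliced": {
            "read": t2.sequence[ann2.env_start : ann2.env_start + 400],
            "locus": t2,
            "annotation": ann2,
            "expected_class": "unspliced",
            "expected_offset": None,
        },
    }
    k111_locus, k111_ann = make_k111_like(family)
    out["np9_plus7"] = {
        "read": rec_np9_product(k111_locus, k111_ann, acceptor=k111_ann.sa2 + 7),
        "locus": k111_locus,
        "annotation": k111_ann,
        "expected_class": "np9",
        "expected_offset": 7,
    }
    return out


def pristine_type1(family: SyntheticFamily) -> LocusRecord:
    """A substitution-free type 1 locus (the ancestor minus the 292-bp
    segment): the canonical reference for type-1 splice/coding fixtures."""
    seq = family.ancestor[: SEGMENT[0]] + family.ancestor[SEGMENT[1] :]
    return LocusRecord(
        locus_id="type1_canonical",
        sequence=seq,
        assembly="synthetic",
        chrom="chrS",
        anchor_pos=998000,
        strand="+",
        provirus_type=1,
        provenance="reference",
    )


def make_k111_like(family: SyntheticFamily) -> tuple[LocusRecord, SpliceAnnotation]:
    """A type 1 locus whose SA2 AG is mutated to GG; the next AG lies 7 nt
    downstream, shifting the np9 acceptor by +7."""
    t1 = pristine_type1(family)
    ann = _annotation_for(t1.locus_id, 1)
    seq = list(t1.sequence)
    seq[ann.sa2 - 2] = "G"  # AG -> GG
    rec = LocusRecord(
        locus_id="K111_like",
        sequence="".join(seq),
        assembly="synthetic",
        chrom="chrS",
        anchor_pos=999000,
        strand="+",
        provirus_type=1,
        provenance="non_reference",
        notes="SA2 AG->GG; acceptor shifts +7",
    )
    annotation = SpliceAnnotation(
        locus_id="K111_like", sd2=ann.sd2, sa2=ann.sa2, sd1=ann.sd1,
        lstart_3ltr=ann.lstart_3ltr, env_start=ann.env_start,
    )
    return rec, annotation


def variant_introns(annotation: SpliceAnnotation, acceptor_offset: int = 0) -> list[Intron]:
    """The intron list of a canonical or offset rec/np9 splice (for building
    in-silico spliced proteins without re-aligning)."""
    acc = annotation.sa2 + acceptor_offset
    return [Intron(donor=annotation.sd2, acceptor=acc, donor_dinucleotide="GT", acceptor_dinucleotide="AG")]


# ---------------------------------------------------------------------------
# qPCR


def simulate_ct_table(
    n_samples: int,
    true_folds,
    replicate_sd: float = 0.0,
    seed: int = 0,
    replicates: int = 4,
    reference_sample: str = "H9-hESC",
    target: str = "HML2_gag",
    normalizer: str = "GAPDH",
    normalizer_ct: float = 20.0,
    reference_dct: float = 6.0,
) -> tuple[pd.DataFrame, str]:
    """Ct tables consistent with the 2^-ddCt model.

    ``true_folds`` gives each non-reference sample's fold change relative to
    the reference sample (whose fold is 1 by construction). Replicate Cts get
    iid Normal(0, replicate_sd) noise; with sd 0 the recovered folds equal the
    planted ones exactly.
    """
    folds = np.asarray(list(true_folds), dtype=float)
    if len(folds) != n_samples:
        raise ValueError("need one true fold per (non-reference) sample")
    if (folds <= 0).any():
        raise ValueError("true folds must be positive")
    rng = np.random.default_rng(seed)
    rows = []

    def add(sample_id: str, dct: float):
        for rep in range(replicates):
            rows.append(
                {
                    "sample_id": sample_id,
                    "target": normalizer,
                    "replicate": rep + 1,
                    "ct": normalizer_ct + rng.normal(0, replicate_sd) if replicate_sd else normalizer_ct,
                }
            )
            rows.append(
                {
                    "sample_id": sample_id,
                    "target": target,
                    "replicate": rep + 1,
                    "ct": normalizer_ct + dct + (rng.normal(0, replicate_sd) if replicate_sd else 0.0),
                }
            )

    add(reference_sample, reference_dct)
    for i, fold in enumerate(folds):
        add(f"sample{i + 1:02d}", reference_dct - float(np.log2(fold)))
    return pd.DataFrame(rows), reference_sample
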