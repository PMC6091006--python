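# Methods

This note documents the models, conventions and numerical choices behind
`hml2profiler`, and what its synthetic fixtures do and do not establish.

## Locus model and coordinates

A locus is a nucleotide sequence (ACGTN) with reporting metadata: a 1-based
single anchor position (the convention used when citing a locus by one
representative genomic coordinate), a strand that may be `unknown` (the cDNA
strategy the package serves is unstranded), a provirus type (1/2/unknown) and
a provenance tag (`reference`, `non_reference`, `retrocopy`). Non-reference
polymorphic proviruses and retrotransposed mRNA copies are ordinary registry
members distinguished only by provenance, so assignment treats all candidate
sources uniformly. All internal sequence arithmetic is 0-based half-open;
1-based anchors exist only at I/O boundaries. The assembly tag is stored
verbatim and never lifted over.

## Primer matching and in-silico amplicons

Degenerate primer mixes are matched with substitutions only (no indels inside
a primer site): primers are short, and indel tolerance creates ambiguous
anchors. A site matched by *any* mix member counts. Each forward hit pairs
with the nearest downstream reverse-complemented reverse hit — PCR yields the
shortest product from a primer pair — and both strands are scanned, since
proviruses may be annotated on either strand. Mix ratios are carried as
metadata and used only by the simulator as optional amplification-bias
weights; matching is a pure sequence question. Extraction filters products by
per-type expected length ranges and records absent loci with a reason
(`no forward primer match`, etc.).

## Difference counting and diagnostic sites

Nucleotide differences between two amplicons are counted on an affine-gap
global alignment (match +1, mismatch −1, gap open −5, gap extend −1):
substitution columns plus indel *events*, where one contiguous gap run of any
length is one event. Without this convention the 292-bp type-1/2 indel would
dominate every type-1-vs-type-2 distance and drown the substitution signal
that locus assignment relies on. The implied multiple alignment behind
diagnostic sites is built progressively: every amplicon is projected onto the
longest amplicon (the anchor) by pairwise alignment; insertions relative to
the anchor are ignored. A diagnostic site is any anchor column with at least
two states among loci (gap is a state); a site where exactly one locus
deviates from an otherwise uniform column is flagged private. Loci at
pairwise distance 0 form indistinguishable groups — reads from them can never
be assigned uniquely over that amplicon, which is a property of the amplicon,
not a pipeline failure.

## Provirus type classification

A query env 5' region is aligned globally to a type-2 reference. Type 2: the
292-bp segment is present (no deletion run ≥ 50 nt inside it). Type 1: the
segment is absent as one deletion of 292 ± 10 nt (absorbing small co-deleted
flanks). Anything else — e.g. a 320-nt deletion — is `unknown` rather than
guessed. Inputs shorter than 100 nt are rejected.

## Read assignment

Distance is unit-cost edit distance between the (possibly truncated) read and
the full per-locus amplicon with free end gaps on the amplicon, computed by a
numba-compiled rolling DP; Sanger reads may truncate, so amplicon overhangs
are not penalised. Orientation is chosen by exhaustive comparison of both
read orientations against all amplicons, ties breaking toward forward. A call
is `unique` when a single locus attains the minimum and the runner-up is more
than `margin` edits away (default margin 0: strict ties only), `ambiguous`
when several loci tie within the margin (reported as a composite
"A|B" category, counted as one row downstream), and `unassigned` when the
best distance exceeds `max_distance` (default 5% of the amplicon length — an
error ceiling absorbing Sanger/PCR error) or the read length falls outside
0.5–1.5× the amplicon length range. Raising `margin` can only grow the
candidate set; raising `max_distance` can only reduce unassigned calls; both
monotonicities are property-tested. No probabilistic reallocation of
ambiguous reads is attempted — explicit ambiguity is the honest output for
paralogs lacking discriminating positions.

## Splice inference

Reads from spliced transcripts are explained as chains of collinear exon
blocks (each ≥ 20 nt) found by exact 20-mer seeding and maximal extension;
gaps ≥ 50 nt between consecutive blocks are introns (the canonical rec intron
is multi-kilobase and the known alternative acceptor offsets are hundreds of
nucleotides, so the threshold excludes alignment noise). When junction
placement is ambiguous — read bases compatible with both flanking exons — the
placement with GT..AG boundary dinucleotides within ±10 nt of the naive
boundary is preferred, remaining ties resolving to the smallest shift.
Coordinates: the donor is the first intronic base, the acceptor the first
exonic base after the intron.

Classification is junction-based, given a per-locus annotation (sd2, sa2, env
start, 3' LTR start): `rec` = sd2 donor to sa2 on a type-2 locus; `np9` = the
type-1 junction donor to sa2, where acceptor shifts up to 20 nt (such as the
+7 shift after an AG→GG mutation of sa2) remain np9 with the offset recorded;
`np9_like_alternative` = sd2 donor to a non-canonical acceptor (e.g. +260 nt,
inside the 3' LTR) on a type-2 locus; `unspliced` = a contiguous match. Any
intron violating GT..AG demotes the call to `unknown`. Real use requires
user-supplied splice annotations; the simulator plants its own.

## Coding prediction

An ORF is a maximal run of non-stop codons bounded by stops or the sequence
ends (so no reported ORF is extendable), in the three forward frames, ≥ 50 aa
(the smallest biologically relevant product class, Np9, is ~70 aa). The env
region is located by a *local* alignment of the canonical Env CDS to the
locus — local, because a global alignment would have to place non-homologous
CDS portions somewhere and scatter the coordinate map. An ORF codon maps to a
canonical residue only when its three bases align to one complete, in-frame
canonical codon, and ORFs with fewer than 15 mapped codons are treated as
unmapped; off-frame ORFs are therefore reported with an empty canonical span
rather than a fictitious one. Classes: `full_length_env` (aa 1–699 on a
type-2 locus), `type1_env` (starts within [junction − 2, junction + 40] aa on
a type-1 locus and reaches the TM region), `pol_env_fusion` (≥ 30 codons of
in-frame upstream extension), `TM_fragment`, `SU_OM_fragment`, `other`.

Cleavage products intersect the ORF span with SP = aa 1–96 (signal-peptidase
boundary), SU/OM = 97–furin, TM = furin+1–699. The furin position is not part
of the published architecture; the default (aa 463) is derived from the
~41/~26 kDa SU/TM mass split of the 79-kDa precursor and is an explicit,
overridable `DomainMap` parameter. Masses are average residue masses plus one
water; published "approx." kDa values reflect gel mobility and glycosylation,
so they are treated as ±15% bands, never exact targets, and the ~13 kDa SP
value is never validated against sequence mass at all.

Spliced-protein prediction removes the called introns, translates from the
annotated Env/Rec/Np9 start (missing ATG → `none` with reason), and
classifies against reference Rec/Np9/Env sequences: exact or ≥95%-identity
matches; `Rec_truncated` must be a proper N-terminal prefix of Rec (the +260
alternative acceptor yields Rec lacking its C-terminal 17 aa, and with it a
reported protein-interaction region); chimeras require both terminal halves
to match their respective references at ≥ 60% identity over ≥ 30 aa — a
simpler, reproducible stand-in for dot-matrix similarity panels. A stop
within the first 25 codons (e.g. codon 19 in a retrotransposed rec mRNA)
yields `none` with the stop position recorded.

## Quantification

Relative cloning frequency — count/column-total per sample — is the proxy for
relative transcript level, assuming equal cloning efficiencies. Ambiguous
composite rows and an explicit unassigned row are kept in denominators by
default (configurable), matching the published per-sample convention; display
rounding is half-up to 2 decimals, full precision is kept internally. Both
aggregation modes are first-class because they answer different questions and
are both used in practice: `per_sample_mean` weights each sample equally and
reports the min–max range; `pooled` weights each clone equally
(100·Σcounts/Σtotals). They coincide exactly when all samples contribute
equal clone numbers.

Group comparison: Shapiro–Wilk per group at α = 0.05; if both groups are
consistent with normality, a Welch two-sample t-test; otherwise the
two-sample Wilcoxon rank-sum test (a paired signed-rank variant exists behind
`paired=True`, but rank-sum is the default for unpaired tissue-group
designs). No multiple-testing correction is applied by default; a
Benjamini–Hochberg helper is provided for per-locus scans.

qPCR: fold = 2^−ΔΔCt with ΔCt = mean Ct(target) − mean Ct(normalizer) per
sample and ΔΔCt taken against a designated high-expression reference sample
(fold ≡ 1). Any constant Ct shift cancels exactly (property-tested). The fold
standard deviation is propagated from replicate Ct variance by the log-normal
delta method; note that ΔΔCt combines four replicate means (target/normalizer
× sample/reference), so its standard error is 2·sd/√replicates, and the
shared reference error is common to all samples. `qc_correlation` is a plain
least-squares R², as used for RNA-integrity-vs-Ct checks.

## The synthetic world

The simulator's defaults are the published survey's conditions: 20 loci plus
one retrocopy; a ~620-nt gag amplicon with pairwise differences spread over
~1–38 (locus *i* carries *i* planted substitutions in the amplicon, plus a
0.005/site background elsewhere); a type-2 fraction of 0.5; one pair with
byte-identical amplicons (forced ambiguity); a retrotransposed rec mRNA with
a stop at Rec codon 19 and two private differences; mixing proportions
(0.53, 0.12, 0.10, 0.05, rest equal) so the dominant locus is ~53% and the
top four ~80% of reads; 820 reads over 28 pseudo-samples (≈29 per sample,
19 ALS / 9 control); a 0.2% per-base substitution error (Sanger-like; errors
are substitution-only — chromatogram-quality reads rarely contain indels
after trimming, and no trace-level simulation is attempted); ~50% of reads
reverse-complemented. Substitutions avoid primer sites and planted functional
elements and are resampled if they would create a stop in the env frame, so
fixtures never lose amplicons or ORFs by accident. Identical seeds give
byte-identical FASTA/TSV outputs.

What a green test establishes: correctness of the contracts above on
sequences whose ground truth is known exactly. What it does not establish:
robustness to PCR chimeras, template switching, cloning bias beyond the
simple primer-bias weights, chromatogram basecalling error structure, or real
HML-2 phylogeny (substitutions are placed independently and uniformly, not on
a tree). The packaged published tables exercise the quantification arithmetic
against real printed numbers, but cannot validate read assignment itself —
the underlying cDNA sequences were never deposited.

## Known limitations

* Assignment is tie-based; no EM reallocation of multi-mapping reads and no
  quality-score-aware alignment (no chromatograms are available).
* Splice inference is exact-match seeded; heavily errored reads (>~2% error)
  may fail to chain and are reported `unknown` rather than force-fit.
* The published forward primer mixes for the three amplicons are not public;
  the packaged primer config carries only the six published env600nt reverse
  primers verbatim, and real-data use requires user-supplied forward primers.
  All shipped analyses therefore run on the simulator's own primer sets.
* Canonical Env/Rec/Np9 references used in tests are synthetic stand-ins
  generated by the simulator, not database sequences.
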