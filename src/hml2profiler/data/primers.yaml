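# Default primer-set definitions for the three RT-PCR amplicons used in locus-resolution
# HML-2 transcription profiling, plus the GAPDH qPCR normalizer pair.
#
# Only the six env600nt reverse primers were published verbatim; the four degenerate
# forward primers shared by the env600nt and rec/np9 amplicons (and the gag primer mixes)
# are cited to earlier work and must be supplied by the user. The synthetic-data module
# ships its own fully specified primer sets for simulated families, so the test suite and
# pipeline never depend on the unpublished sequences.
primer_sets:
  env600nt:
    max_mismatches: 1
    forward: []   # user-supplied (4-primer degenerate mix, published elsewhere)
    reverse:
      - {name: env600ntR1, sequence: ATTTACCCGTGGCCTGAGTG, ratio: 5}
      - {name: env600ntR2, sequence: ATTTACCCGTGGCCTAAGTG, ratio: 1}
      - {name: env600ntR3, sequence: ATTTACCTGTGGCCTGAGCG, ratio: 1}
      - {name: env600ntR4, sequence: ATTTACCTGTGGCCTGAGAG, ratio: 1}
      - {name: env600ntR5, sequence: ATTTTATCTGTGGCCCGAGTG, ratio: 1}
      - {name: env600ntR6, sequence: ATTCATTTGTGACCTGAGC, ratio: 1}
  gag:
    max_mismatches: 1
    forward: []   # user-supplied (4 forward primers)
    reverse: []   # user-supplied (3 reverse primers)
  rec_np9:
    max_mismatches: 1
    forward: []   # same 4 forward primers as env600nt
    reverse: []   # user-supplied
qpcr:
  normalizer: GAPDH
  GAPDH_forward: TGCACCACCAACTGCTTAGC
  GAPDH_reverse: GGCATGGACTGTGGTCATGAG
amplicon_definitions:
  gag:
    expected_lengths: {1: [550, 700], 2: [550, 700], unknown: [550, 700]}
  env600nt:
    # products from the Env/Rec/Np9 start codon across the 292-bp indel region:
    # ~330 bp (type 1) and ~620 bp (type 2)
    expected_lengths: {1: [280, 400], 2: [560, 700]}
  rec_np9:
    # spliced products; np9-typical shorter than rec-typical
    expected_lengths: {1: [300, 550], 2: [400, 700]}
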