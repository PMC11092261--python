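forward ACGGTCCAGACTCCTACG bact_fwd_broad
reverse GGACTACHVGGGTWTCTA bact_rev_broad
forward TTCCGGTTGATCCYGCCGGA arch_fwd
CCTACGGGAGGCAGCAG narrow_unknown
forward TGCATGCATGCATGCA dead_primer
primer GTGCCAGCMGCCGCGGTAA CCGTCAATTCMTTTRAGTTT pair_broad
primer AGAGTTTGATCMTGGCTCAG TACGGYTACCTTGTTACGAC pair_narrow
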