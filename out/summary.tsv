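locus	n_individuals	individuals_with_2	individuals_with_1	individuals_with_0	mode_IBD	mode_PANEL	reason_UNIQUE_PATTERN
L1	170	86	52	32	140	84	116
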