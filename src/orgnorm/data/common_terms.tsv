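# Common organism terms and their candidate NCBI Taxonomy IDs, in priority
# order as observed in caption-annotation practice.
larva	7227,7955,6239
embryo	10090,7955,6239,9031
seedling	3915,3702
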