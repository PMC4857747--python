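miRNA,fc_t0_t3,milk_rank
miR-208b-3p,9891,
miR-126-3p,3177,
miR-181b-5p,242,49
miR-183-5p,160,117
miR-125a-5p,148,56
miR-4732-3p,117,
miR-181a-2-3p,113,42
miR-141-3p,64,91
miR-423-3p,54,15
miR-100-5p,47,121
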