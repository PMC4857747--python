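miRNA,milk_share_pct,fc_t0_t3
let-7b,39.1,-111
let-7a/c,37.0,5
let-7f,2.8,14
miR-30a,1.9,-39
miR-21,1.7,23
miR-99a,1.7,-33
let-7d,1.4,
miR-148a,1.2,32
miR-92a,1.1,8
miR-30d,1.0,-1144
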