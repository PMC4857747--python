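miRNA,T0,T3,T6,T9
bta-mir-1839,1333,5,816,157
bta-mir-2338,,1,698,
bta-mir-2451,250,,1,
bta-mir-2904,4,,,21
bta-mir-6532,,21,,
bta-mir-3956,15,,,
bta-mir-3596,2,,3,3
bta-mir-2284z,2,1,1,1
bta-mir-2887,2,1,,2
bta-mir-2284x,,1,1,1
bta-mir-2484,,1,2,
bta-mir-2285z,,2,,1
bta-mir-2285g,,3,,
bta-mir-2370-5p,1,,,
bta-mir-6529b,,1,,
bta-mir-2892,,1,,
bta-mir-1388-5p,,,,1
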