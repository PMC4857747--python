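run,timepoint,total_reads,mirge_mapped,chimira_mapped,bowtie_mapped
SRR3083757,T0,18104234,17571674,17523557,17490252
SRR3083758,T3,21050196,9898504,9688895,9442374
SRR3083759,T6,17972585,17661827,17620217,17593830
SRR3083760,T9,19298056,19119013,19074396,19065638
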