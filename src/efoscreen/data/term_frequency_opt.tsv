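row	MonomerA	MonomerB	MonomerC	MonomerD	Total
Best	10	11	10	5	36
Mean	11	19	15	18	63
Total	21	30	25	23	99
Mean volume	491.2	884.8	648.2	591.0	653.8
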