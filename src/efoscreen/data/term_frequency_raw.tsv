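row	MonomerA	MonomerB	MonomerC	MonomerD	Total
Best	11	14	16	4	45
Mean	13	15	14	13	55
Total	24	29	30	17	100
Mean volume	365.4	582.2	492.7	439.8	470.0
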