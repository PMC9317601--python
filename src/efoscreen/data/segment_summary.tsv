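segment	ef1_raw	volume_raw	ef1_opt	volume_opt
25–250	14.61	380.6	17.13	556.1
275–500	19.90	428.1	20.40	630.4
525–750	24.48	503.1	23.79	655.2
775–1000	19.14	525.8	25.48	711.8
1025–1250	26.75	512.52	29.70	715.5
Averages	21.38	470.0	23.29	653.8
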