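variant	subset	best_ef1	top20_mean_ef1
raw	all	47.84	37.07
raw	monomer A	29.90	24.17
raw	monomer B	41.86	29.00
raw	monomer C	44.85	36.36
raw	monomer D	44.85	30.65
raw	best scores	35.88	13.85
raw	mean scores	44.84	26.54
opt	all	49.83	38.62
opt	monomer A	44.85	36.13
opt	monomer B	29.90	26.48
opt	monomer C	41.86	26.61
opt	monomer D	44.85	36.63
opt	best scores	35.88	25.12
opt	mean scores	38.94	29.90
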