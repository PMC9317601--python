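metric	prior_best_model	multi_raw	multi_opt
EF1%	67.11	47.84	49.83
% active in top 1%	67.11	80	90
MCC	0.66	0.49	0.64
Sensitivity	0.66	0.50	0.65
Accuracy	0.99	0.99	0.99
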