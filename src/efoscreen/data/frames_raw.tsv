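frame_ns	ef1	equation
25	nd	The frame was fully discarded
50	nd	The frame was fully discarded
75	nd	The frame was fully discarded
100	17.51	1.00 PSmeanB
125	5.84	1.00 CSbestC
150	22.42	−1.00 CSbestC − 0.36 CsoptbestB
175	14.95	1.00 CsoptmeanC + 2.96 CSbestB
200	19.93	1.00 CSmeanB − 1.10 CSbestB − 1.38 CsoptmeanA
225	11.67	1.00 PSmeanA
250	9.96	−1.00 CSmeanC − 2.44 CSmeanB
275	8.54	−1.00 CSmeanC + 0.46 CSbestB
300	11.67	1.00 CSbestC
325	17.81	1.00 CSbestD − 1.11 CSbestC
350	29.90	−1.00 CsoptbestB + 2.15 CsoptbestA
375	29.18	1.00 CSbestD
400	23.12	−1.00 CSmeanD − 8.80 CsoptbestC
425	19.93	1.00 CsoptmeanB − 3.53 CSmeanA
450	23.92	−1.00 CSmeanD − 0.41 CsoptbestB − 0.11 CSmeanA
475	14.95	−1.00 CSmeanD − 9.86 CsoptbestC + 3.87 CsoptbestA
500	19.93	1.00 CSmeanD − 12.42 CsoptbestA
525	12.81	1.00 PSmeanD − 71.23 CSmeanD − 58.51 CsoptbestC
550	23.35	1.00 CSbestA
575	35.88	−1.00 CsoptmeanC + 1.30 CSbestA
600	29.90	−1.00 CsoptbestC − 0.39 CSmeanA
625	29.90	−1.00 CsoptmeanD − 0.082 CSmeanB + 1.26 CsoptmeanA
650	35.88	−1.00 CSbestD − 1.71 CSmeanC + 1.16 CsoptbestB
675	22.42	−1.00 CsoptmeanC + 0.24 CSbestA
700	12.82	−1.00 CSbestB + 0.82 CSmeanA
725	22.42	−1.00 CSmeanB + 0.36 CSbestB
750	19.93	−1.00 CSmeanC − 6.04 CsoptmeanB − 1.51 CsoptmeanA
775	29.90	−1.00 CSmeanC + 0.67 CsoptbestB
800	18.69	−1.00 CsoptmeanB + 0.24 CSbestA
825	17.51	1.00 CSBestA
850	13.29	1.00 CSbestD + 44.18 CsoptbestC
875	12.82	−1.00 CSoptmeanB + 7.20 CSmeanB − 29.71 CSbestA
900	21.36	−1.00 CSbestC + 0.95 CSbestA
925	19.93	1.00 CsoptmeanD + 4.31 CSmeanC + 0.90 CSbestC
950	17.51	1.00 CSbestC
975	22.42	−1.00 CSmeanD + 0.94 CSbestC
1000	17.94	−1.00 CsoptmeanC + 0.42 CSmeanB − 0.15 CSmeanA
1025	37.38	1.00 CSoptmeanD − 1.27 CsoptbestC
1050	35.88	1.00 CsoptmeanD + 1.69 CSmeanC − 9.10 CsoptmeanB
1075	29.90	1.00 CSbestC − 1.86 CsoptmeanB
1100	35.88	−1.00 CSmeanB − 4.56 CsoptbestB − 3.70 CSmeanA
1125	23.35	1.00 CSbestA
1150	14.95	−1.00 CsoptmeanD − 0.67 CsoptmeanC + 0.34 CSbestB
1175	19.93	−1.00 CSbestB + 0.32 CsoptmeanA
1200	25.63	−1.00 CsoptmeanC − 1.85 CsoptbestB + 0.95 CsoptmeanA
1225	21.35	−1.00 CsoptmeanD + 0.27 CSbestC
1250	23.26	1.00 CsoptmeanC − 10.07 CsoptmeanB + 1.90 CsoptmeanA
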