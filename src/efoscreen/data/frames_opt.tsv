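frame_ns	ef1	equation
25	29.18	1.00 PSmeanC
50	11.67	1.00 CSbestB
75	25.63	−1.00 CsoptbestB − 1.27 CsoptmeanA
100	29.90	−1.00 CSbestC + 1.22 CSmeanB − 0.21 CSbestA
125	14.95	−1.00 CsoptmeanD + 0.89 CSmeanD
150	4.27	1.00 CsoptbestC − 1.42 CsoptmeanB
175	8.31	−1.00 CSmeanD + 0.55 CSmeanC + 0.27 CSmeanB
200	19.93	−1.00 CsoptmeanD − 5.44 CSbestA
225	17.51	1.00 CSbestA
250	9.96	−1.00 CSmeanC − 2.44 CSmeanB
275	nd	The frame was fully discarded
300	19.33	1.00 CSmeanD + 2.91 CSbestC − 7.81 CsoptbestB
325	5.84	1.00 CSmeanD
350	14.95	−1.00 CSbestC − 0.70 CsoptbestB
375	14.95	−1.00 CsoptbestC − 1.14 PSmeanA
400	19.33	−1.00 CSmeanC − 4.23 PSmeanB + 18.23 PSbestB
425	29.90	−1.00 CsoptmeanC − 10.07 CSmeanB + 1.95 CsoptbestA
450	24.92	1.00 CsoptmeanD − 3.48 CSmeanA
475	22.42	−1.00 CSmeanD − 21.50 CSmeanC
500	37.38	−1.00 CsoptmeanC + 1.73 CSmeanA
525	29.18	1.00 PSmeanD
550	29.90	−1.00 CsoptmeanC − 8.69 CsoptbestC + 0.27 CSmeanB
575	nd	The frame was fully discarded
600	5.84	1.00 CbestA
625	24.92	1.00 CSbestD − 14.04 CsoptmeanA
650	29.90	1.00 CsoptbestB − 1.66 CSmeanA − 0.94 CsoptbestA
675	18.69	1.00 CsoptbestC − 1.09 CsoptmeanB
700	37.38	1.00 CsoptmeanC − 4.44 CsoptmeanB
725	12.82	−1.00 CSmeanD − 1.38 CsoptbestB
750	29.90	1.00 CSmeanD − 0.12 CsoptbestD − 1.14 CsoptmeanA
775	26.58	1.00 CsoptmeanD − 1.25 CSoptbestC
800	14.95	1.00 CsoptmeanD − 2.89 CsoptmeanA − 9.20 CSbestA
825	35.88	1.00 CsoptmeanD − 1.05 CsoptmeanB
850	21.35	1.00 CsoptmeanC − 3.50 CsoptmeanB
875	33.22	−1.00 CsoptbestD − 0.49 CsoptmeanA
900	29.18	1.00 CSbestA
925	19.93	−1.00 CSbestD − 1.34 CSmeanC − 2.32 CSmeanB
950	17.94	1.00 CsoptbestC − 12.25 CSbestA
975	35.88	−1.00 CsoptmeanD − 0.68 CsoptmeanB
1000	19.93	−1.00 CsoptmeanC − 0.48 CSmeanB − 4.85 CsoptbestB
1025	29.90	−1.00 CsoptmeanB + 0.060 CsoptbestA
1050	Nd	The frame was fully discarded
1075	24.92	−1.00 CsoptbestD − 3.30 CSmeanB
1100	29.90	−1.00 CSmeanC − 0.59 CsoptmeanA
1125	35.88	−1.00 CSmeanC − 4.84 CSbestB
1150	19.93	1.00 CSmeanD − 15.28 CSmeanB
1175	37.38	1.00 CsoptbestB − 1.66 CsoptmeanA
1200	21.35	1.00 CsoptmeanD − 1.73 CsoptmeanB
1225	29.90	−1.00 CsoptmeanC + 0.50 CsoptbestB
1250	28.47	1.00 CsoptmeanD − 0.21 CsoptbestC − 0.98 CSmeanB
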