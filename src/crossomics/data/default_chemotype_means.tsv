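compound	CH	EX	NZ
allyl	37.0	0.2	24.8
S-2OH3-butenyl	48.0	0.0	45.0
3-butenyl	0.0	0.0	8.0
4MTB	0.0	0.0	4.0
4MSOB	0.0	0.0	2.0
3MTP	1.5	4.0	1.0
3MSOP	1.0	8.0	0.8
6MSOH	0.5	20.0	0.5
7MTH	0.2	5.0	0.3
7MSOH	0.3	10.0	0.4
8MSOO	0.2	15.0	0.3
1MOI3M	0.8	2.0	0.9
4OHI3M	0.4	1.5	0.5
4MOI3M	0.6	2.5	0.7
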