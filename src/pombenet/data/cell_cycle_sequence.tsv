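time	Start	SK	Cdc2/Cdc13	Ste9	Rum1	Slp1	Cdc2/Cdc13*	Wee1/Mik1	Cdc25	PP	phase
1	1	0	0	1	1	0	0	1	0	0	START
2	0	1	0	1	1	0	0	1	0	0	G1
3	0	0	0	0	0	0	0	1	0	0	G1/S
4	0	0	1	0	0	0	0	1	0	0	G2
5	0	0	1	0	0	0	0	0	1	0	G2
6	0	0	1	0	0	0	1	0	1	0	G2/M
7	0	0	1	0	0	1	1	0	1	0	G2/M
8	0	0	0	0	0	1	0	0	1	1	M
9	0	0	0	1	1	0	0	1	0	1	M
10	0	0	0	1	1	0	0	1	0	0	G1
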