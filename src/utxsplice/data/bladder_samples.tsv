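sample	group	Δ14	Δ14Δ16	long	Δ16	Δ13	Δ13Δ16	Δ13Δ14	Δ13Δ14Δ16
Normal 1	normal	8	29	2	0	7	10	4	40
Normal 2	normal	20	40	0	0	17	12	5	5
Normal 3	normal	48	16	2	0	11	11	8	3
Normal 4	normal	42	36	4	0	1	15	0	0
Normal 5	normal	13	37	0	0	13	35	0	0
BLCA 1	tumor	42	0	0	0	20	0	37	0
BLCA 2	tumor	18	23	1	1	11	14	12	19
BLCA 3	tumor	20	46	1	0	6	18	3	4
BLCA 4	tumor	21	15	5	2	22	12	11	10
BLCA 5	tumor	47	1	0	0	12	23	15	0
BLCA 6	tumor	15	50	3	0	3	12	0	16
BLCA 7	tumor	0	0	5	0	40	49	5	0
BLCA 8	tumor	14	24	2	2	16	9	9	21
BLCA 9	tumor	36	11	5	0	14	20	0	13
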