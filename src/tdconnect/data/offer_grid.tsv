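delay	amount1	amount2	amount3	amount4	amount5	amount6
7	25	26	28	30	32	35
10	25	26	27	29	30	32
12	25	26	28	31	33	35
14	25	26	28	32	35	39
21	26	27	29	30	32	38
25	27	29	31	33	35	46
28	26	28	32	35	39	46
30	26	27	29	30	32	38
40	27	33	35	40	47	54
45	26	29	31	35	40	46
50	27	30	35	40	46	54
60	29	33	35	40	47	54
90	26	30	33	40	46	54
95	31	33	35	40	47	54
100	26	31	38	39	46	54
150	31	33	35	40	47	54
180	27	31	35	39	46	54
200	26	28	35	39	47	54
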