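pvs	ps	pm	pp	ba	bs	bp	subclass
1	0	0	0	0	0	0	Hot
1	0	0	0	0	0	1	Hot
1	0	0	1	0	0	0	Hot
0	1	0	0	0	0	0	Hot
0	1	0	1	0	0	0	Hot
0	1	0	1	0	0	1	Hot
0	1	0	1	0	1	0	Hot
0	1	0	0	0	0	1	Hot
0	0	2	1	0	0	0	Hot
0	0	2	1	0	0	1	Hot
0	0	2	1	0	1	0	Hot
0	0	1	3	0	0	0	Hot
0	0	1	3	0	0	1	Hot
0	0	1	3	0	1	0	Hot
0	0	0	4	0	0	0	Hot
0	0	0	4	0	0	1	Hot
0	0	2	0	0	0	0	Middle
0	0	2	0	0	0	1	Middle
0	0	1	1	0	0	0	Middle
0	0	1	1	0	0	1	Middle
0	0	1	2	0	0	0	Middle
0	0	1	2	0	0	1	Middle
1	0	0	0	0	1	0	Middle
0	1	0	0	0	1	0	Middle
0	0	0	3	0	0	0	Middle
0	0	0	3	0	0	1	Middle
0	0	1	0	0	0	0	Cold
0	0	1	0	0	0	1	Cold
0	0	0	2	0	0	0	Cold
0	0	0	2	0	0	1	Cold
0	0	0	2	0	1	0	Cold
0	0	0	1	0	0	0	Cold
0	0	0	1	0	0	1	Cold
0	0	0	1	0	1	0	Cold
0	0	0	0	0	0	1	Cold
0	0	0	0	0	1	0	Cold
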