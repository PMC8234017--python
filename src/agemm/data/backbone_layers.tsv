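layer	type	I	C	F	S	K	O	operations
1	c	416	3	3	2	32	208	605696
2	c	208	32	3	2	64	104	3115008
3	c	104	64	3	1	64	104	6230016
4	c	104	64	3	1	32	104	3115008
5	c	104	32	3	1	32	104	1557504
6	c	104	64	1	1	64	104	692224
7	p	104	128	2	2	128	52
8	c	52	128	3	1	128	52	6230016
9	c	52	128	3	1	64	52	3115008
10	c	52	64	3	1	64	52	1557504
11	c	52	128	1	1	128	52	692224
12	p	52	256	2	2	256	26
13	c	26	256	3	1	256	26	6230016
14	c	26	256	3	1	128	26	3115008
15	c	26	128	3	1	128	26	1557504
16	c	26	256	1	1	256	26	692224
17	p	26	512	2	2	512	13
18	c	13	512	3	1	512	13	6340608
19	c	13	512	1	1	256	13	352256
20	c	13	256	3	1	512	13	3170304
21	c	13	512	1	1	255	13	352256
22	c	13	256	1	1	128	13	88064
23	u	13	128	2	0.5	128	26
24	c	26	384	3	1	256	26	9345024
25	c	26	256	1	1	255	26	692224
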