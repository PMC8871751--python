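node	parent	label	edge_sites	frequency	members
0	.	ROOT	.	0	.
1	0	crown	rAX,rAY	0	.
2	1	A	rA	0	.
3	1	T	rW	0	.
4	1	H	fYR	0	.
5	3	Ta	fRL,fTY,fXT,fZK,fZW,sPZ	0	.
6	5	Ta-s	qGB	0	.
7	5	Ta-b	qGC,sPY	0	.
8	7	Ta-bA	qDK	0	.
9	2	Ao-aA1a	.	0	.
10	9	Ao-aA1a2	.	0	.
11	10	Ao-aA1a2a	qFE	0	.
12	9	Ao-aA1a4	fWO,rAB	0	.
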