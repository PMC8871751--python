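site_id	stage	edge_key
rAY	key	crown
rAX	key	crown
rA	clade	A
rW	clade	T
fYR	clade	H
sPZ	ht	Ta
fTY	ht	Ta
fRL	ht	Ta
fXT	ht	Ta
fZK	ht	Ta
fZW	ht	Ta
qGB	ht	Ta-s
qGC	ht	Ta-b
sPY	ht	Ta-b
qDK	ht	Ta-bA
qFE	ht	Ao-aA1a2a
rAB	ht	Ao-aA1a4
fWO	ht	Ao-aA1a4
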