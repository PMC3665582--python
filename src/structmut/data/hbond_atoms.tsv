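# Sidechain hydrogen-bond donor/acceptor heavy atoms per residue, with a
# functional-group label used to decide whether a mutation retains the
# equivalent atom (e.g. Ser OG -> Thr OG1 both carry a hydroxyl).
# residue	atom	role	group
SER	OG	both	hydroxyl
THR	OG1	both	hydroxyl
TYR	OH	both	hydroxyl
CYS	SG	both	thiol
ASN	OD1	acceptor	amide_o
ASN	ND2	donor	amide_n
GLN	OE1	acceptor	amide_o
GLN	NE2	donor	amide_n
ASP	OD1	acceptor	carboxylate
ASP	OD2	acceptor	carboxylate
GLU	OE1	acceptor	carboxylate
GLU	OE2	acceptor	carboxylate
LYS	NZ	donor	amine
ARG	NE	donor	guanidinium
ARG	NH1	donor	guanidinium
ARG	NH2	donor	guanidinium
HIS	ND1	both	imidazole
HIS	NE2	both	imidazole
TRP	NE1	donor	indole_n
MET	SD	acceptor	thioether
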