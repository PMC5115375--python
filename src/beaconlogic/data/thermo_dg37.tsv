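# Unified Watson-Crick nearest-neighbor stacking free energies, dG at 37 C (kcal/mol),
# SantaLucia (1998) unified parameter set, keyed by the top-strand dinucleotide 5'->3'.
# Scalars: duplex initiation, flat internal/terminal mismatch penalties.
# Hairpin loop closure penalties: log-extrapolated table anchored at 5.7 kcal/mol for a
# 3-nt loop, constant beyond 30 nt.
stack	AA	-1.00
stack	AC	-1.44
stack	AG	-1.28
stack	AT	-0.88
stack	CA	-1.45
stack	CC	-1.84
stack	CG	-2.17
stack	CT	-1.28
stack	GA	-1.30
stack	GC	-2.24
stack	GG	-1.84
stack	GT	-1.44
stack	TA	-0.58
stack	TC	-1.30
stack	TG	-1.45
stack	TT	-1.00
scalar	initiation	2.00
scalar	mismatch_internal	1.50
scalar	mismatch_terminal	0.75
loop	3	5.70
loop	4	6.16
loop	5	6.52
loop	6	6.82
loop	7	7.06
loop	8	7.28
loop	9	7.47
loop	10	7.64
loop	11	7.79
loop	12	7.93
loop	13	8.06
loop	14	8.18
loop	15	8.29
loop	16	8.40
loop	17	8.49
loop	18	8.58
loop	19	8.67
loop	20	8.75
loop	21	8.83
loop	22	8.91
loop	23	8.98
loop	24	9.05
loop	25	9.11
loop	26	9.18
loop	27	9.24
loop	28	9.30
loop	29	9.35
loop	30	9.41
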