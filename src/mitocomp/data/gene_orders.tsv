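# Reference mitochondrial gene orders, v1.
# 'ditrysia': the derived lepidopteran order with the trnM-trnI-trnQ cluster.
# 'ancestral': the putative ancestral insect order with trnI-trnQ-trnM.
# columns: order_name, position, gene, strand
order_name	position	gene	strand
ditrysia	1	trnM	J
ditrysia	2	trnI	J
ditrysia	3	trnQ	N
ditrysia	4	ND2	J
ditrysia	5	trnW	J
ditrysia	6	trnC	N
ditrysia	7	trnY	N
ditrysia	8	COI	J
ditrysia	9	trnL^UUR	J
ditrysia	10	COII	J
ditrysia	11	trnK	J
ditrysia	12	trnD	J
ditrysia	13	ATP8	J
ditrysia	14	ATP6	J
ditrysia	15	COIII	J
ditrysia	16	trnG	J
ditrysia	17	ND3	J
ditrysia	18	trnA	J
ditrysia	19	trnR	J
ditrysia	20	trnN	J
ditrysia	21	trnS^AGN	J
ditrysia	22	trnE	J
ditrysia	23	trnF	N
ditrysia	24	ND5	N
ditrysia	25	trnH	N
ditrysia	26	ND4	N
ditrysia	27	ND4L	N
ditrysia	28	trnT	J
ditrysia	29	trnP	N
ditrysia	30	ND6	J
ditrysia	31	CYTB	J
ditrysia	32	trnS^UCN	J
ditrysia	33	ND1	N
ditrysia	34	trnL^CUN	N
ditrysia	35	rrnL	N
ditrysia	36	trnV	N
ditrysia	37	rrnS	N
ditrysia	38	CR	J
ancestral	1	trnI	J
ancestral	2	trnQ	N
ancestral	3	trnM	J
ancestral	4	ND2	J
ancestral	5	trnW	J
ancestral	6	trnC	N
ancestral	7	trnY	N
ancestral	8	COI	J
ancestral	9	trnL^UUR	J
ancestral	10	COII	J
ancestral	11	trnK	J
ancestral	12	trnD	J
ancestral	13	ATP8	J
ancestral	14	ATP6	J
ancestral	15	COIII	J
ancestral	16	trnG	J
ancestral	17	ND3	J
ancestral	18	trnA	J
ancestral	19	trnR	J
ancestral	20	trnN	J
ancestral	21	trnS^AGN	J
ancestral	22	trnE	J
ancestral	23	trnF	N
ancestral	24	ND5	N
ancestral	25	trnH	N
ancestral	26	ND4	N
ancestral	27	ND4L	N
ancestral	28	trnT	J
ancestral	29	trnP	N
ancestral	30	ND6	J
ancestral	31	CYTB	J
ancestral	32	trnS^UCN	J
ancestral	33	ND1	N
ancestral	34	trnL^CUN	N
ancestral	35	rrnL	N
ancestral	36	trnV	N
ancestral	37	rrnS	N
ancestral	38	CR	J
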