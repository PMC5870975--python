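# Canonical mitochondrial gene names, v1.
# columns: canonical, kind, anticodon (RNA, tRNAs only), aliases (|-separated, matched case-insensitively after stripping spaces/hyphens/underscores)
canonical	kind	anticodon	aliases
ATP6	PCG	-	ATP6|ATPASE6|ATP SYNTHASE F0 SUBUNIT 6|ATPASE SUBUNIT 6
ATP8	PCG	-	ATP8|ATPASE8|ATP SYNTHASE F0 SUBUNIT 8|ATPASE SUBUNIT 8
COI	PCG	-	COI|COX1|CO1|COXI|CYTOCHROME C OXIDASE SUBUNIT I|CYTOCHROME C OXIDASE SUBUNIT 1|CYTOCHROME OXIDASE SUBUNIT I|COX I
COII	PCG	-	COII|COX2|CO2|COXII|CYTOCHROME C OXIDASE SUBUNIT II|CYTOCHROME C OXIDASE SUBUNIT 2|CYTOCHROME OXIDASE SUBUNIT II|COX II
COIII	PCG	-	COIII|COX3|CO3|COXIII|CYTOCHROME C OXIDASE SUBUNIT III|CYTOCHROME C OXIDASE SUBUNIT 3|CYTOCHROME OXIDASE SUBUNIT III|COX III
CYTB	PCG	-	CYTB|COB|CYB|CYTOCHROME B|CYTOCHROME B APOENZYME
ND1	PCG	-	ND1|NAD1|NADH1|NADH DEHYDROGENASE SUBUNIT 1
ND2	PCG	-	ND2|NAD2|NADH2|NADH DEHYDROGENASE SUBUNIT 2
ND3	PCG	-	ND3|NAD3|NADH3|NADH DEHYDROGENASE SUBUNIT 3
ND4	PCG	-	ND4|NAD4|NADH4|NADH DEHYDROGENASE SUBUNIT 4
ND4L	PCG	-	ND4L|NAD4L|NADH4L|NADH DEHYDROGENASE SUBUNIT 4L
ND5	PCG	-	ND5|NAD5|NADH5|NADH DEHYDROGENASE SUBUNIT 5
ND6	PCG	-	ND6|NAD6|NADH6|NADH DEHYDROGENASE SUBUNIT 6
rrnL	rRNA	-	RRNL|16S|LRRNA|L-RRNA|16S RIBOSOMAL RNA|16S RRNA|LARGE SUBUNIT RIBOSOMAL RNA|RRN16
rrnS	rRNA	-	RRNS|12S|SRRNA|S-RRNA|12S RIBOSOMAL RNA|12S RRNA|SMALL SUBUNIT RIBOSOMAL RNA|RRN12
trnA	tRNA	UGC	TRNA-ALA|TRNA(ALA)
trnC	tRNA	GCA	TRNA-CYS|TRNC
trnD	tRNA	GUC	TRNA-ASP|TRND
trnE	tRNA	UUC	TRNA-GLU|TRNE
trnF	tRNA	GAA	TRNA-PHE|TRNF
trnG	tRNA	UCC	TRNA-GLY|TRNG
trnH	tRNA	GUG	TRNA-HIS|TRNH
trnI	tRNA	GAU	TRNA-ILE|TRNI
trnK	tRNA	CUU	TRNA-LYS|TRNK
trnL^CUN	tRNA	UAG	TRNL1|TRNL^CUN|TRNL(CUN)|TRNA-LEU(CUN)|TRNA-LEU1
trnL^UUR	tRNA	UAA	TRNL2|TRNL^UUR|TRNL(UUR)|TRNA-LEU(UUR)|TRNA-LEU2
trnM	tRNA	CAU	TRNA-MET|TRNM
trnN	tRNA	GUU	TRNA-ASN|TRNN
trnP	tRNA	UGG	TRNA-PRO|TRNP
trnQ	tRNA	UUG	TRNA-GLN|TRNQ
trnR	tRNA	UCG	TRNA-ARG|TRNR
trnS^AGN	tRNA	GCU	TRNS1|TRNS^AGN|TRNS(AGN)|TRNA-SER(AGN)|TRNA-SER1
trnS^UCN	tRNA	UGA	TRNS2|TRNS^UCN|TRNS(UCN)|TRNA-SER(UCN)|TRNA-SER2
trnT	tRNA	UGU	TRNA-THR|TRNT
trnV	tRNA	UAC	TRNA-VAL|TRNV
trnW	tRNA	UCA	TRNA-TRP|TRNW
trnY	tRNA	GUA	TRNA-TYR|TRNY
CR	CR	-	CR|A+T-RICH REGION|AT-RICH REGION|CONTROL REGION|D-LOOP|PUTATIVE CONTROL REGION
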