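# synonym -> canonical gene label. Lookup is case-insensitive and ignores
# spaces, hyphens, underscores, parentheses and carets, so one row covers
# e.g. "tRNA-Leu(UUR)", "trnL-uur" and "TRNL_UUR".
# synonym	canonical
ND1	ND1
NAD1	ND1
NADH1	ND1
NADH dehydrogenase subunit 1	ND1
ND2	ND2
NAD2	ND2
NADH2	ND2
NADH dehydrogenase subunit 2	ND2
ND3	ND3
NAD3	ND3
NADH3	ND3
NADH dehydrogenase subunit 3	ND3
ND4	ND4
NAD4	ND4
NADH4	ND4
NADH dehydrogenase subunit 4	ND4
ND4L	ND4L
NAD4L	ND4L
NADH4L	ND4L
NADH dehydrogenase subunit 4L	ND4L
ND5	ND5
NAD5	ND5
NADH5	ND5
NADH dehydrogenase subunit 5	ND5
ND6	ND6
NAD6	ND6
NADH6	ND6
NADH dehydrogenase subunit 6	ND6
COX1	COX1
CO1	COX1
COI	COX1
COXI	COX1
cytochrome c oxidase subunit 1	COX1
cytochrome c oxidase subunit I	COX1
cytochrome oxidase subunit 1	COX1
COX2	COX2
CO2	COX2
COII	COX2
COXII	COX2
cytochrome c oxidase subunit 2	COX2
cytochrome c oxidase subunit II	COX2
cytochrome oxidase subunit 2	COX2
COX3	COX3
CO3	COX3
COIII	COX3
COXIII	COX3
cytochrome c oxidase subunit 3	COX3
cytochrome c oxidase subunit III	COX3
cytochrome oxidase subunit 3	COX3
ATP6	ATP6
ATPase6	ATP6
ATPase subunit 6	ATP6
ATP synthase F0 subunit 6	ATP6
ATP8	ATP8
ATPase8	ATP8
ATPase subunit 8	ATP8
ATP synthase F0 subunit 8	ATP8
CYTB	CYTB
CytB	CYTB
COB	CYTB
cytochrome b	CYTB
16S rRNA	16S rRNA
16S	16S rRNA
16S ribosomal RNA	16S rRNA
rrnL	16S rRNA
l-rRNA	16S rRNA
lrRNA	16S rRNA
large subunit ribosomal RNA	16S rRNA
12S rRNA	12S rRNA
12S	12S rRNA
12S ribosomal RNA	12S rRNA
rrnS	12S rRNA
s-rRNA	12S rRNA
srRNA	12S rRNA
small subunit ribosomal RNA	12S rRNA
trnA	trnA
tRNA-Ala	trnA
trnR	trnR
tRNA-Arg	trnR
trnN	trnN
tRNA-Asn	trnN
trnD	trnD
tRNA-Asp	trnD
trnC	trnC
tRNA-Cys	trnC
trnE	trnE
tRNA-Glu	trnE
trnQ	trnQ
tRNA-Gln	trnQ
trnG	trnG
tRNA-Gly	trnG
trnH	trnH
tRNA-His	trnH
trnI	trnI
tRNA-Ile	trnI
trnK	trnK
tRNA-Lys	trnK
trnM	trnM
tRNA-Met	trnM
trnF	trnF
tRNA-Phe	trnF
trnP	trnP
tRNA-Pro	trnP
trnT	trnT
tRNA-Thr	trnT
trnW	trnW
tRNA-Trp	trnW
trnY	trnY
tRNA-Tyr	trnY
trnV	trnV
tRNA-Val	trnV
trnL_UUR	trnL_UUR
trnL UUR	trnL_UUR
tRNA-Leu(UUR)	trnL_UUR
trnL2	trnL_UUR
tRNA-Leu2	trnL_UUR
trnL_CUN	trnL_CUN
trnL CUN	trnL_CUN
tRNA-Leu(CUN)	trnL_CUN
trnL1	trnL_CUN
tRNA-Leu1	trnL_CUN
trnS_AGN	trnS_AGN
trnS AGN	trnS_AGN
tRNA-Ser(AGN)	trnS_AGN
trnS1	trnS_AGN
tRNA-Ser1	trnS_AGN
trnS_UCN	trnS_UCN
trnS UCN	trnS_UCN
tRNA-Ser(UCN)	trnS_UCN
trnS2	trnS_UCN
tRNA-Ser2	trnS_UCN
AT-rich region	AT-rich region
AT rich region	AT-rich region
A+T-rich region	AT-rich region
control region	AT-rich region
D-loop	AT-rich region
putative control region	AT-rich region
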