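# Ancestral insect mitochondrial gene order, major strand = the strand
# carrying the majority of genes. One row per feature in genomic order.
# name	kind	strand
trnI	tRNA	major
trnQ	tRNA	minor
trnM	tRNA	major
ND2	PCG	major
trnW	tRNA	major
trnC	tRNA	minor
trnY	tRNA	minor
COX1	PCG	major
trnL_UUR	tRNA	major
COX2	PCG	major
trnK	tRNA	major
trnD	tRNA	major
ATP8	PCG	major
ATP6	PCG	major
COX3	PCG	major
trnG	tRNA	major
ND3	PCG	major
trnA	tRNA	major
trnR	tRNA	major
trnN	tRNA	major
trnS_AGN	tRNA	major
trnE	tRNA	major
trnF	tRNA	minor
ND5	PCG	minor
trnH	tRNA	minor
ND4	PCG	minor
ND4L	PCG	minor
trnT	tRNA	major
trnP	tRNA	minor
ND6	PCG	major
CYTB	PCG	major
trnS_UCN	tRNA	major
ND1	PCG	minor
trnL_CUN	tRNA	minor
16S rRNA	rRNA	minor
trnV	tRNA	minor
12S rRNA	rRNA	minor
AT-rich region	AT_rich	major
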