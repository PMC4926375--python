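# mitocomp

Comparative analysis of mitochondrial genomes, built for the small
circular genomes of insects (≈15–16 kb; 13 protein-coding genes, 22
tRNAs, 2 rRNAs and one AT-rich control region) but applicable to any
similarly annotated metazoan mitogenome set.

Insect mitogenomes are strongly A+T biased and strand-asymmetric, and
nearly all of their comparative signal lives in a handful of standard
statistics. `mitocomp` computes them from GenBank records, end to end:

* **Composition & strand asymmetry** — per-partition base counts and the
  skew pair AT-skew = (A−T)/(A+T), GC-skew = (G−C)/(G+C), including
  codon positions 1/2/3 split by coding strand.
* **Codon-usage bias** under the invertebrate mitochondrial code
  (translation table 5): RSCU, codon-family third-base shares
  (NNA/NNU/NNC/NNG), the pooled share of the four AT-rich codons
  (UUU, UUA, AUU, AUA), Wright's effective number of codons (ENC), the
  codon bias index (CBI), GC and GC3, and the pairwise correlations
  (ENC~GC3, CBI~ENC, …) used to diagnose mutational vs selective bias.
* **Evolutionary rates** — per-gene Ka, Ks and ω = Ka/Ks by the
  Nei–Gojobori (1986) pathway method with Jukes–Cantor correction,
  averaged over all in-group pairwise comparisons.
* **RNA conservation** — %INUC (percent of identical alignment columns)
  per tRNA/rRNA family and per structural region (cloverleaf stems,
  loops, rRNA helices) given structure masks.
* **Control-region elements** — rule-based scanners for tandem repeats
  (consensus size, copy number, AT%, adjacent-copy identity),
  strand-specific perfect T-stretches, (AT)n≥5 microsatellites,
  T-stretch flanking-motif consensus with X wildcards, perfect
  Watson–Crick stem-loops, and the conserved trnS(UCN)–ND1 spacer motif
  (TACTAA).
* **Supermatrices** — the four standard concatenated datasets (PCG,
  mtDNA, PCG12, mtDNA12) with exact codon-position charsets, exported
  as relaxed PHYLIP and NEXUS.

A first-class synthetic-mitogenome generator
(`mitocomp.synthetic_mitogenome`) emits clades with configurable
composition, strand-specific codon preference, substitution rates and
planted control-region elements, together with an exact ground-truth
record — every analysis stage is testable without downloading anything.

## Worked example

```python
from mitocomp.synthetic_mitogenome import SynthConfig, generate_clade
from mitocomp.genome_io import partition_set, extract_gene
from mitocomp.composition import summarize
from mitocomp.codon_usage import count_codons, summary_row
from mitocomp.at_rich import find_t_stretches, find_tandem_repeats
from mitocomp.evol_rates import gene_rates

genomes, truth = generate_clade(SynthConfig(seed=1, n_genomes=5))
ps = partition_set(genomes[0])

whole = summarize(genomes[0].sequence, "whole_genome")
print(genomes[0].id, genomes[0].length, round(whole.at_content, 3))
# SYN01 15812 0.718      <- 71.8% A+T, typical for a beetle mitogenome

row = summary_row(count_codons(ps.pcgs))
print(round(row["enc"], 2), round(row["cbi"], 3), round(row["gc3"], 3))
# 40.06 0.185 0.132      <- strong A/T codon bias: low ENC, GC3 ~13%

print([(h.strand, h.start, h.end) for h in find_t_stretches(ps.at_rich)])
# [('major', 499, 512), ('minor', 786, 794)]   <- replication-origin signals

print([(h.consensus_size, h.copy_number) for h in find_tandem_repeats(ps.at_rich)])
# [(20, 2.2), (22, 1.9)]                       <- planted control-region repeats

aligned = {g: {x.id: extract_gene(x, g).coding for x in genomes}
           for g in ("ATP8", "COX1")}
aligned = {g: {t: s[: len(s) - len(s) % 3] for t, s in r.items()}
           for g, r in aligned.items()}
for r in gene_rates(aligned):
    print(r.gene, round(r.ka, 4), round(r.ks, 4), round(r.omega, 3))
# ATP8 0.0165 0.1164 0.142
# COX1 0.0060 0.1422 0.042   <- omega << 1: purifying selection, COX1 tightest
```

The same analyses run from the shell over a directory of GenBank files:

```sh
mitocomp synth -o bundle --seed 1 -n 5      # or point at your own records
mitocomp all bundle -o results
```

which writes `composition.tsv`, `codon_summary.tsv`, `correlations.tsv`,
`rates.tsv`, `conservation*.tsv`, the control-region report tables and
BED file, the four supermatrix exports, and a JSON run manifest.

## Layout

| module | contents |
| --- | --- |
| `mitocomp.genome_io` | GenBank/FASTA I/O, gene-name canonicalisation, extraction, partitions |
| `mitocomp.synthetic_mitogenome` | clade generator with ground truth |
| `mitocomp.composition` | base counts, A+T content, AT/GC skews |
| `mitocomp.codon_usage` | RSCU, ENC, CBI, GC3, correlations |
| `mitocomp.evol_rates` | NG86 Ka/Ks/ω |
| `mitocomp.conservation_rna` | %INUC and structural-region summaries |
| `mitocomp.at_rich` | control-region element scanners |
| `mitocomp.phylo_matrix` | supermatrix construction and export |
| `mitocomp.pipeline`, `mitocomp.cli` | orchestration and the `mitocomp` command |

See `docs/methods.md` for the statistical definitions, generator design
and numerical conventions.
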