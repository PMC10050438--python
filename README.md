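# regnominate

Nominate candidate transcriptional regulators of fungal cellulase
secretion by linking three layers of evidence: the frequency of
transcription-factor (TF) binding sites on cellulase promoters, the
abundance of the secreted cellulases, and the transcriptional response
of the TFs themselves when cultures switch from glucose (repressing) to
cellulose (inducing) carbon sources.

It is written for computational biologists studying carbon catabolite
repression and cellulase induction in filamentous fungi
(*Penicillium*, *Trichoderma*, *Aspergillus*, *Neurospora*), where the
regulatory cascade upstream of effectors such as Xyr1/XlnR and Cre1 is
incompletely mapped and candidate regulators must be prioritised from
genome-scale evidence before any genetic intervention.

## The method

1. **Promoters.** For each ORF, the promoter is the intergenic space
   immediately upstream, capped at 1500 bp and cut short by the nearest
   neighbouring gene on either strand or by the contig edge. Sequences
   are reported 5'→3' relative to the gene.
2. **Binding-site counts.** Each TF model — an IUPAC consensus or a
   TRANSFAC-style count matrix — is scanned over both strands of every
   promoter. Matrix models score windows by log₂-odds against the
   pooled promoter base composition (pseudocount 0.5) and call a hit at
   ≥ `threshold_frac` (default 0.85) of the maximum attainable score.
   The result is the TF × gene count matrix **M**.
3. **Expression.** FPKM = 10⁹·C/(N·L), with C the fragments uniquely
   aligned to the gene, N the library's total uniquely aligned
   fragments and L the gene length. Fold change between glucose
   (G‑FPKM) and cellulose (C‑FPKM) supports ratio, log₂ and
   signed-ratio conventions; genes classify as up / down / unchanged /
   unique_induced / unique_control / undetected.
4. **Tier 1.** For each TF, Pearson's r between its row of **M** over
   the cellulase target set and the secretome abundance vector. TFs
   with r > 0 are kept, TFs without a host-genome homolog are dropped,
   TFs sharing a host gene are collapsed into one regulator, and each
   regulator carries its host gene's expression class.
5. **Tier 2.** The promoters of the tier-1 host genes are scanned with
   the full motif library; TFs with at least one site are mapped,
   collapsed and annotated the same way, partitioning the "early
   regulator" set into up- / down-regulated / unchanged members.
6. **Protein descriptors.** Residue count, average molecular weight,
   isoelectric point (EMBOSS pKa set, bisection on the monotone net
   charge) and the Kyte–Doolittle GRAVY index for protein FASTA input.

A synthetic-data module generates multi-contig genomes, motif
libraries, secretome abundances and two-condition counts with planted
ground truth (causal TFs at a controlled effect size, chosen expression
classes), so the full pipeline is testable without any downloads.

## Worked example

Simulate a study (70 genes, 13 cellulase-like targets, 51 TF motifs,
5 causal TFs planted at Pearson r = 0.8) and run the pipeline:

```bash
regnominate simulate --seed 42 --out-dir sim
regnominate promoters  --fasta sim/genome.fa --gff sim/genes.gff3 --out promoters.bed
regnominate scan       --fasta sim/genome.fa --gff sim/genes.gff3 \
                       --motifs sim/motifs.tsv --motif-format iupac_tsv \
                       --threshold 1.0 --out sites.tsv
regnominate expression --counts sim/counts.tsv --n-control 1000000 \
                       --n-test 1000000 --out expr.tsv
regnominate infer      --sites sites.tsv --abundance sim/abundance.tsv \
                       --map sim/homolog_map.tsv --expr expr.tsv \
                       --fasta sim/genome.fa --gff sim/genes.gff3 \
                       --motifs sim/motifs.tsv --motif-format iupac_tsv \
                       --out-dir results
```

which prints

```
simulated 70 genes on 3 contigs; targets=13, motifs=51; files in sim
wrote 70 promoters for 70 genes to promoters.bed
wrote 51 x 70 count matrix to sites.tsv
wrote expression table (70 genes) to expr.tsv
tier 1: 23 regulators (0 positive TFs unmapped)
tier 2: 24 early regulators, classes {'down': 12, 'up': 12}
```

and the head of `results/tier1.tsv`:

```
regulator_id  member_tfs  host_gene_id  r         expr_class  fc
TF05          TF05        g008          0.888688  up          6.8642
TF02          TF02        g002          0.87861   up          1.20175
TF01          TF01        g001          0.84953   down        -4.10112
TF04          TF04        g007          0.788933  down        -6.17308
TF29          TF29        g042          0.737887  up          5.4
```

The planted causal TFs in this run are TF01–TF05: four of them head the
ranking (TF03 sits just below the top five, edged out by a chance
correlation of the non-causal TF29), which is exactly the behaviour the
recovery benchmark quantifies across seeds. The `r` column is the
Pearson correlation between each TF's binding-site counts on the 13
target promoters and the target genes' abundances; `expr_class`/`fc`
describe the TF's own host gene on induction.

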