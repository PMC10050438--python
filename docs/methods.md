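# Methods

This note documents the models, conventions and numerical choices
behind `regnominate`, and what the synthetic benchmarks do and do not
demonstrate about real data.

## Promoter model

A promoter is defined operationally from gene models alone: the
intergenic interval immediately 5' of an ORF, capped at `max_len`
(default 1500 bp). The anchor is the ORF boundary, not a transcription
start site — the analysis is designed for draft annotations without TSS
maps. The bounding neighbour is the nearest gene on *either* strand,
because the defining notion is shared intergenic space, not same-strand
spacing. Consequences of this definition:

- A promoter never overlaps a gene, but two promoters may overlap each
  other (a divergent or convergent gene pair sharing one gap).
- `truncated` is set when the neighbour or the contig edge, rather than
  the cap, fixed a boundary; a gene whose 5' end touches position 0 (or
  the contig end, on the minus strand) has no promoter and is skipped
  with a log message.
- Overlapping gene models are rejected at load rather than resolved:
  the promoter of a gene inside another gene is undefined under this
  model, and silently guessing would corrupt every downstream count.

Coordinates are 0-based half-open internally; GFF3 (1-based inclusive)
and BED (0-based half-open) are converted only at the I/O boundary.
Ambiguous bases (N) are retained in promoter sequences; the scanner
decides their treatment.

## Binding-site scanning

Two motif representations are supported. **Consensus** motifs match
IUPAC-degenerate patterns exactly. **Matrix** motifs are 4 × L count
matrices turned into log₂-odds scores: column frequencies are
pseudocounted (default 0.5 per cell, avoiding −∞ columns), and the
background is the pooled A/C/G/T composition of the promoter set being
scanned, so scores are comparable across genes of one run. A window is
a hit when its score reaches `threshold_frac` × the maximum attainable
score; the default 0.85 is a conventional relative-score cutoff and is
stamped into outputs and the run manifest because no universal value
exists. Scores within 1e-9 of the cutoff count as hits, so
`threshold_frac = 1.0` always admits the maximum-scoring string despite
floating-point summation.

Both strands are scanned and pooled into one count: an opposite-strand
hit at offset *i* means the reverse complement of the window matches.
Overlapping and self-overlapping occurrences all count (no
de-duplication rule is imposed on "frequency"), and a palindromic
pattern therefore counts a matching window once per strand. Windows
containing N never match or score — conservative counting, so ambiguous
sequence can only lose hits, never invent them.

## Expression model

FPKM = 10⁹·C/(N·L). The formula is applied to uniquely aligned
fragment counts as given; multi-mapping resolution is out of scope.
Transcript-level rows are aggregated to gene level by summing C before
the division.

Fold change supports three conventions because reporting styles mix
them in practice: plain ratio c/g, log₂(c/g), and a **signed ratio**
(c/g when c ≥ g, else −g/c) that reproduces "FC > 1 / FC < −1"-style
thresholds while keeping ratio-scale magnitudes. The signed ratio has
no values strictly inside (−1, 1); with the default thresholds (1, −1)
the `unchanged` class therefore collapses to exact equality c = g. This
is a faithful property of the convention, not a bug; analyses that want
a real unchanged band should widen the thresholds (the class-recovery
benchmark uses ±2 against planted ratios of 4–8). Genes detected in
only one condition are classed `unique_induced` / `unique_control`
(zero FPKM on the other side), mirroring not-detected entries in
two-condition tables; fold change is undefined there and propagates as
missing, never as an error.

## Protein descriptors

Molecular weight is the sum of average residue masses plus one water,
in kDa; average (not monoisotopic) masses match the scale used when
reporting whole-protein weights. GRAVY is the mean Kyte–Doolittle
hydropathy per residue. The isoelectric point solves net charge = 0
under the Henderson–Hasselbalch model with the EMBOSS pKa set (N-term
8.6, C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1),
by bisection on [0, 14] to 1e-4; the net charge is strictly decreasing
in pH, so the root is unique. Published pI values computed by other
tools embed different pKa constants and can differ by a few tenths of a
pH unit; they are treated as approximate references, not goldens.
Ambiguity codes (B, Z, X) are rejected rather than averaged.

## Regulator nomination

Tier-1 candidacy is Pearson correlation (the field's default
descriptive statistic for this design) between a TF's binding-site
counts and the secretome abundance vector over the target gene set,
with no significance filter: at the typical n ≈ 13 targets a p-value
would be anti-conservative theatre, so positivity (r > 0, strictly) is
the only correlation filter and the r values are reported
descriptively. Spearman is available behind the Pearson helper for
robustness checks but is never the default. A zero-variance count
vector leaves r undefined (reported, never nominated). TF–TF
correlations are deliberately not computed.

Homolog collapsing consumes an explicit TF → host-gene mapping file;
sequence alignment is upstream of this package and the merges are data.
Collapsed entries carry all member TF names, the maximum member r, and
the host gene's expression class; TFs without a mapping are dropped and
logged. Tier-2 candidacy requires ≥ 1 binding site on ≥ 1 tier-1
promoter (`--min-hits` raises the bar), reflecting a presence-based
definition of "contains binding sites"; the tier-2 report partitions
into up / down / unchanged / no-expression entries.

## Synthetic data: what it emulates, and what it does not

The generator emulates the *structure* of a two-condition induction
study: a multi-contig genome with strand-mixed non-overlapping ORFs and
uniform intergenic gaps (default 200–4000 bp, so truncated and
full-length promoters both occur); a 51-motif library of unique 8-mer
consensuses (mutually distinct including reverse complements, no
palindromes, so plantings cannot cross-register between TFs); 13
target genes with lognormal secretome abundances; and Poisson fragment
counts at N = 10⁶ per library realising planted expression classes with
wide margins (ratios 4–8 against ±2 classification thresholds).

The causal-TF mechanism operates on planted **counts**, because the
pipeline's statistic is a count correlation: per-gene counts are
`round(m + b·z + ε)` clamped at 0, with z the standardised abundance,
m = 5, b = 2.5 and the noise variance solving r = b/√(b² + σ²) for the
target effect size (default 0.8). Rounding and clamping attenuate the
realised correlation slightly — in the noiseless limit the sample r is
≈ 0.99+, not exactly 1 — and clamped draws are recorded in the ground
truth so tests can compare against realised, not just target, values.
Non-causal TFs get Poisson(1) counts independent of abundance. Planted
sites are exact consensus strings inserted at uniformly drawn
non-overlapping offsets on a random strand, replacing background; the
underlying contigs are patched so every emitted file stays mutually
consistent, and every promoter is re-sliced from the patched contigs
(promoters sharing intergenic space with a planted target would
otherwise go stale).

Background sequence is i.i.d. at the configured GC content, not
Markov: sufficient for scan-oracle testing because spurious-hit rates
are *measured* by the tests, not assumed. Real promoters have
repeat structure, composition bias and nucleosome-scale organisation
that this background lacks, so passing benchmarks demonstrate that the
pipeline recovers planted signal under its own model — they do not
certify binding-site calls on real genomes, where the motif library and
threshold dominate the error budget. Target genes are chosen among
promoters ≥ 1200 bp that do not physically overlap one another, which
guarantees planting room (≈ 70 sites × 8 bp ≪ 1200 bp) at the default
densities.

Two deterministic benchmarks encode known filter/merge structures end
to end: a tier-1 benchmark in which 22 positively correlated TFs with 7
unmapped members and two host-sharing pairs must collapse to exactly 13
regulators, and a tier-2 cascade in which 45 candidate TFs (7 without
protein sequence, 3 without a host homolog, one 3-way and three 2-way
merges) must yield 30 regulators of which one lacks expression data,
one is unchanged, 12 are up- and 16 downregulated. These check the
set algebra of the nomination cascade byte-for-byte.

## Problem sizes and determinism

Benchmarks use 50 simulated genomes for promoter invariants, 100
sequences × 10 motifs for scan-oracle equivalence, 20 × 200 genes for
FPKM recovery and 50 seeded runs for planted-regulator recovery —
sizes at which the binomial noise on every reported fraction is well
below the asserted margins while a full run stays interactive. All
randomness flows from one `numpy.random.default_rng` seed per config;
two runs with equal configs are byte-identical across every emitted
file, including the JSON run manifest (which records thresholds, the
fold-change convention, the seed and SHA-256 digests of the inputs).

## Known limitations

- Binding-site presence is treated as regulatory potential; no
  chromatin accessibility, spacing or cooperativity model is applied.
- Correlation-based nomination is descriptive, not causal, and with
  ~13 targets the ranking is sensitive to single-gene perturbations;
  the recovery benchmark quantifies exactly this noise.
- The pI model ignores post-translational modifications and structural
  pKa shifts; descriptors are composition-only by construction.
- The signed-ratio convention cannot express fold changes between −1
  and 1; switch to `log2` for symmetric-scale analyses.
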