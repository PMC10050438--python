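"""Synthetic study generator with known ground truth.

Emulates the structure of a cellulase-induction study: a multi-contig
genome with strand-mixed, non-overlapping ORFs and variable intergenic
gaps; a motif library in which a few "causal" TFs have planted
binding-site counts that correlate with a secretome abundance vector at
a controlled effect size; and two-condition fragment counts realising
chosen expression classes (including condition-unique genes).  All
randomness flows from a single seed; equal configs produce
byte-identical output files.

The effect-size mechanism operates on planted *counts*: for a causal
TF, per-gene site counts are ``round(base + b*z + eps)`` clamped at 0,
where z is the standardised abundance and the noise variance solves
corr = b / sqrt(b^2 + sigma^2) for the target Pearson r.  Planted
instances are exact consensus strings inserted at recorded
non-overlapping offsets, replacing background sequence, so a scan at
threshold 1.0 always recovers at least the planted count.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import expression_table
from .genome_io import Contig, GeneModel, PromoterRegion, extract_promoters
from .motif_scan import MotifModel, reverse_complement

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design
    (13 cellulase targets, 51-TF library, 5 causal TFs, two conditions)."""

    seed: int = 0
    n_contigs: int = 3
    n_genes: int = 70
    gene_length_range: tuple[int, int] = (900, 3000)
    intergenic_gap_range: tuple[int, int] = (200, 4000)
    gc_content: float = 0.5
    motif_library_size: int = 51
    motif_length: int = 8
    n_target_genes: int = 13
    n_causal_tfs: int = 5
    effect_size: float = 0.8
    causal_mean_count: float = 5.0
    causal_count_amplitude: float = 2.5
    noncausal_mean_count: float = 1.0
    abundance_log_mean: float = math.log(50.0)
    abundance_noise_sd: float = 1.0  # lognormal sigma of the abundance vector
    library_size_control: int = 1_000_000
    library_size_test: int = 1_000_000
    planted_class_counts: dict[str, int] | None = None
    max_contig_length: int | None = None
    min_target_promoter_len: int = 1200

    def __post_init__(self) -> None:
        if self.n_causal_tfs > self.motif_library_size:
            raise ValueError("n_causal_tfs cannot exceed motif_library_size")
        if self.n_target_genes < 3:
            raise ValueError("n_target_genes must be >= 3")
        if not (0 < self.effect_size <= 1):
            raise ValueError("effect_size must be in (0, 1]")
        if not (0 < self.gc_content < 1):
            raise ValueError("gc_content must be in (0, 1)")
        if self.planted_class_counts is not None:
            if sum(self.planted_class_counts.values()) != self.n_target_genes:
                raise ValueError("planted_class_counts must sum to n_target_genes")

    def target_class_counts(self) -> dict[str, int]:
        if self.planted_class_counts is not None:
            return dict(self.planted_class_counts)
        # cellulase-like default: mostly induced on the test substrate
        n = self.n_target_genes
        counts = {"up": n - 6, "down": 2, "unchanged": 1,
                  "unique_induced": 2, "unique_control": 1}
        return counts


@dataclass
class GroundTruth:
    """Everything planted: sites, causal set, abundance, FPKM, classes."""

    planted_sites: list[tuple[str, str, int, str]] = field(default_factory=list)
    causal_tfs: set[str] = field(default_factory=set)
    true_abundance: dict[str, float] = field(default_factory=dict)
    planted_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    clamped_draws: list[tuple[str, str]] = field(default_factory=list)
    true_fpkm: dict[str, tuple[float, float]] = field(default_factory=dict)
    true_class: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        data = {
            "planted_sites": self.planted_sites,
            "causal_tfs": sorted(self.causal_tfs),
            "true_abundance": self.true_abundance,
            "planted_counts": self.planted_counts,
            "clamped_draws": self.clamped_draws,
            "true_fpkm": {g: list(v) for g, v in self.true_fpkm.items()},
            "true_class": self.true_class,
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[Contig], list[GeneModel]]:
    """Place non-overlapping genes with mixed strands and variable gaps.

    Genes are laid out left to right per contig: leading gap, gene,
    gap, gene, ...  With the default gap range both truncated (< max
    promoter length) and full-length promoters occur.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    gmin, gmax = config.intergenic_gap_range
    lmin, lmax = config.gene_length_range
    per_contig = [config.n_genes // config.n_contigs] * config.n_contigs
    for i in range(config.n_genes % config.n_contigs):
        per_contig[i] += 1

    contigs: list[Contig] = []
    genes: list[GeneModel] = []
    gene_no = 0
    for ci in range(config.n_contigs):
        contig_id = f"ctg{ci + 1}"
        parts: list[str] = []
        pos = 0
        for _ in range(per_contig[ci]):
            gap = int(rng.integers(gmin, gmax + 1))
            glen = int(rng.integers(lmin, lmax + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            parts.append(_random_dna(rng, gap + glen, config.gc_content))
            gene_no += 1
            genes.append(
                GeneModel(f"g{gene_no:03d}", contig_id, pos + gap, pos + gap + glen, strand)
            )
            pos += gap + glen
        tail = int(rng.integers(gmin, gmax + 1))
        parts.append(_random_dna(rng, tail, config.gc_content))
        pos += tail
        if config.max_contig_length is not None and pos > config.max_contig_length:
            raise ValueError(
                f"contig {contig_id}: genes + gaps ({pos} bp) exceed the "
                f"contig budget of {config.max_contig_length} bp"
            )
        contigs.append(Contig(contig_id, "".join(parts)))
    return contigs, genes


def make_motif_library(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[MotifModel]:
    """Random unambiguous consensus motifs, pairwise distinct including
    reverse complements and excluding palindromes (so a planted site for
    one TF can never register as a hit for another)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    seen: set[str] = set()
    motifs: list[MotifModel] = []
    while len(motifs) < config.motif_library_size:
        cons = "".join(_BASES[rng.integers(0, 4, size=config.motif_length)])
        rc = reverse_complement(cons)
        if cons == rc or cons in seen or rc in seen:
            continue
        seen.update((cons, rc))
        motifs.append(
            MotifModel(
                tf_name=f"TF{len(motifs) + 1:02d}", kind="consensus", consensus=cons
            )
        )
    return motifs


def _draw_abundance(
    config: SimulationConfig, target_ids: list[str], rng: np.random.Generator
) -> dict[str, float]:
    vals = rng.lognormal(config.abundance_log_mean, config.abundance_noise_sd,
                         size=len(target_ids))
    return {g: float(v) for g, v in zip(target_ids, vals)}


def _causal_counts(
    abundance: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Planted counts whose correlation with abundance targets effect_size.

    Returns (counts, clamped_mask).  Noise sd solves
    r = b / sqrt(b^2 + sigma^2) for the pre-rounding linear model.
    """
    z = (abundance - abundance.mean()) / abundance.std()
    b = config.causal_count_amplitude
    r = config.effect_size
    sigma = 0.0 if r >= 1.0 else b * math.sqrt(1.0 / r**2 - 1.0)
    raw = config.causal_mean_count + b * z + rng.normal(0.0, sigma, size=len(z))
    counts = np.round(raw)
    clamped = counts < 0
    return np.clip(counts, 0, None).astype(int), clamped


def plant_motifs_with_effect(
    contigs: list[Contig],
    promoters: list[PromoterRegion],
    target_gene_ids: list[str],
    motifs: list[MotifModel],
    abundance: dict[str, float],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[Contig], list[PromoterRegion], GroundTruth]:
    """Insert exact consensus sites into the target promoters.

    Causal TFs (the first ``n_causal_tfs`` in the library) get per-gene
    counts correlated with abundance; the rest get Poisson counts
    independent of it.  Sites are placed at non-overlapping uniform
    offsets, on a random strand, replacing background sequence; both
    the promoter sequences and the underlying contigs are patched so
    re-extraction reproduces the planted promoters.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    by_gene = {p.gene_id: p for p in promoters}
    missing = [g for g in target_gene_ids if g not in by_gene]
    if missing:
        raise ValueError(f"target gene(s) without promoters: {missing}")

    truth = GroundTruth()
    truth.causal_tfs = {m.tf_name for m in motifs[: config.n_causal_tfs]}
    truth.true_abundance = {g: abundance[g] for g in target_gene_ids}
    ab = np.array([abundance[g] for g in target_gene_ids])

    counts_per_tf: dict[str, np.ndarray] = {}
    for k, motif in enumerate(motifs):
        if k < config.n_causal_tfs:
            counts, clamped = _causal_counts(ab, config, rng)
            for g, was in zip(target_gene_ids, clamped):
                if was:
                    truth.clamped_draws.append((motif.tf_name, g))
        else:
            counts = rng.poisson(config.noncausal_mean_count, size=len(ab))
        counts_per_tf[motif.tf_name] = counts
        truth.planted_counts[motif.tf_name] = {
            g: int(c) for g, c in zip(target_gene_ids, counts)
        }

    L = config.motif_length
    new_seqs: dict[str, str] = {}
    for j, gene_id in enumerate(target_gene_ids):
        promoter = by_gene[gene_id]
        slots: list[tuple[str, str, str]] = []  # (tf_name, oriented site, strand)
        for motif in motifs:
            site = motif.max_score_string()
            for _ in range(counts_per_tf[motif.tf_name][j]):
                if rng.random() < 0.5:
                    slots.append((motif.tf_name, site, "same"))
                else:
                    slots.append((motif.tf_name, reverse_complement(site), "opposite"))
        n = len(promoter.sequence)
        k = len(slots)
        if k * L > n:
            raise ValueError(
                f"gene {gene_id}: {k} planted sites x {L} bp exceed the "
                f"{n} bp promoter"
            )
        order = rng.permutation(k)
        # uniform non-overlapping placement: sort k draws from [0, n-kL],
        # then shift the i-th by i*L
        draws = np.sort(rng.integers(0, n - k * L + 1, size=k))
        offsets = draws + np.arange(k) * L
        seq = list(promoter.sequence)
        for slot_idx, off in zip(order, offsets):
            tf_name, oriented, strand = slots[slot_idx]
            seq[off : off + L] = oriented
            truth.planted_sites.append((tf_name, gene_id, int(off), strand))
        new_seqs[gene_id] = "".join(seq)

    # patch contigs so genome files stay consistent with the promoters
    contig_seqs = {c.id: list(c.sequence) for c in contigs}
    for p in promoters:
        if p.gene_id not in new_seqs:
            continue
        seq = new_seqs[p.gene_id]
        fwd = seq if p.strand == "+" else reverse_complement(seq)
        contig_seqs[p.contig_id][p.start : p.end] = fwd
    new_contigs = [Contig(c.id, "".join(contig_seqs[c.id])) for c in contigs]
    # re-slice every promoter from the patched contigs: a non-target
    # promoter can share intergenic space with a planted target one
    by_contig = {c.id: c.sequence for c in new_contigs}
    new_promoters = [
        PromoterRegion(
            p.gene_id, p.contig_id, p.start, p.end,
            (by_contig[p.contig_id][p.start : p.end] if p.strand == "+"
             else reverse_complement(by_contig[p.contig_id][p.start : p.end])),
            p.strand, p.truncated,
        )
        for p in promoters
    ]
    truth.planted_sites.sort()
    return new_contigs, new_promoters, truth


_CLASS_FPKM_RANGES = {  # (g_fpkm, c_fpkm) generators by planted class
    "up": "ratio_up", "down": "ratio_down", "unchanged": "equal",
    "unique_induced": "only_c", "unique_control": "only_g", "undetected": "zero",
}


def _draw_true_fpkm(expr_class: str, rng: np.random.Generator) -> tuple[float, float]:
    """FPKM pair realising a class with a margin wide enough that Poisson
    count noise rarely flips the classification (ratio draws 4-8 against
    classification thresholds of +/-2)."""
    mode = _CLASS_FPKM_RANGES[expr_class]
    if mode == "ratio_up":
        g = rng.uniform(30, 80)
        return g, g * rng.uniform(4, 8)
    if mode == "ratio_down":
        c = rng.uniform(30, 80)
        return c * rng.uniform(4, 8), c
    if mode == "equal":
        v = rng.uniform(30, 100)
        return v, v
    if mode == "only_c":
        return 0.0, rng.uniform(30, 100)
    if mode == "only_g":
        return rng.uniform(30, 100), 0.0
    return 0.0, 0.0


def simulate_counts(
    genes: list[GeneModel],
    class_by_gene: dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Two-condition fragment counts realising the planted classes.

    C ~ Poisson(fpkm * N * L / 1e9) per condition; zero-FPKM genes get
    C = 0 exactly.  Returns the counts table (gene_id, C_control,
    C_test, L) and a GroundTruth carrying true FPKM pairs and classes.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    truth = GroundTruth()
    rows = []
    for gene in genes:
        cls = class_by_gene[gene.gene_id]
        g_fpkm, c_fpkm = _draw_true_fpkm(cls, rng)
        L = gene.end - gene.start
        lam_g = g_fpkm * config.library_size_control * L / 1e9
        lam_c = c_fpkm * config.library_size_test * L / 1e9
        cg = int(rng.poisson(lam_g)) if lam_g > 0 else 0
        cc = int(rng.poisson(lam_c)) if lam_c > 0 else 0
        truth.true_fpkm[gene.gene_id] = (g_fpkm, c_fpkm)
        truth.true_class[gene.gene_id] = cls
        rows.append((gene.gene_id, cg, cc, L))
    counts = pd.DataFrame(rows, columns=["gene_id", "C_control", "C_test", "L"])
    return counts, truth


@dataclass
class SimulatedStudy:
    """Bundle of everything one seeded run produces."""

    config: SimulationConfig
    contigs: list[Contig]
    genes: list[GeneModel]
    promoters: list[PromoterRegion]
    target_gene_ids: list[str]
    motifs: list[MotifModel]
    abundance: dict[str, float]
    homolog_map: dict[str, str]
    counts: pd.DataFrame
    expression: pd.DataFrame
    truth: GroundTruth


def _select_targets(
    promoters: list[PromoterRegion], config: SimulationConfig
) -> list[str]:
    """Pick target genes with roomy promoters that do not physically
    overlap one another (so plantings cannot collide on the contig)."""
    chosen: list[PromoterRegion] = []
    for p in sorted(promoters, key=lambda p: -len(p.sequence)):
        if len(p.sequence) < config.min_target_promoter_len:
            break
        clash = any(
            p.contig_id == q.contig_id and p.start < q.end and q.start < p.end
            for q in chosen
        )
        if not clash:
            chosen.append(p)
        if len(chosen) == config.n_target_genes:
            break
    if len(chosen) < config.n_target_genes:
        raise ValueError(
            f"only {len(chosen)} promoters of >= {config.min_target_promoter_len} bp "
            f"available for {config.n_target_genes} targets; widen the gap range "
            "or lower min_target_promoter_len"
        )
    return sorted(p.gene_id for p in chosen)


def simulate_study(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SimulatedStudy:
    """Run the whole generator and optionally emit the pipeline's input
    files (genome.fa, genes.gff3, motifs.transfac, abundance.tsv,
    counts.tsv, homolog_map.tsv, truth.json)."""
    rng = np.random.default_rng(config.seed)
    contigs, genes = simulate_genome(config, rng)
    promoters = extract_promoters(contigs, genes)
    target_ids = _select_targets(promoters, config)

    motifs = make_motif_library(config, rng)
    abundance = _draw_abundance(config, target_ids, rng)
    contigs, promoters, truth = plant_motifs_with_effect(
        contigs, promoters, target_ids, motifs, abundance, config, rng
    )

    # each TF's host gene: a distinct non-target gene when available
    non_targets = [g.gene_id for g in genes if g.gene_id not in target_ids]
    if len(non_targets) < len(motifs):
        raise ValueError(
            "n_genes too small: need a distinct host gene per TF beyond the targets"
        )
    homolog_map = {m.tf_name: non_targets[i] for i, m in enumerate(motifs)}

    class_counts = config.target_class_counts()
    target_classes = [c for c, n in sorted(class_counts.items()) for _ in range(n)]
    rng.shuffle(target_classes)
    class_by_gene = dict(zip(target_ids, target_classes))
    host_classes = ["up", "down", "unchanged"]
    for g in genes:
        if g.gene_id not in class_by_gene:
            class_by_gene[g.gene_id] = host_classes[int(rng.integers(0, 3))]

    counts, counts_truth = simulate_counts(genes, class_by_gene, config, rng)
    truth.true_fpkm = counts_truth.true_fpkm
    truth.true_class = counts_truth.true_class

    expr = expression_table(
        counts,
        n_control=config.library_size_control,
        n_test=config.library_size_test,
        up_thresh=2.0,
        down_thresh=-2.0,
    )

    study = SimulatedStudy(
        config=config, contigs=contigs, genes=genes, promoters=promoters,
        target_gene_ids=target_ids, motifs=motifs, abundance=abundance,
        homolog_map=homolog_map, counts=counts, expression=expr, truth=truth,
    )
    if out_dir is not None:
        write_study(study, out_dir)
    return study


def make_tier1_benchmark(seed: int = 0) -> dict:
    """Synthetic tier-1 nomination benchmark with a known filter/merge
    structure: 51 scanned TFs of which 22 correlate positively, 7 of the
    positive set lack a host mapping, and two TF pairs (an amino-acid
    starvation pair and a carbon-repression pair) each share one host
    gene — so nomination must return exactly 13 collapsed regulators.

    Returns a dict with correlation reports, homolog map and expression
    table; every object is synthetic and deterministic in ``seed``.
    """
    from .regulator_inference import CorrelationReport

    rng = np.random.default_rng(seed)
    named = {"Rox1": 0.64, "Ste12": 0.54, "Gcn4": 0.44, "Cpc1": 0.40,
             "Mig1": 0.30, "Cre1": 0.28}
    positive = dict(named)
    for i in range(16):
        positive[f"pos{i:02d}"] = float(rng.uniform(0.01, 0.25))
    reports = [CorrelationReport(tf, r, 13, True) for tf, r in positive.items()]
    reports += [CorrelationReport(f"neg{i:02d}", float(-rng.uniform(0.05, 0.6)),
                                  13, False) for i in range(29)]

    homolog_map = {"Rox1": "hRox1", "Ste12": "hSte12",
                   "Gcn4": "hGcn4", "Cpc1": "hGcn4",
                   "Mig1": "hCre1", "Cre1": "hCre1"}
    for i in range(9):  # 9 more mapped singletons; pos09..pos15 stay unmapped
        homolog_map[f"pos{i:02d}"] = f"hpos{i:02d}"

    rows = []
    for host in sorted(set(homolog_map.values())):
        g, c = (50.0, 10.0) if host in ("hRox1", "hSte12") else (10.0, 50.0)
        from .expression import classify_expression, fold_change

        rows.append((host, g, c, fold_change(g, c), classify_expression(g, c)))
    expr = pd.DataFrame(rows, columns=["gene_id", "g_fpkm", "c_fpkm", "fc",
                                       "expr_class"])
    return {"reports": reports, "homolog_map": homolog_map, "expr": expr,
            "n_positive": 22, "n_unmapped_expected": 7, "n_entries_expected": 13}


def make_cascade_benchmark(seed: int = 123) -> dict:
    """Synthetic tier-2 cascade benchmark: 45 candidate TFs hit the
    tier-1 promoters; 7 have no protein sequence and 3 more no host
    homolog (10 unmapped in total); the mapped 35 collapse through one
    3-way and three 2-way homolog merges into 30 regulators; one host
    gene is absent from the expression table, one is unchanged, 12 are
    upregulated and 16 downregulated.  Deterministic in ``seed``.
    """
    from .expression import classify_expression, fold_change
    from .genome_io import PromoterRegion
    from .regulator_inference import RegulatorEntry, RegulatorReport

    motifs = make_motif_library(
        SimulationConfig(seed=seed, motif_library_size=45, motif_length=8)
    )
    for i, m in enumerate(motifs):
        m.tf_name = f"T{i + 1:02d}"

    homolog_map: dict[str, str] = {}
    homolog_map.update({f"T{i:02d}": "hostA" for i in (1, 2, 3)})
    homolog_map.update({"T04": "hostB", "T05": "hostB"})
    homolog_map.update({"T06": "hostC", "T07": "hostC"})
    homolog_map.update({"T08": "hostD", "T09": "hostD"})
    for i in range(10, 36):
        homolog_map[f"T{i:02d}"] = f"host{i:02d}"
    # T36..T38: no host homolog; T39..T45: no protein sequence at all

    hosts = ["hostA", "hostB", "hostC", "hostD"] + [f"host{i:02d}"
                                                    for i in range(10, 36)]
    no_expression_host = "host10"
    unchanged_host = "host11"
    up_hosts = set(hosts[:2]) | {f"host{i:02d}" for i in range(12, 22)}  # 12
    rows = []
    for host in hosts:
        if host == no_expression_host:
            continue
        if host == unchanged_host:
            g, c = 30.0, 30.0
        elif host in up_hosts:
            g, c = 10.0, 50.0
        else:
            g, c = 50.0, 10.0
        rows.append((host, g, c, fold_change(g, c), classify_expression(g, c)))
    expr = pd.DataFrame(rows, columns=["gene_id", "g_fpkm", "c_fpkm", "fc",
                                       "expr_class"])

    promoter_seq = "".join(m.consensus for m in motifs)
    promoters = []
    tier1_entries = []
    for i in range(13):
        gid = f"t1h{i + 1:02d}"
        promoters.append(
            PromoterRegion(gid, "ctgB", 0, len(promoter_seq), promoter_seq,
                           "+", False)
        )
        tier1_entries.append(
            RegulatorEntry(regulator_id=gid, member_tf_names=(f"seedtf{i}",),
                           host_gene_id=gid, r=0.5, expr_class="up", fc=5.0)
        )
    tier1 = RegulatorReport(tier=1, entries=tier1_entries)
    return {
        "motifs": motifs, "homolog_map": homolog_map, "expr": expr,
        "tier1": tier1, "promoters": promoters,
        "expected": {
            "n_candidates": 45, "n_unmapped": 10, "n_entries": 30,
            "class_counts": {"up": 12, "down": 16, "unchanged": 1,
                             "no_expression": 1},
        },
    }


def write_study(study: SimulatedStudy, out_dir: str | Path) -> None:
    from .motif_scan import write_motifs_transfac

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "genome.fa", "w") as fh:
        for c in study.contigs:
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.sequence), 70):
                fh.write(c.sequence[i : i + 70] + "\n")
    with open(out / "genes.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for g in study.genes:
            fh.write(
                f"{g.contig_id}\tregnominate_sim\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
    write_motifs_transfac(study.motifs, out / "motifs.transfac")
    with open(out / "motifs.tsv", "w") as fh:
        for m in study.motifs:
            fh.write(f"{m.tf_name}\t{m.consensus}\n")
    pd.DataFrame(
        {"gene_id": list(study.abundance), "abundance": list(study.abundance.values())}
    ).to_csv(out / "abundance.tsv", sep="\t", index=False)
    study.counts.to_csv(out / "counts.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"tf_name": list(study.homolog_map), "host_gene_id": list(study.homolog_map.values())}
    ).to_csv(out / "homolog_map.tsv", sep="\t", index=False)
    study.truth.to_json(out / "truth.json")
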