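"""Two-tier nomination of cellulase regulators.

Tier 1: Pearson-correlate each TF's binding-site counts on the target
(cellulase) promoters with secretome protein abundance, keep strictly
positive correlations, collapse TFs that map to the same host gene
(homologs), and attach each host gene's expression class.  Tier 2
("early regulators"): scan the tier-1 host genes' own promoters with
the full motif library and repeat the mapping/collapsing/annotation,
partitioning the result into up / down / unchanged regulators.

No significance filter is applied to the correlations — positivity is
r > 0 strictly — and TF-TF correlations are never computed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import PromoterRegion
from .motif_scan import (
    DEFAULT_THRESHOLD_FRAC,
    MotifModel,
    TFBSCountMatrix,
    base_composition,
    scan_promoter,
)

logger = logging.getLogger(__name__)


@dataclass
class AbundanceTable:
    """Secretome abundance for the target gene set (one condition/time)."""

    gene_ids: list[str]
    abundance: np.ndarray

    def __post_init__(self) -> None:
        self.abundance = np.asarray(self.abundance, dtype=float)
        if len(self.gene_ids) != len(self.abundance):
            raise ValueError("gene_ids and abundance lengths differ")
        if len(self.gene_ids) < 3:
            raise ValueError("need at least 3 genes for correlation")
        if (self.abundance < 0).any():
            raise ValueError("abundance must be non-negative")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AbundanceTable":
        df = pd.read_csv(path, sep="\t")
        return cls(list(df.iloc[:, 0].astype(str)), df.iloc[:, 1].to_numpy(float))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"gene_id": self.gene_ids, "abundance": self.abundance}).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson r between one TF's site counts and protein abundance."""

    tf_name: str
    r: float | None  # None when either vector has zero variance
    n_genes: int
    positive: bool


@dataclass(frozen=True)
class RegulatorEntry:
    """One collapsed regulator: possibly several TFs sharing a host gene."""

    regulator_id: str
    member_tf_names: tuple[str, ...]
    host_gene_id: str | None
    r: float | None  # max member r (tier 1 only)
    expr_class: str | None  # None when the host gene is absent from expression
    fc: float | None


@dataclass
class RegulatorReport:
    tier: int
    entries: list[RegulatorEntry]
    unmapped_tfs: list[str] = field(default_factory=list)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.entries:
            key = e.expr_class if e.expr_class is not None else "no_expression"
            counts[key] = counts.get(key, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    e.regulator_id,
                    ",".join(e.member_tf_names),
                    e.host_gene_id,
                    e.r,
                    e.expr_class,
                    e.fc,
                )
                for e in self.entries
            ],
            columns=["regulator_id", "member_tfs", "host_gene_id", "r",
                     "expr_class", "fc"],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def pearson_r(x: np.ndarray, y: np.ndarray) -> float | None:
    """Pearson correlation; None when either vector has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def correlate_tf_abundance(
    matrix: TFBSCountMatrix, abundance: AbundanceTable
) -> list[CorrelationReport]:
    """One correlation report per TF over the shared gene set.

    The matrix must cover every abundance gene; genes are aligned by id.
    Zero-variance count vectors (e.g. a TF hitting nothing) yield an
    undefined r with positive=False.
    """
    missing = set(abundance.gene_ids) - set(matrix.gene_ids)
    if missing:
        raise ValueError(f"count matrix lacks abundance gene(s): {sorted(missing)}")
    if len(abundance.gene_ids) < 3:
        raise ValueError("need at least 3 shared genes")
    cols = [matrix.gene_ids.index(g) for g in abundance.gene_ids]
    reports = []
    for i, tf in enumerate(matrix.tf_names):
        r = pearson_r(matrix.counts[i, cols], abundance.abundance)
        if r is None:
            logger.warning("TF %s: zero-variance vector, correlation undefined", tf)
        reports.append(
            CorrelationReport(tf, r, len(cols), positive=(r is not None and r > 0))
        )
    return reports


def _load_homolog_map(homolog_map) -> dict[str, str]:
    if isinstance(homolog_map, dict):
        return homolog_map
    df = pd.read_csv(homolog_map, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def _expression_lookup(expr: pd.DataFrame, gene_id: str) -> tuple[str | None, float | None]:
    row = expr.loc[expr["gene_id"] == gene_id]
    if row.empty:
        return None, None
    fc = row.iloc[0]["fc"]
    return row.iloc[0]["expr_class"], (None if pd.isna(fc) else float(fc))


def _collapse(
    tf_r: dict[str, float | None],
    homolog_map: dict[str, str],
    expr: pd.DataFrame,
) -> tuple[list[RegulatorEntry], list[str]]:
    """Collapse TFs sharing a host gene; return (entries, unmapped TFs)."""
    unmapped = [tf for tf in tf_r if tf not in homolog_map]
    by_host: dict[str, list[str]] = {}
    for tf in tf_r:
        if tf in homolog_map:
            by_host.setdefault(homolog_map[tf], []).append(tf)
    entries = []
    for host, members in by_host.items():
        members = sorted(members)
        rs = [tf_r[tf] for tf in members if tf_r[tf] is not None]
        r = max(rs) if rs else None
        expr_class, fc = _expression_lookup(expr, host)
        entries.append(
            RegulatorEntry(
                regulator_id="/".join(members),
                member_tf_names=tuple(members),
                host_gene_id=host,
                r=r,
                expr_class=expr_class,
                fc=fc,
            )
        )
    return entries, sorted(unmapped)


def nominate_tier1(
    reports: list[CorrelationReport],
    homolog_map,
    expr: pd.DataFrame,
) -> RegulatorReport:
    """Tier-1 regulators: positively correlated, host-mapped, collapsed.

    TFs with undefined or non-positive r are filtered out first; TFs
    with no host mapping are dropped (logged with a count); TFs sharing
    a host gene merge into one entry carrying all member names and the
    maximum member r.  Entries are sorted by r descending.
    """
    hmap = _load_homolog_map(homolog_map)
    positive = {rep.tf_name: rep.r for rep in reports if rep.positive}
    entries, unmapped = _collapse(positive, hmap, expr)
    if unmapped:
        logger.info(
            "tier 1: %d positively correlated TF(s) without host mapping dropped: %s",
            len(unmapped), ", ".join(unmapped),
        )
    entries.sort(key=lambda e: (-(e.r if e.r is not None else -np.inf), e.regulator_id))
    return RegulatorReport(tier=1, entries=entries, unmapped_tfs=unmapped)


def infer_tier2(
    tier1: RegulatorReport,
    promoters: list[PromoterRegion],
    motifs: list[MotifModel],
    homolog_map,
    expr: pd.DataFrame,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
    min_hits: int = 1,
) -> RegulatorReport:
    """Tier-2 ("early") regulators: TFs with binding sites on the
    promoters of the tier-1 host genes.

    A TF is a candidate when it has at least ``min_hits`` occurrences
    on at least one tier-1 promoter.  Candidates without a host mapping
    are dropped (logged); the rest collapse by host gene and carry the
    host's expression class, partitioning the report into up / down /
    unchanged / no-expression entries.
    """
    if not tier1.entries:
        raise ValueError("tier-1 report is empty; nothing to recurse on")
    hmap = _load_homolog_map(homolog_map)
    hosts = {e.host_gene_id for e in tier1.entries if e.host_gene_id}
    t1_promoters = [p for p in promoters if p.gene_id in hosts]
    if not t1_promoters:
        raise ValueError("no promoters found for tier-1 host genes")
    background = base_composition([p.sequence for p in t1_promoters])

    candidates: dict[str, float | None] = {}
    for motif in motifs:
        for p in t1_promoters:
            hits = scan_promoter(p, motif, threshold_frac, background=background)
            if len(hits) >= min_hits:
                candidates[motif.tf_name] = None
                break
    entries, unmapped = _collapse(candidates, hmap, expr)
    if unmapped:
        logger.info(
            "tier 2: %d candidate TF(s) without host mapping dropped: %s",
            len(unmapped), ", ".join(unmapped),
        )
    entries.sort(key=lambda e: e.regulator_id)
    return RegulatorReport(tier=2, entries=entries, unmapped_tfs=unmapped)


def write_run_manifest(
    path: str | Path,
    *,
    seed: int | None = None,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
    fc_convention: str = "signed_ratio",
    inputs: dict[str, str | Path] | None = None,
    extra: dict | None = None,
) -> None:
    """JSON manifest of thresholds, convention, seed and input digests."""
    digests = {}
    for name, p in (inputs or {}).items():
        digests[name] = hashlib.sha256(Path(p).read_bytes()).hexdigest()
    manifest = {
        "seed": seed,
        "threshold_frac": threshold_frac,
        "fc_convention": fc_convention,
        "input_sha256": digests,
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
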