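"""Genome input and promoter extraction.

Reads a genome (FASTA) together with its gene models (GFF3) and derives
promoter regions as the bounded intergenic space immediately upstream of
each ORF.  A promoter is capped at ``max_len`` (default 1500 bp), is cut
short by the nearest neighbouring gene on either strand or by the contig
edge, and is reported 5'->3' relative to its gene (reverse-complemented
for minus-strand genes).

Coordinates are 0-based half-open internally; GFF3 (1-based inclusive)
and BED (0-based half-open) are converted at the I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

DEFAULT_MAX_PROMOTER_LEN = 1500


class GenomeLoadError(ValueError):
    """Raised when FASTA/GFF3 content violates the gene-model contract."""


@dataclass(frozen=True)
class Contig:
    """A genome contig: an id unique within the genome and its sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GenomeLoadError(f"contig {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """An ORF on a contig, 0-based half-open, strand '+' or '-'."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GenomeLoadError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise GenomeLoadError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )


@dataclass(frozen=True)
class PromoterRegion:
    """Upstream intergenic sequence attached to a gene.

    ``start``/``end`` are forward-strand contig coordinates; ``sequence``
    is oriented 5'->3' with respect to the gene, i.e. reverse-complemented
    for minus-strand genes.  ``truncated`` is True when a neighbouring
    gene or the contig edge (not the length cap) set the region boundary.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    sequence: str
    strand: str
    truncated: bool

    def __len__(self) -> int:
        return self.end - self.start


def read_genome(
    fasta_path: str | Path,
    gff_path: str | Path,
    feature_type: str = "gene",
) -> tuple[list[Contig], list[GeneModel]]:
    """Load contigs and gene models, validating the promoter contract.

    GFF3 coordinates (1-based inclusive) are converted to 0-based
    half-open.  Errors: a gene referencing a missing contig, coordinates
    with start >= end after conversion, coordinates outside the contig,
    or two overlapping genes on one contig.
    """
    contigs = [
        Contig(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    ]
    if not contigs:
        raise GenomeLoadError(f"no FASTA records in {fasta_path}")
    by_id = {c.id: c for c in contigs}
    if len(by_id) != len(contigs):
        raise GenomeLoadError("duplicate contig ids in FASTA")

    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        if gene_id in seen:
            raise GenomeLoadError(f"duplicate gene id {gene_id!r} in {gff_path}")
        seen.add(gene_id)
        if feat.seqid not in by_id:
            raise GenomeLoadError(
                f"gene {gene_id!r} references missing contig {feat.seqid!r}"
            )
        start, end = feat.start - 1, feat.end  # GFF3 1-based inclusive -> half-open
        if start >= end:
            raise GenomeLoadError(
                f"gene {gene_id!r}: malformed coordinates {feat.start}..{feat.end}"
            )
        if end > len(by_id[feat.seqid]):
            raise GenomeLoadError(
                f"gene {gene_id!r} extends past the end of contig {feat.seqid!r}"
            )
        genes.append(GeneModel(gene_id, feat.seqid, start, end, feat.strand))

    _reject_overlaps(genes)
    return contigs, genes


def _reject_overlaps(genes: list[GeneModel]) -> None:
    """Overlapping gene models make the intergenic promoter undefined."""
    per_contig: dict[str, list[GeneModel]] = {}
    for g in genes:
        per_contig.setdefault(g.contig_id, []).append(g)
    for contig_id, group in per_contig.items():
        group.sort(key=lambda g: g.start)
        for a, b in zip(group, group[1:]):
            if b.start < a.end:
                raise GenomeLoadError(
                    f"overlapping genes on contig {contig_id!r}: "
                    f"{a.gene_id!r} [{a.start},{a.end}) and {b.gene_id!r} [{b.start},{b.end})"
                )


def extract_promoters(
    contigs: list[Contig],
    genes: list[GeneModel],
    max_len: int = DEFAULT_MAX_PROMOTER_LEN,
) -> list[PromoterRegion]:
    """Derive one promoter per gene from the upstream intergenic space.

    For a plus-strand gene at [s, e) the region is
    [max(upstream_neighbour_end, s - max_len), s); for a minus-strand
    gene it is [e, min(downstream_neighbour_start, e + max_len))
    reverse-complemented.  Genes with zero available upstream space are
    skipped with a log message.
    """
    if max_len < 1:
        raise ValueError(f"max_len must be >= 1, got {max_len}")
    by_id = {c.id: c for c in contigs}
    per_contig: dict[str, list[GeneModel]] = {}
    for g in genes:
        per_contig.setdefault(g.contig_id, []).append(g)

    promoters: list[PromoterRegion] = []
    for contig_id, group in per_contig.items():
        contig = by_id[contig_id]
        group.sort(key=lambda g: g.start)
        for i, gene in enumerate(group):
            if gene.strand == "+":
                neighbour_end = group[i - 1].end if i > 0 else 0
                start = max(neighbour_end, gene.start - max_len)
                end = gene.start
                # truncated when the neighbour/contig edge (not the cap) cut the region
                truncated = end - start < max_len and start == neighbour_end
            else:
                neighbour_start = (
                    group[i + 1].start if i + 1 < len(group) else len(contig)
                )
                start = gene.end
                end = min(neighbour_start, gene.end + max_len)
                truncated = end - start < max_len and end == neighbour_start
            if end <= start:
                logger.info(
                    "gene %s has no upstream intergenic space; no promoter emitted",
                    gene.gene_id,
                )
                continue
            seq = contig.sequence[start:end]
            if gene.strand == "-":
                seq = str(Seq(seq).reverse_complement())
            promoters.append(
                PromoterRegion(
                    gene_id=gene.gene_id,
                    contig_id=contig_id,
                    start=start,
                    end=end,
                    sequence=seq,
                    strand=gene.strand,
                    truncated=truncated,
                )
            )
    return promoters


def write_promoters_bed(promoters: list[PromoterRegion], path: str | Path) -> None:
    """Write promoter regions as BED6 (name=gene_id, strand=gene strand)."""
    with open(path, "w") as fh:
        for p in promoters:
            fh.write(
                f"{p.contig_id}\t{p.start}\t{p.end}\t{p.gene_id}\t0\t{p.strand}\n"
            )


def read_promoters_bed(
    path: str | Path, contigs: list[Contig]
) -> list[PromoterRegion]:
    """Re-load BED6 promoter regions, re-slicing sequences from contigs."""
    by_id = {c.id: c for c in contigs}
    promoters = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            contig_id, start, end, name, _score, strand = line.rstrip("\n").split("\t")[:6]
            start, end = int(start), int(end)
            seq = by_id[contig_id].sequence[start:end]
            if strand == "-":
                seq = str(Seq(seq).reverse_complement())
            promoters.append(
                PromoterRegion(name, contig_id, start, end, seq, strand, False)
            )
    return promoters


def write_promoters_fasta(promoters: list[PromoterRegion], path: str | Path) -> None:
    """Write gene-oriented promoter sequences as FASTA (id = gene_id)."""
    with open(path, "w") as fh:
        for p in promoters:
            fh.write(f">{p.gene_id} {p.contig_id}:{p.start}-{p.end}({p.strand})\n")
            for i in range(0, len(p.sequence), 70):
                fh.write(p.sequence[i : i + 70] + "\n")
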