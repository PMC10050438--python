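"""TF binding-site models and promoter scanning.

A motif is either an IUPAC consensus string (exact degenerate matching)
or a TRANSFAC-style count matrix (log-odds scoring against a background
base composition, with a relative score threshold).  Both strands of
every promoter are scanned; overlapping occurrences all count; any
window containing an N is disqualified.  The end product is the
TF x gene binding-site count matrix that downstream correlation
analysis consumes.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import motifs as bio_motifs

from .genome_io import PromoterRegion

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD_FRAC = 0.85
DEFAULT_PSEUDOCOUNT = 0.5

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# IUPAC degenerate nucleotide codes -> the set of concrete bases matched
IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


class MotifParseError(ValueError):
    """Raised for malformed motif files."""


def reverse_complement(seq: str) -> str:
    """Reverse complement over the IUPAC nucleotide alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MotifModel:
    """A named TF binding-site model: IUPAC consensus or count matrix."""

    tf_name: str
    kind: str  # "consensus" | "matrix"
    consensus: str | None = None
    counts: np.ndarray | None = None  # 4 x L over (A, C, G, T)
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        if self.kind == "consensus":
            if not self.consensus:
                raise MotifParseError(f"{self.tf_name}: empty consensus")
            bad = set(self.consensus.upper()) - set(IUPAC_SETS)
            if bad:
                raise MotifParseError(
                    f"{self.tf_name}: unknown IUPAC symbol(s) {sorted(bad)}"
                )
            self.consensus = self.consensus.upper()
        elif self.kind == "matrix":
            self.counts = np.asarray(self.counts, dtype=float)
            if self.counts.shape[0] != 4 or self.counts.shape[1] < 1:
                raise MotifParseError(
                    f"{self.tf_name}: count matrix must be 4 x L, got {self.counts.shape}"
                )
            if (self.counts < 0).any():
                raise MotifParseError(f"{self.tf_name}: negative matrix count")
            if (self.counts.sum(axis=0) <= 0).any():
                raise MotifParseError(f"{self.tf_name}: matrix column sums to zero")
            if self.pseudocount <= 0:
                raise MotifParseError(f"{self.tf_name}: pseudocount must be > 0")
        else:
            raise MotifParseError(f"{self.tf_name}: unknown motif kind {self.kind!r}")

    def __len__(self) -> int:
        if self.kind == "consensus":
            return len(self.consensus)
        return self.counts.shape[1]

    def max_score_string(self) -> str:
        """A concrete sequence attaining the maximum score / exact match."""
        if self.kind == "consensus":
            return "".join(IUPAC_SETS[sym][0] for sym in self.consensus)
        return "".join(_BASES[j] for j in self.counts.argmax(axis=0))


@dataclass(frozen=True)
class MatchHit:
    """One motif occurrence on a promoter, in gene-oriented coordinates."""

    tf_name: str
    gene_id: str
    offset: int
    strand_relative: str  # "same" | "opposite"
    score: float  # log-odds (matrix kind) or 1.0 (consensus exact match)


@dataclass
class TFBSCountMatrix:
    """TF x gene matrix of binding-site counts."""

    tf_names: list[str]
    gene_ids: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.tf_names), len(self.gene_ids)):
            raise ValueError("count matrix dimensions do not match name lists")

    def row(self, tf_name: str) -> np.ndarray:
        return self.counts[self.tf_names.index(tf_name)]

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.counts, index=self.tf_names, columns=self.gene_ids).to_csv(
            path, sep="\t", index_label="tf_name"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TFBSCountMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), list(df.columns), df.to_numpy())


def parse_motifs(path: str | Path, format: str = "transfac") -> list[MotifModel]:
    """Parse a motif library: TRANSFAC count matrices or a 2-column IUPAC TSV.

    TRANSFAC names come from the BF (factor) line, falling back to ID/AC.
    Duplicate TF names are an error.
    """
    models: list[MotifModel] = []
    if format == "transfac":
        with open(path) as fh:
            text = fh.read()
        if text.strip():
            for rec in bio_motifs.parse(io.StringIO(text), "transfac", strict=False):
                name = rec.get("BF") or rec.get("ID") or rec.get("AC")
                if isinstance(name, (list, tuple)):
                    name = name[0]
                counts = np.array([rec.counts[b] for b in _BASES], dtype=float)
                models.append(MotifModel(tf_name=name, kind="matrix", counts=counts))
    elif format == "iupac_tsv":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise MotifParseError(
                        f"{path}:{lineno}: expected 'tf_name<TAB>consensus'"
                    )
                models.append(
                    MotifModel(tf_name=parts[0], kind="consensus", consensus=parts[1])
                )
    else:
        raise ValueError(f"unknown motif format {format!r}")

    if not models:
        logger.warning("no motifs parsed from %s", path)
    names = [m.tf_name for m in models]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise MotifParseError(f"duplicate tf_name(s) in {path}: {sorted(dupes)}")
    return models


def write_motifs_transfac(models: list[MotifModel], path: str | Path) -> None:
    """Write matrix-kind motifs in TRANSFAC format (consensus motifs are
    emitted as unambiguous count matrices)."""
    with open(path, "w") as fh:
        for m in models:
            if m.kind == "matrix":
                counts = m.counts
            else:
                counts = consensus_to_counts(m.consensus)
            fh.write(f"ID  {m.tf_name}\nBF  {m.tf_name}\n")
            fh.write("P0      A      C      G      T\n")
            for j in range(counts.shape[1]):
                row = "".join(f"{int(counts[i, j]):7d}" for i in range(4))
                fh.write(f"{j + 1:02d}{row}\n")
            fh.write("XX\n//\n")


def consensus_to_counts(consensus: str, weight: int = 12) -> np.ndarray:
    """Spread ``weight`` counts uniformly over each IUPAC symbol's base set."""
    L = len(consensus)
    counts = np.zeros((4, L))
    for j, sym in enumerate(consensus.upper()):
        bases = IUPAC_SETS[sym]
        for b in bases:
            counts[_BASE_INDEX[b], j] = weight // len(bases)
    return counts


def _encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else (N, ambiguity) -> 4."""
    out = np.full(len(seq), 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    return out


def _pssm(motif: MotifModel, background: np.ndarray) -> np.ndarray:
    """Log2-odds matrix: pseudocounted column frequencies over background."""
    c = motif.counts + motif.pseudocount
    probs = c / c.sum(axis=0, keepdims=True)
    return np.log2(probs / background[:, None])


def _window_scores(code: np.ndarray, pssm: np.ndarray) -> np.ndarray:
    """Score every window; windows containing a non-ACGT base get -inf."""
    L = pssm.shape[1]
    n = len(code) - L + 1
    if n <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(code, L)
    valid = (windows < 4).all(axis=1)
    scores = np.full(n, -np.inf)
    if valid.any():
        safe = np.where(windows[valid] == 4, 0, windows[valid])
        scores[valid] = pssm[safe, np.arange(L)].sum(axis=1)
    return scores


def _consensus_match_mask(code: np.ndarray, consensus: str) -> np.ndarray:
    """Boolean mask over offsets where the IUPAC pattern matches exactly."""
    L = len(consensus)
    n = len(code) - L + 1
    if n <= 0:
        return np.empty(0, dtype=bool)
    # membership table: allowed[base_code, position]; N row (code 4) all False
    allowed = np.zeros((5, L), dtype=bool)
    for j, sym in enumerate(consensus):
        for b in IUPAC_SETS[sym]:
            allowed[_BASE_INDEX[b], j] = True
    windows = np.lib.stride_tricks.sliding_window_view(code, L)
    return allowed[windows, np.arange(L)].all(axis=1)


def scan_promoter(
    promoter: PromoterRegion,
    motif: MotifModel,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
    background: np.ndarray | None = None,
) -> list[MatchHit]:
    """Find all motif occurrences on both strands of one promoter.

    Consensus kind: exact degenerate matching; a window is an opposite-
    strand hit when its reverse complement matches the pattern.  Matrix
    kind: a window is a hit when its log-odds score is at least
    ``threshold_frac`` times the maximum attainable score (scores within
    1e-9 of the cutoff count as hits, so a threshold of 1.0 always
    admits the maximum-score string).  ``background``
    is the (A,C,G,T) frequency vector used for log-odds; defaults to the
    promoter's own composition (``build_count_matrix`` passes the pooled
    promoter-set composition).
    """
    if not (0 < threshold_frac <= 1):
        raise ValueError(f"threshold_frac must be in (0, 1], got {threshold_frac}")
    seq = promoter.sequence.upper()
    L = len(motif)
    if len(seq) < L:
        return []
    code = _encode(seq)
    hits: list[MatchHit] = []

    if motif.kind == "consensus":
        for pattern, strand in (
            (motif.consensus, "same"),
            (reverse_complement(motif.consensus), "opposite"),
        ):
            for off in np.flatnonzero(_consensus_match_mask(code, pattern)):
                hits.append(MatchHit(motif.tf_name, promoter.gene_id, int(off), strand, 1.0))
    else:
        if background is None:
            background = base_composition([seq])
        pssm = _pssm(motif, background)
        max_score = pssm.max(axis=0).sum()
        cutoff = threshold_frac * max_score - 1e-9
        # opposite-strand score of a window equals scoring it with the
        # reverse-complemented PSSM (rows A<->T, C<->G swapped, columns reversed)
        rc_pssm = pssm[::-1, ::-1]
        for mat, strand in ((pssm, "same"), (rc_pssm, "opposite")):
            scores = _window_scores(code, mat)
            for off in np.flatnonzero(scores >= cutoff):
                hits.append(
                    MatchHit(
                        motif.tf_name, promoter.gene_id, int(off), strand,
                        float(scores[off]),
                    )
                )
    hits.sort(key=lambda h: (h.offset, h.strand_relative))
    return hits


def base_composition(sequences: list[str]) -> np.ndarray:
    """Pooled (A,C,G,T) frequencies; uniform fallback for empty/all-N input."""
    counts = np.zeros(4)
    for seq in sequences:
        code = _encode(seq.upper())
        counts += np.bincount(code[code < 4], minlength=4)
    total = counts.sum()
    if total == 0:
        return np.full(4, 0.25)
    freqs = counts / total
    # guard zero-frequency bases so log-odds stays finite
    freqs = np.clip(freqs, 1e-6, None)
    return freqs / freqs.sum()


def build_count_matrix(
    promoters: list[PromoterRegion],
    motifs: list[MotifModel],
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
) -> TFBSCountMatrix:
    """Count binding sites for every motif on every promoter.

    The log-odds background is the pooled base composition of the whole
    promoter set, so matrix-kind scores are comparable across genes.
    """
    if not motifs or not promoters:
        raise ValueError("need at least one motif and one promoter")
    background = base_composition([p.sequence for p in promoters])
    counts = np.zeros((len(motifs), len(promoters)), dtype=int)
    for i, motif in enumerate(motifs):
        for j, promoter in enumerate(promoters):
            counts[i, j] = len(
                scan_promoter(promoter, motif, threshold_frac, background=background)
            )
    return TFBSCountMatrix(
        tf_names=[m.tf_name for m in motifs],
        gene_ids=[p.gene_id for p in promoters],
        counts=counts,
    )


def write_hits_bed(hits: list[MatchHit], promoters: list[PromoterRegion],
                   path: str | Path) -> None:
    """BED6 of hits in contig coordinates; score = log-odds scaled to 0-1000."""
    by_gene = {p.gene_id: p for p in promoters}
    finite = [h.score for h in hits if np.isfinite(h.score)]
    top = max(finite, default=1.0) or 1.0
    with open(path, "w") as fh:
        for h in hits:
            p = by_gene[h.gene_id]
            if p.strand == "+":
                start = p.start + h.offset
            else:  # gene-oriented offset counts from the gene-proximal (right) end
                start = p.end - h.offset - 1
            score = int(round(1000 * max(h.score, 0.0) / top))
            strand = h.strand_relative == "same"
            bed_strand = p.strand if strand else ("-" if p.strand == "+" else "+")
            fh.write(f"{p.contig_id}\t{start}\t{start + 1}\t{h.tf_name}\t{score}\t{bed_strand}\n")
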