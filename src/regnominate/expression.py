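"""FPKM computation, fold changes and expression classification.

FPKM = 1e9 * C / (N * L), where C is the number of fragments uniquely
aligned to the gene, N the total uniquely aligned fragments in the
library and L the gene length in bases.  Fold change between the
control (glucose) and test (cellulose) conditions supports three
conventions — plain ratio, log2 ratio, and a signed ratio (c/g when
c >= g, else -g/c) that matches the "FC > 1 / FC < -1" style of
reporting — and genes are classified as up / down / unchanged /
unique_induced / unique_control / undetected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

CONVENTIONS = ("ratio", "log2", "signed_ratio")
DEFAULT_CONVENTION = "signed_ratio"
DEFAULT_UP_THRESH = 1.0
DEFAULT_DOWN_THRESH = -1.0

EXPR_CLASSES = (
    "up", "down", "unchanged", "unique_induced", "unique_control", "undetected",
)


@dataclass(frozen=True)
class CountRecord:
    """Per-gene, per-condition unique fragment count with library context."""

    gene_id: str
    C: int  # fragments uniquely aligned to this gene
    L: int  # gene length in bases
    N: int  # total uniquely aligned fragments in the library

    def __post_init__(self) -> None:
        if self.C < 0:
            raise ValueError(f"{self.gene_id}: C must be >= 0")
        if self.L < 1:
            raise ValueError(f"{self.gene_id}: L must be >= 1")
        if self.N < 1:
            raise ValueError(f"{self.gene_id}: N must be >= 1")
        if self.C > self.N:
            raise ValueError(f"{self.gene_id}: C cannot exceed N")


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    g_fpkm: float  # control (glucose)
    c_fpkm: float  # test (cellulose)
    fc: float | None
    fc_convention: str
    expr_class: str


def compute_fpkm(record: CountRecord) -> float:
    """FPKM = 1e9 * C / (N * L)."""
    return 1e9 * record.C / (record.N * record.L)


def fold_change(g_fpkm: float, c_fpkm: float,
                convention: str = DEFAULT_CONVENTION) -> float | None:
    """Fold change under the chosen convention; None when undefined.

    ratio: c/g (undefined at g=0).  log2: log2(c/g) (undefined when
    either is 0).  signed_ratio: c/g when c >= g else -g/c (undefined
    when either is 0) — never takes values strictly inside (-1, 1).
    """
    if g_fpkm < 0 or c_fpkm < 0:
        raise ValueError("FPKM values must be non-negative")
    if convention == "ratio":
        return c_fpkm / g_fpkm if g_fpkm > 0 else None
    if convention == "log2":
        if g_fpkm == 0 or c_fpkm == 0:
            return None
        return math.log2(c_fpkm / g_fpkm)
    if convention == "signed_ratio":
        if g_fpkm == 0 or c_fpkm == 0:
            return None
        return c_fpkm / g_fpkm if c_fpkm >= g_fpkm else -g_fpkm / c_fpkm
    raise ValueError(f"unknown fold-change convention {convention!r}")


def classify_expression(
    g_fpkm: float,
    c_fpkm: float,
    convention: str = DEFAULT_CONVENTION,
    up_thresh: float = DEFAULT_UP_THRESH,
    down_thresh: float = DEFAULT_DOWN_THRESH,
) -> str:
    """Assign one of the six expression classes.

    Condition-unique and undetected genes are decided by the zero
    pattern first; the remainder by comparing fold change against the
    thresholds.  Exhaustive and mutually exclusive over all
    non-negative (g, c) pairs.
    """
    if g_fpkm == 0 and c_fpkm == 0:
        return "undetected"
    if g_fpkm == 0:
        return "unique_induced"
    if c_fpkm == 0:
        return "unique_control"
    fc = fold_change(g_fpkm, c_fpkm, convention)
    if fc is None:  # unreachable for positive pairs; defensive
        return "unchanged"
    if fc > up_thresh:
        return "up"
    if fc < down_thresh:
        return "down"
    return "unchanged"


def expression_table(
    counts: pd.DataFrame,
    n_control: int,
    n_test: int,
    convention: str = DEFAULT_CONVENTION,
    up_thresh: float = DEFAULT_UP_THRESH,
    down_thresh: float = DEFAULT_DOWN_THRESH,
) -> pd.DataFrame:
    """Build the per-gene expression table from a counts DataFrame.

    ``counts`` needs columns gene_id, C_control, C_test, L.  Multiple
    rows per gene (e.g. transcript-level counts) are aggregated by
    summing C before FPKM, with L taken as the maximum transcript
    length.  Returns columns gene_id, g_fpkm, c_fpkm, fc, expr_class.
    """
    required = {"gene_id", "C_control", "C_test", "L"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing column(s): {sorted(missing)}")
    agg = counts.groupby("gene_id", sort=False).agg(
        C_control=("C_control", "sum"), C_test=("C_test", "sum"), L=("L", "max")
    ).reset_index()

    rows = []
    for rec in agg.itertuples(index=False):
        g = compute_fpkm(CountRecord(rec.gene_id, int(rec.C_control), int(rec.L), n_control))
        c = compute_fpkm(CountRecord(rec.gene_id, int(rec.C_test), int(rec.L), n_test))
        fc = fold_change(g, c, convention)
        cls = classify_expression(g, c, convention, up_thresh, down_thresh)
        rows.append((rec.gene_id, g, c, fc, cls))
    out = pd.DataFrame(rows, columns=["gene_id", "g_fpkm", "c_fpkm", "fc", "expr_class"])
    out.attrs["fc_convention"] = convention
    return out


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_expression_tsv(table: pd.DataFrame, path: str | Path) -> None:
    header = table.rename(
        columns={"g_fpkm": "G-FPKM", "c_fpkm": "C-FPKM", "fc": "FC", "expr_class": "class"}
    )
    header.to_csv(path, sep="\t", index=False, float_format="%.6g")
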