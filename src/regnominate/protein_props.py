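"""Physicochemical protein descriptors: residue count, molecular weight,
isoelectric point and GRAVY.

All descriptors are composition-only.  Molecular weight uses average
(not monoisotopic) residue masses plus one water; GRAVY is the mean
Kyte-Doolittle hydropathy per residue (negative = hydrophilic); pI is
the pH of zero net charge under the Henderson-Hasselbalch model with
EMBOSS pKa values, found by bisection (net charge is strictly
decreasing in pH, so the root is unique).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

# Average residue masses (Da): amino acid minus water, standard values.
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153

# Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "E": -3.5, "Q": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# EMBOSS pKa set (iep defaults).
EMBOSS_PKA = {
    "Nterm": 8.6, "Cterm": 3.6,
    "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5,
    "K": 10.8, "R": 12.5, "Y": 10.1,
}

_POSITIVE = ("H", "K", "R")  # plus the N-terminus
_NEGATIVE = ("C", "D", "E", "Y")  # plus the C-terminus


def _validate(sequence: str) -> str:
    if not sequence:
        raise ValueError("empty protein sequence")
    seq = sequence.upper()
    for i, aa in enumerate(seq):
        if aa not in RESIDUE_MASS:
            raise ValueError(f"non-standard amino acid {aa!r} at position {i}")
    return seq


def molecular_weight(sequence: str) -> float:
    """Average molecular weight in kDa (residue masses + one water)."""
    seq = _validate(sequence)
    return (sum(RESIDUE_MASS[aa] for aa in seq) + WATER_MASS) / 1000.0


def gravy(sequence: str) -> float:
    """Grand average of hydropathicity: mean Kyte-Doolittle value."""
    seq = _validate(sequence)
    return sum(KYTE_DOOLITTLE[aa] for aa in seq) / len(seq)


def net_charge(sequence: str, ph: float,
               pka_table: dict[str, float] | None = None) -> float:
    """Henderson-Hasselbalch net charge at a given pH.

    Positive groups (N-terminus, H, K, R) contribute 1/(1+10^(pH-pKa));
    negative groups (C-terminus, D, E, C, Y) contribute -1/(1+10^(pKa-pH)).
    Strictly decreasing in pH.
    """
    seq = _validate(sequence)
    pka = pka_table or EMBOSS_PKA
    charge = 1.0 / (1.0 + 10 ** (ph - pka["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (pka["Cterm"] - ph))
    for aa in _POSITIVE:
        n = seq.count(aa)
        if n:
            charge += n / (1.0 + 10 ** (ph - pka[aa]))
    for aa in _NEGATIVE:
        n = seq.count(aa)
        if n:
            charge -= n / (1.0 + 10 ** (pka[aa] - ph))
    return charge


def isoelectric_point(sequence: str,
                      pka_table: dict[str, float] | None = None,
                      tol: float = 1e-4) -> float:
    """pH of zero net charge, by bisection on [0, 14]."""
    seq = _validate(sequence)
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(seq, mid, pka_table) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    sequence: str
    length: int
    mw_kda: float
    pi: float
    gravy: float


def describe_protein(protein_id: str, sequence: str) -> ProteinRecord:
    seq = _validate(sequence)
    return ProteinRecord(
        protein_id=protein_id,
        sequence=seq,
        length=len(seq),
        mw_kda=molecular_weight(seq),
        pi=isoelectric_point(seq),
        gravy=gravy(seq),
    )


def describe_fasta(path: str | Path) -> pd.DataFrame:
    """Descriptor table for a protein FASTA, one row per record."""
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        r = describe_protein(rec.id, str(rec.seq))
        rows.append((r.protein_id, r.length, r.mw_kda, r.pi, r.gravy))
    return pd.DataFrame(
        rows, columns=["Protein", "Residues", "Mol. Wt. (kDa)", "pI", "GRAVY"]
    )
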