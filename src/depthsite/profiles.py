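"""Evolutionary profiles (PSI-BLAST ASCII PSSMs) and amino-acid property tables.

The PSSM parser reads the dialect produced by ``psiblast -out_ascii_pssm``:
after a two-line header each row carries the position index, the query
residue, 20 integer log-odds scores and 20 weighted observed frequency
percentages in the standard ARNDCQEGHILKMFPSTWYV column order.

The property tables bundle one standard scale per property.  The source
scales for charge, isoelectric point, polarity and hydrophobicity are the
usual single-accession AAindex entries (FAUJ880111/FAUJ880112 charges,
Zimmerman pI, Grantham polarity, Kyte-Doolittle hydropathy); the
hydrogen-bond tendency column is a package default reflecting relative
side-chain donor/acceptor propensity.  All are overridable — downstream
features only require that a total, fixed table exists for the 20 canonical
residues, with X mapping to zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

__all__ = [
    "AA_ALPHABET", "Pssm", "PropertyTable", "PROPERTY_NAMES",
    "read_pssm", "conservation_score", "default_property_table",
]

#: fixed PSSM column order (PSI-BLAST convention)
AA_ALPHABET = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}

PROPERTY_NAMES = ("positive_charge", "negative_charge", "pi_value",
                  "polarity", "hydrophobicity", "hbond_tendency")


class PssmParseError(ValueError):
    pass


@dataclass
class Pssm:
    """Per-position profile: 20 log-odds scores and 20 frequency percentages."""

    sequence: str
    log_odds: np.ndarray     # L x 20
    frequencies: np.ndarray  # L x 20, percents

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        L = len(self.sequence)
        if self.log_odds.shape != (L, 20) or self.frequencies.shape != (L, 20):
            raise ValueError("PSSM arrays must be L x 20 aligned to the sequence")

    def __len__(self) -> int:
        return len(self.sequence)


def read_pssm(path: str | Path) -> Pssm:
    """Parse a PSI-BLAST ASCII PSSM file."""
    lines = Path(path).read_text().splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        cols = line.split()
        if len(cols) >= 40 and all(c in AA_ALPHABET for c in cols[:40]) \
                and "".join(cols[:20]) == AA_ALPHABET:
            header_idx = i
            break
    if header_idx is None:
        raise PssmParseError(f"{path}: no PSSM column header found")

    seq: List[str] = []
    scores: List[List[float]] = []
    freqs: List[List[float]] = []
    for line in lines[header_idx + 1:]:
        cols = line.split()
        if len(cols) < 42:
            if seq:
                break  # footer (K, lambda statistics)
            continue
        if not cols[0].isdigit():
            break
        expected = int(cols[0])
        if expected != len(seq) + 1:
            raise PssmParseError(
                f"{path}: row index {expected} out of order at position {len(seq) + 1}")
        seq.append(cols[1])
        scores.append([float(v) for v in cols[2:22]])
        freqs.append([float(v) for v in cols[22:42]])
    if not seq:
        raise PssmParseError(f"{path}: no profile rows parsed")
    return Pssm(sequence="".join(seq), log_odds=np.array(scores),
                frequencies=np.array(freqs))


def conservation_score(pssm: Pssm, position: int,
                       orientation: str = "one_minus_entropy") -> float:
    """Profile-column conservation from the Shannon entropy of frequencies.

    With the default orientation the score is 1 - H/H_max in [0, 1], where
    H = -sum f_a log2 f_a over the renormalized 20 frequency entries and
    H_max = log2 20, so a fully conserved column scores 1 and a uniform one
    scores 0.  ``orientation="entropy"`` returns H/H_max instead.  An all-zero
    frequency row (no alignment information) scores 0.
    """
    f = np.asarray(pssm.frequencies[position], dtype=float)
    total = f.sum()
    if total <= 0:
        return 0.0
    f = f / total
    nz = f[f > 0]
    h = float(-(nz * np.log2(nz)).sum())
    h_norm = h / math.log2(20)
    if orientation == "entropy":
        return h_norm
    return 1.0 - h_norm


@dataclass
class PropertyTable:
    """Per-amino-acid physicochemical values; total over the 20 canonicals + X."""

    values: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for aa in AA_ALPHABET:
            if aa not in self.values:
                raise ValueError(f"property table missing amino acid {aa}")
            missing = set(PROPERTY_NAMES) - set(self.values[aa])
            if missing:
                raise ValueError(f"amino acid {aa} missing properties {missing}")
        self.values.setdefault("X", {p: 0.0 for p in PROPERTY_NAMES})

    def get(self, aa: str, prop: str) -> float:
        return self.values.get(aa, self.values["X"]).get(prop, 0.0)

    def vector(self, aa: str) -> np.ndarray:
        row = self.values.get(aa, self.values["X"])
        return np.array([row[p] for p in PROPERTY_NAMES])


# charge: FAUJ880111 / FAUJ880112; pI: Zimmerman et al.; polarity: Grantham;
# hydrophobicity: Kyte-Doolittle; hbond: package-default donor/acceptor propensity
_DEFAULTS = {
    #       pos  neg  pI     polar  hydroph  hbond
    "A": (0.0, 0.0, 6.00, 8.1, 1.8, 0.02),
    "R": (1.0, 0.0, 10.76, 10.5, -4.5, 0.30),
    "N": (0.0, 0.0, 5.41, 11.6, -3.5, 0.25),
    "D": (0.0, 1.0, 2.77, 13.0, -3.5, 0.35),
    "C": (0.0, 0.0, 5.07, 5.5, 2.5, 0.04),
    "Q": (0.0, 0.0, 5.65, 10.5, -3.5, 0.22),
    "E": (0.0, 1.0, 3.22, 12.3, -3.5, 0.30),
    "G": (0.0, 0.0, 5.97, 9.0, -0.4, 0.05),
    "H": (1.0, 0.0, 7.59, 10.4, -3.2, 0.18),
    "I": (0.0, 0.0, 6.02, 5.2, 4.5, 0.01),
    "L": (0.0, 0.0, 5.98, 4.9, 3.8, 0.01),
    "K": (1.0, 0.0, 9.74, 11.3, -3.9, 0.20),
    "M": (0.0, 0.0, 5.74, 5.7, 1.9, 0.02),
    "F": (0.0, 0.0, 5.48, 5.2, 2.8, 0.02),
    "P": (0.0, 0.0, 6.30, 8.0, -1.6, 0.03),
    "S": (0.0, 0.0, 5.68, 9.2, -0.8, 0.15),
    "T": (0.0, 0.0, 5.60, 8.6, -0.7, 0.14),
    "W": (0.0, 0.0, 5.89, 5.4, -0.9, 0.05),
    "Y": (0.0, 0.0, 5.66, 6.2, -1.3, 0.12),
    "V": (0.0, 0.0, 5.96, 5.9, 4.2, 0.01),
}


def default_property_table(overrides: Optional[Dict[str, Dict[str, float]]] = None
                           ) -> PropertyTable:
    """The bundled property table, optionally with per-entry overrides."""
    values = {aa: dict(zip(PROPERTY_NAMES, vals)) for aa, vals in _DEFAULTS.items()}
    if overrides:
        for aa, props in overrides.items():
            values.setdefault(aa, {p: 0.0 for p in PROPERTY_NAMES}).update(props)
    return PropertyTable(values=values)
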