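"""Rerank externally detected pockets by counting predicted binding residues.

Geometry-based detectors (grid scanners, alpha-shape methods) emit candidate
pockets ranked by volume or conservation; the classifier's per-residue
probabilities supply an orthogonal signal.  Each pocket is scored by the
number of its residues predicted to bind, and pockets are re-ordered by that
count.  A pocket is "functional" when its geometric centre lies within 8 A
of any ligand atom, and the top-n success rate over a protein set is the
fraction of proteins with a functional pocket among the first n entries —
which makes the top-3 rate invariant under any rerank of the same 3 pockets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structure_io import Ligand, Residue, Structure

__all__ = [
    "Pocket", "RerankResult",
    "pocket_residues_from_center", "score_pocket", "rerank",
    "is_functional", "success_rates", "read_pocket_table", "pockets_from_table",
]


@dataclass
class Pocket:
    id: str
    center: np.ndarray
    source_rank: int
    residues: Optional[List[Tuple[str, int]]] = None  # (chain, seq_index) keys
    volume: Optional[float] = None
    score: Optional[int] = None
    new_rank: Optional[int] = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.center)):
            raise ValueError(f"pocket {self.id}: non-finite center")
        if self.source_rank < 1:
            raise ValueError(f"pocket {self.id}: source_rank must be >= 1")


@dataclass
class RerankResult:
    pockets: List[Pocket] = field(default_factory=list)

    def order(self) -> List[str]:
        return [p.id for p in sorted(self.pockets, key=lambda p: p.new_rank)]


def pocket_residues_from_center(structure: Structure, center: np.ndarray,
                                radius: float,
                                surface_only: bool = True) -> List[Residue]:
    """Surface residues with any heavy atom within ``radius`` of the centre.

    This is the expansion used to compare center-only detector output with
    per-residue predictions; sweeping the radius traces out a nested family
    of residue sets (and hence an ROC curve for the detector).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    center = np.asarray(center, dtype=float).reshape(1, 3)
    out = []
    for res in structure.residues():
        if surface_only and (res.rsa is None or res.rsa <= 0.10):
            continue
        if cdist(res.heavy_coords(), center).min() < radius:
            out.append(res)
    return out


def score_pocket(pocket: Pocket, predictions: Dict[Tuple[str, int], float],
                 threshold: float = 0.5,
                 structure: Optional[Structure] = None,
                 expansion_radius: float = 8.0) -> int:
    """Number of pocket residues predicted to bind (probability >= threshold)."""
    keys = pocket.residues
    if keys is None:
        if structure is None:
            raise ValueError(
                f"pocket {pocket.id} has no residue list and no structure for "
                "center expansion")
        keys = [r.key for r in pocket_residues_from_center(
            structure, pocket.center, expansion_radius)]
    return sum(1 for k in keys if predictions.get(k, 0.0) >= threshold)


def rerank(pockets: Sequence[Pocket],
           predictions: Dict[Tuple[str, int], float],
           threshold: float = 0.5,
           structure: Optional[Structure] = None,
           expansion_radius: float = 8.0) -> RerankResult:
    """Reorder pockets by predicted-binder count, descending.

    Ties keep the detector's original order (stable sort on source_rank).
    """
    if not pockets:
        raise ValueError("no pockets to rerank")
    scored = []
    for p in sorted(pockets, key=lambda p: p.source_rank):
        p.score = score_pocket(p, predictions, threshold, structure,
                               expansion_radius)
        scored.append(p)
    scored.sort(key=lambda p: -p.score)  # stable: preserves source order on ties
    for rank, p in enumerate(scored, start=1):
        p.new_rank = rank
    return RerankResult(pockets=scored)


def is_functional(pocket: Pocket, ligands: Ligand | Sequence[Ligand],
                  cutoff: float = 8.0) -> bool:
    """True iff the pocket centre is strictly within ``cutoff`` of any ligand atom."""
    if isinstance(ligands, Ligand):
        ligands = [ligands]
    if not ligands:
        raise ValueError("no ligands given")
    coords = np.vstack([lig.coords() for lig in ligands])
    d = cdist(coords, pocket.center.reshape(1, 3)).min()
    return bool(d < cutoff)


def success_rates(ranked_pockets_per_protein: Dict[str, Sequence[Pocket]],
                  ligands_per_protein: Dict[str, Sequence[Ligand]],
                  n_max: int = 3, cutoff: float = 8.0,
                  use_new_rank: bool = False) -> Dict[int, float]:
    """Top-n success rates over a protein set.

    For each n in 1..n_max, the fraction of proteins whose first n pockets
    (by ``new_rank`` when requested, else ``source_rank``) include at least
    one functional pocket.
    """
    if not ranked_pockets_per_protein:
        raise ValueError("no proteins given")
    rates = {n: 0 for n in range(1, n_max + 1)}
    for pid, pockets in ranked_pockets_per_protein.items():
        key = (lambda p: p.new_rank) if use_new_rank else (lambda p: p.source_rank)
        ordered = sorted(pockets, key=key)
        functional = [is_functional(p, list(ligands_per_protein[pid]), cutoff)
                      for p in ordered]
        for n in rates:
            if any(functional[:n]):
                rates[n] += 1
    n_proteins = len(ranked_pockets_per_protein)
    return {n: hits / n_proteins for n, hits in rates.items()}


def read_pocket_table(path: str | Path) -> pd.DataFrame:
    """Read a detector's pocket table (TSV).

    Two dialects: center-based with columns ``id, x, y, z[, volume][, rank]``,
    and residue-list with columns ``id, residues`` where residues is a
    comma-separated list of chain:seq_index tokens.
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    if "id" not in df.columns:
        raise ValueError(f"{path}: pocket table needs an 'id' column")
    if not ({"x", "y", "z"} <= set(df.columns) or "residues" in df.columns):
        raise ValueError(f"{path}: need x/y/z or residues columns")
    return df


def pockets_from_table(df: pd.DataFrame,
                       structure: Optional[Structure] = None,
                       top_n: Optional[int] = None) -> List[Pocket]:
    """Build Pocket objects from a table row set.

    Rows without an explicit rank are pre-ranked by volume descending (the
    convention for detectors that emit unranked pockets) or, lacking volume
    too, by row order.  ``top_n`` keeps the best-ranked n pockets.
    """
    df = df.copy()
    if "rank" not in df.columns:
        if "volume" in df.columns:
            df = df.sort_values("volume", ascending=False, kind="stable")
        df["rank"] = np.arange(1, len(df) + 1)
    df = df.sort_values("rank", kind="stable")
    if top_n is not None:
        df = df.head(top_n)

    pockets = []
    for _, row in df.iterrows():
        residues = None
        if "residues" in df.columns and isinstance(row.get("residues"), str):
            residues = []
            for token in row["residues"].split(","):
                chain, idx = token.strip().split(":")
                residues.append((chain, int(idx)))
        if {"x", "y", "z"} <= set(df.columns):
            center = np.array([row["x"], row["y"], row["z"]], dtype=float)
        elif structure is not None and residues:
            coords = np.vstack([
                structure.residue(c, i).heavy_coords() for c, i in residues])
            center = coords.mean(axis=0)
        else:
            raise ValueError(f"pocket {row['id']}: no center and no structure "
                             "to derive one from residues")
        pockets.append(Pocket(
            id=str(row["id"]), center=center, source_rank=int(row["rank"]),
            residues=residues,
            volume=float(row["volume"]) if "volume" in df.columns
            and pd.notna(row.get("volume")) else None))
    return pockets
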