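"""Surface definition, patch construction and three-way sample labeling.

A residue is on the surface when its relative accessibility exceeds 10%; a
patch is a surface residue together with every surface residue within 10 A of
it.  Samples are labeled in two stages: proximity to the ligand (< 7 A from
any heavy atom of the residue to any ligand atom) defines positive/negative
*candidates*, then a neighborhood-consensus rule confirms positives and a
half-space-depth convexity rule confirms negatives.  Residues confirming
neither rule are "NP&NN" (not positive and not negative) and are excluded
from training by default — they are too ambiguous to teach either class.

All threshold comparisons are strict, exactly as the selection rules state
them ("greater than", "less than", "more than").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .depth import ResidueDepthMap
from .structure_io import Residue, Structure

__all__ = [
    "Label", "Candidate", "SamplingConfig", "Patch", "Sample",
    "surface_residues", "build_patches", "label_samples",
    "min_residue_distances",
]


class Label(str, Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    NP_NN = "NP_NN"


class Candidate(str, Enum):
    POS_CAND = "POS_CAND"
    NEG_CAND = "NEG_CAND"


@dataclass
class SamplingConfig:
    """Every threshold of the sample-selection procedure, defaults as published."""

    rsa_surface_threshold: float = 0.10   # surface iff RSA strictly above this
    neighbor_radius: float = 10.0         # A, patch membership cutoff
    ligand_contact_cutoff: float = 7.0    # A, positive-candidate cutoff
    positive_neighbor_fraction: float = 0.30  # strict "more than" consensus
    neg_max_center_depth: int = 5         # drop NEG_CANDs deeper than this
    neg_max_mean_neighbor_depth: float = 8.0
    neg_min_neighbors: int = 5            # strict "greater than"
    distance_mode: str = "min_heavy_atom"  # or "ca" for C-alpha distances
    treat_npnn_as_negative: bool = False  # ablation switch

    def __post_init__(self) -> None:
        for name in ("rsa_surface_threshold", "neighbor_radius",
                     "ligand_contact_cutoff", "positive_neighbor_fraction",
                     "neg_max_center_depth", "neg_max_mean_neighbor_depth",
                     "neg_min_neighbors"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Patch:
    """A surface residue plus its surface neighbors within the patch radius."""

    center: Residue
    neighbors: List[Residue] = field(default_factory=list)

    def members(self) -> List[Residue]:
        return [self.center] + self.neighbors


@dataclass
class Sample:
    patch: Patch
    candidate: Candidate
    label: Label

    @property
    def residue(self) -> Residue:
        return self.patch.center


def surface_residues(structure: Structure, cfg: Optional[SamplingConfig] = None
                     ) -> List[Residue]:
    """Residues with RSA strictly above the surface threshold."""
    cfg = cfg or SamplingConfig()
    out = []
    for res in structure.residues():
        if res.rsa is None:
            raise RuntimeError(
                f"residue {res.chain_id}:{res.seq_index} has no RSA; "
                "run compute_rsa first")
        if res.rsa > cfg.rsa_surface_threshold:
            out.append(res)
    return out


def min_residue_distances(residues: List[Residue], mode: str = "min_heavy_atom"
                          ) -> np.ndarray:
    """Symmetric matrix of residue-residue distances.

    ``min_heavy_atom``: minimum over heavy-atom pairs (matches the atom-level
    phrasing of the ligand-contact rule).  ``ca``: C-alpha / representative
    point distances.
    """
    n = len(residues)
    if mode == "ca":
        reps = np.array([r.representative_point() for r in residues])
        return cdist(reps, reps)
    if mode != "min_heavy_atom":
        raise ValueError(f"unknown distance mode {mode!r}")
    coords = []
    owner = []
    for i, res in enumerate(residues):
        hc = res.heavy_coords()
        coords.append(hc)
        owner.extend([i] * len(hc))
    coords = np.vstack(coords)
    owner = np.asarray(owner)
    atom_d = cdist(coords, coords)
    out = np.full((n, n), np.inf)
    # groupwise min via reduceat-style accumulation
    for i in range(n):
        rows = atom_d[owner == i]
        np.minimum.at(out[i], owner, rows.min(axis=0))
    np.fill_diagonal(out, 0.0)
    return out


def build_patches(surface: List[Residue], cfg: Optional[SamplingConfig] = None
                  ) -> List[Patch]:
    """One patch per surface residue; the neighbor relation is symmetric."""
    cfg = cfg or SamplingConfig()
    if not surface:
        raise ValueError("surface residue list is empty")
    dist = min_residue_distances(surface, cfg.distance_mode)
    patches = []
    for i, res in enumerate(surface):
        nbr_idx = np.nonzero((dist[i] < cfg.neighbor_radius) &
                             (np.arange(len(surface)) != i))[0]
        patches.append(Patch(center=res, neighbors=[surface[j] for j in nbr_idx]))
    return patches


def label_samples(structure: Structure, depths: ResidueDepthMap,
                  patches: List[Patch], cfg: Optional[SamplingConfig] = None
                  ) -> List[Sample]:
    """Assign POSITIVE / NEGATIVE / NP_NN to every surface patch.

    Stage 1 — candidates: a residue whose nearest heavy atom lies within the
    ligand-contact cutoff of *any* ligand atom is a positive candidate,
    otherwise a negative candidate.

    Stage 2 — confirmation:
      * positive candidate -> POSITIVE iff strictly more than 30% of its
        patch neighbors are positive candidates, else NP_NN;
      * negative candidate -> discarded to NP_NN when its own depth exceeds 5,
        else NEGATIVE iff the mean neighbor depth is below 8 *and* it has
        strictly more than 5 neighbors, else NP_NN.
    """
    cfg = cfg or SamplingConfig()
    if not structure.ligands:
        raise ValueError(f"structure {structure.id} has no ligands; labels undefined")

    lig_coords = structure.ligand_coords()
    is_pos_cand: Dict[Tuple[str, int], bool] = {}
    for patch in patches:
        res = patch.center
        d = cdist(res.heavy_coords(), lig_coords).min()
        is_pos_cand[res.key] = bool(d < cfg.ligand_contact_cutoff)

    samples = []
    for patch in patches:
        res = patch.center
        if is_pos_cand[res.key]:
            cand = Candidate.POS_CAND
            n_nbr = len(patch.neighbors)
            n_pos = sum(is_pos_cand[nb.key] for nb in patch.neighbors)
            confirmed = n_nbr > 0 and n_pos / n_nbr > cfg.positive_neighbor_fraction
            label = Label.POSITIVE if confirmed else Label.NP_NN
        else:
            cand = Candidate.NEG_CAND
            if depths[res.key] > cfg.neg_max_center_depth:
                label = Label.NP_NN
            else:
                n_nbr = len(patch.neighbors)
                mean_depth = (np.mean([depths[nb.key] for nb in patch.neighbors])
                              if n_nbr else np.inf)
                ok = (mean_depth < cfg.neg_max_mean_neighbor_depth
                      and n_nbr > cfg.neg_min_neighbors)
                label = Label.NEGATIVE if ok else Label.NP_NN
            if label is Label.NP_NN and cfg.treat_npnn_as_negative:
                label = Label.NEGATIVE
        samples.append(Sample(patch=patch, candidate=cand, label=label))
    return samples
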