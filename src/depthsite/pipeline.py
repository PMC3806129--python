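"""End-to-end glue: from files on disk to labeled feature tables and matrices.

This is plumbing around the library modules: read the complex, compute RSA,
secondary structure and residue depths, label samples, featurize, and stack
per-protein tables into the matrices the classifier consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import depth as depth_mod
from .features import FeatureContext, WindowConfig, feature_names, featurize
from .profiles import PropertyTable, Pssm, default_property_table, read_pssm
from .sampling import Label, SamplingConfig, build_patches, label_samples, \
    surface_residues
from .structure_io import Structure, assign_ss3, compute_rsa, read_pdb

__all__ = ["PipelineConfig", "featurize_structure", "training_matrix",
           "prediction_map"]

_META_COLS = ["structure_id", "chain", "seq_index", "aa", "rsa", "depth",
              "candidate", "label"]


@dataclass
class PipelineConfig:
    """All knobs of the residue-level pipeline in one place."""

    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    window: WindowConfig = field(default_factory=WindowConfig)
    probe_radius: float = 1.4
    sasa_points: int = 960
    depth_method: str = "approx"
    depth_n_dirs: int = 1000
    depth_seed: int = 0
    conservation_orientation: str = "one_minus_entropy"
    include_depth_feature: bool = False
    ligand_codes: Optional[set] = None


def featurize_structure(pdb_path: str | Path,
                        pssm_paths: Dict[str, str | Path],
                        dssp_path: Optional[str | Path] = None,
                        cfg: Optional[PipelineConfig] = None,
                        props: Optional[PropertyTable] = None,
                        require_ligand: bool = True,
                        ) -> Tuple[Structure, pd.DataFrame]:
    """Run the full residue pipeline for one complex.

    Returns the annotated structure and a table with one row per surface
    residue: metadata (label, candidate, rsa, depth) followed by the feature
    columns in frozen layout order.
    """
    cfg = cfg or PipelineConfig()
    props = props or default_property_table()

    structure = read_pdb(pdb_path, ligand_codes=cfg.ligand_codes)
    compute_rsa(structure, probe_radius=cfg.probe_radius, n_points=cfg.sasa_points)
    assign_ss3(structure, dssp_file=dssp_path)
    depths = depth_mod.residue_depths(structure, method=cfg.depth_method,
                                      n_dirs=cfg.depth_n_dirs,
                                      seed=cfg.depth_seed)
    pssms = {chain: read_pssm(path) for chain, path in pssm_paths.items()}
    for chain_id, pssm in pssms.items():
        chain = structure.chains[chain_id]
        if len(pssm) != len(chain):
            raise ValueError(
                f"{pdb_path}: PSSM for chain {chain_id} has {len(pssm)} rows, "
                f"chain has {len(chain)} residues")

    surface = surface_residues(structure, cfg.sampling)
    patches = build_patches(surface, cfg.sampling)
    if require_ligand or structure.ligands:
        samples = label_samples(structure, depths, patches, cfg.sampling)
    else:  # prediction-only mode on apo structures
        from .sampling import Candidate, Sample
        samples = [Sample(patch=p, candidate=Candidate.NEG_CAND,
                          label=Label.NP_NN) for p in patches]

    ctx = FeatureContext(
        structure=structure, pssms=pssms, props=props, window=cfg.window,
        conservation_orientation=cfg.conservation_orientation,
        include_depth=cfg.include_depth_feature, depths=depths)

    cols = feature_names(include_depth=cfg.include_depth_feature)
    rows = []
    for sample in samples:
        res = sample.residue
        vec = featurize(sample, ctx)
        row = {
            "structure_id": structure.id, "chain": res.chain_id,
            "seq_index": res.seq_index, "aa": res.aa, "rsa": res.rsa,
            "depth": depths[res.key], "candidate": sample.candidate.value,
            "label": sample.label.value,
        }
        row.update(zip(cols, vec.values))
        rows.append(row)
    table = pd.DataFrame(rows, columns=_META_COLS + cols)
    return structure, table


def training_matrix(tables: Sequence[pd.DataFrame]
                    ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack per-protein tables into (X, y, groups), POSITIVE/NEGATIVE rows only."""
    df = pd.concat(tables, ignore_index=True)
    df = df[df["label"].isin([Label.POSITIVE.value, Label.NEGATIVE.value])]
    if df.empty:
        raise ValueError("no POSITIVE/NEGATIVE samples in the given tables")
    feat_cols = [c for c in df.columns if c not in _META_COLS]
    X = df[feat_cols].to_numpy(dtype=float)
    y = (df["label"] == Label.POSITIVE.value).to_numpy(dtype=int)
    groups = df["structure_id"].to_numpy()
    return X, y, groups


def prediction_map(table: pd.DataFrame, probabilities: np.ndarray
                   ) -> Dict[Tuple[str, int], float]:
    """Map (chain, seq_index) -> predicted probability for one protein table."""
    return {(row.chain, int(row.seq_index)): float(p)
            for row, p in zip(table.itertuples(), probabilities)}
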