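"""Shared fixtures: toy complexes, a processed benchmark, and tiny helpers.

Everything is generated programmatically at session start; nothing is read
from checked-in data files except small frozen oracles.
"""

from __future__ import annotations

import numpy as np
import pytest

from depthsite import (FixtureSpec, PipelineConfig, featurize_structure,
                       make_benchmark, make_toy_protein, training_matrix)
from depthsite.structure_io import Atom, Ligand, Residue, Structure


@pytest.fixture(scope="session")
def toy_files(tmp_path_factory):
    """One deterministic toy complex with a planted pocket and ligand."""
    d = tmp_path_factory.mktemp("toy")
    return make_toy_protein(FixtureSpec(seed=7), d)


@pytest.fixture(scope="session")
def fast_cfg():
    """Pipeline config with a lighter SASA sphere for test speed."""
    return PipelineConfig(sasa_points=100)


@pytest.fixture(scope="session")
def toy_table(toy_files, fast_cfg):
    """(structure, per-residue feature table) for the toy complex."""
    return featurize_structure(
        toy_files.pdb, {c: str(p) for c, p in toy_files.pssms.items()},
        toy_files.ss, fast_cfg)


@pytest.fixture(scope="session")
def benchmark(tmp_path_factory, fast_cfg):
    """12-protein synthetic benchmark with informative profiles.

    Returns (files, tables, X, y, groups) shared across end-to-end tests.
    """
    d = tmp_path_factory.mktemp("bench")
    files = make_benchmark(d, n_proteins=12, n_residues=64,
                           signal_strength=4.0, seed=11)
    tables = [featurize_structure(
        f.pdb, {c: str(p) for c, p in f.pssms.items()}, f.ss, fast_cfg)[1]
        for f in files]
    X, y, groups = training_matrix(tables)
    return files, tables, X, y, groups


def make_point_structure(coords, ligand_coords=None, rsa=1.0,
                         aa=None, structure_id="test"):
    """A bare structure of single-CA residues at given coordinates.

    Handy for constructing sampling geometries where every distance is known
    by design.
    """
    coords = np.asarray(coords, dtype=float)
    residues = []
    for i, c in enumerate(coords):
        res = Residue(chain_id="A", seq_index=i + 1,
                      aa=(aa[i] if aa else "A"),
                      atoms=[Atom(serial=i + 1, name="CA", element="C", coord=c)],
                      resseq=i + 1)
        res.rsa = rsa if np.isscalar(rsa) else float(rsa[i])
        res.ss3 = "C"
        residues.append(res)
    ligands = []
    if ligand_coords is not None:
        ligands = [Ligand(name="LIG", atoms=[
            Atom(serial=1000 + j, name=f"C{j}", element="C", coord=c)
            for j, c in enumerate(np.atleast_2d(ligand_coords))])]
    return Structure(id=structure_id, chains={"A": residues}, ligands=ligands)
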