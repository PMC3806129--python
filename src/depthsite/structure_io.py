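"""Read PDB complexes into a light typed model; compute per-residue RSA and 3-state SS.

The structure model keeps protein chains (ordered residues of heavy atoms) apart
from HETATM ligand groups, because every downstream rule treats them differently:
protein-side distances and solvent accessibility use heavy atoms only, while
residue-ligand contacts use *all* ligand atoms.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Atom import Atom as _BPAtom
from Bio.PDB.Chain import Chain as _BPChain
from Bio.PDB.Model import Model as _BPModel
from Bio.PDB.Residue import Residue as _BPResidue
from Bio.PDB.SASA import ShrakeRupley
from Bio.PDB.Structure import Structure as _BPStructure

logger = logging.getLogger("depthsite")

WATER_CODES = {"HOH", "WAT", "DOD", "H2O"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Theoretical maximum accessible surface areas (A^2) per residue type
# (Tien et al. 2013, theoretical column).  Used to turn absolute ASA into RSA.
# Overridable via the ``max_asa`` argument of :func:`compute_rsa`.
MAX_ASA_TIEN2013 = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: 8-state DSSP code -> 3-state collapse.  Blank / unknown codes map to coil.
SS8_TO_SS3 = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "C", "S": "C", "C": "C", "-": "C", " ": "C", "": "C", "P": "C",
}


@dataclass
class Atom:
    """One atom: serial, PDB atom name, element symbol and coordinates in A."""

    serial: int
    name: str
    element: str
    coord: np.ndarray
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.serial} has non-finite coordinates")
        if not self.element:
            raise ValueError(f"atom {self.serial} has empty element")


@dataclass
class Residue:
    """A protein residue; ``seq_index`` is the 1-based position within its chain."""

    chain_id: str
    seq_index: int
    aa: str
    atoms: list[Atom] = field(default_factory=list)
    rsa: Optional[float] = None
    asa: Optional[float] = None
    ss3: Optional[str] = None
    resseq: Optional[int] = None  # author-assigned PDB residue number, for DSSP matching

    def __post_init__(self) -> None:
        if self.seq_index < 1:
            raise ValueError("seq_index must be >= 1")

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.heavy_atoms], dtype=float)

    def representative_point(self) -> np.ndarray:
        """C-alpha position; heavy-atom centroid when no CA is present."""
        for a in self.heavy_atoms:
            if a.name.strip() == "CA":
                return a.coord
        return self.heavy_coords().mean(axis=0)

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.seq_index)


@dataclass
class Ligand:
    """A HETATM group; keeps all atoms including hydrogens."""

    name: str
    atoms: list[Atom]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"ligand {self.name} has no atoms")

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)


@dataclass
class Structure:
    """One complex: ordered protein chains plus ligand groups."""

    id: str
    chains: dict[str, list[Residue]]
    ligands: list[Ligand] = field(default_factory=list)

    def residues(self) -> Iterator[Residue]:
        for chain in self.chains.values():
            yield from chain

    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains.values())

    def residue(self, chain_id: str, seq_index: int) -> Residue:
        return self.chains[chain_id][seq_index - 1]

    def protein_heavy_coords(self) -> np.ndarray:
        """All protein heavy-atom coordinates pooled across chains."""
        coords = [r.heavy_coords() for r in self.residues() if r.heavy_atoms]
        return np.vstack(coords)

    def ligand_coords(self) -> np.ndarray:
        if not self.ligands:
            raise ValueError(f"structure {self.id} has no ligands")
        return np.vstack([lig.coords() for lig in self.ligands])


class PDBFormatError(ValueError):
    pass


def read_pdb(path: str | Path, ligand_codes: Optional[set[str]] = None) -> Structure:
    """Parse a PDB file into a :class:`Structure`.

    ATOM records become protein residues (first NMR model only; for disordered
    atoms a single altloc conformer is kept).  HETATM groups become ligands —
    either those whose HET code is in ``ligand_codes``, or, when unset, every
    non-water group.  Waters are always dropped.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bp = parser.get_structure(path.stem, str(path))
    try:
        model = next(bp.get_models())
    except StopIteration:  # pragma: no cover - empty file
        raise PDBFormatError(f"{path}: no model found")

    chains: dict[str, list[Residue]] = {}
    ligands: list[Ligand] = []
    for bp_chain in model:
        residues: list[Residue] = []
        for bp_res in bp_chain:
            hetflag, resseq, _icode = bp_res.get_id()
            resname = bp_res.get_resname().strip()
            atoms = [_convert_atom(a) for a in bp_res.get_atoms()]
            if hetflag == " ":
                aa = THREE_TO_ONE.get(resname)
                if aa is None:
                    logger.warning(
                        "%s: non-canonical residue %s %s:%s mapped to X",
                        path.name, resname, bp_chain.id, resseq)
                    aa = "X"
                residues.append(Residue(
                    chain_id=bp_chain.id, seq_index=len(residues) + 1,
                    aa=aa, atoms=atoms, resseq=resseq))
            else:
                if resname in WATER_CODES or hetflag == "W":
                    continue
                if ligand_codes is not None and resname not in ligand_codes:
                    continue
                ligands.append(Ligand(name=resname, atoms=atoms))
        if residues:
            chains[bp_chain.id] = residues

    if not chains:
        raise PDBFormatError(f"{path}: no protein ATOM records")
    return Structure(id=path.stem, chains=chains, ligands=ligands)


def _convert_atom(bp_atom) -> Atom:
    element = (bp_atom.element or "").strip() or bp_atom.get_name().strip()[0]
    return Atom(
        serial=bp_atom.get_serial_number() or 0,
        name=bp_atom.get_name(),
        element=element,
        coord=np.asarray(bp_atom.get_coord(), dtype=float),
        is_hydrogen=element.upper() in ("H", "D"),
    )


# ---------------------------------------------------------------------------
# Solvent accessibility
# ---------------------------------------------------------------------------

def compute_rsa(
    structure: Structure,
    probe_radius: float = 1.4,
    n_points: int = 960,
    max_asa: Optional[dict[str, float]] = None,
) -> Structure:
    """Set per-residue ``asa`` (A^2) and ``rsa`` (fraction of the maximum ASA).

    The accessible surface is computed with the Shrake-Rupley rolling-probe
    method on *protein heavy atoms only* — ligands are stripped first, so the
    surface definition used for labeling never depends on where the ligand
    sits.  RSA = ASA / max-ASA for the residue type, clipped to [0, 1];
    unknown residue types fall back to the glycine maximum with a warning.
    """
    table = dict(MAX_ASA_TIEN2013)
    if max_asa:
        table.update(max_asa)

    bp_model = _as_biopdb_model(structure)
    sr = ShrakeRupley(probe_radius=probe_radius, n_points=n_points)
    sr.compute(bp_model, level="R")

    for chain in bp_model:
        residues = structure.chains[chain.id]
        for bp_res in chain:
            res = residues[bp_res.get_id()[1] - 1]
            res.asa = float(bp_res.sasa)
            if res.aa not in table:
                logger.warning("residue %s%d aa=%s: unknown type, using glycine max ASA",
                               res.chain_id, res.seq_index, res.aa)
            maximum = table.get(res.aa, table["G"])
            res.rsa = float(np.clip(res.asa / maximum, 0.0, 1.0))
    return structure


def _as_biopdb_model(structure: Structure) -> _BPModel:
    """Build a Bio.PDB model holding the protein heavy atoms (ligand excluded)."""
    model = _BPModel(0)
    for chain_id, residues in structure.chains.items():
        bp_chain = _BPChain(chain_id)
        for res in residues:
            resname = ONE_TO_THREE.get(res.aa, "GLY")
            bp_res = _BPResidue((" ", res.seq_index, " "), resname, "")
            for i, atom in enumerate(res.heavy_atoms):
                bp_atom = _BPAtom(
                    name=atom.name.strip() or f"X{i}",
                    coord=np.asarray(atom.coord, dtype=np.float64),
                    bfactor=0.0, occupancy=1.0, altloc=" ",
                    fullname=f" {atom.name.strip():<3s}"[:4],
                    serial_number=atom.serial,
                    element=atom.element.upper(),
                )
                try:
                    bp_res.add(bp_atom)
                except Exception:  # duplicate atom name in pseudo-structures
                    bp_atom.name = f"{bp_atom.name}{i}"
                    bp_atom.fullname = bp_atom.name
                    bp_res.add(bp_atom)
            bp_chain.add(bp_res)
        model.add(bp_chain)
    # Bio.PDB SASA walks atoms through the parent structure
    parent = _BPStructure(structure.id)
    parent.add(model)
    return model


# ---------------------------------------------------------------------------
# Secondary structure
# ---------------------------------------------------------------------------

class DsspAlignmentError(ValueError):
    pass


def collapse_ss8(code: str) -> str:
    """Total collapse of the 8-state DSSP alphabet (plus blank) to {H, E, C}."""
    return SS8_TO_SS3.get(code.strip().upper() or "-", "C")


def assign_ss3(structure: Structure, dssp_file: Optional[str | Path] = None) -> Structure:
    """Set 3-state secondary structure on every residue.

    With ``dssp_file``, classic DSSP text output is parsed and 8-state codes
    are collapsed (H/G/I -> H, E/B -> E, else C).  Without one, a fallback
    assigner derives states from backbone phi/psi dihedrals so that synthetic
    fixtures need no external program.
    """
    if dssp_file is not None:
        assignments = _parse_dssp(Path(dssp_file))
        for res in structure.residues():
            key = (res.chain_id, res.resseq if res.resseq is not None else res.seq_index)
            if key not in assignments:
                raise DsspAlignmentError(
                    f"DSSP file lacks residue {res.chain_id}:{res.seq_index} "
                    f"(PDB number {key[1]})")
            aa, ss8 = assignments[key]
            if aa != "X" and res.aa != "X" and aa != res.aa:
                raise DsspAlignmentError(
                    f"DSSP residue {res.chain_id}:{key[1]} is {aa}, structure has {res.aa}")
            res.ss3 = collapse_ss8(ss8)
        return structure

    for chain in structure.chains.values():
        phi_psi = _backbone_dihedrals(chain)
        for res, (phi, psi) in zip(chain, phi_psi):
            res.ss3 = _ss3_from_dihedrals(phi, psi)
    return structure


def _parse_dssp(path: Path) -> dict[tuple[str, int], tuple[str, str]]:
    assignments: dict[tuple[str, int], tuple[str, str]] = {}
    in_table = False
    for line in path.read_text().splitlines():
        if line.lstrip().startswith("#  RESIDUE"):
            in_table = True
            continue
        if not in_table or len(line) < 17:
            continue
        resnum_field = line[5:10].strip()
        if not resnum_field:  # chain-break row
            continue
        chain = line[11].strip()
        aa = line[13].upper()
        if aa.islower() or aa == "!":
            aa = "C" if aa.islower() else "X"  # lowercase = SS-bonded cysteine
        ss8 = line[16]
        assignments[(chain, int(resnum_field))] = (aa, ss8)
    if not assignments:
        raise DsspAlignmentError(f"{path}: no residue table found")
    return assignments


def _backbone_dihedrals(chain: Sequence[Residue]) -> list[tuple[float, float]]:
    """(phi, psi) in degrees per residue; NaN where backbone atoms are missing."""
    def atom(res: Residue, name: str) -> Optional[np.ndarray]:
        for a in res.atoms:
            if a.name.strip() == name:
                return a.coord
        return None

    out = []
    for i, res in enumerate(chain):
        n, ca, c = atom(res, "N"), atom(res, "CA"), atom(res, "C")
        prev_c = atom(chain[i - 1], "C") if i > 0 else None
        next_n = atom(chain[i + 1], "N") if i < len(chain) - 1 else None
        phi = _dihedral(prev_c, n, ca, c) if prev_c is not None else math.nan
        psi = _dihedral(n, ca, c, next_n) if next_n is not None else math.nan
        out.append((phi, psi))
    return out


def _dihedral(p0, p1, p2, p3) -> float:
    if any(p is None for p in (p0, p1, p2, p3)):
        return math.nan
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    nrm = np.linalg.norm(b1)
    if nrm < 1e-9:
        return math.nan
    b1 = b1 / nrm
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return math.degrees(math.atan2(y, x))


def _ss3_from_dihedrals(phi: float, psi: float) -> str:
    if math.isnan(phi) or math.isnan(psi):
        return "C"
    if -100.0 <= phi <= -30.0 and -80.0 <= psi <= -5.0:
        return "H"
    if -180.0 <= phi <= -45.0 and (psi >= 90.0 or psi <= -150.0):
        return "E"
    return "C"
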