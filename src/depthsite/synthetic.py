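"""Deterministic synthetic fixtures: point clouds, toy proteins with planted
binding pockets, profile files and pocket tables.

The toy proteins are geometrically honest but deliberately non-physical:
residues sit on a sphere with a hemispherical dimple (the pocket) and carry a
C-alpha plus three pseudo-backbone heavy atoms, so that solvent accessibility,
atom-level distance rules and half-space depth all behave sensibly at a scale
where exact depth enumeration is still affordable.  When requested, a small
HETATM ligand group is placed inside the dimple so the published selection
rules label dimple residues positive and far-side shell residues negative.
Profile files carry label signal tunable by ``signal_strength``: binder
positions get evolutionarily "conserved" columns, so that at high signal a
classifier can recover the planted pocket and at zero signal nothing is
learnable.  Every output is byte-reproducible from the seed, and every
emitted file parses through the package's own readers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from .depth import PointCloud
from .profiles import AA_ALPHABET
from .structure_io import ONE_TO_THREE

__all__ = [
    "FixtureSpec", "ToyProteinFiles",
    "make_cloud", "make_toy_protein", "make_pocket_table", "make_benchmark",
]

_SS_STATES = "HEC"


@dataclass
class FixtureSpec:
    """Parameters of one toy complex."""

    n_residues: int = 64
    pocket_depth_fraction: float = 0.45   # dimple depth as a fraction of the radius
    ligand_in_pocket: bool = True
    signal_strength: float = 4.0          # 0 = uninformative profiles
    seed: int = 0
    pocket_fraction: float = 0.18         # fraction of residues lining the dimple
    spacing: float = 5.5                  # target nearest-neighbor CA spacing, A

    def __post_init__(self) -> None:
        if self.n_residues < 20:
            raise ValueError("n_residues must be >= 20")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be >= 0")


@dataclass
class ToyProteinFiles:
    name: str
    pdb: Path
    ss: Path
    pssms: Dict[str, Path]
    truth: Path


def make_cloud(shape: str, n: int, d: int = 3, seed: int = 0) -> PointCloud:
    """Deterministic test clouds for the depth evaluators.

    Shapes: ``grid`` (lattice, includes interior points of known depth),
    ``sphere`` (all points on the convex hull, depth 0 everywhere),
    ``gaussian`` (generic position), ``degenerate-planar`` (coplanar points
    embedded in 3-D, exercising the degenerate-geometry path).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if shape == "grid":
        side = math.ceil(n ** (1.0 / d))
        axes = [np.arange(side, dtype=float)] * d
        pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, d)
        return PointCloud(pts[:n])
    if shape == "sphere":
        if d == 1:
            pts = np.array([[-1.0], [1.0]] * ((n + 1) // 2))[:n]
            return PointCloud(pts)
        v = rng.standard_normal((n, d))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        return PointCloud(v)
    if shape == "gaussian":
        return PointCloud(rng.standard_normal((n, d)))
    if shape == "degenerate-planar":
        if d != 3:
            raise ValueError("degenerate-planar is a 3-D shape")
        xy = rng.standard_normal((n, 2))
        pts = np.column_stack([xy, np.zeros(n)])
        return PointCloud(pts)
    raise ValueError(f"unknown cloud shape {shape!r}")


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n nearly-even unit directions (Fibonacci lattice)."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _tangent_frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    t1 = np.cross(u, ref)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(u, t1)
    return t1, t2


def _build_geometry(spec: FixtureSpec, rng: np.random.Generator):
    n = spec.n_residues
    radius = spec.spacing * math.sqrt(n / (4.0 * math.pi))
    dirs = _fibonacci_sphere(n)

    # dimple: the cap of directions nearest +z, pulled inward with a smooth
    # falloff so pocket-lining residues gain half-space depth
    z_sorted = np.sort(dirs[:, 2])[::-1]
    n_pocket = max(6, int(round(spec.pocket_fraction * n)))
    z_cut = z_sorted[n_pocket - 1]
    w = np.clip((dirs[:, 2] - z_cut) / (1.0 - z_cut + 1e-12), 0.0, 1.0)
    radii = radius * (1.0 - spec.pocket_depth_fraction * np.sqrt(w))
    indented = w > 0.25  # cap rim (w ~ 0) stays on the convex shell
    ca = dirs * radii[:, None] + rng.normal(0.0, 0.25, size=(n, 3))

    # shuffle sequence order so chain position carries no pocket information
    order = rng.permutation(n)
    ca = ca[order]
    dirs = dirs[order]
    indented = indented[order]

    atoms = []  # per residue: list of (name, element, coord)
    for i in range(n):
        t1, t2 = _tangent_frame(dirs[i])
        jit = rng.normal(0.0, 0.15, size=(3, 3))
        atoms.append([
            ("CA", "C", ca[i]),
            ("N", "N", ca[i] + 1.45 * t1 + jit[0]),
            ("C", "C", ca[i] + 1.52 * t2 + jit[1]),
            ("O", "O", ca[i] - 1.25 * t1 + jit[2]),
        ])

    pocket_center = ca[indented].mean(axis=0)
    if spec.ligand_in_pocket:
        lig_center = pocket_center
    else:
        lig_center = np.array([0.0, 0.0, -3.0 * radius])
    lig_offsets = np.array([[0.0, 0.0, 0.0], [1.2, 0.0, 0.3],
                            [-0.8, 0.9, -0.2], [0.1, -1.1, 0.6]])
    ligand = [(f"C{i+1}", "C", lig_center + off) for i, off in enumerate(lig_offsets)]

    aas = rng.choice(list(AA_ALPHABET), size=n)
    ss = rng.choice(list(_SS_STATES), size=n)

    lig_coords = np.array([c for _, _, c in ligand])
    binder = np.zeros(n, dtype=bool)
    for i in range(n):
        res_coords = np.array([c for _, _, c in atoms[i]])
        d = np.linalg.norm(res_coords[:, None, :] - lig_coords[None, :, :], axis=-1)
        binder[i] = bool(d.min() < 7.0)

    # pocket lining = indented into the dimple, or at its mouth in ligand
    # contact; far-side shell residues are neither
    pocket_mask = indented | binder

    return {
        "ca": ca, "atoms": atoms, "ligand": ligand, "aas": aas, "ss": ss,
        "binder": binder, "pocket": pocket_mask, "radius": radius,
        "pocket_center": pocket_center, "lig_center": lig_center,
    }


def _write_pdb(path: Path, name: str, geo: dict) -> None:
    lines = [f"HEADER    SYNTHETIC TOY COMPLEX                   {name.upper():<10s}"]
    serial = 1
    for i, res_atoms in enumerate(geo["atoms"]):
        resname = ONE_TO_THREE[geo["aas"][i]]
        for atom_name, element, coord in res_atoms:
            lines.append(
                f"ATOM  {serial:5d} {atom_name:^4s} {resname:3s} A{i + 1:4d}    "
                f"{coord[0]:8.3f}{coord[1]:8.3f}{coord[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}")
            serial += 1
    lines.append(f"TER   {serial:5d}      {ONE_TO_THREE[geo['aas'][-1]]:3s} "
                 f"A{len(geo['atoms']):4d}")
    serial += 1
    for atom_name, element, coord in geo["ligand"]:
        lines.append(
            f"HETATM{serial:5d} {atom_name:^4s} LIG A{901:4d}    "
            f"{coord[0]:8.3f}{coord[1]:8.3f}{coord[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}")
        serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _write_dssp_like(path: Path, name: str, geo: dict) -> None:
    lines = [
        f"==== SYNTHETIC SECONDARY STRUCTURE (DSSP-like) FOR {name} ====",
        "  #  RESIDUE AA STRUCTURE",
    ]
    for i, (aa, ss) in enumerate(zip(geo["aas"], geo["ss"])):
        resnum = i + 1
        lines.append(f"{resnum:5d}{resnum:5d} A {aa}  {ss}")
    path.write_text("\n".join(lines) + "\n")


def _make_frequencies(spec: FixtureSpec, geo: dict, rng: np.random.Generator
                      ) -> np.ndarray:
    """Per-position frequency percentages; binder columns carry the signal."""
    n = spec.n_residues
    w = spec.signal_strength / (1.0 + spec.signal_strength)
    freqs = np.empty((n, 20))
    for i in range(n):
        noise = rng.dirichlet(np.full(20, 5.0))
        f = noise.copy()
        if geo["binder"][i] and w > 0:
            onehot = np.zeros(20)
            onehot[AA_ALPHABET.index(geo["aas"][i])] = 1.0
            f = (1.0 - w) * noise + w * onehot
        freqs[i] = np.round(100.0 * f).astype(int)
        if freqs[i].sum() == 0:  # pragma: no cover - dirichlet never all-zero
            freqs[i, 0] = 100
    return freqs


def _write_pssm(path: Path, sequence: str, freqs: np.ndarray) -> None:
    header_aas = "  ".join(AA_ALPHABET)
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "            " + header_aas + "   " + header_aas,
    ]
    for i, aa in enumerate(sequence):
        f = freqs[i]
        with np.errstate(divide="ignore"):
            lo = np.where(f > 0, np.round(2.0 * np.log2(np.maximum(f, 0.5) / 5.0)), -4)
        lo = np.clip(lo, -10, 10).astype(int)
        row = f"{i + 1:5d} {aa} "
        row += " ".join(f"{v:3d}" for v in lo)
        row += "  "
        row += " ".join(f"{int(v):3d}" for v in f)
        row += "  0.50 1.00"
        lines.append(row)
    lines += ["", "                      K         Lambda", "Standard Ungapped"
              "    0.1340     0.3160", ""]
    path.write_text("\n".join(lines) + "\n")


def _write_truth(path: Path, geo: dict) -> None:
    lines = ["chain\tseq_index\taa\tbinder\tpocket"]
    for i, aa in enumerate(geo["aas"]):
        lines.append(f"A\t{i + 1}\t{aa}\t{int(geo['binder'][i])}\t"
                     f"{int(geo['pocket'][i])}")
    path.write_text("\n".join(lines) + "\n")


def make_toy_protein(spec: FixtureSpec, out_dir: str | Path,
                     name: Optional[str] = None) -> ToyProteinFiles:
    """Emit one toy complex: PDB, DSSP-like SS file, per-chain PSSM, truth TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    name = name or f"toy{spec.seed:04d}"
    rng = np.random.default_rng(spec.seed)
    geo = _build_geometry(spec, rng)
    freqs = _make_frequencies(spec, geo, rng)

    pdb = out_dir / f"{name}.pdb"
    ss = out_dir / f"{name}.ss"
    pssm = out_dir / f"{name}_A.pssm"
    truth = out_dir / f"{name}_truth.tsv"
    _write_pdb(pdb, name, geo)
    _write_dssp_like(ss, name, geo)
    _write_pssm(pssm, "".join(geo["aas"]), freqs)
    _write_truth(truth, geo)
    return ToyProteinFiles(name=name, pdb=pdb, ss=ss, pssms={"A": pssm},
                           truth=truth)


def make_pocket_table(spec: FixtureSpec, out_dir: str | Path,
                      n_pockets: int = 3, functional_rank: int = 1,
                      name: Optional[str] = None,
                      seed: Optional[int] = None) -> Path:
    """Emit a detector-style pocket TSV for a toy complex.

    One pocket is centred in the true dimple (adjacent to the ligand) and
    placed at ``functional_rank``; the decoys sit outside the shell on the
    far hemisphere, beyond the functional-pocket distance cutoff.
    """
    if not (1 <= functional_rank <= n_pockets):
        raise ValueError("need n_pockets >= functional_rank >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    name = name or f"toy{spec.seed:04d}"
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    geo = _build_geometry(spec, rng)

    rows = []
    decoy_rng = np.random.default_rng((spec.seed if seed is None else seed) + 1)
    radius = geo["radius"]
    for rank in range(1, n_pockets + 1):
        if rank == functional_rank:
            c = geo["pocket_center"]
        else:
            # decoy on the lower hemisphere, pushed outside the shell
            phi = decoy_rng.uniform(0, 2 * math.pi)
            zdir = decoy_rng.uniform(-1.0, -0.3)
            r = math.sqrt(1 - zdir * zdir)
            c = 1.3 * radius * np.array([r * math.cos(phi), r * math.sin(phi), zdir])
        volume = 400.0 - 60.0 * rank
        rows.append((f"{name}_p{rank}", c, volume, rank))

    path = out_dir / f"{name}_pockets.tsv"
    lines = ["id\tx\ty\tz\tvolume\trank"]
    for pid, c, vol, rank in rows:
        lines.append(f"{pid}\t{c[0]:.3f}\t{c[1]:.3f}\t{c[2]:.3f}\t{vol:.1f}\t{rank}")
    path.write_text("\n".join(lines) + "\n")
    return path


def make_benchmark(out_dir: str | Path, n_proteins: int = 12,
                   n_residues: int = 64, signal_strength: float = 4.0,
                   seed: int = 0, ligand_in_pocket: bool = True
                   ) -> List[ToyProteinFiles]:
    """A set of toy complexes with distinct seeds derived from one master seed."""
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(1, 2 ** 31 - 1, size=n_proteins)
    out = []
    for i, s in enumerate(child_seeds):
        spec = FixtureSpec(n_residues=n_residues,
                           signal_strength=signal_strength,
                           ligand_in_pocket=ligand_in_pocket, seed=int(s))
        out.append(make_toy_protein(spec, out_dir, name=f"prot{i:02d}"))
    return out
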