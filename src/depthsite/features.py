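"""The 330-dimensional feature vector: 35 global + 270 sliding-window + 25 patch.

Layout (frozen; offsets are part of the public contract):

  [0, 35)    global block — three 4-bit one-hot discretizations (chain length,
             distance to the N-terminus, distance to the C-terminus, intervals
             [0,60), [60,120), [120,240), >=240), 20 whole-protein amino-acid
             composition fractions, 3 whole-protein H/E/C content fractions.
  [35, 305)  window block — sliding window of length 9 centred on the residue;
             per position: 20 PSSM log-odds, conservation score, 3-bit
             secondary-structure one-hot, positive charge, negative charge,
             pI, polarity, hydrophobicity, and an out-of-chain indicator.
             Out-of-chain positions carry 29 zeros and indicator 1.
  [305, 330) patch block — hydrogen-bond tendency (min, max, mean, centre
             value: 4), then min/max/mean of positive charge, negative
             charge, pI, polarity, hydrophobicity and conservation over the
             patch members (18), then patch H/E/C content (3).

An optional flag appends the residue's integer half-space depth as a 331st
feature for ablation experiments; it is off by default to keep the layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .depth import ResidueDepthMap
from .profiles import AA_ALPHABET, PropertyTable, Pssm, conservation_score, \
    default_property_table
from .sampling import Patch, Sample
from .structure_io import Residue, Structure

__all__ = [
    "WindowConfig", "FeatureContext", "FeatureVector",
    "GLOBAL_SLICE", "WINDOW_SLICE", "PATCH_SLICE", "N_FEATURES",
    "global_features", "window_features", "patch_features", "featurize",
    "feature_names",
]

N_GLOBAL, N_WINDOW, N_PATCH = 35, 270, 25
N_FEATURES = N_GLOBAL + N_WINDOW + N_PATCH
GLOBAL_SLICE = slice(0, N_GLOBAL)
WINDOW_SLICE = slice(N_GLOBAL, N_GLOBAL + N_WINDOW)
PATCH_SLICE = slice(N_GLOBAL + N_WINDOW, N_FEATURES)

_SS3 = "HEC"
_LENGTH_BINS = (60, 120, 240)
_WINDOW_PROPS = ("positive_charge", "negative_charge", "pi_value",
                 "polarity", "hydrophobicity")
_PATCH_PROPS = _WINDOW_PROPS + ("conservation",)


@dataclass
class WindowConfig:
    window_length: int = 9
    features_per_position: int = 30

    def __post_init__(self) -> None:
        if self.window_length % 2 != 1:
            raise ValueError("window_length must be odd")


@dataclass
class FeatureContext:
    """Everything featurization needs besides the sample itself."""

    structure: Structure
    pssms: Dict[str, Pssm]                 # chain id -> profile
    props: PropertyTable = field(default_factory=default_property_table)
    window: WindowConfig = field(default_factory=WindowConfig)
    conservation_orientation: str = "one_minus_entropy"
    include_depth: bool = False
    depths: Optional[ResidueDepthMap] = None

    def conservation(self, res: Residue) -> float:
        pssm = self.pssms[res.chain_id]
        return conservation_score(pssm, res.seq_index - 1,
                                  self.conservation_orientation)


@dataclass
class FeatureVector:
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def global_block(self) -> np.ndarray:
        return self.values[GLOBAL_SLICE]

    @property
    def window_block(self) -> np.ndarray:
        return self.values[WINDOW_SLICE]

    @property
    def patch_block(self) -> np.ndarray:
        return self.values[PATCH_SLICE]


def _interval_onehot(value: float) -> np.ndarray:
    out = np.zeros(4)
    for i, edge in enumerate(_LENGTH_BINS):
        if value < edge:
            out[i] = 1.0
            return out
    out[3] = 1.0
    return out


def global_features(structure: Structure, residue: Residue) -> np.ndarray:
    """35 protein- and position-level features for one residue."""
    chain = structure.chains[residue.chain_id]
    length = len(chain)
    n_dist = residue.seq_index - 1
    c_dist = length - residue.seq_index

    comp = np.zeros(20)
    ss = np.zeros(3)
    n_total = 0
    for res in structure.residues():
        n_total += 1
        if res.aa in AA_ALPHABET:
            comp[AA_ALPHABET.index(res.aa)] += 1
        if res.ss3 is None:
            raise RuntimeError("ss3 not assigned; run assign_ss3 first")
        ss[_SS3.index(res.ss3)] += 1
    comp /= max(n_total, 1)
    ss /= max(n_total, 1)

    return np.concatenate([
        _interval_onehot(length),
        _interval_onehot(n_dist),
        _interval_onehot(c_dist),
        comp,
        ss,
    ])


def window_features(chain: List[Residue], center_index: int, pssm: Pssm,
                    props: PropertyTable, cfg: Optional[WindowConfig] = None,
                    conservation_orientation: str = "one_minus_entropy",
                    ) -> np.ndarray:
    """270 sequence-context features from a length-9 window around the residue.

    ``center_index`` is 0-based within the chain.  Positions sliding off
    either chain end contribute all-zero features with the trailing indicator
    set to 1.
    """
    cfg = cfg or WindowConfig()
    if len(pssm) != len(chain):
        raise ValueError(
            f"PSSM length {len(pssm)} does not match chain length {len(chain)}")
    half = cfg.window_length // 2
    blocks = []
    for offset in range(-half, half + 1):
        i = center_index + offset
        feats = np.zeros(cfg.features_per_position)
        if 0 <= i < len(chain):
            res = chain[i]
            feats[0:20] = pssm.log_odds[i]
            feats[20] = conservation_score(pssm, i, conservation_orientation)
            if res.ss3 in _SS3:
                feats[21 + _SS3.index(res.ss3)] = 1.0
            for j, prop in enumerate(_WINDOW_PROPS):
                feats[24 + j] = props.get(res.aa, prop)
            feats[29] = 0.0
        else:
            feats[29] = 1.0
        blocks.append(feats)
    return np.concatenate(blocks)


def patch_features(patch: Patch, ctx: FeatureContext) -> np.ndarray:
    """25 patch-statistic features over the centre residue and its neighbors."""
    members = patch.members()
    props = ctx.props

    hbond = np.array([props.get(r.aa, "hbond_tendency") for r in members])
    out = [hbond.min(), hbond.max(), hbond.mean(),
           props.get(patch.center.aa, "hbond_tendency")]

    for prop in _PATCH_PROPS:
        if prop == "conservation":
            vals = np.array([ctx.conservation(r) for r in members])
        else:
            vals = np.array([props.get(r.aa, prop) for r in members])
        out.extend([vals.min(), vals.max(), vals.mean()])

    ss = np.zeros(3)
    for r in members:
        if r.ss3 in _SS3:
            ss[_SS3.index(r.ss3)] += 1
    ss /= len(members)
    out.extend(ss.tolist())
    return np.asarray(out)


def featurize(sample: Sample, ctx: FeatureContext) -> FeatureVector:
    """Concatenate global, window and patch blocks for one sample."""
    res = sample.residue
    chain = ctx.structure.chains[res.chain_id]
    vec = np.concatenate([
        global_features(ctx.structure, res),
        window_features(chain, res.seq_index - 1, ctx.pssms[res.chain_id],
                        ctx.props, ctx.window, ctx.conservation_orientation),
        patch_features(sample.patch, ctx),
    ])
    if ctx.include_depth:
        if ctx.depths is None:
            raise ValueError("include_depth requires a ResidueDepthMap in the context")
        vec = np.append(vec, float(ctx.depths[res.key]))
    return FeatureVector(values=vec)


def feature_names(include_depth: bool = False) -> List[str]:
    """Column names for the full vector, in layout order."""
    names = []
    for block in ("len", "ndist", "cdist"):
        names += [f"g_{block}_bin{i}" for i in range(4)]
    names += [f"g_comp_{aa}" for aa in AA_ALPHABET]
    names += [f"g_ss_{s}" for s in _SS3]
    for pos in range(-4, 5):
        tag = f"w{pos:+d}"
        names += [f"{tag}_pssm_{aa}" for aa in AA_ALPHABET]
        names += [f"{tag}_cons"]
        names += [f"{tag}_ss_{s}" for s in _SS3]
        names += [f"{tag}_{p}" for p in _WINDOW_PROPS]
        names += [f"{tag}_oob"]
    names += ["p_hbond_min", "p_hbond_max", "p_hbond_mean", "p_hbond_center"]
    for p in _PATCH_PROPS:
        names += [f"p_{p}_min", f"p_{p}_max", f"p_{p}_mean"]
    names += [f"p_ss_{s}" for s in _SS3]
    if include_depth:
        names += ["x_depth"]
    return names
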