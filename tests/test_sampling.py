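"""Surface definition, patch construction, and the three-way labeling rules.

Geometries here are constructed, so every distance and every label is known
by design; the rules' strict inequalities are probed exactly at their
boundaries.
"""

from __future__ import annotations

import numpy as np
import pytest

from depthsite.depth import ResidueDepthMap, residue_depths
from depthsite.sampling import (Candidate, Label, SamplingConfig,
                                build_patches, label_samples,
                                min_residue_distances, surface_residues)

from conftest import make_point_structure


def _depth_map(structure, values):
    m = ResidueDepthMap()
    for res, v in zip(structure.residues(), values):
        m.depths[res.key] = v
    return m


class TestSurface:
    def test_strict_threshold(self):
        s = make_point_structure([[0, 0, 0], [20, 0, 0], [40, 0, 0]],
                                 rsa=[0.10, 0.0, 0.11])
        surf = surface_residues(s)
        assert [r.seq_index for r in surf] == [3]

    def test_unset_rsa_raises(self):
        s = make_point_structure([[0, 0, 0]])
        for r in s.residues():
            r.rsa = None
        with pytest.raises(RuntimeError):
            surface_residues(s)


class TestPatches:
    def test_far_apart_residues_have_no_neighbors(self):
        s = make_point_structure([[0, 0, 0], [12, 0, 0]])
        patches = build_patches(list(s.residues()))
        assert [len(p.neighbors) for p in patches] == [0, 0]

    def test_close_residues_are_mutual_neighbors(self):
        s = make_point_structure([[0, 0, 0], [5, 0, 0]])
        patches = build_patches(list(s.residues()))
        assert patches[0].neighbors == [patches[1].center]
        assert patches[1].neighbors == [patches[0].center]

    def test_octagon_ring_has_two_neighbors_each(self):
        # regular octagon with side 6 A: adjacent chord 6 < 10, second
        # chord 2*R*sin(pi/4) = 11.09 > 10 -> exactly two neighbors
        R = 6.0 / (2 * np.sin(np.pi / 8))
        angles = np.arange(8) * 2 * np.pi / 8
        coords = np.column_stack([R * np.cos(angles), R * np.sin(angles),
                                  np.zeros(8)])
        s = make_point_structure(coords)
        # brute-force distance matrix confirms the construction
        d = min_residue_distances(list(s.residues()))
        assert ((d > 0) & (d < 10)).sum(axis=1).tolist() == [2] * 8
        patches = build_patches(list(s.residues()))
        assert [len(p.neighbors) for p in patches] == [2] * 8

    def test_symmetry_of_neighbor_relation(self):
        rng = np.random.default_rng(0)
        s = make_point_structure(rng.uniform(0, 25, size=(15, 3)))
        patches = build_patches(list(s.residues()))
        nbrs = {p.center.key: {n.key for n in p.neighbors} for p in patches}
        for center, ns in nbrs.items():
            assert center not in ns
            for n in ns:
                assert center in nbrs[n]


def _line_structure_with_ligand():
    """11 residues spaced 4 A on a line; ligand over residue 1.

    Residues 1-2 are within 7 A of the ligand (positive candidates), the
    rest are negative candidates.  Patch neighbors: +-2 positions (<10 A).
    """
    coords = [[4.0 * i, 0, 0] for i in range(11)]
    return make_point_structure(coords, ligand_coords=[[0, 0, 3.0]])


class TestLabeling:
    def test_requires_ligand(self):
        s = make_point_structure([[0, 0, 0], [5, 0, 0]])
        patches = build_patches(list(s.residues()))
        with pytest.raises(ValueError):
            label_samples(s, _depth_map(s, [0, 0]), patches)

    def test_candidate_split_at_seven_angstroms(self):
        s = _line_structure_with_ligand()
        patches = build_patches(list(s.residues()))
        samples = label_samples(s, _depth_map(s, [0] * 11), patches)
        cands = {x.residue.seq_index: x.candidate for x in samples}
        # residue 2 at x=4: dist to ligand = sqrt(16+9)=5 < 7; residue 3 at
        # x=8: sqrt(64+9)=8.54 > 7
        assert cands[1] is Candidate.POS_CAND
        assert cands[2] is Candidate.POS_CAND
        assert cands[3] is Candidate.NEG_CAND

    def test_positive_needs_strictly_more_than_30pct_neighbors(self):
        # residue 1's neighbors are 2 and 3 (4 and 8 A): one of two is a
        # positive candidate -> 50% > 30% -> POSITIVE.  residue 2's
        # neighbors are 1, 3, 4: 1/3 = 33.3% > 30% -> POSITIVE.
        s = _line_structure_with_ligand()
        patches = build_patches(list(s.residues()))
        samples = label_samples(s, _depth_map(s, [0] * 11), patches)
        labels = {x.residue.seq_index: x.label for x in samples}
        assert labels[1] is Label.POSITIVE
        assert labels[2] is Label.POSITIVE

    def test_exactly_30pct_is_npnn(self):
        # ligand near residue 1 only; residue 1's patch has 10 neighbors of
        # which exactly 3 are positive candidates -> 30% is not "more than"
        coords = [[0, 0, 0]]
        # 3 positive-candidate neighbors close to the ligand
        coords += [[5, 1.0 * j, 0] for j in range(3)]
        # 7 negative-candidate neighbors within patch range but > 7 of ligand
        coords += [[-7.5, 0.8 * j, 0] for j in range(7)]
        s = make_point_structure(coords, ligand_coords=[[3, 0, 0]])
        patches = build_patches(list(s.residues()))
        samples = label_samples(s, _depth_map(s, [0] * 11), patches)
        center = next(x for x in samples if x.residue.seq_index == 1)
        assert center.candidate is Candidate.POS_CAND
        assert len(center.patch.neighbors) == 10
        assert center.label is Label.NP_NN

    def test_negative_center_depth_rule_strict_at_5(self):
        # hexagonal cluster: center has 6 shallow neighbors, so only its own
        # depth decides; 6 is removed, exactly 5 survives
        coords = [[0, 0, 0]] + [[6 * np.cos(a), 6 * np.sin(a), 0]
                                for a in np.linspace(0, 2 * np.pi, 6,
                                                     endpoint=False)]
        s = make_point_structure(coords, ligand_coords=[[200, 0, 0]])
        patches = build_patches(list(s.residues()))
        for center_depth, expected in [(6, Label.NP_NN), (5, Label.NEGATIVE)]:
            samples = label_samples(
                s, _depth_map(s, [center_depth] + [0] * 6), patches)
            center = next(x for x in samples if x.residue.seq_index == 1)
            assert center.label is expected, f"depth={center_depth}"

    def test_negative_needs_more_than_5_neighbors(self):
        # hexagonal cluster: center residue with exactly 5 vs 6 neighbors
        def cluster(k):
            coords = [[0, 0, 0]]
            coords += [[6 * np.cos(a), 6 * np.sin(a), 0]
                       for a in np.linspace(0, 2 * np.pi, k, endpoint=False)]
            return make_point_structure(coords,
                                        ligand_coords=[[200, 0, 0]])

        for k, expected in [(5, Label.NP_NN), (6, Label.NEGATIVE)]:
            s = cluster(k)
            patches = build_patches(list(s.residues()))
            samples = label_samples(s, _depth_map(s, [0] * (k + 1)), patches)
            center = next(x for x in samples if x.residue.seq_index == 1)
            assert len(center.patch.neighbors) == k
            assert center.label is expected, f"k={k}"

    def test_negative_mean_neighbor_depth_strict_at_8(self):
        coords = [[0, 0, 0]] + [[6 * np.cos(a), 6 * np.sin(a), 0]
                                for a in np.linspace(0, 2 * np.pi, 6,
                                                     endpoint=False)]
        s = make_point_structure(coords, ligand_coords=[[200, 0, 0]])
        patches = build_patches(list(s.residues()))
        for nbr_depth, expected in [(8, Label.NP_NN), (7, Label.NEGATIVE)]:
            samples = label_samples(
                s, _depth_map(s, [0] + [nbr_depth] * 6), patches)
            center = next(x for x in samples if x.residue.seq_index == 1)
            assert center.label is expected

    def test_partition_and_containment(self, toy_table):
        structure, table = toy_table
        assert set(table.label) <= {"POSITIVE", "NEGATIVE", "NP_NN"}
        assert (table.groupby(["chain", "seq_index"]).size() == 1).all()
        pos = table[table.label == "POSITIVE"]
        neg = table[table.label == "NEGATIVE"]
        assert (pos.candidate == "POS_CAND").all()
        assert (neg.candidate == "NEG_CAND").all()

    def test_no_ligand_contact_residue_is_negative(self, toy_table):
        # NEGATIVE implies NEG_CAND implies >= 7 A from the ligand
        structure, table = toy_table
        from scipy.spatial.distance import cdist
        lig = structure.ligand_coords()
        for row in table[table.label == "NEGATIVE"].itertuples():
            res = structure.residue(row.chain, row.seq_index)
            assert cdist(res.heavy_coords(), lig).min() >= 7.0

    def test_planted_pocket_positives_line_the_pocket(self, toy_files,
                                                      toy_table):
        import pandas as pd
        structure, table = toy_table
        truth = pd.read_csv(toy_files.truth, sep="\t")
        pocket = set(truth[truth.pocket == 1].seq_index)
        positives = set(table[table.label == "POSITIVE"].seq_index)
        negatives = set(table[table.label == "NEGATIVE"].seq_index)
        assert positives and positives <= pocket
        assert negatives and not (negatives & pocket)

    def test_raising_depth_cap_never_loses_negatives(self, toy_files):
        from depthsite import read_pdb, compute_rsa
        s = read_pdb(toy_files.pdb)
        compute_rsa(s, n_points=100)
        depths = residue_depths(s, n_dirs=500, seed=0)
        counts = []
        for cap in (1, 3, 5, 9, 15):
            cfg = SamplingConfig(neg_max_center_depth=cap)
            surf = surface_residues(s, cfg)
            patches = build_patches(surf, cfg)
            samples = label_samples(s, depths, patches, cfg)
            counts.append(sum(x.label is Label.NEGATIVE for x in samples))
        assert counts == sorted(counts)

    def test_ca_distance_mode(self):
        s = make_point_structure([[0, 0, 0], [5, 0, 0]],
                                 ligand_coords=[[50, 0, 0]])
        cfg = SamplingConfig(distance_mode="ca")
        patches = build_patches(list(s.residues()), cfg)
        assert [len(p.neighbors) for p in patches] == [1, 1]
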