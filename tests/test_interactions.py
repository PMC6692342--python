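import numpy as np
import pytest

from mutshift.interactions import (
    HBondSite,
    detect_hbonds,
    detect_salt_bridges,
    interaction_timeline,
)
from mutshift.pca_states import StatePartition
from mutshift.trajectory_io import AtomRecord
from conftest import make_trajectory


def _traj_with_atoms(m, atom_specs, n_res=4):
    """Cα trajectory plus explicit atom records.

    atom_specs: list of (resid, resname, atom, element, coords (M,3)).
    """
    coords = np.zeros((m, n_res, 3))
    for k in range(n_res):
        coords[:, k, 0] = 10.0 * k
    labels = [(k + 1, "GLY") for k in range(n_res)]
    detail = []
    for resid, resname, atom, element, c in atom_specs:
        labels[resid - 1] = (resid, resname)
        detail.append(AtomRecord(resid, resname, atom, element, np.asarray(c, dtype=float)))
    traj = make_trajectory(coords, aligned=True, labels=labels)
    traj.atom_detail = detail
    return traj


def _static(m, xyz):
    return np.repeat(np.asarray(xyz, dtype=float)[None], m, axis=0)


class TestSaltBridges:
    def test_static_pair_within_cutoff(self):
        traj = _traj_with_atoms(
            5,
            [
                (1, "ASP", "OD1", "O", _static(5, [0, 0, 0])),
                (2, "LYS", "NZ", "N", _static(5, [3.0, 0, 0])),
            ],
        )
        recs = detect_salt_bridges(traj)
        assert len(recs) == 1
        assert recs[0].occupancy == 1.0
        assert (recs[0].residue_i, recs[0].residue_j) == (1, 2)

    def test_static_pair_beyond_cutoff(self):
        traj = _traj_with_atoms(
            5,
            [
                (1, "ASP", "OD1", "O", _static(5, [0, 0, 0])),
                (2, "LYS", "NZ", "N", _static(5, [4.5, 0, 0])),
            ],
        )
        assert detect_salt_bridges(traj) == []

    def test_partial_occupancy_matches_loop_oracle(self, rng):
        m = 100
        on = _static(m, [0, 0, 0])
        nz = np.zeros((m, 3))
        nz[:, 0] = np.where(np.arange(m) < 60, 3.0, 5.0)
        traj = _traj_with_atoms(
            m,
            [
                (1, "GLU", "OE1", "O", on),
                (3, "ARG", "NH1", "N", nz),
            ],
        )
        recs = detect_salt_bridges(traj, cutoff=3.2)
        assert len(recs) == 1
        assert np.isclose(recs[0].occupancy, 0.60)
        # brute-force oracle over atoms and frames
        oracle = np.array(
            [np.linalg.norm(on[k] - nz[k]) <= 3.2 for k in range(m)]
        )
        np.testing.assert_array_equal(recs[0].presence, oracle)

    def test_cutoff_monotonicity(self, rng):
        m = 50
        on = _static(m, [0, 0, 0])
        nz = rng.normal(scale=1.0, size=(m, 3)) + [3.2, 0, 0]
        traj = _traj_with_atoms(
            m,
            [(1, "ASP", "OD2", "O", on), (2, "LYS", "NZ", "N", nz)],
        )
        small = detect_salt_bridges(traj, cutoff=2.8)
        large = detect_salt_bridges(traj, cutoff=4.0)
        if small:
            assert (small[0].presence <= large[0].presence).all()

    def test_histidine_only_when_enabled(self):
        traj = _traj_with_atoms(
            5,
            [
                (1, "ASP", "OD1", "O", _static(5, [0, 0, 0])),
                (2, "HIS", "NE2", "N", _static(5, [3.0, 0, 0])),
            ],
        )
        assert detect_salt_bridges(traj) == []
        assert len(detect_salt_bridges(traj, include_histidine=True)) == 1

    def test_missing_sidechain_warns(self):
        traj = _traj_with_atoms(
            5,
            [(1, "ASP", "OD1", "O", _static(5, [0, 0, 0]))],
        )
        traj.residue_labels[1] = (2, "LYS")  # LYS with no NZ record
        with pytest.warns(UserWarning):
            detect_salt_bridges(traj)

    def test_occupancy_invariant_to_frame_duplication(self):
        m = 10
        nz = np.zeros((m, 3))
        nz[:, 0] = np.where(np.arange(m) < 4, 3.0, 6.0)
        specs = [
            (1, "ASP", "OD1", "O", _static(m, [0, 0, 0])),
            (2, "LYS", "NZ", "N", nz),
        ]
        one = detect_salt_bridges(_traj_with_atoms(m, specs))[0]
        dup_specs = [(a, b, c, d, np.repeat(e, 2, axis=0)) for a, b, c, d, e in specs]
        two = detect_salt_bridges(_traj_with_atoms(2 * m, dup_specs))[0]
        assert np.isclose(one.occupancy, two.occupancy)


class TestHBonds:
    def test_collinear_bond_present(self):
        m = 5
        traj = _traj_with_atoms(
            m,
            [
                (1, "GLY", "N", "N", _static(m, [0, 0, 0])),
                (1, "GLY", "H", "H", _static(m, [1.0, 0, 0])),
                (3, "GLY", "O", "O", _static(m, [2.9, 0, 0])),
            ],
        )
        recs = detect_hbonds(
            traj,
            donors=[HBondSite(1, "N", "H")],
            acceptors=[HBondSite(3, "O")],
        )
        assert len(recs) == 1 and recs[0].occupancy == 1.0

    def test_bent_geometry_rejected(self):
        m = 5
        traj = _traj_with_atoms(
            m,
            [
                (1, "GLY", "N", "N", _static(m, [0, 0, 0])),
                (1, "GLY", "H", "H", _static(m, [1.0, 0, 0])),
                (3, "GLY", "O", "O", _static(m, [1.0, 2.7, 0])),  # ~90° at H
            ],
        )
        recs = detect_hbonds(
            traj, donors=[HBondSite(1, "N", "H")], acceptors=[HBondSite(3, "O")]
        )
        assert recs == []

    def test_matches_triple_loop_oracle(self, rng):
        m = 50
        n_pos = rng.normal(scale=0.5, size=(m, 3))
        h_pos = n_pos + [1.0, 0, 0] + rng.normal(scale=0.1, size=(m, 3))
        o_pos = n_pos + [2.9, 0, 0] + rng.normal(scale=0.6, size=(m, 3))
        traj = _traj_with_atoms(
            m,
            [
                (1, "GLY", "N", "N", n_pos),
                (1, "GLY", "H", "H", h_pos),
                (3, "GLY", "O", "O", o_pos),
            ],
        )
        recs = detect_hbonds(
            traj, donors=[HBondSite(1, "N", "H")], acceptors=[HBondSite(3, "O")]
        )
        oracle = np.zeros(m, dtype=bool)
        for k in range(m):
            da = np.linalg.norm(n_pos[k] - o_pos[k])
            v1 = n_pos[k] - h_pos[k]
            v2 = o_pos[k] - h_pos[k]
            ang = np.degrees(
                np.arccos(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
            )
            oracle[k] = da <= 3.5 and ang >= 150.0
        if oracle.any():
            assert len(recs) == 1
            np.testing.assert_array_equal(recs[0].presence, oracle)
        else:
            assert recs == []

    def test_distance_only_mode_warns_without_hydrogen(self):
        m = 5
        traj = _traj_with_atoms(
            m,
            [
                (1, "GLY", "N", "N", _static(m, [0, 0, 0])),
                (3, "GLY", "O", "O", _static(m, [2.9, 0, 0])),
            ],
        )
        with pytest.warns(UserWarning, match="distance-only"):
            recs = detect_hbonds(
                traj, donors=[HBondSite(1, "N", "H")], acceptors=[HBondSite(3, "O")]
            )
        assert len(recs) == 1


class TestInteractionTimeline:
    def _partition(self, labels):
        labels = np.asarray(labels)
        probs = {
            int(s): float((labels == s).mean()) for s in np.unique(labels)
        }
        dom = max(probs, key=lambda k: (probs[k], -k))
        return StatePartition(labels, probs, dom)

    def test_always_present_bond(self):
        m = 10
        traj = _traj_with_atoms(
            m,
            [
                (1, "ASP", "OD1", "O", _static(m, [0, 0, 0])),
                (2, "LYS", "NZ", "N", _static(m, [3.0, 0, 0])),
            ],
        )
        recs = detect_salt_bridges(traj)
        part = self._partition([1] * 5 + [2] * 5)
        out = interaction_timeline(recs, part)
        assert out[0]["occupancy_by_state"] == {1: 1.0, 2: 1.0}

    def test_state_coupled_bond(self):
        m = 10
        labels = np.array([1] * 6 + [2] * 4)
        nz = np.zeros((m, 3))
        nz[:, 0] = np.where(labels == 2, 3.0, 6.0)
        traj = _traj_with_atoms(
            m,
            [
                (1, "ASP", "OD1", "O", _static(m, [0, 0, 0])),
                (2, "LYS", "NZ", "N", nz),
            ],
        )
        recs = detect_salt_bridges(traj)
        out = interaction_timeline(recs, self._partition(labels))
        assert out[0]["occupancy_by_state"] == {1: 0.0, 2: 1.0}

    def test_without_partition_overall_only(self):
        m = 10
        traj = _traj_with_atoms(
            m,
            [
                (1, "ASP", "OD1", "O", _static(m, [0, 0, 0])),
                (2, "LYS", "NZ", "N", _static(m, [3.0, 0, 0])),
            ],
        )
        out = interaction_timeline(detect_salt_bridges(traj))
        assert "occupancy_by_state" not in out[0]
        assert out[0]["occupancy"] == 1.0

    def test_frame_count_mismatch_rejected(self):
        m = 10
        traj = _traj_with_atoms(
            m,
            [
                (1, "ASP", "OD1", "O", _static(m, [0, 0, 0])),
                (2, "LYS", "NZ", "N", _static(m, [3.0, 0, 0])),
            ],
        )
        recs = detect_salt_bridges(traj)
        with pytest.raises(ValueError):
            interaction_timeline(recs, self._partition([1] * 5))
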