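"""Structure parsing, superposition and swing metrics."""

from pathlib import Path

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from allosense.structure import (
    FormatError,
    MissingAtomError,
    PairingError,
    Selection,
    StructureModel,
    ploop_distance,
    read_structure,
    rotation_angle,
    superpose,
    superpose_arrays,
    swap_distances,
    swing_metrics,
    write_structure,
)
from allosense.synth import GeneratorConfig, StructureBlock, make_structure_pair

# Deposited coordinates are not bundled; drop e.g. 6hq2.cif into this
# directory to enable the corresponding checks.
DEPOSITED_DIR = Path(__file__).resolve().parents[1] / "data" / "structures"


def deposited(code: str):
    for ext in (".cif", ".pdb"):
        p = DEPOSITED_DIR / f"{code}{ext}"
        if p.exists():
            return p
    return None


def tiny_model() -> StructureModel:
    return StructureModel(
        chain=("A", "A", "A"),
        resnum=(1, 2, 3),
        resname=("GLY", "ALA", "SER"),
        atom_name=("CA", "CA", "CA"),
        coords=np.array([[0.0, 0.0, 0.0], [3.8, 0.0, 0.0], [7.4, 1.2, 0.3]]),
        label="tiny",
    )


class TestIO:
    def test_write_read_round_trip(self, tmp_path):
        m = tiny_model()
        path = tmp_path / "tiny.pdb"
        write_structure(m, path)
        back = read_structure(path)
        assert back.chain == m.chain
        assert back.resnum == m.resnum
        np.testing.assert_allclose(back.coords, m.coords, atol=1e-3)  # PDB precision

    def test_altloc_keeps_highest_occupancy_conformer(self, tmp_path):
        pdb = "\n".join(
            [
                "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C",
                "ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.60  0.00           C",
                "ATOM      3  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C",
                "END",
            ]
        )
        path = tmp_path / "altloc.pdb"
        path.write_text(pdb + "\n")
        m = read_structure(path)
        assert m.n_atoms == 2
        np.testing.assert_allclose(m.ca("A", 1), [9.0, 0.0, 0.0], atol=1e-3)

    def test_empty_file_raises_format_error(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises(FormatError):
            read_structure(path)

    def test_missing_atom_error_names_residue(self):
        with pytest.raises(MissingAtomError, match="A:99"):
            tiny_model().ca("A", 99)


class TestSuperposition:
    def test_self_superposition_is_identity(self):
        m = tiny_model()
        sel = Selection(chains=("A",), residue_ranges=((1, 3),))
        res = superpose(m, m, sel)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-12)

    def test_recovers_known_37_degree_rotation(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 3)) * 10
        R = Rotation.from_euler("z", 37.0, degrees=True).as_matrix()
        Y = X @ R.T + np.array([5.0, -2.0, 3.0])
        res = superpose_arrays(X, Y)
        assert rotation_angle(res.rotation) == pytest.approx(37.0, abs=1e-9)
        np.testing.assert_allclose(Y @ res.rotation.T + res.translation, X, atol=1e-9)

    def test_matches_scipy_align_vectors_on_noisy_pair(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 3)) * 8
        R_true = Rotation.random(random_state=rng).as_matrix()
        Y = X @ R_true.T + rng.normal(scale=0.3, size=(20, 3))
        res = superpose_arrays(X, Y)
        oracle, _ = Rotation.align_vectors(
            X - X.mean(axis=0), Y - Y.mean(axis=0)
        )
        np.testing.assert_allclose(res.rotation, oracle.as_matrix(), atol=1e-8)

    def test_invariant_under_common_rigid_transform(self):
        ref, mov, _ = make_structure_pair(GeneratorConfig(seed=2))
        base = swing_metrics(ref, mov)
        R = Rotation.from_euler("xyz", [21.0, -40.0, 63.0], degrees=True).as_matrix()
        t = np.array([12.0, -7.0, 30.0])
        moved = swing_metrics(ref.transformed(R, t), mov.transformed(R, t))
        assert moved.swing_angle_deg == pytest.approx(base.swing_angle_deg, abs=1e-8)
        assert moved.max_body_shift_A == pytest.approx(base.max_body_shift_A, abs=1e-8)

    def test_unequal_atom_counts_raise_pairing_error(self):
        with pytest.raises(PairingError):
            superpose_arrays(np.zeros((4, 3)), np.zeros((5, 3)))


class TestRotationAngle:
    def test_identity_and_flip(self):
        assert rotation_angle(np.eye(3)) == 0.0
        assert rotation_angle(np.diag([1.0, -1.0, -1.0])) == pytest.approx(180.0)

    def test_random_rotations_match_quaternion_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            rot = Rotation.random(random_state=rng)
            expect = np.degrees(np.linalg.norm(rot.as_rotvec()))
            assert rotation_angle(rot.as_matrix()) == pytest.approx(expect, abs=1e-9)

    def test_non_orthonormal_input_rejected(self):
        with pytest.raises(ValueError):
            rotation_angle(np.eye(3) * 1.1)


class TestProbeDistances:
    def test_synthetic_two_atom_distance_is_exact(self):
        m = StructureModel(
            chain=("A", "A"),
            resnum=(62, 95),
            resname=("ILE", "ASP"),
            atom_name=("CA", "CA"),
            coords=np.array([[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]]),
        )
        assert ploop_distance(m, "A") == pytest.approx(5.0, rel=1e-14)

    def test_symmetric_dimer_has_equal_swap_and_nonswap_distances(self):
        # C2 about z with residue 111 on the twofold-perpendicular axis:
        # |A111-A117| equals |A111-B117| by symmetry
        coords = np.array(
            [[3.0, 0.0, 0.0], [0.0, 4.0, 0.0], [-3.0, 0.0, 0.0], [0.0, -4.0, 0.0]]
        )
        m = StructureModel(
            chain=("A", "A", "B", "B"),
            resnum=(111, 117, 111, 117),
            resname=("ARG",) * 4,
            atom_name=("CA",) * 4,
            coords=coords,
        )
        same, cross = swap_distances(m)
        assert same == pytest.approx(cross, rel=1e-12)

    def test_missing_extension_residue_reported(self):
        m = tiny_model()
        with pytest.raises(MissingAtomError):
            swap_distances(m, chain_pair=("A", "A"))


class TestSwingMetrics:
    @pytest.mark.parametrize("angle", [5.0, 30.0, 50.0, 90.0, 120.0])
    def test_imposed_body_rotation_recovered_exactly(self, angle):
        cfg = GeneratorConfig(seed=3, structure=StructureBlock(angle_deg=angle))
        ref, mov, truth = make_structure_pair(cfg)
        m = swing_metrics(ref, mov)
        assert m.swing_angle_deg == pytest.approx(truth, abs=1e-6)
        assert m.stator_rmsd_A == pytest.approx(0.0, abs=1e-9)
        assert m.body_rmsd_A == pytest.approx(0.0, abs=1e-9)

    def test_identical_states_give_zero_motion(self):
        cfg = GeneratorConfig(seed=4, structure=StructureBlock(angle_deg=0.0))
        ref, mov, _ = make_structure_pair(cfg)
        m = swing_metrics(ref, mov)
        assert m.swing_angle_deg == pytest.approx(0.0, abs=1e-9)
        assert m.max_body_shift_A == pytest.approx(0.0, abs=1e-9)


@pytest.mark.skipif(deposited("6hq2") is None, reason="deposited 6HQ2 coordinates not present")
def test_apo_sensor_ploop_distance_matches_published():
    m = read_structure(deposited("6hq2"), label="apo")
    dists = [ploop_distance(m, c) for c in m.chains[:2]]
    assert any(abs(d - 20.1) <= 0.3 for d in dists)


@pytest.mark.skipif(deposited("6hq3") is None, reason="deposited 6HQ3 coordinates not present")
def test_half_occupied_sensor_ploop_distance_matches_published():
    m = read_structure(deposited("6hq3"), label="mid")
    dists = [ploop_distance(m, c) for c in m.chains]
    assert any(abs(d - 16.7) <= 0.3 for d in dists)


@pytest.mark.skipif(deposited("6hq7") is None, reason="deposited 6HQ7 coordinates not present")
def test_full_length_swap_topology_distances_match_published():
    m = read_structure(deposited("6hq7"), label="bound_cGMP")
    same, cross = swap_distances(m)
    assert cross == pytest.approx(11.0, abs=1.0)
    assert same == pytest.approx(21.0, abs=1.0)
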