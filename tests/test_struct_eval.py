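"""CA parsing, Kabsch superposition, GDT_TS and pLDDT evaluation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from msaforge.struct_eval import (
    DomainDefinition,
    StructureModel,
    gdt_fraction,
    gdt_ts,
    kabsch,
    mean_plddt,
    parse_ca,
    write_ca,
)
from msaforge.synthetic_data import DecoySpec, make_decoy, make_structure

PDB_ONE_CA = (
    "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00 87.30           C\n"
    "END\n"
)


def transformed(model, rot, t):
    return StructureModel(
        residue_numbers=model.residue_numbers, coords=model.coords @ rot.T + t,
        plddt=model.plddt,
    )


class TestParseCa:
    def test_single_atom(self):
        m = parse_ca(PDB_ONE_CA)
        assert len(m) == 1
        assert m.residue_numbers[0] == 1
        np.testing.assert_allclose(m.coords[0], [1.0, 2.0, 3.0])
        assert m.plddt is None

    def test_bfactor_read_as_plddt_on_predicted(self):
        m = parse_ca(PDB_ONE_CA, predicted=True)
        assert m.plddt[0] == pytest.approx(87.3)

    def test_non_ca_atoms_ignored(self):
        text = (
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      3  CB  ALA A   1       2.000   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        m = parse_ca(text)
        assert len(m) == 1
        np.testing.assert_allclose(m.coords[0], [1.0, 0.0, 0.0])

    def test_altloc_first_wins(self):
        text = (
            "ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.50  0.00           C\n"
            "ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.50  0.00           C\n"
            "END\n"
        )
        m = parse_ca(text)
        assert len(m) == 1
        assert m.coords[0, 0] == pytest.approx(1.0)

    def test_no_ca_raises(self):
        with pytest.raises(ValueError, match="no CA"):
            parse_ca("ATOM      1  N   ALA A   1       0.0     0.0     0.0  1.00  0.00           N\n")

    def test_write_read_round_trip(self):
        ref = make_structure(20, 5)
        model = StructureModel(ref.residue_numbers, ref.coords,
                               plddt=np.linspace(50, 99, 20))
        back = parse_ca(write_ca(model), predicted=True)
        np.testing.assert_array_equal(back.residue_numbers, model.residue_numbers)
        np.testing.assert_allclose(back.coords, model.coords, atol=1e-3)
        np.testing.assert_allclose(back.plddt, model.plddt, atol=0.01)


class TestKabsch:
    def test_identity(self):
        P = np.random.default_rng(0).normal(size=(10, 3))
        sup = kabsch(P, P)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-12)

    def test_recovers_known_transforms(self, rng):
        P = rng.normal(size=(15, 3)) * 10
        for _ in range(100):
            R = Rotation.random(random_state=np.random.RandomState(
                rng.integers(2**31))).as_matrix()
            t = rng.uniform(-50, 50, 3)
            sup = kabsch(P, P @ R.T + t)
            assert sup.rmsd < 1e-9
            np.testing.assert_allclose(sup.rotation, R, atol=1e-8)
            np.testing.assert_allclose(sup.translation, t, atol=1e-7)
            assert np.linalg.det(sup.rotation) == pytest.approx(1.0)

    def test_optimal_among_random_transforms(self, rng):
        """Kabsch RMSD lower-bounds the RMSD under any tested rigid transform."""
        P = rng.normal(size=(12, 3)) * 5
        Q = P + rng.normal(size=(12, 3)) * 2.0
        best = kabsch(P, Q).rmsd
        for _ in range(100):
            R = Rotation.random(random_state=np.random.RandomState(
                rng.integers(2**31))).as_matrix()
            t = rng.uniform(-5, 5, 3)
            rms = np.sqrt((((P @ R.T + t) - Q) ** 2).sum() / len(P))
            assert best <= rms + 1e-12

    def test_agrees_with_scipy_align_vectors(self, rng):
        P = rng.normal(size=(20, 3)) * 8
        Q = P + rng.normal(size=(20, 3))
        sup = kabsch(P, Q)
        rot, rssd = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
        np.testing.assert_allclose(sup.rotation, rot.as_matrix(), atol=1e-9)
        assert sup.rmsd == pytest.approx(rssd / np.sqrt(len(P)), abs=1e-9)

    def test_no_reflection(self):
        # mirror-image points: the best PROPER rotation must keep det +1
        P = np.random.default_rng(3).normal(size=(10, 3))
        Q = P.copy()
        Q[:, 2] = -Q[:, 2]
        sup = kabsch(P, Q)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0)
        assert sup.rmsd > 0.1

    def test_errors(self):
        with pytest.raises(ValueError):
            kabsch(np.zeros((4, 3)), np.zeros((5, 3)))
        with pytest.raises(ValueError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


@pytest.fixture(scope="module")
def ref60():
    return make_structure(60, 42)


class TestGdt:
    def test_identical_structures(self, ref60):
        for cutoff in (1.0, 2.0, 4.0, 8.0):
            assert gdt_fraction(ref60, ref60, cutoff) == 1.0
        assert gdt_ts(ref60, ref60) == pytest.approx(100.0)

    def test_rigid_transform_scores_100(self, ref60, rng):
        R = Rotation.random(random_state=np.random.RandomState(7)).as_matrix()
        moved = transformed(ref60, R, rng.uniform(-30, 30, 3))
        assert gdt_ts(moved, ref60) == pytest.approx(100.0, abs=1e-6)

    def test_half_displaced_scores_50(self, ref60):
        decoy = make_decoy(ref60, DecoySpec(
            mode="split_displace", displace_fraction=0.5,
            displace_distance=100.0, seed=1))
        # 30/60 residues exact, 30 moved ~100 A away: fraction 1/2 at all cutoffs
        assert gdt_ts(decoy, ref60) == pytest.approx(50.0, abs=2.0)
        for cutoff in (1.0, 2.0, 4.0, 8.0):
            frac = gdt_fraction(decoy, ref60, cutoff)
            assert abs(frac - 0.5) <= 1 / 60

    def test_monotone_in_noise(self, ref60):
        scores = []
        for sigma in (0.5, 2.0, 8.0):
            reps = [gdt_ts(make_decoy(ref60, DecoySpec(mode="noise", sigma=sigma,
                                                       seed=s)), ref60)
                    for s in range(3)]
            scores.append(np.mean(reps))
        assert scores[0] > scores[1] > scores[2]

    def test_cutoff_monotonicity(self, ref60):
        decoy = make_decoy(ref60, DecoySpec(mode="noise", sigma=3.0, seed=9))
        fracs = [gdt_fraction(decoy, ref60, c) for c in (1, 2, 4, 8)]
        assert fracs == sorted(fracs)

    def test_invariant_under_common_rigid_transform(self, ref60, rng):
        decoy = make_decoy(ref60, DecoySpec(mode="noise", sigma=2.0, seed=4))
        base = gdt_ts(decoy, ref60)
        R = Rotation.random(random_state=np.random.RandomState(11)).as_matrix()
        t = rng.uniform(-20, 20, 3)
        assert gdt_ts(transformed(decoy, R, t), transformed(ref60, R, t)) == \
            pytest.approx(base, abs=1e-6)

    def test_symmetry_for_equal_residue_sets(self, ref60):
        decoy = make_decoy(ref60, DecoySpec(mode="noise", sigma=2.0, seed=5))
        assert gdt_ts(decoy, ref60) == pytest.approx(gdt_ts(ref60, decoy), abs=1e-9)

    def test_at_least_full_set_seed(self, ref60):
        """Heuristic never scores below the single full-set superposition."""
        decoy = make_decoy(ref60, DecoySpec(mode="noise", sigma=4.0, seed=6))
        for cutoff in (1.0, 4.0):
            sup = kabsch(decoy.coords, ref60.coords)
            dist = np.linalg.norm(sup.apply(decoy.coords) - ref60.coords, axis=1)
            assert gdt_fraction(decoy, ref60, cutoff) >= (dist <= cutoff).mean()

    def test_domain_cropping(self, ref60):
        domain = DomainDefinition("T1", "T1-D1", ((1, 30),))
        decoy = make_decoy(ref60, DecoySpec(
            mode="split_displace", displace_fraction=0.5,
            displace_distance=100.0, seed=2))
        # first half exact -> the cropped domain is a perfect model
        assert gdt_ts(decoy, ref60, domain) == pytest.approx(100.0)

    def test_too_few_common_residues(self, ref60):
        tiny = StructureModel(np.array([200, 201]), np.zeros((2, 3)))
        with pytest.raises(ValueError):
            gdt_fraction(tiny, ref60, 4.0)


class TestDomainsAndPlddt:
    def test_from_spec_parsing(self):
        d = DomainDefinition.from_spec("T1104", "T1104-D1", "10-120,140-160", "TBM-hard")
        assert d.ranges == ((10, 120), (140, 160))
        assert len(d.residue_numbers) == 111 + 21

    def test_invalid_domains(self):
        with pytest.raises(ValueError):
            DomainDefinition("t", "d", ((10, 5),))
        with pytest.raises(ValueError):
            DomainDefinition("t", "d", ((1, 10), (5, 20)))
        with pytest.raises(ValueError):
            DomainDefinition("t", "d", ((1, 10),), category="hard")

    def test_mean_plddt(self):
        model = StructureModel(np.arange(1, 5), np.zeros((4, 3)),
                               plddt=np.array([80.0, 100.0, 90.0, 10.0]))
        assert mean_plddt(model, DomainDefinition("t", "d", ((1, 2),))) == 90.0
        assert mean_plddt(model) == pytest.approx(70.0)

    def test_cropping_invariance(self):
        domain = DomainDefinition("t", "d", ((1, 2),))
        a = StructureModel(np.arange(1, 5), np.zeros((4, 3)),
                           plddt=np.array([80.0, 100.0, 5.0, 5.0]))
        b = StructureModel(np.arange(1, 3), np.zeros((2, 3)),
                           plddt=np.array([80.0, 100.0]))
        assert mean_plddt(a, domain) == mean_plddt(b, domain)

    def test_missing_plddt_raises(self):
        model = StructureModel(np.arange(1, 5), np.zeros((4, 3)))
        with pytest.raises(ValueError):
            mean_plddt(model)
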