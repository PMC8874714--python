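"""Distance and superposition operations against independent oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from redoxpath.geometry import (
    domain_rmsd,
    kabsch_superpose,
    min_group_distance,
    residue_group_distance,
    transfer_cofactor,
)
from redoxpath.structure_io import AtomRecord, CofactorGroup, Structure


def _group(coords, label="HEM", idx=1):
    atoms = [
        AtomRecord(i + 1, f"C{i}", "C", label, 1101, "A", tuple(map(float, c)), True)
        for i, c in enumerate(np.atleast_2d(coords))
    ]
    return CofactorGroup(label=label, monomer_index=idx, atoms=atoms)


def _brute_min(a, b):
    best = None
    for pa in a:
        for pb in b:
            d = float(np.linalg.norm(np.asarray(pa) - np.asarray(pb)))
            best = d if best is None or d < best else best
    return best


def _quaternion_rmsd(mobile, target):
    """Horn's closed-form absolute orientation: independent of the SVD path."""
    x = mobile - mobile.mean(axis=0)
    y = target - target.mean(axis=0)
    s = x.T @ y
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    eigvals, eigvecs = np.linalg.eigh(k)
    q = eigvecs[:, -1]  # w, x, y, z
    rot = Rotation.from_quat([q[1], q[2], q[3], q[0]]).as_matrix()
    moved = x @ rot.T
    return float(np.sqrt(np.mean(np.sum((moved - y) ** 2, axis=1)))), rot


class TestMinGroupDistance:
    def test_three_four_five(self):
        r = min_group_distance(_group([(0, 0, 0)]), _group([(3, 4, 0)], "FMN"))
        assert r.distance == pytest.approx(5.0)

    def test_identical_groups_zero(self):
        g = _group([(1, 2, 3), (4, 5, 6)])
        assert min_group_distance(g, g).distance == 0.0

    def test_matches_brute_force_on_random_clouds(self, rng):
        for _ in range(200):
            a = rng.normal(size=(20, 3)) * 5
            b = rng.normal(size=(20, 3)) * 5 + rng.uniform(-10, 10, size=3)
            r = min_group_distance(_group(a), _group(b, "FMN"))
            assert r.distance == pytest.approx(_brute_min(a, b), abs=1e-12)
            # symmetry
            assert min_group_distance(_group(b, "FMN"), _group(a)).distance == pytest.approx(
                r.distance, abs=1e-12
            )

    def test_reported_pair_achieves_minimum(self, rng):
        a = rng.normal(size=(15, 3)) * 4
        b = rng.normal(size=(15, 3)) * 4 + 8
        r = min_group_distance(_group(a), _group(b, "FAD"))
        d = np.linalg.norm(a[r.donor_atom_index] - b[r.acceptor_atom_index])
        assert d == pytest.approx(r.distance, abs=1e-12)

    def test_tie_broken_to_lowest_indices(self):
        # two symmetric closest pairs at identical distance
        a = _group([(0, 0, 0), (0, 1, 0)])
        b = _group([(1, 0, 0), (1, 1, 0)], "FMN")
        r = min_group_distance(a, b)
        assert (r.donor_atom_index, r.acceptor_atom_index) == (0, 0)


class TestKabsch:
    def test_identity(self, rng):
        x = rng.normal(size=(10, 3))
        r = kabsch_superpose(x, x)
        assert r.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(r.rotation, np.eye(3), atol=1e-9)

    def test_rigid_copy_recovered(self, rng):
        x = rng.normal(size=(50, 3))
        rot = Rotation.random(random_state=7).as_matrix()
        y = x @ rot.T + np.array([3.0, -2.0, 5.0])
        r = kabsch_superpose(x, y)
        assert r.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(r.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_matches_quaternion_oracle_with_noise(self, rng):
        x = rng.normal(size=(100, 3)) * 3
        rot = Rotation.random(random_state=1).as_matrix()
        y = x @ rot.T + rng.normal(scale=0.5, size=(100, 3))
        r = kabsch_superpose(x, y)
        oracle_rmsd, _ = _quaternion_rmsd(x, y)
        assert r.rmsd == pytest.approx(oracle_rmsd, abs=1e-9)

    def test_thousand_random_trials_vs_oracle_and_invariance(self, rng):
        """Property sweep: oracle equality and rigid-transform invariance."""
        for trial in range(1000):
            n = int(rng.integers(4, 12))
            x = rng.normal(size=(n, 3)) * 2
            y = x + rng.normal(scale=0.3, size=(n, 3))
            r = kabsch_superpose(x, y)
            oracle, _ = _quaternion_rmsd(x, y)
            assert abs(r.rmsd - oracle) < 1e-9
            assert abs(np.linalg.det(r.rotation) - 1.0) < 1e-9
            if trial % 10 == 0:
                rot = Rotation.random(random_state=trial).as_matrix()
                t = rng.uniform(-5, 5, size=3)
                r2 = kabsch_superpose(x @ rot.T + t, y @ rot.T + t)
                assert abs(r2.rmsd - r.rmsd) < 1e-9

    def test_errors(self, rng):
        x = rng.normal(size=(5, 3))
        with pytest.raises(ValueError, match="shape"):
            kabsch_superpose(x, x[:4])
        with pytest.raises(ValueError, match="at least 3"):
            kabsch_superpose(x[:2], x[:2])
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(line, line)


def _ca_structure(coords, chain="A", start=2):
    atoms = [
        AtomRecord(i + 1, "CA", "C", "GLY", start + i, chain, tuple(map(float, c)), False)
        for i, c in enumerate(coords)
    ]
    return Structure(atoms=atoms, source_label="dom")


class TestDomainRmsd:
    def test_identical_domains_zero(self, rng):
        c = rng.normal(size=(30, 3)) * 4
        assert domain_rmsd(_ca_structure(c), _ca_structure(c)) == pytest.approx(0.0, abs=1e-12)

    def test_hinge_rotation_matches_direct_optimisation(self, rng):
        """A 10-degree hinge on half the atoms, checked against a brute
        grid-plus-refine minimisation over rotations and translations."""
        c = rng.normal(size=(40, 3)) * 5
        hinge = Rotation.from_euler("z", 10, degrees=True).as_matrix()
        moved = c.copy()
        moved[20:] = moved[20:] @ hinge.T
        result = domain_rmsd(_ca_structure(c), _ca_structure(moved))

        def objective(p):
            rot = Rotation.from_euler("xyz", p[:3]).as_matrix()
            diff = c @ rot.T + p[3:] - moved
            return np.sqrt(np.mean(np.sum(diff**2, axis=1)))

        best = np.inf
        for ang in np.linspace(-0.3, 0.3, 5):
            res = minimize(objective, x0=[ang, 0, 0, 0, 0, 0], method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
            best = min(best, res.fun)
        assert result == pytest.approx(best, abs=1e-6)
        assert result > 0

    def test_too_few_matches_raises(self, rng):
        a = _ca_structure(rng.normal(size=(10, 3)))
        b = _ca_structure(rng.normal(size=(10, 3)), start=500)  # disjoint numbering
        with pytest.raises(ValueError, match="matched"):
            domain_rmsd(a, b)


class TestTransferCofactor:
    def test_identity_transform_returns_cofactor_unchanged(self, rng):
        dom = _ca_structure(rng.normal(size=(20, 3)) * 5)
        cof = _group(rng.normal(size=(8, 3)) + 10)
        out = transfer_cofactor(dom, dom, cof)
        assert np.allclose(out.coords_array(), cof.coords_array(), atol=1e-9)

    def test_rigid_move_preserves_internal_and_relative_geometry(self, rng):
        ref_coords = rng.normal(size=(25, 3)) * 5
        rot = Rotation.random(random_state=3).as_matrix()
        t = np.array([4.0, -7.0, 2.0])
        ref = _ca_structure(ref_coords)
        pred = _ca_structure(ref_coords @ rot.T + t)
        cof = _group(rng.normal(size=(10, 3)) + 6)
        out = transfer_cofactor(ref, pred, cof)
        # ground truth: cofactor rigidly moved along with the domain
        expected = cof.coords_array() @ rot.T + t
        assert np.allclose(out.coords_array(), expected, atol=1e-6)
        # intra-cofactor distances exactly preserved
        a, b = cof.coords_array(), out.coords_array()
        da = np.linalg.norm(a[:, None] - a[None], axis=-1)
        db = np.linalg.norm(b[:, None] - b[None], axis=-1)
        assert np.allclose(da, db, atol=1e-9)


class TestResidueGroupDistance:
    def test_probe_fixture_distance(self, scenario_fixtures):
        from redoxpath.structure_io import extract_cofactors, read_pdb

        spec, path, _ = scenario_fixtures["a83f-dimer"]
        s = read_pdb(path)
        heme1 = next(g for g in extract_cofactors(s) if g.key == "HEM1")
        d = residue_group_distance(s, "A", 262, heme1)
        assert d == pytest.approx(spec.aromatic_probe_distance, abs=1e-6)

    def test_coincident_atom_gives_zero_and_brute_force_agreement(self, rng):
        heme = _group(rng.normal(size=(10, 3)))
        atoms = [
            AtomRecord(1, "CA", "C", "PHE", 50, "A", (9.0, 9.0, 9.0), False),
            AtomRecord(2, "CZ", "C", "PHE", 50, "A", tuple(heme.atoms[0].coords), False),
        ]
        s = Structure(atoms=atoms, source_label="t")
        assert residue_group_distance(s, "A", 50, heme) == pytest.approx(0.0)
        brute = _brute_min([atoms[1].coords], [a.coords for a in heme.atoms])
        assert residue_group_distance(s, "A", 50, heme) == pytest.approx(brute)

    def test_missing_residue_raises(self):
        s = Structure(
            atoms=[AtomRecord(1, "CA", "C", "GLY", 2, "A", (0.0, 0.0, 0.0), False)],
            source_label="t",
        )
        with pytest.raises(ValueError, match="not found"):
            residue_group_distance(s, "A", 99, _group([(0, 0, 0)]))
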