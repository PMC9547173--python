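"""SASA engine: lattice quality, analytic oracles, invariances."""

import math

import numpy as np
import pytest

from exthect.sasa import SasaParams, compute_sasa, generate_sphere_points, sasa_of_selection
from exthect.structure import Atom, AtomSelection, Residue, Structure, select_hydrophobic_sidechains
from exthect.synthetic import monte_carlo_sasa, sphere_fixtures, two_sphere_exact_area


def cluster(coords, radius=1.7):
    """Structure of single-atom residues at given coordinates."""
    residues = [
        Residue("SPH", i + 1, "", [Atom("C1", "C", np.asarray(c, float), vdw_radius=radius)])
        for i, c in enumerate(coords)
    ]
    return Structure("cluster", {"A": residues})


class TestSpherePoints:
    def test_unit_norm_and_determinism(self):
        pts = generate_sphere_points(100)
        assert pts.shape == (100, 3)
        assert np.max(np.abs(np.linalg.norm(pts, axis=1) - 1.0)) < 1e-12
        np.testing.assert_array_equal(pts, generate_sphere_points(100))

    def test_angular_separation_near_ideal(self):
        # brute-force min pairwise angle vs the uniform-coverage estimate
        n = 2000
        pts = generate_sphere_points(n)
        dots = pts @ pts.T
        np.fill_diagonal(dots, -1.0)
        min_angle = math.acos(np.clip(dots.max(), -1, 1))
        ideal = math.sqrt(4 * math.pi / n)
        assert abs(min_angle - ideal) / ideal < 0.3

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            generate_sphere_points(11)


class TestAnalyticOracles:
    def test_isolated_sphere_exact(self):
        s = cluster([[0, 0, 0]])
        res = compute_sasa(s, SasaParams(n_points=960))
        assert res.total == pytest.approx(4 * math.pi * 3.1**2, rel=1e-9)

    def test_distant_spheres_unoccluded(self):
        s = cluster([[0, 0, 0], [10.0, 0, 0]])
        res = compute_sasa(s, SasaParams(n_points=960))
        assert res.total == pytest.approx(2 * 4 * math.pi * 3.1**2, rel=1e-9)

    def test_fixture_grid_within_two_percent(self):
        for s, exact, meta in sphere_fixtures():
            res = compute_sasa(s, SasaParams(n_points=960))
            assert res.total == pytest.approx(exact, rel=0.02), meta

    def test_random_two_and_three_sphere_systems(self, rng):
        """Engine vs cap formula (pairs) and Monte-Carlo estimator (triples)."""
        for _ in range(25):
            r1, r2 = rng.uniform(1.4, 2.0, size=2)
            d = rng.uniform(1.5, 6.0)
            s = cluster([[0, 0, 0], [d, 0, 0]])
            s.chains["A"][0].atoms[0].vdw_radius = r1
            s.chains["A"][1].atoms[0].vdw_radius = r2
            res = compute_sasa(s, SasaParams(n_points=960))
            exact = two_sphere_exact_area(r1, r2, d)
            assert res.total == pytest.approx(exact, rel=0.02)
        for _ in range(25):
            coords = rng.uniform(-2.5, 2.5, size=(3, 3))
            radii = rng.uniform(1.4, 2.0, size=3)
            s = cluster(coords)
            for atom_res, r in zip(s.chains["A"], radii):
                atom_res.atoms[0].vdw_radius = float(r)
            res = compute_sasa(s, SasaParams(n_points=960))
            mc = monte_carlo_sasa(coords, radii, n_per_atom=100_000, rng=rng).sum()
            assert res.total == pytest.approx(mc, rel=0.02)

    def test_against_independent_library_implementation(self, rng):
        """Cross-check a random 15-atom cluster against biotite's SASA."""
        biotite_struc = pytest.importorskip("biotite.structure")
        coords = rng.uniform(0, 8, size=(15, 3))
        s = cluster(coords)
        res = compute_sasa(s, SasaParams(n_points=4000))
        arr = biotite_struc.AtomArray(15)
        arr.coord = coords.astype(np.float32)
        arr.set_annotation("element", np.array(["C"] * 15))
        areas = biotite_struc.sasa(
            arr, probe_radius=1.4, vdw_radii=np.full(15, 1.7), point_number=4000
        )
        assert res.total == pytest.approx(float(np.sum(areas)), rel=0.02)


class TestInvariances:
    def test_convergence_960_vs_4000(self, rng):
        coords = rng.uniform(0, 10, size=(20, 3))
        s = cluster(coords)
        lo = compute_sasa(s, SasaParams(n_points=960)).total
        hi = compute_sasa(s, SasaParams(n_points=4000)).total
        assert abs(lo - hi) / hi < 0.01

    def test_rigid_motion_invariance(self, rng):
        coords = rng.uniform(0, 8, size=(12, 3))
        s = cluster(coords)
        base = compute_sasa(s, SasaParams(n_points=960))
        theta = 0.7
        rot = np.array(
            [[math.cos(theta), -math.sin(theta), 0],
             [math.sin(theta), math.cos(theta), 0],
             [0, 0, 1]]
        )
        tilt = np.array(
            [[1, 0, 0],
             [0, math.cos(0.4), -math.sin(0.4)],
             [0, math.sin(0.4), math.cos(0.4)]]
        )
        moved = cluster([tilt @ rot @ c + np.array([11.0, -3.0, 7.0]) for c in coords])
        res = compute_sasa(moved, SasaParams(n_points=960))
        for k in base.per_atom:
            assert res.per_atom[k] == pytest.approx(base.per_atom[k], rel=1e-6)

    def test_occluder_never_increases_area_beyond_noise(self, rng):
        """Adding an atom cannot raise any other atom's area (exact SASA);
        the sampling lattice re-orients with local geometry, so allow a
        small lattice-noise tolerance."""
        coords = rng.uniform(0, 7, size=(10, 3))
        s = cluster(coords)
        base = compute_sasa(s, SasaParams(n_points=960))
        added = cluster(list(coords) + [coords[0] + np.array([2.5, 0.5, 0.5])])
        res = compute_sasa(added, SasaParams(n_points=960))
        for k, a in base.per_atom.items():
            assert res.per_atom[k] <= a + 1.0  # Å², lattice noise bound


class TestSelectionSums:
    def test_empty_selection_is_zero(self, rng):
        s = cluster(rng.uniform(0, 5, size=(4, 3)))
        res = compute_sasa(s, SasaParams(n_points=240))
        assert sasa_of_selection(res, AtomSelection(set())) == 0.0

    def test_full_selection_equals_total(self, rng):
        s = cluster(rng.uniform(0, 5, size=(6, 3)))
        res = compute_sasa(s, SasaParams(n_points=240))
        sel = AtomSelection({("A", i + 1, "", "C1") for i in range(6)})
        assert sasa_of_selection(res, sel) == pytest.approx(res.total)

    def test_unresolvable_key_reported(self, rng):
        s = cluster(rng.uniform(0, 5, size=(3, 3)))
        res = compute_sasa(s, SasaParams(n_points=240))
        with pytest.raises(KeyError, match="selection key"):
            sasa_of_selection(res, AtomSelection({("A", 99, "", "C1")}))

    def test_hydrophobic_selection_equals_hand_sum(self, lkf_pdb):
        from exthect.structure import assign_radii, clean_structure, parse_structure

        s = assign_radii(clean_structure(parse_structure(lkf_pdb), "A"))
        res = compute_sasa(s, SasaParams(n_points=240))
        sel = select_hydrophobic_sidechains(s)
        manual = sum(res.per_atom[k] for k in sel.members)
        assert sasa_of_selection(res, sel) == pytest.approx(manual)

    def test_per_residue_sums_match_per_atom(self, rng):
        s = cluster(rng.uniform(0, 6, size=(8, 3)))
        res = compute_sasa(s, SasaParams(n_points=240))
        assert sum(res.per_residue.values()) == pytest.approx(res.total)

    def test_missing_radius_is_error(self):
        s = cluster([[0, 0, 0]])
        s.chains["A"][0].atoms[0].vdw_radius = None
        with pytest.raises(ValueError, match="no vdW radius"):
            compute_sasa(s)
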