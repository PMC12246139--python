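"""Geometric primitives: minimum image, angles, superposition, traces."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

import bindmode as bm
from bindmode.errors import GeometryError, SelectionError, StatisticsError
from bindmode.geometry import angles_batch, pbc_displacement, rmsd_between
from bindmode.structure_io import Frame, Selection
from oracle_detectors import oracle_dist


def _sel(*idx):
    return Selection(indices=tuple(idx), provenance="test")


def random_triclinic(rng):
    """Reduced triclinic box: dominant diagonal, modest skew."""
    box = np.diag(rng.uniform(8, 20, 3))
    box[1, 0] = rng.uniform(-0.3, 0.3) * box[1, 1]
    box[2, 0] = rng.uniform(-0.3, 0.3) * box[2, 2]
    box[2, 1] = rng.uniform(-0.3, 0.3) * box[2, 2]
    return box


class TestPbcDistance:
    def test_coincident_points(self):
        assert bm.pbc_distance([1, 2, 3], [1, 2, 3]) == 0

    def test_cubic_minimum_image(self):
        box = np.eye(3) * 10
        assert bm.pbc_distance([0, 0, 0], [9, 0, 0], box) == pytest.approx(1.0)

    def test_matches_27_image_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            box = random_triclinic(rng)
            pts = rng.uniform(-30, 30, (50, 2, 3))
            for a, b in pts:
                assert bm.pbc_distance(a, b, box) == pytest.approx(
                    oracle_dist(a, b, box), abs=1e-9)

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(-5, 5, (30, 3))
        for a, b, c in pts.reshape(10, 3, 3):
            assert bm.pbc_distance(a, b) == pytest.approx(
                bm.pbc_distance(b, a))
            assert bm.pbc_distance(a, c) <= bm.pbc_distance(a, b) \
                + bm.pbc_distance(b, c) + 1e-12

    def test_degenerate_box_raises(self):
        with pytest.raises(GeometryError):
            bm.pbc_distance([0, 0, 0], [1, 0, 0], np.zeros((3, 3)))


from hypothesis import given, settings
from hypothesis import strategies as st

_coord = st.floats(-50, 50, allow_nan=False, allow_infinity=False)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.tuples(*([_coord] * 6)))
def test_pbc_distance_properties(vals):
    """Minimum-image distance is symmetric and never exceeds Euclidean."""
    a = np.array(vals[:3])
    b = np.array(vals[3:])
    box = np.eye(3) * 10
    d = bm.pbc_distance(a, b, box)
    assert d <= np.linalg.norm(a - b) + 1e-9
    assert d == pytest.approx(bm.pbc_distance(b, a, box), abs=1e-9)
    assert d <= np.sqrt(3) * 5 + 1e-9  # half the cubic box diagonal


class TestAngle:
    def test_collinear_and_right(self):
        assert bm.angle([0, 0, 0], [1, 0, 0], [2, 0, 0]) == pytest.approx(180)
        assert bm.angle([1, 0, 0], [0, 0, 0], [0, 1, 0]) == pytest.approx(90)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            a, b, c = rng.normal(size=(3, 3))
            u, v = a - b, c - b
            expect = np.degrees(np.arccos(np.clip(
                np.dot(u, v) / np.linalg.norm(u) / np.linalg.norm(v),
                -1, 1)))
            assert bm.angle(a, b, c) == pytest.approx(expect, abs=1e-6)
        batch = angles_batch(rng.normal(size=(5, 3)),
                             rng.normal(size=(5, 3)),
                             rng.normal(size=(5, 3)))
        assert batch.shape == (5,)

    def test_zero_arm_raises(self):
        with pytest.raises(GeometryError):
            bm.angle([0, 0, 0], [0, 0, 0], [1, 0, 0])


class TestSuperpose:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        res = bm.superpose(pts, pts)
        assert res.rmsd == pytest.approx(0, abs=1e-9)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-9)
        assert abs(np.linalg.det(res.rotation) - 1) < 1e-8

    def test_recovers_known_rotation(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(12, 3))
        rot = Rotation.from_euler("xyz", [20, -35, 70],
                                  degrees=True).as_matrix()
        moved = pts @ rot.T + np.array([1.0, -2.0, 3.0])
        res = bm.superpose(moved, pts)
        assert res.rmsd < 1e-6
        assert np.allclose(res.rotation @ rot, np.eye(3), atol=1e-6)

    def test_matches_optimizer_oracle(self):
        """Kabsch RMSD agrees with an independent Euler-angle optimizer."""
        rng = np.random.default_rng(11)
        mobile = rng.normal(size=(8, 3))
        reference = rng.normal(size=(8, 3))

        mc = mobile - mobile.mean(axis=0)
        rc = reference - reference.mean(axis=0)

        def cost(euler):
            r = Rotation.from_euler("xyz", euler).as_matrix()
            return np.sqrt(np.mean(np.sum((mc @ r.T - rc) ** 2, axis=1)))

        best = min(
            minimize(cost, x0, method="Nelder-Mead",
                     options={"xatol": 1e-10, "fatol": 1e-12,
                              "maxiter": 5000}).fun
            for x0 in rng.uniform(-np.pi, np.pi, (12, 3)))
        assert bm.superpose(mobile, reference).rmsd == pytest.approx(
            best, abs=1e-3)

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=(15, 3))
        b = rng.normal(size=(15, 3))
        base = bm.superpose(a, b).rmsd
        for seed in range(5):
            r = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
            t = rng.normal(size=3) * 10
            assert bm.superpose(a @ r.T + t, b).rmsd == pytest.approx(
                base, abs=1e-8)

    def test_too_few_points(self):
        with pytest.raises(GeometryError):
            bm.superpose(np.zeros((2, 3)), np.zeros((2, 3)))


def _frames(coord_list):
    return [Frame(coordinates=np.asarray(c, float), time_ns=float(k))
            for k, c in enumerate(coord_list)]


class TestRmsdTrace:
    def test_identical_frames_zero(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(6, 3))
        frames = _frames([base] * 4)
        sel = _sel(*range(6))
        trace = bm.rmsd_trace(frames, sel, sel, frames[0])
        assert np.allclose(trace.values, 0, atol=1e-9)

    def test_rigid_translation_removed_by_fit(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(6, 3))
        frames = _frames([base, base + [3.0, -1.0, 2.0]])
        sel = _sel(*range(6))
        trace = bm.rmsd_trace(frames, sel, sel, frames[0])
        assert trace.values[1] == pytest.approx(0, abs=1e-9)

    def test_ligand_displacement_reported_exactly(self):
        """Ligand moved d Å after a perfect protein fit reads exactly d."""
        rng = np.random.default_rng(2)
        protein = rng.normal(size=(8, 3))
        ligand = rng.normal(size=(4, 3)) + 5
        d = 2.75
        ref = np.vstack([protein, ligand])
        moved = np.vstack([protein, ligand + [0, 0, d]])
        frames = _frames([ref, moved])
        fit = _sel(*range(8))
        meas = _sel(*range(8, 12))
        trace = bm.rmsd_trace(frames, fit, meas, frames[0])
        assert trace.values[1] == pytest.approx(d, abs=1e-9)

    def test_empty_selection_raises(self):
        frames = _frames([np.zeros((3, 3))])
        with pytest.raises(SelectionError):
            bm.rmsd_trace(frames, Selection(indices=()), _sel(0), frames[0])


class TestRmsf:
    def test_static_trajectory_zero(self):
        base = np.random.default_rng(0).normal(size=(5, 3))
        frames = _frames([base] * 6)
        sel = _sel(*range(5))
        assert np.allclose(bm.rmsf(frames, sel, sel), 0, atol=1e-12)

    def test_two_state_oscillator_closed_form(self):
        """One atom at +-a in equal halves has RMSF exactly a."""
        base = np.zeros((4, 3))
        base[:3] = np.eye(3) * 5  # anchor atoms defining the fit
        a = 0.8
        up = base.copy()
        up[3, 0] = a
        down = base.copy()
        down[3, 0] = -a
        frames = _frames([up, down] * 5)
        fit = _sel(0, 1, 2)
        out = bm.rmsf(frames, fit, _sel(3))
        assert out[0] == pytest.approx(a, abs=1e-9)

    def test_matches_scripted_two_pass_oracle(self):
        rng = np.random.default_rng(9)
        coords = np.cumsum(rng.normal(0, 0.1, (20, 7, 3)), axis=0) \
            + rng.normal(size=(1, 7, 3)) * 5
        frames = _frames(list(coords))
        fit = _sel(*range(7))
        meas = _sel(*range(7))
        got = bm.rmsf(frames, fit, meas)

        def fit_all(ref):
            return np.array([bm.superpose(c, ref).apply(c) for c in coords])

        pass1 = fit_all(coords[0])
        pass2 = fit_all(pass1.mean(axis=0))
        expect = np.sqrt(np.mean(np.sum(
            (pass2 - pass2.mean(axis=0)) ** 2, axis=2), axis=0))
        assert np.allclose(got, expect, atol=1e-9)

    def test_single_frame_raises(self):
        frames = _frames([np.zeros((4, 3))])
        with pytest.raises(StatisticsError):
            bm.rmsf(frames, _sel(0, 1, 2), _sel(3))


class TestMinDistance:
    def test_trivial_cases(self):
        coords = np.array([[0, 0, 0], [4, 0, 0], [0, 0, 0]], float)
        frames = _frames([coords])
        assert bm.min_distance_trace(frames, _sel(0), _sel(2)).values[0] == 0
        assert bm.min_distance_trace(frames, _sel(0), _sel(1)).values[0] == 4

    def test_matches_all_pairs_bruteforce(self):
        rng = np.random.default_rng(4)
        box = np.eye(3) * 15
        for _ in range(5):
            coords = rng.uniform(0, 15, (200, 3))
            frames = [Frame(coordinates=coords, box=box, time_ns=0)]
            sa = _sel(*range(0, 80))
            sb = _sel(*range(80, 200))
            got = bm.min_distance_trace(frames, sa, sb).values[0]
            brute = min(oracle_dist(coords[i], coords[j], box)
                        for i in sa.indices for j in sb.indices)
            assert got == pytest.approx(brute, abs=1e-9)
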