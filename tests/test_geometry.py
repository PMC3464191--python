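"""Superposition, RMSD series and kink-angle geometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from chancav.errors import GeometryError
from chancav.geometry import (DomainDefinition, KinkSegments, apply_transform,
                              kink_angle, kink_angle_trajectory,
                              rmsd_per_residue, rmsd_series, superpose,
                              whole_protein_domain)
from chancav.model import Frame, Topology, Trajectory


def _ca_topology(resids, chains=None):
    n = len(resids)
    chains = chains if chains is not None else ["A"] * n
    return Topology(
        chain_ids=np.asarray(chains), resids=np.asarray(resids, int),
        resnames=np.array(["ALA"] * n), names=np.array(["CA"] * n),
        elements=np.array(["C"] * n), vdw_radii=np.full(n, 1.7),
        species=np.array(["protein"] * n), molecule_ids=np.arange(n))


def _random_cloud(n=40, seed=0):
    return np.random.default_rng(seed).normal(scale=5.0, size=(n, 3))


class TestSuperpose:
    def test_frame_vs_itself(self):
        pts = _random_cloud()
        R, t, r = superpose(pts, pts)
        assert r == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(R, np.eye(3), atol=1e-9)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_rigid_invariance(self, seed):
        """RMSD to a rigidly moved copy is zero after refit."""
        pts = _random_cloud(seed=1)
        rng = np.random.default_rng(seed)
        Q = Rotation.random(random_state=int(seed)).as_matrix()
        moved = pts @ Q.T + rng.normal(scale=10.0, size=3)
        _, _, r = superpose(moved, pts)
        assert r < 1e-6

    def test_rotation_is_proper(self):
        pts = _random_cloud(seed=2)
        # near-reflection scenario: mirrored cloud must still give det +1
        R, _, _ = superpose(pts * np.array([-1.0, 1.0, 1.0]), pts)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_single_displaced_atom_vs_numerical_optimizer(self):
        """Post-fit RMSD <= sqrt(1/N) and matches brute-force minimisation."""
        pts = _random_cloud(n=25, seed=3)
        moved = pts.copy()
        moved[0] += np.array([1.0, 0.0, 0.0])
        _, _, r = superpose(moved, pts)
        assert r <= np.sqrt(1.0 / 25) + 1e-9

        def cost(p):
            R = Rotation.from_rotvec(p[:3]).as_matrix()
            return np.sqrt(np.mean(np.sum(
                (moved @ R.T + p[3:] - pts) ** 2, axis=1)))

        best = min(minimize(cost, x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-12,
                                     "maxiter": 4000}).fun
                   for x0 in (np.zeros(6), np.r_[0.1, -0.1, 0.1, 0.5, 0, 0]))
        assert r == pytest.approx(best, abs=1e-4)

    def test_degenerate_selection_raises(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(GeometryError):
            superpose(line, line)
        with pytest.raises(GeometryError):
            superpose(_random_cloud(2), _random_cloud(2))


class TestRmsdSeries:
    def _traj(self, coords_list):
        top = _ca_topology(np.arange(1, len(coords_list[0]) + 1))
        coords = np.asarray(coords_list)
        return top, Trajectory(top, coords, np.arange(len(coords), dtype=float))

    def test_static_trajectory_is_zero(self):
        pts = _random_cloud(30, seed=4)
        top, traj = self._traj([pts] * 5)
        df, (mean, sd) = rmsd_series(traj, Frame(pts),
                                     whole_protein_domain())
        assert np.allclose(df["rmsd_A"], 0.0, atol=1e-9)
        assert mean == pytest.approx(0.0, abs=1e-9)

    def test_uniform_domain_translation_after_disjoint_fit(self):
        """Domain moved 2 Å while the fit domain stays put -> constant 2 Å."""
        rng = np.random.default_rng(5)
        fit_pts = rng.normal(scale=6.0, size=(30, 3))
        dom_pts = rng.normal(scale=6.0, size=(20, 3)) + np.array([20.0, 0, 0])
        ref = np.vstack([fit_pts, dom_pts])
        moved = ref.copy()
        moved[30:] += np.array([0.0, 2.0, 0.0])
        top = _ca_topology(np.arange(1, 51))
        traj = Trajectory(top, np.stack([ref, moved]), np.array([0.0, 1.0]))
        fit_dom = DomainDefinition("fit", [(1, 30)])
        dom = DomainDefinition("dom", [(31, 50)])
        df, _ = rmsd_series(traj, Frame(ref), dom, fit_domain=fit_dom)
        assert df["rmsd_A"].iloc[1] == pytest.approx(2.0, abs=1e-9)

    def test_random_walk_matches_per_frame_recomputation(self):
        rng = np.random.default_rng(6)
        base = _random_cloud(25, seed=7)
        coords = [base]
        for _ in range(6):
            coords.append(coords[-1] + rng.normal(scale=0.3, size=base.shape))
        top, traj = self._traj(coords)
        dom = whole_protein_domain()
        df, _ = rmsd_series(traj, Frame(base), dom)
        idx = dom.ca_indices(top)
        for i in range(traj.n_frames):
            _, _, r = superpose(traj.coords[i][idx], base[idx])
            assert df["rmsd_A"].iloc[i] == pytest.approx(r, abs=1e-12)


class TestRmsdPerResidue:
    def test_single_displaced_residue(self):
        pts = _random_cloud(20, seed=8)
        moved = pts.copy()
        moved[7] += 40.0  # huge displacement localised to one residue
        top = _ca_topology(np.arange(1, 21))
        traj = Trajectory(top, np.stack([pts, moved]), np.array([0.0, 1.0]))
        fit = DomainDefinition("fit", [(1, 6)])
        df = rmsd_per_residue(traj, Frame(pts), fit)
        big = df[df["rmsd_A"] > 1.0]["resid"].tolist()
        assert big == [8]  # resid of index 7

    def test_static_trajectory_zero_everywhere(self):
        pts = _random_cloud(15, seed=9)
        top = _ca_topology(np.arange(1, 16))
        traj = Trajectory(top, np.stack([pts, pts]), np.array([0.0, 1.0]))
        df = rmsd_per_residue(traj, Frame(pts), whole_protein_domain())
        assert np.allclose(df["rmsd_A"], 0.0, atol=1e-9)


def _rod(resids, direction, start, rise=1.5):
    direction = np.asarray(direction, float)
    direction /= np.linalg.norm(direction)
    return start + np.outer(np.arange(len(resids)) * rise, direction)


def _bent_rod_frame(angle_deg):
    """Two straight C-alpha rods meeting at residue 238 at a set angle."""
    bot_res = np.arange(221, 239)
    top_res = np.arange(238, 246)
    bottom = _rod(bot_res, [0, 0, 1.0], np.zeros(3))
    hinge = bottom[-1]
    a = np.radians(angle_deg)
    top = _rod(top_res, [np.sin(a), 0, np.cos(a)], hinge)
    coords = np.vstack([bottom, top[1:]])
    resids = np.r_[bot_res, top_res[1:]]
    return _ca_topology(resids), Frame(coords)


def _ideal_helix(resids, rise=1.5, radius=2.3, twist_deg=100.0):
    i = np.arange(len(resids))
    ang = np.radians(twist_deg * i)
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                            rise * i])


class TestKinkAngle:
    def test_collinear_rods_give_zero(self):
        top, fr = _bent_rod_frame(0.0)
        assert kink_angle(fr, top, "A") == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("angle", [10.0, 30.0, 60.0])
    def test_constructed_angle_recovered(self, angle):
        top, fr = _bent_rod_frame(angle)
        assert kink_angle(fr, top, "A") == pytest.approx(angle, abs=0.1)

    def test_bent_ideal_alpha_helix(self):
        """An ideal helix bent so its segment principal axes sit at exactly
        20° reads back 20° ± 1°.

        A short helix segment's principal axis is tilted a few degrees off
        the helix axis (the partial turn is laterally asymmetric), so the
        builder constructs the bend between the *principal axes* — the
        quantity the kink measure is defined on.
        """
        resids = np.arange(221, 246)
        pts = _ideal_helix(resids)
        hinge_i = resids.tolist().index(238)
        hinge = pts[hinge_i]
        m = resids > 238

        def pc1(p):  # independent principal-axis computation
            c = p - p.mean(axis=0)
            w, v = np.linalg.eigh(c.T @ c)
            ax = v[:, -1]
            return ax if ax[2] >= 0 else -ax

        u = pc1(pts[resids >= 238])   # top incl. hinge
        v = pc1(pts[resids <= 238])   # bottom incl. hinge
        # rotation A: u -> v, then B: 20° about an axis perpendicular to v
        A = Rotation.align_vectors(v[None], u[None])[0].as_matrix()
        perp = np.cross(v, [1.0, 0.0, 0.0])
        perp /= np.linalg.norm(perp)
        B = Rotation.from_rotvec(np.radians(20.0) * perp).as_matrix()
        R = B @ A
        bent = pts.copy()
        bent[m] = (pts[m] - hinge) @ R.T + hinge
        top = _ca_topology(resids)
        # the hinge atom is shared: it stays on the bottom line, perturbing
        # the top segment's axis slightly -> 1° tolerance
        assert kink_angle(Frame(bent), top, "A") == pytest.approx(20.0, abs=1.0)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000), st.booleans())
    def test_invariant_under_rotation_and_reflection(self, seed, reflect):
        top, fr = _bent_rod_frame(25.0)
        Q = Rotation.random(random_state=int(seed)).as_matrix()
        if reflect:
            Q = Q @ np.diag([1.0, 1.0, -1.0])
        moved = Frame(fr.coords @ Q.T + 3.0)
        a = kink_angle(moved, top, "A")
        assert a == pytest.approx(25.0, abs=1e-6)
        assert 0.0 <= a <= 90.0

    def test_trajectory_average(self):
        top, fr = _bent_rod_frame(15.0)
        traj = Trajectory(top, np.stack([fr.coords, fr.coords]),
                          np.array([0.0, 1.0]))
        summ = kink_angle_trajectory(traj, chains=["A"])
        assert summ.mean == pytest.approx(15.0, abs=0.1)
        assert summ.sd == pytest.approx(0.0, abs=1e-9)

    def test_segments_must_share_hinge(self):
        with pytest.raises(GeometryError):
            KinkSegments((221, 237), (238, 245))
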