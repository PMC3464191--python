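"""Pore-radius profiles along the channel axis.

The pore radius at axial position z is the radius of the largest probe
sphere centred in that plane that does not overlap any protein atom's van
der Waals sphere:

    r(z) = max_c  min_i ( |c - x_i| - vdw_i ),   c in the plane at z

maximised over sphere centres within a small disc around the pore axis.
Atoms within ±6 Å of the plane contribute (spheres protrude into the
slab).  The maximisation uses nine deterministic starts refined by
Nelder-Mead; negative maxima are clamped to zero and empty slabs are
reported as missing (NaN), never as zero.

Frames are first aligned so the pentamer's symmetry axis is +z, the
extracellular side (16' marker) up, and the mean z of the 9' marker
C-alpha atoms is the origin — the "0 Å at I(9')" convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .errors import AlignmentError, GeometryError, SamplingError
from .model import Frame, Topology, Trajectory, prime_to_resid, second_half_mask

SLAB_HALF_WIDTH = 6.0   # Å, atoms within this of the plane contribute
SEARCH_RADIUS = 5.0     # Å, sphere-centre search disc around the axis


# --- axis alignment --------------------------------------------------------

def _symmetry_axis(points: np.ndarray) -> np.ndarray:
    """Axis of a C5-symmetric point set: the distinct inertia eigenvector."""
    c = points - points.mean(axis=0)
    cov = c.T @ c / len(c)
    w, v = np.linalg.eigh(cov)
    # for a symmetric top two eigenvalues coincide; pick the odd one out
    gaps = np.array([abs(w[0] - w[1]) + abs(w[0] - w[2]),
                     abs(w[1] - w[0]) + abs(w[1] - w[2]),
                     abs(w[2] - w[0]) + abs(w[2] - w[1])])
    return v[:, int(np.argmax(gaps))]


def align_to_pore_axis(frame: Frame, topology: Topology,
                       anchor_primes: tuple[int, int] = (9, 16)
                       ) -> tuple[Frame, np.ndarray, np.ndarray]:
    """Rotate/translate a frame so the pore axis is +z, 9' level at z = 0.

    Returns ``(aligned_frame, R, t)`` with ``aligned = coords @ R.T + t``.
    The axis is the distinct principal axis of the protein C-alpha cloud;
    its sign is fixed so the 16' marker lies above the 9' marker.  Falls
    back to the geometric centre with a warning if markers are missing.
    """
    ca = topology.ca_indices()
    if len(ca) < 5:
        raise GeometryError("alignment needs protein C-alpha atoms")
    pts = frame.coords[ca]
    axis = _symmetry_axis(pts)

    lo_res, hi_res = (prime_to_resid(p) for p in anchor_primes)
    lo_idx = topology.ca_indices(resids=[lo_res])
    hi_idx = topology.ca_indices(resids=[hi_res])
    have_markers = len(lo_idx) > 0 and len(hi_idx) > 0
    if not have_markers:
        warnings.warn(
            f"marker residues {lo_res}/{hi_res} missing; using geometric "
            "centre as origin, axis orientation arbitrary", stacklevel=2)

    if have_markers:
        direction = frame.coords[hi_idx].mean(axis=0) - frame.coords[lo_idx].mean(axis=0)
        if np.dot(axis, direction) < 0:
            axis = -axis

    # rotation sending `axis` to +z
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s, cth = np.linalg.norm(v), float(np.dot(axis, z))
    if s < 1e-12:
        R = np.eye(3) if cth > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - cth) / s ** 2)

    rotated = frame.coords @ R.T
    center = rotated[ca].mean(axis=0)
    if have_markers:
        z0 = (frame.coords[lo_idx] @ R.T)[:, 2].mean()
    else:
        z0 = center[2]
    t = -np.array([center[0], center[1], z0])
    return Frame(rotated + t, frame.time, frame.box), R, t


# --- single-frame profile --------------------------------------------------

def _max_probe_radius(atoms_xy: np.ndarray, atoms_z: np.ndarray,
                      vdw: np.ndarray, z: float, xtol: float) -> float:
    dz2 = (atoms_z - z) ** 2

    def negative_clearance(c):
        d = np.sqrt((atoms_xy[:, 0] - c[0]) ** 2
                    + (atoms_xy[:, 1] - c[1]) ** 2 + dz2)
        return -(np.min(d - vdw))

    starts = [np.zeros(2)]
    for k in range(8):
        a = np.pi * k / 4.0
        starts.append(2.5 * np.array([np.cos(a), np.sin(a)]))
    best = np.inf
    for s in starts:
        res = minimize(negative_clearance, s, method="Nelder-Mead",
                       options={"xatol": xtol, "fatol": xtol / 10.0,
                                "maxiter": 400})
        c = res.x
        if np.hypot(*c) <= SEARCH_RADIUS and res.fun < best:
            best = res.fun
    if not np.isfinite(best):
        best = negative_clearance(np.zeros(2))
    return max(0.0, -best)


def radius_profile(frame: Frame, topology: Topology,
                   z_grid: np.ndarray | None = None, z_step: float = 0.5,
                   z_range: tuple[float, float] | None = None,
                   xtol: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
    """Pore radius r(z) for one axis-aligned frame.

    Returns ``(z, r)``; z positions with no protein heavy atom within the
    slab are NaN (missing, not zero).
    """
    heavy = topology.protein_heavy
    coords = frame.coords[heavy]
    vdw = topology.vdw_radii[heavy]
    if z_grid is None:
        if z_range is None:
            zc = coords[:, 2]
            z_range = (float(zc.min()), float(zc.max()))
        z_grid = np.arange(z_range[0], z_range[1] + 1e-9, z_step)
    r = np.full(len(z_grid), np.nan)
    for i, z in enumerate(z_grid):
        m = np.abs(coords[:, 2] - z) <= SLAB_HALF_WIDTH
        if not m.any():
            continue
        r[i] = _max_probe_radius(coords[m, :2], coords[m, 2], vdw[m], z, xtol)
    return np.asarray(z_grid, float), r


# --- trajectory-level ------------------------------------------------------

@dataclass
class PoreProfile:
    """r(z, t) matrix plus the per-frame marker z positions."""

    z: np.ndarray                       # (Z,)
    times: np.ndarray                   # (S,)
    radii: np.ndarray                   # (S, Z)
    marker_z: dict[int, np.ndarray] = field(default_factory=dict)

    def summary(self, window_mask: np.ndarray | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
        """Mean and SD of r(z) over frames (missing values skipped)."""
        R = self.radii if window_mask is None else self.radii[window_mask]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(R, axis=0), np.nanstd(R, axis=0)


def profile_heatmap(traj: Trajectory, stride: int = 1,
                    z_step: float = 0.5,
                    z_range: tuple[float, float] | None = None,
                    marker_primes: tuple[int, ...] = (9, 14, 16),
                    align: bool = True, xtol: float = 1e-3) -> PoreProfile:
    """Per-frame pore profiles at a frame stride, assembled into a matrix."""
    if stride < 1 or stride >= traj.n_frames:
        raise SamplingError(f"stride {stride} does not fit {traj.n_frames} frames")
    top = traj.topology
    heavy = top.protein_heavy
    if z_range is None:
        zc = traj.coords[0][heavy][:, 2]
        z_range = (float(zc.min()), float(zc.max()))
    z_grid = np.arange(z_range[0], z_range[1] + 1e-9, z_step)
    idx = np.arange(0, traj.n_frames, stride)
    radii = np.empty((len(idx), len(z_grid)))
    marker_z = {p: np.empty(len(idx)) for p in marker_primes}
    for row, i in enumerate(idx):
        fr = traj.frame(i)
        if align:
            fr, _, _ = align_to_pore_axis(fr, top)
        _, radii[row] = radius_profile(fr, top, z_grid=z_grid, xtol=xtol)
        for p in marker_primes:
            m = top.ca_indices(resids=[prime_to_resid(p)])
            marker_z[p][row] = fr.coords[m][:, 2].mean() if len(m) else np.nan
    return PoreProfile(z_grid, traj.times[idx], radii, marker_z)


def min_radius_window(profile: PoreProfile, marker_prime: int = 9,
                      window: float = 5.0) -> np.ndarray:
    """Per-frame minimum radius within ±window/2 of the marker's z.

    Frames whose window contains only missing values are NaN.
    """
    if marker_prime not in profile.marker_z:
        raise AlignmentError(f"profile carries no {marker_prime}' marker track")
    out = np.full(len(profile.times), np.nan)
    for i in range(len(profile.times)):
        z0 = profile.marker_z[marker_prime][i]
        if not np.isfinite(z0):
            continue
        m = np.abs(profile.z - z0) <= window / 2.0
        vals = profile.radii[i][m]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            out[i] = vals.min()
    return out


def constriction_summary(profile: PoreProfile, marker_prime: int = 9,
                         window: float = 5.0,
                         second_half: bool = True) -> tuple[float, float]:
    """Mean ± SD of the windowed minimum radius (default: trailing half)."""
    series = min_radius_window(profile, marker_prime, window)
    mask = second_half_mask(profile.times) if second_half else np.ones(len(series), bool)
    vals = series[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return np.nan, np.nan
    return float(vals.mean()), float(vals.std())
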