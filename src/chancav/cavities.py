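"""Void detection, consensus cavity grids, classification, C5
symmetrisation, Monte-Carlo volumes and cavity-lining polarity.

A voxel on the 1 Å analysis lattice is *void* in a frame when its centre
keeps probe clearance from every protein heavy atom (distance >= vdW +
probe, probe 1.4 Å), lies in the transmembrane z-range and outside the
pore lumen, and is *buried*: of 14 scan rays (6 axial, 8 diagonal) at
least 9 hit a protein heavy atom within 8 Å.  Consensus grids keep voxels
void in at least a threshold fraction (default 20%) of frames sampled
every few ns; connected components (26-neighbour) smaller than 8 voxels
are discarded.

Volumes are Monte-Carlo estimates: uniform points in the region's bounding
box count as hits when they fall inside a region voxel cube and keep probe
clearance from the protein.  For consensus regions the sub-voxel boundary
is therefore carried by the clearance test, provided the integration
region covers the cavity — the pipeline dilates symmetrised regions by one
voxel for exactly that reason.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import PrecisionError, SamplingError
from .model import Frame, Topology, Trajectory
from .io import POLAR_ELEMENTS

PROBE_RADIUS = 1.4
VOXEL = 1.0
BURIAL_MIN_HITS = 9
BURIAL_RANGE = 8.0
MIN_COMPONENT_VOXELS = 8

# 6 axial + 8 diagonal scan directions
_DIRS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
    + [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
    dtype=float)
_DIRS /= np.linalg.norm(_DIRS, axis=1, keepdims=True)
BURIAL_RAYS = len(_DIRS)


@dataclass
class VoidGrid:
    """Cubic voxel lattice; ``data`` is boolean (one frame) or float in
    [0, 1] (consensus frequency)."""

    origin: np.ndarray          # centre of voxel (0,0,0) minus half spacing
    spacing: float
    data: np.ndarray            # (nx, ny, nz)
    probe: float = PROBE_RADIUS

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def centers(self, idx: np.ndarray) -> np.ndarray:
        """World coordinates of voxel centres for (M, 3) index arrays."""
        return self.origin + (np.atleast_2d(idx) + 0.5) * self.spacing

    def all_centers(self) -> np.ndarray:
        idx = np.indices(self.shape).reshape(3, -1).T
        return self.centers(idx)

    def index_of(self, pts: np.ndarray) -> np.ndarray:
        return np.floor((np.atleast_2d(pts) - self.origin) / self.spacing).astype(int)


@dataclass
class Cavity:
    """A consensus cavity component."""

    cavity_id: str
    cls: str                              # intra | inter | ambiguous
    chains: tuple[str, ...]
    voxels: np.ndarray                    # (M, 3) int lattice indices
    grid: VoidGrid
    volume: float = np.nan
    volume_se: float = np.nan
    lining_atoms: np.ndarray | None = None

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    def centers(self) -> np.ndarray:
        return self.grid.centers(self.voxels)


# --------------------------------------------------------------------------
# clearance helper
# --------------------------------------------------------------------------

class _ClearanceField:
    """min_i(|x - a_i| - vdw_i) evaluated via one KD-tree per radius class."""

    def __init__(self, coords: np.ndarray, vdw: np.ndarray):
        self.trees = []
        for r in np.unique(np.round(vdw, 6)):
            m = np.isclose(vdw, r)
            self.trees.append((float(r), cKDTree(coords[m])))

    def clearance(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        out = np.full(len(pts), np.inf)
        for r, tree in self.trees:
            d, _ = tree.query(pts, k=1)
            np.minimum(out, d - r, out=out)
        return out


# --------------------------------------------------------------------------
# frame-wise void detection
# --------------------------------------------------------------------------

def detect_voids(frame: Frame, topology: Topology, probe: float = PROBE_RADIUS,
                 spacing: float = VOXEL,
                 z_range: tuple[float, float] = (-20.0, 15.0),
                 lumen_profile: tuple[np.ndarray, np.ndarray] | None = None,
                 lumen_margin: float = 0.5,
                 burial_min_hits: int = BURIAL_MIN_HITS,
                 burial_range: float = BURIAL_RANGE,
                 grid: VoidGrid | None = None) -> VoidGrid:
    """Boolean void grid for one axis-aligned frame.

    ``lumen_profile`` is an optional precomputed (z, r) pore profile used
    to exclude pore-lumen voxels; when omitted it is computed on the fly.
    """
    heavy = topology.protein_heavy
    coords = frame.coords[heavy]
    vdw = topology.vdw_radii[heavy]

    if grid is None:
        xy_max = float(np.abs(coords[:, :2]).max())
        origin = np.array([-xy_max, -xy_max, z_range[0]])
        nx = int(np.ceil(2 * xy_max / spacing))
        nz = int(np.ceil((z_range[1] - z_range[0]) / spacing))
        grid = VoidGrid(origin, spacing, np.zeros((nx, nx, nz), bool), probe)
    data = np.zeros(grid.shape, bool)

    centers = grid.all_centers()
    field = _ClearanceField(coords, vdw)
    clear = field.clearance(centers)
    cand = clear >= probe

    # pore-lumen exclusion
    if lumen_profile is None:
        from .pore import radius_profile
        lumen_profile = radius_profile(frame, topology, z_step=1.0,
                                       z_range=z_range)
    zl, rl = lumen_profile
    ok = np.isfinite(rl)
    if ok.any():
        r_at = np.interp(centers[:, 2], zl[ok], rl[ok])
        lumen = np.hypot(centers[:, 0], centers[:, 1]) <= r_at + lumen_margin
        cand &= ~lumen

    # burial: a voxel cannot collect >= `burial_min_hits` ray hits without
    # at least that many atoms in reach, so reject sparse neighbourhoods
    # cheaply before the per-voxel ray test
    idx_cand = np.flatnonzero(cand)
    if idx_cand.size:
        tree = cKDTree(coords)
        reach = burial_range + float(vdw.max())
        counts = tree.query_ball_point(centers[idx_cand], reach,
                                       return_length=True)
        idx_cand = idx_cand[counts >= burial_min_hits]
    if idx_cand.size:
        near = tree.query_ball_point(centers[idx_cand], reach)
        buried = np.zeros(idx_cand.size, bool)
        for j, neigh in enumerate(near):
            if len(neigh) == 0:
                continue
            rel = coords[neigh] - centers[idx_cand[j]]
            rad = vdw[neigh]
            t = rel @ _DIRS.T                          # (n_atoms, 14)
            perp2 = (rel ** 2).sum(axis=1)[:, None] - t ** 2
            hit = (t > 0) & (t <= burial_range) & (perp2 <= (rad ** 2)[:, None])
            buried[j] = int(hit.any(axis=0).sum()) >= burial_min_hits
        sel = idx_cand[buried]
    else:
        sel = idx_cand
    flat = np.zeros(int(np.prod(grid.shape)), bool)
    flat[sel] = True
    data = flat.reshape(grid.shape)
    return VoidGrid(grid.origin.copy(), grid.spacing, data, probe)


# --------------------------------------------------------------------------
# consensus over a trajectory
# --------------------------------------------------------------------------

def consensus_cavities(traj: Trajectory, stride_ns: float = 5.0,
                       freq_threshold: float = 0.20,
                       min_voxels: int = MIN_COMPONENT_VOXELS,
                       z_range: tuple[float, float] = (-20.0, 15.0),
                       align: bool = True, probe: float = PROBE_RADIUS,
                       ) -> tuple[VoidGrid, list[np.ndarray]]:
    """Frequency grid over sampled frames plus connected components.

    Frequency of a voxel is the arithmetic mean of its per-frame void
    booleans.  Components are 26-connected sets of voxels with frequency
    >= threshold; components smaller than ``min_voxels`` are discarded.
    """
    stride = max(1, int(round(stride_ns / traj.dt)))
    if stride >= traj.n_frames:
        raise SamplingError(
            f"stride of {stride_ns} ns ({stride} frames) exceeds the "
            f"{traj.n_frames}-frame trajectory")
    from .pore import align_to_pore_axis

    idx = np.arange(0, traj.n_frames, stride)
    freq = None
    grid = None
    top = traj.topology
    for i in idx:
        fr = traj.frame(i)
        if align:
            fr, _, _ = align_to_pore_axis(fr, top)
        vg = detect_voids(fr, top, probe=probe, z_range=z_range, grid=grid)
        if freq is None:
            freq = vg.data.astype(float)
            grid = VoidGrid(vg.origin, vg.spacing, np.zeros(vg.shape, bool), probe)
        else:
            freq += vg.data
    freq /= len(idx)
    fgrid = VoidGrid(grid.origin, grid.spacing, freq, probe)

    mask = freq >= freq_threshold
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), int))
    components = []
    for lab in range(1, n + 1):
        vox = np.argwhere(labels == lab)
        if len(vox) >= min_voxels:
            components.append(vox)
    components.sort(key=len, reverse=True)
    return fgrid, components


# --------------------------------------------------------------------------
# classification & symmetrisation
# --------------------------------------------------------------------------

def classify_cavities(components: list[np.ndarray], frame: Frame,
                      topology: Topology, grid: VoidGrid,
                      lining_cutoff: float = 5.0,
                      intra_fraction: float = 0.80,
                      inter_fraction: float = 0.20) -> list[Cavity]:
    """Assign intra/inter class and subunit(s) from lining-atom chains.

    Lining atoms are protein heavy atoms within ``lining_cutoff`` of any
    component voxel centre.  A component is intra-subunit when >= 80% of
    its lining belongs to one chain, inter-subunit when two chains each
    contribute >= 20%; everything else is flagged ambiguous (reported, not
    dropped).
    """
    heavy_idx = np.flatnonzero(topology.protein_heavy)
    tree = cKDTree(frame.coords[heavy_idx])
    cavities: list[Cavity] = []
    counters = {"intra": 0, "inter": 0, "ambiguous": 0}
    for vox in components:
        centers = grid.centers(vox)
        near = tree.query_ball_point(centers, lining_cutoff)
        lining = np.unique(np.concatenate([np.asarray(n, int) for n in near])
                           ) if len(near) else np.array([], int)
        lining = heavy_idx[lining]
        chains, counts = np.unique(topology.chain_ids[lining], return_counts=True)
        fr = counts / counts.sum() if counts.size else np.array([])
        order = np.argsort(fr)[::-1]
        cls, assigned = "ambiguous", tuple(chains[order[:2]])
        if fr.size and fr[order[0]] >= intra_fraction:
            cls, assigned = "intra", (str(chains[order[0]]),)
        elif fr.size >= 2 and fr[order[0]] >= inter_fraction and fr[order[1]] >= inter_fraction:
            cls = "inter"
            assigned = tuple(sorted((str(chains[order[0]]), str(chains[order[1]]))))
        cav_id = f"{cls}_{counters[cls]}"
        counters[cls] += 1
        cavities.append(Cavity(cav_id, cls, assigned, vox, grid,
                               lining_atoms=lining))
    return cavities


def _rotate_voxels(vox: np.ndarray, grid: VoidGrid, angle_deg: float) -> np.ndarray:
    """Rotate voxel centres about the +z axis and re-voxelise."""
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    pts = grid.centers(vox) @ R.T
    idx = grid.index_of(pts)
    shape = np.array(grid.shape)
    ok = np.all((idx >= 0) & (idx < shape), axis=1)
    return np.unique(idx[ok], axis=0)


def symmetrize(cavities: list[Cavity], cls: str, grid: VoidGrid,
               n_fold: int = 5) -> dict[int, np.ndarray]:
    """Map the largest cavity of a class onto all five sites by k·72°.

    Returns {k: voxel indices} for k = 0..4, the k-th entry being the
    template rotated by k·72° about the pore axis.  These are the
    volume-integration regions for the five symmetry-related sites.
    """
    members = [c for c in cavities if c.cls == cls]
    if not members:
        warnings.warn(f"no cavity of class {cls!r}; symmetrize returns nothing",
                      stacklevel=2)
        return {}
    template = max(members, key=lambda c: c.n_voxels)
    return {k: _rotate_voxels(template.voxels, grid, 72.0 * k)
            for k in range(n_fold)}


def dilate_region(vox: np.ndarray, grid: VoidGrid, iterations: int = 1) -> np.ndarray:
    """Grow a voxel set by its 26-neighbourhood (stays inside the grid)."""
    mask = np.zeros(grid.shape, bool)
    mask[tuple(vox.T)] = True
    mask = ndimage.binary_dilation(mask, structure=np.ones((3, 3, 3), bool),
                                   iterations=iterations)
    return np.argwhere(mask)


# --------------------------------------------------------------------------
# volumes
# --------------------------------------------------------------------------

def mc_volume(region: np.ndarray, grid: VoidGrid, n: int = 10_000,
              seed: int = 0, frame: Frame | None = None,
              topology: Topology | None = None,
              probe: float = PROBE_RADIUS) -> tuple[float, float]:
    """Monte-Carlo volume of a voxel region, in Å³, with standard error.

    Uniform samples in the region's bounding box count as hits when their
    containing voxel belongs to the region and (when a frame is given)
    they keep probe clearance from every protein heavy atom.
    SE = V_box · sqrt(p(1-p)/n).
    """
    if n < 100:
        raise PrecisionError("mc_volume needs at least 100 iterations")
    region = np.atleast_2d(np.asarray(region, int))
    if region.size == 0:
        return 0.0, 0.0
    lo = grid.origin + region.min(axis=0) * grid.spacing
    hi = grid.origin + (region.max(axis=0) + 1) * grid.spacing
    vol_box = float(np.prod(hi - lo))
    rng = np.random.default_rng(seed)
    pts = rng.uniform(lo, hi, size=(n, 3))
    idx = np.floor((pts - grid.origin) / grid.spacing).astype(int)
    keyset = {tuple(v) for v in region}
    inside = np.fromiter((tuple(i) in keyset for i in idx), bool, count=n)
    if frame is not None and topology is not None and inside.any():
        heavy = topology.protein_heavy
        fieldc = _ClearanceField(frame.coords[heavy], topology.vdw_radii[heavy])
        ok = fieldc.clearance(pts[inside]) >= probe
        tmp = np.zeros(n, bool)
        tmp[np.flatnonzero(inside)[ok]] = True
        inside = tmp
    p = inside.mean()
    return vol_box * p, vol_box * float(np.sqrt(p * (1 - p) / n))


def cavity_volume_series(traj: Trajectory, region: np.ndarray, grid: VoidGrid,
                         n: int = 10_000, seed: int = 0, stride: int = 1,
                         align: bool = True,
                         probe: float = PROBE_RADIUS) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame MC volume inside a fixed region ("within the previously
    defined grids"). Returns (frame times, volumes)."""
    from .pore import align_to_pore_axis

    idx = np.arange(0, traj.n_frames, stride)
    vols = np.empty(len(idx))
    for j, i in enumerate(idx):
        fr = traj.frame(i)
        if align:
            fr, _, _ = align_to_pore_axis(fr, traj.topology)
        vols[j], _ = mc_volume(region, grid, n=n, seed=seed + 17 * int(i),
                               frame=fr, topology=traj.topology, probe=probe)
    return traj.times[idx], vols


# --------------------------------------------------------------------------
# lining polarity
# --------------------------------------------------------------------------

def _fibonacci_unit_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta), np.cos(phi)])


def polar_surface_fraction(cavity: Cavity, frame: Frame, topology: Topology,
                           probe: float = PROBE_RADIUS, n_points: int = 240,
                           facing_cutoff: float = 1.5,
                           max_atoms: int = 800, seed: int = 0) -> float:
    """Polar fraction of the cavity-facing accessible surface area.

    Shrake-Rupley-style: each lining atom carries ``n_points`` sphere
    points at radius vdW + probe; points overlapped by any neighbouring
    atom's expanded sphere are buried, and only accessible points within
    ``facing_cutoff`` of a cavity voxel centre count towards the cavity
    surface.  Polar atoms are N/O/S.  Returns NaN for an empty lining.

    Only atoms whose expanded sphere can reach the facing zone contribute;
    beyond ``max_atoms`` of those, a seeded uniform subsample is used (the
    polar/total area ratio is insensitive to uniform atom subsampling).
    """
    if cavity.lining_atoms is None or len(cavity.lining_atoms) == 0:
        return np.nan
    lining = np.asarray(cavity.lining_atoms, int)
    heavy_idx = np.flatnonzero(topology.protein_heavy)
    pos_in_heavy = {int(a): j for j, a in enumerate(heavy_idx)}
    coords_all = frame.coords[heavy_idx]
    vdw_all = topology.vdw_radii[heavy_idx]
    tree = cKDTree(coords_all)
    vox_tree = cKDTree(cavity.centers())
    lin = np.array([pos_in_heavy[int(a)] for a in lining], int)

    # only atoms whose expanded sphere can come within facing_cutoff of a
    # cavity voxel centre can contribute surface
    d_vox, _ = vox_tree.query(coords_all[lin], k=1)
    lin = lin[d_vox <= vdw_all[lin] + probe + facing_cutoff]
    if lin.size == 0:
        return np.nan
    if lin.size > max_atoms:
        rng = np.random.default_rng(seed)
        lin = lin[np.sort(rng.choice(lin.size, size=max_atoms, replace=False))]

    unit = _fibonacci_unit_sphere(n_points)
    reach = 2.0 * (float(vdw_all.max()) + probe)
    neighbours = tree.query_ball_point(coords_all[lin], reach)
    polar_area = 0.0
    total_area = 0.0
    for j, neigh in zip(lin, neighbours):
        r = vdw_all[j] + probe
        pts = coords_all[j] + r * unit
        neigh = [k for k in neigh if k != j]
        accessible = np.ones(n_points, bool)
        if neigh:
            nc = coords_all[neigh]
            nr2 = (vdw_all[neigh] + probe) ** 2
            d2 = ((pts[:, None, :] - nc[None, :, :]) ** 2).sum(-1)
            accessible = ~np.any(d2 < nr2[None, :], axis=1)
        if not accessible.any():
            continue
        d, _ = vox_tree.query(pts[accessible], k=1)
        area = 4.0 * np.pi * r ** 2 / n_points * (d <= facing_cutoff).sum()
        total_area += area
        if topology.elements[heavy_idx[j]] in POLAR_ELEMENTS:
            polar_area += area
    if total_area == 0.0:
        return np.nan
    return polar_area / total_area
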