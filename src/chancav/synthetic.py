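"""Synthetic pentameric-channel trajectories with exact ground truth.

The generator emulates, at toy scale, the statistical features a cavity and
occupancy pipeline must recover from a membrane-channel simulation:

* a C5-symmetric wall of pseudo-atoms around a central pore whose radius
  profile r(z) is prescribed (piecewise linear, constriction near z = 0
  where the 9' marker residue sits);
* five pore-lining "M2" C-alpha rods (residues 221-245, 9'/14'/16' markers
  at 233/238/240) with an optional per-subunit kink of prescribed angle at
  residue 238;
* ten buried cavities — five membrane-facing intra-subunit, five interface
  inter-subunit — carved as exact box or sphere voids: every cavity shape
  is wrapped in a shell of pseudo-atoms on its (vdW + probe) offset
  surface, so the void detected with a 1.4 Å probe is the declared shape
  and the declared volume is exact ground truth;
* an ethanol-like 3-atom ligand pool following independent two-state
  (bound/bulk) continuous-time Markov chains with exponential dwell times;
  bound ligands are placed strictly inside an assigned cavity, bulk
  ligands in a distant solvent shell;
* waters that fill inter-subunit cavities when ligand occupancy is low and
  lipid acyl chains that occupy intra-subunit cavities with an insertion
  probability reduced per resident ligand (the anti-correlation knobs);
* optional thermal jitter on the protein pseudo-atoms so frame-wise void
  detection actually fluctuates.

All randomness derives from the spec seed; identical seeds give
byte-identical trajectories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import SpecError
from .model import Frame, Topology, Trajectory

PROBE_RADIUS = 1.4          # Å, water-sized probe used by the cavity stage
WALL_VDW = 1.7              # Å, carbon-like pseudo-atoms
STANDOFF = WALL_VDW + PROBE_RADIUS  # offset of cavity shells: 3.1 Å

_CHAIN_IDS = ("A", "B", "C", "D", "E")


# --------------------------------------------------------------------------
# specification
# --------------------------------------------------------------------------

@dataclass
class CavitySpec:
    """One cavity class template; the five sites are 72° rotated copies.

    ``center`` is the template centre (site 0) in cylindrical terms:
    (radial distance Å, azimuth deg, z Å).  ``size`` is the box edge or
    sphere radius in Å.
    """

    cls: str = "intra"              # "intra" | "inter"
    shape: str = "box"              # "box" | "sphere"
    size: float = 6.0
    center_radius: float = 14.0
    center_angle_deg: float = 0.0
    center_z: float = 7.0
    polar_fraction: float = 0.2     # fraction of shell atoms given polar elements

    @property
    def true_volume(self) -> float:
        if self.shape == "box":
            return float(self.size ** 3)
        return float(4.0 / 3.0 * np.pi * self.size ** 3)


@dataclass
class LigandSpec:
    count: int = 30
    tau_bound: float = 150.0    # ns, mean bound dwell
    tau_unbound: float = 750.0  # ns, mean bulk dwell
    # heavy atoms of an ethanol-like rigid body (local frame, Å)
    atom_offsets: tuple = ((-0.98, -0.29, 0.0), (0.52, -0.29, 0.0), (0.46, 0.58, 0.0))
    elements: tuple = ("C", "C", "O")


@dataclass
class LipidSpec:
    chains_per_cavity: int = 2
    atoms_per_chain: int = 6
    insert_probability: float = 0.6   # per chain per frame, no resident ligand
    ligand_reduction: float = 0.5     # multiplier per resident ligand


@dataclass
class WaterSpec:
    bulk_count: int = 3000
    cavity_baseline_inter: int = 4
    cavity_baseline_intra: int = 0
    anticorrelation: float = 1.0      # waters displaced per resident ligand


@dataclass
class ChannelSpec:
    """Study conditions of the synthetic channel."""

    n_subunits: int = 5
    # piecewise-linear pore radius r(z): control points (z Å, r Å);
    # constriction of 2.25 Å at z = 0 (the 9' level) and a secondary
    # narrowing near +10 (the 16' level)
    pore_profile: tuple = ((-20.0, 3.5), (-10.0, 3.2), (0.0, 2.25),
                           (5.0, 3.0), (10.0, 2.6), (15.0, 3.5))
    wall_atom_spacing: float = 1.0
    wall_ring_step: float = 0.5
    rod_radius: float = 7.0
    kink_angles_deg: tuple = (0.0, 0.0, 0.0, 0.0, 0.0)
    kink_resid: int = 238
    cavity_specs: tuple = (
        CavitySpec(cls="intra", shape="box", size=6.0, center_radius=14.0,
                   center_angle_deg=0.0, center_z=7.0, polar_fraction=0.2),
        CavitySpec(cls="inter", shape="box", size=4.5, center_radius=13.0,
                   center_angle_deg=36.0, center_z=-5.0, polar_fraction=0.41),
    )
    ligand: LigandSpec = field(default_factory=LigandSpec)
    lipid: LipidSpec = field(default_factory=LipidSpec)
    water: WaterSpec = field(default_factory=WaterSpec)
    body_lattice: float = 1.5
    body_inner_radius: float = 7.5
    body_outer_radius: float = 18.0
    shell_spacing: float = 0.5        # sampling step on cavity offset shells
    protein_jitter: float = 0.05      # Å, per-frame thermal noise
    solvent_shell: tuple = (33.0, 50.0)  # distances from the pore centre
    box_edge: float = 110.0
    interior_margin: float = 1.0      # strict-interior margin for occupants
    seed: int = 0

    @property
    def z_range(self) -> tuple[float, float]:
        zs = [z for z, _ in self.pore_profile]
        return min(zs), max(zs)

    def pore_radius(self, z) -> np.ndarray:
        zs = np.array([p[0] for p in self.pore_profile])
        rs = np.array([p[1] for p in self.pore_profile])
        return np.interp(z, zs, rs)

    def validate(self) -> None:
        if self.n_subunits != 5:
            raise SpecError("the generator builds pentamers (n_subunits = 5)")
        if any(r <= 0 for _, r in self.pore_profile):
            raise SpecError("pore radius must be positive everywhere")
        if self.ligand.tau_bound <= 0 or self.ligand.tau_unbound <= 0:
            raise SpecError("dwell means must be positive")
        for cs in self.cavity_specs:
            if cs.true_volume <= 0:
                raise SpecError("cavity volumes must be positive")
            if cs.cls not in ("intra", "inter"):
                raise SpecError(f"unknown cavity class {cs.cls!r}")
            # the shape (plus its atom shell) must stay clear of the pore;
            # the template box is radially aligned, so its closest approach
            # to the axis is center_radius - size/2
            if cs.shape == "box":
                inner = cs.center_radius - cs.size / 2.0
            else:
                inner = cs.center_radius - cs.size
            wall_outer = max(r for _, r in self.pore_profile) + 2 * WALL_VDW
            if inner - STANDOFF < wall_outer:
                raise SpecError(
                    f"cavity {cs.cls} overlaps the pore lumen/wall "
                    f"(inner radial extent {inner:.1f} Å)")


# --------------------------------------------------------------------------
# cavity shapes
# --------------------------------------------------------------------------

def _rotz(deg: float) -> np.ndarray:
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@dataclass
class CavitySite:
    """One realised cavity: a rotated copy of a class template."""

    cavity_id: str
    cls: str
    shape: str
    size: float
    center: np.ndarray
    rotation: np.ndarray      # world = rotation @ local + center

    @property
    def true_volume(self) -> float:
        if self.shape == "box":
            return float(self.size ** 3)
        return float(4.0 / 3.0 * np.pi * self.size ** 3)

    def to_local(self, pts: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(pts) - self.center) @ self.rotation

    def contains(self, pts: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """Points inside the shape, shrunk by ``margin``."""
        loc = self.to_local(pts)
        if self.shape == "box":
            h = self.size / 2.0 - margin
            return np.all(np.abs(loc) <= h, axis=1)
        return np.linalg.norm(loc, axis=1) <= self.size - margin

    def distance(self, pts: np.ndarray) -> np.ndarray:
        """Euclidean distance from points to the shape (0 inside)."""
        loc = self.to_local(pts)
        if self.shape == "box":
            h = self.size / 2.0
            d = np.abs(loc) - h
            return np.linalg.norm(np.maximum(d, 0.0), axis=1)
        return np.maximum(np.linalg.norm(loc, axis=1) - self.size, 0.0)

    def sample_interior(self, n: int, rng: np.random.Generator,
                        margin: float = 0.0) -> np.ndarray:
        if self.shape == "box":
            h = self.size / 2.0 - margin
            loc = rng.uniform(-h, h, size=(n, 3))
        else:
            loc = rng.normal(size=(n, 3))
            loc /= np.linalg.norm(loc, axis=1, keepdims=True)
            loc *= (self.size - margin) * rng.random((n, 1)) ** (1.0 / 3.0)
        return loc @ self.rotation.T + self.center

    def truth_voxels(self, origin: np.ndarray, spacing: float,
                     shape: tuple[int, int, int]) -> np.ndarray:
        """Indices of analysis-grid voxels whose centres lie inside the shape."""
        idx = np.indices(shape).reshape(3, -1).T
        centers = origin + (idx + 0.5) * spacing
        return idx[self.contains(centers)]

    def shell_frame(self, spacing: float) -> tuple[np.ndarray, np.ndarray]:
        """Surface anchors and outward unit normals of the shape (local
        sampling at ``spacing``); a shell atom with van der Waals radius v
        sits at ``anchor + (v + probe) * normal`` so that the void carved
        by a probe-clearance rule is exactly the declared shape."""
        if self.shape == "sphere":
            dirs = _fibonacci_sphere(1.0, spacing / (self.size + STANDOFF))
            anchors = self.size * dirs
        else:
            anchors, dirs = _box_offset_frame(self.size, STANDOFF, spacing)
        anchors = anchors @ self.rotation.T + self.center
        dirs = dirs @ self.rotation.T
        return anchors, dirs

    def shell_atoms(self, spacing: float, standoff: float = STANDOFF) -> np.ndarray:
        """Pseudo-atoms on the offset surface at a uniform ``standoff``."""
        a, d = self.shell_frame(spacing)
        return a + standoff * d


def _fibonacci_sphere(radius: float, spacing: float) -> np.ndarray:
    n = max(32, int(np.ceil(4.0 * np.pi * radius ** 2 / spacing ** 2)))
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * i
    return radius * np.column_stack([np.sin(phi) * np.cos(theta),
                                     np.sin(phi) * np.sin(theta),
                                     np.cos(phi)])


def _box_offset_frame(size: float, standoff: float, spacing: float
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Surface anchors and outward normals sampling a cube's offset surface.

    The offset surface of a box is its six shifted faces, quarter-cylinder
    strips along the twelve edges (anchored on the edge, normals sweeping
    the 90° arc) and sphere octants at the eight corners; ``spacing``
    controls the sampling density at nominal ``standoff``.
    """
    h = size / 2.0
    anchors: list[np.ndarray] = []
    normals: list[np.ndarray] = []
    n1d = max(2, int(np.ceil(size / spacing)) + 1)
    g = np.linspace(-h, h, n1d)
    uu, vv = np.meshgrid(g, g, indexing="ij")
    uu, vv = uu.ravel(), vv.ravel()
    for axis in range(3):
        for sgn in (-1.0, 1.0):
            a = np.empty((uu.size, 3))
            a[:, axis] = sgn * h
            a[:, (axis + 1) % 3] = uu
            a[:, (axis + 2) % 3] = vv
            n = np.zeros((uu.size, 3))
            n[:, axis] = sgn
            anchors.append(a)
            normals.append(n)
    # edges: arc of outward normals between the two face normals
    n_arc = max(2, int(np.ceil((np.pi / 2.0) * standoff / spacing)) + 1)
    phis = np.linspace(0.0, np.pi / 2.0, n_arc)[1:-1]
    for axis in range(3):            # edge parallel to `axis`
        a1, a2 = (axis + 1) % 3, (axis + 2) % 3
        for s1 in (-1.0, 1.0):
            for s2 in (-1.0, 1.0):
                for phi in phis:
                    a = np.empty((len(g), 3))
                    a[:, axis] = g
                    a[:, a1] = s1 * h
                    a[:, a2] = s2 * h
                    n = np.zeros((len(g), 3))
                    n[:, a1] = s1 * np.cos(phi)
                    n[:, a2] = s2 * np.sin(phi)
                    anchors.append(a)
                    normals.append(n)
    # corners: sphere octants
    oct_dirs = _fibonacci_sphere(1.0, spacing / max(standoff, 1e-9))
    for sx in (-1.0, 1.0):
        for sy in (-1.0, 1.0):
            for sz in (-1.0, 1.0):
                d = oct_dirs[(np.sign(oct_dirs[:, 0]) == sx)
                             & (np.sign(oct_dirs[:, 1]) == sy)
                             & (np.sign(oct_dirs[:, 2]) == sz)]
                corner = np.array([sx * h, sy * h, sz * h])
                anchors.append(np.repeat(corner[None, :], len(d), axis=0))
                normals.append(d)
    return np.vstack(anchors), np.vstack(normals)


def spec_from_dict(overrides: dict | None, seed: int = 0) -> ChannelSpec:
    """Build a ChannelSpec from plain YAML/JSON-style overrides.

    Nested dicts map onto the ligand/lipid/water sub-specs; lists become
    tuples (cavity_specs entries may be dicts of CavitySpec fields).
    """
    sub = {"ligand": LigandSpec, "lipid": LipidSpec, "water": WaterSpec}
    kwargs = {}
    for key, val in (overrides or {}).items():
        if key in sub and isinstance(val, dict):
            kwargs[key] = sub[key](**val)
        elif key == "cavity_specs":
            kwargs[key] = tuple(CavitySpec(**v) if isinstance(v, dict) else v
                                for v in val)
        elif isinstance(val, list):
            kwargs[key] = tuple(tuple(v) if isinstance(v, list) else v
                                for v in val)
        else:
            kwargs[key] = val
    kwargs.setdefault("seed", seed)
    return ChannelSpec(**kwargs)


def cavity_sites(spec: ChannelSpec) -> list[CavitySite]:
    """The ten realised cavities: each class template rotated by k·72°."""
    sites: list[CavitySite] = []
    for cs in spec.cavity_specs:
        for k in range(spec.n_subunits):
            ang = cs.center_angle_deg + 72.0 * k
            R = _rotz(ang)
            center = R @ np.array([cs.center_radius, 0.0, cs.center_z])
            sites.append(CavitySite(f"{cs.cls}_{k}", cs.cls, cs.shape,
                                    cs.size, center, R))
    return sites


# --------------------------------------------------------------------------
# ground truth
# --------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    cavity_ids: list[str]
    true_volumes: dict[str, float]
    kink_angles_deg: dict[str, float]
    pore_profile: tuple
    tau_bound: float = np.nan
    tau_unbound: float = np.nan
    # per-frame truth (filled by simulate_trajectory)
    bound: np.ndarray | None = None          # (n_ligands, n_frames) bool
    ligand_cavity: np.ndarray | None = None  # (n_ligands, n_frames) int, -1 = bulk
    water_counts: np.ndarray | None = None   # (n_cavities, n_frames) int
    lipid_atom_counts: np.ndarray | None = None  # (n_cavities, n_frames) int
    sites: list[CavitySite] = field(default_factory=list)

    def site(self, cavity_id: str) -> CavitySite:
        return self.sites[self.cavity_ids.index(cavity_id)]

    def bound_fraction(self) -> float:
        return float(self.bound.mean())

    def to_json(self, path) -> None:
        payload = {
            "cavity_ids": self.cavity_ids,
            "true_volumes": self.true_volumes,
            "kink_angles_deg": self.kink_angles_deg,
            "pore_profile": [list(p) for p in self.pore_profile],
            "tau_bound": self.tau_bound,
            "tau_unbound": self.tau_unbound,
            "bound": None if self.bound is None else self.bound.astype(int).tolist(),
            "ligand_cavity": (None if self.ligand_cavity is None
                              else self.ligand_cavity.tolist()),
            "water_counts": (None if self.water_counts is None
                             else self.water_counts.tolist()),
            "lipid_atom_counts": (None if self.lipid_atom_counts is None
                                  else self.lipid_atom_counts.tolist()),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


# --------------------------------------------------------------------------
# static structure
# --------------------------------------------------------------------------

def _sector_chain(xy: np.ndarray) -> np.ndarray:
    """Chain id by azimuthal sector: sector k is centred on 72k degrees."""
    ang = np.degrees(np.arctan2(xy[:, 1], xy[:, 0])) % 360.0
    k = np.floor(((ang + 36.0) % 360.0) / 72.0).astype(int)
    return np.array([_CHAIN_IDS[i] for i in k])


def _wall_atoms(spec: ChannelSpec) -> np.ndarray:
    zs = np.arange(spec.z_range[0], spec.z_range[1] + 1e-9, spec.wall_ring_step)
    pts = []
    for z in zs:
        ring_r = float(spec.pore_radius(z)) + WALL_VDW
        n = max(6, int(np.ceil(2 * np.pi * ring_r / spec.wall_atom_spacing)))
        th = 2 * np.pi * np.arange(n) / n
        pts.append(np.column_stack([ring_r * np.cos(th), ring_r * np.sin(th),
                                    np.full(n, z)]))
    return np.vstack(pts)


def _rod_atoms(spec: ChannelSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-subunit M2 C-alpha rods; returns (coords, resids, chain index)."""
    resids = np.arange(221, 246)
    z = (resids - 233) * 1.5  # 9' marker at z = 0
    coords, rids, subunits = [], [], []
    for k in range(spec.n_subunits):
        local = np.column_stack([np.full(z.size, spec.rod_radius),
                                 np.zeros(z.size), z])
        alpha = spec.kink_angles_deg[k]
        if alpha:
            hinge = local[resids == spec.kink_resid][0]
            top = resids > spec.kink_resid
            # rotate the top segment about the radial axis through the hinge
            a = np.radians(alpha)
            c, s = np.cos(a), np.sin(a)
            Rx = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])  # about +x (radial)
            local[top] = (local[top] - hinge) @ Rx.T + hinge
        R = _rotz(72.0 * k)
        coords.append(local @ R.T)
        rids.append(resids)
        subunits.append(np.full(resids.size, k))
    return np.vstack(coords), np.concatenate(rids), np.concatenate(subunits)


def _body_atoms(spec: ChannelSpec, sites: list[CavitySite]) -> np.ndarray:
    lo, hi = spec.z_range
    step = spec.body_lattice
    g_xy = np.arange(-spec.body_outer_radius, spec.body_outer_radius + 1e-9, step)
    g_z = np.arange(lo, hi + 1e-9, step)
    X, Y, Z = np.meshgrid(g_xy, g_xy, g_z, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    r = np.hypot(pts[:, 0], pts[:, 1])
    keep = (r >= spec.body_inner_radius) & (r <= spec.body_outer_radius)
    pts = pts[keep]
    for site in sites:
        keep = site.distance(pts) >= STANDOFF
        pts = pts[keep]
    return pts


def build_pentamer(spec: ChannelSpec) -> tuple[Topology, Frame, GroundTruth]:
    """Static structure plus the static part of the ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sites = cavity_sites(spec)

    wall = _wall_atoms(spec)
    rods, rod_resids, rod_subunits = _rod_atoms(spec)
    body = _body_atoms(spec, sites)

    from .io import vdw_radius as _vdw

    shell_coords, shell_elems, shell_site = [], [], []
    for si, site in enumerate(sites):
        anchors, dirs = site.shell_frame(spec.shell_spacing)
        polar_frac = next(cs.polar_fraction for cs in spec.cavity_specs
                          if cs.cls == site.cls)
        elems = np.where(rng.random(len(anchors)) < polar_frac, "O", "C")
        # per-element standoff (vdW + probe) keeps the carved void exactly
        # the declared shape while exposing polar atoms at the surface
        standoff = np.array([_vdw(e) + PROBE_RADIUS for e in elems])
        shell_coords.append(anchors + standoff[:, None] * dirs)
        shell_elems.append(elems)
        shell_site.append(np.full(len(anchors), si))
    shell_coords = np.vstack(shell_coords)
    shell_elems = np.concatenate(shell_elems)
    shell_site = np.concatenate(shell_site)

    parts = []  # (coords, resid, resname, name, element, chain)
    for i, (xyz, rid, sub) in enumerate(zip(rods, rod_resids, rod_subunits)):
        resname = {233: "ILE", 238: "PHE", 240: "ILE"}.get(int(rid), "ALA")
        parts.append((xyz, int(rid), resname, "CA", "C", _CHAIN_IDS[sub]))
    wall_chain = _sector_chain(wall[:, :2])
    for i, xyz in enumerate(wall):
        ring = int(round((xyz[2] - spec.z_range[0]) / spec.wall_ring_step))
        parts.append((xyz, 400 + ring, "WAL", "W", "C", wall_chain[i]))
    body_chain = _sector_chain(body[:, :2])
    for i, xyz in enumerate(body):
        layer = int(round((xyz[2] - spec.z_range[0]) / spec.body_lattice))
        parts.append((xyz, 500 + layer, "BOD", "B", "C", body_chain[i]))
    shell_chain = _sector_chain(shell_coords[:, :2])
    for i, xyz in enumerate(shell_coords):
        parts.append((xyz, 600 + int(shell_site[i]), "CAV", "S",
                      str(shell_elems[i]), shell_chain[i]))

    # order protein atoms by chain so chains are contiguous in file order
    order = np.argsort([_CHAIN_IDS.index(p[5]) for p in parts], kind="stable")
    parts = [parts[i] for i in order]

    from .io import vdw_radius

    coords = np.array([p[0] for p in parts], float)
    topo = Topology(
        chain_ids=np.array([p[5] for p in parts]),
        resids=np.array([p[1] for p in parts], int),
        resnames=np.array([p[2] for p in parts], dtype="U6"),
        names=np.array([p[3] for p in parts], dtype="U6"),
        elements=np.array([p[4] for p in parts], dtype="U2"),
        vdw_radii=np.array([vdw_radius(p[4]) for p in parts]),
        species=np.array(["protein"] * len(parts), dtype="U8"),
        molecule_ids=np.zeros(len(parts), int),
        chains=list(_CHAIN_IDS),
    )
    # recompute molecule ids from (chain, resid) runs
    from .io import _molecule_ids
    topo.molecule_ids = _molecule_ids(topo.chain_ids, topo.resids, topo.resnames)

    truth = GroundTruth(
        cavity_ids=[s.cavity_id for s in sites],
        true_volumes={s.cavity_id: s.true_volume for s in sites},
        kink_angles_deg={_CHAIN_IDS[k]: float(spec.kink_angles_deg[k])
                         for k in range(spec.n_subunits)},
        pore_profile=spec.pore_profile,
        sites=sites,
    )
    box = np.full(3, spec.box_edge)
    return topo, Frame(coords, 0.0, box), truth


# --------------------------------------------------------------------------
# binding kinetics
# --------------------------------------------------------------------------

def simulate_binding_traces(n_ligands: int, n_frames: int, dt: float,
                            tau_bound: float, tau_unbound: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Exact two-state CTMC sampled at the frame times.

    Each ligand alternates exponential bound/bulk dwells; the initial state
    is drawn from the stationary distribution.  Returns a boolean
    (n_ligands, n_frames) array of the state at each frame time.
    """
    out = np.zeros((n_ligands, n_frames), dtype=bool)
    pi_b = tau_bound / (tau_bound + tau_unbound)
    tgrid = np.arange(n_frames) * dt
    horizon = tgrid[-1] if n_frames else 0.0
    for m in range(n_ligands):
        t = 0.0
        state = bool(rng.random() < pi_b)
        i = 0
        while i < n_frames and t <= horizon:
            dwell = rng.exponential(tau_bound if state else tau_unbound)
            j = int(np.searchsorted(tgrid, t + dwell, side="left"))
            out[m, i:j] = state
            i = j
            t += dwell
            state = not state
    return out


def _random_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    """n uniform random rotation matrices (quaternion method)."""
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    return np.stack([
        np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)], -1),
        np.stack([2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)], -1),
        np.stack([2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)], -1),
    ], axis=1)


def _shell_points(n: int, spec: ChannelSpec, rng: np.random.Generator) -> np.ndarray:
    r_lo, r_hi = spec.solvent_shell
    u = rng.random(n)
    r = (r_lo ** 3 + u * (r_hi ** 3 - r_lo ** 3)) ** (1.0 / 3.0)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return r[:, None] * v


# --------------------------------------------------------------------------
# trajectory
# --------------------------------------------------------------------------

def simulate_trajectory(spec: ChannelSpec, n_frames: int, dt: float = 1.0,
                        seed: int | None = None) -> tuple[Trajectory, GroundTruth]:
    """Simulate a trajectory over the static pentamer.

    Bound ligands sit strictly inside their assigned cavity (interior
    margin ``spec.interior_margin``); bulk molecules are resampled in the
    solvent shell each frame.  Waters and lipid-chain atoms realise the
    anti-correlation rules.  Seed defaults to ``spec.seed``.
    """
    if n_frames < 2:
        raise SpecError("n_frames must be >= 2")
    seed = spec.seed if seed is None else seed
    topo_p, frame0, truth = build_pentamer(spec)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC4A5]))
    sites = truth.sites
    n_cav = len(sites)
    intra_idx = [i for i, s in enumerate(sites) if s.cls == "intra"]
    inter_idx = [i for i, s in enumerate(sites) if s.cls == "inter"]

    lig = spec.ligand
    n_lig = lig.count
    bound = simulate_binding_traces(n_lig, n_frames, dt,
                                    lig.tau_bound, lig.tau_unbound, rng)
    # cavity assignment: chosen uniformly at each binding event, constant
    # within a bound dwell
    ligand_cavity = np.full((n_lig, n_frames), -1, dtype=int)
    for m in range(n_lig):
        cav = -1
        for t in range(n_frames):
            if bound[m, t]:
                if t == 0 or not bound[m, t - 1]:
                    cav = int(rng.integers(n_cav))
                ligand_cavity[m, t] = cav

    ws = spec.water
    baseline = np.array([ws.cavity_baseline_inter if s.cls == "inter"
                         else ws.cavity_baseline_intra for s in sites])
    max_cavity_waters = baseline + 2

    lp = spec.lipid
    n_chains = len(intra_idx) * lp.chains_per_cavity

    # --- assemble solvent topology -------------------------------------
    from .io import vdw_radius, _molecule_ids

    records = []  # (resname, name, element, chain, resid)
    lig_atoms = len(lig.atom_offsets)
    for m in range(n_lig):
        for a in range(lig_atoms):
            records.append(("EOH", f"C{a + 1}" if lig.elements[a] == "C" else "O1",
                            lig.elements[a], "X", m + 1))
    n_cavity_water = int(max_cavity_waters.sum())
    for w in range(n_cavity_water + ws.bulk_count):
        records.append(("HOH", "O", "O", "W", w + 1))
    for c in range(n_chains):
        for a in range(lp.atoms_per_chain):
            records.append(("DOP", f"C{a + 1}", "C", "Y", c + 1))

    chain_ids = np.concatenate([topo_p.chain_ids,
                                np.array([r[3] for r in records])])
    resids = np.concatenate([topo_p.resids, np.array([r[4] for r in records], int)])
    resnames = np.concatenate([topo_p.resnames,
                               np.array([r[0] for r in records], dtype="U6")])
    names = np.concatenate([topo_p.names, np.array([r[1] for r in records], dtype="U6")])
    elements = np.concatenate([topo_p.elements,
                               np.array([r[2] for r in records], dtype="U2")])
    species = np.concatenate([
        topo_p.species,
        np.array(["ligand"] * n_lig * lig_atoms
                 + ["water"] * (n_cavity_water + ws.bulk_count)
                 + ["lipid"] * n_chains * lp.atoms_per_chain, dtype="U8")])
    vdw = np.concatenate([topo_p.vdw_radii,
                          np.array([vdw_radius(r[2]) for r in records])])
    topo = Topology(chain_ids=chain_ids, resids=resids, resnames=resnames,
                    names=names, elements=elements, vdw_radii=vdw,
                    species=species,
                    molecule_ids=_molecule_ids(chain_ids, resids, resnames),
                    chains=list(topo_p.chains) + ["X", "W", "Y"])

    n_prot = topo_p.n_atoms
    n_total = topo.n_atoms
    lig_off = n_prot
    wat_off = lig_off + n_lig * lig_atoms
    lip_off = wat_off + n_cavity_water + ws.bulk_count
    offsets = np.asarray(lig.atom_offsets, float)
    offsets = offsets - offsets.mean(axis=0)

    margin = spec.interior_margin
    water_counts = np.zeros((n_cav, n_frames), int)
    lipid_atom_counts = np.zeros((n_cav, n_frames), int)
    coords = np.empty((n_frames, n_total, 3))
    times = np.arange(n_frames) * dt

    # thermal noise is applied per residue (pseudo-rigid groups): protein
    # atoms move collectively, as bonded atoms do.  Independent per-atom
    # noise on a sub-ångström-spaced pseudo-atom surface would shave the
    # probe-accessible volume systematically (clearance is a min over
    # atoms, and the minimum of many jittered distances is biased low).
    prot_mols = topo_p.molecule_ids
    n_prot_mols = int(prot_mols.max()) + 1 if n_prot else 0

    # per-cavity water slot offsets
    wslot = np.concatenate([[0], np.cumsum(max_cavity_waters)])

    for t in range(n_frames):
        c = coords[t]
        c[:n_prot] = frame0.coords
        if spec.protein_jitter > 0:
            disp = rng.normal(scale=spec.protein_jitter,
                              size=(n_prot_mols, 3))
            c[:n_prot] += disp[prot_mols]
        # ligands
        rot = _random_rotations(n_lig, rng)
        centers = np.empty((n_lig, 3))
        bulk = ~bound[:, t]
        if bulk.any():
            centers[bulk] = _shell_points(int(bulk.sum()), spec, rng)
        for m in np.flatnonzero(bound[:, t]):
            site = sites[ligand_cavity[m, t]]
            centers[m] = site.sample_interior(1, rng, margin)[0]
        lig_xyz = centers[:, None, :] + np.einsum("mij,aj->mai", rot, offsets)
        c[lig_off:wat_off] = lig_xyz.reshape(-1, 3)

        # cavity waters: baseline minus resident ligands, small noise
        n_lig_in = np.bincount(ligand_cavity[:, t][ligand_cavity[:, t] >= 0],
                               minlength=n_cav)
        for ci in range(n_cav):
            want = baseline[ci] - int(round(ws.anticorrelation * n_lig_in[ci]))
            want += int(rng.integers(-1, 2)) if baseline[ci] > 0 else 0
            want = int(np.clip(want, 0, max_cavity_waters[ci]))
            water_counts[ci, t] = want
            lo = wat_off + wslot[ci]
            hi = wat_off + wslot[ci + 1]
            slot = np.arange(lo, hi)
            if want:
                c[slot[:want]] = sites[ci].sample_interior(want, rng, margin)
            if want < len(slot):
                c[slot[want:]] = _shell_points(len(slot) - want, spec, rng)
        # bulk waters
        c[wat_off + wslot[-1]:lip_off] = _shell_points(ws.bulk_count, spec, rng)

        # lipid chains in intra cavities
        a_per = lp.atoms_per_chain
        ch = 0
        for ci in intra_idx:
            p = lp.insert_probability * lp.ligand_reduction ** n_lig_in[ci]
            for _ in range(lp.chains_per_cavity):
                base = lip_off + ch * a_per
                if rng.random() < p:
                    start = sites[ci].sample_interior(1, rng, margin + 0.2)[0]
                    d = rng.normal(size=3)
                    d /= np.linalg.norm(d)
                    pts = start + np.outer(np.arange(a_per) * 1.3, d)
                    # keep strictly interior: clamp in the local frame
                    loc = sites[ci].to_local(pts)
                    h = (sites[ci].size / 2.0 if sites[ci].shape == "box"
                         else sites[ci].size) - margin
                    if sites[ci].shape == "box":
                        loc = np.clip(loc, -h, h)
                    else:
                        rr = np.linalg.norm(loc, axis=1)
                        far = rr > h
                        loc[far] *= (h / rr[far])[:, None]
                    pts = loc @ sites[ci].rotation.T + sites[ci].center
                    c[base:base + a_per] = pts
                    lipid_atom_counts[ci, t] += a_per
                else:
                    # parked in the membrane ring, outside every cavity
                    th = rng.random() * 2 * np.pi
                    ring = np.array([26.0 * np.cos(th), 26.0 * np.sin(th), 0.0])
                    d = rng.normal(size=3)
                    d /= np.linalg.norm(d)
                    c[base:base + a_per] = ring + np.outer(np.arange(a_per) * 1.3, d)
                ch += 1

    truth.bound = bound
    truth.ligand_cavity = ligand_cavity
    truth.water_counts = water_counts
    truth.lipid_atom_counts = lipid_atom_counts
    truth.tau_bound = lig.tau_bound
    truth.tau_unbound = lig.tau_unbound
    traj = Trajectory(topo, coords, times, frame0.box)
    return traj, truth
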