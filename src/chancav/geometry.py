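"""Rigid superposition, RMSD time series, and the M2 helix kink angle.

The kink angle follows the standard principal-axis construction: for the
bottom (7'-14', residues 221-238) and top (14'-21', residues 238-245)
segments of the pore-lining M2 helix, take the first principal axis of the
C-alpha coordinates (unit masses) and report the angle between the two
axes, folded into [0°, 90°] because principal axes carry no sign.  The
hinge residue belongs to both segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import GeometryError
from .model import Frame, Topology, Trajectory, trailing_window_mask

# Domain conventions for GLIC-like pentamers: extracellular domain residues
# 5-195, transmembrane domain 196-315, M2 helix 222-245.
ECD_RANGE = (5, 195)
TMD_RANGE = (196, 315)
M2_RANGE = (222, 245)


@dataclass
class DomainDefinition:
    """A named set of residue ranges, optionally restricted to chains."""

    name: str
    ranges: list[tuple[int, int]]
    chains: list[str] | None = None

    def ca_indices(self, topology: Topology) -> np.ndarray:
        masks = [topology.ca_mask(chains=self.chains, resid_range=r)
                 for r in self.ranges]
        m = np.logical_or.reduce(masks)
        idx = np.flatnonzero(m)
        if idx.size == 0:
            raise GeometryError(f"domain {self.name!r} selects no C-alpha atoms")
        return idx


def whole_protein_domain() -> DomainDefinition:
    return DomainDefinition("whole", [(-10**6, 10**6)])


def ecd_domain() -> DomainDefinition:
    return DomainDefinition("ECD", [ECD_RANGE])


def tmd_domain() -> DomainDefinition:
    return DomainDefinition("TMD", [TMD_RANGE])


@dataclass
class KinkSegments:
    """Residue ranges of the two helix segments; they share the hinge residue."""

    bottom: tuple[int, int] = (221, 238)
    top: tuple[int, int] = (238, 245)

    def __post_init__(self) -> None:
        if self.bottom[1] != self.top[0]:
            raise GeometryError("kink segments must share exactly the hinge residue")


# --- superposition ---------------------------------------------------------

def superpose(mobile: np.ndarray, reference: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch).

    Returns ``(R, t, rmsd)`` with proper rotation R (det = +1) and
    translation t such that ``mobile @ R.T + t`` best fits ``reference``;
    ``rmsd`` is the post-fit RMSD in Å.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape:
        raise GeometryError("selections must map 1:1 between frames")
    if len(mobile) < 3:
        raise GeometryError("superposition needs at least 3 atoms")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    a, b = mobile - mc, reference - rc
    if np.linalg.matrix_rank(np.vstack([a, b])) < 2:
        raise GeometryError("degenerate (collinear) selection")
    rot, _ = Rotation.align_vectors(b, a)
    R = rot.as_matrix()
    t = rc - mc @ R.T
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return R, t, rmsd


def apply_transform(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.asarray(coords, float) @ R.T + t


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD without fitting."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


# --- RMSD analyses ---------------------------------------------------------

def rmsd_series(traj: Trajectory, reference: Frame, domain: DomainDefinition,
                fit_domain: DomainDefinition | None = None,
                window_fraction: float = 0.1) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Per-frame C-alpha RMSD of ``domain`` after fitting on ``fit_domain``.

    Returns the series as a DataFrame (time, rmsd) plus (mean, SD) over the
    trailing window (default: last 10% of frames).
    """
    top = traj.topology
    fit_dom = fit_domain or domain
    fit_idx = fit_dom.ca_indices(top)
    dom_idx = domain.ca_indices(top)
    ref_fit = reference.coords[fit_idx]
    ref_dom = reference.coords[dom_idx]
    out = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        R, t, _ = superpose(traj.coords[i][fit_idx], ref_fit)
        out[i] = rmsd(apply_transform(traj.coords[i][dom_idx], R, t), ref_dom)
    df = pd.DataFrame({"time_ns": traj.times, "rmsd_A": out})
    tail = trailing_window_mask(traj.times, window_fraction)
    return df, (float(out[tail].mean()), float(out[tail].std()))


def rmsd_per_residue(traj: Trajectory, reference: Frame,
                     fit_domain: DomainDefinition,
                     chains: list[str] | None = None) -> pd.DataFrame:
    """Mean per-residue C-alpha deviation after a global fit, chain-averaged.

    For each frame the structure is fitted on ``fit_domain``; the deviation
    of every C-alpha is averaged over frames, then over the chains sharing
    a residue number.  Residues without a C-alpha are skipped with a warning.
    """
    top = traj.topology
    chains = chains or top.protein_chains
    fit_idx = fit_domain.ca_indices(top)
    ref_fit = reference.coords[fit_idx]
    ca_idx = top.ca_indices(chains=chains)
    dev = np.zeros(len(ca_idx))
    for i in range(traj.n_frames):
        R, t, _ = superpose(traj.coords[i][fit_idx], ref_fit)
        moved = apply_transform(traj.coords[i][ca_idx], R, t)
        dev += np.linalg.norm(moved - reference.coords[ca_idx], axis=1)
    dev /= traj.n_frames
    df = pd.DataFrame({"chain": top.chain_ids[ca_idx],
                       "resid": top.resids[ca_idx], "rmsd_A": dev})
    per_res = df.groupby("resid", as_index=False)["rmsd_A"].mean()
    expected = set(range(int(top.resids[ca_idx].min()),
                         int(top.resids[ca_idx].max()) + 1))
    missing = expected - set(per_res["resid"])
    if missing:
        warnings.warn(f"residues without C-alpha skipped: {sorted(missing)[:10]}...",
                      stacklevel=2)
    return per_res


# --- kink angle ------------------------------------------------------------

def _principal_axis(points: np.ndarray) -> np.ndarray:
    """First principal axis (unit vector) of a point set with unit masses."""
    pts = np.asarray(points, float)
    if len(pts) < 3:
        raise GeometryError("segment needs at least 3 C-alpha atoms")
    c = pts - pts.mean(axis=0)
    cov = c.T @ c
    w, v = np.linalg.eigh(cov)
    if w[-1] <= 1e-12:
        raise GeometryError("degenerate segment (all atoms coincide)")
    return v[:, -1]


def kink_angle(frame: Frame, topology: Topology, chain: str,
               segments: KinkSegments | None = None) -> float:
    """Kink angle (degrees, in [0, 90]) of one chain's M2 helix."""
    seg = segments or KinkSegments()
    bot_idx = topology.ca_indices(chains=[chain], resid_range=seg.bottom)
    top_idx = topology.ca_indices(chains=[chain], resid_range=seg.top)
    if len(bot_idx) < 3 or len(top_idx) < 3:
        raise GeometryError(
            f"chain {chain}: kink segments need >= 3 C-alpha atoms "
            f"(got {len(bot_idx)}, {len(top_idx)})")
    a1 = _principal_axis(frame.coords[bot_idx])
    a2 = _principal_axis(frame.coords[top_idx])
    cosang = abs(float(np.dot(a1, a2)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


@dataclass
class KinkSummary:
    mean: float
    sd: float
    per_chain: dict[str, float] = field(default_factory=dict)


def kink_angle_trajectory(traj: Trajectory, segments: KinkSegments | None = None,
                          chains: list[str] | None = None) -> KinkSummary:
    """Mean ± SD kink angle over frames and chains, plus per-chain means."""
    chains = chains or traj.topology.protein_chains
    angles = np.empty((traj.n_frames, len(chains)))
    for i in range(traj.n_frames):
        fr = traj.frame(i)
        for j, c in enumerate(chains):
            angles[i, j] = kink_angle(fr, traj.topology, c, segments)
    return KinkSummary(float(angles.mean()), float(angles.std()),
                       {c: float(angles[:, j].mean()) for j, c in enumerate(chains)})
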