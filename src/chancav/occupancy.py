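"""Per-cavity occupant counting and species density maps.

A molecule occupies a cavity when its heavy-atom geometric centre lies
within 1.0 Å of any cavity voxel centre; ligands and waters are counted as
molecules, lipids as individual acyl-chain heavy atoms.  Density maps are
per-voxel mean number densities on a 1 Å lattice, averaged over a time
window (default: the second half of the trajectory, inclusive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ClassificationError, SelectionError
from .model import Topology, Trajectory, second_half_mask

MEMBERSHIP_CUTOFF = 1.0  # Å, centre-to-voxel-centre


@dataclass
class OccupancySeries:
    """Per-frame occupant counts for one cavity."""

    cavity_id: str
    times: np.ndarray
    n_ligand: np.ndarray
    n_water: np.ndarray
    n_lipid: np.ndarray     # acyl-chain heavy atoms, not molecules

    def summary(self, window_mask: np.ndarray | None = None) -> dict[str, tuple[float, float]]:
        """mean ± SD per species over a window (default: second half)."""
        m = second_half_mask(self.times) if window_mask is None else window_mask
        return {k: (float(v[m].mean()), float(v[m].std()))
                for k, v in (("ligand", self.n_ligand), ("water", self.n_water),
                             ("lipid", self.n_lipid))}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times, "n_ligand": self.n_ligand,
                             "n_water": self.n_water, "n_lipid": self.n_lipid})


def molecule_in_cavity(mol_coords: np.ndarray, heavy: np.ndarray,
                       region_centers: np.ndarray,
                       cutoff: float = MEMBERSHIP_CUTOFF) -> bool:
    """True iff the molecule's heavy-atom centre is within ``cutoff`` of a
    cavity voxel centre."""
    mol_coords = np.atleast_2d(mol_coords)
    heavy = np.asarray(heavy, bool)
    if not heavy.any():
        raise ClassificationError("molecule has no heavy atoms")
    c = mol_coords[heavy].mean(axis=0)
    d = np.min(np.linalg.norm(np.atleast_2d(region_centers) - c, axis=1))
    return bool(d <= cutoff)


def _lipid_chain_mask(topology: Topology) -> np.ndarray:
    """Heavy acyl-chain atoms of lipid molecules.

    Glycerol/headgroup atoms (common names C1-C3 glycerol, O*, P, N) are
    excluded by name prefix; with single-species pseudo-lipids every heavy
    atom counts.
    """
    m = (topology.species == "lipid") & topology.heavy
    head = np.isin(topology.elements, ["P", "N"]) | np.char.startswith(
        topology.names.astype(str), "O")
    return m & ~head


def occupancy_series(traj: Trajectory, regions: dict[str, np.ndarray],
                     window_mask: np.ndarray | None = None,
                     cutoff: float = MEMBERSHIP_CUTOFF
                     ) -> tuple[dict[str, OccupancySeries], np.ndarray, list[int]]:
    """Occupant counts per cavity per frame.

    ``regions`` maps cavity id -> (M, 3) voxel-centre coordinates.
    Returns (series per cavity, ligand assignment matrix, ligand molecule
    ids).  The assignment matrix holds, per ligand molecule and frame, the
    index of the occupied cavity in ``regions`` order, or -1.
    """
    top = traj.topology
    cav_ids = list(regions.keys())
    trees = {}
    for cid in cav_ids:
        centers = np.atleast_2d(regions[cid])
        if centers.size == 0:
            warnings.warn(f"cavity {cid} has an empty region; counts will be 0",
                          stacklevel=2)
            trees[cid] = None
        else:
            trees[cid] = cKDTree(centers)

    lig_mols = top.molecules("ligand")
    wat_mols = top.molecules("water")
    lig_ids = sorted(lig_mols)
    lipid_idx = np.flatnonzero(_lipid_chain_mask(top))

    heavy = top.heavy
    lig_groups = [lig_mols[i][heavy[lig_mols[i]]] for i in lig_ids]
    wat_groups = [w[heavy[w]] for w in wat_mols.values()]

    T = traj.n_frames
    series = {cid: OccupancySeries(cid, traj.times,
                                   np.zeros(T, int), np.zeros(T, int), np.zeros(T, int))
              for cid in cav_ids}
    assignment = np.full((len(lig_ids), T), -1, dtype=int)

    for t in range(T):
        c = traj.coords[t]
        lig_centers = np.array([c[g].mean(axis=0) for g in lig_groups]) \
            if lig_groups else np.empty((0, 3))
        wat_centers = np.array([c[g].mean(axis=0) for g in wat_groups]) \
            if wat_groups else np.empty((0, 3))
        lip_pts = c[lipid_idx] if lipid_idx.size else np.empty((0, 3))
        for k, cid in enumerate(cav_ids):
            tree = trees[cid]
            if tree is None:
                continue
            if len(lig_centers):
                d, _ = tree.query(lig_centers, k=1)
                inside = d <= cutoff
                series[cid].n_ligand[t] = int(inside.sum())
                assignment[inside, t] = k
            if len(wat_centers):
                d, _ = tree.query(wat_centers, k=1)
                series[cid].n_water[t] = int((d <= cutoff).sum())
            if len(lip_pts):
                d, _ = tree.query(lip_pts, k=1)
                series[cid].n_lipid[t] = int((d <= cutoff).sum())
    return series, assignment, lig_ids


@dataclass
class DensityMap:
    """Per-voxel mean number density of one species over a time window."""

    species: str
    values: np.ndarray
    origin: np.ndarray
    spacing: float
    n_frames: int

    def total_mean_count(self) -> float:
        """Sum over voxels = mean atom count of the species inside the box."""
        return float(self.values.sum())


def density_map(traj: Trajectory, species: str,
                window_mask: np.ndarray | None = None,
                resolution: float = 1.0,
                bounds: tuple[np.ndarray, np.ndarray] | None = None) -> DensityMap:
    """Accumulate one count per atom per frame into 1 Å voxels, divided by
    the number of averaged frames (default window: second half)."""
    top = traj.topology
    sel = np.flatnonzero(top.species == species)
    if sel.size == 0:
        raise SelectionError(f"no atoms of species {species!r}")
    mask = second_half_mask(traj.times) if window_mask is None else window_mask
    frames = np.flatnonzero(mask)
    if bounds is None:
        pts = traj.coords[frames][:, sel, :].reshape(-1, 3)
        lo = np.floor(pts.min(axis=0)) - resolution
        hi = np.ceil(pts.max(axis=0)) + resolution
    else:
        lo, hi = (np.asarray(b, float) for b in bounds)
    shape = np.maximum(np.ceil((hi - lo) / resolution).astype(int), 1)
    values = np.zeros(shape)
    for t in frames:
        idx = np.floor((traj.coords[t][sel] - lo) / resolution).astype(int)
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        np.add.at(values, tuple(idx[ok].T), 1.0)
    values /= len(frames)
    return DensityMap(species, values, lo, resolution, len(frames))
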