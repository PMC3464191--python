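"""In-memory data model: topology, frames, trajectories.

The pipeline works in ångström and nanoseconds throughout; file readers
convert at the boundary.  A :class:`Topology` is a flat, array-backed atom
table: one species class per atom (protein / water / ligand / lipid / ion),
one molecule id per atom (molecule == residue), and per-atom van der Waals
radii used by the pore and cavity probes.

M2 prime notation: the pore-lining M2 helix of a pentameric ligand-gated
ion channel is numbered from ~1' at the intracellular end to ~20' at the
extracellular end.  For GLIC-style numbering position p' maps to residue
224 + p (14' = 238, 9' = 233, 16' = 240).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import TopologyError

SPECIES_CLASSES = ("protein", "water", "ligand", "lipid", "ion")

#: residue offset of the M2 prime notation: resid = PRIME_OFFSET + prime
PRIME_OFFSET = 224


def prime_to_resid(prime: int) -> int:
    """Residue number of M2 prime position ``prime`` (9' -> 233, 14' -> 238)."""
    return PRIME_OFFSET + prime


def resid_to_prime(resid: int) -> int:
    return resid - PRIME_OFFSET


@dataclass
class Topology:
    """Array-backed atom table.

    All per-atom arrays share the same length.  ``molecule_ids`` groups
    atoms into molecules (residue-level grouping); ``chains`` lists chain
    identifiers in file order, which also defines the subunit indexing
    (first protein chain -> subunit 0).
    """

    chain_ids: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    names: np.ndarray
    elements: np.ndarray
    vdw_radii: np.ndarray
    species: np.ndarray
    molecule_ids: np.ndarray
    chains: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.chain_ids)
        for attr in ("resids", "resnames", "names", "elements",
                     "vdw_radii", "species", "molecule_ids"):
            if len(getattr(self, attr)) != n:
                raise TopologyError(f"atom array {attr!r} has wrong length")
        if n and np.any(self.vdw_radii <= 0):
            raise TopologyError("van der Waals radii must be positive")
        bad = set(np.unique(self.species)) - set(SPECIES_CLASSES)
        if bad:
            raise TopologyError(f"unknown species classes: {sorted(bad)}")
        if not self.chains:
            seen: list[str] = []
            for c in self.chain_ids:
                if c not in seen:
                    seen.append(str(c))
            self.chains = seen

    @property
    def n_atoms(self) -> int:
        return len(self.chain_ids)

    @property
    def protein_chains(self) -> list[str]:
        prot = set(self.chain_ids[self.species == "protein"])
        return [c for c in self.chains if c in prot]

    def subunit_index(self, chain: str) -> int:
        """Subunit index of a protein chain (file order, A..E -> 0..4)."""
        return self.protein_chains.index(chain)

    # --- masks -----------------------------------------------------------
    @property
    def heavy(self) -> np.ndarray:
        return self.elements != "H"

    @property
    def protein_heavy(self) -> np.ndarray:
        return (self.species == "protein") & self.heavy

    def ca_mask(self, chains=None, resid_range=None, resids=None) -> np.ndarray:
        m = (self.names == "CA") & (self.species == "protein")
        if chains is not None:
            m &= np.isin(self.chain_ids, list(chains))
        if resid_range is not None:
            lo, hi = resid_range
            m &= (self.resids >= lo) & (self.resids <= hi)
        if resids is not None:
            m &= np.isin(self.resids, list(resids))
        return m

    def ca_indices(self, **kw) -> np.ndarray:
        return np.flatnonzero(self.ca_mask(**kw))

    def molecules(self, species: str | None = None) -> dict[int, np.ndarray]:
        """Molecule id -> atom index array, optionally restricted to a species."""
        mask = np.ones(self.n_atoms, bool) if species is None else self.species == species
        ids = self.molecule_ids[mask]
        idx = np.flatnonzero(mask)
        order = np.argsort(ids, kind="stable")
        ids, idx = ids[order], idx[order]
        out: dict[int, np.ndarray] = {}
        if len(ids) == 0:
            return out
        cuts = np.flatnonzero(np.diff(ids)) + 1
        for block in np.split(idx, cuts):
            out[int(self.molecule_ids[block[0]])] = block
        return out


@dataclass
class Frame:
    """One coordinate set: positions in Å, time in ns, periodic box in Å."""

    coords: np.ndarray
    time: float = 0.0
    box: np.ndarray | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.coords)


@dataclass
class Trajectory:
    """Ordered frames over a fixed topology.

    ``coords`` has shape (n_frames, n_atoms, 3); ``times`` is in ns and must
    be strictly increasing with uniform spacing (1% tolerance).
    """

    topology: Topology
    coords: np.ndarray
    times: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        self.times = np.asarray(self.times, float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TopologyError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise TopologyError(
                f"coordinate atom count {self.coords.shape[1]} != "
                f"topology atom count {self.topology.n_atoms}")
        if len(self.times) != len(self.coords):
            raise TopologyError("times and coords disagree in frame count")
        if self.n_frames < 2:
            raise TopologyError("a trajectory needs at least 2 frames")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise TopologyError("times must be strictly increasing")
        if np.any(np.abs(dt - dt.mean()) > 0.01 * dt.mean()):
            raise TopologyError("frame spacing must be uniform to within 1%")

    @property
    def n_frames(self) -> int:
        return len(self.coords)

    @property
    def dt(self) -> float:
        """Frame spacing in ns."""
        return float(np.diff(self.times).mean())

    def frame(self, i: int) -> Frame:
        return Frame(self.coords[i], float(self.times[i]), self.box)

    def __iter__(self):
        for i in range(self.n_frames):
            yield self.frame(i)

    def __len__(self) -> int:
        return self.n_frames


def second_half_mask(times: np.ndarray) -> np.ndarray:
    """Frames belonging to the trailing half of the run (t >= midpoint, inclusive)."""
    times = np.asarray(times, float)
    mid = times[0] + (times[-1] - times[0]) / 2.0
    return times >= mid


def trailing_window_mask(times: np.ndarray, fraction: float = 0.1) -> np.ndarray:
    """Frames in the trailing ``fraction`` of the run (last 10% by default)."""
    times = np.asarray(times, float)
    start = times[-1] - fraction * (times[-1] - times[0])
    return times >= start
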