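"""Structure, trajectory and volumetric-grid I/O.

MDAnalysis does the heavy lifting for the standard formats (PDB/GRO
structures; multi-model PDB, DCD, XTC, TRR trajectories); OpenDX scalar
fields go through gridDataFormats.  This module converts between those
libraries' objects and the package's array-backed data model, assigns
species classes from residue-name rules, and attaches van der Waals radii
(Bondi set by element, hydrogens 1.10 Å, configurable override).
"""

from __future__ import annotations

import os
import warnings

import numpy as np

from .errors import (ClassificationError, FormatError, TopologyError,
                     UnsupportedGridError)
from .model import Frame, Topology, Trajectory

# Bondi van der Waals radii (Å); H at 1.10 Å.  Unknown elements fall back
# to DEFAULT_VDW.
BONDI_RADII = {
    "H": 1.10, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "NA": 2.27, "K": 2.75, "MG": 1.73, "ZN": 1.39, "CA": 2.31,
    "FE": 2.00, "SE": 1.90,
}
DEFAULT_VDW = 1.70

#: elements counted as polar for surface-composition analyses
POLAR_ELEMENTS = frozenset({"N", "O", "S"})

# residue names recognised as protein without an explicit species rule
_AMINO = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HSD", "HSE", "HSP", "HID", "HIE", "HIP", "CYX", "MSE",
}

_TWO_LETTER = {"CL", "BR", "NA", "MG", "ZN", "FE", "SE", "MN", "CU"}


def guess_element(name: str) -> str:
    """Element symbol from an atom name (PDB conventions, best effort)."""
    s = "".join(ch for ch in str(name).strip() if ch.isalpha()).upper()
    if not s:
        return "X"
    # two-letter symbols only for bare ion names (avoid eating CA/CB carbons)
    # and for the unambiguous Cl/Br prefixes
    if s in _TWO_LETTER or s[:2] in ("CL", "BR"):
        return s[:2]
    return s[0]


def vdw_radius(element: str, table: dict | None = None) -> float:
    tab = dict(BONDI_RADII)
    if table:
        tab.update({k.upper(): v for k, v in table.items()})
    return float(tab.get(str(element).upper(), DEFAULT_VDW))


def classify_species(resnames, species_rules: dict[str, str] | None,
                     default: str | None = None) -> np.ndarray:
    """Species class per atom from residue-name rules.

    Amino-acid residue names default to ``protein`` even without a rule.
    Raises :class:`ClassificationError` listing every unmatched residue
    name when no default class is configured.
    """
    rules = {k.upper(): v for k, v in (species_rules or {}).items()}
    out = np.empty(len(resnames), dtype=object)
    missing = set()
    for i, rn in enumerate(resnames):
        key = str(rn).upper()
        if key in rules:
            out[i] = rules[key]
        elif key in _AMINO:
            out[i] = "protein"
        elif default is not None:
            out[i] = default
        else:
            missing.add(key)
    if missing:
        raise ClassificationError(
            "no species rule and no default class for residue names: "
            + ", ".join(sorted(missing)))
    return out.astype("U8")


def _molecule_ids(chain_ids, resids, resnames) -> np.ndarray:
    """Molecule id per atom: contiguous (chain, resid, resname) runs."""
    mol = np.zeros(len(resids), dtype=int)
    cur = 0
    for i in range(1, len(resids)):
        if (resids[i] != resids[i - 1] or chain_ids[i] != chain_ids[i - 1]
                or resnames[i] != resnames[i - 1]):
            cur += 1
        mol[i] = cur
    return mol


def _universe_topology(u, species_rules, default_species, radius_table) -> Topology:
    atoms = u.atoms
    names = atoms.names.astype("U6")
    resnames = atoms.resnames.astype("U6")
    resids = atoms.resids.astype(int)
    if hasattr(atoms, "chainIDs") and any(str(c).strip() for c in atoms.chainIDs):
        chain_ids = np.array([str(c).strip() or "A" for c in atoms.chainIDs])
    else:
        chain_ids = np.array([str(s).strip() or "A" for s in atoms.segids])
    if hasattr(atoms, "elements") and any(str(e).strip() for e in atoms.elements):
        elements = np.array([str(e).strip().upper() or guess_element(n)
                             for e, n in zip(atoms.elements, names)])
    else:
        elements = np.array([guess_element(n) for n in names])
    species = classify_species(resnames, species_rules, default_species)
    radii = np.array([vdw_radius(e, radius_table) for e in elements])
    return Topology(
        chain_ids=chain_ids, resids=resids, resnames=resnames, names=names,
        elements=elements.astype("U2"), vdw_radii=radii, species=species,
        molecule_ids=_molecule_ids(chain_ids, resids, resnames))


def read_structure(path, species_rules: dict[str, str] | None = None,
                   default_species: str | None = None,
                   radius_table: dict | None = None) -> tuple[Topology, Frame]:
    """Read a PDB/GRO structure into a topology plus one coordinate frame."""
    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:  # noqa: BLE001 - normalise reader errors
        raise FormatError(f"could not parse structure file {path}: {exc}") from exc
    top = _universe_topology(u, species_rules, default_species, radius_table)
    box = None
    if u.dimensions is not None and np.any(u.dimensions[:3] > 0):
        box = np.asarray(u.dimensions[:3], float)
    return top, Frame(np.asarray(u.atoms.positions, float), 0.0, box)


def read_trajectory(path, topology: Topology, dt: float | None = None,
                    structure_path=None) -> Trajectory:
    """Read a trajectory (multi-model PDB, DCD, XTC, TRR) over a topology.

    ``dt`` (ns) overrides/supplies frame times when the file carries none.
    """
    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if structure_path is not None:
                u = mda.Universe(str(structure_path), str(path))
            else:
                u = mda.Universe(str(path))
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"could not parse trajectory file {path}: {exc}") from exc
    if len(u.atoms) != topology.n_atoms:
        raise TopologyError(
            f"trajectory atom count {len(u.atoms)} != topology "
            f"atom count {topology.n_atoms}")
    coords, times = [], []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for ts in u.trajectory:
                coords.append(np.array(ts.positions, float))
                times.append(float(ts.time) / 1000.0)  # MDAnalysis ps -> ns
    except Exception as exc:  # noqa: BLE001 - truncated file
        raise FormatError(
            f"corrupt frame after index {len(coords) - 1} in {path}: {exc}") from exc
    coords = np.asarray(coords)
    times = np.asarray(times)
    if dt is not None or len(times) < 2 or np.allclose(np.diff(times), 0):
        step = dt if dt is not None else 1.0
        times = np.arange(len(coords)) * step
    box = None
    if u.dimensions is not None and np.any(u.dimensions[:3] > 0):
        box = np.asarray(u.dimensions[:3], float)
    return Trajectory(topology, coords, times, box)


def _mda_universe(topology: Topology, coords: np.ndarray):
    """Build an MDAnalysis Universe for writing."""
    import MDAnalysis as mda

    n = topology.n_atoms
    mol = topology.molecule_ids
    n_res = int(mol.max()) + 1 if n else 0
    res_first = np.zeros(n_res, dtype=int)
    seen = np.zeros(n_res, dtype=bool)
    for i, m in enumerate(mol):
        if not seen[m]:
            res_first[m] = i
            seen[m] = True
    chains = list(dict.fromkeys(topology.chain_ids))
    seg_of_chain = {c: k for k, c in enumerate(chains)}
    residue_seg = np.array([seg_of_chain[topology.chain_ids[i]] for i in res_first])
    u = mda.Universe.empty(
        n_atoms=n, n_residues=n_res, n_segments=len(chains),
        atom_resindex=mol, residue_segindex=residue_seg, trajectory=True)
    u.add_TopologyAttr("names", topology.names)
    u.add_TopologyAttr("elements", topology.elements)
    u.add_TopologyAttr("resnames", topology.resnames[res_first])
    u.add_TopologyAttr("resids", topology.resids[res_first])
    u.add_TopologyAttr("segids", np.array(chains))
    u.add_TopologyAttr("chainIDs", np.array([c[:1] for c in topology.chain_ids]))
    u.atoms.positions = coords
    return u


def write_structure(topology: Topology, frame: Frame, path) -> None:
    """Write a single-frame PDB (or any format MDAnalysis infers from suffix)."""
    u = _mda_universe(topology, frame.coords)
    if frame.box is not None:
        u.dimensions = [*frame.box, 90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory (multi-model PDB, DCD, XTC, TRR by suffix)."""
    import MDAnalysis as mda

    u = _mda_universe(traj.topology, traj.coords[0])
    if traj.box is not None:
        u.dimensions = [*traj.box, 90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.topology.n_atoms,
                        multiframe=True) as w:
            for i in range(traj.n_frames):
                u.atoms.positions = traj.coords[i]
                u.trajectory.ts.time = traj.times[i] * 1000.0
                w.write(u.atoms)


# --- OpenDX scalar fields -------------------------------------------------

def write_density_grid(values: np.ndarray, origin, spacing, path) -> None:
    """Write a 3-D scalar field as an OpenDX file.

    ``origin`` is the centre of voxel (0,0,0); ``spacing`` a scalar or
    3-vector of uniform voxel edge lengths.
    """
    from gridData import Grid

    values = np.asarray(values, float)
    if values.ndim != 3 or values.size == 0:
        raise UnsupportedGridError("grid must be a non-empty 3-D array")
    delta = np.atleast_1d(np.asarray(spacing, float))
    if delta.size == 1:
        delta = np.repeat(delta, 3)
    if delta.size != 3 or np.any(delta <= 0):
        raise UnsupportedGridError("spacing must be positive and uniform per axis")
    g = Grid(values, origin=np.asarray(origin, float), delta=delta)
    g.export(str(path), file_format="dx")


def read_density_grid(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read an OpenDX scalar field; returns (values, origin, spacing)."""
    from gridData import Grid

    if not os.path.exists(str(path)):
        raise FormatError(f"no such grid file: {path}")
    try:
        g = Grid(str(path))
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"could not parse grid file {path}: {exc}") from exc
    return np.asarray(g.grid, float), np.asarray(g.origin, float), np.asarray(g.delta, float)
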