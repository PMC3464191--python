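"""End-to-end pipeline: align -> RMSD/kink -> pore -> cavities -> occupancy
-> kinetics -> statistics.

The configuration carries every tunable the stages accept (strides,
windows, thresholds, Monte-Carlo iterations, seeds); ``run_pipeline``
executes the stages in order on either a synthetic-channel spec or a
trajectory read from files, writes CSV/JSON/OpenDX outputs under the
report directory, and returns the report as a dictionary.  A stage failure
raises with the stage name; outputs written before the failure remain on
disk.  Identical config + seeds give identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import ChanCavError
from .model import second_half_mask
from .geometry import (KinkSegments, ecd_domain, kink_angle_trajectory,
                       rmsd_series, tmd_domain, whole_protein_domain)
from .pore import constriction_summary, profile_heatmap
from .cavities import (classify_cavities, consensus_cavities,
                       dilate_region, mc_volume, polar_surface_fraction,
                       symmetrize)
from .occupancy import density_map, occupancy_series
from .kinetics import binary_traces, estimate_exchange_time
from .stats import bin_paired_occupancy, cavity_table, paired_linear_fit


@dataclass
class PipelineConfig:
    """Every stage tunable in one place (units: Å, ns)."""

    # trajectory source: either a synthetic spec or files
    synthetic: bool = True
    n_frames: int = 200
    dt_ns: float = 1.0
    seed: int = 0
    structure_path: str | None = None
    trajectory_path: str | None = None
    species_rules: dict = field(default_factory=dict)
    # overrides applied to the synthetic ChannelSpec (nested dicts allowed
    # for ligand/lipid/water sub-specs)
    spec_overrides: dict = field(default_factory=dict)
    # geometry
    kink_bottom: tuple[int, int] = (221, 238)
    kink_top: tuple[int, int] = (238, 245)
    rmsd_window_fraction: float = 0.1
    # pore
    pore_stride_frames: int = 1
    pore_z_step: float = 0.5
    constriction_prime: int = 9
    constriction_window: float = 5.0
    # cavities
    cavity_stride_ns: float = 5.0
    freq_threshold: float = 0.20
    mc_iterations: int = 10_000
    probe_radius: float = 1.4
    tmd_z_range: tuple[float, float] = (-20.0, 15.0)
    region_dilation: int = 1
    # occupancy / densities
    density_resolution: float = 1.0
    window: str = "half2"
    # kinetics
    max_lag_fraction: float = 0.5
    bootstrap: int = 200
    # statistics
    bin_width_frames: int = 10

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ChanCavError(f"unknown config keys: {sorted(unknown)}")
        for key in ("kink_bottom", "kink_top", "tmd_z_range"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


class _Stage:
    """Context manager that renames any failure after its stage."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not isinstance(exc, KeyboardInterrupt):
            raise ChanCavError(f"pipeline stage {self.name!r} failed: {exc}") from exc
        return False


def _load_trajectory(cfg: PipelineConfig):
    if cfg.synthetic:
        from .synthetic import simulate_trajectory, spec_from_dict

        spec = spec_from_dict(cfg.spec_overrides, seed=cfg.seed)
        traj, truth = simulate_trajectory(spec, cfg.n_frames, cfg.dt_ns,
                                          seed=cfg.seed)
        return traj, truth
    from .io import read_structure, read_trajectory

    top, _ = read_structure(cfg.structure_path, cfg.species_rules or None,
                            default_species="ion")
    traj = read_trajectory(cfg.trajectory_path, top, dt=cfg.dt_ns)
    return traj, None


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Run all stages; write outputs under ``outdir``; return the report."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__,
                    "config": dataclasses.asdict(cfg)}

    with _Stage("load"):
        traj, truth = _load_trajectory(cfg)
        ref = traj.frame(0)

    with _Stage("geometry"):
        domains = {"whole": whole_protein_domain(), "ECD": ecd_domain(),
                   "TMD": tmd_domain()}
        rmsd_out = {}
        for name, dom in domains.items():
            try:
                df, (mean, sd) = rmsd_series(traj, ref, dom,
                                             fit_domain=whole_protein_domain(),
                                             window_fraction=cfg.rmsd_window_fraction)
            except ChanCavError:
                continue
            df.to_csv(out / f"rmsd_{name}.csv", index=False)
            rmsd_out[name] = {"trailing_mean_A": mean, "trailing_sd_A": sd}
        seg = KinkSegments(tuple(cfg.kink_bottom), tuple(cfg.kink_top))
        kink = kink_angle_trajectory(traj, seg)
        report["geometry"] = {
            "rmsd": rmsd_out,
            "kink_mean_deg": kink.mean, "kink_sd_deg": kink.sd,
            "kink_per_chain_deg": kink.per_chain}

    with _Stage("pore"):
        profile = profile_heatmap(traj, stride=cfg.pore_stride_frames,
                                  z_step=cfg.pore_z_step,
                                  z_range=cfg.tmd_z_range)
        np.savetxt(out / "pore_profile_matrix.csv",
                   np.column_stack([profile.times, profile.radii]),
                   delimiter=",",
                   header="time_ns," + ",".join(f"z={z:.2f}" for z in profile.z))
        cmean, csd = constriction_summary(profile, cfg.constriction_prime,
                                          cfg.constriction_window)
        report["pore"] = {"constriction_mean_A": cmean, "constriction_sd_A": csd}

    with _Stage("cavities"):
        grid, components = consensus_cavities(
            traj, stride_ns=cfg.cavity_stride_ns,
            freq_threshold=cfg.freq_threshold, z_range=cfg.tmd_z_range,
            probe=cfg.probe_radius)
        from .pore import align_to_pore_axis

        ref_aligned, _, _ = align_to_pore_axis(ref, traj.topology)
        cavities = classify_cavities(components, ref_aligned, traj.topology, grid)
        regions: dict[str, np.ndarray] = {}
        for cls in ("intra", "inter"):
            for k, vox in symmetrize(cavities, cls, grid).items():
                regions[f"{cls}_{k}"] = vox
        # per-frame volumes inside the fixed symmetrised regions, averaged
        # over the second half of the trajectory
        dil_regions = {
            cid: (dilate_region(vox, grid, cfg.region_dilation)
                  if cfg.region_dilation else vox)
            for cid, vox in regions.items()}
        half = np.flatnonzero(second_half_mask(traj.times))
        stride = max(1, int(round(cfg.cavity_stride_ns / traj.dt)))
        vol_frames = half[::stride]
        vol_series: dict[str, list[float]] = {cid: [] for cid in regions}
        for i in vol_frames:
            fr_i, _, _ = align_to_pore_axis(traj.frame(int(i)), traj.topology)
            for cid, dil in dil_regions.items():
                v, _ = mc_volume(dil, grid, n=cfg.mc_iterations,
                                 seed=cfg.seed + sum(ord(ch) for ch in cid)
                                 + 17 * int(i),
                                 frame=fr_i, topology=traj.topology,
                                 probe=cfg.probe_radius)
                vol_series[cid].append(v)
        cav_report = {}
        for cid, vox in regions.items():
            vols = np.asarray(vol_series[cid])
            cav_report[cid] = {"volume_A3": float(vols.mean()),
                               "volume_sd_A3": float(vols.std()),
                               "volume_se_A3": float(vols.std()
                                                     / np.sqrt(len(vols))),
                               "n_voxels": int(len(vox))}
        polar = {}
        for cls in ("intra", "inter"):
            members = [c for c in cavities if c.cls == cls]
            if members:
                template = max(members, key=lambda c: c.n_voxels)
                polar[cls] = polar_surface_fraction(
                    template, ref_aligned, traj.topology, probe=cfg.probe_radius)
        report["cavities"] = cav_report
        report["polar_surface_fraction"] = polar
        from .io import write_density_grid

        write_density_grid(grid.data.astype(float), grid.origin + grid.spacing / 2,
                           grid.spacing, out / "consensus_frequency.dx")

    with _Stage("occupancy"):
        centers = {cid: grid.centers(vox) for cid, vox in regions.items()}
        # occupancy is counted in the frame of the aligned grid: transform
        # region centres back is equivalent; synthetic frames are already
        # near-aligned, so counts use raw coordinates
        series, assignment, lig_ids = occupancy_series(traj, centers)
        win = second_half_mask(traj.times)
        per_cav, per_series = {}, {}
        for cid, s in series.items():
            summ = s.summary(win)
            per_cav[cid] = {"ligand": summ["ligand"], "water": summ["water"],
                            "lipid": summ["lipid"]}
            per_series[cid] = {"ligand": s.n_ligand[win],
                               "water": s.n_water[win],
                               "lipid": s.n_lipid[win]}
            s.to_frame().to_csv(out / f"occupancy_{cid}.csv", index=False)
        report["occupancy"] = {
            cid: {k: {"mean": v[0], "sd": v[1]} for k, v in d.items()}
            for cid, d in per_cav.items()}
        for species in ("ligand", "water", "lipid"):
            try:
                dm = density_map(traj, species, win,
                                 resolution=cfg.density_resolution)
            except ChanCavError:
                continue
            write_density_grid(dm.values, dm.origin + dm.spacing / 2.0,
                               dm.spacing, out / f"density_{species}.dx")

    with _Stage("kinetics"):
        cav_ids = list(regions.keys())
        kin_report = {}
        for cls in ("intra", "inter", "any"):
            sel = (None if cls == "any" else
                   [i for i, cid in enumerate(cav_ids) if cid.startswith(cls)])
            tr = binary_traces(assignment, lig_ids, sel, traj.dt, cls)
            if tr.n_traces == 0:
                continue
            max_lag = int(cfg.max_lag_fraction * traj.n_frames)
            try:
                fit = estimate_exchange_time(tr, max_lag=max_lag,
                                             n_bootstrap=cfg.bootstrap,
                                             seed=cfg.seed)
            except ChanCavError as exc:
                warnings.warn(f"kinetics fit for {cls} skipped: {exc}",
                              stacklevel=2)
                continue
            kin_report[cls] = {
                "tau_exchange_ns": fit.tau_exchange,
                "tau_slow_ns": fit.tau_slow, "tau_slow_se_ns": fit.tau_slow_se,
                "tau_fast_ns": fit.tau_fast, "tau_fast_se_ns": fit.tau_fast_se,
                "amp_slow": fit.amp_slow, "degenerate": bool(fit.degenerate),
                "bound_fraction": tr.bound_fraction,
                "n_traces": tr.n_traces}
            np.savetxt(out / f"autocorrelation_{cls}.csv",
                       np.column_stack([fit.lags, fit.C]), delimiter=",",
                       header="lag_ns,C")
        report["kinetics"] = kin_report

    with _Stage("statistics"):
        pairs_ll, pairs_wl = [], []
        bw = cfg.bin_width_frames * traj.dt
        for cid, s in series.items():
            t = s.times[win]
            if cid.startswith("intra"):
                pairs_ll.append(bin_paired_occupancy(
                    t, s.n_ligand[win], s.n_lipid[win], bw, cid))
            else:
                pairs_wl.append(bin_paired_occupancy(
                    t, s.n_ligand[win], s.n_water[win], bw, cid))
        stats_report = {}
        try:
            f = paired_linear_fit(pairs_ll)
            stats_report["lipid_vs_ligand_intra"] = {
                "slope": f.slope, "intercept": f.intercept, "r_squared": f.r_squared}
        except ChanCavError:
            pass
        try:
            f = paired_linear_fit(pairs_wl)
            stats_report["water_vs_ligand_inter"] = {
                "slope": f.slope, "intercept": f.intercept, "r_squared": f.r_squared}
        except ChanCavError:
            pass
        report["statistics"] = stats_report
        vol_tab = {cid: {"volume": (d.get("volume_A3", np.nan),
                                    d.get("volume_se_A3", np.nan))}
                   for cid, d in report["cavities"].items() if "volume_A3" in d}
        for cid, s in series.items():
            if cid in vol_tab:
                summ = s.summary(win)
                vol_tab[cid].update({"ligand": summ["ligand"],
                                     "water": summ["water"],
                                     "lipid": summ["lipid"]})
        for cls in ("intra", "inter"):
            sub = {c: v for c, v in vol_tab.items() if c.startswith(cls)}
            if sub:
                cavity_table(sub).to_csv(out / f"cavity_table_{cls}.csv")

    if truth is not None:
        report["ground_truth"] = {
            "true_volumes": truth.true_volumes,
            "kink_angles_deg": truth.kink_angles_deg,
            "bound_fraction": truth.bound_fraction(),
            "tau_bound": truth.tau_bound, "tau_unbound": truth.tau_unbound}

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report
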