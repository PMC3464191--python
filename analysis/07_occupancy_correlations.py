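"""Occupancy correlations: lipid-chain atoms and waters vs ligand count.

The generator displaces lipid chains from intra-subunit cavities and
waters from inter-subunit cavities when ligands are resident; time-binned
per-cavity pairs pooled over the five sites of a class should therefore
show negative slopes.  Writes results/occupancy_correlations.json.
"""

import json

import numpy as np

from common import RESULTS, ensure_dirs, study_trajectory

from chancav.cavities import VoidGrid
from chancav.model import second_half_mask
from chancav.occupancy import occupancy_series
from chancav.stats import bin_paired_occupancy, paired_linear_fit


def main():
    ensure_dirs()
    traj, truth = study_trajectory()
    origin = np.array([-20.0, -20.0, -20.0])
    grid = VoidGrid(origin, 1.0, np.zeros((40, 40, 36), bool))
    regions = {s.cavity_id: grid.centers(s.truth_voxels(origin, 1.0,
                                                        grid.shape))
               for s in truth.sites}
    series, _, _ = occupancy_series(traj, regions)
    win = second_half_mask(traj.times)

    out = {}
    for cls, other in (("intra", "lipid"), ("inter", "water")):
        pairs = []
        for cid, s in series.items():
            if not cid.startswith(cls):
                continue
            y = s.n_lipid if other == "lipid" else s.n_water
            pairs.append(bin_paired_occupancy(s.times[win], s.n_ligand[win],
                                              y[win], 10.0, cid))
        fit = paired_linear_fit(pairs)
        out[f"{other}_vs_ligand_{cls}"] = {
            "slope": fit.slope, "intercept": fit.intercept,
            "r_squared": fit.r_squared, "slope_se": fit.slope_se,
            "n_points": fit.n}
        print(f"{cls}: {other} vs ligand -> slope {fit.slope:.2f} "
              f"(SE {fit.slope_se:.2f}), R² = {fit.r_squared:.2f}")
    with open(RESULTS / "occupancy_correlations.json", "w") as fh:
        json.dump(out, fh, indent=1)


if __name__ == "__main__":
    main()
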