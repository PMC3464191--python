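"""Occupancy-correlation statistics and publication-style cavity tables.

Correlations between species occupancies (e.g. lipid-chain atoms vs ligand
molecules in the same cavity "at a given time") are computed on time-binned
per-cavity pairs: both series are block-averaged in aligned, non-overlapping
time bins and an ordinary least-squares line is fitted through the pooled
(x, y) points.  R² equals the squared Pearson correlation for simple OLS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AlignmentError, FitError


@dataclass
class PairedOccupancy:
    """Aligned, time-binned (x, y) averages for one cavity."""

    cavity_id: str
    x: np.ndarray
    y: np.ndarray
    bin_width_ns: float


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    slope_se: float
    intercept_se: float
    n: int


def bin_paired_occupancy(times: np.ndarray, x: np.ndarray, y: np.ndarray,
                         bin_width_ns: float,
                         cavity_id: str = "") -> PairedOccupancy:
    """Average two same-time-base series within aligned time bins.

    Bins with no data are dropped.  A bin width equal to the frame spacing
    reproduces the raw series.
    """
    times = np.asarray(times, float)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if not (len(times) == len(x) == len(y)):
        raise AlignmentError("series must share one time base")
    if bin_width_ns <= 0:
        raise AlignmentError("bin width must be positive")
    edges = np.arange(times[0], times[-1] + bin_width_ns, bin_width_ns)
    which = np.clip(np.digitize(times, edges) - 1, 0, len(edges) - 1)
    xs, ys = [], []
    for b in np.unique(which):
        m = which == b
        xs.append(x[m].mean())
        ys.append(y[m].mean())
    return PairedOccupancy(cavity_id, np.array(xs), np.array(ys), bin_width_ns)


def linear_fit(x: np.ndarray, y: np.ndarray) -> LinearFit:
    """Ordinary least squares y = slope·x + intercept with OLS standard
    errors; R² = 1 - SS_res/SS_tot (= squared Pearson r for simple OLS)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise FitError("linear fit needs at least 3 points")
    if np.ptp(x) == 0:
        raise FitError("x has zero variance")
    res = sps.linregress(x, y)
    return LinearFit(slope=float(res.slope), intercept=float(res.intercept),
                     r_squared=float(res.rvalue ** 2),
                     slope_se=float(res.stderr),
                     intercept_se=float(res.intercept_stderr), n=len(x))


def paired_linear_fit(pairs: list[PairedOccupancy]) -> LinearFit:
    """OLS over the pooled binned points of several cavities."""
    x = np.concatenate([p.x for p in pairs])
    y = np.concatenate([p.y for p in pairs])
    return linear_fit(x, y)


def cavity_table(per_cavity: dict[str, dict[str, tuple[float, float]]],
                 quantities: list[str] | None = None,
                 per_cavity_series: dict[str, dict[str, np.ndarray]] | None = None,
                 ) -> pd.DataFrame:
    """Publication-style table: rows = quantities, columns = cavities + Average.

    ``per_cavity`` maps cavity id -> {quantity: (mean, sd)}.  Cells are
    "mean±SD" strings.  The Average column is the mean of per-cavity means;
    its SD is the SD of the cavity-averaged time series when
    ``per_cavity_series`` (cavity id -> {quantity: series}) is supplied,
    otherwise the SD of the five means.  Missing cavities yield "missing".
    """
    cav_ids = list(per_cavity.keys())
    if quantities is None:
        seen: list[str] = []
        for d in per_cavity.values():
            for q in d:
                if q not in seen:
                    seen.append(q)
        quantities = seen
    rows = {}
    for q in quantities:
        cells = []
        means = []
        for cid in cav_ids:
            if q not in per_cavity[cid]:
                cells.append("missing")
                continue
            m, s = per_cavity[cid][q]
            cells.append(f"{m:.1f}±{s:.1f}")
            means.append(m)
        if means:
            avg = float(np.mean(means))
            if per_cavity_series is not None and all(
                    q in per_cavity_series.get(cid, {}) for cid in cav_ids):
                stacked = np.mean([per_cavity_series[cid][q] for cid in cav_ids],
                                  axis=0)
                sd = float(np.std(stacked))
            else:
                sd = float(np.std(means))
            cells.append(f"{avg:.1f}±{sd:.1f}")
        else:
            cells.append("missing")
        rows[q] = cells
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[*cav_ids, "Average"])
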