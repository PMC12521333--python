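"""Lung-field summaries and apico-basal gradient fits.

Per image and lung side, the segment-level MPI and FHPI values are
condensed into their mean and sample standard deviation (STDV-MPI and
STDV-FHPI): higher STDV-MPI means larger differences in air content among
the segments of that lung field, higher STDV-FHPI larger differences in
the focal heterogeneity pattern.  Group-level cell means per (side,
intercostal space) feed an ordinary least-squares line of cell mean
against space index 2..7 — the apico-basal gradient; its Pearson r is
tested with the exact t transform t = r sqrt((n-2)/(1-r^2)) on n-2 df,
two-sided.

Excluded segment measurements (QC flags, typically liver overlap of the
right basal segment) reduce the n of their cell / lung field; the patient
is never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import SIDES, SPACES

__all__ = [
    "LungFieldSummary",
    "GradientFit",
    "lung_field_summary",
    "summarize_cohort",
    "group_segment_means",
    "apicobasal_gradient",
    "gradient_table",
]


@dataclass
class LungFieldSummary:
    image_id: str
    side: str
    mean_mpi: float
    mean_fhpi: float
    stdv_mpi: float
    stdv_fhpi: float
    n_segments: int
    available: bool = True


@dataclass
class GradientFit:
    """OLS fit of per-space cell means against space index."""

    side: str
    group: str
    slope: float
    intercept: float
    r: float
    p: float
    n_points: int
    defined: bool = True


def lung_field_summary(measurements: pd.DataFrame, side: str) -> LungFieldSummary:
    """Summarize one image's segments on one side.

    ``measurements`` is the long-format frame of a single image.  Needs at
    least 2 non-excluded segments, otherwise the summary is marked
    unavailable (NaN statistics).
    """
    sub = measurements[(measurements["side"] == side) & (~measurements["excluded"])]
    image_id = str(measurements["image_id"].iloc[0]) if len(measurements) else ""
    n = len(sub)
    if n < 2:
        return LungFieldSummary(image_id, side, np.nan, np.nan, np.nan, np.nan, n, available=False)
    return LungFieldSummary(
        image_id=image_id,
        side=side,
        mean_mpi=float(sub["mpi"].mean()),
        mean_fhpi=float(sub["fhpi"].mean()),
        stdv_mpi=float(sub["mpi"].std(ddof=1)),
        stdv_fhpi=float(sub["fhpi"].std(ddof=1)),
        n_segments=n,
    )


def summarize_cohort(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per (image, side) lung-field summaries for a cohort measurement frame."""
    rows = []
    for image_id, g in measurements.groupby("image_id", sort=False):
        for side in SIDES:
            s = lung_field_summary(g, side)
            rows.append(
                {
                    "image_id": image_id,
                    "side": side,
                    "mean_mpi": s.mean_mpi,
                    "mean_fhpi": s.mean_fhpi,
                    "stdv_mpi": s.stdv_mpi,
                    "stdv_fhpi": s.stdv_fhpi,
                    "n_segments": s.n_segments,
                    "available": s.available,
                }
            )
    return pd.DataFrame(rows)


def group_segment_means(
    measurements: pd.DataFrame, metric: str = "mpi"
) -> pd.DataFrame:
    """Arithmetic mean of ``metric`` per (side, space) cell over patients.

    Excluded measurements are dropped first; a cell left empty is marked
    missing (NaN mean, n 0) and later skipped by the gradient fit.
    """
    if metric not in ("mpi", "fhpi"):
        raise ValueError("metric must be 'mpi' or 'fhpi'")
    usable = measurements[~measurements["excluded"]]
    rows = []
    for side in SIDES:
        for space in SPACES:
            cell = usable[(usable["side"] == side) & (usable["space"] == space)][metric]
            rows.append(
                {
                    "side": side,
                    "space": space,
                    "mean": float(cell.mean()) if len(cell) else np.nan,
                    "n_patients": int(len(cell)),
                }
            )
    return pd.DataFrame(rows)


def apicobasal_gradient(
    cell_means: pd.DataFrame, side: str, group: str = ""
) -> GradientFit:
    """Fit the apico-basal line for one side from a cell-means frame."""
    sub = cell_means[(cell_means["side"] == side) & cell_means["mean"].notna()]
    x = sub["space"].to_numpy(dtype=float)
    y = sub["mean"].to_numpy(dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError(f"apico-basal fit needs >= 3 cells, got {n} on side {side!r}")
    if np.ptp(y) == 0.0:
        # zero variance in the cell means: r is undefined, not 0
        return GradientFit(side, group, slope=0.0, intercept=float(y[0]), r=np.nan,
                           p=np.nan, n_points=n, defined=False)
    res = sps.linregress(x, y)
    return GradientFit(
        side=side,
        group=group,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p=float(res.pvalue),
        n_points=n,
    )


def gradient_table(
    measurements: pd.DataFrame,
    groups: pd.Series | None = None,
    metric: str = "mpi",
) -> pd.DataFrame:
    """Gradient fits per (group, side).

    ``groups`` maps image_id -> group label; omitted means one pooled group.
    """
    meas = measurements.copy()
    if groups is not None:
        meas["group"] = meas["image_id"].map(groups)
    else:
        meas["group"] = "all"
    rows = []
    for grp, g in meas.groupby("group", sort=False):
        cells = group_segment_means(g, metric=metric)
        for side in SIDES:
            fit = apicobasal_gradient(cells, side, group=str(grp))
            rows.append(
                {
                    "group": grp,
                    "side": side,
                    "metric": metric,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "r": fit.r,
                    "p": fit.p,
                    "n_points": fit.n_points,
                    "defined": fit.defined,
                }
            )
    return pd.DataFrame(rows)
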