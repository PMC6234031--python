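"""Per-cell intensity measurement, SMAD readouts, colony geometry, and population
summaries.

The two readouts used throughout are:

* ``nc_ratio`` — median nuclear reporter intensity divided by the median intensity in
  the perinuclear donut (the N/C ratio, a proxy for SMAD2/SMAD4 pathway activity);
* ``h2b_normalized`` — median nuclear reporter intensity divided by the median nuclear
  H2B intensity (used for SMAD1, which has no detectable cytoplasmic signal; the
  normalization compensates for cells moving through the imaged z-plane).

Dynamic curves are population averages per time point; no single-cell tracking.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .core import Colony, ImageStack, RadialProfile, Trajectory

__all__ = [
    "max_project",
    "measure_cells",
    "nc_ratio",
    "h2b_normalized",
    "detect_colony",
    "radial_profile",
    "average_profiles",
    "fraction_positive",
    "assemble_trajectory",
]

logger = logging.getLogger(__name__)


def max_project(stack, z_axis: int = 0):
    """Pixel-wise maximum-intensity projection over the z axis.

    Accepts an array with a z axis (default axis 0) or an ImageStack whose data has an
    extra leading z axis ``(z, t, c, y, x)``. A single z plane is returned unchanged
    (minus the z axis).
    """
    if isinstance(stack, ImageStack):
        return stack  # already 2-D frames; nothing to project
    arr = np.asarray(stack, dtype=float)
    if arr.shape[z_axis] == 1:
        return np.squeeze(arr, axis=z_axis)
    return arr.max(axis=z_axis)


def measure_cells(
    frame: dict,
    nuclear_labels: np.ndarray,
    donut_labels: np.ndarray | None = None,
    pixel_size_um: float = 1.0,
    time_hr: float = np.nan,
    reporter_channel: str = "reporter",
) -> pd.DataFrame:
    """Median per-cell intensities over nuclear and donut masks.

    ``frame`` maps channel name -> 2-D image (see :meth:`ImageStack.frame`). Returns
    one row per labeled nucleus with columns ``cell``, ``time_hr``, ``area_px``,
    ``row_px``/``col_px`` and ``x_um``/``y_um`` centroids, ``nuc_<channel>`` medians
    for every channel, and ``cyto_<reporter>`` (NaN where the donut is empty, flagged
    by ``donut_empty``).
    """
    nuclear_labels = np.asarray(nuclear_labels)
    n = int(nuclear_labels.max())
    if n == 0:
        cols = ["cell", "time_hr", "area_px", "row_px", "col_px", "x_um", "y_um"]
        cols += [f"nuc_{c}" for c in frame] + [f"cyto_{reporter_channel}", "donut_empty"]
        return pd.DataFrame(columns=cols)
    ids = np.arange(1, n + 1)
    areas = ndimage.sum_labels(np.ones_like(nuclear_labels), nuclear_labels, ids)
    centroids = np.asarray(ndimage.center_of_mass(
        np.ones_like(nuclear_labels), nuclear_labels, ids))
    out = pd.DataFrame(
        {
            "cell": ids,
            "time_hr": time_hr,
            "area_px": areas,
            "row_px": centroids[:, 0],
            "col_px": centroids[:, 1],
            "x_um": (centroids[:, 1] + 0.5) * pixel_size_um,
            "y_um": (centroids[:, 0] + 0.5) * pixel_size_um,
        }
    )
    for name, img in frame.items():
        out[f"nuc_{name}"] = _label_medians(np.asarray(img, dtype=float), nuclear_labels, n)
    if donut_labels is not None:
        rep = np.asarray(frame[reporter_channel], dtype=float)
        cyto = _label_medians(rep, np.asarray(donut_labels), n)
        out[f"cyto_{reporter_channel}"] = cyto
        out["donut_empty"] = np.isnan(cyto)
    return out


def _label_medians(image: np.ndarray, labels: np.ndarray, n: int) -> np.ndarray:
    """Median image value per label 1..n (NaN for absent labels)."""
    flat_l = labels.ravel()
    sel = flat_l > 0
    df = pd.DataFrame({"label": flat_l[sel], "value": image.ravel()[sel]})
    med = df.groupby("label")["value"].median()
    out = np.full(n, np.nan)
    idx = med.index.to_numpy()
    idx = idx[idx <= n]
    out[idx - 1] = med.loc[idx].to_numpy()
    return out


def nc_ratio(records: pd.DataFrame, reporter_channel: str = "reporter") -> pd.Series:
    """Per-cell nuclear/cytoplasmic median reporter ratio.

    Cells with an empty donut or non-positive cytoplasmic median are returned as NaN;
    the number excluded is logged.
    """
    nuc = records[f"nuc_{reporter_channel}"]
    cyto = records[f"cyto_{reporter_channel}"]
    valid = cyto.notna() & (cyto > 0)
    n_excluded = int((~valid).sum())
    if n_excluded:
        logger.info("nc_ratio: excluded %d cells with empty/zero cytoplasmic mask", n_excluded)
    out = pd.Series(np.nan, index=records.index, name="nc_ratio")
    out[valid] = nuc[valid] / cyto[valid]
    return out


def h2b_normalized(
    records: pd.DataFrame,
    reporter_channel: str = "reporter",
    h2b_channel: str = "H2B",
) -> pd.Series:
    """Median nuclear reporter signal normalized to the median nuclear H2B signal."""
    h2b = records[f"nuc_{h2b_channel}"]
    valid = h2b.notna() & (h2b > 0)
    n_excluded = int((~valid).sum())
    if n_excluded:
        logger.info("h2b_normalized: excluded %d cells with zero H2B", n_excluded)
    out = pd.Series(np.nan, index=records.index, name="h2b_normalized")
    out[valid] = records.loc[valid, f"nuc_{reporter_channel}"] / h2b[valid]
    return out


def detect_colony(centroids_um: np.ndarray, nucleus_radius_um: float = 0.0) -> Colony:
    """Least-squares circle fit to the convex hull of cell centroids.

    At least 10 cells are required; collinear centroids are rejected. The algebraic
    (Kasa) fit is exact for points on a true circle. ``nucleus_radius_um``, when
    known, is added to the fitted radius (the colony edge lies about one nucleus
    radius beyond the outermost nucleus centers).
    """
    pts = np.asarray(centroids_um, dtype=float).reshape(-1, 2)
    if len(pts) < 10:
        raise ValueError("colony detection needs >= 10 cells")
    try:
        hull = ConvexHull(pts)
    except QhullError as e:
        raise ValueError("degenerate (collinear) centroids") from e
    p = pts[hull.vertices]
    # Kasa fit: minimize |x^2 + y^2 - 2ax - 2by - c|
    A = np.column_stack([2 * p[:, 0], 2 * p[:, 1], np.ones(len(p))])
    b = (p**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    radius = float(np.sqrt(c + cx**2 + cy**2))
    resid = float(np.sqrt(np.mean((np.hypot(p[:, 0] - cx, p[:, 1] - cy) - radius) ** 2)))
    return Colony(center_um=(float(cx), float(cy)),
                  radius_um=radius + nucleus_radius_um, fit_residual_um=resid)


def _edge_bins(df: pd.DataFrame, colony: Colony, bin_width_um: float, from_edge: bool):
    """Bin index per cell plus (edges, n_bins, n_clipped)."""
    cx, cy = colony.center_um
    r = np.hypot(df["x_um"] - cx, df["y_um"] - cy)
    d = colony.radius_um - r if from_edge else r
    n_bins = max(int(np.ceil(colony.radius_um / bin_width_um)), 1)
    edges = np.arange(n_bins + 1) * bin_width_um
    clipped = int((d < 0).sum())
    idx = np.floor(np.maximum(d, 0.0) / bin_width_um).astype(int)
    idx = np.minimum(idx, n_bins - 1)  # last bin closed
    return idx, edges, n_bins, clipped


def radial_profile(
    records: pd.DataFrame,
    colony: Colony,
    readout: str,
    bin_width_um: float = 25.0,
    from_edge: bool = True,
) -> RadialProfile:
    """Bin cells by radial position and average the readout per bin.

    Distance is measured from the colony edge by default (``from_edge=False`` bins by
    distance from the center instead). Bins are half-open ``[k w, (k+1) w)`` with the
    last bin closed; cells whose centroid falls outside the fitted circle are assigned
    to the edge bin and counted in ``clipped_cells``. SD is the sample (n-1) SD
    across cells within the bin.
    """
    df = records.dropna(subset=[readout])
    if df.empty:
        n_bins = max(int(np.ceil(colony.radius_um / bin_width_um)), 1)
        edges = np.arange(n_bins + 1) * bin_width_um
        nan_arr = np.full(n_bins, np.nan)
        return RadialProfile(edges, nan_arr, nan_arr.copy(), np.zeros(n_bins, dtype=int),
                             n_colonies=1, readout=readout)
    idx, edges, n_bins, clipped = _edge_bins(df, colony, bin_width_um, from_edge)
    vals = df[readout].to_numpy()
    mean = np.full(n_bins, np.nan)
    sd = np.full(n_bins, np.nan)
    n_cells = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        v = vals[idx == b]
        n_cells[b] = len(v)
        if len(v):
            mean[b] = v.mean()
            sd[b] = v.std(ddof=1) if len(v) > 1 else 0.0
    return RadialProfile(edges, mean, sd, n_cells, n_colonies=1, readout=readout,
                         clipped_cells=clipped)


def average_profiles(profiles) -> RadialProfile:
    """Average per-colony radial profiles bin by bin (equal colony weighting).

    All profiles must share bin edges. The returned SD is the sample SD across
    colonies (NaN for a single colony).
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to average")
    edges = profiles[0].bin_edges
    for p in profiles[1:]:
        if len(p.bin_edges) != len(edges) or not np.allclose(p.bin_edges, edges):
            raise ValueError("profiles have mismatched binning")
    stacked = np.vstack([p.mean for p in profiles])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stacked, axis=0)
    if len(profiles) > 1:
        sd = np.nanstd(stacked, axis=0, ddof=1)
    else:
        sd = np.full(stacked.shape[1], np.nan)
    n_cells = np.sum([p.n_cells for p in profiles], axis=0)
    return RadialProfile(edges, mean, sd, n_cells, n_colonies=len(profiles),
                         readout=profiles[0].readout)


def fraction_positive(
    records: pd.DataFrame,
    readout: str,
    threshold: float,
    colony: Colony | None = None,
    bin_width_um: float = 25.0,
    from_edge: bool = True,
) -> pd.DataFrame:
    """Fraction of cells whose readout exceeds a threshold (binary analysis).

    With a colony the fraction is reported per radial bin (NaN where a bin is empty,
    with ``n`` recording the bin occupancy); without one a single overall row is
    returned.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    df = records.dropna(subset=[readout])
    if colony is None:
        n = len(df)
        frac = float((df[readout] > threshold).mean()) if n else np.nan
        return pd.DataFrame({"bin_lo_um": [np.nan], "bin_hi_um": [np.nan],
                             "fraction": [frac], "n": [n]})
    idx, edges, n_bins, _ = _edge_bins(df, colony, bin_width_um, from_edge)
    pos = (df[readout] > threshold).to_numpy()
    rows = []
    for b in range(n_bins):
        sel = idx == b
        n = int(sel.sum())
        rows.append(
            {
                "bin_lo_um": edges[b],
                "bin_hi_um": edges[b + 1],
                "fraction": float(pos[sel].mean()) if n else np.nan,
                "n": n,
            }
        )
    return pd.DataFrame(rows)


def assemble_trajectory(
    records: pd.DataFrame,
    readout: str,
    condition: str = "",
    dose_ng_ml: float = np.nan,
) -> Trajectory:
    """Population mean +/- SD of a readout per time point.

    ``records`` is a concatenation of per-frame cell tables carrying ``time_hr``.
    Time points with no valid cell are kept with NaN mean/SD and n = 0 (flagged).
    """
    if "time_hr" not in records:
        raise ValueError("records must carry a time_hr column")
    times = np.sort(records["time_hr"].unique())
    if times.size == 0:
        raise ValueError("no frames to assemble")
    means, sds, ns = [], [], []
    for t in times:
        v = records.loc[records["time_hr"] == t, readout].dropna().to_numpy()
        ns.append(len(v))
        if len(v):
            means.append(v.mean())
            sds.append(v.std(ddof=1) if len(v) > 1 else 0.0)
        else:
            logger.warning("assemble_trajectory: no valid cells at t=%s hr", t)
            means.append(np.nan)
            sds.append(np.nan)
    return Trajectory(
        times_hr=times, mean=np.asarray(means), sd=np.asarray(sds),
        n_cells=np.asarray(ns), readout=readout, condition=condition,
        dose_ng_ml=dose_ng_ml,
    )
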