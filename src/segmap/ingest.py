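"""Filtering, segment snapping and drive-pass aggregation.

Turns raw 1 Hz records into the data-only map: physically plausible
records are kept, snapped to the nearest street segment, averaged per
segment and driving day (one drive-pass each), and summarised per
segment as an unweighted mean of drive-pass means with its standard
error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry import Point

from segmap.synthetic import StreetNetwork


@dataclass(frozen=True)
class FilterReport:
    """Bookkeeping for the plausibility filter."""

    n_input: int
    n_kept: int
    n_below: int
    n_above: int

    def __post_init__(self) -> None:
        assert self.n_kept + self.n_below + self.n_above == self.n_input


def filter_range(
    records: pd.DataFrame,
    *,
    low: float = 0.0,
    high: float = 500.0,
    value_col: str = "no2_ugm3",
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop records outside [low, high] ug/m3 (bounds inclusive).

    Concentrations strictly below ``low`` or strictly above ``high`` are
    physically implausible for on-road NO2 and removed; order of the
    surviving records is preserved. Returns the filtered frame and a
    report with per-bound removal counts.
    """
    vals = records[value_col].to_numpy()
    below = vals < low
    above = vals > high
    keep = ~(below | above)
    report = FilterReport(
        n_input=len(records),
        n_kept=int(keep.sum()),
        n_below=int(below.sum()),
        n_above=int(above.sum()),
    )
    return records.loc[keep].reset_index(drop=True), report


def _looks_like_degrees(x: np.ndarray, y: np.ndarray) -> bool:
    if len(x) == 0:
        return False
    return bool(
        (np.abs(x) <= 180).all() and (np.abs(y) <= 90).all() and np.ptp(x) < 10
    )


def snap_points(
    x: np.ndarray,
    y: np.ndarray,
    network: StreetNetwork,
    max_dist: float = 50.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each point to its nearest street segment.

    Distance is the point-to-polyline distance; points farther than
    ``max_dist`` from every segment are unassigned (-1). Exact distance
    ties break toward the smaller segment_id, so the assignment is
    deterministic.

    Returns (segment_id array with -1 for unassigned, distance array with
    NaN for unassigned).
    """
    if len(network) == 0:
        raise ValueError("cannot snap to an empty network")
    if max_dist <= 0:
        raise ValueError("max_dist must be > 0")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    seg_ids = network.segment_ids
    geoms = np.asarray(network.segments["geometry"].to_list(), dtype=object)
    tree = STRtree(geoms)
    import shapely

    pts = shapely.points(np.column_stack([x, y]))

    out_id = np.full(len(x), -1, dtype=np.int64)
    out_d = np.full(len(x), np.nan)
    if len(pts) == 0:
        return out_id, out_d

    pt_idx, geom_idx = tree.query_nearest(
        pts, max_distance=max_dist, all_matches=True
    )
    if len(pt_idx) == 0:
        return out_id, out_d
    from shapely import distance as _sdist

    d = _sdist(pts[pt_idx], geoms[geom_idx])
    cand_ids = seg_ids[geom_idx]
    # Per point: minimal distance, then minimal segment_id among ties.
    order = np.lexsort((cand_ids, d, pt_idx))
    pt_sorted = pt_idx[order]
    first = np.ones(len(order), dtype=bool)
    first[1:] = pt_sorted[1:] != pt_sorted[:-1]
    sel = order[first]
    out_id[pt_idx[sel]] = cand_ids[sel]
    out_d[pt_idx[sel]] = d[sel]
    return out_id, out_d


def snap_to_segment(
    x: float, y: float, network: StreetNetwork, max_dist: float = 50.0
) -> int | None:
    """Nearest segment_id for a single point, or None if beyond max_dist."""
    ids, _ = snap_points(np.array([x]), np.array([y]), network, max_dist)
    return None if ids[0] < 0 else int(ids[0])


def snap_records(
    records: pd.DataFrame,
    network: StreetNetwork,
    max_dist: float = 50.0,
    *,
    drop_unassigned: bool = True,
) -> pd.DataFrame:
    """Snap a measurement frame; adds segment_id and snap_dist_m columns."""
    ids, d = snap_points(
        records["x"].to_numpy(), records["y"].to_numpy(), network, max_dist
    )
    out = records.copy()
    out["segment_id"] = ids
    out["snap_dist_m"] = d
    if drop_unassigned:
        out = out.loc[out["segment_id"] >= 0].reset_index(drop=True)
    return out


def aggregate_passes(records: pd.DataFrame) -> pd.DataFrame:
    """Average records per (segment, calendar day): one drive-pass each.

    Returns columns segment_id, pass_date, mean_concentration, n_seconds.
    """
    df = records.copy()
    df["pass_date"] = pd.to_datetime(df["timestamp"]).dt.normalize()
    grouped = (
        df.groupby(["segment_id", "pass_date"], sort=True)["no2_ugm3"]
        .agg(mean_concentration="mean", n_seconds="count")
        .reset_index()
    )
    return grouped


def summarize_segments(pass_means: pd.DataFrame) -> pd.DataFrame:
    """Mean of drive-pass means per segment, with pass count and SEM.

    The mean of means is unweighted over passes (pass durations do not
    weight it). SEM is the sample sd of the pass means (ddof=1) divided
    by sqrt(n_passes); NaN marks segments with a single pass, where the
    between-pass spread is not estimable.
    """
    g = pass_means.groupby("segment_id", sort=True)["mean_concentration"]
    out = g.agg(mean_of_means="mean", n_passes="count", sd="std")
    out["sem"] = out.pop("sd") / np.sqrt(out["n_passes"])
    return out.reset_index()
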