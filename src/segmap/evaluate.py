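"""Validation of map products against external point datasets.

Matches each external point (e.g. a passive-sampler site or a dispersion
model receptor) to its nearest street segment within a radius (default
20 m) and computes the comparison battery: Spearman rank correlation,
RMSE, mean bias, mean relative bias, and a Bland-Altman summary, plus a
five-number distribution block per map product.

Bias convention: mean bias is reported as mean(test - map... strictly
``mean(test - ref)`` where ``ref`` is the external value and ``test``
the map product, so a positive bias means the map sits above the
external data. The convention is recorded in every report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from segmap.ingest import _looks_like_degrees, snap_points
from segmap.synthetic import StreetNetwork

BIAS_CONVENTION = "mean_bias = mean(test - ref); positive => map above external data"


@dataclass
class MetricReport:
    """Agreement metrics for one (map product x external dataset) pair."""

    n: int
    spearman_r: float
    rmse: float
    mean_bias: float
    mean_relative_bias_pct: float
    ba_mean_diff: float
    ba_loa_low: float
    ba_loa_high: float
    ba_slope: float
    bias_convention: str = BIAS_CONVENTION

    def __post_init__(self) -> None:
        assert self.rmse >= abs(self.mean_bias) - 1e-9

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "spearman_r": self.spearman_r,
            "rmse": self.rmse,
            "mean_bias": self.mean_bias,
            "mean_relative_bias_pct": self.mean_relative_bias_pct,
            "bland_altman": {
                "mean_diff": self.ba_mean_diff,
                "loa_low": self.ba_loa_low,
                "loa_high": self.ba_loa_high,
                "slope": self.ba_slope,
            },
            "bias_convention": self.bias_convention,
        }


def match_points(
    external_points: pd.DataFrame,
    network: StreetNetwork,
    radius: float = 20.0,
) -> pd.DataFrame:
    """Match each external point to its nearest segment within ``radius``.

    Both inputs must be in the same planar metre coordinates; inputs that
    look like lon/lat degrees are rejected. Points farther than the
    radius from every segment are excluded; exact-distance ties break to
    the smaller segment_id. Returns columns external_id, segment_id,
    distance_m, ref_value.
    """
    x = external_points["x"].to_numpy(float)
    y = external_points["y"].to_numpy(float)
    net_xy = np.concatenate(
        [np.asarray(g.coords) for g in network.segments["geometry"]]
    )
    if _looks_like_degrees(x, y) and np.ptp(net_xy[:, 0]) > 1000:
        raise ValueError(
            "external point coordinates look like lon/lat degrees but the "
            "network is in planar metres; reproject the points first"
        )
    ids, dist = snap_points(x, y, network, max_dist=radius)
    keep = ids >= 0
    return pd.DataFrame(
        {
            "external_id": external_points["id"].to_numpy()[keep],
            "segment_id": ids[keep],
            "distance_m": dist[keep],
            "ref_value": external_points["value"].to_numpy(float)[keep],
        }
    )


def compute_metrics(pairs: pd.DataFrame) -> MetricReport:
    """Agreement battery on matched (ref_value, test_value) pairs.

    Spearman uses average ranks on ties; RMSE = sqrt(mean((ref-test)^2));
    mean bias = mean(test - ref); relative bias = mean bias / mean(ref)
    in percent. Bland-Altman summarises diff = test - ref against the
    pair average (slope needs n >= 3, NaN below that).
    """
    n = len(pairs)
    if n < 2:
        raise ValueError(f"need at least 2 matched pairs, got {n}")
    ref = pairs["ref_value"].to_numpy(float)
    test = pairs["test_value"].to_numpy(float)
    diff = test - ref
    if np.ptp(ref) == 0 or np.ptp(test) == 0:
        rs = np.nan  # rank correlation undefined for a constant input
    else:
        rs = stats.spearmanr(ref, test).statistic
    rmse = float(np.sqrt(np.mean(diff**2)))
    mean_bias = float(diff.mean())
    rel = mean_bias / ref.mean() * 100.0 if ref.mean() != 0 else np.nan
    sd = float(diff.std(ddof=1))
    avg = (ref + test) / 2.0
    if n >= 3 and np.ptp(avg) > 0:
        slope = float(np.polyfit(avg, diff, 1)[0])
    else:
        slope = np.nan
    return MetricReport(
        n=n,
        spearman_r=float(rs),
        rmse=rmse,
        mean_bias=mean_bias,
        mean_relative_bias_pct=float(rel),
        ba_mean_diff=mean_bias,
        ba_loa_low=mean_bias - 1.96 * sd,
        ba_loa_high=mean_bias + 1.96 * sd,
        ba_slope=slope,
    )


def summary_block(values: pd.Series | np.ndarray) -> dict[str, float]:
    """Five-number summary (linear-interpolation quartiles)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    qs = np.percentile(v, [0, 25, 50, 75, 100], method="linear")
    return dict(zip(["min", "q1", "median", "q3", "max"], map(float, qs)))


@dataclass
class ComparisonTable:
    """All (product x external set) metric reports plus map summaries."""

    reports: dict[tuple[str, str], MetricReport]   # (external, product)
    summaries: dict[str, dict[str, float]]         # product -> 5-number
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "comparisons": {
                f"{ext}|{prod}": rep.to_dict()
                for (ext, prod), rep in self.reports.items()
            },
            "map_summaries": self.summaries,
            "warnings": self.warnings,
        }

    def to_text(self) -> str:
        lines = []
        header = f"{'external':<12}{'product':<12}{'n':>6}{'r_s':>8}{'RMSE':>8}{'bias':>8}{'rel%':>8}"
        for ext in sorted({e for e, _ in self.reports}):
            lines.append(f"Comparison to {ext}")
            lines.append(header)
            for (e, prod), r in self.reports.items():
                if e != ext:
                    continue
                lines.append(
                    f"{e:<12}{prod:<12}{r.n:>6d}{r.spearman_r:>8.2f}"
                    f"{r.rmse:>8.2f}{r.mean_bias:>8.2f}{r.mean_relative_bias_pct:>8.1f}"
                )
            lines.append("")
        lines.append("Map distributions (ug/m3)")
        lines.append(f"{'product':<12}{'min':>8}{'q1':>8}{'median':>8}{'q3':>8}{'max':>8}")
        for prod, s in self.summaries.items():
            lines.append(
                f"{prod:<12}{s['min']:>8.1f}{s['q1']:>8.1f}{s['median']:>8.1f}"
                f"{s['q3']:>8.1f}{s['max']:>8.1f}"
            )
        return "\n".join(lines)


def compare_products(
    maps: dict[str, pd.Series],
    external_sets: dict[str, pd.DataFrame],
    network: StreetNetwork,
    radius: float = 20.0,
) -> ComparisonTable:
    """Run the full metric battery for every map product x external set.

    ``maps`` holds per-segment value Series (indexed by segment_id), e.g.
    {"data_only": ..., "lur": ..., "mixed": ...}; ``external_sets`` holds
    point frames with columns id, x, y, value. Empty external sets yield
    a warning and no report rather than an error.
    """
    reports: dict[tuple[str, str], MetricReport] = {}
    warns: list[str] = []
    for ext_name, pts in external_sets.items():
        if len(pts) == 0:
            msg = f"external set {ext_name!r} is empty; skipped"
            warnings.warn(msg, stacklevel=2)
            warns.append(msg)
            continue
        matched = match_points(pts, network, radius)
        if len(matched) == 0:
            msg = f"external set {ext_name!r}: no point within {radius} m of any segment"
            warnings.warn(msg, stacklevel=2)
            warns.append(msg)
            continue
        for prod_name, series in maps.items():
            pairs = matched.assign(
                test_value=series.reindex(matched["segment_id"]).to_numpy()
            ).dropna(subset=["test_value"])
            reports[(ext_name, prod_name)] = compute_metrics(pairs)
    summaries = {name: summary_block(s) for name, s in maps.items()}
    return ComparisonTable(reports=reports, summaries=summaries, warnings=warns)
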