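"""Temporal correction of mobile records against a reference station.

Mobile campaigns sample each street at a handful of moments; a fixed
reference station records around the clock for the whole period. The
difference between the station's overall mean and its mean within a
record's time window estimates the sampling-time bias, and adding it to
the record makes segment averages reflect long-term concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class WindowSpec:
    """Time-window definition: hour-of-day bins crossed with a day grouping.

    ``hour_bin_h`` is the bin width in hours (1 gives hourly bins);
    ``day_grouping`` is one of "weekday_weekend", "day_of_week" or "all".
    """

    hour_bin_h: int = 1
    day_grouping: str = "weekday_weekend"

    def __post_init__(self) -> None:
        if not (1 <= self.hour_bin_h <= 24) or 24 % self.hour_bin_h:
            raise ValueError("hour_bin_h must divide 24")
        if self.day_grouping not in ("weekday_weekend", "day_of_week", "all"):
            raise ValueError(f"unknown day_grouping {self.day_grouping!r}")

    def keys(self, timestamps) -> pd.Series:
        """Window key ('<day>|h<bin-start>') for each timestamp."""
        ts = pd.to_datetime(pd.Series(np.asarray(timestamps)))
        hour_bin = (ts.dt.hour // self.hour_bin_h) * self.hour_bin_h
        if self.day_grouping == "weekday_weekend":
            day = np.where(ts.dt.dayofweek < 5, "wd", "we")
        elif self.day_grouping == "day_of_week":
            day = ts.dt.dayofweek.astype(str).to_numpy()
        else:
            day = np.full(len(ts), "all")
        return pd.Series(
            np.char.add(np.char.add(day.astype(str), "|h"),
                        hour_bin.to_numpy().astype(str)),
            index=ts.index,
        )


@dataclass
class WindowTable:
    """Per-window reference means plus the overall reference mean."""

    window_means: pd.Series    # indexed by window key
    overall_mean: float
    spec: WindowSpec
    n_per_window: pd.Series


def build_window_table(
    reference: pd.DataFrame, spec: WindowSpec = WindowSpec()
) -> WindowTable:
    """Tabulate reference means per time window and overall.

    The overall mean is the plain mean of the (fixed-cadence) reference
    records — i.e. duration-weighted over the full period including
    nights and weekends — not a mean of window means.
    """
    if len(reference) == 0:
        raise ValueError("reference series is empty")
    vals = reference["no2_ugm3"].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("reference series contains non-finite values")
    keys = spec.keys(reference["timestamp"])
    g = pd.Series(vals).groupby(keys.to_numpy())
    return WindowTable(
        window_means=g.mean(),
        overall_mean=float(vals.mean()),
        spec=spec,
        n_per_window=g.count(),
    )


def correct(
    records: pd.DataFrame,
    table: WindowTable,
    *,
    mode: str = "additive",
    value_col: str = "no2_ugm3",
) -> pd.DataFrame:
    """Apply the reference-station correction to every record.

    additive (default): corrected = measured + (overall - window mean);
    ratio: corrected = measured * overall / window mean. Order-preserving;
    raises if any record falls in a window the reference never observed.
    """
    if mode not in ("additive", "ratio"):
        raise ValueError(f"unknown correction mode {mode!r}")
    keys = table.spec.keys(records["timestamp"]).to_numpy()
    wm = table.window_means.reindex(keys).to_numpy()
    if np.isnan(wm).any():
        missing = sorted(set(keys[np.isnan(wm)]))
        raise ValueError(
            f"no reference data for time window(s) {missing}; "
            "cannot correct records in an unobserved window"
        )
    out = records.copy()
    if mode == "additive":
        out[value_col] = records[value_col].to_numpy() + (table.overall_mean - wm)
    else:
        if (wm <= 0).any():
            raise ValueError("ratio correction needs positive window means")
        out[value_col] = records[value_col].to_numpy() * (table.overall_mean / wm)
    return out
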