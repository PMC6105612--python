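"""Ratiometric normalization of ROI time series to a photostable standard.

Every ROI mean at time ``t`` is divided by the reference standard's mean at
the same ``t`` and scaled to a nominal percent value (default 10%, i.e. the
reference is declared to sit at a constant nominal 10% fluorescence
intensity).  Because the division is per time point, any multiplicative
per-frame factor — lamp fluctuation, exposure change, ambient light gain —
cancels exactly.  Field-of-view inhomogeneity is *not* corrected: ROIs at
different positions see different excitation and that ratio survives
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quantify import ROITimeSeries


class NormalizationError(ValueError):
    """Raised when the reference ROI cannot serve as a denominator."""


@dataclass
class NormalizedSeries:
    """ROI time series on the normalized percent scale."""

    table: pd.DataFrame  # roi, label, time_min, mean, sd, normalized_pct
    reference_id: str
    nominal_pct: float
    times_min: tuple[float, ...]

    def normalized_series(self, roi_id: str) -> pd.Series:
        sub = self.table[self.table["roi"] == roi_id].sort_values("time_min")
        if sub.empty:
            raise KeyError(f"no ROI with id {roi_id!r}")
        return pd.Series(sub["normalized_pct"].to_numpy(),
                         index=sub["time_min"].to_numpy())


def ratiometric_normalize(ts: ROITimeSeries, reference_id: str,
                          nominal_pct: float = 10.0) -> NormalizedSeries:
    """Normalize every ROI mean to the reference standard, per time point.

    ``norm(roi, t) = nominal_pct * mean(roi, t) / mean(reference, t)``.
    The reference ROI maps to exactly ``nominal_pct`` at every time point.

    Raises
    ------
    NormalizationError
        If the reference ROI is absent or its mean is <= 0 at any time
        point (the offending time is named).
    """
    df = ts.table.copy()
    ref = df[df["roi"] == reference_id]
    if ref.empty:
        raise NormalizationError(f"reference ROI {reference_id!r} not present")
    bad = ref[ref["mean"] <= 0]
    if not bad.empty:
        t = bad["time_min"].iloc[0]
        raise NormalizationError(
            f"reference ROI {reference_id!r} has non-positive mean at t={t} min")

    ref_by_time = ref.set_index("time_min")["mean"]
    df["normalized_pct"] = (
        nominal_pct * df["mean"].to_numpy()
        / ref_by_time.loc[df["time_min"]].to_numpy()
    )
    return NormalizedSeries(table=df, reference_id=reference_id,
                            nominal_pct=float(nominal_pct), times_min=ts.times_min)


def normalized_to_timeseries(ns: NormalizedSeries) -> ROITimeSeries:
    """Re-wrap a normalized series as a plain time series (normalized_pct as
    the mean), e.g. to feed the kinetics fitters or re-normalize."""
    df = ns.table[["roi", "label", "time_min"]].copy()
    df["mean"] = ns.table["normalized_pct"]
    df["sd"] = np.nan
    return ROITimeSeries(table=df, times_min=ns.times_min)


def write_normalized_csv(ns: NormalizedSeries, path, specimen: int | str = 0) -> None:
    """CSV with the quantify schema plus ``normalized_pct``; header comment
    names the reference."""
    df = ns.table.copy()
    df.insert(0, "specimen", specimen)
    with open(path, "w") as fh:
        fh.write(f"# reference={ns.reference_id} nominal_pct={ns.nominal_pct} "
                 f"schema_version=1\n")
        df.to_csv(fh, index=False)


def read_normalized_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
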