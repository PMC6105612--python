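"""Photobleaching kinetics: logarithmic decay fits and summary statistics.

Fluorescence loss under continuous excitation is modelled as
``y = c * ln(x) + y0`` with ``x`` in minutes; ``c`` (negative for decay) is
the bleaching coefficient and ``y0`` the intercept.  Goodness of fit is the
Cox–Snell pseudo-R^2, ``1 - (L0 / L1)^(2/n)`` with Gaussian likelihoods —
which for an ordinary least-squares fit equals the classical
``1 - SSE/SST`` exactly (the ML variance estimates make the likelihood
ratio collapse to the error-variance ratio).

A logarithmic decay has no finite half-life from t=0, so the half-life
reported for a trajectory uses the two-point exponential convention:
an exponential through the endpoints, ``t_half = dt * ln 2 / ln(y1/y2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class FitError(ValueError):
    """Raised when a decay fit is not identifiable."""


@dataclass(frozen=True)
class LogDecayFit:
    """Result of a least-squares fit of ``y = c*ln(t + offset) + y0``."""

    c: float
    y0: float
    r2: float
    time_offset: float
    n: int

    def predict(self, t_min) -> np.ndarray:
        return self.c * np.log(np.asarray(t_min, dtype=float) + self.time_offset) + self.y0

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError(f"r2 out of [0,1]: {self.r2}")
        if self.n < 3:
            raise ValueError("fit needs at least 3 samples")


def _cox_snell_r2(y: np.ndarray, resid: np.ndarray) -> float:
    """Cox–Snell pseudo-R^2 via Gaussian log-likelihoods of the null
    (intercept-only) and fitted models, ``1 - exp(2*(ll0 - ll1)/n)``."""
    n = y.size
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum(resid**2))
    if sst == 0:
        return 0.0
    # ML variance per model; log-likelihood of a Gaussian at its MLE
    ll1 = -0.5 * n * (np.log(2 * np.pi * max(sse, 1e-300) / n) + 1)
    ll0 = -0.5 * n * (np.log(2 * np.pi * sst / n) + 1)
    r2 = 1.0 - float(np.exp(2.0 * (ll0 - ll1) / n))
    return min(max(r2, 0.0), 1.0)


def fit_log_decay(times_min, values, time_offset: float = 1.0) -> LogDecayFit:
    """Least-squares fit of ``values`` against ``ln(t + time_offset)``.

    The default offset of 1 minute makes the t=0 frame usable (ln 1 = 0, so
    ``y0`` is the fitted t=0 intensity).  With ``time_offset=0`` any t=0
    samples are dropped with a warning.

    Raises
    ------
    FitError
        Fewer than 3 usable samples.  Zero variance in the values returns
        ``c=0, r2=0`` rather than an error.
    """
    t = np.asarray(times_min, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape:
        raise ValueError("times and values must have the same length")
    usable = t + time_offset > 0
    if not np.all(usable):
        warnings.warn(f"dropping {np.sum(~usable)} sample(s) with "
                      f"t + offset <= 0 (offset={time_offset})", stacklevel=2)
        t, y = t[usable], y[usable]
    if t.size < 3:
        raise FitError(f"need >= 3 usable samples, have {t.size}")

    x = np.log(t + time_offset)
    if np.ptp(y) == 0:
        return LogDecayFit(c=0.0, y0=float(y[0]), r2=0.0,
                           time_offset=float(time_offset), n=int(t.size))
    c, y0 = np.polyfit(x, y, 1)
    resid = y - (c * x + y0)
    return LogDecayFit(c=float(c), y0=float(y0), r2=_cox_snell_r2(y, resid),
                       time_offset=float(time_offset), n=int(t.size))


def half_life_two_point(t1: float, y1: float, t2: float, y2: float) -> float:
    """Half-life (min) of the exponential through two trajectory points.

    ``t_half = (t2 - t1) * ln 2 / ln(y1 / y2)``; scale-invariant in y and
    translation-invariant in t.
    """
    if t2 <= t1:
        raise ValueError("t2 must exceed t1")
    if y2 <= 0 or y1 <= 0:
        raise ValueError("intensities must be positive")
    if y1 <= y2:
        raise ValueError("no decay between the two points (y1 <= y2)")
    return (t2 - t1) * np.log(2.0) / np.log(y1 / y2)


def percent_change(series: pd.Series, t_a: float, t_b: float) -> float:
    """Signed percent change of a time-indexed series between two times,
    ``100 * (v(t_b) - v(t_a)) / v(t_a)``."""
    for t in (t_a, t_b):
        if t not in series.index:
            raise KeyError(f"time point {t} not present in series")
    va, vb = float(series.loc[t_a]), float(series.loc[t_b])
    if va == 0:
        raise ValueError("value at t_a is zero; percent change undefined")
    return 100.0 * (vb - va) / va


def compare_groups(a, b, paired: bool = False) -> tuple[float, float]:
    """Two-sided t-test between two samples; returns ``(t, p)``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test needs equal-length samples")
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ttest_ind(a, b)
    return float(res.statistic), float(res.pvalue)


def fit_table(ts_table: pd.DataFrame, time_offset: float = 1.0) -> pd.DataFrame:
    """Fit every ROI in a quantified time-series table.

    Returns columns ``roi, c, y0, r2, n, time_offset``.
    """
    rows = []
    for roi_id, grp in ts_table.groupby("roi", sort=False):
        grp = grp.sort_values("time_min")
        fit = fit_log_decay(grp["time_min"].to_numpy(), grp["mean"].to_numpy(),
                            time_offset=time_offset)
        rows.append({"roi": roi_id, "c": fit.c, "y0": fit.y0, "r2": fit.r2,
                     "n": fit.n, "time_offset": fit.time_offset})
    return pd.DataFrame(rows)
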