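"""Cell-cycle and differentiation estimators for germline SPC observation tables.

These are the quantitative readouts of a classic EdU/pH3/REC-8 labeling
study of a maintained stem/progenitor pool:

* ``mitotic_index``      -- pH3+ / REC-8+ snapshot fraction (M-phase index).
* ``s_phase_index``      -- EdU+ / REC-8+ fraction after a short pulse.
* ``g2_fraction_series`` -- percent of pH3+ nuclei that are also EdU+ versus
  labeling duration, pooled across germlines per time point.
* ``fit_g2_t50``         -- constrained variable-slope sigmoid through that
  series; its t50 is the median G2 length (the time by which half of the
  M-phase cells have completed G2 since labeling began).
* ``fit_entry_rate``     -- OLS slope of REC-8-/EdU+ accumulation, in cells/h:
  the meiotic entry (differentiation) rate.
* ``fit_doubling_time``  -- log2-linear exponential fit of larval germ-cell
  counts.
* ``percent_difference`` -- signed percent change of a mutant estimate
  relative to a reference genotype.
* ``spc_zone_length``    -- progenitor-zone extent in cell rows from a
  distal-to-proximal REC-8 occupancy table.

All estimators are deterministic functions of their input tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SigmoidFit",
    "RateFit",
    "GrowthFit",
    "ZoneRowTable",
    "mitotic_index",
    "s_phase_index",
    "g2_fraction_series",
    "fit_g2_t50",
    "fit_entry_rate",
    "fit_doubling_time",
    "percent_difference",
    "spc_zone_length",
]


@dataclass(frozen=True)
class SigmoidFit:
    """Constrained sigmoid fit; ``t50`` is the median G2 length in hours."""

    t50: float
    hill_slope: float
    rss: float
    n_points: int
    converged: bool


@dataclass(frozen=True)
class RateFit:
    """OLS line through an accumulation time course; slope in cells/h."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class GrowthFit:
    """Exponential (log2-linear) growth fit."""

    doubling_time: float
    n0_fit: float
    r_squared: float


class ZoneRowTable:
    """Distal-to-proximal rows of (cells in row, REC-8-positive cells in row)."""

    def __init__(self, rows: Iterable[tuple[int, int]]) -> None:
        self.rows = [(int(n), int(k)) for n, k in rows]
        if not self.rows:
            raise ValueError("row table must be non-empty")
        for n, k in self.rows:
            if n <= 0 or k < 0 or k > n:
                raise ValueError(f"malformed row counts (n_cells={n}, n_rec8={k})")


def _counts(obs) -> dict:
    """Accept an ObservationRecord, a mapping, or a pooled DataFrame."""
    if isinstance(obs, pd.DataFrame):
        return {c: int(obs[c].sum()) for c in ("n_rec8", "n_ph3", "n_edu", "n_ph3_edu")
                if c in obs.columns}
    if hasattr(obs, "n_rec8"):
        return {
            "n_rec8": obs.n_rec8,
            "n_ph3": obs.n_ph3,
            "n_edu": obs.n_edu,
            "n_ph3_edu": obs.n_ph3_edu,
        }
    return dict(obs)


def mitotic_index(obs) -> float:
    """Fraction of REC-8+ SPCs that are pH3+ (M-phase index)."""
    c = _counts(obs)
    if c["n_rec8"] <= 0:
        raise ValueError("mitotic_index undefined: no REC-8-positive cells")
    return c["n_ph3"] / c["n_rec8"]


def s_phase_index(obs) -> float:
    """Fraction of REC-8+ SPCs that are EdU+ after a short pulse."""
    c = _counts(obs)
    if c["n_rec8"] <= 0:
        raise ValueError("s_phase_index undefined: no REC-8-positive cells")
    return c["n_edu"] / c["n_rec8"]


def g2_fraction_series(obs: pd.DataFrame) -> pd.DataFrame:
    """Percent of pH3+ nuclei that are EdU+, per time point.

    Counts are pooled (summed) across germlines within each time point
    before taking the percentage.  Time points with no pH3+ nuclei are
    dropped with a warning rather than imputed.

    Returns a DataFrame with columns ``time_h`` and ``percent`` (0-100).
    """
    pooled = obs.groupby("time_h", sort=True)[["n_ph3", "n_ph3_edu"]].sum().reset_index()
    empty = pooled["n_ph3"] == 0
    if empty.any():
        dropped = pooled.loc[empty, "time_h"].tolist()
        warnings.warn(
            f"time points with no pH3-positive nuclei dropped: {dropped}",
            stacklevel=2,
        )
        pooled = pooled.loc[~empty]
    pooled["percent"] = 100.0 * pooled["n_ph3_edu"] / pooled["n_ph3"]
    return pooled[["time_h", "percent"]].reset_index(drop=True)


def _sigmoid(t: np.ndarray, t50: float, h: float) -> np.ndarray:
    # variable-slope logistic with Top=100, Bottom=0 fixed; base 10 as in the
    # standard dose-response parameterization, on linear time
    return 100.0 / (1.0 + 10.0 ** ((t50 - t) * h))


def fit_g2_t50(series: pd.DataFrame | Sequence, *,
               t50_init: float | None = None) -> SigmoidFit:
    """Least-squares fit of the constrained variable-slope sigmoid
    ``y(t) = 100 / (1 + 10**((t50 - t) * h))`` with t50 > 0, h > 0.

    The series must have at least 4 time points and bracket the 50% level;
    a series that never crosses 50 leaves t50 unidentifiable and raises.
    Initialization: t50 from linear interpolation of the 50% crossing, h=1.
    """
    if isinstance(series, pd.DataFrame):
        t = series["time_h"].to_numpy(dtype=float)
        y = series["percent"].to_numpy(dtype=float)
    else:
        arr = np.asarray(series, dtype=float)
        t, y = arr[:, 0], arr[:, 1]
    if t.size < 4:
        raise ValueError("need at least 4 time points to fit the sigmoid")
    if (t < 0).any():
        raise ValueError("negative times are not allowed")
    if not ((y < 50).any() and (y > 50).any()):
        raise ValueError(
            "series never crosses 50%: t50 is unidentifiable "
            f"(range {y.min():.1f}-{y.max():.1f})"
        )

    if t50_init is None:
        order = np.argsort(t)
        ts, ys = t[order], y[order]
        above = np.flatnonzero(ys > 50)
        i = above[0]
        if i == 0:
            t50_init = ts[0]
        else:
            f = (50.0 - ys[i - 1]) / (ys[i] - ys[i - 1])
            t50_init = ts[i - 1] + f * (ts[i] - ts[i - 1])
        t50_init = max(t50_init, 1e-3)

    try:
        popt, _ = optimize.curve_fit(
            _sigmoid,
            t,
            y,
            p0=[t50_init, 1.0],
            bounds=([1e-6, 1e-6], [np.inf, np.inf]),
            maxfev=10000,
        )
        converged = True
    except RuntimeError:
        popt = np.array([t50_init, 1.0])
        converged = False
    resid = y - _sigmoid(t, *popt)
    return SigmoidFit(
        t50=float(popt[0]),
        hill_slope=float(popt[1]),
        rss=float(resid @ resid),
        n_points=int(t.size),
        converged=converged,
    )


def fit_entry_rate(times: Sequence[float], counts: Sequence[float]) -> RateFit:
    """OLS regression of entered-cell counts on labeling duration.

    The slope is the meiotic entry rate in cells per hour.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(counts, dtype=float)
    if t.size != y.size or t.size < 2:
        raise ValueError("need >= 2 (time, count) pairs")
    if np.unique(t).size < 2:
        raise ValueError("all times identical: slope undefined")
    res = stats.linregress(t, y)
    return RateFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=int(t.size),
    )


def fit_doubling_time(times: Sequence[float], counts: Sequence[float]) -> GrowthFit:
    """Exponential fit of germ-cell counts: log2 N = log2 n0 + t/Td.

    Scale-invariant in the counts (a constant factor only shifts n0_fit).
    Raises on non-positive counts and on non-increasing series (which would
    imply an infinite or negative doubling time).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(counts, dtype=float)
    if t.size != y.size or t.size < 2:
        raise ValueError("need >= 2 (time, count) pairs")
    if np.unique(t).size < 2:
        raise ValueError("need counts at >= 2 distinct times")
    if (y <= 0).any():
        raise ValueError("all counts must be positive for an exponential fit")
    res = stats.linregress(t, np.log2(y))
    if res.slope <= 0:
        raise ValueError(
            "fitted growth rate is non-positive (constant or shrinking counts); "
            "doubling time undefined"
        )
    return GrowthFit(
        doubling_time=float(1.0 / res.slope),
        n0_fit=float(2.0**res.intercept),
        r_squared=float(res.rvalue**2),
    )


def percent_difference(reference: float, test: float) -> float:
    """Signed percent change of ``test`` relative to ``reference``.

    Positive means the test value is larger than the reference.  Reported
    magnitudes match the conventional "changed by X%" phrasing.
    """
    if reference == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (test - reference) / reference


def spc_zone_length(table: ZoneRowTable) -> int:
    """SPC-zone extent in germ-cell rows (gcd).

    Counts the distal prefix of rows fully occupied by REC-8-positive cells;
    the zone ends at the last fully positive row before any partial row.
    Returns 0 if the first row is already partial.
    """
    length = 0
    for n, k in table.rows:
        if k == n:
            length += 1
        else:
            break
    return length
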