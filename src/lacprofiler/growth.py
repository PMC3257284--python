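"""Growth-curve parameter extraction by sliding-window log-linear regression.

The maximal growth rate constant μMax (h⁻¹) is the steepest slope of
ln(OD600) versus time over a sliding window of 10 consecutive readings; lag
time is the extrapolation of that regression line to a constant reference
density OD600 = 0.06 (the same reference for every strain, so that lag
comparisons do not depend on variable inoculum densities).  Diauxic curves
are segmented into two exponential phases; the diauxic lag is the time
between the two phase regression lines crossing the OD at the end of the
first growth phase.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GrowthCurve",
    "GrowthFit",
    "DiauxicFit",
    "sliding_window_mu_max",
    "lag_time",
    "segment_diauxie",
    "doubling_rate",
    "read_growth_csv",
    "write_growth_table",
]

#: OD600 floor applied before log transforms (plate-reader detection limit scale).
OD_FLOOR = 1e-3

#: Relative slope deviation beyond which a window is treated as straddling a
#: phase boundary and excluded from the pooled phase regression.
_SLOPE_TRIM = 0.04


@dataclass
class GrowthCurve:
    """An OD600 time series (time in hours, strictly increasing)."""

    time: np.ndarray
    od600: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.od600.shape:
            raise ValueError("time and od600 must be 1-D arrays of equal length")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")

    @property
    def sample_interval(self) -> float:
        """Median sampling interval in hours."""
        return float(np.median(np.diff(self.time)))


@dataclass
class GrowthFit:
    """A single-phase fit: μMax window regression plus the extrapolated lag."""

    mu_max: float                 # hrs^-1
    intercept: float              # ln(OD) at t=0 of the μMax regression line
    window_start_index: int
    window_r2: float
    lag: float | None = None      # hrs, filled by lag_time
    lag_flagged: bool = False     # True when the extrapolated lag is negative
    reference_od: float = 0.06


@dataclass
class DiauxicFit:
    """Two-phase fit for diauxic growth.

    ``lag_2`` is ``None`` when no measurable diauxic lag exists (single
    exponential phase, or an inter-phase slope minimum too shallow to count
    as a pause — reported as "none").
    """

    mu_max_1: float
    lag_1: float
    mu_max_2: float | None
    lag_2: float | None
    phase_boundary_od: float | None
    phase1: GrowthFit | None = None
    phase2: GrowthFit | None = None


def _window_fits(t: np.ndarray, ln_od: np.ndarray, window: int):
    """Vectorized OLS over every contiguous window: slopes, intercepts, r²."""
    n = t.size - window + 1
    tw = np.lib.stride_tricks.sliding_window_view(t, window)
    yw = np.lib.stride_tricks.sliding_window_view(ln_od, window)
    tm = tw.mean(axis=1, keepdims=True)
    ym = yw.mean(axis=1, keepdims=True)
    sxx = np.sum((tw - tm) ** 2, axis=1)
    sxy = np.sum((tw - tm) * (yw - ym), axis=1)
    syy = np.sum((yw - ym) ** 2, axis=1)
    slopes = sxy / sxx
    intercepts = ym.ravel() - slopes * tm.ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(syy > 0, (sxy**2) / (sxx * syy), 1.0)
    return slopes, intercepts, r2


def _ols(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    tm, ym = t.mean(), y.mean()
    sxx = float(np.sum((t - tm) ** 2))
    sxy = float(np.sum((t - tm) * (y - ym)))
    syy = float(np.sum((y - ym) ** 2))
    slope = sxy / sxx
    r2 = (sxy * sxy) / (sxx * syy) if syy > 0 else 1.0
    return slope, ym - slope * tm, r2


def _phase_fit(
    t: np.ndarray,
    ln_od: np.ndarray,
    slopes: np.ndarray,
    candidates: np.ndarray,
    window: int,
    stabilize: bool,
) -> GrowthFit:
    """Pick the steepest-slope window among ``candidates`` and fit the phase.

    With ``stabilize`` the sliding windows serve only to *locate* the steepest
    cleanly-exponential stretch (the contiguous block of candidate windows
    with the largest median slope); the rate is then one pooled regression
    over all of that block's points.  Within a mono-exponential phase the
    true slope is constant, so pooling estimates the same quantity as the
    steepest window but without the upward extreme-value bias of reporting a
    single noisiest window.  On noise-free piecewise-exponential input the
    block is the entire phase and both paths return the rate exactly.
    """
    if not stabilize:
        idx = int(candidates[np.argmax(slopes[candidates])])
        s, b, r2 = _ols(t[idx:idx + window], ln_od[idx:idx + window])
        return GrowthFit(mu_max=s, intercept=b, window_start_index=idx, window_r2=r2)

    # contiguous candidate blocks = cleanly exponential stretches; the phase
    # rate is the pooled regression over the steepest block (by median window
    # slope, which is immune to a single lucky noisy window)
    blocks = _contiguous_runs(np.isin(np.arange(slopes.size), candidates))
    sized = [b for b in blocks if b[1] - b[0] >= 3] or blocks
    lo, hi = max(sized, key=lambda b: np.median(slopes[b[0]:b[1]]))
    block = np.arange(lo, hi)
    # windows straddling a phase boundary can pass the r² floor while their
    # slope is deflected; drop windows >4% off the block median before pooling
    med = float(np.median(slopes[block]))
    keep = block[np.abs(slopes[block] - med) <= _SLOPE_TRIM * abs(med)]
    if keep.size == 0:
        keep = block
    mask = np.zeros(ln_od.size, dtype=bool)
    for i in keep:
        mask[i:i + window] = True
    s0, b0, _ = _ols(t[mask], ln_od[mask])

    # refine the phase support by residuals: expand outward from the block
    # center while points stay within 3 robust SDs of the line, then refit.
    # Off-phase points (lag, plateau, stationary) break the line and stop the
    # expansion; on noise-free input only exactly-on-line points survive, so
    # the refit recovers the phase rate to machine precision.
    resid = ln_od - (b0 + s0 * t)
    sigma = 1.4826 * float(np.median(np.abs(resid[mask])))
    thresh = max(3.0 * sigma, 1e-9)
    center = int(np.flatnonzero(mask)[np.flatnonzero(mask).size // 2])
    left = center
    while left > 0 and abs(resid[left - 1]) <= thresh:
        left -= 1
    right = center
    while right < resid.size - 1 and abs(resid[right + 1]) <= thresh:
        right += 1
    if right - left + 1 >= 5:
        s, b, r2 = _ols(t[left:right + 1], ln_od[left:right + 1])
        start = left
    else:  # refinement collapsed; keep the pooled block fit
        s, b, r2 = _ols(t[mask], ln_od[mask])
        start = int(keep.min())
    return GrowthFit(mu_max=s, intercept=b, window_start_index=start, window_r2=r2)


def sliding_window_mu_max(
    curve: GrowthCurve,
    window: int = 10,
    od_range: tuple[float, float] | None = None,
    r2_floor: float = 0.98,
    od_floor: float = OD_FLOOR,
    stabilize: bool = True,
) -> GrowthFit:
    """Steepest sliding-window slope of ln(OD600) versus time.

    ``od_range`` restricts eligible windows to those whose ODs lie entirely
    within the given band, which allows rate comparisons over matched density
    ranges (e.g. comparing a mutant's single phase with the ancestor's second
    phase).  Windows with regression r² below ``r2_floor`` are ineligible, so
    that read noise cannot masquerade as fast growth; a perfectly flat window
    counts as r² = 1.  ``stabilize`` (default) selects the steepest locally
    averaged window slope and refits over that neighborhood's points, which
    removes the upward selection bias of a literal single-window maximum on
    noisy curves; set it to False for the single-window rule.
    """
    if window < 3:
        raise ValueError("window must be >= 3 points")
    t = curve.time
    od = np.maximum(curve.od600, od_floor)
    if t.size < window:
        raise ValueError("curve shorter than one window")
    ln_od = np.log(od)
    slopes, intercepts, r2 = _window_fits(t, ln_od, window)

    eligible = r2 >= r2_floor
    if od_range is not None:
        lo, hi = od_range
        odw = np.lib.stride_tricks.sliding_window_view(od, window)
        eligible &= np.all((odw >= lo) & (odw <= hi), axis=1)
    if not np.any(eligible):
        raise ValueError("no eligible regression window (check od_range / r2_floor)")
    fit = _phase_fit(t, ln_od, slopes, np.flatnonzero(eligible), window, stabilize)
    if fit.mu_max <= 0:
        raise ValueError("maximal slope is nonpositive; no growth detected")
    return fit


def lag_time(
    curve: GrowthCurve,
    fit: GrowthFit,
    reference_od: float = 0.06,
) -> float:
    """Lag as the μMax regression line's crossing of the reference density.

    ``lag = (ln(reference_od) - intercept) / slope``.  A negative
    extrapolated lag is reported as-is but flagged on the fit (diagnostic of
    a curve already past the reference density at time zero).
    """
    if fit.mu_max <= 0:
        raise ValueError("lag extrapolation requires a positive growth rate")
    lag = (math.log(reference_od) - fit.intercept) / fit.mu_max
    fit.lag = lag
    fit.reference_od = reference_od
    fit.lag_flagged = lag < 0
    if fit.lag_flagged:
        warnings.warn(f"negative extrapolated lag ({lag:.3f} h)")
    return lag


def doubling_rate(
    curve: GrowthCurve,
    window: int = 10,
    od_range: tuple[float, float] | None = None,
) -> float:
    """Maximum doubling rate (doublings/hr): steepest log2(OD) window slope.

    The windowing is identical to :func:`sliding_window_mu_max`, so the
    result equals μMax / ln 2.
    """
    return sliding_window_mu_max(curve, window=window, od_range=od_range).mu_max / math.log(2)


def segment_diauxie(
    curve: GrowthCurve,
    window: int = 10,
    reference_od: float = 0.06,
    none_fraction: float = 0.5,
    r2_floor: float = 0.98,
    od_floor: float = OD_FLOOR,
    stabilize: bool = True,
) -> DiauxicFit:
    """Segment a two-phase (diauxic) curve and measure the diauxic lag.

    Locates two locally-maximal-slope window groups separated by a slope
    minimum.  The OD at the end of the first growth phase is operationalized
    as the OD at the center of the minimum-slope window between the phases;
    ``lag_2`` is the time between the two phase regression lines crossing
    that OD.  When the inter-phase slope minimum exceeds ``none_fraction``
    of the smaller phase rate there is no measurable pause and ``lag_2`` is
    reported as ``None`` ("none").
    """
    t = curve.time
    od = np.maximum(curve.od600, od_floor)
    if t.size < window:
        raise ValueError("curve shorter than one window")
    ln_od = np.log(od)
    slopes, intercepts, r2 = _window_fits(t, ln_od, window)
    smax = float(slopes.max())
    if smax <= 0:
        raise ValueError("no growth detected")

    # contiguous runs of near-maximal slope = candidate exponential phases
    runs = _contiguous_runs(slopes >= none_fraction * smax)
    fits = []
    for lo, hi in runs:
        seg = np.arange(lo, hi)
        ok = seg[r2[seg] >= r2_floor]
        cand = ok if ok.size else seg
        fits.append((lo, hi, _phase_fit(t, ln_od, slopes, cand, window, stabilize)))
    # keep the two steepest candidate phases, in time order
    fits.sort(key=lambda f: -f[2].mu_max)
    tops = sorted(fits[:2], key=lambda f: f[0])

    if len(tops) < 2:
        fit1 = tops[0][2]
        lag_time(curve, fit1, reference_od)
        return DiauxicFit(
            mu_max_1=fit1.mu_max, lag_1=fit1.lag,
            mu_max_2=None, lag_2=None, phase_boundary_od=None, phase1=fit1,
        )

    (lo1, hi1, fit1), (lo2, hi2, fit2) = tops
    lag_time(curve, fit1, reference_od)

    if lo2 - hi1 < 1:  # phases abut with no window between: a kink, not a pause
        return DiauxicFit(
            mu_max_1=fit1.mu_max, lag_1=fit1.lag,
            mu_max_2=fit2.mu_max, lag_2=None, phase_boundary_od=None,
            phase1=fit1, phase2=fit2,
        )
    valley = np.arange(hi1, lo2)
    v_idx = int(valley[np.argmin(slopes[valley])])
    s_min = float(slopes[v_idx])
    mu_small = min(fit1.mu_max, fit2.mu_max)

    if s_min > none_fraction * mu_small:
        # phases not separated by a real pause: no measurable diauxic lag
        return DiauxicFit(
            mu_max_1=fit1.mu_max, lag_1=fit1.lag,
            mu_max_2=fit2.mu_max, lag_2=None, phase_boundary_od=None,
            phase1=fit1, phase2=fit2,
        )

    center = v_idx + window // 2
    boundary_od = float(od[min(center, od.size - 1)])
    ln_b = math.log(boundary_od)
    t1 = (ln_b - fit1.intercept) / fit1.mu_max
    t2 = (ln_b - fit2.intercept) / fit2.mu_max
    return DiauxicFit(
        mu_max_1=fit1.mu_max, lag_1=fit1.lag,
        mu_max_2=fit2.mu_max, lag_2=float(t2 - t1),
        phase_boundary_od=boundary_od, phase1=fit1, phase2=fit2,
    )


def _contiguous_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [lo, hi) index ranges of True runs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[breaks + 1]]
    ends = np.r_[idx[breaks] + 1, idx[-1] + 1]
    return list(zip(starts.tolist(), ends.tolist()))


# ---------------------------------------------------------------------------
# I/O


def read_growth_csv(path: str | Path, time_col: str = "time_hr",
                    od_col: str = "od600", **metadata) -> GrowthCurve:
    df = pd.read_csv(path)
    if time_col not in df.columns or od_col not in df.columns:
        raise ValueError(f"{path}: expected columns {time_col!r}, {od_col!r}")
    return GrowthCurve(df[time_col].to_numpy(), df[od_col].to_numpy(), metadata)


def write_growth_table(fits: dict[str, DiauxicFit | GrowthFit], path: str | Path) -> None:
    """Per-curve parameter table (Lag-1, μMax-1, Lag-2, μMax-2 schema)."""
    rows = []
    for name, f in fits.items():
        if isinstance(f, DiauxicFit):
            rows.append({
                "strain": name,
                "lag_1_hr": f.lag_1,
                "mu_max_1_per_hr": f.mu_max_1,
                "lag_2_hr": "none" if f.lag_2 is None else f.lag_2,
                "mu_max_2_per_hr": f.mu_max_2,
            })
        else:
            rows.append({
                "strain": name,
                "lag_1_hr": f.lag,
                "mu_max_1_per_hr": f.mu_max,
                "lag_2_hr": "none",
                "mu_max_2_per_hr": None,
            })
    pd.DataFrame(rows).to_csv(path, index=False)
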