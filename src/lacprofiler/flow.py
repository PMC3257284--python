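"""Inducer-response profiling from single-cell flow cytometry.

The pipeline turns raw per-event measurements (forward/side scatter and two
fluorescence channels: FL1 = GFP reporter of the *lac* promoter, FL2 = RFP
reporter of CRP activity) across a TMG concentration ladder into:

1. spillover-compensated channels,
2. an elliptical scatter gate (Mahalanobis distance from the peak of cell
   density in FSC-SSC space) that strips size/granularity outliers,
3. per-concentration expression summaries with a bimodality call from a
   1-vs-2 component Gaussian-mixture comparison on log10 fluorescence,
4. the three headline regulation metrics — the TMG concentration of
   half-maximal mean expression (TMG½Max), the concentration range showing a
   bimodal response, and the fully induced expression level — and a
   regulatory-class label (bimodal / constitutive / lower-threshold graded).

Event tables are plain :class:`pandas.DataFrame` objects with columns
``FSC, SSC, FL1, FL2`` (linear RFU; any instrument log scaling must be undone
by the reader).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.mixture import GaussianMixture

__all__ = [
    "EventTable",
    "SpilloverMatrix",
    "GateSpec",
    "BimodalityCall",
    "InducerResponseProfile",
    "compensate",
    "fit_scatter_gate",
    "apply_gate",
    "detect_bimodality",
    "estimate_tmg_half_max",
    "bimodal_range",
    "classify_regulation",
    "crp_reporter_check",
    "build_profile",
    "read_event_csv",
    "write_profile_csv",
]

log = logging.getLogger(__name__)

#: Per-event table: columns ``FSC, SSC, FL1, FL2`` (+ optional extras),
#: metadata in ``DataFrame.attrs``.
EventTable = pd.DataFrame

EVENT_COLUMNS = ("FSC", "SSC", "FL1", "FL2")


@dataclass(frozen=True)
class SpilloverMatrix:
    """2x2 spillover: observed = matrix @ true, channels ordered (FL1, FL2).

    The diagonal is 1 by construction; off-diagonals are the fractional
    bleed-through of each fluorophore into the other detector, estimated from
    single-reporter control strains.
    """

    gfp_to_fl2: float = 0.02
    rfp_to_fl1: float = 0.01

    def __post_init__(self) -> None:
        for v in (self.gfp_to_fl2, self.rfp_to_fl1):
            if not 0 <= v < 1:
                raise ValueError("spillover fractions must be in [0, 1)")

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[1.0, self.rfp_to_fl1], [self.gfp_to_fl2, 1.0]])

    @classmethod
    def identity(cls) -> "SpilloverMatrix":
        return cls(0.0, 0.0)

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "SpilloverMatrix":
        m = np.asarray(m, dtype=float)
        if m.shape != (2, 2) or not np.allclose(np.diag(m), 1.0):
            raise ValueError("spillover matrix must be 2x2 with unit diagonal")
        return cls(gfp_to_fl2=float(m[1, 0]), rfp_to_fl1=float(m[0, 1]))


@dataclass
class GateSpec:
    """Elliptical scatter gate: Mahalanobis distance threshold around the
    density peak in (FSC, SSC)."""

    center: tuple[float, float]
    covariance: np.ndarray
    mahalanobis_threshold: float = 0.5

    def __post_init__(self) -> None:
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
            raise ValueError("covariance must be symmetric 2x2")
        if np.any(np.linalg.eigvalsh(cov) <= 0):
            raise ValueError("covariance must be positive-definite")
        if self.mahalanobis_threshold <= 0:
            raise ValueError("threshold must be positive")
        self.covariance = cov


@dataclass
class BimodalityCall:
    """Outcome of the 1-vs-2 component mixture comparison on log10 RFU."""

    is_bimodal: bool
    mode_locations: list[float]          # RFU, ascending
    mode_weights: list[float]
    separation: float                    # decades between modes
    evidence: float                      # ΔBIC in favor of two components


@dataclass
class ConcentrationRecord:
    conc: float
    mean_expression: float
    bimodality: BimodalityCall
    n_events: int


@dataclass
class InducerResponseProfile:
    """Per-strain summary across the TMG ladder with the three headline metrics."""

    records: list[ConcentrationRecord]
    tmg_half_max: float | None
    bimodal_range: tuple[float, float] | None
    max_expression: float
    response_class: str | None = None
    class_trigger: str | None = None
    strain: str | None = None

    @property
    def concentrations(self) -> list[float]:
        return [r.conc for r in self.records]

    @property
    def means(self) -> list[float]:
        return [r.mean_expression for r in self.records]


# ---------------------------------------------------------------------------
# compensation


def compensate(raw: EventTable, spill: SpilloverMatrix) -> EventTable:
    """Invert spillover mixing per event; clamp negatives to zero.

    Clamped events are counted (``attrs['n_clamped']``) rather than dropped,
    so downstream induced-fraction estimates keep their denominators.
    """
    m = spill.matrix
    if abs(np.linalg.det(m)) < 1e-12:
        raise ValueError("spillover matrix is singular")
    inv = np.linalg.inv(m)
    true = inv @ raw[["FL1", "FL2"]].to_numpy().T
    n_clamped = int(np.sum(np.any(true < 0, axis=0)))
    true = np.maximum(true, 0.0)
    out = raw.copy()
    out["FL1"] = true[0]
    out["FL2"] = true[1]
    out.attrs = dict(raw.attrs)
    out.attrs["n_clamped"] = n_clamped
    if n_clamped:
        log.debug("compensation clamped %d events to zero", n_clamped)
    return out


# ---------------------------------------------------------------------------
# scatter gating

# Consistency factor for a covariance computed after trimming to the central
# chi-square quantile q in 2 dimensions: E[r^2 | r^2 < u] / 2 with
# u = chi2.ppf(q, 2) (chi2_2 is Exp(1/2), so the truncated mean is closed form).


def _trim_consistency(q: float) -> float:
    u = stats.chi2.ppf(q, df=2)
    return (2.0 - (u + 2.0) * math.exp(-u / 2.0)) / q / 2.0


def fit_scatter_gate(
    events: EventTable,
    threshold: float = 0.5,
    grid_bins: int = 64,
    smooth_sigma: float = 3.0,
    trim_q: float = 0.975,
) -> GateSpec:
    """Fit an elliptical gate at the peak of FSC-SSC cell density.

    The center is the mode of a smoothed 2-D histogram density (with local
    quadratic refinement of the peak bin); the covariance is an outlier-
    resistant estimate obtained by trimming events beyond the ``trim_q``
    chi-square contour of an initial fit and rescaling with the analytic
    truncation consistency factor.
    """
    xy = events[["FSC", "SSC"]].to_numpy(dtype=float)
    if xy.shape[0] < 500:
        raise ValueError("need at least 500 events to fit a scatter gate")
    if np.any(np.ptp(xy, axis=0) == 0):
        raise ValueError("degenerate scatter: a channel has zero variance")

    hist, xedges, yedges = np.histogram2d(xy[:, 0], xy[:, 1], bins=grid_bins)
    dens = ndimage.gaussian_filter(hist, sigma=smooth_sigma)
    ix, iy = np.unravel_index(np.argmax(dens), dens.shape)
    xc = _parabolic_peak(xedges, dens[:, iy], ix)
    yc = _parabolic_peak(yedges, dens[ix, :], iy)
    center = np.array([xc, yc])

    # population (ddof=0) covariance keeps the estimator exactly invariant
    # under duplication of the event list
    cov = np.cov(xy, rowvar=False, bias=True)
    d2 = _mahalanobis_sq(xy, center, cov)
    keep = d2 <= stats.chi2.ppf(trim_q, df=2)
    cov = np.cov(xy[keep], rowvar=False, bias=True) / _trim_consistency(trim_q)
    return GateSpec(center=(float(xc), float(yc)), covariance=cov,
                    mahalanobis_threshold=threshold)


def _parabolic_peak(edges: np.ndarray, profile: np.ndarray, i: int) -> float:
    centers = 0.5 * (edges[:-1] + edges[1:])
    if i == 0 or i == len(profile) - 1:
        return centers[i]
    y0, y1, y2 = profile[i - 1], profile[i], profile[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return centers[i]
    shift = 0.5 * (y0 - y2) / denom
    return centers[i] + shift * (centers[1] - centers[0])


def _mahalanobis_sq(xy: np.ndarray, center: np.ndarray, cov: np.ndarray) -> np.ndarray:
    delta = xy - center
    sol = np.linalg.solve(cov, delta.T)
    return np.einsum("ij,ji->i", delta, sol)


def apply_gate(events: EventTable, gate: GateSpec) -> EventTable:
    """Keep events within the gate's Mahalanobis distance of its center."""
    xy = events[["FSC", "SSC"]].to_numpy(dtype=float)
    d2 = _mahalanobis_sq(xy, np.asarray(gate.center), gate.covariance)
    keep = d2 <= gate.mahalanobis_threshold**2
    out = events.loc[keep].reset_index(drop=True)
    out.attrs = dict(events.attrs)
    out.attrs["gate_retained_fraction"] = float(np.mean(keep))
    return out


# ---------------------------------------------------------------------------
# bimodality


def detect_bimodality(
    fl_values: Sequence[float],
    min_events: int = 200,
    delta_bic: float = 10.0,
    min_weight: float = 0.05,
    min_separation: float = 0.5,
    floor: float = 0.01,
    random_state: int = 0,
) -> BimodalityCall:
    """Call bimodality of a fluorescence sample on the log10 scale.

    Fits 1- and 2-component Gaussian mixtures to log10 RFU (values floored at
    ``floor`` RFU) and declares the sample bimodal iff the 2-component model
    is favored by at least ``delta_bic`` BIC units, both components carry at
    least ``min_weight`` of the population, and the component means are at
    least ``min_separation`` decades apart.  Modes are returned ascending in
    RFU; deterministic for fixed ``random_state``.
    """
    x = np.log10(np.maximum(np.asarray(fl_values, dtype=float), floor)).reshape(-1, 1)
    if x.shape[0] < min_events:
        raise ValueError(f"need at least {min_events} events for a bimodality call")

    gm1 = GaussianMixture(n_components=1).fit(x)
    gm2 = GaussianMixture(n_components=2, n_init=2, random_state=random_state).fit(x)
    evidence = float(gm1.bic(x) - gm2.bic(x))  # positive favors two components

    order = np.argsort(gm2.means_.ravel())
    mus = gm2.means_.ravel()[order]
    weights = gm2.weights_[order]
    separation = float(mus[-1] - mus[0])
    is_bimodal = (
        evidence >= delta_bic
        and bool(np.all(weights >= min_weight))
        and separation >= min_separation
    )
    if is_bimodal:
        modes = [float(10**m) for m in mus]
        mode_weights = [float(w) for w in weights]
    else:
        mu1 = float(gm1.means_.ravel()[0])
        modes, mode_weights = [float(10**mu1)], [1.0]
        separation = 0.0
    return BimodalityCall(
        is_bimodal=is_bimodal,
        mode_locations=modes,
        mode_weights=mode_weights,
        separation=separation,
        evidence=evidence,
    )


# ---------------------------------------------------------------------------
# profile metrics


def estimate_tmg_half_max(
    concentrations: Sequence[float],
    means: Sequence[float],
) -> float | None:
    """Concentration at which mean expression crosses halfway between
    baseline (mean at 0 µM) and saturation (mean at the top concentration).

    Interpolation between bracketing tested concentrations is linear in
    log10-concentration (ladders are log-spaced); a crossing that falls
    exactly on a tested concentration is returned exactly.  The segment
    anchored at 0 µM, where log spacing is undefined, is interpolated
    linearly in concentration.  Returns ``None`` (with a warning) for a
    profile that never reaches the half level.
    """
    conc = np.asarray(concentrations, dtype=float)
    mean = np.asarray(means, dtype=float)
    if conc.size < 3:
        raise ValueError("need at least 3 concentrations")
    if not np.all(np.diff(conc) > 0):
        raise ValueError("concentrations must be strictly increasing")
    if conc[0] != 0:
        raise ValueError("profile must include 0 µM")
    if not np.all(np.isfinite(mean)):
        raise ValueError("means must be finite")

    baseline, saturation = mean[0], mean[-1]
    half = 0.5 * (baseline + saturation)
    if abs(saturation - baseline) <= 1e-9 * max(abs(saturation), abs(baseline), 1.0):
        # flat profile (e.g. constitutive): no half-maximal point exists
        warnings.warn("baseline equals saturation; no TMG½Max estimate")
        return None

    exact = np.nonzero(mean == half)[0]
    if exact.size:
        return float(conc[exact[0]])

    sign = np.sign(mean - half)
    for i in range(conc.size - 1):
        if sign[i] != sign[i + 1]:
            frac = (half - mean[i]) / (mean[i + 1] - mean[i])
            if conc[i] == 0:
                return float(conc[i] + frac * (conc[i + 1] - conc[i]))
            lo, hi = math.log10(conc[i]), math.log10(conc[i + 1])
            return float(10 ** (lo + frac * (hi - lo)))
    warnings.warn("profile never crosses the half-maximal level; no TMG½Max estimate")
    return None


def bimodal_range(
    records: Sequence[ConcentrationRecord],
) -> tuple[float, float] | None:
    """Span of tested concentrations flagged bimodal; ``None`` if none.

    A gap (non-bimodal concentration between bimodal ones) is logged as a
    warning but the range still spans the flagged extremes.
    """
    flagged = [r.conc for r in records if r.bimodality.is_bimodal]
    if not flagged:
        return None
    lo, hi = min(flagged), max(flagged)
    interior = [r for r in records if lo < r.conc < hi]
    if any(not r.bimodality.is_bimodal for r in interior):
        warnings.warn(
            f"non-bimodal concentration inside bimodal range [{lo}, {hi}] µM"
        )
    return (lo, hi)


def classify_regulation(profile: InducerResponseProfile) -> tuple[str, str]:
    """Assign a regulatory class with an explicit precedence.

    1. *constitutive* if mean expression varies by less than 2-fold across
       the tested concentrations (the operational definition);
    2. else *bimodal* if any tested concentration shows a bimodal response;
    3. else *lower_threshold_graded*.

    Returns ``(class, triggering metric description)``.
    """
    means = np.asarray(profile.means, dtype=float)
    mmin = max(means.min(), 1e-12)
    fold = float(means.max() / mmin)
    if fold < 2.0:
        return "constitutive", f"fold-change {fold:.2f} < 2"
    if profile.bimodal_range is not None:
        lo, hi = profile.bimodal_range
        return "bimodal", f"bimodal at {lo}-{hi} µM"
    return "lower_threshold_graded", (
        f"unimodal, fold-change {fold:.1f}, TMG½Max {profile.tmg_half_max}"
    )


@dataclass
class CrpReport:
    """Invariance report for the CRP-activity (FL2) reporter."""

    passes: bool
    fold_change: float
    unimodal_at: dict[float, bool]

    @property
    def all_unimodal(self) -> bool:
        return all(self.unimodal_at.values())


def crp_reporter_check(
    fl2_by_conc: Mapping[float, Sequence[float]],
    **bimodality_kwargs,
) -> CrpReport:
    """Check that the CRP reporter is unimodal and inducer-independent.

    Passes iff FL2 is unimodal at every concentration and the max/min
    fold-change of per-concentration means is below 2.
    """
    unimodal: dict[float, bool] = {}
    means: list[float] = []
    for conc in sorted(fl2_by_conc):
        values = np.asarray(fl2_by_conc[conc], dtype=float)
        call = detect_bimodality(values, **bimodality_kwargs)
        unimodal[conc] = not call.is_bimodal
        means.append(float(values.mean()))
    fold = float(max(means) / max(min(means), 1e-12))
    return CrpReport(
        passes=all(unimodal.values()) and fold < 2.0,
        fold_change=fold,
        unimodal_at=unimodal,
    )


# ---------------------------------------------------------------------------
# panel pipeline


def build_profile(
    panel: Mapping[float, EventTable],
    spill: SpilloverMatrix | None = None,
    gate_threshold: float = 0.5,
    strain: str | None = None,
    **bimodality_kwargs,
) -> InducerResponseProfile:
    """Full per-strain pipeline: compensate, gate, summarize, classify.

    ``panel`` maps TMG concentration (µM) to raw event tables.  Each table is
    compensated (if a spillover matrix is given), gated with its own
    density-peak ellipse, and summarized; the profile metrics and the
    regulatory class are then computed across the ladder.
    """
    records: list[ConcentrationRecord] = []
    for conc in sorted(panel):
        events = panel[conc]
        if spill is not None:
            events = compensate(events, spill)
        gate = fit_scatter_gate(events, threshold=gate_threshold)
        gated = apply_gate(events, gate)
        call = detect_bimodality(gated["FL1"], **bimodality_kwargs)
        records.append(
            ConcentrationRecord(
                conc=float(conc),
                mean_expression=float(gated["FL1"].mean()),
                bimodality=call,
                n_events=len(gated),
            )
        )
    concs = [r.conc for r in records]
    means = [r.mean_expression for r in records]
    profile = InducerResponseProfile(
        records=records,
        tmg_half_max=estimate_tmg_half_max(concs, means),
        bimodal_range=bimodal_range(records),
        max_expression=means[-1],
        strain=strain,
    )
    profile.response_class, profile.class_trigger = classify_regulation(profile)
    return profile


# ---------------------------------------------------------------------------
# I/O


def read_event_csv(path: str | Path, **metadata) -> EventTable:
    """Read an event table CSV with header ``FSC,SSC,FL1,FL2``."""
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: empty event table")
    df.attrs.update(metadata)
    return df


def write_profile_csv(profile: InducerResponseProfile, path: str | Path) -> None:
    """Write a long-format per-concentration summary (heat-map ready)."""
    rows = [
        {
            "strain": profile.strain,
            "conc_uM": r.conc,
            "mean_rfu": r.mean_expression,
            "bimodal_flag": r.bimodality.is_bimodal,
            "n_events": r.n_events,
        }
        for r in profile.records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
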