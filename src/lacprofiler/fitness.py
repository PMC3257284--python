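"""Serial-transfer competition fitness.

Relative fitness of a test strain against a reference is the ratio of their
realized Malthusian growth over the competition,

    W = ln(N_T2 / N_T0) / ln(N_R2 / N_R0),

where initial and final densities come from colony counts on indicator
plates.  Competitions run over multiple transfer cycles are corrected by
compounding the intermediate dilutions back into the final densities
(multiplying both finals by dilution^(cycles-1)), which makes W the
Malthusian ratio over the full propagation; because the correction is
applied identically to both competitors it cancels from every between-strain
comparison and reduces to the plain formula for a single cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CompetitionAssay",
    "FitnessEstimate",
    "relative_fitness",
    "summarize_fitness",
    "compare_fitness",
]


@dataclass
class CompetitionAssay:
    """Paired initial/final densities (cfu/mL) for one competition."""

    n_t0: float
    n_r0: float
    n_t2: float
    n_r2: float
    cycles: int = 1
    dilution_factor: float = 100.0

    def __post_init__(self) -> None:
        for v in (self.n_t0, self.n_r0, self.n_t2, self.n_r2):
            if v <= 0:
                raise ValueError("all densities must be positive")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if self.cycles > 1 and self.dilution_factor <= 1:
            raise ValueError("dilution_factor must exceed 1 for multi-cycle assays")


@dataclass
class FitnessEstimate:
    """Replicate summary: mean W, t-based 95% CI, and a test against W = 1."""

    replicate_ws: list[float]
    mean_w: float
    ci95: tuple[float, float]
    p_vs_null: float | None
    null: float = 1.0
    degenerate: bool = False

    @property
    def n(self) -> int:
        return len(self.replicate_ws)


def relative_fitness(a: CompetitionAssay, per_generation: bool = False,
                     generations: float | None = None) -> float:
    """Relative fitness W from one competition's counts.

    With ``per_generation=True`` the alternative normalization
    ``1 + (m_T - m_R) / (generations · ln 2)`` is returned instead (a
    per-generation selection-rate scaling; requires ``generations``).
    """
    corr = a.dilution_factor ** (a.cycles - 1)
    m_t = math.log(a.n_t2 * corr / a.n_t0)
    m_r = math.log(a.n_r2 * corr / a.n_r0)
    if m_r <= 0:
        raise ValueError(
            "reference strain did not grow (denominator ln ratio <= 0); W undefined"
        )
    if per_generation:
        if generations is None or generations <= 0:
            raise ValueError("per-generation normalization needs a generation count")
        return 1.0 + (m_t - m_r) / (generations * math.log(2))
    return m_t / m_r


def summarize_fitness(replicates: Sequence[float], null: float = 1.0) -> FitnessEstimate:
    """Mean, t-based 95% CI, and a two-tailed test of the mean against ``null``.

    With zero between-replicate variance the CI degenerates to a point and
    the p-value is undefined; both are flagged rather than fabricated.
    """
    ws = [float(w) for w in replicates]
    if len(ws) < 2:
        raise ValueError("need at least 2 replicates")
    arr = np.asarray(ws)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if sd == 0:
        return FitnessEstimate(ws, mean, (mean, mean), p_vs_null=None,
                               null=null, degenerate=True)
    sem = sd / math.sqrt(len(ws))
    lo, hi = stats.t.interval(0.95, df=len(ws) - 1, loc=mean, scale=sem)
    p = float(stats.ttest_1samp(arr, popmean=null).pvalue)
    return FitnessEstimate(ws, mean, (float(lo), float(hi)), p_vs_null=p, null=null)


def compare_fitness(ws_a: Sequence[float], ws_b: Sequence[float]) -> float:
    """Two-tailed unequal-variance (Welch) comparison of two replicate sets."""
    return float(stats.ttest_ind(np.asarray(ws_a), np.asarray(ws_b), equal_var=False).pvalue)
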