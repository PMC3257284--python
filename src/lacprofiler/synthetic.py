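"""Synthetic data with known ground truth for every analysis stage.

The generators emulate the statistical structure the downstream analysis
assumes, without any mechanistic model of the *lac* switch:

* **Flow panels** — per-cell fluorescence across a TMG concentration ladder.
  The induced fraction follows a Hill function of inducer concentration,
  ``p(c) = c^h / (c^h + K^h)``; a *bimodal* strain assigns each cell to a low
  or high log-normal expression mode with probability ``p``, a *graded*
  strain shifts a single log-normal mode's log-median from low to high by the
  same Hill fraction, and a *constitutive* strain expresses the high mode at
  every concentration.  A TMG-independent log-normal RFP channel (the
  CRP-activity reporter) and bivariate-normal forward/side scatter are added,
  and a small spillover matrix mixes the true channels into the observed ones.
* **Growth curves** — piecewise-exponential OD600 backbones (flat lag, then
  exponential growth; optionally a diauxic plateau and a second exponential
  phase) with additive Gaussian read noise.
* **Competitions** — serial-transfer head-to-head growth where the test
  strain realizes ``W`` times the reference's Malthusian growth each cycle,
  with exact or Poisson-sampled colony counts.
* **Sequences** — reference *lac* amplicons with named edits applied
  (repeat-unit indels, operator SNPs, known-null missense), designed to
  round-trip through :mod:`lacprofiler.genotyping`.

Defaults mirror the study conditions the analysis was designed around:
25,000 events per well, an ancestor-like bimodal response with half-max at
25 µM TMG, a lower-threshold graded response at 4 µM, and diauxic growth
parameters matching the ancestor's glucose-to-lactose shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from lacprofiler.genotyping import DEFAULT_REFERENCE, ReferenceLocus

__all__ = [
    "FlowSimParams",
    "GrowthSimParams",
    "CompetitionSimParams",
    "generate_flow_panel",
    "generate_growth_curve",
    "generate_competition",
    "generate_lac_sequences",
    "hill_fraction",
    "DEFAULT_TMG_LADDER",
    "GENOTYPE_LABELS",
]

RESPONSE_CLASSES = ("bimodal", "graded", "constitutive")

#: 12-point TMG ladder (µM) spanning 0 to a saturating top concentration.
DEFAULT_TMG_LADDER = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 15.0, 20.0, 30.0, 50.0, 100.0)

#: Genotype vocabulary the sequence generator accepts.
GENOTYPE_LABELS = (
    "wt",
    "lacI-(ΔTGGC)",
    "lacI-(ΩTGGC)",
    "lacI-(L71Q)",
    "lacO1-G5A",
    "lacO1-G9T",
    "lacO1-G11A",
)


def hill_fraction(conc: np.ndarray | float, k: float, h: float) -> np.ndarray | float:
    """Induced fraction ``c^h / (c^h + K^h)``; exactly 0 at c=0 and 0.5 at c=K."""
    c = np.asarray(conc, dtype=float)
    r = np.zeros_like(c)
    pos = c > 0
    # log-space evaluation avoids overflow for tiny c / large h
    log_ratio = h * (np.log(k) - np.log(c, where=pos, out=np.zeros_like(c)))
    r[pos] = 1.0 / (1.0 + np.exp(np.minimum(log_ratio[pos], 700.0)))
    return float(r) if np.isscalar(conc) else r


@dataclass
class FlowSimParams:
    """Ground truth for one strain's single-cell inducer response.

    ``low_mean``/``high_mean`` are the medians (RFU) of the uninduced and
    induced log-normal expression modes; ``cv_low``/``cv_high`` their
    coefficients of variation on the linear scale.  The spillover matrix maps
    true (GFP, RFP) signal to observed (FL1, FL2) channels.
    """

    response_class: str = "bimodal"
    half_max_conc: float = 25.0          # µM; ancestor-like
    hill_coefficient: float = 5.6
    low_mean: float = 1.5                # RFU
    high_mean: float = 84.0              # RFU, ancestor's full-induction level scale
    cv_low: float = 0.40
    cv_high: float = 0.35
    fl2_mean: float = 30.0               # RFU, CRP reporter (TMG-independent)
    fl2_cv: float = 0.35
    n_events: int = 25_000
    spillover: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 0.01), (0.02, 1.0))
    scatter_center: tuple[float, float] = (520.0, 310.0)
    scatter_cov: tuple[tuple[float, float], tuple[float, float]] = (
        (8100.0, 2700.0),
        (2700.0, 3600.0),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.response_class not in RESPONSE_CLASSES:
            raise ValueError(f"unknown response class {self.response_class!r}")
        if self.n_events <= 0:
            raise ValueError("n_events must be positive")
        s = np.asarray(self.spillover, dtype=float)
        if s.shape != (2, 2) or not np.allclose(np.diag(s), 1.0):
            raise ValueError("spillover must be 2x2 with unit diagonal")
        off = s[~np.eye(2, dtype=bool)]
        if np.any(off < 0) or np.any(off >= 1):
            raise ValueError("spillover off-diagonals must be in [0, 1)")
        if self.response_class in ("bimodal", "graded") and not self.high_mean > self.low_mean:
            raise ValueError("high_mean must exceed low_mean for inducible classes")
        for cv in (self.cv_low, self.cv_high, self.fl2_cv):
            if cv <= 0:
                raise ValueError("coefficients of variation must be positive")


@dataclass
class GrowthSimParams:
    """Ground truth for a piecewise-exponential OD600 growth curve.

    Defaults are the ancestor's diauxic glucose-to-lactose profile:
    lag 3.18 h, first-phase rate 0.370 h⁻¹, diauxic lag 0.47 h, second-phase
    rate 0.461 h⁻¹.  ``od_start`` defaults to the 0.06 reference density used
    by the lag convention, so the generated flat-phase duration equals the
    extrapolated lag exactly.
    """

    lag1: float = 3.18        # hrs
    mu1: float = 0.370        # hrs^-1
    diauxic: bool = True
    lag2: float = 0.47        # hrs (plateau duration)
    mu2: float = 0.461        # hrs^-1
    od_start: float = 0.06
    od_break: float = 0.26
    od_max: float = 0.60
    noise_sd: float = 0.002   # OD600 units
    sample_interval: float = 5.0  # minutes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu1 <= 0 or (self.diauxic and self.mu2 <= 0):
            raise ValueError("growth rates must be positive")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if self.diauxic and not (self.od_start < self.od_break < self.od_max):
            raise ValueError("require od_start < od_break < od_max for diauxic curves")
        if not self.diauxic and not (self.od_start < self.od_max):
            raise ValueError("require od_start < od_max")
        if self.lag1 < 0 or self.lag2 < 0 or self.noise_sd < 0:
            raise ValueError("lags and noise_sd must be nonnegative")

    def backbone(self, t: np.ndarray) -> np.ndarray:
        """Noise-free OD600 at times ``t`` (hrs)."""
        t = np.asarray(t, dtype=float)
        od = np.full_like(t, self.od_start)
        grow1 = t >= self.lag1
        od[grow1] = self.od_start * np.exp(self.mu1 * (t[grow1] - self.lag1))
        if self.diauxic:
            t_break = self.lag1 + math.log(self.od_break / self.od_start) / self.mu1
            plateau = (t >= t_break) & (t < t_break + self.lag2)
            od[plateau] = self.od_break
            grow2 = t >= t_break + self.lag2
            od[grow2] = self.od_break * np.exp(self.mu2 * (t[grow2] - t_break - self.lag2))
        return np.minimum(od, self.od_max)

    def duration_to_max(self) -> float:
        """Hours needed for the backbone to reach ``od_max``."""
        if self.diauxic:
            t_break = self.lag1 + math.log(self.od_break / self.od_start) / self.mu1
            return t_break + self.lag2 + math.log(self.od_max / self.od_break) / self.mu2
        return self.lag1 + math.log(self.od_max / self.od_start) / self.mu1


@dataclass
class CompetitionSimParams:
    """Ground truth for a serial-transfer competition.

    Each cycle the reference strain regrows by the dilution factor
    (Malthusian growth ``ln D``) and the test strain realizes
    ``true_fitness`` times that growth.  With ``count_sampling="poisson"``
    plating counts are Poisson draws at a volume targeting
    ``plating_colonies`` total colonies per sample.
    """

    true_fitness: float = 1.0
    n0_test: float = 1.75e6    # cfu/mL after the 1:200 inoculation
    n0_ref: float = 1.75e6
    cycles: int = 2
    dilution_factor: float = 100.0
    generations_per_cycle: float = math.log2(100.0)
    count_sampling: str = "exact"
    plating_colonies: float = 400.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_fitness <= 0:
            raise ValueError("true_fitness must be positive")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must exceed 1")
        if self.count_sampling not in ("poisson", "exact"):
            raise ValueError("count_sampling must be 'poisson' or 'exact'")


# ---------------------------------------------------------------------------
# flow panels


def _lognormal(rng: np.random.Generator, median: float, cv: float, n: int) -> np.ndarray:
    sigma = math.sqrt(math.log1p(cv * cv))
    return median * np.exp(sigma * rng.standard_normal(n))


def generate_flow_panel(
    params: FlowSimParams,
    tmg_ladder: Iterable[float] = DEFAULT_TMG_LADDER,
) -> dict[float, "pd.DataFrame"]:
    """Simulate one strain's event tables across a TMG ladder.

    Returns a mapping from concentration (µM) to an event table with observed
    channels ``FSC, SSC, FL1, FL2`` plus the pre-spillover ground-truth
    channels ``GFP_true, RFP_true`` (used by compensation oracles).
    Deterministic for a fixed ``params.seed``.
    """
    ladder = sorted(float(c) for c in tmg_ladder)
    if not ladder:
        raise ValueError("tmg_ladder must be nonempty")
    if any(c < 0 for c in ladder):
        raise ValueError("concentrations must be nonnegative")
    if 0.0 not in ladder:
        raise ValueError("ladder must include 0 µM")

    spill = np.asarray(params.spillover, dtype=float)
    panel: dict[float, pd.DataFrame] = {}
    for i, conc in enumerate(ladder):
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, i]))
        n = params.n_events
        p = float(hill_fraction(conc, params.half_max_conc, params.hill_coefficient))
        if params.response_class == "constitutive":
            gfp = _lognormal(rng, params.high_mean, params.cv_high, n)
        elif params.response_class == "bimodal":
            induced = rng.random(n) < p
            gfp = np.where(
                induced,
                _lognormal(rng, params.high_mean, params.cv_high, n),
                _lognormal(rng, params.low_mean, params.cv_low, n),
            )
        else:  # graded: single mode whose log-median interpolates low -> high
            log_med = (1 - p) * math.log(params.low_mean) + p * math.log(params.high_mean)
            cv = (1 - p) * params.cv_low + p * params.cv_high
            gfp = _lognormal(rng, math.exp(log_med), cv, n)
        rfp = _lognormal(rng, params.fl2_mean, params.fl2_cv, n)
        observed = spill @ np.vstack([gfp, rfp])
        scatter = rng.multivariate_normal(
            params.scatter_center, np.asarray(params.scatter_cov, float), size=n
        )
        panel[conc] = pd.DataFrame(
            {
                "FSC": scatter[:, 0],
                "SSC": scatter[:, 1],
                "FL1": observed[0],
                "FL2": observed[1],
                "GFP_true": gfp,
                "RFP_true": rfp,
            }
        )
        panel[conc].attrs["tmg_uM"] = conc
        panel[conc].attrs["response_class"] = params.response_class
    return panel


# ---------------------------------------------------------------------------
# growth curves


def generate_growth_curve(params: GrowthSimParams, duration: float | None = None):
    """Simulate an OD600 time series on a regular grid.

    ``duration`` defaults to enough time to reach ``od_max`` plus one hour of
    stationary plateau.  Returns a :class:`lacprofiler.growth.GrowthCurve`.
    """
    from lacprofiler.growth import GrowthCurve

    needed = params.duration_to_max()
    if duration is None:
        duration = needed + 1.0
    elif duration < needed:
        raise ValueError("duration too short to reach od_max")
    step = params.sample_interval / 60.0
    t = np.arange(0.0, duration + step / 2, step)
    od = params.backbone(t)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        od = od + rng.normal(0.0, params.noise_sd, size=t.size)
    return GrowthCurve(time=t, od600=od, metadata={"simulated": True, "params": params})


# ---------------------------------------------------------------------------
# competitions


def generate_competition(params: CompetitionSimParams):
    """Simulate a serial-transfer competition and return a CompetitionAssay.

    With exact sampling the relative-fitness estimator inverts the simulation
    exactly; Poisson sampling adds realistic plating noise.
    """
    from lacprofiler.fitness import CompetitionAssay

    rng = np.random.default_rng(params.seed)
    m_ref = math.log(params.dilution_factor)
    m_test = params.true_fitness * m_ref
    nt, nr = params.n0_test, params.n0_ref
    nt0_obs, nr0_obs = _plate(rng, nt, nr, params)
    for cycle in range(params.cycles):
        nt *= math.exp(m_test)
        nr *= math.exp(m_ref)
        if cycle < params.cycles - 1:
            nt /= params.dilution_factor
            nr /= params.dilution_factor
    nt2_obs, nr2_obs = _plate(rng, nt, nr, params)
    return CompetitionAssay(
        n_t0=nt0_obs,
        n_r0=nr0_obs,
        n_t2=nt2_obs,
        n_r2=nr2_obs,
        cycles=params.cycles,
        dilution_factor=params.dilution_factor,
    )


def _plate(rng: np.random.Generator, n_test: float, n_ref: float,
           params: CompetitionSimParams) -> tuple[float, float]:
    if params.count_sampling == "exact":
        return n_test, n_ref
    # plating volume chosen so the sample yields ~plating_colonies colonies
    vol = params.plating_colonies / (n_test + n_ref)
    ct = rng.poisson(n_test * vol)
    cr = rng.poisson(n_ref * vol)
    if ct == 0 or cr == 0:
        ct, cr = max(ct, 1), max(cr, 1)  # a plate with zero colonies is re-plated
    return ct / vol, cr / vol


# ---------------------------------------------------------------------------
# sequences


def generate_lac_sequences(
    genotype_label: str,
    reference: ReferenceLocus = DEFAULT_REFERENCE,
    clone_name: str | None = None,
) -> list[SeqRecord]:
    """Emit the two *lac* amplicons (lacI hotspot, lacO1 operator) for a genotype.

    ``genotype_label`` must be one of the recognized labels (``wt``,
    ``lacI-(ΔTGGC)``, ``lacI-(ΩTGGC)``, ``lacI-(L71Q)``, ``lacO1-G5A`` ...).
    Record ids are ``<clone>|lacI`` and ``<clone>|lacO1`` so multi-clone FASTA
    files stay unambiguous.  Round-trips through the genotyping module back to
    the same label.
    """
    name = clone_name or genotype_label
    lacI = reference.lacI_amplicon
    lacO1 = reference.lacO1_amplicon
    unit = reference.repeat_unit
    hotspot = unit * reference.n_repeats_wt

    if genotype_label == "wt":
        pass
    elif genotype_label == f"lacI-(Δ{unit})":
        lacI = lacI.replace(hotspot, unit * (reference.n_repeats_wt - 1))
    elif genotype_label == f"lacI-(Ω{unit})":
        lacI = lacI.replace(hotspot, unit * (reference.n_repeats_wt + 1))
    elif genotype_label.startswith("lacI-(") and genotype_label.endswith(")"):
        lacI = _apply_missense(lacI, genotype_label[6:-1], reference)
    elif genotype_label.startswith("lacO1-"):
        lacO1 = _apply_operator_snp(lacO1, genotype_label[6:], reference)
    else:
        raise ValueError(f"unknown genotype label {genotype_label!r}")

    return [
        SeqRecord(Seq(lacI), id=f"{name}|lacI", description="lacI hotspot amplicon (synthetic)"),
        SeqRecord(Seq(lacO1), id=f"{name}|lacO1", description="lacO1 operator amplicon (synthetic)"),
    ]


def _apply_missense(amplicon: str, sub: str, ref: ReferenceLocus) -> str:
    m = _parse_sub(sub)
    aa_from, codon_no, aa_to = m
    idx = codon_no - ref.lacI_first_codon
    if idx < 0 or 3 * idx + 3 > len(amplicon):
        raise ValueError(f"codon {codon_no} outside amplicon")
    codon = amplicon[3 * idx:3 * idx + 3]
    if str(Seq(codon).translate()) != aa_from:
        raise ValueError(f"reference codon {codon_no} is not {aa_from}")
    new_codon = _codon_for(aa_to, codon)
    return amplicon[:3 * idx] + new_codon + amplicon[3 * idx + 3:]


def _apply_operator_snp(amplicon: str, sub: str, ref: ReferenceLocus) -> str:
    base_from, pos, base_to = _parse_sub(sub)
    if not 1 <= pos <= ref.operator_length:
        raise ValueError(f"operator position {pos} outside 1..{ref.operator_length}")
    i = ref.operator_offset - 1 + pos - 1
    if amplicon[i] != base_from:
        raise ValueError(f"reference operator base at {pos} is not {base_from}")
    return amplicon[:i] + base_to + amplicon[i + 1:]


def _parse_sub(sub: str) -> tuple[str, int, str]:
    import re

    m = re.fullmatch(r"([A-Z])(\d+)([A-Z])", sub)
    if not m:
        raise ValueError(f"malformed substitution {sub!r}")
    return m.group(1), int(m.group(2)), m.group(3)


# minimal codon choices for introducing missense edits (single-base where possible)
_PREFERRED_CODONS = {"Q": "CAG", "L": "CTG", "A": "GCA", "V": "GTT", "E": "GAA"}


def _codon_for(aa: str, old_codon: str) -> str:
    # prefer a single-base change from the existing codon
    bases = "ACGT"
    for i in range(3):
        for b in bases:
            if b == old_codon[i]:
                continue
            cand = old_codon[:i] + b + old_codon[i + 1:]
            if str(Seq(cand).translate()) == aa:
                return cand
    try:
        return _PREFERRED_CODONS[aa]
    except KeyError:
        raise ValueError(f"no codon mapping for amino acid {aa!r}")
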