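"""Mutation-target-size modelling and mutation-environment association.

Why did operator (*lacO1*) mutations dominate only in the glucose+lactose
environment when repressor (*lacI*) null mutations arise ~1000-fold more
often?  This module carries the quantitative side of that question:

* a target-size model for the operator — 21 bp × 5×10⁻¹⁰ substitutions/bp/
  generation gives ~1×10⁻⁸ operator substitutions per generation, of which
  roughly a third (of the 63 possible single-base changes) severely impair
  repressor binding, for a loss-of-binding frequency of ~3×10⁻⁹;
* an exact two-sided Fisher test, computed by full enumeration of 2×2 tables
  with the observed margins (summing hypergeometric point probabilities no
  larger than the observed table's);
* a rules engine that reconstructs the environment × genotype contingency
  table from per-population clone records, with an explicit audit trail of
  inclusions and exclusions;
* allele-frequency tabulation for replay-evolution colony counts, with exact
  binomial intervals.
"""

from __future__ import annotations

import importlib.resources
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "MutationTargetModel",
    "ContingencyTable2x2",
    "PopulationRecord",
    "AssociationRules",
    "substitution_probability",
    "lof_frequency",
    "possible_substitutions",
    "frequency_ratio",
    "fisher_exact_two_sided",
    "build_environment_table",
    "allele_frequency_table",
    "load_table1",
    "round_1sf",
]


def round_1sf(x: float) -> float:
    """Round to one significant figure (the convention of order-of-magnitude
    mutation-frequency estimates)."""
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    return round(x, -exp)


@dataclass
class MutationTargetModel:
    """Per-generation mutation frequency model for a small DNA target.

    Defaults describe the 21-bp primary operator with a genomic point
    mutation rate of 5×10⁻¹⁰ per bp per generation; each bp admits 3
    substitutions (63 total) of which an estimated third compromise
    repressor binding severely.
    """

    per_bp_rate: float = 5e-10
    locus_length: int = 21
    substitutions_per_bp: int = 3
    deleterious_fraction: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if self.locus_length < 0:
            raise ValueError("locus_length must be nonnegative")
        if not 0 < self.deleterious_fraction <= 1:
            raise ValueError("deleterious_fraction must be in (0, 1]")
        if self.per_bp_rate < 0:
            raise ValueError("per_bp_rate must be nonnegative")


def substitution_probability(m: MutationTargetModel) -> dict[str, float]:
    """Per-generation probability of any single substitution in the locus.

    Returns the exact product ``locus_length × per_bp_rate`` and its
    1-significant-figure rounding (the order-of-magnitude convention).
    """
    exact = m.locus_length * m.per_bp_rate
    return {"exact": exact, "rounded": round_1sf(exact)}


def lof_frequency(m: MutationTargetModel) -> dict[str, float]:
    """Per-generation frequency of loss-of-function substitutions.

    Computed both exactly (deleterious_fraction × exact substitution
    probability) and along the rounding path (fraction × rounded
    substitution probability, re-rounded), since order-of-magnitude
    estimates are conventionally propagated through rounded intermediates.
    """
    sub = substitution_probability(m)
    exact = m.deleterious_fraction * sub["exact"]
    rounded = round_1sf(m.deleterious_fraction * sub["rounded"])
    return {"exact": exact, "rounded": rounded}


def possible_substitutions(m: MutationTargetModel) -> int:
    """Number of possible single-base substitutions in the locus."""
    return m.locus_length * m.substitutions_per_bp


def frequency_ratio(f_a: float, f_b: float) -> float:
    """Fold difference between two per-generation mutation frequencies."""
    if f_b == 0:
        raise ValueError("denominator frequency must be nonzero")
    return f_a / f_b


# ---------------------------------------------------------------------------
# exact association test


@dataclass
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]] with optional row/column labels."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("row1", "row2")
    col_labels: tuple[str, str] = ("col1", "col2")

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("counts must be nonnegative integers")
        if self.total == 0:
            raise ValueError("table total must be positive")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def fisher_exact_two_sided(t: ContingencyTable2x2, method: str = "minlike") -> float:
    """Exact two-sided P for a 2×2 table by margin-preserving enumeration.

    Enumerates every table with the observed margins and, under the default
    ``minlike`` convention, sums the hypergeometric point probabilities that
    do not exceed the observed table's (with a small numerical tolerance).
    ``method="doubled"`` instead doubles the smaller one-sided tail (capped
    at 1).  Degenerate margins (an empty row or column) carry no information
    and return P = 1 with a warning.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    r1, r2 = a + b, c + d
    c1 = a + c
    n = t.total
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        warnings.warn("degenerate margins: association test is uninformative")
        return 1.0

    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = float(stats.hypergeom.pmf(a, n, r1, c1))
    if method == "minlike":
        p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    elif method == "doubled":
        lower = float(pmf[support <= a].sum())
        upper = float(pmf[support >= a].sum())
        p = 2.0 * min(lower, upper)
    else:
        raise ValueError(f"unknown method {method!r}")
    if p >= 1.0 - 1e-9:  # full-support sums accumulate float error
        p = 1.0
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# population records and table reconstruction


@dataclass
class PopulationRecord:
    """Clones sampled from one evolved population with their frequencies."""

    population: str
    environment: str  # Glu | Lac | G+L | G/L
    clones: list[dict]  # each: {clone, frequency, genotype, regulatory_class}

    def __post_init__(self) -> None:
        if not self.clones:
            raise ValueError(f"population {self.population} has no clone records")
        total = sum(c["frequency"] for c in self.clones)
        if total > 1.005:
            raise ValueError(
                f"clone frequencies of {self.population} sum to {total:.3f} > 1"
            )
        if total < 0.995:
            # isolated clones need not exhaust a population; the remainder is
            # unsampled minority diversity
            warnings.warn(
                f"clone frequencies of {self.population} sum to {total:.3f}; "
                "treating the shortfall as unsampled clones"
            )

    def dominant_genotype(self) -> str:
        return max(self.clones, key=lambda c: c["frequency"])["genotype"]

    def genotype_types(self) -> set[str]:
        return {_genotype_type(c["genotype"]) for c in self.clones}


def _genotype_type(genotype: str) -> str:
    g = genotype.strip()
    if g.startswith("lacO1"):
        return "lacO1"
    if g.startswith("lacI"):
        return "lacI"
    if g.lower() in ("wt", "wild type"):
        return "wt"
    return "other"


@dataclass
class AssociationRules:
    """Declarative inclusion/grouping rules for the environment table.

    ``group_a``/``group_b`` are the environment groupings forming the two
    rows; populations whose clones include both repressor and operator
    lesions are polymorphic and excluded when ``exclude_polymorphic`` is
    set.  A population counts as a ``target`` population when its
    majority-frequency clone carries the target lesion.
    """

    group_a: frozenset[str] = frozenset({"G+L"})
    group_b: frozenset[str] = frozenset({"Lac", "G/L"})
    target: str = "lacO1"
    competitor: str = "lacI"
    exclude_polymorphic: bool = True
    exclude_populations: frozenset[str] = frozenset()


def build_environment_table(
    records: Sequence[PopulationRecord],
    rules: AssociationRules = AssociationRules(),
) -> tuple[ContingencyTable2x2, pd.DataFrame]:
    """Cross-classify populations by environment group × target-lesion presence.

    Returns the 2×2 table and an audit DataFrame listing every population
    with its group, classification, and inclusion status.
    """
    if not records:
        raise ValueError("no population records supplied")
    audit_rows = []
    counts = {("a", True): 0, ("a", False): 0, ("b", True): 0, ("b", False): 0}
    for rec in records:
        if rec.environment in rules.group_a:
            group = "a"
        elif rec.environment in rules.group_b:
            group = "b"
        else:
            audit_rows.append(_audit(rec, None, None, "environment outside groups"))
            continue
        types = rec.genotype_types()
        if rec.population in rules.exclude_populations:
            audit_rows.append(_audit(rec, group, None, "excluded by rule"))
            continue
        if rules.exclude_polymorphic and {rules.target, rules.competitor} <= types:
            audit_rows.append(_audit(rec, group, None,
                                     "polymorphic (target and competitor lesions)"))
            continue
        is_target = _genotype_type(rec.dominant_genotype()) == rules.target
        counts[(group, is_target)] += 1
        audit_rows.append(_audit(rec, group, is_target, "included"))

    table = ContingencyTable2x2(
        a=counts[("a", True)], b=counts[("a", False)],
        c=counts[("b", True)], d=counts[("b", False)],
        row_labels=("+".join(sorted(rules.group_a)), "+".join(sorted(rules.group_b))),
        col_labels=(rules.target, f"non-{rules.target}"),
    )
    return table, pd.DataFrame(audit_rows)


def _audit(rec: PopulationRecord, group, is_target, status) -> dict:
    return {
        "population": rec.population,
        "environment": rec.environment,
        "group": group,
        "dominant_genotype": rec.dominant_genotype(),
        "is_target": is_target,
        "status": status,
    }


# ---------------------------------------------------------------------------
# allele-frequency tabulation (replay experiments)


def allele_frequency_table(
    counts: pd.DataFrame,
    population_col: str = "population",
    generation_col: str = "generation",
    allele_cols: Sequence[str] = ("wt", "lacI", "lacO1"),
    ci_method: str = "beta",
) -> pd.DataFrame:
    """Long-format allele frequencies with binomial 95% intervals.

    ``counts`` holds one row per (population, generation) with colony counts
    per allele.  Frequencies are count/total; intervals are exact binomial
    (Clopper-Pearson) by default.
    """
    rows = []
    for _, row in counts.iterrows():
        ns = np.array([row[c] for c in allele_cols], dtype=float)
        if np.any(ns < 0):
            raise ValueError("counts must be nonnegative")
        total = ns.sum()
        if total == 0:
            raise ValueError(
                f"all-zero counts at {row[population_col]} gen {row[generation_col]}"
            )
        for allele, k in zip(allele_cols, ns):
            lo, hi = proportion_confint(int(k), int(total), alpha=0.05, method=ci_method)
            rows.append({
                "population": row[population_col],
                "generation": row[generation_col],
                "allele": allele,
                "count": int(k),
                "total": int(total),
                "frequency": k / total,
                "ci_low": float(lo),
                "ci_high": float(hi),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# packaged clone records


def load_table1(path: str | Path | None = None) -> tuple[list[PopulationRecord], pd.DataFrame]:
    """Load the packaged evolved-clone records (or a CSV with the same schema).

    Columns: population, environment, clone, frequency, genotype,
    regulatory_class.  Returns per-population records plus the flat frame.
    """
    if path is None:
        source = importlib.resources.files("lacprofiler.data") / "table1_clones.csv"
        with importlib.resources.as_file(source) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    records = []
    for (pop, env), grp in df.groupby(["population", "environment"], sort=False):
        records.append(PopulationRecord(
            population=pop,
            environment=env,
            clones=grp[["clone", "frequency", "genotype", "regulatory_class"]]
            .rename(columns={"regulatory_class": "regulatory_class"})
            .to_dict("records"),
        ))
    return records, df
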