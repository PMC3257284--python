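"""Target-size model, exact association test, and population tabulation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import lacprofiler as lp
from lacprofiler.selection import (
    AssociationRules,
    ContingencyTable2x2,
    MutationTargetModel,
    round_1sf,
)


class TestTargetModel:
    def test_operator_substitution_probability(self):
        sub = lp.substitution_probability(MutationTargetModel())
        assert sub["exact"] == pytest.approx(21 * 5e-10)
        assert sub["rounded"] == pytest.approx(1e-8)

    def test_lof_frequency_both_paths(self):
        lof = lp.lof_frequency(MutationTargetModel())
        assert lof["exact"] == pytest.approx(3.5e-9)
        assert lof["rounded"] == pytest.approx(3e-9)

    def test_literature_survey_fraction(self):
        m = MutationTargetModel(deleterious_fraction=16 / 63)
        assert lp.lof_frequency(m)["exact"] == pytest.approx(16 / 63 * 1.05e-8, rel=1e-9)

    def test_zero_length_locus(self):
        m = MutationTargetModel(locus_length=0, deleterious_fraction=1.0)
        assert lp.substitution_probability(m)["exact"] == 0.0

    def test_linearity_and_monotonicity(self):
        base = lp.lof_frequency(MutationTargetModel())["exact"]
        assert lp.lof_frequency(MutationTargetModel(per_bp_rate=1e-9))["exact"] == pytest.approx(2 * base)
        assert lp.lof_frequency(MutationTargetModel(locus_length=42))["exact"] == pytest.approx(2 * base)
        assert lp.lof_frequency(MutationTargetModel(deleterious_fraction=2 / 3))["exact"] == pytest.approx(2 * base)

    def test_possible_substitutions(self):
        assert lp.possible_substitutions(MutationTargetModel()) == 63

    def test_frequency_ratio(self):
        assert lp.frequency_ratio(3e-6, 3e-9) == pytest.approx(1000.0)
        assert lp.frequency_ratio(2.0, 2.0) == 1.0
        assert lp.frequency_ratio(3e-9, 3e-6) == pytest.approx(1e-3)
        with pytest.raises(ValueError):
            lp.frequency_ratio(1.0, 0.0)

    def test_round_1sf(self):
        assert round_1sf(1.05e-8) == pytest.approx(1e-8)
        assert round_1sf(2.67e-9) == pytest.approx(3e-9)
        assert round_1sf(0.0) == 0.0


def brute_force_two_sided(a, b, c, d):
    """Independent enumeration oracle using exact integer binomials."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    p_obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = math.comb(r1, x) * math.comb(r2, c1 - x)
        if px <= p_obs:
            total += px
    return total / denom


class TestFisherExact:
    def test_balanced_table_is_one(self):
        assert lp.fisher_exact_two_sided(ContingencyTable2x2(1, 1, 1, 1)) == 1.0

    def test_perfect_association_hand_enumeration(self):
        # [[5,0],[0,5]]: 2 of the C(10,5)=252 margin-preserving tables are
        # as extreme as observed
        p = lp.fisher_exact_two_sided(ContingencyTable2x2(5, 0, 0, 5))
        assert p == pytest.approx(2 / 252, rel=1e-9)

    def test_degenerate_margins_flagged(self):
        with pytest.warns(UserWarning):
            assert lp.fisher_exact_two_sided(ContingencyTable2x2(0, 0, 3, 4)) == 1.0

    @given(st.integers(0, 8), st.integers(0, 8), st.integers(0, 8), st.integers(0, 8))
    def test_matches_scipy_and_oracle(self, a, b, c, d):
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        t = ContingencyTable2x2(a, b, c, d)
        p = lp.fisher_exact_two_sided(t)
        assert p == pytest.approx(brute_force_two_sided(a, b, c, d), rel=1e-9)
        assert p == pytest.approx(
            stats.fisher_exact([[a, b], [c, d]]).pvalue, rel=1e-6
        )

    def test_two_sided_at_least_one_sided(self):
        for table in [(4, 1, 0, 12), (3, 2, 1, 9), (6, 1, 2, 2)]:
            t = ContingencyTable2x2(*table)
            p2 = lp.fisher_exact_two_sided(t)
            r1, c1, n = t.a + t.b, t.a + t.c, t.total
            upper = float(stats.hypergeom.sf(t.a - 1, n, r1, c1))
            lower = float(stats.hypergeom.cdf(t.a, n, r1, c1))
            assert p2 >= min(upper, lower) - 1e-12
            assert 0 < p2 <= 1

    def test_doubled_tail_variant(self):
        t = ContingencyTable2x2(4, 1, 0, 12)
        p_min = lp.fisher_exact_two_sided(t, method="minlike")
        p_dbl = lp.fisher_exact_two_sided(t, method="doubled")
        assert p_dbl >= p_min


class TestEnvironmentTable:
    def test_default_reconstruction(self):
        records, _ = lp.load_table1()
        table, audit = lp.build_environment_table(records)
        assert table.as_array().tolist() == [[4, 1], [0, 12]]
        excluded = audit[audit.status.str.startswith("polymorphic")]
        assert list(excluded.population) == ["G+L4"]

    def test_no_exclusion_assigns_by_majority(self):
        records, _ = lp.load_table1()
        table, _ = lp.build_environment_table(
            records, AssociationRules(exclude_polymorphic=False))
        assert table.as_array().tolist() == [[4, 2], [0, 12]]

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            lp.build_environment_table([])

    def test_audit_covers_every_population(self):
        records, _ = lp.load_table1()
        _, audit = lp.build_environment_table(records)
        assert set(audit.population) == {r.population for r in records}


class TestAlleleFrequencies:
    def test_worked_example(self):
        counts = pd.DataFrame([{"population": "R1", "generation": 400,
                                "wt": 2, "lacI": 98, "lacO1": 0}])
        out = lp.allele_frequency_table(counts)
        freqs = dict(zip(out.allele, out.frequency))
        assert freqs == pytest.approx({"wt": 0.02, "lacI": 0.98, "lacO1": 0.0})

    def test_single_allele_frequency_one(self):
        counts = pd.DataFrame([{"population": "R1", "generation": 100,
                                "wt": 0, "lacI": 50, "lacO1": 0}])
        out = lp.allele_frequency_table(counts)
        assert out.loc[out.allele == "lacI", "frequency"].iloc[0] == 1.0

    def test_frequencies_sum_to_one_with_valid_cis(self, rng):
        rows = [{"population": f"P{i}", "generation": g,
                 "wt": int(rng.integers(0, 50)), "lacI": int(rng.integers(1, 100)),
                 "lacO1": int(rng.integers(0, 5))}
                for i in range(3) for g in (100, 200)]
        out = lp.allele_frequency_table(pd.DataFrame(rows))
        sums = out.groupby(["population", "generation"])["frequency"].sum()
        assert np.allclose(sums, 1.0)
        assert ((out.ci_low <= out.frequency) & (out.frequency <= out.ci_high)).all()

    def test_all_zero_row_rejected(self):
        counts = pd.DataFrame([{"population": "R1", "generation": 100,
                                "wt": 0, "lacI": 0, "lacO1": 0}])
        with pytest.raises(ValueError):
            lp.allele_frequency_table(counts)


class TestTable1Fixture:
    def test_clone_and_population_counts(self):
        records, df = lp.load_table1()
        assert len(df) == 46
        assert len(records) == 24
        assert df[df.genotype == "No Seq"].shape[0] == 3

    def test_environments(self):
        _, df = lp.load_table1()
        assert set(df.environment) == {"Glu", "Lac", "G+L", "G/L"}
        assert df.groupby("environment")["population"].nunique().tolist() == [6, 6, 6, 6]
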