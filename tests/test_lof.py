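"""LOF relative levels, FDR machinery, reference set, synergy, enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from zgapipe.lof import (
    DOWN_LEVEL,
    LofCondition,
    amanitin_reference_set,
    bh_adjust,
    classify_lof_effect,
    hypergeometric_enrichment,
    lof_effect_table,
    rate_ratio_pvalues,
    relative_levels,
    synergy_factor,
    synergy_table,
)


def make_condition(cond_counts, ctrl_counts, label="X", intronic=None, ctrl_intronic=None):
    genes = [f"g{i}" for i in range(len(cond_counts))]

    def mat(arr):
        a = np.atleast_2d(np.asarray(arr, dtype=float))
        if a.shape[0] == 1:
            a = a.T
        return pd.DataFrame(a, index=genes)

    return LofCondition(
        label=label, exonic=mat(cond_counts), control_exonic=mat(ctrl_counts),
        intronic=mat(intronic) if intronic is not None else None,
        control_intronic=mat(ctrl_intronic) if ctrl_intronic is not None else None,
    )


class TestRelativeLevels:
    def test_identical_arms_are_100pct(self):
        c = make_condition([100, 200, 50], [100, 200, 50])
        df = relative_levels(c)
        np.testing.assert_allclose(df.relative_level, 100.0)
        assert (df.p_value > 0.9).all()

    def test_half_counts_give_50pct_and_small_p(self):
        n = 50
        c = make_condition([5000] * n + [10000] * n, [10000] * (2 * n))
        df = relative_levels(c)
        # library totals: condition 0.75× control → cpm ratio of halved genes
        # is (0.5/0.75)/1 ≈ 2/3 of the unaffected genes' ratio
        halved = df.relative_level[:n] / df.relative_level[n:].mean() * 100
        np.testing.assert_allclose(halved, 50.0, rtol=0.03)
        assert (df.p_value[:n] < 1e-6).all()

    def test_zero_counts_bounded_by_pseudo_rate(self):
        # one silenced gene among many unaffected ones: level ≈ pseudo-bounded
        c = make_condition([0] + [1000] * 99, [1000] * 100)
        lvl = relative_levels(c).relative_level.iloc[0]
        assert 0 < lvl < 10.0

    def test_more_extreme_signal_wins(self):
        # one gene loses 90% of its nascent (intronic) signal amid an
        # unaffected bulk; the combined level must follow the intronic arm
        c = make_condition(
            [1000] * 60, [1000] * 60,
            intronic=[100] + [1000] * 59, ctrl_intronic=[1000] * 60,
        )
        df = relative_levels(c)
        assert df.relative_level.iloc[0] == df.relative_level_intronic.iloc[0]
        assert df.relative_level.iloc[0] < 30
        assert df.relative_level.iloc[1] == pytest.approx(100.0, rel=0.05)

    def test_tidy_round_trip_treats_missing_gene_as_zero(self):
        tidy = pd.DataFrame(
            {
                "gene_id": ["a", "b", "a", "b", "a"],  # gene b absent in condition arm
                "condition": "X",
                "signal_type": "exonic",
                "arm": ["control", "control", "condition", "condition", "condition"],
                "replicate": [1, 1, 1, 1, 2],
                "count": [100.0, 100.0, 80.0, 0.0, 120.0],
            }
        )
        tidy = pd.concat([tidy, tidy.iloc[:0]])
        c = LofCondition.from_tidy(tidy, "X")
        assert c.exonic.loc["b"].fillna(0).sum() == 0


class TestRateRatio:
    def test_matches_exact_binomial_doubling_oracle(self):
        rng = np.random.default_rng(2)
        xs = rng.integers(0, 60, 30)
        ms = rng.integers(0, 60, 30)
        got = rate_ratio_pvalues(xs, ms, 1e6, 1e6)
        for x, m, p in zip(xs, ms, got):
            n = int(x + m)
            pmf = [math.comb(n, k) * 0.5**n for k in range(n + 1)]
            lo = sum(pmf[: x + 1])
            hi = sum(pmf[x:])
            expect = min(1.0, 2 * min(lo, hi)) if n else 1.0
            assert p == pytest.approx(expect, rel=1e-9)

    def test_unequal_depths_shift_null(self):
        # twice-deep condition library: equal rates means x ≈ 2m
        p_eq = rate_ratio_pvalues(np.array([200]), np.array([100]), 2e6, 1e6)
        p_diff = rate_ratio_pvalues(np.array([100]), np.array([100]), 2e6, 1e6)
        assert p_eq[0] > 0.5
        assert p_diff[0] < 0.01


class TestBHAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.01]), [0.01])

    def test_worked_stepup(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_brute_force_stepup_oracle(self):
        rng = np.random.default_rng(0)
        p = rng.random(25)
        got = bh_adjust(p)
        order = np.argsort(p)
        m = len(p)
        expect = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            expect[i] = running
        np.testing.assert_allclose(got, expect)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        p = rng.random(40)
        q1 = np.sort(bh_adjust(p))
        q2 = np.sort(bh_adjust(p[::-1]))
        np.testing.assert_allclose(q1, q2)

    def test_empty_vector(self):
        assert bh_adjust([]).size == 0


class TestClassification:
    @pytest.mark.parametrize(
        "level,call",
        [(100 / 1.5, "down"), (66.0, "down"), (150.0, "up"), (151.0, "up"),
         (100.0, "unchanged"), (67.0, "unchanged"), (149.9, "unchanged")],
    )
    def test_threshold_boundaries(self, level, call):
        assert classify_lof_effect(level) == call

    def test_reciprocal_antisymmetry(self):
        rng = np.random.default_rng(4)
        r = rng.uniform(10, 400, 500)
        calls = classify_lof_effect(r)
        recip = classify_lof_effect(100.0**2 / r)
        both = (calls == "down") & (recip == "down") | (calls == "up") & (recip == "up")
        assert not both.any()


class TestAmanitinReference:
    def make_effects(self, rows):
        df = pd.DataFrame(
            rows, columns=["relative_level_exonic", "relative_level_intronic", "q_value"]
        )
        df.index = [f"g{i}" for i in range(len(df))]
        df["relative_level"] = df.relative_level_exonic
        return df

    def test_andor_rule_and_fdr(self):
        eff = self.make_effects(
            [
                (40.0, 90.0, 0.05),  # exonic loss, significant → in
                (60.0, 45.0, 0.09),  # intronic loss ("and/or") → in
                (40.0, 40.0, 0.20),  # fails FDR → out
                (60.0, 60.0, 0.01),  # no ≥50% loss → out
            ]
        )
        got = amanitin_reference_set(eff, zygotic_genes=["g0", "g1", "g2", "g3"])
        assert got == {"g0", "g1"}

    def test_intersection_with_zygotic_list(self):
        eff = self.make_effects([(40.0, 40.0, 0.01), (40.0, 40.0, 0.01)])
        assert amanitin_reference_set(eff, zygotic_genes=["g1"]) == {"g1"}


class TestSynergy:
    def test_additive_pair(self):
        s = synergy_factor(80.0, 80.0, 60.0)
        assert s.synergy_factor == pytest.approx(1.0)

    def test_single_sided(self):
        s = synergy_factor(90.0, 100.0, 50.0)
        assert s.synergy_factor == pytest.approx(5.0)

    def test_no_effect_convention(self):
        assert synergy_factor(100.0, 105.0, 100.0).synergy_factor == 1.0

    def test_zero_singles_capped(self):
        assert synergy_factor(100.0, 110.0, 40.0).synergy_factor == 10.0
        assert synergy_factor(100.0, 110.0, 40.0, cap=5.0).synergy_factor == 5.0

    def test_deltas_clipped_to_unit_interval(self):
        s = synergy_factor(250.0, 80.0, -20.0)
        assert s.delta_single_a == 0.0
        assert s.delta_double == 1.0

    def test_table_restricted_to_given_genes(self):
        eff = pd.DataFrame({"relative_level": [80.0, 90.0, 70.0]}, index=["a", "b", "c"])
        tab = synergy_table(eff, eff, eff, pair_label="P", genes=["a", "c"])
        assert sorted(tab.index) == ["a", "c"]


class TestHypergeometric:
    def test_closed_form_full_overlap(self):
        universe = [f"u{i}" for i in range(10)]
        sel = universe[:5]
        p = hypergeometric_enrichment(sel, sel, universe)
        assert p == pytest.approx(1 / 252)  # C(5,5)/C(10,5)

    def test_annotated_equals_universe(self):
        universe = [f"u{i}" for i in range(8)]
        assert hypergeometric_enrichment(universe[:3], universe, universe) == pytest.approx(1.0)

    def test_enumeration_oracle_small_universes(self):
        """Exhaustive combinatorial check for every configuration, |U| ≤ 12."""
        for m in (5, 8, 12):
            universe = list(range(m))
            for big_k in (2, m // 2, m - 1):
                annotated = universe[:big_k]
                for n in (1, m // 2):
                    selected = universe[m - n:]
                    k_obs = len(set(selected) & set(annotated))
                    count = sum(
                        1
                        for combo in itertools.combinations(universe, n)
                        if len(set(combo) & set(annotated)) >= k_obs
                    )
                    expect = count / math.comb(m, n)
                    got = hypergeometric_enrichment(
                        [str(s) for s in selected],
                        [str(a) for a in annotated],
                        [str(u) for u in universe],
                    )
                    assert got == pytest.approx(expect, rel=1e-9)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment([], [], [])


class TestEffectTable:
    def test_columns_and_call_consistency(self):
        rng = np.random.default_rng(9)
        base = rng.poisson(500, 80).astype(float)
        c = make_condition(np.column_stack([base * 0.4] * 3), np.column_stack([base] * 3))
        tab = lof_effect_table(c)
        assert {"relative_level", "p_value", "q_value", "call"} <= set(tab.columns)
        assert (tab.q_value >= 0).all() and (tab.q_value <= 1).all()
        down = tab.relative_level <= DOWN_LEVEL
        assert (tab.call[down] == "down").all()
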