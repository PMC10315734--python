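import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from targetmeta.cohorts import GroupSummary
from targetmeta.meta import (
    EffectSize,
    MetaError,
    egger_test,
    genomewide_smd_screen,
    hedges_g,
    leave_one_out,
    pool_auto,
    pool_fixed,
    pool_random_dl,
    select_model,
    subgroup_smd,
)
from targetmeta.synthetic import SyntheticStudyConfig, generate_multicohort
from tests.conftest import make_cohort


def _effect(g, se, study="s"):
    return EffectSize(study, g, se, g - 1.96 * se, g + 1.96 * se)


def _oracle_hedges(n1, m1, s1, n2, m2, s2):
    """Textbook formulas written independently of the implementation."""
    import math
    df = n1 + n2 - 2
    sp = math.sqrt(((n1 - 1) * s1 * s1 + (n2 - 1) * s2 * s2) / df)
    d = (m1 - m2) / sp
    g = d * (1 - 3 / (4 * df - 1))
    se = math.sqrt((n1 + n2) / (n1 * n2) + g * g / (2 * (n1 + n2)))
    return g, se


class TestHedgesG:
    def test_equal_means_give_zero_effect_with_symmetric_ci(self):
        e = hedges_g(GroupSummary("g", 10, 5.0, 1.0, 10, 5.0, 1.2))
        assert e.g == 0.0
        assert e.ci_low == pytest.approx(-e.ci_high)

    def test_hand_example(self):
        e = hedges_g(GroupSummary("g", 10, 2.0, 1.0, 10, 1.0, 1.0))
        assert e.g == pytest.approx(1 * (1 - 3 / 71), abs=1e-12)
        assert e.g == pytest.approx(0.9577, abs=1e-4)
        assert e.se == pytest.approx(0.4722, abs=1e-4)

    def test_zero_pooled_sd_errors(self):
        with pytest.raises(MetaError, match="degenerate"):
            hedges_g(GroupSummary("g", 5, 1.0, 0.0, 5, 2.0, 0.0))

    def test_matches_formula_oracle_on_random_summaries(self, rng):
        for _ in range(1000):
            n1, n2 = rng.integers(2, 50, 2)
            m1, m2 = rng.normal(0, 3, 2)
            s1, s2 = rng.uniform(0.1, 3, 2)
            e = hedges_g(GroupSummary("g", int(n1), m1, s1, int(n2), m2, s2))
            g, se = _oracle_hedges(int(n1), m1, s1, int(n2), m2, s2)
            assert e.g == pytest.approx(g, abs=1e-12)
            assert e.se == pytest.approx(se, abs=1e-12)


class TestPooling:
    def test_two_identical_effects(self):
        p = pool_fixed([_effect(1, 0.5), _effect(1, 0.5)])
        assert p.mean == pytest.approx(1.0)
        assert p.se == pytest.approx(0.5 / np.sqrt(2), abs=1e-12)
        assert p.Q == 0.0 and p.I2 == 0.0

    def test_heterogeneous_pair_hand_computation(self):
        p = pool_fixed([_effect(0, 0.5), _effect(2, 0.5)])
        assert p.mean == pytest.approx(1.0)
        assert p.Q == pytest.approx(8.0)
        assert p.I2 == pytest.approx(87.5)

    def test_dl_hand_computation(self):
        p = pool_random_dl([_effect(0, 0.5), _effect(2, 0.5)])
        assert p.tau2 == pytest.approx(1.75)
        assert p.mean == pytest.approx(1.0)
        assert p.se == pytest.approx(1.0)

    def test_homogeneous_studies_reduce_dl_to_fixed(self):
        effects = [_effect(1.0, 0.5), _effect(1.01, 0.5), _effect(0.99, 0.5)]
        f, r = pool_fixed(effects), pool_random_dl(effects)
        assert r.tau2 == 0.0
        assert r.mean == pytest.approx(f.mean) and r.se == pytest.approx(f.se)

    def test_pooled_se_never_exceeds_best_study(self, rng):
        for _ in range(20):
            effects = [_effect(g, s) for g, s in
                       zip(rng.normal(0, 1, 5), rng.uniform(0.1, 1, 5))]
            assert pool_fixed(effects).se <= min(e.se for e in effects) + 1e-12

    def test_random_ci_at_least_as_wide_as_fixed(self, rng):
        for _ in range(20):
            effects = [_effect(g, s) for g, s in
                       zip(rng.normal(0, 1, 6), rng.uniform(0.1, 1, 6))]
            f, r = pool_fixed(effects), pool_random_dl(effects)
            assert (r.ci_high - r.ci_low) >= (f.ci_high - f.ci_low) - 1e-12

    def test_k_below_two_errors(self):
        with pytest.raises(MetaError):
            pool_fixed([_effect(1, 0.5)])

    def test_matches_textbook_oracle_on_random_inputs(self, rng):
        for _ in range(100):
            k = int(rng.integers(2, 12))
            g = rng.normal(0, 1, k)
            se = rng.uniform(0.1, 1.0, k)
            w = 1 / se**2
            mu = (w * g).sum() / w.sum()
            Q = (w * (g - mu) ** 2).sum()
            tau2 = max(0.0, (Q - (k - 1)) / (w.sum() - (w**2).sum() / w.sum()))
            ws = 1 / (se**2 + tau2)
            effects = [_effect(gi, si) for gi, si in zip(g, se)]
            f = pool_fixed(effects)
            r = pool_random_dl(effects)
            assert f.mean == pytest.approx(mu, abs=1e-10)
            assert f.Q == pytest.approx(Q, abs=1e-10)
            assert r.tau2 == pytest.approx(tau2, abs=1e-10)
            assert r.mean == pytest.approx((ws * g).sum() / ws.sum(), abs=1e-10)
            assert r.se == pytest.approx(1 / np.sqrt(ws.sum()), abs=1e-10)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.floats(-3, 3), st.floats(0.05, 2)),
                    min_size=2, max_size=10))
    def test_ci_always_brackets_the_pooled_mean(self, pairs):
        effects = [_effect(g, s) for g, s in pairs]
        for p in (pool_fixed(effects), pool_random_dl(effects)):
            assert p.ci_low <= p.mean <= p.ci_high
            assert 0 <= p.I2 < 100
            assert p.tau2 >= 0


class TestModelSelection:
    @pytest.mark.parametrize("i2,p_q,expected", [
        (79.8, 1e-5, "random"),   # high heterogeneity
        (0.0, 0.9, "fixed"),
        (40.0, 0.01, "random"),   # OR condition on the Q test
    ])
    def test_heterogeneity_rule(self, i2, p_q, expected):
        from targetmeta.meta import PooledEffect
        pooled = PooledEffect(5, "fixed", 1, 0.1, 0.8, 1.2, 10, 4, p_q, i2, 0)
        assert select_model(pooled) == expected


class TestEgger:
    def test_exactly_symmetric_funnel_has_zero_intercept(self):
        effects = []
        for dg, se in [(0.2, 0.3), (0.5, 0.5), (0.8, 0.7)]:
            effects.append(_effect(1 + dg, se))
            effects.append(_effect(1 - dg, se))
        res = egger_test(effects)
        assert abs(res.intercept) < 1e-9

    def test_matches_statsmodels_ols_oracle(self, rng):
        import statsmodels.api as sm
        for _ in range(100):
            k = int(rng.integers(3, 12))
            g = rng.normal(0.5, 1, k)
            se = rng.uniform(0.1, 1, k)
            effects = [_effect(gi, si) for gi, si in zip(g, se)]
            res = egger_test(effects)
            fit = sm.OLS(g / se, sm.add_constant(1 / se)).fit()
            assert res.intercept == pytest.approx(fit.params[0], abs=1e-10)
            assert res.se == pytest.approx(fit.bse[0], abs=1e-10)
            assert res.p == pytest.approx(fit.pvalues[0], abs=1e-10)

    def test_fewer_than_three_studies_errors(self):
        with pytest.raises(MetaError):
            egger_test([_effect(1, 0.5), _effect(1, 0.5)])


class TestLeaveOneOut:
    def test_identical_studies_reproduce_full_pooling(self):
        effects = [_effect(1.0, 0.5, f"s{i}") for i in range(4)]
        full = pool_auto(effects)
        for p in leave_one_out(effects):
            assert p.mean == pytest.approx(full.mean)
            assert p.model == full.model

    def test_output_length_is_k(self):
        effects = [_effect(g, 0.5) for g in (0.9, 1.0, 1.1, 1.05)]
        assert len(leave_one_out(effects)) == 4

    def test_omitting_the_outlier_minimizes_heterogeneity(self):
        effects = [_effect(1.0, 0.3), _effect(1.1, 0.3), _effect(0.9, 0.3),
                   _effect(5.0, 0.3)]
        loo = leave_one_out(effects)
        i2 = [p.I2 for p in loo]
        assert int(np.argmin(i2)) == 3


class TestGenomewideScreen:
    def test_planted_target_is_flagged_and_nulls_mostly_not(self, small_study):
        cohorts, truth = small_study
        records = {r.gene: r for r in genomewide_smd_screen(cohorts)}
        assert records[truth.target_gene].up_regulated
        null_genes = [g for g, d in truth.delta.items() if d == 0]
        flag_rate = np.mean([records[g].up_regulated for g in null_genes])
        assert flag_rate < 0.2

    def test_screen_forces_random_effects_model(self, small_study):
        cohorts, _ = small_study
        records = genomewide_smd_screen(cohorts)
        assert all(r.pooled.model == "random" for r in records)

    def test_up_flag_follows_the_ci_rule(self, small_study):
        cohorts, _ = small_study
        for r in genomewide_smd_screen(cohorts):
            assert r.up_regulated == (r.pooled.mean > 0 and r.pooled.ci_low > 0)

    def test_gene_with_one_usable_cohort_is_skipped(self):
        c1 = make_cohort({"A": [1, 2, 3, 4, 2, 3], "B": [5, 5, 5, 5, 5, 5]},
                         "tttccc", study_id="S1")
        c2 = make_cohort({"A": [2, 3, 4, 5, 3, 4], "B": [1, 2, 1, 3, 2, 1]},
                         "tttccc", study_id="S2")
        genes = [r.gene for r in genomewide_smd_screen([c1, c2])]
        assert genes == ["A"]


class TestSubgroupSmd:
    def test_null_subgroup_ci_covers_zero(self, small_study):
        cohorts, _ = small_study
        pooled = subgroup_smd(cohorts, "sex", "G00001")
        assert pooled.ci_low <= 0 <= pooled.ci_high

    def test_planted_sex_difference_is_detected(self, rng):
        import pandas as pd
        cohorts = []
        for s in range(3):
            n = 40
            x = rng.normal(5, 1, n)
            sex = np.array(["male", "female"])[rng.integers(0, 2, n)]
            x[sex == "male"] += 2.0
            c = make_cohort({"T1": x, "F1": rng.normal(size=n)}, "t" * n,
                            study_id=f"S{s}")
            c.clinical = pd.DataFrame({"sex": sex}, index=c.samples)
            cohorts.append(c)
        pooled = subgroup_smd(cohorts, "sex", "T1")
        assert pooled.mean > 0 and pooled.ci_low > 0

    def test_unknown_variable_errors(self, small_study):
        with pytest.raises(MetaError, match="unknown"):
            subgroup_smd(small_study[0], "histology", "G00001")


def test_null_generator_recovers_zero_pooled_effect():
    """Monte-Carlo under the null: mean pooled g of the target ~ 0."""
    cfg = SyntheticStudyConfig(n_cohorts=3, tumor_n=20, control_n=20, n_genes=10,
                               n_up_genes=2, coexpr_block_size=2,
                               target_effect=0.0, up_effect=0.0)
    from targetmeta.meta import effects_per_cohort
    means = []
    for rep in range(200):
        cohorts, truth = generate_multicohort(cfg, seed=rep)
        pooled = pool_auto(effects_per_cohort(cohorts, truth.target_gene))
        means.append(pooled.mean)
    assert abs(np.mean(means)) < 0.05
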