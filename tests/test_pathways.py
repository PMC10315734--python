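import numpy as np
import pandas as pd
import pytest

from targetmeta.pathways import (
    EnrichmentMatrix,
    GeneSetCatalog,
    PathwayDiffRecord,
    PathwayError,
    correlate_with_target,
    differential_pathways,
    pathway_analysis,
    score_catalog,
    select_target_pathways,
    ssgsea_score,
)


def _naive_ssgsea(expression: pd.Series, members, alpha):
    """Direct per-position summation, written independently."""
    order = sorted(expression.index, key=lambda g: (-expression[g], g))
    N = len(order)
    in_set = [g in set(members) for g in order]
    weights = [(N - i) ** alpha if in_set[i] else 0.0 for i in range(N)]
    wsum = sum(weights)
    n_out = N - sum(in_set)
    score, p_in, p_out = 0.0, 0.0, 0.0
    for i in range(N):
        p_in += weights[i] / wsum
        p_out += (0.0 if in_set[i] else 1.0) / n_out
        score += p_in - p_out
    return score


class TestSsgseaScore:
    def test_hand_example_three_genes_single_member(self):
        expr = pd.Series([3.0, 2.0, 1.0], index=["A", "B", "C"])
        assert ssgsea_score(expr, {"A"}, alpha=0.25) == pytest.approx(1.5)

    def test_invariant_to_input_gene_order(self, rng):
        expr = pd.Series(rng.normal(size=20), index=[f"g{i:02d}" for i in range(20)])
        shuffled = expr.sample(frac=1, random_state=0)
        members = {"g03", "g07", "g11"}
        assert ssgsea_score(expr, members) == pytest.approx(
            ssgsea_score(shuffled, members), abs=1e-12)

    def test_matches_naive_oracle_on_random_fixtures(self, rng):
        genes = [f"g{i:03d}" for i in range(200)]
        for _ in range(20):
            expr = pd.Series(rng.normal(size=200), index=genes)
            members = set(rng.choice(genes, size=int(rng.integers(5, 50)),
                                     replace=False))
            assert ssgsea_score(expr, members, 0.25) == pytest.approx(
                _naive_ssgsea(expr, members, 0.25), abs=1e-10)

    def test_empty_or_total_overlap_errors(self):
        expr = pd.Series([1.0, 2.0], index=["A", "B"])
        with pytest.raises(PathwayError):
            ssgsea_score(expr, {"Z"})
        with pytest.raises(PathwayError):
            ssgsea_score(expr, {"A", "B"})


class TestScoreCatalog:
    def test_shape_and_global_min_max_normalization(self, small_study, small_ancillary):
        cohorts, _ = small_study
        catalog = small_ancillary[0]
        em = score_catalog(cohorts[0], catalog)
        assert em.normalized
        assert em.scores.shape == (len(catalog), cohorts[0].n_samples)
        assert em.scores.to_numpy().min() == pytest.approx(0.0)
        assert em.scores.to_numpy().max() == pytest.approx(1.0)

    def test_matches_per_sample_scoring(self, small_study, small_ancillary):
        cohorts, _ = small_study
        catalog = small_ancillary[0]
        cohort = cohorts[0]
        name = list(catalog.sets)[0]
        sample = cohort.samples[3]
        raw = ssgsea_score(cohort.values[sample], catalog.sets[name])
        # undo the global min-max to compare raw scores
        all_raw = np.array([
            [ssgsea_score(cohort.values[s], catalog.sets[n])
             for s in cohort.samples] for n in catalog.sets])
        em = score_catalog(cohort, catalog)
        expected = (raw - all_raw.min()) / (all_raw.max() - all_raw.min())
        assert em.scores.loc[name, sample] == pytest.approx(expected, abs=1e-10)

    def test_non_overlapping_set_dropped_with_warning(self, small_study, caplog):
        cohorts, _ = small_study
        catalog = GeneSetCatalog({"ok": ["G00002", "G00003"], "alien": ["ZZZ1"]})
        with caplog.at_level("WARNING"):
            em = score_catalog(cohorts[0], catalog)
        assert list(em.scores.index) == ["ok"]
        assert "alien" in caplog.text

    def test_constant_expression_sample_scores_without_nan(self):
        from tests.conftest import make_cohort
        c = make_cohort({"A": [1, 1, 1, 1], "B": [1, 1, 1, 1], "C": [1, 1, 1, 1],
                         "D": [1, 1, 1, 1]}, "ttcc")
        em = score_catalog(c, GeneSetCatalog({"s": ["A", "B"]}))
        assert np.isfinite(em.scores.to_numpy()).all()


class TestDifferentialPathways:
    def _em(self, values, samples):
        frame = pd.DataFrame(values, columns=samples)
        return EnrichmentMatrix(frame, normalized=True)

    def test_identical_groups_are_null(self):
        samples = [f"s{i}" for i in range(8)]
        groups = pd.Series(["tumor"] * 4 + ["control"] * 4, index=samples)
        em = self._em({s: [0.5, 0.2] for s in samples}, samples)
        em.scores.index = ["p1", "p2"]
        recs = differential_pathways(em, groups)
        assert all(r.logFC == 0 for r in recs)
        assert all(r.p == pytest.approx(1.0) for r in recs)

    def test_bh_adjustment_hand_example(self, monkeypatch):
        from statsmodels.stats.multitest import multipletests
        adj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_bh_monotone_in_sorted_order(self, small_study, small_ancillary):
        cohorts, _ = small_study
        em = score_catalog(cohorts[0], small_ancillary[0])
        recs = differential_pathways(em, cohorts[0].groups)
        by_p = sorted(recs, key=lambda r: r.p)
        adj = [r.adj_p for r in by_p]
        assert all(a <= b + 1e-15 for a, b in zip(adj, adj[1:]))


class TestCorrelationAndSelection:
    def test_identity_and_antithesis_correlations(self):
        samples = [f"s{i}" for i in range(6)]
        target = pd.Series(np.arange(6.0), index=samples)
        scores = pd.DataFrame([np.arange(6.0), -np.arange(6.0)],
                              index=["same", "anti"], columns=samples)
        out = dict((n, r) for n, r, p, ok in
                   correlate_with_target(EnrichmentMatrix(scores), target))
        assert out["same"] == pytest.approx(1.0)
        assert out["anti"] == pytest.approx(-1.0)

    def test_hand_computed_r_on_four_samples(self):
        samples = list("abcd")
        x = np.array([1.0, 2.0, 4.0, 3.0])
        y = np.array([2.0, 1.0, 5.0, 4.0])
        r_hand = (np.sum((x - x.mean()) * (y - y.mean()))
                  / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
        em = EnrichmentMatrix(pd.DataFrame([x], index=["p"], columns=samples))
        (_, r, _, _), = correlate_with_target(em, pd.Series(y, index=samples))
        assert r == pytest.approx(r_hand, abs=1e-12)

    def test_zero_variance_score_flagged_invalid(self):
        samples = list("abcd")
        em = EnrichmentMatrix(pd.DataFrame([[0.5] * 4], index=["p"], columns=samples))
        (_, r, p, ok), = correlate_with_target(
            em, pd.Series([1.0, 2, 3, 4], index=samples))
        assert not ok and p == 1.0

    @pytest.mark.parametrize("logfc,adj_p,r,p_r,expected", [
        (6.47, 1e-5, 0.30, 1e-5, True),    # up in tumor and positively correlated
        (0.4, 0.01, -0.3, 0.001, False),   # up but anti-correlated
        (-0.4, 0.01, 0.3, 0.001, False),   # down-regulated
        (0.4, 0.2, 0.3, 0.001, False),     # not significant after adjustment
    ])
    def test_selection_rule(self, logfc, adj_p, r, p_r, expected):
        rec = PathwayDiffRecord("p", logfc, adj_p, adj_p, r, p_r)
        select_target_pathways([rec])
        assert rec.selected is expected

    def test_planted_pathway_selected_in_synthetic_study(self):
        # score-vs-target correlation needs a moderately sized tumor arm
        from targetmeta.synthetic import (
            SyntheticStudyConfig, generate_ancillary, generate_multicohort)
        cfg = SyntheticStudyConfig(n_cohorts=1, tumor_n=60, control_n=40,
                                   n_genes=300, n_up_genes=25, coexpr_block_size=15,
                                   n_gene_sets=10, set_size_range=(10, 40))
        cohorts, truth = generate_multicohort(cfg, 31)
        catalog, *_ = generate_ancillary(cfg, truth, 31, cohorts)
        records = pathway_analysis(cohorts[0], catalog, truth.target_gene)
        selected = {r.pathway for r in records if r.selected}
        assert truth.active_pathway in selected
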