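import numpy as np
import pandas as pd
import pytest
from scipy import stats

from budnet import (adjust_bh, estimate_dispersion, filter_degs, run_diffexp,
                    simulate_counts, wald_test)


class TestEstimateDispersion:
    def test_variance_equal_mean_gives_zero(self):
        # construct a row whose within-class variance equals its mean exactly
        row = np.array([2, 4, 3, 3, 2, 4], dtype=float)  # mean 3, var 0.8 < 3
        design = np.zeros(6, dtype=int)
        design[3:] = 1
        # both class halves: mean 3, var 1 -> v - m < 0 -> clipped to 0
        assert estimate_dispersion(row, np.ones(6), design) == 0.0

    def test_poisson_consistency_large_n(self):
        rng = np.random.default_rng(0)
        n = 50
        design = np.repeat([0, 1], n // 2)
        counts = rng.poisson(80.0, size=(1000, n))
        alpha = estimate_dispersion(counts, np.ones(n), design)
        assert np.median(alpha) <= 0.02

    def test_nb_parameter_recovery(self):
        rng = np.random.default_rng(1)
        n = 100
        design = np.repeat([0, 1], n // 2)
        mu, a = 100.0, 0.1
        r = 1 / a
        counts = rng.negative_binomial(r, r / (r + mu), size=(1000, n))
        alpha = estimate_dispersion(counts, np.ones(n), design)
        assert 0.05 <= np.median(alpha) <= 0.2

    def test_all_zero_gene_flagged_nan(self):
        design = np.array([0, 0, 1, 1])
        alpha = estimate_dispersion(np.zeros((1, 4)), np.ones(4), design)
        assert np.isnan(alpha)


class TestWaldTest:
    def test_two_sided_normal_tail(self):
        # printed stat/p pairs pin the two-sided standard-normal convention
        assert 2 * stats.norm.sf(4.6685) == pytest.approx(3.03e-6, rel=2e-3)
        assert 2 * stats.norm.sf(5.1302) == pytest.approx(2.89e-7, rel=2e-3)

    def test_identical_group_means(self):
        counts = np.array([10, 10, 10, 10, 10, 10])
        design = np.array([0, 0, 0, 1, 1, 1])
        row = wald_test(counts, np.ones(6), design, 0.05)
        assert row["logFC"] == pytest.approx(0.0, abs=1e-12)
        assert row["pvalue"] == pytest.approx(1.0)

    def test_stat_equals_lfc_over_se(self, annotation_12v3):
        cm, ann, _ = simulate_counts(n_genes=200, rng_seed=3)
        table = run_diffexp(cm, ann)
        ok = table["tested"]
        np.testing.assert_allclose(table.loc[ok, "stat"],
                                   table.loc[ok, "logFC"] /
                                   table.loc[ok, "lfcSE"], atol=1e-9)

    def test_monotone_in_high_class_counts(self):
        design = np.array([0, 0, 0, 1, 1, 1])
        counts = np.array([5, 7, 6, 12, 9, 14])
        base = wald_test(counts, np.ones(6), design, 0.1)["logFC"]
        for bump in (1, 5, 20):
            bumped = counts.copy()
            bumped[design == 1] += bump
            lfc = wald_test(bumped, np.ones(6), design, 0.1)["logFC"]
            assert lfc >= base
            base = lfc

    def test_poisson_glm_oracle_at_zero_dispersion(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(8)
        design = np.repeat([0, 1], [5, 7])
        sf = rng.uniform(0.5, 2.0, size=12)
        for _ in range(5):
            counts = rng.poisson(sf * np.where(design == 1, 60, 20))
            row = wald_test(counts, sf, design, 0.0)
            X = np.column_stack([np.ones(12), design])
            fit = sm.GLM(counts, X, family=sm.families.Poisson(),
                         offset=np.log(sf)).fit()
            assert row["logFC"] * np.log(2) == pytest.approx(fit.params[1],
                                                             abs=1e-6)
            assert row["lfcSE"] * np.log(2) == pytest.approx(fit.bse[1],
                                                             rel=1e-4)

    def test_zero_class_uses_pseudo_mean_and_flags(self):
        design = np.array([0, 0, 0, 1, 1, 1])
        counts = np.array([0, 0, 0, 40, 50, 60])
        row = wald_test(counts, np.ones(6), design, 0.1)
        assert row["zero_class"]
        assert np.isfinite(row["logFC"]) and row["logFC"] > 0
        # pseudo mean 0.5/mean(sf) = 0.5 for the zero class
        assert row["logFC"] == pytest.approx(np.log2(50 / 0.5), rel=1e-6)

    def test_all_zero_gene_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            wald_test(np.zeros(6), np.ones(6),
                      np.array([0, 0, 0, 1, 1, 1]), 0.1)


class TestAdjustBH:
    def test_worked_step_up_example(self):
        np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.04, 0.05]),
                                   [0.04, 0.04, 0.05, 0.05], atol=1e-12)

    def test_single_p_unchanged(self):
        assert adjust_bh([0.3])[0] == pytest.approx(0.3)

    def test_all_equal_p_unchanged(self):
        np.testing.assert_allclose(adjust_bh([0.2] * 5), 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.2])

    def test_padj_at_least_pvalue_and_monotone(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=100)
        q = adjust_bh(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestFilterDegs:
    def test_thresholds_are_strict(self):
        table = pd.DataFrame({
            "gene": ["kept", "lfc_fails", "padj_boundary"],
            "logFC": [-5.14, 1.2, 3.0],
            "padj": [0.002490, 0.03, 0.05],
        })
        assert filter_degs(table) == ["kept"]

    def test_missing_padj_rejected(self):
        with pytest.raises(ValueError, match="padj"):
            filter_degs(pd.DataFrame({"gene": [], "logFC": []}))


class TestRunDiffexp:
    def test_type_one_error_bounded_under_null(self):
        fracs = []
        for rep in range(20):
            cm, ann, _ = simulate_counts(n_genes=2000, de_fraction=0.0,
                                         n_separators=0, rng_seed=500 + rep)
            table = run_diffexp(cm, ann)
            p = table.loc[table["tested"], "pvalue"]
            fracs.append(np.mean(p < 0.05))
        assert 0.025 <= np.median(fracs) <= 0.10

    def test_all_zero_genes_excluded_from_bh_m(self):
        cm, ann, _ = simulate_counts(n_genes=100, n_separators=3, rng_seed=9)
        cm.counts[:10] = 0
        table = run_diffexp(cm, ann)
        assert not table.loc[:9, "tested"].any()
        assert table.loc[:9, "padj"].isna().all()
        tested = table["tested"] & table["pvalue"].notna()
        redo = adjust_bh(table.loc[tested, "pvalue"].to_numpy())
        np.testing.assert_allclose(table.loc[tested, "padj"], redo, atol=1e-12)

    def test_requires_both_classes(self, tiny_counts):
        from budnet import SampleAnnotation
        ann = SampleAnnotation(pd.DataFrame({
            "sample_id": ["s1", "s2"],
            "tb_level": ["high", "high"],
            "class_label": [1.0, 1.0]}))
        with pytest.raises(ValueError, match="both classes"):
            run_diffexp(tiny_counts, ann)

    def test_trend_mode_runs(self):
        cm, ann, truth = simulate_counts(n_genes=300, rng_seed=12)
        table = run_diffexp(cm, ann, dispersion_mode="trend")
        degs = set(filter_degs(table))
        assert len(degs & set(truth.de_genes)) > 0
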