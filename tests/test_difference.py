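import numpy as np
import pandas as pd
import pytest

import gmtrial as gm
from gmtrial.anova import decompose_cube
from gmtrial.difference import Method, difference_test_cube
from gmtrial.simulate import simulate_response_cube


def _dataset_with_identical_test_entries(design, seed=0):
    """Simulated dataset whose GMO and comparator plots agree plot-for-plot."""
    cfg = gm.SimulationConfig(
        design,
        gm.MeanStructure(mu_overall=1.0),
        gm.VarianceComponents(0.02, 0.01, 0.02, 0.01, None, None, 0.01),
        seed=seed,
    )
    cube = simulate_response_cube(
        design, cfg.means, cfg.varcomps, np.random.default_rng(seed)
    )
    k_gmo = design.genotype_labels.index(design.gmo_label)
    k_comp = design.genotype_labels.index(design.comparator_label)
    cube[:, :, k_gmo] = cube[:, :, k_comp]
    return cube


class TestNaiveDifferenceTest:
    def test_identical_test_entries_give_null_result(self, default_design):
        cube = _dataset_with_identical_test_entries(default_design)
        res = difference_test_cube(cube, default_design, 0.1, Method.NAIVE)
        assert res.estimate == 0
        assert res.t_statistic == 0
        assert res.p_value == 1

    def test_matches_no_interaction_ols_fit(self, simulated_dataset):
        """Independent oracle: the closed form equals the OLS fit of the
        no-interaction fixed-effects model (site + block-in-site + genotype)
        with a t-test on the GMO-minus-comparator contrast."""
        import statsmodels.formula.api as smf

        res = gm.naive_difference_test(simulated_dataset, alpha=0.1)
        df = simulated_dataset.frame.copy()
        df["site"] = df["site"].astype(str)
        df["block"] = df["block"].astype(str)
        fit = smf.ols(
            "response ~ C(site) + C(site):C(block) + C(genotype)", data=df
        ).fit()
        d = simulated_dataset.design
        contrast = f"C(genotype)[T.{d.gmo_label}] - C(genotype)[T.{d.comparator_label}]"
        # patsy drops the first genotype level; build the contrast explicitly
        names = fit.params.index
        vec = np.zeros(len(names))
        for i, n in enumerate(names):
            if n == f"C(genotype)[T.{d.gmo_label}]":
                vec[i] = 1.0
            elif n == f"C(genotype)[T.{d.comparator_label}]":
                vec[i] = -1.0
        tt = fit.t_test(vec)
        assert res.estimate == pytest.approx(float(tt.effect[0]), rel=1e-10)
        assert res.standard_error == pytest.approx(float(tt.sd[0][0]), rel=1e-10)
        assert res.df == fit.df_resid
        assert res.p_value == pytest.approx(float(tt.pvalue), rel=1e-8)

    def test_toy_dataset_hand_arithmetic(self):
        """2-site, 2-block, 3-genotype toy checked against direct arithmetic
        on the plot values (frozen from the explicit textbook formulas)."""
        design = gm.build_design(2, 2, 1)
        # responses laid out (site, block, genotype=[GMO, COMP, REF01])
        cube = np.array(
            [
                [[1.0, 0.8, 1.1], [1.2, 0.9, 1.0]],
                [[0.7, 0.9, 0.8], [1.0, 1.1, 1.2]],
            ]
        )
        res = difference_test_cube(cube, design, 0.1, Method.NAIVE)
        est = cube[:, :, 0].mean() - cube[:, :, 1].mean()  # 0.975 - 0.925
        assert res.estimate == pytest.approx(est)
        # pooled error: total SS minus site, block-in-site and genotype SS,
        # on (N-1) - (s-1) - s(b-1) - (g-1) = 6 df
        grand = cube.mean()
        ss_total = ((cube - grand) ** 2).sum()
        ss_site = 6 * ((cube.mean(axis=(1, 2)) - grand) ** 2).sum()
        ss_block = 3 * (
            (cube.mean(axis=2) - cube.mean(axis=(1, 2))[:, None]) ** 2
        ).sum()
        ss_geno = 4 * ((cube.mean(axis=(0, 1)) - grand) ** 2).sum()
        mse = (ss_total - ss_site - ss_block - ss_geno) / 6
        se = np.sqrt(2 * mse / 4)
        assert res.standard_error == pytest.approx(se, rel=1e-12)
        assert res.df == 6
        assert res.t_statistic == pytest.approx(est / se, rel=1e-12)

    def test_null_level_without_interaction(self, default_design):
        # 1000 null trials, no interaction: rejection rate ~ nominal 0.1
        vc = gm.VarianceComponents(
            sigma2_site=0.04, sigma2_block=0.005,
            sigma2_genotype=0.02, sigma2_residual=0.01,
        )
        rng = np.random.default_rng(2024)
        hits = 0
        for _ in range(1000):
            cube = simulate_response_cube(default_design, gm.MeanStructure(), vc, rng)
            if difference_test_cube(cube, default_design, 0.1, Method.NAIVE).p_value < 0.1:
                hits += 1
        assert abs(hits / 1000 - 0.10) < 2 * np.sqrt(0.1 * 0.9 / 1000)


class TestInteractionAwareTest:
    def test_identical_test_entries_give_null_result(self, default_design):
        cube = _dataset_with_identical_test_entries(default_design, seed=3)
        res = difference_test_cube(cube, default_design, 0.1, Method.INTERACTION_AWARE)
        assert res.t_statistic == 0
        assert res.p_value == 1

    def test_df_is_three_at_four_sites(self, simulated_dataset):
        res = gm.interaction_aware_difference_test(simulated_dataset)
        assert res.df == 3

    def test_equals_paired_t_on_site_differences(self, simulated_dataset):
        """Independent oracle: in the balanced layout the test is the paired
        t-test on per-site GMO-minus-comparator means."""
        from scipy import stats

        d = simulated_dataset.design
        cube = simulated_dataset.response_cube()
        k_gmo = d.genotype_labels.index(d.gmo_label)
        k_comp = d.genotype_labels.index(d.comparator_label)
        d_i = cube[:, :, k_gmo].mean(axis=1) - cube[:, :, k_comp].mean(axis=1)
        t_ref, p_ref = stats.ttest_1samp(d_i, 0.0)
        res = gm.interaction_aware_difference_test(simulated_dataset)
        assert res.t_statistic == pytest.approx(float(t_ref), rel=1e-10)
        assert res.p_value == pytest.approx(float(p_ref), rel=1e-10)

    def test_holds_level_under_interaction(self, default_design):
        vc = gm.VarianceComponents(
            sigma2_site=0.04, sigma2_block=0.005, sigma2_genotype=0.02,
            sigma2_interaction=0.02, sigma2_residual=0.01,
        )
        rng = np.random.default_rng(99)
        hits = 0
        for _ in range(1000):
            cube = simulate_response_cube(default_design, gm.MeanStructure(), vc, rng)
            res = difference_test_cube(
                cube, default_design, 0.1, Method.INTERACTION_AWARE
            )
            if res.p_value < 0.1:
                hits += 1
        assert abs(hits / 1000 - 0.10) < 2 * np.sqrt(0.1 * 0.9 / 1000)


class TestSharedProperties:
    @pytest.mark.parametrize("seed", [0, 7, 31])
    def test_same_estimate_different_error_terms(self, default_design, seed):
        vc = gm.VarianceComponents(0.02, 0.01, 0.02, 0.01, None, None, 0.01)
        cube = simulate_response_cube(
            default_design, gm.MeanStructure(mu_gmo_offset=0.05), vc,
            np.random.default_rng(seed),
        )
        naive = difference_test_cube(cube, default_design, 0.1, Method.NAIVE)
        aware = difference_test_cube(
            cube, default_design, 0.1, Method.INTERACTION_AWARE
        )
        assert naive.estimate == aware.estimate
        assert naive.standard_error != aware.standard_error

    def test_naive_ci_narrower_on_average_under_interaction(self, default_design):
        vc = gm.VarianceComponents(
            sigma2_genotype=0.02, sigma2_interaction=0.02, sigma2_residual=0.01
        )
        rng = np.random.default_rng(14)
        widths_naive, widths_aware = [], []
        for _ in range(300):
            cube = simulate_response_cube(default_design, gm.MeanStructure(), vc, rng)
            n = difference_test_cube(cube, default_design, 0.1, Method.NAIVE)
            a = difference_test_cube(
                cube, default_design, 0.1, Method.INTERACTION_AWARE
            )
            widths_naive.append(n.confidence_interval[1] - n.confidence_interval[0])
            widths_aware.append(a.confidence_interval[1] - a.confidence_interval[0])
        assert np.mean(widths_naive) < np.mean(widths_aware)

    def test_naive_null_rate_nondecreasing_in_interaction(self, default_design):
        rates = []
        for ratio in (0.0, 0.5, 1.0):
            vc = gm.VarianceComponents(
                sigma2_genotype=0.02, sigma2_interaction=ratio * 0.02,
                sigma2_residual=0.01,
            )
            rng = np.random.default_rng(55)
            hits = sum(
                difference_test_cube(
                    simulate_response_cube(
                        default_design, gm.MeanStructure(), vc, rng
                    ),
                    default_design, 0.1, Method.NAIVE,
                ).p_value
                < 0.1
                for _ in range(500)
            )
            rates.append(hits / 500)
        pooled_se = np.sqrt(max(rates) * (1 - max(rates)) / 500)
        assert rates[1] - rates[0] > -2 * pooled_se
        assert rates[2] - rates[1] > -2 * pooled_se
        assert rates[2] > 0.1 + 3 * pooled_se  # materially inflated

    def test_alpha_validated(self, simulated_dataset):
        with pytest.raises(gm.DesignError):
            gm.naive_difference_test(simulated_dataset, alpha=0.7)


class TestGxEInteractionTest:
    def test_additive_noiseless_data_has_zero_interaction_ss(self, default_design):
        s, b, g = 4, 4, 8
        site = np.arange(s)[:, None, None] * 0.3
        geno = np.arange(g)[None, None, :] * 0.1
        cube = 1.0 + site + geno + np.zeros((s, b, g))
        # add block-level noise so the residual MS is nonzero
        rng = np.random.default_rng(0)
        cube = cube + rng.normal(0, 0.01, size=(s, b, g))
        dec = decompose_cube(cube, default_design)
        # interaction SS is pure noise here; the additive structure itself
        # contributes exactly zero
        pure = 1.0 + np.arange(s)[:, None, None] * 0.3 + geno
        dec_pure = decompose_cube(np.broadcast_to(pure, (s, b, g)).copy(), default_design)
        assert dec_pure.ss("site_x_test_entry") == pytest.approx(0, abs=1e-12)
        assert dec_pure.interaction_ss == pytest.approx(0, abs=1e-12)

    def test_fixed_and_random_site_labelings_agree(self, simulated_dataset):
        a = gm.gxe_interaction_test(simulated_dataset, "random")
        b = gm.gxe_interaction_test(simulated_dataset, "fixed")
        assert b.statistic == pytest.approx(a.statistic, rel=1e-12)
        assert (a.df_num, a.df_den) == (b.df_num, b.df_den)

    def test_detects_strong_interaction(self, default_design):
        vc = gm.VarianceComponents(
            sigma2_genotype=0.02, sigma2_interaction=0.1, sigma2_residual=0.01
        )
        rng = np.random.default_rng(21)
        sig = 0
        for _ in range(200):
            cube = simulate_response_cube(default_design, gm.MeanStructure(), vc, rng)
            dec = decompose_cube(cube, default_design)
            from scipy import stats

            f = dec.ms("site_x_test_entry") / dec.ms("residual")
            if stats.f.sf(f, dec.df("site_x_test_entry"), dec.df("residual")) < 0.05:
                sig += 1
        assert sig > 100  # majority of replicates

    def test_invalid_labeling_rejected(self, simulated_dataset):
        with pytest.raises(gm.DesignError):
            gm.gxe_interaction_test(simulated_dataset, "mixed")
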