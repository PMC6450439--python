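"""Background model, control factors, geNorm selection and normalization."""

import numpy as np
import pandas as pd
import pytest

import immunopanel as ip
from immunopanel.io import ValidationError
from immunopanel.normalization import (
    BackgroundModel,
    fit_background,
    flag_low_expression,
    genorm_stability,
    normalize,
    positive_control_factors,
    subtract_background,
)
from immunopanel._utils import geometric_mean

from conftest import make_count_matrix


class TestBackground:
    def test_hand_computed_threshold(self):
        model = fit_background(np.array([10, 12, 8, 10, 10]))
        assert model.mean_background == pytest.approx(10.0)
        assert model.sd_background == pytest.approx(1.4142, abs=1e-4)
        assert model.threshold == pytest.approx(12.8284, abs=1e-4)

    def test_zero_variance_threshold_equals_mean(self):
        model = fit_background(np.full(8, 7.0))
        assert model.threshold == pytest.approx(7.0)

    def test_single_observation_rejected(self):
        with pytest.raises(ValidationError):
            fit_background(np.array([5.0]))

    def test_poisson_background_recovery(self, small_panel, two_group_design):
        """Threshold near 10 + 2*sqrt(10) for Poisson(10) negatives."""
        panel, _, _ = small_panel
        lo, hi = 10 + 2 * np.sqrt(10) * 0.6, 10 + 2 * np.sqrt(10) * 1.4
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            matrix, _ = ip.simulate_counts(panel, two_group_design, seed=seed)
            neg = matrix.counts.loc[panel.probes_of_class("negative")]
            model = fit_background(neg)
            hits += lo <= model.threshold <= hi
        assert hits / n_seeds >= 0.95


class TestSubtraction:
    def test_subtraction_and_floor(self, small_panel, two_group_design):
        panel, _, _ = small_panel
        matrix, _ = ip.simulate_counts(panel, two_group_design, seed=0)
        model = BackgroundModel(mean_background=10.0, sd_background=1.0)
        out = subtract_background(matrix, panel, model)
        endo = panel.probes_of_class("endogenous")
        raw = matrix.counts.loc[endo].to_numpy(float)
        sub = out.counts.loc[endo].to_numpy()
        assert np.array_equal(sub, np.clip(raw - 10.0, 0, None))
        # controls untouched
        pos = panel.probes_of_class("positive")
        assert np.array_equal(
            out.counts.loc[pos].to_numpy(), matrix.counts.loc[pos].to_numpy(float)
        )

    def test_zero_background_is_identity(self, small_panel, two_group_design):
        panel, _, _ = small_panel
        matrix, _ = ip.simulate_counts(panel, two_group_design, seed=0)
        model = BackgroundModel(0.0, 0.0)
        out = subtract_background(matrix, panel, model)
        assert np.array_equal(out.counts.to_numpy(), matrix.counts.to_numpy(float))

    def test_wrong_stage_rejected(self, small_panel, two_group_design):
        panel, _, _ = small_panel
        matrix, _ = ip.simulate_counts(panel, two_group_design, seed=0)
        model = BackgroundModel(0.0, 0.0)
        once = subtract_background(matrix, panel, model)
        with pytest.raises(ValidationError):
            subtract_background(once, panel, model)


class TestLowExpressionFlag:
    @pytest.fixture
    def tiny(self):
        table = pd.DataFrame(
            {
                "gene_symbol": ["GA", "GB", "GC"],
                "probe_class": ["endogenous"] * 3,
                "ladder_concentration": [np.nan] * 3,
            },
            index=["pA", "pB", "pC"],
        )
        panel = ip.PanelAnnotation(table)
        matrix = make_count_matrix(
            {"s1": [12, 13, 20], "s2": [12, 13, 20]}, ["pA", "pB", "pC"]
        )
        return panel, matrix

    def test_strict_below_rule(self, tiny):
        panel, matrix = tiny
        # threshold 12.8284...: gene mean 12 excluded, 13 and 20 retained
        model = BackgroundModel(10.0, 1.41421356)
        assert flag_low_expression(matrix, panel, model) == {"GA"}

    def test_boundary_gene_retained(self, tiny):
        panel, matrix = tiny
        model = BackgroundModel(12.0, 0.0)  # threshold exactly 12
        assert flag_low_expression(matrix, panel, model) == set()

    def test_zero_threshold_excludes_nothing(self, tiny):
        panel, matrix = tiny
        assert flag_low_expression(matrix, panel, BackgroundModel(0.0, 0.0)) == set()

    def test_monotone_in_threshold(self, small_panel, two_group_design):
        panel, _, _ = small_panel
        matrix, _ = ip.simulate_counts(panel, two_group_design, seed=1)
        excluded = [
            flag_low_expression(matrix, panel, BackgroundModel(mean, 0.0))
            for mean in (0.0, 50.0, 200.0, 1000.0)
        ]
        for smaller, larger in zip(excluded, excluded[1:]):
            assert smaller <= larger


class TestPositiveFactors:
    def test_hand_computed_factors(self):
        table = pd.DataFrame(
            {
                "gene_symbol": ["P1", "P2"],
                "probe_class": ["positive"] * 2,
                "ladder_concentration": [128.0, 32.0],
            },
            index=["p1", "p2"],
        )
        panel = ip.PanelAnnotation(table)
        # lane geomeans 100 and 200 -> factors 1.5 and 0.75
        matrix = make_count_matrix({"s1": [50, 200], "s2": [100, 400]}, ["p1", "p2"])
        factors = positive_control_factors(matrix, panel)
        assert factors["s1"] == pytest.approx(1.5)
        assert factors["s2"] == pytest.approx(0.75)

    def test_identical_lanes_give_unit_factors(self, small_panel, two_group_design):
        panel, _, _ = small_panel
        matrix, _ = ip.simulate_counts(panel, two_group_design, seed=0)
        counts = matrix.counts.copy()
        counts.loc[:, :] = counts.iloc[:, [0]].to_numpy()
        same = matrix.with_counts(counts.astype(np.int64), "raw")
        factors = positive_control_factors(same, panel)
        assert np.allclose(factors, 1.0)

    def test_doubling_a_lane_halves_its_factor(self, small_panel, two_group_design):
        panel, _, _ = small_panel
        matrix, _ = ip.simulate_counts(panel, two_group_design, seed=0)
        factors = positive_control_factors(matrix, panel)
        scaled_counts = matrix.counts.copy()
        lane = scaled_counts.columns[0]
        scaled_counts[lane] *= 2
        scaled = matrix.with_counts(scaled_counts, "raw")
        scaled_factors = positive_control_factors(scaled, panel)
        # the grand reference moves for all lanes equally; relative to any
        # unscaled lane the doubled lane's factor is exactly halved
        change = scaled_factors / factors
        other = scaled_factors.index[1]
        assert change[lane] / change[other] == pytest.approx(0.5, rel=1e-12)


class TestGenorm:
    def test_proportional_genes_have_zero_pairwise_sd(self):
        samples = [f"s{i}" for i in range(5)]
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        log_expr = pd.DataFrame(
            {s: [b, b + 1.0, b + 2.0] for s, b in zip(samples, base)},
            index=["g1", "g2", "g3"],
        )
        result = genorm_stability(log_expr)
        assert np.allclose(result.m_values, 0.0)

    def test_constant_genes_deterministic_tiebreak(self):
        log_expr = pd.DataFrame(
            np.ones((4, 5)), index=["gd", "gb", "gc", "ga"],
            columns=[f"s{i}" for i in range(5)],
        )
        result = genorm_stability(log_expr)
        assert result.removal_order == ["ga", "gb"]  # lexicographic among ties
        assert result.ranked[:2] == ["gc", "gd"]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        log_expr = pd.DataFrame(
            rng.normal(8, 1, size=(6, 10)),
            index=[f"g{i}" for i in range(6)],
            columns=[f"s{i}" for i in range(10)],
        )
        base = genorm_stability(log_expr)
        shuffled = log_expr.sample(frac=1.0, axis=0, random_state=1).sample(
            frac=1.0, axis=1, random_state=2
        )
        perm = genorm_stability(shuffled)
        assert base.removal_order == perm.removal_order
        assert base.selected == perm.selected
        pd.testing.assert_series_equal(
            base.m_values.sort_index(), perm.m_values.sort_index()
        )

    def test_too_few_candidates_rejected(self):
        log_expr = pd.DataFrame(np.ones((2, 4)), index=["a", "b"])
        with pytest.raises(ValidationError):
            genorm_stability(log_expr)

    def test_planted_unstable_genes_removed_first(self, small_panel, two_group_design):
        """2 unstable of 7 housekeeping genes leave first in >=95% of seeds."""
        panel, _, _ = small_panel
        hits = 0
        n_seeds = 60
        for seed in range(n_seeds):
            matrix, truth = ip.simulate_counts(panel, two_group_design, seed=seed)
            normalizer = ip.PanelNormalizer().fit(matrix, panel)
            first_removed = set(normalizer.stability_.removal_order[:2])
            hits += first_removed == truth.unstable_housekeeping
        assert hits / n_seeds >= 0.95


class TestNormalize:
    def test_housekeeping_factor_arithmetic(self):
        table = pd.DataFrame(
            {
                "gene_symbol": ["H1", "P1"],
                "probe_class": ["housekeeping", "positive"],
                "ladder_concentration": [np.nan, 128.0],
            },
            index=["h1", "p1"],
        )
        panel = ip.PanelAnnotation(table)
        matrix = make_count_matrix({"s1": [10, 100], "s2": [20, 100]}, ["h1", "p1"])
        sub = subtract_background(matrix, panel, BackgroundModel(0.0, 0.0))
        out: dict = {}
        normalize(sub, panel, ["H1"], factors_out=out)
        hk = out["factors"].housekeeping
        assert hk["s1"] == pytest.approx(1.5)
        assert hk["s2"] == pytest.approx(0.75)

    def test_unit_factors_identity(self, small_panel, two_group_design):
        panel, _, _ = small_panel
        matrix, _ = ip.simulate_counts(panel, two_group_design, seed=0)
        counts = matrix.counts.copy()
        counts.loc[:, :] = counts.iloc[:, [0]].to_numpy()
        same = matrix.with_counts(counts.astype(np.int64), "raw")
        sub = subtract_background(same, panel, BackgroundModel(0.0, 0.0))
        hk_genes = list(panel.genes_of_class("housekeeping"))[:3]
        out = normalize(sub, panel, hk_genes)
        assert np.allclose(out.counts.to_numpy(), sub.counts.to_numpy())

    def test_housekeeping_geomeans_equal_after_normalize(
        self, small_panel, normalized_experiment
    ):
        panel, _, _ = small_panel
        normalized, normalizer = normalized_experiment
        hk_table = panel.table[panel.table["probe_class"] == "housekeeping"]
        probes = hk_table.index[
            hk_table["gene_symbol"].isin(normalizer.selected_housekeeping_)
        ]
        geomeans = geometric_mean(normalized.counts.loc[probes].to_numpy(), axis=0)
        assert np.allclose(geomeans, geomeans[0], rtol=1e-9)

    def test_lane_scale_invariance(self, small_panel, two_group_design):
        """Scaling one lane by c>0 (controls included) leaves the normalized
        matrix unchanged up to one global constant (which cancels in every
        downstream ratio/Z statistic): all entry-wise ratios are equal."""
        panel, _, _ = small_panel
        matrix, _ = ip.simulate_counts(panel, two_group_design, seed=7)
        sub = subtract_background(matrix, panel, BackgroundModel(0.0, 0.0))
        hk_genes = list(panel.genes_of_class("housekeeping"))[:3]
        base = normalize(sub, panel, hk_genes)

        scaled_counts = sub.counts.copy()
        lane = scaled_counts.columns[3]
        scaled_counts[lane] *= 2.7
        scaled = sub.with_counts(scaled_counts, "background_subtracted")
        out = normalize(scaled, panel, hk_genes)

        base_vals = base.counts.to_numpy()
        out_vals = out.counts.to_numpy()
        nonzero = base_vals > 0
        ratios = out_vals[nonzero] / base_vals[nonzero]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)
        assert np.all(out_vals[~nonzero] == 0)

    def test_empty_selection_rejected(self, small_panel, two_group_design):
        panel, _, _ = small_panel
        matrix, _ = ip.simulate_counts(panel, two_group_design, seed=0)
        sub = subtract_background(matrix, panel, BackgroundModel(0.0, 0.0))
        with pytest.raises(ValidationError):
            normalize(sub, panel, [])
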