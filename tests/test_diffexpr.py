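"""Per-gene models, BH adjustment, the joint calling rule, contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import immunopanel as ip
from immunopanel.diffexpr import (
    Contrast,
    bh_adjust,
    call_de,
    fit_log_linear,
    fit_simplified_nb,
    log2_ratio,
    sequential_contrasts,
)
from immunopanel.io import ValidationError


def bh_bruteforce(p):
    """Independent step-up oracle: q_i = min over j>=rank(i) of p_(j)*m/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * m / rank)
        q[idx] = min(running_min, 1.0)
    return q


def _frame(case_vals, ref_vals):
    """Counts frame with case samples c* and reference samples r*."""
    case = np.atleast_2d(np.asarray(case_vals, dtype=float))
    ref = np.atleast_2d(np.asarray(ref_vals, dtype=float))
    data = np.hstack([case, ref])
    cols = [f"c{i}" for i in range(case.shape[1])] + [
        f"r{i}" for i in range(ref.shape[1])
    ]
    frame = pd.DataFrame(data, columns=cols, index=[f"g{i}" for i in range(len(data))])
    contrast = Contrast(
        "test", tuple(cols[: case.shape[1]]), tuple(cols[case.shape[1]:])
    )
    return frame, contrast


class TestLog2Ratio:
    @pytest.mark.parametrize(
        "case, ref, expected",
        [
            ([40, 40, 40], [10, 10, 10], 2.0),
            ([10, 10, 10], [10, 10, 10], 0.0),
            ([10, 10, 10], [40, 40, 40], -2.0),
        ],
    )
    def test_hand_values(self, case, ref, expected):
        frame, contrast = _frame([case], [ref])
        assert log2_ratio(frame, contrast).iloc[0] == pytest.approx(expected)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        frame, contrast = _frame(rng.poisson(100, (20, 4)), rng.poisson(50, (20, 4)))
        fwd = log2_ratio(frame, contrast)
        rev = log2_ratio(frame, contrast.swapped())
        np.testing.assert_allclose(fwd.to_numpy(), -rev.to_numpy())


class TestLogLinear:
    def test_identical_groups_give_t0_p1(self):
        frame, contrast = _frame([[2, 4, 8]], [[2, 4, 8]])
        res = fit_log_linear(frame, contrast)
        assert res["t"].iloc[0] == pytest.approx(0.0)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_zero_variance_flagged_degenerate(self):
        frame, contrast = _frame([[5, 5, 5, 5]], [[3, 3, 3, 3]])
        res = fit_log_linear(frame, contrast)
        assert bool(res["degenerate"].iloc[0])
        assert res["p"].iloc[0] == 0.0

    def test_t_and_swap_antisymmetry(self):
        rng = np.random.default_rng(1)
        frame, contrast = _frame(rng.poisson(100, (30, 6)), rng.poisson(100, (30, 6)))
        fwd = fit_log_linear(frame, contrast)
        rev = fit_log_linear(frame, contrast.swapped())
        np.testing.assert_allclose(fwd["t"].to_numpy(), -rev["t"].to_numpy())
        np.testing.assert_allclose(fwd["estimate"].to_numpy(), -rev["estimate"].to_numpy())

    def test_matches_scipy_ttest(self):
        """The OLS-on-indicator t equals the pooled two-sample t on logs."""
        rng = np.random.default_rng(2)
        frame, contrast = _frame(rng.poisson(80, (50, 8)), rng.poisson(80, (50, 8)))
        res = fit_log_linear(frame, contrast)
        ref = stats.ttest_ind(
            np.log2(frame[list(contrast.case)]),
            np.log2(frame[list(contrast.reference)]),
            axis=1,
        )
        np.testing.assert_allclose(res["t"].to_numpy(), ref.statistic, rtol=1e-12)
        np.testing.assert_allclose(res["p"].to_numpy(), ref.pvalue, rtol=1e-12)

    def test_null_calibration(self):
        """Under an NB null, mean t near 0 and type-I error near 5%."""
        rng = np.random.default_rng(3)
        n_genes = 1000
        counts = rng.negative_binomial(10, 10 / (10 + 100), size=(n_genes, 16))
        frame, contrast = _frame(counts[:, :8], counts[:, 8:])
        res = fit_log_linear(frame, contrast)
        assert abs(res["t"].mean()) < 0.1
        frac = (res["p"] < 0.05).mean()
        assert abs(frac - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / n_genes)


class TestSimplifiedNB:
    def test_identical_groups_near_null(self):
        frame, contrast = _frame([[50, 60, 55, 45]], [[50, 60, 55, 45]])
        offsets = pd.Series(1.0, index=frame.columns)
        res = fit_simplified_nb(frame, contrast, offsets)
        assert res["estimate"].iloc[0] == pytest.approx(0.0, abs=1e-6)
        assert res["p"].iloc[0] > 0.9

    def test_parameter_recovery(self):
        """Planted log2 effect of 2 recovered to within [1.8, 2.2] on average."""
        rng = np.random.default_rng(4)
        n_reps = 60
        mu_ref, alpha = 100.0, 0.1
        estimates = []
        for _ in range(n_reps):
            ref = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu_ref), size=(1, 8))
            case = rng.negative_binomial(
                1 / alpha, 1 / (1 + alpha * mu_ref * 4), size=(1, 8)
            )
            frame, contrast = _frame(case, ref)
            offsets = pd.Series(1.0, index=frame.columns)
            res = fit_simplified_nb(frame, contrast, offsets)
            estimates.append(res["estimate"].iloc[0])
        assert 1.8 <= np.mean(estimates) <= 2.2

    def test_small_dispersion_matches_poisson_wald(self):
        """As alpha -> 0 the NB Wald t approaches the Poisson regression t."""
        import statsmodels.api as sm

        counts = np.array([[12, 15, 11, 18, 30, 33, 29, 35]], dtype=float)
        frame, contrast = _frame(counts[:, 4:], counts[:, :4])
        offsets = pd.Series(1.0, index=frame.columns)
        res = fit_simplified_nb(frame, contrast, offsets)
        x = np.column_stack([np.ones(8), np.r_[np.ones(4), np.zeros(4)]])
        y = frame[list(contrast.case) + list(contrast.reference)].to_numpy()[0]
        pois = sm.GLM(y, x, family=sm.families.Poisson()).fit()
        t_pois = pois.params[1] / pois.bse[1]
        assert res["t"].iloc[0] == pytest.approx(t_pois, rel=0.05)


class TestBH:
    def test_hand_stepup(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    def test_matches_bruteforce_oracle_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            p = rng.random(rng.integers(1, 60))
            np.testing.assert_allclose(bh_adjust(p), bh_bruteforce(p), atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_properties(self, p_list):
        q = bh_adjust(p_list)
        assert ((q >= 0) & (q <= 1)).all()
        order = np.argsort(p_list, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()
        np.testing.assert_allclose(q, bh_bruteforce(p_list), atol=1e-12)


class TestCallRule:
    @pytest.mark.parametrize(
        "q, ratio, expected",
        [
            (0.04, 1.5, True),
            (0.04, 1.0, False),  # strict on the ratio
            (0.05, 3.0, False),  # strict on q
            (0.04, -1.5, True),
            (0.04, -1.0, False),
        ],
    )
    def test_strict_joint_rule(self, q, ratio, expected):
        assert call_de([q], [ratio])[0] == expected


class TestSequential:
    @pytest.fixture
    def chronic(self, small_panel):
        panel, _, _ = small_panel
        design = ip.build_design(
            [("cSiO2", "four_weekly", w, "lung", 8) for w in ("W1", "W5")]
            + [("VEH", "four_weekly", w, "lung", 8) for w in ("W1", "W5")]
        )
        return panel, design

    def test_single_time_point_rejected(self, chronic):
        panel, design = chronic
        matrix, _ = ip.simulate_counts(panel, design, seed=0)
        normalized = ip.PanelNormalizer().fit_transform(matrix, panel)
        with pytest.raises(ValidationError):
            sequential_contrasts(normalized, ["W1"], annotation=panel)

    def test_unknown_time_point_rejected(self, chronic):
        panel, design = chronic
        matrix, _ = ip.simulate_counts(panel, design, seed=0)
        normalized = ip.PanelNormalizer().fit_transform(matrix, panel)
        with pytest.raises(ValidationError):
            sequential_contrasts(normalized, ["W1", "W9"], annotation=panel)

    def test_null_yields_almost_no_calls(self, chronic):
        """Identical distributions at both times: <=1% significant genes."""
        panel, design = chronic
        rates = []
        for seed in range(10):
            matrix, _ = ip.simulate_counts(panel, design, seed=seed)
            normalized = ip.PanelNormalizer().fit_transform(matrix, panel)
            res = sequential_contrasts(normalized, ["W1", "W5"], annotation=panel)
            table = res["W5-vs-W1"]
            rates.append(table["significant"].mean())
        assert np.mean(rates) <= 0.01

    def test_planted_step_recovered(self, small_panel):
        """+2 log2 step between W1 and W5 on 20 genes: >=18/20 recovered."""
        panel, _, _ = small_panel
        genes = list(panel.genes_of_class("endogenous"))[:20]
        design = ip.build_design(
            [("cSiO2", "four_weekly", "W1", "lung", 8),
             ("cSiO2", "four_weekly", "W5", "lung", 8)]
        )
        config = ip.SimulationConfig(
            effects={g: 2.0 for g in genes},
            effect_time_points=("W5",),
            responder_fraction=1.0,
        )
        recovered = []
        for seed in range(10):
            matrix, _ = ip.simulate_counts(panel, design, config, seed=seed)
            normalizer = ip.PanelNormalizer()
            normalized = normalizer.fit_transform(matrix, panel)
            table = sequential_contrasts(
                normalized, ["W1", "W5"], annotation=panel,
                exclude_genes=normalizer.excluded_genes_,
            )["W5-vs-W1"]
            present = [g for g in genes if g in table.index]
            recovered.append(
                table.loc[present, "significant"].sum() + (20 - len(present)) * 0
            )
        assert np.median(recovered) >= 18
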