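import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logit

import ordtrial as ot
from ordtrial.anatomy import LevCode, all_lev_codes
from ordtrial.ordinal import (
    CoefficientSet,
    DesignSpec,
    _Likelihood,
    build_transitional_rows,
    cumulative_probabilities,
    encode_design,
    fit_proportional_odds,
    neg_log_likelihood,
    predict_category_probabilities,
    sample_score,
)

UNIFORM_CUTPOINTS = logit(np.arange(1, 6) / 6.0)


def _rows_df(tuples):
    """tuples of (lev_label, y_base, y_auto, y_out, arm)"""
    recs = []
    for i, (lev, yb, ya, yo, arm) in enumerate(tuples):
        code = LevCode.from_label(lev)
        recs.append((f"p{i}", "left", "C6", code.motor_level, code, yb, ya, yo, arm))
    return pd.DataFrame(
        recs,
        columns=["participant_id", "side", "segment", "motor_level", "lev", "y_base", "y_auto", "y_out", "arm"],
    )


# ---------------------------------------------------------------------------
# coefficient container
# ---------------------------------------------------------------------------


class TestCoefficientSet:
    def test_five_cutpoints_required(self):
        with pytest.raises(ValueError):
            CoefficientSet(cutpoints=np.zeros(4))

    def test_cutpoints_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            CoefficientSet(cutpoints=np.array([0.0, 1.0, 1.0, 2.0, 3.0]))

    def test_reference_levels_fixed_at_zero(self):
        with pytest.raises(ValueError):
            CoefficientSet(cutpoints=np.arange(5.0), beta_base={0: 0.3})

    def test_json_round_trip(self, tmp_path, default_pop):
        coeffs = default_pop.coefficients
        path = tmp_path / "coeffs.json"
        coeffs.to_json(path)
        back = CoefficientSet.from_json(path)
        assert np.allclose(back.cutpoints, coeffs.cutpoints)
        assert back.beta_lev == coeffs.beta_lev
        assert back.beta_base == coeffs.beta_base
        assert back.beta_auto == coeffs.beta_auto
        assert back.beta_trt == coeffs.beta_trt

    def test_odds_ratio_reporting(self):
        c = CoefficientSet(cutpoints=np.arange(5.0), beta_trt=-0.197)
        assert round(c.odds_ratio(), 2) == 0.82


# ---------------------------------------------------------------------------
# long-format construction
# ---------------------------------------------------------------------------


class TestBuildTransitionalRows:
    def test_left_c5_right_t1_gives_four_rows(self, record_factory):
        rec = record_factory("a", 0, "C5", "T1", [5] + [2] * 4 + [5] * 5, [5] + [3] * 4 + [5] * 5)
        rows = build_transitional_rows([rec])
        assert len(rows) == 4
        assert set(rows["side"]) == {"left"}

    def test_both_c8_gives_two_rows_at_c8_minus1(self, record_factory):
        rec = record_factory("a", 1, "C8", "C8", [5, 5, 5, 3, 1] * 2, [5, 5, 5, 4, 2] * 2)
        rows = build_transitional_rows([rec])
        assert len(rows) == 2
        assert all(code == LevCode("C8", -1) for code in rows["lev"])
        assert set(rows["arm"]) == {1}

    def test_autoregressive_alignment(self, record_factory):
        # left ML C5: follow-up chain 5(at C5), then below-level C6..T1
        fu = [4, 3, 2, 1, 0] + [5] * 5
        rec = record_factory("a", 0, "C5", "T1", [5, 1, 1, 1, 1] + [5] * 5, fu)
        rows = build_transitional_rows([rec]).set_index("segment")
        # y_auto at distance -1 is the at-level follow-up score
        assert rows.loc["C6", "y_auto"] == 4
        assert rows.loc["C7", "y_auto"] == 3
        assert rows.loc["C8", "y_auto"] == 2
        assert rows.loc["T1", "y_auto"] == 1
        assert rows.loc["T1", "y_out"] == 0

    def test_row_count_matches_brute_force(self, default_pop):
        rng = np.random.default_rng(5)
        records = ot.simulate_trial(default_pop, 50, 0.0, rng)
        rows = build_transitional_rows(records)
        # independent count: 5 - rank per side, zero for T1
        rank = {"C5": 0, "C6": 1, "C7": 2, "C8": 3, "T1": 4}
        expected = 0
        for rec in records:
            for ml in (rec.constellation.left_ml, rec.constellation.right_ml):
                expected += 4 - rank[ml]
        assert len(rows) == expected

    def test_score_out_of_range_rejected(self, record_factory):
        rec = record_factory("a", 0, "C5", "C5", [6] * 10, [5] * 10)
        with pytest.raises(ValueError, match="score outside"):
            build_transitional_rows([rec])


# ---------------------------------------------------------------------------
# design encoding
# ---------------------------------------------------------------------------


class TestEncodeDesign:
    def test_full_coverage_with_treatment_gives_20_columns(self, default_pop):
        rng = np.random.default_rng(0)
        records = ot.simulate_trial(default_pop, 600, 0.0, rng)
        rows = build_transitional_rows(records)
        spec = encode_design(rows, include_treatment=True)
        assert len(spec.labels) == 9 + 5 + 5 + 1
        assert spec.labels[-1] == "trt"
        assert spec.X.shape == (len(rows), 20)

    def test_constant_baseline_emits_no_base_columns(self):
        rows = _rows_df([("C5.-1", 0, 1, y, 0) for y in (0, 1, 2, 3, 4, 5)])
        spec = encode_design(rows)
        assert not any(lab.startswith("base:") for lab in spec.labels)
        assert spec.dropped_levels["y_base"] == ["1", "2", "3", "4", "5"]

    def test_single_nonreference_lev_becomes_reference(self):
        rows = _rows_df([("C8.-1", 0, 0, y, 0) for y in (0, 1, 2, 3, 4, 5)])
        spec = encode_design(rows)
        assert not any(lab.startswith("lev:") for lab in spec.labels)
        assert spec.lev_reference == LevCode("C8", -1)
        assert "reference->C8.-1" in spec.dropped_levels["lev"]

    def test_degenerate_outcome_rejected(self):
        rows = _rows_df([("C5.-1", 0, 0, 3, 0)] * 4)
        with pytest.raises(ValueError, match="outcome degenerate"):
            encode_design(rows)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


class TestNegLogLikelihood:
    def test_uniform_categories_single_row(self):
        coeffs = CoefficientSet(cutpoints=UNIFORM_CUTPOINTS)
        rows = _rows_df([("C5.-1", 0, 0, 3, 0)])
        assert neg_log_likelihood(coeffs, rows) == pytest.approx(-math.log(1 / 6), rel=1e-12)

    def test_matches_independent_per_row_sum(self):
        # 20-row fixture vs a straight-line reimplementation
        rng = np.random.default_rng(42)
        labels = [c.label for c in all_lev_codes()]
        rows = _rows_df(
            [
                (labels[rng.integers(10)], rng.integers(6), rng.integers(6), rng.integers(6), rng.integers(2))
                for _ in range(20)
            ]
        )
        coeffs = CoefficientSet(
            cutpoints=np.array([-2.0, -1.0, 0.0, 1.0, 2.0]),
            beta_lev={c: 0.1 * i for i, c in enumerate(all_lev_codes()) if i > 0},
            beta_base={i: 0.2 * i for i in range(1, 6)},
            beta_auto={i: 0.15 * i for i in range(1, 6)},
            beta_trt=0.3,
        )
        expected = 0.0
        for _, r in rows.iterrows():
            eta = (
                coeffs.beta_lev.get(r["lev"], 0.0)
                + coeffs.beta_base.get(r["y_base"], 0.0)
                + coeffs.beta_auto.get(r["y_auto"], 0.0)
                + coeffs.beta_trt * r["arm"]
            )
            cdf = [1.0 / (1.0 + math.exp(-(a - eta))) for a in coeffs.cutpoints] + [1.0]
            k = r["y_out"]
            p = cdf[k] - (cdf[k - 1] if k > 0 else 0.0)
            expected -= math.log(p)
        assert neg_log_likelihood(coeffs, rows) == pytest.approx(expected, rel=1e-12)

    def test_strong_treatment_limit(self):
        rows = _rows_df([("C5.-1", 0, 0, 5, 1)])
        coeffs = CoefficientSet(cutpoints=UNIFORM_CUTPOINTS, beta_trt=50.0)
        # P(Y=5 | treated) -> 1, so the row contributes ~0
        assert neg_log_likelihood(coeffs, rows) < 1e-10

    def test_non_increasing_cutpoints_rejected(self):
        with pytest.raises(ValueError):
            CoefficientSet(cutpoints=np.array([1.0, 0.5, 2.0, 3.0, 4.0]))


class TestGradient:
    def test_analytic_gradient_matches_finite_differences(self, default_pop):
        rng = np.random.default_rng(3)
        records = ot.simulate_trial(default_pop, 80, 0.2, rng)
        rows = build_transitional_rows(records)
        spec = encode_design(rows, include_treatment=True)
        lik = _Likelihood(spec.X, spec.y)
        for trial in range(3):
            theta = np.concatenate(
                [[-1.0 + trial * 0.3], np.log(np.full(4, 0.8)), rng.normal(scale=0.2, size=spec.X.shape[1])]
            )
            _, grad = lik(theta)
            eps = 1e-6
            for j in rng.choice(len(theta), size=6, replace=False):
                e = np.zeros_like(theta)
                e[j] = eps
                fd = (lik(theta + e)[0] - lik(theta - e)[0]) / (2 * eps)
                assert grad[j] == pytest.approx(fd, rel=1e-5, abs=1e-6)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


class TestFit:
    def test_intercept_only_closed_form(self):
        # outcome frequencies f_k -> cutpoints logit(cumsum f), ll = sum n_k log f_k
        counts = {0: 4, 1: 6, 2: 10, 3: 8, 4: 7, 5: 5}
        rows = _rows_df([("C5.-1", 0, 0, k, 0) for k, n in counts.items() for _ in range(n)])
        fit = fit_proportional_odds(rows)
        n = sum(counts.values())
        freqs = np.array([counts[k] / n for k in range(6)])
        assert fit.converged
        assert np.allclose(fit.coefficients.cutpoints, logit(np.cumsum(freqs)[:5]), atol=1e-5)
        expected_ll = sum(cnt * math.log(counts[k] / n) for k, cnt in counts.items())
        assert fit.log_likelihood == pytest.approx(expected_ll, abs=1e-8)

    def test_grid_search_oracle(self):
        # 30 rows, one binary covariate; the free MLE must dominate a dense
        # grid over the restricted family (alpha_1, equal increment, beta)
        rng = np.random.default_rng(7)
        rows = _rows_df(
            [("C5.-1", 0, 0, int(y), int(a)) for y, a in zip(rng.integers(0, 6, 30), rng.integers(0, 2, 30))]
        )
        fit = fit_proportional_odds(rows, include_treatment=True)
        best = -np.inf
        for a1 in np.linspace(-3, 1, 41):
            for inc in np.linspace(0.1, 2.0, 39):
                cut = a1 + inc * np.arange(5)
                for b in np.linspace(-2, 2, 41):
                    c = CoefficientSet(cutpoints=cut, beta_trt=b)
                    best = max(best, -neg_log_likelihood(c, rows))
        assert fit.log_likelihood >= best - 1e-6

    def test_treatment_recovery_large_sample(self, default_pop):
        rng = np.random.default_rng(2024)
        records = ot.simulate_trial(default_pop, 4000, math.log(1.3), rng)
        rows = build_transitional_rows(records)
        fit = fit_proportional_odds(rows, include_treatment=True)
        assert fit.converged
        # tolerance ~3 empirical SEs of beta_trt at this size
        assert fit.coefficients.beta_trt == pytest.approx(math.log(1.3), abs=0.05)

    def test_likelihood_invariant_to_factor_recoding(self, default_pop):
        rng = np.random.default_rng(9)
        records = ot.simulate_trial(default_pop, 300, 0.0, rng)
        rows = build_transitional_rows(records)
        spec = encode_design(rows, include_treatment=True)
        fit_ref = fit_proportional_odds(rows, design=spec)
        # recode y_base dummies against reference level 5 instead of 0
        base_cols = [i for i, lab in enumerate(spec.labels) if lab.startswith("base:")]
        other_cols = [i for i in range(spec.X.shape[1]) if i not in base_cols]
        vals = rows["y_base"].to_numpy()
        new_cols = [(vals == lvl).astype(float) for lvl in range(5)]
        X2 = np.column_stack([spec.X[:, other_cols]] + new_cols)
        # neutral labels: these columns are not mapped back into the
        # coefficient container, which is fine for a likelihood comparison
        labels2 = [spec.labels[i] for i in other_cols] + [f"alt:{lvl}" for lvl in range(5)]
        spec2 = DesignSpec(labels2, X2, spec.y, spec.dropped_levels, spec.lev_reference, None)
        fit_alt = fit_proportional_odds(rows, design=spec2)
        assert fit_alt.log_likelihood == pytest.approx(fit_ref.log_likelihood, abs=1e-6)

    def test_nonconvergence_is_flagged_not_raised(self):
        # complete separation: treated rows always 5, control rows always 0
        rows = _rows_df([("C5.-1", 0, 0, 5, 1)] * 10 + [("C5.-1", 0, 0, 0, 0)] * 10)
        fit = fit_proportional_odds(rows, include_treatment=True, options={"maxiter": 40})
        assert isinstance(fit.converged, bool)
        assert fit.separation or not fit.converged

    def test_rank_deficiency_drops_columns(self):
        # y_base and arm perfectly collinear -> one column dropped, fit still works
        rows = _rows_df([("C5.-1", a, 0, y, a) for y in (0, 1, 2, 3, 4, 5) for a in (0, 1)] * 2)
        fit = fit_proportional_odds(rows, include_treatment=True)
        assert "rank_deficient" in fit.dropped_levels
        assert fit.converged

    def test_deterministic(self, default_pop):
        rng = np.random.default_rng(11)
        records = ot.simulate_trial(default_pop, 100, 0.1, rng)
        rows = build_transitional_rows(records)
        f1 = fit_proportional_odds(rows, include_treatment=True)
        f2 = fit_proportional_odds(rows, include_treatment=True)
        assert f1.log_likelihood == f2.log_likelihood
        assert f1.coefficients.beta_trt == f2.coefficients.beta_trt


# ---------------------------------------------------------------------------
# prediction and sampling
# ---------------------------------------------------------------------------


class TestPredict:
    def test_uniform(self):
        coeffs = CoefficientSet(cutpoints=UNIFORM_CUTPOINTS)
        probs = predict_category_probabilities(coeffs, LevCode("C5", -1), 0, 0, 0)
        assert np.allclose(probs, 1 / 6, atol=1e-12)

    def test_treatment_shifts_mass_upward(self, default_pop):
        # the worked example: C8 muscle, ML C5, baseline 1, rostral follow-up 3
        coeffs = CoefficientSet(
            cutpoints=default_pop.coefficients.cutpoints,
            beta_lev=dict(default_pop.coefficients.beta_lev),
            beta_base=dict(default_pop.coefficients.beta_base),
            beta_auto=dict(default_pop.coefficients.beta_auto),
            beta_trt=math.log(1.3),
        )
        lev = LevCode("C5", -3)
        cum_ctrl = cumulative_probabilities(coeffs, lev, 1, 3, 0)
        cum_trt = cumulative_probabilities(coeffs, lev, 1, 3, 1)
        assert np.all(cum_trt[:5] < cum_ctrl[:5])

    def test_proportional_odds_property(self, default_pop):
        coeffs = CoefficientSet(
            cutpoints=default_pop.coefficients.cutpoints,
            beta_lev=dict(default_pop.coefficients.beta_lev),
            beta_base=dict(default_pop.coefficients.beta_base),
            beta_auto=dict(default_pop.coefficients.beta_auto),
            beta_trt=0.7,
        )
        lev = LevCode("C6", -2)
        cum_ctrl = cumulative_probabilities(coeffs, lev, 2, 4, 0)[:5]
        cum_trt = cumulative_probabilities(coeffs, lev, 2, 4, 1)[:5]
        diff = logit(cum_ctrl) - logit(cum_trt)
        assert np.allclose(diff, 0.7, atol=1e-10)

    @given(
        cut1=st.floats(-3, 0),
        incs=st.lists(st.floats(0.1, 1.5), min_size=4, max_size=4),
        eta=st.floats(-4, 4),
    )
    @settings(max_examples=60, deadline=None)
    def test_probabilities_normalize(self, cut1, incs, eta):
        cutpoints = cut1 + np.concatenate([[0.0], np.cumsum(incs)])
        coeffs = CoefficientSet(cutpoints=cutpoints, beta_trt=eta)
        probs = predict_category_probabilities(coeffs, LevCode("C5", -1), 0, 0, 1)
        assert probs.min() >= 0
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        cum = np.cumsum(probs)
        assert np.all(np.diff(cum) >= -1e-12)
        # differencing then re-summing reproduces the cumulative values
        assert np.allclose(cum, cumulative_probabilities(coeffs, LevCode("C5", -1), 0, 0, 1))


class TestSampleScore:
    def test_degenerate(self):
        coeffs = CoefficientSet(cutpoints=UNIFORM_CUTPOINTS, beta_trt=60.0)
        rng = np.random.default_rng(0)
        draws = {sample_score(coeffs, LevCode("C5", -1), 0, 0, 1, rng) for _ in range(50)}
        assert draws == {5}

    def test_same_rng_state_same_draws(self):
        coeffs = CoefficientSet(cutpoints=UNIFORM_CUTPOINTS)
        a = [sample_score(coeffs, LevCode("C5", -1), 0, 0, 0, np.random.default_rng(5)) for _ in range(10)]
        b = [sample_score(coeffs, LevCode("C5", -1), 0, 0, 0, np.random.default_rng(5)) for _ in range(10)]
        assert a == b

    def test_law_of_large_numbers(self, default_pop):
        coeffs = default_pop.coefficients
        lev = LevCode("C5", -2)
        probs = predict_category_probabilities(coeffs, lev, 1, 3, 0)
        rng = np.random.default_rng(77)
        n = 100_000
        counts = np.bincount([sample_score(coeffs, lev, 1, 3, 0, rng) for _ in range(n)], minlength=6)
        assert np.allclose(counts / n, probs, atol=0.01)
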