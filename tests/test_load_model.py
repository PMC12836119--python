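import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from sibload import (
    CrossRecord,
    DesignError,
    FitDegenerateError,
    LoadFit,
    SimConfig,
    beta_from_load,
    beta_to_load,
    expected_survival_curve,
    fit_load_model,
    individual_scale,
    load_standard_errors,
    predicted_success,
    sib_mating_F,
    simulate_line_extinction,
    stagewise_fits,
)
from conftest import bernoulli_records

finite_betas = st.floats(min_value=-10, max_value=10, allow_nan=False)


def make_fit(beta0, beta1, stage="overall"):
    A, B = beta_to_load(beta0, beta1)
    return LoadFit(beta0, beta1, 0.1, 0.1, A, B, 0.5, 100, stage)


# ---------------------------------------------------------------------------
# conversions


@given(b0=finite_betas, b1=finite_betas)
@settings(max_examples=1000, deadline=None)
def test_load_conversion_round_trips(b0, b1):
    A, B = beta_to_load(b0, b1)
    assert A >= 0.0
    b0b, b1b = beta_from_load(A, B)
    assert b0b == pytest.approx(b0, abs=1e-10)
    assert b1b == pytest.approx(b1, abs=1e-10)


def test_zero_slope_means_no_concealed_load():
    for b0 in (-3.0, 0.0, 2.5):
        assert beta_to_load(b0, 0.0)[1] == pytest.approx(0.0, abs=1e-15)


def test_concealed_load_sign_opposes_slope():
    assert beta_to_load(2.0, -1.0)[1] > 0
    assert beta_to_load(2.0, 1.0)[1] < 0


def test_concealed_load_strictly_decreasing_in_slope():
    b1s = np.linspace(-4, 4, 41)
    B = [beta_to_load(1.5, b1)[1] for b1 in b1s]
    assert all(b > a for a, b in zip(B[1:], B))


def test_half_load_at_even_split():
    assert beta_from_load(-np.log(0.5), 0.0) == pytest.approx((0.0, 0.0), abs=1e-12)


def test_out_of_range_load_rejected():
    with pytest.raises(ValueError):
        beta_from_load(-0.5, 0.0)  # implies R0 > 1
    with pytest.raises(ValueError):
        beta_to_load(np.inf, 0.0)


def test_individual_scale_halves_pair_load():
    assert individual_scale(0.322, 0.322) == (0.161, 0.161)
    assert individual_scale(0.0, 0.0) == (0.0, 0.0)


# ---------------------------------------------------------------------------
# predicted success and survival curves


def test_predicted_success_at_full_inbreeding():
    # QG549: cross success at F=1 stays near 94%; fog-2 fails ~18% when outbred
    assert predicted_success(make_fit(4.038, -1.320), 1.0) == pytest.approx(0.94, abs=0.005)
    assert 1 - predicted_success(make_fit(1.517, -0.219), 0.0) == pytest.approx(0.18, abs=0.005)


def test_predicted_success_rejects_F_outside_unit_interval():
    with pytest.raises(ValueError):
        predicted_success(make_fit(1.0, -1.0), 1.5)


def test_constant_survival_curve_is_exponential_decay():
    fit = make_fit(1.517, -0.219)
    S = expected_survival_curve(fit, sib_mating_F(20), 20, mode="constant")
    R0 = expit(1.517)
    assert S[-1] == pytest.approx(R0**20, rel=1e-12)
    assert S[-1] == pytest.approx(0.019, abs=5e-4)
    assert np.all(np.diff(S) < 0)


def test_zero_slope_curves_coincide():
    fit = make_fit(2.0, 0.0)
    sched = sib_mating_F(20)
    np.testing.assert_allclose(
        expected_survival_curve(fit, sched, 20, "constant"),
        expected_survival_curve(fit, sched, 20, "inbreeding"),
        rtol=1e-12,
    )


def test_inbreeding_curve_bounded_by_endpoint_rates():
    # QG704: compounding at the actual F path sits between the two constant
    # curves evaluated at R(F=1) and R(F=0)
    fit = make_fit(3.513, -0.899)
    sched = sib_mating_F(20)
    S = expected_survival_curve(fit, sched, 20, "inbreeding")
    R0, R1 = predicted_success(fit, 0.0), predicted_success(fit, 1.0)
    assert R1**20 < S[-1] < R0**20
    assert np.all(S <= 1.0) and np.all(np.diff(S) < 0)


# ---------------------------------------------------------------------------
# fitting


def test_recovers_generating_coefficients(rng):
    config = SimConfig(seed=411, n_lines=108, max_generations=20, overall_betas=(3.5, -1.0))
    fit = fit_load_model(simulate_line_extinction(config))
    assert abs(fit.beta0 - 3.5) < 3 * fit.se_beta0
    assert abs(fit.beta1 - (-1.0)) < 3 * fit.se_beta1
    assert fit.n_crosses == sum(1 for _ in simulate_line_extinction(config))


def test_wald_test_near_nominal_size_under_null(rng):
    # With beta1 = 0 in truth the slope p-value should reject at ~alpha.
    n_reps, n, alpha = 300, 800, 0.05
    F_grid = np.tile(np.linspace(0.0, 0.9, 10), n // 10)
    rejections = 0
    for _ in range(n_reps):
        records = bernoulli_records(rng, F_grid, expit(1.5))
        rejections += fit_load_model(records).p_beta1 < alpha
    rate = rejections / n_reps
    se = np.sqrt(alpha * (1 - alpha) / n_reps)
    assert abs(rate - alpha) < 3 * se + 1e-12


def test_all_same_outcome_is_degenerate(rng):
    records = bernoulli_records(rng, np.linspace(0, 0.9, 20), 1.0)
    with pytest.raises(FitDegenerateError, match="all-success"):
        fit_load_model(records)


def test_single_F_level_is_design_error(rng):
    records = bernoulli_records(rng, np.zeros(50), 0.5)
    with pytest.raises(DesignError, match="F levels"):
        fit_load_model(records)


def separated_records():
    recs = []
    for f in (0.0, 0.25):
        recs.append(CrossRecord(f"a{f}", 1, f, success=True))
    for f in (0.5, 0.75):
        recs.append(CrossRecord(f"b{f}", 1, f, success=False))
    return recs


def test_complete_separation_is_reported():
    with pytest.raises(FitDegenerateError, match="separation"):
        fit_load_model(separated_records())


def test_firth_fallback_handles_separation():
    fit = fit_load_model(separated_records(), firth=True)
    assert np.isfinite([fit.beta0, fit.beta1, fit.se_beta0, fit.se_beta1]).all()
    assert fit.beta1 < 0


def test_delta_method_errors_are_positive(rng):
    config = SimConfig(seed=7, n_lines=108, max_generations=20, overall_betas=(3.0, -1.5))
    fit = fit_load_model(simulate_line_extinction(config))
    cov = np.array([[fit.se_beta0**2, 0.0], [0.0, fit.se_beta1**2]])
    seA, seB = load_standard_errors(fit, cov)
    assert seA > 0 and seB > 0


# ---------------------------------------------------------------------------
# stage-wise fits


STAGE_TRUTH = {
    "copulation": (3.0, -1.5),
    "fertility": (2.5, -1.0),
    "development": (2.0, -0.5),
}


def staged_records():
    config = SimConfig(
        seed=90125, n_lines=900, max_generations=20, stage_betas=STAGE_TRUTH
    )
    return simulate_line_extinction(config)


def test_stagewise_fits_recover_conditional_slopes():
    fits = stagewise_fits(staged_records())
    for stage, (b0, b1) in STAGE_TRUTH.items():
        f = fits[stage]
        assert isinstance(f, LoadFit), f"{stage} unexpectedly degenerate"
        assert f.stage == stage
        assert abs(f.beta0 - b0) < 3 * f.se_beta0
        assert abs(f.beta1 - b1) < 3 * f.se_beta1


def test_overall_success_is_product_of_stage_rates():
    records = staged_records()
    overall = fit_load_model(records)
    fits = stagewise_fits(records)
    product = np.prod([expit(fits[s].beta0) for s in STAGE_TRUTH])
    assert expit(overall.beta0) == pytest.approx(product, abs=0.02)


def test_degenerate_stage_does_not_poison_others(rng):
    # copulation and fertility always succeed; development carries signal
    records = []
    for i, f in enumerate(np.tile(np.linspace(0, 0.9, 10), 30)):
        dev = bool(rng.random() < expit(1.0 - 2.0 * f))
        records.append(
            CrossRecord(f"L{i}", 1, float(f), success=dev,
                        copulated=True, fertile=True, developed=dev)
        )
    fits = stagewise_fits(records)
    assert isinstance(fits["copulation"], FitDegenerateError)
    assert isinstance(fits["fertility"], FitDegenerateError)
    assert isinstance(fits["development"], LoadFit)
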