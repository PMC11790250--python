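import numpy as np
import pytest

from mint import (
    SectionAdaptConfig,
    TrainingConfig,
    TrialSet,
    adapt_library_sections,
    assemble_library,
    average_behavior,
    average_trials,
    build_rates_from_trials,
    smooth_library,
)
from mint.library import (
    TWO_PI,
    _resample_linear,
    gaussian_filter_spikes,
    soft_norm_params,
    wrap_angle,
)


# ---------------------------------------------------------------------------
# Filtering and extraction
# ---------------------------------------------------------------------------


def test_gaussian_filter_single_spike_peak():
    sigma = 25.0
    counts = np.zeros((1, 801))
    counts[0, 400] = 1
    rates = gaussian_filter_spikes(counts, sigma)
    expected_peak = 1000.0 / (sigma * np.sqrt(2 * np.pi))
    assert rates[0, 400] == pytest.approx(expected_peak, rel=1e-3)
    # unit area: integral of the rate trace equals 1 spike
    assert rates[0].sum() / 1000.0 == pytest.approx(1.0, rel=1e-9)


def test_gaussian_filter_edge_renormalization():
    # constant-rate train keeps its rate at the boundary
    counts = np.ones((1, 500))
    rates = gaussian_filter_spikes(counts, 20.0)
    assert np.allclose(rates, 1000.0, rtol=1e-9)


def _make_trials(n_trials=3, n_neurons=4, T=1500, move=600, seed=0):
    rng = np.random.default_rng(seed)
    spikes = [rng.poisson(0.02, (n_neurons, T)) for _ in range(n_trials)]
    behavior = [rng.standard_normal((2, T)) for _ in range(n_trials)]
    events = [{"move": move} for _ in range(n_trials)]
    return TrialSet(spikes, behavior, np.zeros(n_trials, dtype=int), events)


def test_extraction_window_sample_count():
    # window [-350, +750] around the event -> 1101 samples
    trials = _make_trials()
    cfg = TrainingConfig(sigma_ms=25, start_event="move", window_start=-350,
                         end_event="move", window_end=750)
    X, Z = build_rates_from_trials(trials, cfg)
    assert X[0].shape[1] == 1101
    assert Z[0].shape[1] == 1101


def test_extraction_missing_event_and_bounds():
    trials = _make_trials(move=100)
    cfg = TrainingConfig(start_event="go", window_start=0, end_event="go", window_end=10)
    with pytest.raises(ValueError, match="missing alignment event"):
        build_rates_from_trials(trials, cfg)
    cfg = TrainingConfig(start_event="move", window_start=-500,
                         end_event="move", window_end=10)
    with pytest.raises(ValueError, match="exceeds trial extent"):
        build_rates_from_trials(trials, cfg)


def test_uniform_warp_matches_interp_oracle():
    rng = np.random.default_rng(1)
    trace = np.cumsum(rng.standard_normal((3, 900)), axis=1)
    out = _resample_linear(trace, 1000)
    xs = np.linspace(0, 899, 1000)
    oracle = np.stack([np.interp(xs, np.arange(900), trace[d]) for d in range(3)])
    assert np.allclose(out, oracle, atol=1e-10)


def test_uniform_warp_median_duration():
    # durations 900 and 1100 -> both resampled to median 1000
    rng = np.random.default_rng(2)
    T = 2000
    spikes = [rng.poisson(0.02, (2, T)) for _ in range(2)]
    behavior = [rng.standard_normal((1, T)) for _ in range(2)]
    events = [{"start": 100, "stop": 999}, {"start": 100, "stop": 1199}]
    trials = TrialSet(spikes, behavior, np.zeros(2, dtype=int), events)
    cfg = TrainingConfig(start_event="start", window_start=0,
                         end_event="stop", window_end=0, warp_mode="uniform")
    X, _ = build_rates_from_trials(trials, cfg)
    assert X[0].shape[1] == 1000


def test_variable_durations_without_warp_error():
    rng = np.random.default_rng(2)
    spikes = [rng.poisson(0.02, (2, 2000)) for _ in range(2)]
    behavior = [rng.standard_normal((1, 2000)) for _ in range(2)]
    events = [{"start": 100, "stop": 999}, {"start": 100, "stop": 1199}]
    trials = TrialSet(spikes, behavior, np.zeros(2, dtype=int), events)
    cfg = TrainingConfig(start_event="start", window_start=0, end_event="stop", window_end=0)
    with pytest.raises(ValueError, match="unequal durations"):
        build_rates_from_trials(trials, cfg)


# ---------------------------------------------------------------------------
# Trial averaging
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("mode", ["type1", "type2"])
def test_identical_trials_average_to_common_trial(mode):
    rng = np.random.default_rng(3)
    trial = rng.uniform(0, 50, (4, 30))
    tensor = np.repeat(trial[:, :, None], 5, axis=2)
    out = average_trials(tensor, mode, TrainingConfig())
    assert np.allclose(out, trial, atol=1e-9)


def test_type2_single_trial_is_identity():
    rng = np.random.default_rng(4)
    trial = rng.uniform(0, 50, (4, 30))
    out = average_trials(trial[:, :, None], "type2", TrainingConfig())
    assert np.allclose(out, trial, atol=1e-9)


def test_type2_matches_svd_oracle():
    rng = np.random.default_rng(5)
    N, K, R = 5, 20, 8
    tensor = rng.uniform(0, 60, (N, K, R))
    cfg = TrainingConfig(soft_norm_constant=5.0)
    out = average_trials(tensor, "type2", cfg)

    # independent oracle: explicit eigendecomposition of Xin Xin^T
    type1 = tensor.mean(axis=2)
    offset = type1.mean(axis=1)
    scale = 1.0 / (type1.max(axis=1) - type1.min(axis=1) + 5.0)
    xn = (tensor - offset[:, None, None]) * scale[:, None, None]
    xin = xn.reshape(N * K, R).T
    evals, evecs = np.linalg.eigh(xin @ xin.T)
    w = evecs[:, -1:]
    xout = w @ (w.T @ xin)
    rec = xout.T.reshape(N, K, R) / scale[:, None, None] + offset[:, None, None]
    oracle = rec.mean(axis=2)
    assert np.allclose(out, oracle, atol=1e-10)


def test_average_trials_rejects_bad_input():
    with pytest.raises(ValueError):
        average_trials(np.zeros((3, 4, 0)), "type1", TrainingConfig())
    bad = np.full((2, 3, 2), np.nan)
    with pytest.raises(ValueError, match="non-finite"):
        average_trials(bad, "type1", TrainingConfig())


# ---------------------------------------------------------------------------
# Behavioral averaging (circular)
# ---------------------------------------------------------------------------


def test_circular_average_across_wrap():
    # constant phases 350 deg and 10 deg -> average 0 deg, not 180
    a = np.deg2rad(350.0) * np.ones((1, 10, 1))
    b = np.deg2rad(10.0) * np.ones((1, 10, 1))
    tensor = np.concatenate([a, b], axis=2)
    out = average_behavior(tensor, circular_flags=[True])
    assert np.allclose(np.minimum(out, TWO_PI - out), 0.0, atol=1e-9)


def test_circular_average_rotation_equivariance():
    rng = np.random.default_rng(6)
    base = np.cumsum(rng.uniform(0, 0.2, 50))
    trials = np.stack([wrap_angle(base + 0.1 * rng.standard_normal(50)) for _ in range(4)], axis=1)
    tensor = trials[None, :, :]
    theta = 1.23
    out0 = average_behavior(tensor, circular_flags=[True])
    out1 = average_behavior(wrap_angle(tensor + theta), circular_flags=[True])
    d = np.mod(out1 - out0 - theta + np.pi, TWO_PI) - np.pi
    assert np.allclose(d, 0.0, atol=1e-9)


def test_circular_average_matches_unwrap_oracle():
    rng = np.random.default_rng(7)
    base = np.cumsum(rng.uniform(0, 0.3, 60)) + 1.0
    true_unwrapped = np.stack([base + 0.2 * rng.standard_normal(60) for _ in range(5)], axis=1)
    tensor = wrap_angle(true_unwrapped)[None, :, :]
    out = average_behavior(tensor, circular_flags=[True])
    oracle = wrap_angle(true_unwrapped.mean(axis=1))
    d = np.mod(out[0] - oracle + np.pi, TWO_PI) - np.pi
    assert np.allclose(d, 0.0, atol=1e-10)


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------


def _random_avgs(rng, N=6, C=3, K=40, scale=50.0):
    return {c: rng.uniform(0, scale, (N, K)) for c in range(C)}


def test_full_rank_smoothing_is_identity_up_to_rectification():
    rng = np.random.default_rng(8)
    avgs = _random_avgs(rng)
    cfg = TrainingConfig(d_neural=6, d_condition=3)
    out = smooth_library(avgs, cfg)
    for c in avgs:
        assert np.allclose(out[c], np.maximum(avgs[c], 0.0), atol=1e-8)


def test_smoothing_projection_idempotent():
    from mint.library import _top_pcs

    rng = np.random.default_rng(9)
    avgs = _random_avgs(rng)
    concat = np.concatenate([avgs[c] for c in sorted(avgs)], axis=1)
    offset, scale = soft_norm_params(concat, 5.0)
    xn = (concat - offset[:, None]) * scale[:, None]
    w = _top_pcs(xn, 2)
    once = w @ (w.T @ xn)
    twice = w @ (w.T @ once)
    assert np.allclose(once, twice, atol=1e-12)


def test_neuron_smoothing_matches_pca_oracle():
    rng = np.random.default_rng(10)
    avgs = _random_avgs(rng)
    cfg = TrainingConfig(d_neural=2, soft_norm_constant=5.0)
    out = smooth_library(avgs, cfg)

    concat = np.concatenate([avgs[c] for c in sorted(avgs)], axis=1)
    offset, scale = soft_norm_params(concat, 5.0)
    xn = (concat - offset[:, None]) * scale[:, None]
    # oracle: eigendecomposition of the covariance (rows already centered)
    evals, evecs = np.linalg.eigh(xn @ xn.T)
    w = evecs[:, -2:]
    rec = w @ (w.T @ xn)
    oracle = np.maximum(rec / scale[:, None] + offset[:, None], 0.0)
    got = np.concatenate([out[c] for c in sorted(out)], axis=1)
    assert np.allclose(got, oracle, atol=1e-10)


def test_smoothing_variance_non_increasing():
    rng = np.random.default_rng(11)
    avgs = _random_avgs(rng)
    cfg = TrainingConfig(d_neural=2, soft_norm_constant=5.0)
    concat_in = np.concatenate([avgs[c] for c in sorted(avgs)], axis=1)
    offset, scale = soft_norm_params(concat_in, 5.0)
    out = smooth_library(avgs, cfg)
    concat_out = np.concatenate([out[c] for c in sorted(out)], axis=1)
    xin = (concat_in - offset[:, None]) * scale[:, None]
    xout = (concat_out - offset[:, None]) * scale[:, None]
    assert np.sum(xout**2) <= np.sum(xin**2) + 1e-9


def test_condition_smoothing_skipped_on_unequal_lengths():
    rng = np.random.default_rng(12)
    avgs = {0: rng.uniform(0, 50, (4, 30)), 1: rng.uniform(0, 50, (4, 40))}
    cfg = TrainingConfig(d_condition=1)
    with pytest.warns(UserWarning, match="condition smoothing skipped"):
        smooth_library(avgs, cfg)


def test_smoothing_dimension_errors():
    rng = np.random.default_rng(13)
    avgs = _random_avgs(rng, N=4)
    with pytest.raises(ValueError, match="d_neural"):
        smooth_library(avgs, TrainingConfig(d_neural=5))
    with pytest.raises(ValueError, match="d_condition"):
        smooth_library(avgs, TrainingConfig(d_condition=4))


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def test_assemble_valid_state_count():
    rng = np.random.default_rng(14)
    rates = {0: rng.uniform(0, 50, (3, 1000))}
    behavior = {0: rng.standard_normal((2, 1000))}
    lib = assemble_library(rates, behavior, tau=299, delta_ms=20)
    assert lib.valid_state_mask(0).sum() == 701


def test_assemble_tau_too_large_errors():
    rates = {0: np.ones((2, 50)), 1: np.ones((2, 200))}
    behavior = {0: np.zeros((1, 50)), 1: np.zeros((1, 200))}
    with pytest.raises(ValueError, match=r"conditions \[1\]"):
        assemble_library(rates, behavior, tau=100, delta_ms=20)


def test_transition_iteration_reaches_history_start(small_library):
    k = 150
    for _ in range(small_library.tau):
        k = small_library.transition_back(0, k)
    assert k == 150 - small_library.tau


def test_assemble_rejects_negative_rates():
    with pytest.raises(ValueError, match="non-negative"):
        assemble_library({0: -np.ones((2, 50))}, {0: np.zeros((1, 50))}, tau=10, delta_ms=5)


# ---------------------------------------------------------------------------
# Section adaptation
# ---------------------------------------------------------------------------


def _adapt_setup(seed=15, N=4, C=2, K=30):
    rng = np.random.default_rng(seed)
    rates = {c: rng.uniform(5, 50, (N, K)) for c in range(C)}
    behavior = {c: rng.standard_normal((1, K)) for c in range(C)}
    lib = assemble_library(rates, behavior, tau=9, delta_ms=5)
    return rng, lib


def test_adapt_identity_inputs_return_library_rates():
    _, lib = _adapt_setup()
    sections = [{c: lib.rates[c].copy() for c in range(lib.n_conditions)}]
    out = adapt_library_sections(lib, sections, SectionAdaptConfig(ridge_lambda=10.0))
    for c in range(lib.n_conditions):
        assert np.allclose(out[0].rates[c], lib.rates[c], atol=1e-8)


def test_adapt_large_lambda_reduces_to_mean_offset():
    rng, lib = _adapt_setup(seed=16)
    sections = [{c: lib.rates[c] + rng.uniform(0, 5, lib.rates[c].shape)
                 for c in range(lib.n_conditions)}]
    out = adapt_library_sections(lib, sections, SectionAdaptConfig(ridge_lambda=1e12))
    X = np.concatenate(lib.rates, axis=1)
    Y = np.concatenate([sections[0][c] for c in range(lib.n_conditions)], axis=1)
    mu1 = (Y - X).mean(axis=1)
    expected = np.maximum(X + mu1[:, None], 0.0)
    got = np.concatenate(out[0].rates, axis=1)
    assert np.allclose(got, expected, atol=1e-6)


def test_adapt_matches_weighted_ridge_oracle():
    from sklearn.linear_model import Ridge

    rng, lib = _adapt_setup(seed=17)
    K = sum(lib.lengths)
    weights = np.ones(K)
    weights[10:25] = 4.0  # designated-epoch weighting convention
    lam = 100.0
    sections = [{c: np.maximum(lib.rates[c] * rng.uniform(0.7, 1.3) + rng.normal(0, 2, lib.rates[c].shape), 0)
                 for c in range(lib.n_conditions)}]
    cfg = SectionAdaptConfig(ridge_lambda=lam, epoch_weights=weights, soft_norm_constant=5.0)
    out = adapt_library_sections(lib, sections, cfg)

    # oracle: per-row weighted ridge regression via sklearn
    X = np.concatenate(lib.rates, axis=1)
    Y = np.concatenate([sections[0][c] for c in range(lib.n_conditions)], axis=1)
    scale = 1.0 / (X.max(axis=1) - X.min(axis=1) + 5.0)
    P = scale[:, None] * X
    mu2 = P.mean(axis=1)
    P = P - mu2[:, None]
    Q = Y - X
    mu1 = Q.mean(axis=1)
    Q = Q - mu1[:, None]
    W = np.stack([
        Ridge(alpha=lam, fit_intercept=False, solver="cholesky")
        .fit(P.T, Q[n], sample_weight=weights).coef_
        for n in range(X.shape[0])
    ])
    b = mu1 - W @ mu2
    expected = np.maximum(X + W @ (scale[:, None] * X) + b[:, None], 0.0)
    got = np.concatenate(out[0].rates, axis=1)
    assert np.allclose(got, expected, atol=1e-8)
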