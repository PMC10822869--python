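"""Covariate transforms, condition indexing, likelihood and priors."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit

from emodo import core_data
from emodo import model as m

# ---------------------------------------------------------------------------
# covariates


@pytest.mark.parametrize("rt,expected", [
    (10.0, 0.0),                 # full intensity: no penalty
    (10.0 / math.e, -1.0),
    (5.0, math.log(0.5)),
])
def test_rt_covariate_values(rt, expected):
    assert m.rt_covariate(rt) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("t,expected", [
    (1, 1.0),                    # first presentation: full learning term
    (10, 0.0),                   # last presentation: term vanishes
    (5, (5.0 / 9.0) ** math.e),  # ~0.2023
])
def test_trial_covariate_values(t, expected):
    assert m.trial_covariate(t) == pytest.approx(expected, abs=1e-12)


def test_trial_covariate_strictly_decreasing():
    vals = [m.trial_covariate(t) for t in range(1, 11)]
    assert all(a > b for a, b in zip(vals, vals[1:]))


@pytest.mark.parametrize("bad", [0.0, -1.0, 10.5])
def test_rt_covariate_domain(bad):
    with pytest.raises(m.DomainError):
        m.rt_covariate(bad)


@pytest.mark.parametrize("bad", [0, 11, 2.5])
def test_trial_covariate_domain(bad):
    with pytest.raises(m.DomainError):
        m.trial_covariate(bad)


# ---------------------------------------------------------------------------
# condition indexing


def test_slot_counts_standard(index):
    assert m.count_parameter_slots(index) == (24, 18)


def test_slot_counts_two_emotions(small_index):
    assert m.count_parameter_slots(small_index) == (8, 6)


def test_slot_counts_nofeedback_restriction(index):
    nofb = {k: v for k, v in index.cond24.items() if k[1] == "NoFeedback"}
    assert len(set(nofb.values())) == 12  # 2 groups x 6 emotions


def test_nofeedback_groups_share_slope_slot(index):
    for emo in index.emotions:
        assert (index.slot18("DOP", "NoFeedback", emo)
                == index.slot18("NOP", "NoFeedback", emo))
        assert (index.slot18("DOP", "Feedback", emo)
                != index.slot18("NOP", "Feedback", emo))
        assert (index.slot24("DOP", "NoFeedback", emo)
                != index.slot24("NOP", "NoFeedback", emo))


def test_params_vector_roundtrip(index):
    rng = np.random.default_rng(0)
    p = m.ModelParams.from_vector(rng.normal(size=222), index)
    assert p.n_params == 222
    np.testing.assert_array_equal(
        m.ModelParams.from_vector(p.to_vector(), index).to_vector(),
        p.to_vector())


# ---------------------------------------------------------------------------
# linear predictor


def _one_trial(group="DOP", feedback="Feedback", emotion="Anger",
               rt=10.0, t=10):
    return core_data.TrialRecord("p", group, feedback, emotion, 1, t, rt, 1)


def test_predictor_zero_params(index):
    p = m.ModelParams.zeros(index)
    assert m.linear_predictor(_one_trial(), None, p, index) == 0.0


def test_predictor_alpha_only_at_full_intensity_last_trial(index):
    p = m.ModelParams.zeros(index)
    slot = index.slot24("DOP", "Feedback", "Anger")
    p.alpha[slot] = 1.0
    assert m.linear_predictor(_one_trial(), None, p, index) == pytest.approx(1.0)


def test_predictor_moderation_hand_value(index):
    # alpha=0, beta_rt=1 with CP-moderation 0.5 at z_cp=1, rt=10/e, t=10:
    # eta = 1 * (1 + 0.5) * ln((10/e)/10) = -1.5
    p = m.ModelParams.zeros(index)
    s = index.slot18("DOP", "Feedback", "Anger")
    p.beta_rt[s] = 1.0
    p.spq_rt_mod[0, s] = 0.5
    prof = core_data.SPQProfile(0, 0, 0, 0, z_cp=1.0, z_in=0.0, z_di=0.0)
    got = m.linear_predictor(_one_trial(rt=10.0 / math.e), prof, p, index)
    assert got == pytest.approx(-1.5, abs=1e-12)


@given(st.floats(0.1, 10.0), st.floats(0.1, 10.0))
def test_probability_increases_with_rt(rt_a, rt_b):
    """With beta_rt > 0 a fuller expression is never harder to recognise."""
    index = m.ConditionIndex.standard()
    p = m.ModelParams.zeros(index)
    p.beta_rt[:] = 0.7
    lo, hi = sorted([rt_a, rt_b])
    eta_lo = m.linear_predictor(_one_trial(rt=lo), None, p, index)
    eta_hi = m.linear_predictor(_one_trial(rt=hi), None, p, index)
    assert eta_lo <= eta_hi


@given(st.integers(1, 10), st.floats(0.5, 10.0))
def test_zero_spq_scores_reduce_to_base_model(t, rt):
    """CP=IN=DI=0 makes the extended predictor identical to the base one."""
    index = m.ConditionIndex.standard()
    rng = np.random.default_rng(7)
    p = m.ModelParams.from_vector(rng.normal(0, 0.5, 222), index)
    p.beta_rt = np.abs(p.beta_rt)
    trial = _one_trial(rt=rt, t=t)
    prof0 = core_data.SPQProfile(0, 0, 0, 0, z_cp=0.0, z_in=0.0, z_di=0.0)
    assert (m.linear_predictor(trial, prof0, p, index)
            == pytest.approx(m.linear_predictor(trial, None, p, index)))


# ---------------------------------------------------------------------------
# likelihood


def test_loglik_single_trial_zero_params(index):
    ds = core_data.Dataset.from_records([_one_trial()])
    enc = m.encode_trials(ds, index)
    assert m.log_likelihood(enc, m.ModelParams.zeros(index)) == pytest.approx(
        math.log(0.5), abs=1e-12)


def test_loglik_additivity(tiny_dataset, index):
    rng = np.random.default_rng(1)
    p = m.ModelParams.from_vector(rng.normal(0, 0.4, 222), index)
    p.beta_rt = np.abs(p.beta_rt)
    enc1 = m.encode_trials(tiny_dataset, index)
    doubled = core_data.Dataset(
        trials=__import__("pandas").concat(
            [tiny_dataset.trials, tiny_dataset.trials], ignore_index=True))
    enc2 = m.encode_trials(doubled, index)
    assert m.log_likelihood(enc2, p) == pytest.approx(
        2 * m.log_likelihood(enc1, p), rel=1e-12)


def test_loglik_brute_force_oracle(tiny_dataset, index):
    """Vectorized likelihood == per-trial Bernoulli product to 1e-12."""
    rng = np.random.default_rng(2)
    p = m.ModelParams.from_vector(rng.normal(0, 0.6, 222), index)
    p.beta_rt = np.abs(p.beta_rt)
    enc = m.encode_trials(tiny_dataset, index)
    brute = 0.0
    for rec in tiny_dataset.to_records():
        eta = m.linear_predictor(rec, None, p, index)
        prob = 1.0 / (1.0 + math.exp(-eta))
        brute += math.log(prob if rec.correct else 1.0 - prob)
    assert m.log_likelihood(enc, p) == pytest.approx(brute, abs=1e-12)


# ---------------------------------------------------------------------------
# priors


def test_log_prior_negative_beta_rt_is_minus_inf(index):
    p = m.ModelParams.zeros(index)
    p.beta_rt[3] = -1e-9
    assert m.log_prior(p) == -math.inf


def test_log_prior_at_zero_closed_form(index):
    """Sum of the six families' log densities at 0."""
    from scipy.stats import halfnorm, norm
    p = m.ModelParams.zeros(index)
    expected = (24 * norm.logpdf(0, scale=1.5)
                + 18 * halfnorm.logpdf(0, scale=1.0)
                + 18 * norm.logpdf(0, scale=1.0)
                + 54 * norm.logpdf(0, scale=0.25)
                + 108 * norm.logpdf(0, scale=0.1))
    assert m.log_prior(p) == pytest.approx(expected, rel=1e-12)


def test_log_prior_alpha_shift_lowers_by_half(index):
    p0 = m.ModelParams.zeros(index)
    p1 = m.ModelParams.zeros(index)
    p1.alpha[0] = 1.5  # one prior SD
    assert m.log_prior(p0) - m.log_prior(p1) == pytest.approx(0.5, abs=1e-12)


def test_log_posterior_finite_on_constraint(tiny_dataset, index):
    enc = m.encode_trials(tiny_dataset, index)
    p = m.ModelParams.zeros(index)
    assert math.isfinite(m.log_posterior(enc, p))
    p.beta_rt[0] = -0.1
    assert m.log_posterior(enc, p) == -math.inf


# ---------------------------------------------------------------------------
# gradients


def _numeric_grad(f, theta, h=1e-5):
    g = np.empty(theta.size)
    for i in range(theta.size):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        g[i] = (f(tp) - f(tm)) / (2 * h)
    return g


@pytest.mark.parametrize("transform", ["log", "constrained"])
def test_gradients_match_numeric(small_dataset, small_index, transform):
    """Analytic vs central-difference gradients at random interior points."""
    ds, _, _ = small_dataset
    enc = m.encode_trials(ds, small_index)
    rng = np.random.default_rng(3)
    dim = small_index.n_alpha + 11 * small_index.n_slope
    if transform == "log":
        logp_grad, _, _ = m.make_posterior_fn(enc, small_index)
        theta = rng.normal(0, 0.3, dim)
    else:
        logp_grad, rt_sl = m.make_constrained_posterior_fn(enc, small_index)
        theta = rng.normal(0, 0.3, dim)
        theta[rt_sl] = np.abs(theta[rt_sl]) + 0.05
    lp, ga = logp_grad(theta)
    assert math.isfinite(lp)
    gn = _numeric_grad(lambda th: logp_grad(th)[0], theta)
    rel = np.max(np.abs(ga - gn) / (1.0 + np.abs(gn)))
    assert rel < 1e-6
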