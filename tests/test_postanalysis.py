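"""HDI search, ROPE decisions, contrasts, tables and predictives."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit, logit

from emodo import model as m
from emodo import postanalysis as pa
from emodo.sampler import PosteriorSamples

# ---------------------------------------------------------------------------
# HDI


def brute_force_hdi(x, mass=0.95):
    """Exhaustive shortest-window search (independent oracle)."""
    xs = np.sort(np.asarray(x, dtype=float))
    n = xs.size
    k = int(math.ceil(mass * n))
    if k >= n:
        return float(xs[0]), float(xs[-1])
    best = (math.inf, None)
    for i in range(n - k + 1):
        width = xs[i + k - 1] - xs[i]
        if width < best[0]:
            best = (width, (float(xs[i]), float(xs[i + k - 1])))
    return best[1]


def test_hdi_sorted_integers():
    iv = pa.hdi(np.arange(1, 101), mass=0.95)
    assert iv.upper - iv.lower == 94  # 95 points span width 94


def test_hdi_constant_draws():
    iv = pa.hdi(np.full(50, 3.7))
    assert iv.lower == iv.upper == 3.7


def test_hdi_skewed_sample_left_of_equal_tailed():
    rng = np.random.default_rng(0)
    x = rng.lognormal(0, 1, 4000)
    iv = pa.hdi(x)
    lo, hi = np.quantile(x, [0.025, 0.975])
    assert iv.lower < lo and iv.upper < hi
    assert (iv.lower, iv.upper) == brute_force_hdi(x)


@given(st.integers(0, 2 ** 31 - 1), st.sampled_from([0.5, 0.8, 0.95]),
       st.sampled_from(["normal", "lognormal", "uniform"]))
def test_hdi_matches_brute_force(seed, mass, law):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 200))
    x = {"normal": rng.standard_normal(n),
         "lognormal": rng.lognormal(0, 1, n),
         "uniform": rng.uniform(-1, 1, n)}[law]
    iv = pa.hdi(x, mass)
    assert (iv.lower, iv.upper) == brute_force_hdi(x, mass)


def test_hdi_empty_errors():
    with pytest.raises(ValueError):
        pa.hdi([])


# ---------------------------------------------------------------------------
# ROPE machinery


@pytest.mark.parametrize("interval,rope,expected", [
    ((0.3, 0.5), (-0.2, 0.2), pa.Decision.CREDIBLE),
    ((-0.1, 0.1), (-0.2, 0.2), pa.Decision.NEGLIGIBLE),
    ((-0.1, 0.3), (-0.2, 0.2), pa.Decision.WITHHELD),
    ((-1.47, -0.34), (0.0, 0.0), pa.Decision.CREDIBLE),
    ((0.0, 0.0), (0.0, 0.0), pa.Decision.NEGLIGIBLE),
    ((0.2, 0.5), (-0.2, 0.2), pa.Decision.WITHHELD),  # shared endpoint
])
def test_rope_decision_rule(interval, rope, expected):
    iv = pa.Interval(*interval)
    assert pa.rope_decision(iv, pa.RopeSpec(*rope)) is expected


def test_rope_decision_scale_mismatch():
    with pytest.raises(ValueError):
        pa.rope_decision(pa.Interval(0, 1),
                         pa.RopeSpec(0, 0, scale="percent-probability"),
                         scale="log-odds")


def test_rope_halfwidth_probability():
    assert pa.rope_halfwidth_probability() == pytest.approx(
        float(logit(0.55)), abs=1e-12)
    assert round(pa.rope_halfwidth_probability(), 1) == 0.2
    assert pa.rope_halfwidth_probability(delta_p=0.0) == 0.0
    assert round(pa.rope_halfwidth_probability(sd_span=2.0), 1) == 0.1


def test_rope_halfwidth_moderation():
    assert pa.rope_halfwidth_moderation() == 0.005
    assert pa.rope_halfwidth_moderation(0.02, 2) == 0.01
    assert pa.rope_halfwidth_moderation(0.0) == 0.0


def test_alpha_to_percent():
    assert pa.alpha_to_percent(0.0) == pytest.approx(50.0)
    assert pa.alpha_to_percent(2.0) == pytest.approx(88.08, abs=0.005)
    xs = np.linspace(-4, 4, 50)
    assert np.all(np.diff(pa.alpha_to_percent(xs)) > 0)


@given(st.floats(0.01, 0.99))
def test_alpha_to_percent_inverts_logit(p):
    assert pa.alpha_to_percent(logit(p)) == pytest.approx(100 * p, abs=1e-10)


def test_contrast_and_double_contrast():
    a = np.array([1.0, 2.0, 3.0])
    np.testing.assert_array_equal(pa.contrast(a, a), np.zeros(3))
    b = np.array([0.5, 1.0, 1.5])
    assert pa.contrast(a, b).mean() == pytest.approx(a.mean() - b.mean())
    ten, zero, seven = np.full(4, 10.0), np.zeros(4), np.full(4, 7.0)
    np.testing.assert_array_equal(
        pa.double_contrast((ten, zero), (seven, zero)), np.full(4, 3.0))
    with pytest.raises(ValueError):
        pa.contrast(a, b[:2])


# ---------------------------------------------------------------------------
# tables


def _zero_samples(index, n_draws=40, n_chains=2):
    dim = index.n_alpha + 11 * index.n_slope
    draws = np.zeros((n_chains, n_draws, dim))
    return PosteriorSamples(draws=draws, index=index, has_spq_data=True)


def test_table_alpha_layout_and_null(index):
    df = pa.build_table_alpha(_zero_samples(index))
    assert len(df) == 6
    mean_cols = [c for c in df.columns if c.endswith("_mean")]
    assert len(mean_cols) == 7  # 4 cells + 2 group diffs + 1 double diff
    for g in ("dop", "nop"):
        assert (df[f"{g}_feedback_mean"] == 50.0).all()
        assert (df[f"{g}_diff_mean"] == 0.0).all()
        assert (df[f"{g}_diff_decision"] == "negligible").all()
    assert (df["group_diff_decision"] == "negligible").all()


def test_table_beta_rt_null_decisions(index):
    df = pa.build_table_beta_rt(_zero_samples(index))
    assert len(df) == 6
    # zero-width HDI at 0 against the degenerate {0} ROPE: not credible
    assert (df["dop_vs_nop_decision"] == "negligible").all()
    assert not df["dop_vs_nop_credible"].any()


def test_table_beta_rt_credible_contrast(index):
    samples = _zero_samples(index)
    rng = np.random.default_rng(5)
    sl = m.block_slices(index)["beta_rt"]
    emo0 = index.cond18[("DOP-Feedback", index.emotions[0])]
    nop0 = index.cond18[("NOP-Feedback", index.emotions[0])]
    # draws with DOP - NOP confined to [0.34, 1.47]
    samples.draws[:, :, sl.start + emo0] = rng.uniform(
        1.34, 2.47, samples.draws.shape[:2])
    samples.draws[:, :, sl.start + nop0] = 1.0
    df = pa.build_table_beta_rt(samples)
    assert df.loc[0, "dop_vs_nop_decision"] == "credible"
    assert not df["dop_vs_nop_credible"][1:].any()


def test_table_beta_trial_layout(index):
    df = pa.build_table_beta_trial(_zero_samples(index))
    assert len(df) == 6
    for stem in ("nofeedback_vs_nop", "nofeedback_vs_dop", "dop_vs_nop"):
        assert (df[f"{stem}_decision"] == "negligible").all()


def test_spq_summary_shape_and_null(index):
    df = pa.spq_effect_summary(_zero_samples(index))
    assert len(df) == 162  # 18 conditions x 9 parameter families
    assert (df["decision"] == "negligible").all()


def test_spq_summary_requires_spq_fit(index):
    s = _zero_samples(index)
    s.has_spq_data = False
    with pytest.raises(ValueError):
        pa.spq_effect_summary(s)


def test_table_decisions_reproducible_from_interval_and_rope(small_index):
    """Every emitted decision replays from its own HDI and ROPE."""
    rng = np.random.default_rng(9)
    dim = small_index.n_alpha + 11 * small_index.n_slope
    draws = rng.normal(0, 0.6, size=(2, 300, dim))
    sl = m.block_slices(small_index)["beta_rt"]
    draws[:, :, sl] = np.abs(draws[:, :, sl])
    samples = PosteriorSamples(draws=draws, index=small_index,
                               has_spq_data=True)
    df = pa.build_table_alpha(samples)
    alpha = samples.block("alpha")
    for i, emo in enumerate(small_index.emotions):
        for g in ("DOP", "NOP"):
            d = (pa.alpha_to_percent(alpha[:, small_index.slot24(g, "Feedback", emo)])
                 - pa.alpha_to_percent(alpha[:, small_index.slot24(g, "NoFeedback", emo)]))
            iv = pa.hdi(d)
            dec = pa.rope_decision(iv, pa.ROPE_ALPHA_PCT)
            assert df.loc[i, f"{g.lower()}_diff_decision"] == dec.value
            assert df.loc[i, f"{g.lower()}_diff_hdi_lower"] == pytest.approx(iv.lower)


# ---------------------------------------------------------------------------
# posterior predictive


def test_predictive_all_zero_draws(index):
    out = pa.posterior_predictive(_zero_samples(index),
                                  pa.grid_full_intensity(index))
    assert np.allclose(out["p_mean"], 0.5)
    assert len(out) == 24


def test_predictive_rt_bin_grid(index):
    grid = pa.grid_rt_bins(index)
    per_cond = grid[(grid["group"] == "DOP") & (grid["feedback"] == "Feedback")
                    & (grid["emotion"] == "Anger")]
    centres = per_cond["rt_seconds"].to_numpy()
    assert len(centres) == 15
    assert centres[0] == pytest.approx(1.3)
    assert np.allclose(np.diff(centres), 0.6)


def test_predictive_matches_alpha_at_full_intensity(small_index):
    rng = np.random.default_rng(11)
    dim = small_index.n_alpha + 11 * small_index.n_slope
    draws = rng.normal(0, 0.5, size=(2, 200, dim))
    sl = m.block_slices(small_index)["beta_rt"]
    draws[:, :, sl] = np.abs(draws[:, :, sl])
    samples = PosteriorSamples(draws=draws, index=small_index)
    out = pa.posterior_predictive(samples, pa.grid_full_intensity(small_index))
    alpha = samples.block("alpha")
    for i, (g, f, e) in enumerate(small_index.cond24):
        expected = pa.alpha_to_percent(
            alpha[:, small_index.slot24(g, f, e)]).mean() / 100.0
        assert out.loc[i, "p_mean"] == pytest.approx(expected, abs=1e-12)


def test_predictive_domain_error(index):
    grid = pa.grid_full_intensity(index)
    grid.loc[0, "rt_seconds"] = 0.0
    with pytest.raises(m.DomainError):
        pa.posterior_predictive(_zero_samples(index), grid)
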