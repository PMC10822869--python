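"""Generative model of trial-level emotion-recognition accuracy.

The task shows a face morphing from neutral to one of six basic emotions
over 10 s; a participant responds at reaction time RT (equivalently, at
emotion intensity RT/10) on the ``trial_index``-th presentation of that
emotion within a block.  Correctness of each trial is modelled as

    correct_i ~ Bernoulli(p_i)
    logit(p_i) = alpha[c24_i]
               + beta_rt[c18_i]    * ln(RT_i / 10)
               + beta_trial[c18_i] * ((10 - Trial_i) / 9) ** e

``alpha`` is the log-odds of a correct response at full intensity on the
last trial of a condition; ``beta_rt`` >= 0 is the penalty for responding
before the expression is complete; ``beta_trial`` is the first-vs-last
trial difference in log-odds (the learning curve).  ``c24`` indexes the
2 groups x 2 feedback conditions x 6 emotions; ``c18`` indexes 3 feedback
conditions (the two groups share a slot when no feedback is given, since
group labels cannot matter before feedback differs) x 6 emotions.

For participants with Schizotypal Personality Questionnaire (SPQ) scores,
standardized factor scores CP / IN / DI enter additively (direct effects)
and multiplicatively (proportional moderation of beta_rt and beta_trial):

    logit(p_i) += b_cp[c18]*CP + b_in[c18]*IN + b_di[c18]*DI
    beta_rt    -> beta_rt    * (1 + b_cp_rt[c18]*CP + b_in_rt[c18]*IN + b_di_rt[c18]*DI)
    beta_trial -> beta_trial * (1 + b_cp_tr[c18]*CP + b_in_tr[c18]*IN + b_di_tr[c18]*DI)

Priors: alpha ~ N(0, 1.5); beta_rt ~ HalfNormal(0, 1); beta_trial ~ N(0, 1);
direct effects ~ N(0, 0.25); moderation ~ N(0, 0.1).  Second arguments are
standard deviations.  One joint likelihood covers completers and
non-completers with shared alpha / beta_rt / beta_trial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "EMOTIONS",
    "GROUPS",
    "FEEDBACK_LEVELS",
    "SLOPE_CONDITIONS",
    "ConditionIndex",
    "ModelParams",
    "PriorSpec",
    "EncodedTrials",
    "rt_covariate",
    "trial_covariate",
    "linear_predictor",
    "encode_trials",
    "predicted_probability",
    "log_likelihood",
    "log_likelihood_grad",
    "log_prior",
    "log_prior_grad",
    "log_posterior",
    "count_parameter_slots",
    "make_posterior_fn",
    "make_constrained_posterior_fn",
]

EMOTIONS = ("Anger", "Disgust", "Fear", "Happiness", "Sadness", "Surprise")
GROUPS = ("DOP", "NOP")
FEEDBACK_LEVELS = ("NoFeedback", "Feedback")
#: the three feedback conditions of the slope parameters
SLOPE_CONDITIONS = ("NoFeedback", "DOP-Feedback", "NOP-Feedback")

SPQ_FACTORS = ("CP", "IN", "DI")

_P_FLOOR = 1e-12  # probability clip applied inside the likelihood only


class DomainError(ValueError):
    """A covariate outside the domain of its transform."""


@dataclass(frozen=True)
class ConditionIndex:
    """Maps experimental conditions onto parameter slots.

    ``cond24`` assigns (group, feedback, emotion) a distinct intercept
    slot.  ``cond18`` assigns (slope-condition, emotion) a distinct slope
    slot, where slope-condition collapses the two groups in the
    no-feedback block.  With the full six-emotion design the slot counts
    are 24 and 18; restricted emotion sets scale both down.
    """

    emotions: tuple[str, ...] = EMOTIONS
    cond24: dict = field(default_factory=dict)
    cond18: dict = field(default_factory=dict)

    @classmethod
    def standard(cls, emotions: tuple[str, ...] = EMOTIONS) -> "ConditionIndex":
        emotions = tuple(emotions)
        if len(set(emotions)) != len(emotions) or not emotions:
            raise ValueError("emotions must be a non-empty set of distinct labels")
        c24 = {}
        for g in GROUPS:
            for f in FEEDBACK_LEVELS:
                for e in emotions:
                    c24[(g, f, e)] = len(c24)
        c18 = {}
        for s in SLOPE_CONDITIONS:
            for e in emotions:
                c18[(s, e)] = len(c18)
        return cls(emotions=emotions, cond24=c24, cond18=c18)

    @property
    def n_alpha(self) -> int:
        return len(self.cond24)

    @property
    def n_slope(self) -> int:
        return len(self.cond18)

    def slot24(self, group: str, feedback: str, emotion: str) -> int:
        return self.cond24[(group, feedback, emotion)]

    def slope_condition(self, group: str, feedback: str) -> str:
        return "NoFeedback" if feedback == "NoFeedback" else f"{group}-Feedback"

    def slot18(self, group: str, feedback: str, emotion: str) -> int:
        return self.cond18[(self.slope_condition(group, feedback), emotion)]

    def alpha_labels(self) -> list[str]:
        return [f"alpha[{g},{f},{e}]" for (g, f, e) in self.cond24]

    def slope_labels(self, stem: str) -> list[str]:
        return [f"{stem}[{s},{e}]" for (s, e) in self.cond18]


def count_parameter_slots(index: ConditionIndex) -> tuple[int, int]:
    """Distinct intercept and slope slot counts of a condition index."""
    return (
        len(set(index.cond24.values())),
        len(set(index.cond18.values())),
    )


@dataclass
class ModelParams:
    """All model parameters grouped by role.

    Shapes (S = number of slope slots, A = number of intercept slots):
    ``alpha`` (A,), ``beta_rt`` (S,) nonnegative, ``beta_trial`` (S,),
    ``spq_direct`` / ``spq_rt_mod`` / ``spq_trial_mod`` (3, S) with rows
    ordered CP, IN, DI.  For the standard design A=24, S=18 and the total
    scalar count is 24 + 18 + 18 + 3*54 = 222.
    """

    alpha: np.ndarray
    beta_rt: np.ndarray
    beta_trial: np.ndarray
    spq_direct: np.ndarray
    spq_rt_mod: np.ndarray
    spq_trial_mod: np.ndarray

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta_rt = np.asarray(self.beta_rt, dtype=float)
        self.beta_trial = np.asarray(self.beta_trial, dtype=float)
        self.spq_direct = np.asarray(self.spq_direct, dtype=float)
        self.spq_rt_mod = np.asarray(self.spq_rt_mod, dtype=float)
        self.spq_trial_mod = np.asarray(self.spq_trial_mod, dtype=float)
        s = self.beta_rt.shape[0]
        if self.beta_trial.shape != (s,):
            raise ValueError("beta_trial shape mismatch")
        for name in ("spq_direct", "spq_rt_mod", "spq_trial_mod"):
            if getattr(self, name).shape != (3, s):
                raise ValueError(f"{name} must have shape (3, {s})")

    @classmethod
    def zeros(cls, index: ConditionIndex) -> "ModelParams":
        a, s = index.n_alpha, index.n_slope
        return cls(np.zeros(a), np.zeros(s), np.zeros(s),
                   np.zeros((3, s)), np.zeros((3, s)), np.zeros((3, s)))

    @property
    def n_alpha(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_slope(self) -> int:
        return self.beta_rt.shape[0]

    @property
    def n_params(self) -> int:
        return self.n_alpha + 2 * self.n_slope + 9 * self.n_slope

    def validate(self) -> None:
        if np.any(self.beta_rt < 0):
            raise ValueError("beta_rt must be elementwise nonnegative")

    def to_vector(self) -> np.ndarray:
        return np.concatenate([
            self.alpha, self.beta_rt, self.beta_trial,
            self.spq_direct.ravel(), self.spq_rt_mod.ravel(),
            self.spq_trial_mod.ravel(),
        ])

    @classmethod
    def from_vector(cls, vec: np.ndarray, index: ConditionIndex) -> "ModelParams":
        a, s = index.n_alpha, index.n_slope
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (a + 11 * s,):
            raise ValueError(f"expected vector of length {a + 11 * s}")
        o = 0
        alpha = vec[o:o + a]; o += a
        brt = vec[o:o + s]; o += s
        btr = vec[o:o + s]; o += s
        d = vec[o:o + 3 * s].reshape(3, s); o += 3 * s
        mr = vec[o:o + 3 * s].reshape(3, s); o += 3 * s
        mt = vec[o:o + 3 * s].reshape(3, s)
        return cls(alpha, brt, btr, d, mr, mt)

    def copy(self) -> "ModelParams":
        return ModelParams(*(getattr(self, f).copy() for f in (
            "alpha", "beta_rt", "beta_trial",
            "spq_direct", "spq_rt_mod", "spq_trial_mod")))


def block_slices(index: ConditionIndex) -> dict[str, slice]:
    """Slices of each parameter family within the packed vector."""
    a, s = index.n_alpha, index.n_slope
    names = ["alpha", "beta_rt", "beta_trial",
             "beta_cp", "beta_in", "beta_di",
             "beta_cp_rt", "beta_in_rt", "beta_di_rt",
             "beta_cp_trial", "beta_in_trial", "beta_di_trial"]
    sizes = [a] + [s] * 11
    out, o = {}, 0
    for n, k in zip(names, sizes):
        out[n] = slice(o, o + k)
        o += k
    return out


def parameter_labels(index: ConditionIndex) -> list[str]:
    labels = list(index.alpha_labels())
    for stem in ("beta_rt", "beta_trial",
                 "beta_cp", "beta_in", "beta_di",
                 "beta_cp_rt", "beta_in_rt", "beta_di_rt",
                 "beta_cp_trial", "beta_in_trial", "beta_di_trial"):
        labels.extend(index.slope_labels(stem))
    return labels


@dataclass(frozen=True)
class PriorSpec:
    """Prior standard deviations; all locations are zero.

    ``sd_beta_rt`` parameterizes a half-normal restricted to
    nonnegative values, reflecting that a fuller expression is never
    harder to recognise.
    """

    sd_alpha: float = 1.5
    sd_beta_rt: float = 1.0
    sd_beta_trial: float = 1.0
    sd_spq_direct: float = 0.25
    sd_spq_mod: float = 0.1


# ---------------------------------------------------------------------------
# covariate transforms

def rt_covariate(rt_seconds):
    """ln(RT/10): 0 at full intensity (10 s), unboundedly negative near 0 s."""
    rt = np.asarray(rt_seconds, dtype=float)
    if np.any(rt <= 0) or np.any(rt > 10):
        raise DomainError("rt_seconds must lie in (0, 10]")
    out = np.log(rt / 10.0)
    return out if out.ndim else float(out)

def trial_covariate(trial_index):
    """((10 - t)/9)^e: 1 on the first presentation, 0 on the tenth.

    The exponent e makes the learning curve steepest over the earliest
    trials, approaching an asymptote by the last.
    """
    t = np.asarray(trial_index)
    if np.any(t < 1) or np.any(t > 10) or np.any(t != np.floor(t)):
        raise DomainError("trial_index must be an integer in 1..10")
    out = ((10.0 - np.asarray(t, dtype=float)) / 9.0) ** math.e
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# encoded trial arrays

@dataclass
class EncodedTrials:
    """Vectorized trial covariates ready for likelihood evaluation."""

    a24: np.ndarray      # (n,) intercept slot per trial
    s18: np.ndarray      # (n,) slope slot per trial
    x: np.ndarray        # (n,) ln(RT/10)
    w: np.ndarray        # (n,) ((10-Trial)/9)^e
    y: np.ndarray        # (n,) correctness 0/1
    z: np.ndarray        # (n, 3) SPQ z-scores (CP, IN, DI); zeros if absent
    n_alpha: int = 24
    n_slope: int = 18

    @property
    def n(self) -> int:
        return self.a24.shape[0]

    @classmethod
    def empty(cls, index: ConditionIndex) -> "EncodedTrials":
        zi = np.zeros(0, dtype=np.intp)
        zf = np.zeros(0)
        return cls(zi, zi.copy(), zf, zf.copy(), zf.copy(), np.zeros((0, 3)),
                   n_alpha=index.n_alpha, n_slope=index.n_slope)


def encode_trials(dataset, index: ConditionIndex) -> EncodedTrials:
    """Encode a core_data.Dataset for vectorized likelihood evaluation.

    SPQ z-scores of participants without a profile (or with
    unstandardized profiles) are zero, which reduces the extended
    predictor exactly to the base model for those trials.
    """
    df = dataset.trials
    n = len(df)
    a24 = np.empty(n, dtype=np.intp)
    s18 = np.empty(n, dtype=np.intp)
    groups = df["group"].to_numpy()
    fbs = df["feedback"].to_numpy()
    emos = df["emotion"].to_numpy()
    for i in range(n):
        a24[i] = index.slot24(groups[i], fbs[i], emos[i])
        s18[i] = index.slot18(groups[i], fbs[i], emos[i])
    x = rt_covariate(df["rt_seconds"].to_numpy())
    w = trial_covariate(df["trial_index"].to_numpy())
    y = df["correct"].to_numpy(dtype=float)
    z = np.zeros((n, 3))
    if dataset.spq:
        zmap = {}
        for pid, prof in dataset.spq.items():
            if prof.z_cp is not None:
                zmap[pid] = (prof.z_cp, prof.z_in, prof.z_di)
        if zmap:
            pids = df["participant_id"].to_numpy()
            for i in range(n):
                if pids[i] in zmap:
                    z[i] = zmap[pids[i]]
    return EncodedTrials(a24, s18, np.atleast_1d(x), np.atleast_1d(w), y, z,
                         n_alpha=index.n_alpha, n_slope=index.n_slope)


def _moderation_terms(enc: EncodedTrials, params: ModelParams):
    """Per-trial moderation factors u, v and direct SPQ term d."""
    zT = enc.z.T  # (3, n)
    u = np.einsum("kn,kn->n", params.spq_rt_mod[:, enc.s18], zT)
    v = np.einsum("kn,kn->n", params.spq_trial_mod[:, enc.s18], zT)
    d = np.einsum("kn,kn->n", params.spq_direct[:, enc.s18], zT)
    return u, v, d


def eta(enc: EncodedTrials, params: ModelParams) -> np.ndarray:
    """Per-trial linear predictor (log-odds of a correct response)."""
    u, v, d = _moderation_terms(enc, params)
    return (params.alpha[enc.a24]
            + params.beta_rt[enc.s18] * (1.0 + u) * enc.x
            + params.beta_trial[enc.s18] * (1.0 + v) * enc.w
            + d)


def predicted_probability(enc: EncodedTrials, params: ModelParams) -> np.ndarray:
    from scipy.special import expit
    return expit(eta(enc, params))


def linear_predictor(trial, spq_profile, params: ModelParams,
                     index: ConditionIndex) -> float:
    """Log-odds of a correct response for one trial (scalar convenience)."""
    a = index.slot24(trial.group, trial.feedback, trial.emotion)
    s = index.slot18(trial.group, trial.feedback, trial.emotion)
    x = rt_covariate(trial.rt_seconds)
    w = trial_covariate(trial.trial_index)
    if spq_profile is not None and spq_profile.z_cp is not None:
        z = np.array([spq_profile.z_cp, spq_profile.z_in, spq_profile.z_di])
    else:
        z = np.zeros(3)
    u = float(params.spq_rt_mod[:, s] @ z)
    v = float(params.spq_trial_mod[:, s] @ z)
    d = float(params.spq_direct[:, s] @ z)
    return float(params.alpha[a]
                 + params.beta_rt[s] * (1.0 + u) * x
                 + params.beta_trial[s] * (1.0 + v) * w
                 + d)


# ---------------------------------------------------------------------------
# likelihood, prior, posterior

def log_likelihood(enc: EncodedTrials, params: ModelParams) -> float:
    """Joint Bernoulli log likelihood with probabilities clipped to
    [1e-12, 1 - 1e-12] so rounding alone never produces -inf."""
    from scipy.special import expit
    p = np.clip(expit(eta(enc, params)), _P_FLOOR, 1.0 - _P_FLOOR)
    return float(np.sum(enc.y * np.log(p) + (1.0 - enc.y) * np.log1p(-p)))


def log_likelihood_grad(enc: EncodedTrials, params: ModelParams) -> ModelParams:
    """Analytic gradient of the log likelihood, same shapes as the params."""
    from scipy.special import expit
    u, v, d = _moderation_terms(enc, params)
    brt_s = params.beta_rt[enc.s18]
    btr_s = params.beta_trial[enc.s18]
    e = (params.alpha[enc.a24] + brt_s * (1.0 + u) * enc.x
         + btr_s * (1.0 + v) * enc.w + d)
    g = enc.y - expit(e)  # d loglik / d eta
    na, ns = enc.n_alpha, enc.n_slope
    ga = np.bincount(enc.a24, weights=g, minlength=na)
    gx = g * enc.x
    gw = g * enc.w
    gbrt = np.bincount(enc.s18, weights=gx * (1.0 + u), minlength=ns)
    gbtr = np.bincount(enc.s18, weights=gw * (1.0 + v), minlength=ns)
    gd = np.empty((3, ns))
    gmr = np.empty((3, ns))
    gmt = np.empty((3, ns))
    for k in range(3):
        zk = enc.z[:, k]
        gd[k] = np.bincount(enc.s18, weights=g * zk, minlength=ns)
        gmr[k] = np.bincount(enc.s18, weights=gx * brt_s * zk, minlength=ns)
        gmt[k] = np.bincount(enc.s18, weights=gw * btr_s * zk, minlength=ns)
    return ModelParams(ga, gbrt, gbtr, gd, gmr, gmt)


_LOG_2PI = math.log(2.0 * math.pi)

def _normal_logpdf_sum(x: np.ndarray, sd: float) -> float:
    return float(-0.5 * np.sum((x / sd) ** 2)
                 - x.size * (math.log(sd) + 0.5 * _LOG_2PI))


def log_prior(params: ModelParams, priors: PriorSpec = PriorSpec()) -> float:
    """Sum of the six families' log prior densities; -inf off the
    beta_rt >= 0 half-space."""
    if np.any(params.beta_rt < 0):
        return -math.inf
    lp = _normal_logpdf_sum(params.alpha, priors.sd_alpha)
    # half-normal = 2 * normal density on the nonnegative half-line
    lp += (params.beta_rt.size * math.log(2.0)
           + _normal_logpdf_sum(params.beta_rt, priors.sd_beta_rt))
    lp += _normal_logpdf_sum(params.beta_trial, priors.sd_beta_trial)
    lp += _normal_logpdf_sum(params.spq_direct, priors.sd_spq_direct)
    lp += _normal_logpdf_sum(params.spq_rt_mod, priors.sd_spq_mod)
    lp += _normal_logpdf_sum(params.spq_trial_mod, priors.sd_spq_mod)
    return lp


def log_prior_grad(params: ModelParams,
                   priors: PriorSpec = PriorSpec()) -> ModelParams:
    return ModelParams(
        -params.alpha / priors.sd_alpha ** 2,
        -params.beta_rt / priors.sd_beta_rt ** 2,
        -params.beta_trial / priors.sd_beta_trial ** 2,
        -params.spq_direct / priors.sd_spq_direct ** 2,
        -params.spq_rt_mod / priors.sd_spq_mod ** 2,
        -params.spq_trial_mod / priors.sd_spq_mod ** 2,
    )


def log_posterior(enc: EncodedTrials, params: ModelParams,
                  priors: PriorSpec = PriorSpec()) -> float:
    lp = log_prior(params, priors)
    if not math.isfinite(lp):
        return lp
    return lp + log_likelihood(enc, params)


# ---------------------------------------------------------------------------
# unconstrained parameterization for gradient-based sampling
#
# beta_rt is sampled as theta = log(beta_rt); the log-density gains the
# Jacobian term sum(theta) and gradients pick up the chain-rule factor
# beta_rt, plus 1 from the Jacobian.

def make_posterior_fn(enc: EncodedTrials, index: ConditionIndex,
                      priors: PriorSpec = PriorSpec()):
    """Return (logp_and_grad, to_constrained, to_unconstrained).

    ``logp_and_grad(theta)`` evaluates the unconstrained-space log
    posterior (including the log-transform Jacobian for beta_rt) and its
    gradient.
    """
    sl = block_slices(index)
    rt_sl = sl["beta_rt"]

    def to_constrained(theta: np.ndarray) -> np.ndarray:
        vec = np.array(theta, dtype=float)
        vec[rt_sl] = np.exp(vec[rt_sl])
        return vec

    def to_unconstrained(vec: np.ndarray) -> np.ndarray:
        theta = np.array(vec, dtype=float)
        with np.errstate(divide="ignore"):
            theta[rt_sl] = np.log(theta[rt_sl])
        return theta

    def logp_and_grad(theta: np.ndarray):
        vec = to_constrained(theta)
        params = ModelParams.from_vector(vec, index)
        brt = params.beta_rt
        lp = log_prior(params, priors) + float(np.sum(theta[rt_sl]))
        gl = log_prior_grad(params, priors)
        if enc.n:
            lp += log_likelihood(enc, params)
            gll = log_likelihood_grad(enc, params)
            grad_c = gll.to_vector() + gl.to_vector()
        else:
            grad_c = gl.to_vector()
        grad = grad_c.copy()
        grad[rt_sl] = grad_c[rt_sl] * brt + 1.0
        return lp, grad

    return logp_and_grad, to_constrained, to_unconstrained


def make_constrained_posterior_fn(enc: EncodedTrials, index: ConditionIndex,
                                  priors: PriorSpec = PriorSpec()):
    """Return (logp_and_grad, rt_slice) on the constrained vector.

    For use with boundary-reflecting samplers: the density is the exact
    posterior (no Jacobian) and is -inf off the beta_rt >= 0 half-space;
    ``rt_slice`` marks the coordinates subject to that constraint.
    """
    rt_sl = block_slices(index)["beta_rt"]

    def logp_and_grad(vec: np.ndarray):
        params = ModelParams.from_vector(np.asarray(vec, dtype=float), index)
        lp = log_prior(params, priors)
        if not math.isfinite(lp):
            return lp, np.zeros(vec.size)
        gl = log_prior_grad(params, priors)
        if enc.n:
            lp += log_likelihood(enc, params)
            grad = log_likelihood_grad(enc, params).to_vector() + gl.to_vector()
        else:
            grad = gl.to_vector()
        return lp, grad

    return logp_and_grad, rt_sl
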