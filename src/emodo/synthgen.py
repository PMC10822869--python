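"""Synthetic datasets with the task's design and the model's structure.

Emulates the study conditions: two groups (DOP n=88, NOP n=95), two
60-trial blocks per participant (6 emotions x 10 actors in seeded random
order, no feedback first, feedback second), reaction times on (0, 10] s,
and partial SPQ completion (58 DOP + 51 NOP completers of 183).
Correctness is generated from the model module's own linear predictor at
known ("true") parameters, which makes every downstream stage testable
by parameter recovery without any download.

RTs are fixture machinery — the accuracy model treats RT as an observed
covariate — and are drawn from a per-(feedback, emotion) lognormal
truncated to (0, 10], with default medians in the 3-6 s range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import norm

from . import model as m
from .core_data import Dataset, SPQProfile

__all__ = [
    "DesignSpec", "RtModel", "default_rt_model", "make_design",
    "sample_rts", "sample_spq", "simulate_responses", "preset_true_params",
    "simulate_study", "PRESETS",
]


@dataclass(frozen=True)
class DesignSpec:
    """Counts and labels describing one simulated study.

    Defaults are the study's own conditions: 88 DOP and 95 NOP
    participants, 10 actors per emotion, six emotions, a no-feedback
    block followed by a feedback block, and 58/51 SPQ completers.
    """

    n_dop: int = 88
    n_nop: int = 95
    n_actors: int = 10
    emotions: tuple = m.EMOTIONS
    blocks: tuple = m.FEEDBACK_LEVELS
    spq_completers: tuple = (58, 51)
    seed: int = 0

    def __post_init__(self):
        if self.n_dop < 0 or self.n_nop < 0:
            raise ValueError("participant counts must be nonnegative")
        if not (1 <= self.n_actors <= 10):
            raise ValueError("n_actors must be in 1..10")
        if self.spq_completers[0] > self.n_dop or self.spq_completers[1] > self.n_nop:
            raise ValueError("completer counts cannot exceed group sizes")

    @property
    def trials_per_block(self) -> int:
        return len(self.emotions) * self.n_actors

    def index(self) -> m.ConditionIndex:
        return m.ConditionIndex.standard(self.emotions)


@dataclass(frozen=True)
class RtModel:
    """Log-scale location/scale of the truncated RT law per condition.

    ``mu[(feedback, emotion)]`` is the log-scale location (log median of
    the untruncated law, seconds), ``sigma`` the common log-scale SD.
    All samples fall in (0, 10].
    """

    mu: dict
    sigma: float = 0.45

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.sigma == 0:
            for (fb, emo), mu in self.mu.items():
                if np.exp(mu) > 10:
                    raise ValueError(
                        f"degenerate scale with exp(mu) > 10 s for ({fb}, {emo})")


#: default untruncated medians (s); harder emotions are answered later
_DEFAULT_MEDIANS = {"Anger": 4.5, "Disgust": 4.0, "Fear": 5.5,
                    "Happiness": 3.0, "Sadness": 5.0, "Surprise": 4.0}


def default_rt_model(emotions=m.EMOTIONS) -> RtModel:
    mu = {}
    for fb in m.FEEDBACK_LEVELS:
        for emo in emotions:
            mu[(fb, emo)] = float(np.log(_DEFAULT_MEDIANS.get(emo, 4.5)))
    return RtModel(mu=mu)


# ---------------------------------------------------------------------------
# design skeleton

def make_design(spec: DesignSpec) -> Dataset:
    """Build the trial skeleton (no rt_seconds / correct yet).

    Each participant sees, in each block, every (emotion, actor) pair
    exactly once in seeded random order; trial_index counts the
    presentations of that emotion within the block (1..n_actors).
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    pairs = [(e, a) for e in spec.emotions for a in range(1, spec.n_actors + 1)]
    rows = []
    pids = ([("DOP", f"DOP{i + 1:03d}") for i in range(spec.n_dop)]
            + [("NOP", f"NOP{i + 1:03d}") for i in range(spec.n_nop)])
    for group, pid in pids:
        for block in spec.blocks:
            order = [pairs[k] for k in rng.permutation(len(pairs))]
            seen = {e: 0 for e in spec.emotions}
            for emo, actor in order:
                seen[emo] += 1
                rows.append((pid, group, block, emo, actor, seen[emo]))
    df = pd.DataFrame(rows, columns=["participant_id", "group", "feedback",
                                     "emotion", "actor_id", "trial_index"])
    return Dataset(trials=df)


def sample_rts(skeleton: Dataset, rt_model: RtModel | None = None,
               seed: int = 0) -> Dataset:
    """Attach i.i.d. truncated-lognormal RTs to a design skeleton.

    Sampling is by inverse CDF restricted to (0, 10], so no draw is
    ever rejected and the output is reproducible for a given seed.
    """
    df = skeleton.trials
    if rt_model is None:
        rt_model = default_rt_model(tuple(dict.fromkeys(df["emotion"])))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    mu = np.array([rt_model.mu[(fb, emo)]
                   for fb, emo in zip(df["feedback"], df["emotion"])])
    if rt_model.sigma == 0:
        rt = np.exp(mu)
    else:
        # P(RT <= 10) under the untruncated law, per trial
        cap = norm.cdf((np.log(10.0) - mu) / rt_model.sigma)
        u = rng.uniform(0.0, cap)
        rt = np.exp(mu + rt_model.sigma * ndtri(np.clip(u, 1e-300, None)))
    rt = np.minimum(rt, 10.0)
    out = df.copy()
    out["rt_seconds"] = rt
    return Dataset(trials=out, spq=dict(skeleton.spq))


def truncated_median(rt_model: RtModel, feedback: str, emotion: str) -> float:
    """Closed-form median of the truncated RT law (quantile oracle)."""
    mu = rt_model.mu[(feedback, emotion)]
    if rt_model.sigma == 0:
        return float(np.exp(mu))
    cap = norm.cdf((np.log(10.0) - mu) / rt_model.sigma)
    return float(np.exp(mu + rt_model.sigma * ndtri(0.5 * cap)))


# ---------------------------------------------------------------------------
# SPQ assignment

#: raw-score anchors (mean, SD) for the back-fill map, matching the
#: study sample's descriptives for CP / IN / DI
_RAW_ANCHORS = ((9.53, 5.90, 33), (11.94, 6.34, 33), (4.80, 3.63, 16))

_DEFAULT_FACTOR_CORR = np.array([
    [1.00, 0.45, 0.45],
    [0.45, 1.00, 0.45],
    [0.45, 0.45, 1.00],
])


def sample_spq(dataset: Dataset, completers: tuple = (58, 51),
               correlation: np.ndarray | None = None, seed: int = 0) -> Dataset:
    """Assign SPQ profiles to a random completer subset of each group.

    Standardized factor scores are drawn from a correlated trivariate
    normal; raw scores are back-filled by a rank-preserving affine map
    (rounded, clipped into 0-33/0-33/0-16).  Only the z-scores enter the
    model, so the back-fill affects no inference.  Non-completers get no
    profile.
    """
    corr = _DEFAULT_FACTOR_CORR if correlation is None else np.asarray(correlation)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise ValueError("correlation matrix must be positive definite")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    df = dataset.trials
    spq: dict[str, SPQProfile] = {}
    for gi, group in enumerate(m.GROUPS):
        pids = list(dict.fromkeys(df.loc[df["group"] == group, "participant_id"]))
        k = completers[gi]
        if k > len(pids):
            raise ValueError(f"completer count {k} exceeds {group} size {len(pids)}")
        chosen = [pids[i] for i in rng.choice(len(pids), size=k, replace=False)]
        z = rng.standard_normal((k, 3)) @ chol.T
        for pid, zi in zip(chosen, z):
            raws = []
            for (mean, sd, hi), zv in zip(_RAW_ANCHORS, zi):
                raws.append(int(np.clip(round(mean + sd * zv), 0, hi)))
            cp, in_, di = raws
            # feasible Suspiciousness share so the total stays consistent
            susp = int(np.clip(round(8 * (cp / 33 + in_ / 33) / 2),
                               max(0, cp - 25, in_ - 25), min(8, cp, in_)))
            prof = SPQProfile(cp, in_, di, cp + in_ + di - susp,
                              z_cp=float(zi[0]), z_in=float(zi[1]),
                              z_di=float(zi[2]))
            spq[pid] = prof
    return Dataset(trials=df, spq=spq, meta=dataset.meta)


# ---------------------------------------------------------------------------
# true-parameter presets

#: Table-1-style cell accuracies converted to logits (DOP-F, DOP-NF,
#: NOP-F, NOP-NF per emotion); the one extreme cell is capped at 5.0
_PAPERLIKE_ALPHA = {
    "Anger":     (4.33, 2.03, 3.75, 2.23),
    "Disgust":   (2.40, 1.70, 2.35, 1.67),
    "Fear":      (1.70, 1.13, 2.60, 1.24),
    "Happiness": (4.82, 3.75, 5.00, 4.41),
    "Sadness":   (3.42, 3.01, 4.60, 2.90),
    "Surprise":  (3.03, 2.73, 3.94, 2.72),
}

#: Table-2-style RT penalties (NoFeedback, DOP-Feedback, NOP-Feedback)
_PAPERLIKE_BETA_RT = {
    "Anger":     (0.58, 1.79, 1.24),
    "Disgust":   (0.85, 0.74, 0.52),
    "Fear":      (1.18, 0.75, 1.66),
    "Happiness": (0.13, 0.45, 1.25),
    "Sadness":   (0.84, 0.96, 1.42),
    "Surprise":  (0.38, 0.22, 1.23),
}

#: Table-3-style learning-curve coefficients
_PAPERLIKE_BETA_TRIAL = {
    "Anger":     (-0.75, -0.66, -0.43),
    "Disgust":   (-0.66, -0.58, -0.44),
    "Fear":      (-1.18, -0.71, -0.81),
    "Happiness": (-0.27, 0.97, 0.70),
    "Sadness":   (-0.61, -0.18, 0.25),
    "Surprise":  (-0.33, -0.14, 0.28),
}

PRESETS = ("null", "paper-like", "strong-moderation")


def preset_true_params(name: str,
                       index: m.ConditionIndex | None = None) -> m.ModelParams:
    """Deterministic, documented ground-truth parameter sets.

    'null': every parameter 0.  'paper-like': intercepts/slopes at the
    magnitudes of the study's posterior means, SPQ effects small (the
    study found none credible).  'strong-moderation': paper-like base
    effects with deliberately large SPQ direct and moderation effects.
    """
    index = index or m.ConditionIndex.standard()
    params = m.ModelParams.zeros(index)
    if name == "null":
        return params
    if name not in PRESETS:
        raise ValueError(f"unknown preset '{name}'; choose from {PRESETS}")
    unknown = set(index.emotions) - set(_PAPERLIKE_ALPHA)
    if unknown:
        raise ValueError(f"preset '{name}' is defined for the six basic "
                         f"emotions only; unknown: {sorted(unknown)}")
    fcell = {("DOP", "Feedback"): 0, ("DOP", "NoFeedback"): 1,
             ("NOP", "Feedback"): 2, ("NOP", "NoFeedback"): 3}
    for (g, f, e), slot in index.cond24.items():
        params.alpha[slot] = _PAPERLIKE_ALPHA[e][fcell[(g, f)]]
    scell = {s: i for i, s in enumerate(m.SLOPE_CONDITIONS)}
    for (s, e), slot in index.cond18.items():
        params.beta_rt[slot] = _PAPERLIKE_BETA_RT[e][scell[s]]
        params.beta_trial[slot] = _PAPERLIKE_BETA_TRIAL[e][scell[s]]
    if name == "paper-like":
        direct_amp, mod_amp = 0.05, 0.002
    else:  # strong-moderation
        direct_amp, mod_amp = 0.20, 0.08
    ns = index.n_slope
    signs = np.where(np.arange(3 * ns).reshape(3, ns) % 2 == 0, 1.0, -1.0)
    params.spq_direct = direct_amp * signs
    params.spq_rt_mod = mod_amp * signs * np.where(
        np.arange(ns) % 3 == 0, 1.0, -1.0)
    params.spq_trial_mod = -mod_amp * signs
    params.validate()
    return params


# ---------------------------------------------------------------------------
# responses and the full pipeline

def simulate_responses(dataset: Dataset, true_params: m.ModelParams,
                       index: m.ConditionIndex | None = None,
                       seed: int = 0) -> Dataset:
    """Draw correctness from Bernoulli(p) at the model's own predictor."""
    if "rt_seconds" not in dataset.trials.columns:
        raise ValueError("dataset has no rt_seconds; run sample_rts first")
    index = index or m.ConditionIndex.standard(
        tuple(dict.fromkeys(dataset.trials["emotion"])))
    df = dataset.trials.copy()
    df["correct"] = 0  # placeholder for encoding
    enc = m.encode_trials(Dataset(trials=df, spq=dataset.spq), index)
    p = m.predicted_probability(enc, true_params)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    df["correct"] = rng.binomial(1, p)
    return Dataset(trials=df, spq=dict(dataset.spq), meta=dataset.meta)


def simulate_study(spec: DesignSpec = DesignSpec(), preset: str = "paper-like",
                   rt_model: RtModel | None = None,
                   true_params: m.ModelParams | None = None):
    """Full generation pipeline: design -> RTs -> SPQ -> responses.

    Returns (Dataset, true ModelParams).  Bit-reproducible for a fixed
    ``spec.seed``.
    """
    index = spec.index()
    if true_params is None:
        true_params = preset_true_params(preset, index)
    ds = make_design(spec)
    ds = sample_rts(ds, rt_model or default_rt_model(spec.emotions),
                    seed=spec.seed)
    if sum(spec.spq_completers) > 0:
        ds = sample_spq(ds, completers=spec.spq_completers, seed=spec.seed)
    ds = simulate_responses(ds, true_params, index, seed=spec.seed)
    return ds, true_params
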