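"""Inference over posterior draws: HDIs, ROPE decisions, contrasts,
condition tables, SPQ-effect summaries, and posterior-predictive curves.

Inference follows the HDI+ROPE decision rule: a contrast is *credible*
when its 95% highest-density interval completely excludes the region of
practical equivalence, *negligible* when the HDI lies entirely within
the ROPE, and the decision is *withheld* when they overlap.  The ROPEs
are those of the accuracy analysis: +-5 percentage points for accuracy
contrasts, the degenerate {0} for RT-penalty contrasts, +-0.2 log-odds
for learning-curve coefficients, +-0.1 per SD for direct schizotypy
effects and +-0.005 per SD for proportional moderation effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import model as m
from .sampler import PosteriorSamples

__all__ = [
    "Interval", "RopeSpec", "Decision", "ContrastConvention",
    "hdi", "rope_decision", "rope_halfwidth_probability",
    "rope_halfwidth_moderation", "alpha_to_percent", "contrast",
    "double_contrast", "build_table_alpha", "build_table_beta_rt",
    "build_table_beta_trial", "spq_effect_summary", "posterior_predictive",
    "grid_full_intensity", "grid_rt_bins", "grid_trials",
    "collect_decisions",
]


@dataclass(frozen=True)
class Interval:
    """A highest-density interval with its probability mass."""

    lower: float
    upper: float
    mass: float = 0.95

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValueError("lower must not exceed upper")


@dataclass(frozen=True)
class RopeSpec:
    """Region of practical equivalence; may be degenerate (lower==upper)."""

    lower: float
    upper: float
    scale: str = "log-odds"  # or "percent-probability", "proportional"

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValueError("lower must not exceed upper")

    @classmethod
    def symmetric(cls, halfwidth: float, scale: str = "log-odds") -> "RopeSpec":
        return cls(-halfwidth, halfwidth, scale)

    @classmethod
    def zero(cls, scale: str = "log-odds") -> "RopeSpec":
        return cls(0.0, 0.0, scale)


class Decision(str, Enum):
    CREDIBLE = "credible"      # HDI completely excludes the ROPE
    NEGLIGIBLE = "negligible"  # HDI entirely inside the ROPE
    WITHHELD = "withheld"      # they overlap


def hdi(draws, mass: float = 0.95) -> Interval:
    """Shortest contiguous interval holding ceil(mass * n) sorted draws.

    Deterministic sorted-window search; ties broken toward the leftmost
    shortest window.
    """
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n == 0:
        raise ValueError("empty draw vector")
    if not (0 < mass <= 1):
        raise ValueError("mass must be in (0, 1]")
    k = int(math.ceil(mass * n))
    if k >= n:
        return Interval(float(x[0]), float(x[-1]), mass)
    widths = x[k - 1:] - x[:n - k + 1]
    i = int(np.argmin(widths))  # argmin returns the leftmost minimum
    return Interval(float(x[i]), float(x[i + k - 1]), mass)


def rope_decision(interval: Interval, rope: RopeSpec,
                  scale: str | None = None) -> Decision:
    """Three-way HDI-vs-ROPE decision.

    'Completely excludes' is strict: any shared point (endpoints
    included) blocks a credible verdict.  For the degenerate {0} ROPE
    this reduces to 'credible iff 0 is outside the HDI'.
    """
    if scale is not None and scale != rope.scale:
        raise ValueError(f"scale mismatch: interval on '{scale}', "
                         f"ROPE on '{rope.scale}'")
    if interval.upper < rope.lower or interval.lower > rope.upper:
        return Decision.CREDIBLE
    if rope.lower <= interval.lower and interval.upper <= rope.upper:
        return Decision.NEGLIGIBLE
    return Decision.WITHHELD


def rope_halfwidth_probability(delta_p: float = 0.05,
                               reference_logodds: float = 0.0,
                               sd_span: float = 1.0) -> float:
    """Log-odds change that shifts a reference probability by delta_p,
    optionally spread over a span of sd_span standard deviations.

    At reference log-odds 0 and delta_p=0.05 this is logit(0.55) ~= 0.2007
    (the learning-curve ROPE half-width, rounded to 0.2); divided over a
    2-SD span it gives the 0.1 per-SD bound for direct effects.
    """
    if not (0 <= delta_p < 0.5):
        raise ValueError("delta_p must be in [0, 0.5)")
    if sd_span <= 0:
        raise ValueError("sd_span must be positive")
    p_ref = expit(reference_logodds)
    return float((logit(p_ref + delta_p) - reference_logodds) / sd_span)


def rope_halfwidth_moderation(delta_effect: float = 0.01,
                              sd_span: float = 2.0) -> float:
    """Proportional moderation treated as negligible: a delta_effect
    change in effect magnitude spread over sd_span SDs (default
    0.01 / 2 = 0.005)."""
    if delta_effect < 0 or sd_span <= 0:
        raise ValueError("inputs must be positive (delta_effect may be 0)")
    return float(delta_effect / sd_span)


#: the analysis' five ROPEs
ROPE_ALPHA_PCT = RopeSpec.symmetric(5.0, scale="percent-probability")
ROPE_BETA_RT = RopeSpec.zero()
ROPE_BETA_TRIAL = RopeSpec.symmetric(0.2)
ROPE_SPQ_DIRECT = RopeSpec.symmetric(0.1)
ROPE_SPQ_MOD = RopeSpec.symmetric(0.005, scale="proportional")


def alpha_to_percent(draws) -> np.ndarray:
    """Intercept log-odds -> probability of a correct response, in %."""
    return 100.0 * expit(np.asarray(draws, dtype=float))


def contrast(draws_a, draws_b) -> np.ndarray:
    """Elementwise a - b across aligned posterior draws."""
    a = np.asarray(draws_a, dtype=float)
    b = np.asarray(draws_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("draw vectors must have equal length")
    return a - b


def double_contrast(pair_a, pair_b) -> np.ndarray:
    """(a1 - a0) - (b1 - b0), per draw."""
    return contrast(contrast(*pair_a), contrast(*pair_b))


@dataclass(frozen=True)
class ContrastConvention:
    """Sign conventions of the condition tables (defaults match the
    printed signs: Feedback - NoFeedback, DOP - NOP, and
    NoFeedback-first for the learning-curve feedback contrasts)."""

    feedback_minus_nofeedback: bool = True
    dop_minus_nop: bool = True
    table3_nofeedback_first: bool = True

    def fsign(self) -> float:
        return 1.0 if self.feedback_minus_nofeedback else -1.0

    def gsign(self) -> float:
        return 1.0 if self.dop_minus_nop else -1.0

    def t3sign(self) -> float:
        return 1.0 if self.table3_nofeedback_first else -1.0


def _cell(draws: np.ndarray, mass: float = 0.95) -> dict:
    iv = hdi(draws, mass)
    return {"mean": float(np.mean(draws)),
            "hdi_lower": iv.lower, "hdi_upper": iv.upper}


def _decide(draws: np.ndarray, rope: RopeSpec, mass: float = 0.95):
    iv = hdi(draws, mass)
    return _cell(draws, mass), rope_decision(iv, rope)


def build_table_alpha(samples: PosteriorSamples, mass: float = 0.95,
                      rope: RopeSpec = ROPE_ALPHA_PCT,
                      convention: ContrastConvention = ContrastConvention()
                      ) -> pd.DataFrame:
    """Accuracy (percent scale) per condition, feedback contrasts per
    group, and the group difference-of-differences, per emotion."""
    index = samples.index
    alpha = samples.block("alpha")
    rows = []
    for emo in index.emotions:
        row = {"emotion": emo}
        pct = {}
        for g in m.GROUPS:
            for f in m.FEEDBACK_LEVELS:
                d = alpha_to_percent(alpha[:, index.slot24(g, f, emo)])
                pct[(g, f)] = d
                stem = f"{g.lower()}_{f.lower()}"
                for k, v in _cell(d, mass).items():
                    row[f"{stem}_{k}"] = v
        diffs = {}
        for g in m.GROUPS:
            d = convention.fsign() * contrast(pct[(g, "Feedback")],
                                              pct[(g, "NoFeedback")])
            diffs[g] = d
            cell, dec = _decide(d, rope, mass)
            for k, v in cell.items():
                row[f"{g.lower()}_diff_{k}"] = v
            row[f"{g.lower()}_diff_decision"] = dec.value
            row[f"{g.lower()}_diff_credible"] = dec is Decision.CREDIBLE
        dd = convention.gsign() * contrast(diffs["DOP"], diffs["NOP"])
        cell, dec = _decide(dd, rope, mass)
        for k, v in cell.items():
            row[f"group_diff_{k}"] = v
        row["group_diff_decision"] = dec.value
        row["group_diff_credible"] = dec is Decision.CREDIBLE
        rows.append(row)
    return pd.DataFrame(rows)


def _slope_table(samples: PosteriorSamples, block_name: str, mass: float
                 ) -> tuple[pd.DataFrame, dict]:
    index = samples.index
    blk = samples.block(block_name)
    cells = {}
    rows = []
    for emo in index.emotions:
        row = {"emotion": emo}
        for cond in m.SLOPE_CONDITIONS:
            d = blk[:, index.cond18[(cond, emo)]]
            cells[(cond, emo)] = d
            stem = cond.lower().replace("-", "_")
            for k, v in _cell(d, mass).items():
                row[f"{stem}_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows), cells


def build_table_beta_rt(samples: PosteriorSamples, mass: float = 0.95,
                        rope: RopeSpec = ROPE_BETA_RT,
                        convention: ContrastConvention = ContrastConvention()
                        ) -> pd.DataFrame:
    """RT-penalty posteriors per feedback condition plus the DOP-NOP
    feedback contrast against the degenerate {0} ROPE."""
    df, cells = _slope_table(samples, "beta_rt", mass)
    for i, emo in enumerate(samples.index.emotions):
        d = convention.gsign() * contrast(cells[("DOP-Feedback", emo)],
                                          cells[("NOP-Feedback", emo)])
        cell, dec = _decide(d, rope, mass)
        for k, v in cell.items():
            df.loc[i, f"dop_vs_nop_{k}"] = v
        df.loc[i, "dop_vs_nop_decision"] = dec.value
        df.loc[i, "dop_vs_nop_credible"] = dec is Decision.CREDIBLE
    return df


def build_table_beta_trial(samples: PosteriorSamples, mass: float = 0.95,
                           rope: RopeSpec = ROPE_BETA_TRIAL,
                           convention: ContrastConvention = ContrastConvention()
                           ) -> pd.DataFrame:
    """Learning-curve posteriors per feedback condition plus the three
    pairwise feedback contrasts against the +-0.2 ROPE."""
    df, cells = _slope_table(samples, "beta_trial", mass)
    pairs = [("nofeedback_vs_nop", "NoFeedback", "NOP-Feedback",
              convention.t3sign()),
             ("nofeedback_vs_dop", "NoFeedback", "DOP-Feedback",
              convention.t3sign()),
             ("dop_vs_nop", "DOP-Feedback", "NOP-Feedback",
              convention.gsign())]
    for i, emo in enumerate(samples.index.emotions):
        for stem, a, b, sign in pairs:
            d = sign * contrast(cells[(a, emo)], cells[(b, emo)])
            cell, dec = _decide(d, rope, mass)
            for k, v in cell.items():
                df.loc[i, f"{stem}_{k}"] = v
            df.loc[i, f"{stem}_decision"] = dec.value
            df.loc[i, f"{stem}_credible"] = dec is Decision.CREDIBLE
    return df


_SPQ_FAMILIES = (
    ("beta_cp", ROPE_SPQ_DIRECT), ("beta_in", ROPE_SPQ_DIRECT),
    ("beta_di", ROPE_SPQ_DIRECT),
    ("beta_cp_rt", ROPE_SPQ_MOD), ("beta_in_rt", ROPE_SPQ_MOD),
    ("beta_di_rt", ROPE_SPQ_MOD),
    ("beta_cp_trial", ROPE_SPQ_MOD), ("beta_in_trial", ROPE_SPQ_MOD),
    ("beta_di_trial", ROPE_SPQ_MOD),
)


def spq_effect_summary(samples: PosteriorSamples,
                       mass: float = 0.95) -> pd.DataFrame:
    """Mean, HDI and ROPE decision for the nine schizotypy parameter
    families in each of the 18 conditions (162 rows)."""
    if not samples.has_spq_data:
        raise ValueError("posterior was fit without SPQ data; "
                         "schizotypy effects are prior-only")
    index = samples.index
    rows = []
    for family, rope in _SPQ_FAMILIES:
        blk = samples.block(family)
        for (cond, emo), slot in index.cond18.items():
            d = blk[:, slot]
            cell, dec = _decide(d, rope, mass)
            rows.append({"parameter": family, "condition": cond,
                         "emotion": emo, **cell,
                         "rope_lower": rope.lower, "rope_upper": rope.upper,
                         "decision": dec.value,
                         "credible": dec is Decision.CREDIBLE})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# posterior predictive

def grid_full_intensity(index: m.ConditionIndex) -> pd.DataFrame:
    """One point per condition at full intensity on the last trial."""
    rows = [{"group": g, "feedback": f, "emotion": e,
             "rt_seconds": 10.0, "trial_index": 10}
            for (g, f, e) in index.cond24]
    return pd.DataFrame(rows)


def grid_rt_bins(index: m.ConditionIndex, n_bins: int = 15,
                 lo: float = 1.0, hi: float = 10.0) -> pd.DataFrame:
    """Bin centres of the RT axis (defaults: 15 bins on [1, 10] s, so
    width 0.6 and first centre 1.3), on the last trial."""
    width = (hi - lo) / n_bins
    centres = lo + width * (np.arange(n_bins) + 0.5)
    rows = [{"group": g, "feedback": f, "emotion": e,
             "rt_seconds": float(c), "trial_index": 10}
            for (g, f, e) in index.cond24 for c in centres]
    return pd.DataFrame(rows)


def grid_trials(index: m.ConditionIndex) -> pd.DataFrame:
    """Trials 1..10 at full intensity, per condition."""
    rows = [{"group": g, "feedback": f, "emotion": e,
             "rt_seconds": 10.0, "trial_index": t}
            for (g, f, e) in index.cond24 for t in range(1, 11)]
    return pd.DataFrame(rows)


def posterior_predictive(samples: PosteriorSamples, grid: pd.DataFrame,
                         mass: float = 0.95) -> pd.DataFrame:
    """Draw-wise predicted probability of a correct response per grid
    point, summarized by mean and HDI.

    The grid needs group / feedback / emotion / rt_seconds /
    trial_index columns; optional z_cp / z_in / z_di columns evaluate
    the prediction at non-zero schizotypy levels (default 0).
    """
    index = samples.index
    a24 = np.array([index.slot24(g, f, e) for g, f, e in
                    zip(grid["group"], grid["feedback"], grid["emotion"])])
    s18 = np.array([index.slot18(g, f, e) for g, f, e in
                    zip(grid["group"], grid["feedback"], grid["emotion"])])
    x = m.rt_covariate(grid["rt_seconds"].to_numpy())
    w = m.trial_covariate(grid["trial_index"].to_numpy())
    z = np.zeros((len(grid), 3))
    for k, col in enumerate(("z_cp", "z_in", "z_di")):
        if col in grid.columns:
            z[:, k] = grid[col].to_numpy()
    A = samples.block("alpha")[:, a24]
    Brt = samples.block("beta_rt")[:, s18]
    Btr = samples.block("beta_trial")[:, s18]
    direct = np.zeros_like(A)
    u = np.zeros_like(A)
    v = np.zeros_like(A)
    for k, (dn, rn, tn) in enumerate((("beta_cp", "beta_cp_rt", "beta_cp_trial"),
                                      ("beta_in", "beta_in_rt", "beta_in_trial"),
                                      ("beta_di", "beta_di_rt", "beta_di_trial"))):
        direct += samples.block(dn)[:, s18] * z[:, k]
        u += samples.block(rn)[:, s18] * z[:, k]
        v += samples.block(tn)[:, s18] * z[:, k]
    p = expit(A + Brt * (1.0 + u) * x + Btr * (1.0 + v) * w + direct)
    out = grid.copy()
    out["p_mean"] = p.mean(axis=0)
    ivs = [hdi(p[:, j], mass) for j in range(p.shape[1])]
    out["p_hdi_lower"] = [iv.lower for iv in ivs]
    out["p_hdi_upper"] = [iv.upper for iv in ivs]
    return out


def collect_decisions(tables: dict[str, pd.DataFrame]) -> dict:
    """Flatten every *_decision column of the tables into one JSON-able
    report, with a tally per decision category."""
    decisions = {}
    tally = {d.value: 0 for d in Decision}
    for name, df in tables.items():
        for col in df.columns:
            if col.endswith("_decision") or col == "decision":
                for i, val in enumerate(df[col]):
                    key_cols = [c for c in ("parameter", "condition", "emotion")
                                if c in df.columns]
                    key = ":".join([name, col] +
                                   [str(df[c].iat[i]) for c in key_cols])
                    decisions[key] = val
                    tally[val] += 1
    return {"decisions": decisions, "tally": tally}
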