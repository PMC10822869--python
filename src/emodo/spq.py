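"""Schizotypal Personality Questionnaire (SPQ) scoring.

The SPQ has 74 dichotomous items over nine subscales, aggregated into
three factors: Cognitive-Perceptual (CP, 0-33), Interpersonal (IN,
0-33) and Disorganized (DI, 0-16).  Suspiciousness belongs to both CP
and IN but counts once toward the 0-74 total.  Subscale sizes follow
the standard published key (Ideas of Reference 9, Suspiciousness 8,
Odd Beliefs 7, Unusual Perceptual Experiences 9, Social Anxiety 8,
No Close Friends 9, Constricted Affect 8, Odd Behaviour 7, Odd
Speech 9); the default item->subscale map lays the subscales out
contiguously and can be replaced for questionnaires with a specific
published item order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import SPQProfile, ValidationError

__all__ = [
    "SUBSCALE_SIZES", "DEFAULT_SUBSCALE_MAP", "FactorComposition",
    "SPQItemMatrix", "score_subscales", "factor_scores", "cronbach_alpha",
    "standardize_factors", "factor_items",
]

SUBSCALE_SIZES = {
    "Ideas of Reference": 9,
    "Suspiciousness": 8,
    "Odd Beliefs or Magical Thinking": 7,
    "Unusual Perceptual Experiences": 9,
    "Social Anxiety": 8,
    "No Close Friends": 9,
    "Constricted Affect": 8,
    "Odd or Eccentric Behaviour": 7,
    "Odd Speech": 9,
}

SUBSCALES = tuple(SUBSCALE_SIZES)


def _default_map() -> dict[str, list[int]]:
    out, start = {}, 1
    for name, k in SUBSCALE_SIZES.items():
        out[name] = list(range(start, start + k))
        start += k
    return out


#: contiguous canonical layout; 1-based item numbers
DEFAULT_SUBSCALE_MAP = _default_map()


@dataclass(frozen=True)
class FactorComposition:
    """Which subscales make up each factor."""

    cp_subscales: tuple = ("Odd Beliefs or Magical Thinking",
                           "Unusual Perceptual Experiences",
                           "Ideas of Reference", "Suspiciousness")
    in_subscales: tuple = ("Social Anxiety", "No Close Friends",
                           "Constricted Affect", "Suspiciousness")
    di_subscales: tuple = ("Odd or Eccentric Behaviour", "Odd Speech")


@dataclass
class SPQItemMatrix:
    """participants x 74 binary response matrix with its subscale key."""

    responses: np.ndarray
    subscale_map: dict = field(default_factory=lambda: dict(DEFAULT_SUBSCALE_MAP))

    def __post_init__(self):
        self.responses = np.asarray(self.responses)
        if self.responses.ndim != 2 or self.responses.shape[1] != 74:
            raise ValueError("responses must be a participants x 74 matrix")
        items = sorted(i for lst in self.subscale_map.values() for i in lst)
        if items != list(range(1, 75)):
            raise ValueError("subscale_map must partition items 1..74")


def score_subscales(matrix: SPQItemMatrix) -> np.ndarray:
    """Nine per-participant subscale sums (columns ordered as SUBSCALES)."""
    resp = matrix.responses
    bad = ~np.isin(resp, (0, 1))
    if bad.any():
        rows = sorted(set(np.nonzero(bad)[0].tolist()))
        raise ValidationError(
            [f"row {r}: item value outside {{0,1}}" for r in rows])
    cols = []
    for name in SUBSCALES:
        idx = np.array(matrix.subscale_map[name]) - 1
        cols.append(resp[:, idx].sum(axis=1))
    return np.stack(cols, axis=1)


def factor_scores(subscale_sums: np.ndarray,
                  composition: FactorComposition = FactorComposition()
                  ) -> list[SPQProfile]:
    """Aggregate nine subscale sums into CP/IN/DI profiles.

    Suspiciousness contributes to both CP and IN but once to the total.
    """
    sums = np.atleast_2d(subscale_sums)
    col = {name: i for i, name in enumerate(SUBSCALES)}
    cp = sums[:, [col[s] for s in composition.cp_subscales]].sum(axis=1)
    in_ = sums[:, [col[s] for s in composition.in_subscales]].sum(axis=1)
    di = sums[:, [col[s] for s in composition.di_subscales]].sum(axis=1)
    total = sums.sum(axis=1)
    return [SPQProfile(int(c), int(i), int(d), int(t))
            for c, i, d, t in zip(cp, in_, di, total)]


def factor_items(factor: str,
                 composition: FactorComposition = FactorComposition(),
                 subscale_map: dict = DEFAULT_SUBSCALE_MAP) -> list[int]:
    """1-based item numbers composing a factor ('cp', 'in' or 'di')."""
    subs = {"cp": composition.cp_subscales, "in": composition.in_subscales,
            "di": composition.di_subscales}[factor.lower()]
    return sorted(i for s in subs for i in subscale_map[s])


def cronbach_alpha(items: np.ndarray) -> float:
    """Cronbach's alpha of a participants x items score matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of totals).
    """
    x = np.asarray(items, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 items and >= 2 participants")
    k = x.shape[1]
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total score has zero variance; alpha undefined")
    item_var = x.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def standardize_factors(profiles: dict, ddof: int = 0) -> dict:
    """Fill z_cp / z_in / z_di in place over the completer reference set.

    The reference mean and SD are those of the supplied profiles (the
    completer subsample); SD uses the population divisor by default
    (``ddof=0``), configurable.  Returns the same mapping.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 completers to standardize")
    raw = np.array([[p.raw_cp, p.raw_in, p.raw_di]
                    for p in profiles.values()], dtype=float)
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0, ddof=ddof)
    if np.any(sd == 0):
        raise ValueError("zero SD in a factor; cannot standardize")
    z = (raw - mean) / sd
    for (pid, p), zi in zip(profiles.items(), z):
        p.z_cp, p.z_in, p.z_di = map(float, zi)
    return profiles
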