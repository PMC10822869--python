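"""Posterior sampling over the accuracy model's 222 parameters.

The default algorithm is Hamiltonian Monte Carlo with dual-averaging
step-size adaptation and a diagonal mass matrix estimated in expanding
warmup windows.  The beta_rt >= 0 constraint is handled by boundary
reflection (position and momentum bounce off zero), which keeps the
sampler on the constrained scale where the half-normal density is
finite and well conditioned.  Gradients of the log posterior are
analytic (model module).  An adaptive random-walk Metropolis fallback
is available for cross-checks.

The default budget matches the study: 4 chains, 1000 warmup draws each,
2500 saved draws each — 10,000 saved draws in total.  Convergence is
summarized by the split-chain Gelman-Rubin statistic (plain, computed
here) with a rank-normalized variant delegated to arviz.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import model as m
from .core_data import Dataset

__all__ = [
    "SamplerConfig", "PosteriorSamples", "ConvergenceReport",
    "sample_posterior", "gelman_rubin", "split_rhat",
]


@dataclass(frozen=True)
class SamplerConfig:
    """Chain configuration; defaults reproduce the 4 x 2500 budget."""

    n_chains: int = 4
    n_warmup: int = 1000
    n_saved_per_chain: int = 2500
    seed: int = 0
    algorithm: str = "hmc"  # or "rwm"
    target_accept: float = 0.8
    max_leapfrog: int = 48
    trajectory_length: float = 1.2

    @property
    def n_saved_total(self) -> int:
        return self.n_chains * self.n_saved_per_chain


@dataclass
class PosteriorSamples:
    """Post-warmup draws on the constrained scale, with chain labels.

    ``draws`` has shape (n_chains, n_saved_per_chain, n_params); columns
    follow the packed parameter-vector layout of the model module.
    """

    draws: np.ndarray
    index: m.ConditionIndex
    labels: list = field(default_factory=list)
    has_spq_data: bool = False

    def __post_init__(self):
        if not self.labels:
            self.labels = m.parameter_labels(self.index)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_total(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def flat(self) -> np.ndarray:
        """(total draws, n_params), chains concatenated in order."""
        return self.draws.reshape(-1, self.draws.shape[-1])

    def block(self, name: str) -> np.ndarray:
        """(total draws, block size) for one parameter family."""
        return self.flat()[:, m.block_slices(self.index)[name]]

    def column(self, label: str) -> np.ndarray:
        return self.flat()[:, self.labels.index(label)]

    def params_at(self, draw: int) -> m.ModelParams:
        return m.ModelParams.from_vector(self.flat()[draw], self.index)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.flat(), columns=self.labels)
        df.insert(0, "chain", np.repeat(np.arange(self.n_chains),
                                        self.draws.shape[1]))
        return df

    def save(self, path, sidecar: dict | None = None) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        meta = {"emotions": list(self.index.emotions),
                "n_chains": int(self.n_chains),
                "n_saved_per_chain": int(self.draws.shape[1]),
                "has_spq_data": bool(self.has_spq_data)}
        meta.update(sidecar or {})
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PosteriorSamples":
        path = Path(path)
        df = pd.read_csv(path)
        with open(path.with_suffix(".json")) as fh:
            meta = json.load(fh)
        index = m.ConditionIndex.standard(tuple(meta["emotions"]))
        labels = [c for c in df.columns if c != "chain"]
        draws = df[labels].to_numpy().reshape(
            meta["n_chains"], meta["n_saved_per_chain"], len(labels))
        return cls(draws=draws, index=index, labels=labels,
                   has_spq_data=meta.get("has_spq_data", False))


@dataclass
class ConvergenceReport:
    """Per-parameter potential scale reduction plus sampler metadata."""

    rhat: np.ndarray
    labels: list
    method: str = "split"
    accept_rate: np.ndarray | None = None
    step_size: np.ndarray | None = None
    n_divergent: int = 0

    @property
    def max_rhat(self) -> float:
        finite = self.rhat[np.isfinite(self.rhat)]
        return float(finite.max()) if finite.size else float("nan")

    def summary(self) -> dict:
        return {"max_rhat": self.max_rhat, "method": self.method,
                "n_divergent": int(self.n_divergent),
                "accept_rate": (None if self.accept_rate is None
                                else [float(a) for a in self.accept_rate])}


# ---------------------------------------------------------------------------
# Gelman-Rubin

def split_rhat(chains: np.ndarray) -> float:
    """Plain split-chain potential scale reduction for one parameter.

    Each chain is split in half; R-hat compares between- and
    within-half variances.  Constant, identical chains give 1.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 1 or x.shape[1] < 4:
        raise ValueError("need chains x draws with >= 4 draws per chain")
    n2 = x.shape[1] // 2
    halves = np.concatenate([x[:, :n2], x[:, n2:2 * n2]], axis=0)
    within = halves.var(axis=1, ddof=1).mean()
    between = n2 * halves.mean(axis=1).var(ddof=1)
    if within == 0:
        return 1.0 if between == 0 else math.inf
    var_plus = (n2 - 1) / n2 * within + between / n2
    return float(np.sqrt(var_plus / within))


def gelman_rubin(samples: PosteriorSamples, method: str = "split"
                 ) -> ConvergenceReport:
    """Split-chain R-hat per parameter ('split' plain, or 'rank' via arviz)."""
    if samples.n_chains < 2:
        raise ValueError(
            "need >= 2 chains for the Gelman-Rubin diagnostic; "
            "re-run with more chains (split-chain mode still needs two)")
    if method == "rank":
        import arviz as az
        r = np.array([float(az.rhat(samples.draws[:, :, j]))
                      for j in range(samples.draws.shape[2])])
    elif method == "split":
        r = np.array([split_rhat(samples.draws[:, :, j])
                      for j in range(samples.draws.shape[2])])
    else:
        raise ValueError("method must be 'split' or 'rank'")
    return ConvergenceReport(rhat=r, labels=list(samples.labels), method=method)


# ---------------------------------------------------------------------------
# HMC

def _leapfrog(theta, r, grad, eps, inv_mass, logp_grad, reflect):
    """One leapfrog step with boundary reflection on the ``reflect``
    coordinates (kept nonnegative by bouncing position and momentum)."""
    r = r + 0.5 * eps * grad
    theta = theta + eps * inv_mass * r
    if reflect is not None:
        seg = theta[reflect]
        neg = seg < 0
        if neg.any():
            seg[neg] = -seg[neg]
            theta[reflect] = seg
            rseg = r[reflect]
            rseg[neg] = -rseg[neg]
            r[reflect] = rseg
    lp, grad = logp_grad(theta)
    r = r + 0.5 * eps * grad
    return theta, r, lp, grad


def _find_initial_step(theta, lp, grad, inv_mass, logp_grad, rng, reflect):
    """Double/halve the step until the one-step acceptance crosses 0.5."""
    eps = 0.1
    r0 = rng.standard_normal(theta.size) / np.sqrt(inv_mass)
    h0 = lp - 0.5 * float(np.sum(inv_mass * r0 * r0))
    _, r1, lp1, _ = _leapfrog(theta.copy(), r0.copy(), grad, eps, inv_mass,
                              logp_grad, reflect)
    h1 = lp1 - 0.5 * float(np.sum(inv_mass * r1 * r1))
    if not math.isfinite(h1):
        direction = -1
    else:
        direction = 1 if (h1 - h0) > math.log(0.5) else -1
    for _ in range(50):
        eps *= 2.0 ** direction
        _, r1, lp1, _ = _leapfrog(theta.copy(), r0.copy(), grad, eps,
                                  inv_mass, logp_grad, reflect)
        h1 = lp1 - 0.5 * float(np.sum(inv_mass * r1 * r1))
        ok = math.isfinite(h1) and (h1 - h0) > math.log(0.5)
        if (direction == 1) != ok:
            break
    return eps


def _mass_windows(n_warmup, init_buffer=75, term_buffer=50, base=25):
    """Iteration indices ending each covariance-estimation window
    (expanding, memoryless, as in standard practice)."""
    if n_warmup < init_buffer + term_buffer + base:
        return []
    ends, start, width = [], init_buffer, base
    while True:
        end = start + width
        if end + 2 * width + term_buffer > n_warmup:
            ends.append(n_warmup - term_buffer)
            return ends
        ends.append(end)
        start, width = end, 2 * width


def _hmc_chain(logp_grad, theta0, n_warmup, n_save, rng, *,
               target_accept=0.8, max_leapfrog=48, trajectory_length=1.2,
               reflect=None):
    dim = theta0.size
    theta = np.array(theta0, dtype=float)
    lp, grad = logp_grad(theta)
    inv_mass = np.ones(dim)
    eps = _find_initial_step(theta, lp, grad, inv_mass, logp_grad, rng,
                             reflect)
    # dual averaging (Nesterov-style) toward the target acceptance
    mu, log_eps_bar, h_bar = math.log(10 * eps), math.log(eps), 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    win_ends = _mass_windows(n_warmup)
    window = []
    draws = np.empty((n_save, dim))
    n_accept, n_div, da_iter = 0.0, 0, 0
    total = n_warmup + n_save
    for it in range(total):
        if it == n_warmup and n_warmup > 0:
            eps = math.exp(log_eps_bar)
        r0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = lp - 0.5 * float(np.sum(inv_mass * r0 * r0))
        n_max = max(1, min(max_leapfrog, int(round(trajectory_length / eps))))
        n_steps = int(rng.integers(max(1, n_max // 2), n_max + 1))
        th, r, lpn, gr = theta, r0, lp, grad
        diverged = False
        for _ in range(n_steps):
            th, r, lpn, gr = _leapfrog(th.copy() if th is theta else th,
                                       r.copy() if r is r0 else r,
                                       gr, eps, inv_mass, logp_grad,
                                       reflect)
            if not math.isfinite(lpn):
                diverged = True
                break
        if diverged:
            accept_prob = 0.0
        else:
            h1 = lpn - 0.5 * float(np.sum(inv_mass * r * r))
            delta = h1 - h0
            if delta < -1000.0:
                diverged = True
                accept_prob = 0.0
            else:
                accept_prob = min(1.0, math.exp(min(0.0, delta)))
        if not diverged and rng.uniform() < accept_prob:
            theta, lp, grad = th, lpn, gr
        if it < n_warmup:
            da_iter += 1
            frac = 1.0 / (da_iter + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - accept_prob)
            log_eps = mu - math.sqrt(da_iter) / gamma * h_bar
            w = da_iter ** -kappa
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = math.exp(log_eps)
            window.append(theta.copy())
            if win_ends and it + 1 == win_ends[0]:
                win_ends.pop(0)
                n = len(window)
                if n >= 10:
                    var = np.var(np.asarray(window), axis=0)
                    # shrink toward a small constant, as with few samples
                    # the raw variance is unreliable
                    inv_mass = np.clip(
                        var * n / (n + 5.0) + 1e-3 * 5.0 / (n + 5.0),
                        1e-8, None)
                    eps = _find_initial_step(theta, lp, grad, inv_mass,
                                             logp_grad, rng, reflect)
                    mu = math.log(10 * eps)
                    log_eps_bar, h_bar, da_iter = math.log(eps), 0.0, 0
                window = []
        else:
            draws[it - n_warmup] = theta
            n_accept += accept_prob
            n_div += int(diverged)
    return draws, n_accept / max(n_save, 1), eps, n_div


def _rwm_chain(logp_grad, theta0, n_warmup, n_save, rng, *,
               target_accept=0.3, **_):
    """Adaptive random-walk Metropolis fallback (gradient-free)."""
    dim = theta0.size
    theta = np.array(theta0, dtype=float)
    lp, _ = logp_grad(theta)
    scale = 0.1 / math.sqrt(dim)
    draws = np.empty((n_save, dim))
    n_accept = 0.0
    for it in range(n_warmup + n_save):
        prop = theta + scale * rng.standard_normal(dim)
        lpn, _ = logp_grad(prop)
        a = math.exp(min(0.0, lpn - lp)) if math.isfinite(lpn) else 0.0
        if rng.uniform() < a:
            theta, lp = prop, lpn
        if it < n_warmup:
            scale *= math.exp(0.999 ** it * (a - target_accept))
        else:
            draws[it - n_warmup] = theta
            n_accept += a
    return draws, n_accept / max(n_save, 1), scale, 0


def _initial_vector(index, priors, rng, logp_grad, max_retries=20):
    """Prior draws shrunk toward 0 by 0.5 (constrained scale)."""
    for _ in range(max_retries):
        p = m.ModelParams(
            0.5 * priors.sd_alpha * rng.standard_normal(index.n_alpha),
            np.abs(0.5 * priors.sd_beta_rt
                   * rng.standard_normal(index.n_slope)) + 1e-3,
            0.5 * priors.sd_beta_trial * rng.standard_normal(index.n_slope),
            0.5 * priors.sd_spq_direct * rng.standard_normal((3, index.n_slope)),
            0.5 * priors.sd_spq_mod * rng.standard_normal((3, index.n_slope)),
            0.5 * priors.sd_spq_mod * rng.standard_normal((3, index.n_slope)),
        )
        theta = p.to_vector()
        lp, _ = logp_grad(theta)
        if math.isfinite(lp):
            return theta
    raise RuntimeError("could not find a finite initial point")


def sample_posterior(dataset: Dataset, config: SamplerConfig = SamplerConfig(),
                     index: m.ConditionIndex | None = None,
                     priors: m.PriorSpec = m.PriorSpec(),
                     rhat_method: str = "split"):
    """Sample the posterior of the full 222-parameter model.

    Works on an empty dataset too, in which case the posterior is the
    prior (useful for prior-recovery checks).  Returns
    (PosteriorSamples, ConvergenceReport).
    """
    if index is None:
        if len(dataset.trials):
            present = set(dataset.trials["emotion"])
            emos = tuple([e for e in m.EMOTIONS if e in present]
                         + sorted(present - set(m.EMOTIONS)))
        else:
            emos = m.EMOTIONS
        index = m.ConditionIndex.standard(emos)
    enc = (m.encode_trials(dataset, index) if len(dataset.trials)
           else m.EncodedTrials.empty(index))
    logp_grad, rt_slice = m.make_constrained_posterior_fn(enc, index, priors)
    reflect = np.arange(rt_slice.start, rt_slice.stop)
    ss = np.random.SeedSequence([config.seed, 5])
    chains, accepts, steps, ndiv = [], [], [], 0
    for child in ss.spawn(config.n_chains):
        rng = np.random.default_rng(child)
        theta0 = _initial_vector(index, priors, rng, logp_grad)
        if config.algorithm == "hmc":
            draws, acc, eps, div = _hmc_chain(
                logp_grad, theta0, config.n_warmup,
                config.n_saved_per_chain, rng,
                target_accept=config.target_accept,
                max_leapfrog=config.max_leapfrog,
                trajectory_length=config.trajectory_length,
                reflect=reflect)
        elif config.algorithm == "rwm":
            draws, acc, eps, div = _rwm_chain(
                logp_grad, theta0, config.n_warmup,
                config.n_saved_per_chain, rng)
        else:
            raise ValueError(f"unknown algorithm '{config.algorithm}'")
        chains.append(draws)
        accepts.append(acc)
        steps.append(eps)
        ndiv += div
    samples = PosteriorSamples(
        draws=np.asarray(chains), index=index,
        has_spq_data=bool(enc.n and np.any(enc.z)))
    report = (gelman_rubin(samples, method=rhat_method)
              if config.n_chains >= 2 and config.n_saved_per_chain >= 4
              else ConvergenceReport(rhat=np.full(samples.draws.shape[2],
                                                  np.nan),
                                     labels=list(samples.labels)))
    report.accept_rate = np.asarray(accepts)
    report.step_size = np.asarray(steps)
    report.n_divergent = ndiv
    return samples, report
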