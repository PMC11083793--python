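"""Hierarchical consistency models for arm-based network meta-analysis.

Binary outcomes use a binomial likelihood with a log link, so that the basic
parameters ``d`` are log risk ratios; continuous outcomes use a normal
likelihood on arm means, so ``d`` are (weighted) mean differences.  Study
``i`` has a baseline parameter ``mu_i`` (log event risk of its baseline arm,
or the baseline arm mean), and each non-baseline arm ``k`` a trial-specific
contrast ``delta_ik`` drawn around the consistency mean ``d[t_ik] - d[t_i1]``
with between-study standard deviation ``tau``.  Multi-arm trials use the
conditional (sequential) construction of the exchangeable multivariate normal:
the k-th contrast given the earlier ones is normal with mean

    d(t1 -> tk) + (1/(k-1)) * sum_{j<k} (delta_ij - d(t1 -> tj))

and variance ``tau^2 * k / (2(k-1))``; for a two-arm trial this reduces to
``delta ~ Normal(d, tau^2)``.

Priors follow the skeptical-prior analysis this package reproduces: contrasts
``d ~ Normal(0, 0.4^2)`` on the log-RR scale, heterogeneity
``tau ~ Half-Normal(0, 0.5)``, and weakly informative baselines
``mu ~ Normal(0, 10^2)``.  For continuous outcomes the raw 0.4 scale would be
absurdly tight in units like operative minutes, so by default the effect
scale is multiplied by the pooled outcome SD (disable with
``rescale_continuous_effect=False``).

Everything here is a pure function of parameters and data; the sampler
explores the resulting posterior with its own (equivalent, but incremental)
arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .network_data import NetworkDataset

__all__ = [
    "HeterogeneityPrior",
    "PriorSpec",
    "ModelParameters",
    "ModelSpec",
    "ParamLayout",
    "log_likelihood",
    "log_prior",
    "log_posterior",
    "delta_conditional_moments",
]


@dataclass(frozen=True)
class HeterogeneityPrior:
    """Prior on the between-study SD tau: half-normal(scale) or uniform(0, upper)."""

    kind: str = "half-normal"  # "half-normal" | "uniform"
    scale: float = 0.5

    def __post_init__(self):
        if self.kind not in ("half-normal", "uniform"):
            raise ValueError(f"unknown heterogeneity prior kind {self.kind!r}")
        if not self.scale > 0:
            raise ValueError("heterogeneity prior scale must be > 0")

    def logpdf(self, tau: float) -> float:
        if tau < 0:
            return -math.inf
        if self.kind == "half-normal":
            return math.log(2.0) + stats.norm.logpdf(tau, 0.0, self.scale)
        return -math.log(self.scale) if tau <= self.scale else -math.inf

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "half-normal":
            return abs(rng.normal(0.0, self.scale))
        return rng.uniform(0.0, self.scale)

    def label(self) -> str:
        return f"{self.kind}({self.scale})"


@dataclass(frozen=True)
class PriorSpec:
    """Prior scales; effect/baseline may be ``inf`` for a flat prior."""

    effect_scale: float = 0.4
    baseline_scale: float = 10.0
    heterogeneity: HeterogeneityPrior = field(default_factory=HeterogeneityPrior)
    rescale_continuous_effect: bool = True

    def __post_init__(self):
        if not self.effect_scale > 0 or not self.baseline_scale > 0:
            raise ValueError("prior scales must be > 0")


@dataclass
class ModelParameters:
    """One point in parameter space.

    ``d`` holds the basic contrasts of the non-reference treatments in dataset
    order (the reference contrast is identically 0); ``delta`` holds one entry
    per non-baseline arm, in dataset arm order.
    """

    d: np.ndarray
    mu: np.ndarray
    delta: np.ndarray
    tau: float

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)


@dataclass(frozen=True)
class ModelSpec:
    kind: str  # "binary-log-RR" | "continuous-MD"
    priors: PriorSpec = field(default_factory=PriorSpec)
    consistency: bool = True
    tau_fixed: float | None = None  # fix tau (e.g. 0 for a fixed-effect fit)

    def __post_init__(self):
        if self.kind not in ("binary-log-RR", "continuous-MD"):
            raise ValueError(f"unknown model kind {self.kind!r}")

    @staticmethod
    def for_dataset(ds: NetworkDataset, priors: PriorSpec | None = None, **kw) -> "ModelSpec":
        kind = "binary-log-RR" if ds.outcome_kind == "binary" else "continuous-MD"
        return ModelSpec(kind=kind, priors=priors or PriorSpec(), **kw)

    def matches(self, ds: NetworkDataset) -> bool:
        return (self.kind == "binary-log-RR") == (ds.outcome_kind == "binary")

    def effect_scale(self, ds: NetworkDataset) -> float:
        """Effect-prior SD, rescaled by the pooled outcome SD for continuous data."""
        s = self.priors.effect_scale
        if not math.isfinite(s):
            return s
        if self.kind == "continuous-MD" and self.priors.rescale_continuous_effect:
            sds = np.array([a.sd for a in ds.arms], dtype=float)
            ns = np.array([a.n for a in ds.arms], dtype=float)
            pooled = math.sqrt(float(np.sum((ns - 1) * sds**2) / np.sum(ns - 1)))
            return s * pooled
        return s


class ParamLayout:
    """Index bookkeeping between a dataset and a ModelParameters vector.

    Within each study the baseline arm is the one whose treatment comes first
    in the dataset's treatment ordering (the reference, when present).
    """

    def __init__(self, ds: NetworkDataset):
        self.ds = ds
        self.treat_index = {t: i for i, t in enumerate(ds.treatment_ids)}
        self.study_ids = list(ds.studies().keys())
        self.study_index = {s: i for i, s in enumerate(self.study_ids)}
        self.arm_study = np.array([self.study_index[a.study_id] for a in ds.arms])
        self.arm_treat = np.array([self.treat_index[a.treatment] for a in ds.arms])
        # baseline arm per study = arm with the smallest treatment index
        self.baseline_arm = np.full(len(self.study_ids), -1, dtype=int)
        for j, a in enumerate(ds.arms):
            s = self.arm_study[j]
            b = self.baseline_arm[s]
            if b < 0 or self.arm_treat[j] < self.arm_treat[b]:
                self.baseline_arm[s] = j
        self.is_baseline = np.zeros(len(ds.arms), dtype=bool)
        self.is_baseline[self.baseline_arm] = True
        self.nonbase_arms = np.flatnonzero(~self.is_baseline)
        self.delta_index = {int(j): k for k, j in enumerate(self.nonbase_arms)}
        # position of each non-baseline arm within its study: 2, 3, ... in
        # ascending treatment order (the order the conditional prior uses)
        order: dict[int, list[int]] = {}
        for j in self.nonbase_arms:
            order.setdefault(int(self.arm_study[j]), []).append(int(j))
        self.study_nonbase = {
            s: sorted(js, key=lambda j: self.arm_treat[j]) for s, js in order.items()
        }
        self.n_treat = len(ds.treatment_ids)
        self.n_study = len(self.study_ids)
        self.n_delta = len(self.nonbase_arms)

    def d_full(self, d: np.ndarray) -> np.ndarray:
        """Contrast vector including the reference's 0 at index 0."""
        return np.concatenate(([0.0], np.asarray(d, dtype=float)))

    def consistency_means(self, d: np.ndarray) -> np.ndarray:
        """d(baseline -> arm treatment) for every non-baseline arm."""
        df = self.d_full(d)
        base_treat = self.arm_treat[self.baseline_arm[self.arm_study[self.nonbase_arms]]]
        return df[self.arm_treat[self.nonbase_arms]] - df[base_treat]

    def delta_full(self, delta: np.ndarray) -> np.ndarray:
        full = np.zeros(len(self.ds.arms))
        full[self.nonbase_arms] = delta
        return full

    def linear_predictor(self, params: ModelParameters) -> np.ndarray:
        """mu_study + delta for every arm (delta = 0 on baseline arms)."""
        return params.mu[self.arm_study] + self.delta_full(params.delta)


def delta_conditional_moments(
    layout: ParamLayout,
    study: int,
    d: np.ndarray,
    delta: np.ndarray,
    tau: float,
    omega: float = 0.0,
) -> list[tuple[int, float, float]]:
    """(delta-slot, conditional mean, conditional SD) for one study's contrasts.

    ``omega`` is an optional design-inconsistency offset added to every
    consistency mean of the study (used by the design-by-treatment model).
    """
    df = layout.d_full(d)
    js = layout.study_nonbase[study]
    base_t = layout.arm_treat[layout.baseline_arm[study]]
    out = []
    resid_sum = 0.0
    for pos, j in enumerate(js, start=2):
        mean_cons = df[layout.arm_treat[j]] - df[base_t] + omega
        if pos == 2:
            mean, var = mean_cons, tau**2
        else:
            mean = mean_cons + resid_sum / (pos - 1)
            var = tau**2 * pos / (2.0 * (pos - 1))
        slot = layout.delta_index[j]
        out.append((slot, mean, math.sqrt(var)))
        resid_sum += delta[slot] - mean_cons
    return out


def log_likelihood(
    params: ModelParameters, ds: NetworkDataset, spec: ModelSpec,
    layout: ParamLayout | None = None,
) -> float:
    """Log-likelihood of the arm data at ``params``.

    Binary: sum of Binomial(events | total, exp(mu + delta)) log-masses, with
    ``-inf`` whenever an arm's linear predictor exceeds 0 (a log-risk must be
    the log of a probability; the sampler uses this as rejection).  Continuous:
    sum of Normal(mean | mu + delta, sd/sqrt(n)) log-densities.
    """
    layout = layout or ParamLayout(ds)
    if params.d.shape != (layout.n_treat - 1,):
        raise ValueError(f"d has shape {params.d.shape}, expected ({layout.n_treat - 1},)")
    if params.mu.shape != (layout.n_study,):
        raise ValueError(f"mu has shape {params.mu.shape}, expected ({layout.n_study},)")
    if params.delta.shape != (layout.n_delta,):
        raise ValueError(f"delta has shape {params.delta.shape}, expected ({layout.n_delta},)")
    eta = layout.linear_predictor(params)
    if ds.outcome_kind == "binary":
        if np.any(eta > 0):
            return -math.inf
        r = np.array([a.events for a in ds.arms], dtype=float)
        n = np.array([a.total for a in ds.arms], dtype=float)
        return float(np.sum(stats.binom.logpmf(r, n, np.exp(eta))))
    y = np.array([a.mean for a in ds.arms])
    se = np.array([a.sd / math.sqrt(a.n) for a in ds.arms])
    return float(np.sum(stats.norm.logpdf(y, eta, se)))


def log_prior(
    params: ModelParameters, spec: ModelSpec, ds: NetworkDataset,
    layout: ParamLayout | None = None,
) -> float:
    """Log prior density: effect + baseline + heterogeneity + delta conditionals."""
    layout = layout or ParamLayout(ds)
    tau = params.tau if spec.tau_fixed is None else spec.tau_fixed
    if tau < 0:
        return -math.inf
    total = 0.0
    es = spec.effect_scale(ds)
    if math.isfinite(es):
        total += float(np.sum(stats.norm.logpdf(params.d, 0.0, es)))
    bs = spec.priors.baseline_scale
    if math.isfinite(bs):
        total += float(np.sum(stats.norm.logpdf(params.mu, 0.0, bs)))
    if spec.tau_fixed is None:
        lp = spec.priors.heterogeneity.logpdf(tau)
        if not math.isfinite(lp):
            return -math.inf
        total += lp
    if tau == 0.0:
        # degenerate: delta is deterministic at the consistency means
        means = layout.consistency_means(params.d)
        if not np.allclose(params.delta, means, atol=1e-12):
            return -math.inf
        return total
    for s in layout.study_nonbase:
        for slot, mean, sd in delta_conditional_moments(
            layout, s, params.d, params.delta, tau
        ):
            total += stats.norm.logpdf(params.delta[slot], mean, sd)
    return float(total)


def log_posterior(
    params: ModelParameters, ds: NetworkDataset, spec: ModelSpec,
    layout: ParamLayout | None = None,
) -> float:
    """log_likelihood + log_prior; finite inside the support, -inf outside, never NaN."""
    layout = layout or ParamLayout(ds)
    lp = log_prior(params, spec, ds, layout)
    if not math.isfinite(lp):
        return -math.inf
    ll = log_likelihood(params, ds, spec, layout)
    if math.isnan(ll):  # pragma: no cover - contract guard
        return -math.inf
    return lp + ll
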