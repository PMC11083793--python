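"""Model-fit and assumption checks.

Residual deviance and leverage follow the arm-level definitions standard in
Bayesian meta-analysis: for a binary arm with events r out of n and fitted
expected count r_hat = n * exp(mu + delta),

    dev = 2 * [ r * log(r / r_hat) + (n - r) * log((n - r) / (n - r_hat)) ]

with 0 * log(0 / .) = 0; a well-fitting model has posterior-mean total
deviance close to the number of data points.  Leverage is the posterior-mean
deviance minus the deviance at the posterior-mean fitted values (the plug-in
deviance); leverages sum to the effective number of parameters pD, and
DIC = posterior-mean deviance + pD.

The design-by-treatment interaction check augments the consistency means with
a scalar offset omega per "redundant" design — a design whose treatments are
already connected by the other designs, i.e. one that closes an evidence
loop.  A network in which every comparison is informed by a single design
(such as a star with one extra edge) has no identifiable loop: the check then
returns a structural note instead of a spurious verdict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .network_data import NetworkDataset
from .nma_model import HeterogeneityPrior, ModelSpec, ParamLayout
from .sampler import PosteriorDraws, SamplerConfig, run_mcmc

__all__ = [
    "DevianceDiagnostics",
    "InconsistencyResult",
    "SensitivityResult",
    "residual_deviance",
    "design_by_treatment_check",
    "prior_sensitivity",
    "DEFAULT_ALT_PRIORS",
]

DEFAULT_ALT_PRIORS = (
    HeterogeneityPrior("half-normal", 0.25),
    HeterogeneityPrior("half-normal", 1.0),
    HeterogeneityPrior("uniform", 2.0),
)


@dataclass
class DevianceDiagnostics:
    per_arm: pd.DataFrame  # study, treatment, dev_mean, dev_plugin, leverage, sqrt_dev
    total_deviance: float  # posterior-mean residual deviance, summed over arms
    pD: float
    dic: float

    def plot_table(self) -> pd.DataFrame:
        """Plot-ready (x = sqrt residual deviance, y = leverage) pairs."""
        return self.per_arm[["study", "treatment", "sqrt_dev", "leverage"]].copy()

    def influential(self, leverage_limit: float = 1.0) -> pd.DataFrame:
        return self.per_arm[self.per_arm["leverage"] > leverage_limit]


def _binary_dev(r, n, rhat):
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(r > 0, r * np.log(r / rhat), 0.0)
        t2 = np.where(n - r > 0, (n - r) * np.log((n - r) / (n - rhat)), 0.0)
    return 2.0 * (t1 + t2)


def residual_deviance(
    draws: PosteriorDraws,
    ds: NetworkDataset | None = None,
    spec: ModelSpec | None = None,
    max_draws: int = 4000,
) -> DevianceDiagnostics:
    """Per-arm posterior-mean residual deviance, leverage, pD and DIC.

    The plug-in deviance is evaluated at the posterior means of the arm-level
    fitted values (expected counts / arm means), not of the raw parameters.
    Deviance draws are computed on at most ``max_draws`` pooled samples.
    """
    ds = ds or draws.ds
    spec = spec or draws.spec
    layout = ParamLayout(ds)
    mu = draws.pooled("mu")
    delta = draws.pooled("delta")
    if mu.shape[0] > max_draws:
        idx = np.linspace(0, mu.shape[0] - 1, max_draws).astype(int)
        mu, delta = mu[idx], delta[idx]
    full = np.zeros((mu.shape[0], len(ds.arms)))
    full[:, layout.nonbase_arms] = delta
    eta = mu[:, layout.arm_study] + full  # (draws, arms)

    if ds.outcome_kind == "binary":
        r = np.array([a.events for a in ds.arms], dtype=float)
        n = np.array([a.total for a in ds.arms], dtype=float)
        rhat = n * np.exp(eta)
        dev = _binary_dev(r, n, rhat)
        dev_mean = dev.mean(axis=0)
        dev_plugin = _binary_dev(r, n, rhat.mean(axis=0))
    else:
        y = np.array([a.mean for a in ds.arms])
        se = np.array([a.sd / math.sqrt(a.n) for a in ds.arms])
        dev = ((y - eta) / se) ** 2
        dev_mean = dev.mean(axis=0)
        dev_plugin = ((y - eta.mean(axis=0)) / se) ** 2

    leverage = dev_mean - dev_plugin
    per_arm = pd.DataFrame({
        "study": [a.study_id for a in ds.arms],
        "treatment": [a.treatment for a in ds.arms],
        "dev_mean": dev_mean,
        "dev_plugin": dev_plugin,
        "leverage": leverage,
        "sqrt_dev": np.sqrt(np.maximum(dev_mean, 0.0)),
    })
    total = float(dev_mean.sum())
    pD = float(leverage.sum())
    return DevianceDiagnostics(per_arm, total, pD, total + pD)


# ---------------------------------------------------------------------------
# design-by-treatment interaction


@dataclass
class InconsistencyResult:
    identifiable: bool
    structural_note: str | None
    omegas: list[dict]
    dic_consistency: float | None
    dic_inconsistency: float | None
    delta_dic: float | None
    verdict: str

    def to_dict(self) -> dict:
        return {
            "identifiable": self.identifiable,
            "structural_note": self.structural_note,
            "omegas": self.omegas,
            "dic_consistency": self.dic_consistency,
            "dic_inconsistency": self.dic_inconsistency,
            "delta_dic": self.delta_dic,
            "verdict": self.verdict,
        }


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[ra] = rb
        return True


def _redundant_designs(ds: NetworkDataset) -> tuple[list[tuple], list[tuple]]:
    """Split designs into tree designs and loop-closing (redundant) ones.

    A design is the set of treatments a study compares; studies sharing a
    design share an omega.  Designs are scanned in a deterministic order and a
    design whose treatments are already mutually connected closes a loop.
    """
    designs: dict[tuple, list[str]] = {}
    for sid, arms in ds.studies().items():
        key = tuple(sorted({a.treatment for a in arms}))
        designs.setdefault(key, []).append(sid)
    uf = _UnionFind(ds.treatment_ids)
    tree, redundant = [], []
    for key in sorted(designs):
        merged_any = False
        for t in key[1:]:
            merged_any |= uf.union(key[0], t)
        (tree if merged_any else redundant).append((key, designs[key]))
    return tree, redundant


def design_by_treatment_check(
    ds: NetworkDataset,
    spec: ModelSpec | None = None,
    cfg: SamplerConfig | None = None,
) -> InconsistencyResult:
    """Design-by-treatment interaction assessment of network consistency.

    Fits the consistency model and an augmented model with design offsets
    omega for every loop-closing design, and reports each omega's 95% CrI plus
    the DIC difference (inconsistency minus consistency).  The verdict is
    "no significant inconsistency" only when every omega CrI contains 0 and
    the inconsistency model does not improve DIC by more than 3; both
    ingredients are reported so users can apply their own rule.
    """
    spec = spec or ModelSpec.for_dataset(ds)
    cfg = cfg or SamplerConfig()
    n_designs = len({tuple(sorted({a.treatment for a in arms}))
                     for arms in ds.studies().values()})
    _, redundant = _redundant_designs(ds)
    if n_designs < 2 or not redundant:
        note = (
            "every comparison is informed by a single design (no closed loop "
            "of independent designs); design inconsistency is not statistically "
            "identifiable on this network"
            if n_designs >= 2
            else "single-design network; inconsistency is not defined"
        )
        return InconsistencyResult(
            identifiable=False, structural_note=note, omegas=[],
            dic_consistency=None, dic_inconsistency=None, delta_dic=None,
            verdict="vacuously consistent (no identifiable interaction parameters)",
        )

    cons = run_mcmc(ds, spec, cfg)
    dic_cons = residual_deviance(cons).dic
    omega_designs = [sids for _, sids in redundant]
    incons = run_mcmc(ds, spec, cfg, omega_designs=omega_designs)
    dic_incons = residual_deviance(incons).dic

    omegas = []
    all_contain_zero = True
    w = incons.pooled("omega")
    for i, (key, sids) in enumerate(redundant):
        lo, hi = np.percentile(w[:, i], [2.5, 97.5])
        contains = lo <= 0.0 <= hi
        all_contain_zero &= contains
        omegas.append({
            "design": list(key), "studies": sids,
            "mean": float(np.mean(w[:, i])),
            "cri_low": float(lo), "cri_high": float(hi),
            "cri_contains_zero": bool(contains),
        })
    delta_dic = dic_incons - dic_cons
    if all_contain_zero and delta_dic > -3.0:
        verdict = "no significant inconsistency"
    else:
        verdict = "potential inconsistency"
    return InconsistencyResult(
        identifiable=True, structural_note=None, omegas=omegas,
        dic_consistency=dic_cons, dic_inconsistency=dic_incons,
        delta_dic=delta_dic, verdict=verdict,
    )


# ---------------------------------------------------------------------------
# heterogeneity-prior sensitivity


@dataclass
class SensitivityResult:
    base_label: str
    table: pd.DataFrame  # one row per prior: d means, tau median, max_abs_shift
    max_abs_shift: float

    def to_dict(self) -> dict:
        return {
            "base_prior": self.base_label,
            "rows": self.table.to_dict(orient="records"),
            "max_abs_shift": self.max_abs_shift,
        }


def prior_sensitivity(
    ds: NetworkDataset,
    spec: ModelSpec | None = None,
    alt_priors: Sequence[HeterogeneityPrior] | None = None,
    cfg: SamplerConfig | None = None,
) -> SensitivityResult:
    """Refit under alternative heterogeneity priors and tabulate effect shifts.

    The base prior is included as its own row with shift exactly 0 (the same
    seed drives every fit, so refitting the base prior reproduces it).  The
    reported shift per row is the maximum absolute change of any basic
    contrast's posterior mean relative to the base analysis.
    """
    spec = spec or ModelSpec.for_dataset(ds)
    cfg = cfg or SamplerConfig()
    alts = list(alt_priors) if alt_priors is not None else list(DEFAULT_ALT_PRIORS)

    def _fit(het: HeterogeneityPrior):
        pspec = replace(spec, priors=replace(spec.priors, heterogeneity=het))
        draws = run_mcmc(ds, pspec, cfg)
        d = draws.pooled("d")
        return d.mean(axis=0), float(np.median(draws.pooled("tau")))

    base_het = spec.priors.heterogeneity
    base_d, base_tau = _fit(base_het)
    names = [f"d[{t}]" for t in ds.treatment_ids[1:]]
    rows = [{
        "prior": base_het.label(), "is_base": True, "tau_median": base_tau,
        **dict(zip(names, base_d)), "max_abs_shift": 0.0,
    }]
    for het in alts:
        if het == base_het:
            d_mean, tau_med = base_d, base_tau
        else:
            d_mean, tau_med = _fit(het)
        rows.append({
            "prior": het.label(), "is_base": het == base_het, "tau_median": tau_med,
            **dict(zip(names, d_mean)),
            "max_abs_shift": float(np.max(np.abs(d_mean - base_d))),
        })
    table = pd.DataFrame(rows)
    return SensitivityResult(
        base_label=base_het.label(), table=table,
        max_abs_shift=float(table["max_abs_shift"].max()),
    )
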