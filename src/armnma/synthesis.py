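"""Posterior summaries: league tables, treatment ranking, heterogeneity.

League tables summarize every ordered pairwise contrast from the same pooled
draws, so all cells are internally consistent (an indirect comparison is the
per-draw difference of basic contrasts).  Risk-ratio cells are exponentiated
draw by draw before summarizing, so the reported mean is the posterior mean
RR.  Credible intervals are equal-tailed (2.5/97.5 percentiles).

I-squared follows the Bayesian analogue of the Higgins–Thompson construction:
a "typical" sampling variance s^2 is estimated from the arm-level data and
each tau draw is converted to I^2 = 100 * tau^2 / (tau^2 + s^2); the posterior
median is reported and categorized (low <= 25, 50-75 moderate, >= 75 high;
the undefined 25-50 band is labeled "intermediate").
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .network_data import NetworkDataset
from .sampler import PosteriorDraws

__all__ = [
    "ContrastSummary",
    "LeagueTable",
    "RankResult",
    "HeterogeneityResult",
    "league_table",
    "rank_probabilities",
    "compute_I2",
    "typical_sampling_variance",
]


@dataclass(frozen=True)
class ContrastSummary:
    comparison: tuple[str, str]  # (a, b): effect of b relative to a
    scale: str  # "RR" | "WMD"
    mean: float
    cri_low: float
    cri_high: float

    @property
    def null_value(self) -> float:
        return 1.0 if self.scale == "RR" else 0.0

    @property
    def significant(self) -> bool:
        return not (self.cri_low <= self.null_value <= self.cri_high)


@dataclass
class LeagueTable:
    outcome_name: str
    scale: str
    treatments: list[str]
    cells: dict[tuple[str, str], ContrastSummary]
    i2: "HeterogeneityResult | None" = None

    def cell(self, a: str, b: str) -> ContrastSummary:
        return self.cells[(a, b)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (a, b), c in self.cells.items():
            rows.append({
                "reference": a, "comparator": b, "scale": c.scale,
                "mean": c.mean, "cri_low": c.cri_low, "cri_high": c.cri_high,
                "significant": c.significant,
            })
        return pd.DataFrame(rows)

    def to_grid(self) -> dict:
        """JSON-ready K x K grid: cell [i][j] = effect of treatment j vs i."""
        grid = []
        for a in self.treatments:
            row = []
            for b in self.treatments:
                c = self.cells[(a, b)]
                row.append({"mean": c.mean, "cri_low": c.cri_low,
                            "cri_high": c.cri_high})
            grid.append(row)
        out = {"outcome": self.outcome_name, "scale": self.scale,
               "treatments": self.treatments, "grid": grid}
        if self.i2 is not None:
            out["I2"] = self.i2.i2
            out["I2_category"] = self.i2.category
        return out

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_grid(), indent=2))
        else:
            self.to_frame().to_csv(path, index=False)


@dataclass
class RankResult:
    treatments: list[str]
    direction: str
    prob: np.ndarray  # (K, K): prob[t, r] = P(treatment t has rank r+1)
    p_first: np.ndarray
    sucra: np.ndarray

    def to_dict(self) -> dict:
        return {
            "direction": self.direction,
            "treatments": self.treatments,
            "rank_probabilities": {
                t: [float(p) for p in self.prob[i]]
                for i, t in enumerate(self.treatments)
            },
            "p_first": {t: float(self.p_first[i]) for i, t in enumerate(self.treatments)},
            "sucra": {t: float(self.sucra[i]) for i, t in enumerate(self.treatments)},
        }


@dataclass
class HeterogeneityResult:
    tau_median: float
    tau_cri: tuple[float, float]
    i2: float  # posterior median, percent
    i2_cri: tuple[float, float]
    category: str
    typical_variance: float


def _summaries(draws_1d: np.ndarray, scale: str) -> tuple[float, float, float]:
    # Quantiles are taken on the contrast (log) scale and transformed, which
    # makes CrI bounds exactly reciprocal/negated across the table diagonal;
    # the RR mean is the mean of the exponentiated draws (posterior mean RR).
    lo, hi = np.percentile(draws_1d, [2.5, 97.5])
    if scale == "RR":
        return float(np.mean(np.exp(draws_1d))), float(np.exp(lo)), float(np.exp(hi))
    return float(np.mean(draws_1d)), float(lo), float(hi)


def league_table(draws: PosteriorDraws, ds: NetworkDataset | None = None) -> LeagueTable:
    """All-pairs relative effects from pooled posterior draws.

    Cell ``(a, b)`` summarizes the per-draw contrast ``d_b - d_a`` (effect of
    b relative to a).  By construction the WMD table is antisymmetric and RR
    CrI bounds are reciprocal across the diagonal.
    """
    ds = ds or draws.ds
    scale = "RR" if ds.outcome_kind == "binary" else "WMD"
    treatments = ds.treatment_ids
    dfull = draws.d_full_pooled()
    cells = {}
    for i, a in enumerate(treatments):
        for j, b in enumerate(treatments):
            if i == j:
                null = 1.0 if scale == "RR" else 0.0
                cells[(a, b)] = ContrastSummary((a, b), scale, null, null, null)
                continue
            mean, lo, hi = _summaries(dfull[:, j] - dfull[:, i], scale)
            cells[(a, b)] = ContrastSummary((a, b), scale, mean, lo, hi)
    i2 = None
    if len(ds.studies()) >= 2 and draws.spec.tau_fixed is None:
        i2 = compute_I2(draws, ds)
    return LeagueTable(ds.outcome_name, scale, treatments, cells, i2)


def rank_probabilities(draws: PosteriorDraws, direction: str | None = None) -> RankResult:
    """Per-draw treatment ranking -> rank probabilities, P(best) and SUCRA.

    ``direction`` states whether larger effects are worse: for ``harm``
    outcomes rank 1 is the treatment with the lowest contrast (safest); for
    ``benefit`` the highest.  SUCRA is computed as (K - mean rank) / (K - 1),
    so the SUCRA values across treatments always average to exactly 0.5.
    """
    direction = direction or draws.ds.direction
    if direction not in ("harm", "benefit"):
        raise ValueError("direction must be 'harm' or 'benefit'")
    dfull = draws.d_full_pooled()
    if direction == "benefit":
        dfull = -dfull
    n, K = dfull.shape
    order = np.argsort(dfull, axis=1, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(K)[None, :].repeat(n, axis=0), axis=1)
    prob = np.stack([
        np.bincount(ranks[:, t], minlength=K) / n for t in range(K)
    ])
    mean_rank = ranks.mean(axis=0) + 1.0
    sucra = (K - mean_rank) / (K - 1)
    return RankResult(
        treatments=draws.treatment_ids, direction=direction,
        prob=prob, p_first=prob[:, 0].copy(), sucra=sucra,
    )


def _study_contrast_variance(ds: NetworkDataset, arms) -> float:
    """Estimated sampling variance of a study's (first) pairwise contrast.

    Binary: var(log RR) = 1/r - 1/n summed over the two arms, with a 0.5
    continuity correction applied only when a cell is 0 or n.  Continuous:
    var(mean difference) = sd1^2/n1 + sd2^2/n2.  Multi-arm studies contribute
    the mean variance over baseline-vs-other contrasts.
    """
    base, others = arms[0], arms[1:]

    def _half(a):
        if ds.outcome_kind == "binary":
            r, n = float(a.events), float(a.total)
            if r == 0.0 or r == n:
                r, n = r + 0.5, n + 1.0
            return 1.0 / r - 1.0 / n
        return a.sd**2 / a.n

    return float(np.mean([_half(base) + _half(o) for o in others]))


def typical_sampling_variance(ds: NetworkDataset) -> float:
    """Higgins–Thompson typical within-study variance s^2.

    s^2 = (m - 1) * sum(w) / ((sum w)^2 - sum(w^2)) with w = 1 / var_i over
    the m studies' estimated contrast variances.
    """
    studies = list(ds.studies().values())
    m = len(studies)
    if m < 2:
        raise ValueError("typical sampling variance needs >= 2 studies")
    w = np.array([1.0 / _study_contrast_variance(ds, arms) for arms in studies])
    return float((m - 1) * w.sum() / (w.sum() ** 2 - (w**2).sum()))


def categorize_i2(i2: float) -> str:
    if i2 <= 25.0:
        return "low"
    if i2 < 50.0:
        return "intermediate"
    if i2 < 75.0:
        return "moderate"
    return "high"


def compute_I2(
    draws: PosteriorDraws, ds: NetworkDataset | None = None
) -> HeterogeneityResult | None:
    """Posterior I^2 from tau draws and the data's typical sampling variance.

    With a single study tau is not estimable: a warning is issued and I^2 is
    omitted (``None``).
    """
    ds = ds or draws.ds
    if len(ds.studies()) < 2:
        import warnings

        warnings.warn("single-study dataset: tau not estimable, I^2 omitted")
        return None
    s2 = typical_sampling_variance(ds)
    tau = draws.pooled("tau")
    i2 = 100.0 * tau**2 / (tau**2 + s2)
    med = float(np.median(i2))
    return HeterogeneityResult(
        tau_median=float(np.median(tau)),
        tau_cri=tuple(float(q) for q in np.percentile(tau, [2.5, 97.5])),
        i2=med,
        i2_cri=tuple(float(q) for q in np.percentile(i2, [2.5, 97.5])),
        category=categorize_i2(med),
        typical_variance=s2,
    )
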