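"""Arm-level trial data model for network meta-analysis.

A network dataset is a long-format table of randomized-trial arms for one
outcome: ``(study, treatment, events, total)`` for binary outcomes or
``(study, treatment, n, mean, sd)`` for continuous ones.  Treatments form the
nodes of a comparison graph whose edges are within-study comparisons; the
consistency model downstream requires this graph to be connected.

The module also packages the demographic table of the ten distal-gastrectomy
trials this package was built around (open, totally laparoscopic,
laparoscopic-assisted and robotic distal gastrectomy for locally advanced
gastric cancer) together with descriptive-statistics and transitivity
reporting utilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Treatment",
    "BinaryArm",
    "ContinuousArm",
    "StudyCovariates",
    "NetworkDataset",
    "NetworkValidationError",
    "load_network",
    "write_network",
    "connectivity_report",
    "descriptive_stats",
    "transitivity_table",
    "load_trial_demographics",
    "load_group_rates",
    "fixture_network",
    "fixture_covariates",
]

MISSING_TOKENS = {"NA", "NR", ""}

#: Group labels of the four distal-gastrectomy approaches in the packaged
#: fixture: open, totally laparoscopic, laparoscopic-assisted, robotic.
FIXTURE_GROUPS = ("OpDG", "LapDG", "LapAsDG", "RobDG")


class NetworkValidationError(ValueError):
    """Raised when an arm table violates the dataset invariants."""


@dataclass(frozen=True)
class Treatment:
    id: str
    label: str = ""
    reference: bool = False

    def __post_init__(self):
        if not self.label:
            object.__setattr__(self, "label", self.id)


@dataclass(frozen=True)
class BinaryArm:
    study_id: str
    treatment: str
    events: int
    total: int


@dataclass(frozen=True)
class ContinuousArm:
    study_id: str
    treatment: str
    n: int
    mean: float
    sd: float


@dataclass
class StudyCovariates:
    """Per-study covariate summaries used only by the transitivity report."""

    study_id: str
    n: int | None = None
    age_mean: float | None = None
    prop_male: float | None = None
    bmi_mean: float | None = None
    stage: dict[str, float] | None = None  # proportions, keys I..IV
    neoadjuvant: int | None = None
    adjuvant: int | None = None

    def __post_init__(self):
        for name in ("prop_male",):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise NetworkValidationError(
                    f"study {self.study_id}: {name}={v} outside [0, 1]"
                )
        if self.stage:
            tot = sum(v for v in self.stage.values() if v is not None)
            if tot > 1.0 + 1e-9:
                raise NetworkValidationError(
                    f"study {self.study_id}: stage proportions sum to {tot:.3f} > 1"
                )


@dataclass
class NetworkDataset:
    """A connected set of randomized comparisons of treatments for one outcome."""

    outcome_name: str
    outcome_kind: str  # "binary" | "continuous"
    direction: str  # "harm" | "benefit"
    treatments: list[Treatment]
    arms: list[BinaryArm] | list[ContinuousArm]
    covariates: list[StudyCovariates] | None = None

    def __post_init__(self):
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def reference(self) -> Treatment:
        return next(t for t in self.treatments if t.reference)

    @property
    def treatment_ids(self) -> list[str]:
        return [t.id for t in self.treatments]

    def studies(self) -> dict[str, list]:
        """Arms grouped by study, preserving input order."""
        out: dict[str, list] = {}
        for arm in self.arms:
            out.setdefault(arm.study_id, []).append(arm)
        return out

    def arm_size(self, arm) -> int:
        return arm.total if self.outcome_kind == "binary" else arm.n

    def graph(self) -> nx.Graph:
        """Comparison graph: nodes are treatments, edges within-study pairs."""
        g = nx.Graph()
        g.add_nodes_from(self.treatment_ids)
        for arms in self.studies().values():
            ts = [a.treatment for a in arms]
            for i in range(len(ts)):
                for j in range(i + 1, len(ts)):
                    a, b = sorted((ts[i], ts[j]))
                    if g.has_edge(a, b):
                        g[a][b]["studies"] += 1
                    else:
                        g.add_edge(a, b, studies=1)
        return g

    def validate(self) -> None:
        if self.outcome_kind not in ("binary", "continuous"):
            raise NetworkValidationError(f"unknown outcome kind {self.outcome_kind!r}")
        if self.direction not in ("harm", "benefit"):
            raise NetworkValidationError(f"unknown direction {self.direction!r}")
        ids = self.treatment_ids
        if len(set(ids)) != len(ids):
            raise NetworkValidationError("duplicate treatment ids")
        if sum(t.reference for t in self.treatments) != 1:
            raise NetworkValidationError("exactly one treatment must be the reference")
        if not self.arms:
            raise NetworkValidationError("no studies")
        known = set(ids)
        seen: set[tuple[str, str]] = set()
        for arm in self.arms:
            key = (arm.study_id, arm.treatment)
            if key in seen:
                raise NetworkValidationError(
                    f"duplicate (study, treatment) row: {key}"
                )
            seen.add(key)
            if arm.treatment not in known:
                raise NetworkValidationError(
                    f"study {arm.study_id}: unknown treatment {arm.treatment!r}"
                )
            if self.outcome_kind == "binary":
                if not isinstance(arm, BinaryArm):
                    raise NetworkValidationError("binary outcome requires BinaryArm rows")
                if arm.total <= 0 or not (0 <= arm.events <= arm.total):
                    raise NetworkValidationError(
                        f"study {arm.study_id}, arm {arm.treatment}: "
                        f"events={arm.events}, total={arm.total} violate 0 <= events <= total"
                    )
            else:
                if not isinstance(arm, ContinuousArm):
                    raise NetworkValidationError(
                        "continuous outcome requires ContinuousArm rows"
                    )
                if arm.sd <= 0:
                    raise NetworkValidationError(
                        f"study {arm.study_id}, arm {arm.treatment}: sd={arm.sd} must be > 0"
                    )
                if arm.n < 2:
                    raise NetworkValidationError(
                        f"study {arm.study_id}, arm {arm.treatment}: n={arm.n} must be >= 2"
                    )
        for sid, arms in self.studies().items():
            treats = [a.treatment for a in arms]
            if len(arms) < 2 or len(set(treats)) < 2:
                raise NetworkValidationError(
                    f"study {sid} must have >= 2 arms with distinct treatments"
                )

    def require_connected(self) -> None:
        comps = list(nx.connected_components(self.graph()))
        if len(comps) > 1:
            raise NetworkValidationError(
                "comparison graph is disconnected; components: "
                + "; ".join(",".join(sorted(c)) for c in comps)
            )

    def relabeled(self, mapping: Mapping[str, str]) -> "NetworkDataset":
        """Return a copy with treatment ids renamed (graph-isomorphic)."""
        treatments = [replace(t, id=mapping[t.id]) for t in self.treatments]
        arms = [replace(a, treatment=mapping[a.treatment]) for a in self.arms]
        return NetworkDataset(
            self.outcome_name, self.outcome_kind, self.direction,
            treatments, arms, self.covariates,
        )


# ---------------------------------------------------------------------------
# readers / writers

_BINARY_COLS = ["study", "treatment", "events", "total"]
_CONTINUOUS_COLS = ["study", "treatment", "n", "mean", "sd"]


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"arm table not found: {path}")
    return pd.read_csv(path, na_values=sorted(MISSING_TOKENS), keep_default_na=False)


def load_network(
    table_path,
    outcome_name: str,
    outcome_kind: str,
    direction: str = "harm",
    reference: str | None = None,
    labels: Mapping[str, str] | None = None,
) -> NetworkDataset:
    """Read a long-format CSV of trial arms into a validated NetworkDataset.

    The file must be comma-separated UTF-8 with a header row; ``NA``/``NR``
    denote missing.  ``reference`` defaults to the treatment with the largest
    total enrollment.  Treatments are ordered with the reference first.
    """
    df = _read_table(table_path)
    want = _BINARY_COLS if outcome_kind == "binary" else _CONTINUOUS_COLS
    missing = [c for c in want if c not in df.columns]
    if missing:
        raise NetworkValidationError(
            f"{table_path}: missing column(s) {missing} for {outcome_kind} outcome"
        )
    if df.empty:
        raise NetworkValidationError(f"{table_path}: no studies")

    arms: list = []
    for i, row in df.iterrows():
        where = f"{table_path} row {i + 2} (study {row['study']}, arm {row['treatment']})"
        try:
            if outcome_kind == "binary":
                arms.append(
                    BinaryArm(str(row["study"]), str(row["treatment"]),
                              int(row["events"]), int(row["total"]))
                )
            else:
                arms.append(
                    ContinuousArm(str(row["study"]), str(row["treatment"]),
                                  int(row["n"]), float(row["mean"]), float(row["sd"]))
                )
        except (TypeError, ValueError) as exc:
            raise NetworkValidationError(f"{where}: unreadable value ({exc})") from exc

    size = {}
    for a in arms:
        size[a.treatment] = size.get(a.treatment, 0) + (
            a.total if outcome_kind == "binary" else a.n
        )
    if reference is None:
        reference = max(size, key=lambda t: (size[t], t))
    if reference not in size:
        raise NetworkValidationError(f"reference treatment {reference!r} not in table")
    ordered = [reference] + sorted(t for t in size if t != reference)
    labels = labels or {}
    treatments = [
        Treatment(t, labels.get(t, t), reference=(t == reference)) for t in ordered
    ]
    try:
        return NetworkDataset(outcome_name, outcome_kind, direction, treatments, arms)
    except NetworkValidationError as exc:
        # re-raise with file context for row-level failures
        raise NetworkValidationError(f"{table_path}: {exc}") from exc


def write_network(ds: NetworkDataset, path) -> None:
    """Write the arm table back to long-format CSV (round-trips load_network)."""
    rows = []
    for a in ds.arms:
        if ds.outcome_kind == "binary":
            rows.append({"study": a.study_id, "treatment": a.treatment,
                         "events": a.events, "total": a.total})
        else:
            rows.append({"study": a.study_id, "treatment": a.treatment,
                         "n": a.n, "mean": a.mean, "sd": a.sd})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# geometry and descriptive reports

def connectivity_report(ds: NetworkDataset) -> dict:
    """Component structure, per-edge study counts and per-node patient totals.

    Disconnection is reported, not raised, so callers can decide what to do.
    The edge/node summaries are the quantities that drive edge widths and node
    sizes in network-geometry plots.
    """
    g = ds.graph()
    components = [sorted(c) for c in nx.connected_components(g)]
    components.sort(key=lambda c: (-len(c), c))
    node_totals = {t: 0 for t in ds.treatment_ids}
    for a in ds.arms:
        node_totals[a.treatment] += ds.arm_size(a)
    edge_studies = {
        f"{a}|{b}": data["studies"] for a, b, data in sorted(g.edges(data=True))
    }
    return {
        "n_components": len(components),
        "components": components,
        "connected": len(components) == 1,
        "edge_studies": edge_studies,
        "node_totals": node_totals,
    }


def _data_path(name: str):
    return resources.files("armnma.data").joinpath(name)


def load_trial_demographics() -> pd.DataFrame:
    """Demographics of the ten packaged distal-gastrectomy RCTs.

    ``arm_label_reported`` is the label as published; ``group`` is the
    reconciled treatment-group assignment whose per-group enrollment sums
    match the published cohort accounting (1768 open / 1012 totally
    laparoscopic / 902 laparoscopic-assisted / 141 robotic).  Three comparator
    arms differ between the two columns; all descriptive statistics use
    ``group``.
    """
    with resources.as_file(_data_path("trial_demographics.csv")) as p:
        return pd.read_csv(p, na_values=sorted(MISSING_TOKENS), keep_default_na=False)


def load_group_rates() -> pd.DataFrame:
    """Published per-group crude outcome rates / means (mean, min, max)."""
    with resources.as_file(_data_path("group_outcome_rates.csv")) as p:
        return pd.read_csv(p, na_values=sorted(MISSING_TOKENS), keep_default_na=False)


def fixture_network(reference: str | None = None) -> NetworkDataset:
    """Enrollment network of the packaged trials (geometry/transitivity only).

    Events are a zero placeholder — the arm table carries arm sizes, which is
    all the geometry and transitivity reports need.
    """
    with resources.as_file(_data_path("trial_enrollment.csv")) as p:
        ds = load_network(p, "enrollment", "binary", "harm", reference)
    ds.covariates = fixture_covariates()
    return ds


def fixture_covariates(df: pd.DataFrame | None = None) -> list[StudyCovariates]:
    """Study-level covariate summaries pooled across arms of each trial."""
    if df is None:
        df = load_trial_demographics()
    out = []
    for sid, sub in df.groupby("study", sort=False):
        n = int(sub["n"].sum())
        cov = StudyCovariates(study_id=sid, n=n)
        if sub["age_mean"].notna().all():
            cov.age_mean = float(np.average(sub["age_mean"], weights=sub["n"]))
        if sub["male"].notna().all():
            cov.prop_male = float(sub["male"].sum() / (sub["male"].sum() + sub["female"].sum()))
        if sub["bmi_mean"].notna().all():
            cov.bmi_mean = float(np.average(sub["bmi_mean"], weights=sub["n"]))
        stage_cols = ["stage_i", "stage_ii", "stage_iii", "stage_iv"]
        counts = sub[stage_cols].sum(min_count=1)
        if counts.notna().any():
            cov.stage = {
                c.split("_")[1].upper(): (float(counts[c]) / n if pd.notna(counts[c]) else None)
                for c in stage_cols
            }
        if sub["neoadjuvant"].notna().all():
            cov.neoadjuvant = int(sub["neoadjuvant"].sum())
        if sub["adjuvant"].notna().all():
            cov.adjuvant = int(sub["adjuvant"].sum())
        out.append(cov)
    return out


def descriptive_stats(df: pd.DataFrame | None = None) -> dict:
    """Pooled cohort accounting over the demographic fixture.

    Percentages are reported to one decimal.  Group shares use all patients;
    the male share uses only trials reporting sex; the adjuvant share uses
    only the trials reporting adjuvant exposure (mirroring how such cohort
    summaries handle not-reported fields).
    """
    if df is None:
        df = load_trial_demographics()
    total = int(df["n"].sum())
    groups = {}
    for g in FIXTURE_GROUPS:
        n = int(df.loc[df["group"] == g, "n"].sum())
        groups[g] = {"patients": n, "percent": round(100.0 * n / total, 1)}

    sex = df[df["male"].notna()]
    males = int(sex["male"].sum())
    sex_total = int(sex["male"].sum() + sex["female"].sum())

    neo = df[df["neoadjuvant"].notna()]
    neo_n = int(neo["neoadjuvant"].sum())

    adj_studies = df.groupby("study").filter(lambda s: s["adjuvant"].notna().all())
    adj_n = int(adj_studies["adjuvant"].sum()) if len(adj_studies) else 0
    adj_denom = int(adj_studies["n"].sum()) if len(adj_studies) else 0

    return {
        "total_patients": total,
        "groups": groups,
        "male_percent": round(100.0 * males / sex_total, 1),
        "male_patients": males,
        "sex_reported_patients": sex_total,
        "neoadjuvant_patients": neo_n,
        "neoadjuvant_percent": round(100.0 * neo_n / total, 1),
        "adjuvant_patients": adj_n,
        "adjuvant_reported_patients": adj_denom,
        "adjuvant_percent": round(100.0 * adj_n / adj_denom, 1) if adj_denom else None,
    }


def transitivity_table(ds: NetworkDataset) -> pd.DataFrame:
    """Covariate balance across direct comparisons (transitivity check).

    One row per direct comparison with, for each covariate, the range and the
    sample-size-weighted mean over the studies informing that comparison.
    Missing covariates are flagged (``*_n_missing``), never imputed.
    """
    cov_by_study = {c.study_id: c for c in (ds.covariates or [])}
    per_edge: dict[tuple[str, str], list[str]] = {}
    for sid, arms in ds.studies().items():
        ts = sorted({a.treatment for a in arms})
        for i in range(len(ts)):
            for j in range(i + 1, len(ts)):
                per_edge.setdefault((ts[i], ts[j]), []).append(sid)

    rows = []
    fields = ["age_mean", "prop_male", "bmi_mean"]
    for (a, b), sids in sorted(per_edge.items()):
        row: dict = {"comparison": f"{a} vs {b}", "n_studies": len(sids)}
        for f in fields:
            vals, weights, miss = [], [], 0
            for sid in sids:
                c = cov_by_study.get(sid)
                v = getattr(c, f, None) if c else None
                if v is None:
                    miss += 1
                else:
                    vals.append(v)
                    weights.append(c.n or 1)
            if vals:
                row[f"{f}_wmean"] = float(np.average(vals, weights=weights))
                row[f"{f}_min"] = float(min(vals))
                row[f"{f}_max"] = float(max(vals))
            else:
                row[f"{f}_wmean"] = row[f"{f}_min"] = row[f"{f}_max"] = np.nan
            row[f"{f}_n_missing"] = miss
        # stage mix: weighted mean proportion per stage where reported
        for st in ("I", "II", "III", "IV"):
            vals, weights, miss = [], [], 0
            for sid in sids:
                c = cov_by_study.get(sid)
                v = (c.stage or {}).get(st) if c else None
                if v is None:
                    miss += 1
                else:
                    vals.append(v)
                    weights.append(c.n or 1)
            row[f"stage_{st}_wmean"] = (
                float(np.average(vals, weights=weights)) if vals else np.nan
            )
            row[f"stage_{st}_n_missing"] = miss
        rows.append(row)
    return pd.DataFrame(rows)


def export_report(report, path) -> None:
    """Write a connectivity/descriptive/transitivity report as JSON."""
    if isinstance(report, pd.DataFrame):
        report = report.where(report.notna(), None).to_dict(orient="records")
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
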