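"""Replicate-level quantification and group statistics.

The reported quantity is the percentage of PLA-positive cells in a population
for one biological replicate (one animal/sample).  Replicates are averaged
(unweighted) within each experimental group per independent experiment, and
groups are compared by a two-sided Student t-test on the experiment-level
means -- each independent experiment contributes one value per group.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "percent_positive",
    "aggregate",
    "compare_groups",
    "GroupComparison",
]


def percent_positive(calls: pd.DataFrame, population: str) -> tuple:
    """Percent PLA-positive cells of ``population`` in one replicate.

    ``calls`` is a per-cell call table with ``population`` and
    ``final_pla_pos`` columns.  Returns ``(percent, n)``; a population with
    zero assigned cells yields ``(nan, 0)`` with a warning.
    """
    population = getattr(population, "value", population)
    sel = calls[calls["population"] == population]
    n = len(sel)
    if n == 0:
        warnings.warn(f"no cells assigned to population {population!r}",
                      stacklevel=2)
        return float("nan"), 0
    n_pos = int(sel["final_pla_pos"].sum())
    return 100.0 * n_pos / n, n


def aggregate(design: pd.DataFrame, value: str = "percent") -> pd.DataFrame:
    """Experiment-level group means of replicate percentages.

    ``design`` is a tidy table with columns ``experiment``, ``group``,
    ``replicate`` and the ``value`` column (percent positive per replicate).
    Replicates are averaged unweighted within (experiment, group); replicate
    cell counts, when present as an ``n`` column, are summed and reported but
    never used as weights.
    """
    required = {"experiment", "group", "replicate", value}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table is missing columns: {sorted(missing)}")
    if design.groupby(["experiment", "group"]).size().min() < 1:
        raise ValueError("every (experiment, group) needs at least one replicate")
    agg = {value: "mean", "replicate": "count"}
    if "n" in design.columns:
        agg["n"] = "sum"
    out = (
        design.groupby(["experiment", "group"], sort=True)
        .agg(agg)
        .rename(columns={value: "mean_percent", "replicate": "n_replicates",
                         "n": "n_cells"})
        .reset_index()
    )
    return out


@dataclass
class GroupComparison:
    """Two-sided Student t-test on experiment-level group means."""

    groups: tuple
    means: dict           # group -> mean of experiment-level values
    sems: dict            # group -> s.e.m. over experiment-level values
    experiment_means: dict  # group -> the per-experiment values themselves
    t: float
    p: float
    df: int
    equal_var: bool

    def __str__(self):
        a, b = self.groups
        return (
            f"{a}: {self.means[a]:.3g} +/- {self.sems[a]:.3g} (s.e.m.)  vs  "
            f"{b}: {self.means[b]:.3g} +/- {self.sems[b]:.3g} (s.e.m.)  "
            f"t({self.df}) = {self.t:.4g}, p = {self.p:.4g}"
        )


def compare_groups(
    agg: pd.DataFrame,
    group_a: str,
    group_b: str,
    value: str = "mean_percent",
    welch: bool = False,
) -> GroupComparison:
    """Student t-test between two groups' experiment-level means.

    ``agg`` is the output of :func:`aggregate` (one row per experiment x
    group).  The classical equal-variance test is used by default (Welch
    behind the ``welch`` flag); each group needs at least two experiments.
    Degenerate zero-variance comparisons return ``t = 0, p = 1`` for
    identical groups and infinite ``t`` otherwise, with a warning.
    """
    values = {}
    for g in (group_a, group_b):
        v = agg.loc[agg["group"] == g, value].to_numpy(float)
        if len(v) < 2:
            raise ValueError(
                f"group {g!r} has {len(v)} experiment-level value(s); "
                "at least 2 independent experiments are required"
            )
        values[g] = v
    a, b = values[group_a], values[group_b]
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        warnings.warn("both groups have zero variance", stacklevel=2)
        t = 0.0 if a.mean() == b.mean() else float("inf") * np.sign(a.mean() - b.mean())
        p = 1.0 if a.mean() == b.mean() else 0.0
        df = len(a) + len(b) - 2
    else:
        res = stats.ttest_ind(a, b, equal_var=not welch)
        t, p = float(res.statistic), float(res.pvalue)
        df = int(round(float(res.df)))
    sems = {g: float(v.std(ddof=1) / np.sqrt(len(v))) for g, v in values.items()}
    means = {g: float(v.mean()) for g, v in values.items()}
    return GroupComparison(
        groups=(group_a, group_b),
        means=means,
        sems=sems,
        experiment_means={g: v.tolist() for g, v in values.items()},
        t=t,
        p=p,
        df=df,
        equal_var=not welch,
    )


def replicate_table(
    calls_by_replicate: dict,
    population: str,
) -> pd.DataFrame:
    """Tidy per-replicate percentages from call tables.

    ``calls_by_replicate`` maps ``(experiment, group, replicate)`` tuples to
    per-cell call tables; returns the design table :func:`aggregate` expects.
    """
    rows = []
    for (experiment, group, replicate), calls in calls_by_replicate.items():
        pct, n = percent_positive(calls, population)
        rows.append({
            "experiment": experiment, "group": group, "replicate": replicate,
            "percent": pct, "n": n,
        })
    return pd.DataFrame(rows)
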