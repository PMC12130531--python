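"""Differentially activated signaling components (DASCs).

A DASC is a network node whose simulated steady-state activity distribution
differs between two phenotype groups.  Within one cohort, every sample's
Monte-Carlo draws are pooled per group and per node; the two pooled
empirical distributions are compared with the two-sample Kolmogorov–Smirnov
statistic D, gated by a median-difference effect size, and adjusted across
nodes with Benjamini–Hochberg FDR.  Calls from several cohorts are then
intersected (optionally requiring a concordant direction), which is where
the inferential weight lies: pooled draws are not independent across the
runs of one sample, so p-values are heuristic ranks rather than exact
probabilities.  By default the asymptotic KS p-value is therefore computed
at an effective sample size equal to the number of patient samples per
group — the number of independent units actually pooled — not the pooled
draw count (set ``effective_n='draws'`` for the literal pooled-count
p-value).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .dynamics import ActivityDistribution

__all__ = [
    "GroupedActivities",
    "pool_by_group",
    "score_node",
    "call_dasc",
    "intersect_cohorts",
    "DascDetector",
]


@dataclass
class GroupedActivities:
    """Per-node activity pools for two phenotype groups within one cohort."""

    cohort: str
    nodes: tuple[str, ...]
    groups: tuple[str, str]
    pool_a: np.ndarray  # (draws_a, n_nodes)
    pool_b: np.ndarray  # (draws_b, n_nodes)
    n_samples: tuple[int, int]  # patient samples per group

    def node_pools(self, node: str) -> tuple[np.ndarray, np.ndarray]:
        i = self.nodes.index(node)
        return self.pool_a[:, i], self.pool_b[:, i]


def _thin(pool: np.ndarray, cap: int | None) -> np.ndarray:
    """Deterministic stride thinning to at most ``cap`` rows."""
    m = pool.shape[0]
    if cap is None or m <= cap:
        return pool
    stride = m // cap
    idx = np.arange(0, stride * cap, stride)[:cap]
    return pool[idx]


def pool_by_group(
    activities: Sequence[ActivityDistribution],
    labels: Mapping[str, str] | pd.Series,
    groups: tuple[str, str] | None = None,
    max_per_group: int | None = 10_000,
    cohort: str = "cohort",
) -> GroupedActivities:
    """Pool Monte-Carlo draws of all samples per group, per node.

    Samples are concatenated in sorted sample-id order (so the result does
    not depend on input ordering), then optionally thinned by a
    deterministic stride to at most ``max_per_group`` draws per group.
    ``groups`` fixes the (A, B) role of the two labels; by default labels
    are taken in sorted order.
    """
    labels = dict(pd.Series(labels))
    missing = [d.sample for d in activities if d.sample not in labels]
    if missing:
        raise ValueError(f"unlabeled sample(s): {missing}")
    if not activities:
        raise ValueError("no activity distributions supplied")

    present = sorted({labels[d.sample] for d in activities})
    if groups is None:
        if len(present) != 2:
            raise ValueError(f"expected exactly 2 groups, found {present}")
        groups = (present[0], present[1])
    nodes = activities[0].nodes
    for d in activities:
        if d.nodes != nodes:
            raise ValueError("activity distributions disagree on node order")

    pools = []
    sizes = []
    by_sample = sorted(activities, key=lambda d: d.sample)
    for g in groups:
        members = [d for d in by_sample if labels[d.sample] == g]
        if not members:
            raise ValueError(f"group {g!r} has zero samples")
        pools.append(_thin(np.concatenate([d.activities for d in members]), max_per_group))
        sizes.append(len(members))
    return GroupedActivities(
        cohort=cohort,
        nodes=nodes,
        groups=groups,
        pool_a=pools[0],
        pool_b=pools[1],
        n_samples=(sizes[0], sizes[1]),
    )


def score_node(
    pool_a: np.ndarray,
    pool_b: np.ndarray,
    n_eff: tuple[int, int] | None = None,
) -> tuple[float, float, float]:
    """KS statistic, median difference (B − A) and asymptotic p for one node.

    D = sup_t |ECDF_A(t) − ECDF_B(t)| over the pooled values.  When
    ``n_eff`` is given, the asymptotic p-value is evaluated at those
    effective sample sizes instead of the pooled draw counts.
    """
    a = np.asarray(pool_a, dtype=float)
    b = np.asarray(pool_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("pools must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    d = float(res.statistic)
    if n_eff is None:
        p = float(res.pvalue)
    else:
        na, nb = n_eff
        en = na * nb / (na + nb)
        p = float(stats.kstwobign.sf(np.sqrt(en) * d))
    delta = float(np.median(b) - np.median(a))
    return d, delta, min(p, 1.0)


def call_dasc(
    grouped: GroupedActivities,
    alpha: float = 0.05,
    min_effect: float = 0.1,
    effective_n: str = "samples",
) -> pd.DataFrame:
    """Score every node and call DASCs within one cohort.

    BH adjustment runs across all scored nodes; a node is called when
    q < ``alpha`` and |median(B) − median(A)| ≥ ``min_effect``.  Returns a
    DataFrame with columns node, D, delta_median, p, q, direction, called.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if effective_n not in ("samples", "draws"):
        raise ValueError("effective_n must be 'samples' or 'draws'")
    n_eff = grouped.n_samples if effective_n == "samples" else None
    rows = []
    for i, node in enumerate(grouped.nodes):
        d, delta, p = score_node(grouped.pool_a[:, i], grouped.pool_b[:, i], n_eff=n_eff)
        rows.append((node, d, delta, p))
    df = pd.DataFrame(rows, columns=["node", "D", "delta_median", "p"])
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    ga, gb = grouped.groups
    df["direction"] = np.where(df["delta_median"] > 0, f"up-in-{gb}", f"up-in-{ga}")
    df["called"] = (df["q"] < alpha) & (df["delta_median"].abs() >= min_effect)
    df.attrs["cohort"] = grouped.cohort
    df.attrs["groups"] = grouped.groups
    df.attrs["alpha"] = alpha
    df.attrs["min_effect"] = min_effect
    df.attrs["effective_n"] = effective_n
    df.attrs["pvalue_note"] = (
        "pooled draws are dependent within samples; p-values are heuristic ranks"
    )
    return df


def intersect_cohorts(
    results: Mapping[str, pd.DataFrame] | Sequence[pd.DataFrame],
    require_concordant: bool = True,
) -> pd.DataFrame:
    """Nodes called in every cohort, optionally with concordant direction.

    ``results`` maps cohort name to a :func:`call_dasc` table (a plain
    sequence uses each table's recorded cohort name).  The output is
    independent of cohort ordering: rows are sorted by node and columns by
    cohort name.  A warning lists per-cohort coverage when the node
    universes differ.
    """
    if not isinstance(results, Mapping):
        results = {df.attrs.get("cohort", f"cohort{i}"): df for i, df in enumerate(results)}
    if len(results) < 2:
        raise ValueError("need at least 2 cohorts to intersect")
    names = sorted(results)
    universes = {name: set(results[name]["node"]) for name in names}
    universe_union = set.union(*universes.values())
    if any(u != universe_union for u in universes.values()):
        coverage = {name: len(u) for name, u in universes.items()}
        warnings.warn(
            f"cohorts score different node universes; coverage: {coverage}",
            UserWarning,
            stacklevel=2,
        )

    called = None
    for name in names:
        df = results[name]
        nodes = set(df.loc[df["called"], "node"])
        called = nodes if called is None else called & nodes
    rows = []
    for node in sorted(called):
        directions = {
            name: results[name].set_index("node").loc[node, "direction"] for name in names
        }
        if require_concordant and len(set(directions.values())) > 1:
            continue
        row = {"node": node, "direction": directions[names[0]]}
        for name in names:
            rec = results[name].set_index("node").loc[node]
            row[f"D_{name}"] = rec["D"]
            row[f"delta_median_{name}"] = rec["delta_median"]
            row[f"q_{name}"] = rec["q"]
        rows.append(row)
    cols = ["node", "direction"] + [
        f"{stat}_{name}" for name in names for stat in ("D", "delta_median", "q")
    ]
    return pd.DataFrame(rows, columns=cols)


class DascDetector(BaseEstimator):
    """Two-group differential-activity detector over simulated distributions.

    ``fit(X, y)`` takes a sequence of :class:`ActivityDistribution` (one per
    sample) and the per-sample group labels, pools draws per group, scores
    every node (KS D + median difference), applies BH FDR and the effect
    gate.  Fitted attributes: ``results_`` (full table), ``statistic_``,
    ``pvalues_``, ``qvalues_``, ``delta_median_``, ``direction_``,
    ``called_`` and ``nodes_``.  ``get_support()`` returns the boolean call
    mask, sklearn-selector style.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        min_effect: float = 0.1,
        max_per_group: int | None = 10_000,
        effective_n: str = "samples",
        cohort: str = "cohort",
    ):
        self.alpha = alpha
        self.min_effect = min_effect
        self.max_per_group = max_per_group
        self.effective_n = effective_n
        self.cohort = cohort

    def fit(self, X: Sequence[ActivityDistribution], y):
        if isinstance(y, (pd.Series, Mapping)):
            labels = pd.Series(y)
        else:
            labels = pd.Series(list(y), index=[d.sample for d in X])
        grouped = pool_by_group(
            X, labels, max_per_group=self.max_per_group, cohort=self.cohort
        )
        res = call_dasc(
            grouped,
            alpha=self.alpha,
            min_effect=self.min_effect,
            effective_n=self.effective_n,
        )
        self.groups_ = grouped.groups
        self.nodes_ = grouped.nodes
        self.results_ = res
        self.statistic_ = res["D"].to_numpy()
        self.pvalues_ = res["p"].to_numpy()
        self.qvalues_ = res["q"].to_numpy()
        self.delta_median_ = res["delta_median"].to_numpy()
        self.direction_ = res["direction"].to_numpy()
        self.called_ = res["called"].to_numpy()
        return self

    def get_support(self, indices: bool = False):
        if indices:
            return np.flatnonzero(self.called_)
        return self.called_.copy()
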