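"""Synthetic signed networks and two-group cohorts with planted differential nodes.

Stands in for real patient cohorts so that every pipeline stage — network
IO, normalization, dynamics, DASC calling, cross-cohort intersection — is
testable at desk scale with exact ground truth.

The generator plants the differential signal in node *capacities*
(upstream expression), not in the simulated activities, so recovery
genuinely exercises the dynamics and the statistics.  Planted nodes are
made network sources (their incoming links are removed after motif
insertion): the group shift then enters the model exactly as group-shifted
upstream expression and propagates downstream through the dynamics.  In
multi-cohort studies each cohort gets its own network topology (same node
ids, same planted set), so secondary downstream shifts differ between
cohorts and are removed by the cross-cohort intersection, while the
planted sources survive in every cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .network import ACTIVATION, INHIBITION, SignedLink, SignedNetwork

__all__ = ["SyntheticSpec", "GroundTruth", "generate_network", "generate_cohort", "generate_study"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic cohort.

    Defaults describe the desk-scale benchmark: a 50-node Erdős–Rényi-style
    signed digraph at density 0.04 (~2 links/node, 70% activating), 20
    samples per group, 5 planted nodes shifted by +0.3 capacity in group B,
    and Gaussian observation noise of 0.05 on the [0,1] scale.
    """

    n_nodes: int = 50
    density: float = 0.04
    activation_fraction: float = 0.7
    n_chains: int = 0
    chain_length: int = 3
    n_toggles: int = 0
    n_samples_per_group: int = 20
    n_planted: int = 5
    planted_nodes: tuple[str, ...] | None = None
    shift: float = 0.3
    noise_sd: float = 0.05
    groups: tuple[str, str] = ("groupA", "groupB")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if not 0 < self.density <= 1:
            raise ValueError("density must be in (0, 1]")
        if not 0 <= self.activation_fraction <= 1:
            raise ValueError("activation_fraction must be in [0, 1]")
        if not 0 < self.shift <= 1:
            raise ValueError("shift must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def node_names(self) -> list[str]:
        width = max(3, len(str(self.n_nodes - 1)))
        return [f"N{i:0{width}d}" for i in range(self.n_nodes)]


@dataclass
class GroundTruth:
    """Everything needed to recompute downstream expectations exactly."""

    planted: tuple[str, ...] = ()
    planted_direction: str = ""
    baseline_capacity: dict = field(default_factory=dict)  # node -> capacity (group A)
    sample_capacity: dict = field(default_factory=dict)  # sample -> {node: observed capacity}
    gene_scale: dict = field(default_factory=dict)  # gene -> (lo, span) of back-transform
    n_links: int = 0
    spec: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


def _spec_rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed), stream]))


def _select_planted(spec: SyntheticSpec, names: Sequence[str]) -> tuple[str, ...]:
    if spec.planted_nodes is not None:
        unknown = set(spec.planted_nodes) - set(names)
        if unknown:
            raise ValueError(f"planted nodes not in network: {sorted(unknown)}")
        return tuple(spec.planted_nodes)
    if spec.n_planted == 0:
        return ()
    rng = _spec_rng(spec, 10)
    return tuple(sorted(str(x) for x in rng.choice(list(names), size=spec.n_planted, replace=False)))


def generate_network(spec: SyntheticSpec) -> tuple[SignedNetwork, GroundTruth]:
    """Erdős–Rényi-style signed digraph with motifs spliced in.

    Each ordered pair (i, j), i ≠ j, receives a link with probability
    ``density``; the sign is activating with probability
    ``activation_fraction``.  Requested chain and toggle-switch motifs are
    then spliced onto randomly chosen node tuples, and finally the planted
    nodes lose their incoming links (becoming sources).  Deterministic per
    seed.
    """
    n = spec.n_nodes
    expected_links = spec.density * n * (n - 1)
    if expected_links < 1:
        raise ValueError(
            f"infeasible spec: density {spec.density} yields {expected_links:.2f} expected links"
        )
    if spec.n_chains * spec.chain_length + 2 * spec.n_toggles > n:
        raise ValueError("infeasible spec: motifs need more distinct nodes than available")

    names = spec.node_names()
    rng = _spec_rng(spec, 0)
    adj = rng.random((n, n)) < spec.density
    np.fill_diagonal(adj, False)
    act = rng.random((n, n)) < spec.activation_fraction

    links: dict[tuple[str, str], str] = {}
    for i, j in zip(*np.nonzero(adj)):
        links[(names[i], names[j])] = ACTIVATION if act[i, j] else INHIBITION

    # motifs use disjoint node tuples drawn once
    need = spec.n_chains * spec.chain_length + 2 * spec.n_toggles
    motif_nodes = list(rng.choice(names, size=need, replace=False)) if need else []
    pos = 0
    for _ in range(spec.n_chains):
        chain = motif_nodes[pos : pos + spec.chain_length]
        pos += spec.chain_length
        for a, b in zip(chain, chain[1:]):
            links[(a, b)] = ACTIVATION
    for _ in range(spec.n_toggles):
        a, b = motif_nodes[pos : pos + 2]
        pos += 2
        links[(a, b)] = INHIBITION
        links[(b, a)] = INHIBITION

    planted = _select_planted(spec, names)
    links = {k: v for k, v in links.items() if k[1] not in planted}

    net = SignedNetwork(
        nodes=tuple(names),
        links=tuple(SignedLink(s, t, sign) for (s, t), sign in links.items()),
    )
    truth = GroundTruth(
        planted=planted,
        planted_direction=f"up-in-{spec.groups[1]}",
        n_links=net.n_links,
        spec=asdict(spec),
    )
    return net, truth


def generate_cohort(
    net: SignedNetwork, spec: SyntheticSpec
) -> tuple[ExpressionMatrix, pd.Series, GroundTruth]:
    """Two balanced groups of expression profiles with planted capacity shifts.

    Per node, a baseline capacity is drawn uniform(0.2, 0.8); group B adds
    ``shift`` (clipped to [0,1]) at planted nodes.  Each sample observes
    capacity + Gaussian(0, noise_sd), clipped to [0,1]; the observation is
    written back to a raw expression scale through a per-gene affine map
    (the inverse of a min–max normalization), so per-gene [0,1]
    re-normalization recovers the planted structure up to a monotone
    rescale.  Labels are balanced; everything is deterministic per seed.
    """
    planted = _select_planted(spec, net.nodes)
    rng = _spec_rng(spec, 1)
    nodes = list(net.nodes)
    n = len(nodes)
    baseline = rng.uniform(0.2, 0.8, size=n)

    group_caps = {
        spec.groups[0]: baseline,
        spec.groups[1]: np.clip(
            baseline + spec.shift * np.isin(nodes, list(planted)), 0.0, 1.0
        ),
    }

    lo = rng.uniform(0.0, 10.0, size=n)
    span = rng.uniform(10.0, 100.0, size=n)

    samples, labels, raw_cols = [], [], []
    sample_capacity: dict[str, dict[str, float]] = {}
    for group in spec.groups:
        caps = group_caps[group]
        for k in range(spec.n_samples_per_group):
            sid = f"{group}_{k:02d}"
            obs = np.clip(caps + rng.normal(0.0, spec.noise_sd, size=n), 0.0, 1.0)
            samples.append(sid)
            labels.append(group)
            raw_cols.append(lo + obs * span)
            sample_capacity[sid] = dict(zip(nodes, obs.tolist()))

    data = pd.DataFrame(np.column_stack(raw_cols), index=nodes, columns=samples)
    matrix = ExpressionMatrix(data, normalized=False)
    label_series = pd.Series(labels, index=samples, name="group")
    truth = GroundTruth(
        planted=planted,
        planted_direction=f"up-in-{spec.groups[1]}",
        baseline_capacity=dict(zip(nodes, baseline.tolist())),
        sample_capacity=sample_capacity,
        gene_scale={g: (float(l), float(s)) for g, l, s in zip(nodes, lo, span)},
        n_links=net.n_links,
        spec=asdict(spec),
    )
    return matrix, label_series, truth


def generate_study(
    base_spec: SyntheticSpec, n_cohorts: int = 3
) -> tuple[list[tuple[str, SignedNetwork, ExpressionMatrix, pd.Series]], GroundTruth]:
    """Multi-cohort study sharing one planted node set.

    The planted set is drawn once from the master seed; cohort k then uses
    seed ``[master_seed, k]`` for its own network topology and cohort, so
    only the planted upstream signal is shared across cohorts.
    """
    planted = _select_planted(base_spec, base_spec.node_names())
    cohorts = []
    for k in range(n_cohorts):
        seed_k = int(
            np.random.SeedSequence([int(base_spec.seed), 100 + k]).generate_state(1)[0] % (2**31)
        )
        spec_k = SyntheticSpec(
            **{
                **asdict(base_spec),
                "planted_nodes": planted,
                "seed": seed_k,
            }
        )
        net, _ = generate_network(spec_k)
        matrix, labels, _ = generate_cohort(net, spec_k)
        cohorts.append((f"cohort{k + 1}", net, matrix, labels))
    truth = GroundTruth(
        planted=planted,
        planted_direction=f"up-in-{base_spec.groups[1]}",
        spec=asdict(base_spec),
    )
    return cohorts, truth
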