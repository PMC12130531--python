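"""Normalized regulatory dynamics and Monte-Carlo steady-state sampling.

The network is formulated as a normalized logic-based ODE (HillCube-style)
system on the unit hypercube.  Each node i obeys

    dx_i/dt = (e_i * F_i(x) - x_i) / tau_i,

where e_i in [0,1] is the expression-derived capacity, tau_i > 0 a time
constant, and the regulatory drive F_i combines the node's regulators:

    F_i(x) = A_i(x) * prod_{k in inhibitors(i)} (1 - H(x_k)),
    A_i(x) = sum_{j in activators(i)} w_ij H(x_j) / sum_j w_ij   (1 if none),
    H(x)   = x^n (1 + K^n) / (x^n + K^n),

with the Hill response normalized so H(0) = 0 and H(1) = 1.  Input-free
nodes have F_i = 1 and relax to their capacity, carrying the patient's
expression into the network.  F_i and hence every steady state stays in
[0,1].

Steady-state activity *distributions* are obtained by integrating from many
uniformly random initial states: monostable circuits collapse to a point
mass, multistable circuits (e.g. a toggle switch) yield multimodal
distributions whose mode weights reflect basin sizes.

Integration is fixed-step classical Runge–Kutta (RK4): reproducibility
across platforms beats adaptive steppers for this relaxation-type system,
whose fixed points are exact zeros of the vector field regardless of step
size.  Each run's initial state comes from its own seed substream keyed by
(seed, run index), so results are independent of batch size and of how runs
are distributed over workers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.base import BaseEstimator, TransformerMixin

from .expression import ExpressionMatrix, ModelParameters, ParameterDefaults, build_parameters
from .network import ACTIVATION, SignedNetwork

__all__ = [
    "hill",
    "regulatory_drive",
    "integrate",
    "monte_carlo_activities",
    "ActivityDistribution",
    "ActivitySimulator",
    "IntegrationResult",
    "write_activities",
    "read_activities",
    "write_activity_summary",
]


def hill(x, n: float = 3.0, k: float = 0.5):
    """Normalized Hill response: H(x) = x^n (1+K^n) / (x^n + K^n).

    Maps [0,1] onto [0,1] with H(0)=0, H(1)=1, monotone increasing;
    K is the half-response threshold and n the steepness.
    """
    x = np.asarray(x, dtype=float)
    xn = np.power(x, n)
    kn = k ** n
    return xn * (1.0 + kn) / (xn + kn)


class _CompiledModel:
    """Sparse operators for batched evaluation of the regulatory drive."""

    def __init__(self, params: ModelParameters):
        net = params.network
        n = net.n_nodes
        idx = net.node_index()
        rows_a, cols_a, vals_a = [], [], []
        rows_i, cols_i = [], []
        for link, w in zip(net.links, params.weights):
            t, s = idx[link.target], idx[link.source]
            if link.sign == ACTIVATION:
                rows_a.append(t)
                cols_a.append(s)
                vals_a.append(w)
            else:
                rows_i.append(t)
                cols_i.append(s)
        self.w_act = sparse.csr_matrix((vals_a, (rows_a, cols_a)), shape=(n, n))
        self.act_sum = np.asarray(self.w_act.sum(axis=1)).ravel()
        self.has_act = self.act_sum > 0
        self.b_inh = sparse.csr_matrix(
            (np.ones(len(rows_i)), (rows_i, cols_i)), shape=(n, n)
        )
        self.e = params.capacities
        self.tau = params.tau
        self.hill_n = params.hill_n
        self.hill_k = params.hill_k

    def drive(self, x: np.ndarray) -> np.ndarray:
        """Regulatory drive F for a batch of states; x has shape (batch, n)."""
        hx = hill(np.clip(x, 0.0, 1.0), self.hill_n, self.hill_k)  # (B, N)
        s = self.w_act @ hx.T  # (N, B)
        a = np.ones_like(s)
        a[self.has_act] = s[self.has_act] / self.act_sum[self.has_act, None]
        with np.errstate(divide="ignore"):
            log_rest = np.log(np.maximum(1.0 - hx.T, 0.0))  # (N, B), -inf where H=1
        p = np.exp(self.b_inh @ log_rest)  # empty rows -> exp(0) = 1
        return (a * p).T

    def deriv(self, x: np.ndarray) -> np.ndarray:
        return (self.e * self.drive(x) - x) / self.tau


def _compiled(params: ModelParameters) -> _CompiledModel:
    cache = getattr(params, "_compiled_cache", None)
    if cache is None:
        cache = _CompiledModel(params)
        params._compiled_cache = cache
    return cache


def regulatory_drive(node: str, state, params: ModelParameters) -> float:
    """Drive F_i(x) in [0,1] for one node at one state vector.

    The state is ordered like ``params.network.nodes``.
    """
    comp = _compiled(params)
    x = np.asarray(state, dtype=float).reshape(1, -1)
    if x.shape[1] != params.n_nodes:
        raise ValueError("state length does not match network size")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("state components must lie in [0, 1]")
    i = params.network.node_index()[node]
    return float(comp.drive(x)[0, i])


@dataclass
class IntegrationResult:
    state: np.ndarray
    converged: bool
    steps: int
    clamp_events: int = 0

    def __iter__(self):
        return iter((self.state, self.converged, self.steps))


def _check_integration_args(dt: float, t_max: float, tol: float) -> None:
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if t_max <= 0:
        raise ValueError("t_max must be > 0")
    if tol <= 0:
        raise ValueError("tol must be > 0")


def _integrate_batch(
    comp: _CompiledModel,
    x0: np.ndarray,
    dt: float,
    t_max: float,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """RK4-integrate a batch of initial states until max_i |dx_i/dt| < tol.

    Returns (states, converged, steps, clamp_events).  Runs are frozen the
    moment they converge; per-run results are identical for any batch
    partitioning because every operation is row-wise.
    """
    x = np.clip(np.asarray(x0, dtype=float), 0.0, 1.0)
    batch = x.shape[0]
    max_steps = int(math.ceil(t_max / dt))
    steps = np.zeros(batch, dtype=int)
    converged = np.zeros(batch, dtype=bool)
    clamp_events = 0

    k1 = comp.deriv(x)
    done = np.max(np.abs(k1), axis=1) < tol
    converged[done] = True
    active = np.flatnonzero(~done)

    half = dt / 2.0
    for step in range(1, max_steps + 1):
        if active.size == 0:
            break
        xa = x[active]
        k1a = k1[active]
        k2 = comp.deriv(xa + half * k1a)
        k3 = comp.deriv(xa + half * k2)
        k4 = comp.deriv(xa + dt * k3)
        raw = xa + (dt / 6.0) * (k1a + 2.0 * k2 + 2.0 * k3 + k4)
        clamp_events += int(np.count_nonzero((raw < -1e-12) | (raw > 1.0 + 1e-12)))
        xn = np.clip(raw, 0.0, 1.0)
        k1n = comp.deriv(xn)
        x[active] = xn
        k1[active] = k1n
        steps[active] = step
        now = np.max(np.abs(k1n), axis=1) < tol
        converged[active[now]] = True
        active = active[~now]
    return x, converged, steps, clamp_events


def integrate(
    params: ModelParameters,
    x0,
    dt: float = 0.1,
    t_max: float = 100.0,
    tol: float = 1e-6,
) -> IntegrationResult:
    """Integrate dx_i/dt = (e_i F_i(x) - x_i)/tau_i from one initial state.

    Fixed-step RK4 with post-step clamping to [0,1] (a guard against rare
    overshoot at large dt; at the default step it never triggers).  Stops
    when max_i |dx_i/dt| < ``tol`` or ``t_max`` is reached; the ``converged``
    flag records which.
    """
    _check_integration_args(dt, t_max, tol)
    x0 = np.asarray(x0, dtype=float).reshape(1, -1)
    if x0.shape[1] != params.n_nodes:
        raise ValueError("x0 length does not match network size")
    if np.any((x0 < 0) | (x0 > 1)):
        raise ValueError("x0 components must lie in [0, 1]")
    comp = _compiled(params)
    states, conv, steps, clamps = _integrate_batch(comp, x0, dt, t_max, tol)
    return IntegrationResult(states[0], bool(conv[0]), int(steps[0]), clamps)


@dataclass
class ActivityDistribution:
    """Per-node empirical steady-state distribution for one sample.

    ``activities`` has one row per initial condition (run), one column per
    node (ordered like ``nodes``).
    """

    sample: str
    nodes: tuple[str, ...]
    activities: np.ndarray  # (n_init, n_nodes)
    converged: np.ndarray  # (n_init,)
    convergence_rate: float
    clamp_events: int = 0

    @property
    def n_init(self) -> int:
        return int(self.activities.shape[0])

    def node_activities(self, node: str) -> np.ndarray:
        return self.activities[:, self.nodes.index(node)]

    def summary(self) -> pd.DataFrame:
        """Mean, median, 5th and 95th percentile per node."""
        act = self.activities
        return pd.DataFrame(
            {
                "sample": self.sample,
                "node": list(self.nodes),
                "mean": act.mean(axis=0),
                "median": np.median(act, axis=0),
                "q05": np.quantile(act, 0.05, axis=0),
                "q95": np.quantile(act, 0.95, axis=0),
                "n_init": self.n_init,
                "convergence_rate": self.convergence_rate,
            }
        )


def _initial_states(seed: int, n_init: int, n_nodes: int) -> np.ndarray:
    """Uniform initial states with per-run substreams keyed by (seed, run index)."""
    children = np.random.SeedSequence(seed).spawn(n_init)
    return np.stack(
        [np.random.default_rng(c).uniform(size=n_nodes) for c in children]
    )


def monte_carlo_activities(
    params: ModelParameters,
    n_init: int = 1000,
    seed: int = 0,
    dt: float = 0.1,
    t_max: float = 100.0,
    tol: float = 1e-6,
    batch_size: int = 512,
    sample: str | None = None,
) -> ActivityDistribution:
    """Sample the steady-state activity distribution from random initial states.

    Draws ``n_init`` initial states uniformly on [0,1]^N (one substream per
    run index), integrates each to steady state, and collects the endpoints.
    Deterministic given (seed, n_init, params, dt, t_max, tol); runs can be
    evaluated independently and merged in index order, so the result is
    independent of ``batch_size`` and of any distribution over workers.
    Warns (does not fail) when fewer than 99% of runs converge.
    """
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    _check_integration_args(dt, t_max, tol)
    comp = _compiled(params)
    n = params.n_nodes
    x0 = _initial_states(seed, n_init, n)
    states = np.empty_like(x0)
    converged = np.empty(n_init, dtype=bool)
    clamps = 0
    for start in range(0, n_init, batch_size):
        stop = min(start + batch_size, n_init)
        s, c, _, cl = _integrate_batch(comp, x0[start:stop], dt, t_max, tol)
        states[start:stop] = s
        converged[start:stop] = c
        clamps += cl
    rate = float(converged.mean())
    if rate < 0.99:
        warnings.warn(
            f"only {rate:.1%} of {n_init} runs converged within t_max={t_max}",
            RuntimeWarning,
            stacklevel=2,
        )
    name = sample if sample is not None else (params.sample or "sample")
    return ActivityDistribution(
        sample=name,
        nodes=tuple(params.network.nodes),
        activities=states,
        converged=converged,
        convergence_rate=rate,
        clamp_events=clamps,
    )


class ActivitySimulator(TransformerMixin, BaseEstimator):
    """Transformer mapping normalized expression profiles to activity statistics.

    ``fit`` binds a network and model defaults; ``transform`` takes a
    samples × genes DataFrame of normalized expression and returns the
    samples × nodes matrix of mean steady-state activities.  ``simulate``
    returns the full :class:`ActivityDistribution` per sample.  Per-sample
    seeds derive from ``random_state`` and the sample's row position, so a
    cohort simulation is reproducible and order-stable.
    """

    def __init__(
        self,
        network: SignedNetwork | None = None,
        n_init: int = 1000,
        dt: float = 0.1,
        t_max: float = 100.0,
        tol: float = 1e-6,
        tau: float = 1.0,
        hill_n: float = 3.0,
        hill_k: float = 0.5,
        default_capacity: float = 0.5,
        batch_size: int = 512,
        random_state: int = 0,
    ):
        self.network = network
        self.n_init = n_init
        self.dt = dt
        self.t_max = t_max
        self.tol = tol
        self.tau = tau
        self.hill_n = hill_n
        self.hill_k = hill_k
        self.default_capacity = default_capacity
        self.batch_size = batch_size
        self.random_state = random_state

    def _defaults(self) -> ParameterDefaults:
        return ParameterDefaults(
            tau=self.tau,
            hill_n=self.hill_n,
            hill_k=self.hill_k,
            default_capacity=self.default_capacity,
        )

    def fit(self, X: pd.DataFrame, y=None):
        if self.network is None:
            raise ValueError("a SignedNetwork must be supplied before fitting")
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a samples × genes DataFrame")
        self._defaults()  # validates parameter ranges
        _check_integration_args(self.dt, self.t_max, self.tol)
        self.nodes_ = tuple(self.network.nodes)
        genes = {g.lower() for g in X.columns}
        matched = sum(1 for n in self.nodes_ if n.lower() in genes)
        self.matched_fraction_ = matched / len(self.nodes_) if self.nodes_ else float("nan")
        self.n_features_in_ = X.shape[1]
        return self

    def _sample_seed(self, index: int) -> int:
        return int(
            np.random.SeedSequence([int(self.random_state), int(index)]).generate_state(1)[0]
            % (2**31)
        )

    def simulate(self, X: pd.DataFrame) -> list[ActivityDistribution]:
        """Full Monte-Carlo activity distribution for every row (sample) of X."""
        if not hasattr(self, "nodes_"):
            raise RuntimeError("simulator is not fitted")
        xt = X.T.copy()
        xt.columns = xt.columns.astype(str)
        matrix = ExpressionMatrix(xt, normalized=True)
        out = []
        for pos, sample_id in enumerate(X.index.astype(str)):
            params = build_parameters(self.network, matrix, sample_id, self._defaults())
            out.append(
                monte_carlo_activities(
                    params,
                    n_init=self.n_init,
                    seed=self._sample_seed(pos),
                    dt=self.dt,
                    t_max=self.t_max,
                    tol=self.tol,
                    batch_size=self.batch_size,
                    sample=sample_id,
                )
            )
        return out

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Mean steady-state activity per node (samples × nodes)."""
        dists = self.simulate(X)
        return pd.DataFrame(
            np.stack([d.activities.mean(axis=0) for d in dists]),
            index=X.index,
            columns=list(self.nodes_),
        )


def write_activities(dists: list[ActivityDistribution], path) -> None:
    """Long-format TSV: sample, node, run_index, activity."""
    frames = []
    for d in dists:
        n_runs, n_nodes = d.activities.shape
        frames.append(
            pd.DataFrame(
                {
                    "sample": np.repeat(d.sample, n_runs * n_nodes),
                    "node": np.tile(list(d.nodes), n_runs),
                    "run_index": np.repeat(np.arange(n_runs), n_nodes),
                    "activity": d.activities.ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_activities(path) -> list[ActivityDistribution]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for sample, grp in df.groupby("sample", sort=True):
        nodes = tuple(sorted(grp["node"].unique()))
        wide = grp.pivot(index="run_index", columns="node", values="activity").sort_index()
        act = wide[list(nodes)].to_numpy()
        out.append(
            ActivityDistribution(
                sample=str(sample),
                nodes=nodes,
                activities=act,
                converged=np.ones(act.shape[0], dtype=bool),
                convergence_rate=1.0,
            )
        )
    return out


def write_activity_summary(dists: list[ActivityDistribution], path) -> None:
    pd.concat([d.summary() for d in dists], ignore_index=True).to_csv(path, sep="\t", index=False)
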