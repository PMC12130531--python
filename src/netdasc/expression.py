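"""Expression matrices, per-gene [0,1] normalization, and parameter binding.

The model compares patient profiles by standardizing state variables and
parameters to the unit interval, so raw expression must be mapped per gene
onto [0,1] before it can parameterize the dynamical system.  The default
scheme is winsorized min–max scaling (cross-sample quantile clipping then
linear rescaling); a z-score-then-logistic alternative is available.

Expression enters the model as a per-node *capacity* e_i that multiplies the
regulatory drive (see :mod:`netdasc.dynamics`) rather than as an initial
condition: initial states are randomized per patient, so the expression
profile must shape the vector field, not the start state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, TransformerMixin

from .network import SignedNetwork


@dataclass
class ExpressionMatrix:
    """Gene × sample expression values backed by a pandas DataFrame.

    Rows are genes, columns are samples; identifiers must be unique.
    ``normalized`` records whether values have been mapped to [0,1].
    """

    data: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups[:10]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups[:10]}")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @classmethod
    def from_tsv(cls, path, normalized: bool = False) -> "ExpressionMatrix":
        """Read a TSV whose first column is the gene id and header row the sample ids."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(df, normalized=normalized)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene")


class ExpressionNormalizer(TransformerMixin, BaseEstimator):
    """Per-gene winsorized min–max (or logistic) scaling to [0,1].

    Operates in sklearn orientation (rows = samples, columns = genes).
    ``method='minmax'`` clips each gene at its cross-sample
    (``lower_q``, ``upper_q``) quantiles and rescales linearly; genes with
    zero range after clipping map to 0.5 everywhere.  ``method='logistic'``
    z-scores each gene and squashes through the logistic function.

    Both schemes are monotone per gene (ties allowed at clip boundaries),
    and re-applying min–max with quantiles (0, 1) to already-normalized
    data is the identity, because min–max output always attains 0 and 1.
    """

    def __init__(self, lower_q: float = 0.01, upper_q: float = 0.99, method: str = "minmax"):
        self.lower_q = lower_q
        self.upper_q = upper_q
        self.method = method

    def _validate(self, X) -> np.ndarray:
        arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("expression matrix must be 2-D and non-empty")
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))
            cells = [tuple(int(v) for v in rc) for rc in bad[:10]]
            raise ValueError(
                f"non-finite expression values at {len(bad)} cell(s); first (row, col) indices: {cells}"
            )
        return arr

    def fit(self, X, y=None):
        if not 0 <= self.lower_q < self.upper_q <= 1:
            raise ValueError(f"require 0 <= lower_q < upper_q <= 1, got ({self.lower_q}, {self.upper_q})")
        if self.method not in ("minmax", "logistic"):
            raise ValueError(f"unknown method {self.method!r}")
        arr = self._validate(X)
        if self.method == "minmax":
            self.lo_ = np.quantile(arr, self.lower_q, axis=0)
            self.hi_ = np.quantile(arr, self.upper_q, axis=0)
        else:
            self.lo_ = arr.mean(axis=0)  # mean
            self.hi_ = arr.std(axis=0, ddof=0)  # sd
        self.n_features_in_ = arr.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        arr = self._validate(X)
        if arr.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch with fitted normalizer")
        if self.method == "minmax":
            span = self.hi_ - self.lo_
            out = np.empty_like(arr)
            ok = span > 0
            clipped = np.clip(arr, self.lo_, self.hi_)
            out[:, ok] = (clipped[:, ok] - self.lo_[ok]) / span[ok]
            out[:, ~ok] = 0.5
        else:
            sd = self.hi_
            out = np.empty_like(arr)
            ok = sd > 0
            out[:, ok] = expit((arr[:, ok] - self.lo_[ok]) / sd[ok])
            out[:, ~ok] = 0.5
        return out


def normalize_expression(
    matrix: ExpressionMatrix,
    lower_q: float = 0.01,
    upper_q: float = 0.99,
    method: str = "minmax",
) -> ExpressionMatrix:
    """Normalize every gene of ``matrix`` to [0,1] across samples.

    Thin wrapper over :class:`ExpressionNormalizer` keeping the gene × sample
    orientation of :class:`ExpressionMatrix`.
    """
    norm = ExpressionNormalizer(lower_q=lower_q, upper_q=upper_q, method=method)
    out = norm.fit_transform(matrix.data.T)  # samples × genes
    df = pd.DataFrame(out.T, index=matrix.genes, columns=matrix.samples)
    return ExpressionMatrix(df, normalized=True)


@dataclass(frozen=True)
class ParameterDefaults:
    """Global model defaults (standard normalized-HillCube practice)."""

    tau: float = 1.0
    hill_n: float = 3.0
    hill_k: float = 0.5
    weight: float = 1.0
    default_capacity: float = 0.5

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.hill_n < 1:
            raise ValueError("hill_n must be >= 1")
        if not 0 < self.hill_k < 1:
            raise ValueError("hill_k must be in (0, 1)")
        if not 0 <= self.default_capacity <= 1:
            raise ValueError("default_capacity must be in [0, 1]")


@dataclass
class ModelParameters:
    """One sample's fully-parameterized model: network + capacities + constants.

    ``capacities`` (e_i) are per-node values in [0,1], ordered like
    ``network.nodes``; ``tau`` are per-node time constants; ``weights`` align
    with ``network.links``.
    """

    network: SignedNetwork
    capacities: np.ndarray
    tau: np.ndarray
    hill_n: float
    hill_k: float
    weights: np.ndarray
    sample: str | None = None
    matched_fraction: float = float("nan")

    def __post_init__(self) -> None:
        n = self.network.n_nodes
        self.capacities = np.asarray(self.capacities, dtype=float)
        self.tau = np.broadcast_to(np.asarray(self.tau, dtype=float), (n,)).copy()
        self.weights = np.broadcast_to(np.asarray(self.weights, dtype=float), (self.network.n_links,)).copy()
        if self.capacities.shape != (n,):
            raise ValueError(f"capacities must have shape ({n},)")
        if np.any((self.capacities < 0) | (self.capacities > 1)):
            raise ValueError("all capacities must lie in [0, 1]")
        if np.any(self.tau <= 0):
            raise ValueError("all tau must be > 0")
        if self.hill_n < 1:
            raise ValueError("hill_n must be >= 1")
        if not 0 < self.hill_k < 1:
            raise ValueError("hill_k must be in (0, 1)")
        if np.any(self.weights < 0):
            raise ValueError("link weights must be >= 0")

    @property
    def n_nodes(self) -> int:
        return self.network.n_nodes

    def capacity_table(self) -> pd.DataFrame:
        return pd.DataFrame({"node": self.network.nodes, "capacity": self.capacities, "tau": self.tau})


def build_parameters(
    net: SignedNetwork,
    matrix: ExpressionMatrix,
    sample: str,
    defaults: ParameterDefaults | None = None,
) -> ModelParameters:
    """Bind one sample's normalized expression profile to a network.

    Gene-to-node matching is exact case-insensitive symbol equality (no
    aliasing).  Nodes absent from the matrix — complexes, families,
    chemicals, unmeasured genes — receive the neutral default capacity.
    """
    defaults = defaults or ParameterDefaults()
    if not matrix.normalized:
        raise ValueError("matrix must be normalized before parameter binding")
    if sample not in matrix.samples:
        raise KeyError(f"sample {sample!r} not found in expression matrix")

    lower_map: dict[str, str] = {}
    for g in matrix.genes:
        key = g.lower()
        if key in lower_map:
            raise ValueError(f"gene identifiers {lower_map[key]!r} and {g!r} collide case-insensitively")
        lower_map[key] = g

    col = matrix.data[sample]
    capacities = np.full(net.n_nodes, defaults.default_capacity, dtype=float)
    matched = 0
    for i, node in enumerate(net.nodes):
        gene = lower_map.get(node.lower())
        if gene is not None:
            capacities[i] = float(col.loc[gene])
            matched += 1
    weights = np.array([l.weight * defaults.weight for l in net.links], dtype=float)
    return ModelParameters(
        network=net,
        capacities=capacities,
        tau=np.full(net.n_nodes, defaults.tau),
        hill_n=defaults.hill_n,
        hill_k=defaults.hill_k,
        weights=weights,
        sample=sample,
        matched_fraction=matched / net.n_nodes if net.n_nodes else float("nan"),
    )


def read_labels(path) -> pd.Series:
    """Read a two-column TSV (sample id, group) into a Series indexed by sample."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("labels TSV must have at least two columns: sample, group")
    s = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="group")
    if s.index.has_duplicates:
        raise ValueError("duplicate sample ids in labels TSV")
    return s


def write_labels(labels: Mapping[str, str] | pd.Series, path) -> None:
    s = pd.Series(labels, name="group")
    s.rename_axis("sample").to_frame().to_csv(path, sep="\t")
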