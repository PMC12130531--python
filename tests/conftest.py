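"""Shared fixtures: tiny networks, parameter builders, SIGNOR-dialect text."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from netdasc.expression import ModelParameters
from netdasc.network import ACTIVATION, INHIBITION, SignedLink, SignedNetwork

SIGNOR_TEXT = (
    "ENTITYA\tENTITYB\tEFFECT\n"
    "TP53\tMDM2\tup-regulates\n"
    "AKT1\tGSK3B\tdown-regulates activity\n"
    "EGFR\tMAPK1\tup-regulates quantity by expression\n"
    "PTEN\tAKT1\tdown-regulates\n"
    "FOO\tBAR\tunknown\n"
)


def net_from_edges(*edges: str, extra_nodes: tuple[str, ...] = ()) -> SignedNetwork:
    """Build a network from compact edge strings: 'A->B' activates, 'A-|B' inhibits."""
    links = []
    for e in edges:
        if "->" in e:
            src, tgt = e.split("->")
            sign = ACTIVATION
        elif "-|" in e:
            src, tgt = e.split("-|")
            sign = INHIBITION
        else:
            raise ValueError(f"bad edge spec {e!r}")
        links.append(SignedLink(src.strip(), tgt.strip(), sign))
    return SignedNetwork.from_links(links, extra_nodes=extra_nodes)


def make_params(
    net: SignedNetwork,
    capacities: dict[str, float] | float = 1.0,
    tau: float = 1.0,
    hill_n: float = 3.0,
    hill_k: float = 0.5,
) -> ModelParameters:
    if isinstance(capacities, dict):
        caps = np.array([capacities.get(n, 0.5) for n in net.nodes])
    else:
        caps = np.full(net.n_nodes, float(capacities))
    return ModelParameters(
        network=net,
        capacities=caps,
        tau=np.full(net.n_nodes, tau),
        hill_n=hill_n,
        hill_k=hill_k,
        weights=np.ones(net.n_links),
    )


def random_signed_network(rng: np.random.Generator, n: int = 8, p: float = 0.25) -> SignedNetwork:
    names = [f"G{i}" for i in range(n)]
    links = []
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p:
                sign = ACTIVATION if rng.random() < 0.6 else INHIBITION
                links.append(SignedLink(names[i], names[j], sign))
    return SignedNetwork(nodes=tuple(names), links=tuple(links))


def random_dag(rng: np.random.Generator, n: int = 8, p: float = 0.4) -> SignedNetwork:
    """Acyclic signed network: edges only from lower to higher node index."""
    names = [f"G{i}" for i in range(n)]
    links = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                sign = ACTIVATION if rng.random() < 0.6 else INHIBITION
                links.append(SignedLink(names[i], names[j], sign))
    return SignedNetwork(nodes=tuple(names), links=tuple(links))


@pytest.fixture
def signor_file(tmp_path):
    path = tmp_path / "signor.tsv"
    path.write_text(SIGNOR_TEXT)
    return path


@pytest.fixture
def chain_net():
    """A activates B, B inhibits C."""
    return net_from_edges("A->B", "B-|C")


@pytest.fixture
def toggle_net():
    """Mutually inhibiting pair — the classic bistable switch."""
    return net_from_edges("A-|B", "B-|A")


@pytest.fixture
def expr_small():
    df = pd.DataFrame(
        {"S1": [2.0, 5.0, 1.0], "S2": [4.0, 5.0, 3.0], "S3": [6.0, 5.0, 2.0]},
        index=["FBLN5", "CONST", "TTK"],
    )
    from netdasc.expression import ExpressionMatrix

    return ExpressionMatrix(df)
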