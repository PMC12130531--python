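"""Signed causal networks: types, SIGNOR-dialect parsing, SIF round-trip, summaries.

A :class:`SignedNetwork` is the substrate for the normalized dynamical model:
an ordered (lexicographic) set of node identifiers plus a list of signed
directed links.  Node ordering is deterministic so that state vectors built
on top of a network are reproducible across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

ACTIVATION = "activation"
INHIBITION = "inhibition"
_SIGNS = (ACTIVATION, INHIBITION)

#: SIF relation tokens, one per sign.
_SIF_TOKEN = {ACTIVATION: "activates", INHIBITION: "inhibits"}
_SIF_SIGN = {v: k for k, v in _SIF_TOKEN.items()}


class NetworkFormatError(ValueError):
    """Raised when an input file does not conform to the expected dialect."""


class EmptyNetworkError(ValueError):
    """Raised when parsing/filtering leaves no links at all."""


@dataclass(frozen=True, order=True)
class SignedLink:
    """One signed directed interaction: ``source`` acts on ``target``."""

    source: str
    target: str
    sign: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.sign not in _SIGNS:
            raise ValueError(f"sign must be one of {_SIGNS}, got {self.sign!r}")
        if not self.weight > 0:
            raise ValueError(f"weight must be > 0, got {self.weight!r}")


@dataclass(frozen=True)
class SignedNetwork:
    """Signed directed network with deterministic lexicographic node order.

    ``input_nodes`` (nodes with zero incoming links) is always derived from
    the current link list, never stored, so it cannot go stale.
    """

    nodes: tuple[str, ...]
    links: tuple[SignedLink, ...]

    def __post_init__(self) -> None:
        nodes = tuple(sorted(dict.fromkeys(self.nodes)))
        object.__setattr__(self, "nodes", nodes)
        node_set = set(nodes)
        for link in self.links:
            if link.source not in node_set or link.target not in node_set:
                raise ValueError(f"link endpoint not in node set: {link}")
        object.__setattr__(
            self, "links", tuple(sorted(self.links, key=lambda l: (l.source, l.target, l.sign)))
        )

    @classmethod
    def from_links(cls, links: Iterable[SignedLink], extra_nodes: Iterable[str] = ()) -> "SignedNetwork":
        links = tuple(links)
        nodes = {l.source for l in links} | {l.target for l in links} | set(extra_nodes)
        return cls(nodes=tuple(sorted(nodes)), links=links)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_links(self) -> int:
        return len(self.links)

    @property
    def input_nodes(self) -> frozenset[str]:
        """Nodes with zero incoming links (recomputed on every access)."""
        targets = {l.target for l in self.links}
        return frozenset(n for n in self.nodes if n not in targets)

    def node_index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}

    def to_digraph(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.nodes)
        for l in self.links:
            g.add_edge(l.source, l.target, sign=l.sign, weight=l.weight)
        return g

    def largest_component(self) -> "SignedNetwork":
        """Restrict to the largest weakly connected component."""
        g = self.to_digraph()
        if g.number_of_nodes() == 0:
            return self
        comp = max(nx.weakly_connected_components(g), key=lambda c: (len(c), sorted(c)))
        links = tuple(l for l in self.links if l.source in comp and l.target in comp)
        return SignedNetwork(nodes=tuple(sorted(comp)), links=links)


def _clean_identifier(raw: object, *, line: int) -> str:
    name = str(raw).strip()
    if not name or name.lower() == "nan":
        raise NetworkFormatError(f"empty node identifier on data row {line}")
    return name


def parse_signor(
    path,
    *,
    keep_signs: Sequence[str] = _SIGNS,
    col_source: str = "ENTITYA",
    col_target: str = "ENTITYB",
    col_effect: str = "EFFECT",
    largest_component_only: bool = False,
) -> SignedNetwork:
    """Parse a SIGNOR-style tab-delimited causal-interaction export.

    Effect strings containing ``up-regulates`` map to activation and
    ``down-regulates`` to inhibition (substring match, so sub-annotations
    such as "up-regulates activity" are absorbed); any other effect is
    dropped.  Duplicate (source, target, sign) triples collapse to one link;
    self-loops are retained.  Entities that are complexes, families,
    chemicals or phenotypes are kept as ordinary named nodes.

    Parameters
    ----------
    path : str or file-like
        Tab-delimited file with a header row.
    keep_signs : sequence of {"activation", "inhibition"}
        Signs to retain after effect mapping.
    largest_component_only : bool
        Restrict to the largest weakly connected component (off by default).
    """
    bad = set(keep_signs) - set(_SIGNS)
    if bad:
        raise ValueError(f"unknown signs in keep_signs: {sorted(bad)}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (col_source, col_target, col_effect):
        if col not in df.columns:
            raise NetworkFormatError(f"missing required column {col!r} (found: {list(df.columns)})")

    seen: dict[tuple[str, str, str], SignedLink] = {}
    raw_seen: dict[str, str] = {}  # trimmed -> raw, to flag trim-induced merges

    def register(raw: object, line: int) -> str:
        name = _clean_identifier(raw, line=line)
        prior = raw_seen.setdefault(name, str(raw))
        if prior != str(raw):
            raise NetworkFormatError(
                f"identifier collision after whitespace trimming on row {line}: "
                f"{prior!r} and {str(raw)!r} both trim to {name!r}"
            )
        return name

    cols = list(df.columns)
    i_src, i_tgt, i_eff = cols.index(col_source), cols.index(col_target), cols.index(col_effect)
    for i, row in enumerate(df.itertuples(index=False), start=1):
        effect = str(row[i_eff] or "").lower()
        if "down-regulates" in effect:
            sign = INHIBITION
        elif "up-regulates" in effect:
            sign = ACTIVATION
        else:
            continue
        if sign not in keep_signs:
            continue
        src = register(row[i_src], i)
        tgt = register(row[i_tgt], i)
        seen.setdefault((src, tgt, sign), SignedLink(src, tgt, sign))

    if not seen:
        raise EmptyNetworkError("empty network: no links survived effect filtering")
    net = SignedNetwork.from_links(seen.values())
    if largest_component_only:
        net = net.largest_component()
    return net


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_links: int
    n_activation: int
    n_inhibition: int
    n_input_nodes: int
    largest_component_size: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def network_summary(net: SignedNetwork) -> NetworkSummary:
    """Counts of nodes, links by sign, input nodes and the largest weak component."""
    n_act = sum(1 for l in net.links if l.sign == ACTIVATION)
    g = net.to_digraph()
    lcc = max((len(c) for c in nx.weakly_connected_components(g)), default=0)
    return NetworkSummary(
        n_nodes=net.n_nodes,
        n_links=net.n_links,
        n_activation=n_act,
        n_inhibition=net.n_links - n_act,
        n_input_nodes=len(net.input_nodes),
        largest_component_size=lcc,
    )


def write_sif(net: SignedNetwork, path) -> None:
    """Write a 3-column whitespace-delimited SIF file (``A activates B``)."""
    lines = [f"{l.source}\t{_SIF_TOKEN[l.sign]}\t{l.target}" for l in net.links]
    isolated = sorted(set(net.nodes) - {l.source for l in net.links} - {l.target for l in net.links})
    lines.extend(isolated)
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


def read_sif(path) -> SignedNetwork:
    """Read a SIF file; unknown relation tokens raise :class:`NetworkFormatError`."""
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    links: list[SignedLink] = []
    extra: list[str] = []
    for i, raw in enumerate(text.splitlines(), start=1):
        parts = raw.split()
        if not parts:
            continue
        if len(parts) == 1:
            extra.append(parts[0])
            continue
        if len(parts) != 3:
            raise NetworkFormatError(f"SIF line {i}: expected 1 or 3 fields, got {len(parts)}")
        src, token, tgt = parts
        if token not in _SIF_SIGN:
            raise NetworkFormatError(f"SIF line {i}: unknown relation token {token!r}")
        links.append(SignedLink(src, tgt, _SIF_SIGN[token]))
    if not links and not extra:
        raise EmptyNetworkError("empty network: SIF file has no records")
    return SignedNetwork.from_links(links, extra_nodes=extra)


def write_links_tsv(net: SignedNetwork, path) -> None:
    """Internal links TSV with header: source, target, sign, weight."""
    df = pd.DataFrame(
        [(l.source, l.target, l.sign, l.weight) for l in net.links],
        columns=["source", "target", "sign", "weight"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_links_tsv(path) -> SignedNetwork:
    df = pd.read_csv(path, sep="\t")
    for col in ("source", "target", "sign"):
        if col not in df.columns:
            raise NetworkFormatError(f"missing required column {col!r} in links TSV")
    weights = df["weight"] if "weight" in df.columns else pd.Series(1.0, index=df.index)
    links = [
        SignedLink(str(s).strip(), str(t).strip(), str(sg), float(w))
        for s, t, sg, w in zip(df["source"], df["target"], df["sign"], weights)
    ]
    if not links:
        raise EmptyNetworkError("empty network: links TSV has no rows")
    return SignedNetwork.from_links(links)
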