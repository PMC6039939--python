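"""In-memory attributed networks and the SUID registry.

Nodes are unique by name within a network; edges connect node pairs, carry
one interaction type and a map of named numeric attributes.  Every network,
node and edge gets a SUID — a positive integer from one process-wide
monotonic counter, never reused — so identifiers look and behave like a
desktop session's.

The native store keeps insertion order (it matters when a network is written
back out as a matrix); :meth:`Network.to_networkx` hands the same structure
to networkx for downstream analysis.
"""

from __future__ import annotations

import itertools
import threading
from dataclasses import dataclass, field
from typing import Iterator

import networkx as nx

from .errors import NetworkNotFoundError

_suid_lock = threading.Lock()
_suid_counter = itertools.count(1)


def next_suid() -> int:
    """The next process-wide session-unique identifier."""
    with _suid_lock:
        return next(_suid_counter)


@dataclass(frozen=True)
class Node:
    suid: int
    name: str


@dataclass
class Edge:
    suid: int
    source: int  #: SUID of the source node
    target: int  #: SUID of the target node
    interaction: str
    attributes: dict[str, float] = field(default_factory=dict)


class Network:
    """A registry-addressable network of named nodes and attributed edges."""

    def __init__(self, name: str = "network") -> None:
        self.suid = next_suid()
        self.name = name
        self._nodes: dict[int, Node] = {}
        self._by_name: dict[str, Node] = {}
        self._edges: dict[int, Edge] = {}
        # (source SUID, target SUID) -> edge SUIDs, in creation order
        self._pairs: dict[tuple[int, int], list[int]] = {}

    # -- nodes -----------------------------------------------------------

    @property
    def nodes(self) -> list[Node]:
        return list(self._nodes.values())

    @property
    def node_count(self) -> int:
        return len(self._nodes)

    def node_by_name(self, name: str) -> Node | None:
        return self._by_name.get(name)

    def node(self, suid: int) -> Node:
        return self._nodes[suid]

    def get_or_create_node(self, name: str) -> Node:
        """Match a node by exact (case-sensitive) name, creating it if absent."""
        node = self._by_name.get(name)
        if node is None:
            node = Node(suid=next_suid(), name=name)
            self._nodes[node.suid] = node
            self._by_name[name] = node
        return node

    # -- edges -----------------------------------------------------------

    @property
    def edges(self) -> list[Edge]:
        return list(self._edges.values())

    @property
    def edge_count(self) -> int:
        return len(self._edges)

    def add_edge(self, source: Node, target: Node, interaction: str) -> Edge:
        edge = Edge(
            suid=next_suid(),
            source=source.suid,
            target=target.suid,
            interaction=interaction,
        )
        self._edges[edge.suid] = edge
        self._pairs.setdefault((source.suid, target.suid), []).append(edge.suid)
        return edge

    def find_edge(
        self, source_suid: int, target_suid: int, undirected: bool = False
    ) -> Edge | None:
        """The earliest-created edge between two nodes, if any.

        Directed lookup matches the ordered pair; undirected lookup matches
        either orientation.  Interaction type is not part of the match: an
        extend call sets its attribute on whatever edge already joins the
        pair.
        """
        candidates = list(self._pairs.get((source_suid, target_suid), ()))
        if undirected and source_suid != target_suid:
            candidates += self._pairs.get((target_suid, source_suid), ())
        if not candidates:
            return None
        return self._edges[min(candidates)]

    def edge_between(
        self, source_name: str, target_name: str, undirected: bool = False
    ) -> Edge | None:
        """Convenience name-based edge lookup."""
        src = self._by_name.get(source_name)
        tgt = self._by_name.get(target_name)
        if src is None or tgt is None:
            return None
        return self.find_edge(src.suid, tgt.suid, undirected)

    def attribute_names(self) -> list[str]:
        """All edge-attribute names in the network, sorted."""
        names: set[str] = set()
        for edge in self._edges.values():
            names.update(edge.attributes)
        return sorted(names)

    def isolated_nodes(self) -> list[Node]:
        """Nodes with no incident edge, in insertion order."""
        used: set[int] = set()
        for edge in self._edges.values():
            used.add(edge.source)
            used.add(edge.target)
        return [n for n in self._nodes.values() if n.suid not in used]

    # -- export ----------------------------------------------------------

    def to_networkx(self) -> nx.MultiDiGraph:
        """The network as a networkx MultiDiGraph keyed by node name."""
        graph = nx.MultiDiGraph(name=self.name, suid=self.suid)
        for node in self._nodes.values():
            graph.add_node(node.name, suid=node.suid)
        for edge in self._edges.values():
            graph.add_edge(
                self._nodes[edge.source].name,
                self._nodes[edge.target].name,
                key=edge.suid,
                interaction=edge.interaction,
                **edge.attributes,
            )
        return graph

    def to_dict(self) -> dict:
        """A JSON-serialisable snapshot of the network."""
        return {
            "suid": self.suid,
            "name": self.name,
            "nodes": [{"suid": n.suid, "name": n.name} for n in self._nodes.values()],
            "edges": [
                {
                    "suid": e.suid,
                    "source": self._nodes[e.source].name,
                    "target": self._nodes[e.target].name,
                    "interaction": e.interaction,
                    "attributes": dict(e.attributes),
                }
                for e in self._edges.values()
            ],
        }

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return (
            f"<Network suid={self.suid} name={self.name!r} "
            f"nodes={self.node_count} edges={self.edge_count}>"
        )


class NetworkRegistry:
    """Maps SUIDs to live networks, mimicking a session's network table."""

    def __init__(self) -> None:
        self._networks: dict[int, Network] = {}

    def register(self, network: Network) -> int:
        self._networks[network.suid] = network
        return network.suid

    def get(self, suid: int) -> Network:
        try:
            return self._networks[suid]
        except KeyError:
            raise NetworkNotFoundError(f"no network with SUID {suid}") from None

    def __len__(self) -> int:
        return len(self._networks)

    def __iter__(self) -> Iterator[Network]:
        return iter(self._networks.values())

    def summaries(self) -> list[dict]:
        """One record per registered network: SUID, name and size."""
        return [
            {
                "SUID": net.suid,
                "name": net.name,
                "nodeCount": net.node_count,
                "edgeCount": net.edge_count,
            }
            for net in self._networks.values()
        ]
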