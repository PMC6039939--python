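"""Small helpers shared across the test modules."""

from adjnet import Network


def edge_pairs(network: Network) -> set[tuple[str, str]]:
    """The network's edges as (source name, target name) pairs."""
    return {
        (network.node(e.source).name, network.node(e.target).name)
        for e in network.edges
    }


def edge_map(network: Network, attribute: str) -> dict[tuple[str, str], float]:
    """(source, target) -> value for every edge carrying *attribute*."""
    return {
        (network.node(e.source).name, network.node(e.target).name): e.attributes[
            attribute
        ]
        for e in network.edges
        if attribute in e.attributes
    }


def node_names(network: Network) -> set[str]:
    return {n.name for n in network.nodes}
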