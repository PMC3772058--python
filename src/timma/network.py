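"""Target inhibition network construction and export.

The binarized predicted efficacy function over the selected target set is a
monotone Boolean function: inhibiting more targets can only help. Its
minimal effective target sets (prime implicants) and their minimal hitting
sets (prime implicates) give an equivalent circuit of parallel survival
pathways, each a series chain of target nodes: a target set is effective if
and only if it inhibits at least one node in *every* parallel pathway.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .scoring import EfficacyMatrix

__all__ = [
    "InhibitionNetwork",
    "build_inhibition_network",
    "export_network",
    "pathways_from_graphml",
]


@dataclass
class InhibitionNetwork:
    """Parallel survival pathways equivalent to a binarized efficacy function.

    Each pathway is a tuple of (meta-)target node names in series. A target
    set is effective iff it intersects every pathway.
    """

    pathways: list
    threshold: float
    targets: tuple
    prime_implicants: list = field(default_factory=list)
    monotonicity_violations: list = field(default_factory=list)

    def is_effective(self, subset) -> bool:
        s = set(subset)
        return all(s & set(p) for p in self.pathways)


def _minimal_sets(sets: list[frozenset]) -> list[frozenset]:
    out = []
    for s in sets:
        if not any(o < s for o in sets):
            out.append(s)
    return out


def _minimal_transversals(family: list[frozenset]) -> list[frozenset]:
    """Berge's incremental algorithm for minimal hitting sets."""
    trans: list[frozenset] = [frozenset()]
    for clause in family:
        new: list[frozenset] = []
        for t in trans:
            if t & clause:
                new.append(t)
            else:
                new.extend(t | {x} for x in clause)
        # drop non-minimal candidates
        new = sorted(set(new), key=lambda s: (len(s), sorted(s)))
        trans = [s for s in new if not any(o < s for o in new)]
    return trans


def build_inhibition_network(M: EfficacyMatrix, threshold: float) -> InhibitionNetwork:
    """Construct the target inhibition network from a full efficacy matrix.

    States with predicted efficacy >= ``threshold`` are effective
    (non-identifiable states count as ineffective). A binarized function
    that is non-monotone (possible with noisy predictions) is repaired by
    monotone closure -- a state is effective if any of its subset states is
    -- and the repaired states are reported via a warning and recorded on
    the returned network. The pathway representation is verified to
    round-trip the closed binarized function exactly.
    """
    if M.mode != "full":
        raise ValueError("network construction needs a full-mode efficacy matrix")
    m = len(M.targets)
    n_states = 2**m
    eff = np.zeros(n_states, dtype=bool)
    for mask, v in M.values.items():
        eff[mask] = (not np.isnan(v)) and v >= threshold
    if not eff.any():
        raise ValueError(f"no state reaches the efficacy threshold {threshold}")

    closed = eff.copy()
    for bit in range(m):
        step = 1 << bit
        for mask in range(n_states):
            if mask & step:
                closed[mask] |= closed[mask ^ step]
    violations = [mask for mask in range(n_states) if closed[mask] and not eff[mask]]
    if violations:
        warnings.warn(
            f"binarized efficacy function was non-monotone; {len(violations)} "
            "state(s) repaired by monotone closure",
            stacklevel=2,
        )

    if closed[0]:
        # constant-true function: effective without inhibiting anything, so
        # there is no survival pathway to block (empty pathway family)
        net = InhibitionNetwork(
            pathways=[],
            threshold=threshold,
            targets=M.targets,
            prime_implicants=[[]],
            monotonicity_violations=violations,
        )
        return net

    # prime implicants: minimal effective states
    implicants = []
    for mask in range(1, n_states):
        if closed[mask] and not any(
            closed[mask ^ (1 << b)] for b in range(m) if mask & (1 << b)
        ):
            implicants.append(frozenset(M.targets[b] for b in range(m) if mask & (1 << b)))

    pathways = _minimal_transversals(implicants)
    order = {t: i for i, t in enumerate(M.targets)}
    pathway_lists = sorted(
        (tuple(sorted(p, key=order.get)) for p in pathways),
        key=lambda p: (len(p), [order[t] for t in p]),
    )

    net = InhibitionNetwork(
        pathways=[list(p) for p in pathway_lists],
        threshold=threshold,
        targets=M.targets,
        prime_implicants=[sorted(s, key=order.get) for s in implicants],
        monotonicity_violations=violations,
    )
    # round-trip check: hitting-set semantics must reproduce the closed function
    for mask in range(n_states):
        subset = {M.targets[b] for b in range(m) if mask & (1 << b)}
        if net.is_effective(subset) != bool(closed[mask]):
            raise AssertionError(
                "pathway representation does not round-trip the binarized "
                f"efficacy function at state {sorted(subset)}"
            )
    return net


def to_graph(
    net: InhibitionNetwork, drugs=None, affinities=None, meta_sep: str = "/"
) -> nx.Graph:
    """Networkx graph of the inhibition network with optional drug annotation.

    Target nodes carry their pathway index and series position; if a binary
    drug x target matrix ``drugs`` is given, drug nodes (squares in the
    published layouts) are linked to the target nodes they inhibit. If a
    quantitative Kd matrix ``affinities`` is given, each meta-target node is
    labelled by its member with the tightest (minimal Kd) binding, with the
    remaining members kept as an attribute.
    """
    G = nx.Graph()
    # a meta-target may sit in several pathways, so node ids are per-pathway
    for p_idx, pathway in enumerate(net.pathways):
        for s_idx, node in enumerate(pathway):
            members = node.split(meta_sep)
            label = node
            if affinities is not None:
                present = [t for t in members if t in affinities.columns]
                if present:
                    min_kd = affinities[present].min(axis=0)
                    label = str(min_kd.idxmin())
            G.add_node(
                f"p{p_idx}:{node}",
                kind="target",
                name=node,
                pathway=p_idx,
                position=s_idx,
                label=label,
                members=meta_sep.join(members),
            )
    if drugs is not None:
        for drug in drugs.index:
            hit_nodes = []
            for node_id in list(G.nodes):
                if G.nodes[node_id]["kind"] != "target":
                    continue
                name = G.nodes[node_id]["name"]
                members = [name] + G.nodes[node_id]["members"].split(meta_sep)
                if any(
                    t in drugs.columns and drugs.loc[drug, t] == 1 for t in members
                ):
                    hit_nodes.append(node_id)
            if hit_nodes:
                G.add_node(str(drug), kind="drug")
                for node_id in hit_nodes:
                    G.add_edge(str(drug), node_id)
    return G


def export_network(
    net: InhibitionNetwork,
    graphml_path: str | Path | None = None,
    dot_path: str | Path | None = None,
    drugs=None,
    affinities=None,
) -> nx.Graph:
    """Write the network as GraphML and/or Graphviz DOT; returns the graph."""
    G = to_graph(net, drugs=drugs, affinities=affinities)
    if graphml_path is not None:
        nx.write_graphml(G, graphml_path)
    if dot_path is not None:
        lines = ["graph inhibition_network {"]
        for node in sorted(G.nodes):
            attrs = G.nodes[node]
            if attrs.get("kind") == "target":
                shape, color = "circle", "blue"
            else:
                shape, color = "box", "red"
            label = attrs.get("label", node)
            lines.append(
                f'  "{node}" [shape={shape}, color={color}, label="{label}"];'
            )
        for u, v in sorted(map(tuple, map(sorted, G.edges))):
            lines.append(f'  "{u}" -- "{v}";')
        lines.append("}")
        Path(dot_path).write_text("\n".join(lines) + "\n")
    return G


def pathways_from_graphml(path: str | Path) -> list[list[str]]:
    """Reconstruct the pathway lists from an exported GraphML file."""
    G = nx.read_graphml(path)
    by_pathway: dict[int, list] = {}
    for node, attrs in G.nodes(data=True):
        if attrs.get("kind") != "target":
            continue
        by_pathway.setdefault(int(attrs["pathway"]), []).append(
            (int(attrs["position"]), attrs.get("name", node))
        )
    return [
        [name for _, name in sorted(nodes)]
        for _, nodes in sorted(by_pathway.items())
    ]
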