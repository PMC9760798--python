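"""Cell-fate maps: persistent bit-flip perturbations between attractors.

For each attractor of the unperturbed network and each selected node, the
node is clamped to the opposite of its value in the attractor (both clamps
when the value varies across cycle states), the perturbed trajectory is
followed in the clamped network from every attractor state, and the
destination attractor(s) recorded.  Edges are labeled with the node name
and a sign: ``+`` when an off node is turned on, ``-`` when an on node is
turned off.

A transient variant (flip the bit once, then evolve under the original
rules) is available for comparison via ``mode="transient"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx

from .attractors import Attractor, AttractorSet, trajectory_to_attractor
from .network import BooleanNetwork, clamp_node
from .phenotype import PhenotypeScheme, classify_attractor

__all__ = [
    "Perturbation",
    "FateMap",
    "resolve_perturbation",
    "build_fate_map",
    "export_fate_map",
]

VARIES = "varies"


@dataclass(frozen=True)
class Perturbation:
    """One persistent clamp applied to a source attractor."""

    node: str
    original_value: object   # 0, 1, or "varies"
    clamp_value: int

    def __post_init__(self):
        if self.clamp_value not in (0, 1):
            raise ValueError("clamp_value must be 0 or 1")
        if self.original_value not in (0, 1, VARIES):
            raise ValueError("original_value must be 0, 1 or 'varies'")
        if self.original_value == self.clamp_value:
            raise ValueError(
                "clamp_value must differ from a constant original_value")

    @property
    def sign(self) -> str:
        return "+" if self.clamp_value == 1 else "-"

    def label(self) -> str:
        return f"{self.sign}{self.node}"


@dataclass(frozen=True)
class FateEdge:
    source_key: tuple
    perturbation: Perturbation
    destination_key: tuple
    n_entry_states: int      # how many source states led to this destination


class FateMap:
    """Directed multigraph of attractors connected by clamp perturbations.

    Vertices are identified by their canonical state-code sequence, so a
    destination whose states coincide with an unperturbed attractor is the
    same vertex (self-edges are possible).  Destinations reached only inside
    a clamped network keep a tag naming that clamp.
    """

    def __init__(self, network: BooleanNetwork, scheme: PhenotypeScheme,
                 mode: str = "clamp"):
        self.network = network
        self.scheme = scheme
        self.mode = mode
        self.vertices: dict = {}      # key -> Attractor
        self.annotations: dict = {}   # key -> AttractorAnnotation
        self.origin: dict = {}        # key -> "census" | clamp tag
        self.edges: list = []

    def add_vertex(self, attractor: Attractor, origin: str) -> tuple:
        key = attractor.key()
        if key not in self.vertices:
            self.vertices[key] = attractor
            self.annotations[key] = classify_attractor(
                attractor, self.scheme, self.network)
            self.origin[key] = origin
        return key

    def add_edge(self, source_key: tuple, perturbation: Perturbation,
                 destination_key: tuple, n_entry_states: int) -> None:
        self.edges.append(FateEdge(source_key, perturbation,
                                   destination_key, n_entry_states))

    def vertex_name(self, key: tuple) -> str:
        return self.annotations[key].name

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for key, ann in self.annotations.items():
            g.add_node(
                "|".join(map(str, key)),
                name=ann.name,
                attractor_class=ann.attractor_class,
                period=ann.period,
                origin=self.origin[key],
            )
        for e in self.edges:
            g.add_edge(
                "|".join(map(str, e.source_key)),
                "|".join(map(str, e.destination_key)),
                node=e.perturbation.node,
                sign=e.perturbation.sign,
                label=e.perturbation.label(),
                n_entry_states=e.n_entry_states,
            )
        return g


# ---------------------------------------------------------------------------
# Resolution
# ---------------------------------------------------------------------------

def resolve_perturbation(net: BooleanNetwork, source: Attractor, node: str,
                         clamp_value: int, mode: str = "clamp"):
    """Destinations reached by clamping ``node`` from each source state.

    The node's bit is set to ``clamp_value`` in every state of the source
    attractor and the trajectory followed in the clamped network (or, in
    ``transient`` mode, the original network).  Returns a list of
    ``(destination Attractor, entry_state_index)`` pairs with one entry per
    distinct destination, keeping the first source-state index that reached
    it.  Deterministic: state order follows the canonical rotation.
    """
    idx = net.node_index(node)
    if mode == "clamp":
        dyn_net = clamp_node(net, node, clamp_value)
    elif mode == "transient":
        dyn_net = net
    else:
        raise ValueError(f"unknown mode {mode!r}")
    destinations = []
    seen = set()
    for state_i, state in enumerate(source.states):
        flipped = list(state)
        flipped[idx] = clamp_value
        attractor, _ = trajectory_to_attractor(dyn_net, tuple(flipped))
        key = attractor.key()
        if key not in seen:
            seen.add(key)
            destinations.append((attractor, state_i))
    return destinations


def build_fate_map(net: BooleanNetwork, attr_set: AttractorSet,
                   scheme: PhenotypeScheme,
                   nodes: Optional[Sequence] = None,
                   mode: str = "clamp") -> FateMap:
    """Perturb every attractor at every selected node and collect edges.

    Nodes constant across the source attractor get the single opposite
    clamp; nodes that vary across cycle states get both clamps (recorded
    with ``original_value="varies"``).  Fully deterministic.
    """
    if nodes is None:
        nodes = net.nodes
    else:
        for node in nodes:
            net.node_index(node)
    fmap = FateMap(net, scheme, mode=mode)
    for attractor in attr_set.attractors:
        fmap.add_vertex(attractor, origin="census")
    for attractor in attr_set.attractors:
        source_key = attractor.key()
        for node in nodes:
            idx = net.node_index(node)
            values = {state[idx] for state in attractor.states}
            if len(values) == 1:
                original = values.pop()
                clamps = [Perturbation(node, original, 1 - original)]
            else:
                clamps = [Perturbation(node, VARIES, 0),
                          Perturbation(node, VARIES, 1)]
            for pert in clamps:
                dyn_net = (clamp_node(net, node, pert.clamp_value)
                           if mode == "clamp" else net)
                found: dict = {}  # dest key -> [Attractor, entry count]
                for state in attractor.states:
                    flipped = list(state)
                    flipped[idx] = pert.clamp_value
                    dest, _ = trajectory_to_attractor(dyn_net, tuple(flipped))
                    entry = found.setdefault(dest.key(), [dest, 0])
                    entry[1] += 1
                for destination, n_entry in found.values():
                    dest_key = fmap.add_vertex(
                        destination,
                        origin=f"{mode}:{pert.label()}")
                    fmap.add_edge(source_key, pert, dest_key, n_entry)
    return fmap


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def fate_map_to_tsv(fmap: FateMap) -> str:
    header = ("source\tnode\tsign\tdestination\tdestination_class\t"
              "destination_states\tn_entry_states")
    rows = [header]
    for e in fmap.edges:
        dest_ann = fmap.annotations[e.destination_key]
        rows.append("\t".join([
            fmap.vertex_name(e.source_key),
            e.perturbation.node,
            e.perturbation.sign,
            dest_ann.name,
            dest_ann.attractor_class,
            "/".join(fmap.vertices[e.destination_key].bitstrings()),
            str(e.n_entry_states),
        ]))
    return "\n".join(rows) + "\n"


def fate_map_to_dot(fmap: FateMap) -> str:
    lines = ["digraph fatemap {"]
    ids = {key: f"a{i}" for i, key in enumerate(fmap.vertices)}
    for key, vid in ids.items():
        ann = fmap.annotations[key]
        lines.append(
            f'  {vid} [label="{ann.name}" class="{ann.attractor_class}"];')
    for e in fmap.edges:
        lines.append(
            f'  {ids[e.source_key]} -> {ids[e.destination_key]} '
            f'[label="{e.perturbation.label()}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def export_fate_map(fmap: FateMap, path, fmt: str = "tsv") -> None:
    """Write the edge table (tsv), GraphML or DOT; byte-stable across runs."""
    if not fmap.edges:
        raise ValueError("refusing to export an empty fate map")
    path = str(path)
    if fmt == "tsv":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(fate_map_to_tsv(fmap))
    elif fmt == "graphml":
        nx.write_graphml(fmap.to_networkx(), path)
    elif fmt == "dot":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(fate_map_to_dot(fmap))
    else:
        raise ValueError(f"unsupported format {fmt!r}")


def parse_fate_map_tsv(text: str):
    """Parse the TSV edge table back into a list of row dicts."""
    lines = [ln for ln in text.splitlines() if ln]
    header = lines[0].split("\t")
    return [dict(zip(header, ln.split("\t"))) for ln in lines[1:]]
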