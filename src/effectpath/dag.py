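"""Causal directed acyclic graphs, path analysis, and effect-type classification.

This module answers the qualitative question at the heart of comparing
immigrants and non-immigrants (or any selection-sampled groups) with
regression: when the analysis restricts to the sampled dataset (``S = 1``)
and adjusts for a set of measured outcome risk factors, is the resulting
exposure coefficient a *total effect*, a *controlled direct effect*, or a
*biased* quantity?

The answer is purely graphical.  An exposure--outcome path is *causal* when
every arrow points from exposure toward outcome; all other paths are
non-causal.  A path is *open* given a conditioning set when every interior
chain or fork node is unconditioned and every interior collider has itself
or a descendant conditioned.  The classifier conditions on the selection
node implicitly (the analyzed dataset is always restricted to ``S = 1``),
adds the user's adjustment set, and reports:

* ``BIASED`` -- at least one non-causal path is open,
* ``CONTROLLED_DIRECT`` -- no open non-causal path, but at least one causal
  path is blocked by the conditioning set,
* ``TOTAL`` -- otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from functools import cached_property
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

__all__ = [
    "FORWARD",
    "BACKWARD",
    "GraphError",
    "AdjustmentError",
    "CausalDAG",
    "NodeRoles",
    "Path",
    "EffectType",
    "EffectClassification",
    "build_dag",
    "enumerate_paths",
    "path_open",
    "d_separated",
    "classify_adjusted_effect",
    "to_dot",
]

FORWARD = "->"
BACKWARD = "<-"


class GraphError(ValueError):
    """Structurally invalid graph or role specification."""


class AdjustmentError(ValueError):
    """Adjustment set violates the measurement or role constraints."""


@dataclass(frozen=True)
class CausalDAG:
    """An acyclic directed graph over text-labelled nodes.

    Edges are ordered pairs ``(cause, effect)``.  Construction validates
    acyclicity, absence of self-loops, and that every edge endpoint is a
    declared node.  Instances are immutable and hashable.
    """

    nodes: frozenset
    edges: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        object.__setattr__(self, "edges", frozenset(tuple(e) for e in self.edges))
        for node in self.nodes:
            if not isinstance(node, str) or not node:
                raise GraphError(f"node labels must be nonempty text, got {node!r}")
        for edge in self.edges:
            if len(edge) != 2:
                raise GraphError(f"edge must be an ordered pair, got {edge!r}")
            a, b = edge
            if a == b:
                raise GraphError(f"self-loop on node {a!r}")
            if a not in self.nodes or b not in self.nodes:
                raise GraphError(f"edge {a!r} -> {b!r} has an undeclared endpoint")
        graph = self._graph
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            witness = " -> ".join([cycle[0][0]] + [b for _, b in cycle])
            raise GraphError(f"graph contains a cycle: {witness}")

    @cached_property
    def _graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.edges))
        return g

    def parents(self, node: str) -> frozenset:
        self._require(node)
        return frozenset(self._graph.predecessors(node))

    def children(self, node: str) -> frozenset:
        self._require(node)
        return frozenset(self._graph.successors(node))

    def descendants(self, node: str) -> frozenset:
        self._require(node)
        return frozenset(nx.descendants(self._graph, node))

    def ancestors(self, node: str) -> frozenset:
        self._require(node)
        return frozenset(nx.ancestors(self._graph, node))

    def topological_order(self) -> tuple:
        """Nodes in a deterministic (lexicographic tie-break) causal order."""
        return tuple(nx.lexicographical_topological_sort(self._graph))

    def _require(self, *nodes: str) -> None:
        for node in nodes:
            if node not in self.nodes:
                raise GraphError(f"unknown node {node!r}")


def build_dag(edge_list: Sequence, isolated: Iterable = ()) -> CausalDAG:
    """Build a validated :class:`CausalDAG` from an ordered edge list.

    The node set is inferred from edge endpoints plus the optional
    ``isolated`` node list.  A duplicated edge in ``edge_list`` is rejected
    (it usually signals a typo in a hand-written model), as is any cycle.
    """
    edges = [tuple(e) for e in edge_list]
    seen = set()
    for edge in edges:
        if edge in seen:
            raise GraphError(f"duplicate edge {edge[0]!r} -> {edge[1]!r}")
        seen.add(edge)
    nodes = {n for e in edges for n in e} | set(isolated)
    return CausalDAG(nodes=frozenset(nodes), edges=frozenset(edges))


@dataclass(frozen=True)
class NodeRoles:
    """Causal roles of nodes in a selection-sampled analysis.

    ``exposure`` is the group indicator (country of birth in the motivating
    setting), ``outcome`` the health outcome, and ``selection`` the optional
    binary membership indicator for the analyzed dataset; when present it is
    always treated as conditioned, because the data at hand are restricted
    to selected rows.  ``risk_factors_pre`` are unmeasured pre-migration
    risk factors, ``risk_factors_measured`` their measured post-migration
    counterparts, ``confounders`` mediator-outcome confounders.  Only nodes
    in ``measured`` may enter adjustment sets.
    """

    exposure: str
    outcome: str
    selection: Optional[str] = None
    risk_factors_pre: frozenset = frozenset()
    risk_factors_measured: frozenset = frozenset()
    confounders: frozenset = frozenset()
    measured: frozenset = frozenset()

    def __post_init__(self) -> None:
        for name in ("risk_factors_pre", "risk_factors_measured", "confounders", "measured"):
            object.__setattr__(self, name, frozenset(getattr(self, name)))
        if self.exposure == self.outcome:
            raise GraphError("exposure and outcome must be distinct nodes")
        overlap = self.risk_factors_pre & self.measured
        if overlap:
            raise GraphError(
                f"pre-migration (unmeasured) risk factors cannot be measured: {sorted(overlap)}"
            )
        if self.selection is not None and self.selection in self.measured:
            raise GraphError("the selection node is conditioned by design, not adjustable")

    def validate(self, dag: CausalDAG) -> None:
        role_nodes = (
            {self.exposure, self.outcome}
            | ({self.selection} if self.selection else set())
            | self.risk_factors_pre
            | self.risk_factors_measured
            | self.confounders
            | self.measured
        )
        missing = role_nodes - dag.nodes
        if missing:
            raise GraphError(f"role nodes absent from the DAG: {sorted(missing)}")


@dataclass(frozen=True)
class Path:
    """A simple exposure--outcome walk ignoring edge direction.

    ``edge_directions`` records, per step, whether the DAG edge points along
    the node sequence (``"->"``) or against it (``"<-"``).  Interior nodes
    classify uniquely as chain, fork, or collider from the two adjacent
    directions.
    """

    node_sequence: tuple
    edge_directions: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "node_sequence", tuple(self.node_sequence))
        object.__setattr__(self, "edge_directions", tuple(self.edge_directions))
        if len(self.node_sequence) < 2:
            raise GraphError("a path needs at least two nodes")
        if len(self.edge_directions) != len(self.node_sequence) - 1:
            raise GraphError("one direction flag is required per step")
        if len(set(self.node_sequence)) != len(self.node_sequence):
            raise GraphError("paths are simple: no repeated nodes")

    @property
    def is_causal(self) -> bool:
        """True iff every edge points from the first node toward the last."""
        return all(d == FORWARD for d in self.edge_directions)

    def interior_nodes(self) -> tuple:
        return self.node_sequence[1:-1]

    def is_collider_at(self, index: int) -> bool:
        """Whether the interior node at position ``index`` is a collider."""
        if not 0 < index < len(self.node_sequence) - 1:
            raise GraphError("collider status is defined for interior nodes only")
        return self.edge_directions[index - 1] == FORWARD and self.edge_directions[index] == BACKWARD

    def __str__(self) -> str:
        parts = [self.node_sequence[0]]
        for direction, node in zip(self.edge_directions, self.node_sequence[1:]):
            parts.append(f" {direction} {node}")
        return "".join(parts)


def _as_path(dag: CausalDAG, sequence: Sequence) -> Path:
    directions = []
    for a, b in zip(sequence, sequence[1:]):
        if (a, b) in dag.edges:
            directions.append(FORWARD)
        elif (b, a) in dag.edges:
            directions.append(BACKWARD)
        else:  # pragma: no cover - enumeration only emits adjacent nodes
            raise GraphError(f"nodes {a!r} and {b!r} are not adjacent")
    return Path(tuple(sequence), tuple(directions))


def enumerate_paths(dag: CausalDAG, x: str, y: str) -> list:
    """All simple paths between ``x`` and ``y`` ignoring edge direction.

    Returned in deterministic lexicographic order of the node sequence so
    that diagnostics are reproducible run to run.
    """
    dag._require(x, y)
    if x == y:
        raise GraphError("path endpoints must be distinct")
    graph = dag._graph
    neighbours = {
        n: sorted(set(graph.successors(n)) | set(graph.predecessors(n))) for n in dag.nodes
    }
    found: list = []

    def walk(node: str, trail: tuple) -> None:
        for nxt in neighbours[node]:
            if nxt == y:
                found.append(trail + (nxt,))
            elif nxt not in trail:
                walk(nxt, trail + (nxt,))

    walk(x, (x,))
    found.sort()
    return [_as_path(dag, seq) for seq in found]


def path_open(path: Path, conditioned: Iterable, dag: CausalDAG) -> bool:
    """Open/closed status of a path under a conditioning set.

    A chain or fork node blocks the path when conditioned; a collider blocks
    it unless the collider itself or one of its descendants is conditioned.
    A single-edge path has no interior node and is always open.
    """
    conditioned = frozenset(conditioned)
    unknown = conditioned - dag.nodes
    if unknown:
        raise GraphError(f"conditioning on unknown nodes: {sorted(unknown)}")
    for i in range(1, len(path.node_sequence) - 1):
        node = path.node_sequence[i]
        if path.is_collider_at(i):
            if node not in conditioned and not (dag.descendants(node) & conditioned):
                return False
        elif node in conditioned:
            return False
    return True


def d_separated(dag: CausalDAG, x: str, y: str, conditioned: Iterable = ()) -> bool:
    """Whether ``x`` and ``y`` are d-separated given ``conditioned``.

    Open paths carry statistical association; d-separation holds iff no
    path between the two nodes is open.  Delegates to networkx's
    d-separation routine; the path-enumeration rules in this module provide
    an independent cross-check on small graphs.
    """
    dag._require(x, y)
    if x == y:
        raise GraphError("d-separation is defined for distinct nodes")
    conditioned = frozenset(conditioned)
    unknown = conditioned - dag.nodes
    if unknown:
        raise GraphError(f"conditioning on unknown nodes: {sorted(unknown)}")
    if {x, y} & conditioned:
        raise GraphError("conditioning set must not contain the endpoints")
    return nx.is_d_separator(dag._graph, {x}, {y}, set(conditioned))


class EffectType(str, Enum):
    TOTAL = "TOTAL"
    CONTROLLED_DIRECT = "CONTROLLED_DIRECT"
    BIASED = "BIASED"


@dataclass(frozen=True)
class EffectClassification:
    """Verdict for one adjustment strategy, with the path evidence.

    ``open_noncausal_paths`` are the biasing paths left open by the
    conditioning set (nonempty iff the verdict is ``BIASED``);
    ``blocked_causal_paths`` are directed exposure-to-outcome paths the
    conditioning set blocks (what turns a total effect into a controlled
    direct effect).  ``conditioning_set`` is the adjustment set plus the
    selection node when one is present.
    """

    effect_type: EffectType
    open_noncausal_paths: tuple
    blocked_causal_paths: tuple
    conditioning_set: frozenset

    def summary(self) -> str:
        lines = [f"effect type: {self.effect_type.value}"]
        lines.append(f"conditioning set: {{{', '.join(sorted(self.conditioning_set)) or ''}}}")
        if self.open_noncausal_paths:
            lines.append("open non-causal (biasing) paths:")
            lines.extend(f"  {p}" for p in self.open_noncausal_paths)
        if self.blocked_causal_paths:
            lines.append("blocked causal paths:")
            lines.extend(f"  {p}" for p in self.blocked_causal_paths)
        return "\n".join(lines)


def classify_adjusted_effect(
    dag: CausalDAG,
    roles: NodeRoles,
    adjust_set: Iterable = (),
    *,
    condition_selection: bool = True,
) -> EffectClassification:
    """Classify the estimand of an exposure coefficient under adjustment.

    The selection node, when present and ``condition_selection`` is true
    (the default: the analyzed dataset is the selected sample), is added to
    the conditioning set.  ``condition_selection=False`` expresses an
    analysis that undoes the sampling, e.g. inverse-probability-of-selection
    weighting back to the full population.

    Only measured nodes may be adjusted; the exposure, outcome, and
    selection node are rejected from adjustment sets.
    """
    roles.validate(dag)
    adjust = frozenset(adjust_set)
    unknown = adjust - dag.nodes
    if unknown:
        raise GraphError(f"adjustment set contains unknown nodes: {sorted(unknown)}")
    if roles.exposure in adjust or roles.outcome in adjust:
        raise AdjustmentError("exposure and outcome cannot appear in the adjustment set")
    if roles.selection is not None and roles.selection in adjust:
        raise AdjustmentError("the selection node is conditioned by design, not adjustable")
    unmeasured = adjust - roles.measured
    if unmeasured:
        raise AdjustmentError(f"unmeasured nodes cannot be adjusted for: {sorted(unmeasured)}")

    conditioning = adjust
    if roles.selection is not None and condition_selection:
        conditioning = conditioning | {roles.selection}

    paths = enumerate_paths(dag, roles.exposure, roles.outcome)
    open_noncausal = tuple(
        p for p in paths if not p.is_causal and path_open(p, conditioning, dag)
    )
    blocked_causal = tuple(
        p for p in paths if p.is_causal and not path_open(p, conditioning, dag)
    )
    if open_noncausal:
        effect = EffectType.BIASED
    elif blocked_causal:
        effect = EffectType.CONTROLLED_DIRECT
    else:
        effect = EffectType.TOTAL
    return EffectClassification(
        effect_type=effect,
        open_noncausal_paths=open_noncausal,
        blocked_causal_paths=blocked_causal,
        conditioning_set=frozenset(conditioning),
    )


def to_dot(dag: CausalDAG, roles: Optional[NodeRoles] = None) -> str:
    """Dot-format text export of the DAG for visualization.

    Unmeasured nodes are drawn gray, the selection node double-circled
    (mirroring the usual circled-S convention for a conditioned collider).
    """
    lines = ["digraph causal {"]
    unmeasured: frozenset = frozenset()
    selection = None
    if roles is not None:
        roles.validate(dag)
        selection = roles.selection
        adjustable = roles.measured | {roles.exposure, roles.outcome}
        unmeasured = dag.nodes - adjustable - ({selection} if selection else set())
    for node in sorted(dag.nodes):
        attrs = []
        if node in unmeasured:
            attrs.append('style=filled fillcolor="gray80"')
        if node == selection:
            attrs.append("peripheries=2")
        lines.append(f'  "{node}"' + (f" [{' '.join(attrs)}]" if attrs else "") + ";")
    for a, b in sorted(dag.edges):
        lines.append(f'  "{a}" -> "{b}";')
    lines.append("}")
    return "\n".join(lines)
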