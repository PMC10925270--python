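"""Structural graphs for prior-knowledge-constrained modeling.

A structural graph is a directed graph over three node roles:

* **input nodes** — drugs and 'omic context features; in-degree 0, out-degree >= 1
* **function nodes** — proteins and RNAs, each realized in the model as a small
  node-specific neural map; in- and out-degree >= 1 (cycles allowed)
* **output nodes** — measured readouts (one per assayed RNA); out-degree 0 and
  in-degree exactly 1, fed by the corresponding RNA function node

Edges are classed by position: edges leaving an input node are *input edges*,
edges entering an output node are *output edges* (this takes precedence over
the function class), and everything else is a *function edge*.

Node and edge orderings are deterministic — nodes sort lexicographically by
(entity_class, name), edges by (source index, target index) — so every
downstream matrix layout is reproducible from the serialized TSVs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("gsnn")

ENTITY_CLASSES = ("DRUG", "EXPR", "CNV", "MUT", "METHYL",
                  "PROTEIN", "RNA", "LINCS", "OTHER")
INPUT_CLASSES = frozenset({"DRUG", "EXPR", "CNV", "MUT", "METHYL"})
FUNCTION_CLASSES = frozenset({"PROTEIN", "RNA"})
OUTPUT_CLASSES = frozenset({"LINCS"})

ROLE_INPUT, ROLE_FUNCTION, ROLE_OUTPUT = "input", "function", "output"


class GraphValidationError(ValueError):
    """Raised when a graph violates the structural role invariants."""


@dataclass(frozen=True)
class NodeRecord:
    name: str
    role: str
    entity_class: str
    d_in: int
    d_out: int


@dataclass
class StructuralGraph:
    """Validated, deterministically ordered directed graph.

    ``node_names`` and ``entity_classes`` are parallel sequences sorted by
    (entity_class, name); ``edge_src``/``edge_dst`` hold node indices sorted
    by (source index, target index).
    """

    node_names: Tuple[str, ...]
    entity_classes: Tuple[str, ...]
    edge_src: np.ndarray
    edge_dst: np.ndarray
    _index: Dict[str, int] = field(default_factory=dict, repr=False)

    # ------------------------------------------------------------ construction
    @classmethod
    def from_lists(cls, nodes: Iterable[Tuple[str, str]],
                   edges: Iterable[Tuple[str, str]],
                   validate: bool = True,
                   strict: bool = True) -> "StructuralGraph":
        """Build from (name, entity_class) pairs and (source, target) pairs."""
        node_list = sorted(set(nodes), key=lambda t: (t[1], t[0]))
        names = tuple(n for n, _ in node_list)
        if len(set(names)) != len(names):
            dupes = sorted({n for n, c in set(nodes)
                            if sum(1 for m, _ in set(nodes) if m == n) > 1})
            raise GraphValidationError(
                f"node names declared with multiple entity classes: {dupes}")
        classes = tuple(c for _, c in node_list)
        index = {n: i for i, n in enumerate(names)}
        edge_list = list(edges)
        unknown = [e for e in edge_list if e[0] not in index or e[1] not in index]
        if unknown:
            raise GraphValidationError(
                f"edges reference unknown nodes: {sorted(set(unknown))[:10]}")
        seen: Set[Tuple[str, str]] = set()
        dup = [e for e in edge_list if e in seen or seen.add(e)]
        if dup:
            raise GraphValidationError(
                f"duplicate edges: {sorted(set(dup))[:10]}")
        pairs = sorted((index[s], index[t]) for s, t in edge_list)
        src = np.array([p[0] for p in pairs], dtype=np.int64)
        dst = np.array([p[1] for p in pairs], dtype=np.int64)
        g = cls(names, classes, src, dst, index)
        if validate:
            g.validate(strict=strict)
        return g

    def __post_init__(self):
        if not self._index:
            object.__setattr__(self, "_index",
                               {n: i for i, n in enumerate(self.node_names)})

    # ------------------------------------------------------------- basic views
    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    @property
    def n_edges(self) -> int:
        return len(self.edge_src)

    def node_index(self, name: str) -> int:
        return self._index[name]

    def in_degrees(self) -> np.ndarray:
        return np.bincount(self.edge_dst, minlength=self.n_nodes)

    def out_degrees(self) -> np.ndarray:
        return np.bincount(self.edge_src, minlength=self.n_nodes)

    def roles(self) -> np.ndarray:
        """Node roles derived from entity class (OTHER falls back to degrees)."""
        d_in, d_out = self.in_degrees(), self.out_degrees()
        out = np.empty(self.n_nodes, dtype=object)
        for i, cls_ in enumerate(self.entity_classes):
            if cls_ in INPUT_CLASSES:
                out[i] = ROLE_INPUT
            elif cls_ in FUNCTION_CLASSES:
                out[i] = ROLE_FUNCTION
            elif cls_ in OUTPUT_CLASSES:
                out[i] = ROLE_OUTPUT
            else:  # OTHER: infer from degrees
                if d_in[i] == 0:
                    out[i] = ROLE_INPUT
                elif d_out[i] == 0:
                    out[i] = ROLE_OUTPUT
                else:
                    out[i] = ROLE_FUNCTION
        return out

    def node_records(self) -> List[NodeRecord]:
        d_in, d_out, roles = self.in_degrees(), self.out_degrees(), self.roles()
        return [NodeRecord(n, roles[i], self.entity_classes[i],
                           int(d_in[i]), int(d_out[i]))
                for i, n in enumerate(self.node_names)]

    def nodes_with_role(self, role: str) -> np.ndarray:
        return np.flatnonzero(self.roles() == role)

    @property
    def input_nodes(self) -> List[str]:
        return [self.node_names[i] for i in self.nodes_with_role(ROLE_INPUT)]

    @property
    def function_nodes(self) -> List[str]:
        return [self.node_names[i] for i in self.nodes_with_role(ROLE_FUNCTION)]

    @property
    def output_nodes(self) -> List[str]:
        return [self.node_names[i] for i in self.nodes_with_role(ROLE_OUTPUT)]

    # -------------------------------------------------------------- validation
    def validate(self, strict: bool = True) -> "StructuralGraph":
        """Check role invariants.

        With ``strict=False``, function nodes may have zero in- or out-degree
        (they become inert); randomized control graphs legitimately produce
        such nodes because endpoint resampling does not preserve degrees.
        """
        d_in, d_out, roles = self.in_degrees(), self.out_degrees(), self.roles()
        problems = []
        for i, name in enumerate(self.node_names):
            role = roles[i]
            if role == ROLE_INPUT and not (d_in[i] == 0 and d_out[i] >= 1):
                problems.append(f"input node {name!r}: D_in={d_in[i]}, D_out={d_out[i]}")
            elif role == ROLE_OUTPUT and not (d_out[i] == 0 and d_in[i] == 1):
                problems.append(f"output node {name!r}: D_in={d_in[i]}, D_out={d_out[i]}")
            elif (strict and role == ROLE_FUNCTION
                  and not (d_in[i] >= 1 and d_out[i] >= 1)):
                problems.append(f"function node {name!r}: D_in={d_in[i]}, D_out={d_out[i]}")
        # output nodes are fed by a function node, never directly by an input
        role_of = dict(zip(range(self.n_nodes), roles))
        for s, t in zip(self.edge_src, self.edge_dst):
            if role_of[int(t)] == ROLE_OUTPUT and role_of[int(s)] != ROLE_FUNCTION:
                problems.append(
                    f"output node {self.node_names[t]!r} fed by non-function "
                    f"node {self.node_names[s]!r}")
        if problems:
            raise GraphValidationError("invalid structural graph: "
                                       + "; ".join(problems[:20]))
        return self

    # ------------------------------------------------------------ edge classes
    def edge_classes(self) -> np.ndarray:
        """Per-edge class label: input_edge / function_edge / output_edge.

        Output classification takes precedence over the function class.
        """
        roles = self.roles()
        out = np.empty(self.n_edges, dtype=object)
        for k in range(self.n_edges):
            if roles[self.edge_src[k]] == ROLE_INPUT:
                out[k] = "input_edge"
            elif roles[self.edge_dst[k]] == ROLE_OUTPUT:
                out[k] = "output_edge"
            else:
                out[k] = "function_edge"
        return out

    # ------------------------------------------------------------ reachability
    def to_networkx(self) -> nx.DiGraph:
        dg = nx.DiGraph()
        dg.add_nodes_from(self.node_names)
        dg.add_edges_from((self.node_names[s], self.node_names[t])
                          for s, t in zip(self.edge_src, self.edge_dst))
        return dg

    def descendants(self, sources: Iterable[str]) -> Set[str]:
        """All nodes reachable by directed paths of length >= 1 from `sources`."""
        sources = set(sources)
        unknown = sources - set(self.node_names)
        if unknown:
            raise KeyError(f"unknown source nodes: {sorted(unknown)}")
        dg = self.to_networkx()
        out: Set[str] = set()
        for s in sources:
            d = nx.descendants(dg, s)
            # a source on a cycle reaches itself by a path of length >= 1
            if any(p == s or p in d for p in dg.predecessors(s)):
                d.add(s)
            out |= d
        return out

    # --------------------------------------------------------------------- I/O
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"name": self.node_names,
                      "entity_class": self.entity_classes}
                     ).to_csv(directory / "nodes.tsv", sep="\t", index=False)
        pd.DataFrame({"source": [self.node_names[s] for s in self.edge_src],
                      "target": [self.node_names[t] for t in self.edge_dst]}
                     ).to_csv(directory / "edges.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, directory) -> "StructuralGraph":
        directory = Path(directory)
        return load_graph(directory / "edges.tsv", directory / "nodes.tsv")


def load_graph(edge_table_path, node_table_path) -> StructuralGraph:
    """Load and validate a structural graph from node/edge TSV tables."""
    nodes = pd.read_csv(node_table_path, sep="\t", dtype=str)
    edges = pd.read_csv(edge_table_path, sep="\t", dtype=str)
    for col in ("name", "entity_class"):
        if col not in nodes.columns:
            raise ValueError(f"node table missing column {col!r}")
    for col in ("source", "target"):
        if col not in edges.columns:
            raise ValueError(f"edge table missing column {col!r}")
    return StructuralGraph.from_lists(
        list(zip(nodes["name"], nodes["entity_class"])),
        list(zip(edges["source"], edges["target"])))


def classify_edges(g: StructuralGraph) -> Dict[str, np.ndarray]:
    """Partition edge indices into input / function / output classes."""
    labels = g.edge_classes()
    return {"input_edges": np.flatnonzero(labels == "input_edge"),
            "function_edges": np.flatnonzero(labels == "function_edge"),
            "output_edges": np.flatnonzero(labels == "output_edge")}


def descendants(g: StructuralGraph, sources: Iterable[str]) -> Set[str]:
    return g.descendants(sources)


def add_self_edges(g: StructuralGraph) -> StructuralGraph:
    """Add a (n, n) function edge to every function node; idempotent."""
    existing = set(zip(g.edge_src.tolist(), g.edge_dst.tolist()))
    new_edges = [(g.node_names[int(s)], g.node_names[int(t)])
                 for s, t in existing]
    for i in g.nodes_with_role(ROLE_FUNCTION):
        if (int(i), int(i)) not in existing:
            new_edges.append((g.node_names[i], g.node_names[i]))
    return StructuralGraph.from_lists(
        list(zip(g.node_names, g.entity_classes)), new_edges)
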