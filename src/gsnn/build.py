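"""Pathway-focused biological subgraph construction and randomized controls.

Raw interaction tables (drug→protein targets, protein→protein signaling,
transcription-factor regulation, miRNA regulation, translation) are reduced to
a pathway-centred structural graph in a fixed sequence of steps: define the
protein-space from the requested pathways, expand an rna-space through
regulatory chains, admit drugs with at least one retained target, intersect
with the assay's measurable genes to define the outputs, prune drugs that can
reach too few outputs, prune function nodes with no downstream output, and
finally attach 'omic context inputs.

Node names are prefixed by entity class (``DRUG_x``, ``PROTEIN_p``, ``RNA_r``,
``LINCS_r``, ``EXPR_p`` ...), so a protein and its transcript coexist as
distinct function nodes.

``randomize_graph`` produces the degree-destroying control used to test
whether predictive skill derives from the curated wiring: per-class edge
counts are conserved exactly while endpoints are resampled uniformly among
function nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .graph import (ROLE_FUNCTION, ROLE_INPUT, ROLE_OUTPUT, GraphValidationError,
                    StructuralGraph, classify_edges)

logger = logging.getLogger("gsnn")

RESOURCE_NAMES = ("drug_target", "ppi", "tf_regulation",
                  "mirna_regulation", "translation")
OMIC_CLASSES = ("EXPR", "CNV", "MUT", "METHYL")


def _pairs(df: pd.DataFrame) -> Set[Tuple[str, str]]:
    return set(zip(df["source"], df["target"]))


@dataclass
class InteractionTables:
    """Curated molecular interaction resources, one (source, target) table each.

    drug_target: drug → protein; ppi: protein → protein; tf_regulation:
    protein → rna; mirna_regulation: rna → rna; translation: rna → protein.
    pathway_membership has columns (pathway, protein); available_omics has
    columns (omic_class, entity).
    """

    drug_target: pd.DataFrame
    ppi: pd.DataFrame
    tf_regulation: pd.DataFrame
    mirna_regulation: pd.DataFrame
    translation: pd.DataFrame
    pathway_membership: pd.DataFrame
    available_lincs: Set[str]
    available_omics: pd.DataFrame

    def validate(self) -> "InteractionTables":
        for name in RESOURCE_NAMES:
            df = getattr(self, name)
            if not {"source", "target"} <= set(df.columns):
                raise ValueError(f"table {name!r} needs source/target columns")
            if df[["source", "target"]].isin(["", None]).any().any():
                raise ValueError(f"table {name!r} has empty identifiers")
            if df.duplicated(["source", "target"]).any():
                raise ValueError(f"table {name!r} has duplicate rows")
        return self

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in RESOURCE_NAMES:
            getattr(self, name).to_csv(directory / f"{name}.tsv",
                                       sep="\t", index=False)
        self.pathway_membership.to_csv(directory / "pathway_membership.tsv",
                                       sep="\t", index=False)
        pd.DataFrame({"rna": sorted(self.available_lincs)}).to_csv(
            directory / "available_lincs.tsv", sep="\t", index=False)
        self.available_omics.to_csv(directory / "available_omics.tsv",
                                    sep="\t", index=False)

    @classmethod
    def load(cls, directory) -> "InteractionTables":
        directory = Path(directory)
        kw = {name: pd.read_csv(directory / f"{name}.tsv", sep="\t", dtype=str)
              for name in RESOURCE_NAMES}
        return cls(
            pathway_membership=pd.read_csv(
                directory / "pathway_membership.tsv", sep="\t", dtype=str),
            available_lincs=set(pd.read_csv(
                directory / "available_lincs.tsv", sep="\t", dtype=str)["rna"]),
            available_omics=pd.read_csv(
                directory / "available_omics.tsv", sep="\t", dtype=str),
            **kw).validate()


@dataclass
class BuilderParams:
    pathways: Set[str] = field(default_factory=set)
    rna_descendant_depth: int = 1
    drug_prune_fraction: float = 0.25
    resources: Sequence[str] = RESOURCE_NAMES

    def __post_init__(self):
        if not 0.0 <= self.drug_prune_fraction <= 1.0:
            raise ValueError("drug_prune_fraction must be in [0, 1]")
        if self.rna_descendant_depth < 0:
            raise ValueError("rna_descendant_depth must be >= 0")


def _rna_space(tables: InteractionTables, protein_space: Set[str],
               depth: int) -> Set[str]:
    """RNAs reachable from the protein-space through <= `depth` regulatory edges.

    Traverses tf_regulation (protein→rna), mirna_regulation (rna→rna) and
    translation (rna→protein) chains; depth counts edges, so direct
    transcription-factor targets appear at depth 1.
    """
    tf = _pairs(tables.tf_regulation)
    mir = _pairs(tables.mirna_regulation)
    tra = _pairs(tables.translation)
    frontier_p, frontier_r = set(protein_space), set()
    rnas: Set[str] = set()
    for _ in range(depth):
        next_r = ({t for s, t in tf if s in frontier_p}
                  | {t for s, t in mir if s in frontier_r})
        next_p = {t for s, t in tra if s in frontier_r}
        new_r = next_r - rnas
        rnas |= new_r
        frontier_r, frontier_p = new_r, next_p
        if not frontier_r and not frontier_p:
            break
    return rnas


def build_subgraph(tables: InteractionTables,
                   params: BuilderParams) -> StructuralGraph:
    """Construct a pathway-focused structural graph from interaction tables."""
    tables.validate()
    if not params.pathways:
        raise ValueError("at least one pathway must be requested")

    # (1) protein-space: union of proteins in any requested pathway
    pm = tables.pathway_membership
    protein_space = set(pm.loc[pm["pathway"].isin(params.pathways), "protein"])
    if not protein_space:
        raise ValueError("no proteins match pathways "
                         f"{sorted(params.pathways)}")

    # (2) rna-space via regulator chains
    rna_space = _rna_space(tables, protein_space, params.rna_descendant_depth)

    # (3) drug-space: drugs with >= 1 target in the protein-space
    dt = _pairs(tables.drug_target)
    drug_space = {d for d, p in dt if p in protein_space}

    # (4) measurable outputs
    lincs_space = rna_space & set(tables.available_lincs)

    # (5) edges whose endpoints both survive, from the enabled resources
    endpoint_spaces = {
        "drug_target": (drug_space, protein_space),
        "ppi": (protein_space, protein_space),
        "tf_regulation": (protein_space, rna_space),
        "mirna_regulation": (rna_space, rna_space),
        "translation": (rna_space, protein_space),
    }
    prefix = {"drug_target": ("DRUG_", "PROTEIN_"),
              "ppi": ("PROTEIN_", "PROTEIN_"),
              "tf_regulation": ("PROTEIN_", "RNA_"),
              "mirna_regulation": ("RNA_", "RNA_"),
              "translation": ("RNA_", "PROTEIN_")}
    edges: Set[Tuple[str, str]] = set()
    for name in params.resources:
        src_space, dst_space = endpoint_spaces[name]
        p_src, p_dst = prefix[name]
        for s, t in _pairs(getattr(tables, name)):
            if s in src_space and t in dst_space:
                edges.add((p_src + s, p_dst + t))

    # (6) one output node per measurable RNA
    for r in lincs_space:
        edges.add((f"RNA_{r}", f"LINCS_{r}"))

    node_class: Dict[str, str] = {}
    for d in drug_space:
        node_class[f"DRUG_{d}"] = "DRUG"
    for p in protein_space:
        node_class[f"PROTEIN_{p}"] = "PROTEIN"
    for r in rna_space:
        node_class[f"RNA_{r}"] = "RNA"
    for r in lincs_space:
        node_class[f"LINCS_{r}"] = "LINCS"

    # (7)+(8) pruning on the pre-omics graph
    nodes, edges = _prune(node_class, edges, params.drug_prune_fraction,
                          cleanup=False)
    # (9) attach 'omic context inputs, then a final validity cleanup:
    # function nodes that received neither a regulator, a drug, nor an 'omic
    # input cannot compute anything and are dropped (with their cascade)
    nodes, edges = _attach_omics_sets(nodes, edges, tables)
    nodes, edges = _prune(nodes, edges, params.drug_prune_fraction,
                          cleanup=True)
    return StructuralGraph.from_lists(sorted(nodes.items()), sorted(edges))


def _prune(node_class: Dict[str, str], edges: Set[Tuple[str, str]],
           prune_fraction: float, cleanup: bool
           ) -> Tuple[Dict[str, str], Set[Tuple[str, str]]]:
    """Steps 7-8 (and, with ``cleanup``, validity cleanup), to a fixpoint.

    Removes drugs covering too few outputs and function nodes with no
    downstream output; the cleanup pass additionally removes function nodes
    left without any input, and stranded inputs/outputs.
    """
    import networkx as nx

    nodes = dict(node_class)
    edges = set(edges)
    changed = True
    while changed:
        changed = False
        edges = {(s, t) for s, t in edges if s in nodes and t in nodes}
        dg = nx.DiGraph()
        dg.add_nodes_from(nodes)
        dg.add_edges_from(edges)
        lincs = {n for n, c in nodes.items() if c == "LINCS"}
        if not lincs:
            raise ValueError("zero surviving LINCS outputs")
        # (7) drug pruning by output coverage
        for n, c in list(nodes.items()):
            if c == "DRUG":
                cover = len(nx.descendants(dg, n) & lincs)
                if cover < prune_fraction * len(lincs):
                    del nodes[n]
                    changed = True
        if changed:
            continue
        # (8) function nodes with no downstream output
        for n, c in list(nodes.items()):
            if c in ("PROTEIN", "RNA") and not nx.descendants(dg, n) & lincs:
                del nodes[n]
                changed = True
        if changed or not cleanup:
            continue
        # validity cleanup: function nodes without inputs, stranded terminals
        indeg, outdeg = dict(dg.in_degree()), dict(dg.out_degree())
        for n, c in list(nodes.items()):
            if c in ("PROTEIN", "RNA") and indeg.get(n, 0) == 0:
                del nodes[n]
                changed = True
            elif c == "LINCS" and indeg.get(n, 0) == 0:
                del nodes[n]
                changed = True
            elif c in ("DRUG",) + OMIC_CLASSES and outdeg.get(n, 0) == 0:
                del nodes[n]
                changed = True
    if not any(c == "DRUG" for c in nodes.values()):
        raise ValueError("zero drugs survive pruning")
    return nodes, edges


def _attach_omics_sets(nodes: Dict[str, str], edges: Set[Tuple[str, str]],
                       tables: InteractionTables
                       ) -> Tuple[Dict[str, str], Set[Tuple[str, str]]]:
    nodes = dict(nodes)
    edges = set(edges)
    for _, row in tables.available_omics.iterrows():
        omic, entity = row["omic_class"], row["entity"]
        targets = [n for n in (f"PROTEIN_{entity}", f"RNA_{entity}")
                   if n in nodes]
        if not targets:
            logger.info("skipping omic %s_%s: entity not in graph",
                        omic, entity)
            continue
        name = f"{omic}_{entity}"
        nodes[name] = omic
        edges.update((name, t) for t in targets)
    return nodes, edges


def attach_omics(g: StructuralGraph,
                 tables: InteractionTables) -> StructuralGraph:
    """Add 'omic context input nodes for retained entities.

    For each available (omic_class, entity) whose entity survives in the
    graph, adds an input node ``{omic_class}_{entity}`` with an edge to every
    matching function node present (e.g. expression reaches both the protein
    and the RNA node when both exist). Omics for pruned entities are skipped
    with a log line.
    """
    nodes = dict(zip(g.node_names, g.entity_classes))
    edges = {(g.node_names[int(s)], g.node_names[int(t)])
             for s, t in zip(g.edge_src, g.edge_dst)}
    nodes, edges = _attach_omics_sets(nodes, edges, tables)
    # strict=False: entities awaiting the final cleanup may still lack inputs
    return StructuralGraph.from_lists(sorted(nodes.items()), sorted(edges),
                                      strict=False)


def randomize_graph(g: StructuralGraph, seed: int,
                    max_rounds: int = 1000) -> StructuralGraph:
    """Resample edge endpoints per class, conserving per-class edge counts.

    Input edges keep their source and draw a new function-node destination;
    output edges keep their destination and draw a new function-node source;
    function edges draw both endpoints. Duplicates are resampled until the
    edge set is unique; self-loops are resampled away unless the original
    graph contained self-edges.
    """
    rng = np.random.default_rng(seed)
    classes = classify_edges(g)
    func_idx = g.nodes_with_role(ROLE_FUNCTION)
    if len(func_idx) == 0:
        raise ValueError("graph has no function nodes to randomize over")
    allow_self = bool(np.any(g.edge_src == g.edge_dst))

    src = g.edge_src.copy()
    dst = g.edge_dst.copy()
    k_in, k_fn = classes["input_edges"], classes["function_edges"]
    dst[k_in] = rng.choice(func_idx, size=len(k_in))
    src[classes["output_edges"]] = rng.choice(
        func_idx, size=len(classes["output_edges"]))
    src[k_fn] = rng.choice(func_idx, size=len(k_fn))
    dst[k_fn] = rng.choice(func_idx, size=len(k_fn))

    resamplable = np.concatenate([k_in, k_fn, classes["output_edges"]])
    for _ in range(max_rounds):
        pairs = src * g.n_nodes + dst
        _, first = np.unique(pairs, return_index=True)
        bad = np.ones(g.n_edges, dtype=bool)
        bad[first] = False
        if not allow_self:
            bad |= (src == dst)
        bad &= np.isin(np.arange(g.n_edges), resamplable)
        if not bad.any():
            break
        for k in np.flatnonzero(bad):
            if k in k_in:
                dst[k] = rng.choice(func_idx)
            elif k in classes["output_edges"]:
                src[k] = rng.choice(func_idx)
            else:
                src[k] = rng.choice(func_idx)
                dst[k] = rng.choice(func_idx)
    else:
        raise ValueError("could not realize a duplicate-free randomization "
                         f"in {max_rounds} rounds; graph too small")
    return StructuralGraph.from_lists(
        list(zip(g.node_names, g.entity_classes)),
        [(g.node_names[int(s)], g.node_names[int(t)])
         for s, t in zip(src, dst)],
        strict=False)
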