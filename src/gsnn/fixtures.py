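"""Deterministic synthetic data generators.

Everything the other modules consume can be generated here from a seed: toy
molecular interaction tables with pathway labels, ground-truth structural
graphs, perturbation responses simulated by propagating encoded inputs
through a known graph with random smooth node functions plus Gaussian output
noise, planted-path explanation instances, and viability/indication tables
with a planted selectively-cytotoxic drug.

The simulator gives every function node the map
``s_n = tanh(sum_m w_nm * s_m)`` over its in-neighbors, with fixed random
weights; cellular context enters through 'omic input nodes whose values are
cell-line-specific, so the same drug produces cell-dependent responses.
States are updated synchronously for a fixed number of steps (cycles are
unrolled rather than solved), and measured outputs are the states of the
assayed RNA nodes plus noise. This emulates the *shape* of perturbation data
— graded dose response, cell-context modulation, pathway-local propagation —
not the noise structure or topology of any real assay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .build import BuilderParams, InteractionTables, build_subgraph
from .data import Observation, transform_dose
from .graph import ROLE_FUNCTION, ROLE_INPUT, ROLE_OUTPUT, StructuralGraph

OMIC_INPUT_CLASSES = ("EXPR", "CNV", "MUT", "METHYL")


@dataclass
class FixtureSpec:
    n_drugs: int = 6
    n_proteins: int = 14
    n_rnas: int = 10
    n_lincs: int = 6
    n_cell_lines: int = 8
    density: float = 0.35
    noise_sd: float = 0.1
    seed: int = 0
    doses: Tuple[float, ...] = (0.1, 1.0)
    planted_selective_drug: bool = False
    unroll_steps: int = 10
    drug_weight_scale: float = 1.0   # gain on drug-sourced edge weights
    omics_weight_scale: float = 1.0  # gain on 'omic-sourced edge weights

    def __post_init__(self):
        if min(self.n_drugs, self.n_proteins, self.n_rnas, self.n_lincs,
               self.n_cell_lines) < 1:
            raise ValueError("all sizes must be >= 1")
        if not 0 < self.density <= 1:
            raise ValueError("density must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


#: larger, sparser preset used for the true-vs-random prior-knowledge harness
BENCH_SPEC = FixtureSpec(n_drugs=10, n_proteins=30, n_rnas=20, n_lincs=14,
                         n_cell_lines=20, density=0.15, noise_sd=0.1,
                         doses=(0.1, 1.0, 10.0))


def preset_spec(name: str, seed: int = 0) -> FixtureSpec:
    presets = {
        "smoke": FixtureSpec(),
        "bench": BENCH_SPEC,
        "viability": replace(FixtureSpec(), planted_selective_drug=True,
                             n_cell_lines=15, n_lincs=8, n_rnas=12),
    }
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}")
    return replace(presets[name], seed=seed)


# ------------------------------------------------------------------- tables
def generate_interaction_tables(spec: FixtureSpec) -> InteractionTables:
    """Random toy interaction tables with two pathway labels.

    Guarantees that at least one drug can reach >= 25% of the measurable
    genes, so default builder pruning keeps at least one drug.
    """
    rng = np.random.default_rng(spec.seed)
    drugs = [f"d{i:02d}" for i in range(spec.n_drugs)]
    prots = [f"p{i:02d}" for i in range(spec.n_proteins)]
    rnas = [f"r{i:02d}" for i in range(spec.n_rnas)]

    def sample_pairs(src, dst, p, no_self=True):
        out = []
        for s in src:
            for t in dst:
                if no_self and s == t:
                    continue
                if rng.random() < p:
                    out.append((s, t))
        return out

    drug_target = sample_pairs(drugs, prots, spec.density)
    for i, d in enumerate(drugs):       # every drug has >= 1 target
        if not any(s == d for s, _ in drug_target):
            drug_target.append((d, prots[i % len(prots)]))
    ppi = sample_pairs(prots, prots, spec.density / 2)
    tf = sample_pairs(prots, rnas, spec.density)
    for r in rnas:                      # every RNA has >= 1 regulator
        if not any(t == r for _, t in tf):
            tf.append((prots[rng.integers(len(prots))], r))
    mirna = sample_pairs(rnas, rnas, spec.density / 4)
    translation = sample_pairs(rnas, prots, spec.density / 4)

    pathway = ([("P1", p) for p in prots[: (spec.n_proteins * 2) // 3]]
               + [("P2", p) for p in prots[spec.n_proteins // 3:]])
    lincs = set(rnas[: spec.n_lincs])
    omics = [("EXPR", e) for e in prots + rnas]

    # coverage guarantee: drug d00 targets enough hub proteins
    need = math.ceil(0.25 * spec.n_lincs)
    hubs = sorted({s for s, _ in tf})[:max(3, need)]
    for h in hubs:
        if (drugs[0], h) not in drug_target:
            drug_target.append((drugs[0], h))

    def df(pairs):
        return (pd.DataFrame(sorted(set(pairs)), columns=["source", "target"])
                if pairs else pd.DataFrame(columns=["source", "target"]))

    return InteractionTables(
        drug_target=df(drug_target), ppi=df(ppi), tf_regulation=df(tf),
        mirna_regulation=df(mirna), translation=df(translation),
        pathway_membership=pd.DataFrame(sorted(set(pathway)),
                                        columns=["pathway", "protein"]),
        available_lincs=lincs,
        available_omics=pd.DataFrame(sorted(set(omics)),
                                     columns=["omic_class", "entity"]),
    ).validate()


def generate_graph(spec: FixtureSpec,
                   params: Optional[BuilderParams] = None) -> StructuralGraph:
    """Interaction tables -> built structural graph, in one step."""
    tables = generate_interaction_tables(spec)
    params = params or BuilderParams(pathways={"P1", "P2"})
    return build_subgraph(tables, params)


# ---------------------------------------------------------------- simulation
@dataclass
class SimulatedData:
    graph: StructuralGraph
    obs_table: pd.DataFrame          # obs_id, drug, conc_uM, cell_line
    omics_by_cell: pd.DataFrame      # cell_line x omic node (standardized)
    targets: pd.DataFrame            # obs_id x output node
    cell_lines: List[str]
    target_lines: List[str]          # designated lines for the planted drug
    planted_drug: Optional[str]
    spec: FixtureSpec
    _sim: "GroundTruthSimulator" = None

    def observations(self) -> List[Observation]:
        from .data import observations_from_tables
        return observations_from_tables(self.obs_table, self.omics_by_cell,
                                        self.targets)

    def noiseless_response(self, cell_line: str,
                           doses: Optional[Dict[str, float]] = None
                           ) -> np.ndarray:
        return self._sim.respond(cell_line, doses or {})


class GroundTruthSimulator:
    """Fixed random node functions over a known graph."""

    def __init__(self, g: StructuralGraph, spec: FixtureSpec,
                 rng: np.random.Generator):
        self.g = g
        self.spec = spec
        roles = g.roles()
        self.func_idx = np.flatnonzero(roles == ROLE_FUNCTION)
        self.input_idx = np.flatnonzero(roles == ROLE_INPUT)
        self.output_idx = np.flatnonzero(roles == ROLE_OUTPUT)
        self.input_names = [g.node_names[i] for i in self.input_idx]
        # edge weights: magnitude near 1 so signal survives several hops
        self.edge_w = (rng.uniform(0.7, 1.3, size=g.n_edges)
                       * rng.choice([-1.0, 1.0], size=g.n_edges))
        src_cls = np.array([g.entity_classes[int(s)] for s in g.edge_src])
        self.edge_w[src_cls == "DRUG"] *= spec.drug_weight_scale
        self.edge_w[np.isin(src_cls, OMIC_INPUT_CLASSES)] *= spec.omics_weight_scale
        self.in_edges = {int(n): np.flatnonzero(g.edge_dst == n)
                         for n in self.func_idx}
        self.out_src = g.edge_src[np.array(
            [np.flatnonzero(g.edge_dst == o)[0] for o in self.output_idx])]
        self.omics_by_cell: Dict[str, Dict[str, float]] = {}
        self.gate: Dict[Tuple[str, str], float] = {}  # (drug node, cell) -> gain

    def respond(self, cell_line: str, drug_doses: Dict[str, float]
                ) -> np.ndarray:
        g = self.g
        state = np.zeros(g.n_nodes)
        omics = self.omics_by_cell[cell_line]
        for name, val in omics.items():
            state[g.node_index(name)] = val
        for drug, conc in drug_doses.items():
            state[g.node_index(drug)] = (transform_dose(conc)
                                         * self.gate.get((drug, cell_line), 1.0))
        for _ in range(self.spec.unroll_steps):
            new = state.copy()
            for n in self.func_idx:
                e = self.in_edges[int(n)]
                new[n] = math.tanh(float(
                    (self.edge_w[e] * state[g.edge_src[e]]).sum()))
            state = new
        return state[self.out_src]


def simulate_responses(g: StructuralGraph, spec: FixtureSpec) -> SimulatedData:
    """Simulate perturbation responses for every (drug, cell, dose) triple.

    Emits one unperturbed (zero-dose) observation per cell line in addition
    to the dosed observations. With ``planted_selective_drug``, the first
    drug's stimulus is gated to zero outside the designated target lines
    (the first third of cell lines), producing a selective response.
    """
    rng = np.random.default_rng(spec.seed + 17)
    sim = GroundTruthSimulator(g, spec, rng)
    roles = g.roles()
    drug_nodes = sorted(g.node_names[i] for i in sim.input_idx
                        if g.entity_classes[i] == "DRUG")
    omic_nodes = sorted(g.node_names[i] for i in sim.input_idx
                        if g.entity_classes[i] in OMIC_INPUT_CLASSES)
    cells = [f"cell{i:02d}" for i in range(spec.n_cell_lines)]
    n_target = max(1, spec.n_cell_lines // 3)
    target_lines = cells[:n_target]

    raw = rng.normal(size=(len(cells), len(omic_nodes)))
    raw = (raw - raw.mean(axis=0)) / np.maximum(raw.std(axis=0), 1e-12)
    omics_by_cell = pd.DataFrame(raw, index=pd.Index(cells, name="cell_line"),
                                 columns=omic_nodes)
    for c in cells:
        sim.omics_by_cell[c] = omics_by_cell.loc[c].to_dict()

    planted = drug_nodes[0] if (spec.planted_selective_drug and drug_nodes) else None
    if planted is not None:
        # amplified stimulus in target lines, none elsewhere
        for c in cells:
            sim.gate[(planted, c)] = 2.0 if c in target_lines else 0.0

    out_names = [g.node_names[i] for i in sim.output_idx]
    rows, targets = [], []
    obs_id = 0
    for c in cells:
        rows.append({"obs_id": f"obs{obs_id:05d}", "drug": "",
                     "conc_uM": 0.0, "cell_line": c})
        targets.append(sim.respond(c, {}))
        obs_id += 1
        for d in drug_nodes:
            for dose in spec.doses:
                rows.append({"obs_id": f"obs{obs_id:05d}", "drug": d,
                             "conc_uM": dose, "cell_line": c})
                targets.append(sim.respond(c, {d: dose}))
                obs_id += 1
    noise = rng.normal(0, spec.noise_sd, size=(len(targets), len(out_names)))
    tgt = pd.DataFrame(np.asarray(targets) + noise,
                       index=pd.Index([r["obs_id"] for r in rows],
                                      name="obs_id"),
                       columns=out_names)
    return SimulatedData(graph=g, obs_table=pd.DataFrame(rows),
                         omics_by_cell=omics_by_cell, targets=tgt,
                         cell_lines=cells, target_lines=target_lines,
                         planted_drug=planted, spec=spec, _sim=sim)


# --------------------------------------------------------------- planted path
def planted_path_instance(seed: int, path_len: int = 3,
                          n_cell_lines: int = 12
                          ) -> Tuple[StructuralGraph, SimulatedData, np.ndarray]:
    """Graph where exactly one drug->...->output path carries the drug effect.

    The planted path is DRUG -> protein chain (``path_len`` function-node
    hops) -> RNA -> output. A disjoint decoy chain driven only by 'omic
    context carries no drug signal. Every function node also receives an
    'omic input, so cell context modulates both chains. Returns the graph,
    simulated data, and the planted path's edge indices (input edge through
    output edge).
    """
    if not 2 <= path_len <= 6:
        raise ValueError("path_len must be in 2..6")
    nodes = [("DRUG_dx", "DRUG")]
    edges = []
    chain = [f"PROTEIN_pp{i}" for i in range(path_len - 1)] + ["RNA_rp"]
    nodes += [(n, n.split("_")[0]) for n in chain]
    nodes += [("LINCS_rp", "LINCS")]
    path = [("DRUG_dx", chain[0])]
    path += list(zip(chain[:-1], chain[1:]))
    path += [("RNA_rp", "LINCS_rp")]
    edges += path
    # decoy chain, disjoint from the drug
    decoy = ["PROTEIN_qq0", "PROTEIN_qq1", "RNA_rq"]
    nodes += [(n, n.split("_")[0]) for n in decoy] + [("LINCS_rq", "LINCS")]
    edges += list(zip(decoy[:-1], decoy[1:])) + [("RNA_rq", "LINCS_rq")]
    # 'omic context into every function node
    for n, cls in list(nodes):
        if cls in ("PROTEIN", "RNA"):
            entity = n.split("_", 1)[1]
            nodes.append((f"EXPR_{entity}", "EXPR"))
            edges.append((f"EXPR_{entity}", n))
    g = StructuralGraph.from_lists(nodes, edges)
    spec = FixtureSpec(n_drugs=1, n_proteins=path_len + 1, n_rnas=2,
                       n_lincs=2, n_cell_lines=n_cell_lines, seed=seed,
                       noise_sd=0.02, doses=(0.5, 2.0),
                       unroll_steps=max(10, path_len + 2),
                       drug_weight_scale=2.0, omics_weight_scale=0.5)
    sim = simulate_responses(g, spec)
    pair_set = {p: k for k, p in enumerate(
        zip([g.node_names[int(s)] for s in g.edge_src],
            [g.node_names[int(t)] for t in g.edge_dst]))}
    planted_ids = np.array(sorted(pair_set[p] for p in path), dtype=np.int64)
    return g, sim, planted_ids


def true_vs_random_run(g: StructuralGraph, observations, seed: int,
                       channels: int = 3, layers: int = 4,
                       epochs: int = 30) -> Dict[str, float]:
    """Test mean-Pearson of hyperparameter-matched models on the true graph
    versus a randomized control graph, for one data split / seed."""
    from .build import randomize_graph
    from .data import encode_dataset, mccv_split, split_observations
    from .evaluate import mean_pearson
    from .model import GSNN, GsnnConfig

    pairs = {(o.meta["drugs"][0] if o.meta["drugs"] else "",
              o.meta["cell_line"]) for o in observations}
    split = mccv_split(pairs, seed=seed)
    parts = split_observations(observations, split)
    Xtr, Ytr = encode_dataset(parts["train"], g)
    Xv, Yv = encode_dataset(parts["val"], g)
    Xte, Yte = encode_dataset(parts["test"], g)
    scores = {}
    for name, graph in (("true", g), ("random", randomize_graph(g, seed + 100))):
        model = GSNN(graph, GsnnConfig(channels=channels, layers=layers,
                                       seed=seed))
        model.fit(Xtr, Ytr, Xv, Yv, epochs=epochs, lr=1e-2, batch_size=32,
                  patience=10)
        scores[name] = mean_pearson(model.predict(Xte), Yte).mean_pearson
    return scores


def planted_prioritization_run(seed: int, n_mc: int = 500,
                               ensemble_size: int = 5):
    """Full pipeline on the planted-selective-drug preset for one seed.

    Generates the fixture, trains a GSNN on the simulated responses, trains
    the Beta viability ensemble on the generated viability table over the
    frozen model's predicted expression, and ranks all drugs by p_sens at a
    1 uM dose with the planted target/background line split. Returns
    (ranking, planted drug name).
    """
    from .data import ObservationEncoder, encode_dataset
    from .model import GSNN, GsnnConfig
    from .viability import PrioritizationSpec, rank_drugs, train_viability_head

    spec = preset_spec("viability", seed=seed)
    g = generate_graph(spec)
    sim = simulate_responses(g, spec)
    X, Y = encode_dataset(sim.observations(), g)
    model = GSNN(g, GsnnConfig(channels=4, layers=4, seed=seed))
    model.fit(X, Y, epochs=60, lr=1e-2, batch_size=32)
    viability, _ = generate_viability(spec, sim)
    encoder = ObservationEncoder(g, sim.omics_by_cell)
    feats = np.stack([
        model.predict(encoder.encode(row["cell_line"],
                                     {row["drug"]: row["conc_uM"]}))[0]
        for _, row in viability.iterrows()])
    ensemble = train_viability_head(feats, viability["viability"].to_numpy(),
                                    ensemble_size=ensemble_size, epochs=150,
                                    seed=seed)
    pspec = PrioritizationSpec(
        target_lines=set(sim.target_lines),
        background_lines=set(sim.cell_lines) - set(sim.target_lines),
        n_mc=n_mc, seed=seed)
    ranking = rank_drugs(ensemble, model, encoder,
                         sorted(set(viability["drug"])), 1.0, pspec)
    return ranking, sim.planted_drug


# ------------------------------------------------------------------ viability
def generate_viability(spec: FixtureSpec, sim: SimulatedData,
                       beta_concentration: float = 25.0
                       ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Viability and indication tables with a planted selective drug.

    Mean viability is a logistic function of a fixed linear readout of the
    noiseless expression state, with the readout direction anti-aligned with
    the planted drug's selective response: expression that looks like the
    planted response drives viability down. Because the planted drug's
    response is confined to the target lines, it is selectively cytotoxic
    there with a target/background margin of at least 0.3 by construction
    (the planted rows are clipped to honor the margin even when the simulated
    response is weak). Viability draws come from Beta(mean*k, (1 - mean)*k).
    """
    if sim.planted_drug is None:
        raise ValueError("simulate with planted_selective_drug=True first")
    rng = np.random.default_rng(spec.seed + 71)
    drug_nodes = sorted({d for d in sim.obs_table["drug"] if d})
    top_dose = max(spec.doses)
    planted_shift = np.mean([
        sim.noiseless_response(c, {sim.planted_drug: top_dose})
        - sim.noiseless_response(c) for c in sim.target_lines], axis=0)
    norm = float(np.linalg.norm(planted_shift))
    if norm < 1e-9:
        raise ValueError("planted drug produces no response in target lines")
    readout = -4.0 * planted_shift / norm
    rows = []
    for c in sim.cell_lines:
        for d in drug_nodes:
            for dose in spec.doses:
                y_expr = sim.noiseless_response(c, {d: dose})
                mean = 1.0 / (1.0 + math.exp(-(1.5 + float(readout @ y_expr))))
                if d == sim.planted_drug:
                    # planted contract: selective cytotoxicity holds even if
                    # the simulated response is weak in a particular line
                    mean = (min(mean, 0.30) if c in sim.target_lines
                            else max(mean, 0.70))
                y = rng.beta(mean * beta_concentration,
                             (1 - mean) * beta_concentration)
                rows.append({"drug": d, "cell_line": c, "conc_uM": dose,
                             "viability": float(np.clip(y, 0.0, 1.0))})
    viability = pd.DataFrame(rows)
    indications = pd.DataFrame(
        [{"drug": sim.planted_drug, "disease": "target_disease"}]
        + [{"drug": d, "disease": "other_disease"}
           for d in drug_nodes if d != sim.planted_drug])
    return viability, indications
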