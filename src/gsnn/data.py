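"""Observation encoding, dose transformation, and cross-validation splits.

Drug presence is encoded per drug node as a transformed concentration

    x_dose = -(log10(c + eps) - log10(eps)) / log10(eps)

which is 0 at zero concentration, ~1 at 1 uM for the default eps = 1e-6, and
log-linear over the therapeutically relevant range. 'Omic context values pass
through untransformed. Monte Carlo cross-validation partitions *(drug, cell
line) pairs* — never raw observations — into disjoint train/validation/test
sets, so evaluation measures imputation of unseen drug-cell combinations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .graph import ROLE_INPUT, ROLE_OUTPUT, StructuralGraph


def transform_dose(conc_uM: float, eps: float = 1e-6) -> float:
    """Log-linear dose encoding; strictly increasing, 0 at 0 uM, ~1 at 1 uM."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    conc = np.asarray(conc_uM, dtype=float)
    if np.any(conc < 0):
        raise ValueError("negative drug concentration")
    out = -(np.log10(conc + eps) - math.log10(eps)) / math.log10(eps)
    return float(out) if np.isscalar(conc_uM) else out


@dataclass
class Observation:
    """One perturbation measurement: doses + context in, targets out."""

    drug_doses: Dict[str, float] = field(default_factory=dict)  # node -> uM
    omics: Dict[str, float] = field(default_factory=dict)       # node -> value
    targets: Dict[str, float] = field(default_factory=dict)     # node -> value
    meta: Dict[str, object] = field(default_factory=dict)


def encode_observation(obs: Observation, g: StructuralGraph,
                       cell_agnostic: bool = False,
                       eps: float = 1e-6) -> np.ndarray:
    """Encode an observation as a vector over the graph's input nodes.

    Drug positions carry transformed doses; 'omic positions carry raw values;
    everything unmentioned is zero. ``cell_agnostic`` zeroes all non-drug
    input positions (removing cellular context from the encoding).
    """
    input_idx = g.nodes_with_role(ROLE_INPUT)
    pos = {g.node_names[i]: j for j, i in enumerate(input_idx)}
    cls = {g.node_names[i]: g.entity_classes[i] for i in input_idx}
    x = np.zeros(len(input_idx))
    for name, conc in obs.drug_doses.items():
        if name not in pos:
            raise KeyError(f"unknown input node {name!r}")
        if cls[name] != "DRUG":
            raise ValueError(f"dose assigned to non-DRUG node {name!r}")
        x[pos[name]] = transform_dose(conc, eps)
    if not cell_agnostic:
        for name, val in obs.omics.items():
            if name not in pos:
                raise KeyError(f"unknown input node {name!r}")
            if cls[name] == "DRUG":
                raise ValueError(f"omic value assigned to DRUG node {name!r}")
            x[pos[name]] = val
    return x


def encode_targets(obs: Observation, g: StructuralGraph) -> np.ndarray:
    output_idx = g.nodes_with_role(ROLE_OUTPUT)
    pos = {g.node_names[i]: j for j, i in enumerate(output_idx)}
    y = np.zeros(len(output_idx))
    for name, val in obs.targets.items():
        y[pos[name]] = val
    return y


class ObservationEncoder:
    """Encodes (drug, dose, cell line) tuples against a graph + omics table.

    ``omics_by_cell`` is a wide frame indexed by cell line with one column per
    'omic input node present in the graph.
    """

    def __init__(self, g: StructuralGraph, omics_by_cell: pd.DataFrame,
                 cell_agnostic: bool = False, eps: float = 1e-6):
        self.graph = g
        self.omics_by_cell = omics_by_cell
        self.cell_agnostic = cell_agnostic
        self.eps = eps
        input_idx = g.nodes_with_role(ROLE_INPUT)
        self.input_names = [g.node_names[i] for i in input_idx]
        self._pos = {n: j for j, n in enumerate(self.input_names)}
        self._omic_cols = [c for c in omics_by_cell.columns if c in self._pos]

    def encode(self, cell_line: str,
               doses: Optional[Mapping[str, float]] = None) -> np.ndarray:
        x = np.zeros(len(self.input_names))
        if not self.cell_agnostic:
            row = self.omics_by_cell.loc[cell_line]
            for c in self._omic_cols:
                x[self._pos[c]] = row[c]
        for drug, conc in (doses or {}).items():
            x[self._pos[drug]] = transform_dose(conc, self.eps)
        return x


@dataclass
class DataSplit:
    train: Set[Tuple[str, str]]
    val: Set[Tuple[str, str]]
    test: Set[Tuple[str, str]]
    fractions: Tuple[float, float, float]
    seed: int

    def assign(self, pair: Tuple[str, str]) -> str:
        if pair in self.train:
            return "train"
        if pair in self.val:
            return "val"
        return "test"


def mccv_split(pairs: Iterable[Tuple[str, str]],
               fractions: Tuple[float, float, float] = (0.6, 0.2, 0.2),
               seed: int = 0) -> DataSplit:
    """Partition (drug, cell line) pairs into disjoint train/val/test sets.

    Validation and test receive floor(fraction * n) pairs each; the remainder
    goes to train.
    """
    pairs = sorted(set(pairs))
    if not pairs:
        raise ValueError("empty pair set")
    if len(pairs) < 5:
        raise ValueError("need at least 5 (drug, cell) pairs to split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    n = len(pairs)
    n_val = int(math.floor(fractions[1] * n))
    n_test = int(math.floor(fractions[2] * n))
    val = {pairs[i] for i in order[:n_val]}
    test = {pairs[i] for i in order[n_val:n_val + n_test]}
    train = {pairs[i] for i in order[n_val + n_test:]}
    return DataSplit(train, val, test, tuple(fractions), seed)


# --------------------------------------------------------------------- tables
def observations_from_tables(obs_table: pd.DataFrame,
                             omics_by_cell: pd.DataFrame,
                             targets: pd.DataFrame) -> List[Observation]:
    """Assemble Observations from the TSV dialect used on disk.

    obs_table columns: obs_id, drug, conc_uM, cell_line (drug may be empty for
    unperturbed baselines; two-drug rows add drug2, conc2_uM).
    omics_by_cell: wide, indexed by cell_line, columns are 'omic node names.
    targets: wide, indexed by obs_id, columns are output node names.
    """
    out = []
    for _, row in obs_table.iterrows():
        doses: Dict[str, float] = {}
        if isinstance(row.get("drug"), str) and row["drug"]:
            doses[row["drug"]] = float(row["conc_uM"])
        if isinstance(row.get("drug2"), str) and row.get("drug2"):
            doses[row["drug2"]] = float(row["conc2_uM"])
        cell = row["cell_line"]
        omics = omics_by_cell.loc[cell].to_dict()
        tgt = targets.loc[row["obs_id"]].to_dict()
        out.append(Observation(drug_doses=doses, omics=omics, targets=tgt,
                               meta={"obs_id": row["obs_id"],
                                     "drugs": tuple(sorted(doses)),
                                     "cell_line": cell,
                                     "dose": float(row.get("conc_uM", 0.0) or 0.0)}))
    return out


def encode_dataset(observations: Sequence[Observation], g: StructuralGraph,
                   cell_agnostic: bool = False,
                   eps: float = 1e-6) -> Tuple[np.ndarray, np.ndarray]:
    X = np.stack([encode_observation(o, g, cell_agnostic, eps)
                  for o in observations])
    Y = np.stack([encode_targets(o, g) for o in observations])
    return X, Y


def split_observations(observations: Sequence[Observation],
                       split: DataSplit) -> Dict[str, List[Observation]]:
    """Route every observation to the partition of its (drug, cell) pair.

    The pair key uses the first (alphabetical) drug of an observation; all
    observations sharing a pair land in the same partition.
    """
    out: Dict[str, List[Observation]] = {"train": [], "val": [], "test": []}
    for o in observations:
        drugs = o.meta.get("drugs", ())
        drug = drugs[0] if drugs else ""
        out[split.assign((drug, o.meta["cell_line"]))].append(o)
    return out
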