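"""Disease modules and intracellular drug centrality.

Each cell type's disease module is the largest connected component (LCC)
its DEGs form in the interactome. Gene importance inside the module is
eigenvector centrality (max-normalised); a drug's intracellular
centrality in a cell type is the geometric mean of the centralities of
its targets that lie in the module, or zero when it targets none.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .data_io import CellTypeDEGs, DrugRecord, Interactome

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiseaseModule:
    cell_type: str
    genes: frozenset[int]
    centrality: Mapping[int, float] = field(default_factory=dict)

    @property
    def is_empty(self) -> bool:
        return not self.genes


def eigencentrality(g: nx.Graph) -> dict[int, float]:
    """Principal-eigenvector scores of the undirected adjacency, max = 1.

    Requires a connected graph; Perron-Frobenius then guarantees a
    strictly positive eigenvector, which is asserted to guard against a
    sign-flipped solver output.
    """
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    if n == 1:
        return {int(next(iter(g.nodes()))): 1.0}
    if not nx.is_connected(g):
        raise ValueError("graph must be connected")
    nodes = sorted(g.nodes())
    adj = nx.to_numpy_array(g, nodelist=nodes)
    w, v = np.linalg.eigh(adj)
    vec = np.abs(v[:, int(np.argmax(w))])
    if vec.min() <= 0:
        raise ArithmeticError("eigenvector centrality not strictly positive")
    vec = vec / vec.max()
    return {int(node): float(c) for node, c in zip(nodes, vec)}


def deg_lcc(degs: CellTypeDEGs, g: Interactome) -> DiseaseModule:
    """Largest connected component formed by the cell type's DEGs.

    Ties between equal-sized components break to the one holding the
    smallest gene ID. If no in-network DEG exists or all are isolated,
    the module is empty and every drug scores zero for this cell type.
    """
    in_graph = degs.genes_in_network
    if not in_graph:
        return DiseaseModule(cell_type=degs.cell_type, genes=frozenset())
    sub = g.graph.subgraph(in_graph)
    components = sorted(nx.connected_components(sub), key=lambda c: (-len(c), min(c)))
    largest = components[0]
    if len(largest) < 2:  # all DEGs isolated in the induced subgraph
        return DiseaseModule(cell_type=degs.cell_type, genes=frozenset())
    module_graph = sub.subgraph(largest)
    centrality = eigencentrality(module_graph)
    return DiseaseModule(
        cell_type=degs.cell_type, genes=frozenset(int(x) for x in largest),
        centrality=centrality,
    )


def drug_intracellular(drug: DrugRecord, module: DiseaseModule) -> float:
    """Geometric mean of in-module target centralities; 0 if none in module."""
    in_module = sorted(drug.targets & module.genes)
    if not in_module:
        return 0.0
    logs = np.log([module.centrality[t] for t in in_module])
    return float(np.exp(logs.mean()))


@dataclass(frozen=True)
class IntracellularScore:
    drug_id: str
    per_cell_type: Mapping[str, float]
    combined: float


def intracellular_scores(
    drugs: Sequence[DrugRecord], modules: Mapping[str, DiseaseModule]
) -> dict[str, IntracellularScore]:
    """Per-cell-type and combined (summed) intracellular centralities."""
    out = {}
    for drug in drugs:
        per_ct = {ct: drug_intracellular(drug, mod) for ct, mod in modules.items()}
        out[drug.drug_id] = IntracellularScore(
            drug_id=drug.drug_id, per_cell_type=per_ct, combined=float(sum(per_ct.values()))
        )
    return out


def module_table(modules: Mapping[str, DiseaseModule]) -> pd.DataFrame:
    rows = [
        (ct, gene, mod.centrality[gene])
        for ct, mod in sorted(modules.items())
        for gene in sorted(mod.genes)
    ]
    return pd.DataFrame(rows, columns=["cell_type", "gene", "centrality"])


def intracellular_table(scores: Mapping[str, IntracellularScore]) -> pd.DataFrame:
    rows = [
        (drug_id, ct, val)
        for drug_id, s in sorted(scores.items())
        for ct, val in sorted(s.per_cell_type.items())
    ]
    return pd.DataFrame(rows, columns=["drug_id", "cell_type", "intracellular"])
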