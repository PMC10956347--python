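"""Input readers and the shared in-memory containers.

All inputs are harmonised onto a single integer gene-ID universe. The
protein-protein interaction network (PPIN) is reduced to its largest
connected component at load time; drug targets are restricted to that
component; differential-expression tables keep out-of-network genes but
flag them so downstream network stages can ignore them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from scipy.sparse.csgraph import shortest_path

from .exceptions import ParseError

logger = logging.getLogger(__name__)

ACTIONS = frozenset({"activate", "inhibit", "unknown"})


class Interactome:
    """Undirected PPI graph: the largest connected component of the input.

    Wraps a :class:`networkx.Graph` with a stable node ordering and a
    lazily computed all-pairs shortest-path matrix (unweighted BFS
    distances), which makes the permutation null fast at screening scale.
    """

    def __init__(self, graph: nx.Graph):
        if graph.number_of_nodes() == 0:
            raise ParseError("interactome graph is empty")
        if not nx.is_connected(graph):
            raise ValueError("Interactome must be a single connected component")
        self.graph = graph
        self.node_order: np.ndarray = np.array(sorted(graph.nodes()), dtype=np.int64)
        self._index: dict[int, int] = {int(g): i for i, g in enumerate(self.node_order)}
        self.nodes: frozenset[int] = frozenset(self._index)
        self.degree: dict[int, int] = {int(n): int(d) for n, d in graph.degree()}
        self._dist: Optional[np.ndarray] = None

    def __contains__(self, gene: int) -> bool:
        return gene in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def index_of(self, genes: Iterable[int]) -> np.ndarray:
        return np.array([self._index[int(g)] for g in genes], dtype=np.int64)

    @property
    def dist_matrix(self) -> np.ndarray:
        """Dense all-pairs BFS distance matrix, rows/cols in node_order."""
        if self._dist is None:
            adj = nx.to_scipy_sparse_array(self.graph, nodelist=self.node_order.tolist())
            self._dist = shortest_path(adj, method="D", unweighted=True, directed=False)
        return self._dist

    def distance_submatrix(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return self.dist_matrix[np.ix_(rows, cols)]


def load_interactome(path: str | Path) -> Interactome:
    """Read a headerless two-column integer edge list; return the LCC.

    Self-loops and duplicate edges are dropped. Counts of dropped
    edges/nodes are logged. A malformed row raises :class:`ParseError`
    naming the line number.
    """
    g = nx.Graph()
    n_self, n_dup, n_rows = 0, 0, 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 columns, got {len(parts)}")
            try:
                a, b = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer gene ID ({exc})") from exc
            n_rows += 1
            if a == b:
                n_self += 1
                continue
            if g.has_edge(a, b):
                n_dup += 1
                continue
            g.add_edge(a, b)
    if n_rows == 0 or g.number_of_nodes() == 0:
        raise ParseError(f"{path}: no usable edges (empty graph)")
    components = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    lcc = components[0]
    n_dropped_nodes = g.number_of_nodes() - len(lcc)
    sub = g.subgraph(lcc).copy()
    logger.info(
        "interactome: %d nodes / %d edges in LCC; dropped %d self-loops, %d duplicate edges, "
        "%d nodes outside LCC",
        sub.number_of_nodes(), sub.number_of_edges(), n_self, n_dup, n_dropped_nodes,
    )
    return Interactome(sub)


def write_interactome(g: Interactome, path: str | Path) -> None:
    """Serialise as a sorted, headerless two-column edge list."""
    edges = sorted(tuple(sorted(e)) for e in g.graph.edges())
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


@dataclass(frozen=True)
class DrugRecord:
    """One screened drug: its in-network targets and per-target action."""

    drug_id: str
    name: str
    targets: frozenset[int]
    action: Mapping[int, str]
    is_relevant: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        missing = self.targets - set(self.action)
        if missing:
            raise ValueError(f"{self.drug_id}: targets without an action entry: {sorted(missing)}")


def load_drugs(path: str | Path, interactome: Interactome) -> list[DrugRecord]:
    """Read the drug-target table and restrict targets to the interactome.

    Expected columns: drug_id, name, target, action, plus zero or more
    ``flag_*`` indication columns. Drugs left with no in-network target
    are excluded (count logged). Duplicate (drug, target) rows are
    deduplicated with the last action winning.
    """
    df = pd.read_csv(path, sep="\t", dtype={"drug_id": str, "name": str})
    required = {"drug_id", "name", "target", "action"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    bad = df[~df["action"].isin(ACTIONS)]
    if len(bad):
        rows = ", ".join(str(i + 2) for i in bad.index[:10])  # +2: header + 1-based
        raise ParseError(
            f"{path}: invalid action values {sorted(bad['action'].unique())} at rows {rows}"
        )
    dup_mask = df.duplicated(subset=["drug_id", "target"], keep=False)
    if dup_mask.any():
        logger.warning(
            "%s: %d duplicate (drug, target) rows; keeping last action", path, int(dup_mask.sum())
        )
        df = df.drop_duplicates(subset=["drug_id", "target"], keep="last")
    flag_cols = [c for c in df.columns if c.startswith("flag_")]

    records: list[DrugRecord] = []
    n_excluded = 0
    for drug_id, grp in df.groupby("drug_id", sort=True):
        targets = frozenset(int(t) for t in grp["target"] if int(t) in interactome)
        if not targets:
            n_excluded += 1
            continue
        action = {
            int(t): a for t, a in zip(grp["target"], grp["action"]) if int(t) in interactome
        }
        first = grp.iloc[0]
        relevant = {c[len("flag_"):]: bool(int(first[c])) for c in flag_cols}
        records.append(
            DrugRecord(
                drug_id=str(drug_id), name=str(first["name"]),
                targets=targets, action=action, is_relevant=relevant,
            )
        )
    if n_excluded:
        logger.info("%s: excluded %d drugs with no target in the interactome", path, n_excluded)
    return records


@dataclass
class CellTypeDEGs:
    """One cell type's disease signature (gene, log fold change, adjusted p).

    ``table`` columns: gene, logfc, padj, in_network. Genes outside the
    interactome are kept but flagged; network stages use ``genes_in_network``.
    """

    cell_type: str
    table: pd.DataFrame

    @property
    def genes(self) -> set[int]:
        return set(int(g) for g in self.table["gene"])

    @property
    def genes_in_network(self) -> set[int]:
        return set(int(g) for g in self.table.loc[self.table["in_network"], "gene"])

    @property
    def logfc(self) -> dict[int, float]:
        return dict(zip(self.table["gene"].astype(int), self.table["logfc"].astype(float)))

    def __len__(self) -> int:
        return len(self.table)


def load_degs(
    path: str | Path,
    interactome: Interactome,
    max_degs: Optional[int] = None,
) -> dict[str, CellTypeDEGs]:
    """Read per-cell-type DEG tables (columns cell_type, gene, logfc, padj).

    Rows with logfc == 0 are rejected with a warning; padj outside [0, 1]
    is fatal. With ``max_degs`` set, the ``max_degs`` most significant
    genes per cell type are kept (smallest padj, ties broken by larger
    \\|logfc\\| then smaller gene ID).
    """
    df = pd.read_csv(path, sep="\t", dtype={"cell_type": str})
    required = {"cell_type", "gene", "logfc", "padj"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    if ((df["padj"] < 0) | (df["padj"] > 1)).any():
        raise ParseError(f"{path}: padj values outside [0, 1]")
    zero = df["logfc"] == 0
    if zero.any():
        logger.warning("%s: rejected %d rows with logfc == 0", path, int(zero.sum()))
        df = df[~zero]
    out: dict[str, CellTypeDEGs] = {}
    for ct, grp in df.groupby("cell_type", sort=True):
        grp = grp.copy()
        if grp["gene"].duplicated().any():
            raise ParseError(f"{path}: duplicate genes within cell type {ct!r}")
        if max_degs is not None and len(grp) > max_degs:
            grp = grp.assign(_absfc=grp["logfc"].abs())
            grp = grp.sort_values(
                ["padj", "_absfc", "gene"], ascending=[True, False, True]
            ).head(max_degs).drop(columns="_absfc")
        grp["in_network"] = grp["gene"].astype(int).map(lambda g: g in interactome)
        grp = grp.sort_values("gene").reset_index(drop=True)
        out[str(ct)] = CellTypeDEGs(cell_type=str(ct), table=grp[["gene", "logfc", "padj", "in_network"]])
    return out


@dataclass
class ExpressionMatrix:
    """Denoised genes x cells expression on log10 scale, with cell-type labels."""

    genes: np.ndarray          # ordered int gene IDs
    cells: list[str]           # ordered cell IDs
    values: np.ndarray         # genes x cells, float, >= 0
    cell_type_of: dict[str, str]

    def __post_init__(self):
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError("expression matrix shape does not match gene/cell lists")
        missing = [c for c in self.cells if c not in self.cell_type_of]
        if missing:
            raise ParseError(f"cells without a cell-type label: {missing[:5]}")
        neg = self.values < 0
        if neg.any():
            logger.warning("clipped %d negative expression entries to 0", int(neg.sum()))
            self.values = np.where(neg, 0.0, self.values)
        self._gene_index = {int(g): i for i, g in enumerate(self.genes)}

    def cell_types(self) -> list[str]:
        return sorted(set(self.cell_type_of.values()))

    def columns_of_type(self, cell_type: str) -> np.ndarray:
        idx = [i for i, c in enumerate(self.cells) if self.cell_type_of[c] == cell_type]
        if not idx:
            raise KeyError(f"unknown cell type: {cell_type!r}")
        return np.array(idx, dtype=np.int64)

    def row_of(self, gene: int) -> int:
        return self._gene_index[int(gene)]


def load_expression(
    mtx_path: str | Path, genes_path: str | Path, cells_path: str | Path
) -> ExpressionMatrix:
    """Read MatrixMarket expression plus gene list and cell-label TSVs."""
    mat = scipy.io.mmread(mtx_path)
    values = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
    genes = np.loadtxt(genes_path, dtype=np.int64, ndmin=1)
    labels = pd.read_csv(cells_path, sep="\t", dtype=str)
    if not {"cell_id", "cell_type"}.issubset(labels.columns):
        raise ParseError(f"{cells_path}: expected columns cell_id, cell_type")
    cells = labels["cell_id"].tolist()
    cell_type_of = dict(zip(labels["cell_id"], labels["cell_type"]))
    return ExpressionMatrix(genes=genes, cells=cells, values=values, cell_type_of=cell_type_of)


def load_expression_dense(tsv_path: str | Path, cells_path: str | Path) -> ExpressionMatrix:
    """Read a dense TSV (rows = genes, index = gene ID, columns = cell IDs)."""
    df = pd.read_csv(tsv_path, sep="\t", index_col=0)
    labels = pd.read_csv(cells_path, sep="\t", dtype=str)
    return ExpressionMatrix(
        genes=df.index.to_numpy(dtype=np.int64),
        cells=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
        cell_type_of=dict(zip(labels["cell_id"], labels["cell_type"])),
    )


@dataclass
class LigandTargetPrior:
    """Ligand x gene regulatory-potential prior (non-negative scores)."""

    ligands: np.ndarray    # ordered int ligand gene IDs
    genes: np.ndarray      # ordered int target gene IDs
    potential: np.ndarray  # ligands x genes

    def __post_init__(self):
        if self.potential.shape != (len(self.ligands), len(self.genes)):
            raise ValueError("prior matrix shape mismatch")
        if (self.potential < 0).any():
            raise ParseError("ligand-target prior contains negative potentials")
        self._ligand_index = {int(l): i for i, l in enumerate(self.ligands)}
        self.gene_set: frozenset[int] = frozenset(int(g) for g in self.genes)

    def __contains__(self, ligand: int) -> bool:
        return int(ligand) in self._ligand_index

    def row(self, ligand: int) -> np.ndarray:
        return self.potential[self._ligand_index[int(ligand)]]


def load_prior(path: str | Path) -> LigandTargetPrior:
    """Read the prior TSV: first column ligand gene ID, header = gene IDs."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    all_nan = df.isna().all(axis=1)
    if all_nan.any():
        logger.warning("%s: dropped %d all-missing ligand rows", path, int(all_nan.sum()))
        df = df[~all_nan]
    if df.empty:
        raise ParseError(f"{path}: no usable ligand rows")
    df = df.fillna(0.0)
    return LigandTargetPrior(
        ligands=df.index.to_numpy(dtype=np.int64),
        genes=np.array([int(c) for c in df.columns], dtype=np.int64),
        potential=df.to_numpy(dtype=float),
    )


def load_relevant(path: str | Path) -> set[str]:
    """Read the relevant-drug list (one drug ID per line)."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
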