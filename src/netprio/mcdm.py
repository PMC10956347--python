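"""Multicellular disease model (MCDM): inferred cell-type crosstalk.

Cell-cell communication is scored per ligand: a ligand that is a DEG of
the sender and present in the ligand-target prior gets an activity equal
to the Pearson correlation, over the receiver's background genes, between
the ligand's regulatory-potential scores and the indicator of receiver
DEG membership. Positive-activity ligand interactions are summed into a
directed, weighted cell-type graph whose eigenvector centrality measures
each cell type's importance in disease crosstalk.

Background genes of a cell type are those whose mean aggregate
expression Ea(i) = log2( sum_j 10^D_ij / k ) over its k cells clears a
cut-off (default 0.2), D being the denoised log10-scale matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data_io import CellTypeDEGs, ExpressionMatrix, LigandTargetPrior
from .exceptions import EmptyBackgroundError

logger = logging.getLogger(__name__)

EA_CUTOFF = 0.2


def aggregate_expression(expr: ExpressionMatrix, cell_type: str, gene: int) -> float:
    """Ea(i): log2 of the mean over the cell type's cells of 10^D_ij."""
    cols = expr.columns_of_type(cell_type)
    row = expr.values[expr.row_of(gene), cols]
    return float(np.log2(np.mean(10.0 ** row)))


def aggregate_expression_profile(expr: ExpressionMatrix, cell_type: str) -> pd.Series:
    """Ea(i) for every gene of the matrix at once."""
    cols = expr.columns_of_type(cell_type)
    ea = np.log2(np.mean(10.0 ** expr.values[:, cols], axis=1))
    return pd.Series(ea, index=expr.genes.astype(int))


@dataclass(frozen=True)
class BackgroundSet:
    cell_type: str
    genes: frozenset[int]
    cutoff: float = EA_CUTOFF


def background_genes(
    expr: ExpressionMatrix, cell_type: str, cutoff: float = EA_CUTOFF
) -> BackgroundSet:
    """Genes with Ea >= cutoff (inclusive) in this cell type's cells."""
    ea = aggregate_expression_profile(expr, cell_type)
    genes = frozenset(int(g) for g in ea.index[ea >= cutoff])
    if not genes:
        raise EmptyBackgroundError(
            f"cell type {cell_type!r} has no background gene at Ea >= {cutoff}"
        )
    return BackgroundSet(cell_type=cell_type, genes=genes, cutoff=cutoff)


def ligand_activity(
    ligand: int,
    prior: LigandTargetPrior,
    gene_set: set[int],
    background: BackgroundSet,
) -> float:
    """Pearson correlation of the ligand's potentials with gene-set membership.

    Evaluated over (background genes union gene set) restricted to prior
    genes. A zero-variance potential or indicator vector yields 0 with a
    warning (no meaningful signal either way).
    """
    if int(ligand) not in prior:
        raise KeyError(f"ligand {ligand} not in prior")
    universe = sorted((background.genes | set(gene_set)) & prior.gene_set)
    if len(universe) < 3:
        raise ValueError(
            f"evaluation universe too small ({len(universe)} genes) for ligand {ligand}"
        )
    col_index = {int(g): i for i, g in enumerate(prior.genes)}
    cols = np.array([col_index[g] for g in universe])
    potentials = prior.row(ligand)[cols]
    indicator = np.array([1.0 if g in gene_set else 0.0 for g in universe])
    if np.ptp(potentials) == 0 or np.ptp(indicator) == 0:
        logger.warning("ligand %d: zero-variance vector; activity set to 0", ligand)
        return 0.0
    return float(np.corrcoef(potentials, indicator)[0, 1])


@dataclass(frozen=True)
class LigandInteraction:
    sender: str
    receiver: str
    ligand: int
    pearson: float


@dataclass
class MCDM:
    """Directed, weighted cell-type crosstalk graph."""

    cell_types: list[str]
    edges: dict[tuple[str, str], float]         # weight = sum of positive pearsons
    interactions: list[LigandInteraction]
    centrality: dict[str, float] = field(default_factory=dict)


def build_mcdm(
    degs: Mapping[str, CellTypeDEGs],
    prior: LigandTargetPrior,
    expr: ExpressionMatrix,
    ea_cutoff: float = EA_CUTOFF,
) -> MCDM:
    """Score every ordered cell-type pair (self-pairs included).

    Candidate ligands of a pair are the sender's DEGs that the prior
    covers; the gene set of interest is the receiver's DEG set; only
    positive-activity interactions enter the model. Cell types with no
    DEGs are excluded entirely.
    """
    cell_types = sorted(ct for ct in degs if len(degs[ct]) > 0)
    if not cell_types:
        raise ValueError("no cell type with DEGs")
    backgrounds = {ct: background_genes(expr, ct, ea_cutoff) for ct in cell_types}
    prior_ligands = frozenset(int(l) for l in prior.ligands)

    interactions: list[LigandInteraction] = []
    edges: dict[tuple[str, str], float] = {}
    for sender in cell_types:
        ligands = sorted(degs[sender].genes & prior_ligands)
        if not ligands:
            continue
        for receiver in cell_types:
            gene_set = degs[receiver].genes
            for ligand in ligands:
                r = ligand_activity(ligand, prior, gene_set, backgrounds[receiver])
                if r > 0:
                    interactions.append(
                        LigandInteraction(sender=sender, receiver=receiver, ligand=ligand, pearson=r)
                    )
                    edges[(sender, receiver)] = edges.get((sender, receiver), 0.0) + r
    m = MCDM(cell_types=cell_types, edges=edges, interactions=interactions)
    m.centrality = celltype_centrality(m)
    return m


def celltype_centrality(m: MCDM) -> dict[str, float]:
    """Eigenvector centrality on the weighted directed crosstalk graph.

    Convention: a cell type's score is the weighted sum of the scores of
    cell types pointing to it (receiver importance), i.e. the principal
    eigenvector of the transposed adjacency, max-normalised to 1. On a
    degenerate spectrum (reducible graph whose principal eigenvector
    vanishes on nodes that do have edges) the computation falls back to
    the symmetrised graph, logged. Cell types touching no edge score 0.
    """
    cts = sorted(m.cell_types)
    n = len(cts)
    idx = {ct: i for i, ct in enumerate(cts)}
    if not m.edges:
        logger.warning("MCDM has no edges; all centralities 0")
        return {ct: 0.0 for ct in cts}
    adj = np.zeros((n, n))
    for (s, r), w in m.edges.items():
        adj[idx[s], idx[r]] = w
    touched = (adj.sum(axis=0) + adj.sum(axis=1)) > 0

    vec = _principal_vector(adj.T)
    if vec is None or np.any(vec[touched] <= 1e-9 * vec.max()):
        logger.info("directed spectrum degenerate; falling back to symmetrised graph")
        w, v = np.linalg.eigh((adj + adj.T) / 2.0)
        vec = np.abs(v[:, int(np.argmax(w))])
    vec = np.where(touched, vec, 0.0)
    vec = vec / vec.max()
    return {ct: float(vec[idx[ct]]) for ct in cts}


def _principal_vector(mat: np.ndarray) -> np.ndarray | None:
    """Dominant eigenvector (abs of it) if real and non-trivial, else None."""
    w, v = np.linalg.eig(mat)
    k = int(np.argmax(np.abs(w)))
    if abs(w[k]) < 1e-12:  # nilpotent / no recurrent structure
        return None
    if abs(w[k].imag) > 1e-9 * abs(w[k]):
        return None
    vec = v[:, k]
    if np.abs(vec.imag).max() > 1e-9:
        return None
    return np.abs(vec.real)


def interaction_table(m: MCDM) -> pd.DataFrame:
    rows = [(i.sender, i.receiver, i.ligand, i.pearson) for i in m.interactions]
    return pd.DataFrame(rows, columns=["sender", "receiver", "ligand", "pearson"])


def edge_table(m: MCDM) -> pd.DataFrame:
    rows = [(s, r, w) for (s, r), w in sorted(m.edges.items())]
    return pd.DataFrame(rows, columns=["sender", "receiver", "weight"])


def centrality_table(m: MCDM) -> pd.DataFrame:
    rows = sorted(m.centrality.items())
    return pd.DataFrame(rows, columns=["cell_type", "eigenvector_centrality"])
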