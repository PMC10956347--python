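"""Synthetic benchmark generator with planted, recoverable structure.

Emulates every pipeline input at toy scale: a scale-free interactome
(preferential attachment, m = 2, hence connected), one planted connected
DEG module per cell type, "good" drugs whose targets sit inside a module
with counteracting actions, decoy drugs that are either degree-matched
random-target controls or in-module aggravators, a log10-scale
expression matrix in which each cell type's module genes clear the
background cut-off, and a ligand-target prior in which planted sender
ligands mirror the receiver module. The relevant-drug list is exactly
the good drugs, so precision/recall of planted recovery is measurable.

The generator emulates the interface the framework consumes (post
denoising, post DEG calling); it does not simulate raw scRNA-seq counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from . import data_io
from .proximity import build_degree_bins, sample_degree_matched

logger = logging.getLogger(__name__)

#: bin size used for fixture-scale graphs (the screening default of 100
#: assumes an interactome of ~17k genes; toy graphs need smaller bins)
FIXTURE_MIN_BIN = 20


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 1
    n_genes: int = 400
    n_cell_types: int = 5
    n_cells_per_type: int = 60
    module_size: int = 25
    n_drugs: int = 80
    n_ligands: int = 30
    frac_counteracting: float = 1.0
    noise_sd: float = 0.1

    def __post_init__(self):
        if not 0.0 <= self.frac_counteracting <= 1.0:
            raise ValueError("frac_counteracting must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class FixtureBundle:
    spec: FixtureSpec
    paths: dict[str, Path]
    good_drugs: list[str]
    decoy_drugs: list[str]
    modules: dict[str, list[int]]
    planted_ligands: list[tuple[str, str, int]]  # (sender, receiver, ligand)


def _connected_module(g: nx.Graph, start: int, size: int) -> list[int]:
    """BFS-order connected gene set of the requested size."""
    order = [start]
    seen = {start}
    frontier = [start]
    while frontier and len(order) < size:
        nxt = []
        for node in frontier:
            for nb in sorted(g.neighbors(node)):
                if nb not in seen:
                    seen.add(nb)
                    order.append(nb)
                    nxt.append(nb)
                    if len(order) >= size:
                        return order
        frontier = nxt
    if len(order) < size:
        raise ValueError(f"cannot grow a connected module of size {size}")
    return order


def generate_fixture(spec: FixtureSpec, out_dir: str | Path) -> FixtureBundle:
    """Write the full input bundle to ``out_dir``; deterministic in ``spec``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    # (a) interactome: preferential attachment, relabelled to gene IDs 1..n
    raw = nx.barabasi_albert_graph(spec.n_genes, 2, seed=int(spec.seed))
    g = nx.relabel_nodes(raw, {i: i + 1 for i in raw.nodes()})
    interactome_path = out / "interactome.tsv"
    with open(interactome_path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{a}\t{b}\n")

    cell_types = [f"CT{i + 1}" for i in range(spec.n_cell_types)]

    # (b) planted connected DEG modules with signed fold changes; each
    # gene's dysregulation direction is consistent across cell types
    nodes = np.array(sorted(g.nodes()), dtype=np.int64)
    gene_sign = {int(gene): (1.0 if s < 0.5 else -1.0)
                 for gene, s in zip(nodes, rng.random(spec.n_genes))}
    modules: dict[str, list[int]] = {}
    logfc: dict[str, dict[int, float]] = {}
    deg_rows = []
    for ct in cell_types:
        start = int(rng.choice(nodes))
        module = _connected_module(g, start, spec.module_size)
        modules[ct] = module
        logfc[ct] = {}
        for gene in module:
            fc = gene_sign[gene] * rng.uniform(1.5, 4.0)
            padj = rng.uniform(1e-12, 1e-6)
            logfc[ct][gene] = fc
            deg_rows.append((ct, gene, fc, padj))
    degs_path = out / "degs.tsv"
    pd.DataFrame(deg_rows, columns=["cell_type", "gene", "logfc", "padj"]).to_csv(
        degs_path, sep="\t", index=False, float_format="%.6g"
    )
    deg_anywhere = {gene for ct in cell_types for gene in modules[ct]}

    # (c) drugs: good (in-module, counteracting), decoys (degree-matched
    # random targets, or in-module aggravators)
    n_good = max(4, spec.n_drugs // 4)
    bins = build_degree_bins(
        data_io.Interactome(g.copy()), min_size=min(FIXTURE_MIN_BIN, spec.n_genes)
    )
    drug_rows = []
    good_ids, decoy_ids = [], []
    for i in range(n_good):
        drug_id = f"GOOD{i + 1:03d}"
        good_ids.append(drug_id)
        ct = cell_types[i % len(cell_types)]
        k = int(rng.integers(1, 4))
        targets = rng.choice(np.array(modules[ct]), size=k, replace=False)
        for t in sorted(int(x) for x in targets):
            fc = logfc[ct][t]
            counter = rng.random() < spec.frac_counteracting
            if counter:
                action = "inhibit" if fc > 0 else "activate"
            else:
                action = "activate" if fc > 0 else "inhibit"
            drug_rows.append((drug_id, f"goodnib-{i + 1}", t, action, 1))
    n_decoys = spec.n_drugs - n_good
    for i in range(n_decoys):
        drug_id = f"DECOY{i + 1:03d}"
        decoy_ids.append(drug_id)
        if i % 2 == 0:
            # degree-matched random-target control; never counteracts a DEG
            ct = cell_types[i % len(cell_types)]
            k = int(rng.integers(1, 4))
            template = rng.choice(np.array(modules[ct]), size=k, replace=False)
            targets = sorted(sample_degree_matched([int(x) for x in template], bins, rng))
            for t in targets:
                action = (
                    "unknown" if t in deg_anywhere
                    else ("inhibit" if rng.random() < 0.5 else "activate")
                )
                drug_rows.append((drug_id, f"decoy-{i + 1}", t, action, 0))
        else:
            # in-module targets but aggravating action (mimics an agonist
            # of an upregulated disease gene)
            ct = cell_types[i % len(cell_types)]
            k = int(rng.integers(1, 4))
            targets = rng.choice(np.array(modules[ct]), size=k, replace=False)
            for t in sorted(int(x) for x in targets):
                fc = logfc[ct][t]
                action = "activate" if fc > 0 else "inhibit"
                drug_rows.append((drug_id, f"decoy-{i + 1}", t, action, 0))
    drugs_path = out / "drugs.tsv"
    pd.DataFrame(
        drug_rows, columns=["drug_id", "name", "target", "action", "flag_approved"]
    ).to_csv(drugs_path, sep="\t", index=False)

    relevant_path = out / "relevant.txt"
    with open(relevant_path, "w") as fh:
        for drug_id in good_ids:
            fh.write(drug_id + "\n")

    # (d) expression: log10 scale; module genes high in their own cell
    # type, a housekeeping stratum moderate everywhere, the rest silent
    n_cells = spec.n_cell_types * spec.n_cells_per_type
    gene_index = {int(gene): i for i, gene in enumerate(nodes)}
    housekeeping = nodes[::7]
    values = np.zeros((spec.n_genes, n_cells))
    cell_ids, cell_ct = [], []
    for t, ct in enumerate(cell_types):
        cols = slice(t * spec.n_cells_per_type, (t + 1) * spec.n_cells_per_type)
        for j in range(spec.n_cells_per_type):
            cell_ids.append(f"{ct}_c{j + 1}")
            cell_ct.append(ct)
        rows_mod = [gene_index[gene] for gene in modules[ct]]
        values[rows_mod, cols] = 0.6 + spec.noise_sd * rng.standard_normal(
            (len(rows_mod), spec.n_cells_per_type)
        )
        rows_hk = [gene_index[int(gene)] for gene in housekeeping]
        values[rows_hk, cols] += 0.4 + spec.noise_sd * rng.standard_normal(
            (len(rows_hk), spec.n_cells_per_type)
        )
    values = np.clip(values, 0.0, None).round(4)
    mtx_path = out / "expression.mtx"
    scipy.io.mmwrite(mtx_path, scipy.sparse.csr_matrix(values))
    genes_path = out / "genes.tsv"
    np.savetxt(genes_path, nodes, fmt="%d")
    cells_path = out / "cells.tsv"
    pd.DataFrame({"cell_id": cell_ids, "cell_type": cell_ct}).to_csv(
        cells_path, sep="\t", index=False
    )

    # (e) ligand prior: planted sender ligands mirror the receiver module
    planted: list[tuple[str, str, int]] = []
    prior_rows: dict[int, np.ndarray] = {}
    n = len(cell_types)
    pair_list = [(cell_types[i], cell_types[(i + 1) % n]) for i in range(n)]
    pair_list += [(ct, cell_types[0]) for ct in cell_types[1:]]  # hub: CT1 receives extra
    used_ligands: set[int] = set()
    for which, (sender, receiver) in enumerate(pair_list):
        candidates = [gene for gene in modules[sender] if gene not in used_ligands]
        if not candidates:
            continue
        ligand = candidates[0]
        used_ligands.add(ligand)
        row = 0.02 * rng.random(spec.n_genes)
        recv_rows = [gene_index[gene] for gene in modules[receiver]]
        row[recv_rows] = 0.8 + 0.1 * rng.random(len(recv_rows))
        prior_rows[ligand] = row
        planted.append((sender, receiver, ligand))
    remaining = [int(x) for x in nodes if int(x) not in deg_anywhere and int(x) not in prior_rows]
    n_random = max(0, spec.n_ligands - len(prior_rows))
    for ligand in rng.choice(np.array(remaining), size=min(n_random, len(remaining)), replace=False):
        prior_rows[int(ligand)] = 0.3 * rng.random(spec.n_genes)
    prior_path = out / "prior.tsv"
    prior_df = pd.DataFrame.from_dict(
        {ligand: prior_rows[ligand] for ligand in sorted(prior_rows)},
        orient="index", columns=[str(int(gene)) for gene in nodes],
    )
    prior_df.index.name = "ligand"
    prior_df.to_csv(prior_path, sep="\t", float_format="%.6g")

    logger.info(
        "fixture (seed %d): %d genes, %d cell types, %d drugs (%d good), %d ligands",
        spec.seed, spec.n_genes, spec.n_cell_types, spec.n_drugs, n_good, len(prior_rows),
    )
    return FixtureBundle(
        spec=spec,
        paths={
            "interactome": interactome_path,
            "drugs": drugs_path,
            "degs": degs_path,
            "expression": mtx_path,
            "genes": genes_path,
            "cells": cells_path,
            "prior": prior_path,
            "relevant": relevant_path,
        },
        good_drugs=good_ids,
        decoy_drugs=decoy_ids,
        modules=modules,
        planted_ligands=planted,
    )
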