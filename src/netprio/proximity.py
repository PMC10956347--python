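"""Network proximity between drug targets and disease genes.

The screening statistic is the mean closest distance d_c: for each drug
target, the shortest-path distance to the nearest differentially
expressed gene (DEG), averaged over targets. Significance is assessed
with a degree-preserving permutation null: both the target set and the
DEG set are replaced by random gene sets drawn from degree bins, and
z_c = (d_c - null_mean) / null_sd. A drug is a candidate for a cell
type when z_c < -1.64 (one-sided P < 0.05) and d_c < 1, both strict.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .data_io import CellTypeDEGs, DrugRecord, Interactome
from .exceptions import UndefinedDistanceError

logger = logging.getLogger(__name__)

#: default selection thresholds
Z_THRESHOLD = -1.64
D_THRESHOLD = 1.0
MIN_BIN_SIZE = 100


@dataclass(frozen=True)
class DegreeBins:
    """Partition of interactome nodes into contiguous-degree bins.

    Nodes are sorted by degree; consecutive degree values are pooled
    until a bin holds at least ``min_size`` genes; a trailing undersized
    bin is merged into its predecessor.
    """

    bins: tuple[np.ndarray, ...]      # each sorted ascending by gene ID
    bin_of: Mapping[int, int]
    min_size: int

    def __len__(self) -> int:
        return len(self.bins)


def build_degree_bins(g: Interactome, min_size: int = MIN_BIN_SIZE) -> DegreeBins:
    if min_size < 1:
        raise ValueError("min_size must be positive")
    by_degree: dict[int, list[int]] = {}
    for gene, deg in g.degree.items():
        by_degree.setdefault(deg, []).append(gene)
    bins: list[list[int]] = []
    current: list[int] = []
    for deg in sorted(by_degree):
        current.extend(sorted(by_degree[deg]))
        if len(current) >= min_size:
            bins.append(current)
            current = []
    if current:
        if bins:
            bins[-1].extend(current)  # trailing undersized bin merges back
        else:
            bins.append(current)      # graph smaller than min_size: one bin
    arrays = tuple(np.array(sorted(b), dtype=np.int64) for b in bins)
    bin_of = {int(gene): i for i, arr in enumerate(arrays) for gene in arr}
    return DegreeBins(bins=arrays, bin_of=bin_of, min_size=min_size)


def closest_distance(targets: Iterable[int], degs: Iterable[int], g: Interactome) -> float:
    """Mean over targets of the shortest-path distance to the nearest DEG.

    DEGs outside the interactome are ignored; an empty in-graph DEG set
    makes the distance undefined.
    """
    targets = set(int(t) for t in targets)
    if not targets:
        raise ValueError("empty target set")
    if not targets <= g.nodes:
        raise ValueError("targets must lie inside the interactome")
    degs_in = [int(s) for s in degs if int(s) in g.nodes]
    if not degs_in:
        raise UndefinedDistanceError("no DEG inside the interactome")
    sub = g.distance_submatrix(g.index_of(sorted(targets)), g.index_of(sorted(degs_in)))
    return float(sub.min(axis=1).mean())


def sample_degree_matched(
    genes: Iterable[int], bins: DegreeBins, rng: np.random.Generator
) -> set[int]:
    """Draw a degree-bin-matched random gene set of the same size.

    For every input gene one gene is drawn from its bin, without
    replacement within the sampled set.
    """
    needed: dict[int, int] = {}
    for gene in genes:
        b = bins.bin_of[int(gene)]
        needed[b] = needed.get(b, 0) + 1
    out: set[int] = set()
    for b in sorted(needed):
        members = bins.bins[b]
        k = needed[b]
        if k > len(members):
            raise ValueError(
                f"bin {b} has {len(members)} genes but {k} draws requested"
            )
        out.update(int(x) for x in rng.choice(members, size=k, replace=False))
    return out


@dataclass(frozen=True)
class ProximityResult:
    cell_type: str
    drug_id: str
    d_c: float
    null_mean: float
    null_sd: float
    z_c: float          # NaN when the null distribution is degenerate
    n_iter: int
    seed: int

    @property
    def z_defined(self) -> bool:
        return not math.isnan(self.z_c)


def _substream(seed: int, cell_type: str, drug_id: str) -> np.random.Generator:
    """Deterministic per-(cell type, drug) RNG, independent of evaluation order."""
    digest = hashlib.sha256(f"{cell_type}\x1f{drug_id}".encode()).digest()
    key = int.from_bytes(digest[:4], "little") & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def proximity_z(
    drug: DrugRecord,
    degs: CellTypeDEGs,
    g: Interactome,
    bins: DegreeBins,
    n_iter: int = 1000,
    seed: int = 0,
) -> ProximityResult:
    """Observed d_c plus its degree-matched permutation z-score.

    Each null iteration re-draws BOTH the DEG set and the target set in a
    degree-bin-matched manner. The null standard deviation is the
    population SD over iterations; a zero SD yields z_c = NaN and the
    drug cannot pass z-selection.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be at least 2")
    target_set = sorted(drug.targets)
    deg_set = sorted(degs.genes_in_network)
    if not deg_set:
        raise UndefinedDistanceError(
            f"cell type {degs.cell_type!r} has no DEG inside the interactome"
        )
    d_obs = closest_distance(target_set, deg_set, g)
    rng = _substream(seed, degs.cell_type, drug.drug_id)
    null = np.empty(n_iter)
    for i in range(n_iter):
        rnd_degs = sample_degree_matched(deg_set, bins, rng)
        rnd_targets = sample_degree_matched(target_set, bins, rng)
        null[i] = closest_distance(rnd_targets, rnd_degs, g)
    mu = float(null.mean())
    sd = float(null.std(ddof=0))
    z = (d_obs - mu) / sd if sd > 0 else float("nan")
    return ProximityResult(
        cell_type=degs.cell_type, drug_id=drug.drug_id,
        d_c=d_obs, null_mean=mu, null_sd=sd, z_c=z, n_iter=n_iter, seed=seed,
    )


def proximity_table(
    drugs: Sequence[DrugRecord],
    degs: Mapping[str, CellTypeDEGs],
    g: Interactome,
    bins: DegreeBins,
    n_iter: int = 1000,
    seed: int = 0,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Full (cell type x drug) proximity screen as a tidy table.

    Results are identical for any ``n_jobs`` because each pair owns a
    seed-derived RNG substream. Cell types whose DEGs all fall outside
    the interactome are skipped with a warning.
    """
    g.dist_matrix  # materialise once, before any forked work
    pairs = [
        (ct, drug)
        for ct in sorted(degs)
        for drug in sorted(drugs, key=lambda d: d.drug_id)
        if degs[ct].genes_in_network
    ]
    skipped = [ct for ct in degs if not degs[ct].genes_in_network]
    for ct in skipped:
        logger.warning("cell type %r has no in-network DEG; skipped in proximity", ct)
    if n_jobs == 1:
        results = [proximity_z(drug, degs[ct], g, bins, n_iter, seed) for ct, drug in pairs]
    else:
        results = Parallel(n_jobs=n_jobs)(
            delayed(proximity_z)(drug, degs[ct], g, bins, n_iter, seed) for ct, drug in pairs
        )
    return pd.DataFrame(
        {
            "cell_type": [r.cell_type for r in results],
            "drug_id": [r.drug_id for r in results],
            "d_c": [r.d_c for r in results],
            "null_mean": [r.null_mean for r in results],
            "null_sd": [r.null_sd for r in results],
            "z_c": [r.z_c for r in results],
            "n_iter": [r.n_iter for r in results],
            "seed": [r.seed for r in results],
        }
    )


def select_candidates(
    results: pd.DataFrame | Sequence[ProximityResult],
    z_thresh: float = Z_THRESHOLD,
    d_thresh: float = D_THRESHOLD,
) -> dict[str, set[str]]:
    """Dual cut-off: candidate iff z_c < z_thresh AND d_c < d_thresh (strict).

    NaN z-scores (degenerate nulls) never pass. Every cell type present
    in the input appears in the output, possibly with an empty set.
    """
    if isinstance(results, pd.DataFrame):
        rows = results.itertuples(index=False)
        triples = [(r.cell_type, r.drug_id, r.d_c, r.z_c) for r in rows]
    else:
        triples = [(r.cell_type, r.drug_id, r.d_c, r.z_c) for r in results]
    out: dict[str, set[str]] = {}
    for ct, drug_id, d_c, z_c in triples:
        out.setdefault(ct, set())
        if not math.isnan(z_c) and z_c < z_thresh and d_c < d_thresh:
            out[ct].add(drug_id)
    return out
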