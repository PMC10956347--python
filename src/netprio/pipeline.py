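"""End-to-end orchestration: inputs -> screen -> filter -> centralities -> ranking.

Every stage is a pure function of (inputs, config); outputs are tidy
TSVs plus a JSON manifest with the config echo, library versions, the
seed and input checksums, so a run is reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__, data_io, intracellular, mcdm, pharmacology, proximity, ranking
from .exceptions import StageError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All inputs and tunables of one screening run (defaults = printed values)."""

    interactome: str
    drugs: str
    degs: str
    expression_mtx: Optional[str] = None
    genes: Optional[str] = None
    cells: Optional[str] = None
    expression_tsv: Optional[str] = None
    prior: Optional[str] = None
    relevant: Optional[str] = None
    n_iter: int = 1000
    seed: int = 0
    min_bin: int = 100
    z_thresh: float = -1.64
    d_thresh: float = 1.0
    ea_cutoff: float = 0.2
    max_degs: Optional[int] = None
    intracellular_weight: float = 0.1
    top_k: int = 100
    n_jobs: int = 1

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class PipelineResult:
    config: RunConfig
    proximity_table: pd.DataFrame
    candidates_proximity: dict[str, set[str]]
    candidates: dict[str, set[str]]
    modules: dict[str, intracellular.DiseaseModule]
    intracellular_scores: dict[str, intracellular.IntracellularScore]
    mcdm: mcdm.MCDM
    rankings: list[ranking.DrugRanking]
    ranking_table: pd.DataFrame
    evaluation: Optional[pd.DataFrame] = None


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: RunConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute all stages; optionally write every stage table plus a manifest."""
    timings: dict[str, float] = {}

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", name)

            def __exit__(self, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self.t0
                if exc is not None:
                    raise StageError(name, exc) from exc
                logger.info("stage %s: done in %.2fs", name, timings[name])
        return _Timer()

    with stage("data_io"):
        g = data_io.load_interactome(config.interactome)
        drugs = data_io.load_drugs(config.drugs, g)
        degs = data_io.load_degs(config.degs, g, max_degs=config.max_degs)
        if config.expression_tsv:
            expr = data_io.load_expression_dense(config.expression_tsv, config.cells)
        elif config.expression_mtx:
            expr = data_io.load_expression(config.expression_mtx, config.genes, config.cells)
        else:
            raise ValueError("no expression input configured")
        relevant = data_io.load_relevant(config.relevant) if config.relevant else None

    with stage("proximity"):
        bins = proximity.build_degree_bins(g, min_size=config.min_bin)
        prox = proximity.proximity_table(
            drugs, degs, g, bins,
            n_iter=config.n_iter, seed=config.seed, n_jobs=config.n_jobs,
        )
        cand_prox = proximity.select_candidates(
            prox, z_thresh=config.z_thresh, d_thresh=config.d_thresh
        )

    with stage("pharmacology"):
        cand = pharmacology.filter_by_action(cand_prox, drugs, degs)

    with stage("intracellular"):
        modules = {ct: intracellular.deg_lcc(degs[ct], g) for ct in sorted(degs)}
        intra = intracellular.intracellular_scores(drugs, modules)

    with stage("mcdm"):
        if not config.prior:
            raise ValueError("no ligand-target prior configured")
        prior = data_io.load_prior(config.prior)
        model = mcdm.build_mcdm(degs, prior, expr, ea_cutoff=config.ea_cutoff)

    with stage("ranking"):
        inter = {
            d.drug_id: ranking.drug_intercellular(d.drug_id, cand, model.centrality)
            for d in drugs
        }
        combined = {d.drug_id: intra[d.drug_id].combined for d in drugs}
        scores = {
            d.drug_id: ranking.compound_score(
                inter[d.drug_id], combined[d.drug_id], config.intracellular_weight
            )
            for d in drugs
        }
        ranks = ranking.rank_drugs(
            scores, drugs, intercellular=inter, combined_intracellular=combined
        )
        rank_tbl = ranking.ranking_table(ranks, drugs, candidates=cand, relevant=relevant)
        evaluation = None
        if relevant:
            rows = []
            for k in sorted({config.top_k, len(ranks)}):
                sel = {r.drug_id for r in ranks if r.rank <= k}
                if sel:
                    p, r_ = ranking.precision_recall(sel, relevant)
                    rows.append((k, p, r_))
            evaluation = pd.DataFrame(rows, columns=["k", "precision", "recall"])

    result = PipelineResult(
        config=config, proximity_table=prox, candidates_proximity=cand_prox,
        candidates=cand, modules=modules, intracellular_scores=intra,
        mcdm=model, rankings=ranks, ranking_table=rank_tbl, evaluation=evaluation,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir), timings)
    return result


def _candidate_table(cand: dict[str, set[str]]) -> pd.DataFrame:
    rows = [(ct, d) for ct in sorted(cand) for d in sorted(cand[ct])]
    return pd.DataFrame(rows, columns=["cell_type", "drug_id"])


def _write_outputs(result: PipelineResult, out: Path, timings: dict[str, float]) -> None:
    out.mkdir(parents=True, exist_ok=True)
    fmt = dict(sep="\t", index=False, float_format="%.10g")
    result.proximity_table.to_csv(out / "proximity.tsv", **fmt)
    _candidate_table(result.candidates_proximity).to_csv(out / "candidates_proximity.tsv", **fmt)
    _candidate_table(result.candidates).to_csv(out / "candidates.tsv", **fmt)
    intracellular.module_table(result.modules).to_csv(out / "modules.tsv", **fmt)
    intracellular.intracellular_table(result.intracellular_scores).to_csv(
        out / "intracellular.tsv", **fmt
    )
    mcdm.interaction_table(result.mcdm).to_csv(out / "mcdm_interactions.tsv", **fmt)
    mcdm.edge_table(result.mcdm).to_csv(out / "mcdm_edges.tsv", **fmt)
    mcdm.centrality_table(result.mcdm).to_csv(out / "mcdm_centrality.tsv", **fmt)
    result.ranking_table.to_csv(out / "ranking.tsv", **fmt)
    if result.evaluation is not None:
        result.evaluation.to_csv(out / "evaluation.tsv", **fmt)

    cfg = result.config
    inputs = {
        name: _checksum(path)
        for name, path in (
            ("interactome", cfg.interactome), ("drugs", cfg.drugs), ("degs", cfg.degs),
            ("expression_mtx", cfg.expression_mtx), ("genes", cfg.genes),
            ("cells", cfg.cells), ("expression_tsv", cfg.expression_tsv),
            ("prior", cfg.prior), ("relevant", cfg.relevant),
        )
        if path
    }
    import networkx, numpy, pandas as _pd, scipy
    manifest = {
        "config": dataclasses.asdict(cfg),
        "seed": cfg.seed,
        "versions": {
            "netprio": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": _pd.__version__,
            "networkx": networkx.__version__,
        },
        "input_checksums": inputs,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
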