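"""Final rank aggregation and precision/recall evaluation.

A drug's intercellular centrality is the sum of MCDM cell-type
centralities over the cell types that selected it as a candidate. The
compound score is intercellular + 0.1 x combined intracellular, so
crosstalk importance dominates and intracellular centrality acts as a
tiebreaker. Drugs sharing an identical target set and per-target action
map form one tie group with identical rank; equal scores receive the
average of their positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import rankdata

from .data_io import DrugRecord

INTRACELLULAR_WEIGHT = 0.1
TOP_K = 100


def drug_intercellular(
    drug_id: str,
    candidates: Mapping[str, set[str]],
    centrality: Mapping[str, float],
) -> float:
    """Sum of crosstalk centralities of the cell types selecting the drug."""
    return float(
        sum(centrality.get(ct, 0.0) for ct, sel in candidates.items() if drug_id in sel)
    )


def compound_score(
    intercellular: float, combined_intracellular: float, weight: float = INTRACELLULAR_WEIGHT
) -> float:
    return intercellular + weight * combined_intracellular


@dataclass(frozen=True)
class DrugRanking:
    drug_id: str
    intercellular: float
    combined_intracellular: float
    compound: float
    rank: float
    tie_group: str


def _tie_group_key(drug: DrugRecord) -> str:
    items = ",".join(f"{t}:{drug.action[t]}" for t in sorted(drug.targets))
    return items


def rank_drugs(
    scores: Mapping[str, float],
    drugs: Sequence[DrugRecord],
    intercellular: Mapping[str, float] | None = None,
    combined_intracellular: Mapping[str, float] | None = None,
) -> list[DrugRanking]:
    """Descending-compound ranking with average ties over the full library.

    Drugs with identical targets and identical per-target actions are
    forced into one tie group carrying the group's maximum compound
    score, so biosimilars can never be split by numeric noise.
    """
    if not scores:
        raise ValueError("no scores to rank")
    by_id = {d.drug_id: d for d in drugs}
    groups: dict[str, str] = {}
    for drug_id in scores:
        groups[drug_id] = _tie_group_key(by_id[drug_id])
    group_max: dict[str, float] = {}
    for drug_id, score in scores.items():
        key = groups[drug_id]
        group_max[key] = max(group_max.get(key, float("-inf")), score)
    adjusted = {drug_id: group_max[groups[drug_id]] for drug_id in scores}

    ordered = sorted(adjusted, key=lambda d: (-adjusted[d], d))
    ranks = rankdata([-adjusted[d] for d in ordered], method="average")
    inter = intercellular or {}
    intra = combined_intracellular or {}
    return [
        DrugRanking(
            drug_id=d,
            intercellular=float(inter.get(d, 0.0)),
            combined_intracellular=float(intra.get(d, 0.0)),
            compound=adjusted[d],
            rank=float(r),
            tie_group=groups[d],
        )
        for d, r in zip(ordered, ranks)
    ]


def ranking_table(
    rankings: Sequence[DrugRanking],
    drugs: Sequence[DrugRecord],
    candidates: Mapping[str, set[str]] | None = None,
    relevant: set[str] | None = None,
) -> pd.DataFrame:
    by_id = {d.drug_id: d for d in drugs}
    n_selecting = {
        r.drug_id: sum(1 for sel in (candidates or {}).values() if r.drug_id in sel)
        for r in rankings
    }
    return pd.DataFrame(
        {
            "rank": [r.rank for r in rankings],
            "drug_id": [r.drug_id for r in rankings],
            "name": [by_id[r.drug_id].name for r in rankings],
            "compound": [r.compound for r in rankings],
            "intercellular": [r.intercellular for r in rankings],
            "combined_intracellular": [r.combined_intracellular for r in rankings],
            "n_selecting_cell_types": [n_selecting[r.drug_id] for r in rankings],
            "tie_group": [r.tie_group for r in rankings],
            "is_relevant": [r.drug_id in (relevant or set()) for r in rankings],
        }
    )


def precision_recall(selection: set[str], relevant: set[str]) -> tuple[float, float]:
    """precision = |relevant n selection| / |selection|; recall analogous."""
    if not selection:
        raise ValueError("precision undefined for an empty selection")
    if not relevant:
        raise ValueError("recall undefined for an empty relevant set")
    hits = len(selection & relevant)
    return hits / len(selection), hits / len(relevant)


def precision_at_rank(
    ranking: Sequence[DrugRanking], relevant: set[str], k: float = TOP_K
) -> float:
    """Precision over all drugs with rank <= k (ties can stretch the set)."""
    if not ranking:
        raise ValueError("empty ranking")
    selection = {r.drug_id for r in ranking if r.rank <= k}
    if not selection:
        return 0.0
    return len(selection & relevant) / len(selection)
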