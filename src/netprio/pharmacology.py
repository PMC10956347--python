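"""Pharmacological-action filter.

A proximity-selected drug stays a candidate for a cell type only if it
counteracts the fold change of at least one DEG it targets there: an
inhibitor of an upregulated gene, or an activator of a downregulated
one. Targets whose action is unknown are assumed not to counteract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .data_io import CellTypeDEGs, DrugRecord


def counteracts(action: str, logfc: float) -> bool:
    if logfc == 0:
        raise ValueError("logfc must be non-zero (rejected at load)")
    if action == "inhibit":
        return logfc > 0
    if action == "activate":
        return logfc < 0
    if action == "unknown":
        return False
    raise ValueError(f"invalid action: {action!r}")


@dataclass(frozen=True)
class ActionCall:
    """Per-(drug, cell type, target) record of the counteraction decision."""

    drug_id: str
    cell_type: str
    gene: int
    action: str
    logfc: float
    counteracts: bool


def action_calls(
    drug: DrugRecord, degs: CellTypeDEGs
) -> list[ActionCall]:
    """Evaluate counteraction for every drug target that is a DEG here."""
    logfc = degs.logfc
    calls = []
    for gene in sorted(drug.targets):
        if gene in logfc:
            act = drug.action[gene]
            calls.append(
                ActionCall(
                    drug_id=drug.drug_id, cell_type=degs.cell_type, gene=gene,
                    action=act, logfc=logfc[gene],
                    counteracts=counteracts(act, logfc[gene]),
                )
            )
    return calls


def filter_by_action(
    candidates: Mapping[str, set[str]],
    drugs: Sequence[DrugRecord],
    degs: Mapping[str, CellTypeDEGs],
) -> dict[str, set[str]]:
    """Keep a candidate iff it counteracts >= 1 targeted DEG of that cell type.

    Pure filter: output sets are subsets of the input sets; cell types
    whose whole candidate set is removed stay present as empty sets.
    """
    by_id = {d.drug_id: d for d in drugs}
    out: dict[str, set[str]] = {}
    for ct, drug_ids in candidates.items():
        kept: set[str] = set()
        for drug_id in drug_ids:
            drug = by_id[drug_id]
            if any(c.counteracts for c in action_calls(drug, degs[ct])):
                kept.add(drug_id)
        out[ct] = kept
    return out


def action_table(
    candidates: Mapping[str, set[str]],
    drugs: Sequence[DrugRecord],
    degs: Mapping[str, CellTypeDEGs],
) -> pd.DataFrame:
    """Explain table: one row per (cell type, candidate drug, targeted DEG)."""
    by_id = {d.drug_id: d for d in drugs}
    rows = []
    for ct in sorted(candidates):
        for drug_id in sorted(candidates[ct]):
            for c in action_calls(by_id[drug_id], degs[ct]):
                rows.append(
                    (c.cell_type, c.drug_id, c.gene, c.action, c.logfc, c.counteracts)
                )
    return pd.DataFrame(
        rows, columns=["cell_type", "drug_id", "gene", "action", "logfc", "counteracts"]
    )
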