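"""Consolidation of duplicated trout genes onto mammalian orthologues.

Salmonids carry a large complement of duplicated gene copies, so many trout
genes map onto one mammalian orthologue ID. Network-analysis tools keep a
single record per orthologue by selecting the duplicate copy with the highest
expression level (strongest log2 fold change, either positive or negative).
This module reproduces that selection per strain and quantifies cross-strain
"mismatches": duplicated orthologues whose selected copy flips the direction
of expression between strains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .expression import SharedDEGSet

logger = logging.getLogger(__name__)


def _round1(x: float) -> float:
    """Round half-up to one decimal, matching printed percentage style."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class MismatchSummary:
    """Counts and percentage rates of strain-discordant duplicate selections.

    Rates are percentages rounded half-up to one decimal.
    ``mismatch_rate_among_duplicated`` is denominated by unique duplicated
    orthologue IDs; ``mismatch_rate_among_all_mapped`` by all mapped DEG
    records entering consolidation; ``mismatch_rate_among_unique_mapped`` by
    unique mapped orthologue IDs.
    """

    comparison: str
    n_mapped_deg: int
    n_duplicate_records: int
    n_unique_duplicated_ids: int
    n_mismatches: int
    n_unique_mapped_ids_used: int
    mismatch_rate_among_duplicated: float
    mismatch_rate_among_all_mapped: float
    mismatch_rate_among_unique_mapped: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def consolidate(shared: SharedDEGSet, ortho_map: pd.DataFrame) -> pd.DataFrame:
    """Collapse shared DEG onto orthologue IDs, one record per orthologue.

    Per strain, the copy with the maximum |log2FC| is selected (ties broken
    by larger raw log2FC, then lexicographic gene ID). Genes absent from the
    map are dropped with a logged count. Duplicated orthologues whose
    selected copies disagree in sign between strains are flagged
    (``mismatch``) but retained; per strain, a flag records whether the
    additive total log2FC of all copies opposes the selected copy's sign.

    Returns a DataFrame indexed by ortholog_id with per-strain selected
    gene/log2FC/additive totals and the n_copies / is_duplicated / mismatch /
    additive_opposite columns; ``attrs`` carry the comparison label and the
    number of mapped DEG records.
    """
    if ortho_map.empty:
        raise ValueError("orthologue map is empty")
    dup_genes = ortho_map["trout_gene"].duplicated()
    if dup_genes.any():
        bad = ortho_map.loc[dup_genes, "trout_gene"].iloc[0]
        raise ValueError(f"trout gene {bad!r} maps to multiple orthologue records")

    s1, s2 = shared.strains
    tab = shared.table
    gene_to_orth = ortho_map.set_index("trout_gene")["ortholog_id"]
    mapped_mask = tab.index.isin(gene_to_orth.index)
    n_dropped = int((~mapped_mask).sum())
    if n_dropped:
        logger.info("dropping %d shared DEG absent from the orthologue map", n_dropped)
    tab = tab.loc[mapped_mask].copy()
    tab["ortholog_id"] = gene_to_orth.reindex(tab.index).to_numpy()

    records = []
    for oid, grp in tab.groupby("ortholog_id", sort=True):
        rec = {"ortholog_id": oid, "n_copies": int(len(grp))}
        rec["is_duplicated"] = len(grp) >= 2
        for s in (s1, s2):
            lfc = grp[f"log2fc_{s}"]
            order = sorted(
                zip(-lfc.abs().to_numpy(), -lfc.to_numpy(), grp.index.to_numpy())
            )
            sel_gene = order[0][2]
            sel = float(lfc.loc[sel_gene])
            add = float(lfc.sum())
            rec[f"selected_gene_{s}"] = sel_gene
            rec[f"selected_log2fc_{s}"] = sel
            rec[f"additive_log2fc_{s}"] = add
            rec[f"additive_opposite_{s}"] = bool(
                sel != 0 and add != 0 and np.sign(add) != np.sign(sel)
            )
        rec["mismatch"] = bool(
            np.sign(rec[f"selected_log2fc_{s1}"]) != np.sign(rec[f"selected_log2fc_{s2}"])
        )
        records.append(rec)

    out = pd.DataFrame(records).set_index("ortholog_id") if records else pd.DataFrame(
        columns=["n_copies", "is_duplicated", "mismatch"]
    )
    out.attrs["comparison"] = shared.comparison
    out.attrs["strains"] = (s1, s2)
    out.attrs["n_mapped_deg"] = int(mapped_mask.sum())
    out.attrs["n_dropped_unmapped"] = n_dropped
    return out


def summarize_mismatches(consolidated: pd.DataFrame) -> MismatchSummary:
    """Mismatch counts and percentage rates for one comparison.

    An empty table yields all-zero counts and 0.0 rates.
    """
    if len(consolidated) == 0:
        return MismatchSummary(
            comparison=consolidated.attrs.get("comparison", ""),
            n_mapped_deg=0,
            n_duplicate_records=0,
            n_unique_duplicated_ids=0,
            n_mismatches=0,
            n_unique_mapped_ids_used=0,
            mismatch_rate_among_duplicated=0.0,
            mismatch_rate_among_all_mapped=0.0,
            mismatch_rate_among_unique_mapped=0.0,
        )
    dup = consolidated[consolidated["is_duplicated"]]
    n_unique_dup = int(len(dup))
    n_dup_records = int(dup["n_copies"].sum())
    n_mis = int(dup["mismatch"].sum())
    n_mapped = int(consolidated.attrs.get("n_mapped_deg", consolidated["n_copies"].sum()))
    n_unique = int(len(consolidated))
    rate = lambda num, den: _round1(100.0 * num / den) if den else 0.0
    return MismatchSummary(
        comparison=consolidated.attrs.get("comparison", ""),
        n_mapped_deg=n_mapped,
        n_duplicate_records=n_dup_records,
        n_unique_duplicated_ids=n_unique_dup,
        n_mismatches=n_mis,
        n_unique_mapped_ids_used=n_unique,
        mismatch_rate_among_duplicated=rate(n_mis, n_unique_dup),
        mismatch_rate_among_all_mapped=rate(n_mis, n_mapped),
        mismatch_rate_among_unique_mapped=rate(n_mis, n_unique),
    )
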