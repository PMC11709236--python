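"""GO-slim count tables and the backward-elimination heterogeneity G-test.

For a pairwise comparison, the genes up-regulated in each of the two groups
are counted against a reduced (slim) GO vocabulary, separately per namespace
(biological process, cellular component, molecular function). A gene with k
slim terms contributes k counts. Terms are ranked by the difference in
percent counts between the groups; a positive difference means the term is
overrepresented in the focal group.

Overrepresented terms are identified by backward elimination: while the
overall heterogeneity G-test (G = 2 sum O ln(O/E), df = n_terms - 1) on the
term x group table is significant, the single term whose 2x2 partition
(term vs pooled remainder) carries the largest G is removed and recorded,
and the test is repeated on the reduced table. The likelihood-ratio G
decomposes additively over such partitions, so each removal subtracts its
partition G from the running total exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import NAMESPACES


def count_slim(
    genes_focal: set,
    genes_reference: set,
    annot: pd.DataFrame,
    *,
    namespaces: tuple = NAMESPACES,
) -> dict[str, pd.DataFrame]:
    """Per-namespace term x group count tables with percent differences.

    ``genes_focal`` / ``genes_reference`` are disjoint gene sets (typically
    the genes up-regulated in each group of a comparison); ``annot`` has
    columns (gene, namespace, term). Terms with zero counts in both groups
    are dropped, and each table is sorted by percent difference descending.

    Table columns: term, n_focal, n_ref, pct_focal, pct_ref, pct_diff.
    """
    genes_focal, genes_reference = set(genes_focal), set(genes_reference)
    if not genes_focal and not genes_reference:
        raise ValueError("both gene sets are empty")
    overlap = genes_focal & genes_reference
    if overlap:
        raise ValueError(f"gene sets are not disjoint (e.g. {sorted(overlap)[0]!r})")

    out = {}
    for ns in namespaces:
        sub = annot[annot["namespace"] == ns]
        nf = sub[sub["gene"].isin(genes_focal)]["term"].value_counts()
        nr = sub[sub["gene"].isin(genes_reference)]["term"].value_counts()
        terms = sorted(set(nf.index) | set(nr.index))
        tab = pd.DataFrame(
            {
                "term": terms,
                "n_focal": [int(nf.get(t, 0)) for t in terms],
                "n_ref": [int(nr.get(t, 0)) for t in terms],
            }
        )
        n_tot_f, n_tot_r = tab["n_focal"].sum(), tab["n_ref"].sum()
        tab["pct_focal"] = 100.0 * tab["n_focal"] / n_tot_f if n_tot_f else 0.0
        tab["pct_ref"] = 100.0 * tab["n_ref"] / n_tot_r if n_tot_r else 0.0
        tab["pct_diff"] = tab["pct_focal"] - tab["pct_ref"]
        tab = tab.sort_values(
            ["pct_diff", "term"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        out[ns] = tab
    return out


def g_statistic(table: np.ndarray, *, williams: bool = False):
    """Heterogeneity G-test on an R x 2 count table.

    G = 2 sum O ln(O/E) with E from row/column margins; zero cells
    contribute 0. df = R - 1; p from the chi-square upper tail. With
    ``williams=True`` the Williams small-sample correction divides G by
    q = 1 + (a-1)(b-1)/(6 N df') before computing p (a, b = number of rows
    and columns with positive totals).

    Returns ``(G, df, p)``.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[1] != 2:
        raise ValueError("table must be R x 2")
    row_tot = obs.sum(axis=1)
    obs = obs[row_tot > 0]
    row_tot = row_tot[row_tot > 0]
    if obs.shape[0] < 2:
        raise ValueError("need at least 2 rows with positive totals")
    col_tot = obs.sum(axis=0)
    if (col_tot <= 0).any():
        raise ValueError("both column totals must be positive")
    n = obs.sum()
    expected = np.outer(row_tot, col_tot) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    g = 2.0 * terms.sum()
    g = max(g, 0.0)
    df = obs.shape[0] - 1
    if williams:
        a, b = obs.shape
        q = 1.0 + ((n / row_tot).sum() - 1) * ((n / col_tot).sum() - 1) / (6.0 * n * df)
        g = g / q
    p = float(stats.chi2.sf(g, df))
    return float(g), int(df), p


def _partition_g(counts: np.ndarray, i: int) -> float:
    """G of the 2x2 table (row i vs pooled remainder)."""
    top = counts[i]
    rest = counts.sum(axis=0) - top
    g, _, _ = g_statistic(np.vstack([top, rest]))
    return g


@dataclass
class Removal:
    term: str
    step: int
    partition_g: float
    p_partition: float
    enriched_group: str
    pct_diff: float


@dataclass
class GTestOutcome:
    """Result of the backward-elimination procedure on one count table."""

    alpha: float
    initial_g: float
    initial_df: int
    initial_p: float
    residual_g: float
    residual_df: int
    residual_p: float
    removals: list[Removal] = field(default_factory=list)
    remaining_terms: list[str] = field(default_factory=list)

    @property
    def significant_terms(self) -> list[str]:
        return [r.term for r in self.removals]

    def enriched_in(self, group: str) -> list[str]:
        return [r.term for r in self.removals if r.enriched_group == group]


def backward_eliminate(
    table: pd.DataFrame,
    alpha: float = 0.05,
    *,
    focal_label: str = "focal",
    reference_label: str = "reference",
    williams: bool = False,
) -> GTestOutcome:
    """Iteratively remove the most heterogeneous term until homogeneity.

    ``table`` is a count table as produced by :func:`count_slim` (columns
    term, n_focal, n_ref). While the overall G-test is significant at
    ``alpha`` and more than one term remains, the term with the largest 2x2
    partition G (term vs pooled remainder) is removed; ties are broken by
    larger |percent difference|, then term ID. Each removal records the step,
    partition G and the enriched group — the sign of the percent difference
    at the time of removal (positive = focal group).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    work = table[["term", "n_focal", "n_ref"]].copy()
    # silently drop rows with zero total (untestable)
    work = work[(work["n_focal"] + work["n_ref"]) > 0].reset_index(drop=True)

    counts0 = work[["n_focal", "n_ref"]].to_numpy(dtype=float)
    g0, df0, p0 = g_statistic(counts0, williams=williams)

    removals: list[Removal] = []
    step = 0
    g, df, p = g0, df0, p0
    while p < alpha and len(work) > 2:
        counts = work[["n_focal", "n_ref"]].to_numpy(dtype=float)
        tot_f, tot_r = counts.sum(axis=0)
        cand = []
        for i in range(len(work)):
            gi = _partition_g(counts, i)
            pct_diff = 100.0 * (counts[i, 0] / tot_f - counts[i, 1] / tot_r)
            # maximal partition G; ties -> larger |pct diff|, then term ID
            cand.append((-gi, -abs(pct_diff), str(work.loc[i, "term"]), i, gi, pct_diff))
        _, _, _, i, gi, pct_diff = min(cand)
        step += 1
        removals.append(
            Removal(
                term=str(work.loc[i, "term"]),
                step=step,
                partition_g=gi,
                p_partition=float(stats.chi2.sf(gi, 1)),
                enriched_group=focal_label if pct_diff > 0 else reference_label,
                pct_diff=pct_diff,
            )
        )
        work = work.drop(index=i).reset_index(drop=True)
        g, df, p = g_statistic(
            work[["n_focal", "n_ref"]].to_numpy(dtype=float), williams=williams
        )

    # two terms left and still significant: the pair is mutually heterogeneous
    if p < alpha and len(work) == 2:
        counts = work[["n_focal", "n_ref"]].to_numpy(dtype=float)
        tot_f, tot_r = counts.sum(axis=0)
        diffs = 100.0 * (counts[:, 0] / tot_f - counts[:, 1] / tot_r)
        i = int(np.argmax(np.abs(diffs)))
        step += 1
        removals.append(
            Removal(
                term=str(work.loc[i, "term"]),
                step=step,
                partition_g=g,
                p_partition=p,
                enriched_group=focal_label if diffs[i] > 0 else reference_label,
                pct_diff=float(diffs[i]),
            )
        )
        work = work.drop(index=i).reset_index(drop=True)
        g, df, p = np.nan, 0, 1.0

    return GTestOutcome(
        alpha=alpha,
        initial_g=g0,
        initial_df=df0,
        initial_p=p0,
        residual_g=float(g),
        residual_df=int(df),
        residual_p=float(p),
        removals=removals,
        remaining_terms=[str(t) for t in work["term"]],
    )


def annotate_outcome(table: pd.DataFrame, outcome: GTestOutcome) -> pd.DataFrame:
    """Attach removal step / partition G / enriched group columns to a count table."""
    by_term = {r.term: r for r in outcome.removals}
    out = table.copy()
    out["removal_step"] = [
        by_term[t].step if t in by_term else pd.NA for t in out["term"]
    ]
    out["partition_G"] = [
        by_term[t].partition_g if t in by_term else np.nan for t in out["term"]
    ]
    out["p_at_removal"] = [
        by_term[t].p_partition if t in by_term else np.nan for t in out["term"]
    ]
    out["enriched_group"] = [
        by_term[t].enriched_group if t in by_term else "" for t in out["term"]
    ]
    return out
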