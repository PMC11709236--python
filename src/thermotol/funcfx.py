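"""Pathway/regulator filtering rules and the functional-effects group score.

The inputs here are externally produced network-analysis exports: canonical
pathway tables (pathway, activation z-score, enrichment p), upstream-regulator
tables (orthologue, predicted activation z-score, p) and gene -> function ->
effect association tables stating whether enhanced expression of a gene
increases, decreases or merely affects a physiological function.

Filtering rules:

* directional pathways (z != 0) are dropped when -log10(p) < 1.3 (minor
  interacting gene sets); neutral pathways (z missing or 0) are kept only
  when -log10(p) > 1.3 (major bidirectional gene sets);
* upstream regulators are "major" when |z| >= 2.0, and "matched" when the
  predicted activation state agrees with the observed H-vs-L expression
  direction (activated & up in H, or inhibited & down in H).

The Functional Effects Group score summarizes, per function and tolerance
group g, the effect annotations of the genes enhanced in g:

    FE_g = (n_increase - n_decrease) / (n_increase + n_decrease + n_affect)

bounded in [-1, 1]; a G-test on the groups x categories contingency table
then asks whether the two groups differ in their category proportions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

logger = logging.getLogger(__name__)

EFFECT_LABELS = ("increases", "decreases", "affects")


# ---------------------------------------------------------------------------
# Canonical pathways
# ---------------------------------------------------------------------------

def filter_pathways(records: pd.DataFrame, threshold: float = 1.3) -> pd.DataFrame:
    """Apply the directional/neutral pathway retention rule.

    ``records`` needs columns (pathway, z, p); z may be NaN for neutral
    pathways. Adds ``neg_log10_p`` and ``status`` columns; status is one of
    enhanced (z > 0, retained), repressed (z < 0, retained), neutral
    (z missing/0, retained) or filtered-out.
    """
    out = records.copy()
    p = out["p"].to_numpy(dtype=float)
    if (p <= 0).any() or (p > 1).any():
        bad = out.loc[(p <= 0) | (p > 1), "pathway"].iloc[0]
        raise ValueError(f"p-value out of (0, 1] for pathway {bad!r}")
    nlp = -np.log10(p)
    z = out["z"].to_numpy(dtype=float) if "z" in out else np.full(len(out), np.nan)
    neutral = np.isnan(z) | (z == 0)
    status = np.where(
        neutral,
        np.where(nlp > threshold, "neutral", "filtered-out"),
        np.where(nlp < threshold, "filtered-out", np.where(z > 0, "enhanced", "repressed")),
    )
    out["neg_log10_p"] = nlp
    out["status"] = status
    return out


# ---------------------------------------------------------------------------
# Upstream regulators
# ---------------------------------------------------------------------------

@dataclass
class RegulatorSummary:
    n_input: int
    n_significant: int
    n_major: int
    n_match: dict  # per group
    top_by_z: dict  # group -> list of ortholog IDs
    top_by_expression: dict


def classify_regulators(
    regulators: pd.DataFrame,
    consolidated_hvl: pd.DataFrame,
    *,
    z_major: float = 2.0,
    top_k: int = 10,
    focal_label: str = "H",
    reference_label: str = "L",
):
    """Flag and rank upstream regulators against observed H-vs-L expression.

    ``regulators`` has columns (ortholog_id, z, p); ``consolidated_hvl`` is
    the consolidated H-vs-L table whose cross-strain mean selected log2FC
    gives the observed expression direction (positive = up in H). Regulators
    without a significant consolidated entry are dropped. A regulator is
    major when |z| >= z_major; it matches the prediction when (z >= z_major
    and log2FC > 0) or (z <= -z_major and log2FC < 0). Top-k lists among
    matching regulators are produced per group, by |z| and by |log2FC|.

    Classification is a pure function of (z, log2FC): input order never
    changes flags or rank lists.

    Returns ``(records DataFrame, RegulatorSummary)``.
    """
    if regulators.empty:
        raise ValueError("regulator table is empty")
    s1, s2 = consolidated_hvl.attrs.get("strains", ("strain1", "strain2"))
    obs = (
        consolidated_hvl[f"selected_log2fc_{s1}"]
        + consolidated_hvl[f"selected_log2fc_{s2}"]
    ) / 2.0

    recs = regulators.copy()
    known = recs["ortholog_id"].isin(obs.index)
    n_dropped = int((~known).sum())
    if n_dropped:
        logger.info("dropping %d regulators without significant expression", n_dropped)
    recs = recs.loc[known].copy()
    recs["log2fc"] = obs.reindex(recs["ortholog_id"]).to_numpy()
    z = recs["z"].to_numpy(dtype=float)
    lfc = recs["log2fc"].to_numpy(dtype=float)
    recs["predicted_state"] = np.where(z > 0, "activated", "inhibited")
    recs["is_major"] = np.abs(z) >= z_major
    recs["is_match"] = ((z >= z_major) & (lfc > 0)) | ((z <= -z_major) & (lfc < 0))
    recs["group"] = np.where(lfc > 0, focal_label, reference_label)

    recs = recs.sort_values("ortholog_id", kind="mergesort").reset_index(drop=True)
    match = recs[recs["is_match"]]
    # dense ranks among matching regulators, strongest first
    recs["z_rank"] = pd.NA
    recs["expression_rank"] = pd.NA
    for col, rank_col in (("z", "z_rank"), ("log2fc", "expression_rank")):
        r = match[col].abs().rank(method="dense", ascending=False).astype(int)
        recs.loc[match.index, rank_col] = r

    def top(group: str, col: str) -> list:
        sub = match[match["group"] == group]
        sub = sub.iloc[
            np.lexsort((sub["ortholog_id"].to_numpy(), -sub[col].abs().to_numpy()))
        ]
        return list(sub["ortholog_id"].head(top_k))

    summary = RegulatorSummary(
        n_input=int(len(regulators)),
        n_significant=int(len(recs)),
        n_major=int(recs["is_major"].sum()),
        n_match={
            g: int((match["group"] == g).sum()) for g in (focal_label, reference_label)
        },
        top_by_z={g: top(g, "z") for g in (focal_label, reference_label)},
        top_by_expression={g: top(g, "log2fc") for g in (focal_label, reference_label)},
    )
    return recs, summary


# ---------------------------------------------------------------------------
# Functional Effects Group score
# ---------------------------------------------------------------------------

def _g_test_2xk(counts: np.ndarray):
    """Likelihood-ratio G-test on a 2 x k table (zero cells contribute 0)."""
    obs = np.asarray(counts, dtype=float)
    col_tot = obs.sum(axis=0)
    obs = obs[:, col_tot > 0]
    if obs.shape[1] < 2:
        return np.nan, 0, np.nan
    row_tot = obs.sum(axis=1)
    col_tot = obs.sum(axis=0)
    n = obs.sum()
    expected = np.outer(row_tot, col_tot) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    g = max(2.0 * terms.sum(), 0.0)
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return float(g), int(df), float(stats.chi2.sf(g, df))


def _exact_2xk(counts: np.ndarray) -> float:
    """Freeman-Halton style exact test for a 2 x k table by enumeration.

    Sums the conditional probabilities (fixed margins) of all tables no more
    probable than the observed one. Intended for small totals only.
    """
    obs = np.asarray(counts, dtype=int)
    col_tot = obs.sum(axis=0)
    obs = obs[:, col_tot > 0]
    col_tot = obs.sum(axis=0)
    r1 = int(obs[0].sum())
    n = int(obs.sum())

    def log_prob(row: tuple) -> float:
        lp = -(gammaln(n + 1) - gammaln(r1 + 1) - gammaln(n - r1 + 1))
        for x, c in zip(row, col_tot):
            lp += gammaln(c + 1) - gammaln(x + 1) - gammaln(c - x + 1)
        return lp

    lp_obs = log_prob(tuple(int(x) for x in obs[0]))
    total = 0.0
    ranges = [range(0, int(c) + 1) for c in col_tot[:-1]]
    for head in itertools.product(*ranges):
        last = r1 - sum(head)
        if last < 0 or last > col_tot[-1]:
            continue
        lp = log_prob(head + (last,))
        if lp <= lp_obs + 1e-9:
            total += np.exp(lp)
    return float(min(total, 1.0))


@dataclass
class FEGResult:
    """Per-function two-group functional-effects comparison."""

    function_id: str
    counts: dict  # group -> (n_increase, n_decrease, n_affect)
    feg: dict  # group -> score or NaN
    statistic: float
    p: float
    direction: dict  # group -> increased / decreased / indeterminate


def _feg_score(inc: int, dec: int, aff: int) -> float:
    tot = inc + dec + aff
    return (inc - dec) / tot if tot else np.nan


def compute_feg(
    assoc: pd.DataFrame,
    directions: pd.Series | dict,
    *,
    alpha: float = 0.05,
    groups: tuple = ("H", "L"),
    exact_threshold: float = 1.0,
) -> list[FEGResult]:
    """Functional Effects Group scores with a two-group proportion test.

    ``assoc`` has columns (ortholog_id, function_id, effect) with effect in
    {increases, decreases, affects}; ``directions`` maps orthologue ->
    enhanced group. Orthologues without a direction are skipped with a logged
    count; functions with zero covered genes in both groups are skipped. The
    two-group test is a G-test on the groups x categories table after
    dropping categories empty in both groups, falling back to an exact
    enumeration test when any expected cell drops below ``exact_threshold``.
    Direction calls: increased if FE_g > 0 and p <= alpha, decreased if
    FE_g < 0 and p <= alpha, else indeterminate.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    bad = set(assoc["effect"]) - set(EFFECT_LABELS)
    if bad:
        raise ValueError(f"unknown effect label {sorted(bad)[0]!r}")
    dirs = dict(directions) if not isinstance(directions, dict) else directions

    covered = assoc["ortholog_id"].map(dirs.get).notna()
    n_uncovered = int((~covered).sum())
    if n_uncovered:
        logger.info("skipping %d associations without direction calls", n_uncovered)
    sub = assoc.loc[covered].copy()
    sub["group"] = sub["ortholog_id"].map(dirs)

    tallies = (
        sub.groupby(["function_id", "group", "effect"], sort=True).size()
        if len(sub)
        else pd.Series(dtype=int)
    )
    results = []
    for fid in sorted(assoc["function_id"].unique()):
        counts = {}
        for g in groups:
            counts[g] = tuple(
                int(tallies.get((fid, g, e), 0)) for e in EFFECT_LABELS
            )
        totals = {g: sum(c) for g, c in counts.items()}
        if all(t == 0 for t in totals.values()):
            continue  # nothing to score
        feg = {g: _feg_score(*counts[g]) for g in groups}
        if any(t == 0 for t in totals.values()):
            stat, p = np.nan, np.nan  # one group empty: no test
        else:
            mat = np.array([counts[g] for g in groups], dtype=float)
            keep = mat.sum(axis=0) > 0
            mat = mat[:, keep]
            row_tot = mat.sum(axis=1)
            col_tot = mat.sum(axis=0)
            expected = np.outer(row_tot, col_tot) / mat.sum()
            if (expected < exact_threshold).any() and mat.sum() <= 500:
                stat, p = np.nan, _exact_2xk(mat)
            else:
                stat, _, p = _g_test_2xk(mat)
        direction = {}
        for g in groups:
            score = feg[g]
            if np.isnan(score) or not (p == p) or p > alpha:
                direction[g] = "indeterminate"
            else:
                direction[g] = (
                    "increased" if score > 0 else "decreased" if score < 0 else "indeterminate"
                )
        results.append(
            FEGResult(
                function_id=fid,
                counts=counts,
                feg=feg,
                statistic=stat,
                p=p,
                direction=direction,
            )
        )
    return results


def feg_table(results: list[FEGResult], groups: tuple = ("H", "L")) -> pd.DataFrame:
    """Flatten FEG results to one row per function."""
    rows = []
    for r in results:
        row = {"function_id": r.function_id, "statistic": r.statistic, "p": r.p}
        for g in groups:
            inc, dec, aff = r.counts[g]
            row.update(
                {
                    f"n_increase_{g}": inc,
                    f"n_decrease_{g}": dec,
                    f"n_affect_{g}": aff,
                    f"feg_{g}": r.feg[g],
                    f"direction_{g}": r.direction[g],
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)
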