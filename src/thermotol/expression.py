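"""Normalization, differential expression, PCA, and cross-strain shared-DEG accounting.

The experimental design is two rainbow-trout strains (e.g. Alma, Lyndon), each
with three groups: untreated controls (C), low thermal tolerance (L) and high
thermal tolerance (H) fish sampled from a critical-thermal-maximum trial.
Differential expression is tested pairwise within a strain (HvC, LvC, HvL) and
the per-strain significant sets are then intersected across strains to find the
shared transcriptomic signature of tolerance.

The differential-expression engine is a per-gene negative-binomial Wald test
with method-of-moments dispersion shrunk toward the global mean, plus an
independent filter on average expression applied before Benjamini-Hochberg
correction ("filter on average gene expression for FDR correction").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: sentinel for genes excluded by the expression filter (never significant)
Q_SENTINEL = np.nan

COMPARISONS = ("HvC", "LvC", "HvL")
#: focal (first) and reference (second) group per comparison label; positive
#: log2FC = up in the focal group.
COMPARISON_GROUPS = {"HvC": ("H", "C"), "LvC": ("L", "C"), "HvL": ("H", "L")}


class ThermotolError(Exception):
    """Base class for errors raised by this package."""


@dataclass
class CountMatrix:
    """Integer gene x sample read counts with gene lengths and library sizes.

    Parameters
    ----------
    counts : DataFrame
        Genes in rows, samples in columns, non-negative integers.
    lengths : Series
        Gene length in bp, indexed like ``counts``.
    """

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = self.counts.index.difference(self.lengths.index)
        if len(missing):
            raise ValueError(f"missing gene length for gene {missing[0]!r}")
        self.lengths = self.lengths.reindex(self.counts.index)
        if (self.lengths.to_numpy() <= 0).any():
            bad = self.lengths.index[self.lengths.to_numpy() <= 0][0]
            raise ValueError(f"non-positive length for gene {bad!r}")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        """Total counts per sample (column sums)."""
        return self.counts.sum(axis=0)

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, counts_path, lengths_path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="gene")
        self.lengths.rename("length").to_csv(lengths_path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, counts_path, lengths_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="gene")
        lengths = pd.read_csv(lengths_path, sep="\t", index_col="gene")["length"]
        return cls(counts, lengths)


def normalize(cm: CountMatrix, unit: str = "TPM") -> pd.DataFrame:
    """Length/depth-normalize counts to TPM or RPKM.

    TPM_gs = 1e6 * (c_gs / L_g) / sum_g'(c_g's / L_g');
    RPKM_gs = 1e9 * c_gs / (L_g * N_s) with N_s the library size.

    TPM columns each sum to one million; RPKM columns do not.
    The returned frame carries the unit in ``attrs["unit"]``.
    """
    unit = unit.upper()
    if unit not in ("TPM", "RPKM"):
        raise ValueError(f"unknown unit {unit!r}")
    c = cm.counts.to_numpy(dtype=float)
    lens = cm.lengths.to_numpy(dtype=float)
    lib = c.sum(axis=0)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise ValueError(f"zero library size for sample {cm.samples[zero[0]]!r}")
    if unit == "TPM":
        rate = c / lens[:, None]
        vals = 1e6 * rate / rate.sum(axis=0, keepdims=True)
    else:
        vals = 1e9 * c / (lens[:, None] * lib[None, :])
    out = pd.DataFrame(vals, index=cm.genes, columns=cm.samples)
    out.attrs["unit"] = unit
    return out


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def _size_factors(cm: CountMatrix) -> np.ndarray:
    lib = cm.library_sizes.to_numpy(dtype=float)
    if (lib == 0).any():
        bad = cm.samples[np.flatnonzero(lib == 0)[0]]
        raise ValueError(f"zero library size for sample {bad!r}")
    return lib / lib.mean()


def test_de(
    cm: CountMatrix,
    metadata: pd.DataFrame,
    group_a: str,
    group_b: str,
    *,
    filter_threshold: float = 1.0,
    q_cut: float = 0.01,
    comparison: str | None = None,
    strain: str | None = None,
) -> pd.DataFrame:
    """Two-group negative-binomial Wald test with filtered FDR.

    Counts are normalized by library-size factors; per-gene dispersion is
    estimated by method of moments from within-group variances, floored at
    1e-8 and shrunk 50/50 toward the global mean dispersion. The Wald
    statistic on the difference of log group means is referred to a t
    distribution whose df are moment-matched to the shrunk dispersion
    estimator (4 x (n_a + n_b - 2) at the default 50/50 shrinkage), a
    small-sample correction that keeps null p-values uniform.

    Genes whose mean normalized count over all samples is below
    ``filter_threshold`` are excluded before Benjamini-Hochberg correction and
    carry q = NaN (never significant). Positive log2FC = up in ``group_a``.

    Returns a DataFrame indexed by gene with columns log2fc, p, q,
    passed_filter, significant; comparison/strain labels are stored in
    ``attrs``.
    """
    for g in (group_a, group_b):
        if g not in set(metadata["group"]):
            raise ValueError(f"group {g!r} absent from metadata")
    samples_a = metadata.loc[metadata["group"] == group_a, "sample"]
    samples_b = metadata.loc[metadata["group"] == group_b, "sample"]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each group needs at least 2 replicates")

    f = pd.Series(_size_factors(cm), index=cm.samples)
    q_norm = cm.counts.div(f, axis=1)  # library-size-normalized counts
    qa = q_norm[list(samples_a)].to_numpy(dtype=float)
    qb = q_norm[list(samples_b)].to_numpy(dtype=float)
    na, nb = qa.shape[1], qb.shape[1]
    inv_fa = float(np.mean(1.0 / f[list(samples_a)].to_numpy()))
    inv_fb = float(np.mean(1.0 / f[list(samples_b)].to_numpy()))

    ma, mb = qa.mean(axis=1), qb.mean(axis=1)
    va = qa.var(axis=1, ddof=1)
    vb = qb.var(axis=1, ddof=1)

    # method-of-moments dispersion: Var(c/f) ~ m/f + phi m^2, per group
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_a = (va - ma * inv_fa) / np.square(ma)
        phi_b = (vb - mb * inv_fb) / np.square(mb)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        phi = np.nanmean(np.stack([phi_a, phi_b]), axis=0)
    phi = np.where(np.isfinite(phi), phi, 0.0)
    phi = np.maximum(phi, 1e-8)
    shrink = 0.5
    phi = (1 - shrink) * phi + shrink * float(np.mean(phi))

    pseudo = 0.5
    log2fc = np.log2((ma + pseudo) / (mb + pseudo))
    # delta-method variance of log mean estimates
    var_ma = (ma * inv_fa + phi * np.square(ma)) / na
    var_mb = (mb * inv_fb + phi * np.square(mb)) / nb
    se2 = var_ma / np.square(ma + pseudo) + var_mb / np.square(mb + pseudo)
    se = np.sqrt(np.maximum(se2, 1e-300))
    wald = (np.log(ma + pseudo) - np.log(mb + pseudo)) / se
    # t reference with moment-matched df: shrinking the dispersion by a
    # factor (1 - shrink) scales the variance of its estimator by
    # (1 - shrink)^2, inflating the effective chi-square df accordingly
    df_eff = (na + nb - 2) / (1 - shrink) ** 2
    pvals = 2.0 * stats.t.sf(np.abs(wald), df=df_eff)
    pvals = np.clip(pvals, 0.0, 1.0)

    mean_all = q_norm.mean(axis=1).to_numpy()
    passed = mean_all >= filter_threshold
    qvals = np.full(len(pvals), Q_SENTINEL)
    if passed.any():
        qvals[passed] = stats.false_discovery_control(pvals[passed], method="bh")

    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": pvals,
            "q": qvals,
            "passed_filter": passed,
            "significant": passed & (qvals <= q_cut),
        },
        index=cm.genes,
    )
    out.attrs["comparison"] = comparison or f"{group_a}v{group_b}"
    out.attrs["strain"] = strain
    out.attrs["q_cut"] = q_cut
    return out


# ---------------------------------------------------------------------------
# Cross-strain shared DEG
# ---------------------------------------------------------------------------

@dataclass
class SharedDEGSet:
    """Intersection of two strains' significant gene sets for one comparison.

    ``table`` holds one row per shared gene with per-strain log2FC, the
    cross-strain average, and a concordance flag; it is sorted by average
    log2FC descending (ties broken by gene ID). Direction-discordant shared
    genes are flagged but retained.
    """

    comparison: str
    strains: tuple[str, str]
    sig_sets: dict = field(repr=False)
    table: pd.DataFrame = field(repr=False)
    venn: dict = field(default_factory=dict)
    shared_proportion: dict = field(default_factory=dict)
    upregulated_proportion: dict = field(default_factory=dict)

    @property
    def shared_genes(self) -> list:
        return list(self.table.index)


def intersect_shared(deg1: pd.DataFrame, deg2: pd.DataFrame, q_cut: float = 0.01) -> SharedDEGSet:
    """Intersect the significant gene sets of two strains for one comparison.

    Shared genes receive the average log2FC across strains and are ranked
    from highest to lowest average; Venn counts (unique to each strain,
    shared) and per-group upregulated proportions are recorded.
    """
    c1 = deg1.attrs.get("comparison")
    c2 = deg2.attrs.get("comparison")
    if c1 != c2:
        raise ValueError(f"mismatched comparison labels: {c1!r} vs {c2!r}")
    s1 = deg1.attrs.get("strain") or "strain1"
    s2 = deg2.attrs.get("strain") or "strain2"

    sig1 = deg1.index[(deg1["q"] <= q_cut).fillna(False)]
    sig2 = deg2.index[(deg2["q"] <= q_cut).fillna(False)]
    shared = sig1.intersection(sig2)

    lfc1 = deg1.loc[shared, "log2fc"]
    lfc2 = deg2.loc[shared, "log2fc"]
    tab = pd.DataFrame(
        {
            f"log2fc_{s1}": lfc1,
            f"log2fc_{s2}": lfc2,
            "avg_log2fc": (lfc1 + lfc2) / 2.0,
            "concordant": np.sign(lfc1) == np.sign(lfc2),
        },
        index=shared,
    )
    tab = tab.sort_values(["avg_log2fc"], ascending=False, kind="mergesort")
    # deterministic tie-break on gene ID
    tab = tab.iloc[np.lexsort((tab.index.to_numpy(), -tab["avg_log2fc"].to_numpy()))]

    venn = {
        f"unique_{s1}": int(len(sig1.difference(sig2))),
        f"unique_{s2}": int(len(sig2.difference(sig1))),
        "shared": int(len(shared)),
    }
    shared_prop = {
        s1: len(shared) / len(sig1) if len(sig1) else 0.0,
        s2: len(shared) / len(sig2) if len(sig2) else 0.0,
    }
    focal, reference = COMPARISON_GROUPS.get(c1, ("focal", "reference"))
    up_prop = {}
    for strain, deg, sig in ((s1, deg1, sig1), (s2, deg2, sig2)):
        if len(sig):
            up = float((deg.loc[sig, "log2fc"] > 0).mean())
        else:
            up = 0.0
        up_prop[strain] = {focal: up, reference: 1.0 - up if len(sig) else 0.0}

    return SharedDEGSet(
        comparison=c1,
        strains=(s1, s2),
        sig_sets={s1: set(sig1), s2: set(sig2)},
        table=tab,
        venn=venn,
        shared_proportion=shared_prop,
        upregulated_proportion=up_prop,
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: pd.DataFrame
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    n_retained: int


def run_pca(expr: pd.DataFrame, variance_target: float = 0.843) -> PCAResult:
    """Correlation-matrix PCA with samples as observations.

    Expression values (genes x samples) are transposed, centred and scaled to
    unit variance per gene; zero-variance genes are dropped with a warning.
    Retains the smallest number of components whose cumulative explained
    variance reaches ``variance_target``.
    """
    from sklearn.decomposition import PCA

    if expr.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = expr.to_numpy(dtype=float).T  # samples x genes
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d zero-variance genes before scaling", n_dropped)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 non-constant genes")
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(z)
    pct = pca.explained_variance_ratio_ * 100.0
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_retained = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    n_retained = min(n_retained, len(pct))
    score_df = pd.DataFrame(
        scores,
        index=expr.columns,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    return PCAResult(
        scores=score_df,
        eigenvalues=pca.explained_variance_,
        percent_variance=pct,
        n_retained=n_retained,
    )
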