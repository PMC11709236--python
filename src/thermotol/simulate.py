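"""Seeded synthetic datasets with planted truth for the full analysis pipeline.

Emulates the statistical structure of a two-strain critical-thermal-maximum
RNA-seq experiment: two strains x three groups (control C, low tolerance L,
high tolerance H) x 6 replicates, negative-binomial gene counts with planted
differential-expression fractions and effect sizes, a many-to-one
trout-gene -> mammalian-orthologue map with duplicated (salmonid ohnolog-like)
copies and a small strain-discordance rate, GO-slim annotations with planted
term-enrichment shifts, and gene -> function -> effect association tables with
planted increase/decrease/affect proportions.

All randomness flows through one seed; per-artifact sub-streams are derived
deterministically so identical parameters give bit-identical outputs.

The differential-expression plan and the orthologue/duplicate structure are
planned jointly before counts are drawn, so the planted strain-discordant
duplicated orthologues are exactly recoverable from true log2 fold changes by
the consolidation stage.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import COMPARISON_GROUPS, CountMatrix

NAMESPACES = ("BP", "CC", "MF")

# fixed sub-stream keys, one per artifact
_STREAMS = {
    "abundance": 0,
    "lengths": 1,
    "libsizes": 2,
    "de_plan": 3,
    "ortho_plan": 4,
    "counts": 5,
    "annotations": 6,
    "associations": 7,
    "network": 8,
}


class ParameterError(ValueError):
    """Invalid simulation parameter; the message names the offending field."""


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic experiment.

    Defaults mirror the study design: two strains, groups C/L/H, six
    replicates per group. Effect sizes are log2 fold changes drawn from
    N(lfc_mean, lfc_sd) with a random sign (50/50 up/down); ``shared_frac``
    of planted DE gene identities are common to both strains.
    """

    n_genes: int = 5000
    n_reps_per_group: int = 6
    strains: tuple[str, str] = ("Alma", "Lyndon")
    groups: tuple[str, str, str] = ("C", "L", "H")
    frac_de: float = 0.1
    lfc_mean: float = 2.0
    lfc_sd: float = 0.5
    dispersion: float = 0.1
    lib_size_mean: float = 2e6
    lib_size_cv: float = 0.2
    shared_frac: float = 0.5
    dup_fraction: float = 0.3
    discord_rate: float = 0.05
    n_terms: int = 30
    terms_per_gene_mean: float = 2.0
    enriched_terms: tuple = ()  # (term, group, multiplier) triples
    n_functions: int = 20
    genes_per_function_mean: float = 30.0
    effect_mix_by_group: tuple = (
        ("H", (1 / 3, 1 / 3, 1 / 3)),
        ("L", (1 / 3, 1 / 3, 1 / 3)),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ParameterError("n_genes must be positive")
        if self.n_reps_per_group < 2:
            raise ParameterError("n_reps_per_group must be >= 2")
        if len(self.strains) != 2:
            raise ParameterError("strains must have exactly 2 labels")
        if len(self.groups) != 3:
            raise ParameterError("groups must have exactly 3 labels")
        for name in ("frac_de", "shared_frac", "dup_fraction", "discord_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1]")
        if self.dispersion < 0:
            raise ParameterError("dispersion must be >= 0")
        if self.lib_size_mean <= 0:
            raise ParameterError("lib_size_mean must be positive")
        if self.lib_size_cv < 0:
            raise ParameterError("lib_size_cv must be >= 0")
        if self.terms_per_gene_mean < 0:
            raise ParameterError("terms_per_gene_mean must be >= 0")
        if self.n_terms < 1:
            raise ParameterError("n_terms must be positive")
        for _, mix in self.effect_mix_by_group:
            if len(mix) != 3 or abs(sum(mix) - 1.0) > 1e-9 or min(mix) < 0:
                raise ParameterError(
                    "effect_mix_by_group proportions must be 3 non-negative values summing to 1"
                )
        for term, group, mult in self.enriched_terms:
            if group not in self.groups:
                raise ParameterError(f"enriched_terms group {group!r} not in groups")
            if mult < 0:
                raise ParameterError("enriched_terms multiplier must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([_STREAMS[stream], int(self.seed)])


@dataclass
class GroundTruth:
    """Planted truth emitted alongside every synthetic dataset.

    ``de`` maps "strain:comparison" -> {gene: true log2FC}; ``ortholog_plan``
    maps orthologue ID -> list of trout genes; ``discordant_orthologs`` is the
    set whose dominant (max |log2FC|) copy flips sign between strains;
    ``shared_hvl`` lists genes with a non-zero true HvL log2FC in both
    strains; ``hvl_lfc`` maps strain -> {gene: true HvL log2FC}.
    """

    de: dict = field(default_factory=dict)
    hvl_lfc: dict = field(default_factory=dict)
    shared_hvl: list = field(default_factory=list)
    ortholog_plan: dict = field(default_factory=dict)
    discordant_orthologs: list = field(default_factory=list)
    enriched_terms: list = field(default_factory=list)
    function_mixes: dict = field(default_factory=dict)
    function_genes: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:06d}" for i in range(n)]


def _plan_orthologs(params: SimulationParams, rng: np.random.Generator) -> list[list[int]]:
    """Partition gene indices into orthologue groups of size 1 (singleton) or
    2-3 (duplicated, with probability dup_fraction)."""
    order = rng.permutation(params.n_genes)
    groups: list[list[int]] = []
    i = 0
    while i < params.n_genes:
        if rng.random() < params.dup_fraction:
            size = int(rng.integers(2, 4))
        else:
            size = 1
        groups.append([int(g) for g in order[i : i + size]])
        i += size
    return groups


def simulate_counts(params: SimulationParams):
    """Draw the count matrix, sample metadata and ground truth.

    Counts for gene g in sample s are NB(mean = lib_size_s * p_g *
    2^effect, Var = mu + dispersion * mu^2); dispersion 0 degenerates to
    Poisson. The planted effect depends on the sample's strain and group.

    Returns ``(CountMatrix, metadata DataFrame, GroundTruth)``. Metadata
    columns: sample, strain, group, lib_size (realized column sum).
    """
    genes = _gene_ids(params.n_genes)
    n = params.n_genes
    ctrl, low, high = params.groups

    rng_ab = params.rng("abundance")
    weights = rng_ab.lognormal(mean=0.0, sigma=1.2, size=n)
    rel_abund = weights / weights.sum()

    rng_len = params.rng("lengths")
    lengths = np.exp(rng_len.uniform(np.log(300.0), np.log(10000.0), size=n))
    lengths = np.round(lengths).astype(int)

    # --- effect plan -------------------------------------------------------
    # effects[strain][group] = per-gene log2FC relative to control
    effects = {s: {low: np.zeros(n), high: np.zeros(n)} for s in params.strains}
    rng_de = params.rng("de_plan")
    rng_ortho = params.rng("ortho_plan")
    ortho_groups = _plan_orthologs(params, rng_ortho)

    n_de = int(round(params.frac_de * n))
    n_shared = int(round(params.shared_frac * n_de))
    n_own = n_de - n_shared

    perm = list(rng_de.permutation(n))
    cursor = 0

    def take(k: int) -> list[int]:
        nonlocal cursor
        if cursor + k > n:
            raise ParameterError("n_genes too small for requested frac_de")
        block = perm[cursor : cursor + k]
        cursor += k
        return block

    def draw_lfc(rng: np.random.Generator, size: int) -> np.ndarray:
        mag = np.maximum(np.abs(rng.normal(params.lfc_mean, params.lfc_sd, size)), 0.25)
        sign = rng.choice([-1.0, 1.0], size=size)
        return mag * sign

    for comp, grp in (("HvC", high), ("LvC", low)):
        shared_idx = take(n_shared)
        shared_lfc = draw_lfc(rng_de, n_shared)
        for s in params.strains:
            own_idx = take(n_own)
            own_lfc = draw_lfc(rng_de, n_own)
            eff = effects[s][grp]
            eff[shared_idx] = shared_lfc
            eff[own_idx] = own_lfc

    # --- planted discordant duplicated orthologues -------------------------
    # For a discordant orthologue, copy a dominates in strain 1 with one sign
    # while copy b dominates in strain 2 with the opposite sign; both copies
    # are differentially expressed (H vs L) in both strains.
    discordant: list[str] = []
    dup_groups = [g for g in ortho_groups if len(g) >= 2]
    s1, s2 = params.strains
    # discordance is a property of duplicated DE genes; a null experiment
    # (frac_de = 0) therefore plants none
    for grp_idx, members in enumerate(dup_groups if params.frac_de > 0 else []):
        u = rng_ortho.random()
        if u >= params.discord_rate:
            # paralogous copies are often co-regulated: with probability
            # frac_de plant a concordant shared effect on every copy, so the
            # consolidation stage sees realistic concordant duplicates too
            if u < params.discord_rate + params.frac_de:
                sign = rng_ortho.choice([-1.0, 1.0])
                for g_idx in members:
                    mag = abs(rng_ortho.normal(params.lfc_mean, params.lfc_sd)) + 0.25
                    for s in params.strains:
                        effects[s][high][g_idx] = mag if sign > 0 else 0.0
                        effects[s][low][g_idx] = mag if sign < 0 else 0.0
            continue
        a, b = members[0], members[1]
        hi1 = abs(rng_ortho.normal(params.lfc_mean, params.lfc_sd)) + 0.5
        hi2 = abs(rng_ortho.normal(params.lfc_mean, params.lfc_sd)) + 0.5
        lo_a2 = rng_ortho.uniform(0.2, 0.6) * hi2
        lo_b1 = rng_ortho.uniform(0.2, 0.6) * hi1
        flip = rng_ortho.choice([-1.0, 1.0])
        pattern = {
            a: {s1: flip * hi1, s2: flip * lo_a2},
            b: {s1: -flip * lo_b1, s2: -flip * hi2},
        }
        for g_idx, per_strain in pattern.items():
            for s, hvl in per_strain.items():
                # realize an HvL effect via the H (hvl > 0) or L (hvl < 0) group
                effects[s][high][g_idx] = max(hvl, 0.0)
                effects[s][low][g_idx] = max(-hvl, 0.0)
        for extra in members[2:]:
            for s in params.strains:
                effects[s][high][extra] = 0.0
                effects[s][low][extra] = 0.0
        discordant.append(grp_idx)  # resolved to IDs below

    # --- sampling ----------------------------------------------------------
    n_samples = 2 * 3 * params.n_reps_per_group
    rng_lib = params.rng("libsizes")
    sigma = np.sqrt(np.log1p(params.lib_size_cv**2))
    mu_log = np.log(params.lib_size_mean) - sigma**2 / 2
    lib_sizes = rng_lib.lognormal(mu_log, sigma, size=n_samples)

    rng_counts = params.rng("counts")
    sample_names, strains_col, groups_col = [], [], []
    cols = []
    k = 0
    for s in params.strains:
        for g in params.groups:
            mult = np.ones(n) if g == ctrl else np.exp2(effects[s][g])
            for r in range(params.n_reps_per_group):
                mu = lib_sizes[k] * rel_abund * mult
                if params.dispersion == 0:
                    col = rng_counts.poisson(mu)
                else:
                    size_nb = 1.0 / params.dispersion
                    p_nb = size_nb / (size_nb + mu)
                    col = rng_counts.negative_binomial(size_nb, p_nb)
                cols.append(col)
                sample_names.append(f"{s}_{g}_{r + 1}")
                strains_col.append(s)
                groups_col.append(g)
                k += 1

    counts = pd.DataFrame(
        np.column_stack(cols), index=genes, columns=sample_names
    )
    cm = CountMatrix(counts, pd.Series(lengths, index=genes, name="length"))
    meta = pd.DataFrame(
        {
            "sample": sample_names,
            "strain": strains_col,
            "group": groups_col,
            "lib_size": counts.sum(axis=0).to_numpy(),
        }
    )

    # --- truth -------------------------------------------------------------
    truth = GroundTruth()
    hvl = {}
    for s in params.strains:
        hvl[s] = effects[s][high] - effects[s][low]
        for comp in ("HvC", "LvC", "HvL"):
            if comp == "HvC":
                arr = effects[s][high]
            elif comp == "LvC":
                arr = effects[s][low]
            else:
                arr = hvl[s]
            nz = np.flatnonzero(arr)
            truth.de[f"{s}:{comp}"] = {genes[i]: float(arr[i]) for i in nz}
        truth.hvl_lfc[s] = {genes[i]: float(hvl[s][i]) for i in np.flatnonzero(hvl[s])}
    both = np.flatnonzero((hvl[s1] != 0) & (hvl[s2] != 0))
    truth.shared_hvl = [genes[i] for i in both]

    ortho_ids = {}
    plan = {}
    for j, members in enumerate(ortho_groups):
        oid = f"ORTH{j:06d}"
        plan[oid] = [genes[i] for i in sorted(members)]
        ortho_ids[id(members)] = oid
    truth.ortholog_plan = plan
    truth.discordant_orthologs = sorted(
        ortho_ids[id(dup_groups[j])] for j in discordant
    )
    truth.enriched_terms = [list(t) for t in params.enriched_terms]
    truth.function_mixes = {g: list(mix) for g, mix in params.effect_mix_by_group}
    return cm, meta, truth


def simulate_annotations(params: SimulationParams, truth: GroundTruth) -> pd.DataFrame:
    """Gene -> GO-slim term table (columns gene, namespace, term).

    Each gene draws Poisson(terms_per_gene_mean) distinct terms per namespace
    from a weighted term universe; genes whose planted enhanced group matches
    an entry of ``params.enriched_terms`` have that term's weight multiplied,
    planting a proportion shift detectable by the G-test stage.
    """
    rng = params.rng("annotations")
    genes = _gene_ids(params.n_genes)
    universe = {ns: [f"{ns}:{i:04d}" for i in range(params.n_terms)] for ns in NAMESPACES}
    valid = {t for terms in universe.values() for t in terms}
    for term, group, mult in params.enriched_terms:
        if term not in valid:
            raise ParameterError(f"enriched term {term!r} not in term universe")

    # enhanced group per gene from the sign of the true HvL log2FC (strain 1)
    _, low, high = params.groups[0], params.groups[1], params.groups[2]
    s1 = params.strains[0]
    enhanced: dict[str, str] = {}
    for g, lfc in truth.hvl_lfc.get(s1, {}).items():
        enhanced[g] = high if lfc > 0 else low

    rows_gene, rows_ns, rows_term = [], [], []
    if params.terms_per_gene_mean > 0:
        for ns in NAMESPACES:
            terms = universe[ns]
            base = np.ones(len(terms))
            boosts = [
                (terms.index(t), grp, m)
                for t, grp, m in params.enriched_terms
                if t.startswith(ns + ":")
            ]
            ks = rng.poisson(params.terms_per_gene_mean, size=params.n_genes)
            for gi, k in enumerate(ks):
                if k == 0:
                    continue
                k = min(int(k), len(terms))
                w = base
                gene = genes[gi]
                if boosts and gene in enhanced:
                    w = base.copy()
                    for ti, grp, m in boosts:
                        if enhanced[gene] == grp:
                            w[ti] *= m
                pick = rng.choice(len(terms), size=k, replace=False, p=w / w.sum())
                for ti in pick:
                    rows_gene.append(gene)
                    rows_ns.append(ns)
                    rows_term.append(terms[ti])
    return pd.DataFrame({"gene": rows_gene, "namespace": rows_ns, "term": rows_term})


def simulate_ortholog_map(params: SimulationParams, truth: GroundTruth) -> pd.DataFrame:
    """Materialize the planned trout-gene -> orthologue table.

    Columns (trout_gene, ortholog_id); with dup_fraction 0 the map is a
    bijection. Duplicated orthologues have 2-3 trout copies; the planted
    strain-discordant subset is listed in ``truth.discordant_orthologs``.
    """
    rows = [
        (gene, oid)
        for oid, members in sorted(truth.ortholog_plan.items())
        for gene in members
    ]
    return pd.DataFrame(rows, columns=["trout_gene", "ortholog_id"])


def simulate_function_associations(params: SimulationParams, truth: GroundTruth) -> pd.DataFrame:
    """Gene-function association table (ortholog_id, function_id, effect).

    Each function links ~Poisson(genes_per_function_mean) orthologues whose
    planted enhanced group is known; the effect label (increases / decreases /
    affects) is drawn from ``effect_mix_by_group`` for that group. The
    generating proportions are recorded in ``truth.function_mixes``.
    """
    rng = params.rng("associations")
    mixes = dict(params.effect_mix_by_group)
    _, low, high = params.groups
    s1, s2 = params.strains

    # orthologue-level enhanced group: dominant true HvL copy, concordant only
    gene_lfc1 = truth.hvl_lfc.get(s1, {})
    gene_lfc2 = truth.hvl_lfc.get(s2, {})
    discordant = set(truth.discordant_orthologs)
    orth_group: dict[str, str] = {}
    for oid, members in truth.ortholog_plan.items():
        if oid in discordant:
            continue
        lfcs = [(abs(gene_lfc1.get(g, 0.0)), gene_lfc1.get(g, 0.0), g) for g in members]
        mag, lfc, g = max(lfcs)
        if mag == 0 or g not in gene_lfc2:
            continue
        orth_group[oid] = high if lfc > 0 else low

    pool = sorted(orth_group)
    labels = ["increases", "decreases", "affects"]
    rows = []
    truth.function_genes = {}
    for j in range(params.n_functions):
        fid = f"FN{j:03d}"
        size = int(rng.poisson(params.genes_per_function_mean))
        size = min(size, len(pool))
        chosen = [] if size == 0 else list(rng.choice(pool, size=size, replace=False))
        truth.function_genes[fid] = sorted(chosen)
        for oid in sorted(chosen):
            grp = orth_group[oid]
            mix = mixes.get(grp, (1 / 3, 1 / 3, 1 / 3))
            effect = labels[int(rng.choice(3, p=mix))]
            rows.append((oid, fid, effect))
    return pd.DataFrame(rows, columns=["ortholog_id", "function_id", "effect"])


def simulate_network_tables(params: SimulationParams, truth: GroundTruth):
    """Synthetic stand-ins for externally produced network-analysis tables.

    Returns ``(pathways, regulators)`` DataFrames shaped like the pathway /
    upstream-regulator exports the pipeline consumes: pathways.tsv (pathway,
    z, p, comparison) and regulators.tsv (ortholog_id, z, p). Regulator
    z-scores are centred on the planted activation direction so that matched
    and mismatched predictions both occur.
    """
    rng = params.rng("network")
    _, low, high = params.groups
    s1 = params.strains[0]
    gene_lfc1 = truth.hvl_lfc.get(s1, {})
    discordant = set(truth.discordant_orthologs)
    cand = []
    for oid, members in sorted(truth.ortholog_plan.items()):
        if oid in discordant:
            continue
        lfcs = [gene_lfc1.get(g, 0.0) for g in members]
        dom = max(lfcs, key=abs)
        if dom != 0:
            cand.append((oid, dom))
    m = min(len(cand), max(20, len(cand) // 5))
    idx = rng.choice(len(cand), size=m, replace=False) if cand else []
    reg_rows = []
    for i in sorted(idx):
        oid, dom = cand[i]
        z = rng.normal(2.5 * np.sign(dom), 1.5)
        p = 10 ** (-rng.uniform(0.5, 4.0))
        reg_rows.append((oid, round(float(z), 3), float(p)))
    regulators = pd.DataFrame(reg_rows, columns=["ortholog_id", "z", "p"])

    pw_rows = []
    for j in range(40):
        z = 0.0 if rng.random() < 0.25 else float(rng.normal(0.0, 2.0))
        p = 10 ** (-rng.uniform(0.0, 4.0))
        pw_rows.append((f"PW{j:03d}", round(z, 3), float(p), "HvL"))
    pathways = pd.DataFrame(pw_rows, columns=["pathway", "z", "p", "comparison"])
    return pathways, regulators


def write_dataset(params: SimulationParams, outdir) -> GroundTruth:
    """Run every generator and write the full TSV/MTX/JSON artifact set."""
    import os

    from scipy import io as sio
    from scipy import sparse

    os.makedirs(outdir, exist_ok=True)
    cm, meta, truth = simulate_counts(params)
    annot = simulate_annotations(params, truth)
    omap = simulate_ortholog_map(params, truth)
    assoc = simulate_function_associations(params, truth)
    pathways, regulators = simulate_network_tables(params, truth)

    j = lambda name: os.path.join(outdir, name)
    cm.to_tsv(j("counts.tsv"), j("lengths.tsv"))
    sio.mmwrite(j("counts.mtx"), sparse.csr_matrix(cm.counts.to_numpy()))
    with open(j("counts.mtx.rows"), "w") as fh:
        fh.write("\n".join(cm.genes) + "\n")
    with open(j("counts.mtx.cols"), "w") as fh:
        fh.write("\n".join(cm.samples) + "\n")
    meta.to_csv(j("meta.tsv"), sep="\t", index=False)
    annot.to_csv(j("annot.tsv"), sep="\t", index=False)
    omap.to_csv(j("orthomap.tsv"), sep="\t", index=False)
    assoc.to_csv(j("assoc.tsv"), sep="\t", index=False)
    pathways.to_csv(j("pathways.tsv"), sep="\t", index=False)
    regulators.to_csv(j("regulators.tsv"), sep="\t", index=False)
    truth.to_json(j("truth.json"))
    return truth
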