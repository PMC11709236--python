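"""End-to-end orchestration: counts -> DEG -> shared -> GO -> consolidation ->
pathways/regulators -> functional effects.

Stage order mirrors the analysis workflow: within-strain differential
expression for the three pairwise group comparisons, cross-strain
intersection, correlation PCA of the significant genes, GO-slim counting and
backward-elimination G-tests on the up-regulated gene sets, duplicate
consolidation onto orthologues, then the externally supplied pathway /
regulator tables and the FE_g functional-effects comparison.

Every artifact is a UTF-8 TSV with a header row (JSON for nested
summaries), so the whole run is greppable and diffable; ``report.json`` is a
pure function of (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .expression import (
    COMPARISON_GROUPS,
    COMPARISONS,
    CountMatrix,
    intersect_shared,
    normalize,
    run_pca,
    test_de,
)
from .funcfx import classify_regulators, compute_feg, feg_table, filter_pathways
from .goslim import annotate_outcome, backward_eliminate, count_slim
from .orthomap import consolidate, summarize_mismatches
from .simulate import NAMESPACES

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full pipeline run."""

    counts: str
    lengths: str
    meta: str
    outdir: str
    annot: str | None = None
    orthomap: str | None = None
    assoc: str | None = None
    pathways: str | None = None
    regulators: str | None = None
    q_cut: float = 0.01
    filter_mean: float = 1.0
    g_alpha: float = 0.05
    feg_alpha: float = 0.05
    z_major: float = 2.0
    logp_cut: float = 1.3
    top_k: int = 10
    pca_variance_target: float = 0.843
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("q_cut", "g_alpha", "feg_alpha"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigError(f"{name} must be in (0, 1]")
        if self.filter_mean < 0:
            raise ConfigError("filter_mean must be >= 0")
        if self.z_major < 0:
            raise ConfigError("z_major must be >= 0")
        if self.top_k < 1:
            raise ConfigError("top_k must be >= 1")
        if not 0.0 < self.pca_variance_target <= 1.0:
            raise ConfigError("pca_variance_target must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, writing artifacts and a summary report to outdir.

    Returns the report dict (also written to ``report.json``). Any stage
    failure raises :class:`PipelineError` naming the stage; partial outputs
    are kept and a ``failed/<stage>`` marker directory is written.
    """
    os.makedirs(config.outdir, exist_ok=True)
    out = lambda name: os.path.join(config.outdir, name)
    report: dict = {}
    stages_done: list[str] = []
    current = "load"

    def checkpoint(stage: str) -> None:
        nonlocal current
        stages_done.append(current)
        logger.info("stage %s done (%.1fs elapsed)", current, time.time() - t0)
        current = stage

    t0 = time.time()
    try:
        # ---- load --------------------------------------------------------
        cm = CountMatrix.from_tsv(config.counts, config.lengths)
        meta = pd.read_csv(config.meta, sep="\t")
        strains = sorted(meta["strain"].unique())
        if len(strains) != 2:
            raise ValueError(f"expected 2 strains, found {strains}")

        # ---- deg ---------------------------------------------------------
        checkpoint("deg")
        deg: dict[tuple[str, str], pd.DataFrame] = {}
        report["deg_counts"] = {}
        for strain in strains:
            sub = meta[meta["strain"] == strain]
            for comp in COMPARISONS:
                a, b = COMPARISON_GROUPS[comp]
                tab = test_de(
                    cm,
                    sub,
                    a,
                    b,
                    filter_threshold=config.filter_mean,
                    q_cut=config.q_cut,
                    comparison=comp,
                    strain=strain,
                )
                deg[(strain, comp)] = tab
                tab.to_csv(out(f"deg_{strain}_{comp}.tsv"), sep="\t", index_label="gene")
                report["deg_counts"][f"{strain}:{comp}"] = int(tab["significant"].sum())

        # ---- shared ------------------------------------------------------
        checkpoint("shared")
        shared = {}
        report["shared"] = {}
        for comp in COMPARISONS:
            s = intersect_shared(deg[(strains[0], comp)], deg[(strains[1], comp)], config.q_cut)
            shared[comp] = s
            s.table.to_csv(out(f"shared_{comp}.tsv"), sep="\t", index_label="gene")
            _write_json(out(f"venn_{comp}.json"), s.venn)
            report["shared"][comp] = {
                "venn": s.venn,
                "shared_proportion": {k: round(v, 4) for k, v in s.shared_proportion.items()},
                "upregulated_proportion": {
                    k: {g: round(v, 4) for g, v in d.items()}
                    for k, d in s.upregulated_proportion.items()
                },
            }

        # ---- pca ---------------------------------------------------------
        checkpoint("pca")
        sig_genes = sorted(
            set().union(*(t.index[t["significant"]] for t in deg.values()))
        )
        if len(sig_genes) >= 2:
            expr = normalize(cm, "TPM").loc[sig_genes]
            pca = run_pca(expr, config.pca_variance_target)
            pca.scores.to_csv(out("pca_scores.tsv"), sep="\t", index_label="sample")
            report["pca"] = {
                "n_genes": len(sig_genes),
                "n_retained": pca.n_retained,
                "percent_variance_retained": round(
                    float(pca.percent_variance[: pca.n_retained].sum()), 2
                ),
                "percent_variance_pc1_pc2": [
                    round(float(v), 2) for v in pca.percent_variance[:2]
                ],
            }
        else:
            report["pca"] = {"n_genes": len(sig_genes), "skipped": True}

        # ---- goslim ------------------------------------------------------
        checkpoint("goslim")
        if config.annot:
            annot = pd.read_csv(config.annot, sep="\t")
            report["goslim"] = {}
            for comp in COMPARISONS:
                focal, reference = COMPARISON_GROUPS[comp]
                tab = shared[comp].table
                up_focal = set(tab.index[tab["avg_log2fc"] > 0])
                up_ref = set(tab.index[tab["avg_log2fc"] < 0])
                if not up_focal and not up_ref:
                    report["goslim"][comp] = {"skipped": True}
                    continue
                slim = count_slim(up_focal, up_ref, annot)
                report["goslim"][comp] = {}
                for ns in NAMESPACES:
                    if len(slim[ns]) < 2:
                        report["goslim"][comp][ns] = {"skipped": True}
                        continue
                    outcome = backward_eliminate(
                        slim[ns],
                        config.g_alpha,
                        focal_label=focal,
                        reference_label=reference,
                    )
                    annotated = annotate_outcome(slim[ns], outcome)
                    annotated.to_csv(out(f"goslim_{comp}_{ns}.tsv"), sep="\t", index=False)
                    report["goslim"][comp][ns] = {
                        "n_terms": int(len(slim[ns])),
                        "n_removed": len(outcome.removals),
                        "enriched": {
                            g: outcome.enriched_in(g) for g in (focal, reference)
                        },
                    }

        # ---- consolidate -------------------------------------------------
        checkpoint("consolidate")
        consolidated = {}
        if config.orthomap:
            omap = pd.read_csv(config.orthomap, sep="\t")
            mism = {}
            for comp in COMPARISONS:
                cons = consolidate(shared[comp], omap)
                consolidated[comp] = cons
                cons.to_csv(out(f"consolidated_{comp}.tsv"), sep="\t", index_label="ortholog_id")
                mism[comp] = summarize_mismatches(cons).to_dict()
            _write_json(out("mismatch_summary.json"), mism)
            report["mismatch"] = mism

        # ---- network (pathways / regulators) ------------------------------
        checkpoint("network")
        if config.pathways:
            pw = filter_pathways(pd.read_csv(config.pathways, sep="\t"), config.logp_cut)
            pw.to_csv(out("pathways_filtered.tsv"), sep="\t", index=False)
            report["pathways"] = {
                "n_input": int(len(pw)),
                "status_counts": {
                    k: int(v) for k, v in pw["status"].value_counts().sort_index().items()
                },
            }
        if config.regulators and "HvL" in consolidated:
            regs_in = pd.read_csv(config.regulators, sep="\t")
            recs, summary = classify_regulators(
                regs_in,
                consolidated["HvL"],
                z_major=config.z_major,
                top_k=config.top_k,
            )
            recs.to_csv(out("regulators_classified.tsv"), sep="\t", index=False)
            for grp, ids in summary.top_by_z.items():
                sub = recs[recs["ortholog_id"].isin(ids)]
                sub.to_csv(out(f"top_regulators_{grp}.tsv"), sep="\t", index=False)
            report["regulators"] = {
                "n_input": summary.n_input,
                "n_significant": summary.n_significant,
                "n_major": summary.n_major,
                "n_match": summary.n_match,
                "top_by_z": summary.top_by_z,
                "top_by_expression": summary.top_by_expression,
            }

        # ---- feg ----------------------------------------------------------
        checkpoint("feg")
        if config.assoc and "HvL" in consolidated:
            assoc = pd.read_csv(config.assoc, sep="\t")
            cons = consolidated["HvL"]
            s1, s2 = cons.attrs["strains"]
            mean_lfc = (
                cons[f"selected_log2fc_{s1}"] + cons[f"selected_log2fc_{s2}"]
            ) / 2.0
            focal, reference = COMPARISON_GROUPS["HvL"]
            ok = ~cons["mismatch"]
            directions = {
                oid: (focal if v > 0 else reference)
                for oid, v in mean_lfc[ok].items()
                if v != 0
            }
            results = compute_feg(
                assoc, directions, alpha=config.feg_alpha, groups=(focal, reference)
            )
            ftab = feg_table(results, groups=(focal, reference))
            ftab.to_csv(out("feg_results.tsv"), sep="\t", index=False)
            report["feg"] = {
                "n_functions": int(len(ftab)),
                "n_significant": int((ftab["p"] <= config.feg_alpha).sum())
                if len(ftab)
                else 0,
                "direction_counts": {
                    g: {
                        k: int(v)
                        for k, v in ftab[f"direction_{g}"].value_counts().sort_index().items()
                    }
                    for g in (focal, reference)
                }
                if len(ftab)
                else {},
            }

        checkpoint("done")
    except Exception as exc:
        failed_dir = out("failed")
        os.makedirs(failed_dir, exist_ok=True)
        with open(os.path.join(failed_dir, current), "w") as fh:
            fh.write(f"{type(exc).__name__}: {exc}\n")
        raise PipelineError(current, str(exc)) from exc

    _write_json(out("report.json"), report)
    cfg = config.to_dict()
    manifest = {
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "stages": stages_done,
        "versions": {
            "thermotol": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    _write_json(out("manifest.json"), manifest)
    return report
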