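"""Config-driven end-to-end analysis.

Stages run in the order the analysis dictates: enterotype assignment first,
then per-enterotype diversity, biomarkers, co-occurrence network, assembly
and niche breadth, and finally the trait association (RDA).  One global
seed fans out to per-stage seeds derived from the stage name, so toggling
one stage never shifts another stage's randomness.  The JSON report is
byte-identical across runs with the same config.
"""

from __future__ import annotations

import json
import logging
import sys
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assembly as asm
from . import association as assoc
from . import differential as diff
from . import diversity as div
from . import network as net
from . import niche as nic
from .core_io import (
    CountTable,
    SampleMetadata,
    TaxonomyMap,
    collapse_rank,
    filter_taxa,
    read_count_table,
    read_metadata,
    read_taxonomy,
    read_tree,
    to_relative,
)
from .enterotyping import pcoa, select_enterotypes

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "stage_seed"]

logger = logging.getLogger("enterostrat")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage derived seed (stage-name hashed, stable across runs)."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """All inputs and thresholds; defaults are the study's values."""

    counts: str | Path = ""
    taxonomy: str | Path = ""
    metadata: str | Path = ""
    tree: str | Path | None = None
    outdir: str | Path = "enterostrat_out"
    seed: int = -1  # mandatory; validated in run_pipeline

    # thresholds
    min_mean_relabund: float = 1e-4  # 0.01 %
    min_prevalence: float = 0.30
    rho_min: float = 0.6
    q_max: float = 0.05
    lda_threshold: float = 2.5
    alpha: float = 0.05
    k_min: int = 2
    k_max: int = 6
    n_perm: int = 999
    n_perm_niche: int = 1000
    train_split: float = 0.7

    # stage toggles
    run_diversity: bool = True
    run_differential: bool = True
    run_network: bool = True
    run_assembly: bool = True
    run_niche: bool = True
    run_association: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.seed is None or self.seed < 0:
            raise ValueError("seed is mandatory and must be a nonnegative integer")
        for name, v, lo, hi in (
            ("min_mean_relabund", self.min_mean_relabund, 0, 1),
            ("min_prevalence", self.min_prevalence, 0, 1),
            ("rho_min", self.rho_min, 0, 1),
            ("q_max", self.q_max, 0, 1),
            ("alpha", self.alpha, 0, 1),
            ("train_split", self.train_split, 0, 1),
        ):
            if not lo <= v <= hi:
                raise ValueError(f"{name} must be in [{lo}, {hi}], got {v}")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("need 2 <= k_min <= k_max")
        if self.run_assembly and not self.tree:
            raise ValueError(
                "assembly stage requires a phylogenetic tree (set 'tree' or "
                "disable run_assembly)"
            )


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, float)):
        return round(float(x), 10)
    if isinstance(x, (np.integer, int)):
        return int(x)
    return x


def run_pipeline(
    cfg: PipelineConfig,
    inputs: tuple | None = None,
) -> dict:
    """Execute all enabled stages; returns (and writes) the report dict.

    ``inputs`` may pass pre-loaded ``(CountTable, TaxonomyMap,
    SampleMetadata, tree-or-None)`` to skip file reading (used by tests and
    the simulate-then-run path).
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    report: dict = {"config": {
        k: (str(v) if isinstance(v, Path) else v) for k, v in asdict(cfg).items()
    }}

    def _finish_stage(name: str, t0: float) -> None:
        manifest.append(name)
        logger.info("stage=%s event=done wall=%.2fs", name, time.perf_counter() - t0)
        (outdir / "manifest.json").write_text(json.dumps({"completed": manifest}, indent=2))

    try:
        stage = "load"
        t0 = time.perf_counter()
        if inputs is not None:
            ct, tax, meta, tree = inputs
        else:
            ct = read_count_table(cfg.counts)
            tax = read_taxonomy(cfg.taxonomy)
            meta = read_metadata(cfg.metadata)
            tree = read_tree(cfg.tree) if cfg.tree else None
        if cfg.run_assembly and tree is None:
            raise ValueError("assembly stage requires a phylogenetic tree")
        shared = [s for s in ct.sample_ids if s in meta.sample_ids]
        if len(shared) < ct.n_samples:
            raise ValueError("metadata does not cover all samples")
        _finish_stage(stage, t0)

        # ------------------------------------------------------------------
        stage = "enterotype"
        t0 = time.perf_counter()
        ent = select_enterotypes(
            ct, tax, k_range=range(cfg.k_min, cfg.k_max + 1)
        )
        ent.labels.to_frame().assign(
            enterotype_name=lambda d: "E" + d["enterotype"].astype(str)
        ).to_csv(outdir / "enterotypes.tsv", sep="\t")
        groups = ent.labels.map(lambda c: f"E{c}")
        group_names = sorted(groups.unique())
        report["enterotype"] = {
            "chosen_k": ent.chosen_k,
            "n_per_group": {g: int((groups == g).sum()) for g in group_names},
            "medoids": list(ent.medoids),
            "ch_by_k": {str(k): v for k, v in ent.ch_by_k.items()},
            "silhouette_by_k": {str(k): v for k, v in ent.silhouette_by_k.items()},
        }
        _finish_stage(stage, t0)

        group_tables = {
            g: ct.subset_samples(list(groups.index[groups == g])) for g in group_names
        }

        # ------------------------------------------------------------------
        if cfg.run_diversity:
            stage = "diversity"
            t0 = time.perf_counter()
            seed = stage_seed(cfg.seed, stage)
            alpha_tbl = div.alpha_diversity(ct, tree)
            alpha_tbl.to_csv(outdir / "alpha_diversity.tsv", sep="\t")
            cmp_alpha = div.compare_groups(alpha_tbl, groups, test="mannwhitney")
            bc = div.bray_curtis(ct)
            perma = div.permanova(bc, groups, n_perm=cfg.n_perm, seed=seed)
            disp = div.permdisp(bc, groups, n_perm=cfg.n_perm, seed=seed + 1)
            coords = pcoa(bc, n_axes=2).coordinates
            coords.to_csv(outdir / "pcoa_bray_curtis.tsv", sep="\t")
            upset = div.upset_partition(ct, groups)
            cmp_traits = div.compare_groups(
                meta.body_size().loc[ct.sample_ids], groups, test="t"
            )
            report["diversity"] = {
                "alpha_mean_by_group": {
                    g: alpha_tbl.loc[groups == g].mean().round(6).to_dict()
                    for g in group_names
                },
                "alpha_tests": cmp_alpha.round(10).to_dict(orient="index"),
                "trait_tests": cmp_traits.round(10).to_dict(orient="index"),
                "permanova": {
                    "pseudo_F": perma.pseudo_F,
                    "R2": perma.R2,
                    "p": perma.p,
                },
                "permdisp": disp,
                "upset": {
                    "+".join(k): v for k, v in sorted(upset.items())
                },
            }
            _finish_stage(stage, t0)

        # ------------------------------------------------------------------
        genus_ct = collapse_rank(ct, tax, "genus")
        genus_rel = to_relative(genus_ct)

        if cfg.run_differential:
            stage = "differential"
            t0 = time.perf_counter()
            seed = stage_seed(cfg.seed, stage)
            lefse = diff.lefse_like(
                genus_rel, groups, alpha=cfg.alpha,
                lda_threshold=cfg.lda_threshold, seed=seed,
            )
            lefse.table.to_csv(outdir / "lefse_genus.tsv", sep="\t")
            simp = diff.simper(genus_rel, groups)
            simp.table.head(50).to_csv(outdir / "simper_genus.tsv", sep="\t")
            screen = diff.screen_classifiers(
                genus_rel, groups, split=cfg.train_split, seed=seed + 1
            )
            screen.importance.head(25).to_csv(outdir / "importance.tsv", sep="\t")
            report["differential"] = {
                "lefse_n_biomarkers": int(len(lefse.table)),
                "lefse_top": {
                    str(f): {
                        "lda_score": float(r["lda_score"]),
                        "enriched_group": str(r["enriched_group"]),
                    }
                    for f, r in lefse.table.head(10).iterrows()
                },
                "simper_top": simp.table.head(10)["mean_contribution"].round(6).to_dict(),
                "screen_auc": {k: round(v, 6) for k, v in screen.aucs.items()},
                "best_model": screen.best_model,
                "top_importance": screen.importance.head(10).round(6).to_dict(),
            }
            _finish_stage(stage, t0)

        # ------------------------------------------------------------------
        if cfg.run_network:
            stage = "network"
            t0 = time.perf_counter()
            report["network"] = {}
            for g in group_names:
                graph = net.build_network(
                    group_tables[g],
                    min_mean_relabund=cfg.min_mean_relabund,
                    min_prev=cfg.min_prevalence,
                    rho_min=cfg.rho_min,
                    q_max=cfg.q_max,
                )
                net.write_edge_list(graph, outdir / f"network_edges_{g}.tsv")
                if graph.number_of_nodes() == 0:
                    report["network"][g] = {"n_nodes": 0, "n_edges": 0}
                    continue
                ns = net.network_stats(graph)
                ns.node_stats.to_csv(outdir / f"network_nodes_{g}.tsv", sep="\t")
                report["network"][g] = {
                    "n_nodes": ns.n_nodes,
                    "n_edges": ns.n_edges,
                    "positive_edges": ns.positive_edges,
                    "negative_edges": ns.negative_edges,
                    "avg_degree": ns.avg_degree,
                    "density": ns.density,
                    "avg_clustering": ns.avg_clustering,
                    "avg_path_length": ns.avg_path_length,
                    "modularity": ns.modularity,
                }
            _finish_stage(stage, t0)

        # ------------------------------------------------------------------
        if cfg.run_assembly:
            stage = "assembly"
            t0 = time.perf_counter()
            seed = stage_seed(cfg.seed, stage)
            report["assembly"] = {}
            for g in group_names:
                gct = group_tables[g]
                ncm = asm.fit_ncm(gct)
                ncm.table.to_csv(outdir / f"ncm_{g}.tsv", sep="\t")
                kept = filter_taxa(gct, min_mean_relabund=cfg.min_mean_relabund)
                bnti = asm.beta_nti(kept, tree, n_null=cfg.n_perm, seed=seed)
                rc = asm.raup_crick_matrix(kept, n_null=cfg.n_perm, seed=seed + 1)
                result = asm.classify_processes(bnti, rc)
                result.pairs.to_csv(outdir / f"assembly_pairs_{g}.tsv", sep="\t", index=False)
                report["assembly"][g] = {
                    "ncm": {"m": ncm.m, "N": ncm.N, "Nm": ncm.Nm, "r2": ncm.r2},
                    "median_bnti": float(result.pairs["bnti"].median()),
                    "process_fractions": result.fractions,
                }
            _finish_stage(stage, t0)

        # ------------------------------------------------------------------
        if cfg.run_niche:
            stage = "niche"
            t0 = time.perf_counter()
            seed = stage_seed(cfg.seed, stage)
            report["niche"] = {}
            for g in group_names:
                kept = filter_taxa(
                    group_tables[g], cfg.min_mean_relabund, cfg.min_prevalence
                )
                cls = nic.classify_niche(
                    kept, n_perm=cfg.n_perm_niche, seed=seed
                )
                cls.table.to_csv(outdir / f"niche_{g}.tsv", sep="\t")
                report["niche"][g] = {
                    "mean_b": cls.mean_b,
                    "fractions": cls.fractions,
                }
            breadth_cmp = nic.compare_group_breadth(ct, groups)
            report["niche"]["between_groups"] = {
                "p": breadth_cmp["p"],
                "median_b": breadth_cmp["median_b"],
            }
            _finish_stage(stage, t0)

        # ------------------------------------------------------------------
        if cfg.run_association:
            stage = "association"
            t0 = time.perf_counter()
            seed = stage_seed(cfg.seed, stage)
            alpha_tbl = div.alpha_diversity(ct, tree)
            body = meta.body_size().loc[ct.sample_ids]
            kept_alpha = assoc.collinearity_filter(alpha_tbl, r_max=cfg.rho_min)
            kept_body = assoc.collinearity_filter(body, r_max=cfg.rho_min)
            expl = pd.concat([alpha_tbl[kept_alpha], body[kept_body]], axis=1)
            for g in group_names[1:]:  # dummy-code enterotype membership
                expl[f"enterotype_{g}"] = (groups == g).astype(float)
            res = assoc.rda(genus_rel, expl, n_perm=cfg.n_perm, seed=seed)
            res.site_scores.round(8).to_csv(outdir / "rda_sites.tsv", sep="\t")
            res.biplot_scores.round(8).to_csv(outdir / "rda_biplot.tsv", sep="\t")
            report["association"] = {
                "retained_variables": list(expl.columns),
                "F": res.F,
                "p": res.p,
                "constrained_fraction": res.constrained_fraction,
                "marginal": res.marginal.round(10).to_dict(orient="index"),
            }
            _finish_stage(stage, t0)

    except Exception as exc:  # annotate with stage, keep partial outputs
        (outdir / "manifest.json").write_text(
            json.dumps({"completed": manifest, "failed": stage}, indent=2)
        )
        raise PipelineError(stage, exc) from exc

    payload = json.dumps(_jsonable(report), indent=2, sort_keys=True)
    (outdir / "report.json").write_text(payload + "\n")
    return report
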