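"""End-to-end orchestration: simulate -> diffexp -> score -> gsea -> cnv -> fish.

Stages run in dependency order from a single run configuration; every
artifact is a plain TSV/JSON file and the run manifest records the seed,
parameters and a sha256 checksum per artifact, so re-running any stage from
stored intermediates reproduces its outputs byte-identically.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__, copynumber, diffexp, enrichment, fish, io, score
from .simulate import simulate_cohort

logger = logging.getLogger("brcadel")

STAGES = ("simulate", "diffexp", "score", "gsea", "cnv", "fishcall")


class PipelineError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def default_run_config(seed: int = 0) -> dict:
    return {
        "seed": seed,
        "stages": list(STAGES),
        "simulate": {},  # CohortConfig overrides
        "diffexp": {"fdr_threshold": 0.01},
        "score": {"validation": True},
        "gsea": {"n_perm": 1000, "min_size": 5, "max_size": 500},
        "cnv": {"loss_thr": copynumber.LOSS_THRESHOLD,
                "gain_thr": copynumber.GAIN_THRESHOLD},
        "fishcall": {"threshold": fish.DELETION_THRESHOLD, "scope": "both"},
    }


def _require(outdir: Path, stage: str, *files: str) -> None:
    for name in files:
        if not (outdir / name).exists():
            raise PipelineError(
                f"stage {stage!r} requires missing artifact {name!r}; "
                "enable the upstream stage or provide the file")


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the enabled stages; returns (and writes) the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = default_run_config()
    for key, val in (config or {}).items():
        if isinstance(val, dict) and key in cfg:
            cfg[key] = {**cfg[key], **val}
        else:
            cfg[key] = val
    seed = int(cfg.get("seed", 0))
    stages = list(cfg["stages"])
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")

    artifacts: list[str] = []

    def save(name: str) -> Path:
        artifacts.append(name)
        return outdir / name

    cohort_cfg = io.cohort_config_from_dict({**cfg["simulate"], "seed": seed})

    if "simulate" in stages:
        logger.info("simulate: %d case + %d control samples",
                    cohort_cfg.n_case, cohort_cfg.n_control)
        cohort = simulate_cohort(cohort_cfg)
        io.write_expression(cohort.expression, save("expression.tsv"))
        io.write_labels(cohort.expression.labels, save("labels.tsv"))
        cohort.truth.genes.reset_index().to_csv(
            save("gene_annotation.tsv"), sep="\t", index=False)
        io.write_probes(cohort.cgh, save("cgh_probes.tsv"))
        io.write_baf(cohort.baf, save("baf.tsv"))
        io.write_fish(cohort.fish, save("fish_counts.tsv"))
        io.write_truth(cohort.truth, save("truth.json"))

    if "diffexp" in stages:
        _require(outdir, "diffexp", "expression.tsv", "labels.tsv")
        matrix = io.read_expression(outdir / "expression.tsv", outdir / "labels.tsv")
        stats = diffexp.moderated_t(matrix)
        io.write_gene_stats(stats, save("gene_stats.tsv"))
        sig = diffexp.select_signature(stats, cfg["diffexp"]["fdr_threshold"])
        io.write_signature(sig, save("signature.tsv"))
        logger.info("diffexp: %d genes at FDR<%g (d0=%.3g)", len(sig),
                    cfg["diffexp"]["fdr_threshold"], stats.df_prior)

    if "score" in stages:
        _require(outdir, "score", "expression.tsv", "labels.tsv", "signature.tsv")
        matrix = io.read_expression(outdir / "expression.tsv", outdir / "labels.tsv")
        sig = io.read_signature(outdir / "signature.tsv")
        scores = score.score_samples(matrix, sig, center="reference")
        result = score.roc_auc(scores, matrix.labels)
        frame = pd.DataFrame({"sample_id": scores.index, "score": scores.to_numpy(),
                              "label": matrix.labels.to_numpy()})
        frame.to_csv(save("scores.tsv"), sep="\t", index=False,
                     float_format=io.FLOAT_FORMAT)
        result.roc.to_csv(save("roc.tsv"), sep="\t", index=False,
                          float_format=io.FLOAT_FORMAT)
        summary = {"auc_training": result.auc}
        if cfg["score"].get("validation"):
            val_cfg = dataclasses.replace(cohort_cfg, seed=seed + 2**20)
            val = simulate_cohort(val_cfg)
            val_scores = score.score_samples(val.expression, sig, center="reference")
            summary["auc_validation"] = score.roc_auc(
                val_scores, val.expression.labels).auc
        Path(save("auc.json")).write_text(json.dumps(summary, indent=1) + "\n")
        logger.info("score: %s", summary)

    if "gsea" in stages:
        _require(outdir, "gsea", "gene_stats.tsv", "gene_annotation.tsv")
        stats = pd.read_csv(outdir / "gene_stats.tsv", sep="\t", index_col=0)
        ann = pd.read_csv(outdir / "gene_annotation.tsv", sep="\t")
        ranked = enrichment.rank_genes(stats.index.to_numpy(), stats["t"].to_numpy())
        sets = enrichment.make_band_sets(
            ann.rename(columns={"gene_id": "gene"}), ranked,
            min_size=cfg["gsea"]["min_size"], max_size=cfg["gsea"]["max_size"])
        result = enrichment.preranked_gsea(ranked, sets,
                                           n_perm=cfg["gsea"]["n_perm"], seed=seed)
        result.to_csv(save("gsea.tsv"), sep="\t", float_format=io.FLOAT_FORMAT)
        logger.info("gsea: %d band sets, top depleted %s", len(result),
                    result.index[0] if len(result) else "-")

    if "cnv" in stages:
        _require(outdir, "cnv", "cgh_probes.tsv", "labels.tsv")
        probes = io.read_probes(outdir / "cgh_probes.tsv")
        labels = io.read_labels(outdir / "labels.tsv")
        called = copynumber.call_probes(probes, cfg["cnv"]["loss_thr"],
                                        cfg["cnv"]["gain_thr"])
        io.write_probes(called, save("cgh_calls.tsv"))
        case_ids = labels[labels == "BRCA2"].index
        per_sample = [grp for sid, grp in called.groupby("sample_id", sort=False)
                      if sid in set(case_ids)]
        regions = copynumber.common_region_overlap(per_sample)
        io.write_regions(regions, save("common_regions.tsv"))
        for group in ("BRCA2", "BRCAX"):
            ids = set(labels[labels == group].index)
            profs = [grp for sid, grp in called.groupby("sample_id", sort=False)
                     if sid in ids]
            track = copynumber.cumulative_frequency(profs)
            track.to_csv(save(f"frequency_{group}.tsv"), sep="\t", index=False,
                         float_format=io.FLOAT_FORMAT)
        logger.info("cnv: %d common loss regions", len(regions))

    if "fishcall" in stages:
        _require(outdir, "fishcall", "fish_counts.tsv", "labels.tsv")
        counts = io.read_fish(outdir / "fish_counts.tsv")
        labels = io.read_labels(outdir / "labels.tsv")
        calls = fish.summarize_fish(counts, labels,
                                    threshold=cfg["fishcall"]["threshold"])
        calls.reset_index().to_csv(save("fish_calls.tsv"), sep="\t", index=False,
                                   float_format=io.FLOAT_FORMAT)
        stats_out = {}
        scopes = [cfg["fishcall"]["scope"]] if cfg["fishcall"]["scope"] != "all" \
            else ["both"] + sorted(counts["chromosome"].astype(str).unique())
        for scope in scopes:
            table = fish.build_contingency(calls, scope=scope)
            p = fish.fisher_exact_two_sided(table)
            sens, spec = fish.diagnostic_metrics(table)
            stats_out[scope] = {"table": table.tolist(), "fisher_p": p,
                                "sensitivity": sens, "specificity": spec}
        Path(save("fish_stats.json")).write_text(
            json.dumps(stats_out, indent=1, sort_keys=True) + "\n")
        logger.info("fishcall: %s", {k: v["fisher_p"] for k, v in stats_out.items()})

    manifest = {
        "version": __version__,
        "seed": seed,
        "stages": stages,
        "parameters": {k: cfg[k] for k in STAGES if k in cfg},
        "artifacts": {name: _sha256(outdir / name) for name in artifacts},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
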