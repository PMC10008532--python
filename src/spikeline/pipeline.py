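"""End-to-end pipeline: detect → qc → quantify → transform → diversity.

``run_pipeline`` consumes a configuration mapping (typically loaded from
YAML) naming the inputs — or requesting a simulated experiment — and
writes all result tables, a couple of overview figures and a plain-text
log to the output directory. Deterministic given a seed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import detect, diversity, io, quantify
from .model import CountTable, ValidationError
from .simulate import SimulationConfig, simulate_experiment, study_design_config
from .synthetic_references import default_references

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _load_inputs(config: dict, seed: int, outdir: Path, log: logging.Logger):
    if config.get("simulate", False):
        sim_cfg = dict(config.get("simulation", {}))
        sim_cfg.setdefault("seed", seed)
        if "biomass_mass" in sim_cfg:
            cfg = SimulationConfig(**sim_cfg)
        else:
            cfg = study_design_config(**sim_cfg)
        exp = simulate_experiment(cfg)
        log.info("simulated experiment: %d samples, %d SVs", *exp.table.counts.shape)
        exp.truth.per_sample.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
        refs = exp.config.references if config.get("use_default_references", True) else []
        return exp.table, exp.sequences, exp.metadata, refs
    try:
        table = io.read_count_table(
            config["counts"],
            format=config.get("counts_format", "tsv"),
            orientation=config.get("counts_orientation", "samples"),
        )
        seqs = io.read_fasta(config["sequences"])
        meta = io.read_metadata(config["metadata"])
    except KeyError as exc:
        raise PipelineError("config", f"missing input entry {exc}") from exc
    if config.get("mc_references"):
        refs = io.read_mc_references(
            config["mc_references"]["fasta"], config["mc_references"]["taxa"]
        )
    elif config.get("use_default_references", True):
        refs = default_references()
    else:
        refs = []
    return table, seqs, meta, refs


def run_pipeline(config: dict, seed: int = 0, outdir: str | Path = "spikeline_out") -> dict:
    """Execute the full analysis and write a report bundle to ``outdir``.

    Returns a dict of the main in-memory results (assignment, QC metrics,
    copy-number estimates, transformed table, diversity outputs).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = logging.getLogger("spikeline")
    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("seed=%d", seed)

    results: dict = {}
    try:
        table, seqs, meta, refs = _load_inputs(config, seed, outdir, log)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("input", str(exc)) from exc

    if config.get("transform", True) and not refs:
        raise PipelineError("config", "transform requested but no MC reference given")

    try:
        assignment = detect.assign_mc_svs(
            seqs, refs, table, min_identity=config.get("min_identity", 97.0)
        )
        qc = detect.qc_metrics(table, assignment, refs)
        assignment.table.to_csv(outdir / "mc_assignment.tsv", sep="\t", index=False)
        qc.per_sample.to_csv(outdir / "mc_qc.tsv", sep="\t", index_label="sample_id")
        with open(outdir / "mc_qc_summary.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    "ratio_mean": qc.ratio_mean,
                    "ratio_sd": qc.ratio_sd,
                    "expected_ratio": qc.expected_ratio,
                    "band": list(qc.band),
                },
                fh,
            )
        results["assignment"] = assignment
        results["qc"] = qc
    except Exception as exc:
        raise PipelineError("detect", str(exc)) from exc

    try:
        gcn = quantify.estimate_gcn(table, assignment, meta, refs)
        gcn.table.to_csv(outdir / "gcn_estimates.tsv", sep="\t", index=False)
        stripped, original_totals = detect.strip_mc(table, assignment)
        io.write_count_table(stripped, outdir / "sample_svs.tsv")
        transformed = quantify.transform_counts(
            stripped, original_totals, assignment, gcn, refs
        )
        transformed.to_csv(outdir / "transformed_counts.tsv", sep="\t", index_label="sample_id")
        results["gcn"] = gcn
        results["stripped"] = stripped
        results["transformed"] = transformed
    except Exception as exc:
        raise PipelineError("quantify", str(exc)) from exc

    try:
        clr = diversity.clr_normalize(stripped)
        dist_eu = diversity.distance(clr, "euclidean")
        rarefied = diversity.rarefy(stripped, seed=seed)
        dist_bc = diversity.distance(rarefied, "bray-curtis")
        alpha = diversity.alpha_diversity(rarefied)
        ord_eu = diversity.pcoa(dist_eu)
        alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t", index_label="sample_id")
        dist_eu.to_frame().to_csv(outdir / "euclidean_clr.tsv", sep="\t")
        dist_bc.to_frame().to_csv(outdir / "bray_curtis.tsv", sep="\t")
        ord_eu["coordinates"].to_csv(outdir / "pcoa_euclidean.tsv", sep="\t", index_label="sample_id")
        results.update(
            {"alpha": alpha, "dist_euclidean": dist_eu, "dist_bray_curtis": dist_bc, "pcoa": ord_eu}
        )
        terms = config.get("permanova_terms")
        if terms is None:
            terms = [t for t in ("pool_id", "mc_biomass_ratio") if meta[t].notna().all() and meta[t].nunique() > 1]
        if terms:
            perm = diversity.permanova(dist_eu, meta, terms, seed=seed)
            perm.table.to_csv(outdir / "permanova_euclidean.tsv", sep="\t")
            results["permanova"] = perm
    except Exception as exc:
        raise PipelineError("diversity", str(exc)) from exc

    try:
        _write_figures(outdir, results, meta)
    except Exception as exc:
        log.warning("figure generation failed: %s", exc)

    log.info("pipeline complete")
    handler.close()
    log.removeHandler(handler)
    return results


def _write_figures(outdir: Path, results: dict, meta: pd.DataFrame) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    qc = results["qc"]
    fig, ax = plt.subplots(figsize=(8, 3))
    frac = qc.per_sample["mc_fraction"].dropna()
    ax.bar(range(len(frac)), frac.to_numpy())
    ax.axhline(qc.band[0], color="grey", ls="--", lw=0.8)
    ax.axhline(qc.band[1], color="grey", ls="--", lw=0.8)
    ax.set_ylabel("MC read fraction")
    ax.set_xticks(range(len(frac)))
    ax.set_xticklabels(frac.index, rotation=90, fontsize=4)
    fig.tight_layout()
    fig.savefig(outdir / "mc_fraction.png", dpi=150)
    plt.close(fig)

    coords = results["pcoa"]["coordinates"]
    if coords.shape[1] >= 2:
        fig, ax = plt.subplots(figsize=(5, 4))
        groups = meta.loc[coords.index, "pool_id"].fillna("sample")
        for group in pd.unique(groups):
            sel = groups == group
            ax.scatter(coords.loc[sel, "PCo1"], coords.loc[sel, "PCo2"], label=str(group), s=12)
        ax.set_xlabel("PCo1")
        ax.set_ylabel("PCo2")
        ax.legend(fontsize=6)
        fig.tight_layout()
        fig.savefig(outdir / "pcoa.png", dpi=150)
        plt.close(fig)
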