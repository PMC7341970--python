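"""Configuration-driven orchestration: simulate -> quantify -> classify ->
correlate -> report.

A single top-level seed is expanded into per-stage seeds through
``numpy.random.SeedSequence(seed).spawn``, so any stage re-run alone with
its recorded seed reproduces its outputs. The resolved configuration is
written beside the outputs of every run, and every number in the report is
recomputable from the persisted stage TSVs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bivalency as bv
from . import cooccupancy as co
from . import differential as diff
from . import signal as sig
from .core import write_bed, write_gene_table
from .simulate import (
    SimulationConfig,
    emit_accessible_peaks,
    emit_true_peaks,
    simulate_annotation,
    simulate_atac_fragments,
    simulate_chip_fragments,
    simulate_expression,
)

log = logging.getLogger("chromstate")

_STAGE_DEFAULTS = {
    "promoter_flank": 3000,
    "cluster_flank": 4000,
    "bin_size": 10,
    "spearman_window": 100,
    "spearman_step": 1,
    "fdr": 0.05,
    "lfc": 1.0,
    "min_support": 2,
    "alpha": 1.0,
    "n_chip_replicates": 2,
}


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Stage parameters (defaults are the published analysis settings) plus
    either a simulation block or input paths."""

    simulation: SimulationConfig | None = None
    stages: dict = field(default_factory=lambda: dict(_STAGE_DEFAULTS))
    seed: int = 0
    output_dir: str = "chromstate_out"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return validate_config(raw)

    def to_dict(self) -> dict:
        return {
            "simulation": dataclasses.asdict(self.simulation)
            if self.simulation else None,
            "stages": dict(self.stages),
            "seed": self.seed,
            "output_dir": self.output_dir,
        }


def validate_config(raw: dict) -> PipelineConfig:
    """Normalize a raw config mapping; all problems reported together."""
    errors: list[str] = []
    known = {"simulation", "stages", "seed", "output_dir"}
    for key in set(raw) - known:
        errors.append(f"unknown key: {key!r}")
    stages = dict(_STAGE_DEFAULTS)
    for key, val in (raw.get("stages") or {}).items():
        if key not in _STAGE_DEFAULTS:
            errors.append(f"unknown stage parameter: {key!r}")
        elif not isinstance(val, (int, float)):
            errors.append(f"stage parameter {key!r} must be numeric, got {val!r}")
        else:
            stages[key] = val
    sim_cfg = None
    sim_raw = raw.get("simulation")
    if "simulation" in raw and sim_raw is None:
        # the block was explicitly nulled out and nothing replaces it
        errors.append("a simulation block is required (none given)")
    elif sim_raw is not None:
        if not isinstance(sim_raw, dict):
            errors.append("simulation block must be a mapping")
        else:
            try:
                fields = {f.name for f in dataclasses.fields(SimulationConfig)}
                unknown = set(sim_raw) - fields
                for key in unknown:
                    errors.append(f"unknown simulation key: {key!r}")
                clean = {k: v for k, v in sim_raw.items() if k in fields}
                for key in ("chip_fragment_size_range", "atac_sub_range",
                            "atac_mono_range", "atac_mix_weights"):
                    if key in clean:
                        clean[key] = tuple(clean[key])
                sim_cfg = SimulationConfig(**clean).validate()
            except Exception as exc:  # collected, not first-failure
                errors.append(str(exc))
    else:
        sim_cfg = SimulationConfig()
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        errors.append(f"seed must be an integer, got {seed!r}")
        seed = 0
    if errors:
        raise ConfigError("; ".join(errors))
    return PipelineConfig(
        simulation=sim_cfg,
        stages=stages,
        seed=seed,
        output_dir=str(raw.get("output_dir", "chromstate_out")),
    )


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Deterministic per-stage seeds below 2^31 from one top-level seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in children]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full synthetic-epigenome analysis; returns the report dict.

    Stages: simulation, ChIP/ATAC quantification, bivalency tables and
    knockout-relative ratios, promoter classification, factor Venn overlap
    and TSS clusters, differential expression and accessibility, meta
    profile, sliding-window correlation, and truth-recovery metrics.
    """
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "INCOMPLETE"
    marker.write_text("pipeline running or aborted\n")
    with open(out / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    st = config.stages
    seeds = _stage_seeds(config.seed)
    report: dict = {"seed": config.seed, "stages": {}}

    def _stage(name):
        log.info("stage %s starting (t=%.1fs)", name, time.time() - t0)

    try:
        # --- simulate ------------------------------------------------------
        _stage("simulate")
        sim_cfg = dataclasses.replace(config.simulation, seed=seeds[0])
        genes, truth = simulate_annotation(sim_cfg)
        write_gene_table(genes, out / "genes.tsv")
        truth.table.to_csv(out / "truth.tsv", sep="\t")
        truth.enhancers.to_csv(out / "enhancers.tsv", sep="\t", index=False)

        n_rep = int(st["n_chip_replicates"])
        chip = {
            (mark, geno, r): simulate_chip_fragments(
                truth, mark, geno, replicate=r, seed=seeds[1]
            )
            for mark in ("H3K4me3", "H3K27me3")
            for geno in ("control", "knockout")
            for r in range(n_rep)
        }
        atac = {
            (geno, r): simulate_atac_fragments(
                truth, geno, replicate=r, seed=seeds[2]
            )
            for geno in ("control", "knockout")
            for r in range(sim_cfg.n_replicates)
        }
        expr = {
            geno: simulate_expression(truth, geno, seed=seeds[3])
            for geno in ("control", "knockout")
        }
        expr_matrix = pd.concat(expr.values(), axis=1)
        expr_matrix.to_csv(out / "expression_counts.tsv", sep="\t")

        # --- bivalency -----------------------------------------------------
        _stage("bivalency")
        flank, alpha = int(st["promoter_flank"]), float(st["alpha"])
        tables = {}
        for geno in ("control", "knockout"):
            reps = [
                bv.promoter_signal(
                    chip[("H3K4me3", geno, r)], chip[("H3K27me3", geno, r)],
                    genes, flank=flank, alpha=alpha,
                )
                for r in range(n_rep)
            ]
            tables[geno] = bv.mean_of_replicate_ratios(reps)
        rel = bv.relative_ratio(tables["knockout"], tables["control"])
        ranking = bv.rank_genes_by_ratio_change(tables["knockout"],
                                                tables["control"])
        ranking.to_csv(out / "ratio_change_ranking.tsv", sep="\t", index=False)

        k4_thr = bv.background_threshold(
            chip[("H3K4me3", "control", 0)], genes, truth.chrom_sizes,
            flank=flank, seed=seeds[4],
        )
        k27_thr = bv.background_threshold(
            chip[("H3K27me3", "control", 0)], genes, truth.chrom_sizes,
            flank=flank, seed=seeds[4],
        )
        for geno in tables:
            bv.classify_table(tables[geno], k4_thr, k27_thr)
            tables[geno].to_tsv(out / f"bivalency_{geno}.tsv")
        class_counts = {
            geno: tables[geno].records["promoter_class"].value_counts().to_dict()
            for geno in tables
        }
        report["stages"]["bivalency"] = {
            "k4_threshold_cpm": round(k4_thr, 4),
            "k27_threshold_cpm": round(k27_thr, 4),
            "promoter_class_counts": class_counts,
        }

        # --- recovery of responsive genes by relative-ratio ranking --------
        truth_resp = set(truth.responsive_genes)
        n_resp = len(truth_resp)
        called = set(
            rel.sort_values(ascending=False).index[: max(1, int(0.1 * len(rel)))]
        )
        tp = len(called & truth_resp)
        report["stages"]["recovery"] = {
            "responsive_sensitivity": round(tp / n_resp, 4) if n_resp else None,
            "responsive_precision": round(tp / len(called), 4),
            "median_relative_ratio_responsive": round(
                float(rel[rel.index.isin(truth_resp)].median()), 4),
            "median_relative_ratio_other": round(
                float(rel[~rel.index.isin(truth_resp)].median()), 4),
        }

        # --- factor co-occupancy -------------------------------------------
        _stage("cooccupancy")
        pa = emit_true_peaks(truth, "factorA")
        pb = emit_true_peaks(truth, "factorB")
        pc = emit_true_peaks(truth, "factorC")
        for ps in (pa, pb, pc):
            write_bed(ps, out / f"peaks_{ps.name}.bed")
        venn_pair = co.intersect_pair(pa, pb)
        venn_triple = co.intersect_triple(pa, pb, pc)
        venn_pair.to_json(out / "venn_pair.json")
        venn_triple.to_json(out / "venn_triple.json")
        clusters = co.assign_tss_clusters(
            genes, pa, pb, pc, flank=int(st["cluster_flank"])
        )
        clusters.to_tsv(out / "tss_clusters.tsv")
        report["stages"]["cooccupancy"] = {
            "pair_fractions_pct": venn_pair.per_side_fractions_pct,
            "triple_fraction_pct": venn_triple.triple_fraction_pct,
            "cluster_sizes": clusters.counts().to_dict(),
        }

        # --- differential expression ---------------------------------------
        _stage("differential_expression")
        de = diff.differential_test(
            expr["control"].to_numpy(),
            expr["knockout"].to_numpy(),
            feature_ids=expr["control"].index,
            fdr=float(st["fdr"]), lfc=float(st["lfc"]),
        )
        de.to_tsv(out / "diff_expression.tsv")
        degs = diff.call_deg(de, fdr=float(st["fdr"]), lfc=float(st["lfc"]))
        deg_all = set(degs["up"]) | set(degs["down"])
        report["stages"]["expression"] = {
            "n_deg_up": len(degs["up"]),
            "n_deg_down": len(degs["down"]),
            "deg_true_positives": len(set(degs["up"]) & truth_resp),
            "deg_false_positives": len(deg_all - truth_resp),
        }

        # --- differential accessibility ------------------------------------
        _stage("differential_accessibility")
        peaks, loci = emit_accessible_peaks(truth)
        windows = peaks.intervals
        wt_counts = np.column_stack([
            sig.window_counts(atac[("control", r)], windows)
            for r in range(sim_cfg.n_replicates)
        ])
        ko_counts = np.column_stack([
            sig.window_counts(atac[("knockout", r)], windows)
            for r in range(sim_cfg.n_replicates)
        ])
        da = diff.diff_accessibility(
            wt_counts, ko_counts, peak_ids=loci["locus_id"],
            fdr=float(st["fdr"]), lfc=float(st["lfc"]),
        )
        da.to_tsv(out / "diff_accessibility.tsv")
        dep, indep = diff.classify_dependent_peaks(da, peaks)
        write_bed(dep, out / "atac_dependent.bed")
        write_bed(indep, out / "atac_independent.bed")
        dep_ids = set(da.table.index[da.table["significant"]
                                     & (da.table["log2FC"] > 0)])
        true_ids = set(loci.loc[loci["responsive"], "locus_id"])
        jacc = (len(dep_ids & true_ids) / len(dep_ids | true_ids)
                if dep_ids | true_ids else 1.0)
        report["stages"]["accessibility"] = {
            "n_consensus_peaks": len(peaks),
            "n_dependent": len(dep),
            "n_independent": len(indep),
            "dependent_jaccard_vs_truth": round(jacc, 4),
        }

        # --- meta-profile ---------------------------------------------------
        _stage("metaprofile")
        profile = sig.metaprofile(
            atac[("control", 0)], genes, flank=2000,
            bin_size=int(st["bin_size"]),
        )
        profile.to_tsv(out / "metaprofile_atac_control.tsv")
        report["stages"]["metaprofile"] = {
            "edge_mean": round(profile.edge_mean, 12),
            "max_over_background": round(float(profile.values.max()), 4),
        }

        # --- ratio/expression correlation ----------------------------------
        _stage("correlation")
        mean_expr = expr["control"].mean(axis=1)
        ratios = tables["control"].records["ratio"]
        rho, n_windows = bv.sliding_window_spearman(
            ratios.to_numpy(), mean_expr.to_numpy(),
            window=int(st["spearman_window"]), step=int(st["spearman_step"]),
        )
        report["stages"]["correlation"] = {
            "spearman_rho": round(rho, 4),
            "n_windows": n_windows,
        }

        report["runtime_s"] = round(time.time() - t0, 2)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        marker.unlink()
    except Exception:
        log.error("pipeline aborted; partial outputs retained in %s", out)
        raise
    return report


def configure_logging(verbose: bool = True) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
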