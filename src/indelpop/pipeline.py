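"""End-to-end orchestration of the synthetic study.

``run_all`` wires every stage together on one configuration: simulate a
population, call and filter SVs, call SNPs, compute population-genetic
summaries and the neutral envelope, run the annotation-overlap analyses
and the joint D/H selection scan, and aggregate everything into a
JSON-able report with per-stage attrition accounting.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (alignio, discordant_sv, feature_overlap, neutral_sim,
               popgen_stats, selection_scan, snp_caller, sv_filters,
               synthetic_data)

logger = logging.getLogger(__name__)


def validation_rate(confirmed: int, conclusive: int) -> float:
    """Experimental validation rate in percent: confirmed calls over
    conclusive assays (inconclusive assays are excluded)."""
    if conclusive <= 0 or confirmed > conclusive:
        raise ValueError("need 0 < confirmed <= conclusive")
    return round(100.0 * confirmed / conclusive, 1)


@dataclass
class PipelineConfig:
    """All thresholds of the pipeline with their study defaults."""

    sim: synthetic_data.SimConfig = field(
        default_factory=synthetic_data.SimConfig)
    min_mapq: int = 29
    min_insert: int = 1000
    cluster_window: int = 225
    min_support: int = 3
    min_size: int = 1000
    depth_low_pct: float = 10.0
    density_high_window: int = 5000
    coverage_band: tuple = (10.0, 90.0)
    snp_min_depth: int = 3
    snp_max_depth: int = 25
    snp_majority: float = 0.75
    pi_a_window: int = 500
    scan_window: int = 10_000
    freq_min: float = 0.8
    envelope_reps: int = 10_000
    envelope_S: int = 100
    maf_error_reps: int = 50_000
    outdir: str | None = None

    def __post_init__(self):
        if isinstance(self.sim, dict):
            self.sim = synthetic_data.SimConfig(**self.sim)
        for name in ("min_mapq", "min_insert", "cluster_window", "min_support",
                     "min_size", "scan_window", "pi_a_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for pct in (self.depth_low_pct, *self.coverage_band):
            if not 0 <= pct <= 100:
                raise ValueError("percentiles must be in [0,100]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def run_all(config: PipelineConfig) -> dict:
    """Run the full synthetic study; returns the aggregated report."""
    report: dict = {"thresholds": {
        k: v for k, v in dataclasses.asdict(config).items() if k != "sim"}}
    report["sim_config"] = dataclasses.asdict(config.sim)
    logger.info("thresholds: %s", report["thresholds"])

    logger.info("stage simulate")
    truth = synthetic_data.generate_truth(config.sim)
    streams, depths, sim_counters = synthetic_data.simulate_read_pairs(truth)
    report["simulate"] = {
        "planted_deletions": int(len(truth.variants)),
        "planted_snps": int(len(truth.snp_pos)),
        "pair_counters": sim_counters,
    }

    logger.info("stage callsv")
    candidates, pooled, class_counts = discordant_sv.call_svs(
        streams, window=config.cluster_window, min_support=config.min_support,
        min_mapq=config.min_mapq, min_insert=config.min_insert)
    report["callsv"] = {
        "pooled_discordant": len(pooled),
        "candidates": len(candidates),
        "by_type": pd.Series([c.sv_type for c in candidates])
        .value_counts().to_dict(),
        "per_accession": class_counts,
    }

    logger.info("stage filtersv")
    index = sv_filters.DiscordantIndex(pooled, config.sim.genome_length,
                                       config.density_high_window)
    retained, verdicts = sv_filters.apply_cascade(
        candidates, depths, index, config.sim.reference_line,
        min_size=config.min_size, low_pct=config.depth_low_pct,
        high_pct=config.coverage_band[1])
    dropped = len(candidates) - len(retained)
    report["filtersv"] = {
        "input": len(candidates), "retained": len(retained),
        "dropped": dropped,
        "attrition_ok": len(candidates) == len(retained) + dropped,
    }
    precision, recall, match = synthetic_data.evaluate_calls(retained, truth)
    report["evaluation"] = {"precision": precision, "recall": recall}

    logger.info("stage callsnp")
    pileups = synthetic_data.make_pileups(truth)
    calls = {line: snp_caller.call_pileup(
        df, line, max_depth=config.snp_max_depth,
        min_depth=config.snp_min_depth, majority=config.snp_majority)
        for line, df in pileups.items()}
    snp_table = snp_caller.build_snp_table(calls, config.sim.focal_lines)
    report["callsnp"] = {"snps": int(len(snp_table))}

    logger.info("stage popgen")
    geno = truth.indel_genotypes()
    counts = geno.sum(axis=1).to_numpy()
    n = len(config.sim.focal_lines)
    folded, maf, mean_maf = popgen_stats.sfs_and_maf(counts, n)
    # polarize indels by outgroup deletion status (ancestral = outgroup state)
    og = pd.DataFrame(
        {o: [0 if row.deletion_is_derived else 1
             for row in truth.variants.itertuples()]
         for o in config.sim.outgroup_lines}, index=geno.index)
    pol = popgen_stats.polarize(geno, og)
    report["popgen"] = {
        "indel_mean_maf": mean_maf,
        "indel_folded_sfs": folded.tolist(),
        "minor_derived_fraction": pol.attrs["minor_derived_fraction"],
    }
    sizes = truth.variants["size"].to_numpy()
    try:
        report["popgen"]["size_by_maf"] = feature_overlap.size_by_maf(sizes, maf)
    except ValueError as exc:
        report["popgen"]["size_by_maf"] = {"error": str(exc)}

    logger.info("stage envelope")
    env = neutral_sim.neutral_envelope(
        n=n, S=config.envelope_S, reps=config.envelope_reps,
        seed=config.sim.seed)
    report["envelope"] = dataclasses.asdict(env)
    maf_err = neutral_sim.maf_sampling_error(
        n, config.maf_error_reps,
        np.random.default_rng([config.sim.seed, 0x3AF]))
    report["maf_sampling_error"] = maf_err.mean_abs_error

    logger.info("stage overlap")
    retained_or_truth = retained if retained else list(truth.variants.itertuples())
    assignments, composition, chi2 = feature_overlap.assign_context(
        retained_or_truth, truth.features, truth.alignable_mask)
    report["overlap"] = {
        "composition": composition.to_dict(orient="records"),
        "chi2": chi2,
        "genic_indels": sum(a.genic for a in assignments),
        "te_indels": sum(a.te for a in assignments),
    }
    cov_per_window = (config.sim.coverage_mean
                      * (len(config.sim.focal_lines)
                         + config.sim.n_outgroup_lines))
    n_win = config.sim.genome_length // 500_000
    if n_win >= 3:
        report["overlap"]["window_correlation"] = \
            feature_overlap.window_density_correlation(
                truth.variants["start"].to_numpy(), truth.snp_pos,
                cov_per_window, config.sim.genome_length)

    logger.info("stage scan")
    alleles = truth.snp_allele_matrix()
    derived_freq = []
    for row in truth.variants.itertuples():
        f_del = row.mac / n
        derived_freq.append(f_del if row.deletion_is_derived else 1 - f_del)
    indels = truth.variants.assign(derived_freq=derived_freq)
    scan = selection_scan.scan_indels(
        indels, alleles, env, config.sim.focal_lines,
        config.sim.outgroup_lines, window=config.scan_window,
        freq_min=config.freq_min)
    report["scan"] = {
        "n_scored": int(len(scan)),
        "outliers": scan.loc[scan.outlier, "indel_id"].tolist(),
        "outliers_high_freq": scan.loc[scan.outlier & scan.passes_freq,
                                       "indel_id"].tolist(),
    }

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        alignio.write_calls(retained, outdir / "retained.tsv", "tsv")
        alignio.write_calls(retained, outdir / "retained.bed", "bed")
        verdicts.to_csv(outdir / "verdicts.tsv", sep="\t", index=False)
        scan.to_csv(outdir / "scan.tsv", sep="\t", index=False)
        env.to_json(outdir / "envelope.json")
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=str)
        logger.info("report written to %s", outdir / "report.json")
    return report
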