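"""End-to-end orchestration: simulate -> joint call -> statistics -> QC ->
zero-out -> rescue -> concordance, with per-stage logging and checksums."""
from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np

from . import __version__, bestpractices, caller, concord, io, simchip, snpstats
from .errors import ConfigError
from .io import PipelineConfig

log = logging.getLogger(__name__)

# stage-named exit codes for the command-line wrapper
STAGE_EXIT_CODES = {
    "config": 2,
    "simulate": 3,
    "call": 4,
    "stats": 5,
    "qc": 6,
    "rescue": 7,
    "concord": 8,
}


class StageError(Exception):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.exit_code = STAGE_EXIT_CODES.get(stage, 1)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _log_artifact(path: Path) -> None:
    log.info("wrote %s (sha256 %s)", path, _checksum(path))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the key result objects.

    Outputs are reproducible bit-for-bit for a fixed seed: the simulator is
    the only source of randomness and every fit is deterministic.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    log.info("exochip %s, seed %d", __version__, config.seed)
    try:
        config.validate()
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
    except (ConfigError, OSError) as e:
        raise StageError("config", e) from e

    # --- simulate -----------------------------------------------------
    try:
        sim_cfg = simchip.SimConfig(**{**config.sim, "seed": config.seed})
        log.info("simulating %d samples x %d variants", sim_cfg.n_samples, sim_cfg.n_variants)
        intensities, truth = simchip.simulate_dataset(sim_cfg)
        rng = np.random.default_rng(config.seed + 1)
        comparator = simchip.simulate_comparator(
            truth, sim_cfg.seq_error_rate, sim_cfg.seq_missing_rate, rng
        )
        io.write_sample_sheet(truth.sample_meta, out / "samples.tsv")
        io.write_variant_sheet(truth.variant_meta, out / "variants.tsv")
        io.write_genotype_tsv(truth.genotypes, out / "truth.tsv")
        for p in ("samples.tsv", "variants.tsv", "truth.tsv"):
            _log_artifact(out / p)
    except (ConfigError, ValueError) as e:
        raise StageError("simulate", e) from e

    sexes = truth.sample_meta["sex"].to_numpy()
    chrom = truth.variant_meta["chrom_class"].to_numpy()

    # --- joint call ---------------------------------------------------
    try:
        ncall = config.caller.get("no_call_threshold", caller.DEFAULT_NO_CALL_THRESHOLD)
        calls, scores, cluster_file = caller.joint_call(
            intensities,
            sexes,
            chrom,
            no_call_threshold=ncall,
            cluster_def_call_rate=config.caller.get(
                "cluster_def_call_rate", caller.DEFAULT_CLUSTER_DEF_CALL_RATE
            ),
        )
        io.write_genotype_tsv(calls, out / "calls.tsv")
        cluster_file.write(out / "clusters.tsv")
        _log_artifact(out / "calls.tsv")
        _log_artifact(out / "clusters.tsv")
    except Exception as e:
        raise StageError("call", e) from e

    # --- statistics ---------------------------------------------------
    try:
        stats = snpstats.compute_all_snp_stats(
            calls, intensities.theta, intensities.r, sexes, chrom
        )
        meta = truth.sample_meta
        rep_pairs = [
            (row.replicate_of, row.sample_id)
            for row in meta.itertuples(index=False)
            if row.replicate_of
        ]
        trios = [
            (row.sample_id, row.father_id or None, row.mother_id or None)
            for row in meta.itertuples(index=False)
            if row.father_id or row.mother_id
        ]
        rep = snpstats.replicate_errors(calls, rep_pairs)
        ppc, pc = snpstats.mendel_errors(calls, trios, chrom)
        for i, s in enumerate(stats):
            s.rep_errors, s.ppc_errors, s.pc_errors = int(rep[i]), int(ppc[i]), int(pc[i])
        sample_stats = snpstats.compute_all_sample_stats(calls)
        snpstats.snp_stats_frame(stats).to_csv(out / "snp_stats.tsv", sep="\t", index=False)
        snpstats.sample_stats_frame(sample_stats).to_csv(
            out / "sample_stats.tsv", sep="\t", index=False
        )
        _log_artifact(out / "snp_stats.tsv")
        _log_artifact(out / "sample_stats.tsv")
    except Exception as e:
        raise StageError("stats", e) from e

    # --- QC -----------------------------------------------------------
    try:
        thresholds = bestpractices.QCThresholds.from_dict(config.thresholds)
        log.info("thresholds: %s", thresholds)
        batch = bestpractices.batch_effect_stat(
            calls, meta["batch"].to_numpy(), alpha=thresholds.batch_alpha
        )
        batch_excluded = dict(zip(batch["variant_id"], batch["excluded"]))
        decisions = [
            bestpractices.exclude_snps(s, thresholds, batch_excluded.get(s.variant_id, False))
            for s in stats
        ]
        sample_qc = bestpractices.exclude_samples(sample_stats, thresholds)
        excluded_ids = [d.variant_id for d in decisions if d.excluded]
        zeroed = bestpractices.zero_out(cluster_file, excluded_ids)
        bestpractices.qc_report(decisions).to_csv(out / "snp_qc.tsv", sep="\t", index=False)
        sample_qc.to_csv(out / "sample_qc.tsv", sep="\t", index=False)
        zeroed.write(out / "clusters_qc.tsv")
        for p in ("snp_qc.tsv", "sample_qc.tsv", "clusters_qc.tsv"):
            _log_artifact(out / p)
        log.info("excluded %d/%d variants, %d/%d samples",
                 len(excluded_ids), len(stats), int(sample_qc["excluded"].sum()), len(sample_qc))
    except Exception as e:
        raise StageError("qc", e) from e

    # --- re-call from zeroed cluster file, optional rescue -------------
    try:
        final_calls, _ = caller.apply_cluster_file(
            zeroed, intensities, sexes, chrom, no_call_threshold=ncall
        )
        if config.rescue:
            final_calls = caller.rescue_nocalls(
                final_calls, intensities, zeroed, z=config.caller.get("rescue_z", caller.DEFAULT_ZCALL_Z)
            )
        io.write_genotype_tsv(final_calls, out / "calls_final.tsv")
        _log_artifact(out / "calls_final.tsv")
    except Exception as e:
        raise StageError("rescue", e) from e

    # --- concordance ----------------------------------------------------
    try:
        keep = [d.variant_id for d in decisions if not d.excluded]
        keep_idx = [calls.variant_index()[v] for v in keep]
        sub_test = _subset(final_calls, keep_idx)
        sub_truth = _subset(comparator, keep_idx)
        table = concord.build_contingency(sub_test, sub_truth)
        summary = concord.concordance_summary(table).rounded()
        report = concord.concordance_report(table)
        mac = concord.mac_bin_concordance(
            sub_test, sub_truth, tuple(config.concord.get("mac_bins", (1, 2, 3)))
        )
        with open(out / "concordance.txt", "w") as fh:
            fh.write(report + "\n")
            for b, v in sorted(mac.items()):
                fh.write(f"MAC={b} concordance: {v:.2f}%\n")
        table.write(out / "contingency.tsv")
        _log_artifact(out / "concordance.txt")
        _log_artifact(out / "contingency.tsv")
    except Exception as e:
        raise StageError("concord", e) from e

    return {
        "intensities": intensities,
        "truth": truth,
        "comparator": comparator,
        "calls": calls,
        "final_calls": final_calls,
        "cluster_file": cluster_file,
        "zeroed_cluster_file": zeroed,
        "snp_stats": stats,
        "sample_stats": sample_stats,
        "decisions": decisions,
        "sample_qc": sample_qc,
        "contingency": table,
        "summary": summary,
        "mac_concordance": mac,
    }


def _subset(gm, variant_indices):
    from .genotypes import GenotypeMatrix

    return GenotypeMatrix(
        [gm.variants[i] for i in variant_indices],
        list(gm.samples),
        gm.genotypes[variant_indices],
        None if gm.scores is None else gm.scores[variant_indices],
    )
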