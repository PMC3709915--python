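"""Best-practices SNP and sample quality control.

Two tiers of criteria act on the per-SNP statistics:

* *review flags* mark variants for visual inspection (sex-chromosome and
  mitochondrial variants, borderline call frequency, replicate/Mendelian
  inconsistencies, list memberships, ...). Flags never exclude by
  themselves.
* *exclusion criteria* remove failing variants outright; excluded variants
  are zeroed in the cluster file so re-applied calling forces them missing.

Samples are excluded when p10GC < 0.38 or call rate < 0.97 (strict
inequalities). "Obvious batch effects" — a visual judgement in laboratory
practice — is operationalized as a Bonferroni-screened chi-square test of
no-call counts and of allele counts across batches.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy import stats as sps

from .caller import ClusterFile
from .genotypes import GT_AA, GT_AB, GT_BB, GT_XX, GenotypeMatrix
from .snpstats import SampleStats, SnpStats

log = logging.getLogger(__name__)


@dataclass
class QCThresholds:
    """Every numeric bound of the review and exclusion criteria.

    Review bounds are never stricter than the matching exclusion bound
    where both exist (homozygote theta deviation: 0.025 review vs 0.06
    exclusion).
    """

    # review (flag-only) bounds
    review_call_freq_low: float = 0.95
    review_call_freq_high: float = 0.99
    review_aa_theta_mean_low: float = 0.2
    review_aa_theta_mean_high: float = 0.3
    review_bb_theta_mean_low: float = 0.7
    review_bb_theta_mean_high: float = 0.8
    review_hom_theta_dev: float = 0.025
    review_rare_maf: float = 0.0001
    rep_error_max: int = 2
    ppc_error_max: int = 1
    pc_error_max: int = 1
    # bounds shared by review and exclusion
    cluster_sep_min: float = 0.4
    ab_freq_max: float = 0.6
    ab_r_mean_min: float = 0.2
    het_excess_max: float = 0.1
    het_excess_min: float = -0.9
    ab_theta_dev_max: float = 0.07  # inclusive bound (>=)
    # exclusion-only bounds
    excl_call_freq_min: float = 0.95
    excl_aa_theta_mean_max: float = 0.3
    excl_bb_theta_mean_min: float = 0.7
    excl_ab_theta_mean_low: float = 0.2
    excl_ab_theta_mean_high: float = 0.8
    excl_hom_theta_dev_max: float = 0.06
    # sample bounds
    p10gc_min: float = 0.38
    sample_call_rate_min: float = 0.97
    # family-wise significance level of the batch-effect screen
    batch_alpha: float = 0.05

    def validate(self) -> None:
        if self.review_hom_theta_dev > self.excl_hom_theta_dev_max:
            raise ValueError("review theta-dev bound stricter than exclusion bound")

    @classmethod
    def from_dict(cls, d: dict) -> "QCThresholds":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown threshold fields: {sorted(unknown)}")
        obj = cls(**d)
        obj.validate()
        return obj


@dataclass
class QCDecision:
    """Outcome for one variant: review flags and the exclusion verdict."""

    variant_id: str
    flags: set[str] = field(default_factory=set)
    excluded: bool = False
    exclusion_reasons: set[str] = field(default_factory=set)


def _is(x) -> bool:
    return x is not None


def flag_for_review(
    stats: SnpStats,
    thresholds: QCThresholds | None = None,
    cautious_ids: set[str] | None = None,
    removed_v11_ids: set[str] | None = None,
) -> set[str]:
    """All review criteria matched by one variant's statistics."""
    t = thresholds or QCThresholds()
    s = stats
    flags: set[str] = set()
    if s.chrom_class in ("X", "Y", "XY", "MT"):
        flags.add("sex_or_mt_variant")
    if t.review_call_freq_low <= s.call_frequency <= t.review_call_freq_high:
        flags.add("call_freq_0.95_0.99")
    if s.cluster_sep < t.cluster_sep_min:
        flags.add("cluster_sep")
    if _is(s.ab_freq) and s.ab_freq > t.ab_freq_max:
        flags.add("ab_freq_high")
    if _is(s.ab_r_mean) and s.ab_r_mean < t.ab_r_mean_min:
        flags.add("ab_r_mean_low")
    if _is(s.het_excess) and s.het_excess > t.het_excess_max:
        flags.add("het_excess_high")
    if _is(s.het_excess) and s.het_excess < t.het_excess_min:
        flags.add("het_excess_low")
    if _is(s.aa_theta_mean) and t.review_aa_theta_mean_low <= s.aa_theta_mean <= t.review_aa_theta_mean_high:
        flags.add("aa_theta_mean_0.2_0.3")
    if _is(s.bb_theta_mean) and t.review_bb_theta_mean_low <= s.bb_theta_mean <= t.review_bb_theta_mean_high:
        flags.add("bb_theta_mean_0.7_0.8")
    if _is(s.ab_theta_mean) and t.review_aa_theta_mean_low <= s.ab_theta_mean <= t.review_aa_theta_mean_high:
        flags.add("ab_theta_mean_0.2_0.3")
    if _is(s.ab_theta_mean) and t.review_bb_theta_mean_low <= s.ab_theta_mean <= t.review_bb_theta_mean_high:
        flags.add("ab_theta_mean_0.7_0.8")
    if _is(s.aa_theta_dev) and s.aa_theta_dev > t.review_hom_theta_dev:
        flags.add("aa_theta_dev_review")
    if _is(s.ab_theta_dev) and s.ab_theta_dev >= t.ab_theta_dev_max:
        flags.add("ab_theta_dev")
    if _is(s.bb_theta_dev) and s.bb_theta_dev > t.review_hom_theta_dev:
        flags.add("bb_theta_dev_review")
    if _is(s.ab_freq) and s.ab_freq == 0 and _is(s.maf) and s.maf > 0:
        flags.add("ab_freq_zero_maf_pos")
    if _is(s.aa_freq) and s.aa_freq == 1 and s.call_frequency < 1:
        flags.add("aa_freq_one_incomplete")
    if _is(s.bb_freq) and s.bb_freq == 1 and s.call_frequency < 1:
        flags.add("bb_freq_one_incomplete")
    if _is(s.maf) and s.maf < t.review_rare_maf and s.call_frequency != 1:
        flags.add("rare_maf_incomplete")
    if s.rep_errors > t.rep_error_max:
        flags.add("rep_error")
    if s.ppc_errors > t.ppc_error_max:
        flags.add("ppc_error")
    if s.pc_errors > t.pc_error_max:
        flags.add("pc_error")
    if removed_v11_ids and s.variant_id in removed_v11_ids:
        flags.add("removed_v1.1")
    if cautious_ids and s.variant_id in cautious_ids:
        flags.add("cautious_site")
    return flags


def exclude_snps(
    stats: SnpStats,
    thresholds: QCThresholds | None = None,
    batch_excluded: bool = False,
    cautious_ids: set[str] | None = None,
    removed_v11_ids: set[str] | None = None,
) -> QCDecision:
    """Apply the exclusion criteria to one variant (flags included)."""
    t = thresholds or QCThresholds()
    s = stats
    reasons: set[str] = set()
    if s.call_frequency < t.excl_call_freq_min and s.chrom_class != "Y":
        reasons.add("call_freq")
    if s.cluster_sep < t.cluster_sep_min:
        reasons.add("cluster_sep")
    if _is(s.ab_freq) and s.ab_freq > t.ab_freq_max:
        reasons.add("ab_freq_high")
    if _is(s.ab_r_mean) and s.ab_r_mean < t.ab_r_mean_min:
        reasons.add("ab_r_mean_low")
    if _is(s.het_excess) and s.het_excess > t.het_excess_max:
        reasons.add("het_excess_high")
    if _is(s.het_excess) and s.het_excess < t.het_excess_min:
        reasons.add("het_excess_low")
    if _is(s.aa_theta_mean) and s.aa_theta_mean > t.excl_aa_theta_mean_max:
        reasons.add("aa_theta_mean")
    if _is(s.bb_theta_mean) and s.bb_theta_mean < t.excl_bb_theta_mean_min:
        reasons.add("bb_theta_mean")
    if _is(s.ab_theta_mean) and (
        s.ab_theta_mean < t.excl_ab_theta_mean_low or s.ab_theta_mean > t.excl_ab_theta_mean_high
    ):
        reasons.add("ab_theta_mean")
    if _is(s.aa_theta_dev) and s.aa_theta_dev > t.excl_hom_theta_dev_max:
        reasons.add("aa_theta_dev")
    if _is(s.ab_theta_dev) and s.ab_theta_dev >= t.ab_theta_dev_max:
        reasons.add("ab_theta_dev")
    if _is(s.bb_theta_dev) and s.bb_theta_dev > t.excl_hom_theta_dev_max:
        reasons.add("bb_theta_dev")
    if batch_excluded:
        reasons.add("batch_effect")
    return QCDecision(
        variant_id=s.variant_id,
        flags=flag_for_review(s, t, cautious_ids, removed_v11_ids),
        excluded=bool(reasons),
        exclusion_reasons=reasons,
    )


def exclude_samples(
    sample_stats: list[SampleStats], thresholds: QCThresholds | None = None
) -> pd.DataFrame:
    """Per-sample exclusion: p10GC < 0.38 or call rate < 0.97 (strict)."""
    t = thresholds or QCThresholds()
    rows = [
        {
            "sample_id": s.sample_id,
            "call_rate": s.call_rate,
            "p10gc": s.p10gc,
            "excluded": s.p10gc < t.p10gc_min or s.call_rate < t.sample_call_rate_min,
        }
        for s in sample_stats
    ]
    return pd.DataFrame(rows)


def _chi2_table(table: np.ndarray) -> float:
    """p-value of independence for a 2 x B count table; degenerate -> 1."""
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2 or (table.sum(axis=1) > 0).sum() < 2:
        return 1.0
    return float(sps.chi2_contingency(table)[1])


def batch_effect_stat(
    calls: GenotypeMatrix, batches: np.ndarray, alpha: float = 0.05
) -> pd.DataFrame:
    """Chi-square screen for batch effects, per variant.

    Tests independence of (a) no-call counts and (b) allele counts across
    batches; the per-variant p-value is the Bonferroni-combined minimum of
    the two, and the excluded flag applies a second Bonferroni correction
    across variants at family-wise level ``alpha``.
    """
    batches = np.asarray(batches)
    levels = np.unique(batches)
    n_var = calls.n_variants
    if levels.size < 2:
        log.warning("single batch: batch-effect screen is a no-op")
        return pd.DataFrame(
            {
                "variant_id": calls.variants,
                "p_value": np.ones(n_var),
                "excluded": np.zeros(n_var, dtype=bool),
            }
        )
    masks = [batches == b for b in levels]
    g = calls.genotypes
    pvals = np.ones(n_var)
    for vi in range(n_var):
        row = g[vi]
        nocall = np.array(
            [[(row[m] == GT_XX).sum(), (row[m] != GT_XX).sum()] for m in masks]
        ).T
        a_counts = []
        b_counts = []
        for m in masks:
            sub = row[m]
            n_aa = (sub == GT_AA).sum()
            n_ab = (sub == GT_AB).sum()
            n_bb = (sub == GT_BB).sum()
            a_counts.append(2 * n_aa + n_ab)
            b_counts.append(2 * n_bb + n_ab)
        alleles = np.array([a_counts, b_counts])
        p = min(_chi2_table(nocall), _chi2_table(alleles)) * 2.0
        pvals[vi] = min(p, 1.0)
    excluded = pvals * n_var < alpha
    return pd.DataFrame(
        {"variant_id": calls.variants, "p_value": pvals, "excluded": excluded}
    )


def zero_out(cluster_file: ClusterFile, excluded_ids: list[str]) -> ClusterFile:
    """Zero the listed variants in a copy of the cluster file."""
    out = cluster_file.copy()
    for vid in excluded_ids:
        model = out[vid]  # raises MissingVariantError for unknown ids
        out._models[vid] = model.zeroed()
    return out


def dedupe_variants(
    stats: list[SnpStats], duplicate_keys: dict[str, str]
) -> set[str]:
    """Among variants sharing a duplicate key, drop all but the one with the
    highest call frequency (ties broken toward the lexicographically
    smallest id). Returns the set of variant ids to drop."""
    groups: dict[str, list[SnpStats]] = {}
    for s in stats:
        key = duplicate_keys.get(s.variant_id)
        if key is not None:
            groups.setdefault(key, []).append(s)
    drop: set[str] = set()
    for members in groups.values():
        if len(members) < 2:
            continue
        keep = min(members, key=lambda s: (-s.call_frequency, s.variant_id))
        drop.update(s.variant_id for s in members if s is not keep)
    return drop


def qc_report(decisions: list[QCDecision]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variant_id": d.variant_id,
                "flags": ";".join(sorted(d.flags)),
                "excluded": d.excluded,
                "exclusion_reasons": ";".join(sorted(d.exclusion_reasons)),
            }
            for d in decisions
        ]
    )
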