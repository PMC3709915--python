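"""Per-SNP and per-sample statistics consumed by the QC criteria.

Conventions (fixed by test vectors):

* Genotype frequencies are computed over called samples only; for Y
  variants, female samples are excluded from every denominator.
* Allele counts respect ploidy: one allele per male on X and per sample on
  Y/MT, two otherwise. The B allele is counted as the minor candidate and
  MAF = min(p, 1 - p).
* ``het_excess`` = (AB frequency - e) / e with e = 2 p (1 - p) estimated
  from called genotypes; 0 when e = 0 and no heterozygotes were called,
  capped at 10 when e = 0 but heterozygotes exist. Absent for haploid
  classes (Y, MT) where a Hardy-Weinberg expectation is meaningless.
* Per-class theta mean/dev are the mean and (population) standard deviation
  of member points' theta; ``cluster_sep`` is the minimum over adjacent
  called classes of gap / (gap + dev1 + dev2), 1.0 with fewer than two
  called classes.
* ``p10gc`` is the 10th-percentile order statistic (the largest score not
  exceeding the 10% rank position) of a sample's per-call scores, no-calls
  included.
"""
from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .genotypes import GT_AA, GT_AB, GT_BB, GT_XX, GenotypeMatrix, HAPLOID_CLASSES

HET_EXCESS_CAP = 10.0

MAF_BIN_EDGES = (0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.5)
MAF_BIN_LABELS = (
    "0",
    "(0, 0.001]",
    "(0.001, 0.005]",
    "(0.005, 0.01]",
    "(0.01, 0.05]",
    "(0.05, 0.1]",
    "(0.1, 0.2]",
    "(0.2, 0.5]",
)


@dataclass
class SnpStats:
    """The per-variant statistic vector the QC tables consume."""

    variant_id: str
    chrom_class: str = "autosome"
    n_called: int = 0
    n_total: int = 0
    call_frequency: float = 0.0
    aa_freq: float | None = None
    ab_freq: float | None = None
    bb_freq: float | None = None
    maf: float | None = None
    minor_allele_count: int = 0
    aa_theta_mean: float | None = None
    aa_theta_dev: float | None = None
    ab_theta_mean: float | None = None
    ab_theta_dev: float | None = None
    bb_theta_mean: float | None = None
    bb_theta_dev: float | None = None
    ab_r_mean: float | None = None
    cluster_sep: float = 1.0
    het_excess: float | None = None
    rep_errors: int = 0
    ppc_errors: int = 0
    pc_errors: int = 0


@dataclass
class SampleStats:
    """Per-sample quality: call rate and the p10GC score summary."""

    sample_id: str
    call_rate: float
    p10gc: float


def _allele_multiplicity(chrom_class: str, is_female: np.ndarray) -> np.ndarray:
    """Allele copies each sample contributes at this variant class."""
    if chrom_class in HAPLOID_CLASSES:
        return np.ones(is_female.shape)
    if chrom_class == "X":
        return np.where(is_female, 2.0, 1.0)
    return np.full(is_female.shape, 2.0)


def cluster_separation(
    means: list[float], devs: list[float]
) -> float:
    """min over adjacent class pairs of gap / (gap + dev1 + dev2)."""
    if len(means) < 2:
        return 1.0
    seps = []
    for (m1, d1), (m2, d2) in zip(zip(means, devs), zip(means[1:], devs[1:])):
        gap = max(0.0, abs(m2 - m1))
        denom = gap + d1 + d2
        seps.append(gap / denom if denom > 0 else 0.0)
    return min(seps)


def het_excess_statistic(ab_freq: float, p: float) -> float:
    """(observed AB frequency - 2p(1-p)) / 2p(1-p), with guarded e = 0."""
    e = 2.0 * p * (1.0 - p)
    if e == 0.0:
        return 0.0 if ab_freq == 0.0 else HET_EXCESS_CAP
    return (ab_freq - e) / e


def compute_snp_stats(
    variant_id: str,
    genotypes: np.ndarray,
    scores: np.ndarray | None,
    theta: np.ndarray,
    r: np.ndarray,
    sexes: np.ndarray,
    chrom_class: str = "autosome",
) -> SnpStats:
    """Compute the full statistic vector for one variant.

    ``genotypes``/``theta``/``r`` are per-sample arrays; ``sexes`` holds
    "F"/"M" labels used for the female-Y exclusion and X allele counting.
    """
    genotypes = np.asarray(genotypes)
    sexes = np.asarray(sexes)
    is_female = sexes == "F"
    mask = ~is_female if chrom_class == "Y" else np.ones(genotypes.shape, dtype=bool)

    g = genotypes[mask]
    th = np.asarray(theta, dtype=float)[mask]
    rr = np.asarray(r, dtype=float)[mask]
    mult = _allele_multiplicity(chrom_class, is_female)[mask]

    stats = SnpStats(variant_id=variant_id, chrom_class=chrom_class, n_total=int(g.size))
    called = g != GT_XX
    n_called = int(called.sum())
    stats.n_called = n_called
    stats.call_frequency = n_called / g.size if g.size else 0.0
    if n_called == 0:
        return stats

    n_aa = int((g == GT_AA).sum())
    n_ab = int((g == GT_AB).sum())
    n_bb = int((g == GT_BB).sum())
    stats.aa_freq = n_aa / n_called
    stats.ab_freq = n_ab / n_called
    stats.bb_freq = n_bb / n_called

    # ploidy-aware allele counts: B-allele dosage is 0/1/2 for diploid
    # calls and 0/1 for haploid ones (AB cannot occur on a haploid call)
    m = mult[called]
    dose = np.clip(g[called], 0, 2).astype(float)
    b_count = float(np.sum(np.where(m == 1.0, dose / 2.0, dose)))
    total_alleles = float(m.sum())
    p_b = b_count / total_alleles
    stats.maf = min(p_b, 1.0 - p_b)
    stats.minor_allele_count = int(round(min(b_count, total_alleles - b_count)))

    if chrom_class not in HAPLOID_CLASSES:
        stats.het_excess = het_excess_statistic(stats.ab_freq, p_b)

    class_means: list[float] = []
    class_devs: list[float] = []
    for cls, prefix in ((GT_AA, "aa"), (GT_AB, "ab"), (GT_BB, "bb")):
        members = g == cls
        if not members.any():
            continue
        mean = float(np.mean(th[members]))
        dev = float(np.std(th[members]))
        setattr(stats, f"{prefix}_theta_mean", mean)
        setattr(stats, f"{prefix}_theta_dev", dev)
        if cls == GT_AB:
            stats.ab_r_mean = float(np.mean(rr[members]))
        class_means.append(mean)
        class_devs.append(dev)
    stats.cluster_sep = cluster_separation(class_means, class_devs)
    return stats


def compute_all_snp_stats(
    calls: GenotypeMatrix,
    theta: np.ndarray,
    r: np.ndarray,
    sexes: np.ndarray,
    chrom_classes: np.ndarray | None = None,
) -> list[SnpStats]:
    if chrom_classes is None:
        chrom_classes = np.full(calls.n_variants, "autosome")
    return [
        compute_snp_stats(
            calls.variants[vi],
            calls.genotypes[vi],
            None if calls.scores is None else calls.scores[vi],
            theta[vi],
            r[vi],
            sexes,
            chrom_class=str(chrom_classes[vi]),
        )
        for vi in range(calls.n_variants)
    ]


def compute_sample_stats(
    sample_id: str,
    genotypes: np.ndarray,
    scores: np.ndarray,
) -> SampleStats:
    """Call rate and p10GC for one sample.

    ``genotypes``/``scores`` are per-variant arrays restricted to variants
    applicable to the sample; NaN scores mark inapplicable cells (female-Y)
    and are dropped from both denominators.
    """
    genotypes = np.asarray(genotypes)
    scores = np.asarray(scores, dtype=float)
    applicable = ~np.isnan(scores)
    if not applicable.any():
        raise ValueError(f"sample {sample_id!r} has no applicable variants")
    g = genotypes[applicable]
    s = scores[applicable]
    call_rate = float(np.mean(g != GT_XX))
    # lower order statistic: 100 scores with the lowest ten at 0.10 -> 0.10
    p10gc = float(np.percentile(s, 10.0, method="lower"))
    return SampleStats(sample_id=sample_id, call_rate=call_rate, p10gc=p10gc)


def compute_all_sample_stats(calls: GenotypeMatrix) -> list[SampleStats]:
    if calls.scores is None:
        raise ValueError("sample statistics require per-call scores")
    return [
        compute_sample_stats(
            calls.samples[si], calls.genotypes[:, si], calls.scores[:, si]
        )
        for si in range(calls.n_samples)
    ]


def replicate_errors(
    calls: GenotypeMatrix, replicate_pairs: list[tuple[str, str]]
) -> np.ndarray:
    """Per-variant count of replicate pairs with two unequal non-missing calls."""
    idx = calls.sample_index()
    counts = np.zeros(calls.n_variants, dtype=int)
    for a, b in replicate_pairs:
        ga = calls.genotypes[:, idx[a]]
        gb = calls.genotypes[:, idx[b]]
        counts += ((ga != GT_XX) & (gb != GT_XX) & (ga != gb)).astype(int)
    return counts


_ALLELES = {GT_AA: (0,), GT_AB: (0, 1), GT_BB: (1,)}


def _ppc_possible(father: int, mother: int, child: int) -> bool:
    return any(
        a + b == child for a in _ALLELES[father] for b in _ALLELES[mother]
    )


def _pc_possible(parent: int, child: int) -> bool:
    # single-parent impossibility: opposite homozygotes only
    return not (
        (parent == GT_AA and child == GT_BB) or (parent == GT_BB and child == GT_AA)
    )


def mendel_errors(
    calls: GenotypeMatrix,
    trios: list[tuple[str, str | None, str | None]],
    chrom_classes: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant (PPC, PC) Mendelian inconsistency counts.

    ``trios`` lists (child, father, mother); a missing parent id is None.
    PPC errors need both parents called; with one informative parent
    (by design or because the other parent's call is missing) the pairwise
    opposite-homozygote rule applies. Autosomal variants only: sex
    chromosomes and MT are exempt.
    """
    idx = calls.sample_index()
    n_var = calls.n_variants
    ppc = np.zeros(n_var, dtype=int)
    pc = np.zeros(n_var, dtype=int)
    if chrom_classes is None:
        chrom_classes = np.full(n_var, "autosome")
    autosomal = np.asarray(chrom_classes) == "autosome"
    g = calls.genotypes
    for child, father, mother in trios:
        gc = g[:, idx[child]]
        gf = g[:, idx[father]] if father else np.full(n_var, GT_XX, dtype=np.int8)
        gm = g[:, idx[mother]] if mother else np.full(n_var, GT_XX, dtype=np.int8)
        for vi in np.nonzero(autosomal & (gc != GT_XX))[0]:
            f_ok, m_ok = gf[vi] != GT_XX, gm[vi] != GT_XX
            if f_ok and m_ok:
                if not _ppc_possible(int(gf[vi]), int(gm[vi]), int(np.clip(gc[vi], 0, 2))):
                    ppc[vi] += 1
            elif f_ok or m_ok:
                parent = int(gf[vi]) if f_ok else int(gm[vi])
                if not _pc_possible(parent, int(gc[vi])):
                    pc[vi] += 1
    return ppc, pc


def maf_bin_label(maf: float) -> str:
    """Bin a MAF into the standard spectrum intervals (left-open, right-closed)."""
    if maf < 0 or maf > 0.5:
        raise ValueError(f"MAF {maf} outside [0, 0.5]")
    if maf == 0.0:
        return MAF_BIN_LABELS[0]
    i = int(np.searchsorted(MAF_BIN_EDGES, maf, side="left"))
    return MAF_BIN_LABELS[1 + i]


def maf_table(
    mafs: np.ndarray, group_labels: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-group percentage of variants in each MAF spectrum bin."""
    mafs = np.asarray(mafs, dtype=float)
    groups = (
        np.full(mafs.shape, "All") if group_labels is None else np.asarray(group_labels)
    )
    rows = {}
    for grp in pd.unique(groups):
        sel = mafs[groups == grp]
        labels = [maf_bin_label(m) for m in sel]
        counts = pd.Series(labels).value_counts()
        rows[grp] = [100.0 * counts.get(lbl, 0) / len(sel) for lbl in MAF_BIN_LABELS]
    return pd.DataFrame(rows, index=list(MAF_BIN_LABELS))


def snp_stats_frame(stats: list[SnpStats]) -> pd.DataFrame:
    """Tabular report, one row per variant, columns exactly the stat fields."""
    return pd.DataFrame([{f.name: getattr(s, f.name) for f in fields(SnpStats)} for s in stats])


def sample_stats_frame(stats: list[SampleStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [{f.name: getattr(s, f.name) for f in fields(SampleStats)} for s in stats]
    )
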