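"""Synthetic exome-array intensity data with known truth genotypes.

The generator emulates the statistical structure a joint-calling pipeline
assumes: per-SNP three-cluster geometry in polar (theta, R) space, a minor
allele frequency spectrum dominated by very rare variants, hemizygous
(two-cluster) Y/MT systems, planted failing-SNP archetypes matching the
standard exclusion criteria, low-quality samples, plate/batch effects,
replicate pairs and parent-parent-child trios, and a paired "sequence"
comparator genotype set with independent error and missingness.

Truth genotypes for clean diploid variants are Hardy-Weinberg draws at each
variant's generating MAF (the B allele is the minor allele, so AA is the
common homozygote). Trio children receive one allele transmitted from each
parent; replicate samples copy their source's truth genotype but receive
independent intensity draws.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .genotypes import (
    GT_AA,
    GT_AB,
    GT_BB,
    GT_XX,
    GenotypeMatrix,
    IntensityMatrix,
)

# minor allele frequency spectrum of an exome-focused array: the vast
# majority of sites have MAF < 0.005. Proportions are normalized so they
# sum to exactly 1 (the source percentages carry rounding error).
_RAW_SPECTRUM = [
    (0.0, 0.045),      # monomorphic
    (0.001, 0.588),
    (0.005, 0.153),
    (0.01, 0.043),
    (0.05, 0.057),
    (0.1, 0.018),
    (0.2, 0.024),
    (0.5, 0.073),
]
_total = sum(p for _, p in _RAW_SPECTRUM)
DEFAULT_MAF_SPECTRUM: tuple[tuple[float, float], ...] = tuple(
    (edge, p / _total) for edge, p in _RAW_SPECTRUM
)

#: failing-SNP archetypes, one per SNP exclusion criterion. Each override
#: dict replaces parts of the clean generating geometry so that the matched
#: statistic violates its exclusion bound by construction.
ARCHETYPES: dict[str, dict] = {
    # a fraction of samples yield no measurable signal (failed assay,
    # x = y = 0) -> call frequency < 0.95
    "low_call_freq": {"null_fraction": 0.10, "maf": 0.30},
    # wide heterozygote cluster with the BB cluster inside its flank ->
    # cluster separation < 0.4
    "compressed": {"centers": (0.05, 0.52, 0.60), "devs": (0.02, 0.20, 0.02), "maf": 0.45},
    # genotype frequencies drawn directly -> AB frequency > 0.6
    "ab_freq_high": {"geno_freqs": (0.15, 0.70, 0.15)},
    # dim heterozygote intensities -> AB R mean < 0.2
    "low_ab_r": {"ab_r_mean": 0.10, "maf": 0.30},
    # moderate heterozygote inflation -> het excess > 0.1 (AB freq stays <= 0.6)
    "het_excess_high": {"geno_freqs": (0.20, 0.60, 0.20)},
    # heterozygote dropout at a common site -> het excess < -0.9
    "het_excess_low": {"geno_freqs": (0.50, 0.02, 0.48)},
    "aa_theta_shifted": {"centers": (0.35, 0.60, 0.95), "maf": 0.35},
    "bb_theta_shifted": {"centers": (0.05, 0.40, 0.65), "maf": 0.35},
    "ab_theta_shifted": {"centers": (0.02, 0.15, 0.95), "maf": 0.35},
    "aa_theta_dev": {"centers": (0.20, 0.55, 0.95), "devs": (0.10, 0.02, 0.02), "maf": 0.35},
    "ab_theta_dev": {"devs": (0.02, 0.09, 0.02), "maf": 0.35},
    "bb_theta_dev": {"centers": (0.05, 0.45, 0.80), "devs": (0.02, 0.02, 0.10), "maf": 0.35},
    # theta shifted in one batch only -> differential calls / missingness
    "batch": {"batch_shift": True, "maf": 0.30},
}

_CHROM_DEFAULT = {"autosome": 0.97, "X": 0.015, "Y": 0.01, "MT": 0.005}


@dataclass
class SimConfig:
    """Generating conditions for one synthetic dataset.

    ``maf_spectrum`` is an ordered list of (bin upper edge, proportion)
    pairs; the first entry with edge 0.0 is the monomorphic bin. Cluster
    geometry defaults place well-separated clusters so that clean variants
    pass every exclusion criterion with wide margin.
    """

    n_samples: int = 1000
    n_variants: int = 5000
    maf_spectrum: tuple[tuple[float, float], ...] = DEFAULT_MAF_SPECTRUM
    theta_centers: tuple[float, float, float] = (0.05, 0.50, 0.95)
    theta_jitter: float = 0.01
    theta_dev: float = 0.02
    r_means: tuple[float, float, float] = (1.0, 1.1, 1.0)
    r_dev: float = 0.1
    archetype_fractions: dict[str, float] = field(default_factory=dict)
    lowq_sample_fraction: float = 0.0
    lowq_noise_multiplier: float = 4.0
    n_batches: int = 4
    batch_shift: float = 0.25
    n_replicate_pairs: int = 0
    n_trios: int = 0
    chrom_fractions: dict[str, float] = field(default_factory=lambda: dict(_CHROM_DEFAULT))
    seq_error_rate: float = 0.0005
    seq_missing_rate: float = 0.001
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0 or self.n_variants <= 0:
            raise ConfigError("n_samples and n_variants must be positive")
        props = [p for _, p in self.maf_spectrum]
        if any(p < 0 or p > 1 for p in props):
            raise ConfigError("spectrum proportions must lie in [0, 1]")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ConfigError(f"spectrum proportions sum to {sum(props)}, not 1")
        edges = [e for e, _ in self.maf_spectrum]
        if any(b <= a for a, b in zip(edges[1:], edges[2:])):
            raise ConfigError("spectrum bin edges must be increasing")
        if edges and edges[-1] > 0.5:
            raise ConfigError("MAF bin edges cannot exceed 0.5")
        for name, frac in self.archetype_fractions.items():
            if name not in ARCHETYPES:
                raise ConfigError(f"unknown archetype {name!r}")
            if not 0 <= frac <= 1:
                raise ConfigError("archetype fractions must lie in [0, 1]")
        if sum(self.archetype_fractions.values()) > 1:
            raise ConfigError("archetype fractions sum to more than 1")
        if not 0 <= self.lowq_sample_fraction <= 1:
            raise ConfigError("lowq_sample_fraction must lie in [0, 1]")
        if self.lowq_noise_multiplier < 1:
            raise ConfigError("lowq_noise_multiplier must be >= 1")
        if self.n_batches <= 0:
            raise ConfigError("n_batches must be positive")
        if self.batch_shift < 0:
            raise ConfigError("batch_shift must be >= 0")
        if not all(a < b for a, b in zip(self.theta_centers, self.theta_centers[1:])):
            raise ConfigError("theta centers must be strictly increasing")
        if 3 * self.n_trios + 2 * self.n_replicate_pairs > self.n_samples:
            raise ConfigError("n_samples too small for requested trios/replicates")
        for rate in (self.seq_error_rate, self.seq_missing_rate):
            if not 0 <= rate <= 1:
                raise ConfigError("sequence comparator rates must lie in [0, 1]")


@dataclass
class TruthSet:
    """Generating truth: genotypes plus variant and sample annotations."""

    genotypes: GenotypeMatrix
    variant_meta: pd.DataFrame  # variant_id, chrom_class, archetype, maf, realized_maf
    sample_meta: pd.DataFrame   # sample_id, sex, batch, quality_class, replicate_of, father_id, mother_id


def sample_maf_spectrum(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw one MAF per variant: choose a spectrum bin by its proportion,
    then uniformly within the bin; the monomorphic bin yields exactly 0."""
    config.validate()
    edges = [e for e, _ in config.maf_spectrum]
    props = np.array([p for _, p in config.maf_spectrum])
    bins = rng.choice(len(edges), size=config.n_variants, p=props)
    lowers = np.array([0.0] + edges[:-1])
    uppers = np.array(edges)
    u = rng.uniform(size=config.n_variants)
    mafs = lowers[bins] + u * (uppers[bins] - lowers[bins])
    mafs[uppers[bins] == 0.0] = 0.0
    return mafs


def _hwe_draw(rng: np.random.Generator, p: float, n: int) -> np.ndarray:
    """Diploid Hardy-Weinberg genotypes at B-allele frequency p."""
    u = rng.uniform(size=n)
    g = np.full(n, GT_AA, dtype=np.int8)
    g[u < p * p + 2 * p * (1 - p)] = GT_AB
    g[u < p * p] = GT_BB
    return g


def _haploid_draw(rng: np.random.Generator, p: float, n: int) -> np.ndarray:
    return np.where(rng.uniform(size=n) < p, GT_BB, GT_AA).astype(np.int8)


def _transmit(rng: np.random.Generator, father: np.int8, mother: np.int8) -> np.int8:
    """Child genotype from Mendelian transmission (B-allele dosage)."""
    def allele(g):
        if g == GT_AA:
            return 0
        if g == GT_BB:
            return 1
        return int(rng.integers(0, 2))
    return np.int8(allele(father) + allele(mother))


def _freq_draw(rng: np.random.Generator, freqs: tuple[float, float, float], n: int) -> np.ndarray:
    u = rng.uniform(size=n)
    g = np.full(n, GT_AA, dtype=np.int8)
    g[u < freqs[1] + freqs[2]] = GT_AB
    g[u < freqs[2]] = GT_BB
    return g


def _theta_r_to_xy(theta: np.ndarray, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = np.tan(theta * math.pi / 2.0)
    with np.errstate(over="ignore", invalid="ignore"):
        x = np.where(np.isinf(t), 0.0, r / (1.0 + t))
    y = r - x
    return x, y


def _make_sample_meta(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_samples
    ids = [f"S{i + 1:05d}" for i in range(n)]
    sex = np.where(rng.uniform(size=n) < 0.5, "F", "M")
    batch = rng.integers(0, config.n_batches, size=n)
    quality = np.full(n, "clean", dtype=object)
    n_lowq = int(round(config.lowq_sample_fraction * n))
    structured = 3 * config.n_trios + 2 * config.n_replicate_pairs
    if n_lowq:
        lowq_pool = np.arange(structured, n)  # keep pedigree/replicate samples clean
        quality[rng.choice(lowq_pool, size=min(n_lowq, lowq_pool.size), replace=False)] = "lowq"
    father = np.full(n, "", dtype=object)
    mother = np.full(n, "", dtype=object)
    replicate_of = np.full(n, "", dtype=object)
    pos = 0
    for _ in range(config.n_trios):
        f, m, c = pos, pos + 1, pos + 2
        sex[f], sex[m] = "M", "F"
        father[c], mother[c] = ids[f], ids[m]
        pos += 3
    for _ in range(config.n_replicate_pairs):
        src, rep = pos, pos + 1
        replicate_of[rep] = ids[src]
        sex[rep] = sex[src]
        pos += 2
    return pd.DataFrame(
        {
            "sample_id": ids,
            "sex": sex,
            "batch": batch,
            "quality_class": quality,
            "replicate_of": replicate_of,
            "father_id": father,
            "mother_id": mother,
        }
    )


def _make_variant_meta(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_variants
    ids = [f"V{i + 1:06d}" for i in range(n)]
    names = list(config.archetype_fractions)
    probs = [config.archetype_fractions[a] for a in names]
    arch = rng.choice(
        names + ["clean"], size=n, p=probs + [1.0 - sum(probs)]
    )
    classes = list(config.chrom_fractions)
    cprobs = np.array([config.chrom_fractions[c] for c in classes], dtype=float)
    cprobs /= cprobs.sum()
    chrom = rng.choice(classes, size=n, p=cprobs)
    chrom[arch != "clean"] = "autosome"  # archetypes are planted on autosomes
    mafs = sample_maf_spectrum(config, rng)
    for i in range(n):
        override = ARCHETYPES.get(arch[i], {})
        if "maf" in override:
            mafs[i] = override["maf"]
        elif "geno_freqs" in override:
            f = override["geno_freqs"]
            mafs[i] = min(f[2] + f[1] / 2.0, 1.0 - (f[2] + f[1] / 2.0))
        elif arch[i] != "clean" and mafs[i] < 0.05:
            mafs[i] = 0.30  # archetype statistics need populated clusters
    return pd.DataFrame(
        {"variant_id": ids, "chrom_class": chrom, "archetype": arch, "maf": mafs}
    )


def _draw_truth_variant(
    rng: np.random.Generator,
    meta_row,
    sample_meta: pd.DataFrame,
    trio_index: list[tuple[int, int, int]],
    rep_index: list[tuple[int, int]],
) -> np.ndarray:
    """Truth genotypes for one variant across all samples."""
    n = len(sample_meta)
    p = meta_row.maf
    cc = meta_row.chrom_class
    is_female = (sample_meta["sex"] == "F").to_numpy()
    override = ARCHETYPES.get(meta_row.archetype, {})
    if "geno_freqs" in override:
        g = _freq_draw(rng, override["geno_freqs"], n)
    elif cc == "autosome" or cc == "XY":
        g = _hwe_draw(rng, p, n)
        for f, m, c in trio_index:
            g[c] = _transmit(rng, g[f], g[m])
    elif cc == "X":
        g = _hwe_draw(rng, p, n)
        males = ~is_female
        g[males] = _haploid_draw(rng, p, int(males.sum()))
    elif cc == "Y":
        g = _haploid_draw(rng, p, n)
        g[is_female] = GT_XX
    elif cc == "MT":
        g = _haploid_draw(rng, p, n)
    else:  # pragma: no cover
        raise ConfigError(f"unknown chrom class {cc!r}")
    for src, rep in rep_index:
        g[rep] = g[src]
    return g


def simulate_dataset(config: SimConfig) -> tuple[IntensityMatrix, TruthSet]:
    """Generate an intensity dataset and its truth set under ``config``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    sample_meta = _make_sample_meta(config, rng)
    variant_meta = _make_variant_meta(config, rng)
    n_smp, n_var = config.n_samples, config.n_variants

    trio_index = [
        (i, i + 1, i + 2) for i in range(0, 3 * config.n_trios, 3)
    ]
    base = 3 * config.n_trios
    rep_index = [
        (base + 2 * i, base + 2 * i + 1) for i in range(config.n_replicate_pairs)
    ]

    is_female = (sample_meta["sex"] == "F").to_numpy()
    batch = sample_meta["batch"].to_numpy()
    lowq = (sample_meta["quality_class"] == "lowq").to_numpy()
    dev_mult = np.where(lowq, config.lowq_noise_multiplier, 1.0)

    genotypes = np.empty((n_var, n_smp), dtype=np.int8)
    theta = np.empty((n_var, n_smp))
    r = np.empty((n_var, n_smp))
    realized = np.empty(n_var)

    for vi, meta_row in enumerate(variant_meta.itertuples(index=False)):
        g = _draw_truth_variant(rng, meta_row, sample_meta, trio_index, rep_index)
        genotypes[vi] = g
        override = ARCHETYPES.get(meta_row.archetype, {})

        # per-variant assay jitter; overridden (archetype) geometry is exact
        jitter = rng.uniform(-config.theta_jitter, config.theta_jitter, size=3)
        if "centers" in override:
            centers = np.asarray(override["centers"], dtype=float)
        else:
            centers = np.clip(np.asarray(config.theta_centers) + jitter, 0.0, 1.0)
        devs = np.array(override.get("devs", (config.theta_dev,) * 3))
        r_means = np.array(config.r_means, dtype=float)
        if "ab_r_mean" in override:
            r_means[GT_AB] = override["ab_r_mean"]

        # hemizygous systems occupy the homozygote clusters only
        cls = np.clip(g, 0, 2)
        th = rng.normal(centers[cls], devs[cls] * dev_mult)
        # reflect at the theta boundaries: real channel intensities are
        # non-negative, so boundary clusters compress without piling up
        # a point mass at exactly 0 or 1
        th = np.abs(th)
        th = np.where(th > 1.0, 2.0 - th, th)
        rr = rng.normal(r_means[cls], config.r_dev * dev_mult)

        if meta_row.chrom_class == "Y" and is_female.any():
            nf = int(is_female.sum())
            th[is_female] = rng.uniform(0.0, 1.0, size=nf)
            rr[is_female] = rng.normal(0.15, 0.05, size=nf)
        if override.get("batch_shift"):
            th[batch == 0] += config.batch_shift

        theta[vi] = np.clip(th, 0.0, 1.0)
        r[vi] = np.clip(rr, 0.01, None)
        if "null_fraction" in override:
            failed = rng.uniform(size=n_smp) < override["null_fraction"]
            r[vi, failed] = 0.0  # x = y = 0: no hybridization signal
            theta[vi, failed] = 0.0

        called = g != GT_XX
        nc = int(called.sum())
        if nc:
            dose = np.clip(g[called], 0, 2).astype(float)
            pb = dose.sum() / (2.0 * nc)
            realized[vi] = min(pb, 1.0 - pb)
        else:
            realized[vi] = np.nan

    variant_meta = variant_meta.assign(realized_maf=realized)
    x, y = _theta_r_to_xy(theta, r)
    intensities = IntensityMatrix(
        list(variant_meta["variant_id"]), list(sample_meta["sample_id"]), x, y
    )
    gm = GenotypeMatrix(
        list(variant_meta["variant_id"]), list(sample_meta["sample_id"]), genotypes
    )
    return intensities, TruthSet(gm, variant_meta, sample_meta)


def simulate_comparator(
    truth: TruthSet,
    seq_error_rate: float,
    seq_missing_rate: float,
    rng: np.random.Generator,
) -> GenotypeMatrix:
    """Synthetic sequencing-derived genotype set paired to ``truth``.

    Each called genotype is independently dropped to XX with probability
    ``seq_missing_rate``; each surviving genotype is perturbed to an
    adjacent class with probability ``seq_error_rate`` (heterozygotes move
    to the common-allele homozygote — the dominant real misclassification —
    and homozygotes move to the heterozygote).
    """
    for rate in (seq_error_rate, seq_missing_rate):
        if not 0 <= rate <= 1:
            raise ConfigError("rates must lie in [0, 1]")
    g = truth.genotypes.genotypes.copy()
    called = g != GT_XX
    drop = called & (rng.uniform(size=g.shape) < seq_missing_rate)
    g[drop] = GT_XX
    perturb = (g != GT_XX) & (rng.uniform(size=g.shape) < seq_error_rate)
    if perturb.any():
        # common homozygote per variant from truth called genotypes
        n_aa = (truth.genotypes.genotypes == GT_AA).sum(axis=1)
        n_bb = (truth.genotypes.genotypes == GT_BB).sum(axis=1)
        common_hom = np.where(n_aa >= n_bb, GT_AA, GT_BB).astype(np.int8)
        rows = np.nonzero(perturb.any(axis=1))[0]
        for vi in rows:
            mask = perturb[vi]
            vals = g[vi, mask]
            new = np.where(vals == GT_AB, common_hom[vi], GT_AB).astype(np.int8)
            g[vi, mask] = new
    return GenotypeMatrix(
        list(truth.genotypes.variants), list(truth.genotypes.samples), g
    )
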