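"""Joint genotype calling from two-channel array intensities.

The calling model is an open substitute for the proprietary clustering used
by array-vendor software: per variant, a one-dimensional Gaussian mixture is
fit on the polar coordinate theta across all samples (components capped at
the expected cluster count: 3 for diploid variants, 2 for hemizygous Y/MT),
the component count is selected by BIC, and components are mapped to the
genotype classes AA < AB < BB by theta order.

Each call carries a quality score in [0, 1]::

    s     = 1 - posterior(second-best class) / posterior(best class)
    d     = min over classes of |theta - theta_mean| / theta_dev
    score = s                      if d <= 3
          = s * exp(-(d - 3))      otherwise

so the score decays toward zero for points far from every cluster. A call
is a no-call (XX) exactly when its score falls below the no-call threshold
(default 0.15) or when the variant's cluster record is zeroed.

Cluster parameters for every variant form a :class:`ClusterFile`, a
re-appliable open-text analogue of a binary vendor cluster file: new
intensity data can be called against the stored models without refitting,
and QC can zero out failing variants so they are forced missing.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InsufficientDataError, MissingVariantError, ParseError, UndefinedPointError
from .genotypes import (
    GT_AA,
    GT_AB,
    GT_BB,
    GT_XX,
    GenotypeMatrix,
    IntensityMatrix,
)

log = logging.getLogger(__name__)

#: canonical theta positions of the three diploid genotype clusters; used to
#: attach class labels when a variant exhibits fewer clusters than expected
CANONICAL_THETA = {GT_AA: 0.05, GT_AB: 0.50, GT_BB: 0.95}

CLASS_ORDER = (GT_AA, GT_AB, GT_BB)
CLASS_NAMES = {GT_AA: "aa", GT_AB: "ab", GT_BB: "bb"}

#: floor on a fitted cluster's theta standard deviation (absorbs
#: single-member clusters and numerically degenerate variances)
THETA_DEV_FLOOR = 0.01

DEFAULT_NO_CALL_THRESHOLD = 0.15
DEFAULT_CLUSTER_DEF_CALL_RATE = 0.99
DEFAULT_ZCALL_Z = 7.0

_MIN_POINTS = 10


# ---------------------------------------------------------------------------
# polar transform
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PolarPoint:
    """Polar representation of a two-channel intensity: theta in [0,1], r >= 0."""

    theta: float
    r: float


def to_polar(x: float, y: float) -> PolarPoint:
    """Map non-negative channel intensities (x, y) to (theta, R).

    theta = (2/pi) * arctan2(y, x), r = x + y. Raises
    :class:`UndefinedPointError` when both channels are zero.
    """
    if x == 0.0 and y == 0.0:
        raise UndefinedPointError("polar transform undefined at (0, 0)")
    theta = (2.0 / math.pi) * math.atan2(y, x)
    return PolarPoint(theta=min(max(theta, 0.0), 1.0), r=x + y)


def to_polar_arrays(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`to_polar`; zero-zero cells yield theta = 0, r = 0."""
    theta = (2.0 / math.pi) * np.arctan2(y, x)
    return np.clip(theta, 0.0, 1.0), x + y


# ---------------------------------------------------------------------------
# 1-D Gaussian mixture (deterministic EM)
# ---------------------------------------------------------------------------

def _em_1d(
    data: np.ndarray,
    weights: np.ndarray,
    means0: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Weighted EM for a k-component 1-D Gaussian mixture.

    Fully deterministic given the initial means. Returns (weights, means,
    sds, loglik); component sds are floored at THETA_DEV_FLOOR.
    """
    k = len(means0)
    n = data.size
    w_total = weights.sum()
    pis = np.full(k, 1.0 / k)
    mus = means0.astype(float).copy()
    var0 = max(np.average((data - np.average(data, weights=weights)) ** 2, weights=weights), 1e-6)
    sds = np.full(k, max(math.sqrt(var0) / k, THETA_DEV_FLOOR))
    prev_ll = -np.inf
    log_w = np.log(weights)
    for _ in range(max_iter):
        # E step in log space (well-separated clusters underflow otherwise)
        logp = (
            np.log(np.maximum(pis, 1e-300))[:, None]
            - 0.5 * ((data[None, :] - mus[:, None]) / sds[:, None]) ** 2
            - np.log(sds)[:, None]
            - 0.5 * math.log(2.0 * math.pi)
        )
        m = logp.max(axis=0)
        lse = m + np.log(np.exp(logp - m).sum(axis=0))
        ll = float(np.sum(weights * lse))
        resp = np.exp(logp - lse) * weights[None, :]
        nk = resp.sum(axis=1)
        # M step; empty components keep their params and collapse in weight
        safe = nk > 1e-12
        pis = nk / w_total
        mus[safe] = (resp[safe] @ data) / nk[safe]
        var = np.empty(k)
        var[safe] = (resp[safe] * (data[None, :] - mus[:, None])[safe] ** 2).sum(axis=1) / nk[safe]
        var[~safe] = THETA_DEV_FLOOR**2
        sds = np.maximum(np.sqrt(var), THETA_DEV_FLOOR)
        if ll - prev_ll < tol * max(1.0, w_total):
            prev_ll = ll
            break
        prev_ll = ll
    order = np.argsort(mus)
    return pis[order], mus[order], sds[order], prev_ll


def _fit_candidates(
    data: np.ndarray,
    weights: np.ndarray,
    k: int,
    prev_fit=None,
    island_bounds=None,
):
    """All deterministic k-component fits (one per EM start).

    Starts: data quantiles, the canonical cluster positions, a wide and a
    tight split of the broadest (k-1)-fit component — which resolves narrow
    subclusters sitting inside a broad one — and island centroids, which
    resolve tiny rare-genotype islands a likelihood-guided start would
    spend on shape quirks of the dominant cluster.
    """
    if k == 1:
        mu = float(np.average(data, weights=weights))
        sd = max(math.sqrt(np.average((data - mu) ** 2, weights=weights)), THETA_DEV_FLOOR)
        ll = float(
            np.sum(weights * (-0.5 * ((data - mu) / sd) ** 2 - math.log(sd) - 0.5 * math.log(2 * math.pi)))
        )
        return [(np.array([1.0]), np.array([mu]), np.array([sd]), ll)]
    qs = np.quantile(data, (np.arange(k) + 0.5) / k)
    canonical = {2: np.array([0.05, 0.95]), 3: np.array([0.05, 0.50, 0.95])}[k]
    starts = [qs, canonical]
    if prev_fit is not None:
        _, pmus, psds, _ = prev_fit
        widest = int(np.argmax(psds))
        kept = np.delete(pmus, widest)
        for h in (1.0, 0.5):  # wide and tight splits of the broadest component
            split = np.concatenate(
                [kept, [pmus[widest] - h * psds[widest], pmus[widest] + h * psds[widest]]]
            )
            starts.append(np.sort(split))
    if island_bounds is not None and 2 <= len(island_bounds) <= k:
        starts.append(_island_start(data, island_bounds, k))
    return [_em_1d(data, weights, np.asarray(m, dtype=float)) for m in starts]


_ISLAND_GAP = 0.15


def _find_islands(data: np.ndarray) -> list[tuple[float, float]]:
    """Occupied theta regions separated by empty gaps wider than 0.15.

    Genotype clusters sit >= ~0.4 apart while within-cluster spread is a
    few hundredths, so an empty gap of 0.15 between occupied regions is
    conclusive evidence of distinct clusters — even when one region holds
    a single rare-genotype sample that a likelihood penalty would rather
    absorb into a broad neighbour.
    """
    srt = np.sort(data)
    cuts = np.nonzero(np.diff(srt) > _ISLAND_GAP)[0]
    bounds = []
    start = 0
    for c in cuts:
        bounds.append((float(srt[start]), float(srt[c])))
        start = c + 1
    bounds.append((float(srt[start]), float(srt[-1])))
    return bounds


def _island_start(data: np.ndarray, bounds, k: int) -> np.ndarray:
    """Initial means: one per island centroid; spare components go to
    quantiles of the most populous island."""
    members = [data[(data >= lo) & (data <= hi)] for lo, hi in bounds]
    cents = np.array([m.mean() for m in members])
    extra = k - cents.size
    if extra <= 0:
        return np.sort(cents)
    big = int(np.argmax([m.size for m in members]))
    qs = np.quantile(members[big], (np.arange(extra + 1) + 0.5) / (extra + 1))
    return np.sort(np.concatenate([np.delete(cents, big), qs]))


def _covers_islands(mus: np.ndarray, bounds, tol: float = 0.01) -> bool:
    """Every island interval holds at least one component mean."""
    return all(np.any((mus >= lo - tol) & (mus <= hi + tol)) for lo, hi in bounds)


def _select_components(data: np.ndarray, weights: np.ndarray, max_k: int):
    """Choose the fit: island-aware starts, island floor on k, penalized
    likelihood beyond it.

    The island count is a hard lower bound on k, and a fit whose component
    means leave some island empty loses to the best island-covering fit of
    the same k — the likelihood optimum otherwise spends a forced component
    on shape quirks of the dominant cluster while two separated
    rare-genotype islands share one broad component. Components beyond the
    island evidence must clear a doubled BIC penalty: within one occupied
    region only strong multimodality (a genuine sub-cluster, likelihood
    gain in the hundreds) justifies an extra component — mild skew from
    boundary compression does not.
    """
    n = data.size
    # a data range this small can only hold one cluster: skip multi-k fits
    if data.max() - data.min() < _ISLAND_GAP:
        max_k = 1
    bounds = _find_islands(data)
    k_min = min(len(bounds), max_k)
    best = None
    best_k = 1
    prev = None
    for k in range(1, max_k + 1):
        fits = _fit_candidates(data, weights, k, prev_fit=prev, island_bounds=bounds)
        covering = [f for f in fits if _covers_islands(f[1], bounds)]
        pis, mus, sds, ll = max(covering or fits, key=lambda f: f[3])
        prev = (pis, mus, sds, ll)
        if k < k_min:
            continue
        bic = -2.0 * ll + (3 * k - 1) * math.log(n) + 3 * (k - k_min) * math.log(n)
        if best is None or bic < best[0]:
            best = (bic, pis, mus, sds, ll)
            best_k = k
    _, pis, mus, sds, ll = best
    return best_k, pis, mus, sds


# ---------------------------------------------------------------------------
# cluster models
# ---------------------------------------------------------------------------

@dataclass
class ClassParams:
    """Fitted parameters of one genotype class cluster."""

    theta_mean: float
    theta_dev: float
    r_mean: float
    weight: float


@dataclass
class ClusterModel:
    """Per-variant cluster record: fitted class parameters or a zeroed stub."""

    variant_id: str
    status: str = "active"  # "active" | "zeroed"
    expected_clusters: int = 3
    classes: dict[int, ClassParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status not in ("active", "zeroed"):
            raise ValueError(f"bad status {self.status!r}")
        if self.expected_clusters not in (2, 3):
            raise ValueError("expected_clusters must be 2 or 3")
        if self.status == "zeroed" and self.classes:
            raise ValueError("zeroed models carry no class parameters")

    @property
    def is_zeroed(self) -> bool:
        return self.status == "zeroed"

    def present_classes(self) -> list[int]:
        return [c for c in CLASS_ORDER if c in self.classes]

    def zeroed(self) -> "ClusterModel":
        return ClusterModel(self.variant_id, "zeroed", self.expected_clusters, {})


def _assign_classes(mus: np.ndarray, expected_clusters: int) -> list[int]:
    """Map fitted components (sorted by theta) to genotype classes.

    Full fits take classes in theta order. Degenerate fits pick the subset of
    allowed classes whose canonical centers best match the component means,
    with ties broken toward the more common class (AA).
    """
    k = len(mus)
    allowed = [GT_AA, GT_BB] if expected_clusters == 2 else list(CLASS_ORDER)
    if k == len(allowed):
        return allowed
    if k == 1:
        # single cluster: the homozygote class nearer its theta (AA on ties)
        candidates = [GT_AA, GT_BB]
        dists = [abs(mus[0] - CANONICAL_THETA[c]) for c in candidates]
        return [candidates[int(np.argmin(dists))]]
    # k == 2 under expected 3: ordered class pair with minimal total distance
    pairs = [(GT_AA, GT_AB), (GT_AA, GT_BB), (GT_AB, GT_BB)]
    costs = [
        abs(mus[0] - CANONICAL_THETA[a]) + abs(mus[1] - CANONICAL_THETA[b])
        for a, b in pairs
    ]
    return list(pairs[int(np.argmin(costs))])


def fit_clusters(
    theta: np.ndarray,
    r: np.ndarray,
    variant_id: str = "",
    expected_clusters: int = 3,
    sample_weights: np.ndarray | None = None,
) -> ClusterModel:
    """Fit genotype clusters for one variant from its theta/R points.

    Fits 1..expected_clusters Gaussian components on theta, selects the
    count by BIC, labels components by theta order (degenerate fits use
    nearest canonical centers), and records each class's r_mean from its
    member points (hard assignment by posterior).
    """
    theta = np.asarray(theta, dtype=float)
    r = np.asarray(r, dtype=float)
    if theta.size < _MIN_POINTS:
        raise InsufficientDataError(
            f"variant {variant_id!r}: {theta.size} points < {_MIN_POINTS} required"
        )
    w = (
        np.ones_like(theta)
        if sample_weights is None
        else np.asarray(sample_weights, dtype=float)
    )
    k, pis, mus, sds = _select_components(theta, w, expected_clusters)
    labels = _assign_classes(mus, expected_clusters)
    # hard membership for r_mean
    logp = (
        np.log(np.maximum(pis, 1e-300))[:, None]
        - 0.5 * ((theta[None, :] - mus[:, None]) / sds[:, None]) ** 2
        - np.log(sds)[:, None]
    )
    member = np.argmax(logp, axis=0)
    classes: dict[int, ClassParams] = {}
    for i, cls in enumerate(labels):
        mask = member == i
        r_mean = float(np.mean(r[mask])) if mask.any() else float(np.mean(r))
        classes[cls] = ClassParams(
            theta_mean=float(mus[i]),
            theta_dev=float(sds[i]),
            r_mean=r_mean,
            weight=float(pis[i]),
        )
    return ClusterModel(variant_id, "active", expected_clusters, classes)


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CallResult:
    """A single genotype call with its quality score."""

    genotype: int
    score: float


def _score_points(model: ClusterModel, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best class and score for an array of theta values under one model."""
    classes = model.present_classes()
    mus = np.array([model.classes[c].theta_mean for c in classes])
    sds = np.array([model.classes[c].theta_dev for c in classes])
    pis = np.array([max(model.classes[c].weight, 1e-12) for c in classes])
    logp = (
        np.log(pis)[:, None]
        - 0.5 * ((theta[None, :] - mus[:, None]) / sds[:, None]) ** 2
        - np.log(sds)[:, None]
    )
    best_idx = np.argmax(logp, axis=0)
    best_logp = np.take_along_axis(logp, best_idx[None, :], axis=0)[0]
    if len(classes) == 1:
        ratio_score = np.ones_like(theta)
    else:
        masked = logp.copy()
        np.put_along_axis(masked, best_idx[None, :], -np.inf, axis=0)
        second = masked.max(axis=0)
        ratio_score = 1.0 - np.exp(second - best_logp)
    d = np.min(np.abs(theta[None, :] - mus[:, None]) / sds[:, None], axis=0)
    penalty = np.where(d <= 3.0, 1.0, np.exp(-(d - 3.0)))
    score = ratio_score * penalty
    genotype = np.array(classes, dtype=np.int8)[best_idx]
    return genotype, score


def call_genotype(
    model: ClusterModel,
    point: PolarPoint,
    no_call_threshold: float = DEFAULT_NO_CALL_THRESHOLD,
) -> CallResult:
    """Call a single polar point against a cluster model."""
    if model.is_zeroed:
        return CallResult(GT_XX, 0.0)
    genos, scores = _score_points(model, np.array([point.theta]))
    score = float(scores[0])
    geno = int(genos[0]) if score >= no_call_threshold else GT_XX
    return CallResult(geno, score)


def call_variant(
    model: ClusterModel,
    theta: np.ndarray,
    no_call_threshold: float = DEFAULT_NO_CALL_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized calling of all samples for one variant."""
    theta = np.asarray(theta, dtype=float)
    if model.is_zeroed:
        return np.full(theta.shape, GT_XX, dtype=np.int8), np.zeros_like(theta)
    genos, scores = _score_points(model, theta)
    genos = np.where(scores >= no_call_threshold, genos, GT_XX).astype(np.int8)
    return genos, scores


# ---------------------------------------------------------------------------
# cluster file
# ---------------------------------------------------------------------------

_CLUSTER_FILE_VERSION = "exochip-clusterfile\tv1"
_CLUSTER_COLUMNS = ["variant_id", "status", "expected_clusters"] + [
    f"{name}_{p}"
    for name in ("aa", "ab", "bb")
    for p in ("theta_mean", "theta_dev", "r_mean", "weight")
]


class ClusterFile:
    """Ordered collection of per-variant cluster models, serializable as TSV.

    Serialization uses ``repr``-precision decimals so a write/read round
    trip reproduces calls bit-identically.
    """

    def __init__(self, models: list[ClusterModel] | None = None):
        self._models: dict[str, ClusterModel] = {}
        for m in models or []:
            self.add(m)

    def add(self, model: ClusterModel) -> None:
        if model.variant_id in self._models:
            raise ValueError(f"duplicate variant {model.variant_id!r} in cluster file")
        self._models[model.variant_id] = model

    def __len__(self) -> int:
        return len(self._models)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._models

    def __getitem__(self, variant_id: str) -> ClusterModel:
        try:
            return self._models[variant_id]
        except KeyError:
            raise MissingVariantError(f"variant {variant_id!r} not in cluster file") from None

    def __iter__(self):
        return iter(self._models.values())

    @property
    def variant_ids(self) -> list[str]:
        return list(self._models)

    def copy(self) -> "ClusterFile":
        out = ClusterFile()
        for m in self:
            out._models[m.variant_id] = replace(m, classes=dict(m.classes))
        return out

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#{_CLUSTER_FILE_VERSION}\n")
            fh.write("\t".join(_CLUSTER_COLUMNS) + "\n")
            for m in self:
                row = [m.variant_id, m.status, str(m.expected_clusters)]
                for cls in CLASS_ORDER:
                    if cls in m.classes:
                        p = m.classes[cls]
                        row += [repr(p.theta_mean), repr(p.theta_dev), repr(p.r_mean), repr(p.weight)]
                    else:
                        row += ["", "", "", ""]
                fh.write("\t".join(row) + "\n")

    @classmethod
    def read(cls, path) -> "ClusterFile":
        out = cls()
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
            if header != f"#{_CLUSTER_FILE_VERSION}":
                raise ParseError(f"not a cluster file (header {header!r})", line=1)
            columns = fh.readline().rstrip("\n").split("\t")
            if columns != _CLUSTER_COLUMNS:
                raise ParseError("unexpected cluster-file columns", line=2)
            for lineno, line in enumerate(fh, start=3):
                fields = line.rstrip("\n").split("\t")
                if len(fields) != len(_CLUSTER_COLUMNS):
                    raise ParseError("wrong field count", line=lineno)
                vid, status, expected = fields[0], fields[1], int(fields[2])
                classes: dict[int, ClassParams] = {}
                for i, gt in enumerate(CLASS_ORDER):
                    chunk = fields[3 + 4 * i : 7 + 4 * i]
                    if any(chunk):
                        classes[gt] = ClassParams(*(float(v) for v in chunk))
                out.add(ClusterModel(vid, status, expected, classes))
        return out


# ---------------------------------------------------------------------------
# joint calling
# ---------------------------------------------------------------------------

def expected_clusters_for(chrom_class: str) -> int:
    """Hemizygous variant classes (Y, MT) are modelled with two clusters."""
    return 2 if chrom_class in ("Y", "MT") else 3


def _applicable_mask(chrom_class: str, is_female: np.ndarray) -> np.ndarray:
    """Samples a variant applies to (females carry no Y chromosome)."""
    if chrom_class == "Y":
        return ~is_female
    return np.ones_like(is_female, dtype=bool)


def _call_all(
    intensities: IntensityMatrix,
    chrom_classes: np.ndarray,
    is_female: np.ndarray,
    no_call_threshold: float,
    fit_mask_per_variant: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, ClusterFile]:
    """Fit every variant on (optionally restricted) samples, then call all."""
    n_var, n_smp = intensities.n_variants, intensities.n_samples
    theta, r = intensities.theta, intensities.r
    genos = np.full((n_var, n_smp), GT_XX, dtype=np.int8)
    scores = np.full((n_var, n_smp), np.nan)
    cluster_file = ClusterFile()
    for vi in range(n_var):
        cc = chrom_classes[vi]
        applicable = _applicable_mask(cc, is_female)
        has_signal = r[vi] > 0  # zero-intensity assays carry no information
        fit_mask = applicable & has_signal
        if fit_mask_per_variant is not None:
            restricted = fit_mask & fit_mask_per_variant
            if restricted.sum() >= _MIN_POINTS:
                fit_mask = restricted
        model = fit_clusters(
            theta[vi, fit_mask],
            r[vi, fit_mask],
            variant_id=intensities.variants[vi],
            expected_clusters=expected_clusters_for(cc),
        )
        callable_ = applicable & has_signal
        g, s = call_variant(model, theta[vi, callable_], no_call_threshold)
        genos[vi, callable_] = g
        scores[vi, callable_] = s
        scores[vi, applicable & ~has_signal] = 0.0
        cluster_file.add(model)
    return genos, scores, cluster_file


def joint_call(
    intensities: IntensityMatrix,
    sexes: np.ndarray | list[str],
    chrom_classes: np.ndarray | list[str] | None = None,
    no_call_threshold: float = DEFAULT_NO_CALL_THRESHOLD,
    cluster_def_call_rate: float = DEFAULT_CLUSTER_DEF_CALL_RATE,
) -> tuple[GenotypeMatrix, np.ndarray, ClusterFile]:
    """Two-pass joint calling across all samples.

    Pass 1 fits clusters on every sample and computes provisional per-sample
    call rates; pass 2 refits each variant using only samples whose
    provisional call rate exceeds ``cluster_def_call_rate`` (mirroring the
    practice of defining clusters from samples with call rates > 99%), then
    calls all samples from the refit models. Females never contribute to,
    nor receive calls for, Y variants.
    """
    if intensities.n_samples < _MIN_POINTS:
        raise InsufficientDataError("joint calling needs at least 10 samples")
    sexes = np.asarray(sexes)
    is_female = sexes == "F"
    if chrom_classes is None:
        chrom_classes = np.full(intensities.n_variants, "autosome")
    chrom_classes = np.asarray(chrom_classes)

    genos1, scores1, _ = _call_all(
        intensities, chrom_classes, is_female, no_call_threshold
    )
    applicable = np.ones_like(genos1, dtype=bool)
    y_rows = chrom_classes == "Y"
    if y_rows.any():
        applicable[np.ix_(y_rows, is_female)] = False
    with np.errstate(invalid="ignore"):
        call_rate = (genos1 != GT_XX).sum(axis=0) / np.maximum(applicable.sum(axis=0), 1)
    good = call_rate > cluster_def_call_rate
    if not good.any():
        log.warning(
            "no sample exceeds cluster-definition call rate %.3f; using all samples",
            cluster_def_call_rate,
        )
        good = np.ones_like(good)
    genos2, scores2, cluster_file = _call_all(
        intensities, chrom_classes, is_female, no_call_threshold, fit_mask_per_variant=good
    )
    gm = GenotypeMatrix(
        list(intensities.variants), list(intensities.samples), genos2, scores2
    )
    return gm, scores2, cluster_file


def apply_cluster_file(
    cluster_file: ClusterFile,
    intensities: IntensityMatrix,
    sexes: np.ndarray | list[str] | None = None,
    chrom_classes: np.ndarray | list[str] | None = None,
    no_call_threshold: float = DEFAULT_NO_CALL_THRESHOLD,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Call intensities against fixed cluster models without refitting."""
    missing = [v for v in intensities.variants if v not in cluster_file]
    if missing:
        raise MissingVariantError(
            f"{len(missing)} variant(s) absent from cluster file: "
            + ", ".join(missing[:10])
            + ("..." if len(missing) > 10 else "")
        )
    n_var, n_smp = intensities.n_variants, intensities.n_samples
    sexes = np.asarray(sexes) if sexes is not None else np.full(n_smp, "U")
    is_female = sexes == "F"
    if chrom_classes is None:
        chrom_classes = np.full(n_var, "autosome")
    chrom_classes = np.asarray(chrom_classes)
    theta = intensities.theta
    genos = np.full((n_var, n_smp), GT_XX, dtype=np.int8)
    scores = np.full((n_var, n_smp), np.nan)
    r = intensities.r
    for vi in range(n_var):
        model = cluster_file[intensities.variants[vi]]
        applicable = _applicable_mask(chrom_classes[vi], is_female)
        callable_ = applicable & (r[vi] > 0)
        g, s = call_variant(model, theta[vi, callable_], no_call_threshold)
        genos[vi, callable_] = g
        scores[vi, callable_] = s
        scores[vi, applicable & (r[vi] <= 0)] = 0.0
    gm = GenotypeMatrix(list(intensities.variants), list(intensities.samples), genos, scores)
    return gm, scores


# ---------------------------------------------------------------------------
# zCall-style rescue of no-calls
# ---------------------------------------------------------------------------

def _hom_channel_stats(
    genos: np.ndarray, chan: np.ndarray, hom: int, min_calls: int = 3
) -> tuple[float, float] | None:
    """Mean/sd of the noise channel within one called homozygote cluster."""
    mask = genos == hom
    if mask.sum() < min_calls:
        return None
    vals = chan[mask]
    return float(np.mean(vals)), float(np.std(vals))


def rescue_nocalls(
    calls: GenotypeMatrix,
    intensities: IntensityMatrix,
    cluster_file: ClusterFile,
    z: float = DEFAULT_ZCALL_Z,
) -> GenotypeMatrix:
    """Simplified zCall-style rescue of no-calls.

    Per variant, channel thresholds are placed z standard deviations above
    the homozygote clusters' noise-channel signal estimated from called
    homozygotes: t_y from the AA cluster's Y channel, t_x from the BB
    cluster's X channel. When one homozygote class has no calls its
    threshold statistics are imputed by a cross-variant linear regression on
    the observed class's noise-channel statistics. Each XX call is then
    reassigned by quadrant: (x > t_x, y <= t_y) -> AA, (x > t_x, y > t_y)
    -> AB, (x <= t_x, y > t_y) -> BB; points below both thresholds stay
    missing, and called genotypes are never changed.
    """
    if z <= 0:
        raise ValueError("z must be positive")
    genos = calls.genotypes
    x, y = intensities.x, intensities.y
    n_var = calls.n_variants

    # per-variant homozygote noise-channel stats
    aa_stats: list[tuple[float, float] | None] = []
    bb_stats: list[tuple[float, float] | None] = []
    for vi in range(n_var):
        aa_stats.append(_hom_channel_stats(genos[vi], y[vi], GT_AA))
        bb_stats.append(_hom_channel_stats(genos[vi], x[vi], GT_BB))

    # cross-variant regression: predict the missing homozygote's noise stats
    # from the observed homozygote's (variants with both classes train it)
    both = [i for i in range(n_var) if aa_stats[i] and bb_stats[i]]
    coef_bb_from_aa = coef_aa_from_bb = None
    if len(both) >= 10:
        A = np.array([[1.0, *aa_stats[i]] for i in both])
        B = np.array([[1.0, *bb_stats[i]] for i in both])
        tgt_bb = np.array([bb_stats[i] for i in both])
        tgt_aa = np.array([aa_stats[i] for i in both])
        coef_bb_from_aa = np.linalg.lstsq(A, tgt_bb, rcond=None)[0]
        coef_aa_from_bb = np.linalg.lstsq(B, tgt_aa, rcond=None)[0]

    out = calls.copy()
    n_rescued = n_skipped = 0
    for vi in range(n_var):
        if calls.variants[vi] in cluster_file and cluster_file[calls.variants[vi]].is_zeroed:
            continue
        aa, bb = aa_stats[vi], bb_stats[vi]
        if aa is None and bb is None:
            n_skipped += 1
            continue
        if aa is None:
            if coef_aa_from_bb is None:
                aa = bb  # mirror the observed class when no regression is trainable
            else:
                aa = tuple(np.array([1.0, *bb]) @ coef_aa_from_bb)
        if bb is None:
            if coef_bb_from_aa is None:
                bb = aa
            else:
                bb = tuple(np.array([1.0, *aa]) @ coef_bb_from_aa)
        t_y = aa[0] + z * max(aa[1], 1e-6)
        t_x = bb[0] + z * max(bb[1], 1e-6)
        row = genos[vi]
        nocall = row == GT_XX
        if calls.scores is not None:
            nocall &= ~np.isnan(calls.scores[vi])  # NaN marks inapplicable cells
        if not nocall.any():
            continue
        xv, yv = x[vi, nocall], y[vi, nocall]
        assigned = np.full(xv.shape, GT_XX, dtype=np.int8)
        assigned[(xv > t_x) & (yv <= t_y)] = GT_AA
        assigned[(xv > t_x) & (yv > t_y)] = GT_AB
        assigned[(xv <= t_x) & (yv > t_y)] = GT_BB
        out.genotypes[vi, nocall] = assigned
        n_rescued += int((assigned != GT_XX).sum())
    if n_skipped:
        log.info("rescue skipped %d variants with no called homozygotes", n_skipped)
    log.info("rescue reassigned %d no-calls", n_rescued)
    return out
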