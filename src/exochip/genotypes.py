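"""Core in-memory containers: genotype and intensity matrices.

Genotypes are stored as small integers over a variants x samples layout
(the natural orientation of both the TSV dialect and PLINK transposed text):

====  =====  =============================
code  label  meaning
====  =====  =============================
0     AA     common-allele homozygote
1     AB     heterozygote
2     BB     rare-allele homozygote
-1    XX     missing / no-call
====  =====  =============================
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GT_AA = 0
GT_AB = 1
GT_BB = 2
GT_XX = -1

GT_LABELS = {GT_AA: "AA", GT_AB: "AB", GT_BB: "BB", GT_XX: "XX"}
GT_CODES = {v: k for k, v in GT_LABELS.items()}
#: label used for a missing call in the on-disk TSV dialect
NC_LABEL = "NC"

CHROM_CLASSES = ("autosome", "X", "Y", "XY", "MT")
#: variant classes carried on one allele copy in males (or everyone, for MT)
HAPLOID_CLASSES = ("Y", "MT")


def codes_to_labels(codes: np.ndarray) -> np.ndarray:
    """Map integer genotype codes to the AA/AB/BB/XX string labels."""
    out = np.empty(codes.shape, dtype="<U2")
    for code, label in GT_LABELS.items():
        out[codes == code] = label
    return out


def labels_to_codes(labels: np.ndarray) -> np.ndarray:
    codes = np.full(labels.shape, GT_XX, dtype=np.int8)
    arr = np.asarray(labels)
    for label, code in GT_CODES.items():
        codes[arr == label] = code
    codes[arr == NC_LABEL] = GT_XX
    return codes


@dataclass
class GenotypeMatrix:
    """AA/AB/BB/XX calls for ``variants x samples``, with optional scores.

    ``scores`` (same shape) holds the per-call quality score; NaN marks a
    cell that is not applicable to the sample (e.g. a Y variant in a female).
    """

    variants: list[str]
    samples: list[str]
    genotypes: np.ndarray
    scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.variants), len(self.samples)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=float)
            if self.scores.shape != self.genotypes.shape:
                raise ValueError("score matrix shape mismatch")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.variants),
            list(self.samples),
            self.genotypes.copy(),
            None if self.scores is None else self.scores.copy(),
        )

    def variant_index(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.variants)}

    def sample_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.samples)}

    def missing_rate(self) -> float:
        return float(np.mean(self.genotypes == GT_XX))


@dataclass
class IntensityMatrix:
    """Two-channel normalized intensities for ``variants x samples``.

    ``x``/``y`` are the A- and B-allele channels. The polar transform
    (theta, R) used throughout cluster fitting and the SNP statistics is
    derived lazily and cached.
    """

    variants: list[str]
    samples: list[str]
    x: np.ndarray
    y: np.ndarray
    _theta: np.ndarray | None = field(default=None, repr=False)
    _r: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        shape = (len(self.variants), len(self.samples))
        if self.x.shape != shape or self.y.shape != shape:
            raise ValueError("intensity matrix shape mismatch")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def theta(self) -> np.ndarray:
        if self._theta is None:
            self._compute_polar()
        return self._theta

    @property
    def r(self) -> np.ndarray:
        if self._r is None:
            self._compute_polar()
        return self._r

    def _compute_polar(self) -> None:
        from .caller import to_polar_arrays

        self._theta, self._r = to_polar_arrays(self.x, self.y)

    def variant_index(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.variants)}
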