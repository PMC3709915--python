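"""Concordance evaluation of called genotypes against a truth set.

Array calls and a sequencing-derived comparator are summarized in a 4x4
contingency table over the classes AA / AB / BB / XX (rows: truth, columns:
test). Three summary percentages decompose every genotype pair:

* *missing*: pairs with XX on either side (the XX/XX cell counted once),
* *concordant*: equal non-missing pairs (the AA/AB/BB diagonal),
* *discordant*: the remainder (unequal non-missing pairs).

Because near-perfect concordance is almost guaranteed when most sites are
rare (the common homozygote dominates), association is additionally
measured by entropy-based uncertainty coefficients: the fraction of one
margin's Shannon entropy explained by the other (Theil's U), computed from
the mutual information of the table. Natural logarithms are used
internally; the coefficient is base-invariant.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd

from .errors import DegenerateTableError
from .genotypes import GT_AA, GT_AB, GT_BB, GT_XX, GenotypeMatrix

log = logging.getLogger(__name__)

_CLASS_LABELS = ("AA", "AB", "BB", "XX")
_CODE_TO_INDEX = {GT_AA: 0, GT_AB: 1, GT_BB: 2, GT_XX: 3}


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, matching printed report precision."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ContingencyTable4:
    """4x4 truth (rows) vs test (columns) genotype-class counts."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4, 4):
            raise ValueError("contingency table must be 4x4")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ContingencyTable4") -> "ContingencyTable4":
        return ContingencyTable4(self.counts + other.counts)

    def transpose(self) -> "ContingencyTable4":
        return ContingencyTable4(self.counts.T)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=_CLASS_LABELS, columns=_CLASS_LABELS)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read(cls, path) -> "ContingencyTable4":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(_CLASS_LABELS) or list(df.columns) != list(_CLASS_LABELS):
            raise ValueError(f"expected AA/AB/BB/XX rows and columns in {path}")
        return cls(df.to_numpy())


def load_table2_fixture(dataset: str) -> ContingencyTable4:
    """Shipped reference matrices for the three calling strategies.

    ``dataset`` is one of "I" (vendor cluster file), "Z" (zCall rescue
    applied to I) or "C" (joint calling with best practices).
    """
    if dataset not in ("I", "Z", "C"):
        raise ValueError("dataset must be 'I', 'Z' or 'C'")
    ref = resources.files("exochip.data") / f"table2_dataset_{dataset}.tsv"
    with resources.as_file(ref) as path:
        return ContingencyTable4.read(path)


@dataclass(frozen=True)
class ConcordanceSummary:
    concordant_pct: float
    missing_pct: float
    discordant_pct: float

    def rounded(self, ndigits: int = 2) -> "ConcordanceSummary":
        return ConcordanceSummary(
            round_half_up(self.concordant_pct, ndigits),
            round_half_up(self.missing_pct, ndigits),
            round_half_up(self.discordant_pct, ndigits),
        )


def build_contingency(
    test: GenotypeMatrix,
    truth: GenotypeMatrix,
    allele_map: pd.DataFrame | None = None,
) -> ContingencyTable4:
    """Count every (sample, variant) genotype pair into the 4x4 table.

    ``allele_map`` (columns variant_id, truth_ref, truth_alt, chip_a,
    chip_b) orients the test calls to the truth set's allele labels: a
    flipped variant has its AA and BB calls swapped, and a variant whose
    alleles cannot be reconciled is dropped with a logged reason.
    """
    if test.samples != truth.samples:
        raise ValueError("test and truth sample sets differ")
    if test.variants != truth.variants:
        raise ValueError("test and truth variant sets differ")
    g_test = test.genotypes.copy()
    keep = np.ones(test.n_variants, dtype=bool)
    if allele_map is not None:
        vidx = test.variant_index()
        oriented = set()
        for row in allele_map.itertuples(index=False):
            vi = vidx.get(row.variant_id)
            if vi is None:
                continue
            oriented.add(row.variant_id)
            if (row.truth_ref, row.truth_alt) == (row.chip_a, row.chip_b):
                continue
            if (row.truth_ref, row.truth_alt) == (row.chip_b, row.chip_a):
                flip = {GT_AA: GT_BB, GT_BB: GT_AA}
                g = g_test[vi]
                g_test[vi] = np.select(
                    [g == GT_AA, g == GT_BB], [GT_BB, GT_AA], default=g
                ).astype(np.int8)
            else:
                keep[vi] = False
                log.warning(
                    "variant %s dropped: alleles %s/%s vs %s/%s cannot be oriented",
                    row.variant_id, row.truth_ref, row.truth_alt, row.chip_a, row.chip_b,
                )
        missing = [v for v in test.variants if v not in oriented]
        if missing:
            raise ValueError(f"{len(missing)} variants absent from allele map")
    tru = np.vectorize(_CODE_TO_INDEX.get)(truth.genotypes[keep])
    tst = np.vectorize(_CODE_TO_INDEX.get)(g_test[keep])
    counts = np.bincount((4 * tru + tst).ravel(), minlength=16).reshape(4, 4)
    return ContingencyTable4(counts)


def concordance_summary(table: ContingencyTable4) -> ConcordanceSummary:
    """Decompose the table into concordant / missing / discordant percent."""
    n = table.n_total
    if n <= 0:
        raise ValueError("empty contingency table")
    c = table.counts
    missing = c[3, :].sum() + c[:, 3].sum() - c[3, 3]
    concordant = c[0, 0] + c[1, 1] + c[2, 2]
    concordant_pct = 100.0 * concordant / n
    missing_pct = 100.0 * missing / n
    return ConcordanceSummary(
        concordant_pct=concordant_pct,
        missing_pct=missing_pct,
        discordant_pct=100.0 - concordant_pct - missing_pct,
    )


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def uncertainty_coefficient(
    table: ContingencyTable4,
    direction: str = "test_given_truth",
    include_missing: bool = True,
) -> float:
    """Entropy-based uncertainty coefficient (Theil's U) of the table.

    With I the mutual information and H(.) marginal Shannon entropies,
    U(X|Y) = I/H(X) is the fraction of X's entropy explained by Y:
    ``test_given_truth`` returns I/H(cols), ``truth_given_test`` returns
    I/H(rows), and ``symmetric`` returns 2I/(H(rows)+H(cols)).
    ``include_missing=False`` drops the XX row and column first.
    """
    if direction not in ("truth_given_test", "test_given_truth", "symmetric"):
        raise ValueError(f"unknown direction {direction!r}")
    c = table.counts.astype(float)
    if not include_missing:
        c = c[:3, :3]
    n = c.sum()
    if n <= 0:
        raise ValueError("empty contingency table")
    p = c / n
    prow = p.sum(axis=1)
    pcol = p.sum(axis=0)
    if (prow > 0).sum() < 2 or (pcol > 0).sum() < 2:
        raise DegenerateTableError("a margin has fewer than two categories")
    h_row = _entropy(prow)
    h_col = _entropy(pcol)
    nz = p > 0
    mi = float(np.sum(p[nz] * np.log(p[nz] / np.outer(prow, pcol)[nz])))
    if direction == "test_given_truth":
        return mi / h_col
    if direction == "truth_given_test":
        return mi / h_row
    return 2.0 * mi / (h_row + h_col)


def uncertainty_report(table: ContingencyTable4) -> pd.DataFrame:
    """The coefficient under every direction/missing-class convention."""
    rows = []
    for include_missing in (True, False):
        for direction in ("test_given_truth", "truth_given_test", "symmetric"):
            rows.append(
                {
                    "direction": direction,
                    "include_missing": include_missing,
                    "coefficient": uncertainty_coefficient(table, direction, include_missing),
                }
            )
    return pd.DataFrame(rows)


def truth_minor_allele_counts(truth: GenotypeMatrix) -> np.ndarray:
    """Per-variant minor allele count from the truth set's called genotypes."""
    g = truth.genotypes
    n_ab = (g == GT_AB).sum(axis=1)
    n_bb = (g == GT_BB).sum(axis=1)
    n_aa = (g == GT_AA).sum(axis=1)
    b = 2 * n_bb + n_ab
    a = 2 * n_aa + n_ab
    return np.minimum(a, b)


def mac_bin_concordance(
    test: GenotypeMatrix,
    truth: GenotypeMatrix,
    bins: tuple[int, ...] = (1, 2, 3),
) -> dict[int, float]:
    """Concordance (%) over non-missing pairs, per truth minor-allele-count bin.

    Bins with no variants are absent from the result, not zero.
    """
    mac = truth_minor_allele_counts(truth)
    out: dict[int, float] = {}
    for b in bins:
        rows = mac == b
        if not rows.any():
            continue
        t = truth.genotypes[rows]
        s = test.genotypes[rows]
        both = (t != GT_XX) & (s != GT_XX)
        n = int(both.sum())
        if n == 0:
            continue
        out[b] = 100.0 * float((t[both] == s[both]).sum()) / n
    return out


def concordance_report(table: ContingencyTable4) -> str:
    """Human-readable summary block for one comparison."""
    s = concordance_summary(table).rounded()
    lines = [str(table.to_frame()), ""]
    lines.append(f"concordant: {s.concordant_pct:.2f}%")
    lines.append(f"missing:    {s.missing_pct:.2f}%")
    lines.append(f"discordant: {s.discordant_pct:.2f}%")
    lines.append("")
    rep = uncertainty_report(table)
    for row in rep.itertuples(index=False):
        lines.append(
            f"U[{row.direction}, missing {'in' if row.include_missing else 'out'}]"
            f" = {row.coefficient:.4f}"
        )
    return "\n".join(lines)
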