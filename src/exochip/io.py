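"""File formats: genotype TSV dialect, PLINK transposed text, intensity TSV,
sample/variant sheets and YAML pipeline configuration.

The primary genotype dialect is a compact variants x samples TSV with cell
values AA/AB/BB/NC (NC on disk marks a no-call, XX in memory), because
A/B space is the caller's native representation. PLINK transposed text
(.tped/.tfam) export is provided for interoperability; positions are not
modelled, so exported coordinates are running indices.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, ParseError
from .genotypes import (
    GT_XX,
    NC_LABEL,
    GenotypeMatrix,
    IntensityMatrix,
    codes_to_labels,
    labels_to_codes,
)

_PLINK_CHROM = {"autosome": "1", "X": "23", "Y": "24", "XY": "25", "MT": "26"}


# ---------------------------------------------------------------------------
# genotype matrices
# ---------------------------------------------------------------------------

def write_genotype_tsv(gm: GenotypeMatrix, path) -> None:
    labels = codes_to_labels(gm.genotypes)
    labels[gm.genotypes == GT_XX] = NC_LABEL
    with open(path, "w") as fh:
        fh.write("variant_id\t" + "\t".join(gm.samples) + "\n")
        for vi, vid in enumerate(gm.variants):
            fh.write(vid + "\t" + "\t".join(labels[vi]) + "\n")


def read_genotype_tsv(path) -> GenotypeMatrix:
    valid = {"AA", "AB", "BB", NC_LABEL, "XX"}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "variant_id":
            raise ParseError("expected 'variant_id' header column", line=1)
        samples = header[1:]
        if len(set(samples)) != len(samples):
            raise ParseError("duplicate sample ids in header", line=1)
        variants: list[str] = []
        seen: set[str] = set()
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(samples) + 1:
                raise ParseError(
                    f"expected {len(samples) + 1} fields, found {len(fields)}", line=lineno
                )
            vid = fields[0]
            if vid in seen:
                raise ParseError(f"duplicate variant id {vid!r}", line=lineno)
            bad = set(fields[1:]) - valid
            if bad:
                raise ParseError(f"invalid genotype label(s) {sorted(bad)}", line=lineno)
            seen.add(vid)
            variants.append(vid)
            rows.append(labels_to_codes(np.array(fields[1:])))
    genos = np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    return GenotypeMatrix(variants, samples, genos)


def write_score_tsv(gm: GenotypeMatrix, path) -> None:
    if gm.scores is None:
        raise ValueError("matrix carries no scores")
    df = pd.DataFrame(gm.scores, index=pd.Index(gm.variants, name="variant_id"), columns=gm.samples)
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_score_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_plink_tped(
    gm: GenotypeMatrix,
    prefix,
    allele_map: pd.DataFrame | None = None,
    sample_meta: pd.DataFrame | None = None,
    chrom_classes: np.ndarray | None = None,
) -> None:
    """PLINK transposed text export: <prefix>.tped and <prefix>.tfam.

    ``allele_map`` (variant_id, chip_a, chip_b) supplies nucleotide labels;
    without it the alleles are written literally as A and B. Missing calls
    become "0 0".
    """
    prefix = Path(prefix)
    alleles = {}
    if allele_map is not None:
        for row in allele_map.itertuples(index=False):
            alleles[row.variant_id] = (str(row.chip_a), str(row.chip_b))
    if chrom_classes is None:
        chrom_classes = np.full(gm.n_variants, "autosome")
    pair_for = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    with open(prefix.with_suffix(".tped"), "w") as fh:
        for vi, vid in enumerate(gm.variants):
            a, b = alleles.get(vid, ("A", "B"))
            cells = []
            for code in gm.genotypes[vi]:
                if code == GT_XX:
                    cells.append("0 0")
                else:
                    i, j = pair_for[int(code)]
                    cells.append(f"{(a, b)[i]} {(a, b)[j]}")
            chrom = _PLINK_CHROM[str(chrom_classes[vi])]
            fh.write(f"{chrom} {vid} 0 {vi + 1} " + " ".join(cells) + "\n")
    sex_code = {}
    if sample_meta is not None:
        sex_code = dict(
            zip(sample_meta["sample_id"], sample_meta["sex"].map({"M": "1", "F": "2"}).fillna("0"))
        )
    with open(prefix.with_suffix(".tfam"), "w") as fh:
        for sid in gm.samples:
            fh.write(f"{sid} {sid} 0 0 {sex_code.get(sid, '0')} -9\n")


def read_plink_tped(prefix) -> GenotypeMatrix:
    """Read a transposed-text fileset written by :func:`write_plink_tped`.

    The first allele seen per variant is taken as A unless the literal
    labels A/B are used; genotype classes and ids round-trip losslessly.
    """
    prefix = Path(prefix)
    samples = []
    with open(prefix.with_suffix(".tfam")) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if len(fields) < 2:
                raise ParseError("malformed .tfam row", line=lineno)
            samples.append(fields[1])
    variants: list[str] = []
    rows: list[np.ndarray] = []
    with open(prefix.with_suffix(".tped")) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if len(fields) != 4 + 2 * len(samples):
                raise ParseError(
                    f"expected {4 + 2 * len(samples)} fields, found {len(fields)}",
                    line=lineno,
                )
            vid = fields[1]
            if vid in variants:
                raise ParseError(f"duplicate variant id {vid!r}", line=lineno)
            pairs = list(zip(fields[4::2], fields[5::2]))
            labels = sorted({a for p in pairs for a in p if a != "0"})
            if "A" in labels and "B" in labels:
                a_lab, b_lab = "A", "B"
            else:
                a_lab = labels[0] if labels else "A"
                b_lab = labels[1] if len(labels) > 1 else "B"
            codes = np.full(len(pairs), GT_XX, dtype=np.int8)
            for si, (p, q) in enumerate(pairs):
                if p == "0" or q == "0":
                    continue
                codes[si] = (p == b_lab) + (q == b_lab)
            variants.append(vid)
            rows.append(codes)
    genos = np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    return GenotypeMatrix(variants, samples, genos)


# ---------------------------------------------------------------------------
# intensities and sheets
# ---------------------------------------------------------------------------

def write_intensity_tsv(im: IntensityMatrix, path) -> None:
    """Long-format intensity table: sample_id, variant_id, x, y."""
    n_var, n_smp = im.n_variants, im.n_samples
    df = pd.DataFrame(
        {
            "sample_id": np.repeat(im.samples, n_var),
            "variant_id": np.tile(im.variants, n_smp),
            "x": im.x.T.ravel(),
            "y": im.y.T.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_intensity_tsv(path) -> IntensityMatrix:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "variant_id", "x", "y"}
    if not required.issubset(df.columns):
        raise ParseError(f"intensity TSV needs columns {sorted(required)}")
    samples = list(pd.unique(df["sample_id"]))
    variants = list(pd.unique(df["variant_id"]))
    xs = df.pivot(index="variant_id", columns="sample_id", values="x")
    ys = df.pivot(index="variant_id", columns="sample_id", values="y")
    xs = xs.reindex(index=variants, columns=samples)
    ys = ys.reindex(index=variants, columns=samples)
    if xs.isna().any().any():
        raise ParseError("intensity TSV is not a complete sample x variant grid")
    return IntensityMatrix(variants, samples, xs.to_numpy(), ys.to_numpy())


def write_sample_sheet(sample_meta: pd.DataFrame, path) -> None:
    sample_meta.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ParseError("sample sheet needs a sample_id column")
    return df


def write_variant_sheet(variant_meta: pd.DataFrame, path) -> None:
    variant_meta.to_csv(path, sep="\t", index=False)


def read_variant_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str}, keep_default_na=False)
    if "variant_id" not in df.columns:
        raise ParseError("variant sheet needs a variant_id column")
    return df


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Resolved configuration for an end-to-end run."""

    out_dir: str = "exochip_out"
    seed: int = 0
    log_level: str = "INFO"
    sim: dict = field(default_factory=dict)
    caller: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    concord: dict = field(default_factory=dict)
    rescue: bool = True

    def validate(self) -> None:
        ncall = self.caller.get("no_call_threshold", 0.15)
        if not 0 <= ncall <= 1:
            raise ConfigError("no_call_threshold must lie in [0, 1]")
        z = self.caller.get("rescue_z", 7.0)
        if z <= 0:
            raise ConfigError("rescue z must be positive")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in PipelineConfig.__dataclass_fields__.values()}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg
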