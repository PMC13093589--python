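"""Data model, readers/writers, validation, and shared configuration.

The pipeline analyses offspring of 2x2 reciprocal crosses between
hatchery-origin (H) and natural-origin (N) steelhead parents.  Cross codes
are always written mother-first: ``HN`` means a hatchery mother crossed to
a natural-origin father.  Each crossing matrix contributes four full-sib
families (HH, HN, NH, NN), and two offspring (one female, one male) are
sequenced per family.

All tabular formats are plain TSV; genotypes are VCF v4.x.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "ValidationError",
    "CROSS_TYPES",
    "CountMatrix",
    "GenotypeMatrix",
    "PipelineConfig",
    "MISSING",
    "get_logger",
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
    "validate_metadata",
    "read_genotypes_vcf",
    "write_genotypes_vcf",
    "read_terms",
    "write_terms",
    "load_config",
    "save_config",
]

CROSS_TYPES = ("HH", "HN", "NH", "NN")
SEXES = ("F", "M")

#: integer code for a missing genotype call
MISSING = -1

META_COLUMNS = ["sample_id", "matrix_id", "cross", "family_code", "sex", "cross_date"]
TERM_COLUMNS = ["go_id", "name", "count", "pc1", "pc2"]


class FormatError(ValueError):
    """A file does not conform to its expected on-disk format."""


class ValidationError(ValueError):
    """Parsed data violates a domain-type invariant."""


# ---------------------------------------------------------------------------
# logging / configuration
# ---------------------------------------------------------------------------

_LOG_CONFIGURED = False


def get_logger(name: str = "recipcross") -> logging.Logger:
    """Return the package logger, writing structured lines to stderr."""
    global _LOG_CONFIGURED
    logger = logging.getLogger(name)
    if not _LOG_CONFIGURED:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        root = logging.getLogger("recipcross")
        root.addHandler(handler)
        root.setLevel(logging.INFO)
        _LOG_CONFIGURED = True
    return logger


@dataclass
class PipelineConfig:
    """Analysis thresholds, with the study's defaults.

    fdr
        BH-adjusted p-value cutoff declaring a gene differentially expressed.
    maf_min
        minimum minor allele frequency for a locus to be retained.
    locus_missing_max / indiv_missing_max
        maximum tolerated missing-call fraction per locus / individual.
    replicates
        number of randomization replicates for the reshuffling procedures.
    """

    fdr: float = 0.05
    maf_min: float = 0.01
    locus_missing_max: float = 0.20
    indiv_missing_max: float = 0.20
    replicates: int = 1000


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Gene-by-sample matrix of non-negative integer read counts."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_genes, n_samples), integer

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            g, s = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count for gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        for label, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dup = pd.Index(ids)[pd.Index(ids).duplicated()][0]
                raise ValidationError(f"duplicate {label} id {dup!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(list(self.gene_ids), list(sample_ids), self.counts[:, idx])

    def subset_genes(self, gene_ids: list[str]) -> "CountMatrix":
        idx = [self.gene_ids.index(g) for g in gene_ids]
        return CountMatrix(list(gene_ids), list(self.sample_ids), self.counts[idx, :])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


def read_counts(path: str | Path) -> CountMatrix:
    """Read a TSV count table (first column gene ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    genes = [str(g) for g in df.index]
    samples = [str(s) for s in df.columns]
    try:
        counts = df.to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric count cell ({exc})") from exc
    bad = ~np.isfinite(counts) | (np.mod(counts, 1) != 0)
    if bad.any():
        g, s = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: non-integer count for gene {genes[g]!r}, sample {samples[s]!r}"
        )
    if (counts < 0).any():
        g, s = np.argwhere(counts < 0)[0]
        raise FormatError(
            f"{path}: negative count for gene {genes[g]!r}, sample {samples[s]!r}"
        )
    return CountMatrix(genes, samples, counts.astype(np.int64))


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.to_frame().to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------


def validate_metadata(meta: pd.DataFrame, complete_design: bool = False) -> pd.DataFrame:
    """Validate a sample-metadata table; returns the validated frame.

    With ``complete_design=True``, additionally require every
    (matrix, cross) family to contribute exactly two offspring, one of
    each sex, and cross_date to be constant within a matrix.
    """
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata missing required columns: {missing}")
    meta = meta.copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    meta["cross"] = meta["cross"].astype(str)
    meta["sex"] = meta["sex"].astype(str)
    meta["cross_date"] = meta["cross_date"].astype(str)
    meta["matrix_id"] = meta["matrix_id"].astype(int)
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample id {dup!r}")
    bad_cross = set(meta["cross"]) - set(CROSS_TYPES)
    if bad_cross:
        raise ValidationError(
            f"unknown cross code(s) {sorted(bad_cross)}; expected one of "
            f"{CROSS_TYPES} (mother listed first)"
        )
    bad_sex = set(meta["sex"]) - set(SEXES)
    if bad_sex:
        raise ValidationError(f"unknown sex code(s) {sorted(bad_sex)}")
    if complete_design:
        per_fam = meta.groupby(["matrix_id", "cross"], sort=False)
        for (mid, cross), grp in per_fam:
            if len(grp) != 2 or sorted(grp["sex"]) != ["F", "M"]:
                raise ValidationError(
                    f"family (matrix {mid}, {cross}) must have exactly one "
                    f"female and one male offspring; got {list(grp['sex'])}"
                )
        n_dates = meta.groupby("matrix_id")["cross_date"].nunique()
        if (n_dates > 1).any():
            mid = n_dates[n_dates > 1].index[0]
            raise ValidationError(f"cross_date varies within matrix {mid}")
    return meta


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata TSV (cross codes mother-first)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "matrix_id" not in df.columns and "family_code" in df.columns:
        df["matrix_id"] = df["family_code"].str.extract(r"^(\d+)")[0]
    return validate_metadata(df)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta[META_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Samples x biallelic loci, coded as alternate-allele copies 0/1/2.

    Missing calls are stored as :data:`MISSING` (-1).  Locus ids are
    ``chrom:pos`` strings.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    genotypes: np.ndarray  # shape (n_samples, n_loci), int8

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise ValidationError(
                f"genotype shape {self.genotypes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        allowed = {0, 1, 2, MISSING}
        present = set(np.unique(self.genotypes).tolist())
        if not present <= allowed:
            raise ValidationError(
                f"genotype codes {sorted(present - allowed)} outside {{0,1,2,missing}}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.genotypes.shape

    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING


def read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    """Read GT fields from a VCF into 0/1/2/missing coding.

    Multiallelic records are skipped with a logged count; ``./.`` becomes
    missing.
    """
    from cyvcf2 import VCF

    log = get_logger("recipcross.core_io")
    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise FormatError(f"{path}: cannot open as VCF ({exc})") from exc
    samples = list(vcf.samples)
    loci: list[str] = []
    rows: list[np.ndarray] = []
    n_multi = 0
    for i, var in enumerate(vcf, start=1):
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        g = np.asarray(var.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        rows.append(g)
        loci.append(f"{var.CHROM}:{var.POS}")
    if n_multi:
        log.info("skipped %d multiallelic VCF record(s)", n_multi)
    geno = (
        np.vstack(rows).T if rows else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, loci, geno)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_genotypes_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal biallelic VCF v4.2 (A/T placeholder alleles)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = sorted({loc.split(":")[0] for loc in gm.locus_ids})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j, locus in enumerate(gm.locus_ids):
            chrom, pos = locus.split(":")
            gts = "\t".join(_GT_STRINGS[int(g)] for g in gm.genotypes[:, j])
            fh.write(f"{chrom}\t{pos}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# GO term tables
# ---------------------------------------------------------------------------


def read_terms(path: str | Path) -> pd.DataFrame:
    """Read a GO-term summary table (go_id, name, count, pc1, pc2)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TERM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"term table missing required columns: {missing}")
    df = df[TERM_COLUMNS].copy()
    df["count"] = df["count"].astype(int)
    if (df["count"] < 1).any():
        bad = df.loc[df["count"] < 1, "go_id"].iloc[0]
        raise ValidationError(f"term {bad!r} has non-positive DEG count")
    coords = df[["pc1", "pc2"]].to_numpy(dtype=float)
    if not np.isfinite(coords).all():
        bad = df.loc[~np.isfinite(coords).all(axis=1), "go_id"].iloc[0]
        raise ValidationError(f"term {bad!r} has non-finite coordinates")
    return df


def write_terms(terms: pd.DataFrame, path: str | Path) -> None:
    terms[TERM_COLUMNS].to_csv(path, sep="\t", index=False)
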