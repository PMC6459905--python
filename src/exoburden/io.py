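"""Reading, writing and assembling case-control genotype studies.

Genotypes are held as an ``int8`` samples x variants matrix counting
copies of the minor allele (0/1/2), with ``-1`` marking a missing call.
The on-disk interchange format is the PLINK bed/bim/fam triplet
(variant-major bed, magic bytes ``6C 1B 01``) plus tab-separated
annotation and covariate tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = np.int8(-1)

#: 2-bit PLINK bed codes -> minor(A1)-allele dosage; 0b01 is missing.
_BED_DECODE = np.array([2, -1, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}
_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

PHENO_CASE = 1
PHENO_CONTROL = 0
PHENO_MISSING = -1

REQUIRED_COVARIATE_COLUMNS = ("sample_id", "phenotype", "sex", "country")
REQUIRED_ANNOTATION_COLUMNS = ("variant_id", "gene", "functional_class")


class FormatError(ValueError):
    """Malformed input file (bad magic bytes, dimension mismatch, ...)."""


@dataclass
class GenotypeStudy:
    """A samples x variants hard-call matrix with sample and variant metadata.

    Attributes
    ----------
    genotypes
        ``int8`` array of shape ``(n_samples, n_variants)``; entries are
        minor-allele dosages in {0, 1, 2} or -1 for a missing call.
    samples
        One row per sample: ``sample_id``, ``phenotype`` (1 case,
        0 control, -1 missing), ``sex`` (1 male, 2 female, 0 unknown),
        ``country``.
    variants
        One row per variant: ``variant_id``, ``chrom``, ``pos`` (1-based,
        build 37), ``a1`` (minor), ``a2`` (major), plus — once
        annotations are attached — ``gene``, ``functional_class``,
        ``score``, ``label`` and ``ref_maf`` columns.
    """

    genotypes: np.ndarray
    samples: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        n, m = self.genotypes.shape
        if len(self.samples) != n or len(self.variants) != m:
            raise ValueError(
                f"genotype matrix is {n}x{m} but tables have "
                f"{len(self.samples)} samples / {len(self.variants)} variants"
            )
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id")
        if self.variants["variant_id"].duplicated().any():
            raise ValueError("duplicate variant_id")
        g = self.genotypes
        if g.dtype != np.int8 or (g < MISSING).any() or (g > 2).any():
            raise ValueError("genotype codes outside {0,1,2,missing}")

    # -- basic dimensions -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def phenotype(self) -> np.ndarray:
        return self.samples["phenotype"].to_numpy()

    @property
    def is_case(self) -> np.ndarray:
        return self.phenotype == PHENO_CASE

    @property
    def is_control(self) -> np.ndarray:
        return self.phenotype == PHENO_CONTROL

    # -- per-variant summaries --------------------------------------------
    def allele_counts(self, sample_mask: np.ndarray | None = None):
        """Return (minor-allele count, called-allele count) per variant."""
        g = self.genotypes if sample_mask is None else self.genotypes[sample_mask]
        # codes are {-1,0,1,2}: raw sum + count of missing = dosage sum
        n_missing = (g == MISSING).sum(axis=0)
        mac = g.sum(axis=0, dtype=np.int64) + n_missing
        n_alleles = 2 * (g.shape[0] - n_missing)
        return mac, n_alleles

    def maf(self, sample_mask: np.ndarray | None = None) -> np.ndarray:
        mac, n_alleles = self.allele_counts(sample_mask)
        with np.errstate(invalid="ignore"):
            return np.where(n_alleles > 0, mac / np.maximum(n_alleles, 1), np.nan)

    def variant_call_rate(self) -> np.ndarray:
        return (self.genotypes >= 0).mean(axis=0)

    def sample_missing_rate(self) -> np.ndarray:
        return (self.genotypes < 0).mean(axis=1)

    # -- subsetting --------------------------------------------------------
    def take_samples(self, index: np.ndarray) -> "GenotypeStudy":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeStudy(
            self.genotypes[idx],
            self.samples.iloc[idx].reset_index(drop=True),
            self.variants.copy(),
        )

    def take_variants(self, index: np.ndarray) -> "GenotypeStudy":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeStudy(
            self.genotypes[:, idx],
            self.samples.copy(),
            self.variants.iloc[idx].reset_index(drop=True),
        )

    def copy(self) -> "GenotypeStudy":
        return GenotypeStudy(
            self.genotypes.copy(), self.samples.copy(), self.variants.copy()
        )


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------

def read_plink(prefix: str | Path) -> GenotypeStudy:
    """Read a PLINK bed/bim/fam triplet into a :class:`GenotypeStudy`.

    The bed file must be in variant-major mode (third magic byte 0x01);
    fam phenotypes 2/1 are mapped to case/control and -9/0 to missing.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "sample_id", "pat", "mat", "sex", "pheno_raw"],
        dtype={"fid": str, "sample_id": str},
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "variant_id", "cm", "pos", "a1", "a2"],
        dtype={"variant_id": str, "a1": str, "a2": str},
    )
    n, m = len(fam), len(bim)

    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:2] != _BED_MAGIC[:2]:
        raise FormatError(f"{prefix}.bed: bad magic bytes {raw[:2].hex()}")
    if raw[2:3] != _BED_MAGIC[2:3]:
        raise FormatError(f"{prefix}.bed: not variant-major (mode byte {raw[2]:#x})")
    bytes_per_variant = (n + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != bytes_per_variant * m:
        raise FormatError(
            f"{prefix}.bed: payload is {payload.size} bytes, expected "
            f"{bytes_per_variant * m} for {n} samples x {m} variants"
        )
    blocks = payload.reshape(m, bytes_per_variant)
    # unpack 2-bit codes, low bits first within each byte
    codes = np.stack(
        [(blocks >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2
    ).reshape(m, -1)[:, :n]
    genotypes = _BED_DECODE[codes].T.copy()  # samples x variants

    pheno = np.full(n, PHENO_MISSING, dtype=np.int8)
    pheno[fam["pheno_raw"] == 2] = PHENO_CASE
    pheno[fam["pheno_raw"] == 1] = PHENO_CONTROL
    samples = pd.DataFrame(
        {
            "sample_id": fam["sample_id"],
            "phenotype": pheno,
            "sex": fam["sex"].astype(int),
            "country": "NA",
        }
    )
    variants = bim[["variant_id", "chrom", "pos", "a1", "a2"]].copy()
    logger.info("read_plink: %d samples, %d variants from %s", n, m, prefix)
    return GenotypeStudy(genotypes, samples, variants)


def write_plink(study: GenotypeStudy, prefix: str | Path) -> None:
    """Write ``study`` as a variant-major PLINK bed/bim/fam triplet."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = study.genotypes.shape

    fam = pd.DataFrame(
        {
            "fid": study.samples["sample_id"],
            "iid": study.samples["sample_id"],
            "pat": 0,
            "mat": 0,
            "sex": study.samples.get("sex", pd.Series([0] * n)),
            "pheno": study.samples["phenotype"].map(
                {PHENO_CASE: 2, PHENO_CONTROL: 1, PHENO_MISSING: -9}
            ),
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    v = study.variants
    bim = pd.DataFrame(
        {
            "chrom": v["chrom"],
            "variant_id": v["variant_id"],
            "cm": 0,
            "pos": v["pos"],
            "a1": v.get("a1", pd.Series(["A"] * m)),
            "a2": v.get("a2", pd.Series(["G"] * m)),
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    code_map = np.zeros(4, dtype=np.uint8)
    for dosage, code in _BED_ENCODE.items():
        code_map[dosage % 4] = code  # -1 -> index 3
    codes = code_map[study.genotypes.T % 4].astype(np.uint8)  # m x n
    pad = (-n) % 4
    if pad:
        # padding bits are written as homozygous-major (0b11), per PLINK
        codes = np.hstack([codes, np.full((m, pad), 0b11, dtype=np.uint8)])
    packed = (
        codes.reshape(m, -1, 4)
        * np.array([1, 4, 16, 64], dtype=np.uint8)
    ).sum(axis=2, dtype=np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())
    logger.info("write_plink: %d samples, %d variants to %s", n, m, prefix)


# ---------------------------------------------------------------------------
# Annotation / covariate tables
# ---------------------------------------------------------------------------

def read_annotation_table(path: str | Path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    missing = [c for c in REQUIRED_ANNOTATION_COLUMNS if c not in tab.columns]
    if missing:
        raise FormatError(f"annotation table lacks required columns: {missing}")
    return tab


def read_covariate_table(path: str | Path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in REQUIRED_COVARIATE_COLUMNS if c not in tab.columns]
    if missing:
        raise FormatError(f"covariate table lacks required columns: {missing}")
    return tab


def attach_annotations(
    study: GenotypeStudy,
    annotation: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> GenotypeStudy:
    """Join per-variant annotations (and optionally per-sample covariates).

    Variants absent from the annotation table are kept and flagged
    (``annotated == False``), never silently dropped. Joins are
    validated one-to-one; duplicate keys raise.
    """
    if annotation["variant_id"].duplicated().any():
        raise ValueError("duplicate variant_id in annotation table")
    if "score" in annotation.columns:
        s = annotation["score"].dropna()
        if ((s < 0) | (s > 1)).any():
            raise ValueError("deleteriousness scores must lie in [0,1]")

    variants = study.variants.merge(annotation, on="variant_id", how="left")
    variants["annotated"] = variants["variant_id"].isin(annotation["variant_id"])
    n_un = int((~variants["annotated"]).sum())
    if n_un:
        logger.warning("attach_annotations: %d variants unannotated", n_un)

    samples = study.samples
    if covariates is not None:
        if len(covariates) == 0:
            raise ValueError(
                "empty covariate table; required columns: "
                + ", ".join(REQUIRED_COVARIATE_COLUMNS)
            )
        if covariates["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in covariate table")
        merged = study.samples[["sample_id"]].merge(
            covariates, on="sample_id", how="left", validate="one_to_one"
        )
        absent = merged["phenotype"].isna()
        if absent.any():
            logger.warning(
                "attach_annotations: %d samples absent from covariate table",
                int(absent.sum()),
            )
        merged["phenotype"] = merged["phenotype"].fillna(PHENO_MISSING).astype(int)
        samples = merged

    return GenotypeStudy(study.genotypes.copy(), samples, variants)
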