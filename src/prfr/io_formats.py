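"""Shared data model and readers/writers for the external formats the pipeline touches.

Conventions
-----------
* All internal genomic positions are **1-based inclusive**; only the BED reader
  converts (BED is 0-based half-open on disk).
* A genotype dosage counts copies of ``allele_a`` (0, 1 or 2).  Readers never
  flip alleles; minor/major orientation is decided downstream from the MAF.
* Missing genotypes are ``NaN`` in the dosage array — never ``-1`` or ``3`` —
  so missing cells can never silently enter arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("prfr")

#: number of fixed leading sample columns in the PLINK additive-recode dialect
_RAW_FIXED_COLS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SNPInfo:
    """A biallelic variant: identifier, 1-based coordinate and allele pair.

    ``allele_a`` is the counted allele (the dosage counts its copies);
    ``allele_b`` is the other allele.
    """

    snp_id: str
    chrom: str
    pos: int
    allele_a: str = "A"
    allele_b: str = "B"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP {self.snp_id}: position must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class GeneInterval:
    """A gene locus as a 1-based inclusive interval."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id}: end ({self.end}) < start ({self.start})"
            )


class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with SNP and sample metadata.

    Dosages are stored as float64 with values in {0, 1, 2, NaN}; NaN marks a
    missing genotype call.
    """

    def __init__(
        self,
        dosages: np.ndarray,
        snps: Sequence[SNPInfo],
        sample_ids: Sequence[str],
    ) -> None:
        dosages = np.asarray(dosages, dtype=np.float64)
        if dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D array (individuals x SNPs)")
        if dosages.shape != (len(sample_ids), len(snps)):
            raise ValueError(
                f"dosage shape {dosages.shape} does not match "
                f"{len(sample_ids)} samples x {len(snps)} SNPs"
            )
        finite = dosages[~np.isnan(dosages)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))][0]
            raise ValueError(f"non-missing dosage outside {{0,1,2}}: {bad}")
        ids = [s.snp_id for s in snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP ids")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids")
        self.dosages = dosages
        self.snps = list(snps)
        self.sample_ids = list(sample_ids)
        self._snp_index = {s.snp_id: j for j, s in enumerate(self.snps)}

    # -- basic introspection ------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def snp_column(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self._snp_index[snp_id]]

    # -- subsetting ---------------------------------------------------------

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        try:
            cols = [self._snp_index[s] for s in snp_ids]
        except KeyError as exc:
            raise KeyError(f"SNP not in matrix: {exc.args[0]}") from None
        return GenotypeMatrix(
            self.dosages[:, cols], [self.snps[j] for j in cols], self.sample_ids
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = [index[s] for s in sample_ids]
        except KeyError as exc:
            raise KeyError(f"sample not in matrix: {exc.args[0]}") from None
        return GenotypeMatrix(self.dosages[rows, :], self.snps, list(sample_ids))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.snps == other.snps
            and np.array_equal(self.dosages, other.dosages, equal_nan=True)
        )


class PhenotypeTable:
    """Binary case/control outcome plus clinical covariates, keyed by sample id.

    ``covariate_types`` declares each covariate as "categorical" or
    "continuous"; undeclared covariates are inferred from dtype (non-numeric
    -> categorical).  ``reference_levels`` fixes the reference level used for
    odds ratios of categorical variables (default: lexicographically first).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        covariate_types: Mapping[str, str] | None = None,
        reference_levels: Mapping[str, str] | None = None,
    ) -> None:
        if "sample_id" in data.columns:
            data = data.set_index("sample_id")
        if "outcome" not in data.columns:
            raise ValueError("phenotype table requires an 'outcome' column")
        outcome = data["outcome"]
        if not set(pd.unique(outcome)).issubset({0, 1}):
            raise ValueError("outcome must be strictly binary (0=control, 1=case)")
        if data.index.has_duplicates:
            raise ValueError("duplicate sample ids in phenotype table")
        self.data = data.copy()
        self.data.index = self.data.index.astype(str)
        self.data["outcome"] = self.data["outcome"].astype(int)
        self.covariate_types = dict(covariate_types or {})
        for col in self.covariates:
            if col not in self.covariate_types:
                self.covariate_types[col] = (
                    "continuous"
                    if pd.api.types.is_numeric_dtype(self.data[col])
                    else "categorical"
                )
        self.reference_levels = dict(reference_levels or {})

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def outcome(self) -> np.ndarray:
        return self.data["outcome"].to_numpy(dtype=int)

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.data.columns if c != "outcome"]

    def outcomes_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        return self.data.loc[list(sample_ids), "outcome"].to_numpy(dtype=int)

    def subset(self, sample_ids: Sequence[str]) -> "PhenotypeTable":
        return PhenotypeTable(
            self.data.loc[list(sample_ids)].reset_index(names="sample_id"),
            self.covariate_types,
            self.reference_levels,
        )

    def reference_level(self, covariate: str) -> str:
        if covariate in self.reference_levels:
            return self.reference_levels[covariate]
        return sorted(self.data[covariate].astype(str).unique())[0]


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. GO biological processes) with descriptions."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, set_id: str) -> list[str]:
        return self.sets[set_id][1]

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# PLINK additive-recode ("raw"-style) text
# ---------------------------------------------------------------------------


def read_genotypes_raw(path: str | Path) -> GenotypeMatrix:
    """Read a PLINK additive-recode text file into a :class:`GenotypeMatrix`.

    The dialect is whitespace-separated with the six fixed sample columns
    (FID IID PAT MAT SEX PHENOTYPE) followed by one ``snpid_allele`` column
    per SNP; dosages are 0/1/2 and ``NA`` marks missing.  If a sidecar
    ``<path>.snps.tsv`` written by :func:`write_genotypes_raw` exists, SNP
    coordinates are taken from it; otherwise chrom="0" and pos=column index.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().split()
        if header[: len(_RAW_FIXED_COLS)] != _RAW_FIXED_COLS:
            raise FormatError(
                f"{path}: expected fixed columns {' '.join(_RAW_FIXED_COLS)}"
            )
        snp_cols = header[len(_RAW_FIXED_COLS):]
        sample_ids: list[str] = []
        rows: list[np.ndarray] = []
        for line_no, line in enumerate(fh, start=2):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != len(header):
                raise FormatError(
                    f"{path}:{line_no}: expected {len(header)} fields, got {len(tokens)}"
                )
            sample_ids.append(tokens[1])
            row = np.empty(len(snp_cols))
            for j, tok in enumerate(tokens[len(_RAW_FIXED_COLS):]):
                if tok == "NA":
                    row[j] = np.nan
                elif tok in ("0", "1", "2"):
                    row[j] = float(tok)
                else:
                    raise FormatError(
                        f"{path}:{line_no}: bad dosage {tok!r} in column "
                        f"{snp_cols[j]} (expected 0/1/2/NA)"
                    )
            rows.append(row)
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError(f"{path}: duplicate sample id")
    snps = _snps_from_raw_columns(snp_cols, path)
    dosages = np.vstack(rows) if rows else np.empty((0, len(snp_cols)))
    return GenotypeMatrix(dosages, snps, sample_ids)


def _snps_from_raw_columns(snp_cols: list[str], path: Path) -> list[SNPInfo]:
    sidecar = path.with_name(path.name + ".snps.tsv")
    meta: dict[str, SNPInfo] = {}
    if sidecar.exists():
        df = pd.read_csv(sidecar, sep="\t", dtype=str)
        for rec in df.itertuples(index=False):
            meta[rec.snp_id] = SNPInfo(
                rec.snp_id, rec.chrom, int(rec.pos), rec.allele_a, rec.allele_b
            )
    snps = []
    for j, col in enumerate(snp_cols):
        snp_id, _, allele = col.rpartition("_")
        if not snp_id:
            snp_id, allele = col, "A"
        if snp_id in meta:
            snps.append(meta[snp_id])
        else:
            snps.append(SNPInfo(snp_id, "0", j + 1, allele, "B"))
    return snps


def write_genotypes_raw(
    genotypes: GenotypeMatrix, path: str | Path, phenotypes: PhenotypeTable | None = None
) -> None:
    """Write the additive-recode dialect plus a ``.snps.tsv`` coordinate sidecar."""
    path = Path(path)
    pheno_codes = {}
    if phenotypes is not None:
        # PLINK codes phenotype 1=control, 2=case
        pheno_codes = {
            s: str(int(y) + 1)
            for s, y in zip(phenotypes.sample_ids, phenotypes.outcome)
        }
    with open(path, "w") as fh:
        cols = _RAW_FIXED_COLS + [f"{s.snp_id}_{s.allele_a}" for s in genotypes.snps]
        fh.write(" ".join(cols) + "\n")
        for i, sid in enumerate(genotypes.sample_ids):
            row = genotypes.dosages[i]
            tokens = [sid, sid, "0", "0", "0", pheno_codes.get(sid, "-9")]
            tokens += ["NA" if np.isnan(d) else str(int(d)) for d in row]
            fh.write(" ".join(tokens) + "\n")
    sidecar = path.with_name(path.name + ".snps.tsv")
    pd.DataFrame(
        [
            (s.snp_id, s.chrom, s.pos, s.allele_a, s.allele_b)
            for s in genotypes.snps
        ],
        columns=["snp_id", "chrom", "pos", "allele_a", "allele_b"],
    ).to_csv(sidecar, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF (GT only, biallelic)
# ---------------------------------------------------------------------------


def read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a minimal VCF (biallelic records, GT field) into a GenotypeMatrix.

    Dosage counts ALT alleles; ``./.`` becomes missing.  Phased separators
    are accepted.  Multi-allelic records and records without GT are errors.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    snps: list[SNPInfo] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise FormatError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS} "
                f"({rec.REF}->{','.join(rec.ALT) or '.'}) is not supported"
            )
        if "GT" not in (rec.FORMAT or ""):
            raise FormatError(f"record at {rec.CHROM}:{rec.POS} has no GT field")
        # gts012: 0/1/2 = ALT dosage, 3 = missing
        gt = rec.gt_types.astype(float)
        gt[gt == 3] = np.nan
        snp_id = rec.ID if rec.ID and rec.ID != "." else f"{rec.CHROM}:{rec.POS}"
        snps.append(SNPInfo(snp_id, rec.CHROM, rec.POS, rec.ALT[0], rec.REF))
        columns.append(gt)
    vcf.close()
    dosages = (
        np.column_stack(columns) if columns else np.empty((len(sample_ids), 0))
    )
    return GenotypeMatrix(dosages, snps, sample_ids)


# ---------------------------------------------------------------------------
# Phenotype TSV
# ---------------------------------------------------------------------------


def read_phenotypes(
    path: str | Path,
    covariate_types: Mapping[str, str] | None = None,
    reference_levels: Mapping[str, str] | None = None,
) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing 'sample_id' column")
    df["sample_id"] = df["sample_id"].astype(str)
    return PhenotypeTable(df, covariate_types, reference_levels)


def write_phenotypes(phenotypes: PhenotypeTable, path: str | Path) -> None:
    phenotypes.data.reset_index(names="sample_id").to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED4 gene intervals
# ---------------------------------------------------------------------------


def read_gene_bed(path: str | Path) -> list[GeneInterval]:
    """Read BED4 gene intervals, converting to 1-based inclusive coordinates."""
    genes: list[GeneInterval] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{line_no}: BED4 requires >= 4 fields")
            chrom, start0, end0, name = fields[:4]
            start, end = int(start0) + 1, int(end0)
            if end < start:
                raise FormatError(
                    f"{path}:{line_no}: empty or inverted interval [{start0},{end0})"
                )
            genes.append(GeneInterval(name, chrom, start, end))
    return genes


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one gene set per line (id, description, members...)."""
    collection = GeneSetCollection()
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{line_no}: GMT line needs id, description and >=1 member"
                )
            set_id, description = fields[0], fields[1]
            members = list(dict.fromkeys(g for g in fields[2:] if g))
            if not members:
                logger.warning("GMT set %s has no members; dropped", set_id)
                continue
            collection.sets[set_id] = (description, members)
    return collection


# ---------------------------------------------------------------------------
# LD-pair and eQTL TSVs
# ---------------------------------------------------------------------------


def read_ld_pairs(path: str | Path) -> pd.DataFrame:
    """Read an LD table with columns snp_a, snp_b, r2 (r2 in [0,1])."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_a": str, "snp_b": str})
    for col in ("snp_a", "snp_b", "r2"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    r2 = df["r2"].to_numpy(dtype=float)
    if ((r2 < 0) | (r2 > 1)).any():
        raise FormatError(f"{path}: r2 outside [0,1]")
    return df


def read_eqtl(path: str | Path) -> pd.DataFrame:
    """Read an eQTL table with columns snp, target_gene."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("snp", "target_gene"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return df
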