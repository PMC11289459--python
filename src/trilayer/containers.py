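"""Typed in-memory containers shared by all pipeline stages.

Conventions
-----------
* Genomic positions are 1-based inclusive throughout the package; BED export
  converts to 0-based half-open at write time.
* Genotype dosages count copies of the effect (minor) allele: 0/1/2, with
  ``numpy.nan`` for missing calls.
* Methylation beta values live in [0, 1].
* Expression matrices are genes x samples on a log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "MethylationMatrix",
    "ExpressionMatrix",
    "PhenotypeTable",
]


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dup = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dup[:5]}")


@dataclass
class GenotypeMatrix:
    """Samples x SNPs minor-allele dosage matrix with per-SNP metadata.

    Parameters
    ----------
    dosage:
        float array of shape (n_samples, n_snps); entries in {0, 1, 2} or NaN.
    snps:
        DataFrame with one row per SNP and columns
        ``snp_id, chrom, pos, effect_allele, other_allele`` (``maf`` is added
        on construction if absent).
    sample_ids:
        list of sample identifiers, one per dosage row.
    """

    dosage: np.ndarray
    snps: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (samples x SNPs)")
        if self.dosage.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match dosage rows")
        if self.dosage.shape[1] != len(self.snps):
            raise ValueError("snps table length does not match dosage columns")
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValueError(
                f"dosage out of domain {{0,1,2,NaN}} at sample "
                f"{self.sample_ids[i]!r}, SNP {self.snps['snp_id'].iloc[j]!r}"
            )
        required = {"snp_id", "chrom", "pos", "effect_allele", "other_allele"}
        missing = required - set(self.snps.columns)
        if missing:
            raise ValueError(f"snps table missing columns: {sorted(missing)}")
        _check_unique(self.snps["snp_id"], "snp ids")
        _check_unique(self.sample_ids, "sample ids")
        self.snps = self.snps.reset_index(drop=True)
        if "maf" not in self.snps.columns:
            with np.errstate(invalid="ignore"):
                freq = np.nanmean(self.dosage, axis=0) / 2.0
            self.snps["maf"] = np.minimum(freq, 1.0 - freq)

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def call_rate(self) -> np.ndarray:
        """Per-SNP fraction of non-missing calls."""
        return 1.0 - np.isnan(self.dosage).mean(axis=0)

    def subset_snps(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypeMatrix(
            dosage=self.dosage[:, idx],
            snps=self.snps.iloc[idx].reset_index(drop=True),
            sample_ids=list(self.sample_ids),
        )


@dataclass
class MethylationMatrix:
    """Samples x CpGs beta-value matrix with probe genomic coordinates."""

    beta: np.ndarray
    probes: pd.DataFrame  # probe_id, chrom, pos (1-based)
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.ndim != 2:
            raise ValueError("beta must be 2-D (samples x CpGs)")
        if self.beta.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match beta rows")
        if self.beta.shape[1] != len(self.probes):
            raise ValueError("probes table length does not match beta columns")
        bad = (self.beta < 0) | (self.beta > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"beta value {self.beta[i, j]!r} outside [0,1] at sample "
                f"{self.sample_ids[i]!r}, probe {self.probes['probe_id'].iloc[j]!r}"
            )
        required = {"probe_id", "chrom", "pos"}
        missing = required - set(self.probes.columns)
        if missing:
            raise ValueError(f"probes table missing columns: {sorted(missing)}")
        _check_unique(self.probes["probe_id"], "probe ids")
        _check_unique(self.sample_ids, "sample ids")
        self.probes = self.probes.reset_index(drop=True)
        for _, grp in self.probes.groupby("chrom"):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("probe positions must be sorted within chromosome")

    @property
    def n_samples(self) -> int:
        return self.beta.shape[0]

    @property
    def n_probes(self) -> int:
        return self.beta.shape[1]


@dataclass
class ExpressionMatrix:
    """Genes x samples log-scale expression matrix."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes x samples)")
        if self.values.shape[0] != len(self.gene_ids):
            raise ValueError("gene_ids length does not match value rows")
        if self.values.shape[1] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match value columns")
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.sample_ids, "sample ids")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class PhenotypeTable:
    """Per-sample disease-course label and covariates.

    ``table`` is indexed by sample id with at least a ``course`` column
    (e.g. PPMS / BOMS / HC) and a binary ``case`` indicator; covariate
    columns (age, sex, smoking, batch, cell-fraction columns ``cell_*``,
    ancestry PCs ``ancPC*``) are carried alongside.
    """

    table: pd.DataFrame
    case_label: str = "PPMS"
    cell_fraction_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if "course" not in self.table.columns:
            raise ValueError("phenotype table must have a 'course' column")
        _check_unique(self.table.index, "sample ids")
        if "case" not in self.table.columns:
            self.table = self.table.copy()
            self.table["case"] = (self.table["course"] == self.case_label).astype(int)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def indicator(self, label: str) -> np.ndarray:
        """0/1 indicator for a disease-course label (label vs rest)."""
        return (self.table["course"] == label).to_numpy(dtype=float)
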