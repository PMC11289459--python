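"""Readers and writers for the pipeline's interchange formats.

TSV is canonical for every layer (methylation and expression with samples
in columns, genotypes one row per SNP with CHROM/POS/ID/REF/ALT metadata
columns, i.e. a minimal VCF-like TSV); biallelic GT-only VCF is supported
read-only through cyvcf2. DMRs export to BED with the package's 1-based
inclusive internal coordinates converted to 0-based half-open.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    GenotypeMatrix,
    MethylationMatrix,
    PhenotypeTable,
)
from .dmr import DMRResult

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_vcf_dosage",
    "write_regions_bed",
]

_GENO_META = ["CHROM", "POS", "ID", "REF", "ALT"]


def write_matrix(obj, path, header_comment: str | None = None) -> None:
    """Write a typed matrix to TSV. Layout per kind:

    * methylation: probe rows (probe_id, chrom, pos, then sample columns);
    * expression: gene rows (gene_id, then sample columns);
    * dosage: SNP rows (CHROM, POS, ID, REF, ALT, then sample columns);
    * phenotype: sample rows.
    """
    if isinstance(obj, MethylationMatrix):
        df = pd.concat(
            [obj.probes.reset_index(drop=True),
             pd.DataFrame(obj.beta.T, columns=obj.sample_ids)],
            axis=1,
        )
    elif isinstance(obj, ExpressionMatrix):
        df = pd.concat(
            [pd.DataFrame({"gene_id": obj.gene_ids}),
             pd.DataFrame(obj.values, columns=obj.sample_ids)],
            axis=1,
        )
    elif isinstance(obj, GenotypeMatrix):
        meta = pd.DataFrame(
            {
                "CHROM": obj.snps["chrom"],
                "POS": obj.snps["pos"],
                "ID": obj.snps["snp_id"],
                "REF": obj.snps["other_allele"],
                "ALT": obj.snps["effect_allele"],
            }
        ).reset_index(drop=True)
        df = pd.concat(
            [meta, pd.DataFrame(obj.dosage.T, columns=obj.sample_ids)], axis=1
        )
    elif isinstance(obj, PhenotypeTable):
        df = obj.table.reset_index()
    else:
        raise TypeError(f"unsupported matrix type {type(obj).__name__}")
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_matrix(path, kind: str):
    """Read a TSV written by :func:`write_matrix`; ``kind`` is one of
    methylation / expression / dosage / phenotype. Domain invariants are
    validated on construction with errors naming the offending cell."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if kind == "methylation":
        meta = ["probe_id", "chrom", "pos"]
        _require(df, meta, path)
        samples = [c for c in df.columns if c not in meta]
        return MethylationMatrix(
            beta=df[samples].to_numpy(float).T,
            probes=df[meta].astype({"chrom": str}),
            sample_ids=samples,
        )
    if kind == "expression":
        _require(df, ["gene_id"], path)
        samples = [c for c in df.columns if c != "gene_id"]
        return ExpressionMatrix(
            values=df[samples].to_numpy(float),
            gene_ids=df["gene_id"].astype(str).tolist(),
            sample_ids=samples,
        )
    if kind == "dosage":
        _require(df, _GENO_META, path)
        samples = [c for c in df.columns if c not in _GENO_META]
        snps = pd.DataFrame(
            {
                "snp_id": df["ID"].astype(str),
                "chrom": df["CHROM"].astype(str),
                "pos": df["POS"].astype(int),
                "effect_allele": df["ALT"].astype(str),
                "other_allele": df["REF"].astype(str),
            }
        )
        return GenotypeMatrix(
            dosage=df[samples].to_numpy(float).T, snps=snps, sample_ids=samples
        )
    if kind == "phenotype":
        _require(df, ["sample_id", "course"], path)
        table = df.set_index("sample_id")
        cells = [c for c in table.columns if c.startswith("cell_")]
        return PhenotypeTable(table=table, cell_fraction_columns=cells)
    raise ValueError(f"unknown matrix kind {kind!r}")


def _require(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: malformed header, missing columns {missing}")


def read_vcf_dosage(path) -> GenotypeMatrix:
    """Read biallelic GT-only records from a VCF into effect(ALT)-allele
    dosages (``./.`` becomes missing). Multi-allelic records are rejected."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"multi-allelic record at {var.CHROM}:{var.POS}")
        dos = np.empty(len(samples))
        for i, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1]]
            if any(a < 0 for a in alleles):
                dos[i] = np.nan
            else:
                dos[i] = float(sum(alleles))
        rows.append(dos)
        meta.append(
            {
                "snp_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "effect_allele": var.ALT[0],
                "other_allele": var.REF,
            }
        )
    return GenotypeMatrix(
        dosage=np.array(rows).T, snps=pd.DataFrame(meta), sample_ids=samples
    )


def write_regions_bed(dmrs: list[DMRResult], path, score_cap: float = 10.0) -> None:
    """Export DMRs as BED (0-based half-open): start = first probe - 1,
    end = last probe; score = -log10(fwer_p) capped."""
    lines = []
    for d in dmrs:
        assert d.n_probes >= 2, "single-probe regions violate the DMR invariant"
        score = score_cap
        if d.fwer_p is not None and d.fwer_p > 0:
            score = min(score_cap, -np.log10(d.fwer_p))
        lines.append((str(d.chrom), d.start - 1, d.end,
                      f"dmr_{d.chrom}_{d.start}", round(score, 4)))
    lines.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        for row in lines:
            fh.write("\t".join(str(x) for x in row) + "\n")
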