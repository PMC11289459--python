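"""meQTL / eQTL scanning and direction-of-effect concordance triage.

A QTL here is an additive minor-allele dosage linear model: the feature
(CpG beta or log expression) is regressed on dosage plus covariates, one
test per (SNP, feature) pair, with Bonferroni adjustment over the tests
actually performed in the scan (Benjamini-Hochberg optional). The triage
step joins three layers of directions — disease (odds ratio above/below 1),
meQTL sign, eQTL sign — into qualitative concordance labels such as the
risk -> hypermethylation -> lower-expression pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, GenotypeMatrix, MethylationMatrix
from .genetics import AssocResult, LDBlockSet

__all__ = [
    "QTLResult",
    "ExternalQTLRecord",
    "ConcordanceRecord",
    "linear_qtl_scan",
    "select_window",
    "concordance_triage",
]


@dataclass
class QTLResult:
    snp_id: str
    feature_id: str
    beta: float          # per minor-allele-copy effect
    se: float
    t: float
    p: float
    p_adjusted: float
    n: int


@dataclass
class ExternalQTLRecord:
    """Sign-level annotation from an external QTL resource (e.g. a brain
    eQTL table): only the effect sign / normalized effect score and a
    significance flag are used."""

    snp_id: str
    feature_id: str
    source: str
    effect_sign: str      # "+", "-", or "NA"
    nes: float | None = None
    significant: bool = True


@dataclass
class ConcordanceRecord:
    snp_id: str
    block_id: int | None
    gene_id: str | None
    disease_direction: str   # "risk" / "protective" / "NA"
    meqtl_direction: str     # "+" / "-" / "NA"
    eqtl_direction: str      # "+" / "-" / "NA"
    label: str               # concordant-repressive / concordant-protective /
                             # discordant / incomplete


def _feature_arrays(features) -> tuple[np.ndarray, list[str]]:
    """Samples x features array plus ids, for either matrix kind."""
    if isinstance(features, MethylationMatrix):
        return features.beta, list(features.probes["probe_id"])
    if isinstance(features, ExpressionMatrix):
        return features.values.T, list(features.gene_ids)
    raise TypeError("features must be a MethylationMatrix or ExpressionMatrix")


def linear_qtl_scan(
    geno: GenotypeMatrix,
    features,
    covariates: np.ndarray | None = None,
    pairs: list[tuple[str, str]] | None = None,
    adjust: str = "bonferroni",
    family: str = "scan",
) -> list[QTLResult]:
    """OLS of each tested feature on dosage + covariates.

    ``pairs`` restricts the scan to explicit (snp_id, feature_id) pairs;
    by default every SNP x feature combination is tested. Adjustment
    (``bonferroni`` or ``bh``) runs over the whole scan by default;
    ``family="per_feature"`` adjusts within each feature's tests instead.
    """
    feat, feat_ids = _feature_arrays(features)
    n = feat.shape[0]
    if geno.n_samples != n:
        raise ValueError("genotypes and features must share samples")
    snp_col = {s: i for i, s in enumerate(geno.snps["snp_id"])}
    feat_col = {f: i for i, f in enumerate(feat_ids)}
    if pairs is None:
        pairs = [(s, f) for s in snp_col for f in feat_col]
    if not pairs:
        raise ValueError("no (SNP, feature) pairs to test")

    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]

    results = []
    for snp_id, feature_id in pairs:
        dos = geno.dosage[:, snp_col[snp_id]]
        y = feat[:, feat_col[feature_id]]
        ok = ~np.isnan(dos)
        cols = [np.ones(ok.sum()), dos[ok]]
        if covariates is not None:
            cols.append(covariates[ok])
        X = np.column_stack(cols)
        yy = y[ok]
        coef, _, _, _ = np.linalg.lstsq(X, yy, rcond=None)
        resid = yy - X @ coef
        dof = len(yy) - X.shape[1]
        if dof <= 0:
            raise ValueError("not enough samples for the covariate set")
        sigma2 = (resid**2).sum() / dof
        xtx_inv = np.linalg.inv(X.T @ X)
        se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
        beta = float(coef[1])
        t = beta / se if se > 0 else 0.0
        p = float(2 * stats.t.sf(abs(t), dof))
        results.append(
            QTLResult(snp_id, feature_id, beta, se, float(t), p, p, int(len(yy)))
        )

    def _adjust(subset: list[QTLResult]) -> None:
        pvals = np.array([r.p for r in subset])
        if adjust == "bonferroni":
            adj = np.minimum(1.0, pvals * len(pvals))
        elif adjust == "bh":
            adj = multipletests(pvals, method="fdr_bh")[1]
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")
        for r, a in zip(subset, adj):
            r.p_adjusted = float(a)

    if family == "scan":
        _adjust(results)
    elif family == "per_feature":
        by_feature: dict[str, list[QTLResult]] = {}
        for r in results:
            by_feature.setdefault(r.feature_id, []).append(r)
        for subset in by_feature.values():
            _adjust(subset)
    else:
        raise ValueError(f"unknown family {family!r}")
    return results


def select_window(
    snps: pd.DataFrame,
    chrom: str,
    region_start: int,
    region_end: int,
    flank: int = 500_000,
) -> pd.DataFrame:
    """SNPs within [region_start - flank, region_end + flank], inclusive
    on both bounds, on the region's chromosome."""
    lo = region_start - flank
    hi = region_end + flank
    mask = (
        (snps["chrom"].astype(str) == str(chrom))
        & (snps["pos"] >= lo)
        & (snps["pos"] <= hi)
    )
    return snps[mask].reset_index(drop=True)


def _sig_sign(value: float | None, p: float | None, threshold: float) -> str:
    if value is None or p is None or not np.isfinite(p) or p >= threshold:
        return "NA"
    return "+" if value > 0 else "-"


def concordance_triage(
    assoc: list[AssocResult],
    meqtl: list[QTLResult],
    eqtl: list[ExternalQTLRecord],
    block_map: LDBlockSet | None = None,
    assoc_threshold: float = 0.05,
    meqtl_threshold: float = 0.05,
    use_adjusted_meqtl: bool = True,
) -> tuple[list[ConcordanceRecord], dict[str, int]]:
    """Three-layer direction-of-effect triage.

    Per SNP (crossed with every annotated gene): the disease direction is
    read off the odds ratio of a significant association (>1 risk,
    <1 protective), the meQTL direction off the sign of a significant
    dosage-methylation effect, and the eQTL direction off the external
    record's sign. Labels:

    * ``concordant-repressive`` — risk & meQTL+ & eQTL- (the
      risk -> hypermethylation -> lower-expression pattern);
    * ``concordant-protective`` — protective & meQTL- & eQTL+;
    * ``incomplete`` — any of the three directions NA;
    * ``discordant`` — otherwise.
    """
    blk = block_map.block_of() if block_map is not None else {}
    disease: dict[str, str] = {}
    for a in assoc:
        if a.odds_ratio is None:
            disease[a.snp_id] = "NA"
        else:
            d = _sig_sign(np.log(a.odds_ratio), a.p, assoc_threshold)
            disease[a.snp_id] = {"+": "risk", "-": "protective", "NA": "NA"}[d]
    me: dict[str, str] = {}
    for q in meqtl:
        p = q.p_adjusted if use_adjusted_meqtl else q.p
        sign = _sig_sign(q.beta, p, meqtl_threshold)
        # strongest significant CpG wins; NA never overwrites a sign
        if me.get(q.snp_id, "NA") == "NA":
            me[q.snp_id] = sign
    ex: dict[str, list[ExternalQTLRecord]] = {}
    for rec in eqtl:
        ex.setdefault(rec.snp_id, []).append(rec)

    records: list[ConcordanceRecord] = []
    counts = {
        "concordant-repressive": 0,
        "concordant-protective": 0,
        "discordant": 0,
        "incomplete": 0,
    }
    for snp_id in disease:
        dd = disease[snp_id]
        md = me.get(snp_id, "NA")
        gene_records = ex.get(snp_id) or [None]
        for rec in gene_records:
            if rec is None:
                ed, gene = "NA", None
            else:
                ed = rec.effect_sign if rec.significant else "NA"
                gene = rec.feature_id
            if "NA" in (dd, md, ed):
                label = "incomplete"
            elif dd == "risk" and md == "+" and ed == "-":
                label = "concordant-repressive"
            elif dd == "protective" and md == "-" and ed == "+":
                label = "concordant-protective"
            else:
                label = "discordant"
            counts[label] += 1
            records.append(
                ConcordanceRecord(
                    snp_id=snp_id,
                    block_id=blk.get(snp_id),
                    gene_id=gene,
                    disease_direction=dd,
                    meqtl_direction=md,
                    eqtl_direction=ed,
                    label=label,
                )
            )
    return records, counts
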