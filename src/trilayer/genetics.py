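"""Case-control genetics: QC, logistic association, LD blocks, meta-analysis.

Implements the genetic arm of the pipeline: SNP call-rate filtering and the
exact Hardy-Weinberg test, per-SNP additive-dosage logistic regression of a
binary disease-course phenotype, pairwise LD (r-squared of dosage vectors),
greedy significance-seeded LD-block clumping, the block-count Bonferroni
threshold, and inverse-variance fixed/random-effects meta-analysis of log
odds ratios (with SE reconstruction from printed OR and P, the form needed
to pool published per-cohort summary statistics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import gammaln

from .containers import GenotypeMatrix

__all__ = [
    "AssocResult",
    "LDBlockSet",
    "MetaResult",
    "filter_call_rate",
    "hwe_test",
    "logistic_assoc",
    "ld_r2",
    "cluster_ld_blocks",
    "bonferroni_by_blocks",
    "se_from_or_p",
    "meta_analyze",
    "meta_from_or_p",
]


@dataclass
class AssocResult:
    snp_id: str
    beta: float | None
    se: float | None
    odds_ratio: float | None
    z: float | None
    p: float | None
    n_cases: int
    n_controls: int
    converged: bool


@dataclass
class LDBlockSet:
    """Disjoint SNP blocks, each seeded by its most significant member."""

    blocks: list[dict]        # {"seed": snp_id, "members": [snp_id, ...]}
    r2_threshold: float

    def block_of(self) -> dict[str, int]:
        out = {}
        for i, blk in enumerate(self.blocks):
            for snp in blk["members"]:
                out[snp] = i
        return out

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


@dataclass
class MetaResult:
    snp_id: str
    per_study: list[tuple[float, float]]     # (logOR, SE)
    pooled_log_or: float
    pooled_se: float
    pooled_or: float
    z: float
    p: float
    q_statistic: float
    i_squared: float
    tau_squared: float
    model: str
    reconstructed: list[bool] = field(default_factory=list)


def filter_call_rate(
    geno: GenotypeMatrix, min_rate: float = 0.98
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop SNPs whose non-missing call fraction falls below ``min_rate``
    (default 98%); returns the filtered matrix and an exclusion report."""
    rates = geno.call_rate()
    keep = rates >= min_rate
    report = pd.DataFrame(
        {
            "snp_id": geno.snps["snp_id"],
            "call_rate": rates,
            "excluded": ~keep,
        }
    )
    return geno.subset_snps(keep), report


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg equilibrium test.

    Conditional on the observed allele counts, sums the probabilities of
    all heterozygote counts no more probable than the observed one
    (the standard exact SNP-HWE formulation, computed by enumeration in
    log space).
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0 or int(c) != c:
            raise ValueError("genotype counts must be non-negative integers")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotypes")
    rare = 2 * min(n_AA, n_aa) + n_Aa
    if rare == 0 or rare == 2 * n:
        return 1.0  # monomorphic: HWE trivially satisfied

    # P(het = h | allele counts) over all feasible h with the same parity
    hets = np.arange(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    homr = (rare - hets) // 2
    homc = n - hets - homr
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(homr + 1)
        - gammaln(homc + 1)
        + hets * np.log(2.0)
        + gammaln(rare + 1)
        + gammaln(2 * n - rare + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hets == n_Aa][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def logistic_assoc(
    geno: GenotypeMatrix,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
) -> list[AssocResult]:
    """Per-SNP logistic regression of case status on minor-allele dosage.

    Fits by IRLS (statsmodels Logit). Samples with a missing call are
    dropped per SNP. Non-convergence and (quasi-)separation are reported
    via ``converged=False`` with estimates withheld.
    """
    phenotype = np.asarray(phenotype, dtype=float)
    uniq = set(np.unique(phenotype))
    if not uniq <= {0.0, 1.0}:
        raise ValueError("phenotype must be binary 0/1")
    if len(uniq) < 2:
        raise ValueError("phenotype is constant")
    n = len(phenotype)
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        if np.linalg.matrix_rank(
            np.column_stack([np.ones(n), covariates])
        ) < covariates.shape[1] + 1:
            raise ValueError("covariates not full rank")

    results = []
    for j in range(geno.n_snps):
        dos = geno.dosage[:, j]
        ok = ~np.isnan(dos)
        y = phenotype[ok]
        cols = [np.ones(ok.sum()), dos[ok]]
        if covariates is not None:
            cols.append(covariates[ok])
        X = np.column_stack(cols)
        snp_id = geno.snps["snp_id"].iloc[j]
        n_cases = int(y.sum())
        n_controls = int(len(y) - y.sum())
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", category=RuntimeWarning)
                fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
            converged = bool(fit.mle_retvals.get("converged", True))
            se = fit.bse[1]
            if not np.isfinite(se) or se > 50:
                converged = False  # quasi-separation: SE blown up
        except Exception:
            converged = False
        if not converged:
            results.append(
                AssocResult(snp_id, None, None, None, None, None,
                            n_cases, n_controls, False)
            )
            continue
        beta = float(fit.params[1])
        se = float(fit.bse[1])
        z = beta / se
        results.append(
            AssocResult(
                snp_id=snp_id,
                beta=beta,
                se=se,
                odds_ratio=float(np.exp(beta)),
                z=float(z),
                p=float(2 * stats.norm.sf(abs(z))),
                n_cases=n_cases,
                n_controls=n_controls,
                converged=True,
            )
        )
    return results


def ld_r2(dosage_i: np.ndarray, dosage_j: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over
    pairwise-complete samples; NaN when monomorphic in the overlap."""
    a = np.asarray(dosage_i, dtype=float)
    b = np.asarray(dosage_j, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 2:
        raise ValueError("need >= 2 pairwise-complete samples")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def cluster_ld_blocks(
    geno: GenotypeMatrix,
    assoc: list[AssocResult],
    r2_threshold: float = 0.8,
) -> LDBlockSet:
    """Greedy significance-seeded clumping.

    Repeatedly take the most significant unassigned SNP as a block seed and
    absorb every unassigned SNP with r^2 > threshold against the seed.
    Ties in significance are broken by (chromosome, position, snp_id) so
    the partition is invariant to SNP order.
    """
    pmap = {a.snp_id: (a.p if a.p is not None else 1.0) for a in assoc}
    meta = geno.snps.set_index("snp_id")
    order = sorted(
        meta.index,
        key=lambda s: (
            pmap.get(s, 1.0),
            str(meta.loc[s, "chrom"]),
            int(meta.loc[s, "pos"]),
            s,
        ),
    )
    col = {s: i for i, s in enumerate(geno.snps["snp_id"])}
    unassigned = set(meta.index)
    blocks = []
    for seed in order:
        if seed not in unassigned:
            continue
        members = [seed]
        unassigned.discard(seed)
        seed_dos = geno.dosage[:, col[seed]]
        for other in sorted(unassigned, key=lambda s: col[s]):
            r2 = ld_r2(seed_dos, geno.dosage[:, col[other]])
            if np.isfinite(r2) and r2 > r2_threshold:
                members.append(other)
        for m in members[1:]:
            unassigned.discard(m)
        blocks.append({"seed": seed, "members": members})
    return LDBlockSet(blocks=blocks, r2_threshold=r2_threshold)


def bonferroni_by_blocks(alpha: float = 0.05, n_blocks: int = 1) -> float:
    """Bonferroni threshold counting LD blocks rather than SNPs."""
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    return alpha / n_blocks


def se_from_or_p(odds_ratio: float, p: float) -> float:
    """Reconstruct the SE of log(OR) from a printed OR and two-sided P:
    SE = |ln OR| / Phi^-1(1 - P/2). Needed to meta-analyse published
    per-cohort summary rows."""
    if odds_ratio <= 0:
        raise ValueError("OR must be > 0")
    if odds_ratio == 1:
        raise ValueError("OR = 1 leaves z (hence SE) undefined")
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    return abs(np.log(odds_ratio)) / stats.norm.isf(p / 2)


def meta_analyze(
    effects: list[tuple[float, float]],
    model: str = "fixed",
    snp_id: str = "",
    reconstructed: list[bool] | None = None,
) -> MetaResult:
    """Inverse-variance meta-analysis of per-study (logOR, SE) pairs.

    Fixed effect: weights 1/SE^2, pooled SE = 1/sqrt(sum w). Random
    effects: DerSimonian-Laird tau^2 added to each study variance.
    Cochran's Q and I^2 are reported for both models.
    """
    if not effects:
        raise ValueError("empty study list")
    b = np.array([e[0] for e in effects], dtype=float)
    se = np.array([e[1] for e in effects], dtype=float)
    if (se <= 0).any():
        raise ValueError("SEs must be > 0")
    w = 1.0 / se**2
    b_fixed = (w * b).sum() / w.sum()
    q = float((w * (b - b_fixed) ** 2).sum())
    k = len(b)
    i2 = max(0.0, (q - (k - 1)) / q) * 100 if q > 0 and k > 1 else 0.0
    tau2 = 0.0
    if model == "random" and k > 1:
        c = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
        w = 1.0 / (se**2 + tau2)
    elif model not in ("fixed", "random"):
        raise ValueError(f"unknown model {model!r}")
    pooled = (w * b).sum() / w.sum()
    pooled_se = 1.0 / np.sqrt(w.sum())
    z = pooled / pooled_se
    return MetaResult(
        snp_id=snp_id,
        per_study=list(zip(b.tolist(), se.tolist())),
        pooled_log_or=float(pooled),
        pooled_se=float(pooled_se),
        pooled_or=float(np.exp(pooled)),
        z=float(z),
        p=float(2 * stats.norm.sf(abs(z))),
        q_statistic=q,
        i_squared=float(i2),
        tau_squared=float(tau2),
        model=model,
        reconstructed=reconstructed or [False] * k,
    )


def meta_from_or_p(
    rows: list[tuple[float, float]], model: str = "fixed", snp_id: str = ""
) -> MetaResult:
    """Meta-analysis straight from printed per-cohort (OR, P) pairs, with
    SEs reconstructed via :func:`se_from_or_p`."""
    effects = [(float(np.log(orv)), se_from_or_p(orv, p)) for orv, p in rows]
    return meta_analyze(effects, model=model, snp_id=snp_id,
                        reconstructed=[True] * len(rows))
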