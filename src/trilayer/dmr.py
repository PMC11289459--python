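"""Differentially methylated region (DMR) detection by bump hunting.

The procedure follows the classic array-DMR recipe: fit a per-probe linear
model of methylation beta on a case-group indicator with covariates
partialled out, cluster probes by genomic gap, call candidate regions as
runs of >= 2 consecutive probes whose coefficients jointly exceed a cutoff,
and control the family-wise error rate by resampling — here Freedman-Lane
residual permutation, which permutes the residuals of the covariate-only
model and re-runs the entire candidate pipeline on each null draw, scoring
each observed region against the null distribution of the maximum |area|.

Also provides the per-CpG replication test (exact Mann-Whitney U) and the
rank-based inverse-normal transform used for locus-specific scans.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import comb

from .containers import MethylationMatrix, PhenotypeTable
from .network import principal_components

__all__ = [
    "DesignMatrix",
    "DMRResult",
    "CpGTestResult",
    "design_from_phenotype",
    "beta_to_mvalues",
    "fit_probewise",
    "cluster_probes",
    "detect_bumps",
    "fwer_by_resampling",
    "mann_whitney_cpg",
    "rank_inverse_normal",
]


@dataclass
class DesignMatrix:
    """Full-rank design with an intercept, the case-group indicator of
    interest, and nuisance covariates."""

    matrix: np.ndarray        # n_samples x n_columns, first column intercept
    group_col: int            # index of the case-indicator column
    column_names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("design must be 2-D")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("design matrix is rank deficient")
        if self.matrix.shape[0] <= self.matrix.shape[1]:
            raise ValueError("fewer samples than design columns: no residual df")


def design_from_phenotype(
    pheno: PhenotypeTable,
    contrast: str = "PPMS",
    covariates: tuple[str, ...] = ("age", "sex", "smoking", "batch"),
    n_cell_pcs: int = 2,
    samples: list[str] | None = None,
) -> DesignMatrix:
    """Build the adjusted design: intercast + contrast indicator + named
    covariates + the first ``n_cell_pcs`` principal components of the
    cell-composition fractions (the usual surrogate for differential cell
    counts on blood arrays)."""
    tab = pheno.table if samples is None else pheno.table.loc[samples]
    cols = [np.ones(len(tab)), (tab["course"] == contrast).to_numpy(float)]
    names = ["intercept", f"group[{contrast}]"]
    for cov in covariates:
        cols.append(tab[cov].to_numpy(float))
        names.append(cov)
    if n_cell_pcs > 0 and pheno.cell_fraction_columns:
        fractions = tab[pheno.cell_fraction_columns].to_numpy(float)
        scores, _ = principal_components(fractions, k=n_cell_pcs)
        for i in range(n_cell_pcs):
            cols.append(scores[:, i])
            names.append(f"cellPC{i + 1}")
    return DesignMatrix(matrix=np.column_stack(cols), group_col=1,
                        column_names=names)


def beta_to_mvalues(beta: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """M-value transform log2(beta/(1-beta)), with betas clamped to
    [eps, 1-eps] first. The analysis runs on betas by default; pass the
    transformed matrix to :func:`fit_probewise` to model M-values instead
    (coefficients are then in M units, not delta-beta)."""
    b = np.clip(np.asarray(beta, dtype=float), eps, 1 - eps)
    return np.log2(b / (1 - b))


@dataclass
class DMRResult:
    chrom: str
    start: int                # 1-based position of first probe
    end: int                  # 1-based position of last probe
    n_probes: int
    probe_indices: list[int]
    coefficients: np.ndarray  # per-probe delta-beta estimates
    value: float              # mean coefficient
    area: float               # sum of |coefficients|
    fwer_p: float | None = None
    resamples: int | None = None

    def __post_init__(self) -> None:
        if self.n_probes < 2:
            raise ValueError("a reported region must contain at least 2 probes")
        if self.start > self.end:
            raise ValueError("region start after end")
        if self.fwer_p is not None and not 0 <= self.fwer_p <= 1:
            raise ValueError("fwer_p outside [0,1]")


@dataclass
class CpGTestResult:
    probe_id: str
    u_statistic: float
    p_value: float
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float


def fit_probewise(
    meth_or_beta, design: DesignMatrix
) -> pd.DataFrame:
    """Per-probe OLS of beta on the design; returns the group-indicator
    coefficient (delta-beta units), its SE and t for every probe.

    Vectorised over probes: with pseudo-inverse P = (X'X)^-1 X', the
    coefficient row is P[group] @ Y and the SE follows from the residual
    variance and the corresponding diagonal of (X'X)^-1.
    """
    if isinstance(meth_or_beta, MethylationMatrix):
        Y = meth_or_beta.beta
        probe_ids = list(meth_or_beta.probes["probe_id"])
    else:
        Y = np.asarray(meth_or_beta, dtype=float)
        probe_ids = [f"p{j}" for j in range(Y.shape[1])]
    X = design.matrix
    if Y.shape[0] != X.shape[0]:
        raise ValueError("design rows do not match number of samples")
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    pinv = xtx_inv @ X.T
    coefs_all = pinv @ Y                       # p x n_probes
    resid = Y - X @ coefs_all
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    g = design.group_col
    se = np.sqrt(sigma2 * xtx_inv[g, g])
    coef = coefs_all[g]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, 0.0)
    return pd.DataFrame(
        {"probe_id": probe_ids, "coef": coef, "se": se, "t": t,
         "p": 2 * stats.t.sf(np.abs(t), dof)}
    )


def cluster_probes(
    positions, chroms=None, max_gap: int = 500
) -> list[np.ndarray]:
    """Maximal runs of consecutive probes with inter-probe gap <= max_gap,
    split by chromosome. Returns lists of probe indices."""
    positions = np.asarray(positions)
    if chroms is None:
        chroms = np.zeros(len(positions))
    chroms = np.asarray(chroms)
    clusters: list[np.ndarray] = []
    order = np.arange(len(positions))
    for chrom in pd.unique(chroms):
        idx = order[chroms == chrom]
        pos = positions[chroms == chrom]
        if np.any(np.diff(pos) < 0):
            raise ValueError("positions must be sorted within chromosome")
        if len(idx) == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > max_gap) + 1
        for chunk in np.split(idx, breaks):
            clusters.append(chunk)
    return clusters


def _smooth(values: np.ndarray, k: int) -> np.ndarray:
    if k <= 1 or len(values) < k:
        return values
    kernel = np.ones(k) / k
    sm = np.convolve(values, kernel, mode="same")
    # renormalise the edges where the window is truncated
    norm = np.convolve(np.ones_like(values), kernel, mode="same")
    return sm / norm


def detect_bumps(
    coefficients: np.ndarray,
    clusters: list[np.ndarray],
    cutoff: float | None = None,
    cutoff_quantile: float = 0.975,
    smooth_k: int = 1,
) -> list[dict]:
    """Candidate regions: within each probe cluster, maximal runs of >= 2
    probes whose (optionally running-mean smoothed) coefficients all exceed
    +cutoff or all fall below -cutoff.

    With ``cutoff=None`` the cutoff is the ``cutoff_quantile`` quantile of
    |coefficients| over all probes in this run — sensible when planted
    effects occupy a small fraction of the probe set, as on a genome-scale
    array.
    """
    coefficients = np.asarray(coefficients, dtype=float)
    if cutoff is None:
        cutoff = float(np.quantile(np.abs(coefficients), cutoff_quantile))
    regions = []
    for cluster in clusters:
        vals = coefficients[cluster]
        if smooth_k > 1:
            vals = _smooth(vals, smooth_k)
        sign = np.where(vals > cutoff, 1, np.where(vals < -cutoff, -1, 0))
        start = 0
        while start < len(sign):
            if sign[start] == 0:
                start += 1
                continue
            stop = start
            while stop + 1 < len(sign) and sign[stop + 1] == sign[start]:
                stop += 1
            if stop - start + 1 >= 2:
                run = cluster[start : stop + 1]
                regions.append(
                    {
                        "probe_indices": run,
                        "coefficients": coefficients[run],
                        "value": float(coefficients[run].mean()),
                        "area": float(np.abs(coefficients[run]).sum()),
                        "direction": int(sign[start]),
                    }
                )
            start = stop + 1
    return regions


def fwer_by_resampling(
    meth: MethylationMatrix,
    design: DesignMatrix,
    B: int = 1000,
    cutoff: float | None = None,
    cutoff_quantile: float = 0.975,
    max_gap: int = 500,
    smooth_k: int = 1,
    seed: int | None = None,
) -> list[DMRResult]:
    """Full bump-hunting run with resampling FWER control.

    Candidate regions are found on the observed data; for each of B
    Freedman-Lane resamples, residuals of the covariate-only (reduced)
    model are permuted, re-added to its fitted values, and the whole
    candidate pipeline (probe fits, cutoff, run detection) re-run to record
    the maximum |area| under the null. Each observed region's
    ``fwer_p = (1 + #{null max |area| >= observed |area|}) / (B + 1)``.
    """
    if B < 100:
        raise ValueError("B < 100 gives too coarse a FWER resolution")
    rng = np.random.default_rng(seed)
    X = design.matrix
    Y = meth.beta
    n = Y.shape[0]

    clusters = cluster_probes(
        meth.probes["pos"].to_numpy(), meth.probes["chrom"].to_numpy(), max_gap
    )
    fit = fit_probewise(meth, design)
    coefs = fit["coef"].to_numpy()
    candidates = detect_bumps(coefs, clusters, cutoff, cutoff_quantile, smooth_k)

    # reduced model: everything but the group column
    keep = [j for j in range(X.shape[1]) if j != design.group_col]
    Xr = X[:, keep]
    beta_r = np.linalg.lstsq(Xr, Y, rcond=None)[0]
    fitted = Xr @ beta_r
    resid = Y - fitted

    g = design.group_col
    xtx_inv = np.linalg.inv(X.T @ X)
    h = (xtx_inv @ X.T)[g]  # 1 x n row extracting the group coefficient

    null_max = np.empty(B)
    for b in range(B):
        perm = rng.permutation(n)
        coefs_b = h @ (fitted + resid[perm])
        regs = detect_bumps(coefs_b, clusters, cutoff, cutoff_quantile, smooth_k)
        null_max[b] = max((r["area"] for r in regs), default=0.0)

    results = []
    positions = meth.probes["pos"].to_numpy()
    chroms = meth.probes["chrom"].to_numpy()
    for cand in candidates:
        run = cand["probe_indices"]
        exceed = int(np.sum(null_max >= cand["area"]))
        results.append(
            DMRResult(
                chrom=str(chroms[run[0]]),
                start=int(positions[run[0]]),
                end=int(positions[run[-1]]),
                n_probes=len(run),
                probe_indices=[int(i) for i in run],
                coefficients=cand["coefficients"],
                value=cand["value"],
                area=cand["area"],
                fwer_p=(1 + exceed) / (B + 1),
                resamples=B,
            )
        )
    results.sort(key=lambda r: (r.fwer_p, -r.area))
    return results


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U for group a (ties counted half)."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt + 0.5 * eq)


def mann_whitney_cpg(
    group_a, group_b, probe_id: str = "", exact_limit: int = 400
) -> CpGTestResult:
    """Two-sided Mann-Whitney U test for one CpG.

    Exact p by full enumeration of all C(n1+n2, n1) group assignments when
    n1*n2 <= ``exact_limit`` (valid under ties); otherwise the tie-corrected
    normal approximation with continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(a), len(b)
    u_obs = _u_statistic(a, b)
    mu = n1 * n2 / 2.0
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < n1 + n2
    n_arrangements = comb(n1 + n2, n1, exact=True)

    if n1 * n2 <= exact_limit and not has_ties:
        # no ties: the exact null U distribution; two-sided by symmetry
        p = float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        )
    elif n1 * n2 <= exact_limit and n_arrangements <= 300_000:
        # ties present: enumerate every group assignment of the pooled values
        dev_obs = abs(u_obs - mu)
        extreme = 0
        for combo in combinations(range(n1 + n2), n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(combo)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            if abs(u - mu) >= dev_obs - 1e-12:
                extreme += 1
        p = extreme / n_arrangements
    else:
        n = n1 + n2
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
        var = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if var == 0:
            p = 1.0
        else:
            z = (abs(u_obs - mu) - 0.5) / np.sqrt(var)
            p = min(1.0, 2 * stats.norm.sf(max(z, 0.0)))

    return CpGTestResult(
        probe_id=probe_id,
        u_statistic=u_obs,
        p_value=p,
        mean_a=float(a.mean()),
        sem_a=float(a.std(ddof=1) / np.sqrt(n1)) if n1 > 1 else 0.0,
        mean_b=float(b.mean()),
        sem_b=float(b.std(ddof=1) / np.sqrt(n2)) if n2 > 1 else 0.0,
    )


def rank_inverse_normal(values, c: float = 0.5) -> np.ndarray:
    """Rank-based inverse-normal transform: value_i -> Phi^-1((r_i - c)/n)
    with average ranks for ties (Blom-family offset, default c = 0.5)."""
    values = np.asarray(values, dtype=float)
    if np.unique(values).size < 2:
        raise ValueError("need at least 2 distinct values to rank-transform")
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - c) / len(values))
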