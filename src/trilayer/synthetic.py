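"""Synthetic genotype / methylation / expression / phenotype generator.

Emulates the causal structure the downstream analyses assume:

* LD-blocked genotypes, generated haplotype-wise so dosage correlation
  (r-squared) arises mechanistically from within-block haplotype copying;
* tri-modal, genotype-controlled CpG methylation plus one planted
  case-specific hypermethylated region (a run of consecutive probes with a
  group mean-beta shift, default delta-beta 0.24 over 8 probes);
* methylation-repressed gene expression with planted trait-correlated
  co-expression modules driven by shared latent factors;
* a logistic disease-course phenotype (case vs bout-onset control) driven
  by per-allele odds ratios at risk SNPs.

Every dataset carries a :class:`GroundTruth` record sufficient to score
region recovery, QTL effect recovery, odds-ratio recovery and module
membership downstream. All randomness flows from ``SimConfig.seed`` through
named per-layer substreams, so identical configs give identical data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .containers import (
    ExpressionMatrix,
    GenotypeMatrix,
    MethylationMatrix,
    PhenotypeTable,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimulatedStudy",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_methylation",
    "simulate_expression",
    "simulate_study",
]

BETA_CLIP = (0.001, 0.999)


@dataclass
class SimConfig:
    """All knobs of the generator; defaults emulate the study's structure
    at desk scale (a planted 8-probe region with delta-beta 0.24, tri-modal
    CpG levels 0.2/0.5/0.8, a rare-case disease-course contrast)."""

    # cohort sizes
    n_ppms: int = 60
    n_boms: int = 120
    n_hc: int = 60

    # genotype layer
    n_snps: int = 60
    ld_blocks: list[tuple[int, float]] = field(
        default_factory=lambda: [(6, 0.95)] * 10
    )
    maf_range: tuple[float, float] = (0.1, 0.5)
    genotype_missing_rate: float = 0.0

    # methylation layer
    n_cpgs: int = 500
    cpg_spacing: int = 300           # bp between consecutive probes
    cpg_cluster_every: int = 25      # insert a large gap every k probes
    cpg_cluster_gap: int = 10_000
    cpg_chrom: str = "1"
    cpg_start: int = 146_500_000
    meqtl_targets: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(0, 40, 0.3), (6, 45, 0.3), (12, 50, -0.2)]
    )
    dmr_spec: tuple[tuple[int, int], float] = ((100, 108), 0.24)
    tri_modal_levels: tuple[float, float, float] = (0.2, 0.5, 0.8)
    noise_sd_meth: float = 0.03
    meth_noise_scale: str = "beta"  # "beta" (additive, clipped) or "logit"

    # phenotype layer
    risk_snps: list[tuple[int, float]] = field(
        default_factory=lambda: [(0, 1.8), (18, 0.7)]
    )
    covariate_confounding: bool = False
    n_cell_types: int = 5
    n_ancestry_pcs: int = 2

    # expression layer
    n_genes: int = 200
    planted_modules: list[tuple[list[int], float, str | None]] = field(
        default_factory=lambda: [
            (list(range(0, 50)), 0.7, "PPMS"),
            (list(range(50, 100)), 0.7, None),
        ]
    )
    meth_to_expr: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(40, 0, -2.0), (45, 1, -2.0)]
    )
    module_between_rho: float = 0.0   # shared-background correlation between modules
    trait_latent_shift: float = 1.0
    noise_sd_expr: float = 1.0

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_ppms", "n_boms", "n_hc", "n_snps", "n_cpgs", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        a, b, c = self.tri_modal_levels
        if not (0 < a < b < c < 1):
            raise ValueError("tri_modal_levels must be strictly increasing in (0,1)")
        (start, stop), _ = self.dmr_spec
        if stop - start < 2:
            raise ValueError("dmr_spec must span at least 2 probes")
        if not (0 <= start < stop <= self.n_cpgs):
            raise ValueError("dmr_spec probe range out of bounds")
        for snp, odds in self.risk_snps:
            if odds <= 0:
                raise ValueError(f"odds ratio must be > 0 (snp {snp}: {odds})")
            if not 0 <= snp < self.n_snps:
                raise ValueError(f"risk SNP index {snp} out of bounds")
        for snp, cpg, _ in self.meqtl_targets:
            if not (0 <= snp < self.n_snps and 0 <= cpg < self.n_cpgs):
                raise ValueError(f"meQTL target ({snp},{cpg}) out of bounds")
        for genes, rho, _trait in self.planted_modules:
            if not genes:
                raise ValueError("planted module with empty gene set")
            if any(g < 0 or g >= self.n_genes for g in genes):
                raise ValueError("planted module gene index out of bounds")
            if not 0 <= rho < 1:
                raise ValueError("module latent correlation must be in [0,1)")
        for cpg, gene, _ in self.meth_to_expr:
            if not (0 <= cpg < self.n_cpgs and 0 <= gene < self.n_genes):
                raise ValueError(f"meth_to_expr link ({cpg},{gene}) out of bounds")
        if self.meth_noise_scale not in ("beta", "logit"):
            raise ValueError("meth_noise_scale must be 'beta' or 'logit'")

    @property
    def n_samples(self) -> int:
        return self.n_ppms + self.n_boms + self.n_hc


def _layer_rng(config: SimConfig, layer: str) -> np.random.Generator:
    salt = {"genotype": 1, "phenotype": 2, "methylation": 3, "expression": 4}[layer]
    return np.random.default_rng([config.seed, salt])


@dataclass
class GroundTruth:
    """True planted effects, stored alongside every simulated dataset."""

    dmr: dict = field(default_factory=dict)       # chrom/start/end/probe indices/delta
    meqtl: list = field(default_factory=list)     # (snp_id, probe_id, beta per allele)
    risk_snps: list = field(default_factory=list) # (snp_id, odds ratio)
    modules: dict = field(default_factory=dict)   # module name -> {genes, rho, trait}
    meth_to_expr: list = field(default_factory=list)  # (probe_id, gene_id, slope)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw LD-blocked dosages haplotype-wise.

    Each block has an anchor SNP whose two haplotypes are Bernoulli(maf);
    every other SNP in the block copies the anchor haplotype with the
    block's copy probability and is redrawn at the same maf otherwise, so
    within-block dosage r-squared approaches the squared copy probability.
    """
    sizes = [s for s, _ in config.ld_blocks]
    if sum(sizes) != config.n_snps:
        raise ValueError(
            f"LD block sizes sum to {sum(sizes)}, expected n_snps={config.n_snps}"
        )
    rng = _layer_rng(config, "genotype")
    n = config.n_samples
    lo, hi = config.maf_range

    dosage = np.empty((n, config.n_snps))
    mafs = np.empty(config.n_snps)
    col = 0
    for size, copy_p in config.ld_blocks:
        if not 0 <= copy_p <= 1:
            raise ValueError("copy probability must be in [0,1]")
        maf = rng.uniform(lo, hi)
        anchor = rng.random((n, 2)) < maf  # two haplotypes per sample
        for k in range(size):
            if k == 0:
                hap = anchor
            else:
                keep = rng.random((n, 2)) < copy_p
                fresh = rng.random((n, 2)) < maf
                hap = np.where(keep, anchor, fresh)
            dosage[:, col] = hap.sum(axis=1)
            mafs[col] = maf
            col += 1

    if config.genotype_missing_rate > 0:
        miss = rng.random(dosage.shape) < config.genotype_missing_rate
        dosage[miss] = np.nan

    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{i:04d}" for i in range(config.n_snps)],
            "chrom": config.cpg_chrom,
            "pos": config.cpg_start - 500_000 + 2_000 * np.arange(config.n_snps),
            "effect_allele": "A",
            "other_allele": "G",
            "maf": mafs,
        }
    )
    sample_ids = [f"S{i:04d}" for i in range(n)]
    return GenotypeMatrix(dosage=dosage, snps=snps, sample_ids=sample_ids)


def _calibrate_intercept(linpred: np.ndarray, target: float) -> float:
    """Intercept c such that mean(sigmoid(c + linpred)) == target."""
    f = lambda c: expit(c + linpred).mean() - target
    return brentq(f, -30, 30)


def simulate_phenotype(geno: GenotypeMatrix, config: SimConfig) -> PhenotypeTable:
    """Draw disease-course labels from a logistic model on risk-SNP dosages.

    The first ``n_ppms + n_boms`` samples form the case-control cohort
    (case = progressive course, control = bout-onset); the remaining
    ``n_hc`` samples are labelled HC and excluded from the disease draw.
    The intercept is calibrated so the expected case fraction equals
    ``n_ppms / (n_ppms + n_boms)``.
    """
    rng = _layer_rng(config, "phenotype")
    n = geno.n_samples
    n_cc = config.n_ppms + config.n_boms

    logodds = np.zeros(n_cc)
    dos = np.nan_to_num(geno.dosage[:n_cc], nan=0.0)
    for snp, odds in config.risk_snps:
        logodds += np.log(odds) * dos[:, snp]
    target = config.n_ppms / n_cc
    intercept = _calibrate_intercept(logodds, target)
    p_case = expit(intercept + logodds)
    is_case = rng.random(n_cc) < p_case

    course = np.array(["HC"] * n, dtype=object)
    course[:n_cc] = np.where(is_case, "PPMS", "BOMS")

    age = rng.normal(45, 10, n)
    sex = rng.integers(0, 2, n)
    smoking = rng.integers(0, 2, n)
    batch = rng.integers(0, 2, n)
    cells = rng.dirichlet(np.ones(config.n_cell_types) * 5, size=n)
    anc = rng.normal(0, 1, (n, config.n_ancestry_pcs))
    if config.covariate_confounding:
        # age and smoking drift with the risk burden; lets adjustment be tested
        burden = np.zeros(n)
        burden[:n_cc] = logodds
        age = age + 2.0 * burden
        smoking = (rng.random(n) < expit(-0.4 + 0.5 * burden)).astype(int)

    cell_cols = [f"cell_{i}" for i in range(config.n_cell_types)]
    table = pd.DataFrame(
        {
            "course": course,
            "age": age,
            "sex": sex,
            "smoking": smoking,
            "batch": batch,
            **{c: cells[:, i] for i, c in enumerate(cell_cols)},
            **{f"ancPC{i + 1}": anc[:, i] for i in range(config.n_ancestry_pcs)},
        },
        index=pd.Index(geno.sample_ids, name="sample_id"),
    )
    return PhenotypeTable(table=table, case_label="PPMS",
                          cell_fraction_columns=cell_cols)


def _cpg_positions(config: SimConfig) -> np.ndarray:
    steps = np.full(config.n_cpgs, config.cpg_spacing, dtype=np.int64)
    steps[:: config.cpg_cluster_every] = config.cpg_cluster_gap
    steps[0] = 0
    return config.cpg_start + np.cumsum(steps)


def simulate_methylation(
    geno: GenotypeMatrix, pheno: PhenotypeTable, config: SimConfig
) -> tuple[MethylationMatrix, GroundTruth]:
    """Beta values = base level + dosage*shift at meQTL CpGs + case-group
    delta-beta over the planted region + Gaussian noise, clipped to (0,1).

    Full-strength meQTL targets (base = lowest tri-modal level, shift =
    half the level span) land the dosage-0/1/2 group means on the three
    tri-modal levels.
    """
    rng = _layer_rng(config, "methylation")
    n, m = geno.n_samples, config.n_cpgs
    low, mid, high = config.tri_modal_levels

    base = rng.uniform(low, high, m)
    signal = np.tile(base, (n, 1))

    truth = GroundTruth()
    dos = np.nan_to_num(geno.dosage, nan=0.0)
    for snp, cpg, shift in config.meqtl_targets:
        signal[:, cpg] = low if shift > 0 else high
        signal[:, cpg] += dos[:, snp] * shift
        truth.meqtl.append(
            (geno.snps["snp_id"].iloc[snp], f"cg{cpg:05d}", float(shift))
        )

    (start, stop), delta = config.dmr_spec
    # keep the planted region's shifted group mean inside (0,1)
    if delta >= 0:
        signal[:, start:stop] = np.minimum(signal[:, start:stop], 0.95 - delta)
    else:
        signal[:, start:stop] = np.maximum(signal[:, start:stop], 0.05 - delta)
    case = pheno.table["case"].to_numpy(dtype=bool)
    signal[np.ix_(case, np.arange(start, stop))] += delta

    if ((signal < 0) | (signal > 1)).any():
        raise ValueError("configured group means fall outside (0,1) before noise")

    noise = rng.normal(0, config.noise_sd_meth, (n, m))
    if config.meth_noise_scale == "logit":
        # perturb on the logit scale: stays in (0,1) without clipping
        logit = np.log(signal / (1 - signal))
        beta = expit(logit + noise)
    else:
        beta = signal + noise
    beta = np.clip(beta, *BETA_CLIP)

    positions = _cpg_positions(config)
    probes = pd.DataFrame(
        {
            "probe_id": [f"cg{j:05d}" for j in range(m)],
            "chrom": config.cpg_chrom,
            "pos": positions,
        }
    )
    truth.dmr = {
        "chrom": config.cpg_chrom,
        "start": int(positions[start]),
        "end": int(positions[stop - 1]),
        "probe_start": start,
        "probe_stop": stop,
        "delta_beta": float(delta),
    }
    truth.risk_snps = [
        (geno.snps["snp_id"].iloc[s], float(o)) for s, o in config.risk_snps
    ]
    meth = MethylationMatrix(beta=beta, probes=probes, sample_ids=geno.sample_ids)
    return meth, truth


def simulate_expression(
    meth: MethylationMatrix,
    pheno: PhenotypeTable,
    config: SimConfig,
    truth: GroundTruth | None = None,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Log-scale expression with methylation-linked genes and planted
    latent-factor co-expression modules.

    Module genes load on a shared standard-normal factor with loading
    sqrt(rho), so the expected within-module pairwise correlation is rho;
    a trait-coupled factor is shifted by ``trait_latent_shift`` SD in the
    coupled trait's samples.
    """
    rng = _layer_rng(config, "expression")
    truth = truth if truth is not None else GroundTruth()
    n = meth.n_samples
    g = config.n_genes

    baseline = rng.normal(6, 1, g)
    z = rng.normal(0, 1, (g, n))
    expr = baseline[:, None] + config.noise_sd_expr * z

    background = rng.normal(0, 1, n)
    b = config.module_between_rho
    for idx, (genes, rho, trait) in enumerate(config.planted_modules):
        if b > rho:
            raise ValueError("module_between_rho cannot exceed within-module rho")
        factor = rng.normal(0, 1, n)
        if trait is not None:
            factor = factor + config.trait_latent_shift * pheno.indicator(trait)
        latent = np.sqrt(b) * background + np.sqrt(rho - b) * factor
        resid = np.sqrt(1 - rho)
        sub = rng.normal(0, 1, (len(genes), n))
        expr[genes, :] = (
            baseline[genes][:, None]
            + config.noise_sd_expr * (latent[None, :] + resid * sub)
        )
        truth.modules[f"module_{idx}"] = {
            "genes": [f"gene{j:04d}" for j in genes],
            "rho": float(rho),
            "trait": trait,
        }

    for cpg, gene, slope in config.meth_to_expr:
        expr[gene, :] += slope * meth.beta[:, cpg]
        truth.meth_to_expr.append(
            (meth.probes["probe_id"].iloc[cpg], f"gene{gene:04d}", float(slope))
        )

    mat = ExpressionMatrix(
        values=expr,
        gene_ids=[f"gene{j:04d}" for j in range(g)],
        sample_ids=meth.sample_ids,
    )
    return mat, truth


@dataclass
class SimulatedStudy:
    """One fully simulated study: all four layers plus ground truth."""

    config: SimConfig
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    methylation: MethylationMatrix
    expression: ExpressionMatrix
    truth: GroundTruth


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Generate the four layers in causal order under one seed."""
    geno = simulate_genotypes(config)
    pheno = simulate_phenotype(geno, config)
    meth, truth = simulate_methylation(geno, pheno, config)
    expr, truth = simulate_expression(meth, pheno, config, truth)
    return SimulatedStudy(
        config=config,
        genotypes=geno,
        phenotypes=pheno,
        methylation=meth,
        expression=expr,
        truth=truth,
    )
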