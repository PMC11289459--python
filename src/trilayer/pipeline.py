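"""Seeded end-to-end orchestration of the trilayer analysis.

``run_pipeline`` executes the stages in dependency order on a simulated
study — simulate -> dmr -> qc/assoc -> meta (per-batch strata) -> meqtl ->
triage -> network — writing every result table as TSV plus a manifest
(parameters, seed, per-output SHA-256 hashes). A fixed seed gives
bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("trilayer.pipeline")

from . import dmr as dmr_mod
from . import genetics, network, qtl
from .io import write_matrix, write_regions_bed
from .synthetic import SimConfig, simulate_study

__all__ = ["RunConfig", "run_pipeline"]

_STAGES = ("simulate", "dmr", "assoc", "meta", "meqtl", "triage", "network")


@dataclasses.dataclass
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    stages: tuple[str, ...] = _STAGES
    dmr_B: int = 200
    dmr_max_gap: int = 500
    dmr_cutoff: float | None = None
    network_B: int = 100
    network_fdr: float = 0.05
    module_min_size: int = 10
    r2_threshold: float = 0.8
    seed: int = 0
    out_dir: str = "trilayer_run"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        deps = {"meta": {"assoc"}, "triage": {"assoc", "meqtl"}}
        for stage, needed in deps.items():
            if stage in self.stages and not needed <= set(self.stages):
                missing = sorted(needed - set(self.stages))
                raise ValueError(
                    f"stage '{stage}' requires upstream stage(s) {missing}"
                )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        sim_raw = raw.pop("sim", {})
        sim_known = {f.name for f in dataclasses.fields(SimConfig)}
        sim_unknown = set(sim_raw) - sim_known
        if sim_unknown:
            raise ValueError(f"unknown sim config keys {sorted(sim_unknown)}")
        # YAML gives lists where the dataclass wants tuples
        for key in ("ld_blocks", "meqtl_targets", "risk_snps",
                    "planted_modules", "meth_to_expr"):
            if key in sim_raw:
                sim_raw[key] = [tuple(x) for x in sim_raw[key]]
        for key in ("maf_range", "tri_modal_levels"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        if "dmr_spec" in sim_raw:
            rng_, delta = sim_raw["dmr_spec"]
            sim_raw["dmr_spec"] = (tuple(rng_), float(delta))
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(sim=SimConfig(**sim_raw), **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _param_hash(config: RunConfig) -> str:
    params = dataclasses.asdict(config)
    params.pop("out_dir", None)  # identical analyses hash equal regardless of destination
    blob = json.dumps(params, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> Path:
    """Run the requested stages; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
    header = f"trilayer run seed={config.seed} params={_param_hash(config)}"

    def write_table(df: pd.DataFrame, name: str) -> None:
        path = out / name
        with open(path, "w") as fh:
            fh.write(f"# {header}\n")
            df.to_csv(fh, sep="\t", index=False)
        outputs[name] = path

    t0 = time.perf_counter()
    study = simulate_study(sim_cfg)
    logger.info("stage=simulate elapsed=%.2fs samples=%d snps=%d cpgs=%d genes=%d",
                time.perf_counter() - t0, study.genotypes.n_samples,
                study.genotypes.n_snps, study.methylation.n_probes,
                study.expression.n_genes)
    outputs: dict[str, Path] = {}

    if "simulate" in config.stages:
        for name, obj in (
            ("genotypes.tsv", study.genotypes),
            ("methylation.tsv", study.methylation),
            ("expression.tsv", study.expression),
            ("phenotypes.tsv", study.phenotypes),
        ):
            write_matrix(obj, out / name, header_comment=header)
            outputs[name] = out / name
        study.truth.to_json(out / "ground_truth.json")
        outputs["ground_truth.json"] = out / "ground_truth.json"

    design = dmr_mod.design_from_phenotype(study.phenotypes, contrast="PPMS")

    if "dmr" in config.stages:
        dmrs = dmr_mod.fwer_by_resampling(
            study.methylation,
            design,
            B=config.dmr_B,
            cutoff=config.dmr_cutoff,
            max_gap=config.dmr_max_gap,
            seed=config.seed + 1,
        )
        df = pd.DataFrame(
            [
                {
                    "chrom": d.chrom,
                    "start": d.start,
                    "end": d.end,
                    "n_probes": d.n_probes,
                    "value": d.value,
                    "area": d.area,
                    "fwer_p": d.fwer_p,
                }
                for d in dmrs
            ],
            columns=["chrom", "start", "end", "n_probes", "value", "area",
                     "fwer_p"],
        )
        write_table(df, "dmr.tsv")
        logger.info("stage=dmr regions=%d significant=%d",
                    len(dmrs), sum(d.fwer_p < 0.05 for d in dmrs))
        if dmrs:
            write_regions_bed(dmrs, out / "dmr.bed")
            outputs["dmr.bed"] = out / "dmr.bed"

    cc = study.phenotypes.table["course"].isin(["PPMS", "BOMS"]).to_numpy()
    pheno_cc = study.phenotypes.table[cc]
    geno_cc = genetics.GenotypeMatrix(
        dosage=study.genotypes.dosage[cc],
        snps=study.genotypes.snps.copy(),
        sample_ids=list(np.array(study.genotypes.sample_ids)[cc]),
    )
    y = pheno_cc["case"].to_numpy(float)
    covs = pheno_cc[["age", "sex"]].to_numpy(float)

    assoc = None
    if "assoc" in config.stages or "meta" in config.stages or "triage" in config.stages:
        geno_qc, report = genetics.filter_call_rate(geno_cc)
        write_table(report, "snp_qc.tsv")
        assoc = genetics.logistic_assoc(geno_qc, y, covs)
        write_table(pd.DataFrame([dataclasses.asdict(a) for a in assoc]),
                    "assoc.tsv")
        blocks = genetics.cluster_ld_blocks(geno_qc, assoc, config.r2_threshold)
        write_table(
            pd.DataFrame(
                [
                    {"block": i, "seed": b["seed"],
                     "members": ",".join(b["members"])}
                    for i, b in enumerate(blocks.blocks)
                ]
            ),
            "ld_blocks.tsv",
        )
        logger.info("stage=assoc snps_in=%d snps_tested=%d blocks=%d",
                    geno_cc.n_snps, geno_qc.n_snps, blocks.n_blocks)
        threshold = genetics.bonferroni_by_blocks(0.05, blocks.n_blocks)
        (out / "bonferroni.json").write_text(
            json.dumps({"n_blocks": blocks.n_blocks, "threshold": threshold})
        )
        outputs["bonferroni.json"] = out / "bonferroni.json"

    if "meta" in config.stages:
        # per-batch strata, pooled by fixed-effect inverse variance
        metas = []
        strata = [pheno_cc["batch"].to_numpy() == b
                  for b in np.unique(pheno_cc["batch"])]
        for j, snp_id in enumerate(geno_qc.snps["snp_id"]):
            effects = []
            for mask in strata:
                sub = genetics.GenotypeMatrix(
                    dosage=geno_qc.dosage[mask][:, [j]],
                    snps=geno_qc.snps.iloc[[j]],
                    sample_ids=list(np.array(geno_qc.sample_ids)[mask]),
                )
                try:
                    res = genetics.logistic_assoc(sub, y[mask], covs[mask])[0]
                except ValueError:
                    continue
                if res.converged:
                    effects.append((res.beta, res.se))
            if len(effects) >= 1:
                m = genetics.meta_analyze(effects, snp_id=snp_id)
                metas.append(
                    {"snp_id": snp_id, "pooled_or": m.pooled_or, "p": m.p,
                     "q": m.q_statistic, "i2": m.i_squared}
                )
        write_table(pd.DataFrame(metas), "meta.tsv")
        logger.info("stage=meta snps_pooled=%d strata=%d",
                    len(metas), len(strata))

    meqtl_res = None
    if "meqtl" in config.stages or "triage" in config.stages:
        (dmr_range, _) = sim_cfg.dmr_spec
        probe_ids = [
            study.methylation.probes["probe_id"].iloc[j]
            for j in range(dmr_range[0], dmr_range[1])
        ]
        pairs = [(s, p) for s in study.genotypes.snps["snp_id"] for p in probe_ids]
        meqtl_res = qtl.linear_qtl_scan(study.genotypes, study.methylation,
                                        pairs=pairs)
        write_table(pd.DataFrame([dataclasses.asdict(r) for r in meqtl_res]),
                    "meqtl.tsv")
        logger.info("stage=meqtl pairs_tested=%d", len(meqtl_res))

    if "triage" in config.stages:
        external = [
            qtl.ExternalQTLRecord(
                snp_id=snp_id, feature_id=gene_id, source="synthetic-annotation",
                effect_sign="-" if slope < 0 else "+",
            )
            for probe_id, gene_id, slope in study.truth.meth_to_expr
            for snp_id, target_probe, _ in study.truth.meqtl
            if probe_id == target_probe
        ]
        records, counts = qtl.concordance_triage(assoc, meqtl_res, external)
        write_table(pd.DataFrame([dataclasses.asdict(r) for r in records]),
                    "triage.tsv")
        (out / "triage_counts.json").write_text(json.dumps(counts))
        outputs["triage_counts.json"] = out / "triage_counts.json"
        logger.info("stage=triage records=%d counts=%s", len(records), counts)

    if "network" in config.stages:
        net = network.permutation_edge_filter(
            study.expression, B=config.network_B,
            q_threshold=config.network_fdr, seed=config.seed + 2
        )
        pmfg = network.build_pmfg(net)
        tree = network.multiscale_cluster(
            pmfg, min_size=config.module_min_size, seed=config.seed + 3
        )
        traits = {
            "PPMS": study.phenotypes.indicator("PPMS"),
            "BOMS": study.phenotypes.indicator("BOMS"),
        }
        mt = network.module_trait_association(
            tree, study.expression, traits, node_gene_ids=pmfg.nodes
        )
        edge_df = pmfg.edges.copy()
        edge_df["gene_i"] = [pmfg.nodes[i] for i in edge_df["i"]]
        edge_df["gene_j"] = [pmfg.nodes[j] for j in edge_df["j"]]
        write_table(edge_df, "pmfg_edges.tsv")
        members = [
            {"gene": pmfg.nodes[g], "module": leaf.module_id}
            for leaf in tree.leaves()
            for g in leaf.members
        ]
        write_table(pd.DataFrame(members), "modules.tsv")
        write_table(pd.DataFrame([dataclasses.asdict(r) for r in mt]),
                    "module_trait.tsv")
        logger.info("stage=network edges=%d modules=%d significant=%d",
                    len(pmfg.edges), len(tree.leaves()),
                    sum(r.significant for r in mt))

    manifest = {
        "seed": config.seed,
        "stages": list(config.stages),
        "sim": {k: v for k, v in dataclasses.asdict(sim_cfg).items()},
        "outputs": {name: _sha256(p) for name, p in sorted(outputs.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out
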