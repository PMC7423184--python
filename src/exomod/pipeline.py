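"""End-to-end orchestration: simulate -> prioritize -> burden ->
differentiate -> skato -> enrich, from one validated YAML config.

Every tunable of the analysis (consensus 17/21, 40 kb flank, 0.9
missingness cutoff, adaptive 1/sqrt(2n) MAF rule, rho grid, permutation
count, alpha and the 0.017 adjusted level) surfaces as a named config key
with the study value as default.  Unknown keys are rejected before any
compute.  A manifest records config hash, per-stage seeds, input/output
checksums and row counts; re-running an identical config reproduces
byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from typing import Literal

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from ._rng import derive_seed
from .burden import burden_table
from .datatypes import GROUPS
from .differentiation import DiffConfig, run_differentiation
from .enrichment import GeneSetCollection, hypergeometric_enrichment
from .io import (
    assign_variants_to_genes,
    read_annotation,
    read_cohort_table,
    read_gene_bed,
    read_vcf,
    write_results_table,
)
from .prioritize import FilterCriteria, prioritize, siphy_gene_table
from .simulate import (
    DEFAULT_GROUP_SIZES,
    NeSchedule,
    PredictorModel,
    SimConfig,
    simulate_cohort,
    write_cohort,
)
from .skat import SkatConfig, run_contrasts

logger = logging.getLogger(__name__)

_strict = ConfigDict(extra="forbid")


class PlantedDiff(BaseModel):
    model_config = _strict
    groups: tuple[str, str]
    delta: float


class SimulateSection(BaseModel):
    model_config = _strict
    n_per_group: dict[str, int] = Field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_genes: int = 30
    variants_per_gene: tuple[int, int] = (10, 200)
    theta: float = 60.0
    ne_epochs: list[tuple[int, int]] = Field(default_factory=lambda: [(1, 1_000_000)])
    planted_burden: dict[str, float] = Field(default_factory=dict)
    planted_diff: dict[str, PlantedDiff] = Field(default_factory=dict)
    sensitivity: float = 0.95
    specificity: float = 0.95
    predictor_correlation: float = 0.3
    p_deleterious: float = 0.05
    missing_rate: float = 0.02
    gene_length_range: tuple[int, int] = (2_000, 20_000)
    freq_grid_haploids: int = 2_000
    gmt_sets: int = 6


class PrioritizeSection(BaseModel):
    model_config = _strict
    min_damaging: int = 17
    max_pop_freq: float = 0.01
    allowed_func_classes: list[str] = Field(
        default_factory=lambda: ["nonsynonymous", "stopgain", "stoploss"]
    )
    siphy_aggregation: Literal["stouffer", "sum"] = "stouffer"


class BurdenSection(BaseModel):
    model_config = _strict
    alpha: float = 0.05


class DifferentiateSection(BaseModel):
    model_config = _strict
    contrasts: list[str] = Field(
        default_factory=lambda: ["stroke:long_survivor", "long_survivor:random",
                                 "stroke:random"]
    )
    n_permutations: int = 2_000
    drift_from_schedule: bool = False
    drift_factor: float = 0.0


class SkatoSection(BaseModel):
    model_config = _strict
    contrasts: list[str] | None = None  # None = the six standard comparisons
    n_permutations: int = 2_000
    permute: Literal["phenotype", "residual"] = "phenotype"
    use_age: bool = True
    n_pcs: int = 2
    weight_beta: tuple[float, float] = (1.0, 25.0)
    missingness_cutoff: float = 0.9
    alpha: float = 0.05
    alpha_adjusted: float = 0.017
    min_rare_variants: int = 2


class EnrichSection(BaseModel):
    model_config = _strict
    gmt: str | None = None  # default: the simulated pathway collection
    source: Literal["burden", "skato", "differentiation"] = "burden"
    group: str = "random"
    top_n: int = 15


class PipelineConfig(BaseModel):
    model_config = _strict
    seed: int = 0
    flank_bp: int = 40_000
    simulate: SimulateSection = Field(default_factory=SimulateSection)
    prioritize: PrioritizeSection = Field(default_factory=PrioritizeSection)
    burden: BurdenSection = Field(default_factory=BurdenSection)
    differentiate: DifferentiateSection = Field(default_factory=DifferentiateSection)
    skato: SkatoSection = Field(default_factory=SkatoSection)
    enrich: EnrichSection = Field(default_factory=EnrichSection)


def load_config(path: str) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig(**data)


def _sim_config(cfg: PipelineConfig) -> SimConfig:
    s = cfg.simulate
    return SimConfig(
        n_per_group=dict(s.n_per_group),
        n_genes=s.n_genes,
        variants_per_gene=tuple(s.variants_per_gene),
        theta=s.theta,
        ne_schedule=NeSchedule(tuple(tuple(e) for e in s.ne_epochs)),
        planted_burden=dict(s.planted_burden),
        planted_diff={
            g: (tuple(pd_.groups), pd_.delta) for g, pd_ in s.planted_diff.items()
        },
        predictor_model=PredictorModel(
            sensitivity=s.sensitivity,
            specificity=s.specificity,
            correlation=s.predictor_correlation,
        ),
        p_deleterious=s.p_deleterious,
        missing_rate=s.missing_rate,
        gene_length_range=tuple(s.gene_length_range),
        flank_bp=cfg.flank_bp,
        freq_grid_haploids=s.freq_grid_haploids,
        seed=derive_seed(cfg.seed, "simulate") % (2**31),
    )


def _parse_contrast(text: str) -> tuple[str, str]:
    a, _, b = text.partition(":")
    if not a or not b or a not in GROUPS or b not in GROUPS:
        raise ValueError(f"malformed contrast {text!r}; expected 'group_a:group_b'")
    return a, b


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig | str, outdir: str,
                 overwrite: bool = False) -> dict:
    """Run every stage in dependency order; return the manifest dict.

    Stage outputs land in ``outdir`` (data files under ``outdir/data``).
    A ``.INCOMPLETE`` marker flags partially written runs; it is removed
    only after the manifest is on disk.
    """
    if isinstance(config, str):
        config = load_config(config)
    os.makedirs(outdir, exist_ok=True)
    marker = os.path.join(outdir, ".INCOMPLETE")
    with open(marker, "w") as fh:
        fh.write("run in progress or aborted\n")

    config_json = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    manifest: dict = {
        "tool": "exomod",
        "version": __version__,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seeds": {}, "inputs": {}, "outputs": {}, "row_counts": {},
    }

    # --- simulate -----------------------------------------------------
    sim_cfg = _sim_config(config)
    manifest["seeds"]["simulate"] = sim_cfg.seed
    sim = simulate_cohort(sim_cfg)
    data_dir = os.path.join(outdir, "data")
    paths = write_cohort(sim, data_dir, overwrite=overwrite,
                         gmt_sets=config.simulate.gmt_sets)
    manifest["inputs"] = {name: _sha256(p) for name, p in paths.items()}
    logger.info("simulate: %d genes, %d variants, %d samples",
                len(sim.genes), sim.matrix.n_variants, sim.matrix.n_samples)

    # --- read back through the format layer ---------------------------
    cohort = read_cohort_table(paths["cohort"])
    matrix, sites = read_vcf(paths["vcf"], cohort)
    profiles = read_annotation(paths["annotation"])
    genes = read_gene_bed(paths["genes"], flank_bp=config.flank_bp)
    assignments = assign_variants_to_genes(sites, genes)

    # --- prioritize ----------------------------------------------------
    criteria = FilterCriteria(
        min_damaging=config.prioritize.min_damaging,
        max_pop_freq=config.prioritize.max_pop_freq,
        allowed_func_classes=frozenset(config.prioritize.allowed_func_classes),
    )
    result = prioritize(matrix, profiles, criteria, cohort)
    retained_path = os.path.join(outdir, "retained.tsv")
    result.to_frame().to_csv(retained_path, sep="\t", index=False)
    logger.info("prioritize: %d variants retained (of %d)",
                len(result.retained), matrix.n_variants)

    siphy = siphy_gene_table(
        assignments, matrix.variant_keys, profiles, retained=result.retained,
        method=config.prioritize.siphy_aggregation,
    )
    siphy_path = os.path.join(outdir, "siphy.tsv")
    siphy.to_csv(siphy_path, sep="\t", index=False, float_format="%.10g")

    # --- burden --------------------------------------------------------
    retained_idx = {k: matrix.variant_index(k) for k in result.retained}
    burden_frames = []
    for group in sorted(set(cohort.groups)):
        keys = set(result.per_group[group])
        counts = {
            gene: sum(1 for i in idx if matrix.variant_keys[i] in keys)
            for gene, idx in assignments.items()
        }
        burden_frames.append(burden_table(genes, counts, group=group,
                                          alpha=config.burden.alpha))
    burden_df = pd.concat(burden_frames, ignore_index=True)
    burden_path = os.path.join(outdir, "burden.tsv")
    write_results_table(burden_df, burden_path)

    # --- differentiation ----------------------------------------------
    drift = (
        sim_cfg.ne_schedule.drift_factor
        if config.differentiate.drift_from_schedule
        else config.differentiate.drift_factor
    )
    diff_cfg = DiffConfig(
        drift_factor=drift,
        n_permutations=config.differentiate.n_permutations,
        seed=derive_seed(config.seed, "differentiate") % (2**31),
    )
    manifest["seeds"]["differentiate"] = diff_cfg.seed
    diff_contrasts = [_parse_contrast(c) for c in config.differentiate.contrasts]
    diff_df = run_differentiation(matrix, assignments, cohort, diff_contrasts, diff_cfg)
    diff_path = os.path.join(outdir, "differentiation.tsv")
    write_results_table(diff_df, diff_path)

    # --- SKAT-O --------------------------------------------------------
    skat_cfg = SkatConfig(
        weight_beta=tuple(config.skato.weight_beta),
        missingness_cutoff=config.skato.missingness_cutoff,
        n_permutations=config.skato.n_permutations,
        alpha=config.skato.alpha,
        alpha_adjusted=config.skato.alpha_adjusted,
        min_rare_variants=config.skato.min_rare_variants,
        permute=config.skato.permute,
        seed=derive_seed(config.seed, "skato") % (2**31),
    )
    manifest["seeds"]["skato"] = skat_cfg.seed
    skato_contrasts = (
        [_parse_contrast(c) for c in config.skato.contrasts]
        if config.skato.contrasts is not None
        else None
    )
    skato_df = run_contrasts(
        matrix, assignments, cohort, skat_cfg, contrasts=skato_contrasts,
        use_age=config.skato.use_age, n_pcs=config.skato.n_pcs,
    )
    skato_path = os.path.join(outdir, "skato.tsv")
    write_results_table(skato_df, skato_path)

    # --- enrichment ----------------------------------------------------
    source_df = {
        "burden": burden_df, "skato": skato_df, "differentiation": diff_df,
    }[config.enrich.source]
    p_col = "p_analytic" if config.enrich.source == "burden" else "p_empirical"
    if config.enrich.source == "burden":
        source_df = source_df[source_df["comparison"] == config.enrich.group]
    hits = (
        source_df.sort_values([p_col, "gene"], kind="stable")["gene"]
        .drop_duplicates()
        .head(config.enrich.top_n)
        .tolist()
    )
    universe = {g.symbol for g in genes}
    gmt_path = config.enrich.gmt or paths.get("gmt")
    enrich_path = None
    if gmt_path:
        collection = GeneSetCollection.from_gmt(gmt_path, universe)
        enrich_df = hypergeometric_enrichment(hits, collection)
        enrich_path = os.path.join(outdir, "enrichment.tsv")
        enrich_df.to_csv(enrich_path, sep="\t", index=False, float_format="%.10g")

    # --- manifest ------------------------------------------------------
    outputs = {
        "retained": retained_path, "siphy": siphy_path, "burden": burden_path,
        "differentiation": diff_path, "skato": skato_path,
    }
    if enrich_path:
        outputs["enrichment"] = enrich_path
    manifest["outputs"] = {k: _sha256(p) for k, p in outputs.items()}
    manifest["row_counts"] = {
        "variants": matrix.n_variants,
        "retained": len(result.retained),
        "burden": len(burden_df),
        "differentiation": len(diff_df),
        "skato": len(skato_df),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    os.remove(marker)
    return manifest
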