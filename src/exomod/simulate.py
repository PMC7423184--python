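"""Synthetic exome-cohort generator.

Generates cohorts with the statistical structure the downstream analysis
assumes: a neutral site-frequency spectrum under a stepwise-constant
effective population size, binomially sampled genotypes for the four
phenotype groups, planted per-gene burden excess and between-group
allele-frequency shifts, and correlated categorical verdicts from the 21
deleteriousness predictors.

Site frequencies are drawn by inverse-CDF sampling of the closed-form
neutral density (mass proportional to ``1/i`` for derived-allele count
``i`` on a discretization grid) rather than by forward Wright-Fisher
simulation; the demographic schedule enters through a single aggregate
drift factor ``F = 1 - exp(-sum(t_k / (2 N_k)))`` applied as a Beta
perturbation of the ancestral frequency.  This reproduces the marginal
SFS structure orders of magnitude faster than forward simulation.

Linkage is induced only through gene-block sharing of latent frequency
draws; there is no recombination map, haplotype structure, selection or
sequencing-error model.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._rng import derive_rng
from .datatypes import (
    GROUPS,
    MISSING,
    N_PREDICTORS,
    CohortDesign,
    GeneRegion,
    GenotypeMatrix,
    PredictionProfile,
    variant_key,
)

logger = logging.getLogger(__name__)

#: Paper cohort: three SCA case groups plus HbAA controls.
DEFAULT_GROUP_SIZES: dict[str, int] = {
    "long_survivor": 26,
    "stroke": 23,
    "random": 56,
    "control": 58,
}

#: Age ranges (years) used when synthesizing the cohort table; chosen to
#: bracket the reported group medians (44 / 20.5 / 16.5 years and adult
#: blood-donor controls).
_AGE_RANGES = {
    "long_survivor": (41, 60),
    "stroke": (16, 27),
    "random": (9, 27),
    "control": (18, 60),
}


@dataclass(frozen=True)
class NeSchedule:
    """Stepwise-constant effective population size, most recent epoch first.

    Each epoch is ``(duration_generations, Ne)``; both strictly positive.
    The schedule is summarized by the aggregate drift factor
    ``F = 1 - exp(-sum(t_k / (2 N_k)))`` in [0, 1).
    """

    epochs: tuple[tuple[int, int], ...] = ((1, 1_000_000),)

    def __post_init__(self) -> None:
        if len(self.epochs) == 0:
            raise ValueError("NeSchedule needs at least one epoch")
        for t, ne in self.epochs:
            if t <= 0 or ne <= 0:
                raise ValueError("epoch durations and Ne must be strictly positive")

    @property
    def drift_factor(self) -> float:
        total = sum(t / (2.0 * ne) for t, ne in self.epochs)
        return 1.0 - float(np.exp(-total))


@dataclass(frozen=True)
class PredictorModel:
    """Exchangeably correlated Bernoulli model for the 21 predictor verdicts.

    A truly deleterious variant is called damaging by each predictor with
    probability ``sensitivity``; a benign one with ``1 - specificity``.
    Verdicts share a latent Gaussian factor with pairwise correlation
    controlled by ``correlation`` in [0, 1).
    """

    sensitivity: float = 0.95
    specificity: float = 0.95
    correlation: float = 0.3
    unknown_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.sensitivity <= 1.0:
            raise ValueError("sensitivity must lie in (0, 1]")
        if not 0.0 < self.specificity <= 1.0:
            raise ValueError("specificity must lie in (0, 1]")
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError("correlation must lie in [0, 1)")
        if not 0.0 <= self.unknown_rate < 1.0:
            raise ValueError("unknown_rate must lie in [0, 1)")


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one synthetic cohort; the seed determines output.

    ``theta`` is the scaled mutation rate per gene region: the expected
    number of segregating sites in a region of average (flanked) length,
    scaled linearly with each region's flanked length and clipped to
    ``variants_per_gene``.  ``planted_burden`` maps gene symbols to a
    deleterious-rate excess factor >= 1; ``planted_diff`` maps gene symbols
    to ``((group_a, group_b), delta)`` and shifts ``group_a``'s allele
    frequency by ``+delta`` (clipped to [0, 1]) at every site of the gene.
    """

    n_per_group: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_genes: int = 50
    variants_per_gene: tuple[int, int] = (10, 200)
    theta: float = 60.0
    ne_schedule: NeSchedule = NeSchedule()
    planted_burden: dict[str, float] = field(default_factory=dict)
    planted_diff: dict[str, tuple[tuple[str, str], float]] = field(default_factory=dict)
    predictor_model: PredictorModel = PredictorModel()
    p_deleterious: float = 0.05
    missing_rate: float = 0.02
    gene_length_range: tuple[int, int] = (2_000, 20_000)
    region_gap: int = 50_000
    flank_bp: int = 40_000
    freq_grid_haploids: int = 2_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError("theta must be non-negative")
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 2:
                raise ValueError(f"group {g} needs at least 2 samples")
        lo, hi = self.variants_per_gene
        if not (0 <= lo <= hi):
            raise ValueError("variants_per_gene range must satisfy 0 <= lo <= hi")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for gene, factor in self.planted_burden.items():
            if factor < 1.0:
                raise ValueError(f"planted burden factor for {gene} must be >= 1")
        for gene, (pair, delta) in self.planted_diff.items():
            if len(pair) != 2 or any(g not in self.n_per_group for g in pair):
                raise ValueError(f"planted_diff for {gene}: unknown group pair {pair}")
            if not 0.0 <= delta <= 0.5:
                raise ValueError(f"planted_diff delta for {gene} must lie in [0, 0.5]")
        if not 0.0 <= self.p_deleterious <= 1.0:
            raise ValueError("p_deleterious must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.freq_grid_haploids < 4:
            raise ValueError("freq_grid_haploids must be >= 4")
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")


@dataclass
class SimulatedCohort:
    """Everything :func:`simulate_cohort` produces, ready to write or analyze."""

    config: SimConfig
    genes: list[GeneRegion]
    cohort: CohortDesign
    matrix: GenotypeMatrix
    variants: pd.DataFrame  # gene, chrom, pos, ref, alt, base_freq, deleterious
    profiles: dict[str, PredictionProfile]


def make_gene_models(config: SimConfig) -> list[GeneRegion]:
    """Non-overlapping gene intervals laid out across chromosomes 1-22.

    Genes are spaced so that their +/- flank regions never overlap, which
    keeps variant-to-gene assignment unambiguous in the synthetic world
    (overlapping regions are still supported by the assignment code).
    """
    rng = derive_rng(config.seed, "gene-models")
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    cursors = {f"chr{c}": 100_000 for c in range(1, 23)}
    genes: list[GeneRegion] = []
    width = len(str(config.n_genes))
    for g in range(config.n_genes):
        chrom = f"chr{(g % 22) + 1}"
        start = cursors[chrom] + config.flank_bp
        end = start + int(lengths[g]) - 1
        cursors[chrom] = end + config.flank_bp + config.region_gap
        genes.append(
            GeneRegion(
                symbol=f"G{g + 1:0{width}d}",
                chrom=chrom,
                start=start,
                end=end,
                flank_bp=config.flank_bp,
            )
        )
    return genes


def _neutral_frequency_sampler(config: SimConfig):
    """Inverse-CDF sampler of derived-allele counts with weights 1/i."""
    two_n = config.freq_grid_haploids
    i = np.arange(1, two_n)
    weights = 1.0 / i
    cdf = np.cumsum(weights)
    cdf /= cdf[-1]

    def draw(rng: np.random.Generator, size: int) -> np.ndarray:
        counts = i[np.searchsorted(cdf, rng.random(size))]
        return counts / float(two_n)

    return draw


def _apply_drift(freqs: np.ndarray, drift: float, rng: np.random.Generator,
                 floor: float) -> np.ndarray:
    """Beta-perturb ancestral frequencies with variance ``F p (1-p)``."""
    if drift <= 0.0 or freqs.size == 0:
        return freqs
    scale = (1.0 - drift) / drift
    out = rng.beta(freqs * scale, (1.0 - freqs) * scale)
    return np.clip(out, floor, 1.0 - floor)


def simulate_site_frequencies(
    config: SimConfig, genes: list[GeneRegion] | None = None
) -> list[np.ndarray]:
    """Per-gene arrays of ancestral population alt-allele frequencies.

    The number of sites per gene region is Poisson with mean
    ``theta * L_g / mean(L)`` (flanked lengths), clipped to the configured
    range; frequencies follow the neutral 1/i law on the discretization
    grid, modulated by the schedule's drift factor.
    """
    if genes is None:
        genes = make_gene_models(config)
    rng = derive_rng(config.seed, "site-frequencies")
    draw = _neutral_frequency_sampler(config)
    drift = config.ne_schedule.drift_factor
    floor = 1.0 / (2.0 * config.freq_grid_haploids)
    lengths = np.array([g.flanked_length for g in genes], dtype=float)
    mean_len = lengths.mean()
    lo, hi = config.variants_per_gene
    out: list[np.ndarray] = []
    for g, length in zip(genes, lengths):
        if config.theta == 0.0:
            out.append(np.empty(0))
            continue
        n_sites = int(np.clip(rng.poisson(config.theta * length / mean_len), lo, hi))
        freqs = draw(rng, n_sites)
        freqs = _apply_drift(freqs, drift, rng, floor)
        out.append(freqs)
    return out


def make_cohort(config: SimConfig) -> CohortDesign:
    """Synthesize the sample table: ids, group labels and ages."""
    rng = derive_rng(config.seed, "cohort")
    prefix = {"long_survivor": "LS", "stroke": "ST", "random": "RD", "control": "CT"}
    rows = []
    for group in GROUPS:
        n = config.n_per_group.get(group, 0)
        lo, hi = _AGE_RANGES[group]
        ages = rng.integers(lo, hi + 1, size=n)
        for i in range(n):
            rows.append((f"{prefix[group]}{i + 1:03d}", group, int(ages[i])))
    table = pd.DataFrame(rows, columns=["sample_id", "group", "age"])
    return CohortDesign(table)


def _group_frequencies(
    base: np.ndarray,
    gene_of_variant: np.ndarray,
    gene_symbols: list[str],
    planted_diff: dict[str, tuple[tuple[str, str], float]],
    groups: list[str],
) -> dict[str, np.ndarray]:
    """Per-group sampling frequencies; planted genes shift one group by +delta."""
    freqs = {g: base.copy() for g in groups}
    for symbol, (pair, delta) in planted_diff.items():
        if symbol not in gene_symbols:
            raise ValueError(f"planted_diff references unknown gene {symbol!r}")
        mask = gene_of_variant == gene_symbols.index(symbol)
        shifted, _ = pair
        freqs[shifted][mask] = np.clip(freqs[shifted][mask] + delta, 0.0, 1.0)
    return freqs


def simulate_genotypes(
    freqs: list[np.ndarray],
    cohort: CohortDesign,
    planted_diff: dict[str, tuple[tuple[str, str], float]] | None = None,
    seed: int = 0,
    *,
    genes: list[GeneRegion] | None = None,
    missing_rate: float = 0.0,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Binomially sample genotypes (2 draws per sample) per group.

    ``freqs`` is one array of site frequencies per gene.  Variant positions
    are placed uniformly (without replacement) within each gene's flanked
    region; when ``genes`` is omitted a synthetic single-chromosome layout
    is fabricated.  Missing dosages are injected independently at
    ``missing_rate`` and encoded as :data:`~exomod.datatypes.MISSING`.

    Returns the genotype matrix (cohort sample order) and a variant table
    with columns ``gene, chrom, pos, ref, alt, base_freq``.
    """
    planted_diff = planted_diff or {}
    rng = derive_rng(seed, "genotypes")
    if genes is None:
        genes = [
            GeneRegion(f"G{i + 1:04d}", "chr1", 1 + 200_000 * i, 200_000 * i + 100_000,
                       flank_bp=0)
            for i in range(len(freqs))
        ]
    if len(genes) != len(freqs):
        raise ValueError("freqs and genes must have equal length")

    base = np.concatenate(freqs) if freqs else np.empty(0)
    gene_of_variant = np.concatenate(
        [np.full(len(f), i, dtype=int) for i, f in enumerate(freqs)]
    ) if freqs else np.empty(0, dtype=int)

    # Positions: uniform without replacement inside each flanked region.
    nucs = np.array(list("ACGT"))
    rows = []
    for i, (gene, f) in enumerate(zip(genes, freqs)):
        span = np.arange(gene.region_start, gene.region_end + 1)
        if len(f) > len(span):
            raise ValueError(f"{gene.symbol}: more variants than positions in region")
        pos = np.sort(rng.choice(span, size=len(f), replace=False))
        ref_idx = rng.integers(0, 4, size=len(f))
        alt_idx = (ref_idx + rng.integers(1, 4, size=len(f))) % 4
        for p, r, a in zip(pos, nucs[ref_idx], nucs[alt_idx]):
            rows.append((gene.symbol, gene.chrom, int(p), r, a))
    variants = pd.DataFrame(rows, columns=["gene", "chrom", "pos", "ref", "alt"])
    variants["base_freq"] = base

    group_labels = [g for g in GROUPS if (cohort.groups == g).any()]
    gfreq = _group_frequencies(
        base, gene_of_variant, [g.symbol for g in genes], planted_diff, group_labels
    )

    n_samples, n_var = len(cohort.samples), len(base)
    dosages = np.zeros((n_samples, n_var), dtype=np.int16)
    for group in group_labels:
        idx = cohort.indices_of(group)
        dosages[idx] = rng.binomial(2, gfreq[group], size=(len(idx), n_var))
    if missing_rate > 0.0 and n_var:
        mask = rng.random((n_samples, n_var)) < missing_rate
        dosages[mask] = MISSING

    keys = [
        variant_key(c, p, r, a)
        for c, p, r, a in zip(variants.chrom, variants.pos, variants.ref, variants.alt)
    ]
    return GenotypeMatrix(cohort.samples, keys, dosages), variants


def simulate_prediction_profiles(
    truth: np.ndarray,
    model: PredictorModel,
    seed: int = 0,
    *,
    siphy_deleterious: tuple[float, float] = (12.0, 2.0),
    siphy_benign: tuple[float, float] = (4.0, 2.0),
) -> list[PredictionProfile]:
    """Correlated 21-predictor verdicts plus SiPhy score and annotations.

    Verdicts are exchangeably correlated Bernoullis through a shared latent
    Gaussian per variant.  SiPhy 29-way scores are drawn from separated
    normals for deleterious vs benign sites.  Deleterious variants are
    nonsynonymous or stop variants and rare (or absent) in the reference
    panels; benign variants mix functional classes and span the frequency
    range.
    """
    truth = np.asarray(truth, dtype=bool)
    rng = derive_rng(seed, "profiles")
    n = len(truth)
    rho = model.correlation
    latent = rng.standard_normal((n, 1))
    noise = rng.standard_normal((n, N_PREDICTORS))
    x = np.sqrt(rho) * latent + np.sqrt(1.0 - rho) * noise
    p_damaging = np.where(truth, model.sensitivity, 1.0 - model.specificity)
    damaging = norm.cdf(x) < p_damaging[:, None]
    verdicts = np.where(damaging, "damaging", "tolerated")
    if model.unknown_rate > 0.0:
        verdicts[rng.random((n, N_PREDICTORS)) < model.unknown_rate] = "unknown"

    mu_d, sd_d = siphy_deleterious
    mu_b, sd_b = siphy_benign
    siphy = np.where(
        truth,
        rng.normal(mu_d, sd_d, size=n),
        rng.normal(mu_b, sd_b, size=n),
    )

    del_classes = np.array(["nonsynonymous", "stopgain", "stoploss"])
    ben_classes = np.array(["synonymous", "nonsynonymous", "splice", "other"])
    fc = np.where(
        truth,
        rng.choice(del_classes, size=n, p=(0.90, 0.06, 0.04)),
        rng.choice(ben_classes, size=n, p=(0.45, 0.45, 0.05, 0.05)),
    )

    # Reference-panel frequencies: deleterious sites unseen or very rare;
    # benign sites span common frequencies with occasional absent entries.
    afr = np.where(truth, rng.uniform(0, 0.005, n), rng.uniform(0, 0.3, n))
    eur = np.where(truth, np.zeros(n), rng.uniform(0, 0.3, n))
    afr_absent = rng.random(n) < np.where(truth, 0.5, 0.1)
    eur_absent = rng.random(n) < np.where(truth, 0.7, 0.1)

    profiles = []
    for j in range(n):
        profiles.append(
            PredictionProfile(
                verdicts=tuple(verdicts[j]),
                siphy29=float(siphy[j]),
                func_class=str(fc[j]),
                afr_freq=None if afr_absent[j] else float(afr[j]),
                eur_freq=None if eur_absent[j] else float(eur[j]),
            )
        )
    return profiles


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Run the full generator: genes, cohort, genotypes, truth, profiles."""
    genes = make_gene_models(config)
    cohort = make_cohort(config)
    freqs = simulate_site_frequencies(config, genes)
    matrix, variants = simulate_genotypes(
        freqs,
        cohort,
        config.planted_diff,
        config.seed,
        genes=genes,
        missing_rate=config.missing_rate,
    )
    rng = derive_rng(config.seed, "truth")
    p_del = np.full(len(variants), config.p_deleterious)
    for symbol, factor in config.planted_burden.items():
        p_del[variants["gene"].to_numpy() == symbol] = min(
            1.0, config.p_deleterious * factor
        )
    truth = rng.random(len(variants)) < p_del
    variants = variants.assign(deleterious=truth)
    profile_list = simulate_prediction_profiles(
        truth, config.predictor_model, config.seed
    )
    profiles = dict(zip(matrix.variant_keys, profile_list))
    return SimulatedCohort(config, genes, cohort, matrix, variants, profiles)


# ---------------------------------------------------------------------------
# On-disk output
# ---------------------------------------------------------------------------

_VERDICT_CODE = {"damaging": "D", "tolerated": "T", "unknown": "."}
#: MutationTaster uses "A" (disease_causing_automatic) for its damaging code.
_MUTATIONTASTER_IDX = 2

_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_cohort(
    sim: SimulatedCohort,
    outdir: str,
    overwrite: bool = False,
    gmt_sets: int = 0,
) -> dict[str, str]:
    """Write VCF, annotation TSV, cohort TSV and gene BED for a cohort.

    Refuses to overwrite existing files unless ``overwrite`` is set.  With
    ``gmt_sets > 0`` a synthetic pathway collection (GMT) over the gene
    universe is emitted as well, with one set concentrated on the planted
    genes when any exist.  Returns the mapping of logical name -> path.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, "cohort.vcf"),
        "annotation": os.path.join(outdir, "annotations.tsv"),
        "cohort": os.path.join(outdir, "cohort.tsv"),
        "genes": os.path.join(outdir, "genes.bed"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    if gmt_sets > 0:
        paths["gmt"] = os.path.join(outdir, "pathways.gmt")
    for path in paths.values():
        if os.path.exists(path) and not overwrite:
            raise FileExistsError(f"{path} exists; pass overwrite=True to replace")

    _write_vcf(sim, paths["vcf"])
    _write_annotation(sim, paths["annotation"])
    sim.cohort.table.to_csv(paths["cohort"], sep="\t", index=False)
    with open(paths["genes"], "w") as fh:  # BED: 0-based half-open
        for g in sim.genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.symbol}\n")
    sim.variants[["gene", "chrom", "pos", "ref", "alt", "deleterious"]].to_csv(
        paths["truth"], sep="\t", index=False
    )
    if gmt_sets > 0:
        _write_gmt(sim, paths["gmt"], gmt_sets)
    logger.info("wrote synthetic cohort to %s (%d variants, %d samples)",
                outdir, sim.matrix.n_variants, sim.matrix.n_samples)
    return paths


def _write_vcf(sim: SimulatedCohort, path: str) -> None:
    chroms = sorted(
        {g.chrom for g in sim.genes}, key=lambda c: int(c.removeprefix("chr"))
    )
    gt = np.vectorize(_GT_STRING.__getitem__)(sim.matrix.dosages.T)  # variants x samples
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=exomod-simulate\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sim.matrix.samples)
            + "\n"
        )
        v = sim.variants
        order = np.lexsort((v["pos"].to_numpy(),
                            [int(c.removeprefix("chr")) for c in v["chrom"]]))
        for j in order:
            row = v.iloc[j]
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gt[j])
                + "\n"
            )


def _write_annotation(sim: SimulatedCohort, path: str) -> None:
    from .datatypes import PREDICTORS

    header = ["chrom", "pos", "ref", "alt", "func_class", *PREDICTORS,
              "siphy29", "afr_freq", "eur_freq"]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for key, row in zip(sim.matrix.variant_keys, sim.variants.itertuples()):
            prof = sim.profiles[key]
            codes = [_VERDICT_CODE[v] for v in prof.verdicts]
            if codes[_MUTATIONTASTER_IDX] == "D":
                codes[_MUTATIONTASTER_IDX] = "A"
            fields = [
                row.chrom, str(row.pos), row.ref, row.alt, prof.func_class, *codes,
                "" if prof.siphy29 is None else f"{prof.siphy29:.6f}",
                "" if prof.afr_freq is None else f"{prof.afr_freq:.6f}",
                "" if prof.eur_freq is None else f"{prof.eur_freq:.6f}",
            ]
            fh.write("\t".join(fields) + "\n")


def _write_gmt(sim: SimulatedCohort, path: str, n_sets: int) -> None:
    rng = derive_rng(sim.config.seed, "gmt")
    symbols = [g.symbol for g in sim.genes]
    planted = sorted(set(sim.config.planted_burden) | set(sim.config.planted_diff))
    with open(path, "w") as fh:
        if planted:
            extra = rng.choice(symbols, size=min(5, len(symbols)), replace=False)
            members = sorted(set(planted) | set(extra))
            fh.write("PLANTED_SET\tsynthetic set enriched in planted genes\t"
                     + "\t".join(members) + "\n")
            n_sets -= 1
        for k in range(n_sets):
            size = int(rng.integers(5, max(6, len(symbols) // 3)))
            members = sorted(rng.choice(symbols, size=min(size, len(symbols)),
                                        replace=False))
            fh.write(f"RANDOM_SET_{k + 1}\tsynthetic random set\t"
                     + "\t".join(members) + "\n")


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Convenience: copy a config with a different master seed."""
    return replace(config, seed=seed)
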