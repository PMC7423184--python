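"""Readers and writers for every on-disk format the pipeline touches.

Conventions
-----------
* Internal coordinates are 1-based inclusive (VCF-native); BED input is
  0-based half-open and converted at the boundary.
* Multi-allelic VCF records are split into biallelic sites with
  allele-specific counts; half-calls (one missing allele) are treated as
  fully missing.
* Annotation verdicts: ``D``/``A``/``H`` count as damaging (``A`` is
  MutationTaster's disease_causing_automatic code), ``T``/``N``/``B``/``P``/
  ``L``/``M`` as tolerated; numeric entries are thresholded against a
  per-predictor cutoff table; anything else maps to "unknown".
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from intervaltree import IntervalTree

from .datatypes import (
    MISSING,
    PREDICTORS,
    CohortDesign,
    GeneRegion,
    GenotypeMatrix,
    PredictionProfile,
    VariantSite,
    variant_key,
)

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "comparison", "gene", "n_variants", "statistic",
    "p_analytic", "p_empirical", "n_perm", "seed",
]

_DAMAGING_CODES = {"D", "A", "H"}
_TOLERATED_CODES = {"T", "N", "B", "P", "L", "M"}
_UNKNOWN_STRINGS = {"", ".", "NA", "NAN", "NONE", "U"}

#: Default damaging cutoffs for predictors whose raw dbNSFP output is a
#: score rather than a categorical call (value >= cutoff counts damaging).
SCORE_CUTOFFS: dict[str, float] = {
    "CADD": 20.0,
    "GERP++": 4.0,
    "DANN": 0.98,
    "PhyloP": 1.6,
    "SiPhy": 12.0,
    "Eigen": 0.0,
    "GenoCanyon": 0.5,
    "M-CAP": 0.025,
}

_FUNC_ALIASES = {
    "nonsynonymous": "nonsynonymous",
    "nonsynonymous_snv": "nonsynonymous",
    "missense": "nonsynonymous",
    "synonymous": "synonymous",
    "synonymous_snv": "synonymous",
    "stopgain": "stopgain",
    "stoploss": "stoploss",
    "splice": "splice",
    "splicing": "splice",
}


def _chrom_sort_key(chrom: str):
    m = re.fullmatch(r"chr(\d+)", chrom)
    return (0, int(m.group(1)), "") if m else (1, 0, chrom)


def read_vcf(path: str, cohort: CohortDesign) -> tuple[GenotypeMatrix, list[VariantSite]]:
    """Parse a multi-sample VCF into a dosage matrix and per-site counts.

    Every cohort sample must carry a GT column; a mismatch raises with the
    list of missing samples.  Records are sorted internally by
    (chrom, pos, ref, alt) so the result is independent of file order.
    """
    vcf = VCF(path, gts012=True)
    vcf_samples = list(vcf.samples)
    missing_samples = [s for s in cohort.samples if s not in vcf_samples]
    if missing_samples:
        raise ValueError(
            f"VCF {path} lacks genotypes for cohort samples: {missing_samples}"
        )
    col_of = [vcf_samples.index(s) for s in cohort.samples]

    group_labels = sorted(set(cohort.groups))
    group_idx = {g: cohort.indices_of(g) for g in group_labels}

    records = []  # (sortkey, key, chrom, pos, ref, alt, dosage vector)
    for i, rec in enumerate(vcf):
        try:
            gts = np.asarray(rec.genotypes, dtype=int)[:, :2]
        except Exception as exc:  # pragma: no cover - htslib-level corruption
            raise ValueError(
                f"malformed GT in record {i + 1} at {rec.CHROM}:{rec.POS}"
            ) from exc
        if gts.shape[0] != len(vcf_samples):
            raise ValueError(
                f"record {i + 1} at {rec.CHROM}:{rec.POS} has "
                f"{gts.shape[0]} GT entries for {len(vcf_samples)} samples"
            )
        gts = gts[col_of]  # cohort order
        missing_any = (gts == -1).any(axis=1)  # half-calls become missing
        for k, alt in enumerate(rec.ALT):
            dos = (gts == k + 1).sum(axis=1).astype(np.int16)
            dos[missing_any] = MISSING
            key = variant_key(rec.CHROM, rec.POS, rec.REF, alt)
            records.append(
                ((_chrom_sort_key(rec.CHROM), rec.POS, rec.REF, alt),
                 key, rec.CHROM, rec.POS, rec.REF, alt, dos)
            )
    records.sort(key=lambda r: r[0])

    keys = [r[1] for r in records]
    dosages = (
        np.stack([r[6] for r in records], axis=1)
        if records
        else np.empty((len(cohort.samples), 0), dtype=np.int16)
    )
    matrix = GenotypeMatrix(cohort.samples, keys, dosages)

    sites = []
    for (_, key, chrom, pos, ref, alt, dos) in records:
        called = dos != MISSING
        alt_counts, called_counts = {}, {}
        for g, idx in group_idx.items():
            c = called[idx]
            alt_counts[g] = int(dos[idx][c].sum())
            called_counts[g] = int(2 * c.sum())
        sites.append(
            VariantSite(
                chrom=chrom, pos=pos, ref=ref, alt=alt,
                alt_counts=alt_counts, called_counts=called_counts,
                call_rate=float(called.mean()),
            )
        )
    return matrix, sites


def _parse_verdict(raw, predictor: str,
                   cutoffs: dict[str, float] | None = None) -> str:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return "unknown"
    s = str(raw).strip()
    if s.upper() in _UNKNOWN_STRINGS:
        return "unknown"
    if s in _DAMAGING_CODES:
        return "damaging"
    if s in _TOLERATED_CODES:
        return "tolerated"
    try:
        value = float(s)
    except ValueError:
        return "unknown"
    table = SCORE_CUTOFFS if cutoffs is None else cutoffs
    if predictor in table:
        return "damaging" if value >= table[predictor] else "tolerated"
    return "unknown"


def read_annotation(
    path: str, score_cutoffs: dict[str, float] | None = None
) -> dict[str, PredictionProfile]:
    """Load a dbNSFP-style annotation TSV into per-variant profiles.

    Keys are ``chrom:pos:ref:alt``.  Duplicate keys raise; absent
    frequencies and SiPhy cells become ``None``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["chrom", "pos", "ref", "alt", "func_class", *PREDICTORS,
                "siphy29", "afr_freq", "eur_freq"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"annotation table missing columns: {missing_cols}")

    pred_cols = [df[p].to_numpy() for p in PREDICTORS]
    profiles: dict[str, PredictionProfile] = {}
    for i in range(len(df)):
        key = variant_key(
            df["chrom"].iat[i], int(df["pos"].iat[i]), df["ref"].iat[i], df["alt"].iat[i]
        )
        if key in profiles:
            raise ValueError(f"duplicate annotation entry for {key}")
        verdicts = tuple(
            _parse_verdict(col[i], p, score_cutoffs)
            for p, col in zip(PREDICTORS, pred_cols)
        )
        profiles[key] = PredictionProfile(
            verdicts=verdicts,
            siphy29=_parse_optional_float(df["siphy29"].iat[i]),
            func_class=_FUNC_ALIASES.get(
                str(df["func_class"].iat[i]).strip().lower(), "other"
            ),
            afr_freq=_parse_optional_float(df["afr_freq"].iat[i]),
            eur_freq=_parse_optional_float(df["eur_freq"].iat[i]),
        )
    return profiles


def _parse_optional_float(raw: str) -> float | None:
    s = str(raw).strip()
    if s == "" or s == ".":
        return None
    return float(s)


def read_gene_bed(path: str, flank_bp: int = 40_000) -> list[GeneRegion]:
    """BED (0-based half-open) gene models -> 1-based inclusive regions."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "symbol"], usecols=range(4),
    )
    genes = [
        GeneRegion(symbol=str(r.symbol), chrom=str(r.chrom),
                   start=int(r.start) + 1, end=int(r.end), flank_bp=flank_bp)
        for r in df.itertuples(index=False)
    ]
    return sorted(genes, key=lambda g: (_chrom_sort_key(g.chrom), g.start))


def write_gene_bed(genes: list[GeneRegion], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.symbol}\n")


def read_cohort_table(path: str) -> CohortDesign:
    table = pd.read_csv(path, sep="\t")
    return CohortDesign(table)


def assign_variants_to_genes(
    sites: list[VariantSite] | pd.DataFrame,
    genes: list[GeneRegion],
) -> dict[str, list[int]]:
    """Map gene symbol -> indices of sites in its closed flanked interval.

    A variant at exactly ``start - flank`` or ``end + flank`` is included; a
    variant may belong to several overlapping flanked genes.  All genes
    appear in the result, possibly with empty lists.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(
            g.region_start, g.region_end + 1, g.symbol
        )
    if isinstance(sites, pd.DataFrame):
        coords = list(zip(sites["chrom"], sites["pos"]))
    else:
        coords = [(s.chrom, s.pos) for s in sites]
    out: dict[str, list[int]] = {g.symbol: [] for g in genes}
    for i, (chrom, pos) in enumerate(coords):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for iv in tree[pos]:
            out[iv.data].append(i)
    return out


def write_results_table(df: pd.DataFrame, path: str) -> None:
    """Write a per-gene result table with the stable pipeline column order."""
    cols = [c for c in RESULT_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")
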