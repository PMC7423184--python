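"""Core in-memory containers shared by all pipeline stages.

The analysis operates on four phenotype groups of a sickle-cell-anemia
exome cohort -- ``random`` (typical patients), ``stroke`` (overt stroke),
``long_survivor`` (alive past age 40) and HbAA ``control`` -- and on
per-variant annotation profiles from 21 in-silico deleteriousness
predictors plus the SiPhy 29-way conservation score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype dosage.  Never encoded as 0.
MISSING: int = -1

#: The 21 deleteriousness predictors whose categorical verdicts feed the
#: consensus filter.
PREDICTORS: tuple[str, ...] = (
    "SIFT",
    "LRT",
    "MutationTaster",
    "MutationAssessor",
    "FATHMM",
    "fathmm-MKL",
    "RadialSVM",
    "LR",
    "PROVEAN",
    "MetaSVM",
    "MetaLR",
    "CADD",
    "GERP++",
    "DANN",
    "M-CAP",
    "Eigen",
    "GenoCanyon",
    "Polyphen2_HVAR",
    "Polyphen2_HDIV",
    "PhyloP",
    "SiPhy",
)
N_PREDICTORS = len(PREDICTORS)

FUNC_CLASSES: tuple[str, ...] = (
    "nonsynonymous",
    "synonymous",
    "stopgain",
    "stoploss",
    "splice",
    "other",
)

GROUPS: tuple[str, ...] = ("random", "stroke", "long_survivor", "control")

#: Default flank around a gene interval; variants within this distance of
#: the transcript boundary are attributed to the gene.
DEFAULT_FLANK_BP: int = 40_000


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}:{alt}"


@dataclass(frozen=True)
class GeneRegion:
    """A gene interval (1-based, inclusive) plus its analysis flank.

    Membership tests use the closed flanked interval
    ``[start - flank_bp, end + flank_bp]``.
    """

    symbol: str
    chrom: str
    start: int
    end: int
    flank_bp: int = DEFAULT_FLANK_BP

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.symbol}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError(f"{self.symbol}: 1-based start must be >= 1")
        if self.flank_bp < 0:
            raise ValueError(f"{self.symbol}: flank_bp must be >= 0")

    @property
    def region_start(self) -> int:
        return self.start - self.flank_bp

    @property
    def region_end(self) -> int:
        return self.end + self.flank_bp

    @property
    def flanked_length(self) -> int:
        return self.region_end - self.region_start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.region_start <= pos <= self.region_end


@dataclass
class PredictionProfile:
    """Annotation profile of one variant.

    ``verdicts`` holds one entry per predictor in :data:`PREDICTORS`, each
    ``"damaging"``, ``"tolerated"`` or ``"unknown"``.  Unknown verdicts never
    count toward the damaging consensus.  ``siphy29`` / population
    frequencies are ``None`` when absent (absent is not zero).
    """

    verdicts: tuple[str, ...]
    siphy29: float | None = None
    func_class: str = "other"
    afr_freq: float | None = None
    eur_freq: float | None = None

    def __post_init__(self) -> None:
        if len(self.verdicts) != N_PREDICTORS:
            raise ValueError(
                f"expected {N_PREDICTORS} predictor verdicts, got {len(self.verdicts)}"
            )
        bad = set(self.verdicts) - {"damaging", "tolerated", "unknown"}
        if bad:
            raise ValueError(f"invalid verdict values: {sorted(bad)}")
        if self.func_class not in FUNC_CLASSES:
            raise ValueError(f"invalid func_class {self.func_class!r}")

    @property
    def damaging_count(self) -> int:
        return sum(v == "damaging" for v in self.verdicts)

    @property
    def max_ref_freq(self) -> float | None:
        """Largest reference-panel frequency among those present."""
        present = [f for f in (self.afr_freq, self.eur_freq) if f is not None]
        return max(present) if present else None


@dataclass
class VariantSite:
    """One biallelic site with per-group allele counts.

    ``alt_counts[g]`` / ``called_counts[g]`` are alt-allele and called-allele
    (2 x called samples) counts in group ``g``; they carry the sample allele
    frequency p-hat used by the differentiation statistic.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    alt_counts: dict[str, int] = field(default_factory=dict)
    called_counts: dict[str, int] = field(default_factory=dict)
    call_rate: float = 1.0

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref/alt alleles must be non-empty")
        for g, ac in self.alt_counts.items():
            cc = self.called_counts.get(g, 0)
            if not 0 <= ac <= cc:
                raise ValueError(
                    f"{self.key}: alt count {ac} outside [0, called {cc}] in group {g}"
                )
        if not 0.0 <= self.call_rate <= 1.0:
            raise ValueError("call_rate must lie in [0, 1]")

    @property
    def key(self) -> str:
        return variant_key(self.chrom, self.pos, self.ref, self.alt)

    def frequency(self, group: str) -> float | None:
        cc = self.called_counts.get(group, 0)
        if cc == 0:
            return None
        return self.alt_counts[group] / cc


class GenotypeMatrix:
    """Samples x variants dosage matrix with {0,1,2,MISSING} entries."""

    def __init__(
        self,
        samples: list[str],
        variant_keys: list[str],
        dosages: np.ndarray,
    ) -> None:
        dosages = np.asarray(dosages, dtype=np.int16)
        if dosages.shape != (len(samples), len(variant_keys)):
            raise ValueError(
                f"dosage shape {dosages.shape} inconsistent with "
                f"{len(samples)} samples x {len(variant_keys)} variants"
            )
        valid = np.isin(dosages, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or MISSING")
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample ids")
        if len(set(variant_keys)) != len(variant_keys):
            raise ValueError("duplicate variant keys")
        self.samples = list(samples)
        self.variant_keys = list(variant_keys)
        self.dosages = dosages
        self._sample_index = {s: i for i, s in enumerate(self.samples)}
        self._variant_index = {k: i for i, k in enumerate(self.variant_keys)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variant_keys)

    def sample_indices(self, samples: list[str]) -> np.ndarray:
        return np.array([self._sample_index[s] for s in samples], dtype=int)

    def variant_index(self, key: str) -> int:
        return self._variant_index[key]

    def call_rates(self) -> np.ndarray:
        """Per-variant fraction of non-missing genotypes."""
        return (self.dosages != MISSING).mean(axis=0)

    def allele_counts(self, sample_idx: np.ndarray | None = None):
        """(alt alleles, called alleles) per variant over a sample subset."""
        d = self.dosages if sample_idx is None else self.dosages[sample_idx]
        called = (d != MISSING)
        alt = np.where(called, d, 0).sum(axis=0)
        return alt.astype(np.int64), 2 * called.sum(axis=0).astype(np.int64)

    def minor_allele_frequency(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """Per-variant MAF over called alleles; NaN where nothing is called."""
        alt, called = self.allele_counts(sample_idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called > 0, alt / np.maximum(called, 1), np.nan)
        return np.where(np.isnan(p), np.nan, np.minimum(p, 1.0 - p))


class CohortDesign:
    """Sample -> phenotype-group assignment plus covariates.

    Backed by a DataFrame with columns ``sample_id``, ``group``, ``age`` and
    an optional numeric covariate block (appended genotype PCs).
    """

    def __init__(self, table: pd.DataFrame, covariates: np.ndarray | None = None) -> None:
        required = {"sample_id", "group", "age"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        if table["sample_id"].duplicated().any():
            dups = table.loc[table["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        unknown = set(table["group"]) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
        self.table = table.reset_index(drop=True)
        if covariates is None:
            covariates = np.empty((len(self.table), 0))
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim != 2 or covariates.shape[0] != len(self.table):
            raise ValueError("covariate block must be (n_samples, k)")
        self.covariates = covariates

    @property
    def samples(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    @property
    def ages(self) -> np.ndarray:
        return self.table["age"].to_numpy(dtype=float)

    def group_sizes(self) -> dict[str, int]:
        return self.table["group"].value_counts().to_dict()

    def indices_of(self, group: str) -> np.ndarray:
        idx = np.flatnonzero((self.table["group"] == group).to_numpy())
        return idx

    def contrast(self, group_a: str, group_b: str):
        """Sample indices and 0/1 phenotype (1 = ``group_a``) for a contrast."""
        ia, ib = self.indices_of(group_a), self.indices_of(group_b)
        if len(ia) == 0 or len(ib) == 0:
            raise ValueError(f"contrast {group_a}:{group_b} has an empty group")
        idx = np.concatenate([ia, ib])
        y = np.concatenate([np.ones(len(ia)), np.zeros(len(ib))])
        return idx, y

    def with_covariates(self, extra: np.ndarray) -> "CohortDesign":
        extra = np.asarray(extra, dtype=float)
        if extra.ndim == 1:
            extra = extra[:, None]
        return CohortDesign(self.table, np.hstack([self.covariates, extra]))
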