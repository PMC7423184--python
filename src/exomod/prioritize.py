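"""Deleterious-variant prioritization and per-gene SiPhy aggregation.

A variant is retained when (i) at least ``min_damaging`` of the 21
predictors call it damaging (unknown verdicts never count), (ii) its
functional class is in the allowed set (nonsynonymous and stop variants
by default), and (iii) every available reference-panel frequency is at or
below the rarity threshold.  Variants with no reference frequency at all
are treated as rare.

Per-gene SiPhy 29-way scores are aggregated to a z-score.  The default is
a Stouffer combination ``sum(s_j) / sqrt(k)`` of per-variant scores
standardized against the empirical mean/sd of all scored variants in the
dataset; a plain standardized sum is available by option.  This
aggregation is a documented reconstruction -- the combination rule behind
published per-gene conservation z-scores is not uniquely determined by
the score itself -- so absolute z values should be compared only within a
dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    CohortDesign,
    GenotypeMatrix,
    MISSING,
    PredictionProfile,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterCriteria:
    """Thresholds of the consensus prioritization filter."""

    min_damaging: int = 17
    max_pop_freq: float = 0.01
    allowed_func_classes: frozenset[str] = frozenset(
        {"nonsynonymous", "stopgain", "stoploss"}
    )

    def __post_init__(self) -> None:
        if not 0 <= self.min_damaging <= 21:
            raise ValueError("min_damaging must lie in [0, 21]")
        if not 0.0 <= self.max_pop_freq <= 1.0:
            raise ValueError("max_pop_freq must lie in [0, 1]")


def consensus_deleterious(profile: PredictionProfile, criteria: FilterCriteria) -> bool:
    """True iff at least ``min_damaging`` predictors call the variant damaging."""
    return profile.damaging_count >= criteria.min_damaging


def passes_filters(profile: PredictionProfile, criteria: FilterCriteria) -> bool:
    """Full prioritization conjunction: consensus AND class AND rarity."""
    if not consensus_deleterious(profile, criteria):
        return False
    if profile.func_class not in criteria.allowed_func_classes:
        return False
    ref = profile.max_ref_freq
    return ref is None or ref <= criteria.max_pop_freq


@dataclass
class PrioritizationResult:
    """Retained variants overall, per phenotype group, and the Venn partition."""

    retained: list[str]
    per_group: dict[str, list[str]]
    venn: dict[frozenset, list[str]] = field(default_factory=dict)
    missing_profile: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (key, group)
            for group, keys in sorted(self.per_group.items())
            for key in keys
        ]
        return pd.DataFrame(rows, columns=["variant", "group"])


def prioritize(
    matrix: GenotypeMatrix,
    profiles: dict[str, PredictionProfile],
    criteria: FilterCriteria,
    cohort: CohortDesign,
) -> PrioritizationResult:
    """Apply the consensus filter; report per-group retained sets.

    A variant belongs to a group's list when it passes all filters and at
    least one sample of the group carries the alternate allele.  Variants
    lacking an annotation profile are excluded and logged.  The ``venn``
    field partitions the union of group lists by the exact subset of
    groups each variant appears in (the cross-group overlap structure).
    """
    missing = [k for k in matrix.variant_keys if k not in profiles]
    if missing:
        logger.warning("%d variants lack annotation profiles; excluded", len(missing))

    retained = [
        k for k in matrix.variant_keys
        if k in profiles and passes_filters(profiles[k], criteria)
    ]
    retained_idx = np.array([matrix.variant_index(k) for k in retained], dtype=int)

    groups = sorted(set(cohort.groups))
    per_group: dict[str, list[str]] = {}
    membership: dict[str, set[str]] = {k: set() for k in retained}
    for g in groups:
        idx = cohort.indices_of(g)
        if len(retained_idx):
            d = matrix.dosages[np.ix_(idx, retained_idx)]
            present = (np.where(d == MISSING, 0, d) > 0).any(axis=0)
        else:
            present = np.empty(0, dtype=bool)
        keys = [k for k, p in zip(retained, present) if p]
        per_group[g] = keys
        for k in keys:
            membership[k].add(g)

    venn: dict[frozenset, list[str]] = {}
    for k, cell in membership.items():
        if cell:
            venn.setdefault(frozenset(cell), []).append(k)

    return PrioritizationResult(
        retained=retained, per_group=per_group, venn=venn, missing_profile=missing
    )


def aggregate_siphy(
    scores: np.ndarray,
    dataset_mean: float,
    dataset_sd: float,
    method: str = "stouffer",
) -> tuple[float, int]:
    """Aggregate per-variant SiPhy scores of one gene to a z-score.

    Scores are standardized against the dataset-wide mean/sd, then combined
    as ``sum(s)/sqrt(k)`` (``stouffer``, default) or ``sum(s)`` (``sum``).
    Returns ``(z, k)``.  Raises when no scores are given.
    """
    scores = np.asarray(scores, dtype=float)
    scores = scores[~np.isnan(scores)]
    k = len(scores)
    if k == 0:
        raise ValueError("no SiPhy-scored variants to aggregate")
    if dataset_sd <= 0:
        raise ValueError("dataset SiPhy sd must be positive")
    s = (scores - dataset_mean) / dataset_sd
    if method == "stouffer":
        return float(s.sum() / np.sqrt(k)), k
    if method == "sum":
        return float(s.sum()), k
    raise ValueError(f"unknown aggregation method {method!r}")


def siphy_gene_table(
    assignments: dict[str, list[int]],
    variant_keys: list[str],
    profiles: dict[str, PredictionProfile],
    retained: list[str] | None = None,
    method: str = "stouffer",
) -> pd.DataFrame:
    """Per-gene aggregated SiPhy z-scores over (optionally filtered) variants.

    Standardization uses all scored variants in the dataset, matching the
    convention that gene z-scores are comparable within one callset.  Genes
    with no scored retained variant are omitted (absent, not zero).
    """
    all_scores = np.array(
        [p.siphy29 for p in profiles.values() if p.siphy29 is not None], dtype=float
    )
    if all_scores.size < 2:
        raise ValueError("need at least two scored variants to standardize")
    mean, sd = float(all_scores.mean()), float(all_scores.std(ddof=1))
    keep = set(retained) if retained is not None else None

    rows = []
    for gene, idx in sorted(assignments.items()):
        scores = []
        for i in idx:
            key = variant_keys[i]
            if keep is not None and key not in keep:
                continue
            prof = profiles.get(key)
            if prof is not None and prof.siphy29 is not None:
                scores.append(prof.siphy29)
        if not scores:
            continue
        z, k = aggregate_siphy(np.array(scores), mean, sd, method=method)
        rows.append((gene, k, z))
    return pd.DataFrame(rows, columns=["gene", "n_snps", "siphy_z"])
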