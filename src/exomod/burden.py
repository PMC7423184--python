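"""Per-gene mutational-burden test against a neutral length-proportional null.

The null model allocates the group's total count of qualifying
(deleterious / loss-of-function) variants across genes in proportion to
each gene's flanked length -- the mutational-target logic of de novo
burden testing, calibrated so expectations sum exactly to the observed
total.  Each gene's observed count of distinct qualifying variants is
then tested against ``Poisson(expected)`` with an upper-tail p-value;
multiplicity is handled by Benjamini-Hochberg within the group.

The null is deliberately isolated behind ``estimate_null_expectations``
so alternatives (per-gene mutability tables, drift-inflated rates) can be
swapped in without touching the test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import poisson
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneRegion


@dataclass
class BurdenResult:
    gene: str
    group: str
    observed_count: int
    expected_count: float
    p_upper: float
    q_value: float


def estimate_null_expectations(
    genes: list[GeneRegion], counts: dict[str, int]
) -> dict[str, float]:
    """Length-proportional neutral allocation of the observed total.

    ``expected_g = T * L_g / sum(L)`` with ``L_g`` the flanked gene length
    and ``T`` the total qualifying count; expectations sum to ``T`` exactly.
    """
    if len(genes) < 2:
        raise ValueError("need at least two genes to calibrate the null")
    lengths = np.array([g.flanked_length for g in genes], dtype=float)
    total_length = lengths.sum()
    if total_length <= 0:
        raise ValueError("total gene length is zero")
    total = float(sum(counts.get(g.symbol, 0) for g in genes))
    return {
        g.symbol: total * length / total_length
        for g, length in zip(genes, lengths)
    }


def burden_test(observed: int, expected: float) -> float:
    """Upper-tail Poisson p-value ``P(Poisson(expected) >= observed)``."""
    if expected <= 0:
        raise ValueError("expected count must be positive")
    if observed < 0:
        raise ValueError("observed count must be non-negative")
    return float(poisson.sf(observed - 1, expected))


def burden_table(
    genes: list[GeneRegion],
    counts: dict[str, int],
    group: str = "",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Burden test for every gene of one group, BH-adjusted across genes."""
    expectations = estimate_null_expectations(genes, counts)
    symbols = [g.symbol for g in genes]
    observed = np.array([counts.get(s, 0) for s in symbols], dtype=int)
    expected = np.array([expectations[s] for s in symbols], dtype=float)
    p_upper = poisson.sf(observed - 1, expected)
    _, q_values, _, _ = multipletests(p_upper, method="fdr_bh")
    return pd.DataFrame(
        {
            "comparison": group,
            "gene": symbols,
            "n_variants": observed,
            "expected": expected,
            "statistic": observed,
            "p_analytic": p_upper,
            "q_value": q_values,
            "significant": q_values <= alpha,
        }
    )


def randomized_pit(observed: np.ndarray, expected: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Randomized probability integral transform of Poisson upper-tail p's.

    ``p' = P(X > obs) + U * P(X = obs)`` is exactly Uniform(0,1) when the
    Poisson null holds, which makes the discrete test's calibration
    checkable with a continuous goodness-of-fit test.
    """
    observed = np.asarray(observed)
    expected = np.asarray(expected, dtype=float)
    upper_strict = poisson.sf(observed, expected)
    point = poisson.pmf(observed, expected)
    return upper_strict + rng.random(len(observed)) * point
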