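"""Gene-set over-representation of result gene lists.

A hit list (e.g. genes flagged by the burden or rare-variant analyses) is
tested against each set of a GMT pathway collection with the upper-tail
hypergeometric probability of the observed overlap given the universe,
plus fold-enrichment (observed / expected overlap), BH-adjusted across
sets.  The universe defaults to all genes of the gene-model table and is
overridable; no external database is queried.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets harmonized to a universe of gene symbols."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    @classmethod
    def from_sets(cls, sets: dict[str, set[str]], universe: set[str]) -> "GeneSetCollection":
        harmonized: dict[str, frozenset[str]] = {}
        for name, members in sets.items():
            inside = frozenset(members) & frozenset(universe)
            if not inside:
                logger.warning("dropping empty gene set %r after harmonization", name)
                continue
            harmonized[name] = inside
        return cls(sets=harmonized, universe=frozenset(universe))

    @classmethod
    def from_gmt(cls, path: str, universe: set[str]) -> "GeneSetCollection":
        from gseapy.parser import read_gmt

        raw = read_gmt(path)
        return cls.from_sets({k: set(v) for k, v in raw.items()}, universe)


def hypergeometric_enrichment(
    hits: list[str], collection: GeneSetCollection
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``hits`` in each set.

    Hits outside the universe are logged and dropped; an empty (effective)
    hit list raises.  Returns a table with columns
    ``set, overlap, size, fold, p, q`` sorted by p.
    """
    universe = collection.universe
    hit_set = set(hits)
    outside = hit_set - universe
    if outside:
        logger.warning("dropping %d hits outside the universe: %s",
                       len(outside), sorted(outside)[:10])
    hit_set &= universe
    if not hit_set:
        raise ValueError("no hits remain inside the universe")

    m = len(universe)
    n_hits = len(hit_set)
    rows = []
    for name, members in sorted(collection.sets.items()):
        size = len(members)
        overlap = len(hit_set & members)
        expected = size * n_hits / m
        fold = overlap / expected if expected > 0 else 0.0
        p = float(hypergeom.sf(overlap - 1, m, size, n_hits))
        rows.append((name, overlap, size, fold, p))
    df = pd.DataFrame(rows, columns=["set", "overlap", "size", "fold", "p"])
    if len(df):
        _, q, _, _ = multipletests(df["p"], method="fdr_bh")
        df["q"] = q
    else:
        df["q"] = np.empty(0)
    return df.sort_values("p", kind="stable").reset_index(drop=True)
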