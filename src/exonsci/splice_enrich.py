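"""Splicing-factor target enrichment among DEE parent genes.

For each differentially expressed splicing factor, the genes tested for
differential expression (the universe) are cross-classified as DEE-parent vs
non-DEE-parent and CLIP target vs non-target, and enrichment of targets among
DEE parents is assessed by a one-sided (greater) Fisher exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def select_de_splicing_factors(deg_table: pd.DataFrame,
                               splicing_factors: set[str]) -> pd.DataFrame:
    """Intersect the DEG list with a known splicing-factor gene set.

    Returns the DEG rows for splicing factors (direction of change retained
    via log2fc).  An empty factor set is an error; an empty intersection is
    a valid (empty) result.
    """
    if not splicing_factors:
        raise ValueError("splicing factor gene set is empty")
    degs = deg_table[deg_table["is_DEG"]] if "is_DEG" in deg_table else deg_table
    return degs[degs["feature_id"].isin(splicing_factors)].reset_index(drop=True)


@dataclass
class EnrichmentResult:
    factor_id: str
    table: tuple[tuple[int, int], tuple[int, int]]  # rows: DEE-parent / non; cols: target / non
    odds_ratio: float
    p_value: float
    n_dee_targets: int  # DEE parents that are targets of this factor

    def as_row(self) -> dict:
        (a, b), (c, d) = self.table
        return {"factor_id": self.factor_id, "dee_target": a, "dee_nontarget": b,
                "nondee_target": c, "nondee_nontarget": d,
                "odds_ratio": self.odds_ratio, "p": self.p_value,
                "n_dee_targets": self.n_dee_targets}


def fisher_target_enrichment(dee_parents: set[str], universe: set[str],
                             targets_per_factor: dict[str, set[str]]
                             ) -> list[EnrichmentResult]:
    """One-sided Fisher exact test per splicing factor.

    ``dee_parents`` must lie within ``universe``; target genes outside the
    universe are dropped (logged).  p is the hypergeometric upper tail of the
    2x2 table; the odds ratio is the sample odds ratio (inf representable).
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not dee_parents <= universe:
        raise ValueError("dee_parents must be a subset of the universe")
    results = []
    for factor, targets in sorted(targets_per_factor.items()):
        dropped = targets - universe
        if dropped:
            logger.info("factor %s: %d targets outside universe dropped",
                        factor, len(dropped))
        t = targets & universe
        a = len(dee_parents & t)
        b = len(dee_parents - t)
        c = len(t - dee_parents)
        d = len(universe) - a - b - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        results.append(EnrichmentResult(
            factor_id=factor, table=((a, b), (c, d)),
            odds_ratio=float(odds), p_value=float(p), n_dee_targets=a))
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in results])
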