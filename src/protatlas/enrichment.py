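"""Hypergeometric over-representation analysis (ORA) and the dynamics of
enriched process sets across adjacent stages.

ORA tests, for each named gene set, whether the query contains more of the
set's genes than a hypergeometric draw from the universe would yield:
p = P(X >= k) with X ~ Hypergeom(N, K, n).  Benjamini-Hochberg controls the
FDR across the sets of one query; a set is "enriched" at q < 0.05.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from ._stats import bh_adjust
from .core import GeneSetCollection


def ora(query: Iterable[str], sets: GeneSetCollection,
        universe: Iterable[str], q_threshold: float = 0.05) -> pd.DataFrame:
    """Over-representation of ``query`` in each set, within ``universe``.

    Genes outside the universe are dropped from both query and sets (the
    standard ORA background convention).  Returns one row per set with the
    overlap, exact upper-tail hypergeometric p and BH q.
    """
    uni = frozenset(universe)
    if not uni:
        raise ValueError("empty universe")
    q = frozenset(query) & uni
    rows = []
    n_uni = len(uni)
    for name, members in sorted(sets.items()):
        k_set = members & uni
        overlap = q & k_set
        k, big_k, n = len(overlap), len(k_set), len(q)
        p = float(hypergeom.sf(k - 1, n_uni, big_k, n)) if k > 0 else 1.0
        rows.append((name, k, n, big_k, n_uni, p, sorted(overlap)))
    df = pd.DataFrame(rows, columns=["set_name", "k", "n_query", "set_size",
                                     "universe_size", "p", "overlap_genes"])
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["enriched"] = df["q"] < q_threshold
    return df.sort_values(["p", "set_name"], kind="mergesort").reset_index(drop=True)


def overlap_rate(sets_a: Iterable[str], sets_b: Iterable[str],
                 rule: str = "union") -> float:
    """Percentage overlap between the enriched-set names of two adjacent
    stages.

    ``rule="union"``: 100*|A∩B|/|A∪B| (symmetric, Jaccard); ``rule="later"``:
    100*|A∩B|/|B| (share of the later stage's processes already present).
    Returns NaN when the denominator is empty.
    """
    a, b = set(sets_a), set(sets_b)
    if rule == "union":
        denom = len(a | b)
    elif rule == "later":
        denom = len(b)
    else:
        raise ValueError(f"unknown overlap rule {rule!r}")
    if denom == 0:
        return float("nan")
    return 100.0 * len(a & b) / denom


def newly_enriched(sets_a: Iterable[str], sets_b: Iterable[str]) -> set[str]:
    """Process names enriched at the later stage but not the earlier: B \\ A."""
    return set(sets_b) - set(sets_a)


def enrichment_by_stage(marker_sets: dict[str, set[str]], collection: GeneSetCollection,
                        universe: Iterable[str], q_threshold: float = 0.05) -> dict[str, pd.DataFrame]:
    """Run ORA per stage on its marker-protein query set."""
    return {stage: ora(genes, collection, universe, q_threshold)
            for stage, genes in marker_sets.items()}


def overlap_curve(enrichments: dict[str, pd.DataFrame], stage_order: Sequence[str]) -> pd.DataFrame:
    """Adjacent-stage overlap rates (both denominator rules) and the newly
    enriched set names, over consecutive stages with results."""
    stages = [s for s in stage_order if s in enrichments]
    rows = []
    for s0, s1 in zip(stages, stages[1:]):
        a = set(enrichments[s0].loc[enrichments[s0]["enriched"], "set_name"])
        b = set(enrichments[s1].loc[enrichments[s1]["enriched"], "set_name"])
        rows.append((f"{s1} vs {s0}", len(a), len(b), len(a & b),
                     overlap_rate(a, b, "union"), overlap_rate(a, b, "later"),
                     ";".join(sorted(newly_enriched(a, b)))))
    return pd.DataFrame(rows, columns=["comparison", "n_earlier", "n_later", "n_overlap",
                                       "overlap_pct_union", "overlap_pct_later",
                                       "newly_enriched"])
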