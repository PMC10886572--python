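"""Candidate target cell types of sEV-enriched miRNAs.

Pools the target mRNAs of the secretory miRNAs, tests each cell-type
marker set for over-representation in the pool with the one-sided
hypergeometric test, and exports per-cell-type bipartite subnetworks of
secretory miRNAs and the marker genes they target.  The same
over-representation operation serves functional annotation when handed
pathway gene sets (GMT) instead of marker tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .differential import adjust_pvalues_bh
from .io_formats import InteractionTable, MarkerTable

logger = logging.getLogger(__name__)


@dataclass
class TargetPool:
    """Per-miRNA target sets, their pooled union, and the gene universe."""

    per_mirna: dict[str, frozenset[str]]
    pooled: frozenset[str]
    universe: frozenset[str]


def collect_target_pool(
    secretory,
    interactions: InteractionTable,
    universe_policy: str = "interaction",
    marker_genes=None,
) -> TargetPool:
    """Pool the target genes of the secretory miRNAs.

    The gene universe is, under the default ``interaction`` policy, every
    gene targeted by at least one miRNA in the interaction table; under
    ``union`` it additionally includes all marker genes.  Secretory miRNAs
    without any edge contribute nothing (logged).
    """
    if interactions.kind != "mirna-mrna":
        raise ValueError("interactions must be of kind 'mirna-mrna'")
    if universe_policy not in ("interaction", "union"):
        raise ValueError("universe_policy must be 'interaction' or 'union'")
    universe = set(interactions.edges["target"])
    if universe_policy == "union":
        universe |= set().union(*marker_genes) if marker_genes else set()

    grouped = interactions.edges.groupby("source")["target"].agg(set)
    per_mirna: dict[str, frozenset[str]] = {}
    missing = 0
    for mirna in sorted(set(secretory)):
        targets = set(grouped.get(mirna, set())) & universe
        if not targets:
            missing += 1
            continue
        per_mirna[mirna] = frozenset(targets)
    if missing:
        logger.info("%d secretory miRNAs have no targets in the table", missing)
    if not per_mirna:
        raise ValueError("no secretory miRNA has any target in the interaction table")
    pooled = frozenset(set().union(*per_mirna.values()))
    return TargetPool(
        per_mirna=per_mirna, pooled=pooled, universe=frozenset(universe)
    )


def hypergeometric_p(N: int, K: int, n: int, k: int) -> float:
    """One-sided over-representation p-value P[X >= k], X ~ Hypergeom(N, K, n)."""
    if k > min(K, n):
        raise ValueError("overlap k cannot exceed min(set size, pool size)")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeometric_overrepresentation(
    pool: TargetPool, sets: MarkerTable | Mapping[str, set]
) -> pd.DataFrame:
    """Over-representation of each gene set within the pooled targets.

    For each set, counts the overlap k between the pooled target genes
    (size n) and the set restricted to the universe (size K, universe
    size N), and computes the exact one-sided hypergeometric tail.
    BH adjustment across tested sets; rows sorted by p.
    """
    if not pool.universe:
        raise ValueError("empty gene universe")
    if not pool.pooled:
        raise ValueError("empty target pool")
    items = sets.items() if hasattr(sets, "items") else sets
    N = len(pool.universe)
    n = len(pool.pooled)
    rows = []
    for name, genes in items:
        restricted = frozenset(genes) & pool.universe
        overlap = restricted & pool.pooled
        k, K = len(overlap), len(restricted)
        p = hypergeometric_p(N, K, n, k) if K else 1.0
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": K,
                "pool_size": n,
                "universe_size": N,
                "p": p,
                "neg_log10_p": -np.log10(p) if p > 0 else np.inf,
                "overlap_genes": ",".join(sorted(overlap)),
            }
        )
    table = pd.DataFrame(rows).set_index("set_name")
    table["p_adjusted"] = adjust_pvalues_bh(table["p"].to_numpy())
    return table.loc[
        sorted(table.index, key=lambda s: (table.at[s, "p"], s))
    ]


@dataclass
class CellTypeScreenResult:
    enrichment: pd.DataFrame
    subnetworks: dict[str, pd.DataFrame] = field(default_factory=dict)
    headline: str | None = None  # globally most significant cell type


def cell_type_screen(
    diff: pd.DataFrame,
    interactions: InteractionTable,
    markers: MarkerTable,
    p_adj_threshold: float = 0.05,
    universe_policy: str = "interaction",
) -> CellTypeScreenResult:
    """End-to-end target-cell-type inference from a classified table.

    Takes a differential table with the ``compartment`` column filled,
    pools the secretory miRNAs' targets, tests every marker set, and for
    each significant cell type exports the bipartite subnetwork of
    secretory miRNAs -> target genes that are that type's markers.
    """
    if "compartment" not in diff.columns:
        raise ValueError("differential table must be classified first")
    secretory = diff.index[diff["compartment"] == "secretory"]
    if len(secretory) == 0:
        raise ValueError("no secretory miRNAs after classification")
    pool = collect_target_pool(
        secretory,
        interactions,
        universe_policy=universe_policy,
        marker_genes=list(markers.markers.values()),
    )
    enrichment = hypergeometric_overrepresentation(pool, markers)
    headline = enrichment.index[0] if len(enrichment) else None

    subnetworks: dict[str, pd.DataFrame] = {}
    for cell_type in enrichment.index[enrichment["p_adjusted"] < p_adj_threshold]:
        marker_genes = markers.markers[cell_type]
        rows = [
            (mirna, gene)
            for mirna, targets in sorted(pool.per_mirna.items())
            for gene in sorted(targets & marker_genes)
        ]
        subnetworks[cell_type] = pd.DataFrame(rows, columns=["source", "target"])
    return CellTypeScreenResult(
        enrichment=enrichment, subnetworks=subnetworks, headline=headline
    )
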