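"""RNA-binding-protein enrichment among compartment-enriched miRNAs.

For each RBP, a 2x2 contingency table counts interactions with the
compartment-enriched miRNAs versus the background (the remaining miRNAs of
the detected universe; the two groups are disjoint).  Pearson's chi-squared
test without continuity correction scores each table, with a two-sided
Fisher exact fallback for small expected counts; BH adjustment across RBPs;
ranking by the observed/expected interaction ratio among significant RBPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential import adjust_pvalues_bh
from .io_formats import InteractionTable

logger = logging.getLogger(__name__)


@dataclass
class RbpContingency:
    """Counts for one RBP: enriched bound/unbound (a, b), background (c, d)."""

    rbp_id: str
    a: int
    b: int
    c: int
    d: int

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def build_contingencies(
    interactions: InteractionTable, enriched, universe
) -> list[RbpContingency]:
    """One 2x2 table per RBP with at least one interaction in the universe.

    ``enriched`` must be a subset of ``universe`` (the miRNAs present in
    the differential table); edges to miRNAs outside the universe are
    ignored with a logged count.
    """
    if interactions.kind != "mirna-rbp":
        raise ValueError("interactions must be of kind 'mirna-rbp'")
    enriched = set(enriched)
    universe = set(universe)
    if not enriched <= universe:
        raise ValueError("enriched miRNAs must be a subset of the universe")
    background = universe - enriched

    in_universe = interactions.edges["source"].isin(universe)
    dropped = int((~in_universe).sum())
    if dropped:
        logger.info("%d interactions outside the detected universe ignored", dropped)
    edges = interactions.edges[in_universe]

    out = []
    for rbp_id, group in edges.groupby("target", sort=True):
        bound = set(group["source"])
        a = len(bound & enriched)
        c = len(bound & background)
        out.append(
            RbpContingency(
                rbp_id=str(rbp_id),
                a=a,
                b=len(enriched) - a,
                c=c,
                d=len(background) - c,
            )
        )
    return out


def chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-squared (no continuity correction) on a 2x2 table.

    Returns (statistic, p) with p from the chi-square distribution with
    1 degree of freedom; equivalent to the closed form
    ``n * (ad - bc)**2 / (r1 * r2 * c1 * c2)``.
    """
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("zero-margin table is untestable")
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(stat), float(stats.chi2.sf(stat, df=1))


@dataclass
class RbpScreenConfig:
    small_expected_policy: str = "exact"  # "exact" or "flag" for expected < 5
    p_adj_threshold: float = 0.05
    top_k: int = 10


def rbp_screen(
    contingencies: list[RbpContingency], cfg: RbpScreenConfig | None = None
) -> pd.DataFrame:
    """Test every RBP table and rank the over-represented RBPs.

    Tables with any expected cell below 5 are flagged; under the default
    policy they are tested with a two-sided Fisher exact test instead of
    chi-squared.  Zero-margin tables are marked untestable and excluded
    from ranking.  The result carries ``rank`` (by observed/expected ratio
    among RBPs with adjusted p below the threshold; ties broken by p then
    id) and ``top`` (membership of the top-``top_k`` report).
    """
    cfg = cfg or RbpScreenConfig()
    if cfg.small_expected_policy not in ("exact", "flag"):
        raise ValueError("small_expected_policy must be 'exact' or 'flag'")
    rows = []
    for ct in contingencies:
        if ct.total < 1:
            raise ValueError(f"empty table for {ct.rbp_id}")
        a, b, c, d = ct.a, ct.b, ct.c, ct.d
        n = ct.total
        r1, c1 = a + b, a + c
        untestable = min(a + b, c + d, a + c, b + d) == 0
        enriched_rate = a / r1 if r1 else np.nan
        overall_rate = c1 / n
        ratio = enriched_rate / overall_rate if overall_rate > 0 else np.nan
        expected_min = (
            min((a + b) * (a + c), (a + b) * (b + d), (c + d) * (a + c), (c + d) * (b + d)) / n
        )
        small = expected_min < 5
        if untestable:
            stat, p = np.nan, np.nan
        elif small and cfg.small_expected_policy == "exact":
            stat = np.nan
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        else:
            stat, p = chi2_2x2(a, b, c, d)
        rows.append(
            {
                "rbp_id": ct.rbp_id,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "chi2": stat,
                "p": p,
                "obs_exp_ratio": ratio,
                "direction": "over" if (np.isnan(ratio) or ratio >= 1) else "under",
                "small_expected": small,
                "untestable": untestable,
            }
        )
    table = pd.DataFrame(rows).set_index("rbp_id")
    testable = table.index[~table["untestable"]]
    p_adj = pd.Series(np.nan, index=table.index)
    if len(testable):
        p_adj.loc[testable] = adjust_pvalues_bh(table.loc[testable, "p"].to_numpy())
    table["p_adjusted"] = p_adj

    significant = table[
        (~table["untestable"]) & (table["p_adjusted"] < cfg.p_adj_threshold)
    ].copy()
    significant = significant.sort_values(
        ["obs_exp_ratio", "p"], ascending=[False, True], kind="stable"
    )
    significant = significant.loc[
        sorted(
            significant.index,
            key=lambda rid: (
                -significant.at[rid, "obs_exp_ratio"],
                significant.at[rid, "p"],
                rid,
            ),
        )
    ]
    rank = pd.Series(np.nan, index=table.index)
    rank.loc[significant.index] = np.arange(1, len(significant) + 1)
    table["rank"] = rank
    table["top"] = table["rank"] <= cfg.top_k
    return table.sort_values(
        ["rank", "p"], na_position="last", kind="stable"
    )
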