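"""k-mer sorting/retention motif discovery by pre-ranked enrichment.

Every k-mer over {A, C, G, U} (k = 4..7 by default) defines a gene set: the
miRNAs whose mature sequence contains it as a contiguous substring (sets
with fewer than ``min_size`` members are dropped).  Each surviving set is
scored against the log2 fold-change-ranked miRNA list with the weighted
Kolmogorov-Smirnov running-sum enrichment score; significance comes from
size-matched random member sets (gene permutation), normalized to an NES by
the same-sign null mean.  Positive-NES motifs are candidate sEV-sorting
signals, negative-NES motifs candidate cell-retention signals.

The running sum never needs to be materialized to score a set: the signed
maximum deviation is reachable only immediately after a hit (maximum
candidates) or immediately before one (minimum candidates), so the ES is
computed from the sorted hit positions alone.  This is what makes the
permutation null cheap enough to share across thousands of motifs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .differential import adjust_pvalues_bh
from .io_formats import SequenceSet

logger = logging.getLogger(__name__)

ALPHABET = "ACGU"
MIN_SET_SIZE = 6


def enumerate_motifs(k_min: int, k_max: int) -> list[str]:
    """All 4**k strings over {A, C, G, U} for each k, lexicographic order."""
    if k_min < 1 or k_min > k_max:
        raise ValueError("need 1 <= k_min <= k_max")
    motifs: list[str] = []
    for k in range(k_min, k_max + 1):
        motifs.extend("".join(p) for p in itertools.product(ALPHABET, repeat=k))
    return motifs


def build_motif_sets(
    motifs: list[str], sequences: SequenceSet, min_size: int = MIN_SET_SIZE
) -> dict[str, frozenset[str]]:
    """Membership sets: miRNAs whose sequence contains each motif.

    Overlapping occurrences count membership once (binary membership).
    Sets smaller than ``min_size`` are dropped.  Implemented with an
    inverted k-mer index over the sequences, so cost is linear in the total
    sequence length rather than |motifs| x |sequences|.
    """
    bad = [m for m in motifs if set(m) - set(ALPHABET)]
    if bad:
        raise ValueError(f"motif outside alphabet {ALPHABET}: {bad[0]!r}")
    lengths = sorted({len(m) for m in motifs})
    index: dict[str, set[str]] = {}
    for mirna_id, seq in sequences.items():
        for k in lengths:
            for start in range(len(seq) - k + 1):
                index.setdefault(seq[start : start + k], set()).add(mirna_id)
    wanted = set(motifs)
    return {
        kmer: frozenset(members)
        for kmer, members in index.items()
        if kmer in wanted and len(members) >= min_size
    }


# ---------------------------------------------------------------------------
# Enrichment score
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentScore:
    es: float
    running: np.ndarray  # running-sum value after each ranked position
    leading_edge: list[str]


def _es_from_hit_positions(
    positions: np.ndarray, abs_weights: np.ndarray, n_total: int
) -> tuple[np.ndarray, np.ndarray]:
    """Signed maximum deviation of the running sum for batched hit sets.

    Parameters
    ----------
    positions
        (batch, m) sorted 0-based ranks of the hits.
    abs_weights
        (n_total,) nonnegative per-position hit increments before
        normalization (``|metric|**weight``).
    n_total
        Length of the ranked list.

    Returns
    -------
    es, extremum_index
        (batch,) signed ES and the hit index (0-based within the set) of
        the extremum that realized it.
    """
    batch, m = positions.shape
    if m == 0 or m >= n_total:
        raise ValueError("set must hit some but not all ranked positions")
    hw = abs_weights[positions]
    totals = hw.sum(axis=1, keepdims=True)
    # all-zero metrics inside the set: fall back to equal increments
    zero = totals[:, 0] <= 0
    if zero.any():
        hw = hw.copy()
        hw[zero] = 1.0
        totals = hw.sum(axis=1, keepdims=True)
    cum = np.cumsum(hw, axis=1) / totals
    miss_step = 1.0 / (n_total - m)
    k = np.arange(1, m + 1)
    after = cum - (positions + 1 - k) * miss_step  # value just after each hit
    before = np.concatenate(
        [np.zeros((batch, 1)), cum[:, :-1]], axis=1
    ) - (positions - (k - 1)) * miss_step  # value just before each hit
    hi = after.max(axis=1)
    lo = np.minimum(before.min(axis=1), 0.0)
    pick_hi = hi >= -lo - 1e-12  # ties resolve to the positive deviation
    es = np.where(pick_hi, hi, lo)
    idx = np.where(pick_hi, after.argmax(axis=1), before.argmin(axis=1))
    return es, idx


def enrichment_score(
    ranked: pd.Series, members, weight: float = 1.0
) -> EnrichmentScore:
    """Weighted KS enrichment score of a member set on a ranked list.

    ``ranked`` maps miRNA id -> ranking metric, already in rank order
    (descending metric).  A hit at position i adds
    ``|metric_i|**weight / sum_hits`` and a miss subtracts ``1/(N - N_h)``;
    the ES is the signed maximum deviation of the running sum.  The leading
    edge is the hits at or before the extremum (at or after it for a
    negative ES).  Members absent from the ranked list are ignored with a
    logged count.
    """
    ids = list(ranked.index)
    id_pos = {mid: i for i, mid in enumerate(ids)}
    members = set(members)
    outside = len(members - id_pos.keys())
    if outside:
        logger.info("%d set members absent from the ranked list; ignored", outside)
    hit_pos = np.sort([id_pos[m] for m in members if m in id_pos])
    n = len(ids)
    if len(hit_pos) == 0:
        raise ValueError("set has no members on the ranked list")
    if len(hit_pos) == n:
        raise ValueError("set covers the entire ranked list; ES is degenerate")

    metric = ranked.to_numpy(dtype=float)
    abs_w = np.abs(metric) ** weight
    es_arr, idx_arr = _es_from_hit_positions(hit_pos[None, :], abs_w, n)
    es, extremum = float(es_arr[0]), int(idx_arr[0])

    is_hit = np.zeros(n, dtype=bool)
    is_hit[hit_pos] = True
    hw = abs_w.copy()
    if hw[hit_pos].sum() <= 0:
        hw = np.ones(n)
    increments = np.where(is_hit, hw / hw[hit_pos].sum(), -1.0 / (n - len(hit_pos)))
    running = np.cumsum(increments)

    if es >= 0:
        leading = [ids[p] for p in hit_pos[: extremum + 1]]
    else:
        leading = [ids[p] for p in hit_pos[extremum:]]
    return EnrichmentScore(es=es, running=running, leading_edge=leading)


# ---------------------------------------------------------------------------
# Permutation null and NES
# ---------------------------------------------------------------------------


@dataclass
class NesResult:
    es: float
    nes: float
    p_perm: float
    low_power: bool  # fewer than 10 same-sign null draws; p is an upper bound
    leading_edge: list[str]


def _nes_and_p(es: float, null_es: np.ndarray) -> tuple[float, float, bool]:
    """NES and permutation p from a null ES sample, sign-stratified."""
    if es == 0.0:
        return 0.0, 1.0, False
    same_sign = null_es > 0 if es > 0 else null_es < 0
    n_same = int(same_sign.sum())
    low_power = n_same < 10
    denom = np.abs(null_es[same_sign]).mean() if n_same else np.abs(es)
    nes = es / denom if denom > 0 else 0.0
    extreme = int((np.abs(null_es[same_sign]) >= abs(es)).sum())
    p = (1.0 + extreme) / (1.0 + n_same) if n_same else 1.0
    return float(nes), float(p), low_power


def permutation_nes(
    ranked: pd.Series,
    members,
    n_perm: int = 1000,
    seed: int | None = None,
    weight: float = 1.0,
) -> NesResult:
    """NES and permutation p for one member set.

    The null is ``n_perm`` random member sets of identical size drawn
    without replacement from the ranked ids; NES = ES divided by the mean
    |null ES| of the same sign; p is the plus-one permutation estimator
    over same-sign nulls.  Deterministic given ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    score = enrichment_score(ranked, members, weight=weight)
    id_pos = {mid: i for i, mid in enumerate(ranked.index)}
    m = len({mem for mem in members if mem in id_pos})
    n = len(ranked)
    rng = np.random.default_rng(seed)
    null_pos = np.sort(
        rng.random((n_perm, n)).argpartition(m - 1, axis=1)[:, :m], axis=1
    )
    abs_w = np.abs(ranked.to_numpy(dtype=float)) ** weight
    null_es, _ = _es_from_hit_positions(null_pos, abs_w, n)
    nes, p, low_power = _nes_and_p(score.es, null_es)
    return NesResult(
        es=score.es, nes=nes, p_perm=p, low_power=low_power,
        leading_edge=score.leading_edge,
    )


# ---------------------------------------------------------------------------
# Full screen
# ---------------------------------------------------------------------------


@dataclass
class MotifScreenConfig:
    k_min: int = 4
    k_max: int = 7
    min_size: int = MIN_SET_SIZE
    weight: float = 1.0
    n_perm: int = 1000
    seed: int = 0
    fdr_threshold: float = 0.05


def motif_screen(
    diff: pd.DataFrame, sequences: SequenceSet, cfg: MotifScreenConfig | None = None
) -> pd.DataFrame:
    """Screen every surviving k-mer motif for sorting/retention enrichment.

    Builds the ranked list from the differential table (log2fc descending,
    ties by id), the membership sets from the sequences, then computes
    ES/NES/permutation p per motif.  BH FDR is reported both within each k
    ("fdr_per_k") and jointly across all motifs ("fdr_joint").  One shared
    permutation block per set size serves as the null for all motifs of
    that size, which keeps the screen at a single O(n_perm x N) shuffle.

    Output is sorted by NES descending: top rows are candidate sEV-sorting
    motifs, bottom rows candidate cell-retention motifs.
    """
    from .differential import ranked_list  # local import to avoid cycle at import time

    cfg = cfg or MotifScreenConfig()
    ranked = ranked_list(diff)
    shared = [mid for mid in ranked.index if mid in sequences]
    if len(shared) < cfg.min_size:
        raise ValueError("differential table and sequences share too few miRNAs")
    ranked = ranked.loc[shared]
    n = len(ranked)

    motifs = enumerate_motifs(cfg.k_min, cfg.k_max)
    sets = build_motif_sets(motifs, sequences, min_size=cfg.min_size)
    # re-filter against the ranked universe (sequences absent from the
    # differential table do not count toward set size)
    ranked_ids = set(ranked.index)
    sets = {
        motif: frozenset(mem & ranked_ids)
        for motif, mem in sets.items()
        if len(mem & ranked_ids) >= cfg.min_size and len(mem & ranked_ids) < n
    }
    if not sets:
        raise ValueError("no motif set survives the minimum-size filter")

    id_pos = {mid: i for i, mid in enumerate(ranked.index)}
    abs_w = np.abs(ranked.to_numpy(dtype=float)) ** cfg.weight

    rng = np.random.default_rng(cfg.seed)
    perm_block = rng.random((cfg.n_perm, n)).argsort(axis=1)
    null_cache: dict[int, np.ndarray] = {}

    def null_for_size(m: int) -> np.ndarray:
        if m not in null_cache:
            pos = np.sort(perm_block[:, :m], axis=1)
            null_cache[m], _ = _es_from_hit_positions(pos, abs_w, n)
        return null_cache[m]

    rows = []
    for motif, members in sorted(sets.items()):
        positions = np.sort([id_pos[mem] for mem in members])
        es_arr, idx_arr = _es_from_hit_positions(positions[None, :], abs_w, n)
        es, extremum = float(es_arr[0]), int(idx_arr[0])
        nes, p, low_power = _nes_and_p(es, null_for_size(len(positions)))
        if es >= 0:
            leading = [ranked.index[p_] for p_ in positions[: extremum + 1]]
        else:
            leading = [ranked.index[p_] for p_ in positions[extremum:]]
        rows.append(
            {
                "motif": motif,
                "k": len(motif),
                "size": len(positions),
                "es": es,
                "nes": nes,
                "p_perm": p,
                "low_power": low_power,
                "direction": "sev_sorting" if nes >= 0 else "cell_retention",
                "leading_edge": ",".join(leading),
            }
        )
    table = pd.DataFrame(rows).set_index("motif")
    table["fdr_joint"] = adjust_pvalues_bh(table["p_perm"].to_numpy())
    fdr_per_k = pd.Series(np.nan, index=table.index)
    for k, sub in table.groupby("k"):
        fdr_per_k.loc[sub.index] = adjust_pvalues_bh(sub["p_perm"].to_numpy())
    table["fdr_per_k"] = fdr_per_k
    return table.sort_values(["nes", "motif"], ascending=[False, True])
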