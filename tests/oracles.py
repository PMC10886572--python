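"""Independent brute-force reference implementations used only by tests.

Each oracle is a literal transcription of the defining formula or
procedure, deliberately naive and separate from the package's optimized
code paths.
"""

from __future__ import annotations

import math

import numpy as np


def naive_enrichment_walk(metrics, is_hit, weight=1.0):
    """O(N) literal running-sum walk; returns (es, running values)."""
    metrics = np.asarray(metrics, dtype=float)
    is_hit = np.asarray(is_hit, dtype=bool)
    n = len(metrics)
    n_hit = int(is_hit.sum())
    hit_weights = np.abs(metrics[is_hit]) ** weight
    total = hit_weights.sum()
    if total <= 0:
        hit_weights = np.ones(n_hit)
        total = float(n_hit)
    miss_step = 1.0 / (n - n_hit)
    running = []
    value = 0.0
    k = 0
    for i in range(n):
        if is_hit[i]:
            value += hit_weights[k] / total
            k += 1
        else:
            value -= miss_step
        running.append(value)
    running = np.array(running)
    hi = running.max()
    lo = running.min()
    es = hi if hi >= -lo - 1e-12 else lo  # ties prefer the positive deviation
    return float(es), running


def brute_bh(p):
    """Literal Benjamini-Hochberg step-up definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        candidate = min(1.0, p[idx] * m / rank_from_top)
        running_min = min(running_min, candidate)
        adjusted[idx] = running_min
    return adjusted


def brute_hypergeom_sf(N, K, n, k):
    """P[X >= k] by exact pmf summation with integer binomials."""
    denom = math.comb(N, n)
    total = 0
    for i in range(k, min(K, n) + 1):
        if n - i > N - K:
            continue
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / denom


def chi2_closed_form(a, b, c, d):
    """(ad - bc)^2 * n / (r1 r2 c1 c2)."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def hand_logrank(times, events, group):
    """Per-event-time O/E/V tabulation, the textbook log-rank procedure."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group, dtype=bool)
    o_minus_e = 0.0
    var = 0.0
    for u in sorted(set(times[events == 1])):
        at_risk = times >= u
        n_total = int(at_risk.sum())
        n1 = int((at_risk & group).sum())
        deaths = (times == u) & (events == 1)
        d = int(deaths.sum())
        d1 = int((deaths & group).sum())
        expected = d * n1 / n_total
        o_minus_e += d1 - expected
        if n_total > 1:
            var += (
                d * (n1 / n_total) * (1 - n1 / n_total) * (n_total - d) / (n_total - 1)
            )
    if var <= 0:
        return 0.0
    return o_minus_e**2 / var


def hand_km(times, events):
    """Empirical product-limit steps: list of (time, survival) at event times."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    surv = 1.0
    steps = []
    for u in sorted(set(times[events == 1])):
        at_risk = int((times >= u).sum())
        d = int(((times == u) & (events == 1)).sum())
        surv *= 1 - d / at_risk
        steps.append((u, surv))
    return steps


def naive_motif_membership(motifs, sequences):
    """Double-loop substring scan: motif -> ids containing it."""
    out = {}
    for motif in motifs:
        members = {mid for mid, seq in sequences.items() if motif in seq}
        if members:
            out[motif] = members
    return out
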