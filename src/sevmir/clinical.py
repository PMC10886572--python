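"""Clinical relevance of secretory/retention miRNA signatures.

Scores each patient as the mean of per-miRNA z-scored log2 expressions of
the signature miRNAs, contrasts the score across nodal and tumor stages
(Welch t-test for two groups, one-way ANOVA with Tukey HSD for more),
isolates the occult-metastasis contrast (clinically node-negative but
pathologically node-positive), and runs Kaplan-Meier / log-rank survival
comparisons between high- and low-score arms.  The cutpoint is chosen to
minimize the log-rank p over a score grid, exactly as screening studies
do; because that minimum is selection-biased, the full scan and an
optional permutation-adjusted p are always reported alongside.

The two-group log-rank statistic and product-limit estimator are computed
in numpy (the cutpoint scan and its permutation null evaluate them tens of
thousands of times); at tied times deaths precede censorings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ClinicalTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Signature scoring
# ---------------------------------------------------------------------------


def signature_score(
    clinical: ClinicalTable, signature, min_coverage: float = 0.5
) -> pd.DataFrame:
    """Per-patient signature score: mean of z-scored log2(expression + 1).

    Each signature miRNA column is log2(x+1)-transformed and z-scored
    across patients; the patient score is the mean over the signature
    miRNAs available for that patient.  Zero-variance columns are excluded
    with a warning; an empty usable intersection is an error.  Patients
    covered by fewer than ``min_coverage`` of the signature are flagged.

    Returns a DataFrame indexed by patient id with columns ``score``,
    ``coverage`` and ``low_coverage``.
    """
    present = [m for m in signature if m in clinical.data.columns]
    if not present:
        raise ValueError("no signature miRNA found among the expression columns")
    log_expr = np.log2(clinical.data[present].astype(float) + 1.0)
    usable = []
    for col in present:
        sd = log_expr[col].std(ddof=0)
        if not np.isfinite(sd) or sd == 0:
            logger.warning("signature miRNA %s has zero variance; excluded", col)
            continue
        usable.append(col)
    if not usable:
        raise ValueError("every signature miRNA column has zero variance")
    z = (log_expr[usable] - log_expr[usable].mean()) / log_expr[usable].std(ddof=0)
    coverage = z.notna().mean(axis=1)
    return pd.DataFrame(
        {
            "score": z.mean(axis=1),
            "coverage": coverage,
            "low_coverage": coverage < min_coverage,
        }
    )


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    design: str  # "two_group" or "multi_group"
    statistic: float
    p: float
    group_sizes: dict[str, int]
    pairwise: pd.DataFrame | None = None  # Tukey HSD table for multi_group
    n_dropped: int = 0  # patients with missing grouping


def compare_groups(
    scores: pd.Series, grouping: pd.Series, design: str = "two_group"
) -> GroupComparison:
    """Compare signature scores across patient groups.

    ``two_group``: Welch unpaired t-test.  ``multi_group``: one-way ANOVA
    with Tukey HSD pairwise adjusted p-values.  Patients with a missing
    group label are dropped and counted.
    """
    if design not in ("two_group", "multi_group"):
        raise ValueError("design must be 'two_group' or 'multi_group'")
    aligned = pd.DataFrame({"score": scores, "group": grouping}).dropna()
    n_dropped = len(scores) - len(aligned)
    labels = sorted(aligned["group"].unique())
    if len(labels) < 2:
        raise ValueError("need at least 2 non-empty groups")
    samples = {lab: aligned.loc[aligned["group"] == lab, "score"].to_numpy() for lab in labels}
    for lab, values in samples.items():
        if len(values) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 patients")
    sizes = {lab: len(v) for lab, v in samples.items()}

    if design == "two_group":
        if len(labels) != 2:
            raise ValueError("two_group design requires exactly 2 groups")
        stat, p = stats.ttest_ind(samples[labels[0]], samples[labels[1]], equal_var=False)
        return GroupComparison("two_group", float(stat), float(p), sizes, None, n_dropped)

    stat, p = stats.f_oneway(*(samples[lab] for lab in labels))
    tukey = stats.tukey_hsd(*(samples[lab] for lab in labels))
    rows = []
    for i, lab_i in enumerate(labels):
        for j, lab_j in enumerate(labels):
            if i < j:
                rows.append(
                    {
                        "group_a": lab_i,
                        "group_b": lab_j,
                        "mean_diff": float(
                            samples[lab_i].mean() - samples[lab_j].mean()
                        ),
                        "p_adjusted": float(tukey.pvalue[i, j]),
                    }
                )
    return GroupComparison(
        "multi_group", float(stat), float(p), sizes, pd.DataFrame(rows), n_dropped
    )


def occult_contrast(scores: pd.Series, clinical: ClinicalTable) -> dict[str, dict]:
    """The three nodal contrasts around occult metastasis.

    (i) cN0 vs cN1-3, (ii) within cN0: pN0 vs pN+ (the occult contrast),
    (iii) pN0 vs pN+ overall; each a Welch two-group comparison.  A
    contrast whose subgroup is empty or too small is reported with status
    ``skipped`` instead of raising.
    """
    data = clinical.data
    for col in ("cN", "pN"):
        if col not in data.columns:
            raise ValueError(f"clinical table lacks the {col} stage column")

    def binarize(stage: pd.Series) -> pd.Series:
        return stage.map(lambda s: None if pd.isna(s) else ("N0" if s == "N0" else "N+"))

    cn = binarize(data["cN"])
    pn = binarize(data["pN"])
    contrasts = {
        "cN0_vs_cN_positive": (scores, cn),
        "occult_within_cN0": (scores[cn == "N0"], pn[cn == "N0"]),
        "pN0_vs_pN_positive": (scores, pn),
    }
    results: dict[str, dict] = {}
    for name, (sc, grouping) in contrasts.items():
        try:
            cmp_res = compare_groups(sc, grouping, design="two_group")
        except ValueError as exc:
            results[name] = {"status": "skipped", "reason": str(exc)}
            continue
        high, low = "N+", "N0"
        aligned = pd.DataFrame({"score": sc, "group": grouping}).dropna()
        mean_diff = (
            aligned.loc[aligned["group"] == high, "score"].mean()
            - aligned.loc[aligned["group"] == low, "score"].mean()
        )
        results[name] = {
            "status": "ok",
            "statistic": cmp_res.statistic,
            "p": cmp_res.p,
            "mean_diff_positive_minus_negative": float(mean_diff),
            "group_sizes": cmp_res.group_sizes,
        }
    return results


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------


@dataclass
class SurvivalFit:
    """Two-group KM curves plus the log-rank comparison."""

    curves: dict[str, pd.DataFrame]  # label -> time / at_risk / events / survival
    statistic: float
    p: float
    group_sizes: dict[str, int]
    cutpoint: float | None = None


def km_curve(times, events) -> pd.DataFrame:
    """Product-limit survival estimate for one group.

    At tied times, deaths are processed before censorings.  Returns a step
    table with one row per distinct event time: ``time``, ``at_risk``,
    ``events`` and the post-step ``survival``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    n = len(t)
    uniq, start = np.unique(t, return_index=True)
    rows = []
    surv = 1.0
    for u, s in zip(uniq, start):
        block = t == u
        d = int(e[block].sum())
        at_risk = n - s
        if d == 0:
            continue
        surv *= 1.0 - d / at_risk
        rows.append({"time": u, "at_risk": at_risk, "events": d, "survival": surv})
    return pd.DataFrame(rows, columns=["time", "at_risk", "events", "survival"])


def logrank_statistic(times, events, group) -> tuple[float, float]:
    """Two-group log-rank statistic and chi-square(1) p-value.

    statistic = (sum(O - E))**2 / sum(V) with the hypergeometric variance
    at each distinct event time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group, dtype=bool)
    if events.sum() < 1:
        raise ValueError("log-rank requires at least one event")
    if group.all() or (~group).all():
        raise ValueError("both groups must be non-empty")

    order = np.argsort(times, kind="stable")
    t, e, g = times[order], events[order], group[order]
    n = len(t)
    n1_from = np.cumsum(g[::-1])[::-1]
    _, start = np.unique(t, return_index=True)

    d = np.add.reduceat(e, start)
    d1 = np.add.reduceat(e & g, start)
    at_risk = (n - start).astype(float)
    n1 = n1_from[start].astype(float)
    has_event = d > 0
    d, d1, at_risk, n1 = d[has_event], d1[has_event], at_risk[has_event], n1[has_event]
    frac = n1 / at_risk
    o_minus_e = float((d1 - d * frac).sum())
    multi = at_risk > 1
    var = float(
        (d[multi] * frac[multi] * (1.0 - frac[multi])
         * (at_risk[multi] - d[multi]) / (at_risk[multi] - 1)).sum()
    )
    if var <= 0:
        return 0.0, 1.0
    stat = o_minus_e**2 / var
    return float(stat), float(stats.chi2.sf(stat, df=1))


def km_logrank(times, events, group, labels=("low", "high")) -> SurvivalFit:
    """Kaplan-Meier curves for two groups with the log-rank comparison."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group, dtype=bool)
    stat, p = logrank_statistic(times, events, group)
    curves = {
        labels[0]: km_curve(times[~group], events[~group]),
        labels[1]: km_curve(times[group], events[group]),
    }
    sizes = {labels[0]: int((~group).sum()), labels[1]: int(group.sum())}
    return SurvivalFit(curves=curves, statistic=stat, p=p, group_sizes=sizes)


# ---------------------------------------------------------------------------
# Optimal cutpoint
# ---------------------------------------------------------------------------


@dataclass
class CutpointResult:
    fit: SurvivalFit
    cutpoint: float
    p: float  # minimal (uncorrected, selection-biased) log-rank p
    scan: pd.DataFrame  # full (cutpoint, sizes, statistic, p) scan
    p_permutation: float | None = None  # adjusted for the cutpoint search
    selection_biased: bool = True
    high_arm_worse: bool = field(default=False)


def _candidate_cuts(scores: np.ndarray, grid_policy: str) -> np.ndarray:
    lo, hi = np.quantile(scores, [0.10, 0.90])
    if grid_policy == "all":
        cand = np.unique(scores)
        return cand[(cand >= lo) & (cand < hi)]
    if grid_policy.startswith("quantile:"):
        k = int(grid_policy.split(":", 1)[1])
        return np.unique(np.quantile(scores, np.linspace(0.10, 0.90, k)))
    raise ValueError("grid_policy must be 'all' or 'quantile:<k>'")


def _min_p_scan(times, events, scores, cuts, floor) -> tuple[pd.DataFrame, int]:
    rows = []
    best = -1
    best_p = np.inf
    for i, cut in enumerate(cuts):
        high = scores > cut
        n_high = int(high.sum())
        n_low = len(scores) - n_high
        if min(n_high, n_low) < floor:
            continue
        stat, p = logrank_statistic(times, events, high)
        rows.append(
            {"cutpoint": cut, "n_low": n_low, "n_high": n_high, "statistic": stat, "p": p}
        )
        if p < best_p:
            best_p, best = p, len(rows) - 1
    return pd.DataFrame(rows), best


def optimal_cutpoint_survival(
    scores: pd.Series,
    times,
    events,
    grid_policy: str = "all",
    min_arm: int | None = None,
    n_permutations: int = 0,
    seed: int | None = None,
) -> CutpointResult:
    """Lowest-p dichotomization of the signature score for survival.

    Evaluates the two-group log-rank test at every candidate cut (score
    values between the 10% and 90% quantiles; ``quantile:<k>`` for a
    k-point grid) subject to each arm holding at least
    ``max(10, 10% of n)`` patients, and returns the cut minimizing p.
    The minimal p is selection-biased; the full scan is always attached,
    and with ``n_permutations > 0`` a permutation-adjusted p (min-p null
    from shuffling scores against outcomes) is reported alongside.
    """
    score_values = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = len(score_values)
    if n < 20:
        raise ValueError("need at least 20 patients for a cutpoint search")
    floor = min_arm if min_arm is not None else max(10, int(np.ceil(0.1 * n)))
    cuts = _candidate_cuts(score_values, grid_policy)
    scan, best = _min_p_scan(times, events, score_values, cuts, floor)
    if best < 0:
        raise ValueError("no admissible cutpoint (arms below the size floor)")
    best_row = scan.iloc[best]
    cut = float(best_row["cutpoint"])
    high = score_values > cut
    fit = km_logrank(times, events, high)
    fit.cutpoint = cut

    final_low = fit.curves["low"]["survival"].iloc[-1] if len(fit.curves["low"]) else 1.0
    final_high = fit.curves["high"]["survival"].iloc[-1] if len(fit.curves["high"]) else 1.0
    high_arm_worse = final_high < final_low

    p_perm = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        observed = float(best_row["p"])
        hits = 0
        for _ in range(n_permutations):
            shuffled = rng.permutation(score_values)
            perm_scan, perm_best = _min_p_scan(times, events, shuffled, cuts, floor)
            if perm_best >= 0 and perm_scan.iloc[perm_best]["p"] <= observed:
                hits += 1
        p_perm = (1.0 + hits) / (1.0 + n_permutations)

    return CutpointResult(
        fit=fit,
        cutpoint=cut,
        p=float(best_row["p"]),
        scan=scan,
        p_permutation=p_perm,
        high_arm_worse=bool(high_arm_worse),
    )
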