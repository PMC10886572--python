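"""Differential abundance of miRNAs between cells and sEVs.

A self-contained, simplified negative-binomial pipeline: median-of-ratios
size factors, method-of-moments dispersion estimates (no shrinkage toward a
fitted trend, no outlier filtering), a per-miRNA Wald test on the log scale,
Benjamini-Hochberg adjustment, compartment classification (secretory /
retained / neutral under a screen or strict fold-change profile), and
average-linkage correlation clustering of the expression profiles.

The NB model is parameterized by mean mu and dispersion alpha with
variance mu + alpha * mu**2, matching the synthetic generator so that
parameter recovery is well-posed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io_formats import CountMatrix

DISPERSION_FLOOR = 1e-8

#: classification profiles: (p_adj cutoff, minimum |log2 fold change|)
PROFILES = {"screen": (0.05, 0.0), "strict": (0.05, 1.0)}


def compute_size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample j, the factor is the median over miRNAs (restricted to
    miRNAs with strictly positive counts in every sample) of
    ``count_gj / geometric_mean_g``.

    Raises
    ------
    ValueError
        If no miRNA is expressed in all samples.
    """
    matrix = counts.counts if isinstance(counts, CountMatrix) else counts
    values = matrix.to_numpy(dtype=float)
    all_positive = (values > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no miRNA has nonzero counts in every sample; "
            "filter empty samples or low-coverage miRNAs first"
        )
    ref = values[all_positive]
    log_geo_mean = np.log(ref).mean(axis=1)
    ratios = np.exp(np.log(ref) - log_geo_mean[:, None])
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=matrix.columns, name="size_factor")


def estimate_dispersions(
    counts: CountMatrix, size_factors: pd.Series | None = None
) -> pd.Series:
    """Method-of-moments NB dispersion per miRNA, floored at 1e-8.

    Uses the pooled within-condition variance of size-factor-normalized
    counts: ``alpha = max(floor, (var - mean) / mean**2)``.
    """
    if size_factors is None:
        size_factors = compute_size_factors(counts)
    meta = counts.sample_meta
    for condition in ("cell", "sev"):
        if (meta["condition"] == condition).sum() < 2:
            raise ValueError(
                f"condition {condition!r} has fewer than 2 replicates; "
                "dispersion is unidentifiable"
            )
    normalized = counts.counts.to_numpy(dtype=float) / size_factors.to_numpy()
    pooled_ss = np.zeros(normalized.shape[0])
    pooled_df = 0
    for condition in ("cell", "sev"):
        mask = counts.condition_mask(condition)
        sub = normalized[:, mask]
        pooled_ss += sub.var(axis=1, ddof=1) * (mask.sum() - 1)
        pooled_df += mask.sum() - 1
    pooled_var = pooled_ss / pooled_df
    mean = normalized.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - mean) / np.square(mean)
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)
    return pd.Series(alpha, index=counts.mirna_ids, name="dispersion")


def adjust_pvalues_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values with monotonicity.

    Accepts any finite vector of p-values in [0, 1]; preserves the input
    order of the vector.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def differential_test(
    counts: CountMatrix,
    cell_line: str | None = None,
    trim_fraction: float = 0.25,
) -> pd.DataFrame:
    """Per-miRNA Wald test of sEV vs cell abundance on the NB model.

    The contrast pools both cell lines by default (pass ``cell_line`` for a
    stratified run).  Size factors are median-of-ratios, refined by one
    trimming pass: after a preliminary fit, the ``trim_fraction`` of miRNAs
    with the most extreme preliminary |log2fc| are excluded and the factors
    re-estimated on the remainder.  The trim counters the composition bias
    that one-sided differential secretion induces in the per-sample ratio
    median (the same rationale as trimmed-mean-of-M normalization); under a
    null experiment the trim is symmetric and changes nothing
    systematically.  Set ``trim_fraction=0`` for the plain estimator.

    The reported ``log2fc`` is moderated by a +0.5 pseudo-count on the
    normalized condition means; the Wald statistic itself uses the
    unmoderated means (falling back to the moderated ones only when a
    condition mean is exactly zero).  Two-sided p-values come from the
    t reference with n - 2 degrees of freedom; BH adjustment across tested
    miRNAs.  miRNAs with all-zero counts are excluded (column ``tested``
    False).

    Returns a DataFrame indexed by miRNA id with columns ``base_mean``,
    ``log2fc``, ``se_log2fc``, ``p_value``, ``p_adjusted``, ``tested``.
    """
    if cell_line is not None:
        keep = counts.sample_meta["cell_line"] == cell_line
        if not keep.any():
            raise ValueError(f"no samples from cell line {cell_line!r}")
        counts = CountMatrix(
            counts=counts.counts.loc[:, keep.to_numpy()],
            sample_meta=counts.sample_meta.loc[keep],
        )
    meta = counts.sample_meta
    for condition in ("cell", "sev"):
        if (meta["condition"] == condition).sum() < 2:
            raise ValueError(f"condition {condition!r} needs >= 2 replicates")

    raw = counts.counts.to_numpy(dtype=float)
    nonzero = raw.sum(axis=1) > 0
    matrix = counts.counts.loc[nonzero]
    sf = compute_size_factors(matrix)
    sev = counts.condition_mask("sev")
    cell = ~sev

    if trim_fraction > 0:
        y0 = matrix.to_numpy(dtype=float) / sf.to_numpy()
        prelim = np.log2((y0[:, sev].mean(axis=1) + 0.5) / (y0[:, cell].mean(axis=1) + 0.5))
        cutoff = np.quantile(np.abs(prelim), 1.0 - trim_fraction)
        keep = np.abs(prelim) <= cutoff
        if keep.sum() >= 2 and (matrix.loc[keep].to_numpy() > 0).all(axis=1).any():
            sf = compute_size_factors(matrix.loc[keep])

    alpha = estimate_dispersions(
        CountMatrix(matrix.copy(), counts.sample_meta.copy()), sf
    ).to_numpy()

    y = raw[nonzero] / sf.to_numpy()
    n_sev, n_cell = int(sev.sum()), int(cell.sum())
    inv_s = 1.0 / sf.to_numpy()
    mu_sev = y[:, sev].mean(axis=1)
    mu_cell = y[:, cell].mean(axis=1)

    # delta-method variance of log(mean of normalized counts):
    # Var(y_j) = mu / s_j + alpha * mu^2  =>  Var(mu_hat) summed over replicates
    def _log_var(mu: np.ndarray, mask: np.ndarray, n: int) -> np.ndarray:
        a_sum = inv_s[mask].sum()
        var_mean = mu * a_sum / n**2 + alpha * mu**2 / n
        with np.errstate(divide="ignore", invalid="ignore"):
            return var_mean / np.square(mu)

    mu_sev_safe = np.where(mu_sev > 0, mu_sev, mu_sev + 0.5)
    mu_cell_safe = np.where(mu_cell > 0, mu_cell, mu_cell + 0.5)
    var_log = _log_var(mu_sev_safe, sev, n_sev) + _log_var(mu_cell_safe, cell, n_cell)
    se_log = np.sqrt(var_log)
    stat = np.log(mu_sev_safe / mu_cell_safe) / se_log
    df = n_sev + n_cell - 2
    p = 2.0 * stats.t.sf(np.abs(stat), df)

    log2fc = np.log2((mu_sev + 0.5) / (mu_cell + 0.5))
    table = pd.DataFrame(
        {
            "base_mean": y.mean(axis=1),
            "log2fc": log2fc,
            "se_log2fc": se_log / np.log(2.0),
            "p_value": p,
            "p_adjusted": adjust_pvalues_bh(p),
            "tested": True,
        },
        index=counts.mirna_ids[nonzero],
    )
    dropped = counts.mirna_ids[~nonzero]
    if len(dropped):
        filler = pd.DataFrame(
            {
                "base_mean": 0.0,
                "log2fc": np.nan,
                "se_log2fc": np.nan,
                "p_value": np.nan,
                "p_adjusted": np.nan,
                "tested": False,
            },
            index=dropped,
        )
        table = pd.concat([table, filler]).loc[counts.mirna_ids]
    return table


def classify_compartments(table: pd.DataFrame, profile: str = "screen") -> pd.DataFrame:
    """Assign each miRNA a compartment under a named threshold profile.

    ``screen``: secretory iff p_adjusted < 0.05 and log2fc > 0, retained iff
    p_adjusted < 0.05 and log2fc < 0.  ``strict``: the same with
    |log2fc| > 1.  Everything else (including untested miRNAs) is neutral.
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {list(PROFILES)}")
    p_cut, fc_cut = PROFILES[profile]
    out = table.copy()
    significant = (out["p_adjusted"] < p_cut) & out["tested"].fillna(False)
    compartment = np.where(
        significant & (out["log2fc"] > fc_cut),
        "secretory",
        np.where(significant & (out["log2fc"] < -fc_cut), "retained", "neutral"),
    )
    out["compartment"] = compartment
    return out


def ranked_list(table: pd.DataFrame) -> pd.Series:
    """log2fc-ranked miRNA list, descending, ties broken by id.

    Returns a Series of metrics indexed by miRNA id in rank order; only
    tested miRNAs participate.
    """
    tested = table[table["tested"].fillna(False)]
    ordering = sorted(
        tested.index, key=lambda mid: (-tested.at[mid, "log2fc"], mid)
    )
    return tested.loc[ordering, "log2fc"]


def cluster_expression(counts: CountMatrix, k: int) -> pd.DataFrame:
    """Agglomerative clustering of expression profiles into k clusters.

    Rows are log2(normalized count + 1), z-scored; distance is
    1 - Pearson correlation; average linkage; the tree is cut to exactly
    k clusters labeled C1..Ck in order of first appearance.  Deterministic
    given row order.
    """
    n = len(counts.mirna_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of miRNAs ({n})")
    sf = compute_size_factors(counts)
    expr = np.log2(counts.counts.to_numpy(dtype=float) / sf.to_numpy() + 1.0)
    sd = expr.std(axis=1, ddof=0)
    centered = expr - expr.mean(axis=1, keepdims=True)
    z = np.divide(centered, sd[:, None], out=np.zeros_like(centered), where=sd[:, None] > 0)

    # 1 - Pearson; zero-variance rows correlate 1 with each other, 0 otherwise
    norms = np.linalg.norm(z, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = z / safe[:, None]
    corr = unit @ unit.T
    flat = norms == 0
    if flat.any():
        corr[flat, :] = 0.0
        corr[:, flat] = 0.0
        corr[np.ix_(flat, flat)] = 1.0
    np.fill_diagonal(corr, 1.0)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    condensed = squareform(dist, checks=False)
    merge_tree = linkage(condensed, method="average")
    raw_labels = fcluster(merge_tree, t=k, criterion="maxclust")

    relabel: dict[int, str] = {}
    for lab in raw_labels:
        if lab not in relabel:
            relabel[lab] = f"C{len(relabel) + 1}"
    return pd.DataFrame(
        {"cluster": [relabel[lab] for lab in raw_labels]}, index=counts.mirna_ids
    )
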