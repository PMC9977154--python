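"""Negative-binomial differential expression and ERV quantification.

The differential engine follows the standard NB workflow: median-of-
ratios size factors, per-gene dispersion by method of moments shrunk
toward a fitted 1/mean trend, and a Wald test on the log2 fold change
of group means, with Benjamini-Hochberg adjustment.  Calls additionally
require a large fold change (|log2FC| >= 1.5 by default), reflecting
the conservative filter appropriate for shallow oocyte libraries.
Libraries can be equalised by hypergeometric down-sampling before
testing when comparing across datasets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import false_discovery_control

from .genome import gap_to_nearest

logger = logging.getLogger(__name__)

DOWNSAMPLE_TARGET = 1_900_000
MIN_DISPERSION = 1e-8


def log_cpm(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(counts-per-million + pseudocount)."""
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    return np.log2(counts / lib * 1e6 + pseudocount)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalisation factors, scaled to geometric mean 1.

    Uses genes with nonzero counts in all samples; errors if none exist.
    """
    x = counts.to_numpy(float)
    allpos = (x > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene with nonzero counts in every sample; "
            "median-of-ratios needs a pseudo-reference — filter or pool first"
        )
    lg = np.log(x[allpos])
    ref = lg.mean(axis=1, keepdims=True)  # log geometric mean per gene
    f = np.exp(np.median(lg - ref, axis=0))
    f = f / np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=counts.columns, name="size_factor")


def nb_wald_test(
    counts: pd.DataFrame,
    groups: "pd.Series | dict",
    shrink: float = 0.5,
) -> pd.DataFrame:
    """Per-gene NB Wald test between two groups.

    Dispersion = method-of-moments estimate (floored at 1e-8) averaged
    50/50 with a fitted ``a0 + a1/mean`` trend across genes.  The Wald
    statistic is the log2 fold change of size-factor-normalised group
    means over its delta-method standard error; two-sided normal p,
    BH-adjusted.  All-zero genes are excluded (logged, NaN results).
    """
    groups = pd.Series(groups).reindex(counts.columns)
    levels = list(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    cols_a = groups.index[groups == levels[0]]
    cols_b = groups.index[groups == levels[1]]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >= 2 samples per group")

    sf = size_factors(counts)
    k = counts.to_numpy(float)
    s = sf.to_numpy()
    q = k / s  # normalised counts
    ia = counts.columns.isin(cols_a)
    ib = counts.columns.isin(cols_b)

    nonzero = k.sum(axis=1) > 0
    if (~nonzero).any():
        logger.info("excluding %d all-zero genes", int((~nonzero).sum()))

    mu_a = k[:, ia].sum(axis=1) / s[ia].sum()
    mu_b = k[:, ib].sum(axis=1) / s[ib].sum()
    base_mean = q.mean(axis=1)

    # method-of-moments dispersion from within-group residuals
    resid_ss = np.zeros(len(k))
    mu_fit = np.zeros_like(q)
    mu_fit[:, ia] = mu_a[:, None]
    mu_fit[:, ib] = mu_b[:, None]
    resid_ss = ((q - mu_fit) ** 2).sum(axis=1)
    dof = k.shape[1] - 2
    var_hat = resid_ss / max(dof, 1)
    inv_s = (1.0 / s).mean()
    mu_bar = np.maximum((mu_a + mu_b) / 2, 1e-12)
    alpha_mom = np.maximum((var_hat - mu_bar * inv_s) / mu_bar**2, MIN_DISPERSION)

    # 1/mean trend fitted on informative genes
    fit_sel = nonzero & (mu_bar > 1e-8) & (alpha_mom > MIN_DISPERSION)
    if fit_sel.sum() >= 10:
        X = np.column_stack([np.ones(fit_sel.sum()), 1.0 / mu_bar[fit_sel]])
        coef, *_ = np.linalg.lstsq(X, alpha_mom[fit_sel], rcond=None)
        a0, a1 = max(coef[0], MIN_DISPERSION), max(coef[1], 0.0)
    else:
        a0, a1 = float(np.median(alpha_mom[nonzero])) if nonzero.any() else 0.1, 0.0
    alpha_trend = a0 + a1 / mu_bar
    alpha = (1 - shrink) * alpha_mom + shrink * alpha_trend

    mu_a_f = np.maximum(mu_a, 1e-12)
    mu_b_f = np.maximum(mu_b, 1e-12)
    lfc = np.log2(mu_b_f / mu_a_f)

    def var_log_mu(mu, cols):
        ssum = s[cols].sum()
        num = (s[cols][None, :] * mu[:, None] + alpha[:, None] * (s[cols][None, :] * mu[:, None]) ** 2).sum(axis=1)
        return num / (ssum**2 * np.maximum(mu, 1e-12) ** 2)

    se_lfc = np.sqrt(var_log_mu(mu_a_f, ia) + var_log_mu(mu_b_f, ib)) / np.log(2)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = lfc / se_lfc
    p = 2 * stats.norm.sf(np.abs(z))

    p = np.where(nonzero, p, np.nan)
    lfc = np.where(nonzero, lfc, np.nan)
    padj = np.full(len(p), np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        padj[ok] = false_discovery_control(p[ok], method="bh")

    return pd.DataFrame(
        {
            "unit_id": counts.index,
            "base_mean": base_mean,
            "mean_a": mu_a,
            "mean_b": mu_b,
            "log2fc": lfc,
            "se": se_lfc,
            "p": p,
            "padj": padj,
        }
    ).set_index("unit_id")


def call_degs(
    results: pd.DataFrame, lfc: float = 1.5, alpha: float = 0.05
) -> pd.DataFrame:
    """Call up/down: BH-adjusted p < alpha and |log2FC| >= lfc."""
    out = results.copy()
    sig = out["padj"] < alpha
    out["call"] = np.where(
        sig & (out["log2fc"] >= lfc),
        "up",
        np.where(sig & (out["log2fc"] <= -lfc), "down", "none"),
    )
    return out


def downsample(
    counts: pd.DataFrame, target: int = DOWNSAMPLE_TARGET, seed: int = 0
) -> pd.DataFrame:
    """Down-sample each column to ``target`` reads without replacement
    (multivariate hypergeometric).  Columns at or below the target pass
    through unchanged (with a warning when below)."""
    rng = np.random.default_rng(seed)
    out = {}
    for col in counts.columns:
        v = counts[col].to_numpy(np.int64)
        tot = int(v.sum())
        if tot <= target:
            if tot < target:
                logger.warning("column %s has %d < target %d reads; passed through", col, tot, target)
            out[col] = v
        else:
            out[col] = rng.multivariate_hypergeometric(v, target, method="marginals")
    return pd.DataFrame(out, index=counts.index)


def quantify_ervs(
    erv_counts: pd.DataFrame,
    ervs: pd.DataFrame,
    genes: pd.DataFrame,
    library_sizes: pd.Series,
    exclusion_bp: int = 2000,
) -> tuple[pd.Series, pd.DataFrame]:
    """ERV expression as % of total library counts per sample.

    ERVs with an end-to-start gap strictly below ``exclusion_bp`` to any
    gene are excluded (an ERV exactly 2 kb away is retained) to avoid
    counting read-through from normal genic transcription.  Returns the
    per-sample percentage and the per-ERV retained count table.
    """
    if len(erv_counts) != len(ervs):
        raise ValueError("erv_counts rows must align with erv intervals")
    ervs = ervs.reset_index(drop=True)
    gaps = gap_to_nearest(ervs, genes[["chrom", "start", "end"]])
    keep = np.flatnonzero(gaps >= exclusion_bp)
    kept = erv_counts.reset_index(drop=True).iloc[keep]
    pct = kept.sum(axis=0) / pd.Series(library_sizes).reindex(erv_counts.columns) * 100
    table = ervs.iloc[keep].reset_index(drop=True).join(kept.reset_index(drop=True))
    return pct, table


_DEG_PATTERNS = {
    "down_both": np.array([-1.0, -1.0]),
    "up_both": np.array([1.0, 1.0]),
    "up_cdko_only": np.array([0.0, 1.0]),
}


def cluster_degs(expr: pd.DataFrame, lfc: pd.DataFrame, k: int = 3) -> pd.Series:
    """Cluster union DEGs into k=3 expression patterns.

    Ward/Euclidean on row-standardised log2 expression, cut at k; the
    clusters are labelled down-in-both / up-in-both / up-in-double-KO-
    only by matching cluster mean fold-change vectors (single-KO,
    double-KO columns of ``lfc``) to the three reference directions
    with the assignment minimising total distance.
    """
    if len(expr) < k:
        raise ValueError(f"need at least {k} DEGs to cluster")
    x = expr.to_numpy(float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    xz = (x - mu) / np.where(sd > 0, sd, 1.0)
    lab = fcluster(linkage(xz, method="ward"), t=k, criterion="maxclust")

    lfc = lfc.reindex(expr.index)
    means = {}
    for c in range(1, k + 1):
        sel = lab == c
        means[c] = lfc.to_numpy(float)[sel].mean(axis=0) if sel.any() else np.zeros(2)

    from itertools import permutations

    names = list(_DEG_PATTERNS)
    best, best_cost = None, np.inf
    for perm in permutations(range(1, k + 1)):
        cost = 0.0
        for name, c in zip(names, perm):
            v = means[c]
            ref = _DEG_PATTERNS[name]
            scale = max(np.abs(v).max(), 1e-9)
            cost += float(np.linalg.norm(v / scale - ref / max(np.abs(ref).max(), 1e-9)))
        if cost < best_cost:
            best, best_cost = perm, cost
    mapping = {c: name for name, c in zip(names, best)}
    return pd.Series([mapping[c] for c in lab], index=expr.index, name="deg_cluster")
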