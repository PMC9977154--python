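"""Cross-omics statistics.

Overlap enrichment of a query region or gene set against a feature set
relative to a random background (two-tailed Fisher's exact test or
chi-square with Bonferroni adjustment); barcode-style rank enrichment
of differentially abundant proteins within the genome-wide transcript
fold-change ranking; and Spearman correlation between methylation and
expression changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import RegionSet, overlaps_any

logger = logging.getLogger(__name__)


def overlap_fraction(query, features) -> float:
    """Fraction of query units hitting the features.

    Interval mode (RegionSet/DataFrame): >= 1 bp intersection.  Set
    mode (set/list of ids): membership.
    """
    if isinstance(query, (set, frozenset, list, tuple, pd.Index)):
        q = set(query)
        if not q:
            raise ValueError("empty query set")
        f = set(features)
        return len(q & f) / len(q)
    qdf = query.intervals if isinstance(query, RegionSet) else query
    fdf = features.intervals if isinstance(features, RegionSet) else features
    if len(qdf) == 0:
        raise ValueError("empty query region set")
    return float(overlaps_any(qdf, fdf).mean())


@dataclass
class OverlapEnrichmentResult:
    query_name: str
    feature_name: str
    query_fraction: float
    background_fraction: float
    test: str
    p: float
    p_bonferroni: float


def enrichment_test(
    k: int,
    n: int,
    K: int,
    Nb: int,
    test: str = "fisher",
    family_size: int = 1,
    query_name: str = "query",
    feature_name: str = "feature",
) -> OverlapEnrichmentResult:
    """Compare hit rates k/n (query) vs K/Nb (background) on a 2x2 table.

    Two-tailed Fisher's exact test, or chi-square (no continuity
    correction) falling back to Fisher whenever any expected cell is
    below 5.  Bonferroni = p x family_size, capped at 1.
    """
    if min(k, n - k, K, Nb - K) < 0 or n <= 0 or Nb <= 0:
        raise ValueError("invalid 2x2 counts")
    table = np.array([[k, n - k], [K, Nb - K]])
    used = test
    if test == "chisq":
        tot = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / tot
        if (expected < 5).any():
            logger.info("expected cell < 5: falling back to Fisher's exact test")
            used = "fisher"
        else:
            _, p, _, _ = stats.chi2_contingency(table, correction=False)
    if used == "fisher":
        _, p = stats.fisher_exact(table, alternative="two-sided")
    elif used != "chisq":
        raise ValueError(f"unknown test {test!r}")
    return OverlapEnrichmentResult(
        query_name,
        feature_name,
        k / n,
        K / Nb,
        used,
        float(p),
        min(float(p) * family_size, 1.0),
    )


def fisher_two_sided_oracle(k: int, n: int, K: int, Nb: int) -> float:
    """Exhaustive two-sided Fisher p by hypergeometric enumeration:
    the sum of probabilities of all tables (same margins) no more
    likely than the observed one."""
    row1, col1, tot = n, k + K, n + Nb
    lo = max(0, col1 - (tot - row1))
    hi = min(row1, col1)
    xs = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(xs, tot, col1, row1)
    p_obs = stats.hypergeom.pmf(k, tot, col1, row1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


@dataclass
class RankEnrichmentResult:
    n_ranked: int
    set_sizes: dict
    worm: pd.DataFrame            # rank position x set: relative enrichment
    rank_p: dict                  # one-sided rank-sum p per set
    spearman_rho: "float | None"
    spearman_p: "float | None"


def _worm(in_set: np.ndarray, span: float) -> np.ndarray:
    n = len(in_set)
    w = max(int(round(span * n)), 1)
    half = w // 2
    cum = np.concatenate([[0], np.cumsum(in_set)])
    pos = np.arange(n)
    lo = np.maximum(pos - half, 0)
    hi = np.minimum(pos + (w - half), n)
    dens = (cum[hi] - cum[lo]) / (hi - lo)
    base = in_set.sum() / n
    return dens / base if base > 0 else np.full(n, np.nan)


def barcode_enrichment(
    ranked_lfc: pd.Series,
    up_set,
    down_set,
    span: float = 0.25,
    paired_effects: "pd.Series | None" = None,
) -> RankEnrichmentResult:
    """Where do the up/down protein sets fall in the transcript ranking?

    ``ranked_lfc``: fold change per gene (any order; ranked descending
    internally).  The worm is the set density in a centred rectangular
    window of width span*N relative to a uniform spread (baseline 1).
    Each set is tested with a one-sided rank-sum test in its nominal
    direction; Spearman rho is computed over ``paired_effects`` when
    supplied (e.g., protein log2FC matched by gene).
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    order = ranked_lfc.sort_values(ascending=False, kind="mergesort")
    n = len(order)
    sets = {"up": set(up_set), "down": set(down_set)}
    worm = {}
    rank_p = {}
    for name, s in sets.items():
        in_set = order.index.isin(s).astype(float)
        worm[name] = _worm(in_set, span)
        if in_set.sum() < 3:
            logger.warning("set %r has < 3 members in the ranking: test skipped", name)
            rank_p[name] = np.nan
            continue
        x = order[in_set.astype(bool)].to_numpy()
        y = order[~in_set.astype(bool)].to_numpy()
        alt = "greater" if name == "up" else "less"
        rank_p[name] = float(
            stats.mannwhitneyu(x, y, alternative=alt, method="asymptotic").pvalue
        )
    rho = p_rho = None
    if paired_effects is not None:
        common = ranked_lfc.index.intersection(paired_effects.index)
        if len(common) >= 4:
            rho, p_rho = stats.spearmanr(
                ranked_lfc.loc[common], paired_effects.loc[common]
            )
            rho, p_rho = float(rho), float(p_rho)
    return RankEnrichmentResult(
        n,
        {k: len(v) for k, v in sets.items()},
        pd.DataFrame(worm, index=np.arange(n)),
        rank_p,
        rho,
        p_rho,
    )


def methylation_expression_correlation(
    meth_diff: pd.Series,
    log2fc: pd.Series,
    subset=None,
) -> tuple[float, float]:
    """Spearman correlation between per-gene methylation difference
    (percentage points) and expression log2FC."""
    common = meth_diff.index.intersection(log2fc.index)
    if subset is not None:
        common = common.intersection(pd.Index(list(subset)))
    x = meth_diff.loc[common].to_numpy(float)
    y = log2fc.loc[common].to_numpy(float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise ValueError("need >= 4 paired genes")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def set_overlap(set_a, set_b) -> tuple[int, int, int]:
    """(only in A, shared, only in B) membership counts."""
    a, b = set(set_a), set(set_b)
    shared = len(a & b)
    return len(a) - shared, shared, len(b) - shared
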