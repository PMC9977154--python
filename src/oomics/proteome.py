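"""Moderated differential protein abundance for TMT log2 intensities.

Reporter signal-to-noise matrices are median-normalised per channel,
then each protein is tested with an empirical-Bayes moderated t-test:
per-protein residual variances are shrunk toward a prior variance whose
weight (prior degrees of freedom d0) is estimated by matching the first
two moments of log s^2, with the trigamma equation inverted by Newton
iteration.  Calls gate on the raw two-sided p-value (P < 0.05) and a
modest fold change (|log2FC| >= 0.3), as appropriate for the compressed
fold changes of isobaric quantification.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

logger = logging.getLogger(__name__)


def normalize_median(matrix: pd.DataFrame) -> pd.DataFrame:
    """Shift each column so its median equals the grand median."""
    med = matrix.median(axis=0)
    return matrix - med + float(np.median(matrix.to_numpy()))


def _trigamma_inverse(x: float, iters: int = 50, tol: float = 1e-10) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(iters):
        tri = polygamma(1, y)
        step = tri * (1 - tri / x) / polygamma(2, y)
        y = y + step
        if y <= 0:
            y = 1e-8
        if abs(step) < tol * y:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Moment-match the scaled-F model of residual variances.

    Returns (d0, s0^2): prior degrees of freedom and prior variance.
    d0 = inf when the observed spread of log s^2 does not exceed the
    chi-square expectation (no excess variability to shrink against).
    """
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if len(s2) < 2:
        return np.inf, float(np.mean(s2)) if len(s2) else 1.0
    e = np.log(s2) - digamma(d / 2) + np.log(d / 2)
    ebar = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, d / 2))
    if evar <= 0:
        return np.inf, float(np.exp(ebar))
    half_d0 = _trigamma_inverse(evar)
    if not np.isfinite(half_d0):
        return np.inf, float(np.exp(ebar))
    s0_2 = float(np.exp(ebar + digamma(half_d0) - np.log(half_d0)))
    return 2 * half_d0, s0_2


def moderated_t(
    matrix: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    prior_df: "float | None" = None,
    prior_var: "float | None" = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-sample t-test per protein.

    Posterior variance = (d0*s0^2 + d*s^2) / (d0 + d); t on d0 + d
    degrees of freedom; raw two-sided p (no multiplicity adjustment at
    this stage).  ``prior_df``/``prior_var`` override the estimated
    prior — prior_df=0 reduces to the ordinary t-test, prior_df=inf to
    a z-test against the prior variance.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 replicates per group")
    xa = matrix[group_a].to_numpy(float)
    xb = matrix[group_b].to_numpy(float)
    na, nb = xa.shape[1], xb.shape[1]
    d = na + nb - 2
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    lfc = mean_b - mean_a
    ss = ((xa - mean_a[:, None]) ** 2).sum(axis=1) + ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / d

    if prior_df is None:
        d0, s0_2 = estimate_prior(s2, d)
        if not np.isfinite(d0):
            logger.info("no excess variance spread: prior df -> inf (pooled variance)")
    else:
        d0 = float(prior_df)
        s0_2 = prior_var if prior_var is not None else float(np.median(s2[s2 > 0])) if (s2 > 0).any() else 1.0

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = d
    else:
        s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
        df_total = d0 + d

    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = lfc / se
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)

    return pd.DataFrame(
        {
            "unit_id": matrix.index,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": lfc,
            "s2": s2,
            "s2_post": s2_post,
            "t": t,
            "p": p,
            "df": df_total if np.isscalar(df_total) else df_total,
            "prior_df": d0,
        }
    ).set_index("unit_id")


def call_diff_proteins(
    results: pd.DataFrame, p: float = 0.05, lfc: float = 0.3
) -> pd.DataFrame:
    """Call up/down: raw p below threshold and |log2FC| >= lfc."""
    out = results.copy()
    sig = out["p"] < p
    out["call"] = np.where(
        sig & (out["log2fc"] >= lfc),
        "up",
        np.where(sig & (out["log2fc"] <= -lfc), "down", "none"),
    )
    return out
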