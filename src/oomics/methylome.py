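"""CpG-tiled differential DNA methylation.

The genome is partitioned into consecutive windows of exactly 100 CpGs
(equal CpG content, variable bp span), tiles are kept only when every
sample has at least 10 observed cytosines, and each tile is tested for
differential methylation between two groups with a beta-binomial
likelihood-ratio test on per-replicate (methylated, unmethylated)
totals.  Significant tiles (BH-adjusted p and an absolute difference
gate) are DMRs; same-direction DMRs near each other merge into
differentially methylated domains (DMDs) that are clustered across
genotypes into "common" and "unique" responses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import false_discovery_control

logger = logging.getLogger(__name__)

TILE_CPGS = 100
MIN_OBS = 10


def tile_spans_from_positions(positions: np.ndarray, n: int = TILE_CPGS) -> np.ndarray:
    """(k, 2) array of [start, end) spans for consecutive groups of n CpGs.

    The trailing group of fewer than n CpGs is dropped.  The span runs
    from the first CpG to one past the last CpG of the group.
    """
    positions = np.asarray(positions, dtype=np.int64)
    if len(positions) > 1 and (np.diff(positions) <= 0).any():
        raise ValueError("CpG positions must be sorted and unique")
    k = len(positions) // n
    if k == 0:
        return np.empty((0, 2), dtype=np.int64)
    starts = positions[: k * n : n]
    ends = positions[n - 1 : k * n : n] + 1
    return np.stack([starts, ends], axis=1)


@dataclass
class MethylationTiles:
    """Tiles plus per-sample aggregates.

    ``tiles``: chrom, start, end, n_cpgs.  The stat frames are tiles x
    samples: ``meth``/``unmeth`` summed counts, ``obs`` observed
    cytosines (meth+unmeth), ``pct`` unweighted mean of per-CpG
    methylation percentages over covered CpGs, ``pct_pooled``
    coverage-weighted percentage.
    """

    tiles: pd.DataFrame
    meth: pd.DataFrame
    unmeth: pd.DataFrame
    obs: pd.DataFrame
    pct: pd.DataFrame
    pct_pooled: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return list(self.meth.columns)

    def subset(self, keep: np.ndarray) -> "MethylationTiles":
        keep = np.asarray(keep)
        return MethylationTiles(
            self.tiles.loc[keep].reset_index(drop=True),
            *(f.loc[keep].reset_index(drop=True) for f in (
                self.meth, self.unmeth, self.obs, self.pct, self.pct_pooled)),
        )


def tile_by_cpg(
    cpg_records: dict[str, pd.DataFrame],
    n: int = TILE_CPGS,
    positions: "dict[str, np.ndarray] | None" = None,
) -> MethylationTiles:
    """Aggregate per-CpG records into consecutive n-CpG tiles.

    ``cpg_records`` maps sample -> DataFrame(chrom, pos, meth, unmeth).
    The CpG universe is ``positions`` (per chromosome) when given, else
    the union of positions observed in any sample.
    """
    samples = list(cpg_records)
    if positions is None:
        positions = {}
        allrec = pd.concat(
            [df[["chrom", "pos"]] for df in cpg_records.values()], ignore_index=True
        )
        for chrom, grp in allrec.groupby("chrom"):
            positions[chrom] = np.unique(grp["pos"].to_numpy(np.int64))

    tile_rows = []
    agg = {s: {"meth": [], "unmeth": [], "obs": [], "pct": [], "pooled": []} for s in samples}
    for chrom in sorted(positions):
        pos = np.asarray(positions[chrom], dtype=np.int64)
        spans = tile_spans_from_positions(pos, n)
        k = len(spans)
        if k == 0:
            continue
        for s_, e_ in spans:
            tile_rows.append((chrom, int(s_), int(e_), n))
        for s in samples:
            df = cpg_records[s]
            sub = df[df["chrom"] == chrom]
            sp = sub["pos"].to_numpy(np.int64)
            order = np.argsort(sp, kind="stable")
            sp = sp[order]
            meth = sub["meth"].to_numpy(float)[order]
            unmeth = sub["unmeth"].to_numpy(float)[order]
            idx = np.searchsorted(pos, sp)
            valid = (idx < len(pos)) & (pos[np.clip(idx, 0, len(pos) - 1)] == sp)
            tid = idx[valid] // n
            in_tile = tid < k
            tid = tid[in_tile]
            m = meth[valid][in_tile]
            u = unmeth[valid][in_tile]
            cov = m + u
            covered = cov > 0
            msum = np.bincount(tid, weights=m, minlength=k)
            usum = np.bincount(tid, weights=u, minlength=k)
            ncov = np.bincount(tid[covered], minlength=k)
            with np.errstate(invalid="ignore", divide="ignore"):
                perbase = np.where(covered, m / np.where(cov > 0, cov, 1), 0.0)
            psum = np.bincount(tid[covered], weights=perbase[covered] * 100, minlength=k)
            with np.errstate(invalid="ignore", divide="ignore"):
                pct = np.where(ncov > 0, psum / np.maximum(ncov, 1), np.nan)
                pooled = np.where(
                    msum + usum > 0, msum / np.maximum(msum + usum, 1e-300) * 100, np.nan
                )
            agg[s]["meth"].append(msum)
            agg[s]["unmeth"].append(usum)
            agg[s]["obs"].append(msum + usum)
            agg[s]["pct"].append(pct)
            agg[s]["pooled"].append(pooled)

    tiles = pd.DataFrame(tile_rows, columns=["chrom", "start", "end", "n_cpgs"])
    tiles["tile_id"] = np.arange(len(tiles))

    def frame(key):
        return pd.DataFrame(
            {s: np.concatenate(agg[s][key]) if agg[s][key] else np.array([]) for s in samples}
        )

    return MethylationTiles(
        tiles, frame("meth"), frame("unmeth"), frame("obs"), frame("pct"), frame("pooled")
    )


def coverage_filter(tiles: MethylationTiles, min_obs: int = MIN_OBS) -> MethylationTiles:
    """Retain tiles with >= min_obs observed cytosines in every sample."""
    keep = (tiles.obs >= min_obs).all(axis=1).to_numpy()
    logger.info("coverage filter: retained %d of %d tiles", int(keep.sum()), len(keep))
    return tiles.subset(np.flatnonzero(keep))


def tile_percent(tiles: MethylationTiles, mode: str = "per-base-mean") -> pd.DataFrame:
    """Per-sample tile methylation percentage.

    ``per-base-mean`` (default): unweighted mean over covered CpGs of
    per-CpG percentages.  ``pooled``: total meth / total observed.
    """
    if mode == "per-base-mean":
        return tiles.pct
    if mode == "pooled":
        return tiles.pct_pooled
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# beta-binomial differential test


def _bb_loglik(m: float, phi: float, y: np.ndarray, ntot: np.ndarray) -> float:
    if phi <= 0:
        return float(stats.binom.logpmf(y, ntot, m).sum())
    a = m * (1 - phi) / phi
    b = (1 - m) * (1 - phi) / phi
    return float(stats.betabinom.logpmf(y, ntot, a, b).sum())


def _bb_mle(phi: float, y: np.ndarray, ntot: np.ndarray) -> tuple[float, float]:
    p0 = min(max(y.sum() / ntot.sum(), 1e-9), 1 - 1e-9)
    if phi <= 0:
        return p0, _bb_loglik(p0, 0.0, y, ntot)
    res = optimize.minimize_scalar(
        lambda m: -_bb_loglik(m, phi, y, ntot),
        bounds=(1e-9, 1 - 1e-9),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if -res.fun < _bb_loglik(p0, phi, y, ntot):
        return p0, _bb_loglik(p0, phi, y, ntot)
    return float(res.x), float(-res.fun)


def estimate_dispersion(
    meth: np.ndarray, tot: np.ndarray, group_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-tile method-of-moments beta-binomial dispersion, floored at 0.

    ``meth``/``tot``: tiles x replicates; ``group_idx``: 0/1 per column.
    Returns (phi per tile, Pearson chi-square per tile, residual df per
    tile).  The estimator equates the group-conditional Pearson
    chi-square to its beta-binomial expectation
    ``df x (1 + (n_mean - 1) phi)``.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        phat = np.empty_like(meth, dtype=float)
        for g in (0, 1):
            cols = group_idx == g
            pg = meth[:, cols].sum(axis=1) / np.maximum(tot[:, cols].sum(axis=1), 1e-300)
            phat[:, cols] = pg[:, None]
        denom = tot * phat * (1 - phat)
        x2 = np.where(denom > 0, (meth - tot * phat) ** 2 / np.maximum(denom, 1e-300), 0.0)
    df = np.maximum((tot > 0).sum(axis=1) - 2, 1)
    nbar = np.maximum(tot.mean(axis=1), 2)
    x2sum = x2.sum(axis=1)
    phi = (x2sum / df - 1) / (nbar - 1)
    return np.maximum(phi, 0.0), x2sum, df


def dmr_test(
    tiles: MethylationTiles,
    group_a: list[str],
    group_b: list[str],
    dispersion_shrink: float = 1.0,
) -> pd.DataFrame:
    """Beta-binomial likelihood-ratio test per tile.

    Per-replicate (meth, unmeth) totals; a common dispersion per tile by
    method of moments (floored at 0), stabilised by shrinking each
    tile's estimate toward the dataset-wide pooled estimate with weight
    ``dispersion_shrink`` (1.0 = fully pooled — the default, since the
    per-tile estimate has only ~2 residual degrees of freedom at
    duplicate designs); 1-df chi-square p.  Difference is group B - A
    in per-base-mean percentage points.
    """
    cols = group_a + group_b
    gidx = np.array([0] * len(group_a) + [1] * len(group_b))
    meth = tiles.meth[cols].to_numpy(float)
    tot = tiles.obs[cols].to_numpy(float)

    phi_tile, x2sum, df = estimate_dispersion(meth, tot, gidx)
    # pooled estimate across tiles: ratio of summed chi-square to summed df
    nbar = np.maximum(tot.mean(axis=1), 2)
    factor_pool = float(x2sum.sum() / max(df.sum(), 1))
    phi_pool = max(factor_pool - 1, 0.0) / max(float(nbar.mean()) - 1, 1)
    w = float(np.clip(dispersion_shrink, 0.0, 1.0))
    phi = (1 - w) * phi_tile + w * phi_pool

    n_tiles = len(tiles.tiles)
    p = np.full(n_tiles, np.nan)
    for i in range(n_tiles):
        y, ntot = meth[i], tot[i]
        ok = ntot > 0
        ya, na = y[gidx == 0], ntot[gidx == 0]
        yb, nb = y[gidx == 1], ntot[gidx == 1]
        if na.sum() == 0 or nb.sum() == 0:
            logger.warning("tile %d skipped: zero total counts in a group", i)
            continue
        ph = float(phi[i])
        _, ll0 = _bb_mle(ph, y[ok], ntot[ok])
        _, lla = _bb_mle(ph, ya[na > 0], na[na > 0])
        _, llb = _bb_mle(ph, yb[nb > 0], nb[nb > 0])
        lrt = max(2.0 * (lla + llb - ll0), 0.0)
        p[i] = stats.chi2.sf(lrt, df=1)

    pct = tiles.pct
    diff = pct[group_b].mean(axis=1) - pct[group_a].mean(axis=1)
    out = tiles.tiles.copy()
    out["mean_a"] = pct[group_a].mean(axis=1)
    out["mean_b"] = pct[group_b].mean(axis=1)
    out["diff"] = diff
    out["p"] = p
    out["phi"] = phi
    return out


def call_dmrs(results: pd.DataFrame, alpha: float = 0.05, min_diff: float = 20.0) -> pd.DataFrame:
    """DMR call: BH-adjusted p < alpha AND |difference| >= min_diff."""
    out = results.copy()
    padj = np.full(len(out), np.nan)
    valid = out["p"].notna().to_numpy()
    if valid.any():
        padj[valid] = false_discovery_control(out.loc[valid, "p"].to_numpy(), method="bh")
    out["padj"] = padj
    out["direction"] = np.where(out["diff"] > 0, "hyper", "hypo")
    out["call"] = (out["padj"] < alpha) & (out["diff"].abs() >= min_diff)
    return out


def merge_dmrs(dmrs: pd.DataFrame, max_tile_gap: int = 1) -> pd.DataFrame:
    """Merge same-direction called DMR tiles into domains (DMDs).

    Tiles merge when adjacent in the tile index or separated by up to
    ``max_tile_gap`` intervening tiles on the same chromosome.  Hyper
    and hypo never merge.
    """
    called = dmrs[dmrs["call"]].sort_values(["chrom", "start"]).reset_index(drop=True)
    rows = []
    for (chrom, direction), grp in called.groupby(["chrom", "direction"], sort=True):
        grp = grp.sort_values("tile_id")
        tids = grp["tile_id"].to_numpy()
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        diffs = grp["diff"].to_numpy()
        cur = [0]
        for j in range(1, len(grp)):
            if tids[j] - tids[cur[-1]] <= max_tile_gap + 1:
                cur.append(j)
            else:
                rows.append(
                    (chrom, starts[cur[0]], ends[cur[-1]], direction,
                     list(tids[cur]), float(np.mean(diffs[cur])))
                )
                cur = [j]
        if cur:
            rows.append(
                (chrom, starts[cur[0]], ends[cur[-1]], direction,
                 list(tids[cur]), float(np.mean(diffs[cur])))
            )
    out = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "direction", "member_tiles", "mean_diff"]
    )
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def cluster_domains(domains: pd.DataFrame, genotype_cols: list[str]) -> pd.DataFrame:
    """Label DMDs "common" vs "unique" across genotypes.

    Ward/Euclidean agglomerative clustering of the per-genotype
    difference matrix, cut at k=2 within each direction.  The cluster
    whose first-genotype (single-knockout) mean difference is closer to
    the last-genotype (double-knockout) column is "common"; the other
    is "unique".  The last column of ``genotype_cols`` is the
    reference (most-affected) genotype.
    """
    out = domains.copy()
    out["cluster"] = "unassigned"
    if len(out) < 2:
        logger.warning("fewer than 2 domains: all labelled common")
        out["cluster"] = "common"
        return out
    for direction, grp in out.groupby("direction"):
        x = grp[genotype_cols].to_numpy(float)
        if len(grp) < 2:
            out.loc[grp.index, "cluster"] = "common"
            continue
        lab = fcluster(linkage(x, method="ward"), t=2, criterion="maxclust")
        gap = {}
        for c in (1, 2):
            sel = lab == c
            if not sel.any():
                gap[c] = np.inf
                continue
            gap[c] = abs(x[sel, 0].mean() - x[sel, -1].mean())
        common = min(gap, key=lambda c: (gap[c], c))
        out.loc[grp.index, "cluster"] = np.where(lab == common, "common", "unique")
    return out


def region_methylation(
    regions: pd.DataFrame, cpg_records: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Per-base-mean methylation % of CpGs inside each region, per sample.

    Regions with no covered CpG in a sample get NaN.
    """
    samples = list(cpg_records)
    out = regions[["chrom", "start", "end"]].copy().reset_index(drop=True)
    for s in samples:
        df = cpg_records[s].sort_values(["chrom", "pos"])
        vals = np.full(len(out), np.nan)
        for chrom, grp in df.groupby("chrom"):
            mask = (out["chrom"] == chrom).to_numpy()
            if not mask.any():
                continue
            pos = grp["pos"].to_numpy(np.int64)
            meth = grp["meth"].to_numpy(float)
            unmeth = grp["unmeth"].to_numpy(float)
            cov = meth + unmeth
            with np.errstate(invalid="ignore", divide="ignore"):
                perbase = np.where(cov > 0, meth / np.maximum(cov, 1e-300) * 100, np.nan)
            for i in np.flatnonzero(mask):
                lo = np.searchsorted(pos, out.at[i, "start"], side="left")
                hi = np.searchsorted(pos, out.at[i, "end"], side="left")
                seg = perbase[lo:hi]
                seg = seg[~np.isnan(seg)]
                if len(seg):
                    vals[i] = float(seg.mean())
        out[s] = vals
    return out
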