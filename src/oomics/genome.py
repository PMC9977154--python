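"""Genome annotation container and interval algebra.

All coordinates are 0-based, half-open ``[start, end)`` — the BED
convention — throughout the package.  The :class:`GenomeAnnotation`
holds everything downstream stages need to share a coordinate frame:
chromosome sizes, CpG positions, gene models with strand and an
expression class, CpG islands and ERV intervals.

:class:`RegionSet` is the named interval collection used for enriched
domains, differentially methylated domains, random domains and any
feature track; it guarantees sorted, merged, in-bounds intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REGION_COLUMNS = ["chrom", "start", "end"]


class ConfigError(ValueError):
    """Raised for invalid configuration (non-positive sizes, bad ranges)."""


def _as_region_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REGION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"interval frame missing columns {missing}")
    out = df.copy()
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    if (out["start"] >= out["end"]).any():
        bad = out.index[out["start"] >= out["end"]][0]
        raise ValueError(f"interval with start >= end at row {bad}")
    return out.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def merge_intervals(df: pd.DataFrame, max_gap: int = 0) -> pd.DataFrame:
    """Union of intervals, joining neighbours separated by ``<= max_gap`` bp.

    ``max_gap=0`` merges only touching/overlapping intervals.  Returns a
    sorted, non-overlapping frame; idempotent.
    """
    df = _as_region_frame(df[REGION_COLUMNS])
    if df.empty:
        return df
    rows = []
    for chrom, grp in df.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s - cur_e <= max_gap:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def overlaps_any(query: pd.DataFrame, features: pd.DataFrame) -> np.ndarray:
    """Boolean per query interval (in input row order): does it intersect
    >= 1 bp of any feature?"""
    query = query[REGION_COLUMNS].reset_index(drop=True)
    hit = np.zeros(len(query), dtype=bool)
    if features.empty or query.empty:
        return hit
    merged = merge_intervals(features)
    for chrom, grp in merged.groupby("chrom"):
        mask = (query["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        qs = query.loc[mask, "start"].to_numpy()
        qe = query.loc[mask, "end"].to_numpy()
        fs = grp["start"].to_numpy()
        fe = grp["end"].to_numpy()
        # merged features are sorted & disjoint: any overlapper must be the
        # last feature starting before the query end
        idx = np.searchsorted(fs, qe, side="left") - 1
        ok = idx >= 0
        sub = np.zeros(mask.sum(), dtype=bool)
        sub[ok] = fe[idx[ok]] > qs[ok]
        hit[np.flatnonzero(mask)] = sub
    return hit


def gap_to_nearest(query: pd.DataFrame, features: pd.DataFrame) -> np.ndarray:
    """Per query interval, the end-to-start gap (bp) to the nearest feature.

    Overlapping or touching intervals have gap 0.  Queries on chromosomes
    with no feature get ``np.inf``.  Results follow input row order.
    """
    query = query[REGION_COLUMNS].reset_index(drop=True)
    out = np.full(len(query), np.inf)
    if features.empty:
        return out
    merged = merge_intervals(features)
    for chrom, grp in merged.groupby("chrom"):
        mask = (query["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        qs = query.loc[mask, "start"].to_numpy()
        qe = query.loc[mask, "end"].to_numpy()
        fs = grp["start"].to_numpy()
        fe = grp["end"].to_numpy()
        n = len(fs)
        idx = np.searchsorted(fs, qe, side="left") - 1  # last feature starting before query end
        gaps = np.full(mask.sum(), np.inf)
        ok = idx >= 0
        gaps[ok] = np.maximum(qs[ok] - fe[idx[ok]], 0)
        nxt = np.clip(idx + 1, 0, n - 1)
        ok2 = idx + 1 < n
        gaps[ok2] = np.minimum(gaps[ok2], np.maximum(fs[nxt[ok2]] - qe[ok2], 0))
        # overlap anywhere -> 0 (covered by the two cases above since merged)
        out[np.flatnonzero(mask)] = gaps
    return out


@dataclass
class RegionSet:
    """Named, sorted, per-chromosome non-overlapping interval collection."""

    name: str
    intervals: pd.DataFrame  # chrom, start, end [, score]

    def __post_init__(self) -> None:
        keep = [c for c in ["chrom", "start", "end", "score"] if c in self.intervals.columns]
        self.intervals = _as_region_frame(self.intervals)[keep] if len(self.intervals) else (
            pd.DataFrame(columns=REGION_COLUMNS)
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def merged(self, max_gap: int = 0) -> "RegionSet":
        return RegionSet(self.name, merge_intervals(self.intervals, max_gap))

    def total_bp(self) -> int:
        m = merge_intervals(self.intervals)
        return int((m["end"] - m["start"]).sum()) if len(m) else 0

    def overlaps(self, other: "RegionSet | pd.DataFrame") -> np.ndarray:
        feats = other.intervals if isinstance(other, RegionSet) else other
        return overlaps_any(self.intervals, feats)

    def validate_bounds(self, chrom_sizes: dict[str, int]) -> None:
        for chrom, grp in self.intervals.groupby("chrom"):
            if chrom not in chrom_sizes:
                raise ValueError(f"unknown chromosome {chrom!r} in region set {self.name!r}")
            if int(grp["end"].max()) > chrom_sizes[chrom]:
                raise ValueError(f"interval beyond end of {chrom} in region set {self.name!r}")


@dataclass
class GenomeAnnotation:
    """Coordinate frame shared by every omic layer.

    ``genes`` columns: gene_id, chrom, start, end, strand, expression_class.
    ``cgis`` / ``ervs`` columns: chrom, start, end (ervs also ``near_gene``).
    """

    chrom_sizes: dict[str, int]
    cpg_positions: dict[str, np.ndarray] = field(default_factory=dict)
    genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    cgis: pd.DataFrame = field(default_factory=pd.DataFrame)
    ervs: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ConfigError(f"chromosome {chrom!r} has non-positive size {size}")
        for chrom, pos in self.cpg_positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            if len(pos) and (np.diff(pos) <= 0).any():
                raise ValueError(f"CpG positions not strictly increasing on {chrom}")
            if len(pos) and (pos[0] < 0 or pos[-1] >= self.chrom_sizes[chrom]):
                raise ValueError(f"CpG position out of bounds on {chrom}")
            self.cpg_positions[chrom] = pos
        if len(self.genes) and (self.genes["start"] >= self.genes["end"]).any():
            raise ValueError("gene with start >= end")

    @property
    def chroms(self) -> list[str]:
        return sorted(self.chrom_sizes)

    def n_cpgs(self) -> int:
        return int(sum(len(p) for p in self.cpg_positions.values()))
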