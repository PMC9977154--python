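"""Broad-domain calling from windowed ChIP-seq counts.

H3K9me2 in growing oocytes forms megabase-scale, low-amplitude domains
rather than punctate peaks, so enrichment is quantified on fixed 10-kb
genome tiles as RPKM, artifact windows (inflated input signal) are
masked, windows above a log2RPKM threshold are called enriched, and
called windows within a gap tolerance are merged into domains.  A
matched random-domain null is built by sampling windows uniformly and
applying the same merge.

Note on scale: because reads are distributed over windows that tile the
whole genome, the expected background RPKM is ``1e9 / genome_length``
independent of sequencing depth and window width.  The default absolute
thresholds (log2RPKM > 2.5 for enrichment, RPKM > 6 for artifacts)
correspond to a mammalian-scale genome (~2.7 Gb); on small synthetic
genomes pass thresholds appropriate to the background level (see
:func:`auto_log2_threshold`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeAnnotation, RegionSet, overlaps_any

logger = logging.getLogger(__name__)

DEFAULT_WIDTH = 10_000
DEFAULT_PSEUDOCOUNT = 2.0 ** -4  # keeps zero-count windows far below any threshold


def tile_windows(genome: GenomeAnnotation, width: int = DEFAULT_WIDTH) -> pd.DataFrame:
    """Consecutive non-overlapping tiles per chromosome.

    A terminal partial tile is retained when it is at least half the
    window width, otherwise dropped.
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    rows = []
    for chrom in genome.chroms:
        size = genome.chrom_sizes[chrom]
        n_full = size // width
        for i in range(n_full):
            rows.append((chrom, i * width, (i + 1) * width))
        rem = size - n_full * width
        if rem * 2 >= width and rem > 0:
            rows.append((chrom, n_full * width, size))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


@dataclass
class WindowQuant:
    """Per-window, per-sample quantification with an artifact mask."""

    windows: pd.DataFrame            # chrom, start, end
    counts: pd.DataFrame             # windows x samples, raw counts
    rpkm: pd.DataFrame
    log2rpkm: pd.DataFrame
    mask: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    def __post_init__(self) -> None:
        if self.mask.size == 0:
            self.mask = np.zeros(len(self.windows), dtype=bool)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


def quantify_rpkm(
    windows: pd.DataFrame,
    counts: pd.DataFrame,
    library_size: "pd.Series | dict | None" = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> WindowQuant:
    """RPKM = count / ((width/1000) x (library/1e6)) per window and sample.

    ``library_size`` defaults to the per-sample column sum.
    """
    counts = counts.reset_index(drop=True)
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative window counts")
    if library_size is None:
        lib = counts.sum(axis=0).astype(float)
    else:
        lib = pd.Series(library_size, dtype=float).reindex(counts.columns)
    if (lib <= 0).any():
        raise ValueError("library size must be positive")
    width_kb = (windows["end"] - windows["start"]).to_numpy(dtype=float)[:, None] / 1000.0
    rpkm = counts.to_numpy(dtype=float) / (width_kb * (lib.to_numpy() / 1e6))
    rpkm = pd.DataFrame(rpkm, columns=counts.columns)
    log2rpkm = np.log2(rpkm + pseudocount)
    return WindowQuant(windows.reset_index(drop=True), counts, rpkm, log2rpkm)


def mask_artifacts(
    wq: WindowQuant,
    replicate_sets: dict[str, list[str]],
    rpkm_threshold: float = 6.0,
) -> np.ndarray:
    """Mask windows whose mean input RPKM exceeds the threshold in any
    replicate set of input libraries (strict ``>``).

    ``replicate_sets`` maps a set name to the input sample columns it
    contains.  The mask is stored on ``wq`` and returned.
    """
    if not replicate_sets or not any(replicate_sets.values()):
        raise ValueError("at least one input replicate set required")
    mask = np.zeros(len(wq.windows), dtype=bool)
    for name, cols in replicate_sets.items():
        if not cols:
            raise ValueError(f"replicate set {name!r} has no samples")
        mask |= (wq.rpkm[cols].mean(axis=1) > rpkm_threshold).to_numpy()
    wq.mask = mask
    logger.info("artifact mask: %d of %d windows", int(mask.sum()), len(mask))
    return mask


def auto_log2_threshold(wq: WindowQuant, columns: list[str], enrichment_fold: float) -> float:
    """Midpoint threshold for small genomes: median log2RPKM of the
    reference samples (the background, when enriched windows are a
    minority) plus half the expected fold in log2 units."""
    med = float(np.median(wq.log2rpkm[columns].to_numpy()))
    return med + np.log2(enrichment_fold) / 2.0


def call_enriched_windows(
    wq: WindowQuant,
    columns: "str | list[str]",
    log2_threshold: float = 2.5,
) -> np.ndarray:
    """Enriched iff mean log2RPKM of the reference sample(s) is strictly
    above the threshold and the window is not masked."""
    if isinstance(columns, str):
        columns = [columns]
    sig = wq.log2rpkm[columns].mean(axis=1).to_numpy()
    return (sig > log2_threshold) & ~wq.mask


def merge_windows(
    windows: pd.DataFrame,
    called: np.ndarray,
    max_gap: int = DEFAULT_WIDTH,
    name: str = "domains",
) -> RegionSet:
    """Join called windows whose gap is ``<= max_gap`` into domains.

    The gap between windows is absorbed into the domain span.  Input
    windows must be sorted by (chrom, start); idempotent by construction.
    """
    w = windows.reset_index(drop=True)
    order_ok = all(
        (grp["start"].is_monotonic_increasing for _, grp in w.groupby("chrom"))
    )
    if not order_ok:
        raise ValueError("windows must be sorted by (chrom, start)")
    sel = w.loc[np.asarray(called, dtype=bool), ["chrom", "start", "end"]]
    if sel.empty:
        return RegionSet(name, pd.DataFrame(columns=["chrom", "start", "end"]))
    from .genome import merge_intervals

    return RegionSet(name, merge_intervals(sel, max_gap=max_gap))


def sample_random_domains(
    wq: WindowQuant,
    n: int,
    max_gap: int = DEFAULT_WIDTH,
    seed: int = 0,
    name: str = "random_domains",
) -> RegionSet:
    """Uniformly sample ``n`` unmasked windows without replacement and
    merge them with the same gap rule as real domains."""
    avail = np.flatnonzero(~wq.mask)
    if n > len(avail):
        raise ValueError(f"requested {n} windows but only {len(avail)} unmasked")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(avail, size=n, replace=False)
    called = np.zeros(len(wq.windows), dtype=bool)
    called[chosen] = True
    return merge_windows(wq.windows, called, max_gap=max_gap, name=name)


def composite_profile(
    regions: RegionSet,
    wq: WindowQuant,
    columns: "list[str] | None" = None,
    flank: int = 5000,
    interior_bins: int = 20,
    flank_bin: int = 1000,
) -> pd.DataFrame:
    """Probe-trend profile: mean log2RPKM across regions scaled to a
    fixed number of interior bins plus fixed-width flank bins.

    Rows are ordered left flank -> interior -> right flank; per-bin
    values are window means weighted by overlap fraction, averaged over
    regions.  Regions shorter than one bin contribute their single mean
    to every interior bin.
    """
    if len(regions) == 0:
        raise ValueError("empty region set")
    if columns is None:
        columns = wq.samples
    n_flank = flank // flank_bin
    n_bins = 2 * n_flank + interior_bins
    sig = wq.log2rpkm[columns].to_numpy()
    acc = np.zeros((n_bins, len(columns)))
    cnt = np.zeros(n_bins)

    by_chrom = {}
    w = wq.windows
    for chrom, grp in w.groupby("chrom"):
        by_chrom[chrom] = (
            grp["start"].to_numpy(float),
            grp["end"].to_numpy(float),
            grp.index.to_numpy(),
        )

    def bin_mean(chrom_dat, bs: float, be: float):
        ws, we, idx = chrom_dat
        lo = np.searchsorted(we, bs, side="right")
        hi = np.searchsorted(ws, be, side="left")
        if hi <= lo:
            return None
        ov = np.minimum(we[lo:hi], be) - np.maximum(ws[lo:hi], bs)
        wsum = ov.sum()
        if wsum <= 0:
            return None
        return (ov[:, None] * sig[idx[lo:hi]]).sum(axis=0) / wsum

    for _, reg in regions.intervals.iterrows():
        chrom_dat = by_chrom.get(reg["chrom"])
        if chrom_dat is None:
            continue
        start, end = float(reg["start"]), float(reg["end"])
        edges = []
        for k in range(n_flank):
            edges.append((start - flank + k * flank_bin, start - flank + (k + 1) * flank_bin))
        if end - start < interior_bins:
            mid = bin_mean(chrom_dat, start, end)
            interior = [(start, end)] * interior_bins
        else:
            mid = None
            step = (end - start) / interior_bins
            interior = [(start + k * step, start + (k + 1) * step) for k in range(interior_bins)]
        edges.extend(interior)
        for k in range(n_flank):
            edges.append((end + k * flank_bin, end + (k + 1) * flank_bin))
        for b, (bs, be) in enumerate(edges):
            if mid is not None and n_flank <= b < n_flank + interior_bins:
                val = mid
            else:
                val = bin_mean(chrom_dat, bs, be)
            if val is not None:
                acc[b] += val
                cnt[b] += 1

    with np.errstate(invalid="ignore"):
        prof = acc / cnt[:, None]
    labels = (
        [f"flank_l{k}" for k in range(n_flank)]
        + [f"interior{k}" for k in range(interior_bins)]
        + [f"flank_r{k}" for k in range(n_flank)]
    )
    return pd.DataFrame(prof, index=labels, columns=columns)


def classify_promoters(
    genes: pd.DataFrame,
    fpkm: pd.Series,
    cgis: pd.DataFrame,
    flank: int = 500,
) -> pd.DataFrame:
    """Promoters as +/-500 bp around the strand-aware TSS, classified by
    expression (FPKM < 0.1 not expressed; 0.1 <= FPKM < 1 low; >= 1
    high; boundaries assigned upward) and CGI overlap."""
    if genes["strand"].isna().any() or (~genes["strand"].isin(["+", "-"])).any():
        raise ValueError("every gene needs a '+' or '-' strand")
    tss = np.where(genes["strand"] == "+", genes["start"], genes["end"])
    prom = pd.DataFrame(
        {
            "gene_id": genes["gene_id"].to_numpy(),
            "chrom": genes["chrom"].to_numpy(),
            "start": np.maximum(tss - flank, 0),
            "end": tss + flank,
            "strand": genes["strand"].to_numpy(),
        }
    )
    f = fpkm.reindex(genes["gene_id"]).to_numpy(dtype=float)
    cls = np.where(f < 0.1, "not_expressed", np.where(f < 1.0, "low", "high"))
    prom["fpkm"] = f
    prom["expression_class"] = cls
    prom["cgi_promoter"] = overlaps_any(prom, cgis) if len(cgis) else False
    return prom
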