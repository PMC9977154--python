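"""Synthetic multi-omics data with recorded planted truth.

Every generator is a pure function of its configuration and seed, and
returns both the data and the truth that was planted, so each
downstream stage has a parameter-recovery test:

* :func:`make_genome` — chromosome sizes, CpG positions (clustered at
  CpG islands), gene models with strand, CGIs, and ERVs placed both
  within and beyond 2 kb of genes so the exclusion rule is exercised.
* :func:`simulate_chip` — multinomial window counts with a fold
  enrichment inside planted broad domains, plus artifact windows with
  inflated input signal.
* :func:`simulate_bisulfite` — beta-binomial per-CpG counts with
  group-level shifts on planted 100-CpG tiles.
* :func:`simulate_rnaseq` — NB gene counts with planted fold changes
  biased toward up-regulation (90/10 by default, mirroring the
  derepression phenotype).
* :func:`simulate_proteome` — log2 intensities whose fold changes are
  rank-coupled to transcript fold changes at a target Spearman rho.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chip import tile_windows
from .genome import ConfigError, GenomeAnnotation, overlaps_any
from .methylome import tile_spans_from_positions

logger = logging.getLogger(__name__)

DEFAULT_SIZES = {"chr1": 5_000_000, "chr2": 5_000_000, "chr3": 5_000_000}


@dataclass
class PlantedTruth:
    """What was planted, for parameter-recovery tests."""

    true_enriched_domains: pd.DataFrame = field(default_factory=pd.DataFrame)
    artifact_windows: list = field(default_factory=list)
    true_dmr_tiles: pd.DataFrame = field(default_factory=pd.DataFrame)
    true_de_genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    protein_coupling: float = 0.0
    protein_log2fc: "pd.Series | None" = None
    seeds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "true_enriched_domains": self.true_enriched_domains.to_dict("list"),
            "artifact_windows": [int(i) for i in self.artifact_windows],
            "true_dmr_tiles": self.true_dmr_tiles.to_dict("list"),
            "true_de_genes": self.true_de_genes.to_dict("list"),
            "protein_coupling": self.protein_coupling,
            "protein_log2fc": (
                None
                if self.protein_log2fc is None
                else {str(k): float(v) for k, v in self.protein_log2fc.items()}
            ),
            "seeds": {k: int(v) for k, v in self.seeds.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlantedTruth":
        return cls(
            pd.DataFrame(d.get("true_enriched_domains", {})),
            list(d.get("artifact_windows", [])),
            pd.DataFrame(d.get("true_dmr_tiles", {})),
            pd.DataFrame(d.get("true_de_genes", {})),
            float(d.get("protein_coupling", 0.0)),
            None
            if d.get("protein_log2fc") is None
            else pd.Series(d["protein_log2fc"], dtype=float),
            dict(d.get("seeds", {})),
        )


def _child_seed(seed: int, tag: str) -> int:
    """Deterministic sub-stream seed below 2^31 derived from (seed, tag)."""
    h = int(seed) & 0x7FFFFFFF
    for ch in tag:
        h = (h * 31 + ord(ch)) % 2147483647
    return h


def make_genome(
    sizes: "dict[str, int] | None" = None,
    n_genes: int = 400,
    n_cgis: int = 150,
    n_ervs: int = 60,
    cpg_density: float = 0.008,
    cgi_cpg_density: float = 0.08,
    seed: int = 0,
    near_gene_fraction: float = 0.5,
) -> GenomeAnnotation:
    """Random genome annotation, deterministic for a fixed seed.

    CpGs are dense inside CGIs and sparse (``cpg_density`` per bp)
    elsewhere; ``near_gene_fraction`` of ERVs are placed within 2 kb of
    a gene, the rest at least 2 kb away.
    """
    sizes = dict(DEFAULT_SIZES if sizes is None else sizes)
    for chrom, size in sizes.items():
        if size <= 0:
            raise ConfigError(f"chromosome {chrom!r} has non-positive size {size}")
    rng = np.random.default_rng(seed)
    chroms = sorted(sizes)
    total = sum(sizes.values())

    def alloc(n):
        # distribute n items over chroms proportional to length
        quotas = np.array([sizes[c] for c in chroms], float) / total * n
        counts = np.floor(quotas).astype(int)
        rem = n - counts.sum()
        order = np.argsort(-(quotas - counts), kind="stable")
        counts[order[:rem]] += 1
        return dict(zip(chroms, counts))

    # CGIs
    cgi_rows = []
    for chrom, cnt in alloc(n_cgis).items():
        for _ in range(cnt):
            length = int(rng.integers(500, 2000))
            start = int(rng.integers(0, max(sizes[chrom] - length, 1)))
            cgi_rows.append((chrom, start, start + length))
    cgis = pd.DataFrame(cgi_rows, columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start"]).reset_index(drop=True)

    # genes
    gene_rows = []
    gid = 0
    for chrom, cnt in alloc(n_genes).items():
        for _ in range(cnt):
            length = int(np.clip(rng.lognormal(np.log(10_000), 0.8), 2_000, sizes[chrom] // 2))
            start = int(rng.integers(0, max(sizes[chrom] - length, 1)))
            strand = "+" if rng.random() < 0.5 else "-"
            cls = rng.choice(["not_expressed", "low", "high"], p=[0.3, 0.3, 0.4])
            gene_rows.append((f"gene{gid:05d}", chrom, start, start + length, strand, cls))
            gid += 1
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "strand", "expression_class"]
    ).sort_values(["chrom", "start"]).reset_index(drop=True)

    # ERVs: some deliberately near genes, the rest kept clear.  Gap
    # checks use pre-merged gene intervals per chromosome for speed.
    from .genome import merge_intervals

    merged_genes = merge_intervals(genes[["chrom", "start", "end"]]) if len(genes) else (
        pd.DataFrame(columns=["chrom", "start", "end"])
    )
    gene_arr = {
        c: (grp["start"].to_numpy(), grp["end"].to_numpy())
        for c, grp in merged_genes.groupby("chrom")
    }

    def min_gap(chrom, start, end):
        if chrom not in gene_arr:
            return np.inf
        fs, fe = gene_arr[chrom]
        i = np.searchsorted(fs, end, side="left") - 1
        gap = np.inf
        if i >= 0:
            gap = max(start - fe[i], 0)
        if i + 1 < len(fs):
            gap = min(gap, max(fs[i + 1] - end, 0))
        return gap

    erv_rows = []
    n_near = int(round(n_ervs * near_gene_fraction))
    genes_by_chrom = {c: g.reset_index(drop=True) for c, g in genes.groupby("chrom")}
    for i in range(n_ervs):
        length = int(rng.integers(500, 5000))
        near = i < n_near
        start, chrom = 0, chroms[0]
        for _ in range(500):
            chrom = chroms[int(rng.integers(len(chroms)))]
            if near and chrom in genes_by_chrom and len(genes_by_chrom[chrom]):
                gsub = genes_by_chrom[chrom]
                g = gsub.iloc[int(rng.integers(len(gsub)))]
                offset = int(rng.integers(0, 2000))
                start = int(g["end"]) + offset
                if start + length > sizes[chrom]:
                    start = max(int(g["start"]) - offset - length, 0)
            else:
                start = int(rng.integers(0, max(sizes[chrom] - length, 1)))
            if start < 0 or start + length > sizes[chrom]:
                continue
            gap = min_gap(chrom, start, start + length)
            if near and gap < 2000:
                break
            if not near and gap >= 4000:
                break
        erv_rows.append((chrom, start, start + length, bool(near)))
    ervs = pd.DataFrame(erv_rows, columns=["chrom", "start", "end", "near_gene"]).sort_values(
        ["chrom", "start"]).reset_index(drop=True)

    # CpGs: background positions from geometric inter-CpG gaps plus
    # dense positions inside CGIs
    def thinned_positions(offset, span, density):
        # geometric inter-CpG gaps <=> Bernoulli(density) per base
        if density <= 0 or span <= 0:
            return np.array([], dtype=np.int64)
        mean_n = span * density
        n_draw = int(mean_n + 10 * np.sqrt(mean_n + 1) + 100)
        gaps = rng.geometric(min(density, 1.0), size=n_draw)
        while gaps.sum() < span:
            gaps = np.concatenate([gaps, rng.geometric(min(density, 1.0), size=n_draw)])
        pos = np.cumsum(gaps) - 1
        pos = pos[pos < span]
        return (offset + pos).astype(np.int64)

    cpg_positions = {}
    for chrom in chroms:
        size = sizes[chrom]
        bg = thinned_positions(0, size, cpg_density)
        cgi_pos = [
            thinned_positions(int(row["start"]), int(row["end"] - row["start"]), cgi_cpg_density)
            for _, row in cgis[cgis["chrom"] == chrom].iterrows()
        ]
        allpos = np.concatenate([bg] + cgi_pos) if cgi_pos else bg
        cpg_positions[chrom] = np.unique(allpos.astype(np.int64))

    return GenomeAnnotation(sizes, cpg_positions, genes, cgis, ervs)


def plant_domains(
    genome: GenomeAnnotation,
    n_domains: int = 12,
    width: int = 10_000,
    min_windows: int = 3,
    max_windows: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Non-overlapping broad domains aligned to the window grid."""
    rng = np.random.default_rng(seed)
    windows = tile_windows(genome, width)
    chosen: set[int] = set()
    rows = []
    by_chrom = {c: g.index.to_numpy() for c, g in windows.groupby("chrom")}
    for _ in range(n_domains):
        for _ in range(200):
            chrom = genome.chroms[int(rng.integers(len(genome.chroms)))]
            idx = by_chrom[chrom]
            span = int(rng.integers(min_windows, max_windows + 1))
            if len(idx) <= span + 2:
                continue
            i0 = int(rng.integers(0, len(idx) - span))
            block = idx[i0 : i0 + span]
            # keep a >=1-window buffer so planted domains never merge
            buffered = set(range(block[0] - 2, block[-1] + 3))
            if buffered & chosen:
                continue
            chosen.update(buffered)
            rows.append(
                (chrom, int(windows.loc[block[0], "start"]), int(windows.loc[block[-1], "end"]))
            )
            break
    return pd.DataFrame(rows, columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start"]).reset_index(drop=True)


def simulate_chip(
    genome: GenomeAnnotation,
    truth_domains: pd.DataFrame,
    enrichment_fold: float = 6.0,
    n_reads_chip: int = 1_000_000,
    n_reads_input: int = 1_000_000,
    n_replicates: int = 2,
    seed: int = 0,
    width: int = 10_000,
    n_artifact_windows: int = 0,
    artifact_fold: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Multinomial window counts for ChIP and input libraries.

    ChIP window weights are the background rate times ``enrichment_fold``
    inside truth domains; input weights are uniform except for
    ``n_artifact_windows`` windows (outside domains) inflated by
    ``artifact_fold`` in the input — mimicking mapping artifacts.
    Returns (windows, counts, truth); counts columns are
    ``chip_r*``/``input_r*`` and sum exactly to the library sizes.
    """
    if enrichment_fold < 1:
        raise ValueError("enrichment_fold must be >= 1")
    if n_reads_chip <= 0 or n_reads_input <= 0:
        raise ValueError("read counts must be positive")
    for _, row in truth_domains.iterrows():
        if row["chrom"] not in genome.chrom_sizes:
            raise ValueError(f"truth domain on unknown chromosome {row['chrom']!r}")
        if row["end"] > genome.chrom_sizes[row["chrom"]] or row["start"] < 0:
            raise ValueError("truth domain outside chromosome bounds")
    rng = np.random.default_rng(seed)
    windows = tile_windows(genome, width)
    in_domain = overlaps_any(windows, truth_domains) if len(truth_domains) else (
        np.zeros(len(windows), dtype=bool)
    )
    wlen = (windows["end"] - windows["start"]).to_numpy(float)
    w_chip = wlen * np.where(in_domain, enrichment_fold, 1.0)

    artifact_idx: list[int] = []
    w_input = wlen.copy()
    if n_artifact_windows:
        candidates = np.flatnonzero(~in_domain)
        artifact_idx = sorted(
            int(i) for i in rng.choice(candidates, size=n_artifact_windows, replace=False)
        )
        w_input[artifact_idx] *= artifact_fold

    data = {}
    for r in range(1, n_replicates + 1):
        data[f"chip_r{r}"] = rng.multinomial(n_reads_chip, w_chip / w_chip.sum())
    for r in range(1, n_replicates + 1):
        data[f"input_r{r}"] = rng.multinomial(n_reads_input, w_input / w_input.sum())
    counts = pd.DataFrame(data)
    truth = PlantedTruth(
        true_enriched_domains=truth_domains.reset_index(drop=True),
        artifact_windows=artifact_idx,
        seeds={"chip": seed},
    )
    return windows, counts, truth


def plant_dmr_tiles(
    genome: GenomeAnnotation,
    n_tiles: int = 60,
    effect: float = 30.0,
    hyper_fraction: float = 0.5,
    tile_cpgs: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Pick tiles of the canonical 100-CpG tiling and assign +/- effects
    in percentage points."""
    rng = np.random.default_rng(seed)
    rows = []
    offset = 0
    for chrom in genome.chroms:
        spans = tile_spans_from_positions(genome.cpg_positions[chrom], tile_cpgs)
        for s_, e_ in spans:
            rows.append((chrom, int(s_), int(e_)))
        offset += len(spans)
    tiles = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    tiles["tile_id"] = np.arange(len(tiles))
    if n_tiles > len(tiles):
        raise ValueError(f"requested {n_tiles} effect tiles but only {len(tiles)} exist")
    chosen = np.sort(rng.choice(len(tiles), size=n_tiles, replace=False))
    out = tiles.iloc[chosen].reset_index(drop=True)
    n_hyper = int(round(n_tiles * hyper_fraction))
    sign = np.where(np.arange(n_tiles) < n_hyper, 1.0, -1.0)
    sign = rng.permutation(sign)
    out["direction"] = np.where(sign > 0, "hyper", "hypo")
    out["effect"] = sign * effect
    return out


def simulate_bisulfite(
    genome: GenomeAnnotation,
    group_means: "dict[str, float]",
    effect_tiles: "pd.DataFrame | None" = None,
    coverage_mean: float = 30.0,
    beta_dispersion: float = 0.02,
    n_replicates: int = 2,
    seed: int = 0,
    tile_cpgs: int = 100,
) -> tuple[dict[str, pd.DataFrame], dict[str, str], PlantedTruth]:
    """Replicate per-CpG (meth, unmeth) counts with planted tile shifts.

    Per CpG and replicate: coverage ~ Poisson(coverage_mean) and
    methylated ~ Binomial(coverage, p) with p ~ Beta parameterised by
    the group mean m and dispersion phi (a = m(1-phi)/phi,
    b = (1-m)(1-phi)/phi; phi = 0 means pure binomial).  ``effect_tiles``
    (from :func:`plant_dmr_tiles`) shift the second group's mean by the
    planted percentage points, clipped to [0, 100] with a warning.
    Returns (records per sample, sample->group, truth).
    """
    if beta_dispersion < 0:
        raise ValueError("beta_dispersion must be >= 0")
    for g, m in group_means.items():
        if not 0 <= m <= 100:
            raise ValueError(f"group mean for {g!r} outside [0, 100]")
    groups = list(group_means)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    rng = np.random.default_rng(seed)

    # per-CpG base mean for the shifted group
    shift = {chrom: np.zeros(len(genome.cpg_positions[chrom])) for chrom in genome.chroms}
    if effect_tiles is not None and len(effect_tiles):
        for _, row in effect_tiles.iterrows():
            pos = genome.cpg_positions[row["chrom"]]
            lo = np.searchsorted(pos, row["start"], side="left")
            hi = np.searchsorted(pos, row["end"], side="left")
            shift[row["chrom"]][lo:hi] = row["effect"]
        target = group_means[groups[1]] + effect_tiles["effect"]
        if ((target < 0) | (target > 100)).any():
            logger.warning("planted effect pushes a group mean outside [0, 100]; clipping")

    records: dict[str, pd.DataFrame] = {}
    sample_groups: dict[str, str] = {}
    phi = beta_dispersion
    for gi, g in enumerate(groups):
        for r in range(1, n_replicates + 1):
            frames = []
            for chrom in genome.chroms:
                pos = genome.cpg_positions[chrom]
                m = np.full(len(pos), group_means[g], float)
                if gi == 1:
                    m = np.clip(m + shift[chrom], 0.0, 100.0)
                m = m / 100.0
                cov = rng.poisson(coverage_mean, size=len(pos))
                if phi > 0:
                    interior = (m > 0) & (m < 1)
                    p = m.copy()
                    a = m[interior] * (1 - phi) / phi
                    b = (1 - m[interior]) * (1 - phi) / phi
                    p[interior] = rng.beta(a, b)
                else:
                    p = m
                meth = rng.binomial(cov, p)
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "pos": pos,
                            "meth": meth,
                            "unmeth": cov - meth,
                        }
                    )
                )
            name = f"{g}_r{r}"
            records[name] = pd.concat(frames, ignore_index=True)
            sample_groups[name] = g
    truth = PlantedTruth(
        true_dmr_tiles=(effect_tiles if effect_tiles is not None else pd.DataFrame()).copy(),
        seeds={"bisulfite": seed},
    )
    return records, sample_groups, truth


def make_de_truth(
    genome: GenomeAnnotation,
    n_de: int = 60,
    log2fc: float = 2.0,
    up_fraction: float = 0.9,
    seed: int = 0,
) -> pd.DataFrame:
    """Planted DE genes, ``up_fraction`` up-regulated (default 90/10,
    mirroring the strong up-bias of derepression)."""
    rng = np.random.default_rng(seed)
    ids = genome.genes["gene_id"].to_numpy()
    if n_de > len(ids):
        raise ValueError("more DE genes requested than genes in the genome")
    chosen = rng.choice(ids, size=n_de, replace=False)
    n_up = int(round(n_de * up_fraction))
    sign = np.where(np.arange(n_de) < n_up, 1.0, -1.0)
    sign = rng.permutation(sign)
    return pd.DataFrame({"gene_id": chosen, "log2fc": sign * log2fc})


def simulate_rnaseq(
    genome: GenomeAnnotation,
    de_truth: pd.DataFrame,
    baseline_mean: float = 100.0,
    dispersion: float = 0.05,
    library_sizes: "dict[str, list[float]] | None" = None,
    n_replicates: int = 4,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str], PlantedTruth]:
    """NB gene count matrix with planted fold changes.

    Mean of gene g in sample j = size_factor_j x baseline_g x
    2^log2FC(g) for the mutant group; counts ~ NB via gamma-Poisson
    (dispersion 0 = Poisson).  Baselines are log-normal around
    ``baseline_mean``.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    known = set(genome.genes["gene_id"])
    missing = set(de_truth["gene_id"]) - known
    if missing:
        raise ValueError(f"de_truth genes absent from genome: {sorted(missing)[:3]}...")
    rng = np.random.default_rng(seed)
    ids = genome.genes["gene_id"].to_numpy()
    n_genes = len(ids)
    baseline = rng.lognormal(np.log(baseline_mean), 0.6, size=n_genes)
    lfc = pd.Series(0.0, index=ids)
    lfc.loc[de_truth["gene_id"].to_numpy()] = de_truth["log2fc"].to_numpy(float)

    if library_sizes is None:
        library_sizes = {
            "control": [1.0] * n_replicates,
            "mutant": [1.0] * n_replicates,
        }
    for g, libs in library_sizes.items():
        if any(l <= 0 for l in libs):
            raise ValueError(f"non-positive library size factor in group {g!r}")
    groups = list(library_sizes)

    data = {}
    sample_groups = {}
    for gi, g in enumerate(groups):
        for r, sf in enumerate(library_sizes[g], start=1):
            mu = sf * baseline * (2.0 ** lfc.to_numpy() if gi == 1 else 1.0)
            if dispersion > 0:
                lam = rng.gamma(1.0 / dispersion, dispersion * mu)
            else:
                lam = mu
            name = f"{g}_r{r}"
            data[name] = rng.poisson(lam)
            sample_groups[name] = g
    counts = pd.DataFrame(data, index=ids)
    truth = PlantedTruth(true_de_genes=de_truth.reset_index(drop=True), seeds={"rnaseq": seed})
    return counts, sample_groups, truth


def simulate_proteome(
    transcript_log2fc: pd.Series,
    coupling_rho: float = 0.43,
    n_proteins: int = 2933,
    noise_sd: float = 0.2,
    n_replicates: int = 5,
    seed: int = 0,
    lfc_scale: float = 0.5,
    baseline_mean: float = 10.0,
) -> tuple[pd.DataFrame, dict[str, str], PlantedTruth]:
    """Protein log2 intensities rank-coupled to transcript fold changes.

    Protein fold changes are built from the normal scores of the
    transcript fold-change ranks mixed with independent Gaussian noise;
    the mixing weight is ``2 sin(pi * rho / 6)``, which makes the
    expected Spearman correlation across shared genes equal
    ``coupling_rho`` (exact for the bivariate normal; within
    Monte-Carlo error here).  Replicate intensities are the group mean
    plus N(0, noise_sd).
    """
    if not 0 <= coupling_rho <= 1:
        raise ValueError("coupling_rho must be in [0, 1]")
    if n_proteins > len(transcript_log2fc):
        raise ValueError("n_proteins exceeds available matched transcripts")
    rng = np.random.default_rng(seed)
    chosen = transcript_log2fc.sample(n=n_proteins, random_state=int(seed) % (2**31)) if (
        n_proteins < len(transcript_log2fc)
    ) else transcript_log2fc
    t = chosen.to_numpy(float)
    from scipy import stats as _st

    ranks = _st.rankdata(t, method="average")
    scores = _st.norm.ppf(ranks / (len(t) + 1))
    scores = (scores - scores.mean()) / max(scores.std(), 1e-12)
    lam = 2.0 * np.sin(np.pi * coupling_rho / 6.0)
    eps = rng.standard_normal(len(t))
    coupled = lam * scores + np.sqrt(max(1.0 - lam**2, 0.0)) * eps
    protein_lfc = pd.Series(lfc_scale * coupled, index=chosen.index)

    baseline = baseline_mean + rng.standard_normal(len(t))
    data = {}
    sample_groups = {}
    for gi, g in enumerate(["control", "mutant"]):
        for r in range(1, n_replicates + 1):
            mean = baseline + (protein_lfc.to_numpy() if gi == 1 else 0.0)
            name = f"{g}_r{r}"
            data[name] = mean + noise_sd * rng.standard_normal(len(t))
            sample_groups[name] = g
    matrix = pd.DataFrame(data, index=chosen.index)
    truth = PlantedTruth(
        protein_coupling=coupling_rho,
        protein_log2fc=protein_lfc,
        seeds={"proteome": seed},
    )
    return matrix, sample_groups, truth
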