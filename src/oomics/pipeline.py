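"""End-to-end orchestration on synthetic data.

``run_pipeline`` executes the requested stages in dependency order —
simulate, chip, methylome, rnaseq, proteome, integrate — writing every
artifact with a provenance header (package version, config hash, seed)
so that a rerun with the same config and seed is byte-identical.

The default configuration is the desk-scale study design: a 3 x 5 Mb
genome, fold-6 H3K9me2 domains at 1e6 reads, 30x bisulfite coverage
with 2 replicates per genotype, NB RNA counts with 90%-up planted fold
changes in 4v4, and a 5v5 TMT-style proteome rank-coupled to the
transcriptome at Spearman rho 0.43.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chip as chipmod
from . import integrate as integmod
from . import io as iomod
from . import methylome as methmod
from . import proteome as protmod
from . import rnaseq as rnamod
from . import simulate as simmod
from .genome import RegionSet

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "stages": ["simulate", "chip", "methylome", "rnaseq", "proteome", "integrate"],
    "genome": {
        "sizes": dict(simmod.DEFAULT_SIZES),
        "n_genes": 400,
        "n_cgis": 150,
        "n_ervs": 60,
        "cpg_density": 0.008,
    },
    "chip": {
        "enrichment_fold": 6.0,
        "n_reads": 1_000_000,
        "n_replicates": 2,
        "n_domains": 12,
        "n_artifact_windows": 20,
        "artifact_fold": 10.0,
        "width": 10_000,
        "threshold": "auto",
        "artifact_threshold": "auto",
        "gap": 10_000,
        "random_n": 150,
    },
    "bsseq": {
        "group_means": {"control": 70.0, "mutant": 70.0},
        "n_effect_tiles": 40,
        "effect": 30.0,
        "hyper_fraction": 0.5,
        "coverage_mean": 30.0,
        "beta_dispersion": 0.02,
        "n_replicates": 2,
        "alpha": 0.05,
        "min_diff": 20.0,
    },
    "rnaseq": {
        "n_de": 40,
        "log2fc": 2.0,
        "up_fraction": 0.9,
        "baseline_mean": 100.0,
        "dispersion": 0.05,
        "n_replicates": 4,
        "lfc": 1.5,
        "alpha": 0.05,
        "erv_fold_mutant": 2.0,
        "background_lfc_sd": 0.3,
    },
    "proteome": {
        "coupling_rho": 0.43,
        "n_proteins": 300,
        "noise_sd": 0.2,
        "n_replicates": 5,
        "p": 0.05,
        "lfc": 0.3,
        "lfc_scale": 0.5,
    },
}


def load_config(path: "str | Path | None" = None, overrides: "dict | None" = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _deep_update(cfg, user)
    if overrides:
        _deep_update(cfg, overrides)
    return cfg


def _deep_update(base: dict, upd: dict) -> None:
    for k, v in upd.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


class MissingStageError(RuntimeError):
    pass


def run_pipeline(config: dict, outdir: "str | Path") -> dict:
    """Run the configured stages; returns the in-memory artifact dict.

    Raises :class:`MissingStageError` naming the stage to run first
    when a downstream stage lacks its inputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    chash = iomod.config_hash(config)
    header = iomod.provenance_line(chash, seed)
    stages = list(config.get("stages", []))
    # stages whose simulation block was removed are skipped entirely
    stages = [
        s for s in stages
        if not (s in ("methylome",) and "bsseq" not in config)
        and not (s in ("chip", "rnaseq", "proteome") and s not in config and s != "simulate")
    ]
    art: dict = {"config": config, "config_hash": chash}
    counters: dict[str, int] = {}

    log_path = outdir / "pipeline.log"
    fh = logging.FileHandler(log_path, mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("oomics")
    root.addHandler(fh)
    try:
        if "simulate" in stages:
            _stage_simulate(config, seed, art, outdir, header)
        if "chip" in stages:
            _require(art, "chip_counts", "simulate")
            _stage_chip(config["chip"], art, outdir, header, counters)
        if "methylome" in stages:
            _require(art, "bsseq_records", "simulate")
            _stage_methylome(config["bsseq"], art, outdir, header, counters)
        if "rnaseq" in stages:
            _require(art, "rna_counts", "simulate")
            _stage_rnaseq(config["rnaseq"], art, outdir, header, counters)
        if "proteome" in stages:
            _require(art, "protein_matrix", "simulate")
            _stage_proteome(config["proteome"], art, outdir, header)
        if "integrate" in stages:
            for key, stage in [
                ("domains", "chip"), ("dmrs", "methylome"),
                ("de_results", "rnaseq"), ("protein_results", "proteome"),
            ]:
                _require(art, key, stage)
            _stage_integrate(art, outdir, header)
        with open(outdir / "filter_counts.json", "w") as f:
            json.dump(counters, f, indent=1, sort_keys=True)
            f.write("\n")
    finally:
        root.removeHandler(fh)
        fh.close()
    return art


def _require(art: dict, key: str, stage: str) -> None:
    if key not in art:
        raise MissingStageError(f"missing artifact {key!r}: run stage {stage!r} first")


def _stage_simulate(config, seed, art, outdir, header):
    gcfg = config["genome"]
    genome = simmod.make_genome(
        sizes=gcfg["sizes"],
        n_genes=gcfg["n_genes"],
        n_cgis=gcfg["n_cgis"],
        n_ervs=gcfg["n_ervs"],
        cpg_density=gcfg["cpg_density"],
        seed=simmod._child_seed(seed, "genome"),
    )
    art["genome"] = genome
    truth_all: dict = {}

    if "chip" in config:
        c = config["chip"]
        domains = simmod.plant_domains(
            genome, n_domains=c["n_domains"], width=c["width"],
            seed=simmod._child_seed(seed, "domains"),
        )
        windows, counts, truth = simmod.simulate_chip(
            genome, domains,
            enrichment_fold=c["enrichment_fold"],
            n_reads_chip=c["n_reads"], n_reads_input=c["n_reads"],
            n_replicates=c["n_replicates"],
            seed=simmod._child_seed(seed, "chip"),
            width=c["width"],
            n_artifact_windows=c["n_artifact_windows"],
            artifact_fold=c["artifact_fold"],
        )
        art["chip_windows"], art["chip_counts"], art["chip_truth"] = windows, counts, truth
        truth_all["chip"] = truth.to_dict()
        iomod.write_matrix(counts, outdir / "chip_window_counts.tsv", header)

    if "bsseq" in config:
        b = config["bsseq"]
        effect = simmod.plant_dmr_tiles(
            genome, n_tiles=b["n_effect_tiles"], effect=b["effect"],
            hyper_fraction=b["hyper_fraction"],
            seed=simmod._child_seed(seed, "dmr_truth"),
        )
        records, groups, truth = simmod.simulate_bisulfite(
            genome, b["group_means"], effect,
            coverage_mean=b["coverage_mean"], beta_dispersion=b["beta_dispersion"],
            n_replicates=b["n_replicates"], seed=simmod._child_seed(seed, "bsseq"),
        )
        art["bsseq_records"], art["bsseq_groups"], art["bsseq_truth"] = records, groups, truth
        truth_all["bsseq"] = truth.to_dict()

    if "rnaseq" in config:
        r = config["rnaseq"]
        de_truth = simmod.make_de_truth(
            genome, n_de=r["n_de"], log2fc=r["log2fc"], up_fraction=r["up_fraction"],
            seed=simmod._child_seed(seed, "de_truth"),
        )
        # every gene also carries a small continuous true shift, as in
        # real knockouts; the large planted effects sit on top of it
        rng_bg = np.random.default_rng(simmod._child_seed(seed, "rna_background"))
        ids = genome.genes["gene_id"].to_numpy()
        lfc_full = pd.Series(
            r.get("background_lfc_sd", 0.0) * rng_bg.standard_normal(len(ids)),
            index=ids,
        )
        lfc_full.loc[de_truth["gene_id"].to_numpy()] += de_truth["log2fc"].to_numpy(float)
        counts, groups, truth = simmod.simulate_rnaseq(
            genome,
            pd.DataFrame({"gene_id": ids, "log2fc": lfc_full.to_numpy()}),
            baseline_mean=r["baseline_mean"],
            dispersion=r["dispersion"], n_replicates=r["n_replicates"],
            seed=simmod._child_seed(seed, "rnaseq"),
        )
        truth.true_de_genes = de_truth.reset_index(drop=True)  # planted large effects
        art["rna_counts"], art["rna_groups"], art["rna_truth"] = counts, groups, truth
        art["transcript_effect"] = lfc_full
        truth_all["rnaseq"] = truth.to_dict()
        iomod.write_matrix(counts, outdir / "rna_counts.tsv", header)
        # per-ERV interval counts, up-regulated in the mutant group
        rng = np.random.default_rng(simmod._child_seed(seed, "erv"))
        n_erv = len(genome.ervs)
        base = rng.lognormal(np.log(50), 0.5, size=n_erv)
        erv_counts = {}
        for s, g in groups.items():
            mu = base * (r["erv_fold_mutant"] if g != "control" else 1.0)
            erv_counts[s] = rng.poisson(mu)
        art["erv_counts"] = pd.DataFrame(erv_counts)

    if "proteome" in config:
        p = config["proteome"]
        _require(art, "transcript_effect", "simulate")
        lfc = art["transcript_effect"]
        matrix, groups, truth = simmod.simulate_proteome(
            lfc, coupling_rho=p["coupling_rho"], n_proteins=p["n_proteins"],
            noise_sd=p["noise_sd"], n_replicates=p["n_replicates"],
            seed=simmod._child_seed(seed, "proteome"), lfc_scale=p["lfc_scale"],
        )
        art["protein_matrix"], art["protein_groups"], art["protein_truth"] = matrix, groups, truth
        art["transcript_effect"] = lfc
        truth_all["proteome"] = truth.to_dict()
        iomod.write_matrix(matrix.round(6), outdir / "protein_matrix.tsv", header)

    iomod.write_truth(truth_all, outdir / "truth.json")


def _stage_chip(cfg, art, outdir, header, counters):
    windows, counts = art["chip_windows"], art["chip_counts"]
    wq = chipmod.quantify_rpkm(windows, counts)
    chip_cols = [c for c in counts.columns if c.startswith("chip_")]
    input_cols = [c for c in counts.columns if c.startswith("input_")]
    athr = cfg["artifact_threshold"]
    if athr == "auto":
        athr = 3.0 * float(np.median(wq.rpkm[input_cols].to_numpy()))
    chipmod.mask_artifacts(wq, {"input": input_cols}, rpkm_threshold=athr)
    counters["windows_masked"] = int(wq.mask.sum())
    thr = cfg["threshold"]
    if thr == "auto":
        thr = chipmod.auto_log2_threshold(wq, chip_cols, cfg["enrichment_fold"])
    called = chipmod.call_enriched_windows(wq, chip_cols, log2_threshold=thr)
    domains = chipmod.merge_windows(windows, called, max_gap=cfg["gap"], name="enriched_domains")
    rnd = chipmod.sample_random_domains(
        wq, n=min(cfg["random_n"], int((~wq.mask).sum())), max_gap=cfg["gap"],
        seed=simmod._child_seed(int(art["config"]["seed"]), "random_domains"),
    )
    art["window_quant"], art["domains"], art["random_domains"] = wq, domains, rnd
    art["chip_threshold"] = thr
    counters["windows_called"] = int(called.sum())
    counters["domains"] = len(domains)
    counters["random_domains"] = len(rnd)
    iomod.write_regions(domains, outdir / "enriched_domains.bed", header)
    iomod.write_regions(rnd, outdir / "random_domains.bed", header)
    if len(domains):
        prof = chipmod.composite_profile(domains, wq, columns=chip_cols + input_cols)
        art["profile"] = prof
        iomod.write_matrix(prof.round(6), outdir / "probe_trend.tsv", header)


def _stage_methylome(cfg, art, outdir, header, counters):
    records, groups = art["bsseq_records"], art["bsseq_groups"]
    genome = art["genome"]
    tiles = methmod.tile_by_cpg(records, positions=genome.cpg_positions)
    kept = methmod.coverage_filter(tiles)
    counters["tiles_total"] = len(tiles.tiles)
    counters["tiles_retained"] = len(kept.tiles)
    ga = [s for s, g in groups.items() if g == "control"]
    gb = [s for s, g in groups.items() if g != "control"]
    res = methmod.dmr_test(kept, ga, gb)
    dmrs = methmod.call_dmrs(res, alpha=cfg["alpha"], min_diff=cfg["min_diff"])
    dmds = methmod.merge_dmrs(dmrs)
    art["meth_tiles"], art["dmrs"], art["dmds"] = kept, dmrs, dmds
    counters["dmrs_called"] = int(dmrs["call"].sum())
    counters["dmds"] = len(dmds)
    out = dmrs.drop(columns=["n_cpgs"]).round(6)
    iomod.write_matrix(out.set_index("tile_id"), outdir / "dmrs.tsv", header)
    iomod.write_matrix(
        dmds.assign(member_tiles=dmds["member_tiles"].apply(lambda x: ",".join(map(str, x))))
        .round(6), outdir / "dmds.tsv", header,
    )


def _stage_rnaseq(cfg, art, outdir, header, counters):
    counts, groups = art["rna_counts"], art["rna_groups"]
    res = rnamod.nb_wald_test(counts, groups)
    res = rnamod.call_degs(res, lfc=cfg["lfc"], alpha=cfg["alpha"])
    art["de_results"] = res
    counters["degs_up"] = int((res["call"] == "up").sum())
    counters["degs_down"] = int((res["call"] == "down").sum())
    iomod.write_matrix(res.round(6), outdir / "de_results.tsv", header)
    if "erv_counts" in art:
        genome = art["genome"]
        lib = counts.sum(axis=0)
        pct, table = rnamod.quantify_ervs(
            art["erv_counts"], genome.ervs, genome.genes, lib
        )
        art["erv_pct"] = pct
        iomod.write_matrix(pct.round(6).to_frame("erv_pct").T, outdir / "erv_pct.tsv", header)


def _stage_proteome(cfg, art, outdir, header):
    matrix, groups = art["protein_matrix"], art["protein_groups"]
    norm = protmod.normalize_median(matrix)
    ga = [s for s, g in groups.items() if g == "control"]
    gb = [s for s, g in groups.items() if g != "control"]
    res = protmod.moderated_t(norm, ga, gb)
    res = protmod.call_diff_proteins(res, p=cfg["p"], lfc=cfg["lfc"])
    art["protein_results"] = res
    iomod.write_matrix(res.round(6), outdir / "protein_results.tsv", header)


def _stage_integrate(art, outdir, header):
    dmrs = art["dmrs"]
    domains: RegionSet = art["domains"]
    rnd: RegionSet = art["random_domains"]
    rows = []
    for direction in ("hyper", "hypo"):
        q = dmrs[dmrs["call"] & (dmrs["direction"] == direction)]
        if len(q) == 0 or len(rnd) == 0:
            continue
        from .genome import overlaps_any

        k = int(overlaps_any(q[["chrom", "start", "end"]], domains.intervals).sum())
        K = int(overlaps_any(rnd.intervals, domains.intervals).sum())
        r = integmod.enrichment_test(
            k, len(q), K, len(rnd), test="fisher", family_size=2,
            query_name=f"dmr_{direction}", feature_name="h3k9me2_domains",
        )
        rows.append(r.__dict__)
    enr = pd.DataFrame(rows)
    art["overlap_enrichment"] = enr
    if len(enr):
        iomod.write_matrix(enr.set_index("query_name").round(6),
                           outdir / "overlap_enrichment.tsv", header)

    de = art["de_results"]
    prot = art["protein_results"]
    up = set(prot.index[prot["call"] == "up"])
    down = set(prot.index[prot["call"] == "down"])
    ranked = de["log2fc"].dropna()
    bc = integmod.barcode_enrichment(
        ranked, up, down, paired_effects=prot["log2fc"]
    )
    art["barcode"] = bc
    iomod.write_matrix(bc.worm.round(6), outdir / "barcode_worm.tsv", header)

    genome = art["genome"]
    regions = genome.genes[["chrom", "start", "end"]].copy()
    meth = methmod.region_methylation(regions, art["bsseq_records"])
    groups = art["bsseq_groups"]
    ga = [s for s, g in groups.items() if g == "control"]
    gb = [s for s, g in groups.items() if g != "control"]
    diff = meth[gb].mean(axis=1) - meth[ga].mean(axis=1)
    diff.index = genome.genes["gene_id"]
    degs = de.index[de["call"] != "none"]
    summary = {
        "spearman_rho": bc.spearman_rho,
        "spearman_p": bc.spearman_p,
        "rank_p": bc.rank_p,
    }
    try:
        rho, p = integmod.methylation_expression_correlation(
            diff, de["log2fc"], subset=set(degs)
        )
        summary["meth_expr_rho"], summary["meth_expr_p"] = rho, p
    except ValueError as exc:
        summary["meth_expr_error"] = str(exc)
    art["integration_summary"] = summary
    with open(outdir / "integration_summary.json", "w") as f:
        json.dump(summary, f, indent=1, sort_keys=True, default=float)
        f.write("\n")
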