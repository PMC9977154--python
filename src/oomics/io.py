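"""Readers and writers for the interchange formats.

BED is the sole interval format (0-based, half-open); count and
intensity matrices are TSV with the unit id in the first column; per-
CpG methylation records come in the 6-column coverage dialect
(chrom, start, end, %, meth, unmeth) or a minimal 4-column TSV
(chrom, pos, meth, unmeth).  Writers emit deterministic column and row
order and a provenance comment line; readers skip ``#`` lines.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import RegionSet

logger = logging.getLogger(__name__)

PKG_VERSION = "0.1.0"


class ParseError(ValueError):
    pass


def provenance_line(config_hash: str = "-", seed: "int | None" = None) -> str:
    return f"# oomics v{PKG_VERSION} config={config_hash} seed={seed if seed is not None else '-'}"


def config_hash(config: dict) -> str:
    """Stable hash of the semantic content of a config mapping."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def read_regions(path: "str | Path", name: "str | None" = None) -> RegionSet:
    """Read a 3+ column BED file into a RegionSet.

    Score column (BED column 5, or column 4 when numeric) is preserved.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path.name}:{ln}: expected >= 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path.name}:{ln}: non-integer coordinates") from exc
            if start >= end:
                raise ParseError(f"{path.name}:{ln}: start >= end ({start} >= {end})")
            score = np.nan
            if len(parts) >= 5:
                try:
                    score = float(parts[4])
                except ValueError:
                    pass
            elif len(parts) == 4:
                try:
                    score = float(parts[3])
                except ValueError:
                    pass
            rows.append((parts[0], start, end, score))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
    if df["score"].isna().all():
        df = df.drop(columns="score")
    return RegionSet(name or path.stem, df)


def write_regions(
    rs: RegionSet, path: "str | Path", header: "str | None" = None
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write(header + "\n")
        has_score = "score" in rs.intervals.columns
        for i, row in enumerate(rs.intervals.itertuples(index=False)):
            if has_score:
                fh.write(
                    f"{row.chrom}\t{row.start}\t{row.end}\t{rs.name}_{i}\t{row.score:.6g}\n"
                )
            else:
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\n")


def read_cpg_coverage(
    path: "str | Path", dialect: str = "synthetic4", one_based: bool = False
) -> pd.DataFrame:
    """Per-CpG records (chrom, pos, meth, unmeth).

    ``coverage6``: chrom, start, end, percent, meth, unmeth — the
    percent column is cross-checked against the counts and a warning
    logged when they disagree by more than 0.5 points.
    ``synthetic4``: chrom, pos, meth, unmeth.
    """
    path = Path(path)
    if dialect == "synthetic4":
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "pos", "meth", "unmeth"],
            dtype={"chrom": str},
        )
    elif dialect == "coverage6":
        raw = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "start", "end", "percent", "meth", "unmeth"],
            dtype={"chrom": str},
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            calc = raw["meth"] / (raw["meth"] + raw["unmeth"]).replace(0, np.nan) * 100
        bad = (calc - raw["percent"]).abs() > 0.5
        if bad.any():
            logger.warning(
                "%s: %% column disagrees with counts in %d of %d rows",
                path.name, int(bad.sum()), len(raw),
            )
        df = raw[["chrom", "start", "meth", "unmeth"]].rename(columns={"start": "pos"})
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if one_based:
        df["pos"] = df["pos"] - 1
    return df


def write_cpg_coverage(df: pd.DataFrame, path: "str | Path", header: "str | None" = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header + "\n")
        df[["chrom", "pos", "meth", "unmeth"]].to_csv(fh, sep="\t", header=False, index=False)


def read_matrix(path: "str | Path") -> pd.DataFrame:
    """TSV matrix: unit id in column 1, one column per sample."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def write_matrix(df: pd.DataFrame, path: "str | Path", header: "str | None" = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header + "\n")
        df.to_csv(fh, sep="\t")


def write_truth(truth_dict: dict, path: "str | Path") -> None:
    with open(path, "w") as fh:
        json.dump(truth_dict, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth(path: "str | Path") -> dict:
    with open(path) as fh:
        return json.load(fh)


VALID_ASSAYS = {"chip", "input", "igg", "bsseq", "rnaseq", "proteome"}


def read_sample_sheet(path: "str | Path", check_files: bool = True) -> pd.DataFrame:
    """Sample sheet TSV: sample, path, assay, group, replicate_set."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample", "path", "assay", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path.name}: missing sample-sheet columns {sorted(missing)}")
    if "replicate_set" not in df.columns:
        df["replicate_set"] = df["group"]
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise ParseError(f"{path.name}: duplicate sample id {dup!r}")
    bad = set(df["assay"]) - VALID_ASSAYS
    if bad:
        raise ParseError(f"{path.name}: unknown assay values {sorted(bad)}")
    if check_files:
        for _, row in df.iterrows():
            p = Path(row["path"])
            if not p.is_absolute():
                p = path.parent / p
            if not p.exists():
                raise ParseError(f"{path.name}: file not found for sample {row['sample']!r}: {p}")
    return df
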