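"""The tab-separated contact-pairs dialect.

Files start with a header line ``#columns: readID chrom1 pos1 strand1
chrom2 pos2 strand2 [mapq1 mapq2] [homolog1 homolog2]``; positions are
1-based in the file and converted to the package's 0-based convention on
read.  Pairs are canonically ordered so that (chrom1, pos1) <= (chrom2,
pos2), swapping ends (and their strands/mapqs/homolog labels) as needed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import pandas as pd

log = logging.getLogger(__name__)

BASE_COLUMNS = ["readID", "chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]
OPTIONAL = ["mapq1", "mapq2", "homolog1", "homolog2"]


@dataclass
class PairsReadReport:
    n_read: int
    n_malformed: int
    n_mapq_dropped: int


def read_pairs(
    path,
    min_mapq: Optional[int] = None,
    chrom_sizes: Optional[dict] = None,
):
    """Read a pairs file; returns (events DataFrame, report).

    Malformed lines are counted and skipped; ``min_mapq`` drops pairs with
    either mapping quality below the threshold (requires mapq columns);
    ``chrom_sizes`` enables bounds checking.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#columns:"):
            raise ValueError("pairs file must start with a '#columns:' header")
        cols = header.split(":", 1)[1].split()
        unknown = [c for c in cols if c not in BASE_COLUMNS + OPTIONAL]
        if unknown:
            raise ValueError(f"unknown pairs columns: {unknown}")
        missing = [c for c in BASE_COLUMNS if c not in cols]
        if missing:
            raise ValueError(f"missing pairs columns: {missing}")
        rows, malformed = [], 0
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(cols):
                malformed += 1
                continue
            rows.append(parts)
    df = pd.DataFrame(rows, columns=cols)
    for c in ("pos1", "pos2"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    for c in ("mapq1", "mapq2"):
        if c in df.columns:
            df[c] = pd.to_numeric(df[c], errors="coerce")
    bad = df[["pos1", "pos2"]].isna().any(axis=1)
    malformed += int(bad.sum())
    df = df[~bad].copy()
    df["pos1"] = df["pos1"].astype(int) - 1  # to 0-based
    df["pos2"] = df["pos2"].astype(int) - 1

    if chrom_sizes:
        for side in ("1", "2"):
            limit = df[f"chrom{side}"].map(chrom_sizes)
            out = limit.notna() & ((df[f"pos{side}"] < 0) | (df[f"pos{side}"] >= limit))
            if out.any():
                raise ValueError(
                    f"{int(out.sum())} position(s) outside declared chromosome bounds"
                )
            unknown_chrom = limit.isna()
            if unknown_chrom.any():
                raise ValueError(
                    f"unknown chromosome(s): {sorted(df.loc[unknown_chrom, f'chrom{side}'].unique())}"
                )

    n_mapq = 0
    if min_mapq is not None:
        if "mapq1" not in df.columns or "mapq2" not in df.columns:
            raise ValueError("min_mapq filter requires mapq columns")
        keep = (df["mapq1"] >= min_mapq) & (df["mapq2"] >= min_mapq)
        n_mapq = int((~keep).sum())
        df = df[keep].copy()

    df = canonicalize(df)
    report = PairsReadReport(len(df), malformed, n_mapq)
    if malformed:
        log.warning("%d malformed line(s) skipped", malformed)
    return df.reset_index(drop=True), report


def canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    """Enforce (chrom1, pos1) <= (chrom2, pos2), swapping end-specific
    columns where needed."""
    df = df.copy()
    swap = (df["chrom1"].astype(str) > df["chrom2"].astype(str)) | (
        (df["chrom1"] == df["chrom2"]) & (df["pos1"] > df["pos2"])
    )
    pairs = [("chrom1", "chrom2"), ("pos1", "pos2"), ("strand1", "strand2")]
    for opt in (("mapq1", "mapq2"), ("homolog1", "homolog2"), ("frag1", "frag2")):
        if opt[0] in df.columns:
            pairs.append(opt)
    for a, b in pairs:
        df.loc[swap, [a, b]] = df.loc[swap, [b, a]].to_numpy()
    return df


def write_pairs(df: pd.DataFrame, path) -> None:
    cols = [c for c in BASE_COLUMNS + OPTIONAL if c in df.columns or c == "readID"]
    out = df.copy()
    if "readID" not in out.columns:
        out["readID"] = [f"r{i}" for i in range(len(out))]
    out = out[[c for c in cols if c in out.columns]]
    out["pos1"] = out["pos1"].astype(int) + 1  # back to 1-based
    out["pos2"] = out["pos2"].astype(int) + 1
    with open(path, "w") as fh:
        fh.write("#columns: " + " ".join(out.columns) + "\n")
        out.to_csv(fh, sep="\t", header=False, index=False)
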