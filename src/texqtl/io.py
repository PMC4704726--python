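"""Readers and writers for count tables, recombination maps and QTL calls.

The native interchange format is a tab-separated BulkCounts table with one
row per marker:

    chrom  pos_bp  [pos_cm]  countA_bulk1  countB_bulk1  countA_bulk2  countB_bulk2  [replicate]

Coordinates are 1-based bp; QTL support intervals are written 1-based
closed in the TSV and 0-based half-open in BED output.  A VarScan-style
adapter maps upstream variant-caller columns onto this schema.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import DEFAULT_CM_PER_MB, RecombMap

log = logging.getLogger(__name__)

COUNT_COLS = ("countA_bulk1", "countB_bulk1", "countA_bulk2", "countB_bulk2")


@dataclass(frozen=True)
class CountTableSchema:
    """Column mapping from an input table onto the native BulkCounts schema."""

    chrom: str = "chrom"
    pos_bp: str = "pos_bp"
    pos_cm: str | None = "pos_cm"
    countA_bulk1: str = "countA_bulk1"
    countB_bulk1: str = "countB_bulk1"
    countA_bulk2: str = "countA_bulk2"
    countB_bulk2: str = "countB_bulk2"
    replicate: str | None = "replicate"


NATIVE_SCHEMA = CountTableSchema()

#: adapter for a merged VarScan mpileup2snp table with per-bulk
#: reference/variant read counts
VARSCAN_SCHEMA = CountTableSchema(
    chrom="Chrom", pos_bp="Position", pos_cm=None,
    countA_bulk1="Reads1_bulk1", countB_bulk1="Reads2_bulk1",
    countA_bulk2="Reads1_bulk2", countB_bulk2="Reads2_bulk2",
    replicate=None,
)


def read_counts(path, schema: CountTableSchema = NATIVE_SCHEMA,
                min_coverage: int | None = None) -> pd.DataFrame:
    """Read and validate a BulkCounts table.

    Counts must be nonnegative integers; duplicate (chrom, position) rows
    are rejected; unsorted input is sorted with a warning.  ``min_coverage``
    re-applies the upstream coverage prefilter if requested.
    """
    raw = pd.read_csv(path, sep="\t")
    cols = {
        "chrom": schema.chrom, "pos_bp": schema.pos_bp,
        "countA_bulk1": schema.countA_bulk1, "countB_bulk1": schema.countB_bulk1,
        "countA_bulk2": schema.countA_bulk2, "countB_bulk2": schema.countB_bulk2,
    }
    if schema.pos_cm and schema.pos_cm in raw.columns:
        cols["pos_cm"] = schema.pos_cm
    if schema.replicate and schema.replicate in raw.columns:
        cols["replicate"] = schema.replicate
    missing = [c for c in cols.values() if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = raw[list(cols.values())].copy()
    df.columns = list(cols.keys())
    for c in COUNT_COLS:
        vals = df[c]
        bad = vals.isna() | (vals < 0) | (vals != vals.astype(np.int64, errors="ignore"))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: invalid count in column {c} at data row {row + 1} "
                f"(value {vals.iloc[row]!r})"
            )
        df[c] = vals.astype(np.int64)
    key_cols = ["chrom", "pos_bp"] + (["replicate"] if "replicate" in df else [])
    if df.duplicated(subset=key_cols).any():
        raise ValueError(f"{path}: duplicate marker rows")
    sort_cols = (["replicate"] if "replicate" in df else []) + ["chrom", "pos_bp"]
    if not df[sort_cols].equals(df[sort_cols].sort_values(sort_cols)):
        log.warning("%s: input not sorted by position; sorting", path)
        df = df.sort_values(sort_cols).reset_index(drop=True)
    if min_coverage is not None:
        cov_ok = ((df["countA_bulk1"] + df["countB_bulk1"] >= min_coverage)
                  & (df["countA_bulk2"] + df["countB_bulk2"] >= min_coverage))
        n_drop = int((~cov_ok).sum())
        if n_drop:
            log.info("%s: dropped %d markers below %dx coverage", path, n_drop,
                     min_coverage)
        df = df.loc[cov_ok].reset_index(drop=True)
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    """Write a BulkCounts table in the native TSV schema (lossless round
    trip with :func:`read_counts`)."""
    cols = [c for c in ("chrom", "pos_bp", "pos_cm", *COUNT_COLS, "replicate")
            if c in counts.columns]
    counts[cols].to_csv(path, sep="\t", index=False)


def write_fixture(counts: pd.DataFrame, path, truth=None, seed=None,
                  config=None) -> None:
    """Emit a long-format fixture table (chrom, pos_cm, pos_bp, bulk,
    countA, countB, replicate) plus a JSON truth sidecar at ``path +
    '.truth.json'``."""
    frames = []
    for bulk, (ca, cb) in {"bulk1": COUNT_COLS[:2], "bulk2": COUNT_COLS[2:]}.items():
        sub = counts[[c for c in ("chrom", "pos_cm", "pos_bp", "replicate")
                      if c in counts.columns]].copy()
        sub["bulk"] = bulk
        sub["countA"] = counts[ca].to_numpy()
        sub["countB"] = counts[cb].to_numpy()
        frames.append(sub)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
    sidecar = {"seed": seed, "config": config}
    if truth is not None:
        sidecar["qtl"] = [
            {"chrom": c, "pos_cm": p, "effect": e} for c, p, e in truth.loci
        ]
    with open(str(path) + ".truth.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_recomb_map(path) -> RecombMap:
    """Read a cM<->bp recombination map (TSV: chrom, pos_bp, pos_cm; >= 2
    monotone rows per chromosome)."""
    df = pd.read_csv(path, sep="\t")
    need = {"chrom", "pos_bp", "pos_cm"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: recombination map needs columns {sorted(need)}")
    tables = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("pos_bp")
        tables[chrom] = (sub["pos_bp"].to_numpy(float), sub["pos_cm"].to_numpy(float))
    return RecombMap(tables)


def default_recomb_map(chrom_extents_bp: dict) -> RecombMap:
    """Uniform 4 cM/Mb fallback map (9 Mb == 36 cM) with a warning."""
    log.warning("no recombination map supplied; assuming uniform %.1f cM/Mb",
                DEFAULT_CM_PER_MB)
    return RecombMap.uniform(chrom_extents_bp)


def write_qtl_table(fits, path) -> None:
    """QTL calls as TSV: chrom, peak position, support interval, allele
    frequency, fitted G', model size and fit statistics."""
    rows = []
    for fit in fits:
        for _, q in fit.qtl.iterrows():
            rows.append({
                "chrom": fit.chrom,
                "peak_bp": int(q["pos_bp"]) if "pos_bp" in q else np.nan,
                "peak_cm": q["pos_cm"],
                "interval_lo_bp": int(q["ci_lo_bp"]) if "ci_lo_bp" in q else np.nan,
                "interval_hi_bp": int(q["ci_hi_bp"]) if "ci_hi_bp" in q else np.nan,
                "interval_lo_cm": q["ci_lo_cm"],
                "interval_hi_cm": q["ci_hi_cm"],
                "allele_freq": q["freq"],
                "fitted_Gprime": q["fitted_gprime"],
                "m": fit.m,
                "RMSE": fit.rmse,
                "BIC": fit.bic,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_bed(fits, path) -> None:
    """Support intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for fit in fits:
            for i, (_, q) in enumerate(fit.qtl.iterrows(), 1):
                if "ci_lo_bp" not in q:
                    continue
                fh.write(f"{fit.chrom}\t{int(q['ci_lo_bp']) - 1}\t"
                         f"{int(q['ci_hi_bp'])}\t{fit.chrom}_QTL{i}\n")
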