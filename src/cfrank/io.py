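"""Readers, writers and cohort bookkeeping.

All tabular interchange is plain TSV with a header row; genomic fragments
travel as BED3/BED4 (0-based half-open, optional 4th column = fragment GC
fraction).  Missing values are accepted as empty string or ``NA`` on read
and always written back as ``NA``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("cfrank")

NA_VALUES = ["", "NA"]

#: columns every sample sheet must carry; anything numeric beyond these is
#: treated as a per-sample covariate (e.g. an externally estimated T-cell
#: fraction).
SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "patient_id",
    "group",
    "timepoint",
    "relapse",
    "surv_time_months",
    "surv_event",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class FragmentSet:
    """cfDNA fragments of one sample as 0-based half-open intervals.

    ``records`` has columns chrom, start, end and (optionally all-NaN) gc.
    """

    records: pd.DataFrame
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        df = self.records
        if len(df) and not (df["end"] > df["start"]).all():
            bad = df.index[df["end"] <= df["start"]][0]
            raise FormatError(f"end <= start in fragment record {bad}")
        gc = df["gc"].dropna()
        if len(gc) and ((gc < 0) | (gc > 1)).any():
            raise FormatError("fragment gc outside [0, 1]")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def has_gc(self) -> bool:
        return bool(self.records["gc"].notna().any())

    def lengths(self) -> np.ndarray:
        return (self.records["end"] - self.records["start"]).to_numpy()


def read_fragments(path: str | Path, sample_id: str | None = None) -> FragmentSet:
    """Read a BED3/BED4 fragment file (4th column = GC fraction)."""
    path = Path(path)
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    gcs: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: fewer than 3 columns at line {lineno}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}: non-integer coordinate at line {lineno}") from exc
            if start < 0:
                raise FormatError(f"{path}: negative start at line {lineno}")
            if end <= start:
                raise FormatError(f"{path}: end <= start at line {lineno}")
            gc = math.nan
            if len(parts) >= 4 and parts[3] not in NA_VALUES:
                gc = float(parts[3])
                if not 0.0 <= gc <= 1.0:
                    raise FormatError(f"{path}: gc outside [0,1] at line {lineno}")
            chroms.append(parts[0])
            starts.append(start)
            ends.append(end)
            gcs.append(gc)
    if not chroms:
        raise FormatError(f"{path}: no fragment records")
    records = pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": ends, "gc": gcs}
    )
    log.info("read %d fragments from %s", len(records), path)
    return FragmentSet(records, sample_id=sample_id or path.stem)


def write_fragments(fragments: FragmentSet, path: str | Path) -> None:
    """Write BED3 (or BED4 when any gc present); round-trips read_fragments."""
    with open(path, "w") as fh:
        with_gc = fragments.has_gc
        for row in fragments.records.itertuples(index=False):
            if with_gc:
                gc = "NA" if pd.isna(row.gc) else format(row.gc, "g")
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{gc}\n")
            else:
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\n")
    log.info("wrote %d fragments to %s", len(fragments), path)


def read_tss_annotation(path: str | Path) -> pd.DataFrame:
    """Read a TSS annotation table (gene_id, transcript_id, chrom, tss, strand).

    TSS positions are 0-based.  (gene_id, transcript_id) must be unique and
    strand must be + or -.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False,
                     na_values=NA_VALUES)
    required = ["gene_id", "transcript_id", "chrom", "tss", "strand"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise FormatError(f"{path}: no TSS records")
    dup = df.duplicated(["gene_id", "transcript_id"])
    if dup.any():
        raise FormatError(
            f"{path}: duplicate (gene_id, transcript_id): "
            f"{df.loc[dup, ['gene_id', 'transcript_id']].iloc[0].tolist()}"
        )
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise FormatError(f"{path}: invalid strand {df.loc[bad_strand, 'strand'].iloc[0]!r}")
    if (df["tss"] < 0).any():
        raise FormatError(f"{path}: negative TSS position")
    df["tss"] = df["tss"].astype(int)
    log.info("read %d TSS records (%d genes) from %s", len(df), df["gene_id"].nunique(), path)
    return df.reset_index(drop=True)


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene x entity expression matrix (first column = gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False, na_values=NA_VALUES)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            raise FormatError(
                f"{path}: non-numeric value at gene {df.index[bad][0]!r}, column {col!r}"
            )
        df[col] = vals
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative expression value")
    log.info("read %d x %d expression matrix from %s", df.shape[0], df.shape[1], path)
    return df


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read the cohort sample sheet; extra numeric columns become covariates."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=NA_VALUES)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return validate_cohort(df)


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Enforce sample-sheet invariants: unique sample ids, event follows time."""
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicate sample_id {dup!r}")
    has_time = df["surv_time_months"].notna()
    if (has_time & df["surv_event"].isna()).any():
        raise FormatError("surv_event missing for a sample with surv_time_months")
    if (pd.to_numeric(df.loc[has_time, "surv_time_months"]) < 0).any():
        raise FormatError("negative surv_time_months")
    return df.reset_index(drop=True)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep="NA")
    log.info("wrote %d rows to %s", len(df), path)


def round_half_up(x: float) -> int:
    """Round to nearest integer with halves away from zero (presentation rule)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def summarize_cohort(
    cohort: pd.DataFrame,
    variables: Iterable[str] | None = None,
    numeric: Iterable[str] = (),
) -> pd.DataFrame:
    """Descriptive summaries: n (%) per level for categorical variables,
    median (Q1, Q3) for numeric ones.

    Percentages use the non-missing denominator and half-up integer
    rounding; an all-missing variable is reported with n = 0.
    """
    if len(cohort) == 0:
        raise FormatError("empty cohort")
    numeric = list(numeric)
    if variables is None:
        variables = [
            c for c in cohort.columns
            if c not in ("sample_id", "patient_id") and c not in numeric
        ]
    rows = []
    for var in variables:
        col = cohort[var]
        nonmiss = col.dropna()
        n = len(nonmiss)
        if n == 0:
            rows.append({"variable": var, "level": None, "n": 0, "percent": np.nan,
                         "median": np.nan, "q1": np.nan, "q3": np.nan})
            continue
        counts = nonmiss.value_counts().sort_index()
        for level, count in counts.items():
            rows.append({
                "variable": var, "level": str(level), "n": int(count),
                "percent": round_half_up(100.0 * count / n),
                "median": np.nan, "q1": np.nan, "q3": np.nan,
            })
    for var in numeric:
        vals = pd.to_numeric(cohort[var], errors="coerce").dropna()
        q1, med, q3 = (np.percentile(vals, [25, 50, 75]) if len(vals)
                       else (np.nan, np.nan, np.nan))
        rows.append({"variable": var, "level": None, "n": len(vals), "percent": np.nan,
                     "median": med, "q1": q1, "q3": q3})
    return pd.DataFrame(rows)


@dataclass
class PipelineConfig:
    """Run configuration read from a flat YAML file naming inputs and knobs."""

    fragments: list[str] = field(default_factory=list)
    tss_annotation: str | None = None
    reference_expression: str | None = None
    reference_annotation: str | None = None
    bulk_expression: str | None = None
    sample_sheet: str | None = None
    window_bp: int = 1000
    gc_bins: int = 50
    seed: int = 0
    out_dir: str = "."
    extra: dict = field(default_factory=dict)


def read_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise FormatError(f"{path}: config must be a mapping")
    known = {f for f in PipelineConfig.__dataclass_fields__ if f != "extra"}
    kwargs = {k: v for k, v in raw.items() if k in known}
    extra = {k: v for k, v in raw.items() if k not in known}
    return PipelineConfig(extra=extra, **kwargs)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
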