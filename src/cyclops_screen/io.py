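"""Readers and writers for the on-disk formats.

All tabular formats are TSV with "NA" as the missing-value marker. Genomic
intervals are 0-based half-open throughout, including SEG input, so the
length of [a, b) is exactly b - a. Output tables carry '#'-prefixed
provenance header lines (seed, config hash, stage) and are byte-identical
across re-runs with the same config and seed.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

NA_MARKER = "NA"

MATRIX_KINDS = ("copy_number", "dependency", "expression")

#: columns of a gene annotation table
ANNOTATION_COLUMNS = ["gene_id", "chromosome", "arm", "start", "end"]


class FormatError(ValueError):
    """Raised for malformed input files; messages name the offending line."""


# ---------------------------------------------------------------------------
# numeric matrices


def read_matrix(path, kind: str) -> pd.DataFrame:
    """Read a genes x samples TSV matrix.

    First column = gene ids, header row = sample ids. Returns a float
    DataFrame (NaN for missing) with .attrs['kind'] set. Duplicate gene or
    sample ids and non-numeric cells are rejected.
    """
    if kind not in MATRIX_KINDS:
        raise ValueError(f"kind must be one of {MATRIX_KINDS}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#",
                         na_values=[NA_MARKER], keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise FormatError(f"{path}: malformed matrix: {exc}") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicated gene ids: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicated sample ids: {dups}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise FormatError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} "
                f"at line {row + 2}, column {col!r}"
            )
        df[col] = coerced
    df.index.name = "gene_id"
    df = df.astype(float)
    df.attrs["kind"] = kind
    return df


def write_matrix(matrix: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    """Write a matrix as TSV with NA for missing values."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        matrix.to_csv(fh, sep="\t", na_rep=NA_MARKER)


# ---------------------------------------------------------------------------
# annotations


def validate_annotation(ann: pd.DataFrame, arm_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Validate a gene annotation table (gene_id, chromosome, arm, start, end)."""
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise FormatError(f"annotation lacks columns {missing}")
    if (ann["start"] >= ann["end"]).any():
        bad = ann.loc[ann["start"] >= ann["end"], "gene_id"].tolist()[:5]
        raise FormatError(f"annotation has start >= end for genes {bad}")
    if ann.duplicated(subset=["chromosome", "gene_id"]).any():
        raise FormatError("annotation has duplicated (chromosome, gene_id) pairs")
    if arm_table is not None:
        arms = arm_table.set_index(["chromosome", "arm"])
        for _, row in ann.iterrows():
            key = (row["chromosome"], row["arm"])
            if key not in arms.index:
                raise FormatError(f"gene {row['gene_id']}: arm {key} not in arm table")
            a = arms.loc[key]
            if not (a["start"] <= row["start"] and row["end"] <= a["end"]):
                raise FormatError(f"gene {row['gene_id']} outside its declared arm {key}")
    return ann


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", comment="#")
    return validate_annotation(ann)


def read_sample_annotation(path) -> pd.DataFrame:
    """Read sample annotation (sample_id, lineage[, condition])."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("sample_id", "lineage"):
        if col not in df.columns:
            raise FormatError(f"{path}: sample annotation lacks column {col!r}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"{path}: duplicated sample ids: {dups}")
    return df


# ---------------------------------------------------------------------------
# SEG segments


def read_segments(path) -> pd.DataFrame:
    """Read SEG-style TSV: sample, chromosome, start, end, log2.

    Coordinates are 0-based half-open; abutting segments (end1 == start2)
    are legal, overlapping segments within a sample are a format error.
    Returns a DataFrame sorted by (sample, chromosome, start).
    """
    seg = pd.read_csv(path, sep="\t", comment="#",
                      names=["sample", "chromosome", "start", "end", "log2"],
                      header=0)
    if seg[["start", "end"]].isna().any().any():
        raise FormatError(f"{path}: missing coordinates in segment file")
    seg["start"] = seg["start"].astype(int)
    seg["end"] = seg["end"].astype(int)
    bad = seg["start"] >= seg["end"]
    if bad.any():
        i = int(np.nonzero(bad.to_numpy())[0][0])
        raise FormatError(f"{path}: start >= end at line {i + 2}")
    seg = seg.sort_values(["sample", "chromosome", "start"], kind="stable")
    for (sample, chrom), grp in seg.groupby(["sample", "chromosome"], sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if (starts[1:] < ends[:-1]).any():
            raise FormatError(
                f"{path}: overlapping segments for sample {sample!r} on {chrom!r}"
            )
    return seg.reset_index(drop=True)


def write_segments(seg: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        seg.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets and paralogs


def read_gmt(path) -> dict[str, set[str]]:
    """Read GMT gene sets: name <tab> description <tab> member..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: GMT set with no members")
            name, members = parts[0], {m for m in parts[2:] if m}
            if not members:
                raise FormatError(f"{path}: line {lineno}: empty gene set {name!r}")
            sets[name] = members
    return sets


def read_paralogs(path) -> dict[str, set[str]]:
    """Read a two-column gene<->gene paralog map; symmetric closure applied."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}: line {lineno}: expected two columns")
            a, b = parts
            out.setdefault(a, set()).add(b)
            out.setdefault(b, set()).add(a)
    return out


# ---------------------------------------------------------------------------
# junction counts


def read_junctions(path) -> pd.DataFrame:
    """Read a juncBase-style junction count table.

    Columns: junction_id, event_class, then per-sample paired columns
    '<sample>_incl' and '<sample>_excl' holding non-negative integer read
    counts for the inclusion and exclusion forms. Returns a DataFrame
    indexed by junction_id with a MultiIndex column level (sample, which).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("junction_id", "event_class"):
        if col not in df.columns:
            raise FormatError(f"{path}: junction table lacks column {col!r}")
    count_cols = [c for c in df.columns if c not in ("junction_id", "event_class")]
    if len(count_cols) % 2 != 0:
        raise FormatError(f"{path}: odd number of count columns (need incl/excl pairs)")
    samples = []
    for c in count_cols:
        if c.endswith("_incl"):
            s = c[: -len("_incl")]
            if f"{s}_excl" not in count_cols:
                raise FormatError(f"{path}: column {c!r} lacks its _excl partner")
            samples.append(s)
        elif not c.endswith("_excl"):
            raise FormatError(f"{path}: count column {c!r} must end in _incl or _excl")
    counts = df[count_cols]
    if counts.isna().any().any() or (counts.to_numpy() < 0).any():
        raise FormatError(f"{path}: junction counts must be non-negative integers")
    if not (counts.to_numpy() == counts.to_numpy().astype(int)).all():
        raise FormatError(f"{path}: junction counts must be integral")
    out = df.set_index("junction_id")
    if out.index.has_duplicates:
        raise FormatError(f"{path}: duplicated junction ids")
    cols = pd.MultiIndex.from_tuples(
        [(s, w) for s in samples for w in ("incl", "excl")], names=["sample", "which"]
    )
    data = pd.DataFrame(
        np.column_stack([out[f"{s}_{w}"].to_numpy(dtype=int) for s, w in cols]),
        index=out.index, columns=cols,
    )
    data.insert(0, ("event_class", ""), out["event_class"].to_numpy())
    return data


def write_junctions(junctions: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    """Write junction counts in the flat juncBase-style layout read_junctions reads."""
    flat = pd.DataFrame(index=junctions.index)
    flat["event_class"] = junctions[("event_class", "")]
    for sample, which in junctions.columns:
        if sample == "event_class":
            continue
        flat[f"{sample}_{which}"] = junctions[(sample, which)]
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        flat.to_csv(fh, sep="\t", index_label="junction_id")


# ---------------------------------------------------------------------------
# generic provenance-stamped tables


def provenance_header(stage: str, seed: int, cfg_hash: str) -> list[str]:
    return [f"stage={stage}", f"seed={seed}", f"config={cfg_hash}"]


def write_table(df: pd.DataFrame, path, header_lines: list[str] | None = None,
                index: bool = False) -> None:
    buf = _io.StringIO()
    for line in header_lines or []:
        buf.write(f"# {line}\n")
    df.to_csv(buf, sep="\t", index=index, na_rep=NA_MARKER)
    Path(path).write_text(buf.getvalue())


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=[NA_MARKER],
                       keep_default_na=True)
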