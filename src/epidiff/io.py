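"""Readers and writers for the plain-text formats the pipeline speaks.

All tabular data is held in :class:`pandas.DataFrame` objects with fixed
column names; small per-object types live in :mod:`epidiff.types`.
Coordinates are converted to 0-based half-open on the way in (GFF3 and
cytosine reports are 1-based) and back on the way out.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import GenomicInterval, SyntenyBlock, VALID_CONTEXTS

logger = logging.getLogger("epidiff")

CX_COLUMNS = ["contig", "position", "strand", "meth", "unmeth", "context", "tri"]
FEATURE_COLUMNS = ["contig", "start", "end", "strand", "kind", "id"]
READ_COLUMNS = ["contig", "start", "end", "sequence", "copies"]

#: default mapping from GFF3 ``type`` column to the internal feature kind
DEFAULT_KIND_MAP = {
    "gene": "gene",
    "mRNA": "gene",
    "transposable_element": "TE",
    "TE": "TE",
    "repeat_region": "TE",
    "LTR_retrotransposon": "TE",
}


class FormatError(ValueError):
    """Raised when a file does not match its declared format."""


# ---------------------------------------------------------------------------
# cytosine reports


def read_cytosine_report(path: str | Path) -> pd.DataFrame:
    """Read a strand-resolved per-cytosine methylation call table.

    Expects seven tab-separated columns: contig, 1-based position,
    strand, methylated count, unmethylated count, context (CG/CHG/CHH)
    and trinucleotide.  Malformed rows raise with their line numbers.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=CX_COLUMNS, comment="#",
            dtype={"contig": str, "strand": str, "context": str, "tri": str},
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=CX_COLUMNS)
    if df.shape[1] != len(CX_COLUMNS):
        raise FormatError(f"{path}: expected {len(CX_COLUMNS)} columns")
    for col in ("position", "meth", "unmeth"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            lines = (np.flatnonzero(bad) + 1)[:5].tolist()
            raise FormatError(f"{path}: non-numeric {col} at lines {lines}")
        df[col] = vals.astype(np.int64)
    bad = ~df["context"].isin(VALID_CONTEXTS)
    if bad.any():
        lines = (np.flatnonzero(bad) + 1)[:5].tolist()
        raise FormatError(f"{path}: invalid context at lines {lines}")
    bad = (df["meth"] < 0) | (df["unmeth"] < 0)
    if bad.any():
        lines = (np.flatnonzero(bad) + 1)[:5].tolist()
        raise FormatError(f"{path}: negative counts at lines {lines}")
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        lines = (np.flatnonzero(bad) + 1)[:5].tolist()
        raise FormatError(f"{path}: invalid strand at lines {lines}")
    return df


def write_cytosine_report(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=CX_COLUMNS)


# ---------------------------------------------------------------------------
# features (GFF3 / BED)


def read_features(
    path: str | Path,
    kind_map: dict | None = None,
    fmt: str | None = None,
) -> pd.DataFrame:
    """Read gene/TE annotations from GFF3 or BED into internal coordinates.

    Format is auto-detected from the extension unless ``fmt`` is given
    ("gff3" or "bed").  GFF3 is 1-based inclusive and converted; BED is
    already 0-based half-open.  Overlapping features are retained as-is.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "gff3" if suffix in (".gff", ".gff3") else "bed"
    kind_map = DEFAULT_KIND_MAP if kind_map is None else kind_map

    if fmt == "gff3":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["contig", "source", "type", "start", "end",
                   "score", "strand", "phase", "attributes"],
            dtype={"contig": str},
        )
        ids = df["attributes"].str.extract(r"ID=([^;]+)", expand=False)
        out = pd.DataFrame({
            "contig": df["contig"],
            "start": df["start"].astype(np.int64) - 1,
            "end": df["end"].astype(np.int64),
            "strand": df["strand"].where(df["strand"].isin(["+", "-"]), "."),
            "kind": df["type"].map(kind_map).fillna("other"),
            "id": ids.fillna(
                pd.Series(
                    [f"feat_{i}" for i in range(len(df))], index=df.index
                )
            ),
        })
    elif fmt == "bed":
        raw = pd.read_csv(path, sep="\t", header=None, comment="#",
                          dtype={0: str})
        ncol = raw.shape[1]
        out = pd.DataFrame({
            "contig": raw[0],
            "start": raw[1].astype(np.int64),
            "end": raw[2].astype(np.int64),
            "strand": raw[5] if ncol > 5 else ".",
            "kind": (raw[3].map(kind_map).fillna("other")
                     if ncol > 3 else "other"),
            "id": (raw[3] if ncol > 3
                   else [f"feat_{i}" for i in range(len(raw))]),
        })
    else:
        raise ValueError(f"unknown feature format {fmt!r}")

    bad = out["start"] >= out["end"]
    if bad.any():
        lines = (np.flatnonzero(bad) + 1)[:5].tolist()
        raise FormatError(f"{path}: empty/inverted intervals at lines {lines}")
    if (out["start"] < 0).any():
        raise FormatError(f"{path}: negative start coordinate")
    return out.reset_index(drop=True)


def write_bed(features: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table as 6-column BED."""
    out = features.copy()
    out["score"] = 0
    out[["contig", "start", "end", "id", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False)


def write_bedgraph(windows: pd.DataFrame, path: str | Path) -> None:
    """Write per-window values as 4-column BEDGraph.

    ``windows`` needs columns contig/start/end/value, sorted and
    non-overlapping per contig.  Rows with NaN value (no covered sites)
    are omitted and counted in the log.
    """
    for contig, grp in windows.groupby("contig", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if np.any(np.diff(starts) < 0) or np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"unsorted or overlapping windows on {contig}")
    defined = windows.dropna(subset=["value"])
    n_skipped = len(windows) - len(defined)
    if n_skipped:
        logger.info("write_bedgraph: %d windows without data omitted",
                    n_skipped)
    with open(path, "w") as fh:
        for row in defined.itertuples(index=False):
            fh.write(f"{row.contig}\t{row.start}\t{row.end}\t"
                     f"{row.value:.6g}\n")


# ---------------------------------------------------------------------------
# expression tables


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if not {"gene_id", "fpkm"}.issubset(df.columns):
        raise FormatError(f"{path}: expected columns gene_id, fpkm")
    if (df["fpkm"] < 0).any():
        raise FormatError(f"{path}: negative FPKM values")
    return df[["gene_id", "fpkm"]]


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df[["gene_id", "fpkm"]].to_csv(
        path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# synteny blocks


def read_synteny(path: str | Path) -> list[SyntenyBlock]:
    df = pd.read_csv(
        path, sep="\t",
        names=["block_id", "contig_a", "start_a", "end_a",
               "contig_b", "start_b", "end_b", "orientation"],
        dtype={"block_id": str, "contig_a": str, "contig_b": str},
        comment="#",
    )
    blocks = []
    for row in df.itertuples(index=False):
        blocks.append(SyntenyBlock(
            id=row.block_id,
            interval_a=GenomicInterval(row.contig_a, int(row.start_a),
                                       int(row.end_a)),
            interval_b=GenomicInterval(row.contig_b, int(row.start_b),
                                       int(row.end_b)),
            orientation=row.orientation,
        ))
    return blocks


def write_synteny(blocks: Sequence[SyntenyBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            a, bb = b.interval_a, b.interval_b
            fh.write(f"{b.id}\t{a.contig}\t{a.start}\t{a.end}\t"
                     f"{bb.contig}\t{bb.start}\t{bb.end}\t{b.orientation}\n")


# ---------------------------------------------------------------------------
# small-RNA reads


def read_sirna_reads(path: str | Path) -> pd.DataFrame:
    """Read collapsed siRNA reads from a BED-like table.

    Columns: contig, start, end (0-based half-open), sequence, copies.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=READ_COLUMNS,
                         comment="#", dtype={"contig": str, "sequence": str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=READ_COLUMNS)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["copies"] = df["copies"].astype(np.int64)
    bad = (df["end"] - df["start"]) != df["sequence"].str.len()
    if bad.any():
        lines = (np.flatnonzero(bad) + 1)[:5].tolist()
        raise FormatError(f"{path}: span/sequence mismatch at lines {lines}")
    if (df["copies"] < 1).any():
        raise FormatError(f"{path}: copies must be >= 1")
    return df


def write_sirna_reads(df: pd.DataFrame, path: str | Path) -> None:
    df[READ_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file fully into memory as {name: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]],
                path: str | Path, width: int = 80) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in items]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
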