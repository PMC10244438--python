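"""Readers and writers for the text formats the pipeline touches.

BED and bedGraph are parsed directly because the operation contracts here are
stricter than generic readers provide: line-numbered parse errors, rejection
of end <= start, overlap detection in bedGraph, and length-weighted partial
bin assignment.  bigWig input goes through pyBigWig when available.

All output is tab-separated UTF-8 with LF line endings.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DEGRecord, GeneModel, GenomicInterval, PeakSet
from .tracks import RAW, SignalTrack

__all__ = [
    "ParseError",
    "read_intervals",
    "write_intervals",
    "read_signal_track",
    "read_gene_models",
    "read_deg_table",
    "read_gene_list",
]

logger = logging.getLogger(__name__)

_SKIP_PREFIXES = ("track", "browser", "#")


class ParseError(ValueError):
    """A malformed line in an input file; the message names file and line number."""


def _strip_chr(name: str) -> str:
    return name[3:] if name.lower().startswith("chr") else name


def read_intervals(
    path: str | os.PathLike,
    format: str = "auto",
    source: str = "",
    marker: str = "",
    harmonize_chr_prefix: bool = False,
) -> PeakSet:
    """Read a BED3/BED6 file into a sorted :class:`PeakSet`.

    ``format`` may be ``BED3``, ``BED6`` or ``auto`` (accept 3+ columns, use
    name/strand when present).  Track/browser/comment lines are skipped; an
    empty file yields an empty PeakSet.  ``harmonize_chr_prefix`` strips a
    leading ``chr`` so datasets with mixed naming can be combined explicitly.
    """
    if format not in ("auto", "BED3", "BED6"):
        raise ValueError(f"unknown BED format {format!r}")
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinate: {exc}"
                ) from None
            if start < 0:
                raise ParseError(f"{path}:{lineno}: negative start {start}")
            if end <= start:
                raise ParseError(
                    f"{path}:{lineno}: end <= start ({start} >= {end})"
                )
            name = None
            strand = "."
            if format != "BED3" and len(fields) >= 4:
                name = fields[3] or None
            if format != "BED3" and len(fields) >= 6 and fields[5] in ("+", "-"):
                strand = fields[5]
            if harmonize_chr_prefix:
                chrom = _strip_chr(chrom)
            intervals.append(
                GenomicInterval(chrom=chrom, start=start, end=end, strand=strand, name=name)
            )
    return PeakSet(intervals=intervals, source=source or str(path), marker=marker)


def write_intervals(
    intervals,
    path: str | os.PathLike,
    scores=None,
) -> None:
    """Write intervals as BED6; ``scores`` (optional, parallel) fills column 5."""
    ivs = list(intervals)
    if scores is None:
        scores = [0.0] * len(ivs)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for iv, score in zip(ivs, scores):
            name = iv.name if iv.name is not None else "."
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
            )


def _bedgraph_to_bins(df: pd.DataFrame, bin_width: int, path) -> dict[str, np.ndarray]:
    bins: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        vals = sub["value"].to_numpy(dtype=float)
        order = np.argsort(starts, kind="stable")
        starts, ends, vals = starts[order], ends[order], vals[order]
        if np.any(starts[1:] < ends[:-1]):
            i = int(np.flatnonzero(starts[1:] < ends[:-1])[0])
            raise ParseError(
                f"{path}: overlapping bedGraph records on {chrom} near "
                f"{starts[i + 1]} (previous record ends at {ends[i]})"
            )
        n_bins = int(np.ceil(ends.max() / bin_width))
        mass = np.zeros(n_bins)
        first_bin = starts // bin_width
        last_bin = (ends - 1) // bin_width
        single = first_bin == last_bin
        # fast path: record within one bin (the common per-bin bedGraph case)
        np.add.at(
            mass,
            first_bin[single],
            vals[single] * (ends[single] - starts[single]),
        )
        for s, e, v in zip(starts[~single], ends[~single], vals[~single]):
            b0, b1 = s // bin_width, (e - 1) // bin_width
            mass[b0] += v * ((b0 + 1) * bin_width - s)
            mass[b1] += v * (e - b1 * bin_width)
            if b1 > b0 + 1:
                mass[b0 + 1 : b1] += v * bin_width
        bins[chrom] = mass / bin_width
    return bins


def read_signal_track(
    path: str | os.PathLike,
    bin_width: int,
    format: str = "auto",
    library_size: float | None = None,
) -> SignalTrack:
    """Read coverage into fixed-width bins.

    bedGraph records must be non-overlapping within a chromosome; a record
    partially covering a bin contributes its length-weighted share, so
    integrated mass is conserved exactly and uncovered positions are zero.
    ``format`` is ``bedGraph``, ``bigWig`` or ``auto`` (by file extension).
    """
    if bin_width < 1:
        raise ValueError(f"bin_width must be >= 1, got {bin_width}")
    path = Path(path)
    if format == "auto":
        format = "bigWig" if path.suffix.lower() in (".bw", ".bigwig") else "bedGraph"
    if format == "bigWig":
        return _read_bigwig(path, bin_width, library_size)
    if format != "bedGraph":
        raise ValueError(f"unknown signal format {format!r}")
    try:
        df = pd.read_csv(
            path,
            sep=r"\s+",
            comment="#",
            header=None,
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
            skiprows=_count_header_lines(path),
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end", "value"])
    if len(df) and (df[["start", "end", "value"]].isna().any().any()):
        raise ParseError(f"{path}: malformed bedGraph record (missing fields)")
    if len(df) and (df["end"] <= df["start"]).any():
        bad = df.index[(df["end"] <= df["start"])][0]
        raise ParseError(f"{path}: record {bad}: end <= start")
    bins = _bedgraph_to_bins(df, bin_width, path) if len(df) else {}
    return SignalTrack(
        bins=bins, bin_width=bin_width, library_size=library_size, normalized=RAW
    )


def _count_header_lines(path) -> int:
    n = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith(("track", "browser")):
                n += 1
            else:
                break
    return n


def _read_bigwig(path, bin_width: int, library_size):
    try:
        import pyBigWig
    except ImportError as exc:  # pragma: no cover
        raise ImportError("bigWig input requires the pyBigWig package") from exc
    bw = pyBigWig.open(str(path))
    bins: dict[str, np.ndarray] = {}
    try:
        for chrom, length in bw.chroms().items():
            n = int(np.ceil(length / bin_width))
            vals = bw.stats(chrom, 0, length, type="mean", nBins=n, exact=True)
            bins[chrom] = np.array([v if v is not None else 0.0 for v in vals])
    finally:
        bw.close()
    return SignalTrack(
        bins=bins, bin_width=bin_width, library_size=library_size, normalized=RAW
    )


def read_gene_models(path: str | os.PathLike, format: str = "auto") -> list[GeneModel]:
    """Read a gene model table (TSV) or GTF-lite (gene feature lines).

    The TSV needs columns gene_id, chrom, start, end, strand with 0-based
    half-open coordinates.  GTF coordinates are 1-based inclusive and are
    converted at this boundary.  gene_id must be unique.
    """
    path = Path(path)
    if format == "auto":
        format = "gtf" if path.suffix.lower() in (".gtf", ".gff") else "tsv"
    genes: list[GeneModel] = []
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        required = {"gene_id", "chrom", "start", "end", "strand"}
        missing = required - set(df.columns)
        if missing:
            raise ParseError(f"{path}: missing gene model columns {sorted(missing)}")
        for row in df.itertuples(index=False):
            genes.append(
                GeneModel(
                    gene_id=str(row.gene_id),
                    interval=GenomicInterval(
                        chrom=str(row.chrom),
                        start=int(row.start),
                        end=int(row.end),
                        strand=str(row.strand),
                    ),
                )
            )
    elif format == "gtf":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 9:
                    raise ParseError(f"{path}:{lineno}: expected 9 GTF fields")
                if fields[2] != "gene":
                    continue
                attrs = fields[8]
                gene_id = None
                for part in attrs.split(";"):
                    part = part.strip()
                    if part.startswith("gene_id"):
                        gene_id = part.split(None, 1)[1].strip().strip('"')
                        break
                if gene_id is None:
                    raise ParseError(f"{path}:{lineno}: gene line without gene_id")
                genes.append(
                    GeneModel(
                        gene_id=gene_id,
                        interval=GenomicInterval(
                            chrom=fields[0],
                            start=int(fields[3]) - 1,  # GTF is 1-based inclusive
                            end=int(fields[4]),
                            strand=fields[6],
                        ),
                    )
                )
    else:
        raise ValueError(f"unknown gene model format {format!r}")
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        dup = next(g for g in ids if ids.count(g) > 1)
        raise ParseError(f"{path}: duplicate gene_id {dup!r}")
    return genes


_GENE_ALIASES = ("gene", "gene_id", "gene_name", "symbol")
_LFC_ALIASES = ("log2fc", "log2foldchange", "log2_fc", "lfc")
_P_ALIASES = ("pvalue", "pval", "p_value", "p")
_Q_ALIASES = ("qvalue", "qval", "padj", "q_value", "fdr", "q")


def _find_column(df: pd.DataFrame, requested: str | None, aliases) -> str | None:
    if requested is not None:
        if requested not in df.columns:
            raise ParseError(f"column {requested!r} not found in DEG table")
        return requested
    lower = {c.lower(): c for c in df.columns}
    for alias in aliases:
        if alias in lower:
            return lower[alias]
    return None


def read_deg_table(
    path: str | os.PathLike,
    gene_col: str | None = None,
    lfc_col: str | None = None,
    pvalue_col: str | None = None,
    qvalue_col: str | None = None,
) -> list[DEGRecord]:
    """Read a TSV of differential-expression results into DEGRecords.

    Column names are configurable; common aliases (log2FoldChange, padj, ...)
    are recognised automatically.  Rows keep input order.  A missing q-value
    column yields records with ``qvalue=None`` for later BH adjustment.
    Duplicate gene ids and absence of both p and q columns are errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    gcol = _find_column(df, gene_col, _GENE_ALIASES)
    lcol = _find_column(df, lfc_col, _LFC_ALIASES)
    pcol = _find_column(df, pvalue_col, _P_ALIASES)
    qcol = _find_column(df, qvalue_col, _Q_ALIASES)
    if gcol is None or lcol is None:
        raise ParseError(f"{path}: could not locate gene and log2fc columns")
    if pcol is None and qcol is None:
        raise ParseError(f"{path}: table has neither a p-value nor a q-value column")
    genes = df[gcol].astype(str)
    if genes.duplicated().any():
        dup = genes[genes.duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate gene_id {dup!r}")
    records = []
    for i in range(len(df)):
        p = df[pcol].iloc[i] if pcol else None
        q = df[qcol].iloc[i] if qcol else None
        records.append(
            DEGRecord(
                gene_id=genes.iloc[i],
                log2fc=float(df[lcol].iloc[i]),
                pvalue=None if p is None or pd.isna(p) else float(p),
                qvalue=None if q is None or pd.isna(q) else float(q),
            )
        )
    return records


def read_gene_list(path: str | os.PathLike) -> list[str]:
    """Read a plain gene list, one id per line; ``#`` comments and blanks skipped."""
    genes = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    return genes
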