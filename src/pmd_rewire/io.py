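"""Text-format readers and writers.

Formats handled: bedGraph-dialect per-CpG count tables, per-read call TSVs,
BED3/BED6 interval files, binned depth TSVs, and FASTA (via pyfaidx for
indexed access).  Everything is validated at the boundary; internal code can
then assume the invariants in :mod:`pmd_rewire.core`.

Coordinate conventions: all internal coordinates are 0-based half-open, the
native convention of BED/bedGraph, so no shifting happens on these formats.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .core import (
    CONTEXTS,
    DepthTrack,
    MethylomeTrack,
    ReadCallRecord,
    ValidationError,
)
from .intervals import validate_intervals

log = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed on-disk record; message carries the 1-based line number."""


def _open_lines(path) -> Iterator[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


# ---------------------------------------------------------------------------
# CpG count tables (bedGraph dialect)
# ---------------------------------------------------------------------------

def read_cpg_table(
    path,
    sample_id: str | None = None,
    dialect: str = "counts",
    context_filter: str | None = None,
    chrom_sizes: Mapping[str, int] | None = None,
    fasta=None,
) -> MethylomeTrack:
    """Read a per-CpG methylation count table.

    dialect="counts": chrom, start, end, meth, unmeth [, context]
    dialect="percent": chrom, start, end, percent, meth, unmeth [, context]
    (the percent column is ignored; counts are authoritative).

    Context is taken from the optional trailing column, else looked up in
    ``fasta`` (dinucleotide at pos), else assumed CG.
    """
    if dialect not in ("counts", "percent"):
        raise ValueError(f"unknown dialect {dialect!r}")
    ncount = 5 if dialect == "counts" else 6
    chroms, poss, meths, totals, ctxs = [], [], [], [], []
    for lineno, fields in _open_lines(path):
        if len(fields) < ncount:
            raise ParseError(f"line {lineno}: expected ≥{ncount} columns, got {len(fields)}")
        try:
            start = int(fields[1])
            end = int(fields[2])
            if dialect == "counts":
                meth, unmeth = int(fields[3]), int(fields[4])
            else:
                meth, unmeth = int(fields[4]), int(fields[5])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
        if end != start + 1:
            raise ParseError(f"line {lineno}: CpG record must span one base")
        if meth < 0 or unmeth < 0:
            raise ValidationError(f"line {lineno}: negative count")
        ctx = fields[ncount] if len(fields) > ncount else None
        if ctx is None and fasta is not None:
            dinuc = str(fasta[fields[0]][start:start + 2]).upper()
            ctx = dinuc if dinuc in CONTEXTS else "CG"
        chroms.append(fields[0])
        poss.append(start)
        meths.append(meth)
        totals.append(meth + unmeth)
        ctxs.append(ctx if ctx is not None else "CG")
    sites = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "context": ctxs, "meth": meths, "total": totals}
    )
    if len(sites) and not sites.sort_values(["chrom", "pos"]).equals(sites):
        log.warning("%s: input not coordinate-sorted; sorting", path)
    track = MethylomeTrack(sample_id or Path(str(path)).stem, sites, chrom_sizes or {})
    if context_filter is not None:
        track = track.filter(context=context_filter)
    return track


def write_cpg_table(track: MethylomeTrack, path, dialect: str = "counts") -> None:
    with open(path, "w") as fh:
        for row in track.sites.itertuples(index=False):
            unmeth = row.total - row.meth
            if dialect == "counts":
                fh.write(f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{row.meth}\t{unmeth}\t{row.context}\n")
            else:
                pct = 100.0 * row.meth / row.total if row.total else 0.0
                fh.write(
                    f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{pct:.6g}\t{row.meth}\t{unmeth}\t{row.context}\n"
                )


# ---------------------------------------------------------------------------
# Per-read call tables
# ---------------------------------------------------------------------------

def read_per_read_calls(path) -> Iterator[ReadCallRecord]:
    """Stream per-read methylation calls.

    Format: ``read_id<TAB>chrom<TAB>pos:call,pos:call,...`` with call in
    {M, U}; positions strictly increasing within a read.  Records are yielded
    in file order without materialising the whole file.
    """
    for lineno, fields in _open_lines(path):
        if len(fields) < 3:
            raise ParseError(f"line {lineno}: expected 3 columns")
        read_id, chrom, callspec = fields[0], fields[1], fields[2]
        positions, calls = [], []
        for token in callspec.split(","):
            try:
                pos_s, call_s = token.split(":")
                pos = int(pos_s)
            except ValueError:
                raise ParseError(f"line {lineno}: bad call token {token!r}") from None
            if call_s not in ("M", "U"):
                raise ValidationError(
                    f"read {read_id!r}: call symbol {call_s!r} not in {{M,U}}"
                )
            positions.append(pos)
            calls.append(call_s == "M")
        if len(set(positions)) != len(positions):
            raise ValidationError(f"read {read_id!r}: duplicate call position")
        try:
            yield ReadCallRecord(read_id, chrom, np.array(positions), np.array(calls))
        except ValidationError as exc:
            raise ValidationError(f"read {read_id!r}: {exc}") from None


def write_per_read_calls(records: Iterable[ReadCallRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            spec = ",".join(
                f"{p}:{'M' if c else 'U'}" for p, c in zip(rec.positions, rec.calls)
            )
            fh.write(f"{rec.read_id}\t{rec.chrom}\t{spec}\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read BED3+ into an interval frame; name/score preserved when present."""
    rows = []
    ncols = 3
    for lineno, fields in _open_lines(path):
        if len(fields) < 3:
            raise ParseError(f"line {lineno}: BED needs ≥3 columns")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
        if start >= end:
            raise ValidationError(f"line {lineno}: start {start} >= end {end}")
        row = [fields[0], start, end]
        if len(fields) > 3:
            row.append(fields[3])
        if len(fields) > 4:
            row.append(fields[4])
        ncols = max(ncols, len(row))
        rows.append(row)
    columns = ["chrom", "start", "end", "name", "score"][:ncols]
    rows = [r + [None] * (ncols - len(r)) for r in rows]
    df = pd.DataFrame(rows, columns=columns)
    return validate_intervals(df)


def write_bed(df: pd.DataFrame, path) -> None:
    df = validate_intervals(df)
    cols = [c for c in ("chrom", "start", "end", "name", "score") if c in df.columns]
    with open(path, "w") as fh:
        for row in df[cols].itertuples(index=False):
            fh.write("\t".join(str(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Depth tracks
# ---------------------------------------------------------------------------

def read_depth_track(path, sample_id: str | None = None) -> DepthTrack:
    """Read a binned depth TSV: chrom, start, end, mean_depth (bins sorted,
    tiling each chromosome)."""
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, fields in _open_lines(path):
        if len(fields) < 4:
            raise ParseError(f"line {lineno}: expected 4 columns")
        try:
            start, end, depth = int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
        per_chrom.setdefault(fields[0], []).append((start, end, depth))
    depth: dict[str, np.ndarray] = {}
    chrom_sizes: dict[str, int] = {}
    bin_size = None
    for chrom, bins in per_chrom.items():
        bins.sort()
        starts = np.array([b[0] for b in bins])
        ends = np.array([b[1] for b in bins])
        if starts[0] != 0 or np.any(starts[1:] != ends[:-1]):
            raise ValidationError(f"{chrom}: depth bins do not tile the chromosome")
        widths = ends - starts
        bs = int(widths[0])
        if bin_size is None:
            bin_size = bs
        if bs != bin_size or np.any(widths[:-1] != bin_size):
            raise ValidationError(f"{chrom}: inconsistent bin size")
        depth[chrom] = np.array([b[2] for b in bins])
        chrom_sizes[chrom] = int(ends[-1])
    if bin_size is None:
        raise ParseError("empty depth file")
    return DepthTrack(sample_id or Path(str(path)).stem, bin_size, depth, chrom_sizes)


def write_depth_track(track: DepthTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            size = track.chrom_sizes[chrom]
            arr = track.depth[chrom]
            for i, d in enumerate(arr):
                start = i * track.bin_size
                end = min(start + track.bin_size, size)
                fh.write(f"{chrom}\t{start}\t{end}\t{d:.6g}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def open_fasta(path):
    """Indexed FASTA access (pyfaidx)."""
    from pyfaidx import Fasta

    return Fasta(str(path), sequence_always_upper=True)
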