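"""Interval-set algebra on 0-based half-open genomic intervals.

Intervals live in pandas DataFrames with at least ``chrom, start, end``
columns (BED order); optional ``name`` and ``score`` columns are preserved
where the operation allows it.  All operations here are pure and return new
sorted frames.  The arithmetic is deliberately simple (sorted sweeps over
numpy arrays) so that each operation can be checked against a per-base
brute-force oracle on small genomes.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ValidationError

BED3 = ["chrom", "start", "end"]


def make_intervals(rows: Iterable[tuple], columns: Sequence[str] = BED3) -> pd.DataFrame:
    df = pd.DataFrame(list(rows), columns=list(columns))
    return validate_intervals(df)


def empty_intervals(extra: Sequence[str] = ()) -> pd.DataFrame:
    return pd.DataFrame(
        {"chrom": pd.Series(dtype=str),
         "start": pd.Series(dtype=np.int64),
         "end": pd.Series(dtype=np.int64),
         **{c: pd.Series(dtype=object) for c in extra}}
    )


def validate_intervals(df: pd.DataFrame, require_disjoint: bool = False) -> pd.DataFrame:
    """Sort and validate; start < end everywhere, optionally non-overlapping."""
    if df.empty:
        out = df.copy()
        for col in ("start", "end"):
            if col in out.columns:
                out[col] = out[col].astype(np.int64)
        return out.reset_index(drop=True)
    out = df.copy()
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    bad = out["start"] >= out["end"]
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"interval with start >= end at row {i}: "
            f"{out.iloc[i]['chrom']}:{out.iloc[i]['start']}-{out.iloc[i]['end']}"
        )
    out = out.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    if require_disjoint:
        same = out["chrom"].to_numpy()[1:] == out["chrom"].to_numpy()[:-1]
        overlap = out["start"].to_numpy()[1:] < out["end"].to_numpy()[:-1]
        if np.any(same & overlap):
            raise ValidationError("overlapping intervals where disjoint required")
    return out


def total_bases(df: pd.DataFrame) -> int:
    if df.empty:
        return 0
    return int((df["end"] - df["start"]).sum())


def merge_intervals(df: pd.DataFrame, gap: int = 0) -> pd.DataFrame:
    """Union-merge intervals closer than or equal to ``gap`` bases apart."""
    df = validate_intervals(df[BED3])
    if df.empty:
        return df
    rows = []
    for chrom, grp in df.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e + gap:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        rows.append((chrom, cur_s, cur_e))
    return make_intervals(rows)


def intersect(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Base-level intersection of two interval sets (result merged)."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    if a.empty or b.empty:
        return empty_intervals()
    rows = []
    bg = {c: g for c, g in b.groupby("chrom", sort=False)}
    for chrom, ga in a.groupby("chrom", sort=True):
        gb = bg.get(chrom)
        if gb is None:
            continue
        sa, ea = ga["start"].to_numpy(), ga["end"].to_numpy()
        sb, eb = gb["start"].to_numpy(), gb["end"].to_numpy()
        i = j = 0
        while i < sa.size and j < sb.size:
            s = max(sa[i], sb[j])
            e = min(ea[i], eb[j])
            if s < e:
                rows.append((chrom, s, e))
            if ea[i] <= eb[j]:
                i += 1
            else:
                j += 1
    return make_intervals(rows) if rows else empty_intervals()


def multi_intersect(sets: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Maximal intervals covered by *every* input set."""
    if not sets:
        raise ValidationError("multi_intersect needs at least one interval set")
    acc = merge_intervals(sets[0])
    for other in sets[1:]:
        acc = intersect(acc, other)
        if acc.empty:
            break
    return acc


def complement(df: pd.DataFrame, chrom_sizes: Mapping[str, int]) -> pd.DataFrame:
    """Bases of the genome not covered by ``df``."""
    df = merge_intervals(df)
    rows = []
    by_chrom = {c: g for c, g in df.groupby("chrom", sort=False)}
    for chrom in sorted(chrom_sizes):
        size = int(chrom_sizes[chrom])
        grp = by_chrom.get(chrom)
        if grp is None:
            rows.append((chrom, 0, size))
            continue
        if grp["end"].max() > size:
            raise ValidationError(f"interval beyond {chrom} length {size}")
        prev = 0
        for s, e in zip(grp["start"], grp["end"]):
            if s > prev:
                rows.append((chrom, prev, s))
            prev = e
        if prev < size:
            rows.append((chrom, prev, size))
    return make_intervals(rows) if rows else empty_intervals()


def overlap_bases(a: pd.DataFrame, b: pd.DataFrame) -> int:
    return total_bases(intersect(a, b))


def overlap_fraction(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """|A ∩ B| / |A| — the asymmetric fraction-mode overlap."""
    na = total_bases(a)
    if na == 0:
        return float("nan")
    return overlap_bases(a, b) / na


def intervals_overlapping(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
    """Boolean mask over rows of ``a``: does the row overlap ≥1 bp of ``b``?"""
    if a.empty:
        return np.zeros(0, dtype=bool)
    bm = merge_intervals(b)
    mask = np.zeros(len(a), dtype=bool)
    bg = {c: g for c, g in bm.groupby("chrom", sort=False)}
    a_sorted = a.reset_index(drop=True)
    for chrom, ga in a_sorted.groupby("chrom", sort=False):
        gb = bg.get(chrom)
        if gb is None:
            continue
        sb = gb["start"].to_numpy()
        eb = gb["end"].to_numpy()
        s = ga["start"].to_numpy()
        e = ga["end"].to_numpy()
        # first b-interval whose end is > a.start
        j = np.searchsorted(eb, s, side="right")
        hit = (j < sb.size) & (np.where(j < sb.size, sb[np.minimum(j, sb.size - 1)], 0) < e)
        mask[ga.index.to_numpy()] = hit
    return mask


def points_covered(points: pd.DataFrame, regions: pd.DataFrame) -> np.ndarray:
    """Mask over 1-bp (or point) intervals: covered by ≥1 bp of regions."""
    return intervals_overlapping(points, regions)


def per_base_mask(df: pd.DataFrame, chrom_sizes: Mapping[str, int]) -> dict[str, np.ndarray]:
    """Brute-force boolean coverage arrays — the testing oracle, small genomes only."""
    masks = {c: np.zeros(int(n), dtype=bool) for c, n in chrom_sizes.items()}
    for row in df.itertuples(index=False):
        masks[row.chrom][row.start:row.end] = True
    return masks
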