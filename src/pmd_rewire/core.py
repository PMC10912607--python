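"""Core in-memory containers for the methylome pipeline.

Coordinates are 0-based half-open everywhere.  A methylome is a table of
per-CpG (dyad-level) methylated / total call counts; per-read data carry the
ordered binary methylation calls of one sequenced molecule; depth tracks are
binned mean coverage.  All containers validate their invariants on
construction so that downstream math can assume clean input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: cytosine contexts carried in CpG tables; CA/CC/CT jointly form CH
CONTEXTS = ("CG", "CA", "CC", "CT")

SEGMENT_STATES = ("UMR", "LMR", "PMD", "hyperMR")


class ValidationError(ValueError):
    """Raised when a record violates a container invariant."""


def _as_chrom_sizes(chrom_sizes: Mapping[str, int]) -> dict[str, int]:
    out = {str(c): int(n) for c, n in chrom_sizes.items()}
    for c, n in out.items():
        if n <= 0:
            raise ValidationError(f"chromosome {c!r} has non-positive length {n}")
    return out


@dataclass
class MethylomeTrack:
    """Per-CpG methylation counts for one WGBS sample.

    ``sites`` has columns ``chrom, pos, context, meth, total`` sorted by
    (chrom, pos) with no duplicate positions.  ``pos`` is the 0-based
    coordinate of the C of the CpG dyad (dyad-merged counts).
    """

    sample_id: str
    sites: pd.DataFrame
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.sites
        required = ["chrom", "pos", "meth", "total"]
        for col in required:
            if col not in df.columns:
                raise ValidationError(f"sites table missing column {col!r}")
        if "context" not in df.columns:
            df = df.assign(context="CG")
        df = df[["chrom", "pos", "context", "meth", "total"]].copy()
        df["pos"] = df["pos"].astype(np.int64)
        df["meth"] = df["meth"].astype(np.int64)
        df["total"] = df["total"].astype(np.int64)
        if len(df):
            if (df["pos"] < 0).any():
                raise ValidationError("negative CpG position")
            if (df["meth"] < 0).any() or (df["meth"] > df["total"]).any():
                raise ValidationError("meth count outside [0, total]")
            bad = ~df["context"].isin(CONTEXTS)
            if bad.any():
                raise ValidationError(
                    f"unknown context {df.loc[bad, 'context'].iloc[0]!r}"
                )
            df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
            if df.duplicated(["chrom", "pos"]).any():
                raise ValidationError("duplicate (chrom, pos) in methylome track")
        else:
            df = df.reset_index(drop=True)
        self.sites = df
        self.chrom_sizes = _as_chrom_sizes(self.chrom_sizes)
        for chrom, grp in df.groupby("chrom", sort=False):
            size = self.chrom_sizes.get(str(chrom))
            if size is not None and grp["pos"].iloc[-1] >= size:
                raise ValidationError(
                    f"site at {chrom}:{grp['pos'].iloc[-1]} beyond chromosome "
                    f"length {size}"
                )

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.sites["chrom"]))

    def m(self) -> np.ndarray:
        """Per-site methylation level meth/total (NaN where total == 0)."""
        total = self.sites["total"].to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, self.sites["meth"].to_numpy(float) / total, np.nan)

    def filter(
        self,
        context: str | None = "CG",
        min_total: int = 0,
        chroms: Iterable[str] | None = None,
        exclude_chroms: Iterable[str] = (),
    ) -> "MethylomeTrack":
        """Return a sub-track; ``context='CH'`` selects CA/CC/CT jointly."""
        df = self.sites
        mask = np.ones(len(df), dtype=bool)
        if context is not None:
            if context == "CH":
                mask &= df["context"].isin(["CA", "CC", "CT"]).to_numpy()
            else:
                mask &= (df["context"] == context).to_numpy()
        if min_total > 0:
            mask &= (df["total"] >= min_total).to_numpy()
        if chroms is not None:
            mask &= df["chrom"].isin(list(chroms)).to_numpy()
        excl = list(exclude_chroms)
        if excl:
            mask &= ~df["chrom"].isin(excl).to_numpy()
        return MethylomeTrack(self.sample_id, df[mask], self.chrom_sizes)


@dataclass
class ReadCallRecord:
    """Ordered per-CpG methylation calls of one sequenced molecule."""

    read_id: str
    chrom: str
    positions: np.ndarray  # strictly increasing, int64
    calls: np.ndarray      # bool, True = methylated (M)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=bool)
        if self.positions.size == 0:
            raise ValidationError(f"read {self.read_id!r} has no calls")
        if self.positions.size != self.calls.size:
            raise ValidationError(f"read {self.read_id!r}: positions/calls mismatch")
        if np.any(np.diff(self.positions) <= 0):
            raise ValidationError(
                f"read {self.read_id!r}: positions not strictly increasing"
            )

    @property
    def n_calls(self) -> int:
        return int(self.positions.size)


class ReadTable:
    """Flat columnar view over many :class:`ReadCallRecord`.

    Stored as a DataFrame with one row per call
    (``read_idx, read_id, chrom, pos, call``); vectorised statistics such as
    PDR operate on this layout.
    """

    def __init__(self, df: pd.DataFrame):
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable[ReadCallRecord]) -> "ReadTable":
        idx, rid, chrom, pos, call = [], [], [], [], []
        for i, rec in enumerate(records):
            n = rec.n_calls
            idx.append(np.full(n, i, dtype=np.int64))
            rid.extend([rec.read_id] * n)
            chrom.extend([rec.chrom] * n)
            pos.append(rec.positions)
            call.append(rec.calls)
        if not idx:
            df = pd.DataFrame(
                {"read_idx": np.array([], np.int64), "read_id": [], "chrom": [],
                 "pos": np.array([], np.int64), "call": np.array([], bool)}
            )
            return cls(df)
        df = pd.DataFrame(
            {
                "read_idx": np.concatenate(idx),
                "read_id": rid,
                "chrom": chrom,
                "pos": np.concatenate(pos),
                "call": np.concatenate(call),
            }
        )
        return cls(df)

    def __len__(self) -> int:
        """Number of reads."""
        if self.df.empty:
            return 0
        return int(self.df["read_idx"].nunique())

    def iter_records(self) -> Iterable[ReadCallRecord]:
        for (ridx, rid, chrom), grp in self.df.groupby(
            ["read_idx", "read_id", "chrom"], sort=True
        ):
            yield ReadCallRecord(
                str(rid), str(chrom), grp["pos"].to_numpy(), grp["call"].to_numpy()
            )

    def aggregate_track(
        self, sample_id: str, chrom_sizes: Mapping[str, int] | None = None
    ) -> MethylomeTrack:
        """Collapse calls to per-CpG meth/total counts."""
        if self.df.empty:
            sites = pd.DataFrame(columns=["chrom", "pos", "context", "meth", "total"])
            return MethylomeTrack(sample_id, sites, chrom_sizes or {})
        g = self.df.groupby(["chrom", "pos"], sort=True)["call"]
        agg = g.agg(meth="sum", total="size").reset_index()
        agg["context"] = "CG"
        return MethylomeTrack(sample_id, agg, chrom_sizes or {})


@dataclass
class DepthTrack:
    """Binned mean sequencing depth for one sample.

    ``depth`` maps chromosome name to a float array; bin ``i`` covers
    ``[i*bin_size, min((i+1)*bin_size, chrom_len))`` so bins tile each
    chromosome without gaps.
    """

    sample_id: str
    bin_size: int
    depth: dict[str, np.ndarray]
    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValidationError("bin size must be positive")
        self.chrom_sizes = _as_chrom_sizes(self.chrom_sizes)
        clean: dict[str, np.ndarray] = {}
        for chrom, arr in self.depth.items():
            arr = np.asarray(arr, dtype=float)
            if np.any(arr < 0):
                raise ValidationError(f"negative depth on {chrom}")
            size = self.chrom_sizes.get(chrom)
            if size is not None:
                n_expected = -(-size // self.bin_size)
                if arr.size != n_expected:
                    raise ValidationError(
                        f"{chrom}: {arr.size} bins do not tile length {size} "
                        f"at bin size {self.bin_size} (expected {n_expected})"
                    )
            clean[chrom] = arr
        self.depth = clean

    @property
    def chroms(self) -> list[str]:
        return list(self.depth)

    def values(self, chroms: Iterable[str] | None = None) -> np.ndarray:
        keys = list(chroms) if chroms is not None else list(self.depth)
        return np.concatenate([self.depth[c] for c in keys]) if keys else np.array([])

    def same_grid(self, other: "DepthTrack") -> bool:
        if self.bin_size != other.bin_size:
            return False
        if set(self.depth) != set(other.depth):
            return False
        return all(self.depth[c].size == other.depth[c].size for c in self.depth)
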