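"""Read-level methylation discordance (PDR).

A read with at least ``min_cpgs`` CpG calls is *discordant* when it carries
both methylated and unmethylated calls, and concordant otherwise.  The PDR
of a region is the discordant fraction of qualifying reads overlapping it
by at least one call.  Under the PMD molecule mixture (discordant fraction
pi, within-molecule methylation q) the expected PDR of a read with c calls
is pi·(1 − q^c − (1−q)^c).

Discordance is always judged from all calls on the read, not only the calls
falling inside the region — classification precedes the interval
intersection, mirroring how per-read calls are intersected with regions in
practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .core import MethylomeTrack, ReadCallRecord, ReadTable, ValidationError

CATEGORIES = ("concordant_M", "concordant_U", "discordant", "excluded")


@dataclass
class PDRParams:
    min_cpgs: int = 4        # calls required for a read to qualify
    min_reads: int = 10      # qualifying reads required per region

    def __post_init__(self) -> None:
        if self.min_cpgs < 2:
            raise ValidationError("min_cpgs must be at least 2")
        if self.min_reads < 1:
            raise ValidationError("min_reads must be positive")


def classify_read(record: ReadCallRecord, params: PDRParams | None = None) -> str:
    """Classify one read: concordant_M / concordant_U / discordant / excluded."""
    params = params or PDRParams()
    if record.n_calls < params.min_cpgs:
        return "excluded"
    n_m = int(record.calls.sum())
    if n_m == 0:
        return "concordant_U"
    if n_m == record.n_calls:
        return "concordant_M"
    return "discordant"


def classify_reads(table: ReadTable, params: PDRParams | None = None) -> pd.DataFrame:
    """Vectorised per-read classification over a flat call table."""
    params = params or PDRParams()
    df = table.df
    if df.empty:
        return pd.DataFrame(columns=["read_idx", "chrom", "n_calls", "n_meth", "category"])
    g = df.groupby("read_idx", sort=True)
    out = g.agg(chrom=("chrom", "first"), n_calls=("call", "size"), n_meth=("call", "sum"))
    out = out.reset_index()
    cat = np.where(
        out["n_calls"] < params.min_cpgs,
        "excluded",
        np.where(
            out["n_meth"] == 0,
            "concordant_U",
            np.where(out["n_meth"] == out["n_calls"], "concordant_M", "discordant"),
        ),
    )
    out["category"] = cat
    return out


def region_pdr(
    reads: ReadTable,
    regions: pd.DataFrame,
    track: MethylomeTrack | None = None,
    params: PDRParams | None = None,
) -> pd.DataFrame:
    """Per-region PDR and coverage-weighted mCG.

    A read counts toward every region it overlaps by at least one call
    position; regions with fewer than ``min_reads`` qualifying reads get
    ``NaN`` PDR.  Region mCG is Σmeth/Σtotal over the CpGs contained in the
    region (``NaN`` when no track given or no CpGs covered).
    """
    params = params or PDRParams()
    cls = classify_reads(reads, params)
    max_idx = int(cls["read_idx"].max()) + 1 if len(cls) else 0
    is_qual = np.zeros(max_idx, dtype=bool)
    is_disc = np.zeros(max_idx, dtype=bool)
    if max_idx:
        ridx_all = cls["read_idx"].to_numpy()
        is_qual[ridx_all] = (cls["category"] != "excluded").to_numpy()
        is_disc[ridx_all] = (cls["category"] == "discordant").to_numpy()
    # per-chromosome call positions sorted once
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in reads.df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        order = np.argsort(pos, kind="mergesort")
        by_chrom[chrom] = (pos[order], sub["read_idx"].to_numpy()[order])
    track_cum: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    rows = []
    for row in regions.itertuples(index=False):
        pos_sorted, read_sorted = by_chrom.get(row.chrom, (np.array([]), np.array([], int)))
        lo, hi = np.searchsorted(pos_sorted, [row.start, row.end])
        ridx = np.unique(read_sorted[lo:hi])
        ridx = ridx[is_qual[ridx]] if ridx.size else ridx
        n_qual = int(ridx.size)
        n_disc = int(is_disc[ridx].sum()) if n_qual else 0
        pdr = n_disc / n_qual if n_qual >= params.min_reads else np.nan
        mcg = np.nan
        if track is not None:
            if row.chrom not in track_cum:
                grp = track.sites[track.sites["chrom"] == row.chrom]
                track_cum[row.chrom] = (
                    grp["pos"].to_numpy(),
                    np.concatenate([[0], np.cumsum(grp["meth"].to_numpy(float))]),
                    np.concatenate([[0], np.cumsum(grp["total"].to_numpy(float))]),
                )
            tpos, cmeth, ctot = track_cum[row.chrom]
            a, b = np.searchsorted(tpos, [row.start, row.end])
            tot = ctot[b] - ctot[a]
            if tot > 0:
                mcg = float((cmeth[b] - cmeth[a]) / tot)
        rows.append(
            {
                "chrom": row.chrom, "start": row.start, "end": row.end,
                "n_reads": n_qual, "n_discordant": n_disc, "pdr": pdr, "mcg": mcg,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_reads", "n_discordant", "pdr", "mcg"],
    )


def pdr_mcg_join(
    region_pdrs: Mapping[str, pd.DataFrame],
    transition_labels: pd.DataFrame,
) -> pd.DataFrame:
    """Long table of (sample, region, transition class, PDR, mCG).

    ``transition_labels`` carries chrom/start/end plus a ``label`` column
    (e.g. "UMR->PMD"); every labelled region must be present in every
    sample's PDR table.
    """
    frames = []
    for sample, df in region_pdrs.items():
        merged = transition_labels.merge(df, on=["chrom", "start", "end"], how="left")
        if merged["pdr"].isna().all() and len(merged) and df.empty:
            raise ValidationError(f"sample {sample!r}: no PDR rows for labelled regions")
        missing = merged["n_reads"].isna()
        if missing.any():
            r = merged[missing].iloc[0]
            raise ValidationError(
                f"sample {sample!r}: region {r['chrom']}:{r['start']}-{r['end']} "
                "absent from PDR table"
            )
        merged.insert(0, "sample", sample)
        frames.append(merged)
    if not frames:
        return pd.DataFrame(
            columns=["sample", "chrom", "start", "end", "label",
                     "n_reads", "n_discordant", "pdr", "mcg"]
        )
    return pd.concat(frames, ignore_index=True)
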