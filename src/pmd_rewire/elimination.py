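"""Detection of somatically eliminated (germline-restricted) sequences.

Programmed genome rearrangement removes germline DNA from somatic lineages;
the deleted sequence shows copy number 0 in somatic tissue while remaining
fully covered in the germline.  The caller works on median-normalised
binned depth: bins with somatic depth at most ``cn0_threshold`` (default
0.1, guarding against stray misaligned reads rather than demanding a
literal zero) *and* germline depth at least ``germline_support`` (default
0.5, excluding assembly gaps that mimic deletions) are marked, runs are
merged across small gaps, and short runs are dropped.  Median normalisation
makes the calls invariant to uniform depth rescaling of either sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DepthTrack, MethylomeTrack, ValidationError
from .intervals import intervals_overlapping, make_intervals

log = logging.getLogger(__name__)


@dataclass
class EliminationParams:
    bin_size: int = 1_000
    cn0_threshold: float = 0.1       # normalised somatic depth for copy number 0
    germline_support: float = 0.5    # normalised germline depth required
    min_bins: int = 3
    merge_gap_bins: int = 1

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValidationError("bin size must be positive")
        for name in ("cn0_threshold", "germline_support"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValidationError(f"{name} must lie in (0, 1]")
        if self.min_bins < 1 or self.merge_gap_bins < 0:
            raise ValidationError("invalid region thresholds")


def normalize_depth(track: DepthTrack) -> DepthTrack:
    """Divide every bin by the genome-wide median; output median is 1."""
    values = track.values()
    if values.size == 0:
        raise ValidationError("empty depth track")
    med = float(np.median(values))
    if med <= 0:
        raise ValidationError("all-zero depth track cannot be normalised")
    return DepthTrack(
        track.sample_id,
        track.bin_size,
        {c: v / med for c, v in track.depth.items()},
        track.chrom_sizes,
    )


def call_cn0(
    soma: DepthTrack,
    germline: DepthTrack,
    params: EliminationParams | None = None,
) -> pd.DataFrame:
    """Call copy-number-0 regions in soma with germline support.

    Returns intervals with mean normalised soma and germline depth per
    region.  Both tracks are median-normalised internally.
    """
    params = params or EliminationParams()
    if not soma.same_grid(germline):
        raise ValidationError("soma and germline depth tracks use different bin grids")
    soma_n = normalize_depth(soma)
    germ_n = normalize_depth(germline)
    rows = []
    for chrom in soma_n.chroms:
        s = soma_n.depth[chrom]
        g = germ_n.depth[chrom]
        marked = (s <= params.cn0_threshold) & (g >= params.germline_support)
        if not marked.any():
            continue
        idx = np.flatnonzero(marked)
        # merge runs across gaps of at most merge_gap_bins unmarked bins
        brk = np.flatnonzero(np.diff(idx) > params.merge_gap_bins + 1)
        starts = np.concatenate([[0], brk + 1])
        ends = np.concatenate([brk, [idx.size - 1]])
        bs = soma_n.bin_size
        size = soma_n.chrom_sizes[chrom]
        for a, b in zip(starts, ends):
            b0, b1 = int(idx[a]), int(idx[b])
            if b1 - b0 + 1 < params.min_bins:
                continue
            rows.append(
                {
                    "chrom": chrom,
                    "start": b0 * bs,
                    "end": min((b1 + 1) * bs, size),
                    "soma_depth": float(np.mean(s[b0:b1 + 1])),
                    "germline_depth": float(np.mean(g[b0:b1 + 1])),
                }
            )
    cols = ["chrom", "start", "end", "soma_depth", "germline_depth"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows, columns=cols).sort_values(["chrom", "start"]).reset_index(drop=True)


def overlap_reference(
    calls: pd.DataFrame, reference: pd.DataFrame, min_fraction: float = 0.0
) -> tuple[pd.DataFrame, float]:
    """Stringent call set (≥1 bp reference overlap) and the overlap fraction.

    ``min_fraction`` optionally requires that share of each call's bases to
    be covered by the reference (0 keeps the ≥1 bp rule).
    """
    if calls.empty:
        return calls.copy(), float("nan")
    if reference.empty:
        stringent = calls.iloc[0:0].copy()
        return stringent, 0.0
    mask = intervals_overlapping(calls[["chrom", "start", "end"]], reference)
    if min_fraction > 0:
        from .intervals import intersect

        fracs = np.zeros(len(calls))
        for i, row in enumerate(calls.itertuples(index=False)):
            one = make_intervals([(row.chrom, row.start, row.end)])
            ov = intersect(one, reference)
            fracs[i] = (ov["end"] - ov["start"]).sum() / (row.end - row.start) if len(ov) else 0.0
        mask &= fracs >= min_fraction
    stringent = calls[mask].reset_index(drop=True)
    return stringent, float(mask.mean())


def profile_eliminated(
    regions: pd.DataFrame,
    track: MethylomeTrack,
    high_cutoff: float = 0.75,
    min_coverage: int = 4,
) -> pd.DataFrame:
    """Per-region mCG summaries plus a genome-background row.

    For each region: coverage-weighted mean mCG, CpG count and the fraction
    of CpGs with methylation above ``high_cutoff``.  The final row
    (``chrom == "__background__"``) summarises all CpGs outside the regions.
    """
    cg = track.filter(context="CG", min_total=min_coverage)
    sites = cg.sites
    m = sites["meth"].to_numpy(float) / sites["total"].to_numpy(float)
    in_any = np.zeros(len(sites), dtype=bool)
    rows = []
    pos_by_chrom = {c: g for c, g in sites.groupby("chrom", sort=False)}
    for row in regions.itertuples(index=False):
        grp = pos_by_chrom.get(row.chrom)
        if grp is None:
            log.warning("region %s:%d-%d has no CpGs; skipped", row.chrom, row.start, row.end)
            continue
        pos = grp["pos"].to_numpy()
        lo, hi = np.searchsorted(pos, [row.start, row.end])
        if hi == lo:
            log.warning("region %s:%d-%d has no CpGs; skipped", row.chrom, row.start, row.end)
            continue
        sel = grp.index.to_numpy()[lo:hi]
        in_any[sites.index.get_indexer(sel)] = True
        mm = m[sites.index.get_indexer(sel)]
        tot = sites.loc[sel, "total"].to_numpy(float)
        meth = sites.loc[sel, "meth"].to_numpy(float)
        rows.append(
            {
                "chrom": row.chrom, "start": row.start, "end": row.end,
                "n_cpg": int(mm.size),
                "mean_mcg": float(meth.sum() / tot.sum()),
                "frac_high": float(np.mean(mm > high_cutoff)),
            }
        )
    bg = ~in_any
    if bg.any():
        rows.append(
            {
                "chrom": "__background__", "start": 0, "end": 0,
                "n_cpg": int(bg.sum()),
                "mean_mcg": float(
                    sites.loc[bg, "meth"].sum() / sites.loc[bg, "total"].sum()
                ),
                "frac_high": float(np.mean(m[bg] > high_cutoff)),
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_cpg", "mean_mcg", "frac_high"]
    )
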