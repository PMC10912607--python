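"""Two-sample differential methylation region (DMR) calling.

Per-CpG differences are assessed with a two-proportion score test on raw
counts while the methylation *difference* is taken from 500 bp
coverage-weighted smoothed levels — the smoothing stabilises the effect
size, the raw-count test keeps the significance calculation honest about
the observed read depth.  Candidate CpGs (p below threshold and an absolute
smoothed difference above ``delta``, consistent in sign) are merged across
gaps of at most ``dis_merge`` bases, and merged regions are kept when they
span at least ``minlen`` bases and ``min_cpg`` CpGs with a mean difference
of at least ``delta``.

Regions are directional: sample-B-higher regions are "gain", lower "loss";
swapping the inputs flips every direction and preserves the intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import MethylomeTrack, ValidationError


@dataclass
class DMRParams:
    delta: float = 0.2            # min methylation difference
    p_threshold: float = 0.05     # per-CpG significance
    minlen: int = 100             # bp
    min_cpg: int = 10
    dis_merge: int = 100          # bp gap merged
    smooth_window: int = 500      # bp, coverage-weighted moving average
    min_coverage: int = 1
    fdr: bool = False             # BH-adjust per-CpG p before thresholding

    def __post_init__(self) -> None:
        if not 0.0 < self.delta < 1.0:
            raise ValidationError("delta must lie in (0, 1)")
        for name in ("p_threshold", "minlen", "min_cpg", "dis_merge", "smooth_window"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


def smooth_track(track: MethylomeTrack, window_bp: int = 500) -> pd.DataFrame:
    """Coverage-weighted smoothed methylation per CpG.

    Each site's smoothed level is Σmeth/Σtotal over all sites within
    ±window/2 bases; an isolated CpG keeps its raw level.
    """
    half = window_bp // 2
    frames = []
    for chrom, grp in track.sites.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        cm = np.concatenate([[0.0], np.cumsum(grp["meth"].to_numpy(float))])
        ct = np.concatenate([[0.0], np.cumsum(grp["total"].to_numpy(float))])
        lo = np.searchsorted(pos, pos - half, side="left")
        hi = np.searchsorted(pos, pos + half, side="right")
        sm = (cm[hi] - cm[lo]) / (ct[hi] - ct[lo])
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos, "smoothed": sm}))
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "smoothed"])
    return pd.concat(frames, ignore_index=True)


def score_test(
    meth_a: np.ndarray, tot_a: np.ndarray, meth_b: np.ndarray, tot_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-proportion score test; returns (z, two-sided p)."""
    ma, na = np.asarray(meth_a, float), np.asarray(tot_a, float)
    mb, nb = np.asarray(meth_b, float), np.asarray(tot_b, float)
    pa, pb = ma / na, mb / nb
    pooled = (ma + mb) / (na + nb)
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / na + 1.0 / nb))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, (pb - pa) / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return z, np.clip(p, np.finfo(float).tiny, 1.0)


def per_cpg_test(
    site_a: tuple[int, int],
    site_b: tuple[int, int],
    smoothed_a: float,
    smoothed_b: float,
) -> tuple[float, float]:
    """Single-site difference and p-value.

    ``site_*`` are (meth, total) count pairs; the difference is taken from
    the smoothed levels (B − A), the p-value from the raw counts.
    """
    ma, na = site_a
    mb, nb = site_b
    if na <= 0 or nb <= 0:
        raise ValidationError("site with zero total must be skipped upstream")
    _, p = score_test(np.array([ma]), np.array([na]), np.array([mb]), np.array([nb]))
    return float(smoothed_b - smoothed_a), float(p[0])


def _aligned_counts(track_a: MethylomeTrack, track_b: MethylomeTrack, min_cov: int):
    a = track_a.filter(context="CG", min_total=min_cov).sites
    b = track_b.filter(context="CG", min_total=min_cov).sites
    merged = a.merge(b, on=["chrom", "pos"], suffixes=("_a", "_b"))
    return merged


def call_dmrs(
    track_a: MethylomeTrack,
    track_b: MethylomeTrack,
    params: DMRParams | None = None,
) -> pd.DataFrame:
    """Call differential regions between two methylomes (direction: B vs A)."""
    params = params or DMRParams()
    sites = _aligned_counts(track_a, track_b, params.min_coverage)
    if sites.empty:
        return _empty_dmrs()
    sm_a = smooth_track(track_a, params.smooth_window).rename(columns={"smoothed": "sm_a"})
    sm_b = smooth_track(track_b, params.smooth_window).rename(columns={"smoothed": "sm_b"})
    sites = sites.merge(sm_a, on=["chrom", "pos"]).merge(sm_b, on=["chrom", "pos"])
    z, p = score_test(
        sites["meth_a"].to_numpy(), sites["total_a"].to_numpy(),
        sites["meth_b"].to_numpy(), sites["total_b"].to_numpy(),
    )
    if params.fdr:
        from statsmodels.stats.multitest import multipletests

        p = multipletests(p, method="fdr_bh")[1]
    diff = sites["sm_b"].to_numpy() - sites["sm_a"].to_numpy()
    candidate = (p < params.p_threshold) & (np.abs(diff) > params.delta)
    rows = []
    for chrom, grp_idx in sites.groupby("chrom", sort=True).indices.items():
        idx = np.asarray(grp_idx)
        cand = idx[candidate[idx]]
        if cand.size == 0:
            continue
        pos = sites["pos"].to_numpy()[cand]
        d = diff[cand]
        zz = z[cand]
        sign = np.sign(d)
        # split whenever the gap exceeds dis_merge or the sign flips
        brk = np.flatnonzero(
            (np.diff(pos) > params.dis_merge) | (sign[1:] != sign[:-1])
        )
        starts = np.concatenate([[0], brk + 1])
        ends = np.concatenate([brk, [cand.size - 1]])
        for a, b in zip(starts, ends):
            n_cpg = b - a + 1
            start, end = int(pos[a]), int(pos[b]) + 2  # include the dyad
            mean_diff = float(np.mean(d[a:b + 1]))
            if n_cpg < params.min_cpg or end - start < params.minlen:
                continue
            if abs(mean_diff) < params.delta:
                continue
            rows.append(
                {
                    "chrom": chrom, "start": start, "end": end, "n_cpg": int(n_cpg),
                    "mean_diff": mean_diff,
                    "direction": "gain" if mean_diff > 0 else "loss",
                    "stat": float(np.sum(zz[a:b + 1])),
                }
            )
    if not rows:
        return _empty_dmrs()
    return pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)


def _empty_dmrs() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["chrom", "start", "end", "n_cpg", "mean_diff", "direction", "stat"]
    )
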