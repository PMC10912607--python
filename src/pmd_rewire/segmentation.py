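"""Four-state methylome segmentation: UMR, LMR, PMD and hyperMR.

Partially methylated domains are detected from a *disorder score*: for a
window of per-CpG methylation levels m_i,

    d = 1 − mean_i |2·m_i − 1|

which is 1 when every site sits at 0.5 (maximally heterogeneous across
molecules) and 0 when every site is fully methylated or fully unmethylated.
A two-state Gaussian HMM over the windowed score separates high-disorder
(PMD) from low-disorder genome, and runs of the high state with enough CpGs
become PMD calls.  Outside PMDs, runs of smoothed methylation below a
hypomethylation cutoff become UMRs (long, promoter-like) or LMRs (short,
enhancer-like); everything else is hyperMR.  PMDs take precedence over
UMR/LMR calls on overlap, and the final segmentation tiles the genome
exactly.

Segment boundaries are placed at the midpoint between the last CpG inside
and the first CpG outside a call (ties toward the lower coordinate), so
segmentations do not depend on coverage in CpG deserts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .core import MethylomeTrack, ValidationError
from .intervals import (
    complement,
    make_intervals,
    merge_intervals,
    total_bases,
    validate_intervals,
)

log = logging.getLogger(__name__)

STATES = ("UMR", "LMR", "PMD", "hyperMR")


@dataclass
class SegmentationParams:
    window: int = 101            # CpGs per disorder window (odd)
    self_transition: float = 0.999
    min_pmd_cpgs: int = 101
    smooth_k: int = 3            # CpGs for UMR/LMR smoothing
    hypo_cutoff: float = 0.5
    umr_min_cpgs: int = 30       # ≥30 CpGs → UMR, 5–29 → LMR
    min_region_cpgs: int = 5
    min_coverage: int = 4        # sites below this are too noisy for m
    hmm_tol: float = 1e-6
    hmm_max_iter: int = 200
    train_chrom: str | None = None  # optionally train the HMM on one chromosome
    # PMD edges are trimmed where a confidently hypomethylated run abuts the
    # boundary; 0.4 is the midpoint between the LMR regime (~0.3) and the
    # intermediate PMD level (~0.5)
    edge_hypo_mean: float = 0.4

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.window < 1:
            raise ValidationError("disorder window must be odd and positive")
        if not 0.0 < self.hypo_cutoff < 1.0:
            raise ValidationError("hypomethylation cutoff must lie in (0, 1)")
        for name in ("min_pmd_cpgs", "smooth_k", "umr_min_cpgs", "min_region_cpgs"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


@dataclass
class Segmentation:
    """Disjoint labelled intervals tiling the genome of one sample."""

    sample_id: str
    segments: pd.DataFrame        # chrom, start, end, state
    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        seg = validate_intervals(self.segments, require_disjoint=True)
        bad = ~seg["state"].isin(STATES)
        if bad.any():
            raise ValidationError(f"unknown state {seg.loc[bad, 'state'].iloc[0]!r}")
        for chrom, size in self.chrom_sizes.items():
            grp = seg[seg["chrom"] == chrom]
            if grp.empty:
                raise ValidationError(f"no segments on {chrom}")
            if grp["start"].iloc[0] != 0 or grp["end"].iloc[-1] != size:
                raise ValidationError(f"segments do not tile {chrom}")
            if np.any(grp["start"].to_numpy()[1:] != grp["end"].to_numpy()[:-1]):
                raise ValidationError(f"gap in segmentation of {chrom}")
        self.segments = seg

    def genome_size(self) -> int:
        return sum(self.chrom_sizes.values())

    def state_intervals(self, state: str) -> pd.DataFrame:
        return self.segments[self.segments["state"] == state][
            ["chrom", "start", "end"]
        ].reset_index(drop=True)

    def state_fractions(self) -> dict[str, float]:
        total = self.genome_size()
        lengths = (self.segments["end"] - self.segments["start"]).groupby(
            self.segments["state"]
        ).sum()
        return {s: float(lengths.get(s, 0)) / total for s in STATES}


# ---------------------------------------------------------------------------
# disorder score
# ---------------------------------------------------------------------------

def disorder_score(m: np.ndarray) -> float:
    """d = 1 − mean|2m−1| over a window of methylation levels."""
    m = np.asarray(m, dtype=float)
    if m.size == 0:
        raise ValidationError("disorder window must be non-empty")
    return float(1.0 - np.mean(np.abs(2.0 * m - 1.0)))


def disorder_profile(m: np.ndarray, window: int) -> np.ndarray:
    """Centred moving disorder score per site (window truncated at the ends)."""
    d = 1.0 - np.abs(2.0 * np.asarray(m, dtype=float) - 1.0)
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(d)])
    n = d.size
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def _best_split(x: np.ndarray) -> int:
    """Index k (1..n−1) minimising the two-segment least-squares split of x."""
    n = x.size
    c1 = np.cumsum(x)
    c2 = np.cumsum(x * x)
    k = np.arange(1, n)
    left = c2[k - 1] - c1[k - 1] ** 2 / k
    right = (c2[-1] - c2[k - 1]) - (c1[-1] - c1[k - 1]) ** 2 / (n - k)
    return int(k[np.argmin(left + right)])


def _refine_run(
    d_raw: np.ndarray, first: int, last: int, lo_limit: int, hi_limit: int, half: int
) -> tuple[int, int]:
    """Re-locate the edges of a decoded PMD run on the raw disorder score.

    The HMM decodes a *windowed* score, which smears each boundary over up
    to half a window of CpGs; the raw per-site score still carries the jump,
    so a least-squares changepoint in a window-sized neighbourhood of each
    decoded edge recovers the sharp boundary.
    """
    centre = (first + last) // 2
    lo = max(first - half, lo_limit)
    hi = min(first + half, centre)
    if hi - lo >= 4:
        first = lo + _best_split(d_raw[lo:hi + 1])
    lo = max(last - half, centre)
    hi = min(last + half, hi_limit)
    if hi - lo >= 4:
        last = lo + _best_split(d_raw[lo:hi + 1]) - 1
    return first, last


def _confident_hypo_runs(
    meth: np.ndarray, total: np.ndarray, params: SegmentationParams
) -> list[tuple[int, int]]:
    """Maximal runs of smoothed m < cutoff with a run mean below edge_hypo_mean.

    These runs mark UMR/LMR-grade hypomethylation, which the disorder score
    cannot tell apart from the intermediate PMD regime at domain edges.
    """
    sm = _smooth_counts(meth, total, params.smooth_k)
    hypo = sm < params.hypo_cutoff
    padded = np.concatenate([[False], hypo, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:]) - 1
    runs = []
    for a, b in zip(starts, ends):
        if b - a + 1 < params.min_region_cpgs:
            continue
        if meth[a:b + 1].sum() / total[a:b + 1].sum() < params.edge_hypo_mean:
            runs.append((int(a), int(b)))
    return runs


def _trim_by_hypo_runs(
    first: int, last: int, runs: list[tuple[int, int]], half: int
) -> tuple[int, int]:
    """Shrink a PMD run whose edge zone is claimed by a hypomethylated run.

    Single pass, edge zone a quarter window deep: only runs overlapping the
    decode's boundary-smear region trim the domain, so occasional spurious
    hypomethylated stretches inside a genuine PMD are left alone.
    """
    zone = max(half // 2, 1)
    for a, b in runs:
        if b < first or a > last:
            continue
        if a <= first + zone and b < last:
            first = max(first, b + 1)
        elif b >= last - zone and a > first:
            last = min(last, a - 1)
    return first, last


def _midpoint_boundaries(
    pos: np.ndarray, first: int, last: int, chrom_len: int
) -> tuple[int, int]:
    """Segment edges between a CpG run [first, last] and its flanking CpGs."""
    start = 0 if first == 0 else (pos[first - 1] + pos[first]) // 2
    end = chrom_len if last == pos.size - 1 else (pos[last] + pos[last + 1]) // 2
    return int(start), int(end)


# ---------------------------------------------------------------------------
# PMD calling
# ---------------------------------------------------------------------------

def _fit_disorder_hmm(obs_per_chrom: dict[str, np.ndarray], params: SegmentationParams):
    from hmmlearn.hmm import GaussianHMM

    if params.train_chrom is not None:
        train = {params.train_chrom: obs_per_chrom[params.train_chrom]}
    else:
        train = obs_per_chrom
    X = np.concatenate([v for v in train.values()])[:, None]
    lengths = [v.size for v in train.values()]
    # Variances are tied and held fixed (equal-variance emissions): with a
    # shared variance the decode boundary sits at the midpoint of the state
    # means, so segment edges are not dragged toward the tighter state.
    model = GaussianHMM(
        n_components=2,
        covariance_type="diag",
        init_params="",
        params="stm",
        n_iter=params.hmm_max_iter,
        tol=params.hmm_tol,
    )
    lo, hi = np.percentile(X, [25, 75])
    if hi - lo < 1e-6:
        return None
    model.startprob_ = np.array([0.5, 0.5])
    st = params.self_transition
    model.transmat_ = np.array([[st, 1 - st], [1 - st, st]])
    model.means_ = np.array([[lo], [hi]])
    # pooled within-state variance by hard assignment to the nearer centre
    assign_hi = np.abs(X - hi) < np.abs(X - lo)
    var = float(
        (np.var(X[~assign_hi]) * (~assign_hi).sum() + np.var(X[assign_hi]) * assign_hi.sum())
        / X.size
    )
    var = max(var, 1e-4)
    model.covars_ = np.array([[var], [var]])
    model.fit(X, lengths)
    return model


def call_pmds(track: MethylomeTrack, params: SegmentationParams | None = None) -> pd.DataFrame:
    """Call partially methylated domains from the windowed disorder score."""
    params = params or SegmentationParams()
    cg = track.filter(context="CG", min_total=params.min_coverage)
    obs: dict[str, np.ndarray] = {}
    raw_d: dict[str, np.ndarray] = {}
    hypo_runs: dict[str, list[tuple[int, int]]] = {}
    pos_by_chrom: dict[str, np.ndarray] = {}
    for chrom, grp in cg.sites.groupby("chrom", sort=True):
        m = grp["meth"].to_numpy(float) / grp["total"].to_numpy(float)
        if m.size < params.window:
            log.warning("%s: only %d covered CpGs (< window %d); labelled non-PMD",
                        chrom, m.size, params.window)
            continue
        obs[chrom] = disorder_profile(m, params.window)
        raw_d[chrom] = 1.0 - np.abs(2.0 * m - 1.0)
        pos_by_chrom[chrom] = grp["pos"].to_numpy()
        hypo_runs[chrom] = _confident_hypo_runs(
            grp["meth"].to_numpy(float), grp["total"].to_numpy(float), params
        )
    if not obs:
        return make_intervals([])
    model = _fit_disorder_hmm(obs, params)
    rows = []
    for chrom, o in obs.items():
        if model is not None:
            states = model.predict(o[:, None])
            high = int(np.argmax(model.means_.ravel()))
            is_pmd = states == high
            if is_pmd.all() or (~is_pmd).all():
                # check the degenerate single-state decode against the score scale
                mean_d = float(np.mean(o))
                if is_pmd.all() and mean_d < 0.5:
                    log.warning("%s: degenerate HMM decode; threshold fallback", chrom)
                    is_pmd = o > 0.5
                elif (~is_pmd).all() and mean_d > 0.5:
                    log.warning("%s: degenerate HMM decode; threshold fallback", chrom)
                    is_pmd = o > 0.5
        else:
            log.warning("disorder distribution degenerate; threshold fallback")
            is_pmd = o > 0.5
        pos = pos_by_chrom[chrom]
        chrom_len = track.chrom_sizes.get(chrom, int(pos[-1]) + 2)
        # maximal runs of the PMD state
        padded = np.concatenate([[False], is_pmd, [False]])
        starts = np.flatnonzero(~padded[:-1] & padded[1:])
        ends = np.flatnonzero(padded[:-1] & ~padded[1:]) - 1
        half = params.window // 2
        d = raw_d[chrom]
        for i, (first, last) in enumerate(zip(starts, ends)):
            lo_limit = int(ends[i - 1]) + 1 if i > 0 else 0
            hi_limit = int(starts[i + 1]) - 1 if i + 1 < starts.size else d.size - 1
            first, last = _refine_run(d, int(first), int(last), lo_limit, hi_limit, half)
            first, last = _trim_by_hypo_runs(first, last, hypo_runs[chrom], half)
            if last - first + 1 < params.min_pmd_cpgs:
                continue
            s, e = _midpoint_boundaries(pos, first, last, chrom_len)
            rows.append((chrom, s, e))
    return make_intervals(rows) if rows else make_intervals([])


# ---------------------------------------------------------------------------
# UMR / LMR calling
# ---------------------------------------------------------------------------

def _smooth_counts(meth: np.ndarray, total: np.ndarray, k: int) -> np.ndarray:
    """Coverage-weighted moving methylation over k consecutive CpGs."""
    half = k // 2
    n = meth.size
    cm = np.concatenate([[0.0], np.cumsum(meth)])
    ct = np.concatenate([[0.0], np.cumsum(total)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (cm[hi] - cm[lo]) / (ct[hi] - ct[lo])


def call_umr_lmr(
    track: MethylomeTrack,
    pmds: pd.DataFrame,
    params: SegmentationParams | None = None,
) -> pd.DataFrame:
    """Call UMRs and LMRs outside PMDs from smoothed methylation levels."""
    params = params or SegmentationParams()
    cg = track.filter(context="CG", min_total=params.min_coverage)
    pmds = merge_intervals(pmds) if not pmds.empty else pmds
    rows = []
    for chrom, grp in cg.sites.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        meth = grp["meth"].to_numpy(float)
        total = grp["total"].to_numpy(float)
        chrom_len = track.chrom_sizes.get(chrom, int(pos[-1]) + 2)
        # compartment index: sites between consecutive PMDs share an index
        if pmds.empty or chrom not in set(pmds["chrom"]):
            compartment = np.zeros(pos.size, dtype=int)
            outside = np.ones(pos.size, dtype=bool)
        else:
            gp = pmds[pmds["chrom"] == chrom]
            starts = gp["start"].to_numpy()
            ends = gp["end"].to_numpy()
            compartment = np.searchsorted(ends, pos, side="right")
            inside = (compartment < starts.size) & (
                pos >= starts[np.minimum(compartment, starts.size - 1)]
            )
            outside = ~inside
        for comp in np.unique(compartment[outside]):
            sel = np.flatnonzero(outside & (compartment == comp))
            if sel.size < params.min_region_cpgs:
                continue
            sm = _smooth_counts(meth[sel], total[sel], params.smooth_k)
            hypo = sm < params.hypo_cutoff
            padded = np.concatenate([[False], hypo, [False]])
            run_s = np.flatnonzero(~padded[:-1] & padded[1:])
            run_e = np.flatnonzero(padded[:-1] & ~padded[1:]) - 1
            for a, b in zip(run_s, run_e):
                n_cpg = b - a + 1
                if n_cpg < params.min_region_cpgs:
                    continue
                label = "UMR" if n_cpg >= params.umr_min_cpgs else "LMR"
                first, last = int(sel[a]), int(sel[b])
                s, e = _midpoint_boundaries(pos, first, last, chrom_len)
                rows.append((chrom, s, e, label))
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end", "state"])
    return validate_intervals(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
    )


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assemble_segmentation(
    pmds: pd.DataFrame,
    umr_lmr: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    sample_id: str = "sample",
) -> Segmentation:
    """Combine calls into a full four-state tiling.

    Bases where a UMR/LMR overlaps a PMD are counted as PMD; all bases not
    covered by any call become hyperMR.  The result tiles the genome exactly.
    """
    chrom_sizes = dict(chrom_sizes)
    for df in (pmds, umr_lmr):
        if df is None or df.empty:
            continue
        for row in df.itertuples(index=False):
            size = chrom_sizes.get(row.chrom)
            if size is None or row.end > size:
                raise ValidationError(
                    f"call {row.chrom}:{row.start}-{row.end} exceeds chromosome bounds"
                )
    pmds = merge_intervals(pmds) if pmds is not None and not pmds.empty else make_intervals([])
    rows: list[tuple] = [
        (r.chrom, r.start, r.end, "PMD") for r in pmds.itertuples(index=False)
    ]
    if umr_lmr is not None and not umr_lmr.empty:
        pmd_by_chrom = {c: g for c, g in pmds.groupby("chrom", sort=False)}
        for row in umr_lmr.itertuples(index=False):
            pieces = [(row.start, row.end)]
            gp = pmd_by_chrom.get(row.chrom)
            if gp is not None:
                for p in gp.itertuples(index=False):
                    nxt = []
                    for s, e in pieces:
                        if p.end <= s or p.start >= e:
                            nxt.append((s, e))
                            continue
                        if s < p.start:
                            nxt.append((s, p.start))
                        if p.end < e:
                            nxt.append((p.end, e))
                    pieces = nxt
            for s, e in pieces:
                rows.append((row.chrom, s, e, row.state))
    called = validate_intervals(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
    ) if rows else pd.DataFrame(columns=["chrom", "start", "end", "state"])
    gaps = complement(called[["chrom", "start", "end"]] if len(called) else make_intervals([]),
                      chrom_sizes)
    hyper = gaps.assign(state="hyperMR")
    full = pd.concat([called, hyper], ignore_index=True) if len(called) else hyper
    full = validate_intervals(full)
    seg = Segmentation(sample_id, full, chrom_sizes)
    assert total_bases(seg.segments) == seg.genome_size()
    return seg


def segment_methylome(
    track: MethylomeTrack,
    params: SegmentationParams | None = None,
    chrom_sizes: Mapping[str, int] | None = None,
    exclude_chroms: tuple[str, ...] = ("chrM", "chrL"),
) -> Segmentation:
    """End-to-end segmentation of one methylome (PMDs → UMR/LMR → assembly)."""
    params = params or SegmentationParams()
    sizes = dict(chrom_sizes or track.chrom_sizes)
    for c in exclude_chroms:
        sizes.pop(c, None)
    nuc = track.filter(context=None, exclude_chroms=exclude_chroms)
    # chromosomes without a declared length extend to just past the last dyad
    for chrom, grp in nuc.sites.groupby("chrom", sort=False):
        sizes.setdefault(str(chrom), int(grp["pos"].max()) + 2)
    nuc = MethylomeTrack(track.sample_id, nuc.sites, sizes)
    pmds = call_pmds(nuc, params)
    umr_lmr = call_umr_lmr(nuc, pmds, params)
    return assemble_segmentation(pmds, umr_lmr, sizes, sample_id=track.sample_id)
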