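"""Pairwise segmentation comparison: PMD overlap and state-transition accounting.

The central object is the 4×4 base-count matrix between two genome tilings:
cell (sA, sB) holds the number of bases labelled sA in the first sample and
sB in the second.  Fractions use the total assembled genome length as the
denominator, so "29% of the genome altered" means 29% of all assembled
bases changed PMD status.  PMD gain collects UMR/LMR/hyperMR→PMD cells;
PMD loss the reverse.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError
from .intervals import overlap_fraction
from .segmentation import STATES, Segmentation


@dataclass
class TransitionSummary:
    """Base-level accounting of state changes between an ordered sample pair."""

    sample_a: str
    sample_b: str
    counts: pd.DataFrame      # 4×4 integer bases, rows = state in A
    genome_size: int

    def __post_init__(self) -> None:
        if int(self.counts.to_numpy().sum()) != self.genome_size:
            raise ValidationError("transition counts do not sum to genome size")

    def fractions(self) -> pd.DataFrame:
        return self.counts / self.genome_size

    def altered_pmd_fraction(self) -> float:
        """Fraction of genome where exactly one side is PMD."""
        f = self.fractions()
        gain = f.loc[[s for s in STATES if s != "PMD"], "PMD"].sum()
        loss = f.loc["PMD", [s for s in STATES if s != "PMD"]].sum()
        return float(gain + loss)

    def pmd_gain_fraction(self) -> float:
        f = self.fractions()
        return float(f.loc[[s for s in STATES if s != "PMD"], "PMD"].sum())

    def pmd_loss_fraction(self) -> float:
        f = self.fractions()
        return float(f.loc["PMD", [s for s in STATES if s != "PMD"]].sum())


def transition_matrix(seg_a: Segmentation, seg_b: Segmentation) -> TransitionSummary:
    """Exact base-level 4×4 transition counts between two tilings."""
    if seg_a.chrom_sizes != seg_b.chrom_sizes:
        raise ValidationError("segmentations are on different genomes")
    idx = {s: i for i, s in enumerate(STATES)}
    counts = np.zeros((4, 4), dtype=np.int64)
    for chrom, size in seg_a.chrom_sizes.items():
        ga = seg_a.segments[seg_a.segments["chrom"] == chrom]
        gb = seg_b.segments[seg_b.segments["chrom"] == chrom]
        ea = ga["end"].to_numpy()
        eb = gb["end"].to_numpy()
        sa = np.array([idx[s] for s in ga["state"]])
        sb = np.array([idx[s] for s in gb["state"]])
        # sweep over the union of breakpoints
        bounds = np.unique(np.concatenate([[0], ea, eb]))
        seg_len = np.diff(bounds)
        mid = bounds[:-1]
        ia = np.searchsorted(ea, mid, side="right")
        ib = np.searchsorted(eb, mid, side="right")
        np.add.at(counts, (sa[ia], sb[ib]), seg_len)
    df = pd.DataFrame(counts, index=list(STATES), columns=list(STATES))
    return TransitionSummary(seg_a.sample_id, seg_b.sample_id, df, seg_a.genome_size())


def pairwise_pmd_overlap(
    segmentations: Sequence[Segmentation],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Asymmetric PMD overlap fractions and their Spearman correlation.

    Cell (i, j) of the fraction matrix is |PMD_i ∩ PMD_j| / |PMD_i|; the
    correlation matrix is the Spearman correlation between columns of the
    fraction matrix.  A sample without PMD bases yields an undefined (NaN)
    row.
    """
    if len(segmentations) < 2:
        raise ValidationError("need at least two segmentations")
    names = [s.sample_id for s in segmentations]
    pmds = [s.state_intervals("PMD") for s in segmentations]
    n = len(names)
    frac = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            frac[i, j] = 1.0 if i == j and len(pmds[i]) else overlap_fraction(
                pmds[i], pmds[j]
            )
    frac_df = pd.DataFrame(frac, index=names, columns=names)
    corr = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            xi, xj = frac[:, i], frac[:, j]
            ok = ~(np.isnan(xi) | np.isnan(xj))
            if ok.sum() < 2:
                continue
            if i == j or np.allclose(xi[ok], xj[ok]):
                corr[i, j] = 1.0  # identical profiles (possibly constant)
            else:
                corr[i, j] = stats.spearmanr(xi[ok], xj[ok]).statistic
    return frac_df, pd.DataFrame(corr, index=names, columns=names)


def transition_report(summaries: Sequence[TransitionSummary]) -> pd.DataFrame:
    """Per-pair altered/gain/loss rollup plus the cross-pair mean.

    PMD gain decomposes into UMR→PMD, hyperMR→PMD and LMR→PMD; PMD loss is
    PMD→ any non-PMD state.  All values are genome fractions.
    """
    if not summaries:
        raise ValidationError("no summaries to report")
    sizes = {s.genome_size for s in summaries}
    if len(sizes) != 1:
        raise ValidationError("summaries use different genome sizes")
    rows = []
    for s in summaries:
        f = s.fractions()
        rows.append(
            {
                "pair": f"{s.sample_a}/{s.sample_b}",
                "altered": s.altered_pmd_fraction(),
                "pmd_gain": s.pmd_gain_fraction(),
                "pmd_loss": s.pmd_loss_fraction(),
                "umr_to_pmd": float(f.loc["UMR", "PMD"]),
                "hypermr_to_pmd": float(f.loc["hyperMR", "PMD"]),
                "lmr_to_pmd": float(f.loc["LMR", "PMD"]),
                "pmd_to_umr": float(f.loc["PMD", "UMR"]),
            }
        )
    report = pd.DataFrame(rows)
    mean = report.drop(columns="pair").mean()
    mean["pair"] = "mean"
    return pd.concat([report, mean.to_frame().T], ignore_index=True)[report.columns]


def grouped_correlation_split(corr: pd.DataFrame, groups: dict[str, Sequence[str]]) -> bool:
    """Do within-group correlations exceed every between-group correlation?

    A lightweight check that correlation structure separates planted sample
    groups (the clustering heatmap's substance without the rendering).
    """
    names = list(corr.index)
    label = {}
    for g, members in groups.items():
        for m in members:
            label[m] = g
    within, between = [], []
    for a, b in combinations(names, 2):
        (within if label[a] == label[b] else between).append(float(corr.loc[a, b]))
    if not within or not between:
        raise ValidationError("need both within- and between-group pairs")
    return min(within) > max(between)
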