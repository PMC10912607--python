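"""Global and regional methylation statistics, NMI set algebra, sequence
composition and methylation–expression correlation.

Global levels are coverage-weighted (Σmeth/Σtotal), never site-averaged.
Non-methylated islands (NMIs, the experimentally identified analogue of CpG
islands) are handled as interval sets: the *core* set is the base-level
intersection across all tissues, and differential NMIs come from a
normalised two-group count test with Benjamini–Hochberg adjustment
(FDR < 0.05) plus a fold-change cutoff (> 2).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import MethylomeTrack, ValidationError
from .intervals import multi_intersect, points_covered, validate_intervals

log = logging.getLogger(__name__)

SPIKE_CHROM = "chrL"
MITO_CHROM = "chrM"


# ---------------------------------------------------------------------------
# global levels
# ---------------------------------------------------------------------------

def global_levels(
    track: MethylomeTrack,
    context: str = "CG",
    min_coverage: int = 1,
    chroms: Sequence[str] | None = None,
    exclude_chroms: Sequence[str] = (SPIKE_CHROM,),
) -> float:
    """Coverage-weighted mean methylation for a context over selected chromosomes.

    ``context`` may be CG, CH (= CA/CC/CT jointly) or a single CH subtype.
    Returns NaN when no site qualifies.
    """
    sub = track.filter(
        context=context, min_total=min_coverage, chroms=chroms,
        exclude_chroms=exclude_chroms,
    )
    total = int(sub.sites["total"].sum())
    if total == 0:
        return float("nan")
    return float(sub.sites["meth"].sum()) / total


def methylation_histogram(
    track: MethylomeTrack,
    context: str = "CG",
    min_coverage: int = 10,
    bin_width: float = 0.05,
    exclude_chroms: Sequence[str] = (SPIKE_CHROM, MITO_CHROM),
) -> pd.DataFrame:
    """Per-CpG methylation-level histogram with fixed bins.

    Low-coverage sites are excluded (per-site levels below ~10 reads are too
    granular for density comparisons); counts sum to the filtered site count.
    """
    sub = track.filter(context=context, min_total=min_coverage,
                       exclude_chroms=exclude_chroms)
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    m = sub.m()
    counts, _ = np.histogram(m, bins=edges)
    # a site at exactly 1.0 belongs in the last bin (numpy already does this)
    return pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts}
    )


def conversion_efficiency(track: MethylomeTrack, spike_chrom: str = SPIKE_CHROM) -> float:
    """Bisulfite conversion efficiency from the unmethylated spike-in contig.

    efficiency = 1 − Σmeth/Σtotal over all cytosine contexts on the spike-in.
    """
    sub = track.filter(context=None, chroms=[spike_chrom])
    total = int(sub.sites["total"].sum())
    if total == 0:
        raise ValidationError(f"spike-in contig {spike_chrom!r} absent or uncovered")
    return 1.0 - float(sub.sites["meth"].sum()) / total


# ---------------------------------------------------------------------------
# NMI set algebra
# ---------------------------------------------------------------------------

def core_nmis(tissue_sets: Mapping[str, pd.DataFrame] | Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Maximal intervals present (base-level) in every tissue's NMI set."""
    sets = list(tissue_sets.values()) if isinstance(tissue_sets, Mapping) else list(tissue_sets)
    if len(sets) < 2:
        raise ValidationError("core NMIs need at least two tissue sets")
    return multi_intersect([s[["chrom", "start", "end"]] for s in sets])


def median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Library size factors (median-of-ratios against the geometric mean row)."""
    arr = counts.to_numpy(float)
    logs = np.log(np.where(arr > 0, arr, np.nan))
    ref = np.nanmean(logs, axis=1)
    usable = np.isfinite(ref)
    if not usable.any():
        raise ValidationError("no interval with counts in every library")
    ratios = logs[usable] - ref[usable, None]
    return pd.Series(np.exp(np.nanmedian(ratios, axis=0)), index=counts.columns)


def differential_nmis(
    counts: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    fdr: float = 0.05,
    min_fold: float = 2.0,
) -> pd.DataFrame:
    """Two-group differential enrichment over a merged NMI count matrix.

    ``counts`` carries chrom/start/end plus one column per library.  Counts
    are normalised with median-of-ratios size factors; per interval the
    normalised group sums are compared with a binomial test (a count-split
    test under the per-group totals), p-values are BH-adjusted and intervals
    pass at adjusted p < ``fdr`` with a normalised-mean fold change above
    ``min_fold``.  Direction "A" means enriched in group A.
    """
    if not len(group_a) or not len(group_b):
        raise ValidationError("both groups need at least one library")
    libs = list(group_a) + list(group_b)
    mat = counts[libs]
    sf = median_of_ratios(mat)
    norm = mat / sf
    mean_a = norm[list(group_a)].mean(axis=1).to_numpy()
    mean_b = norm[list(group_b)].mean(axis=1).to_numpy()
    sum_a = norm[list(group_a)].sum(axis=1).round().astype(int).to_numpy()
    sum_b = norm[list(group_b)].sum(axis=1).round().astype(int).to_numpy()
    n = sum_a + sum_b
    expected = len(group_a) / (len(group_a) + len(group_b))
    pvals = np.array([
        stats.binomtest(int(a), int(t), expected).pvalue if t > 0 else 1.0
        for a, t in zip(sum_a, n)
    ])
    from statsmodels.stats.multitest import multipletests

    padj = multipletests(pvals, method="fdr_bh")[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(mean_b > 0, mean_a / mean_b, np.inf)
        fold = np.where(mean_a == 0, 0.0, fold)
    big = np.maximum(fold, np.where(fold > 0, 1.0 / fold, np.inf))
    hits = (padj < fdr) & (big > min_fold)
    out = counts.loc[hits, ["chrom", "start", "end"]].copy()
    out["fold_change"] = fold[hits]
    out["padj"] = padj[hits]
    out["direction"] = np.where(fold[hits] > 1, "A", "B")
    return out.reset_index(drop=True)


def tss_overlap(tss: pd.DataFrame, nmis: pd.DataFrame) -> float:
    """Percentage of TSS (points or 1-bp intervals) overlapped ≥1 bp by NMIs."""
    tss = validate_intervals(tss)
    if tss.empty:
        return float("nan")
    if nmis.empty:
        return 0.0
    covered = points_covered(tss[["chrom", "start", "end"]], nmis)
    return 100.0 * float(np.mean(covered))


# ---------------------------------------------------------------------------
# sequence composition
# ---------------------------------------------------------------------------

def sequence_composition(intervals: pd.DataFrame, fasta) -> pd.DataFrame:
    """Per-interval GC content and CpG observed/expected.

    GC = (N_G + N_C) / L and O/E = N_CpG · L / (N_C · N_G), with Ns excluded
    from L; O/E is NaN when the sequence lacks C or G.  ``fasta`` is any
    mapping from contig name to indexable sequence (e.g. pyfaidx.Fasta).
    """
    rows = []
    for row in validate_intervals(intervals).itertuples(index=False):
        try:
            seq = str(fasta[row.chrom][row.start:row.end]).upper()
        except (KeyError, IndexError):
            raise ValidationError(f"interval beyond contig {row.chrom}") from None
        if len(seq) < row.end - row.start:
            raise ValidationError(f"interval beyond contig {row.chrom}")
        n_c = seq.count("C")
        n_g = seq.count("G")
        n_cpg = seq.count("CG")
        length = len(seq) - seq.count("N")
        gc = (n_c + n_g) / length if length else float("nan")
        oe = n_cpg * length / (n_c * n_g) if n_c and n_g else float("nan")
        rows.append(
            {"chrom": row.chrom, "start": row.start, "end": row.end,
             "gc": gc, "cpg_oe": oe}
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gc", "cpg_oe"])


# ---------------------------------------------------------------------------
# methylation vs expression
# ---------------------------------------------------------------------------

def promoter_methylation_expression(
    track: MethylomeTrack,
    tss: pd.DataFrame,
    nmis: pd.DataFrame,
    expression: pd.DataFrame,
    flank: int = 1_000,
    log_scale: bool = True,
    min_coverage: int = 1,
) -> tuple[pd.DataFrame, float]:
    """Promoter mCG vs expression for genes whose TSS overlaps an NMI.

    Promoters are TSS ± ``flank``; promoter mCG is coverage-weighted over
    contained CpGs; expression is log10(TPM+1) unless ``log_scale`` is off.
    Returns the per-gene table and the Pearson r (NaN if degenerate, e.g.
    constant methylation).
    """
    tss = validate_intervals(tss)
    if "name" not in tss.columns:
        raise ValidationError("TSS set needs a gene name column")
    covered = points_covered(tss[["chrom", "start", "end"]], nmis) if not nmis.empty \
        else np.zeros(len(tss), bool)
    qualifying = tss[covered]
    expr = expression.set_index("gene")["tpm"]
    cg = track.filter(context="CG", min_total=min_coverage)
    cum = {}
    for chrom, grp in cg.sites.groupby("chrom", sort=False):
        cum[chrom] = (
            grp["pos"].to_numpy(),
            np.concatenate([[0.0], np.cumsum(grp["meth"].to_numpy(float))]),
            np.concatenate([[0.0], np.cumsum(grp["total"].to_numpy(float))]),
        )
    rows = []
    for row in qualifying.itertuples(index=False):
        if row.name not in expr.index:
            continue
        if row.chrom not in cum:
            continue
        pos, cm, ct = cum[row.chrom]
        lo, hi = np.searchsorted(pos, [row.start - flank, row.start + flank + 1])
        tot = ct[hi] - ct[lo]
        if tot <= 0:
            continue
        m = (cm[hi] - cm[lo]) / tot
        tpm = float(expr.loc[row.name])
        e = np.log10(tpm + 1.0) if log_scale else tpm
        rows.append({"gene": row.name, "promoter_mcg": m, "expression": e})
    table = pd.DataFrame(rows, columns=["gene", "promoter_mcg", "expression"])
    if table.empty:
        raise ValidationError("no qualifying genes (NMI-overlapping TSS with data)")
    if table["promoter_mcg"].nunique() < 2 or table["expression"].nunique() < 2:
        log.warning("degenerate methylation or expression values; r undefined")
        return table, float("nan")
    r = float(stats.pearsonr(table["promoter_mcg"], table["expression"]).statistic)
    return table, r
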