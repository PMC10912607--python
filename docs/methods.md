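# Methods

## The problem

Early lamprey development involves a maternal-to-paternal methylome
transition: large genomic blocks switch between an intermediate,
molecule-heterogeneous methylation regime (partially methylated domains,
PMDs) and the discrete regimes around them — unmethylated regions (UMRs,
large and promoter-like), lowly methylated regions (LMRs, short and
enhancer-like) and hypermethylated regions (hyperMRs). Alongside this,
programmed genome rearrangement (PGR) physically removes germline-restricted
DNA from somatic lineages, and those sequences carry high methylation in
sperm before elimination. This package implements the analysis layer for
those observations: a four-state methylome segmentation, base-exact
transition accounting between segmentations, a read-level discordance
statistic (PDR), a two-sample DMR caller, a coverage-ratio caller for
eliminated sequences, non-methylated-island (NMI) set algebra, and global
methylation/QC statistics — together with a synthetic WGBS generator that
provides planted ground truth for every stage.

## Four-state segmentation

Per-CpG methylation is m = meth/total on dyad-merged counts; sites with
fewer than 4 reads are excluded from m (levels below 4 reads are too coarse
for a statistic centred on 0.5). The **disorder score** of a window of
levels is

    d = 1 − mean_i |2·m_i − 1|,

1 when every site sits at 0.5 and 0 when every site is 0 or 1. Each covered
CpG gets the score of its centred 101-CpG window; a two-state Gaussian HMM
over this profile separates high-disorder (PMD) from low-disorder genome.

HMM numerics: state means initialise at the 25th/75th percentiles of the
observations; the emission variances are *tied and fixed* at the pooled
within-state variance (hard assignment to the nearer percentile mean);
Baum-Welch updates start, transition and mean parameters to tolerance 1e-6
(max 200 iterations) and Viterbi decodes. Tying the variances is essential,
not cosmetic: with free variances the PMD state learns a far tighter
emission than the heterogeneous non-PMD state, which moves the decode
boundary deep into each domain; with a shared variance the boundary sits at
the midpoint of the state means. If the disorder distribution is degenerate
(no spread between percentiles) the caller falls back to a d > 0.5
threshold rule, logged.

Decoded high-state runs are post-processed in two steps before the ≥101-CpG
filter:

1. **Changepoint refinement.** The windowed score smears each boundary over
   up to half a window of CpGs. Each decoded edge is re-located by a
   two-segment least-squares changepoint on the *raw* per-site disorder
   score in a window-sized neighbourhood of the edge.
2. **Hypomethylated-edge trim.** The disorder score cannot separate an LMR
   (raw d ≈ 0.58 at its 0.3 methylation level) from PMD (≈ 0.79), so a
   hypomethylated element abutting a domain is otherwise absorbed into it.
   Runs of smoothed methylation below the 0.5 cutoff with a raw run mean
   below 0.4 (the midpoint between the LMR and PMD levels) that claim a
   domain's edge zone (a quarter window deep) trim the domain. The trim is
   single-pass so occasional spurious dips inside a genuine PMD cannot
   cascade.

Outside PMDs, methylation is smoothed over 3 consecutive CpGs
(coverage-weighted); maximal runs of smoothed m < 0.5 with at least 5 CpGs
become UMRs (≥ 30 CpGs) or LMRs (5–29 CpGs). Segment edges always sit at
the midpoint between the last CpG inside and the first outside (ties toward
the lower coordinate), so segmentations do not depend on coverage in CpG
deserts. Assembly applies PMD precedence — bases of a UMR/LMR overlapping a
PMD count as PMD — and labels all remaining bases hyperMR; the output tiles
the genome exactly (asserted).

This segmentation is a fully specified stand-in for MethylSeekR's
PMD/UMR/LMR machinery: the disorder score replaces the alpha statistic
(both measure intermediate-methylation enrichment) and no FDR-calibrated
cutoff selection or CpG-island masking is attempted. Outputs are therefore
not numerically identical to MethylSeekR's.

## Transition accounting

Two segmentations of the same genome yield an exact 4×4 base-count matrix
by sweeping the union of their breakpoints; fractions use the total
assembled genome length as denominator. The altered-PMD fraction sums the
cells where exactly one side is PMD; PMD gain decomposes into
UMR/LMR/hyperMR→PMD and PMD loss into the reverse. PMD overlap between many
samples uses the asymmetric fraction |PMD_i ∩ PMD_j| / |PMD_i| with
Spearman correlation over the fraction-matrix columns; identical profiles
(including the all-ones diagonal case) are defined as correlation 1.

## Read-level discordance (PDR)

A read qualifies with ≥ 4 CpG calls; it is discordant when it carries both
methylated and unmethylated calls. A region's PDR is the discordant
fraction of qualifying reads overlapping it by at least one call position
(reads spanning two regions count in both); discordance always uses all
calls on the read. Regions with fewer than 10 qualifying reads are reported
missing — the threshold is a package choice exposed in `PDRParams`. Under
the PMD molecule mixture (discordant fraction π, within-molecule Bernoulli
q), a read with c calls is discordant with probability
π·(1 − q^c − (1−q)^c); the generator's defaults (π = 0.6, q = 0.5, ρ = 0.5)
give 4-CpG reads an expected PDR of 0.525 and a PMD mean mCG of 0.5.

## DMR calling

Per CpG shared by both samples, a two-proportion score test runs on the raw
counts while the effect size is the difference of 500 bp coverage-weighted
smoothed levels. Candidates (p < 0.05 and |smoothed difference| > 0.2) with
consistent sign merge across gaps ≤ 100 bp; regions survive at ≥ 100 bp,
≥ 10 CpGs and |mean difference| ≥ 0.2. These region parameters match the
DSS parameterisation standard for two-sample WGBS comparisons
(delta, p.threshold, minlen, minCG, dis.merge); the per-CpG test replaces a beta-binomial
shrinkage model because with merged replicates there is no within-group
dispersion to estimate. P-values are unadjusted by default (`fdr=True`
switches to BH). Swapping samples flips every direction and preserves
intervals.

## Eliminated-sequence detection

Binned depth (default 1 kb) is median-normalised per sample, making calls
invariant to uniform rescaling. Bins with somatic depth ≤ 0.1 (tolerating
stray misaligned reads rather than demanding literal zero) *and* germline
depth ≥ 0.5 (excluding assembly gaps) are marked; runs merge across ≤ 1
unmarked bin and must span ≥ 3 bins. Calls intersect a reference set by the
≥ 1 bp rule (a minimum-fraction flag exists); per-region methylation
profiling reports the coverage-weighted mean mCG and the fraction of CpGs
above 0.75, with a genome-background row.

## NMI and global statistics

Core NMIs are the base-level intersection across all tissue sets.
Differential NMIs: counts are normalised by median-of-ratios size factors;
per interval the normalised group sums are compared with a two-sided
binomial count-split test, BH-adjusted (FDR < 0.05) with a fold change > 2
on normalised means. Global levels are Σmeth/Σtotal (coverage-weighted) per
context; conversion efficiency is 1 − that level on the unmethylated
spike-in contig over all cytosine contexts; the per-CpG histogram uses 0.05
bins with a ≥ 10-read filter. Sequence composition: GC = (N_G+N_C)/L and
CpG O/E = N_CpG·L/(N_C·N_G) with Ns excluded from L. The
methylation–expression analysis takes genes whose TSS overlaps an NMI,
computes promoter (TSS ± 1 kb) coverage-weighted mCG, and correlates it
with log10(TPM+1) (raw scale by flag).

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, with
all randomness from seeded streams (a fixed seed is byte-reproducible):

- **Genome.** Chromosomes with CpG dyads at geometric spacing (density
  0.01 ≈ one dyad per 100 bp), plus a 16 kb mitochondrial contig
  (methylation 0.005, matching the sub-1% mitochondrial regime) and a 48 kb
  spike-in contig whose apparent methylation is the conversion-failure rate
  ε = 0.002. The spike-in is CpG-dense (0.14) so it yields ~1e5 calls at
  default coverage, the scale at which ε is recoverable to ±0.001. FASTA
  output carries CG exactly at the planted dyads and nowhere else.
- **State tiling.** Blocks drawn per state — PMD 25–70 kb, hyperMR 1–4 kb,
  UMR 6–11 kb, LMR 1–2.4 kb — interleaved so two hypomethylated blocks are
  never adjacent (a methylated spacer always separates regulatory elements,
  as a run-based caller requires to resolve them), then rescaled within each
  state so planted genome fractions match their targets exactly. Default
  fractions 0.4 PMD / 0.2 UMR / 0.1 LMR / 0.3 hyperMR.
- **Reads.** Molecules are runs of consecutive CpG calls, count truncated
  geometric (mean 5, max 50) — base-pair fragment structure is irrelevant to
  every downstream statistic. Outside PMDs calls are Bernoulli with the
  state's level (UMR 0.03, LMR 0.30, hyperMR 0.90); inside PMDs the
  molecule mixture applies. Aggregated counts equal read column sums
  exactly. Mean coverage 15 (the regime the segmentation criteria state).
- **Depth.** Per-bin Poisson around the target coverage, zeroed (pro rata)
  in eliminated intervals for somatic samples; deletions are bin-aligned,
  non-adjacent, 3–10 bins.
- **Paired samples.** A derived truth relabels whole blocks until planted
  transition budgets are met (defaults UMR→PMD 16%, hyperMR→PMD 7%,
  LMR→PMD 2%, PMD→UMR 4%), sharing the CpG coordinate map.
- **Peaks and expression.** NMI genes (30% of TSS) draw their promoter
  state from a mostly-UMR mixture (0.8/0.1/0.05/0.05 over
  UMR/LMR/PMD/hyperMR) — the NMI universe behaves like a merged multi-tissue
  set, so some NMI promoters are methylated in the profiled sample, which is
  what makes a methylation–expression correlation measurable. Expression is
  log10(TPM+1) = 3 − 2·(window-expected promoter mCG) + noise, with the
  noise level calibrated by simulating the full chain (including the
  zero-TPM floor) so the expected Pearson r is −0.25.

What the generator does **not** emulate: sequence-level bisulfite reads and
alignment error, strand asymmetries, CpG-density covariation with state
(CpG-rich islands), replicate structure, overdispersed (non-Poisson) depth,
and copy-number states other than 0/2. Passing recovery tests therefore
demonstrates that the analysis recovers the planted statistical structure
at realistic coverage; it does not certify behaviour under alignment
artefacts or biological dispersion absent from the model.

## Problem sizes and numerical choices

The demo and recovery suite use a 2 × 3 Mb nuclear genome (~60k CpGs,
~180k reads) for segmentation and transition stages, 30k CpGs of fixed
4-CpG reads for the PDR closed forms, 40 planted 20-CpG blocks at coverage
30 for DMR power, 50 bin-aligned deletions under Poisson(30) depth for
elimination, and 1,500 genes for the expression stage — sizes chosen so
each recovered quantity's sampling error is several times smaller than its
acceptance band. Degenerate inputs are defined, not crashed on: empty
windows and zero-coverage sites raise or skip with logs, single-state HMM
decodes fall back to thresholding, constant-methylation correlation is
reported missing, and all-zero depth tracks are rejected.

## Known limitations

The segmentation is not MethylSeekR and the DMR caller is not DSS; both are
documented functional stand-ins that keep the standard region-level
parameters of those tools.
The disorder score cannot distinguish LMR from PMD levels at a boundary on
its own (hence the hypomethylated-edge trim); very short PMDs (< 101 CpGs)
are invisible by design; the elimination caller reports mean depths rather
than discrete copy-number classes, leaving intermediate (mosaic) states to
the user; and the differential-NMI test assumes Poisson-scale counts —
with strongly overdispersed real libraries its FDR control would need a
dispersion-aware replacement.
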