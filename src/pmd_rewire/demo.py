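"""End-to-end demonstration pipeline on synthetic data with known truth.

``run_demo`` simulates a genome, runs every analysis stage against the
planted ground truth and returns a flat report of recovery metrics:
segmentation F1 and state-fraction errors, transition-class fractions, PDR
values against their closed forms, DMR operating characteristics,
elimination precision/recall, conversion efficiency and global methylation
levels, NMI set statistics and the methylation–expression correlation.
Every quantity is recomputed from scratch for the given seed; a fixed seed
gives an identical report.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import discordance, dmr, elimination, region_stats, reprogramming, simulate
from .core import ValidationError
from .intervals import make_intervals, overlap_bases, total_bases
from .segmentation import Segmentation, SegmentationParams, segment_methylome


@dataclass
class DemoConfig:
    """Problem sizes and model parameters of the demo run."""

    seed: int = 0
    # segmentation stage
    n_chrom: int = 2
    chrom_len: int = 3_000_000
    cpg_density: float = 0.01
    coverage: float = 15.0
    pmd_pi: float = 0.6
    fractions: dict = field(
        default_factory=lambda: {"PMD": 0.4, "UMR": 0.2, "LMR": 0.1, "hyperMR": 0.3}
    )
    # global-level stage (state mix tuned so the expected genome mCG is 0.35)
    # expected genome mCG = 0.476·0.03 + 0.04·0.30 + 0.28·0.50 + 0.204·0.90 ≈ 0.35
    global_fractions: dict = field(
        default_factory=lambda: {"PMD": 0.28, "UMR": 0.476, "LMR": 0.04, "hyperMR": 0.204}
    )
    global_chrom_len: int = 2_000_000
    # PDR stage
    pdr_n_cpg: int = 30_000
    # DMR stage
    dmr_blocks: int = 40
    dmr_null_cpgs: int = 100          # gap blocks in the null pair
    # elimination stage
    n_deletions: int = 50
    depth_coverage: float = 30.0
    depth_bin_size: int = 1_000
    # NMI / expression stage
    n_tss: int = 1_500
    nmi_gene_fraction: float = 0.3
    n_tissues: int = 3
    nmi_dropout: float = 0.1
    expression_slope: float = 2.0
    target_expression_r: float = -0.25

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "DemoConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def _pmd_truth_segmentation(truth: simulate.SimTruth) -> Segmentation:
    sizes = {c: truth.chrom_sizes[c] for c in truth.nuclear_chroms}
    return Segmentation(truth.sample_id, truth.states, sizes)


def _f1(called, planted) -> float:
    tp = overlap_bases(called, planted)
    fp = total_bases(called) - tp
    fn = total_bases(planted) - tp
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else float("nan")


def run_demo(config: DemoConfig | None = None, seed: int | None = None) -> dict:
    """Run every stage on synthetic data; return {metric: {value, n}}."""
    cfg = config or DemoConfig()
    if seed is not None:
        cfg.seed = seed
    report: dict[str, dict] = {}

    def put(key: str, value: float, n: int) -> None:
        report[key] = {"value": float(value), "n": int(n)}

    # ----------------------------------------------------------------- stage 1
    # four-state segmentation recovery
    truth = simulate.simulate_truth(
        n_chrom=cfg.n_chrom, chrom_len=cfg.chrom_len, cpg_density=cfg.cpg_density,
        fractions=cfg.fractions, seed=cfg.seed, n_deletions=cfg.n_deletions,
        coverage=cfg.coverage, pmd_pi=cfg.pmd_pi, sample_id="egg_like",
    )
    reads, track = simulate.simulate_reads(truth)
    seg = segment_methylome(track, SegmentationParams())
    truth_seg = _pmd_truth_segmentation(truth)
    put("segmentation_pmd_f1",
        _f1(seg.state_intervals("PMD"), truth_seg.state_intervals("PMD")),
        truth.nuclear_genome_size())
    called_frac = seg.state_fractions()
    planted_frac = truth.state_fractions()
    for state in ("PMD", "UMR", "LMR", "hyperMR"):
        put(f"segmentation_{state.lower()}_error_pp",
            abs(called_frac[state] - planted_frac[state]) * 100.0,
            truth.nuclear_genome_size())

    # ----------------------------------------------------------------- stage 2
    # transition accounting on a planted maternal-to-paternal pair
    truth_b = simulate.plant_transitions(truth, sample_id="sperm_like")
    summary = reprogramming.transition_matrix(
        _pmd_truth_segmentation(truth), _pmd_truth_segmentation(truth_b)
    )
    rep = reprogramming.transition_report([summary])
    row = rep[rep["pair"] != "mean"].iloc[0]
    put("transition_altered_pct", row["altered"] * 100.0, summary.genome_size)
    put("transition_pmd_gain_pct", row["pmd_gain"] * 100.0, summary.genome_size)
    put("transition_umr_to_pmd_pct", row["umr_to_pmd"] * 100.0, summary.genome_size)
    put("transition_hypermr_to_pmd_pct", row["hypermr_to_pmd"] * 100.0, summary.genome_size)
    put("transition_lmr_to_pmd_pct", row["lmr_to_pmd"] * 100.0, summary.genome_size)
    put("transition_pmd_to_umr_pct", row["pmd_to_umr"] * 100.0, summary.genome_size)

    # ----------------------------------------------------------------- stage 3
    # PDR against the closed-form mixture expectation (4-CpG reads)
    for key, pi, rho in (
        ("pdr_fully_discordant", 1.0, 0.5),
        ("pdr_mixture", cfg.pmd_pi, 0.5),
        ("pdr_concordant_only", 0.0, 0.5),
    ):
        spacing = 100
        n = cfg.pdr_n_cpg
        pdr_truth = simulate.SimTruth(
            chrom_sizes={"chr1": (n + 1) * spacing},
            cpg_pos={"chr1": (np.arange(n) + 1) * spacing},
            states=make_intervals([("chr1", 0, (n + 1) * spacing)]).assign(state="PMD"),
            pmd_pi=pi, pmd_rho=rho, coverage=4.0,
            read_len_p=1e-9, read_len_max=4,   # every read carries exactly 4 CpGs
            seed=cfg.seed + 17,
        )
        pdr_reads, pdr_track = simulate.simulate_reads(pdr_truth)
        regions = make_intervals([("chr1", 0, (n + 1) * spacing)])
        res = discordance.region_pdr(pdr_reads, regions, pdr_track)
        put(key, float(res["pdr"].iloc[0]), int(res["n_reads"].iloc[0]))

    # ----------------------------------------------------------------- stage 4
    # DMR null rate and power
    null_a, null_b, _ = simulate.simulate_dmr_pair(
        n_blocks=0, gap_cpgs=cfg.dmr_null_cpgs * 100, seed=cfg.seed + 23
    )
    null_calls = dmr.call_dmrs(null_a, null_b)
    genome = null_a.chrom_sizes["chr1"]
    null_bases = int((null_calls["end"] - null_calls["start"]).sum()) if len(null_calls) else 0
    put("dmr_null_genome_pct", 100.0 * null_bases / genome, genome)
    pa, pb, planted = simulate.simulate_dmr_pair(
        n_blocks=cfg.dmr_blocks, seed=cfg.seed + 29
    )
    calls = dmr.call_dmrs(pa, pb)
    call_iv = calls[["chrom", "start", "end"]] if len(calls) else make_intervals([])
    hit = 0
    for row_ in planted.itertuples(index=False):
        one = make_intervals([(row_.chrom, row_.start, row_.end)])
        if overlap_bases(one, call_iv) >= 0.9 * (row_.end - row_.start):
            hit += 1
    recall = hit / len(planted) if len(planted) else float("nan")
    if len(calls):
        from .intervals import intervals_overlapping

        precision = float(np.mean(intervals_overlapping(call_iv, planted)))
    else:
        precision = float("nan")
    put("dmr_recall", recall, len(planted))
    put("dmr_precision", precision, len(calls))

    # ----------------------------------------------------------------- stage 5
    # programmed-elimination recovery from depth
    soma = simulate.simulate_depth(
        truth, coverage=cfg.depth_coverage, bin_size=cfg.depth_bin_size,
        somatic=True, seed=cfg.seed + 31,
    )
    germ = simulate.simulate_depth(
        truth, coverage=cfg.depth_coverage, bin_size=cfg.depth_bin_size,
        somatic=False, seed=cfg.seed + 37,
    )
    cn0 = elimination.call_cn0(soma, germ)
    calls_iv = cn0[["chrom", "start", "end"]] if len(cn0) else make_intervals([])
    planted_iv = truth.eliminated
    bs = cfg.depth_bin_size
    tp_bins = overlap_bases(calls_iv, planted_iv) // bs
    called_bins = total_bases(calls_iv) // bs
    planted_bins = total_bases(planted_iv) // bs
    put("elimination_recall", tp_bins / planted_bins if planted_bins else float("nan"),
        planted_bins)
    put("elimination_precision", tp_bins / called_bins if called_bins else float("nan"),
        called_bins)
    _, ref_frac = elimination.overlap_reference(cn0, planted_iv)
    put("elimination_reference_overlap", ref_frac, len(cn0))

    # ----------------------------------------------------------------- stage 6
    # conversion efficiency, mitochondrial and tuned global levels
    put("conversion_efficiency", region_stats.conversion_efficiency(track),
        int(track.filter(context=None, chroms=["chrL"]).sites["total"].sum()))
    chrm = region_stats.global_levels(track, chroms=["chrM"], exclude_chroms=())
    put("mitochondrial_mcg_pct", 100.0 * chrm,
        int(track.filter(context=None, chroms=["chrM"]).sites["total"].sum()))
    truth_g = simulate.simulate_truth(
        n_chrom=1, chrom_len=cfg.global_chrom_len, cpg_density=cfg.cpg_density,
        fractions=cfg.global_fractions, seed=cfg.seed + 41, n_deletions=0,
        coverage=cfg.coverage, sample_id="tuned_mix",
    )
    _, track_g = simulate.simulate_reads(truth_g)
    put("global_mcg_tuned", region_stats.global_levels(
        track_g, exclude_chroms=("chrL", "chrM")), len(track_g.sites))

    # ----------------------------------------------------------------- stage 7
    # NMI sets, TSS overlap, expression correlation, differential NMIs
    sim = simulate.simulate_peaks_and_expression(
        truth, n_tss=cfg.n_tss, n_tissues=cfg.n_tissues, dropout=cfg.nmi_dropout,
        slope=cfg.expression_slope, target_r=cfg.target_expression_r,
        nmi_gene_fraction=cfg.nmi_gene_fraction, seed=cfg.seed + 43,
    )
    core = region_stats.core_nmis(sim["peaks"])
    put("core_nmi_count", len(core), len(sim["peaks"]))
    put("tss_overlap_pct", region_stats.tss_overlap(sim["tss"], core), cfg.n_tss)
    union = pd.concat(list(sim["peaks"].values()), ignore_index=True)
    table, r = region_stats.promoter_methylation_expression(
        track, sim["tss"], union, sim["expression"]
    )
    put("expression_correlation_r", r, len(table))
    counts, enriched = simulate.simulate_nmi_counts(seed=cfg.seed + 47)
    libs_a, libs_b = ["A1", "A2", "A3"], ["B1", "B2", "B3"]
    diff = region_stats.differential_nmis(counts, libs_a, libs_b)
    called = set(zip(diff["chrom"], diff["start"]))
    called_mask = np.array([
        (c, s) in called for c, s in zip(counts["chrom"], counts["start"])
    ])
    n_true = int(enriched.sum())
    put("differential_nmi_recall",
        float((called_mask & enriched).sum() / n_true) if n_true else float("nan"),
        n_true)
    put("differential_nmi_false_discovery_rate",
        float((called_mask & ~enriched).sum() / max(called_mask.sum(), 1)),
        int(called_mask.sum()))
    return report
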