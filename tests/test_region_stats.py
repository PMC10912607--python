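"""Global levels, NMI algebra, sequence composition, expression correlation."""

import numpy as np
import pandas as pd
import pytest

from pmd_rewire import simulate
from pmd_rewire.core import MethylomeTrack, ValidationError
from pmd_rewire.intervals import make_intervals, per_base_mask
from pmd_rewire import region_stats as rs
from conftest import make_track


def track_sites(rows, sizes=None, sample="t"):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "context", "meth", "total"])
    return MethylomeTrack(sample, df, sizes or {})


class TestGlobalLevels:
    def test_equal_sites(self):
        t = track_sites([("chr1", 10, "CG", 5, 10), ("chr1", 20, "CG", 5, 10)])
        assert rs.global_levels(t) == pytest.approx(0.5)

    def test_coverage_weighting(self):
        t = track_sites([("chr1", 10, "CG", 1, 1), ("chr1", 20, "CG", 9, 100)])
        assert rs.global_levels(t) == pytest.approx(10 / 101)

    def test_ch_context_pools_subtypes(self):
        t = track_sites([
            ("chr1", 10, "CA", 1, 10), ("chr1", 20, "CC", 1, 10),
            ("chr1", 30, "CT", 1, 10), ("chr1", 40, "CG", 9, 10),
        ])
        assert rs.global_levels(t, context="CH") == pytest.approx(3 / 30)

    def test_no_qualifying_sites_missing(self):
        t = track_sites([("chrL", 10, "CG", 0, 10)])
        assert np.isnan(rs.global_levels(t))

    def test_split_counts_invariant_after_merge(self):
        # the same calls split across sites of equal weight give the same level
        a = track_sites([("chr1", 10, "CG", 4, 10), ("chr1", 20, "CG", 4, 10)])
        b = track_sites([("chr1", 10, "CG", 8, 20)])
        assert rs.global_levels(a) == rs.global_levels(b)


class TestHistogram:
    def test_counts_conserve_filtered_sites(self):
        t = make_track(np.linspace(0, 1, 37), coverage=20)
        h = rs.methylation_histogram(t, min_coverage=10)
        assert h["count"].sum() == 37
        assert len(h) == 20

    def test_low_coverage_excluded(self):
        t = track_sites([("chr1", 10, "CG", 1, 2), ("chr1", 20, "CG", 10, 20)])
        h = rs.methylation_histogram(t, min_coverage=10)
        assert h["count"].sum() == 1


class TestConversion:
    def test_arithmetic(self):
        t = track_sites([("chrL", 10, "CG", 3, 1_500)])
        assert rs.conversion_efficiency(t) == pytest.approx(0.998)

    def test_fully_converted(self):
        t = track_sites([("chrL", 10, "CG", 0, 500)])
        assert rs.conversion_efficiency(t) == 1.0

    def test_absent_contig_rejected(self):
        t = track_sites([("chr1", 10, "CG", 0, 10)])
        with pytest.raises(ValidationError):
            rs.conversion_efficiency(t)

    def test_planted_epsilon_recovered(self):
        truth = simulate.simulate_truth(n_chrom=1, chrom_len=200_000, seed=15,
                                        n_deletions=0)
        _, track = simulate.simulate_reads(truth)
        eff = rs.conversion_efficiency(track)
        assert eff == pytest.approx(1 - truth.epsilon, abs=0.001)


class TestNmiAlgebra:
    def test_core_toy(self):
        sets = [
            make_intervals([("chr1", 0, 100)]),
            make_intervals([("chr1", 50, 150)]),
            make_intervals([("chr1", 60, 90)]),
        ]
        core = rs.core_nmis(sets)
        assert [tuple(r) for r in core.itertuples(index=False)] == [("chr1", 60, 90)]

    def test_one_empty_set_empty_core(self):
        sets = [make_intervals([("chr1", 0, 100)]), make_intervals([])]
        assert rs.core_nmis(sets).empty

    def test_core_equals_brute_force_and(self, rng):
        sizes = {"chr1": 5_000}
        sets = []
        for _ in range(3):
            starts = np.sort(rng.choice(4_500, 10, replace=False))
            sets.append(make_intervals([
                ("chr1", int(s), int(min(s + w, 5_000)))
                for s, w in zip(starts, rng.integers(50, 600, 10))
            ]))
        core = rs.core_nmis(sets)
        masks = [per_base_mask(s, sizes)["chr1"] for s in sets]
        want = np.logical_and.reduce(masks)
        got = np.zeros(5_000, bool)
        for r in core.itertuples(index=False):
            got[r.start:r.end] = True
        assert np.array_equal(got, want)


class TestDifferentialNmis:
    def test_identical_groups_empty(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame({
            "chrom": "chr1", "start": np.arange(100) * 1000,
            "end": np.arange(100) * 1000 + 500,
        })
        for lib in ("A1", "A2", "B1", "B2"):
            counts[lib] = rng.poisson(100, 100)
        diff = rs.differential_nmis(counts, ["A1", "A2"], ["B1", "B2"])
        assert len(diff) <= 2  # at most chance-level stragglers past BH + fold filters

    def test_planted_enrichment_recovered(self):
        counts, enriched = simulate.simulate_nmi_counts(seed=7)
        diff = rs.differential_nmis(counts, ["A1", "A2", "A3"], ["B1", "B2", "B3"])
        called = np.zeros(len(counts), bool)
        key = set(zip(diff["chrom"], diff["start"]))
        for i, (c, s) in enumerate(zip(counts["chrom"], counts["start"])):
            called[i] = (c, s) in key
        recall = (called & enriched).sum() / enriched.sum()
        assert recall >= 0.9
        assert (diff["direction"] == "A").all()

    def test_depth_doubling_leaves_calls_unchanged(self):
        counts, _ = simulate.simulate_nmi_counts(seed=8)
        doubled = counts.copy()
        doubled["A1"] = doubled["A1"] * 2
        a = rs.differential_nmis(counts, ["A1", "A2", "A3"], ["B1", "B2", "B3"])
        b = rs.differential_nmis(doubled, ["A1", "A2", "A3"], ["B1", "B2", "B3"])
        pd.testing.assert_frame_equal(
            a[["chrom", "start", "end", "direction"]],
            b[["chrom", "start", "end", "direction"]],
        )

    def test_empty_group_rejected(self):
        counts, _ = simulate.simulate_nmi_counts(n_intervals=10, seed=9)
        with pytest.raises(ValidationError):
            rs.differential_nmis(counts, [], ["B1"])


class TestTssOverlap:
    def test_one_of_four(self):
        tss = make_intervals([("chr1", 10, 11), ("chr1", 500, 501),
                              ("chr1", 900, 901), ("chr2", 10, 11)])
        nmis = make_intervals([("chr1", 0, 100)])
        assert rs.tss_overlap(tss, nmis) == pytest.approx(25.0)

    def test_empty_nmi_set(self):
        tss = make_intervals([("chr1", 10, 11)])
        assert rs.tss_overlap(tss, make_intervals([])) == 0.0

    def test_matches_brute_force_membership(self, rng):
        pts = np.sort(rng.choice(5_000, 60, replace=False))
        tss = make_intervals([("chr1", int(p), int(p) + 1) for p in pts])
        starts = np.sort(rng.choice(4_500, 8, replace=False))
        nmis = make_intervals([
            ("chr1", int(s), int(s + w)) for s, w in zip(starts, rng.integers(50, 400, 8))
        ])
        mask = per_base_mask(nmis, {"chr1": 5_000})["chr1"]
        want = 100.0 * np.mean([mask[p] for p in pts])
        assert rs.tss_overlap(tss, nmis) == pytest.approx(want)


class TestSequenceComposition:
    def test_formulae(self):
        fasta = {"chr1": "ACGCGT"}
        out = rs.sequence_composition(make_intervals([("chr1", 0, 6)]), fasta)
        assert out.iloc[0]["gc"] == pytest.approx(4 / 6)
        assert out.iloc[0]["cpg_oe"] == pytest.approx(3.0)

    def test_no_c_or_g_gives_missing_oe(self):
        fasta = {"chr1": "AATTAATT"}
        out = rs.sequence_composition(make_intervals([("chr1", 0, 8)]), fasta)
        assert np.isnan(out.iloc[0]["cpg_oe"])

    def test_uniform_random_sequence_oe_near_one(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=100_000))
        out = rs.sequence_composition(make_intervals([("chr1", 0, 100_000)]),
                                      {"chr1": seq})
        assert out.iloc[0]["cpg_oe"] == pytest.approx(1.0, abs=0.05)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValidationError):
            rs.sequence_composition(make_intervals([("chr1", 0, 10)]), {"chr1": "ACGT"})


class TestExpressionCorrelation:
    def test_two_genes_perfect_anticorrelation(self):
        track = track_sites(
            [("chr1", p, "CG", 0, 10) for p in range(100, 1100, 100)]
            + [("chr1", p, "CG", 10, 10) for p in range(5100, 6100, 100)],
            {"chr1": 10_000},
        )
        tss = make_intervals([("chr1", 600, 601), ("chr1", 5600, 5601)])
        tss = tss.assign(name=["g1", "g2"])
        nmis = make_intervals([("chr1", 0, 10_000)])
        expr = pd.DataFrame({"gene": ["g1", "g2"], "tpm": [1000.0, 1.0]})
        table, r = rs.promoter_methylation_expression(track, tss, nmis, expr)
        assert len(table) == 2
        assert r == pytest.approx(-1.0)

    def test_constant_methylation_r_undefined(self, caplog):
        track = track_sites(
            [("chr1", p, "CG", 5, 10) for p in range(100, 2000, 100)], {"chr1": 10_000}
        )
        tss = make_intervals([("chr1", 500, 501), ("chr1", 1500, 1501)])
        tss = tss.assign(name=["g1", "g2"])
        nmis = make_intervals([("chr1", 0, 10_000)])
        expr = pd.DataFrame({"gene": ["g1", "g2"], "tpm": [10.0, 100.0]})
        with caplog.at_level("WARNING"):
            _, r = rs.promoter_methylation_expression(track, tss, nmis, expr)
        assert np.isnan(r)

    def test_planted_negative_correlation_recovered(self):
        truth = simulate.simulate_truth(seed=16, n_deletions=0)
        _, track = simulate.simulate_reads(truth)
        sim = simulate.simulate_peaks_and_expression(truth, seed=17)
        union = pd.concat(list(sim["peaks"].values()), ignore_index=True)
        table, r = rs.promoter_methylation_expression(
            track, sim["tss"], union, sim["expression"]
        )
        assert len(table) >= 400
        assert r == pytest.approx(-0.25, abs=0.1)
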