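"""Ground-truth generator: determinism, planted structure, model moments."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pmd_rewire import simulate
from pmd_rewire.core import ValidationError
from pmd_rewire.intervals import make_intervals, total_bases


def small_truth(seed=0, **kw):
    kw.setdefault("n_chrom", 1)
    kw.setdefault("chrom_len", 400_000)
    kw.setdefault("n_deletions", 10)
    return simulate.simulate_truth(seed=seed, **kw)


class TestGenome:
    def test_fixed_seed_is_byte_identical(self):
        a = simulate.simulate_genome(n_chrom=1, chrom_len=50_000, seed=5)
        b = simulate.simulate_genome(n_chrom=1, chrom_len=50_000, seed=5)
        assert a[2] == b[2]
        assert all(np.array_equal(a[1][c], b[1][c]) for c in a[1])

    def test_cpg_count_within_binomial_bound(self):
        _, cpg, _ = simulate.simulate_genome(
            n_chrom=1, chrom_len=1_000_000, cpg_density=0.01, seed=3
        )
        n = cpg["chr1"].size
        assert abs(n - 10_000) < 3 * np.sqrt(1_000_000 * 0.01 * 0.99)

    def test_every_dyad_is_cg_in_fasta_and_nowhere_else(self):
        sizes, cpg, seqs = simulate.simulate_genome(
            n_chrom=1, chrom_len=20_000, seed=7
        )
        for chrom, pos in cpg.items():
            seq = seqs[chrom]
            assert all(seq[p:p + 2] == "CG" for p in pos)
            found = {i for i in range(len(seq) - 1) if seq[i:i + 2] == "CG"}
            assert found == set(pos.tolist())

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ValidationError):
            simulate.simulate_genome(chrom_len=0)


class TestPlantedStates:
    def test_tiling_and_exact_fractions(self):
        truth = small_truth(seed=2)
        fr = truth.state_fractions()
        assert sum(fr.values()) == pytest.approx(1.0)
        for state, want in simulate.DEFAULT_FRACTIONS.items():
            assert fr[state] == pytest.approx(want, abs=1e-4)

    def test_no_adjacent_hypomethylated_blocks(self):
        truth = small_truth(seed=4)
        states = truth.states["state"].tolist()
        for a, b in zip(states, states[1:]):
            assert not (a in ("UMR", "LMR") and b in ("UMR", "LMR"))


class TestReads:
    def test_aggregate_equals_read_sums_exactly(self):
        truth = small_truth(seed=1, chrom_len=100_000, n_deletions=0)
        reads, track = simulate.simulate_reads(truth)
        want = (
            reads.df.groupby(["chrom", "pos"])["call"]
            .agg(meth="sum", total="size")
            .reset_index()
        )
        got = track.sites[["chrom", "pos", "meth", "total"]].reset_index(drop=True)
        pd.testing.assert_frame_equal(
            got, want[["chrom", "pos", "meth", "total"]].astype(got.dtypes)
        )

    def test_forced_concordant_pmd_is_all_methylated(self):
        truth = small_truth(seed=3, chrom_len=100_000, n_deletions=0, pmd_pi=0.0, pmd_rho=1.0)
        reads, _ = simulate.simulate_reads(truth)
        codes = {c: truth.cpg_state_codes(c) for c in truth.nuclear_chroms}
        df = reads.df[reads.df["chrom"].isin(truth.nuclear_chroms)]
        pos_idx = {
            c: dict(zip(truth.cpg_pos[c].tolist(), range(truth.cpg_pos[c].size)))
            for c in codes
        }
        pmd_mask = np.array([
            codes[c][pos_idx[c][p]] == simulate.STATE_CODES["PMD"]
            for c, p in zip(df["chrom"], df["pos"])
        ])
        assert df["call"].to_numpy()[pmd_mask].all()

    def test_state_means_within_three_se(self):
        truth = small_truth(seed=5)
        _, track = simulate.simulate_reads(truth)
        sites = track.sites[track.sites["chrom"] == "chr1"]
        codes = truth.cpg_state_codes("chr1")
        pos_to_code = dict(zip(truth.cpg_pos["chr1"].tolist(), codes.tolist()))
        site_codes = np.array([pos_to_code[p] for p in sites["pos"]])
        expected = {
            "UMR": 0.03, "LMR": 0.30, "hyperMR": 0.90,
            "PMD": truth.pmd_pi * truth.pmd_q + (1 - truth.pmd_pi) * truth.pmd_rho,
        }
        for state, code in simulate.STATE_CODES.items():
            sel = sites[site_codes == code]
            n = sel["total"].sum()
            if n == 0:
                continue
            level = sel["meth"].sum() / n
            p = expected[state]
            # concordant molecules correlate calls within a read; bound the SE
            # with an effective sample size of one call per read (mean 5 calls)
            se = np.sqrt(p * (1 - p) / (n / 5))
            assert abs(level - p) < 3 * max(se, 1e-4)

    def test_expected_pdr_closed_form_matches_enumeration(self):
        # brute-force over all call patterns of a discordant molecule
        for q in (0.3, 0.5):
            for c in (2, 4, 5):
                p_mixed = 0.0
                for bits in range(2**c):
                    calls = [(bits >> i) & 1 for i in range(c)]
                    pr = np.prod([q if b else 1 - q for b in calls])
                    if 0 < sum(calls) < c:
                        p_mixed += pr
                assert simulate.expected_pdr(0.7, q, c) == pytest.approx(0.7 * p_mixed)

    def test_spike_in_and_mito_levels(self):
        truth = small_truth(seed=6, chrom_len=100_000, n_deletions=0)
        _, track = simulate.simulate_reads(truth)
        spike = track.filter(context=None, chroms=["chrL"]).sites
        eps_hat = spike["meth"].sum() / spike["total"].sum()
        assert eps_hat == pytest.approx(truth.epsilon, abs=0.002)
        mito = track.filter(context=None, chroms=["chrM"]).sites
        assert mito["meth"].sum() / mito["total"].sum() < 0.01


class TestDepth:
    def test_somatic_bins_inside_deletions_are_zero(self):
        truth = small_truth(seed=7)
        soma = simulate.simulate_depth(truth, coverage=30, bin_size=1_000, somatic=True)
        for row in truth.eliminated.itertuples(index=False):
            b0, b1 = row.start // 1_000, row.end // 1_000
            assert np.all(soma.depth[row.chrom][b0:b1] == 0.0)

    def test_median_depth_near_coverage(self):
        truth = small_truth(seed=8, n_deletions=0, chrom_len=1_000_000)
        soma = simulate.simulate_depth(truth, coverage=30, bin_size=1_000)
        assert abs(np.median(soma.values()) - 30) / 30 < 0.10

    def test_germline_somatic_same_distribution_outside_deletions(self):
        truth = small_truth(seed=9, chrom_len=500_000, n_deletions=5)
        soma = simulate.simulate_depth(truth, coverage=30, bin_size=1_000, somatic=True)
        germ = simulate.simulate_depth(truth, coverage=30, bin_size=1_000, somatic=False)
        elim_bins = set()
        for row in truth.eliminated.itertuples(index=False):
            elim_bins.update(range(row.start // 1_000, -(-row.end // 1_000)))
        keep = np.array([i not in elim_bins for i in range(soma.depth["chr1"].size)])
        ks = stats.ks_2samp(soma.depth["chr1"][keep], germ.depth["chr1"][keep])
        assert ks.pvalue > 0.01

    def test_bin_larger_than_chromosome_rejected(self):
        truth = small_truth(seed=10, chrom_len=100_000, n_deletions=0)
        with pytest.raises(ValidationError):
            simulate.simulate_depth(truth, bin_size=200_000)


class TestTransitionsAndPairs:
    def test_planted_transition_budgets_met(self):
        truth = simulate.simulate_truth(seed=11)  # default 2×3 Mb genome
        other = simulate.plant_transitions(truth)
        genome = truth.nuclear_genome_size()
        a = truth.states
        b = other.states
        # base-level cross-tab via the cpg-independent per-base scan
        from pmd_rewire.segmentation import Segmentation
        from pmd_rewire.reprogramming import transition_matrix

        sizes = {c: truth.chrom_sizes[c] for c in truth.nuclear_chroms}
        tm = transition_matrix(Segmentation("a", a, sizes), Segmentation("b", b, sizes))
        f = tm.fractions()
        assert f.loc["UMR", "PMD"] == pytest.approx(0.16, abs=0.02)
        assert f.loc["hyperMR", "PMD"] == pytest.approx(0.07, abs=0.02)
        assert f.loc["LMR", "PMD"] == pytest.approx(0.02, abs=0.02)
        assert f.loc["PMD", "UMR"] == pytest.approx(0.04, abs=0.02)
        assert other.cpg_pos is truth.cpg_pos

    def test_dmr_pair_null_has_identical_parameters(self):
        a, b, planted = simulate.simulate_dmr_pair(n_blocks=0, seed=3)
        assert planted.empty
        assert len(a) == len(b)

    def test_dmr_pair_planted_blocks_differ(self):
        a, b, planted = simulate.simulate_dmr_pair(n_blocks=5, seed=4)
        assert len(planted) == 5
        total = total_bases(planted)
        assert total > 0


class TestPeaksExpression:
    def test_zero_dropout_core_equals_union(self):
        truth = small_truth(seed=12)
        sim = simulate.simulate_peaks_and_expression(truth, n_tss=200, dropout=0.0)
        from pmd_rewire.region_stats import core_nmis
        from pmd_rewire.intervals import merge_intervals

        union = merge_intervals(pd.concat(list(sim["peaks"].values()), ignore_index=True))
        pd.testing.assert_frame_equal(core_nmis(sim["peaks"]), union)

    def test_near_zero_noise_gives_near_perfect_anticorrelation(self):
        truth = small_truth(seed=13)
        sim = simulate.simulate_peaks_and_expression(
            truth, n_tss=300, noise_sd=1e-6, seed=14
        )
        expr = np.log10(sim["expression"]["tpm"].to_numpy() + 1.0)
        keep = expr > 0  # genes off the TPM floor follow the linear model
        r = np.corrcoef(sim["tss_true_mcg"][keep], expr[keep])[0, 1]
        assert r < -0.99

    def test_nmi_counts_shape_and_truth(self):
        counts, enriched = simulate.simulate_nmi_counts(n_intervals=50, seed=5)
        assert len(counts) == 50 and enriched.size == 50
        assert {"A1", "A2", "A3", "B1", "B2", "B3"} <= set(counts.columns)
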