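"""Coverage-based detection of somatically eliminated sequences."""

import numpy as np
import pandas as pd
import pytest

from pmd_rewire import simulate
from pmd_rewire.core import DepthTrack, ValidationError
from pmd_rewire.elimination import (
    EliminationParams,
    call_cn0,
    normalize_depth,
    overlap_reference,
    profile_eliminated,
)
from pmd_rewire.intervals import make_intervals
from conftest import make_track


def depth(sample, values, bin_size=1_000, chrom="chr1"):
    arr = np.asarray(values, float)
    return DepthTrack(sample, bin_size, {chrom: arr}, {chrom: arr.size * bin_size})


class TestNormalize:
    def test_constant_depth_becomes_one(self):
        t = normalize_depth(depth("s", [30.0] * 10))
        np.testing.assert_allclose(t.depth["chr1"], 1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.poisson(30, 50).astype(float)
        a = normalize_depth(depth("s", vals))
        b = normalize_depth(depth("s", vals * 2))
        np.testing.assert_allclose(a.depth["chr1"], b.depth["chr1"])

    def test_poisson_track_median_exactly_one(self):
        rng = np.random.default_rng(1)
        t = normalize_depth(depth("s", rng.poisson(30, 1_000).astype(float)))
        assert np.median(t.values()) == 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            normalize_depth(depth("s", [0.0] * 10))


class TestCallCn0:
    def test_clean_deletion_called(self):
        soma = depth("soma", [30] * 10 + [0] * 5 + [30] * 10)
        germ = depth("germ", [30] * 25)
        calls = call_cn0(soma, germ)
        assert len(calls) == 1
        assert (calls.iloc[0]["start"], calls.iloc[0]["end"]) == (10_000, 15_000)

    def test_high_soma_depth_never_called(self):
        soma = depth("soma", [27.0] * 30)  # 0.9 × germline everywhere
        germ = depth("germ", [30.0] * 30)
        assert call_cn0(soma, germ).empty

    def test_no_germline_support_no_call(self):
        soma = depth("soma", [30] * 10 + [0] * 5 + [30] * 10)
        germ = depth("germ", [30] * 10 + [0] * 5 + [30] * 10)  # assembly gap
        assert call_cn0(soma, germ).empty

    def test_invariant_to_uniform_rescaling(self):
        truth = simulate.simulate_truth(n_chrom=1, chrom_len=500_000, seed=12,
                                        n_deletions=15)
        soma = simulate.simulate_depth(truth, coverage=30, somatic=True)
        germ = simulate.simulate_depth(truth, coverage=30, somatic=False)
        base = call_cn0(soma, germ)
        scaled = DepthTrack("soma", soma.bin_size,
                            {c: v * 3.7 for c, v in soma.depth.items()},
                            soma.chrom_sizes)
        pd.testing.assert_frame_equal(call_cn0(scaled, germ), base)

    def test_zero_false_calls_on_noise_free_pair(self):
        soma = depth("soma", [30.0] * 100)
        germ = depth("germ", [30.0] * 100)
        assert call_cn0(soma, germ).empty

    def test_recall_monotone_in_coverage(self):
        truth = simulate.simulate_truth(n_chrom=1, chrom_len=1_000_000, seed=13,
                                        n_deletions=20)
        recalls = []
        for lam in (5, 15, 30):
            soma = simulate.simulate_depth(truth, coverage=lam, somatic=True)
            germ = simulate.simulate_depth(truth, coverage=lam, somatic=False)
            calls = call_cn0(soma, germ)
            iv = calls[["chrom", "start", "end"]] if len(calls) else make_intervals([])
            from pmd_rewire.intervals import overlap_bases, total_bases

            recalls.append(overlap_bases(iv, truth.eliminated)
                           / total_bases(truth.eliminated))
        assert recalls[0] <= recalls[1] <= recalls[2]
        assert recalls[2] >= 0.95

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            call_cn0(depth("a", [1] * 10), depth("b", [1] * 11))


class TestOverlapReference:
    def test_toy_fraction(self):
        calls = pd.DataFrame(
            [("chr1", 0, 100), ("chr1", 200, 300)], columns=["chrom", "start", "end"]
        )
        reference = make_intervals([("chr1", 50, 150)])
        stringent, frac = overlap_reference(calls, reference)
        assert frac == pytest.approx(0.5)
        assert len(stringent) == 1

    def test_empty_reference(self):
        calls = pd.DataFrame([("chr1", 0, 100)], columns=["chrom", "start", "end"])
        _, frac = overlap_reference(calls, make_intervals([]))
        assert frac == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        starts = np.sort(rng.choice(9_000, 20, replace=False))
        calls = pd.DataFrame(
            {"chrom": "chr1", "start": starts, "end": starts + rng.integers(10, 400, 20)}
        )
        rstarts = np.sort(rng.choice(9_000, 10, replace=False))
        ref = make_intervals([
            ("chr1", int(s), int(s + w))
            for s, w in zip(rstarts, rng.integers(10, 400, 10))
        ])
        _, frac = overlap_reference(calls, ref)
        brute = np.mean([
            any(max(s, rs) < min(e, re_) for rs, re_ in zip(ref["start"], ref["end"]))
            for s, e in zip(calls["start"], calls["end"])
        ])
        assert frac == pytest.approx(brute)


class TestProfile:
    def test_all_high_fraction_one(self):
        t = make_track([0.9] * 50, coverage=20, spacing=100)
        regions = make_intervals([("chr1", 0, 10_000)])
        prof = profile_eliminated(regions, t)
        assert prof.iloc[0]["frac_high"] == 1.0

    def test_intermediate_fraction_zero(self):
        t = make_track([0.5] * 50, coverage=20, spacing=100)
        regions = make_intervals([("chr1", 0, 10_000)])
        prof = profile_eliminated(regions, t)
        assert prof.iloc[0]["frac_high"] == 0.0

    def test_hypermethylated_regions_exceed_pmd_background(self):
        # sperm-like: eliminated regions at p=0.9 against a PMD-style 0.5 background
        rng = np.random.default_rng(3)
        n = 2_000
        pos = np.arange(n) * 100 + 50
        inside = (pos >= 50_000) & (pos < 80_000)
        p = np.where(inside, 0.9, 0.5)
        total = np.full(n, 20)
        meth = rng.binomial(total, p)
        from pmd_rewire.core import MethylomeTrack

        t = MethylomeTrack(
            "sperm", pd.DataFrame({"chrom": "chr1", "pos": pos, "meth": meth,
                                   "total": total}), {"chr1": n * 100 + 100},
        )
        prof = profile_eliminated(make_intervals([("chr1", 50_000, 80_000)]), t)
        region = prof.iloc[0]
        bg = prof[prof["chrom"] == "__background__"].iloc[0]
        n_r = region["n_cpg"]
        se = 3 * np.sqrt(0.25 / n_r)
        assert region["frac_high"] > bg["frac_high"] + se

    def test_region_without_cpgs_skipped(self, caplog):
        t = make_track([0.5] * 10, coverage=20, spacing=100)
        regions = make_intervals([("chr2", 0, 1_000)])
        with caplog.at_level("WARNING"):
            prof = profile_eliminated(regions, t)
        assert (prof["chrom"] == "__background__").all()
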