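"""Synthetic WGBS data with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes:

* nuclear chromosomes tiled with UMR / LMR / PMD / hyperMR segments, each
  state with its own per-CpG methylation probability (UMR 0.03, LMR 0.30,
  hyperMR 0.90 by default);
* inside PMDs a molecule-level mixture — a fraction ``pi`` of molecules is
  *discordant* (each CpG methylated independently with probability ``q``)
  and the remainder is *concordant*, fully methylated with probability
  ``rho`` or fully unmethylated otherwise.  With the defaults
  ``pi=0.6, q=0.5, rho=0.5`` the PMD mean mCG is 0.5 with high read-level
  discordance;
* a near-unmethylated mitochondrial contig (``chrM``, methylation 0.005)
  and an unmethylated spike-in contig (``chrL``) whose apparent methylation
  equals the bisulfite conversion-failure rate ``epsilon``;
* somatic samples carrying homozygous deletions (copy number 0) that are
  intact in the germline — the coverage signature of programmed genome
  rearrangement.

Reads are modelled as runs of consecutive CpG calls (count drawn from a
truncated geometric with mean 5) because only the CpG calls matter to any
downstream statistic.  All randomness flows from seeded
``numpy.random.Generator`` streams, so a fixed seed gives byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import DepthTrack, MethylomeTrack, ReadTable, ValidationError
from .intervals import make_intervals, merge_intervals, validate_intervals

STATE_CODES = {"UMR": 0, "LMR": 1, "PMD": 2, "hyperMR": 3}
CODE_STATES = {v: k for k, v in STATE_CODES.items()}

DEFAULT_STATE_P = {"UMR": 0.03, "LMR": 0.30, "hyperMR": 0.90}
DEFAULT_FRACTIONS = {"PMD": 0.4, "UMR": 0.2, "LMR": 0.1, "hyperMR": 0.3}

#: state block length ranges (bp); UMRs are promoter-scale, LMRs
#: enhancer-scale, PMDs domain-scale, hyperMRs the methylated matrix between
STATE_LENGTH_RANGES = {
    "PMD": (25_000, 70_000),
    "hyperMR": (1_000, 4_000),
    "UMR": (6_000, 11_000),
    "LMR": (1_000, 2_400),
}

MITO_CHROM = "chrM"
SPIKE_CHROM = "chrL"


def _rng(seed, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), stream])


@dataclass
class SimTruth:
    """Planted ground truth for one synthetic WGBS sample."""

    chrom_sizes: dict[str, int]
    cpg_pos: dict[str, np.ndarray]
    states: pd.DataFrame              # nuclear tiling: chrom, start, end, state
    state_p: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_STATE_P))
    pmd_pi: float = 0.6
    pmd_q: float = 0.5
    pmd_rho: float = 0.5
    coverage: float = 15.0
    read_len_p: float = 0.2           # geometric p; mean CpGs per read = 1/p
    read_len_max: int = 50
    eliminated: pd.DataFrame = field(default_factory=lambda: make_intervals([]))
    epsilon: float = 0.002
    chrm_p: float = 0.005
    seed: int = 0
    sample_id: str = "sim"

    def __post_init__(self) -> None:
        for name, v in (("pi", self.pmd_pi), ("q", self.pmd_q),
                        ("rho", self.pmd_rho), ("epsilon", self.epsilon)):
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.coverage <= 0:
            raise ValidationError("coverage must be positive")
        self.states = validate_intervals(self.states, require_disjoint=True)
        # the state map must tile every nuclear chromosome
        for chrom, grp in self.states.groupby("chrom", sort=False):
            size = self.chrom_sizes[chrom]
            if grp["start"].iloc[0] != 0 or grp["end"].iloc[-1] != size:
                raise ValidationError(f"states do not tile {chrom}")
            if np.any(grp["start"].to_numpy()[1:] != grp["end"].to_numpy()[:-1]):
                raise ValidationError(f"gap in state tiling of {chrom}")

    @property
    def nuclear_chroms(self) -> list[str]:
        return [c for c in self.chrom_sizes if c not in (MITO_CHROM, SPIKE_CHROM)]

    def nuclear_genome_size(self) -> int:
        return sum(self.chrom_sizes[c] for c in self.nuclear_chroms)

    def state_fractions(self) -> dict[str, float]:
        """Realised planted genome fraction of each state (nuclear genome)."""
        total = self.nuclear_genome_size()
        lengths = (self.states["end"] - self.states["start"]).groupby(
            self.states["state"]
        ).sum()
        return {s: float(lengths.get(s, 0)) / total for s in STATE_CODES}

    def cpg_state_codes(self, chrom: str) -> np.ndarray:
        """State code of every CpG on a nuclear chromosome."""
        grp = self.states[self.states["chrom"] == chrom]
        starts = grp["start"].to_numpy()
        codes = np.array([STATE_CODES[s] for s in grp["state"]])
        idx = np.searchsorted(starts, self.cpg_pos[chrom], side="right") - 1
        return codes[idx]

    def segmentation(self) -> pd.DataFrame:
        """The planted state map as a segmentation frame (truth tiling)."""
        return self.states.copy()


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def simulate_genome(
    n_chrom: int = 2,
    chrom_len: int = 1_000_000,
    cpg_density: float = 0.01,
    seed: int = 0,
    mito_len: int = 16_000,
    spike_len: int = 48_000,
    spike_cpg_density: float = 0.14,
) -> tuple[dict[str, int], dict[str, np.ndarray], dict[str, str]]:
    """Plant CpG dyads on random chromosomes plus chrM and chrL contigs.

    Returns ``(chrom_sizes, cpg_positions, sequences)``; every planted dyad
    has "CG" at its position in the returned sequence and no CG dyad exists
    anywhere else, so the sequence and the coordinate map agree exactly.
    """
    if not 0.0 < cpg_density < 1.0:
        raise ValidationError("cpg_density must lie in (0, 1)")
    if chrom_len <= 0 or mito_len <= 0 or spike_len <= 0:
        raise ValidationError("chromosome lengths must be positive")
    rng = _rng(seed, 1)
    chrom_sizes: dict[str, int] = {}
    cpg_pos: dict[str, np.ndarray] = {}
    sequences: dict[str, str] = {}
    layout = [(f"chr{i + 1}", chrom_len, cpg_density) for i in range(n_chrom)]
    layout += [(MITO_CHROM, mito_len, cpg_density), (SPIKE_CHROM, spike_len, spike_cpg_density)]
    for chrom, length, density in layout:
        # inter-CpG gaps: 1 + geometric(density) keeps dyads non-overlapping
        est = int(length * density * 1.5) + 64
        gaps = 1 + rng.geometric(density, size=est)
        pos = np.cumsum(gaps) - 1
        pos = pos[pos < length - 1]
        while pos.size and pos[-1] < length - 1:
            extra = pos[-1] + 1 + rng.geometric(density)
            if extra >= length - 1:
                break
            pos = np.append(pos, extra)
        chrom_sizes[chrom] = length
        cpg_pos[chrom] = pos.astype(np.int64)
        seq = rng.choice(list("ACGT"), size=length)
        seq[pos] = "C"
        seq[pos + 1] = "G"
        # break accidental CG dyads outside the planted map
        is_c = seq == "C"
        is_g = np.roll(seq == "G", -1)
        is_g[-1] = False
        accidental = is_c & is_g
        accidental[pos] = False
        seq[np.flatnonzero(accidental) + 1] = "A"
        sequences[chrom] = "".join(seq)
    return chrom_sizes, cpg_pos, sequences


def plant_states(
    chrom_sizes: Mapping[str, int],
    fractions: Mapping[str, float] | None = None,
    seed: int = 0,
    length_ranges: Mapping[str, tuple[int, int]] | None = None,
    exclude: Sequence[str] = (MITO_CHROM, SPIKE_CHROM),
) -> pd.DataFrame:
    """Tile nuclear chromosomes with state blocks near target genome fractions.

    Block states are chosen proportionally to the *remaining* base budget of
    each state, which keeps realised fractions close to the targets; UMR/LMR
    blocks are never adjacent (a methylated spacer always separates them, as
    hypomethylated elements are separated in real genomes).
    """
    fractions = dict(fractions or DEFAULT_FRACTIONS)
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValidationError("state fractions must sum to 1")
    ranges = dict(length_ranges or STATE_LENGTH_RANGES)
    rng = _rng(seed, 2)
    rows = []
    for chrom, size in chrom_sizes.items():
        if chrom in exclude:
            continue
        n_blocks = {
            s: int(round(fractions.get(s, 0.0) * size / np.mean(ranges[s])))
            for s in ranges
        }
        spacers = ["PMD"] * n_blocks["PMD"] + ["hyperMR"] * n_blocks["hyperMR"]
        focals = ["UMR"] * n_blocks["UMR"] + ["LMR"] * n_blocks["LMR"]
        if len(focals) > len(spacers) + 1:
            raise ValidationError(
                "cannot separate every UMR/LMR block with a methylated spacer; "
                "lower the UMR/LMR fractions or lengthen their blocks"
            )
        spacers = [spacers[i] for i in rng.permutation(len(spacers))]
        focals = [focals[i] for i in rng.permutation(len(focals))]
        # one focal per gap between spacers keeps UMR/LMR blocks apart
        gaps = rng.choice(len(spacers) + 1, size=len(focals), replace=False)
        by_gap = dict(zip(gaps.tolist(), focals))
        order: list[str] = []
        for i, sp in enumerate(spacers):
            if i in by_gap:
                order.append(by_gap[i])
            order.append(sp)
        if len(spacers) in by_gap:
            order.append(by_gap[len(spacers)])
        # draw lengths, then rescale within each state so the planted base
        # fractions match the targets exactly (planted fractions are ground
        # truth for recovery tests, so they should not wander with the draw)
        drawn = np.array([
            rng.integers(ranges[s][0], ranges[s][1] + 1) for s in order
        ], dtype=float)
        scaled = drawn.copy()
        for s in set(order):
            sel = np.array([o == s for o in order])
            scaled[sel] = drawn[sel] * (fractions.get(s, 0.0) * size / drawn[sel].sum())
        bounds = np.round(np.concatenate([[0.0], np.cumsum(scaled)])).astype(np.int64)
        bounds[-1] = size
        for state, s0, s1 in zip(order, bounds[:-1], bounds[1:]):
            if s1 > s0:
                rows.append((chrom, int(s0), int(s1), state))
    return validate_intervals(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
    )


def plant_deletions(
    chrom_sizes: Mapping[str, int],
    n_deletions: int = 50,
    bin_size: int = 1_000,
    len_bins_range: tuple[int, int] = (3, 10),
    seed: int = 0,
    exclude: Sequence[str] = (MITO_CHROM, SPIKE_CHROM),
    min_gap_bins: int = 3,
) -> pd.DataFrame:
    """Place bin-aligned, non-adjacent homozygous deletions on nuclear chromosomes."""
    rng = _rng(seed, 3)
    chroms = [c for c in chrom_sizes if c not in exclude]
    sizes = np.array([chrom_sizes[c] // bin_size for c in chroms], dtype=float)
    rows = []
    occupied: dict[str, set[int]] = {c: set() for c in chroms}
    attempts = 0
    while len(rows) < n_deletions and attempts < 100 * n_deletions:
        attempts += 1
        ci = rng.choice(len(chroms), p=sizes / sizes.sum())
        chrom = chroms[ci]
        n_bins = int(rng.integers(len_bins_range[0], len_bins_range[1] + 1))
        max_start = chrom_sizes[chrom] // bin_size - n_bins
        if max_start <= 0:
            continue
        b0 = int(rng.integers(0, max_start))
        span = range(b0 - min_gap_bins, b0 + n_bins + min_gap_bins)
        if any(b in occupied[chrom] for b in span):
            continue
        occupied[chrom].update(range(b0, b0 + n_bins))
        rows.append((chrom, b0 * bin_size, (b0 + n_bins) * bin_size))
    if len(rows) < n_deletions:
        raise ValidationError("could not place requested deletions; genome too small")
    return make_intervals(rows)


def simulate_truth(
    n_chrom: int = 2,
    chrom_len: int = 3_000_000,
    cpg_density: float = 0.01,
    fractions: Mapping[str, float] | None = None,
    seed: int = 0,
    n_deletions: int = 50,
    deletion_bin_size: int = 1_000,
    sample_id: str = "sim",
    **kwargs,
) -> SimTruth:
    """Convenience builder: genome + state tiling + deletions in one truth object."""
    chrom_sizes, cpg_pos, _ = simulate_genome(
        n_chrom=n_chrom, chrom_len=chrom_len, cpg_density=cpg_density, seed=seed
    )
    states = plant_states(chrom_sizes, fractions=fractions, seed=seed)
    eliminated = plant_deletions(
        chrom_sizes, n_deletions=n_deletions, bin_size=deletion_bin_size, seed=seed
    ) if n_deletions else make_intervals([])
    return SimTruth(
        chrom_sizes=chrom_sizes,
        cpg_pos=cpg_pos,
        states=states,
        eliminated=eliminated,
        seed=seed,
        sample_id=sample_id,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def _truncated_geometric(rng, p: float, size: int, cap: int) -> np.ndarray:
    lens = rng.geometric(p, size=size)
    return np.minimum(lens, cap)


def simulate_reads(
    truth: SimTruth, seed: int | None = None
) -> tuple[ReadTable, MethylomeTrack]:
    """Draw sequenced molecules and their per-CpG calls under the truth model.

    Within PMDs each molecule is discordant with probability ``pi`` (its CpG
    calls are iid Bernoulli(q)) or concordant (all methylated with
    probability ``rho``, else all unmethylated).  Outside PMDs each call is
    an independent Bernoulli with the state's methylation probability; chrM
    uses ``chrm_p`` and the chrL spike-in uses the conversion-failure rate
    ``epsilon``.  The aggregated per-CpG track equals the column sums of the
    emitted reads exactly.
    """
    rng = _rng(truth.seed if seed is None else seed, 4)
    frames = []
    read_counter = 0
    special_p = {MITO_CHROM: truth.chrm_p, SPIKE_CHROM: truth.epsilon}
    for chrom in truth.cpg_pos:
        pos = truth.cpg_pos[chrom]
        n_cpg = pos.size
        if n_cpg == 0:
            continue
        mean_len = min(1.0 / truth.read_len_p, truth.read_len_max)
        n_reads = int(round(truth.coverage * n_cpg / mean_len))
        if n_reads == 0:
            continue
        starts = rng.integers(0, n_cpg, size=n_reads)
        lens = _truncated_geometric(rng, truth.read_len_p, n_reads, truth.read_len_max)
        lens = np.minimum(lens, n_cpg - starts)
        # flat call layout
        read_idx = np.repeat(np.arange(n_reads), lens)
        offset = np.arange(lens.sum()) - np.repeat(np.cumsum(lens) - lens, lens)
        site = starts[read_idx] + offset
        if chrom in special_p:
            p_call = np.full(site.size, special_p[chrom])
            calls = rng.random(site.size) < p_call
        else:
            codes = truth.cpg_state_codes(chrom)[site]
            is_pmd = codes == STATE_CODES["PMD"]
            discordant = rng.random(n_reads) < truth.pmd_pi
            conc_m = rng.random(n_reads) < truth.pmd_rho
            p_state = np.empty(4)
            p_state[STATE_CODES["UMR"]] = truth.state_p["UMR"]
            p_state[STATE_CODES["LMR"]] = truth.state_p["LMR"]
            p_state[STATE_CODES["hyperMR"]] = truth.state_p["hyperMR"]
            p_state[STATE_CODES["PMD"]] = truth.pmd_q  # used for discordant draws
            u = rng.random(site.size)
            bern = u < p_state[codes]
            calls = np.where(
                is_pmd,
                np.where(discordant[read_idx], bern, conc_m[read_idx]),
                bern,
            )
        frames.append(
            pd.DataFrame(
                {
                    "read_idx": read_idx + read_counter,
                    "read_id": pd.array(
                        [f"r{chrom}_{i}" for i in read_idx + read_counter],
                        dtype="string",
                    ),
                    "chrom": chrom,
                    "pos": pos[site],
                    "call": calls,
                }
            )
        )
        read_counter += n_reads
    if frames:
        table = ReadTable(pd.concat(frames, ignore_index=True))
    else:
        table = ReadTable.from_records([])
    track = table.aggregate_track(truth.sample_id, truth.chrom_sizes)
    return table, track


def expected_pdr(pi: float, q: float, n_cpg: int) -> float:
    """Closed-form expected discordant-read fraction in a PMD.

    A discordant molecule with ``c`` CpG calls shows both call types unless
    all calls agree: P(mixed) = 1 − q^c − (1−q)^c; concordant molecules are
    never mixed, so the region expectation is pi times that.
    """
    return pi * (1.0 - q**n_cpg - (1.0 - q) ** n_cpg)


# ---------------------------------------------------------------------------
# depth
# ---------------------------------------------------------------------------

def simulate_depth(
    truth: SimTruth,
    coverage: float = 30.0,
    bin_size: int = 1_000,
    seed: int | None = None,
    somatic: bool = True,
    sample_id: str | None = None,
) -> DepthTrack:
    """Binned mean depth; somatic samples lose coverage in eliminated regions."""
    if bin_size <= 0:
        raise ValidationError("bin size must be positive")
    rng = _rng(truth.seed if seed is None else seed, 6 if somatic else 7)
    depth: dict[str, np.ndarray] = {}
    chrom_sizes = {c: truth.chrom_sizes[c] for c in truth.nuclear_chroms}
    elim = truth.eliminated
    for chrom, size in chrom_sizes.items():
        if bin_size > size:
            raise ValidationError(f"bin size {bin_size} exceeds {chrom} length {size}")
        n_bins = -(-size // bin_size)
        retained = np.ones(n_bins)
        if somatic and not elim.empty:
            for row in elim[elim["chrom"] == chrom].itertuples(index=False):
                b0, b1 = row.start // bin_size, -(-row.end // bin_size)
                for b in range(b0, min(b1, n_bins)):
                    lo = max(row.start, b * bin_size)
                    hi = min(row.end, min((b + 1) * bin_size, size))
                    retained[b] -= (hi - lo) / (min((b + 1) * bin_size, size) - b * bin_size)
        retained = np.clip(retained, 0.0, 1.0)
        widths = np.full(n_bins, bin_size, dtype=float)
        widths[-1] = size - (n_bins - 1) * bin_size
        lam = coverage * retained * widths
        depth[chrom] = rng.poisson(lam).astype(float) / widths
    name = sample_id or ("soma" if somatic else "germline")
    return DepthTrack(name, bin_size, depth, chrom_sizes)


# ---------------------------------------------------------------------------
# transitions between paired samples
# ---------------------------------------------------------------------------

def plant_transitions(
    truth: SimTruth,
    targets: Mapping[tuple[str, str], float] | None = None,
    seed: int | None = None,
    sample_id: str = "simB",
) -> SimTruth:
    """Derive a paired truth with planted state transitions.

    ``targets`` maps (state_from, state_to) to the genome fraction that
    should switch; whole planted blocks are relabelled until each budget is
    met, so realised fractions land within one block length of the target.
    Defaults mirror a maternal-to-paternal PMD reprogramming event:
    UMR→PMD 16%, hyperMR→PMD 7%, LMR→PMD 2% (25% PMD gain) and
    PMD→UMR 4% (PMD loss).
    """
    if targets is None:
        targets = {
            ("UMR", "PMD"): 0.16,
            ("hyperMR", "PMD"): 0.07,
            ("LMR", "PMD"): 0.02,
            ("PMD", "UMR"): 0.04,
        }
    rng = _rng(truth.seed if seed is None else seed, 8)
    genome = truth.nuclear_genome_size()
    states = truth.states.reset_index(drop=True)
    new_state = states["state"].to_numpy(dtype=object).copy()
    taken = np.zeros(len(states), dtype=bool)
    for (src, dst), frac in targets.items():
        budget = frac * genome
        idx = np.flatnonzero((states["state"] == src).to_numpy() & ~taken)
        idx = idx[rng.permutation(idx.size)]
        lengths = (states["end"] - states["start"]).to_numpy()
        got = 0.0
        for i in idx:
            if got >= budget:
                break
            if got + lengths[i] > budget + lengths[i] * 0.5:
                continue  # skip blocks that would badly overshoot
            new_state[i] = dst
            taken[i] = True
            got += lengths[i]
    out = states.copy()
    out["state"] = new_state
    # merge equal-state neighbours to keep a clean tiling
    merged_rows = []
    for chrom, grp in out.groupby("chrom", sort=True):
        cur = None
        for row in grp.itertuples(index=False):
            if cur is not None and cur[3] == row.state and cur[2] == row.start:
                cur[2] = row.end
            else:
                if cur is not None:
                    merged_rows.append(tuple(cur))
                cur = [row.chrom, row.start, row.end, row.state]
        if cur is not None:
            merged_rows.append(tuple(cur))
    outdf = pd.DataFrame(merged_rows, columns=["chrom", "start", "end", "state"])
    return replace(truth, states=validate_intervals(outdf), sample_id=sample_id)


# ---------------------------------------------------------------------------
# peaks, counts, expression
# ---------------------------------------------------------------------------

def simulate_peaks_and_expression(
    truth: SimTruth,
    n_tss: int = 1_500,
    n_tissues: int = 3,
    dropout: float = 0.1,
    slope: float = 2.0,
    noise_sd: float | None = None,
    target_r: float = -0.25,
    intercept: float = 3.0,
    nmi_gene_fraction: float = 0.3,
    nmi_state_probs: Mapping[str, float] | None = None,
    peak_halfwidth: int = 300,
    seed: int | None = None,
) -> dict:
    """Emit per-tissue NMI peak sets, a TSS set and an expression table.

    A fraction of genes are *NMI genes*: their promoter carries a peak in
    every tissue (subject to per-tissue dropout).  NMI peak sets come from a
    merged multi-tissue universe, so NMI promoters are not uniformly
    unmethylated in this sample: their underlying state is drawn from
    ``nmi_state_probs`` (mostly UMR, with a methylated minority) — this is
    what makes a methylation–expression correlation measurable at NMI
    promoters.  Tissue peak sets additionally contain the sample's UMR
    blocks with dropout.  Expression follows
    ``log10(TPM+1) = intercept − slope · promoter_mCG + N(0, noise_sd)``;
    when ``noise_sd`` is omitted it is calibrated from the realised
    promoter-mCG variance of the NMI genes so the expected Pearson r equals
    ``target_r``.
    """
    rng = _rng(truth.seed if seed is None else seed, 9)
    probs = dict(nmi_state_probs or
                 {"UMR": 0.8, "LMR": 0.1, "PMD": 0.05, "hyperMR": 0.05})
    state_p = dict(truth.state_p)
    state_p["PMD"] = truth.pmd_pi * truth.pmd_q + (1 - truth.pmd_pi) * truth.pmd_rho
    blocks = truth.states.reset_index(drop=True)
    by_state = {s: g.reset_index(drop=True) for s, g in blocks.groupby("state")}
    missing = [s for s, w in probs.items() if w > 0 and s not in by_state]
    if missing:
        raise ValidationError(f"no planted blocks for NMI states {missing}")
    lengths = (blocks["end"] - blocks["start"]).to_numpy(float)
    mass = lengths / lengths.sum()
    names = list(probs)
    weights = np.array([probs[s] for s in names], dtype=float)
    weights = weights / weights.sum()

    flank = 1_000  # promoter half-width used downstream (TSS ± 1 kb)
    bounds_by_chrom = {
        c: (g["start"].to_numpy(), np.array([state_p[s] for s in g["state"]]))
        for c, g in blocks.groupby("chrom", sort=False)
    }

    def window_mcg(chrom: str, tss_pos: int) -> float:
        """Expected promoter mCG: state p integrated over TSS ± flank."""
        starts, pvals = bounds_by_chrom[chrom]
        size = truth.chrom_sizes[chrom]
        lo, hi = max(tss_pos - flank, 0), min(tss_pos + flank + 1, size)
        i = max(int(np.searchsorted(starts, lo, side="right")) - 1, 0)
        acc = w = 0.0
        while i < starts.size and starts[i] < hi:
            seg_end = starts[i + 1] if i + 1 < starts.size else size
            span = min(seg_end, hi) - max(starts[i], lo)
            if span > 0:
                acc += span * pvals[i]
                w += span
            i += 1
        return acc / w

    rows, genes, mcg, is_nmi, promoter_peaks = [], [], [], [], []
    for g in range(n_tss):
        nmi_gene = rng.random() < nmi_gene_fraction
        if nmi_gene:
            state = names[int(rng.choice(len(names), p=weights))]
            grp = by_state[state]
            blk = grp.iloc[int(rng.integers(0, len(grp)))]
        else:
            blk = blocks.iloc[int(rng.choice(len(blocks), p=mass))]
            state = blk["state"]
        p = int(rng.integers(blk["start"], blk["end"]))
        gene = f"gene{g + 1}"
        rows.append((blk["chrom"], p, p + 1, gene))
        genes.append(gene)
        mcg.append(window_mcg(blk["chrom"], p))
        is_nmi.append(nmi_gene)
        if nmi_gene:
            size = truth.chrom_sizes[blk["chrom"]]
            promoter_peaks.append(
                (blk["chrom"], max(p - peak_halfwidth, 0),
                 min(p + peak_halfwidth + 1, size))
            )
    tss = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    mcg_arr = np.array(mcg)
    is_nmi = np.array(is_nmi)

    umrs = by_state.get("UMR", blocks.iloc[0:0])
    peak_sets: dict[str, pd.DataFrame] = {}
    for t in range(n_tissues):
        keep_umr = rng.random(len(umrs)) >= dropout
        keep_prom = rng.random(len(promoter_peaks)) >= dropout
        parts = [umrs.loc[keep_umr, ["chrom", "start", "end"]]]
        if promoter_peaks:
            prom = pd.DataFrame(promoter_peaks, columns=["chrom", "start", "end"])
            parts.append(prom[keep_prom])
        peak_sets[f"tissue{t + 1}"] = merge_intervals(
            pd.concat(parts, ignore_index=True)
        )

    if noise_sd is None:
        # calibrate on the genes a downstream NMI-overlap filter will keep:
        # those covered by the union of the emitted peak sets
        from .intervals import points_covered
        union = merge_intervals(pd.concat(list(peak_sets.values()), ignore_index=True))
        covered = points_covered(tss[["chrom", "start", "end"]], union)  # gene order
        if not covered.any() or np.var(mcg_arr[covered]) <= 0:
            raise ValidationError("degenerate NMI promoter methylation; set noise_sd")
        noise_sd = _calibrate_noise_sd(
            mcg_arr[covered], slope, intercept, target_r, seed=rng.integers(2**31)
        )
    log_expr = intercept - slope * mcg_arr + rng.normal(0.0, noise_sd, size=n_tss)
    expression = pd.DataFrame(
        {"gene": genes, "tpm": np.maximum(10.0 ** log_expr - 1.0, 0.0)}
    )
    return {
        "peaks": peak_sets,
        "tss": validate_intervals(tss),
        "expression": expression,
        "tss_true_mcg": mcg_arr,
        "is_nmi_gene": is_nmi,
        "noise_sd": noise_sd,
    }


def _calibrate_noise_sd(
    mcg_pool: np.ndarray,
    slope: float,
    intercept: float,
    target_r: float,
    seed: int,
    n_aux: int = 20_000,
) -> float:
    """Noise level whose *realised* correlation hits the target.

    The closed form of :func:`noise_sd_for_target_r` ignores the TPM floor
    (expression cannot go below zero), which compresses the methylated tail
    and attenuates the correlation.  Here the full generative chain —
    linear model, noise, clipping, log scale — is simulated on an auxiliary
    sample and the noise level solved by bisection, so the expected Pearson
    r of the emitted data matches ``target_r``.
    """
    rng = np.random.default_rng([int(seed), 12])
    m = rng.choice(mcg_pool, size=n_aux, replace=True)
    z = rng.standard_normal(n_aux)

    def realised_r(sd: float) -> float:
        log_expr = intercept - slope * m + sd * z
        y = np.log10(np.maximum(10.0 ** log_expr - 1.0, 0.0) + 1.0)
        return float(np.corrcoef(m, y)[0, 1])

    lo, hi = 1e-3, 50.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        # |r| shrinks as sd grows
        if abs(realised_r(mid)) > abs(target_r):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def noise_sd_for_target_r(slope: float, mcg_var: float, target_r: float) -> float:
    """Noise level giving an expected Pearson r between mCG and log-expression.

    With log-expression = a − slope·m + e, r² = s²V/(s²V + σ²), so
    σ = |slope|·sqrt(V)·sqrt(1/r² − 1).
    """
    if not 0 < abs(target_r) < 1:
        raise ValidationError("target r must lie in (0, 1) in magnitude")
    return abs(slope) * np.sqrt(mcg_var) * np.sqrt(1.0 / target_r**2 - 1.0)


def simulate_dmr_pair(
    n_blocks: int = 40,
    block_cpgs: int = 20,
    spacing: int = 20,
    gap_cpgs: int = 100,
    coverage: int = 30,
    p_background: float = 0.2,
    p_block_b: float = 0.7,
    seed: int = 0,
) -> tuple[MethylomeTrack, MethylomeTrack, pd.DataFrame]:
    """Paired count tracks with planted differentially methylated blocks.

    Both samples share evenly spaced CpGs at probability ``p_background``;
    inside each planted block sample B switches to ``p_block_b`` (a planted
    difference of ``p_block_b − p_background``).  With ``n_blocks=0`` the
    pair is an exact null (identical generative parameters).  Returns
    (track_a, track_b, planted block intervals).
    """
    rng = _rng(seed, 11)
    n_cpg = n_blocks * (block_cpgs + gap_cpgs) + gap_cpgs
    pos = (np.arange(n_cpg) + 1) * spacing
    chrom_len = int(pos[-1]) + spacing
    p_a = np.full(n_cpg, p_background)
    p_b = np.full(n_cpg, p_background)
    blocks = []
    for i in range(n_blocks):
        first = gap_cpgs + i * (block_cpgs + gap_cpgs)
        last = first + block_cpgs - 1
        p_b[first:last + 1] = p_block_b
        blocks.append(("chr1", int(pos[first]), int(pos[last]) + 2))
    tot_a = rng.poisson(coverage, size=n_cpg)
    tot_b = rng.poisson(coverage, size=n_cpg)
    meth_a = rng.binomial(tot_a, p_a)
    meth_b = rng.binomial(tot_b, p_b)
    keep_a = tot_a > 0
    keep_b = tot_b > 0
    sizes = {"chr1": chrom_len}
    track_a = MethylomeTrack(
        "simA",
        pd.DataFrame({"chrom": "chr1", "pos": pos[keep_a],
                      "meth": meth_a[keep_a], "total": tot_a[keep_a]}),
        sizes,
    )
    track_b = MethylomeTrack(
        "simB",
        pd.DataFrame({"chrom": "chr1", "pos": pos[keep_b],
                      "meth": meth_b[keep_b], "total": tot_b[keep_b]}),
        sizes,
    )
    planted = make_intervals(blocks) if blocks else make_intervals([])
    return track_a, track_b, planted


def simulate_nmi_counts(
    n_intervals: int = 200,
    n_rep: int = 3,
    depth: float = 100.0,
    frac_enriched: float = 0.15,
    fold: float = 4.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-interval read-count matrix for two tissue groups with replicates.

    Counts are Poisson around ``depth`` (times a per-library size factor in
    [0.7, 1.3]); a ``frac_enriched`` subset is ``fold``-times enriched in
    group A.  Returns the count frame (columns A1.. B1..) and the boolean
    enrichment truth.
    """
    rng = _rng(seed, 10)
    enriched = rng.random(n_intervals) < frac_enriched
    base = depth * np.exp(rng.normal(0, 0.25, size=n_intervals))
    data = {}
    for grp, label in ((0, "A"), (1, "B")):
        for r in range(n_rep):
            sf = rng.uniform(0.7, 1.3)
            mean = base * sf * np.where(enriched & (grp == 0), fold, 1.0)
            data[f"{label}{r + 1}"] = rng.poisson(mean)
    counts = pd.DataFrame(data)
    counts.insert(0, "chrom", "chr1")
    counts.insert(1, "start", np.arange(n_intervals) * 2_000)
    counts.insert(2, "end", np.arange(n_intervals) * 2_000 + 1_000)
    return counts, enriched
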