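"""Synthetic bisulfite read generator with full ground truth.

Emulates a high-quality directional WGBS experiment: reads are sampled
uniformly over valid start positions and both strands; each CpG carries a
true methylation rate drawn from a bimodal Gaussian mixture
(N(0.2, 0.08) / N(0.8, 0.08), fair coin, clamped to [0, 1]); cytosines on
the sampled strand are methylated with the owning CpG's rate (non-CpG
context: probability 0.01), unmethylated cytosines convert to T with 99%
success, and l ~ Poisson(0.5) uniformly placed base-call errors replace a
base with a uniformly chosen different base.  Paired-end mates sit
100-400 bp apart (start-to-start, uniform) on opposite strands and share
the fragment's methylation states at shared CpGs.

Every draw flows from one numpy Generator, so a fixed seed reproduces the
read set bit for bit; the ground truth records per-read origins, per-read
methylation/conversion/error positions and aggregate counters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .reference_index import (
    A, C, G, T, N,
    FORWARD, REVERSE,
    ReferenceGenome,
    decode,
)
from .bisulfite_matcher import Read
from .methylation_caller import CellBatch


@dataclass(frozen=True)
class SimulationConfig:
    read_len: int = 100
    n_reads: int | None = None
    n_pairs: int | None = None
    paired: bool = False
    insert_min: int = 100
    insert_max: int = 400
    conversion_success: float = 0.99
    non_cpg_meth_prob: float = 0.01
    error_lambda: float = 0.5
    mix_means: tuple = (0.2, 0.8)
    mix_sd: float = 0.08
    hypo_prob: float = 0.5
    rng_seed: int | None = None

    def __post_init__(self):
        for p in (self.conversion_success, self.non_cpg_meth_prob,
                  self.hypo_prob, *self.mix_means):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


class MethylationProfile(NamedTuple):
    rates: np.ndarray     # per-CpG true methylation rate, clamped to [0, 1]
    is_hypo: np.ndarray   # True where the hypomethylated component was drawn


class ReadTruth(NamedTuple):
    read_id: str
    chrom: int
    start: int            # 0-based leftmost forward coordinate of the read window
    strand: int
    meth_positions: np.ndarray       # read positions (strand orientation) set methylated
    converted_positions: np.ndarray  # read positions converted C->T (pre error)
    error_positions: np.ndarray      # read positions hit by injected errors


@dataclass
class GroundTruth:
    """True rates plus per-read provenance and aggregate calibration counters."""

    true_rates: np.ndarray
    reads: list = field(default_factory=list)
    n_reads: int = 0
    n_cytosines: int = 0          # strand-orientation Cs before conversion
    n_unmethylated: int = 0
    n_converted: int = 0          # among unmethylated Cs
    n_noncpg_c: int = 0
    n_noncpg_meth: int = 0
    n_errors: int = 0

    def conversion_fraction(self) -> float:
        return self.n_converted / max(self.n_unmethylated, 1)

    def noncpg_meth_fraction(self) -> float:
        return self.n_noncpg_meth / max(self.n_noncpg_c, 1)

    def mean_errors_per_read(self) -> float:
        return self.n_errors / max(self.n_reads, 1)


# ---------------------------------------------------------------------------
# genome & profile


def random_genome(length: int, rng, name: str = "chr1") -> ReferenceGenome:
    """Uniform-random ACGT chromosome (no N)."""
    rng = np.random.default_rng(rng)
    codes = rng.integers(0, 4, size=length).astype(np.uint8)
    return ReferenceGenome([(name, decode(codes))])


def draw_methylation_profile(cpg_sites, config: SimulationConfig,
                             rng) -> MethylationProfile:
    """Independent bimodal Gaussian rate per CpG.

    ``cpg_sites`` may be a list of sites or a plain integer count.
    """
    rng = np.random.default_rng(rng)
    n = cpg_sites if isinstance(cpg_sites, int) else len(cpg_sites)
    is_hypo = rng.random(n) < config.hypo_prob
    means = np.where(is_hypo, config.mix_means[0], config.mix_means[1])
    rates = np.clip(rng.normal(means, config.mix_sd), 0.0, 1.0)
    return MethylationProfile(rates, is_hypo)


# ---------------------------------------------------------------------------
# read synthesis


class _SimContext:
    """Precomputed per-chromosome lookups shared by all reads of a run."""

    def __init__(self, genome: ReferenceGenome, read_len: int,
                 window_size: int = 2000):
        from .reference_index import enumerate_cpgs

        self.genome = genome
        self.read_len = read_len
        sites = enumerate_cpgs(genome, window_size)
        self.n_cpgs = len(sites)
        self.cpg_at_c = []
        self.cpg_at_g = []
        self.valid_starts = []
        for ci in range(len(genome)):
            codes = genome.codes(ci)
            L = len(codes)
            at_c = np.full(L, -1, dtype=np.int64)
            at_g = np.full(L, -1, dtype=np.int64)
            for s in sites:
                if s.chrom == ci:
                    at_c[s.pos] = s.cpg_id
                    at_g[s.pos + 1] = s.cpg_id
            self.cpg_at_c.append(at_c)
            self.cpg_at_g.append(at_g)
            if L < read_len:
                self.valid_starts.append(np.empty(0, dtype=np.int64))
                continue
            is_n = (codes == N).astype(np.int32)
            cs = np.cumsum(np.concatenate(([0], is_n)))
            clean = (cs[read_len:] - cs[:-read_len]) == 0
            self.valid_starts.append(np.flatnonzero(clean))
        self._start_counts = np.array([len(v) for v in self.valid_starts])
        self._cum = np.cumsum(self._start_counts)
        if self._cum[-1] == 0:
            raise ValueError("genome shorter than read length (no valid starts)")

    def draw_start(self, rng) -> tuple:
        u = int(rng.integers(0, self._cum[-1]))
        ci = int(np.searchsorted(self._cum, u, side="right"))
        off = u - (self._cum[ci - 1] if ci else 0)
        return ci, int(self.valid_starts[ci][off])


_COMP = np.array([T, G, C, A, N], dtype=np.uint8)


def _synth_read(ctx: _SimContext, chrom: int, start: int, strand: int,
                profile: MethylationProfile, config: SimulationConfig,
                rng, truth: GroundTruth, read_id: str,
                frag_states: dict | None = None) -> Read:
    """Bisulfite-convert one read window and record its truth."""
    L = config.read_len
    codes = ctx.genome.codes(chrom)[start:start + L]
    if strand == FORWARD:
        sc = codes.copy()
        c_idx = np.flatnonzero(sc == C)
        gpos = start + c_idx
        cpg_ids = ctx.cpg_at_c[chrom][gpos]
    else:
        sc = _COMP[codes][::-1].copy()    # sequencing orientation
        c_idx = np.flatnonzero(sc == C)
        gpos = start + (L - 1 - c_idx)    # forward positions of the source Gs
        cpg_ids = ctx.cpg_at_g[chrom][gpos]

    p = np.where(cpg_ids >= 0, profile.rates[np.maximum(cpg_ids, 0)],
                 config.non_cpg_meth_prob)
    meth = rng.random(len(c_idx)) < p
    if frag_states is not None:
        for k, cid in enumerate(cpg_ids):
            if cid >= 0:
                cid = int(cid)
                if cid in frag_states:
                    meth[k] = frag_states[cid]
                else:
                    frag_states[cid] = bool(meth[k])
    converted = ~meth & (rng.random(len(c_idx)) < config.conversion_success)
    sc[c_idx[converted]] = T

    n_err = int(rng.poisson(config.error_lambda))
    n_err = min(n_err, L)
    if n_err:
        err_pos = rng.choice(L, size=n_err, replace=False)
        sc[err_pos] = (sc[err_pos] + 1 + rng.integers(0, 3, size=n_err)) % 4
        err_pos = np.sort(err_pos)
    else:
        err_pos = np.empty(0, dtype=np.int64)

    is_cpg = cpg_ids >= 0
    truth.n_reads += 1
    truth.n_cytosines += len(c_idx)
    truth.n_unmethylated += int(np.sum(~meth))
    truth.n_converted += int(np.sum(converted))
    truth.n_noncpg_c += int(np.sum(~is_cpg))
    truth.n_noncpg_meth += int(np.sum(meth & ~is_cpg))
    truth.n_errors += n_err
    truth.reads.append(ReadTruth(
        read_id, chrom, start, strand,
        c_idx[meth].astype(np.int16),
        c_idx[converted].astype(np.int16),
        err_pos.astype(np.int16),
    ))
    return Read(read_id, decode(sc))


def simulate_reads(genome: ReferenceGenome, profile: MethylationProfile,
                   config: SimulationConfig, rng) -> tuple:
    """Single-end simulation: (reads, GroundTruth)."""
    rng = np.random.default_rng(rng)
    if config.n_reads is None:
        raise ValueError("config.n_reads must be set for single-end simulation")
    ctx = _SimContext(genome, config.read_len)
    truth = GroundTruth(true_rates=profile.rates)
    reads = []
    for i in range(config.n_reads):
        chrom, start = ctx.draw_start(rng)
        strand = FORWARD if rng.integers(0, 2) == 0 else REVERSE
        reads.append(_synth_read(ctx, chrom, start, strand, profile, config,
                                 rng, truth, f"r{i:07d}"))
    return reads, truth


def simulate_pairs(genome: ReferenceGenome, profile: MethylationProfile,
                   config: SimulationConfig, rng) -> tuple:
    """Paired-end simulation: (list of (mate1, mate2), GroundTruth).

    Mate starts are ``Uniform{insert_min..insert_max}`` apart
    (start-to-start); mates sit on opposite strands and share the
    fragment's methylation states at CpGs both cover.  Fragments that
    would exceed the chromosome are resampled.
    """
    rng = np.random.default_rng(rng)
    if config.n_pairs is None:
        raise ValueError("config.n_pairs must be set for paired simulation")
    ctx = _SimContext(genome, config.read_len)
    truth = GroundTruth(true_rates=profile.rates)
    pairs = []
    for i in range(config.n_pairs):
        while True:
            chrom, a = ctx.draw_start(rng)
            d = int(rng.integers(config.insert_min, config.insert_max + 1))
            b = a + d
            L = len(genome.sequences[chrom])
            if b + config.read_len > L:
                continue
            window = ctx.genome.codes(chrom)[b:b + config.read_len]
            if np.any(window == N):
                continue
            break
        frag_states: dict = {}
        if rng.integers(0, 2) == 0:
            r1 = _synth_read(ctx, chrom, a, FORWARD, profile, config, rng,
                             truth, f"p{i:07d}/1", frag_states)
            r2 = _synth_read(ctx, chrom, b, REVERSE, profile, config, rng,
                             truth, f"p{i:07d}/2", frag_states)
        else:
            r1 = _synth_read(ctx, chrom, b, REVERSE, profile, config, rng,
                             truth, f"p{i:07d}/1", frag_states)
            r2 = _synth_read(ctx, chrom, a, FORWARD, profile, config, rng,
                             truth, f"p{i:07d}/2", frag_states)
        pairs.append((r1._replace(mate="mate1"), r2._replace(mate="mate2")))
    return pairs, truth


def simulate_cells(genome: ReferenceGenome, config: SimulationConfig,
                   n_cells: int, reads_per_cell: int, rng) -> tuple:
    """Independent per-cell profiles and read batches.

    Returns (batches, per-cell GroundTruth list); each cell draws its own
    methylation profile and then its own reads (pairs when
    ``config.paired``).
    """
    rng = np.random.default_rng(rng)
    from .reference_index import enumerate_cpgs

    n_cpgs = len(enumerate_cpgs(genome))
    batches, truths = [], []
    for c in range(n_cells):
        profile = draw_methylation_profile(n_cpgs, config, rng)
        if config.paired:
            cfg = _replace_cfg(config, n_pairs=reads_per_cell)
            items, truth = simulate_pairs(genome, profile, cfg, rng)
        else:
            cfg = _replace_cfg(config, n_reads=reads_per_cell)
            items, truth = simulate_reads(genome, profile, cfg, rng)
        batches.append(CellBatch(f"cell{c:03d}", items))
        truths.append(truth)
    return batches, truths


def _replace_cfg(config: SimulationConfig, **kw) -> SimulationConfig:
    from dataclasses import replace

    return replace(config, **kw)
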