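"""Banded asymmetric alignment, count updates, bulk and single-cell calling."""

import numpy as np
import pytest

import methdirect as md
from methdirect.reference_index import FORWARD, REVERSE, revcomp
from methdirect.bisulfite_matcher import C_ASYM, G_ASYM
from methdirect.methylation_caller import (
    AlignmentConsistencyError,
    _align_hit,
    accumulate_counts,
    banded_levenshtein_align,
)

from oracles import asym_best_distance, random_dna


# ---------------------------------------------------------------------------
# banded_levenshtein_align


def test_identity_alignment():
    aln = banded_levenshtein_align("ACGT", "ACGT", 0, C_ASYM)
    assert aln.errors == 0
    assert all(op == "M" for op, _, _ in aln.ops)
    assert aln.ref_start == 0


def test_read_t_over_reference_c_is_free():
    aln = banded_levenshtein_align("TT", "CT", 0, C_ASYM)
    assert aln.errors == 0


def test_band_too_small_raises():
    with pytest.raises(AlignmentConsistencyError):
        banded_levenshtein_align("AAAA", "TTTT", 0, C_ASYM, expected_errors=0)


def test_banded_cost_equals_unbanded_dp():
    rng = np.random.default_rng(2024)
    for _ in range(200):
        m = int(rng.integers(4, 30))
        pat = random_dna(rng, m)
        text = random_dna(rng, m + int(rng.integers(0, 10)))
        asym = C_ASYM if rng.integers(0, 2) == 0 else G_ASYM
        true_d = asym_best_distance(pat, text, asym)
        full = banded_levenshtein_align(pat, text, None, asym)
        assert full.errors == true_d
        # band = true distance around the optimal start diagonal
        banded = banded_levenshtein_align(pat, text, true_d, asym,
                                          start_offset=full.ref_start)
        assert banded.errors == true_d


def test_ops_reconstruct_read_from_reference():
    rng = np.random.default_rng(5)
    for _ in range(50):
        ref = random_dna(rng, 40)
        pat = random_dna(rng, 20)
        aln = banded_levenshtein_align(pat, ref, None, C_ASYM)
        rebuilt = []
        for op, ri, rp in aln.ops:
            if op == "M":
                rebuilt.append(pat[ri])
            elif op == "I":
                rebuilt.append(pat[ri])
        assert "".join(rebuilt) == pat


def test_diagonal_fast_path_matches_dp(genome20k, index20k, rng):
    """The positional shortcut yields the same alignment the DP would."""
    for _ in range(30):
        start = int(rng.integers(0, 19_900))
        seq = list(genome20k.sequences[0][start:start + 100])
        k = int(rng.integers(0, 3))
        for p in rng.choice(100, size=k, replace=False):
            seq[p] = "ACGT"[(("ACGT".index(seq[p])) + 1) % 4]
        read = md.Read("r", "".join(seq))
        out = md.match_single(read, index20k, md.MatcherConfig())
        if out.status != "unique":
            continue
        aln, pattern = _align_hit(read.seq, out.hit, index20k)
        ref_seg = genome20k.sequences[0][aln.ref_start:aln.ref_start + 120]
        dp = banded_levenshtein_align(pattern, ref_seg, None,
                                      C_ASYM if out.hit.strand == FORWARD else G_ASYM)
        assert aln.errors == dp.errors == out.hit.errors


# ---------------------------------------------------------------------------
# update_counts


def _tiny_index(seq):
    return md.build_index(md.ReferenceGenome([("c", seq)]),
                          md.IndexConfig(window_size=2000))


def test_forward_read_c_and_t_over_cpg():
    seq = "ATTACGATTA" + "A" * 2000
    idx = _tiny_index(seq)
    counts = md.MethylationCounts(idx.n_cpgs)
    aln = md.AlignmentResult(0, FORWARD, 0, tuple(("M", i, i) for i in range(10)),
                             0, diagonal=True)
    md.update_counts(aln, "ATTACGATTA", idx, counts)          # C over CpG C
    assert (counts.meth[0], counts.unmeth[0]) == (1, 0)
    md.update_counts(aln, "ATTATGATTA", idx, counts)          # T over CpG C
    assert (counts.meth[0], counts.unmeth[0]) == (1, 1)
    md.update_counts(aln, "ATTAGGATTA", idx, counts)          # other base ignored
    assert (counts.meth[0], counts.unmeth[0]) == (1, 1)


def test_reverse_read_g_and_a_over_cpg():
    seq = "ATTACGATTA" + "A" * 2000
    idx = _tiny_index(seq)
    counts = md.MethylationCounts(idx.n_cpgs)
    aln = md.AlignmentResult(0, REVERSE, 0, tuple(("M", i, i) for i in range(10)),
                             0, diagonal=True)
    md.update_counts(aln, "ATTACGATTA", idx, counts)          # G over CpG G
    assert (counts.meth[0], counts.unmeth[0]) == (1, 0)
    md.update_counts(aln, "ATTACAATTA", idx, counts)          # A over CpG G
    assert (counts.meth[0], counts.unmeth[0]) == (1, 1)


def test_mate_overlap_counted_once():
    seq = "ATTACGATTA" + "A" * 2000
    idx = _tiny_index(seq)
    counts = md.MethylationCounts(idx.n_cpgs)
    aln = md.AlignmentResult(0, FORWARD, 0, tuple(("M", i, i) for i in range(10)),
                             0, diagonal=True)
    counted = md.update_counts(aln, "ATTACGATTA", idx, counts)
    md.update_counts(aln, "ATTACGATTA", idx, counts, mask_cpgs=counted)
    assert (counts.meth[0], counts.unmeth[0]) == (1, 0)


def test_overlapping_simulated_mates_increment_once(genome20k, index20k, rng):
    """A fragment whose mates both cover a CpG yields exactly one observation."""
    prof = md.MethylationProfile(np.ones(index20k.n_cpgs),
                                 np.zeros(index20k.n_cpgs, bool))
    cfg = md.SimulationConfig(n_pairs=30, paired=True, insert_min=10,
                              insert_max=60, conversion_success=1.0,
                              error_lambda=0.0)
    pairs, truth = md.simulate_pairs(genome20k, prof, cfg, rng)
    counts, stats = accumulate_counts(pairs, index20k)
    assert stats.n_unique == 30
    # exact expected coverage: one observation per fragment per CpG whose
    # informative base (C forward / G reverse) is covered by either mate
    expected = np.zeros(index20k.n_cpgs, dtype=int)
    frags = {}
    for tr in truth.reads:
        frags.setdefault(tr.read_id.split("/")[0], []).append(tr)
    sites = index20k.cpg_sites
    for mates in frags.values():
        seen = set()
        for tr in mates:
            for s in sites:
                if tr.strand == FORWARD:
                    covered = tr.start <= s.pos < tr.start + cfg.read_len
                else:
                    covered = tr.start <= s.pos + 1 < tr.start + cfg.read_len
                if covered:
                    seen.add(s.cpg_id)
        for cid in seen:
            expected[cid] += 1
    assert np.array_equal(counts.coverage(), expected)


# ---------------------------------------------------------------------------
# methylation_rates


def test_rates_and_undefined_marker():
    idx = _tiny_index("ACGAACGAAA" + "A" * 2000)
    counts = md.MethylationCounts(idx.n_cpgs)
    for _ in range(3):
        counts.add(0, True)
    counts.add(0, False)
    table = md.methylation_rates(counts, idx)
    assert table.loc[0, "rate"] == pytest.approx(0.75)
    assert np.isnan(table.loc[1, "rate"])        # uncovered: NaN, never 0


def test_fully_methylated_simulation_rates_are_one(genome20k, index20k, rng):
    prof = md.MethylationProfile(np.ones(index20k.n_cpgs),
                                 np.zeros(index20k.n_cpgs, bool))
    cfg = md.SimulationConfig(n_reads=300, conversion_success=1.0,
                              error_lambda=0.0, non_cpg_meth_prob=0.0)
    reads, _ = md.simulate_reads(genome20k, prof, cfg, rng)
    table, _ = md.process_bulk(reads, index20k)
    covered = table.dropna(subset=["rate"])
    assert (covered["rate"] == 1.0).all()


# ---------------------------------------------------------------------------
# process_bulk


def _handplaced_fixture():
    """10 error-free reads at chosen positions with chosen methylation."""
    rng = np.random.default_rng(31337)
    genome = md.random_genome(10_000, rng)
    idx = md.build_index(genome)
    sites = idx.cpg_sites
    # deterministic alternating methylation truth per CpG
    state = {s.cpg_id: (s.cpg_id % 2 == 0) for s in sites}
    reads = []
    expected = {s.cpg_id: [0, 0] for s in sites}
    placements = [(200, FORWARD), (900, REVERSE), (2100, FORWARD), (3300, FORWARD),
                  (4550, REVERSE), (5200, FORWARD), (6666, REVERSE), (7700, FORWARD),
                  (8400, REVERSE), (9850, FORWARD)]
    for i, (start, strand) in enumerate(placements):
        frag = genome.sequences[0][start:start + 100]
        seq = list(frag if strand == FORWARD else revcomp(frag))
        if strand == FORWARD:
            for s in sites:
                if start <= s.pos < start + 100:
                    j = s.pos - start
                    if not state[s.cpg_id]:
                        seq[j] = "T"
                    expected[s.cpg_id][0 if state[s.cpg_id] else 1] += 1
            # convert non-CpG cytosines fully
            for j, ch in enumerate(seq):
                gpos = start + j
                if ch == "C" and idx.cpg_at_c(0, gpos) < 0:
                    seq[j] = "T"
        else:
            for s in sites:
                gpos = s.pos + 1
                if start <= gpos < start + 100:
                    j = 100 - 1 - (gpos - start)
                    if not state[s.cpg_id]:
                        seq[j] = "T"
                    expected[s.cpg_id][0 if state[s.cpg_id] else 1] += 1
            for j, ch in enumerate(seq):
                gpos = start + (100 - 1 - j)
                # reverse-strand C corresponds to a forward G
                if ch == "C" and idx.cpg_at_g(0, gpos) < 0:
                    seq[j] = "T"
        reads.append(md.Read(f"hand{i}", "".join(seq)))
    return genome, idx, reads, expected


def test_handplaced_reads_reproduce_hand_counts():
    genome, idx, reads, expected = _handplaced_fixture()
    table, stats = md.process_bulk(reads, idx)
    assert stats.n_unique == len(reads)
    for cid, (m, u) in expected.items():
        assert (table.loc[cid, "meth"], table.loc[cid, "unmeth"]) == (m, u)


def test_result_independent_of_read_order_and_threads():
    genome, idx, reads, _ = _handplaced_fixture()
    t1, _ = md.process_bulk(reads, idx)
    shuffled = list(reads)
    np.random.default_rng(0).shuffle(shuffled)
    t2, _ = md.process_bulk(shuffled, idx)
    t3, _ = md.process_bulk(reads, idx, threads=3)
    assert t1.equals(t2)
    assert t1.equals(t3)


def test_empty_read_set():
    genome, idx, _, _ = _handplaced_fixture()[:2] + (None, None)
    table, stats = md.process_bulk([], idx)
    assert stats.n_fragments == 0
    assert table["meth"].sum() == 0
    assert table["rate"].isna().all()


def test_overlong_read_rejected(index20k):
    with pytest.raises(ValueError, match="longer than half"):
        md.process_bulk([md.Read("x", "A" * 1500)], index20k)


# ---------------------------------------------------------------------------
# single-cell


def test_degenerate_cell_profiles(genome20k, index20k, rng):
    zeros = md.MethylationProfile(np.zeros(index20k.n_cpgs),
                                  np.ones(index20k.n_cpgs, bool))
    ones = md.MethylationProfile(np.ones(index20k.n_cpgs),
                                 np.zeros(index20k.n_cpgs, bool))
    cfg = md.SimulationConfig(n_reads=200, conversion_success=1.0,
                              error_lambda=0.0, non_cpg_meth_prob=0.0)
    r0, _ = md.simulate_reads(genome20k, zeros, cfg, rng)
    r1, _ = md.simulate_reads(genome20k, ones, cfg, rng)
    batches = [md.CellBatch("hypo", r0), md.CellBatch("hyper", r1),
               md.CellBatch("empty", [])]
    matrix, stats = md.process_single_cell(batches, index20k)
    hypo = matrix.loc["hypo"].dropna()
    hyper = matrix.loc["hyper"].dropna()
    assert (hypo == 0.0).all() and len(hypo) > 0
    assert (hyper == 1.0).all() and len(hyper) > 0
    assert matrix.loc["empty"].isna().all()


def test_duplicate_cell_id_rejected(index20k):
    batches = [md.CellBatch("a", []), md.CellBatch("a", [])]
    with pytest.raises(ValueError, match="duplicate cell_id"):
        md.process_single_cell(batches, index20k)


def test_cells_concatenated_equal_bulk_sum(genome20k, index20k, rng):
    batches, _ = md.simulate_cells(genome20k, md.SimulationConfig(n_reads=150),
                                   2, 150, rng)
    per_cell = [accumulate_counts(b.items, index20k)[0] for b in batches]
    pooled, _ = accumulate_counts(
        [r for b in batches for r in b.items], index20k)
    summed_meth = sum(c.meth for c in per_cell)
    summed_unmeth = sum(c.unmeth for c in per_cell)
    assert np.array_equal(pooled.meth, summed_meth)
    assert np.array_equal(pooled.unmeth, summed_unmeth)
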