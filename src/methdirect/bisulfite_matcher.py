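"""Candidate retrieval and bisulfite-aware approximate matching.

Phase 1 looks up every spaced k-mer of the read (stride 1, C->T reduced)
in the index; entries are pre-filtered with the T-bitmask (a read C can
never sit on a genuine reference T) and tallied per (window, strand),
counting each distinct read k-mer hash once.  Windows reaching ``q`` hits
-- alone or pooled with an adjacent same-strand window, for reads that
straddle a window boundary -- go to Phase 2.

Phase 2 verifies candidates with a k-error Shift-And automaton
(Wu-Manber style: one bitvector per error level, multi-word so read
length is unbounded) under the asymmetric bisulfite rule: a reference C
is matched for free by a read T (forward strand) and a reference G by a
read A (reverse strand, applied to the reverse-complemented read), while
the opposite direction counts as an error.  The unique best hit across
all candidates -- if one exists -- proceeds to methylation calling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from numba import njit

from .reference_index import (
    A, C, G, T, N,
    FORWARD, REVERSE,
    KmerIndex,
    care_letter_mask,
    encode,
    reduce_ct,
    revcomp,
    spaced_kmer_hashes,
)

C_ASYM = "C"   # forward strand: reference C matched by read C or T
G_ASYM = "G"   # reverse strand: reference G matched by read G or A


class Read(NamedTuple):
    read_id: str
    seq: str
    mate: str = "single"   # single | mate1 | mate2


@dataclass(frozen=True)
class MatcherConfig:
    q: int = 5
    max_errors: int = 5
    insert_min: int = 0
    insert_max: int = 1000

    def __post_init__(self):
        if self.q < 1:
            raise ValueError("q must be >= 1")
        if self.max_errors < 0:
            raise ValueError("max_errors must be >= 0")
        if self.insert_min > self.insert_max:
            raise ValueError("insert_min must be <= insert_max")


class CandidateScore(NamedTuple):
    mcpg_id: int
    strand: int
    count: int


class MatchHit(NamedTuple):
    chrom: int
    mcpg_id: int
    strand: int
    ref_end: int      # 0-based inclusive end on forward reference coordinates
    errors: int


UNIQUE = "unique"
AMBIGUOUS = "ambiguous"
UNMAPPED = "unmapped"


@dataclass(frozen=True)
class MatchOutcome:
    status: str
    hit: MatchHit | None = None

    def __post_init__(self):
        if (self.status == UNIQUE) != (self.hit is not None):
            raise ValueError("hit must be present iff status is unique")


# ---------------------------------------------------------------------------
# bisulfite-aware masks


def build_bisulfite_masks(read_seq: str, asym: str) -> dict:
    """Per-letter Shift-And bitmasks (bit i = read position i).

    ``masks[X]`` marks the read positions compatible with reference letter
    X.  In C-asym mode a reference C is matched by read C *or* T; in
    G-asym mode a reference G is matched by read G *or* A.  Read Ns set no
    bit anywhere (always a mismatch).
    """
    masks = {b: 0 for b in "ACGTN"}
    for i, ch in enumerate(read_seq):
        bit = 1 << i
        if ch == "N":
            continue
        masks[ch] |= bit
        if asym == C_ASYM and ch == "T":
            masks["C"] |= bit
        elif asym == G_ASYM and ch == "A":
            masks["G"] |= bit
    return masks


def _masks_to_words(masks: dict, m: int) -> np.ndarray:
    W = (m + 63) // 64
    B = np.zeros((5, W), dtype=np.uint64)
    full = (1 << 64) - 1
    for letter, code in (("A", A), ("C", C), ("G", G), ("T", T), ("N", N)):
        bits = masks[letter]
        for w in range(W):
            B[code, w] = (bits >> (64 * w)) & full
    return B


# ---------------------------------------------------------------------------
# k-error Shift-And kernel


@njit(cache=True)
def _kerror_levels(text, B, m, k):   # pragma: no cover - exercised via wrapper
    """Minimal error level (<=k) of a full-pattern match ending at each text
    position, or -1.  Multi-word Wu-Manber update, one bitvector per level."""
    W = B.shape[1]
    n = text.shape[0]
    one = np.uint64(1)
    s63 = np.uint64(63)
    R = np.zeros((k + 1, W), dtype=np.uint64)
    for j in range(1, k + 1):          # level j starts with first j chars deletable
        for b in range(j):
            R[j, b >> 6] |= one << np.uint64(b & 63)
    old = np.zeros((k + 1, W), dtype=np.uint64)
    shold = np.zeros((k + 1, W), dtype=np.uint64)
    out = np.full(n, -1, dtype=np.int16)
    hw = (m - 1) >> 6
    hb = np.uint64((m - 1) & 63)
    for t in range(n):
        c = text[t]
        for j in range(k + 1):
            carry = np.uint64(0)
            for w in range(W):
                v = R[j, w]
                old[j, w] = v
                shold[j, w] = (v << one) | carry
                carry = v >> s63
        # level 0: exact (asymmetric) matching
        for w in range(W):
            x = shold[0, w]
            if w == 0:
                x |= one
            R[0, w] = x & B[c, w]
        # higher levels: substitution / insertion / deletion transitions
        for j in range(1, k + 1):
            carry = np.uint64(0)
            for w in range(W):
                v = R[j - 1, w]        # freshly updated level j-1
                shnew = (v << one) | carry
                carry = v >> s63
                x = shold[j, w]
                if w == 0:
                    x |= one
                x &= B[c, w]
                sub = shold[j - 1, w]
                dele = shnew
                if w == 0:
                    sub |= one
                    dele |= one
                R[j, w] = x | sub | old[j - 1, w] | dele
        for j in range(k + 1):
            if (R[j, hw] >> hb) & one:
                out[t] = j
                break
    return out


def shift_and_search(read_seq: str, text, asym: str, max_errors: int) -> list:
    """Semi-global k-error search of ``read_seq`` in ``text``.

    Returns ``(end_pos, errors)`` tuples: every text position where the
    full read matches with edit distance <= ``max_errors`` under the
    asymmetric substitution rule, with the minimal error count at that end
    position.  ``text`` may be a string or a uint8 code array.
    """
    m = len(read_seq)
    if m == 0:
        raise ValueError("empty read")
    codes = encode(text) if isinstance(text, str) else np.ascontiguousarray(text)
    if len(codes) == 0:
        return []
    B = _masks_to_words(build_bisulfite_masks(read_seq, asym), m)
    levels = _kerror_levels(codes.astype(np.uint8), B, m, int(max_errors))
    return [(int(t), int(l)) for t, l in enumerate(levels) if l >= 0]


# ---------------------------------------------------------------------------
# Phase 1: candidate retrieval


def _adjacent(index: KmerIndex, m1: int, m2: int) -> bool:
    if abs(m1 - m2) != 1:
        return False
    return index.mcpgs[m1].chrom == index.mcpgs[m2].chrom


def retrieve_candidates(read: Read, index: KmerIndex, q: int) -> list:
    """Score (window, strand) pairs by distinct read k-mer hash hits.

    A window passes if it collects >= q distinct hits on its own, or
    pooled with an adjacent same-strand window (reads straddling a window
    boundary); in the pooled case both windows pass.
    """
    seed = index.config.seed
    codes = encode(read.seq)
    if len(codes) < seed.span:
        return []
    hashes, valid = spaced_kmer_hashes(reduce_ct(codes), seed)
    cmask = care_letter_mask(codes, seed, C)
    table = index.table
    seen: dict = {}
    for p in range(len(hashes)):
        if not valid[p]:
            continue
        h = int(hashes[p])
        cell = table.get(h)
        if not cell:
            continue
        cm = int(cmask[p])
        for e in cell:
            if cm & e.t_mask:
                continue   # read C over a genuine reference T: impossible origin
            s = seen.get((e.mcpg_id, e.strand))
            if s is None:
                seen[(e.mcpg_id, e.strand)] = {h}
            else:
                s.add(h)
    counts = {key: len(s) for key, s in seen.items()}
    passing = set()
    for (m, s), c in counts.items():
        if c >= q:
            passing.add((m, s))
            continue
        for mn in (m - 1, m + 1):
            if (mn, s) in counts and _adjacent(index, m, mn) \
                    and c + counts[(mn, s)] >= q:
                passing.add((m, s))
                passing.add((mn, s))
    return sorted(CandidateScore(m, s, counts[(m, s)]) for m, s in passing)


# ---------------------------------------------------------------------------
# Phase 2: verification


def _oriented_pattern(read_seq: str, strand: int) -> tuple:
    """Pattern and asymmetry mode for verifying against the forward reference."""
    if strand == FORWARD:
        return read_seq, C_ASYM
    return revcomp(read_seq), G_ASYM


def verify_candidates(read: Read, index: KmerIndex, candidates,
                      max_errors: int) -> list:
    """Run the Shift-And automaton on every candidate window.

    Each window is extended by (read length - 1) bp on both sides (clipped
    at chromosome ends) so boundary-straddling placements are found.  Hits
    landing at the same (chrom, strand, ref_end) via overlapping extended
    windows are deduplicated.
    """
    m = len(read.seq)
    ext = m - 1
    pattern_cache: dict = {}
    best: dict = {}
    for cand in candidates:
        win = index.mcpgs[cand.mcpg_id]
        chrom_codes = index.genome.codes(win.chrom)
        a = max(0, win.start - ext)
        b = min(len(chrom_codes), win.end + ext)
        if b - a < 1:
            continue
        cached = pattern_cache.get(cand.strand)
        if cached is None:
            pat, asym = _oriented_pattern(read.seq, cand.strand)
            B = _masks_to_words(build_bisulfite_masks(pat, asym), m)
            pattern_cache[cand.strand] = B
            cached = B
        levels = _kerror_levels(chrom_codes[a:b].astype(np.uint8), cached,
                                m, int(max_errors))
        for t in np.flatnonzero(levels >= 0):
            key = (win.chrom, cand.strand, a + int(t))
            err = int(levels[t])
            if key not in best or err < best[key][1]:
                best[key] = (cand.mcpg_id, err)
    return [MatchHit(chrom, mcpg, strand, end, err)
            for (chrom, strand, end), (mcpg, err) in sorted(best.items())]


def _alignment_start(pattern_codes: np.ndarray, chrom_codes: np.ndarray,
                     ref_end: int, errors: int, asym: str) -> int:
    """Start coordinate of an optimal alignment ending exactly at ``ref_end``.

    Small forward DP over the (read + errors)-wide text slice, propagating
    the start column of the best path; predecessor preference substitution
    > deletion > insertion matches the Phase-3 traceback order.
    """
    m = len(pattern_codes)
    a = max(0, ref_end + 1 - m - errors)
    text = chrom_codes[a:ref_end + 1]
    n = len(text)
    INF = m + n + 1
    D = np.zeros(n + 1, dtype=np.int32)
    S = np.arange(n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        p = int(pattern_codes[i - 1])
        prevD, prevS = D, S
        D = np.full(n + 1, INF, dtype=np.int32)
        S = np.zeros(n + 1, dtype=np.int32)
        D[0] = i
        S[0] = 0
        for j in range(1, n + 1):
            r = int(text[j - 1])
            free = (p == r and p != 4) or \
                   (asym == C_ASYM and r == C and p == T) or \
                   (asym == G_ASYM and r == G and p == A)
            best = prevD[j - 1] + (0 if free else 1)
            src = prevS[j - 1]
            if D[j - 1] + 1 < best:
                best = D[j - 1] + 1
                src = S[j - 1]
            if prevD[j] + 1 < best:
                best = prevD[j] + 1
                src = prevS[j]
            D[j] = best
            S[j] = src
    return a + int(S[n])


def _placement(read_seq: str, hit: MatchHit, index: KmerIndex) -> tuple:
    """(chrom, strand, alignment start) identifying a genomic placement."""
    pat, asym = _oriented_pattern(read_seq, hit.strand)
    start = _alignment_start(encode(pat), index.genome.codes(hit.chrom),
                             hit.ref_end, hit.errors, asym)
    return (hit.chrom, hit.strand, start)


def select_unique_best(hits, read: Read | None = None,
                       index: KmerIndex | None = None) -> MatchOutcome:
    """Unique minimal-error hit -> unique; tied placements -> ambiguous.

    Adjacent end positions with equal cost (e.g. a mismatch at the read's
    last base, reachable as substitution or as trailing insertion) are the
    same genomic placement: when ``read`` and ``index`` are supplied, tied
    hits are grouped by their alignment start and a tie collapses to
    unique if all share one start.
    """
    dedup: dict = {}
    for h in hits:
        key = (h.chrom, h.strand, h.ref_end)
        if key not in dedup or h.errors < dedup[key].errors:
            dedup[key] = h
    if not dedup:
        return MatchOutcome(UNMAPPED)
    ranked = sorted(dedup.values(), key=lambda h: (h.errors, h.chrom, h.strand, h.ref_end))
    if len(ranked) == 1 or ranked[1].errors > ranked[0].errors:
        return MatchOutcome(UNIQUE, ranked[0])
    tied = [h for h in ranked if h.errors == ranked[0].errors]
    if read is None or index is None:
        return MatchOutcome(AMBIGUOUS)
    placements = {}
    for h in tied:
        placements.setdefault(_placement(read.seq, h, index), []).append(h)
    if len(placements) > 1:
        return MatchOutcome(AMBIGUOUS)
    (chrom, strand, start), group = next(iter(placements.items()))
    m = len(read.seq)
    for h in group:
        if h.ref_end == start + m - 1:    # pure-substitution end, if present
            return MatchOutcome(UNIQUE, h)
    return MatchOutcome(UNIQUE, max(group, key=lambda h: h.ref_end))


def _precheck(read: Read, index: KmerIndex, config: MatcherConfig) -> bool:
    if len(read.seq) < index.config.seed.span:
        return False          # unmapped: too short for the index
    if read.seq.count("N") > config.max_errors:
        return False          # every N costs >= 1 error
    return True


def match_single(read: Read, index: KmerIndex, config: MatcherConfig) -> MatchOutcome:
    """Three-phase single-end matching up to unique-best-hit selection."""
    if not _precheck(read, index, config):
        return MatchOutcome(UNMAPPED)
    cands = retrieve_candidates(read, index, config.q)
    if not cands:
        return MatchOutcome(UNMAPPED)
    hits = verify_candidates(read, index, cands, config.max_errors)
    return select_unique_best(hits, read, index)


# ---------------------------------------------------------------------------
# paired-end


def _five_prime(hit: MatchHit, read_len: int) -> int:
    """5'-most forward-reference coordinate of the mate at this hit."""
    if hit.strand == FORWARD:
        return hit.ref_end - (read_len - 1)
    return hit.ref_end


def _prune_mates(index, cands1, cands2):
    """Keep a candidate only if the other mate has one in the same or an
    adjacent window on the opposite strand (2 kb windows vs <=1 kb inserts)."""
    def survives(c, others):
        for o in others:
            if o.strand == c.strand:
                continue
            if o.mcpg_id == c.mcpg_id or _adjacent(index, c.mcpg_id, o.mcpg_id):
                return True
        return False

    k1 = [c for c in cands1 if survives(c, cands2)]
    k2 = [c for c in cands2 if survives(c, cands1)]
    return k1, k2


def match_pair(read1: Read, read2: Read, index: KmerIndex,
               config: MatcherConfig) -> tuple:
    """Paired matching with insert-size pruning and joint best-pair selection.

    The selected pair is the opposite-strand hit combination whose 5'-start
    distance lies within [insert_min, insert_max] and whose total error
    count is minimal; ties make both mates ambiguous, no valid combination
    makes both unmapped (no single-end rescue).
    """
    if not (_precheck(read1, index, config) and _precheck(read2, index, config)):
        return MatchOutcome(UNMAPPED), MatchOutcome(UNMAPPED)
    c1 = retrieve_candidates(read1, index, config.q)
    c2 = retrieve_candidates(read2, index, config.q)
    c1, c2 = _prune_mates(index, c1, c2)
    if not c1 or not c2:
        return MatchOutcome(UNMAPPED), MatchOutcome(UNMAPPED)
    h1 = verify_candidates(read1, index, c1, config.max_errors)
    h2 = verify_candidates(read2, index, c2, config.max_errors)
    best_pairs = []
    best_cost = None
    for a in h1:
        for b in h2:
            if a.chrom != b.chrom or a.strand == b.strand:
                continue
            d = abs(_five_prime(b, len(read2.seq)) - _five_prime(a, len(read1.seq)))
            if not (config.insert_min <= d <= config.insert_max):
                continue
            cost = a.errors + b.errors
            if best_cost is None or cost < best_cost:
                best_cost = cost
                best_pairs = [(a, b)]
            elif cost == best_cost:
                best_pairs.append((a, b))
    if not best_pairs:
        return MatchOutcome(UNMAPPED), MatchOutcome(UNMAPPED)
    placements: dict = {}
    for a, b in best_pairs:
        key = (_placement(read1.seq, a, index), _placement(read2.seq, b, index))
        placements.setdefault(key, []).append((a, b))
    if len(placements) > 1:
        return MatchOutcome(AMBIGUOUS), MatchOutcome(AMBIGUOUS)
    group = next(iter(placements.values()))
    (key1, key2) = next(iter(placements.keys()))

    def pick(hits_reads):
        hits, read_len, start = hits_reads
        for h in hits:
            if h.ref_end == start + read_len - 1:
                return h
        return max(hits, key=lambda h: h.ref_end)

    a = pick(([p[0] for p in group], len(read1.seq), key1[2]))
    b = pick(([p[1] for p in group], len(read2.seq), key2[2]))
    return MatchOutcome(UNIQUE, a), MatchOutcome(UNIQUE, b)
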