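"""Reference genome handling and the spaced k-mer Meta-CpG index.

The genome is segmented into non-overlapping ~2 kb windows ("Meta-CpGs"),
each owning the CpG sites whose C falls inside it.  Both bisulfite strand
representations are indexed: the forward sequence and its reverse
complement, each reduced C->T before hashing, so that bisulfite-converted
read k-mers hash to the same cells as their genomic origin.  Hashing uses
a rotate-XOR scheme over the seed's care positions (incrementally
updatable along the sequence; computed vectorised here).

Three index optimizations are applied after the raw build:

1. entries in one cell sharing (window, strand) are merged (masks ANDed),
2. cells holding more entries than ``filter_t`` are emptied (repeats),
3. every entry carries a T-bitmask over the seed's care positions marking
   genuine reference Ts, letting the matcher reject candidates where a
   read C would have to sit on a reference T.
"""

from __future__ import annotations

import gzip
import pickle
import warnings
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np
from Bio import SeqIO

# ---------------------------------------------------------------------------
# encoding

BASE_ORDER = "ACGTN"
CODE = {b: i for i, b in enumerate(BASE_ORDER)}
A, C, G, T, N = range(5)
_COMPLEMENT = np.array([T, G, C, A, N], dtype=np.uint8)
_TRANS = np.full(256, N, dtype=np.uint8)
for _b, _i in CODE.items():
    _TRANS[ord(_b)] = _i

FORWARD = 0   # C->T reduced forward strand representation
REVERSE = 1   # C->T reduced reverse-complement representation

INDEX_FORMAT_VERSION = 2


def encode(seq: str) -> np.ndarray:
    """Encode an uppercase DNA string as uint8 codes (A=0,C=1,G=2,T=3,N=4)."""
    return _TRANS[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join(BASE_ORDER[c] for c in codes)


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes][::-1]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def reduce_ct(codes: np.ndarray) -> np.ndarray:
    """Collapse C onto T (the bisulfite reduction used for hashing)."""
    out = codes.copy()
    out[out == C] = T
    return out


# ---------------------------------------------------------------------------
# spaced seed & hashing


@dataclass(frozen=True)
class SpacedSeed:
    """Care/wildcard pattern applied to every k-mer before hashing.

    ``care`` is a tuple of booleans of length ``span``; True marks a care
    position.  The first and last positions must be care positions and the
    weight (number of care positions) must be at least 12.
    """

    care: tuple

    def __post_init__(self):
        if len(self.care) < 2 or not self.care[0] or not self.care[-1]:
            raise ValueError("seed must begin and end with care positions")
        if self.weight < 12:
            raise ValueError("seed weight must be >= 12")

    @property
    def span(self) -> int:
        return len(self.care)

    @property
    def weight(self) -> int:
        return sum(self.care)

    @property
    def care_offsets(self) -> tuple:
        return tuple(j for j, c in enumerate(self.care) if c)

    @classmethod
    def default(cls) -> "SpacedSeed":
        """Span-20 seed, wildcards at offsets 4, 9 and 14 (weight 17).

        The interior wildcards absorb isolated base-call errors so that a
        single miscalled base does not wipe out every overlapping k-mer.
        """
        wild = {4, 9, 14}
        return cls(tuple(j not in wild for j in range(20)))

    @classmethod
    def from_pattern(cls, pattern: str) -> "SpacedSeed":
        """Build from a string like '####_####' (# = care, _ = wildcard)."""
        return cls(tuple(ch == "#" for ch in pattern))

    def pattern(self) -> str:
        return "".join("#" if c else "_" for c in self.care)


# fixed 64-bit mixing constants per letter (ntHash-style rotate-XOR)
_HASH_SEEDS = np.array(
    [
        0x3C8BFBB395C60474,  # A
        0x3193C18562A02B4C,  # C (never hashed after reduction; kept for masks)
        0x20323ED082572324,  # G
        0x295549F54BE24456,  # T
        0x0000000000000000,  # N (windows containing N are skipped anyway)
    ],
    dtype=np.uint64,
)


def _rot64(v: np.uint64, r: int) -> np.uint64:
    r %= 64
    if r == 0:
        return v
    return np.uint64((int(v) << r | int(v) >> (64 - r)) & 0xFFFFFFFFFFFFFFFF)


_ROT_CACHE: dict = {}


def _rot_table(seed: SpacedSeed) -> np.ndarray:
    """(span, 5) table: letter constant rotated by its offset from the seed end."""
    key = seed.care
    tab = _ROT_CACHE.get(key)
    if tab is None:
        span = seed.span
        tab = np.zeros((span, 5), dtype=np.uint64)
        for j in seed.care_offsets:
            for letter in range(5):
                tab[j, letter] = _rot64(_HASH_SEEDS[letter], span - 1 - j)
        _ROT_CACHE[key] = tab
    return tab


def spaced_kmer_hashes(codes: np.ndarray, seed: SpacedSeed) -> tuple:
    """Hashes of every spaced k-mer of ``codes`` plus a validity mask.

    Returns ``(hashes, valid)`` where ``hashes[i]`` is the 64-bit hash of
    the k-mer starting at i and ``valid[i]`` is False when the k-mer span
    overlaps an N.  ``codes`` must already be C->T reduced by the caller
    when bisulfite-reduced hashing is wanted.
    """
    span = seed.span
    n = len(codes) - span + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    tab = _rot_table(seed)
    h = np.zeros(n, dtype=np.uint64)
    for j in seed.care_offsets:
        h ^= tab[j][codes[j : j + n]]
    is_n = (codes == N).astype(np.int32)
    win = np.cumsum(np.concatenate(([0], is_n)))
    valid = (win[span:] - win[:-span]) == 0
    return h, valid


def care_letter_mask(codes: np.ndarray, seed: SpacedSeed, letter: int) -> np.ndarray:
    """Per-start bitmask over care positions where ``codes`` holds ``letter``.

    Bit b of the result corresponds to the b-th care offset of the seed.
    """
    span = seed.span
    n = len(codes) - span + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    m = np.zeros(n, dtype=np.uint64)
    for b, j in enumerate(seed.care_offsets):
        m |= (codes[j : j + n] == letter).astype(np.uint64) << np.uint64(b)
    return m


# ---------------------------------------------------------------------------
# domain types


class ReferenceGenome:
    """Ordered collection of chromosomes with cached code arrays."""

    def __init__(self, chromosomes):
        names = [n for n, _ in chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in reference")
        if not chromosomes:
            raise ValueError("empty reference")
        self.names = names
        self.sequences = [s for _, s in chromosomes]
        if any(len(s) == 0 for s in self.sequences):
            raise ValueError("empty chromosome sequence in reference")
        self._codes = [None] * len(names)

    def __len__(self):
        return len(self.names)

    def codes(self, chrom_idx: int) -> np.ndarray:
        c = self._codes[chrom_idx]
        if c is None:
            c = encode(self.sequences[chrom_idx])
            self._codes[chrom_idx] = c
        return c

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences)


class CpGSite(NamedTuple):
    cpg_id: int
    chrom: int        # chromosome index into the genome
    pos: int          # 0-based position of the C of the forward-strand CG
    mcpg_id: int


class MetaCpG(NamedTuple):
    mcpg_id: int
    chrom: int
    start: int        # 0-based half-open window on the forward strand
    end: int
    cpg_ids: tuple


@dataclass(frozen=True)
class IndexConfig:
    window_size: int = 2000
    seed: SpacedSeed = field(default_factory=SpacedSeed.default)
    stride: int = 2
    filter_t: int = 1500
    table_size_hint: int | None = None

    def __post_init__(self):
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.filter_t < 1:
            raise ValueError("filter_t must be >= 1")


class IndexEntry(NamedTuple):
    mcpg_id: int
    strand: int       # FORWARD or REVERSE
    t_mask: int       # 1-bits at care positions holding T in the unconverted reference


# ---------------------------------------------------------------------------
# operations


def _open_maybe_gzip(path):
    p = str(path)
    if p.endswith(".gz"):
        return gzip.open(p, "rt")
    return open(p, "rt")


def load_reference(fasta_path) -> ReferenceGenome:
    """Load a (possibly gzipped) multi-record FASTA.

    Sequences are uppercased and any letter outside {A,C,G,T,N} is mapped
    to N.  Duplicate record names and empty files are hard errors.
    """
    chroms = []
    with _open_maybe_gzip(fasta_path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            seq = decode(encode(seq))  # fold unknown letters to N
            chroms.append((rec.id, seq))
    if not chroms:
        raise ValueError(f"no FASTA records in {fasta_path}")
    return ReferenceGenome(chroms)


def enumerate_cpgs(genome: ReferenceGenome, window_size: int = 2000) -> list:
    """One CpGSite per forward-strand CG dinucleotide, dense ids in genomic order."""
    sites = []
    cpg_id = 0
    win_offsets = _window_offsets(genome, window_size)
    for ci in range(len(genome)):
        codes = genome.codes(ci)
        pos = np.flatnonzero((codes[:-1] == C) & (codes[1:] == G))
        for p in pos:
            mcpg = win_offsets[ci] + int(p) // window_size
            sites.append(CpGSite(cpg_id, ci, int(p), mcpg))
            cpg_id += 1
    return sites


def _window_offsets(genome: ReferenceGenome, window_size: int) -> list:
    offs, total = [], 0
    for ci in range(len(genome)):
        offs.append(total)
        total += -(-len(genome.sequences[ci]) // window_size)
    return offs


def segment_meta_cpgs(genome: ReferenceGenome, window_size: int = 2000,
                      cpg_sites=None) -> list:
    """Tile each chromosome with half-open ``window_size`` windows.

    The final window of a chromosome may be shorter.  Each CpG is assigned
    to the window containing its C.
    """
    if window_size < 100:
        raise ValueError("window_size must be >= 100")
    if cpg_sites is None:
        cpg_sites = enumerate_cpgs(genome, window_size)
    per_window: dict = {}
    for s in cpg_sites:
        per_window.setdefault(s.mcpg_id, []).append(s.cpg_id)
    mcpgs = []
    mid = 0
    for ci in range(len(genome)):
        L = len(genome.sequences[ci])
        for start in range(0, L, window_size):
            mcpgs.append(
                MetaCpG(mid, ci, start, min(start + window_size, L),
                        tuple(per_window.get(mid, ())))
            )
            mid += 1
    return mcpgs


class KmerIndex:
    """Spaced k-mer hash table over Meta-CpG windows plus the CpG registry."""

    def __init__(self, genome: ReferenceGenome, config: IndexConfig):
        self.genome = genome
        self.config = config
        self.cpg_sites = enumerate_cpgs(genome, config.window_size)
        self.mcpgs = segment_meta_cpgs(genome, config.window_size, self.cpg_sites)
        self.table: dict = {}
        self.filtered: set = set()
        self._win_offsets = _window_offsets(genome, config.window_size)
        # per-chrom sorted C positions and their cpg ids, for O(log n) lookup
        self._cpg_pos = []
        self._cpg_ids = []
        for ci in range(len(genome)):
            ps = [s.pos for s in self.cpg_sites if s.chrom == ci]
            ids = [s.cpg_id for s in self.cpg_sites if s.chrom == ci]
            self._cpg_pos.append(np.asarray(ps, dtype=np.int64))
            self._cpg_ids.append(np.asarray(ids, dtype=np.int64))

    # -- geometry ----------------------------------------------------------
    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_sites)

    def window_of(self, chrom_idx: int, pos: int) -> int:
        return self._win_offsets[chrom_idx] + pos // self.config.window_size

    def cpg_at_c(self, chrom_idx: int, pos: int) -> int:
        """cpg_id whose C sits at ``pos`` on ``chrom_idx``, or -1."""
        ps = self._cpg_pos[chrom_idx]
        i = np.searchsorted(ps, pos)
        if i < len(ps) and ps[i] == pos:
            return int(self._cpg_ids[chrom_idx][i])
        return -1

    def cpg_at_g(self, chrom_idx: int, pos: int) -> int:
        """cpg_id whose G sits at ``pos`` (i.e. C at pos-1), or -1."""
        return self.cpg_at_c(chrom_idx, pos - 1) if pos >= 1 else -1

    # -- retrieval ---------------------------------------------------------
    def lookup(self, h: int) -> list:
        return self.table.get(h, ())

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        payload = {
            "format_version": INDEX_FORMAT_VERSION,
            "config": {
                "window_size": self.config.window_size,
                "seed_pattern": self.config.seed.pattern(),
                "stride": self.config.stride,
                "filter_t": self.config.filter_t,
            },
            "chromosomes": list(zip(self.genome.names, self.genome.sequences)),
            "table": self.table,
            "filtered": self.filtered,
        }
        with open(path, "wb") as fh:
            pickle.dump(payload, fh, protocol=4)

    @classmethod
    def load(cls, path) -> "KmerIndex":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("format_version") != INDEX_FORMAT_VERSION:
            raise ValueError(
                f"unsupported index format version {payload.get('format_version')}"
            )
        cfg = payload["config"]
        config = IndexConfig(
            window_size=cfg["window_size"],
            seed=SpacedSeed.from_pattern(cfg["seed_pattern"]),
            stride=cfg["stride"],
            filter_t=cfg["filter_t"],
        )
        idx = cls(ReferenceGenome(payload["chromosomes"]), config)
        idx.table = payload["table"]
        idx.filtered = payload["filtered"]
        return idx


def build_index(genome: ReferenceGenome, config: IndexConfig | None = None,
                optimize: bool = True) -> KmerIndex:
    """Populate the spaced k-mer hash table for both strand representations.

    Every ``stride``-th k-mer start (anchored at 0 within each strand
    representation) is hashed after C->T reduction; entries are tagged with
    the Meta-CpG window their start lies in (on forward coordinates) and
    carry the T-bitmask of the unconverted reference letters.
    """
    if config is None:
        config = IndexConfig()
    idx = KmerIndex(genome, config)
    seed = config.seed
    span = seed.span
    if all(len(s) < span for s in genome.sequences):
        warnings.warn("genome shorter than seed span; index is empty")
        return idx
    table = idx.table
    for ci in range(len(genome)):
        codes = genome.codes(ci)
        Lc = len(codes)
        if Lc < span:
            continue
        for strand in (FORWARD, REVERSE):
            strand_codes = codes if strand == FORWARD else revcomp_codes(codes)
            hashes, valid = spaced_kmer_hashes(reduce_ct(strand_codes), seed)
            tmask = care_letter_mask(strand_codes, seed, T)
            for p in range(0, len(hashes), config.stride):
                if not valid[p]:
                    continue
                fstart = p if strand == FORWARD else Lc - p - span
                entry = IndexEntry(idx.window_of(ci, fstart), strand, int(tmask[p]))
                table.setdefault(int(hashes[p]), []).append(entry)
    if optimize:
        apply_index_optimizations(idx)
    return idx


def apply_index_optimizations(index: KmerIndex, filter_t: int | None = None) -> KmerIndex:
    """Dedup per (window, strand) with AND-merged T-masks; drop repeat cells.

    Merging masks with AND is conservative: a bit survives only if every
    merged occurrence has a genuine reference T there, so the matcher's
    rejection test can never produce a false rejection.  Cells whose
    post-merge entry count exceeds ``filter_t`` are emptied and recorded in
    ``index.filtered``.
    """
    if filter_t is None:
        filter_t = index.config.filter_t
    table = index.table
    for h in list(table):
        cell = table[h]
        merged: dict = {}
        for e in cell:
            key = (e.mcpg_id, e.strand)
            prev = merged.get(key)
            merged[key] = e.t_mask if prev is None else (prev & e.t_mask)
        if len(merged) > filter_t:
            del table[h]
            index.filtered.add(h)
        else:
            table[h] = [IndexEntry(m, s, tm) for (m, s), tm in merged.items()]
    return index
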