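"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive (full DP tables, quadratic scans,
explicit loops) and shares no code with the package internals.
"""

import numpy as np


def asym_sub_cost(p: str, r: str, asym: str) -> int:
    """0/1 substitution cost under the one-directional bisulfite rule."""
    if p == r and p != "N":
        return 0
    if asym == "C" and r == "C" and p == "T":
        return 0
    if asym == "G" and r == "G" and p == "A":
        return 0
    return 1


def asym_dp_table(pattern: str, text: str, asym: str):
    """Full semi-global DP table (free text prefix), D[i][j] for pat[:i] vs text[:j]."""
    m, n = len(pattern), len(text)
    D = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        D[i][0] = i
        for j in range(1, n + 1):
            D[i][j] = min(
                D[i - 1][j - 1] + asym_sub_cost(pattern[i - 1], text[j - 1], asym),
                D[i - 1][j] + 1,
                D[i][j - 1] + 1,
            )
    return D


def asym_match_ends(pattern: str, text: str, asym: str, max_errors: int):
    """(end_pos, distance) for every end position with distance <= max_errors."""
    D = asym_dp_table(pattern, text, asym)
    m = len(pattern)
    return [(j - 1, D[m][j]) for j in range(1, len(text) + 1)
            if D[m][j] <= max_errors]


def asym_best_distance(pattern: str, text: str, asym: str) -> int:
    """Minimal semi-global distance anywhere in the text."""
    D = asym_dp_table(pattern, text, asym)
    return min(D[len(pattern)][j] for j in range(len(text) + 1))


def scan_cg_positions(seq: str):
    """Positions of every CG dinucleotide by naive substring scan."""
    out = []
    i = seq.find("CG")
    while i != -1:
        out.append(i)
        i = seq.find("CG", i + 1)
    return out


def naive_rmse(truth, pred) -> float:
    total = 0.0
    for t, p in zip(truth, pred):
        total += (t - p) ** 2
    return (total / len(truth)) ** 0.5


def naive_spearman(truth, pred) -> float:
    """Average-rank transform followed by a hand-rolled Pearson correlation."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    a, b = ranks(list(truth)), ranks(list(pred))
    ma, mb = sum(a) / len(a), sum(b) / len(b)
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    va = sum((x - ma) ** 2 for x in a) ** 0.5
    vb = sum((y - mb) ** 2 for y in b) ** 0.5
    return cov / (va * vb)


def count_spaced_kmer_occurrences(seq: str, kmer_reduced: str, care) -> int:
    """Occurrences of a reduced spaced k-mer by brute scan of a reduced sequence."""
    red = seq.replace("C", "T")
    span = len(care)
    n = 0
    for i in range(len(red) - span + 1):
        if all(red[i + j] == kmer_reduced[j] for j in range(span) if care[j]):
            n += 1
    return n


def random_dna(rng, n: int, with_n: float = 0.0) -> str:
    probs = [(1 - with_n) / 4] * 4 + [with_n]
    return "".join(rng.choice(list("ACGTN"), p=probs) for _ in range(n))
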