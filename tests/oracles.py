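"""Independent brute-force oracles used to cross-check the implementations.

Each oracle is deliberately naive — plain Python loops and exact
combinatorics — and shares no code with the package internals it checks.
"""

from __future__ import annotations

import math


def bruteforce_enrichment_score(scores, hit_flags, exponent=1.0):
    """Weighted running sum by direct enumeration; returns (ES, peak_index)."""
    n = len(scores)
    n_hits = sum(hit_flags)
    hit_total = sum(abs(s) ** exponent for s, h in zip(scores, hit_flags) if h)
    running = 0.0
    best = 0.0
    peak = 0
    for i in range(n):
        if hit_flags[i]:
            if hit_total > 0:
                running += abs(scores[i]) ** exponent / hit_total
            else:
                running += 1.0 / n_hits
        else:
            running -= 1.0 / (n - n_hits)
        if abs(running) > abs(best):
            best = running
            peak = i
    return best, peak


_ALLOWED = {"A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"}, "R": {"G", "A"}, "N": {"A", "C", "G", "T"}}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def expand_consensus(consensus: str) -> list[set[str]]:
    out: list[set[str]] = []
    i = 0
    while i < len(consensus):
        sym = consensus[i]
        i += 1
        repeat = 1
        if i < len(consensus) and consensus[i] == "{":
            j = consensus.index("}", i)
            repeat = int(consensus[i + 1 : j])
            i = j + 1
        out.extend([_ALLOWED[sym]] * repeat)
    return out


def naive_scan(sequence: str, consensus: str, both_strands: bool = True):
    """Position-by-position sliding-window match; returns [(start, strand)]."""
    allowed = expand_consensus(consensus)
    w = len(allowed)
    hits = []
    for start in range(len(sequence) - w + 1):
        if all(sequence[start + j] in allowed[j] for j in range(w)):
            hits.append((start, "+"))
    if both_strands:
        rc = "".join(_COMP[b] for b in reversed(sequence))
        for start in range(len(rc) - w + 1):
            if all(rc[start + j] in allowed[j] for j in range(w)):
                hits.append((len(sequence) - start - w, "-"))
    return sorted(hits)


def hypergeom_upper_tail_exact(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by exact binomial-coefficient arithmetic (Fraction-free, exact for small N)."""
    total = math.comb(N, n)
    return sum(math.comb(K, x) * math.comb(N - K, n - x) for x in range(k, min(K, n) + 1)) / total


def hypergeom_lower_tail_exact(k: int, K: int, n: int, N: int) -> float:
    total = math.comb(N, n)
    return sum(math.comb(K, x) * math.comb(N - K, n - x) for x in range(max(0, n - (N - K)), k + 1)) / total
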