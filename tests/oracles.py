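"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's own primitives (no reverse-complement
reduction, no substring search): complementarity is checked pair-by-pair so
the oracles constitute a second, independent route to the same quantities.
"""

from __future__ import annotations

import itertools

WC_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}


def is_complementary(transcript_base: str, guide_base: str) -> bool:
    return (transcript_base, guide_base) in WC_PAIRS


def dp_longest_complementary_run(transcript: str, guide: str) -> int:
    """O(n*m) dynamic program over antiparallel Watson-Crick pairings.

    run[i][j] = length of the complementary stretch ending at transcript
    position i (0-based) paired with guide position j, where the stretch
    extends with increasing i and decreasing j (antiparallel).
    """
    n, m = len(transcript), len(guide)
    best = 0
    prev = [0] * m  # prev[j] = run ending at (i-1, j)
    for i in range(n):
        cur = [0] * m
        for j in range(m):
            if is_complementary(transcript[i], guide[j]):
                cur[j] = (prev[j + 1] if j + 1 < m else 0) + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def naive_seed_complement_count(guide: str, utrs: list[str]) -> int:
    """Transcript-level seed-complement frequency by exhaustive pairing.

    Counts UTRs containing at least one 7-mer window whose bases pair,
    antiparallel, with guide positions 2..8 (1-based).
    """
    seed = guide[1:8]
    count = 0
    for utr in utrs:
        hit = False
        for i in range(len(utr) - 6):
            window = utr[i : i + 7]
            # antiparallel: window base k pairs with seed base 6-k
            if all(is_complementary(window[k], seed[6 - k]) for k in range(7)):
                hit = True
                break
        count += hit
    return count


def brute_force_candidate_starts(
    length: int, utr3: tuple[int, int] | None, window: int = 19
) -> list[int]:
    """All 1-based window starts whose closed window avoids the UTR interval,
    by exhaustive position-set intersection."""
    starts = []
    for s in range(1, length - window + 2):
        positions = set(range(s, s + window))
        if utr3 is not None and positions & set(range(utr3[0], utr3[1] + 1)):
            continue
        starts.append(s)
    return starts


def brute_force_pool(template: str) -> set[str]:
    """All concretizations of a template with Ns, by product enumeration."""
    options = [("ACGU" if c == "N" else c) for c in template]
    return {"".join(p) for p in itertools.product(*options)}
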