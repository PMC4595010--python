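"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the dynamic programming used in the package:
structures are enumerated recursively, alignments are enumerated
column-by-column, and substring scans are naive, so each oracle checks
its counterpart by a different computational route.
"""

from __future__ import annotations

from functools import lru_cache

CANONICAL = {"au", "ua", "gc", "cg", "gu", "ug"}


def enumerate_structures(seq: str, min_loop: int = 3):
    """Yield every nested dot-bracket structure of seq (canonical pairs,
    minimum hairpin loop min_loop).  Exponential; use only for short seqs."""
    n = len(seq)

    def helper(positions: tuple[int, ...]):
        # structures over a sorted tuple of available positions
        if not positions:
            yield ()
            return
        first, rest = positions[0], positions[1:]
        # first unpaired
        for pairs in helper(rest):
            yield pairs
        # first paired with a later position
        for idx, j in enumerate(rest):
            if j - first <= min_loop:
                continue
            if seq[first] + seq[j] not in CANONICAL:
                continue
            inside = tuple(p for p in rest[:idx])
            outside = tuple(p for p in rest[idx + 1:])
            # nesting: inside positions pair among themselves only
            for in_pairs in helper(inside):
                for out_pairs in helper(outside):
                    yield ((first, j),) + in_pairs + out_pairs

    seen = set()
    for pairs in helper(tuple(range(n))):
        key = tuple(sorted(pairs))
        if key in seen:
            continue
        seen.add(key)
        db = ["."] * n
        for i, j in pairs:
            db[i], db[j] = "(", ")"
        yield "".join(db)


def max_pairs_bruteforce(seq: str, min_loop: int = 3) -> int:
    """Maximum pair count over all enumerated structures."""
    return max(db.count("(") for db in enumerate_structures(seq, min_loop))


def naive_substring_hits(needle: str, hay: str) -> list[int]:
    """1-based start positions of exact occurrences, by position-wise scan."""
    out = []
    for start in range(len(hay) - len(needle) + 1):
        if all(hay[start + k] == needle[k] for k in range(len(needle))):
            out.append(start + 1)
    return out


def best_duplex_score_bruteforce(mirna: str, target_rev: str, scheme) -> float:
    """Best semi-global duplex alignment score by exhaustive enumeration.

    mirna is consumed fully in order; target_rev (already reversed) bases
    may be skipped freely at both ends; internal alignments are built
    column-by-column.  Gap runs are charged open + extend per extra column.
    """
    WC = {("a", "u"), ("u", "a"), ("g", "c"), ("c", "g")}
    GU = {("g", "u"), ("u", "g")}
    lo, hi = scheme.scale_span
    M, N = len(mirna), len(target_rev)

    def scale(pos):
        return scheme.seed_scale if lo <= pos <= hi else 1.0

    def pair_score(i, j):
        duo = (mirna[i - 1], target_rev[j - 1])
        if duo in WC:
            base = scheme.match
        elif duo in GU:
            base = scheme.gu_wobble
        else:
            base = scheme.mismatch
        return base * scale(i)

    @lru_cache(maxsize=None)
    def best(i, j, last):
        # best score consuming miRNA i..M given target position j (next target
        # base to use is j) and the kind of the previous column in {"P","Qm","Qt"}
        if i > M:
            return 0.0  # trailing target bases are free
        options = []
        if j <= N:
            options.append(pair_score(i, j) + best(i + 1, j + 1, "P"))
        pen = scheme.gap_extend if last == "Qm" else scheme.gap_open
        options.append(pen * scale(i) + best(i + 1, j, "Qm"))
        if j <= N:
            pen = scheme.gap_extend if last == "Qt" else scheme.gap_open
            options.append(pen * scale(i) + best(i, j + 1, "Qt"))
        return max(options)

    # free leading target bases: start at any j with a fresh state
    result = max(best(1, j, "P") for j in range(1, N + 2))
    best.cache_clear()
    return result
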