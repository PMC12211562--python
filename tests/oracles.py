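"""Independent brute-force oracles used by the test suite.

These are deliberately naive re-implementations (exhaustive scans,
union-find over the written rule, brute-force canonicalization) kept
separate from the library code paths they check.
"""

from __future__ import annotations

from collections import Counter

import edlib


def exhaustive_tag_scan(read: str, tag: str, max_edits: int):
    """Exhaustive sliding-window edit-distance search for tag copies.

    For every start position the best prefix-mode (SHW) edit distance of
    the tag against the remaining read is computed; hits at most
    ``max_edits`` away are accepted greedily (best distance first,
    leftmost on ties) subject to non-overlap. Both strands are scanned.
    Returns a list of (start, approx_end, distance, strand).
    """
    comp = str.maketrans("ACGTN", "TGCAN")
    candidates = []
    for strand, q in (("+", tag), ("-", tag.translate(comp)[::-1])):
        for i in range(len(read)):
            window = read[i:]
            if len(window) < len(q) - max_edits:
                break
            res = edlib.align(q, window, mode="SHW", task="locations")
            d = res["editDistance"]
            if 0 <= d <= max_edits:
                end = i + res["locations"][0][1] + 1
                candidates.append((d, i, end, strand))
    candidates.sort()
    chosen = []
    for d, i, end, strand in candidates:
        if all(end <= s or i >= e for s, e, _, _ in chosen):
            chosen.append((i, end, d, strand))
    chosen.sort()
    return chosen


def brute_force_directional_groups(umis: list, merge_distance: int) -> dict:
    """Union-find over the directional rule: a UMI group merges into a
    neighbour (Hamming distance <= merge_distance) at least twice its
    initial size; smallest groups first, largest neighbour wins, ties to
    the lexicographically smallest UMI. Returns umi -> root umi."""
    counts = Counter(umis)
    keys = sorted(counts)
    parent = {u: u for u in keys}

    def find(u):
        while parent[u] != u:
            u = parent[u]
        return u

    def ham(a, b):
        return sum(x != y for x, y in zip(a, b)) if len(a) == len(b) else 99

    if merge_distance >= 1:
        for u in sorted(keys, key=lambda x: (counts[x], x)):
            cands = [v for v in keys
                     if v != u and counts[v] >= 2 * counts[u]
                     and ham(u, v) <= merge_distance]
            if cands:
                best = sorted(cands, key=lambda v: (-counts[v], v))[0]
                parent[find(u)] = find(best)
    return {u: find(u) for u in keys}


def brute_force_representative(seqs: list) -> str:
    """Modal sequence; ties to longest, then lexicographically smallest,
    by explicit enumeration."""
    counts = Counter(seqs)
    best = None
    for s, n in counts.items():
        key = (n, len(s), tuple(-ord(c) for c in s))
        if best is None or key > best[0]:
            best = (key, s)
    return best[1]


def canonical_deletion(ref: str, mutated: str, size: int) -> int:
    """Leftmost position p with ref[:p] + ref[p+size:] == mutated,
    found by exhaustive scan."""
    for p in range(len(ref) - size + 1):
        if ref[:p] + ref[p + size:] == mutated:
            return p
    raise AssertionError("no deletion position reproduces the mutated read")


def canonical_insertion(ref: str, mutated: str, size: int) -> int:
    """Leftmost position p admitting mutated == ref[:p] + X + ref[p:]
    for some X of the given size, found by exhaustive scan."""
    for p in range(len(ref) + 1):
        if mutated[:p] == ref[:p] and mutated[p + size:] == ref[p:]:
            return p
    raise AssertionError("no insertion position reproduces the mutated read")
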