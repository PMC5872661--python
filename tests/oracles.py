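"""Independent brute-force oracles used to validate the fast detectors.

These deliberately re-derive results from definitions (exhaustive
enumeration, O(n^2) scans) and share no algorithmic code with the package
paths they check.
"""

from __future__ import annotations

import numpy as np

COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(COMP)[::-1]


def brute_force_ssrs(seq: str, thresholds=(10, 5, 4, 3, 3, 3)):
    """Every maximal perfect tandem repeat meeting the thresholds, by
    definition: for each (start, unit length) count whole-unit repetitions,
    keep irreducible units and left-maximal starts."""
    found = set()
    n = len(seq)
    for k in range(1, 7):
        thr = thresholds[k - 1]
        for start in range(0, n - k + 1):
            unit = seq[start : start + k]
            if "N" in unit:
                continue
            if any(
                k % d == 0 and unit == unit[:d] * (k // d) for d in range(1, k)
            ):
                continue  # repetition of a shorter unit
            t = 1
            while seq[start + t * k : start + (t + 1) * k] == unit:
                t += 1
            if t < thr:
                continue
            if start > 0 and seq[start - 1] == seq[start - 1 + k]:
                continue  # not left-maximal: the tandem run extends left
            found.add((start, k, t, unit))
    return found


def brute_force_longest_inverted_pair(seq: str, min_len: int = 1):
    """O(n^2) scan for the longest pair of disjoint, exactly reverse-
    complementary substrings (linear coordinates).

    Returns (best_length, {frozenset({(startA, len), (startB, len)}), ...}).
    """
    n = len(seq)
    s = np.frombuffer(seq.encode(), dtype="S1")
    r = np.frombuffer(rc(seq).encode(), dtype="S1")
    best_len = 0
    best_pairs: set[frozenset] = set()
    for d in range(-(n - 1), n):
        i0, i1 = max(0, d), min(n, n + d)
        if i1 - i0 < max(min_len, best_len):
            continue
        eq = s[i0:i1] == r[i0 - d : i1 - d]
        if not eq.any():
            continue
        idx = np.flatnonzero(eq)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(idx) - 1]))
        for a_, b_ in zip(idx[starts], idx[ends]):
            a = i0 + int(a_)
            length = int(b_) - int(a_) + 1
            if length < max(min_len, 1) or length < best_len:
                continue
            j0 = a - d
            pair = frozenset({(a, length), (n - j0 - length, length)})
            if len(pair) == 1:
                continue  # palindrome matched against itself
            (s1, l1), (s2, l2) = sorted(pair)
            if s1 + l1 > s2:
                continue  # overlapping arcs
            if length > best_len:
                best_len = length
                best_pairs = {pair}
            elif length == best_len:
                best_pairs.add(pair)
    return best_len, best_pairs


def column_site_classes(rows: list[str]):
    """Per-column variable / parsimony-informative flags, the slow way."""
    variable = informative = 0
    for col in zip(*rows):
        if "-" in col:
            continue
        states = {}
        for b in col:
            if b in "ACGT":
                states[b] = states.get(b, 0) + 1
        if len(states) >= 2:
            variable += 1
        if sum(1 for v in states.values() if v >= 2) >= 2:
            informative += 1
    return variable, informative
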