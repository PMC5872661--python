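"""Small sequence helpers shared across modules."""

from __future__ import annotations

_COMP = str.maketrans("ACGTN", "TGCAN")

#: Unordered substitution classes (sorted-pair labels), transitions first.
SUBST_CLASSES = ("A/G", "C/T", "A/C", "A/T", "C/G", "G/T")
TRANSITIONS = frozenset({"A/G", "C/T"})


def complement(base: str) -> str:
    return base.translate(_COMP)


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMP)[::-1]


def gc_fraction(seq: str) -> float:
    """G+C fraction of non-N bases (0.0 for empty / all-N input)."""
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


def subst_class(a: str, b: str) -> str:
    """Canonical label of the unordered pair {a, b}, e.g. ('G','A') -> 'A/G'."""
    if a == b or a not in "ACGT" or b not in "ACGT":
        raise ValueError(f"not a substitution pair: {a!r}, {b!r}")
    x, y = sorted((a, b))
    return f"{x}/{y}"


def is_transition(a: str, b: str) -> bool:
    return subst_class(a, b) in TRANSITIONS


def minimal_period(s: str) -> int:
    """Smallest p such that s is a prefix of (s[:p] repeated)."""
    n = len(s)
    for p in range(1, n + 1):
        if all(s[i] == s[i - p] for i in range(p, n)):
            return p
    return n


def motif_is_reducible(motif: str) -> bool:
    """True if motif is an integer repetition of a shorter unit (e.g. 'ATAT')."""
    k = len(motif)
    for d in range(1, k):
        if k % d == 0 and motif == motif[:d] * (k // d):
            return True
    return False


def canonical_motif_class(motif: str) -> str:
    """Strand- and rotation-independent motif class.

    All rotations of the motif and of its reverse complement are pooled; the
    class is the lexicographic minimum, rendered together with its reverse
    complement when the two differ (``A`` and ``T`` both -> ``"A/T"``,
    ``AT`` -> ``"AT"``).
    """
    rots = {motif[i:] + motif[:i] for i in range(len(motif))}
    rc = revcomp(motif)
    rots |= {rc[i:] + rc[:i] for i in range(len(rc))}
    canon = min(rots)  # <= every pooled rotation, including revcomp(canon)
    partner = revcomp(canon)
    if partner == canon:
        return canon
    return f"{canon}/{partner}"
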