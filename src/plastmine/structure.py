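"""Quadripartite plastome structure: LSC / IRb / SSC / IRa delimitation.

The two IR copies are required to be *exact* reverse complements (per-
genotype IR lengths in real plastome tables are equal, so exactness is the
working definition here); near-identical IRs with internal mismatches are
out of scope and surface as a no-IR / ambiguity outcome instead of a guess.

Detection is seed-and-extend: k-mer seeds of the genome against its reverse
complement, extended to maximal exact matches, with circular wrap-around
handled on a doubled sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import AmbiguousStructureError, DataError
from .io import GenomeRecord
from .util import gc_fraction, revcomp

REGIONS = ("LSC", "IRb", "SSC", "IRa")


@dataclass
class QuadripartiteStructure:
    """Four region spans on the canonicalized genome (0-based half-open).

    ``rotation``/``flipped`` record the transform from the input genome to
    the canonical presentation: ``canonical = rotate_left(revcomp(seq) if
    flipped else seq, rotation)``. When the input already reads LSC, IRb,
    SSC, IRa from position 0 the spans apply to it directly
    (``input_is_canonical_order``).
    """

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    genome_length: int
    has_ir: bool = True
    rotation: int = 0
    flipped: bool = False
    input_is_canonical_order: bool = True
    gc: dict = field(default_factory=dict)

    @property
    def spans(self) -> dict[str, tuple[int, int]]:
        return {"LSC": self.lsc, "IRb": self.irb, "SSC": self.ssc, "IRa": self.ira}

    @property
    def lengths(self) -> dict[str, int]:
        return {k: e - s for k, (s, e) in self.spans.items()}

    @property
    def ir_length(self) -> int:
        return self.irb[1] - self.irb[0]


def _maximal_inverted_matches(seq: str, min_len: int, seed_k: int, circular: bool):
    """All maximal exact reverse-complement repeat pairs of length >= min_len.

    Returns a set of frozensets {(start, length), (start, length)} with starts
    on the circle [0, n); the two arcs of a pair are disjoint.
    """
    n = len(seq)
    w = seq + seq if circular else seq
    m = len(w)
    rw = revcomp(w)
    index: dict[str, list[int]] = {}
    for i in range(m - seed_k + 1):
        index.setdefault(w[i : i + seed_k], []).append(i)
    covered: dict[int, int] = {}  # diagonal (i - j) -> extended end in rw coords
    pairs = set()
    for j in range(m - seed_k + 1):
        hits = index.get(rw[j : j + seed_k])
        if not hits:
            continue
        for i in hits:
            d = i - j
            if j < covered.get(d, 0):
                continue
            li, lj = i, j
            while li > 0 and lj > 0 and w[li - 1] == rw[lj - 1]:
                li -= 1
                lj -= 1
            ri, rj = i + seed_k, j + seed_k
            while ri < m and rj < m and w[ri] == rw[rj]:
                ri += 1
                rj += 1
            covered[d] = rj
            length = ri - li
            if length < min_len or length > n:
                continue
            a = (li % n, length)
            b = ((m - lj - length) % n, length)
            if a == b:
                continue  # a perfect palindrome matched against itself
            # disjoint on the circle?
            if (b[0] - a[0]) % n < a[1] or (a[0] - b[0]) % n < b[1]:
                continue
            pairs.add(frozenset((a, b)))
    return pairs


def detect_quadripartite(
    genome: GenomeRecord, min_ir_len: int = 1000, seed_k: int = 25
) -> QuadripartiteStructure:
    """Delimit LSC/IRb/SSC/IRa as the maximal disjoint exact inverted-repeat
    pair of length >= ``min_ir_len``; the shorter single-copy arc is the SSC.

    With no qualifying IR the genome is treated as a single region
    (``has_ir=False``; region labels downstream become ``"whole"``).
    Multiple distinct candidate pairs of equal maximal length raise
    :class:`AmbiguousStructureError`.
    """
    n = len(genome)
    if n <= 2 * min_ir_len:
        raise DataError(
            f"genome {genome.id} (len {n}) too short for min_ir_len={min_ir_len}"
        )
    pairs = _maximal_inverted_matches(genome.seq, min_ir_len, seed_k, genome.circular)
    if not pairs:
        return QuadripartiteStructure(
            lsc=(0, n), irb=(n, n), ssc=(n, n), ira=(n, n),
            genome_length=n, has_ir=False,
            gc={"LSC": genome.gc, "IRb": 0.0, "SSC": 0.0, "IRa": 0.0,
                "whole": genome.gc},
        )
    best_len = max(next(iter(p))[1] for p in pairs)
    cands = [p for p in pairs if next(iter(p))[1] == best_len]
    if len(cands) > 1:
        raise AmbiguousStructureError(sorted(tuple(sorted(p)) for p in cands))
    a, b = sorted(cands[0])
    (sa, L), (sb, _) = a, b
    gap_ab = (sb - (sa + L)) % n  # arc from end(a) to start(b)
    gap_ba = (sa - (sb + L)) % n
    if gap_ab == gap_ba:
        raise DataError(
            f"genome {genome.id}: single-copy arcs have equal length {gap_ab}; "
            "cannot assign LSC vs SSC"
        )
    if gap_ab > gap_ba:  # LSC runs end(a) -> start(b): order LSC, b, SSC, a
        lsc_start, lsc_len, ssc_len = (sa + L) % n, gap_ab, gap_ba
    else:
        lsc_start, lsc_len, ssc_len = (sb + L) % n, gap_ba, gap_ab

    doubled = genome.seq + genome.seq
    lsc_str = doubled[lsc_start : lsc_start + lsc_len]
    flipped = revcomp(lsc_str) < lsc_str
    if flipped:
        # LSC arc start in the reverse-complemented frame
        rotation = (n - lsc_start - lsc_len) % n
    else:
        rotation = lsc_start
    spans = {}
    off = 0
    for name, ln in (("LSC", lsc_len), ("IRb", L), ("SSC", ssc_len), ("IRa", L)):
        spans[name] = (off, off + ln)
        off += ln
    if off != n:
        raise DataError(f"region lengths {lsc_len}+{L}+{ssc_len}+{L} != {n}")
    base = revcomp(genome.seq) if flipped else genome.seq
    canon = base[rotation:] + base[:rotation]
    if canon[spans["IRa"][0] : spans["IRa"][1]] != revcomp(
        canon[spans["IRb"][0] : spans["IRb"][1]]
    ):
        raise DataError("internal error: IRa is not the reverse complement of IRb")
    gc = {name: gc_fraction(canon[s:e]) for name, (s, e) in spans.items()}
    gc["whole"] = gc_fraction(canon)
    return QuadripartiteStructure(
        lsc=spans["LSC"], irb=spans["IRb"], ssc=spans["SSC"], ira=spans["IRa"],
        genome_length=n, has_ir=True, rotation=rotation, flipped=flipped,
        input_is_canonical_order=(not flipped and rotation == 0)
        or (flipped and lsc_start == 0),
        gc=gc,
    )


def canonicalize_orientation(
    genome: GenomeRecord, structure: QuadripartiteStructure
) -> GenomeRecord:
    """Rotate (and reverse-complement if needed) so the genome reads
    LSC, IRb, SSC, IRa from position 0; features are remapped."""
    if not structure.has_ir or (structure.rotation == 0 and not structure.flipped):
        return genome
    seq = revcomp(genome.seq) if structure.flipped else genome.seq
    r = structure.rotation
    seq = seq[r:] + seq[:r]
    feats = (
        genome.features.transformed(r, structure.flipped)
        if genome.features is not None
        else None
    )
    return GenomeRecord(id=genome.id, seq=seq, circular=genome.circular, features=feats)


def region_of(
    position: int, structure: QuadripartiteStructure, collapsed: bool = False
) -> str:
    """Region label of a (canonical) coordinate; IRb/IRa collapse to 'IR'."""
    if not (0 <= position < structure.genome_length):
        raise DataError(f"position {position} outside genome")
    if not structure.has_ir:
        return "whole"
    for name, (s, e) in structure.spans.items():
        if s <= position < e:
            return "IR" if collapsed and name in ("IRb", "IRa") else name
    raise DataError(f"position {position} not covered by any region")
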