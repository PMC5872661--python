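"""Microsatellite (cpSSR) mining and cross-genotype polymorphism calls.

Mining follows the MISA convention: a locus is a maximal perfect tandem
repeat of a 1-6 bp unit whose repeat-unit count meets a per-unit-length
minimum (defaults 10, 5, 4, 3, 3, 3 for mono- through hexanucleotide
units). Repeats whose unit is itself a repetition of a shorter unit are
reported at the shorter unit length only; qualifying repeats separated by a
short interruption are merged into one compound locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AnchorCollisionError, DataError
from .io import AlignmentMatrix, FeatureTable, GenomeRecord
from .structure import QuadripartiteStructure, region_of
from .util import canonical_motif_class, motif_is_reducible

DEFAULT_THRESHOLDS = (10, 5, 4, 3, 3, 3)


@dataclass
class SsrLocus:
    """A perfect or compound tandem repeat on one genotype's genome."""

    genotype: str
    span: tuple[int, int]  # 0-based half-open on the genome
    motif: str  # unit of the (first) perfect part, forward strand
    unit_len: int
    n_units: int  # units of the (first) perfect part
    #: ordered (motif, n_units, interruption-after) triples; None for perfect
    compound_parts: list[tuple[str, int, str]] | None = None
    region: str = ""
    context: tuple[str, str] = ("", "")

    @property
    def is_compound(self) -> bool:
        return self.compound_parts is not None

    @property
    def tract_length(self) -> int:
        return self.span[1] - self.span[0]

    @property
    def total_units(self) -> int:
        if not self.is_compound:
            return self.n_units
        return sum(u for _, u, _ in self.compound_parts)

    @property
    def ssr_type(self) -> str:
        if not self.is_compound:
            return f"({self.motif}){self.n_units}"
        out = []
        for motif, units, gap in self.compound_parts:
            out.append(f"({motif}){units}{gap.lower()}")
        return "".join(out)

    @property
    def canonical_class(self) -> str:
        if not self.is_compound:
            return canonical_motif_class(self.motif)
        return ";".join(canonical_motif_class(m) for m, _, _ in self.compound_parts)

    def expected_sequence(self) -> str:
        if not self.is_compound:
            return self.motif * self.n_units
        return "".join(m * u + gap.upper() for m, u, gap in self.compound_parts)


@dataclass
class SsrPolymorphism:
    """One alignment-anchored SSR locus compared across genotypes."""

    locus_key: str
    canonical_class: str
    anchor_col: int
    per_genotype: dict[str, tuple[int, int] | None]  # id -> (n_units, tract bp)
    members: dict[str, SsrLocus] = field(default_factory=dict)
    context: tuple[str, str] = ("", "")

    @property
    def is_polymorphic(self) -> bool:
        lengths = {
            self.per_genotype[g][1] for g in self.members if self.per_genotype[g]
        }
        return len(lengths) >= 2


def _perfect_repeats(seq: str, thresholds) -> list[tuple[int, int, int, str]]:
    """All maximal perfect tandem repeats meeting the thresholds.

    Returns (start, unit_len, n_units, motif); unit-reducible motifs are
    dropped (they are reported at the shorter unit length).
    """
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype="S1")
    out = []
    for k, min_units in enumerate(thresholds, start=1):
        if n <= k:
            continue
        match = arr[: n - k] == arr[k:]
        if not match.any():
            continue
        idx = np.flatnonzero(match)
        # maximal runs of consecutive True
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(idx) - 1]))
        for a, b in zip(idx[starts], idx[ends]):
            total = (b - a + 1) + k
            units = total // k
            if units < min_units:
                continue
            motif = seq[a : a + k]
            if "N" in motif or motif_is_reducible(motif):
                continue
            out.append((int(a), k, int(units), motif))
    return out


def deduplicate_ssrs(loci: list[SsrLocus]) -> list[SsrLocus]:
    """Resolve overlapping loci of one genotype: keep the greater tract
    length, then the smaller unit length, then the leftmost."""
    order = sorted(loci, key=lambda l: (-l.tract_length, l.unit_len, l.span[0]))
    kept: list[SsrLocus] = []
    for loc in order:
        if all(
            loc.span[1] <= k.span[0] or loc.span[0] >= k.span[1] for k in kept
        ):
            kept.append(loc)
    return sorted(kept, key=lambda l: l.span[0])


def _merge_compound(
    loci: list[SsrLocus], seq: str, max_gap: int
) -> list[SsrLocus]:
    loci = sorted(loci, key=lambda l: l.span[0])
    out: list[SsrLocus] = []
    i = 0
    while i < len(loci):
        chain = [loci[i]]
        while (
            i + 1 < len(loci)
            and 0 <= loci[i + 1].span[0] - chain[-1].span[1] <= max_gap
        ):
            chain.append(loci[i + 1])
            i += 1
        i += 1
        if len(chain) == 1:
            out.append(chain[0])
            continue
        parts = []
        for j, loc in enumerate(chain):
            gap = (
                seq[loc.span[1] : chain[j + 1].span[0]] if j + 1 < len(chain) else ""
            )
            parts.append((loc.motif, loc.n_units, gap))
        out.append(
            SsrLocus(
                genotype=chain[0].genotype,
                span=(chain[0].span[0], chain[-1].span[1]),
                motif=chain[0].motif,
                unit_len=chain[0].unit_len,
                n_units=chain[0].n_units,
                compound_parts=parts,
            )
        )
    return out


def detect_ssrs(
    genome: GenomeRecord,
    thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS,
    compound_max_gap: int | None = 100,
    structure: QuadripartiteStructure | None = None,
    features: FeatureTable | None = None,
) -> list[SsrLocus]:
    """Mine perfect (and, unless disabled, compound) SSR loci on one genome.

    ``compound_max_gap=None`` skips compound merging. When a structure is
    given, loci entirely inside IRa are suppressed (the IR is counted once)
    and region labels are filled; a feature table fills genic context.
    """
    if len(thresholds) != 6 or any(t < 1 for t in thresholds):
        raise DataError(f"need six positive thresholds, got {thresholds!r}")
    raw = [
        SsrLocus(genome.id, (a, a + k * u), motif, k, u)
        for a, k, u, motif in _perfect_repeats(genome.seq, thresholds)
    ]
    loci = deduplicate_ssrs(raw)
    if compound_max_gap is not None:
        loci = _merge_compound(loci, genome.seq, compound_max_gap)
    if structure is not None and structure.has_ir:
        s, e = structure.ira
        loci = [l for l in loci if not (s <= l.span[0] and l.span[1] <= e)]
    for loc in loci:
        if structure is not None:
            loc.region = region_of(loc.span[0], structure, collapsed=True)
        if features is not None:
            loc.context = features.context_at(loc.span[0])
    return loci


def extract_flanks(
    genome: GenomeRecord, locus: SsrLocus, flank_len: int = 250
) -> tuple[str, str]:
    """Forward-strand sequences flanking the tract, wrapping across the
    origin of a circular genome when needed."""
    if flank_len < 0:
        raise DataError("flank_len must be >= 0")
    if flank_len == 0:
        return "", ""
    s, e = locus.span
    return genome.fetch(s - flank_len, s), genome.fetch(e, e + flank_len)


def _measure_tract(seq: str, pos: int, k: int) -> tuple[int, int]:
    """Maximal period-k tandem tract containing ``pos`` (may be a single,
    sub-threshold unit); returns (n_units, tract bp)."""
    n = len(seq)
    pos = min(max(pos, 0), n - 1)
    st = min(pos, n - k)
    while st > 0 and st - 1 + k < n and seq[st - 1] == seq[st - 1 + k]:
        st -= 1
    en = pos
    while en + k < n and seq[en] == seq[en + k]:
        en += 1
    total = (en - st) + k if en >= st else k
    units = total // k
    return units, units * k


def compare_ssrs(
    per_genotype_loci: dict[str, list[SsrLocus]],
    aln: AlignmentMatrix,
    genomes: dict[str, GenomeRecord] | None = None,
) -> list[SsrPolymorphism]:
    """Match loci across genotypes through the alignment and call
    length polymorphisms.

    Loci with the same canonical class whose alignment projections overlap
    are one locus; a genotype lacking a qualifying tract there is recorded
    with its actual (sub-threshold) tract length measured on its genome
    (``genomes``) or on its ungapped alignment row.
    """
    items = []  # (class, col_start, col_end, locus)
    for gid, loci in per_genotype_loci.items():
        if gid not in aln.ids:
            raise DataError(f"genotype {gid!r} not in alignment")
        row = aln.ids.index(gid)
        for loc in loci:
            c0 = int(aln.pos_to_col[row][loc.span[0]])
            c1 = int(aln.pos_to_col[row][loc.span[1] - 1]) + 1
            items.append((loc.canonical_class, c0, c1, loc))

    # union-find clustering on same-class overlapping column intervals
    parent = list(range(len(items)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    by_class: dict[str, list[int]] = {}
    for i, it in enumerate(items):
        by_class.setdefault(it[0], []).append(i)
    for idxs in by_class.values():
        idxs.sort(key=lambda i: items[i][1])
        for a, b in zip(idxs, idxs[1:]):
            if items[b][1] < items[a][2]:  # overlap in column space
                parent[find(b)] = find(a)

    clusters: dict[int, list[int]] = {}
    for i in range(len(items)):
        clusters.setdefault(find(i), []).append(i)

    out = []
    for members in clusters.values():
        locs = [items[i][3] for i in members]
        gids = [l.genotype for l in locs]
        if len(set(gids)) != len(gids):
            raise AnchorCollisionError(
                [(l.genotype, l.span, l.ssr_type) for l in locs]
            )
        rep = max(locs, key=lambda l: l.tract_length)
        rep_i = members[locs.index(rep)]
        anchor = (items[rep_i][1] + items[rep_i][2]) // 2
        context = next((l.context for l in locs if l.context[1]), rep.context)
        per: dict[str, tuple[int, int] | None] = {}
        mem: dict[str, SsrLocus] = {}
        for loc in locs:
            per[loc.genotype] = (loc.total_units, loc.tract_length)
            mem[loc.genotype] = loc
        for gid in aln.ids:
            if gid in per:
                continue
            row = aln.ids.index(gid)
            pos = int(aln.col_to_pos[row][anchor])
            if pos < 0:  # anchor falls in a gap: nearest base to the left
                left = aln.col_to_pos[row][: anchor + 1]
                nz = left[left >= 0]
                pos = int(nz[-1]) if len(nz) else 0
            seq = genomes[gid].seq if genomes else aln.ungapped(gid)
            per[gid] = _measure_tract(seq, pos, rep.unit_len)
        key = f"{context[1] or 'locus'}|{rep.canonical_class}|col{anchor}"
        out.append(
            SsrPolymorphism(
                locus_key=key,
                canonical_class=rep.canonical_class,
                anchor_col=anchor,
                per_genotype=per,
                members=mem,
                context=context,
            )
        )
    out.sort(key=lambda p: p.anchor_col)
    return out
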