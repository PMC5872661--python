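"""Microstructural events: indels from the alignment and small inversions.

Indels are maximal runs of alignment columns sharing one constant
gap/base pattern across genotypes; runs are split where the genotypes that
do carry sequence disagree. Events are polarized against a designated
standard reference genotype (insertion/deletion labels are reference-
relative, not ancestral-state claims) and separated into SSR-slippage
("SSR-related") versus common indels.

Small inversions are maximal runs of gap-free mismatch columns whose query
core equals the reverse complement of the reference core, bracketed by an
exact inverted-repeat pair (the hairpin stem); exact flank complementarity
replaces thermodynamic folding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .io import AlignmentMatrix, FeatureTable
from .structure import QuadripartiteStructure, region_of
from .util import complement, revcomp


@dataclass
class IndelEvent:
    aln_span: tuple[int, int]  # contiguous gap-column run (half-open)
    ref_span: tuple[int, int]  # on reference; zero-length for insertions
    allele_present: str  # the inserted/deleted sequence
    pattern: dict[str, str]  # genotype -> has_sequence | has_gap
    size: int
    polarity: dict[str, str]  # genotype -> insertion|deletion|reference-state
    region: str = ""
    context: tuple[str, str] = ("", "")
    ssr_related: bool = False


@dataclass
class Inversion:
    aln_span: tuple[int, int]
    ref_span: tuple[int, int]
    length: int  # bp of the inverted core
    inverted_genotypes: set[str] = field(default_factory=set)
    flank_repeat_len: int = 0
    loop_len: int = 0  # hairpin loop = core length
    stem_loop_ok: bool = False
    palindromic_core: bool = False
    region: str = ""
    context: tuple[str, str] = ("", "")


def _ref_point(aln: AlignmentMatrix, ref_row: int, col: int) -> int:
    """Reference coordinate just right of everything before ``col``."""
    left = aln.col_to_pos[ref_row][:col]
    nz = left[left >= 0]
    return int(nz[-1]) + 1 if len(nz) else 0


def extract_indels(
    aln: AlignmentMatrix,
    ref_id: str,
    structure: QuadripartiteStructure | None = None,
    features: FeatureTable | None = None,
) -> list[IndelEvent]:
    """Collapse constant gap-pattern column runs into indel events.

    A gap run shared by several genotypes is one event. Polarity per
    genotype: sequence where the reference has a gap -> insertion; gap where
    the reference has sequence -> deletion; otherwise reference-state.
    """
    if ref_id not in aln.ids:
        raise DataError(f"reference {ref_id!r} not in alignment")
    ref_row = aln.ids.index(ref_id)
    nrows, ncols = aln.nrows, aln.ncols
    weights = 1 << np.arange(nrows, dtype=np.int64)
    pat = (aln.gap_mask * weights[:, None]).sum(axis=0)
    all_gaps = (1 << nrows) - 1
    if (pat == all_gaps).any():
        c = int(np.flatnonzero(pat == all_gaps)[0])
        raise DataError(f"malformed alignment: column {c} is gaps in all genotypes")

    events: list[IndelEvent] = []

    def emit(c0: int, c1: int, pattern_bits: int) -> None:
        gap_rows = [i for i in range(nrows) if pattern_bits >> i & 1]
        present_rows = [i for i in range(nrows) if i not in gap_rows]
        allele = aln.rows[present_rows[0]][c0:c1]
        if ref_row in gap_rows:
            p = _ref_point(aln, ref_row, c0)
            ref_span = (p, p)
        else:
            ref_span = (
                int(aln.col_to_pos[ref_row][c0]),
                int(aln.col_to_pos[ref_row][c1 - 1]) + 1,
            )
        pattern = {
            aln.ids[i]: "has_gap" if i in gap_rows else "has_sequence"
            for i in range(nrows)
        }
        polarity = {}
        for i in range(nrows):
            if i in gap_rows and ref_row not in gap_rows:
                polarity[aln.ids[i]] = "deletion"
            elif i not in gap_rows and ref_row in gap_rows:
                polarity[aln.ids[i]] = "insertion"
            else:
                polarity[aln.ids[i]] = "reference-state"
        anchor = ref_span[0] if ref_span[1] > ref_span[0] else max(ref_span[0] - 1, 0)
        ev = IndelEvent(
            aln_span=(c0, c1),
            ref_span=ref_span,
            allele_present=allele,
            pattern=pattern,
            size=c1 - c0,
            polarity=polarity,
        )
        if structure is not None:
            ev.region = region_of(anchor, structure, collapsed=True)
        if features is not None:
            ev.context = features.context_at(anchor)
        events.append(ev)

    c = 0
    while c < ncols:
        if pat[c] == 0:
            c += 1
            continue
        c0 = c
        while c < ncols and pat[c] == pat[c0]:
            c += 1
        # split where the present genotypes disagree in sequence
        present_rows = [
            i for i in range(nrows) if not (int(pat[c0]) >> i & 1)
        ]
        sub = aln.array[np.ix_(present_rows, range(c0, c))]
        agree = (sub == sub[0]).all(axis=0)
        run_len = c - c0
        s = 0
        for t in range(1, run_len + 1):
            # disagreement columns become single-column events of their own
            if t == run_len or agree[t] != agree[s] or not agree[s]:
                emit(c0 + s, c0 + t, int(pat[c0]))
                s = t
    return events


def filter_ssr_indels(
    events: list[IndelEvent],
    per_genotype_loci: dict[str, list],
    aln: AlignmentMatrix,
) -> tuple[list[IndelEvent], list[IndelEvent]]:
    """Partition events into (common, SSR-related).

    An event is SSR-related iff its present allele is a whole-number tandem
    repetition of (a rotation of) some unit of an SSR locus whose alignment
    projection overlaps or directly abuts the event's columns.
    """
    spans = []  # (col_start, col_end, motifs)
    for gid, loci in per_genotype_loci.items():
        row = aln.ids.index(gid)
        for loc in loci:
            c0 = int(aln.pos_to_col[row][loc.span[0]])
            c1 = int(aln.pos_to_col[row][loc.span[1] - 1]) + 1
            motifs = (
                [m for m, _, _ in loc.compound_parts]
                if loc.compound_parts
                else [loc.motif]
            )
            spans.append((c0, c1, motifs))

    def is_unit_multiple(allele: str, motif: str) -> bool:
        k = len(motif)
        if len(allele) == 0 or len(allele) % k != 0:
            return False
        rots = {motif[i:] + motif[:i] for i in range(k)}
        return any(allele == r * (len(allele) // k) for r in rots)

    common, related = [], []
    for ev in events:
        e0, e1 = ev.aln_span
        hit = False
        for c0, c1, motifs in spans:
            if c0 <= e1 and c1 >= e0:  # overlap or abut (distance 0)
                if any(is_unit_multiple(ev.allele_present, m) for m in motifs):
                    hit = True
                    break
        ev.ssr_related = hit
        (related if hit else common).append(ev)
    return common, related


def indel_size_spectrum(
    common: list[IndelEvent],
) -> tuple[dict[int, int], dict[str, int]]:
    """Histogram of event sizes and counts per collapsed region."""
    sizes: dict[int, int] = {}
    regions: dict[str, int] = {}
    for ev in common:
        sizes[ev.size] = sizes.get(ev.size, 0) + 1
        if ev.region:
            regions[ev.region] = regions.get(ev.region, 0) + 1
    return dict(sorted(sizes.items())), regions


def detect_inversions(
    aln: AlignmentMatrix,
    ref_id: str,
    min_len: int = 2,
    max_len: int = 100,
    flank_window: int = 30,
    min_stem: int = 6,
    structure: QuadripartiteStructure | None = None,
    features: FeatureTable | None = None,
) -> list[Inversion]:
    """Find small inversions as reverse-complemented mismatch cores.

    For every maximal run of gap-free mismatch columns between the reference
    and a genotype whose length lies in [min_len, max_len], the run is an
    inversion iff the genotype core equals the reverse complement of the
    reference core. The hairpin stem is the longest exact inverted-repeat
    pair immediately bracketing the core on the reference
    (``stem_loop_ok`` iff its length >= ``min_stem``). Mismatch runs failing
    the reverse-complement test are left to the SNP caller.
    """
    if ref_id not in aln.ids:
        raise DataError(f"reference {ref_id!r} not in alignment")
    ref_row = aln.ids.index(ref_id)
    ref_seq = aln.ungapped(ref_id)
    n = len(ref_seq)
    ref_arr = aln.array[ref_row]
    by_span: dict[tuple[int, int], set[str]] = {}
    for row, gid in enumerate(aln.ids):
        if gid == ref_id:
            continue
        both = ~aln.gap_mask[ref_row] & ~aln.gap_mask[row]
        mism = both & (aln.array[row] != ref_arr)
        idx = np.flatnonzero(mism)
        if not len(idx):
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(idx) - 1]))
        for a, b in zip(idx[starts], idx[ends]):
            c0, c1 = int(a), int(b) + 1
            length = c1 - c0
            if not (min_len <= length <= max_len):
                continue
            core_ref = aln.rows[ref_row][c0:c1]
            core_g = aln.rows[row][c0:c1]
            if "-" in core_ref or "-" in core_g:
                continue  # other-genotype gaps may interleave; pairwise must be clean
            if core_g != revcomp(core_ref):
                continue
            by_span.setdefault((c0, c1), set()).add(gid)

    out = []
    for (c0, c1), gids in sorted(by_span.items()):
        s = int(aln.col_to_pos[ref_row][c0])
        e = int(aln.col_to_pos[ref_row][c1 - 1]) + 1
        core_ref = ref_seq[s:e]
        flank = 0
        while (
            flank < flank_window
            and s - flank - 1 >= 0
            and e + flank < n
            and ref_seq[s - flank - 1] == complement(ref_seq[e + flank])
        ):
            flank += 1
        inv = Inversion(
            aln_span=(c0, c1),
            ref_span=(s, e),
            length=e - s,
            inverted_genotypes=gids,
            flank_repeat_len=flank,
            loop_len=e - s,
            stem_loop_ok=flank >= min_stem,
            palindromic_core=core_ref == revcomp(core_ref),
        )
        if structure is not None:
            inv.region = region_of(s, structure, collapsed=True)
        if features is not None:
            inv.context = features.context_at(s)
        out.append(inv)
    return out


def hairpin_stats(inv: Inversion, min_stem: int = 6) -> tuple[int, int, bool]:
    """(stem length, loop length, stem-loop ok) of an inversion's hairpin."""
    return inv.flank_repeat_len, inv.loop_len, inv.flank_repeat_len >= min_stem
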