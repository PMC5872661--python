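"""SNP calling from the multiple alignment and the substitution spectrum.

A SNP is an alignment column with no gap in any genotype and at least two
distinct non-N bases. Gap-containing columns are indel territory and are
handled by the microstructure module; columns whose reference coordinate
falls in IRa are masked so each IR variant is counted once. Biallelic sites
are tallied into the six non-strand-specific substitution classes
(A/G and C/T are the transitions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .io import AlignmentMatrix, FeatureTable
from .structure import QuadripartiteStructure, region_of
from .util import SUBST_CLASSES, TRANSITIONS, subst_class

_BASES = (b"A", b"C", b"G", b"T")


@dataclass
class Snp:
    aln_col: int
    ref_pos: int
    alleles: dict[str, str]  # genotype -> base (may include 'N')
    n_alleles: int  # distinct non-N bases
    subst_class: str | None  # one of the six classes; None if multiallelic
    is_transition: bool | None
    region: str = ""
    context: tuple[str, str] = ("", "")


@dataclass
class SpectrumTable:
    counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in SUBST_CLASSES}
    )
    multiallelic: int = 0

    @property
    def ts_total(self) -> int:
        return sum(self.counts[c] for c in SUBST_CLASSES if c in TRANSITIONS)

    @property
    def tv_total(self) -> int:
        return sum(self.counts[c] for c in SUBST_CLASSES if c not in TRANSITIONS)

    @property
    def tv_ts_ratio(self) -> float | None:
        """Tv/Ts as a plain number; None (reported 'NA') when Ts = 0."""
        if self.ts_total == 0:
            return None
        return self.tv_total / self.ts_total


def _variable_columns(aln: AlignmentMatrix):
    """Boolean masks: gap-free columns, and per-column non-N state counts."""
    gap_free = ~aln.gap_mask.any(axis=0)
    counts = np.zeros((4, aln.ncols), dtype=np.int32)
    for bi, b in enumerate(_BASES):
        counts[bi] = (aln.array == b).sum(axis=0)
    n_states = (counts > 0).sum(axis=0)
    return gap_free, counts, n_states


def call_snps(
    aln: AlignmentMatrix,
    structure: QuadripartiteStructure,
    ref_id: str,
    features: FeatureTable | None = None,
    exclude_cols: set[int] | None = None,
) -> list[Snp]:
    """One Snp per gap-free column with >= 2 distinct non-N bases.

    ``structure`` must describe the reference genotype as it appears in the
    alignment (canonical LSC-first order). ``exclude_cols`` lets the
    pipeline mask columns already explained by small inversions.
    """
    if ref_id not in aln.ids:
        raise DataError(f"reference {ref_id!r} not in alignment")
    ref_row = aln.ids.index(ref_id)
    gap_free, counts, n_states = _variable_columns(aln)
    candidate = gap_free & (n_states >= 2)
    ira_s, ira_e = structure.ira
    out = []
    for c in np.flatnonzero(candidate):
        c = int(c)
        if exclude_cols and c in exclude_cols:
            continue
        ref_pos = int(aln.col_to_pos[ref_row][c])
        if structure.has_ir and ira_s <= ref_pos < ira_e:
            continue  # IR counted once: IRa columns mirror IRb
        col = aln.column(c)
        bases = sorted({b for b in col if b in "ACGT"})
        if len(bases) == 2:
            cls = subst_class(*bases)
            ts = cls in TRANSITIONS
        else:
            cls, ts = None, None
        region = region_of(ref_pos, structure, collapsed=True)
        context = features.context_at(ref_pos) if features is not None else ("", "")
        out.append(
            Snp(
                aln_col=c,
                ref_pos=ref_pos,
                alleles=dict(zip(aln.ids, col)),
                n_alleles=len(bases),
                subst_class=cls,
                is_transition=ts,
                region=region,
                context=context,
            )
        )
    return out


def substitution_spectrum(snps: list[Snp]) -> SpectrumTable:
    """Tally biallelic SNPs into the six classes; multiallelic sites go to a
    separate overflow bucket excluded from the Ts/Tv totals."""
    table = SpectrumTable()
    for s in snps:
        if s.subst_class is None:
            table.multiallelic += 1
        else:
            table.counts[s.subst_class] += 1
    return table


def count_site_classes(aln: AlignmentMatrix) -> tuple[int, int]:
    """(variable sites, parsimony-informative sites) over gap-free columns.

    Variable: >= 2 distinct non-N states. Parsimony-informative: >= 2 states
    each carried by >= 2 genotypes.
    """
    if aln.nrows < 2:
        raise DataError("need at least two rows")
    gap_free, counts, n_states = _variable_columns(aln)
    variable = gap_free & (n_states >= 2)
    informative = gap_free & ((counts >= 2).sum(axis=0) >= 2)
    return int(variable.sum()), int(informative.sum())
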