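"""Input/output for the standard formats the pipeline touches.

Reads FASTA / GenBank genomes, GFF3 feature tables and aligned FASTA;
writes VCF, BED and TSV reports. Internal coordinates are 0-based
half-open everywhere; human-facing report columns are 1-based inclusive
and every report file states its convention in a header comment.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .errors import DataError
from .util import gc_fraction, revcomp

log = logging.getLogger(__name__)

_VALID = set("ACGTN")
#: feature kinds whose span counts as coding sequence
_CODING_KINDS = {"CDS", "exon", "tRNA", "rRNA"}


def zero_to_one(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


def one_to_zero(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open (self-inverse with zero_to_one)."""
    return start - 1, end


@dataclass(frozen=True)
class Feature:
    kind: str  # gene | CDS | tRNA | rRNA | intron | spacer | exon
    name: str
    spans: tuple[tuple[int, int], ...]  # 0-based half-open; multi-interval ok
    strand: str = "+"

    @property
    def start(self) -> int:
        return min(s for s, _ in self.spans)

    @property
    def end(self) -> int:
        return max(e for _, e in self.spans)

    def contains(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.spans)


class FeatureTable:
    """Gene-level annotation used only for context labelling.

    Spacer records are derivable: a position covered by no gene envelope is
    labelled ``"geneA-geneB"`` after its flanking genes.
    """

    def __init__(self, features: Iterable[Feature], genome_length: int):
        self.features = list(features)
        self.genome_length = int(genome_length)
        for f in self.features:
            for s, e in f.spans:
                if not (0 <= s < e <= self.genome_length):
                    raise DataError(
                        f"feature {f.name} span ({s},{e}) outside genome "
                        f"of length {self.genome_length}"
                    )
        self._genes = sorted(
            (f for f in self.features if f.kind == "gene"), key=lambda f: f.start
        )

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def context_at(self, pos: int) -> tuple[str, str]:
        """Classify a position as (coding|intron|spacer, name)."""
        if not (0 <= pos < self.genome_length):
            raise DataError(f"position {pos} outside genome")
        for f in self.features:
            if f.kind == "intron" and f.contains(pos):
                return "intron", f.name
        for f in self.features:
            if f.kind in _CODING_KINDS and f.contains(pos):
                return "coding", f.name
        for f in self._genes:
            if f.start <= pos < f.end:
                # inside the gene envelope: implicit intron if some exon-level
                # record exists for this gene but does not cover pos
                sub = [
                    g
                    for g in self.features
                    if g.name == f.name and g.kind in _CODING_KINDS
                ]
                if sub and not any(g.contains(pos) for g in sub):
                    return "intron", f.name
                return "coding", f.name
        left = None
        right = None
        for f in self._genes:
            if f.end <= pos:
                left = f
            elif f.start > pos and right is None:
                right = f
        lname = left.name if left else (self._genes[-1].name if self._genes else "start")
        rname = right.name if right else (self._genes[0].name if self._genes else "end")
        return "spacer", f"{lname}-{rname}"

    def transformed(self, rotation: int, flipped: bool) -> "FeatureTable":
        """Feature table after revcomp (optional) then left-rotation.

        Matches the genome transform ``rotate(revcomp(seq) if flipped else
        seq, rotation)``. Intervals that come to straddle the origin are
        split into two intervals.
        """
        n = self.genome_length
        out = []
        for f in self.features:
            spans = []
            for s, e in f.spans:
                if flipped:
                    s, e = n - e, n - s
                s, e = (s - rotation) % n, (e - rotation) % n
                if e == 0:
                    e = n
                if s < e:
                    spans.append((s, e))
                else:  # straddles the origin after rotation
                    spans.append((s, n))
                    spans.append((0, e))
            strand = f.strand
            if flipped and strand in "+-":
                strand = "-" if strand == "+" else "+"
            out.append(Feature(f.kind, f.name, tuple(spans), strand))
        return FeatureTable(out, n)


@dataclass
class GenomeRecord:
    """One plastome sequence with identity, circularity and annotation."""

    id: str
    seq: str
    circular: bool = True
    features: FeatureTable | None = None

    def __post_init__(self):
        if not self.seq:
            raise DataError(f"genome {self.id!r} has an empty sequence")
        seq = self.seq.upper()
        bad = set(seq) - _VALID
        if bad:
            log.warning(
                "genome %s: residues %s outside {A,C,G,T,N} mapped to N",
                self.id,
                "".join(sorted(bad)),
            )
            seq = re.sub(f"[{''.join(re.escape(b) for b in sorted(bad))}]", "N", seq)
        self.seq = seq

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def gc(self) -> float:
        return gc_fraction(self.seq)

    def fetch(self, start: int, end: int) -> str:
        """Subsequence with circular wrap-around when end > length."""
        n = len(self.seq)
        if end < start or end - start > n:
            raise DataError(f"invalid span ({start},{end}) on genome {self.id}")
        if 0 <= start and end <= n:
            return self.seq[start:end]
        if not self.circular:
            raise DataError(f"span ({start},{end}) outside linear genome {self.id}")
        length = end - start
        start %= n
        return (self.seq + self.seq)[start : start + length]


def _genbank_features(rec) -> FeatureTable:
    feats = []
    for f in rec.features:
        if f.type not in {"gene", "CDS", "tRNA", "rRNA", "intron", "exon"}:
            continue
        name = (
            f.qualifiers.get("gene", [None])[0]
            or f.qualifiers.get("locus_tag", [None])[0]
            or f.type
        )
        spans = tuple(
            (int(p.start), int(p.end)) for p in f.location.parts
        )
        strand = "+" if (f.location.strand or 1) >= 0 else "-"
        feats.append(Feature(f.type, name, spans, strand))
    return FeatureTable(feats, len(rec.seq))


def read_genomes(
    paths: Sequence[str | Path], format: str = "fasta", circular: bool = True
) -> dict[str, GenomeRecord]:
    """Read one or more FASTA / GenBank files into GenomeRecords.

    Duplicate ids across the whole set are a hard error; GenBank features
    are captured verbatim into a FeatureTable.
    """
    if format not in ("fasta", "genbank"):
        raise DataError(f"unknown genome format {format!r}")
    out: dict[str, GenomeRecord] = {}
    for path in paths:
        for rec in SeqIO.parse(str(path), format):
            if rec.id in out:
                raise DataError(f"duplicate genome id {rec.id!r} in {path}")
            features = _genbank_features(rec) if format == "genbank" else None
            out[rec.id] = GenomeRecord(
                id=rec.id, seq=str(rec.seq), circular=circular, features=features
            )
    if not out:
        raise DataError(f"no sequences parsed from {list(map(str, paths))}")
    return out


def read_features_gff3(path: str | Path, genome: GenomeRecord) -> FeatureTable:
    """Load gene/CDS/tRNA/rRNA/intron/exon records from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    feats = []
    for f in db.all_features():
        if f.featuretype not in {"gene", "CDS", "tRNA", "rRNA", "intron", "exon"}:
            continue
        name = f.attributes.get("Name", f.attributes.get("ID", [f.featuretype]))[0]
        feats.append(
            Feature(f.featuretype, name, ((f.start - 1, f.end),), f.strand or "+")
        )
    return FeatureTable(feats, len(genome))


class AlignmentMatrix:
    """A multiple alignment with per-row column <-> coordinate maps.

    ``col_to_pos[i][c]`` is the ungapped coordinate on genome i at column c,
    or -1 at a gap; ``pos_to_col[i][p]`` is the column holding coordinate p.
    """

    GAP = "-"

    def __init__(self, ids: Sequence[str], rows: Sequence[str]):
        self.ids = list(ids)
        self.rows = [r.upper() for r in rows]
        if len(self.ids) != len(self.rows):
            raise DataError("ids and rows differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise DataError("duplicate ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise DataError(f"ragged alignment rows, lengths {sorted(lengths)}")
        (self.ncols,) = lengths
        arr = np.frombuffer(
            "".join(self.rows).encode(), dtype="S1"
        ).reshape(len(self.rows), self.ncols)
        self.array = arr  # bytes matrix, shape (n_rows, ncols)
        self.gap_mask = arr == b"-"
        self.col_to_pos: list[np.ndarray] = []
        self.pos_to_col: list[np.ndarray] = []
        for i in range(len(self.rows)):
            nongap = ~self.gap_mask[i]
            c2p = np.cumsum(nongap) - 1
            c2p[self.gap_mask[i]] = -1
            self.col_to_pos.append(c2p)
            self.pos_to_col.append(np.flatnonzero(nongap))

    @property
    def nrows(self) -> int:
        return len(self.rows)

    def row(self, id: str) -> str:
        return self.rows[self.ids.index(id)]

    def ungapped(self, id: str) -> str:
        return self.row(id).replace(self.GAP, "")

    def column(self, c: int) -> str:
        return "".join(r[c] for r in self.rows)


def read_alignment(
    path: str | Path, genomes: dict[str, GenomeRecord] | None = None
) -> AlignmentMatrix:
    """Read an aligned FASTA and (optionally) validate rows against genomes.

    Each ungapped row must reproduce its genome sequence exactly; a mismatch
    is reported with the first differing ungapped coordinate.
    """
    recs = list(SeqIO.parse(str(path), "fasta"))
    if not recs:
        raise DataError(f"no alignment rows in {path}")
    aln = AlignmentMatrix([r.id for r in recs], [str(r.seq) for r in recs])
    if genomes is not None:
        for id_ in aln.ids:
            if id_ not in genomes:
                raise DataError(f"alignment row {id_!r} not in genome set")
            ung = aln.ungapped(id_)
            ref = genomes[id_].seq
            if ung != ref:
                k = next(
                    (i for i, (a, b) in enumerate(zip(ung, ref)) if a != b),
                    min(len(ung), len(ref)),
                )
                raise DataError(
                    f"ungapped alignment row {id_!r} differs from genome at "
                    f"coordinate {k} (row len {len(ung)}, genome len {len(ref)})"
                )
    return aln


def write_genomes_fasta(genomes: Iterable[GenomeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, len(g.seq), 70):
                fh.write(g.seq[i : i + 70] + "\n")


def write_alignment_fasta(aln: AlignmentMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for id_, row in zip(aln.ids, aln.rows):
            fh.write(f">{id_}\n")
            for i in range(0, len(row), 70):
                fh.write(row[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# report writing


_BED_HEADER = "# BED6: 0-based half-open intervals\n"
_TSV_HEADER = "# coordinates: 1-based inclusive unless suffixed _0based\n"


def _write_bed(path: Path, rows: list[tuple]) -> None:
    with open(path, "w") as fh:
        fh.write(_BED_HEADER)
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER)
        fh.write("\t".join(header) + "\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def write_snp_vcf(path: Path, snps, ref_genome: GenomeRecord, genotype_ids) -> None:
    """Emit biallelic/multiallelic SNPs as a minimal VCF 4.2 with one
    haploid pseudo-sample per genotype."""
    ids = list(genotype_ids)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={ref_genome.id},length={len(ref_genome)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##INFO=<ID=CLASS,Number=1,Type=String,Description='
            '"Unordered substitution class">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(ids) + "\n")
        for s in snps:
            ref_allele = s.alleles[ref_genome.id]
            alts = sorted({a for a in s.alleles.values() if a not in (ref_allele, "N")})
            allele_idx = {ref_allele: 0}
            for j, a in enumerate(alts, start=1):
                allele_idx[a] = j
            gts = [
                "." if s.alleles[i] == "N" else str(allele_idx[s.alleles[i]])
                for i in ids
            ]
            info = f"CLASS={s.subst_class}" if s.subst_class else "CLASS=multiallelic"
            fh.write(
                f"{ref_genome.id}\t{s.ref_pos + 1}\t.\t{ref_allele}\t"
                f"{','.join(alts) or '.'}\t.\t.\t{info}\tGT\t" + "\t".join(gts) + "\n"
            )


def write_reports(results, outdir: str | Path) -> dict[str, Path]:
    """Write every downstream result set as TSV/BED/VCF files.

    ``results`` is a MarkerReport (duck-typed); empty result lists still
    produce valid, headered files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    ids = results.genotype_ids
    ref = results.reference

    # --- structure (per-genotype region table)
    rows = []
    for gid in ids:
        st = results.structures[gid]
        g = results.genomes[gid]
        rows.append(
            [gid, len(g), st.lengths["LSC"], st.lengths["IRb"], st.lengths["SSC"],
             st.lengths["IRa"], f"{g.gc:.4f}", f"{st.gc['LSC']:.4f}",
             f"{st.gc['SSC']:.4f}", f"{st.gc['IRb']:.4f}"]
        )
    paths["structure"] = outdir / "structure.tsv"
    _write_tsv(
        paths["structure"],
        ["genotype", "size_bp", "lsc_bp", "irb_bp", "ssc_bp", "ira_bp",
         "gc_total", "gc_lsc", "gc_ssc", "gc_ir"],
        rows,
    )

    # --- SNPs
    paths["snps_vcf"] = outdir / "snps.vcf"
    write_snp_vcf(paths["snps_vcf"], results.snps, results.genomes[ref], ids)
    rows = [
        [s.ref_pos + 1, s.aln_col + 1, s.region, s.context[0], s.context[1],
         s.subst_class or "multiallelic",
         {True: "Ts", False: "Tv", None: "NA"}[s.is_transition],
         ";".join(f"{i}={s.alleles[i]}" for i in ids)]
        for s in results.snps
    ]
    paths["snps_tsv"] = outdir / "snps.tsv"
    _write_tsv(
        paths["snps_tsv"],
        ["ref_pos", "aln_col", "region", "context_kind", "context_name",
         "class", "ts_tv", "alleles"],
        rows,
    )
    sp = results.spectrum
    paths["spectrum"] = outdir / "spectrum.tsv"
    _write_tsv(
        paths["spectrum"],
        ["class", "count"],
        [[c, sp.counts[c]] for c in sp.counts]
        + [["transitions", sp.ts_total], ["transversions", sp.tv_total],
           ["multiallelic", sp.multiallelic],
           ["tv_ts_ratio", "NA" if sp.tv_ts_ratio is None else f"{sp.tv_ts_ratio:.4f}"]],
    )

    # --- SSRs
    rows, bed = [], []
    for gid in ids:
        for loc in results.ssr_loci[gid]:
            rows.append(
                [gid, loc.span[0] + 1, loc.span[1], loc.region, loc.context[0],
                 loc.context[1], loc.ssr_type, loc.motif, loc.n_units,
                 loc.tract_length, loc.canonical_class]
            )
            bed.append((gid, loc.span[0], loc.span[1], loc.ssr_type, 0, "+"))
    paths["ssr_tsv"] = outdir / "ssr_loci.tsv"
    _write_tsv(
        paths["ssr_tsv"],
        ["genotype", "start", "end", "region", "location", "context_name",
         "ssr_type", "motif", "n_units", "tract_bp", "class"],
        rows,
    )
    paths["ssr_bed"] = outdir / "ssrs.bed"
    _write_bed(paths["ssr_bed"], bed)
    rows = []
    for p in results.ssr_polymorphisms:
        rows.append(
            [p.locus_key, p.is_polymorphic]
            + [
                "absent" if p.per_genotype.get(i) is None
                else f"{p.per_genotype[i][0]}({p.per_genotype[i][1]}bp)"
                for i in ids
            ]
        )
    paths["ssr_matrix"] = outdir / "ssr_matrix.tsv"
    _write_tsv(paths["ssr_matrix"], ["locus", "polymorphic"] + ids, rows)

    # --- indels
    def _indel_rows(events):
        out, bed = [], []
        for k, ev in enumerate(events):
            s, e = ev.ref_span
            out.append(
                [k, s + 1, e, ev.size, ev.allele_present, ev.ssr_related,
                 ev.region, ev.context[0], ev.context[1]]
                + [ev.polarity[i] for i in ids]
            )
            bed.append((ref, s, max(e, s + 1), f"indel{k}_{ev.size}bp", 0, "+"))
        return out, bed

    common_rows, common_bed = _indel_rows(results.common_indels)
    ssr_rows, _ = _indel_rows(results.ssr_indels)
    hdr = ["id", "ref_start", "ref_end", "size_bp", "allele", "ssr_related",
           "region", "context_kind", "context_name"] + ids
    paths["indels_tsv"] = outdir / "indels.tsv"
    _write_tsv(paths["indels_tsv"], hdr, common_rows + ssr_rows)
    paths["indels_bed"] = outdir / "indels.bed"
    _write_bed(paths["indels_bed"], common_bed)

    # --- inversions
    rows, bed = [], []
    for k, inv in enumerate(results.inversions):
        s, e = inv.ref_span
        rows.append(
            [k, s + 1, e, inv.length, inv.flank_repeat_len, inv.loop_len,
             inv.stem_loop_ok, inv.region, inv.context[0], inv.context[1],
             ";".join(sorted(inv.inverted_genotypes))]
        )
        bed.append((ref, s, e, f"inversion{k}_{inv.length}bp", 0, "+"))
    paths["inversions_tsv"] = outdir / "inversions.tsv"
    _write_tsv(
        paths["inversions_tsv"],
        ["id", "ref_start", "ref_end", "core_bp", "flank_repeat_bp", "loop_bp",
         "stem_loop_ok", "region", "context_kind", "context_name", "inverted_in"],
        rows,
    )
    paths["inversions_bed"] = outdir / "inversions.bed"
    _write_bed(paths["inversions_bed"], bed)

    # --- summary (counts layout of the SNP / SSR / indel figures)
    summary = results.summary_rows()
    paths["summary"] = outdir / "summary.tsv"
    _write_tsv(paths["summary"], ["metric", "value"], summary)
    return paths
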