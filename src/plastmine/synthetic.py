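"""Plastome simulator with planted events and a ground-truth ledger.

The simulator emits a quadripartite reference (~30 kb by default, ~37% GC),
derives genotype genomes by planting SNPs, SSR unit-count changes, indels
and small inversions, and constructs the TRUE alignment directly from the
edit script (no aligner). The background is screened by rejection sampling
so that the only qualifying SSR tracts are the planted ones and planted
inversion stems cannot extend; with non-overlapping, well-separated events
this makes every detector's recovery exact, which is what the planted-truth
tests rely on.

All events are placed in the single-copy regions: an event written into one
IR copy only would break the exact IRa == revcomp(IRb) invariant that
structure detection is defined by.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import DataError, SimulationError
from .io import (
    AlignmentMatrix,
    Feature,
    FeatureTable,
    GenomeRecord,
    write_alignment_fasta,
    write_genomes_fasta,
)
from .ssr import DEFAULT_THRESHOLDS, _perfect_repeats
from .structure import QuadripartiteStructure, detect_quadripartite
from .util import complement, revcomp

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationParams:
    """Stated world of the simulator.

    Region lengths give a ~32 kb desk-scale plastome; the event budget
    mirrors a six-genotype comparative study (141 SNPs at Ts:Tv 88:53,
    44 non-SSR indels of 1-28 bp, 5 inversions with 2-51 bp cores and
    6-22 bp hairpin stems, SSR unit-length mix dominated by A/T
    mononucleotides).
    """

    lsc_len: int = 23_000
    ir_len: int = 3_000
    ssc_len: int = 4_000
    gc: float = 0.37
    n_genotypes: int = 6
    n_snps: int = 141
    ts_tv_ratio: float = 88 / 53
    n_ssr_tracts: int = 30
    #: sampling weights for unit lengths 1..6 (mono..hexa)
    ssr_unit_mix: tuple[float, ...] = (0.56, 0.17, 0.10, 0.06, 0.11, 0.0)
    n_ssr_polymorphic: int = 20
    n_indels: int = 44
    indel_size_range: tuple[int, int] = (1, 28)
    n_inversions: int = 5
    inversion_core_range: tuple[int, int] = (2, 51)
    inversion_flank_range: tuple[int, int] = (6, 22)
    noncoding_only: bool = True
    min_separation: int = 50
    thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS
    seed: int = 0

    def validate(self) -> None:
        if min(self.lsc_len, self.ir_len, self.ssc_len) <= 0:
            raise DataError("region lengths must be positive")
        if self.ssc_len >= self.lsc_len:
            raise DataError("SSC must be shorter than LSC")
        if not (0.0 < self.gc < 1.0):
            raise DataError("gc must be in (0, 1)")
        if self.n_genotypes < 2:
            raise DataError("need at least two genotypes")
        if self.n_ssr_polymorphic > self.n_ssr_tracts:
            raise DataError("n_ssr_polymorphic cannot exceed n_ssr_tracts")
        for v in (self.n_snps, self.n_ssr_tracts, self.n_indels, self.n_inversions):
            if v < 0:
                raise DataError("event counts must be >= 0")

    @property
    def genome_length(self) -> int:
        return self.lsc_len + 2 * self.ir_len + self.ssc_len


@dataclass
class TruthEvent:
    kind: str  # snp | ssr | indel | inversion
    genotypes: tuple[str, ...]  # genotypes carrying the non-reference state
    ref_span: tuple[int, int]  # on the reference genotype, 0-based half-open
    payload: dict = field(default_factory=dict)


@dataclass
class TruthTable:
    """Planted-event ledger; the recovery-test contract."""

    events: list[TruthEvent] = field(default_factory=list)

    def of_kind(self, kind: str) -> list[TruthEvent]:
        return [e for e in self.events if e.kind == kind]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.events:
            out[e.kind] = out.get(e.kind, 0) + 1
        return out

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# coordinates: 0-based half-open on the reference\n")
            fh.write("kind\tgenotypes\tref_start\tref_end\tpayload\n")
            for e in self.events:
                fh.write(
                    f"{e.kind}\t{';'.join(e.genotypes)}\t{e.ref_span[0]}\t"
                    f"{e.ref_span[1]}\t{json.dumps(e.payload, sort_keys=True)}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthTable":
        events = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or line.startswith("kind\t"):
                    continue
                kind, gids, s, e, payload = line.rstrip("\n").split("\t")
                events.append(
                    TruthEvent(
                        kind, tuple(gids.split(";")) if gids else (),
                        (int(s), int(e)), json.loads(payload),
                    )
                )
        return cls(events)


@dataclass
class _Planted:
    kind: str  # ssr | inversion | indel | snp
    start: int  # reference start of the reserved content
    width: int  # reference width reserved (0 for pure insertion point)
    payload: dict = field(default_factory=dict)

    @property
    def end(self) -> int:
        return self.start + self.width


@dataclass
class Simulation:
    params: SimulationParams
    reference: GenomeRecord
    structure: QuadripartiteStructure
    features: FeatureTable
    genotypes: dict[str, GenomeRecord]
    alignment: AlignmentMatrix
    truth: TruthTable


# ---------------------------------------------------------------------------
# building blocks


def _random_seq(rng, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p)


def _toy_features(params: SimulationParams) -> FeatureTable:
    """Alternating gene/spacer blocks over the single-copy regions; every
    third gene carries an intron. Spacers are implicit (derived)."""
    n = params.genome_length
    feats = []
    gene_len, spacer_len, intron_len = 500, 900, 150
    idx = 0
    for rs, re_ in (
        (0, params.lsc_len),
        (params.lsc_len + params.ir_len, params.lsc_len + params.ir_len + params.ssc_len),
    ):
        pos = rs + spacer_len
        while pos + gene_len + spacer_len <= re_:
            idx += 1
            name = f"gene{idx:03d}"
            feats.append(Feature("gene", name, ((pos, pos + gene_len),), "+"))
            if idx % 3 == 0:
                mid = pos + (gene_len - intron_len) // 2
                feats.append(
                    Feature("intron", name, ((mid, mid + intron_len),), "+")
                )
            pos += gene_len + spacer_len
    return FeatureTable(feats, n)


def _noncoding_intervals(params: SimulationParams, features: FeatureTable):
    """Intervals available for event placement: single-copy, margin-clipped,
    minus gene bodies (introns added back) when noncoding_only."""
    m = params.min_separation
    sc = [
        (m, params.lsc_len - m),
        (params.lsc_len + params.ir_len + m,
         params.lsc_len + params.ir_len + params.ssc_len - m),
    ]
    if not params.noncoding_only:
        return sc, sc
    blocked = sorted(
        (f.start, f.end) for f in features if f.kind == "gene"
    )
    introns = [(f.start, f.end) for f in features if f.kind == "intron"]
    noncoding = []
    for s, e in sc:
        pos = s
        for bs, be in blocked:
            if be <= pos or bs >= e:
                continue
            if bs > pos:
                noncoding.append((pos, min(bs, e)))
            pos = max(pos, be)
        if pos < e:
            noncoding.append((pos, e))
    noncoding.extend((max(s + 2, 0), e - 2) for s, e in introns)
    noncoding.sort()
    return noncoding, sc


class _Allocator:
    """Carves non-overlapping slots (with pairwise separation) out of a set
    of free intervals."""

    def __init__(self, rng, intervals, separation: int):
        self.rng = rng
        self.free = [(s, e) for s, e in intervals if e > s]
        self.sep = separation

    def take(self, width: int) -> int:
        # reserving `sep` on the right side only still guarantees pairwise
        # separation: any later event carved to the left must itself leave
        # `sep` to the right of its own slot
        need = width + self.sep
        fits = [i for i, (s, e) in enumerate(self.free) if e - s >= need]
        if not fits:
            raise SimulationError(
                f"event placement exhausted free space (width {width}); "
                "use a longer genome or a smaller event budget"
            )
        weights = np.array([self.free[i][1] - self.free[i][0] for i in fits], float)
        i = fits[self.rng.choice(len(fits), p=weights / weights.sum())]
        s, e = self.free[i]
        start = int(self.rng.integers(s, e - width - self.sep + 1))
        self.free[i : i + 1] = [
            iv for iv in ((s, start), (start + width + self.sep, e))
            if iv[1] > iv[0]
        ]
        return start


def _random_motif(rng, k: int) -> str:
    from .util import motif_is_reducible

    while True:
        motif = "".join(_BASES[rng.integers(0, 4, size=k)])
        if not motif_is_reducible(motif):
            return motif


def _anti_palindromic_core(rng, length: int) -> str:
    """Random core such that every position of its reverse complement
    mismatches the original: core[i] != complement(core[L-1-i]) for all i.
    This guarantees the inversion shows up as one full-length mismatch run."""
    core = [""] * length
    for i in range((length + 1) // 2):
        j = length - 1 - i
        if i == j:  # middle base: comp(b) != b always holds for DNA
            core[i] = str(rng.choice(_BASES))
            continue
        while True:
            a, b = rng.choice(_BASES), rng.choice(_BASES)
            if b != complement(a):
                core[i], core[j] = str(a), str(b)
                break
    return "".join(core)


def _qualifying_tracts(seq: str, thresholds) -> list[tuple[int, int]]:
    """Spans of all threshold-meeting perfect repeats (screening primitive;
    the scan itself is validated elsewhere against a brute-force oracle)."""
    return [(a, a + k * u) for a, k, u, _ in _perfect_repeats(seq, thresholds)]


# ---------------------------------------------------------------------------
# the build itself


def _plan_events(params: SimulationParams, rng, features) -> list[_Planted]:
    noncoding, singlecopy = _noncoding_intervals(params, features)
    alloc_nc = _Allocator(rng, noncoding, params.min_separation)
    # SNPs may sit in coding sequence too, but must respect the same
    # separation; share one allocator over the wider pool is unsound
    # (slots would overlap), so all events come from one pool.
    pool = alloc_nc if params.noncoding_only else _Allocator(
        rng, singlecopy, params.min_separation
    )
    planted: list[_Planted] = []
    gids = [f"g{i + 1:02d}" for i in range(params.n_genotypes)]
    nonref = gids[1:]

    def pick_genotypes(n: int) -> tuple[str, ...]:
        idx = rng.choice(len(nonref), size=n, replace=False)
        return tuple(sorted(nonref[int(i)] for i in np.atleast_1d(idx)))

    # SSR tracts (first n_ssr_polymorphic get a unit-count change)
    mix = np.array(params.ssr_unit_mix, float)
    mix = mix / mix.sum()
    for t in range(params.n_ssr_tracts):
        k = int(rng.choice(6, p=mix)) + 1
        thr = params.thresholds[k - 1]
        hi = 16 if k == 1 else thr + 3
        units = int(rng.integers(thr, hi + 1))
        motif = _random_motif(rng, k)
        payload = {"motif": motif, "units": units, "unit_len": k}
        if t < params.n_ssr_polymorphic:
            delta = int(rng.choice([-2, -1, 1, 2]))
            if units + delta < thr:
                delta = abs(delta)
            payload["delta"] = delta
            payload["genotype"] = pick_genotypes(1)[0]
        # pad both sides so two planted tracts always lie further apart than
        # the MISA compound-merge gap (100 bp): each tract is its own locus
        pad = 32
        start = pool.take(units * k + 2 + 2 * pad)
        planted.append(_Planted("ssr", start + pad + 1, units * k, payload))

    # inversions: left flank + core + right flank written into the reference
    for _ in range(params.n_inversions):
        core_len = int(rng.integers(*params.inversion_core_range, endpoint=True))
        flank = int(rng.integers(*params.inversion_flank_range, endpoint=True))
        n_car = 2 if rng.random() < 0.2 and len(nonref) >= 2 else 1
        width = core_len + 2 * flank
        start = pool.take(width + 2)
        planted.append(
            _Planted(
                "inversion", start + 1, width,
                {
                    "core_len": core_len,
                    "flank": flank,
                    "genotypes": pick_genotypes(n_car),
                },
            )
        )

    # indels (insertions have zero reference width; reserve the size anyway
    # so the separation also holds on the inserted genotype). Real plastome
    # indel sizes are heavily skewed toward 1 bp with a long tail; draw a
    # truncated geometric over the configured range and pin the first event
    # to the maximum so the full range is always exercised.
    lo, hi = params.indel_size_range
    for j in range(params.n_indels):
        if j == 0:
            size = hi
        else:
            size = lo + int(rng.geometric(0.35)) - 1
            size = min(max(size, lo), hi)
        is_del = bool(rng.random() < 0.5)
        n_car = 2 if rng.random() < 0.1 and len(nonref) >= 2 else 1
        start = pool.take(size + 2)
        planted.append(
            _Planted(
                "indel", start + 1, size if is_del else 0,
                {
                    "size": size,
                    "op": "del" if is_del else "ins",
                    "genotypes": pick_genotypes(n_car),
                },
            )
        )

    # SNPs
    n_ts = int(round(params.n_snps * params.ts_tv_ratio / (1 + params.ts_tv_ratio)))
    flags = [True] * n_ts + [False] * (params.n_snps - n_ts)
    rng.shuffle(flags)
    for is_ts in flags:
        start = pool.take(1)
        n_car = 2 if rng.random() < 0.2 and len(nonref) >= 2 else 1
        planted.append(
            _Planted(
                "snp", start, 1,
                {
                    "is_ts": bool(is_ts),
                    "tv_choice": int(rng.integers(0, 2)),
                    "genotypes": pick_genotypes(n_car),
                },
            )
        )
    return planted


_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TV_PARTNERS = {"A": "CT", "C": "AG", "G": "CT", "T": "AG"}


def _build_reference(params: SimulationParams, rng, planted) -> np.ndarray:
    """Background + reference-side planted content, screened and patched."""
    L, I, S = params.lsc_len, params.ir_len, params.ssc_len
    n = params.genome_length
    seq = np.empty(n, dtype="<U1")
    seq[: L + I] = _BASES[_random_seq(rng, L + I, params.gc)]
    seq[L + I : L + I + S] = _BASES[_random_seq(rng, S, params.gc)]

    reserved = np.zeros(n, dtype=bool)

    def stamp(start: int, text: str) -> None:
        seq[start : start + len(text)] = list(text)
        reserved[start : start + len(text)] = True

    for ev in planted:
        p = ev.payload
        if ev.kind == "ssr":
            tract = p["motif"] * p["units"]
            stamp(ev.start, tract)
            # break tandem extension on both sides
            if seq[ev.start - 1] == p["motif"][-1]:
                choices = [b for b in "ACGT" if b != p["motif"][-1]]
                seq[ev.start - 1] = choices[int(rng.integers(len(choices)))]
            if seq[ev.end] == p["motif"][0]:
                choices = [b for b in "ACGT" if b != p["motif"][0]]
                seq[ev.end] = choices[int(rng.integers(len(choices)))]
            reserved[ev.start - 1] = reserved[ev.end] = True
        elif ev.kind == "inversion":
            flank_seq = "".join(_BASES[rng.integers(0, 4, size=p["flank"])])
            core = _anti_palindromic_core(rng, p["core_len"])
            stamp(ev.start, flank_seq + core + revcomp(flank_seq))
            # break stem extension beyond the planted flank
            if seq[ev.start - 1] == complement(seq[ev.end]):
                choices = [b for b in "ACGT" if b != complement(seq[ev.end])]
                seq[ev.start - 1] = choices[int(rng.integers(len(choices)))]
            reserved[ev.start - 1] = reserved[ev.end] = True
            p["core"] = core
            p["flank_seq"] = flank_seq
        elif ev.kind == "indel" and p["op"] == "ins":
            p["seq"] = "".join(_BASES[rng.integers(0, 4, size=p["size"])])

    # screen the single-copy background: the only threshold-meeting tandem
    # repeats may be the planted tracts
    planted_spans = [
        (ev.start, ev.end) for ev in planted if ev.kind == "ssr"
    ]
    for attempt in range(60):
        # keep IRa an exact mirror while screening
        seq[L + I + S :] = list(revcomp("".join(seq[L : L + I])))
        s = "".join(seq)
        bad = [
            (a, b)
            for a, b in _qualifying_tracts(s, params.thresholds)
            if (a, b) not in planted_spans
        ]
        # fixed anchors: make the LSC lexicographically smaller than its
        # reverse complement so every genotype is already canonical
        patches = []
        if not (seq[0] == "A" and seq[1] == "A"):
            patches.append((0, "AA"))
        if not (seq[L - 2] == "G" and seq[L - 1] == "G"):
            patches.append((L - 2, "GG"))
        if seq[L - 1] == complement(seq[0]):  # IR wrap-around extension
            patches.append((L - 1, "G" if seq[0] != "C" else "A"))
        if seq[L + I] == complement(seq[L + I + S - 1]):  # inner IR extension
            alt = "A" if complement(seq[L + I + S - 1]) != "A" else "C"
            patches.append((L + I, alt))
        if not bad and not patches:
            break
        for a, b in bad:
            lo_, hi_ = a, b
            repl = _BASES[rng.integers(0, 4, size=hi_ - lo_)]
            keep = reserved[lo_:hi_]
            seq[lo_:hi_] = np.where(keep, seq[lo_:hi_], repl)
        for pos, text in patches:
            seq[pos : pos + len(text)] = list(text)
    else:
        raise SimulationError(
            "background screening exceeded its retry budget; "
            "use a longer genome or a looser screen"
        )
    return seq


def _apply_edits(params, rng, ref_seq: str, planted, gids):
    """Derive genotype rows + the true alignment + truth events."""
    nonref_states: list[tuple] = []  # (sort_pos, spec...) see below
    truth = TruthTable()

    subs: list[tuple[int, dict]] = []  # (pos, {gid: base})
    invs: list[tuple[int, int, str, tuple]] = []  # (s, e, inverted_core, gids)
    dels: list[tuple[int, int, tuple]] = []  # (s, e, gids)
    inss: list[tuple[int, str, tuple]] = []  # (point, seq, gids)

    for ev in sorted(planted, key=lambda e: e.start):
        p = ev.payload
        if ev.kind == "snp":
            ref_base = ref_seq[ev.start]
            if p["is_ts"]:
                alt = _TS_PARTNER[ref_base]
            else:
                alt = _TV_PARTNERS[ref_base][p["tv_choice"]]
            subs.append((ev.start, {g: alt for g in p["genotypes"]}))
            truth.events.append(
                TruthEvent(
                    "snp", p["genotypes"], (ev.start, ev.start + 1),
                    {"ref": ref_base, "alt": alt, "is_ts": p["is_ts"]},
                )
            )
        elif ev.kind == "inversion":
            s = ev.start + p["flank"]
            e = s + p["core_len"]
            invs.append((s, e, revcomp(ref_seq[s:e]), p["genotypes"]))
            truth.events.append(
                TruthEvent(
                    "inversion", p["genotypes"], (s, e),
                    {"core_len": p["core_len"], "flank": p["flank"]},
                )
            )
        elif ev.kind == "indel":
            if p["op"] == "del":
                dels.append((ev.start, ev.end, p["genotypes"]))
                truth.events.append(
                    TruthEvent(
                        "indel", p["genotypes"], (ev.start, ev.end),
                        {"op": "del", "size": p["size"],
                         "seq": ref_seq[ev.start : ev.end]},
                    )
                )
            else:
                inss.append((ev.start, p["seq"], p["genotypes"]))
                truth.events.append(
                    TruthEvent(
                        "indel", p["genotypes"], (ev.start, ev.start),
                        {"op": "ins", "size": p["size"], "seq": p["seq"]},
                    )
                )
        elif ev.kind == "ssr":
            tract_span = (ev.start, ev.end)
            if "delta" not in p:
                truth.events.append(
                    TruthEvent("ssr", (), tract_span,
                               {**{k: p[k] for k in ("motif", "units", "unit_len")},
                                "polymorphic": False})
                )
                continue
            k, d, g = p["unit_len"], p["delta"], p["genotype"]
            if d > 0:
                inss.append((ev.end, p["motif"] * d, (g,)))
            else:
                dels.append((ev.end + d * k, ev.end, (g,)))
            truth.events.append(
                TruthEvent(
                    "ssr", (g,), tract_span,
                    {**{k_: p[k_] for k_ in ("motif", "units", "unit_len")},
                     "polymorphic": True, "delta": d},
                )
            )

    # build rows left to right
    rows = {g: [] for g in gids}
    breakpoints = sorted(
        {0, len(ref_seq)}
        | {s for s, _ in subs} | {s + 1 for s, _ in subs}
        | {s for s, e, *_ in invs} | {e for s, e, *_ in invs}
        | {s for s, e, _ in dels} | {e for s, e, _ in dels}
        | {pt for pt, _, _ in inss}
    )
    ins_at = {pt: (text, gset) for pt, text, gset in inss}
    sub_at = {s: d for s, d in subs}
    inv_at = {s: (e, core, gset) for s, e, core, gset in invs}
    del_at = {s: (e, gset) for s, e, gset in dels}
    for a, b in zip(breakpoints, breakpoints[1:] + [None]):
        if a in ins_at:
            text, gset = ins_at[a]
            for g in gids:
                rows[g].append(text if g in gset else "-" * len(text))
        if b is None:
            break
        segment = ref_seq[a:b]
        if a in sub_at:
            alt_map = sub_at[a]
            for g in gids:
                rows[g].append(alt_map.get(g, segment))
        elif a in inv_at and inv_at[a][0] == b:
            _, core, gset = inv_at[a]
            for g in gids:
                rows[g].append(core if g in gset else segment)
        elif a in del_at and del_at[a][0] == b:
            _, gset = del_at[a]
            for g in gids:
                rows[g].append("-" * len(segment) if g in gset else segment)
        else:
            for g in gids:
                rows[g].append(segment)
    aln = AlignmentMatrix(gids, ["".join(rows[g]) for g in gids])
    return aln, truth


def _verify(sim_aln: AlignmentMatrix, params, truth, gids) -> bool:
    """Structural screen of the finished genotype set: every genotype's
    qualifying tandem-repeat tracts must project onto planted tract columns
    and match the planted count (event edits can create chance tracts at
    junctions; such draws are rejected and rebuilt with a fresh substream)."""
    ref_row = 0
    planted_cols = []
    for ev in truth.of_kind("ssr"):
        s, e = ev.ref_span
        c0 = int(sim_aln.pos_to_col[ref_row][s])
        c1 = int(sim_aln.pos_to_col[ref_row][e - 1]) + 1
        planted_cols.append((max(c0 - 2 * ev.payload["unit_len"], 0),
                             c1 + 3 * ev.payload["unit_len"]))
    for row, gid in enumerate(gids):
        seq = sim_aln.ungapped(gid)
        tracts = _qualifying_tracts(seq, params.thresholds)
        if len(tracts) != len(planted_cols):
            return False
        for a, b in tracts:
            c0 = int(sim_aln.pos_to_col[row][a])
            if not any(lo <= c0 < hi for lo, hi in planted_cols):
                return False
    return True


def _build(params: SimulationParams) -> Simulation:
    params.validate()
    gids = [f"g{i + 1:02d}" for i in range(params.n_genotypes)]
    features = _toy_features(params)
    for salt in range(20):
        ss = np.random.SeedSequence([int(params.seed) & 0x7FFFFFFF, salt])
        rng_plan, rng_bg = [np.random.default_rng(s) for s in ss.spawn(2)]
        planted = _plan_events(params, rng_plan, features)
        seq_arr = _build_reference(params, rng_bg, planted)
        ref_seq = "".join(seq_arr)
        aln, truth = _apply_edits(params, rng_bg, ref_seq, planted, gids)
        if not _verify(aln, params, truth, gids):
            continue
        genotypes = {
            g: GenomeRecord(id=g, seq=aln.ungapped(g), circular=True,
                            features=features if g == gids[0] else None)
            for g in gids
        }
        structure = detect_quadripartite(
            genotypes[gids[0]], min_ir_len=min(1000, params.ir_len)
        )
        return Simulation(
            params=params,
            reference=genotypes[gids[0]],
            structure=structure,
            features=features,
            genotypes=genotypes,
            alignment=aln,
            truth=truth,
        )
    raise SimulationError(
        "rejection sampling exceeded its retry budget; use a longer genome "
        "or a looser screen"
    )


# ---------------------------------------------------------------------------
# public operations


def simulate_reference(
    params: SimulationParams,
) -> tuple[GenomeRecord, QuadripartiteStructure, FeatureTable]:
    """Simulate the reference plastome only (identical to the reference
    genotype that :func:`mutate_genotypes` compares against)."""
    sim = _build(params)
    return sim.reference, sim.structure, sim.features


def mutate_genotypes(
    ref: GenomeRecord,
    structure: QuadripartiteStructure,
    features: FeatureTable,
    params: SimulationParams,
) -> tuple[dict[str, GenomeRecord], AlignmentMatrix, TruthTable]:
    """Derive the genotype set, the true alignment and the truth ledger.

    Rebuilds deterministically from ``params`` and checks that ``ref``
    matches, so the two public calls always agree.
    """
    sim = _build(params)
    if ref.seq != sim.reference.seq:
        raise DataError(
            "reference does not match this parameter set; pass the genome "
            "returned by simulate_reference(params)"
        )
    return sim.genotypes, sim.alignment, sim.truth


def simulate(params: SimulationParams | None = None) -> Simulation:
    """One-call convenience wrapper returning the full simulation bundle."""
    return _build(params or SimulationParams())


def emit_fixture(sim: Simulation, outdir: str | Path) -> dict[str, Path]:
    """Write genomes.fasta, alignment.fasta, features.gff3, truth.tsv and
    params.json; everything is re-readable by the io module."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genomes": outdir / "genomes.fasta",
        "alignment": outdir / "alignment.fasta",
        "features": outdir / "features.gff3",
        "truth": outdir / "truth.tsv",
        "params": outdir / "params.json",
    }
    write_genomes_fasta(sim.genotypes.values(), paths["genomes"])
    write_alignment_fasta(sim.alignment, paths["alignment"])
    ref_id = sim.reference.id
    with open(paths["features"], "w") as fh:
        fh.write("##gff-version 3\n")
        for f in sim.features:
            for s, e in f.spans:
                fh.write(
                    f"{ref_id}\tplastmine\t{f.kind}\t{s + 1}\t{e}\t.\t"
                    f"{f.strand}\t.\tID={f.name};Name={f.name}\n"
                )
    sim.truth.to_tsv(paths["truth"])
    with open(paths["params"], "w") as fh:
        json.dump(asdict(sim.params), fh, indent=1, sort_keys=True)
    return paths
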