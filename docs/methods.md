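# Methods

This note records the models and decision rules `plastmine` implements,
the parameters that matter, what the simulator does and does not emulate,
and the numerical/tie-break choices a maintainer would want written down.

## Quadripartite structure

Plastomes of most land plants are circular molecules partitioned into a
large single-copy region (LSC, ~80–90 kb), a small single-copy region
(SSC, ~18–20 kb) and two inverted-repeat copies (IRb/IRa, ~20–26 kb each)
carrying identical sequence in opposite orientations.

**Definition used.** The IR pair is the *maximal pair of disjoint, exactly
reverse-complementary substrings* of length ≥ `min_ir_len` (default
1000 bp — real plastome IRs are far longer; the threshold only excludes
small dispersed repeats). Detection is seed-and-extend: `seed_k`-mers
(default 25) of the genome are indexed and matched against its reverse
complement, each seed extended to a maximal exact match, with a
per-diagonal coverage map so the work stays near-linear. Circularity is
handled on a doubled sequence and arcs are reduced modulo the genome
length.

Exactness is deliberate: per-genotype IR lengths in comparative tables are
equal for the two copies, so "exact reverse complement" is the operative
definition. Near-identical IRs with internal mismatches are out of scope;
they surface as a structured no-IR outcome (single region labelled
`whole`) or, when two distinct pairs tie at maximal length, an ambiguity
error listing the candidates — never a silent guess. The two single-copy
arcs are assigned so the shorter is the SSC.

**Canonical presentation.** Reports use the rotation that starts the LSC at
position 0 in the order LSC, IRb, SSC, IRa. Because annotation is not
required, strand is otherwise undetermined; the strand whose LSC sequence
is lexicographically ≤ its reverse complement is chosen, which is
deterministic and orientation-blind. `canonicalize_orientation` applies
the recorded rotation/flip and remaps features (intervals that come to
straddle the origin are split). The analysis pipeline requires the
reference genome to already be in canonical order, because the alignment
is tied to the input coordinates and cannot be rotated after the fact.

## SNPs and the substitution spectrum

A SNP is an alignment column with **no gap in any genotype** and ≥ 2
distinct non-N bases. Gap-containing columns are indel territory: keeping
them out of the SNP set keeps the arithmetic "total = transitions +
transversions" exact. N never counts as an allele; a column whose only
variation involves N is not a SNP.

Biallelic sites are tallied into the six unordered, non-strand-specific
classes A/G, C/T (transitions) and A/C, A/T, C/G, G/T (transversions);
multiallelic columns are counted once each in a separate overflow bucket
excluded from the Ts/Tv totals. The ratio is reported as the plain number
Tv/Ts (NA when Ts = 0).

Strand symmetry caveat: complementation maps the *pairs* A/G↔C/T and
A/C↔G/T onto each other, so the individual six-class counts are **not**
invariant under reverse-complementing the input — only the pooled
complement classes, A/T, C/G and the Ts/Tv totals are. The symmetry tests
assert exactly that invariant.

IR deduplication: variants whose reference coordinate falls in IRa are
masked, so each IR variant is counted once (from IRb). Variable and
parsimony-informative site counts use the standard definitions over
gap-free columns (≥ 2 states; ≥ 2 states each carried by ≥ 2 genotypes).

Within the pipeline, inversion detection runs first and the columns of
reported inversion cores are masked from SNP calling; otherwise every base
of a reverse-complemented core would be double-counted as a substitution.

## SSR mining and polymorphism

Mining follows the MISA convention. A locus is a maximal perfect tandem
repeat of a 1–6 bp unit whose *unit count* meets the per-unit-length
minima (defaults 10, 5, 4, 3, 3, 3; a mono ≥ 10 units is 10 bp, a penta
≥ 3 units is 15 bp). Hexanucleotides are searched even though they are
rare to absent in real plastomes. Units that are themselves repetitions of
a shorter unit (e.g. ATAT) are reported at the shorter unit length only;
tract spans cover whole units (a trailing partial unit neither extends the
span nor adds a unit).

Overlap resolution keeps the locus with the greater tract length, then the
smaller unit length, then the leftmost start. Qualifying tracts separated
by ≤ `compound_max_gap` (default 100 bp, the cited tool's default) merge
into one compound locus rendered like `(ATA)4g(TAA)6` (interruption in
lower case). Loci entirely inside IRa are suppressed (IR counted once).

Motifs are reported as found on the forward strand; the canonical class
pools all rotations of the motif and of its reverse complement (A and T
both map to class `A/T`), which is what statements like "46 of 48
mono+dinucleotide SSRs contained only A or T" quantify over.

**Cross-genotype comparison** anchors loci through the alignment: each
tract is projected to alignment columns, and loci of identical canonical
class with overlapping projections are one locus (union-find). Two
same-class loci of one genotype in a single cluster is an anchor-collision
error. A genotype with no qualifying locus at an anchored position is
still tabulated with its actual, sub-threshold tract length measured
around the projected anchor. A locus is polymorphic iff ≥ 2 distinct
tract lengths occur among the genotypes that carry it.

`extract_flanks` returns forward-strand sequence on both sides of a tract
(default 250 bp), wrapping across the origin of circular genomes — input
for external primer design, which is itself out of scope.

## Indels and small inversions

**Events.** Maximal runs of alignment columns with one constant gap/base
pattern form one event (a gap shared by several genotypes is one event);
runs are split wherever the genotypes carrying sequence disagree, and
disagreement columns become single-column events of their own. Polarity is
reference-relative and descriptive, not ancestral: sequence where the
standard reference has a gap → insertion; gap where the reference has
sequence → deletion. Swapping the reference changes polarity labels only.

**SSR-relatedness.** An event is SSR slippage iff (a) its present allele is
a whole-number tandem repetition of a rotation of some unit of (b) an SSR
locus whose alignment projection overlaps or directly abuts (distance 0)
the event's columns. All other events are "common" indels. The abut
distance is 0 by default (configurable); a ±1 window would only matter for
tracts separated from the event by exactly one base.

**Inversions.** For each maximal run of gap-free mismatch columns between
the reference and a genotype with core length in [`min_len`, `max_len`]
(defaults 2, 100), the run is an inversion iff the genotype core equals
the reverse complement of the reference core; failing runs are left to the
SNP caller. The hairpin stem is the longest exact inverted-repeat pair
immediately bracketing the core on the reference, searched outward up to
`flank_window` (30 bp); `stem_loop_ok` iff stem ≥ `min_stem` (6 bp,
matching the shortest stems reported for real plastome inversions).
Exact flank complementarity deliberately replaces thermodynamic folding:
the quantities tabulated for such inversions (core length, stem length)
are fully determined by the flanking repeats, so a folding engine would
add a dependency without changing any number.

Limitation: an inversion whose core is a perfect palindrome leaves the
genotype sequence identical to the reference and is physically
undetectable from sequence comparison; the `palindromic_core` flag exists
on the data type, but such events cannot arise from mismatch runs and are
not reported.

## The simulator (stated world)

Defaults describe a desk-scale six-genotype comparative study: 23 kb LSC +
3 kb IR ×2 + 4 kb SSC (~33 kb total; real plastomes are ~153 kb — region
proportions, not absolute sizes, are preserved), 37% GC, 141 SNPs at a
Ts:Tv budget of 88:53, 30 SSR tracts (unit-length mix ≈ 56/17/10/6/11/0%
mono→hexa, mirroring reported plastome SSR inventories; 20 tracts carry a
unit-count change in one genotype), 44 non-SSR indels of 1–28 bp drawn
from a truncated geometric distribution (1 bp modal, the first event
pinned at the 28 bp maximum, matching the skew of published indel size
spectra), and 5 inversions with 2–51 bp cores and 6–22 bp stems.

Construction guarantees that make recovery exact rather than approximate:

- Backgrounds are rejection-screened so the only tandem repeats meeting
  the SSR thresholds are the planted tracts; tract neighbours are chosen
  to break tandem extension, and planted tracts are spaced further apart
  than the compound-merge gap so each is its own locus.
- Inversion cores are sampled so that every position of the
  reverse-complemented core mismatches the original (no position pairs
  with its mirror's complement); the full core is then one mismatch run.
  Stems are written into the *reference*, so all genotypes share the
  flanks, and the base beyond each stem is chosen to break extension —
  the detected stem length equals the planted one exactly.
- All events are planted in the single-copy regions with ≥ 50 bp pairwise
  separation; an event written into one IR copy only would break the
  exact IRa = revcomp(IRb) invariant the structure detector is defined by.
- The true alignment is constructed directly from the edit script; no
  aligner runs. Detector tests are therefore independent of aligner
  behaviour, which is an input contract, not logic under test.
- A final structural screen re-scans every genotype for qualifying tracts
  (event junctions can create one by chance) and rebuilds from a salted
  substream if violated — rejection sampling over worlds, bounded at 20
  attempts. The screen uses the raw repeat-scan primitive, which is
  itself validated against a brute-force enumerator in the test suite, so
  miner recovery tests are not circular.
- Everything derives from a single integer seed; identical parameters and
  seed give byte-identical outputs.

What the simulator does **not** emulate: phylogenetic correlation between
genotypes (events are planted independently), mutation-rate heterogeneity
along the genome, base-composition skew, repeat-rich backgrounds,
IR boundary shifts, and aligner artefacts. A green recovery test
establishes that the detectors invert the simulator's edit model on
screened backgrounds — not that they are robust to misalignment or to
repeat structures real plastomes may contain.

## Numerical and interface choices

- Internal coordinates are 0-based half-open everywhere; VCF/TSV report
  columns are 1-based inclusive, BED stays 0-based half-open, and every
  report file states its convention in a header comment.
- Ties in structure detection (two equal maximal IR pairs, equal
  single-copy arcs) are errors, not choices.
- The reference genotype defaults to the lexicographically first id, with
  a loud warning; all thresholds live in one config block and are logged
  on every run.
- CLI exit codes: 0 ok, 1 usage error, 2 data error.
- The pipeline contains no randomness; only `simulate` consumes the seed.
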