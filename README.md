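# plastmine

Comparative mining of micro-variation in chloroplast genomes (plastomes).

Given a set of plastome sequences from closely related genotypes and their
multiple alignment, `plastmine` delimits the quadripartite genome
architecture and builds the complete marker inventory that intraspecific
chloroplast studies report:

- **Quadripartite structure** — the large single-copy (LSC), small
  single-copy (SSC) and the two inverted-repeat regions (IRb/IRa), found as
  the maximal pair of disjoint, exactly reverse-complementary repeats, with
  per-region lengths and GC content.
- **SNPs** — alignment columns with no gaps and ≥ 2 distinct bases, with the
  six-class non-strand-specific substitution spectrum
  (A↔G, C↔T transitions; A↔C, A↔T, C↔G, G↔T transversions) and the Tv/Ts
  ratio. Variants inside the IR are counted once.
- **cpSSRs (microsatellites)** — maximal perfect tandem repeats of 1–6 bp
  units at the MISA thresholds (≥ 10, 5, 4, 3, 3, 3 units for mono- through
  hexanucleotide motifs), compound loci for interrupted tracts, and
  cross-genotype length-polymorphism calls anchored through the alignment.
- **Indels** — maximal constant gap-pattern runs, split into SSR-slippage
  events (the inserted/deleted sequence is a whole number of repeat units
  at an adjoining tract) versus *common* indels, each polarized as
  insertion/deletion relative to a designated standard reference genotype.
- **Small inversions** — short reverse-complemented cores bracketed by an
  exact inverted-repeat pair that can fold into a hairpin; the stem is the
  flanking repeat, the loop is the inverted core.

A built-in simulator generates plastome genotype sets with planted events
and a ground-truth ledger, so the whole pipeline is testable offline.

## Worked example

Simulate a six-genotype set (~33 kb each, 37% GC) with 141 planted SNPs at
a transition:transversion budget of 88:53, 30 SSR tracts (20 with
unit-count changes), 44 non-SSR indels of 1–28 bp and 5 inversions with
6–22 bp hairpin stems, then analyze it:

```sh
plastmine simulate --seed 1 --out sim
plastmine all --genomes sim/genomes.fasta --alignment sim/alignment.fasta \
    --features sim/features.gff3 --reference g01 --out results
```

The summary (`results/summary.tsv`, also echoed to the terminal) begins:

```
n_genotypes            6
reference              g01
variable_sites         278
parsimony_informative_sites  34
snps_total             141
snps_A/G               34
snps_C/T               54
...
snps_transitions       88
snps_transversions     53
tv_ts_ratio            0.6023
ssrs_reference         30
ssr_polymorphic_loci   20
common_indels          44
ssr_related_indels     20
indel_max_bp           28
indel_modal_bp         1
inversions             5
```

Reading: all 141 SNP columns were recovered and tallied into the six
substitution classes (88 transitions / 53 transversions, Tv/Ts ≈ 0.60);
variable sites exceed the SNP count because inverted cores also vary. The
30 SSR loci yield 20 polymorphic tract-length comparisons, whose slippage
indels are filtered out of the 44 common indels (longest 28 bp, 1 bp most
frequent). The five inversions are listed with core length, stem length and
carrier genotypes. Per-marker detail lands in `snps.vcf`, `snps.tsv`,
`ssr_loci.tsv`, `ssr_matrix.tsv`, `indels.tsv`, `inversions.tsv` and BED
companions (internal coordinates 0-based half-open; report columns 1-based,
as each file header states).

The same API is available in Python:

```python
import plastmine as pm

sim = pm.simulate(pm.SimulationParams(seed=1))
report = pm.analyze(sim.genotypes, sim.alignment,
                    reference="g01", features=sim.features)
print(len(report.snps), report.spectrum.ts_total, report.spectrum.tv_total)
# 141 88 53
```

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computation from
scratch: it simulates the default stated world from the given seed,
executes every detector through the pipeline, checks the detected marker
counts against the planted truth ledger, and writes the results JSON.

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

A non-zero exit means a detector failed to reproduce the planted truth.

## Layout

- `src/plastmine/io.py` — FASTA/GenBank/GFF3/aligned-FASTA in; VCF/BED/TSV out
- `src/plastmine/structure.py` — quadripartite delimitation, canonical orientation
- `src/plastmine/snps.py` — SNP calling, substitution spectrum, site classes
- `src/plastmine/ssr.py` — SSR mining, deduplication, polymorphism calls, flanks
- `src/plastmine/microstructure.py` — indels, SSR-relatedness, small inversions
- `src/plastmine/synthetic.py` — simulator + truth ledger
- `src/plastmine/pipeline.py`, `cli.py` — orchestration and the `plastmine` CLI
- `docs/methods.md` — models, rules, parameters and limitations
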