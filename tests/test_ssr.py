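"""SSR mining (MISA thresholds), deduplication, compounds, polymorphisms."""

import numpy as np
import pytest

import plastmine as pm
from plastmine.ssr import (
    SsrLocus,
    _perfect_repeats,
    compare_ssrs,
    deduplicate_ssrs,
    detect_ssrs,
    extract_flanks,
)
from plastmine.util import canonical_motif_class, revcomp

from .conftest import random_dna
from .oracles import brute_force_ssrs

#: hand-checked tract-free padding; starts and ends with C so none of the
#: planted test tracts (which never abut a C-compatible unit edge) extends
PAD = "CTGACGTGATCGAGTCGATC"


def genome(seq: str, gid: str = "t") -> pm.GenomeRecord:
    return pm.GenomeRecord(id=gid, seq=seq, circular=True)


class TestDetect:
    def test_mono_threshold_boundary(self):
        below = PAD + "G" * 9 + PAD
        at = PAD + "A" * 10 + PAD
        assert detect_ssrs(genome(below)) == []
        (loc,) = detect_ssrs(genome(at))
        assert (loc.motif, loc.n_units, loc.span) == ("A", 10, (20, 30))

    def test_all_six_unit_lengths_searched(self):
        parts = ["A" * 10, "AG" * 5, "AAG" * 4, "AAGT" * 3, "AACAG" * 3,
                 "AACGAT" * 3]
        seq = PAD + PAD.join(parts) + PAD
        loci = detect_ssrs(genome(seq), compound_max_gap=None)
        assert sorted(l.unit_len for l in loci) == [1, 2, 3, 4, 5, 6]

    def test_compound_locus_type_string(self):
        """Two qualifying tracts split by a 1 bp interruption merge into a
        compound, rendered like '(ATA)4g(TAA)6'."""
        seq = PAD + "ATA" * 4 + "G" + "TAA" * 6 + PAD
        (loc,) = detect_ssrs(genome(seq))
        assert loc.is_compound
        assert loc.ssr_type == "(ATA)4g(TAA)6"
        assert loc.span == (20, 20 + 12 + 1 + 18)
        assert loc.expected_sequence() == genome(seq).seq[loc.span[0]:loc.span[1]]

    def test_compound_merging_disabled(self):
        seq = PAD + "ATA" * 4 + "G" + "TAA" * 6 + PAD
        loci = detect_ssrs(genome(seq), compound_max_gap=None)
        assert [l.ssr_type for l in loci] == ["(ATA)4", "(TAA)6"]

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_scan_equals_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 10_000)
        got = set(_perfect_repeats(seq, (10, 5, 4, 3, 3, 3)))
        assert got == brute_force_ssrs(seq)

    def test_reducible_unit_reported_at_shorter_length(self):
        seq = PAD + "AT" * 10 + PAD  # (AT)x10, not (ATAT)x5
        loci = detect_ssrs(genome(seq))
        assert [(l.motif, l.n_units) for l in loci] == [("AT", 10)]

    def test_ira_loci_suppressed(self, rng):
        from .test_structure import toy_plastome

        g = toy_plastome(rng, lsc=1000, ir=300, ssc=200)
        seq = list(g.seq)
        seq[1100:1110] = "A" * 10  # inside IRb
        g2 = genome("".join(seq))
        g2.seq = (
            g2.seq[:1500] + revcomp(g2.seq[1000:1300]) + g2.seq[1800:]
        )  # keep IRa an exact mirror
        st = pm.detect_quadripartite(g2, min_ir_len=100, seed_k=15)
        loci = detect_ssrs(g2, structure=st)
        a_loci = [l for l in loci if l.canonical_class == "A/T"]
        assert any(1000 <= l.span[0] < 1300 for l in a_loci)
        assert not any(st.ira[0] <= l.span[0] for l in a_loci)

    def test_planted_tracts_recovered_exactly(self, default_sim, default_report):
        truth_tracts = default_sim.truth.of_kind("ssr")
        for gid in default_sim.genotypes:
            assert len(default_report.ssr_loci[gid]) == len(truth_tracts) == 30

    def test_revcomp_mining_same_classes(self, default_sim):
        g = default_sim.reference
        fwd = detect_ssrs(g)
        rev = detect_ssrs(genome(revcomp(g.seq), "rc"))
        assert len(fwd) == len(rev)
        assert sorted(l.canonical_class for l in fwd) == sorted(
            l.canonical_class for l in rev
        )

    def test_every_locus_revalidates(self, default_sim):
        for gid, g in default_sim.genotypes.items():
            for loc in detect_ssrs(g):
                assert g.seq[loc.span[0] : loc.span[1]] == loc.expected_sequence()


class TestDeduplicate:
    def test_overlap_keeps_longer_tract(self):
        a = SsrLocus("g", (10, 30), "AT", 2, 10)
        b = SsrLocus("g", (25, 37), "TAG", 3, 4)
        assert deduplicate_ssrs([a, b]) == [a]

    def test_tie_prefers_smaller_unit_then_leftmost(self):
        a = SsrLocus("g", (10, 22), "ATG", 3, 4)
        b = SsrLocus("g", (12, 24), "TA", 2, 6)
        assert deduplicate_ssrs([a, b]) == [b]  # same 12 bp, smaller unit
        c = SsrLocus("g", (10, 22), "AT", 2, 6)
        d = SsrLocus("g", (12, 24), "GC", 2, 6)
        assert deduplicate_ssrs([c, d]) == [c]  # full tie -> leftmost

    def test_disjoint_loci_all_kept(self):
        a = SsrLocus("g", (0, 10), "A", 1, 10)
        b = SsrLocus("g", (50, 60), "T", 1, 10)
        assert deduplicate_ssrs([a, b]) == [a, b]

    def test_random_sets_become_overlap_free(self, rng):
        for _ in range(50):
            loci = []
            for _ in range(int(rng.integers(2, 12))):
                start = int(rng.integers(0, 100))
                k = int(rng.integers(1, 4))
                units = int(rng.integers(3, 12))
                loci.append(SsrLocus("g", (start, start + k * units), "A" * k, k, units))
            kept = deduplicate_ssrs(loci)
            kept.sort(key=lambda l: l.span)
            for x, y in zip(kept, kept[1:]):
                assert x.span[1] <= y.span[0]


class TestFlanks:
    def test_coordinate_arithmetic(self):
        g = genome("ACGT" * 300)
        loc = SsrLocus("t", (1000, 1010), "A", 1, 10)
        left, right = extract_flanks(g, loc, flank_len=50)
        assert left == g.seq[950:1000]
        assert right == g.seq[1010:1060]

    def test_circular_wrap_at_origin(self):
        g = genome("ACGT" * 25)  # 100 bp
        loc = SsrLocus("t", (5, 15), "A", 1, 10)
        left, _ = extract_flanks(g, loc, flank_len=20)
        assert left == (g.seq + g.seq)[85:105]
        assert len(left) == 20

    def test_zero_flank(self):
        g = genome("ACGT" * 10)
        loc = SsrLocus("t", (10, 20), "A", 1, 10)
        assert extract_flanks(g, loc, flank_len=0) == ("", "")


class TestCompare:
    def test_identical_genotypes_nothing_polymorphic(self):
        seq = PAD + "A" * 12 + PAD
        genomes = {g: genome(seq, g) for g in ("g1", "g2", "g3")}
        aln = pm.AlignmentMatrix(list(genomes), [seq] * 3)
        loci = {g: detect_ssrs(genomes[g]) for g in genomes}
        polys = compare_ssrs(loci, aln, genomes)
        assert len(polys) == 1
        assert not polys[0].is_polymorphic

    def test_planted_length_difference_detected(self):
        s1 = PAD + "A" * 10 + PAD
        s2 = PAD + "A" * 12 + PAD
        aln = pm.AlignmentMatrix(
            ["g1", "g2"], [PAD + "A" * 10 + "--" + PAD, s2]
        )
        genomes = {"g1": genome(s1, "g1"), "g2": genome(s2, "g2")}
        loci = {g: detect_ssrs(genomes[g]) for g in genomes}
        (poly,) = compare_ssrs(loci, aln, genomes)
        assert poly.is_polymorphic
        assert poly.per_genotype["g1"] == (10, 10)
        assert poly.per_genotype["g2"] == (12, 12)

    def test_sub_threshold_tract_recorded(self):
        s1 = PAD + "A" * 12 + PAD
        s2 = PAD + "A" * 8 + PAD  # below the mono threshold: no locus mined
        aln = pm.AlignmentMatrix(
            ["g1", "g2"], [s1, PAD + "A" * 8 + "----" + PAD]
        )
        genomes = {"g1": genome(s1, "g1"), "g2": genome(s2, "g2")}
        loci = {g: detect_ssrs(genomes[g]) for g in genomes}
        assert loci["g2"] == []
        (poly,) = compare_ssrs(loci, aln, genomes)
        assert poly.per_genotype["g2"] == (8, 8)
        assert "g2" not in poly.members

    def test_anchor_collision_raises(self):
        seq = "A" * 40
        aln = pm.AlignmentMatrix(["g1", "g2"], [seq, seq])
        genomes = {"g1": genome(seq, "g1"), "g2": genome(seq, "g2")}
        loci = {
            "g1": [
                SsrLocus("g1", (0, 12), "A", 1, 12),
                SsrLocus("g1", (20, 32), "A", 1, 12),
            ],
            "g2": [SsrLocus("g2", (2, 30), "A", 1, 28)],
        }
        with pytest.raises(pm.AnchorCollisionError):
            compare_ssrs(loci, aln, genomes)

    def test_simulated_polymorphism_budget_recovered(
        self, default_sim, default_report
    ):
        polys = default_report.ssr_polymorphisms
        assert sum(p.is_polymorphic for p in polys) == 20
        truth = {
            e.ref_span: e.payload
            for e in default_sim.truth.of_kind("ssr")
            if e.payload["polymorphic"]
        }
        # each polymorphic cluster shows exactly the planted tract lengths
        ref_row = default_sim.alignment.ids.index("g01")
        for p in polys:
            if not p.is_polymorphic:
                continue
            span = next(
                l.span for g, l in p.members.items() if g == "g01"
            )
            payload = truth[span]
            k, u, d = payload["unit_len"], payload["units"], payload["delta"]
            carrier = next(
                e.genotypes[0]
                for e in default_sim.truth.of_kind("ssr")
                if e.ref_span == span
            )
            assert p.per_genotype[carrier] == ((u + d), (u + d) * k)
            assert p.per_genotype["g01"] == (u, u * k)


class TestMotifClass:
    @pytest.mark.parametrize(
        "motif,expected",
        [("A", "A/T"), ("T", "A/T"), ("AT", "AT"), ("AG", "AG/CT"),
         ("ATA", "AAT/ATT"), ("AAG", "AAG/CTT")],
    )
    def test_rotation_and_strand_collapse(self, motif, expected):
        assert canonical_motif_class(motif) == expected
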