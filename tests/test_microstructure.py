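"""Indel extraction/classification and small-inversion detection."""

import pytest

import plastmine as pm
from plastmine.microstructure import (
    Inversion,
    detect_inversions,
    extract_indels,
    filter_ssr_indels,
    hairpin_stats,
    indel_size_spectrum,
)
from plastmine.ssr import detect_ssrs
from plastmine.util import revcomp

PAD = "CTGACGTGATCGAGTCGATC"


def aln_of(rows, ids=None):
    ids = ids or [f"g{i}" for i in range(1, len(rows) + 1)]
    return pm.AlignmentMatrix(ids, rows)


class TestExtractIndels:
    def test_single_deletion_event(self):
        rows = ["ACGTACGTA", "ACG---GTA"] + ["ACGTACGTA"] * 4
        events = extract_indels(aln_of(rows), "g1")
        assert len(events) == 1
        (ev,) = events
        assert ev.aln_span == (3, 6) and ev.size == 3
        assert ev.ref_span == (3, 6)
        assert ev.allele_present == "TAC"
        assert ev.polarity["g2"] == "deletion"
        assert all(ev.polarity[g] == "reference-state" for g in ev.polarity
                   if g != "g2")

    def test_insertion_relative_to_reference(self):
        rows = ["ACG--GTA", "ACGTTGTA", "ACG--GTA"]
        (ev,) = extract_indels(aln_of(rows), "g1")
        assert ev.ref_span == (3, 3)  # zero-length insertion point
        assert ev.allele_present == "TT"
        assert ev.polarity["g2"] == "insertion"
        assert ev.polarity["g3"] == "reference-state"

    def test_shared_gap_is_one_event(self):
        rows = ["ACGTACGTA", "ACG---GTA", "ACG---GTA"]
        events = extract_indels(aln_of(rows), "g1")
        assert len(events) == 1
        assert events[0].pattern["g2"] == events[0].pattern["g3"] == "has_gap"

    def test_all_gap_column_is_malformed(self):
        rows = ["AC-TA", "AC-TA"]
        with pytest.raises(pm.DataError, match="malformed"):
            extract_indels(aln_of(rows), "g1")

    def test_split_at_sequence_disagreement(self):
        # g2/g3 share the gap, but the present genotypes disagree mid-run
        rows = ["ACGTACGTA", "ACG---GTA", "ACGTTCGTA"]
        events = extract_indels(aln_of(rows), "g1")
        spans = sorted(ev.aln_span for ev in events)
        assert spans == [(3, 4), (4, 5), (5, 6)]

    def test_planted_events_recovered(self, default_sim, default_report):
        truth = default_sim.truth
        exp = {(e.ref_span, e.genotypes) for e in truth.of_kind("indel")}
        got = set()
        for ev in default_report.common_indels:
            carriers = tuple(
                sorted(g for g, p in ev.polarity.items() if p != "reference-state")
            )
            got.add((ev.ref_span, carriers))
        assert got == exp
        assert max(e.size for e in default_report.common_indels) <= 28

    def test_reference_swap_keeps_spans_flips_polarity(self, default_sim):
        aln = default_sim.alignment
        ev1 = {e.aln_span: e for e in extract_indels(aln, "g01")}
        ev2 = {e.aln_span: e for e in extract_indels(aln, "g02")}
        assert ev1.keys() == ev2.keys()
        for span, a in ev1.items():
            b = ev2[span]
            assert a.size == b.size and a.pattern == b.pattern
            for gid in a.polarity:
                gap_g = a.pattern[gid] == "has_gap"
                gap_ref2 = a.pattern["g02"] == "has_gap"
                if gap_g == gap_ref2:
                    assert b.polarity[gid] == "reference-state"
                elif gap_g:
                    assert b.polarity[gid] == "deletion"
                else:
                    assert b.polarity[gid] == "insertion"


class TestFilterSsrIndels:
    def _world(self, ref_tract, alt_tract):
        s1 = PAD + ref_tract + PAD + "CCTTGG" + PAD
        s2 = PAD + alt_tract + PAD + "CCGG" + PAD
        pad_gap = "-" * (len(s1) - len(s2) - (len(ref_tract) - len(alt_tract)))
        row2 = (
            PAD + alt_tract + "-" * (len(ref_tract) - len(alt_tract))
            + PAD + "CC" + "--" + "GG" + PAD
        )
        g1 = pm.GenomeRecord(id="g1", seq=s1)
        g2 = pm.GenomeRecord(id="g2", seq=s2)
        aln = pm.AlignmentMatrix(["g1", "g2"], [s1, row2])
        loci = {g.id: detect_ssrs(g) for g in (g1, g2)}
        return aln, loci

    def test_slippage_vs_common_partition(self):
        """A 2 bp 'TA' gap at a (TA)x7 tract is SSR-related; the unrelated
        2 bp 'TT' gap in tract-free sequence stays common."""
        aln, loci = self._world("TA" * 7, "TA" * 6)
        events = extract_indels(aln, "g1")
        common, related = filter_ssr_indels(events, loci, aln)
        assert len(related) == 1 and len(common) == 1
        assert related[0].allele_present == "TA"
        assert common[0].allele_present == "TT"

    def test_partition_is_exact_and_disjoint(self, default_sim, default_report):
        n_poly = sum(
            1 for e in default_sim.truth.of_kind("ssr") if e.payload["polymorphic"]
        )
        assert len(default_report.ssr_indels) == n_poly == 20
        assert len(default_report.common_indels) == 44
        spans = {e.aln_span for e in default_report.common_indels}
        assert spans.isdisjoint(e.aln_span for e in default_report.ssr_indels)


class TestSizeSpectrum:
    def test_empty(self):
        assert indel_size_spectrum([]) == ({}, {})

    def test_binning(self):
        def ev(size, region):
            return pm.IndelEvent(
                aln_span=(0, size), ref_span=(0, size), allele_present="A" * size,
                pattern={}, size=size, polarity={}, region=region,
            )

        sizes, regions = indel_size_spectrum(
            [ev(1, "LSC"), ev(1, "LSC"), ev(2, "SSC"), ev(28, "LSC")]
        )
        assert sizes == {1: 2, 2: 1, 28: 1}
        assert regions == {"LSC": 3, "SSC": 1}

    def test_modal_size_one_bp(self, default_report):
        sizes, _ = indel_size_spectrum(default_report.common_indels)
        modal = max(sizes.items(), key=lambda kv: kv[1])[0]
        assert modal == 1


class TestInversions:
    def test_constructed_stem_loop_case(self):
        # core AAGG -> revcomp CCTT (all four positions mismatch), bracketed
        # by the exact 6 bp inverted pair AAGCTG / CAGCTT
        left, core, right = "AAGCTG", "AAGG", "CAGCTT"
        ref = PAD + "A" + left + core + right + "A" + PAD
        query = PAD + "A" + left + revcomp(core) + right + "A" + PAD
        aln = aln_of([ref, query])
        (inv,) = detect_inversions(aln, "g1")
        assert inv.length == 4 and inv.loop_len == 4
        assert inv.flank_repeat_len == 6
        assert inv.stem_loop_ok
        assert inv.inverted_genotypes == {"g2"}
        assert hairpin_stats(inv) == (6, 4, True)

    def test_short_stem_not_ok(self):
        left, core, right = "AGCTG", "AAGG", "CAGCT"  # only a 5 bp stem
        ref = PAD + "A" + left + core + right + "A" + PAD
        query = PAD + "A" + left + revcomp(core) + right + "A" + PAD
        (inv,) = detect_inversions(aln_of([ref, query]), "g1", min_stem=6)
        assert inv.flank_repeat_len == 5
        assert not inv.stem_loop_ok
        assert hairpin_stats(inv, min_stem=6) == (5, 4, False)

    def test_single_column_mismatch_left_to_snp_caller(self):
        ref = PAD + "A" + PAD
        query = PAD + "T" + PAD
        assert detect_inversions(aln_of([ref, query]), "g1", min_len=2) == []

    def test_non_revcomp_mismatch_run_not_reported(self):
        ref = PAD + "AAGG" + PAD
        query = PAD + "GGTT" + PAD  # not the reverse complement (CCTT)
        assert detect_inversions(aln_of([ref, query]), "g1") == []

    def test_hairpin_paper_scale_row(self):
        inv = Inversion(
            aln_span=(0, 51), ref_span=(0, 51), length=51,
            flank_repeat_len=13, loop_len=51, stem_loop_ok=True,
        )
        assert hairpin_stats(inv) == (13, 51, True)

    def test_planted_inversions_recovered(self, default_sim, default_report):
        exp = {
            (e.ref_span, e.payload["flank"], e.genotypes)
            for e in default_sim.truth.of_kind("inversion")
        }
        got = {
            (i.ref_span, i.flank_repeat_len, tuple(sorted(i.inverted_genotypes)))
            for i in default_report.inversions
        }
        assert got == exp
        assert all(i.stem_loop_ok for i in default_report.inversions)
        assert all(
            2 <= i.length <= 51 and 6 <= i.flank_repeat_len <= 22
            for i in default_report.inversions
        )

    def test_reference_swap_symmetry(self):
        left, core, right = "AAGCTG", "AAGGC", "CAGCTT"
        ref = PAD + "A" + left + core + right + "A" + PAD
        query = PAD + "A" + left + revcomp(core) + right + "A" + PAD
        a = detect_inversions(aln_of([ref, query]), "g1")
        b = detect_inversions(aln_of([ref, query]), "g2")
        assert len(a) == len(b) == 1
        assert a[0].aln_span == b[0].aln_span
        assert a[0].inverted_genotypes == {"g2"}
        assert b[0].inverted_genotypes == {"g1"}
        assert a[0].flank_repeat_len == b[0].flank_repeat_len


class TestSwapInvariance:
    def test_hairpin_stats_reference_invariant(self, default_sim):
        aln = default_sim.alignment
        carrier = next(
            e.genotypes[0] for e in default_sim.truth.of_kind("inversion")
        )
        a = {i.aln_span: i for i in detect_inversions(aln, "g01")}
        b = {i.aln_span: i for i in detect_inversions(aln, carrier)}
        for span in set(a) & set(b):
            assert hairpin_stats(a[span]) == hairpin_stats(b[span])
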