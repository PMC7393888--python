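"""Structural-event extraction, classification, direction and inversions."""

import random

import numpy as np
import pytest

from oracles import brute_force_revcomp_spans, stem_loop_split
from plastmut.genomic_io import (
    EXON, INTRON, SPACER, Gene, Interval, MultipleAlignment,
    build_coordinate_map, project_regions, region_map_from_genes,
)
from plastmut.structural_analysis import (
    DELETION, INDEL, INSERTION, INVERSION, MICROSATELLITE, REPEAT,
    StructuralEvent, _pair_candidate_spans, classify_structural,
    detect_inversions, direction_bias_p, extract_gap_events,
    infer_structural_direction, inversion_table, locate_event, revcomp,
    summarize_structural,
)

TAXA = ["Calycanthus_chinensis", "Calycanthus_floridus",
        "Chimonanthus_nitens", "Chimonanthus_praecox",
        "Idiospermum_australiense",
        "Liriodendron_tulipifera", "Magnolia_kwangsiensis"]


def make_aln(rows, reference=TAXA[0]):
    return MultipleAlignment(list(TAXA), rows, reference_taxon=reference)


BASE = "ATTCGCATGCATCAATGGGCCTTACGATCGCA"  # 32 bp context


class TestGapExtraction:
    def test_single_taxon_gap_run(self, topology):
        rows = [BASE] * 7
        rows[0] = BASE[:10] + "-----" + BASE[15:]
        events = extract_gap_events(make_aln(rows), topology)
        assert len(events) == 1
        ev = events[0]
        assert ev.columns == (10, 15)
        assert ev.carriers == ("Calycanthus_chinensis",)
        assert ev.rank == "species"

    def test_sister_shared_gap_maps_to_stem(self, topology):
        rows = [BASE] * 7
        for i in (0, 1):  # both Calycanthus species
            rows[i] = BASE[:10] + "-----" + BASE[15:]
        events = extract_gap_events(make_aln(rows), topology)
        assert len(events) == 1
        assert events[0].branch == "cherryA_crown"
        assert events[0].rank == "genus"

    def test_nested_patterns_split_at_boundaries(self, topology):
        rows = [BASE] * 7
        rows[0] = BASE[:8] + "-" * 9 + BASE[17:]
        rows[1] = BASE[:11] + "-" * 3 + BASE[14:]
        events = extract_gap_events(make_aln(rows), topology)
        spans = sorted(e.columns for e in events)
        assert spans == [(8, 11), (11, 14), (14, 17)]

    def test_gap_census_completeness(self, sim, sim_analysis):
        """Every gap column of every taxon lies in exactly one event span."""
        aln = sim.alignment
        events = [e for e in sim_analysis["events"] if e.category != INVERSION]
        covered = np.zeros(aln.length, dtype=int)
        for e in events:
            covered[e.columns[0]:e.columns[1]] += 1
        gap_cols = np.zeros(aln.length, dtype=bool)
        for t in aln.taxon_ids:
            gap_cols |= np.frombuffer(aln.row(t).encode(), "S1") == b"-"
        assert (covered[gap_cols] == 1).all()
        assert (covered[~gap_cols] == 0).all()

    def test_category_counts_invariant_under_taxon_reorder(self, topology):
        rows = [BASE] * 7
        rows[2] = BASE[:10] + "-----" + BASE[15:]
        aln = make_aln(rows)
        ev1 = extract_gap_events(aln, topology)
        perm = list(reversed(range(7)))
        aln2 = MultipleAlignment([TAXA[i] for i in perm],
                                 [rows[i] for i in perm])
        ev2 = extract_gap_events(aln2, topology)
        assert [(e.columns, e.carriers) for e in ev1] == \
               [(e.columns, e.carriers) for e in ev2]


class TestClassification:
    def _event(self, rows, span, gapped):
        return StructuralEvent(category=INDEL, columns=span,
                               length=span[1] - span[0],
                               gapped_taxa=tuple(gapped)), make_aln(rows)

    def test_mononucleotide_run_is_microsatellite(self):
        longer = "GCTC" + "AAAAAAAA" + "TCGATCGT"
        shorter = "GCTC" + "AAAAAA--" + "TCGATCGT"
        rows = [longer] * 7
        rows[0] = shorter
        ev, aln = self._event(rows, (10, 12), [TAXA[0]])
        classify_structural(ev, aln)
        assert ev.category == MICROSATELLITE and ev.motif == "A"

    def test_adjacent_duplicate_is_repeat(self):
        longer = "TTGCA" + "ACCTG" + "ACCTG" + "GTACTT"
        shorter = "TTGCA" + "ACCTG" + "-----" + "GTACTT"
        rows = [longer] * 7
        rows[0] = shorter
        ev, aln = self._event(rows, (10, 15), [TAXA[0]])
        classify_structural(ev, aln)
        assert ev.category == REPEAT and ev.length == 5

    def test_plain_segment_is_indel(self):
        longer = "TTGCA" + "GATCGCA" + "GTACTT"
        shorter = "TTGCA" + "-------" + "GTACTT"
        rows = [longer] * 7
        rows[0] = shorter
        ev, aln = self._event(rows, (5, 12), [TAXA[0]])
        classify_structural(ev, aln)
        assert ev.category == INDEL

    def test_unresolvable_segment_flagged_indel(self):
        rows = ["AAAA" + "---" + "TTTT"] * 7
        ev, aln = self._event(rows, (4, 7), list(TAXA))
        classify_structural(ev, aln)
        assert ev.category == INDEL and "unresolvable" in ev.flag

    def test_simulated_category_recovery(self, sim, sim_analysis):
        from plastmut.synthetic_data import score_recovery
        m = score_recovery(sim.truth, sim_analysis["events"])
        for cat in (INDEL, REPEAT, MICROSATELLITE):
            assert m[f"{cat}_recall"] >= 0.9, cat


class TestStructuralDirection:
    def test_outgroups_carry_segment_deletion(self, topology):
        rows = [BASE] * 7
        for i in range(5):  # whole core subfamily gapped, Ia + outgroups intact
            if i < 4:
                rows[i] = BASE[:10] + "-----" + BASE[15:]
        events = extract_gap_events(make_aln(rows), topology)
        ev = infer_structural_direction(events[0], topology, make_aln(rows))
        assert ev.rank == "subfamily" and ev.direction == DELETION

    def test_insertion_when_outgroups_lack_segment(self, topology):
        rows = [BASE[:10] + "-----" + BASE[15:]] * 7
        rows[4] = BASE  # Idiospermum alone carries the segment
        aln = make_aln(rows)
        events = extract_gap_events(aln, topology)
        ev = infer_structural_direction(events[0], topology, aln)
        assert ev.carriers == ("Idiospermum_australiense",)
        assert ev.direction == INSERTION

    def test_outgroup_disagreement_uncertain(self, topology):
        rows = [BASE] * 7
        rows[4] = BASE[:10] + "-----" + BASE[15:]   # event on Ia
        rows[5] = BASE[:10] + "-----" + BASE[15:]   # one outgroup also lacks it
        aln = make_aln(rows)
        events = extract_gap_events(aln, topology)
        for ev in events:
            infer_structural_direction(ev, topology, aln)
            assert ev.direction == "uncertain"

    def test_simulated_direction_accuracy(self, sim, sim_analysis):
        from plastmut.synthetic_data import score_recovery
        m = score_recovery(sim.truth, sim_analysis["events"])
        assert m["direction_n"] > 20
        assert m["direction_accuracy"] >= 0.95


def plant_inversion(seq, pos, stem, loop):
    """Insert stem + loop + revcomp(stem); returns (sequence, flipped copy)."""
    cassette = stem + loop + revcomp(stem)
    flipped = stem + revcomp(loop) + revcomp(stem)
    return (seq[:pos] + cassette + seq[pos + len(cassette):],
            seq[:pos] + flipped + seq[pos + len(cassette):])


class TestInversions:
    STEM = "GATTCCGCA"          # 9 bp
    LOOP = "ATGC"               # 4 bp, ends don't pair

    def test_planted_stem_loop_detected(self, topology):
        rng = random.Random(3)
        seq = "".join(rng.choice("ACGT") for _ in range(400))
        ref, flipped = plant_inversion(seq, 150, self.STEM, self.LOOP)
        rows = [ref] * 7
        rows[0] = flipped
        events = detect_inversions(make_aln(rows), topology)
        assert len(events) == 1
        ev = events[0]
        assert ev.loop_length == 4 and ev.stem_length == 9
        assert ev.carriers == ("Calycanthus_chinensis",)
        assert ev.columns == (150 + 9, 150 + 9 + 4)

    def test_no_reverse_complement_segment_empty(self, topology):
        rng = random.Random(4)
        seq = "".join(rng.choice("ACGT") for _ in range(300))
        events = detect_inversions(make_aln([seq] * 7), topology)
        assert events == []

    def test_convergent_inversion_reported_per_branch(self, topology):
        rng = random.Random(5)
        seq = "".join(rng.choice("ACGT") for _ in range(400))
        ref, flipped = plant_inversion(seq, 100, self.STEM, "ATTGC")
        rows = [ref] * 7
        rows[0] = flipped   # C. chinensis
        rows[2] = flipped   # Ch. nitens: non-sister -> two events
        events = detect_inversions(make_aln(rows), topology)
        assert len(events) == 2
        assert {e.branch for e in events} == {
            "Calycanthus_chinensis", "Chimonanthus_nitens"}
        assert all(e.parallel for e in events)

    def test_pair_scan_matches_brute_force(self, topology):
        rng = random.Random(9)
        n = 2000
        seq = "".join(rng.choice("ACGT") for _ in range(n))
        cassettes = ((300, "GATTCCGCA", "ATGCAGT"),
                     (1200, "CCATTAGGCAT", "ATGGACCTGATC"))
        a = seq
        for pos, stem, loop in cassettes:
            cas = stem + loop + revcomp(stem)
            a = a[:pos] + cas + a[pos + len(cas):]
        b = a
        for pos, stem, loop in cassettes:
            flip = stem + revcomp(loop) + revcomp(stem)
            b = b[:pos] + flip + b[pos + len(flip):]
        # sprinkle substitutions away from the cassettes
        b = list(b)
        for _ in range(40):
            i = rng.randrange(n)
            if any(p - 40 <= i < p + 45 for p, _, _ in cassettes):
                continue
            b[i] = rng.choice([x for x in "ACGT" if x != b[i]])
        b = "".join(b)
        min_total, max_total = 2 + 2 * 7, 100 + 2 * 60
        got = _pair_candidate_spans(a, b, min_total, max_total)
        expected = brute_force_revcomp_spans(a, b, min_total, max_total)
        assert got == expected
        assert len(got) >= 2  # both planted cassettes recovered
        for s, e in got:
            st, loop = stem_loop_split(a[s:e], b[s:e])
            assert st >= 7 and loop >= 2


class TestLocateAndSummarize:
    def _regions(self):
        g1 = Gene("ndhA", "+", True,
                  [Interval(10, 40, EXON, "ndhA"), Interval(70, 100, EXON, "ndhA")])
        g2 = Gene("psbK", "+", True, [Interval(120, 180, EXON, "psbK")])
        return region_map_from_genes([g1, g2], 220)

    def _labels(self, rm):
        row = "A" * 220
        aln = MultipleAlignment(list(TAXA), [row] * 7, reference_taxon=TAXA[0])
        cmap = build_coordinate_map(aln, TAXA[0])
        return project_regions(rm, cmap, 220)

    def test_intron_event(self):
        rm = self._regions()
        ev = StructuralEvent(INDEL, (45, 50), 5)
        locate_event(ev, rm, self._labels(rm))
        assert ev.location == INTRON and ev.locus == "ndhA"

    def test_spacer_named_by_flanking_genes(self):
        rm = self._regions()
        ev = StructuralEvent(INDEL, (105, 110), 5)
        locate_event(ev, rm, self._labels(rm))
        assert ev.location == SPACER and ev.locus == "ndhA-psbK"

    def test_boundary_spanning_uses_5prime_and_flags(self):
        rm = self._regions()
        ev = StructuralEvent(INDEL, (35, 45), 10)
        locate_event(ev, rm, self._labels(rm))
        assert ev.location == EXON and ev.span_boundary

    def test_direction_bias_ratio_and_fisher(self):
        assert round(145 / 17, 1) == 8.5
        assert direction_bias_p(145, 17) < 0.001

    def test_empty_event_list_all_zero(self, topology):
        df = summarize_structural([], topology)
        assert (df["total"] == 0).all()

    def test_summary_marginals_match_events(self, sim, sim_analysis, topology):
        events = sim_analysis["events"]
        df = summarize_structural(events, topology)
        for cat in (INDEL, REPEAT, MICROSATELLITE, INVERSION):
            assert df.loc[cat, "total"] == sum(
                1 for e in events if e.category == cat)
        ind = df.loc[INDEL]
        size_total = sum(ind[f"size_{n}"] for n in
                         ("1-10", "11-50", "51-100", ">100"))
        assert size_total == ind["total"]

    def test_inversion_table_shape(self, sim, sim_analysis):
        df = inversion_table(sim_analysis["events"])
        assert set(["loop", "stem", "rank", "carriers"]) <= set(df.columns)
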