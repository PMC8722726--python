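import random

import pytest

from stemfuse.errors import FusionError
from stemfuse.fusion_model import (
    FusionEvent,
    canonicalize_event,
    event_report,
    events_from_json,
    events_to_bedpe,
    events_to_json,
    infer_breakpoint,
    make_fusion_allele,
    microhomology_at,
    splice_fusion_transcript,
)
from stemfuse.synthetic_data import EventPlan, SyntheticSpec, generate_genome

from conftest import random_dna
from oracles import ambiguity_span, brute_force_split


def _event(bp_a, bp_b, insertion="", mh=0, eid="e"):
    return FusionEvent(eid, "geneA", "geneB", bp_a, bp_b, insertion, mh)


class TestMakeFusionAllele:
    def test_allele_length_arithmetic(self, synth, sense_pair):
        sa, sb = sense_pair
        ev = synth.events[0]
        allele = make_fusion_allele(synth.genome, synth.gene_a, synth.gene_b, ev)
        assert len(allele.sequence) == (ev.breakpoint_a + 1) + (
            len(sb) - ev.breakpoint_b
        ) + len(ev.insertion)

    def test_preset_retains_3_plus_15_exons(self, synth):
        # breakpoints in intron 3 of the 5-exon gene and intron 1 of the
        # 16-exon gene retain exons 1-3 and 2-16
        allele = make_fusion_allele(
            synth.genome, synth.gene_a, synth.gene_b, synth.events[0]
        )
        assert [n for n, _, _ in allele.retained_exons_a] == [1, 2, 3]
        assert [n for n, _, _ in allele.retained_exons_b] == list(range(2, 17))

    def test_exonic_breakpoint_rejected(self, synth):
        with pytest.raises(FusionError, match="not intronic"):
            make_fusion_allele(
                synth.genome, synth.gene_a, synth.gene_b, _event(10, 500)
            )

    def test_insertion_alphabet_checked(self, synth):
        ev = synth.events[0]
        bad = _event(ev.breakpoint_a, ev.breakpoint_b, insertion="AXA")
        with pytest.raises(FusionError):
            make_fusion_allele(synth.genome, synth.gene_a, synth.gene_b, bad)

    def test_new_intron_between_retained_exons(self, synth):
        allele = make_fusion_allele(
            synth.genome, synth.gene_a, synth.gene_b, synth.events[0]
        )
        assert allele.new_intron[0] == allele.retained_exons_a[-1][2]
        assert allele.new_intron[1] == allele.retained_exons_b[0][1]

    def test_insertion_present_in_sequence(self, synth):
        ev = synth.events[1]  # the "AA"-insertion event
        allele = make_fusion_allele(synth.genome, synth.gene_a, synth.gene_b, ev)
        j = ev.breakpoint_a + 1
        assert allele.sequence[j : j + 2] == "AA"


class TestSpliceFusionTranscript:
    def test_preset_junction_exon3_to_exon2(self, synth):
        allele = make_fusion_allele(
            synth.genome, synth.gene_a, synth.gene_b, synth.events[0]
        )
        tx = splice_fusion_transcript(allele)
        assert tx.junction == (3, 2)
        assert len([e for e in tx.exon_list if e[0] == "geneA"]) == 3
        assert len([e for e in tx.exon_list if e[0] == "geneB"]) == 15

    def test_first_intron_breakpoints_junction_1_2(self, synth):
        spec = synth.spec
        bp_a = synth.gene_a.intron_local_intervals()[0][0] + 50
        bp_b = synth.gene_b.intron_local_intervals()[0][0] + 50
        allele = make_fusion_allele(
            synth.genome, synth.gene_a, synth.gene_b, _event(bp_a, bp_b)
        )
        assert splice_fusion_transcript(allele).junction == (1, 2)

    def test_mature_length_is_sum_of_retained_exons(self, synth):
        allele = make_fusion_allele(
            synth.genome, synth.gene_a, synth.gene_b, synth.events[0]
        )
        tx = splice_fusion_transcript(allele)
        expected = sum(e - s for _, s, e in allele.retained_exons_a) + sum(
            e - s for _, s, e in allele.retained_exons_b
        )
        assert len(tx.mature_sequence) == expected

    def test_junction_on_annotated_exon_boundaries(self, synth):
        # the junction must coincide with annotated exon ends, never mid-exon
        allele = make_fusion_allele(
            synth.genome, synth.gene_a, synth.gene_b, synth.events[0]
        )
        tx = splice_fusion_transcript(allele)
        last_a = allele.retained_exons_a[-1]
        exon_ends_a = {e for _, e in synth.gene_a.exon_local_intervals()}
        assert last_a[2] in exon_ends_a
        first_b_local = synth.gene_b.exon_local_intervals()[tx.junction[1] - 1]
        # the B exon retained first is a full annotated exon
        assert (first_b_local[1] - first_b_local[0]) == (
            allele.retained_exons_b[0][2] - allele.retained_exons_b[0][1]
        )


class TestInferBreakpoint:
    def test_clean_junction(self, sense_pair):
        sa, sb = sense_pair
        read = sa[1700:1826] + sb[132:260]
        call = infer_breakpoint(read, sa, sb)
        assert call.mappable
        assert call.event.insertion == ""
        assert call.event.microhomology_length == 0

    def test_two_nt_insertion_recovered(self, synth, sense_pair):
        sa, sb = sense_pair
        ev = synth.events[1]
        read = sa[ev.breakpoint_a - 150 : ev.breakpoint_a + 1] + "AA" + sb[
            ev.breakpoint_b : ev.breakpoint_b + 150
        ]
        call = infer_breakpoint(read, sa, sb)
        assert call.event.insertion == "AA"
        assert len(call.event.insertion) == 2
        assert call.event.breakpoint_a == ev.breakpoint_a
        assert call.event.breakpoint_b == ev.breakpoint_b

    def test_unmappable_junction_is_result_not_exception(self, sense_pair):
        sa, sb = sense_pair
        rng = random.Random(23)
        call = infer_breakpoint(random_dna(rng, 200), sa, sb)
        assert not call.mappable
        assert call.event is None

    def test_short_read_unmappable(self, sense_pair):
        sa, sb = sense_pair
        assert not infer_breakpoint(sa[:30], sa, sb).mappable

    @pytest.mark.parametrize("seed", range(10))
    def test_brute_force_split_oracle(self, sense_pair, seed):
        # reads <= 300 nt: production call matches exhaustive enumeration
        sa, sb = sense_pair
        rng = random.Random(seed)
        bp_a = rng.randint(900, 2600)
        bp_b = rng.randint(120, 2000)
        ins = random_dna(rng, rng.randint(0, 8)) if rng.random() < 0.5 else ""
        left = rng.randint(60, 140)
        right = rng.randint(60, 140)
        read = sa[bp_a + 1 - left : bp_a + 1] + ins + sb[bp_b : bp_b + right]
        assert len(read) <= 300
        oracle = brute_force_split(read, sa, sb, k=20)
        call = infer_breakpoint(read, sa, sb, mismatch_rate=0.0)
        if oracle is None:
            assert not call.mappable
        else:
            o_bp_a, o_bp_b, o_ins = oracle
            assert call.mappable
            assert (
                call.event.breakpoint_a,
                call.event.breakpoint_b,
                call.event.insertion,
            ) == (o_bp_a, o_bp_b, o_ins)

    def test_pipeline_inversion_50_random_events(self, synth, sense_pair):
        # canonical events with insertion <= 10 are recovered exactly from a
        # read drawn from the rebuilt allele
        sa, sb = sense_pair
        rng = random.Random(99)
        intr_a = synth.gene_a.intron_local_intervals()
        intr_b = synth.gene_b.intron_local_intervals()
        n_ok = 0
        for _ in range(50):
            ia = rng.choice(intr_a)
            ib = rng.choice(intr_b)
            bp_a = rng.randint(ia[0] + 30, ia[1] - 30)
            bp_b = rng.randint(ib[0] + 30, ib[1] - 30)
            ins = random_dna(rng, rng.randint(0, 10)) if rng.random() < 0.6 else ""
            truth = canonicalize_event(_event(bp_a, bp_b, ins), sa, sb)
            allele = make_fusion_allele(
                synth.genome, synth.gene_a, synth.gene_b, truth
            )
            j = truth.breakpoint_a + 1
            read = allele.sequence[max(0, j - 200) : j + len(truth.insertion) + 200]
            call = infer_breakpoint(read, sa, sb)
            assert call.mappable
            assert call.event.breakpoint_a == truth.breakpoint_a
            assert call.event.breakpoint_b == truth.breakpoint_b
            assert call.event.insertion == truth.insertion
            assert call.event.microhomology_length == truth.microhomology_length
            n_ok += 1
        assert n_ok == 50

    def test_planted_microhomology_recovered(self):
        # generator-planted microhomology up to 6 nt round-trips exactly
        spec = SyntheticSpec(
            seed=31,
            gene_a_exons=(80, 80, 80),
            gene_a_introns=(700, 700),
            gene_b_exons=(80, 80, 80),
            gene_b_introns=(700, 700),
            planted_events=(
                EventPlan("m2", 1, 150, 1, 200, microhomology=2),
                EventPlan("m4", 2, 300, 2, 350, microhomology=4),
                EventPlan("m6", 1, 500, 2, 120, microhomology=6),
            ),
            read_length=240,
        )
        synth = generate_genome(spec)
        sa = synth.gene_a.sense_sequence(synth.genome["chrA"])
        sb = synth.gene_b.sense_sequence(synth.genome["chrB"])
        for ev in synth.events:
            allele = make_fusion_allele(synth.genome, synth.gene_a, synth.gene_b, ev)
            j = ev.breakpoint_a + 1
            read = allele.sequence[j - 120 : j + 120]
            call = infer_breakpoint(read, sa, sb)
            assert call.event.breakpoint_a == ev.breakpoint_a
            assert call.event.breakpoint_b == ev.breakpoint_b
            assert call.event.microhomology_length == ev.microhomology_length

    def test_tolerates_internal_sequencing_errors(self, sense_pair):
        sa, sb = sense_pair
        read = sa[1526:1826] + sb[132:432]
        # two substitutions well inside the anchors (1 per 300 bases < 1%+tip rule)
        corrupted = list(read)
        corrupted[100] = {"A": "C", "C": "A", "G": "T", "T": "G"}[corrupted[100]]
        corrupted[450] = {"A": "C", "C": "A", "G": "T", "T": "G"}[corrupted[450]]
        call = infer_breakpoint("".join(corrupted), sa, sb)
        assert call.mappable
        assert call.event.breakpoint_a == 1825
        assert call.event.breakpoint_b == 132


class TestMicrohomology:
    def test_planted_4nt_shared_motif(self):
        rng = random.Random(5)
        a = random_dna(rng, 200)
        motif = "GATC"
        bp_a, bp_b = 99, 80
        # B carries the same 4 bases immediately before its breakpoint
        b = random_dna(rng, 200)
        b = b[: bp_b - 4] + motif + b[bp_b:]
        a = a[: bp_a - 3] + motif + a[bp_a + 1 :]
        # cap the run on both sides
        ev = _event(bp_a, bp_b)
        got = microhomology_at(ev, a, b)
        assert got >= 4  # at least the planted motif is ambiguous

    def test_no_shared_flank_gives_zero(self, synth, sense_pair):
        sa, sb = sense_pair
        ev = synth.events[0]  # generator caps both flanks
        assert microhomology_at(ev, sa, sb) == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_exhaustive_shift_oracle(self, seed):
        rng = random.Random(seed)
        a = random_dna(rng, 300)
        b = random_dna(rng, 300)
        bp_a = rng.randint(60, 240)
        bp_b = rng.randint(60, 240)
        ev = _event(bp_a, bp_b)
        assert microhomology_at(ev, a, b) == ambiguity_span(a, b, bp_a, bp_b)

    def test_insertion_event_zero(self, sense_pair):
        sa, sb = sense_pair
        assert microhomology_at(_event(1825, 132, insertion="GG"), sa, sb) == 0


class TestSerialization:
    def test_event_json_roundtrip(self, synth):
        text = events_to_json(synth.events)
        assert events_from_json(text) == synth.events

    def test_event_report_1based_coordinates(self, synth):
        ev = synth.events[0]
        rep = event_report(ev, synth.gene_a, synth.gene_b)
        contig, pos = rep["breakpoint_a"].split(":")
        assert contig == "chrA"
        assert int(pos) == synth.gene_a.local_to_genomic_pos(ev.breakpoint_a) + 1

    def test_bedpe_rows(self, synth):
        bedpe = events_to_bedpe(synth.events, synth.gene_a, synth.gene_b)
        lines = bedpe.strip().splitlines()
        assert len(lines) == 2
        assert lines[1].split("\t")[10] == "AA"  # insertion column of event y

    def test_mutually_exclusive_features(self):
        with pytest.raises(FusionError):
            _event(10, 10, insertion="A", mh=2)
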