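"""Reference alignment, indel calling and outcome classification."""

from collections import Counter

import numpy as np
import pytest

from conftest import random_dna
from oracles import canonical_deletion, canonical_insertion
from kiquant import indel_classifier as ic
from kiquant.align import GapEvent, RefAlignment
from kiquant.indel_classifier import (IndelEvent, align_to_reference,
                                      apply_control_filter, call_indels,
                                      classify_no_tag_read, classify_read,
                                      classify_single_tag_read,
                                      filter_natural_indels, parse_snp)
from kiquant.preprocess import ProcessedRead
from kiquant.read_simulator import (ErrorModel, JackpotModel, OutcomeMixture,
                                    make_amplicon, simulate_run)
from kiquant.target_model import build_references


def _read(seq, rid="r1"):
    return ProcessedRead(rid, "s", "A" * 8, seq, False)


class TestAlignToReference:
    def test_identical_read_gives_all_match(self, refs):
        aln = align_to_reference(refs.unmodified_ref, refs.unmodified_ref)
        assert aln.events == []
        assert aln.mismatches == 0
        assert aln.identity() == 1.0

    def test_constructed_deletion_recovered(self, refs):
        ref = refs.unmodified_ref
        p = 700
        read = ref[:p] + ref[p + 5:]
        aln = align_to_reference(read, ref)
        events = call_indels(aln, ref)
        assert len(events) == 1
        e = events[0]
        assert e.kind == "deletion" and e.size == 5
        assert e.ref_pos == canonical_deletion(ref, read, 5)

    @pytest.mark.parametrize("kind", ["deletion", "insertion"])
    def test_perturbation_oracle_200_trials(self, refs, kind):
        """Random single indels on the 2 kb reference are recovered at
        the left-shift-canonical position and exact size (oracle: leftmost
        position whose splice reproduces the read, by exhaustive scan)."""
        rng = np.random.default_rng(55)
        ref = refs.unmodified_ref
        for _ in range(100):
            size = int(rng.integers(1, 21))
            p = int(rng.integers(50, len(ref) - 50 - size))
            if kind == "deletion":
                read = ref[:p] + ref[p + size:]
                want = canonical_deletion(ref, read, size)
            else:
                ins = random_dna(rng, size)
                read = ref[:p] + ins + ref[p:]
                want = canonical_insertion(ref, read, size)
            events = call_indels(align_to_reference(read, ref), ref)
            assert len(events) == 1
            e = events[0]
            assert (e.kind, e.size, e.ref_pos) == (kind, size, want)

    def test_left_shift_in_repeat_context(self):
        """Deleting any one unit of a homopolymer run yields the same
        canonical event regardless of which copy was removed."""
        ref = random_dna(np.random.default_rng(1), 600) + "TTTTTTTT" \
            + random_dna(np.random.default_rng(2), 600)
        run_start = 600
        got = set()
        for offset in range(8):
            read = ref[: run_start + offset] + ref[run_start + offset + 1:]
            events = call_indels(align_to_reference(read, ref), ref)
            assert len(events) == 1
            got.add((events[0].kind, events[0].ref_pos, events[0].size))
        assert got == {("deletion", run_start, 1)}


class TestCallIndels:
    def test_all_match_gives_no_events(self, refs):
        aln = align_to_reference(refs.unmodified_ref, refs.unmodified_ref)
        assert call_indels(aln, refs.unmodified_ref) == []

    def test_window_semantics(self):
        ref = "ACGT" * 300
        aln = RefAlignment(len(ref), len(ref), [(0, len(ref), 0, len(ref))],
                           [GapEvent(100, 2, "insertion", "TT"),
                            GapEvent(600, 1, "deletion")], 1200, 0)
        events = call_indels(aln, ref, window=(50, 200))
        assert len(events) == 1 and events[0].kind == "insertion"

    def test_deletion_overlap_with_window_suffices(self):
        ref = random_dna(np.random.default_rng(3), 1200)
        aln = RefAlignment(len(ref), 400, [(0, 100, 0, 100),
                                           (900, 1200, 100, 400)],
                           [GapEvent(100, 800, "deletion")], 400, 0)
        events = call_indels(aln, ref, window=(540, 660))
        assert len(events) == 1 and events[0].size == 800

    def test_simulated_indel_reads_match_truth_details(self, spec):
        """Events called on simulated indel molecules equal the
        simulator's planted indels after canonicalization by the
        exhaustive-splice oracle."""
        rng = np.random.default_rng(66)
        refs = build_references(spec)
        ref = refs.unmodified_ref
        for _ in range(100):
            seq, details = make_amplicon(spec, "indel_no_tag", rng)
            (pos, size, kind), = details
            want = (canonical_deletion(ref, seq, size) if kind == "deletion"
                    else canonical_insertion(ref, seq, size))
            events = call_indels(align_to_reference(seq, ref), ref)
            assert len(events) == 1
            assert (events[0].kind, events[0].size, events[0].ref_pos) \
                == (kind, size, want)


class TestClassifySingleTag:
    def test_error_free_precise_read_is_precise(self, spec, refs):
        rc = classify_single_tag_read(_read(refs.precise_ref), refs, spec)
        assert rc.label == ic.PRECISE_TAG and rc.events == []

    def test_deletion_near_5p_junction(self, spec, refs):
        p = refs.junction_5p - 4 - 3  # 3 bp deletion ending 4 bp left
        read = refs.precise_ref[:p] + refs.precise_ref[p + 3:]
        rc = classify_single_tag_read(_read(read), refs, spec)
        assert rc.label == ic.TAG_5P_INDEL
        assert rc.events[0].kind == "deletion" and rc.events[0].size == 3

    def test_insertion_near_3p_junction(self, spec, refs):
        p = refs.junction_3p + 5
        read = refs.precise_ref[:p] + "TTAA" + refs.precise_ref[p:]
        rc = classify_single_tag_read(_read(read), refs, spec)
        assert rc.label == ic.TAG_3P_INDEL

    def test_indels_on_both_sides(self, spec, refs):
        p5 = refs.junction_5p - 8
        p3 = refs.junction_3p + 8
        read = refs.precise_ref[:p5] + refs.precise_ref[p5 + 2:p3] \
            + "GGCC" + refs.precise_ref[p3:]
        rc = classify_single_tag_read(_read(read), refs, spec)
        assert rc.label == ic.TAG_BOTH_INDEL

    def test_substitutions_do_not_break_precise(self, spec, refs):
        ref = refs.precise_ref
        j5 = refs.junction_5p
        read = ref[: j5 - 20] + {"A": "C", "C": "G", "G": "T",
                                 "T": "A"}[ref[j5 - 20]] + ref[j5 - 19:]
        rc = classify_single_tag_read(_read(read), refs, spec)
        assert rc.label == ic.PRECISE_TAG

    def test_indel_outside_arms_does_not_affect_label(self, spec, refs):
        p = 200  # far upstream of the 5' homology arm
        read = refs.precise_ref[:p] + refs.precise_ref[p + 4:]
        rc = classify_single_tag_read(_read(read), refs, spec)
        assert rc.label == ic.PRECISE_TAG

    def test_require_template_snp_gates_precise(self, spec, refs):
        # precise product still carrying the unedited (ref) allele
        rc = classify_single_tag_read(_read(refs.precise_ref), refs, spec,
                                      require_template_snp=True)
        assert rc.label == ic.TAG_5P_INDEL  # snp site is in the left arm
        seq, _ = make_amplicon(spec, "precise_tag",
                               np.random.default_rng(0))
        rc = classify_single_tag_read(_read(seq), refs, spec,
                                      require_template_snp=True)
        assert rc.label == ic.PRECISE_TAG


class TestClassifyNoTag:
    def test_error_free_unmodified_read(self, spec, refs):
        rc = classify_no_tag_read(_read(refs.unmodified_ref), refs, spec)
        assert rc.label == ic.UNMODIFIED and rc.events == []

    def test_800bp_deletion_spanning_cut_site(self, spec, refs):
        ip = spec.insertion_point
        start = ip - 400
        read = refs.unmodified_ref[:start] + refs.unmodified_ref[start + 800:]
        rc = classify_no_tag_read(_read(read), refs, spec)
        assert rc.label == ic.INDEL_NO_TAG
        assert rc.events == [IndelEvent(
            canonical_deletion(refs.unmodified_ref, read, 800), 800,
            "deletion")]

    def test_distant_indel_is_not_a_target_site_edit(self, spec, refs):
        read = refs.unmodified_ref[:100] + refs.unmodified_ref[104:]
        rc = classify_no_tag_read(_read(read), refs, spec)
        assert rc.label == ic.UNMODIFIED


class TestParseSnp:
    def test_alleles_on_constructed_reads(self, spec, refs):
        snp = spec.snp_site
        aln = align_to_reference(refs.unmodified_ref, refs.unmodified_ref)
        assert parse_snp(aln, refs.unmodified_ref, snp.position, snp) == "ref"
        template_read = refs.unmodified_ref[: snp.position] \
            + snp.template_base + refs.unmodified_ref[snp.position + 1:]
        aln = align_to_reference(template_read, refs.unmodified_ref)
        assert parse_snp(aln, template_read, snp.position, snp) == "template"

    def test_deletion_over_site_is_uncovered(self, spec, refs):
        snp = spec.snp_site
        read = refs.unmodified_ref[: snp.position - 2] \
            + refs.unmodified_ref[snp.position + 3:]
        aln = align_to_reference(read, refs.unmodified_ref)
        assert parse_snp(aln, read, snp.position, snp) == "uncovered"

    def test_mixed_alleles_tally_close_to_half(self, spec, tmp_path):
        """50/50 unmodified (ref allele) vs precise (template allele)
        molecules: per-allele tallies within 3 binomial SE of 50%."""
        refs = build_references(spec)
        mix = OutcomeMixture({"unmodified": 0.5, "precise_tag": 0.5})
        run = simulate_run(spec, mix, 300, str(tmp_path), seed=88,
                           error_model=ErrorModel.perfect(),
                           jackpot=JackpotModel(mean=1.0))
        calls = Counter()
        for t in run.truths:
            seq, _ = make_amplicon(spec, t.true_label,
                                   np.random.default_rng(0))
            rc = classify_read(_read(seq, t.molecule_id), refs, spec)
            calls[rc.snp_allele] += 1
        frac = calls["template"] / (calls["template"] + calls["ref"])
        se = (0.25 / 300) ** 0.5
        assert abs(frac - 0.5) <= 3 * se


class TestNaturalIndelFilter:
    def test_empty_control_is_noop(self):
        events = {"r1": [IndelEvent(10, 2, "deletion")]}
        assert filter_natural_indels(events, []) == events

    def test_exact_control_match_removed(self):
        e = IndelEvent(10, 2, "deletion")
        assert filter_natural_indels({"r1": [e]}, [e]) == {"r1": []}

    def test_tolerance_windows(self):
        e = IndelEvent(100, 5, "deletion")
        near = IndelEvent(108, 6, "deletion")
        far = IndelEvent(115, 5, "deletion")
        wrong_kind = IndelEvent(100, 5, "insertion")
        assert filter_natural_indels({"r": [e]}, [near]) == {"r": []}
        assert filter_natural_indels({"r": [e]}, [far]) == {"r": [e]}
        assert filter_natural_indels({"r": [e]}, [wrong_kind]) == {"r": [e]}

    def test_planted_germline_indel_filtered_from_sample(self, rng, spec,
                                                         refs):
        """A 2 bp deletion present in all control and sample molecules is
        removed from sample multi-tag reads; the knock-in-specific event
        is retained."""
        germline_pos = spec.insertion_point - 40
        ref = refs.precise_ref

        def with_germline(seq):
            return seq[:germline_pos] + seq[germline_pos + 2:]

        control = [ic.ReadClass("c1", "U", ic.INDEL_NO_TAG,
                                [IndelEvent(germline_pos, 2, "deletion")])]
        extra = IndelEvent(refs.junction_3p, 90, "insertion")
        sample = [ic.ReadClass("s1", "U", ic.MULTIPLE_TAGS,
                               [IndelEvent(germline_pos, 2, "deletion"),
                                extra])]
        out = apply_control_filter(sample, control)
        assert out[0].events == [extra]


class TestExhaustiveness:
    def test_every_read_gets_exactly_one_label(self, spec, tmp_path):
        from kiquant.preprocess import preprocess_run

        refs = build_references(spec)
        mix = OutcomeMixture({"unmodified": 0.3, "indel_no_tag": 0.3,
                              "precise_tag": 0.2, "multiple_tags": 0.1,
                              "large_deletion": 0.1})
        run = simulate_run(spec, mix, 120, str(tmp_path), seed=99)
        pre = preprocess_run(run.fastq_path, spec)
        reps = [r for s in pre.groups_by_sample for r in pre.representatives(s)]
        classes = [classify_read(r, refs, spec) for r in reps]
        assert all(rc.label in ic.CLASS_LABELS for rc in classes)
        assert sum(Counter(rc.label for rc in classes).values()) == len(reps)

    def test_precise_read_excision_consistency(self, spec, refs):
        """Excising the detected tag interval from a precise read leaves
        a sequence that aligns to the unmodified reference with no indels
        at the target site."""
        from kiquant.tag_classifier import classify_by_tag

        read = _read(refs.precise_ref)
        tag = classify_by_tag(read, spec)
        (hit,) = tag.hits
        excised = read.seq[: hit.read_start] + read.seq[hit.read_end:]
        rc = classify_no_tag_read(_read(excised), refs, spec)
        assert rc.label == ic.UNMODIFIED
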