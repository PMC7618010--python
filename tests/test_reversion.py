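"""Unit and property tests for reversion detection primitives."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from revtrace.reversion import (
    LocusReference,
    PathogenicVariant,
    RealignConfig,
    Read,
    SecondaryEvent,
    apply_events,
    assign_reads,
    call_reversions,
    classify_stopgain,
    detect_reversions,
    enumerate_candidate_haplotypes,
    events_overlap,
    left_align,
    microhomology,
    net_frame_change,
    spans_pathogenic,
)
from revtrace.synthcohort import gen_locus, sim_reads

DNA = st.text(alphabet="ACGT", min_size=1)


# ---------------------------------------------------------------------------
# left_align
# ---------------------------------------------------------------------------

class TestLeftAlign:
    def test_homopolymer_deletion_moves_to_run_start(self):
        ref = LocusReference("r", "CCAAAACC")
        # deleting any single A of the run is the same haplotype; the leftmost
        # representation deletes the first A (position 3, anchored at 2)
        for anchor in (3, 4, 5):
            ev = SecondaryEvent(anchor, ref.slice(anchor, anchor + 1), ref.base(anchor))
            la = left_align(ev, ref)
            assert la.pos == 2 and (la.ref, la.alt) == ("CA", "C")
            assert la.deleted_span == (3, 3)

    def test_idempotent(self):
        ref = LocusReference("r", "CCAAAACC")
        ev = left_align(SecondaryEvent(4, "AA", "A"), ref)
        assert left_align(ev, ref) == ev

    def test_substitution_unchanged(self):
        ref = LocusReference("r", "ACGTACGT")
        ev = SecondaryEvent(3, "G", "C")
        assert left_align(ev, ref) == ev

    def test_ref_mismatch_raises(self):
        ref = LocusReference("r", "ACGTACGT")
        with pytest.raises(ValueError):
            left_align(SecondaryEvent(2, "GG", "G"), ref)

    @given(st.data())
    def test_haplotype_preserved_and_idempotent(self, data):
        """Left-alignment never changes the haplotype the event produces."""
        seq = data.draw(st.text(alphabet="ACGT", min_size=20, max_size=60))
        pos = data.draw(st.integers(2, len(seq) - 8))
        dlen = data.draw(st.integers(1, 5))
        ref = LocusReference("r", seq)
        ev = SecondaryEvent(pos, ref.slice(pos, pos + dlen), ref.base(pos))
        la = left_align(ev, ref)
        assert apply_events(ref, [ev]) == apply_events(ref, [la])
        assert left_align(la, ref) == la
        assert la.pos <= ev.pos


# ---------------------------------------------------------------------------
# frame arithmetic
# ---------------------------------------------------------------------------

def _frame_oracle(
    locus: LocusReference, pathogenic: PathogenicVariant, events
) -> int:
    """Brute force: build the haplotype string and compare its length mod 3."""
    if any(spans_pathogenic(e, pathogenic) for e in events):
        applied = list(events)
    else:
        applied = [*events, pathogenic.as_event()]
    hap = apply_events(locus, sorted(applied, key=lambda e: e.pos))
    return (len(hap) - len(locus.sequence)) % 3


class TestNetFrameChange:
    @pytest.mark.parametrize(
        "path_net,event_net,expected",
        [(-1, -2, 0), (-1, 1, 0), (-1, -3, 2)],
    )
    def test_arithmetic(self, locus, path_net, event_net, expected):
        from revtrace.synthcohort import gen_pathogenic

        path = gen_pathogenic(locus, "frameshift", seed=1, net_len=path_net)
        pos = path.pos + 30
        if event_net < 0:
            ev = SecondaryEvent(pos, locus.slice(pos, pos - event_net), locus.base(pos))
        else:
            ev = SecondaryEvent(pos, locus.base(pos), locus.base(pos) + "A" * event_net)
        assert net_frame_change(path, [ev]) == expected

    def test_spanning_deletion_drops_pathogenic_contribution(self, locus, frameshift):
        lo = frameshift.pos - 2
        ev = SecondaryEvent(lo, locus.slice(lo, lo + 6), locus.base(lo))  # deletes 6
        assert spans_pathogenic(ev, frameshift)
        assert net_frame_change(frameshift, [ev]) == (-6) % 3 == 0

    def test_overlapping_events_raise(self, locus, frameshift):
        a = SecondaryEvent(100, locus.slice(100, 103), locus.base(100))
        b = SecondaryEvent(102, locus.slice(102, 104), locus.base(102))
        with pytest.raises(ValueError):
            net_frame_change(frameshift, [a, b])

    def test_agrees_with_haplotype_length_oracle(self, locus, frameshift, rng):
        """Frame arithmetic equals brute-force haplotype construction."""
        for _ in range(300):
            events = []
            cursor = frameshift.pos + 5
            for _k in range(int(rng.integers(1, 3))):
                pos = cursor + int(rng.integers(3, 40))
                if rng.random() < 0.5:
                    d = int(rng.integers(1, 9))
                    ev = SecondaryEvent(pos, locus.slice(pos, pos + d), locus.base(pos))
                else:
                    ins = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 7))))
                    ev = SecondaryEvent(pos, locus.base(pos), locus.base(pos) + ins)
                events.append(ev)
                cursor = ev.ref_span[1] + 1
            assert net_frame_change(frameshift, events) == _frame_oracle(
                locus, frameshift, events
            )


# ---------------------------------------------------------------------------
# microhomology
# ---------------------------------------------------------------------------

def _mh_oracle(deleted: str, left_flank: str, right_flank: str) -> int:
    """Exhaustive junction comparison, O(L^2)."""
    best = 0
    for l in range(1, len(deleted) + 1):
        if len(right_flank) >= l and deleted[:l] == right_flank[:l]:
            best = max(best, l)
        if len(left_flank) >= l and deleted[-l:] == left_flank[-l:]:
            best = max(best, l)
    return min(best, len(deleted))


class TestMicrohomology:
    def test_full_length_homology(self):
        ref = LocusReference("r", "GGGTCGATCGATAGG")
        # delete CGAT at positions 5-8; the retained 3' flank starts CGAT...
        ev = left_align(SecondaryEvent(4, "TCGAT", "T"), ref)
        mh, mmej = microhomology(ev, ref)
        assert mh == 4 and mmej

    def test_no_homology(self):
        ref = LocusReference("r", "TTGCAAACGTT")
        ev = left_align(SecondaryEvent(4, "CAAA", "C"), ref)
        mh, mmej = microhomology(ev, ref)
        assert mh == 0 and not mmej

    def test_single_nt_deletion_not_evaluable(self):
        ref = LocusReference("r", "ACGTACGTAC")
        with pytest.raises(ValueError):
            microhomology(SecondaryEvent(3, "GT", "G"), ref)

    def test_agrees_with_exhaustive_oracle(self, rng):
        """2,000 random deletions on random sequence match the O(L^2) oracle."""
        for _ in range(2000):
            seq = "".join(rng.choice(list("ACGT"), size=60))
            ref = LocusReference("r", seq)
            pos = int(rng.integers(2, 40))
            d = int(rng.integers(2, 12))
            ev = left_align(SecondaryEvent(pos, ref.slice(pos, pos + d), ref.base(pos)), ref)
            lo, hi = ev.deleted_span
            deleted = ref.slice(lo, hi)
            mh, mmej = microhomology(ev, ref)
            expect = _mh_oracle(
                deleted,
                ref.slice(max(1, lo - len(deleted)), lo - 1),
                ref.slice(hi + 1, min(len(seq), hi + len(deleted))),
            )
            assert mh == expect
            assert mh <= abs(ev.net_len)
            assert mmej == (2 <= mh <= 6)


# ---------------------------------------------------------------------------
# haplotype enumeration
# ---------------------------------------------------------------------------

class TestEnumerate:
    def test_no_candidates_two_haplotypes(self, locus, frameshift):
        haps = enumerate_candidate_haplotypes(frameshift, [], RealignConfig(), locus)
        assert [h.name for h in haps] == ["ref", "pathogenic"]

    def test_single_restoring_candidate_three_haplotypes(self, locus, frameshift):
        pos = frameshift.pos + 12
        ev = left_align(
            SecondaryEvent(pos, locus.slice(pos, pos + 2), locus.base(pos)), locus
        )
        assert net_frame_change(frameshift, [ev]) == 0
        haps = enumerate_candidate_haplotypes(frameshift, [ev], RealignConfig(), locus)
        frame_restored = [h for h in haps if h.frame_restored]
        assert len(haps) <= 3 and len(frame_restored) <= 1
        # the candidate may be rejected only by the ORF check; verify directly
        if len(haps) == 3:
            assert frame_restored[0].events == (ev,)

    def test_three_singles_no_valid_pairs(self, locus, frameshift):
        """Candidates that each restore the frame alone cannot pair up."""
        events = []
        pos = frameshift.pos + 10
        for _ in range(3):
            ev = left_align(
                SecondaryEvent(pos, locus.slice(pos, pos + 2), locus.base(pos)), locus
            )
            events.append(ev)
            pos += 15
        haps = enumerate_candidate_haplotypes(frameshift, events, RealignConfig(), locus)
        combos = [h.events for h in haps if h.frame_restored]
        # brute-force: any subset of size <= 2 with combined net frame 0
        expected = []
        for k in (1, 2):
            import itertools

            for combo in itertools.combinations(events, k):
                if any(events_overlap(a, b) for a, b in itertools.combinations(combo, 2)):
                    continue
                if net_frame_change(frameshift, list(combo)) == 0:
                    expected.append(set(e.key() for e in combo))
        got = [set(e.key() for e in c) for c in combos]
        for e in expected:
            assert e in got
        assert len(got) <= len(expected)

    def test_window_must_contain_pathogenic(self, locus):
        bad = PathogenicVariant("G", "r", 50_000, "AC", "A", "frameshift")
        with pytest.raises(ValueError):
            enumerate_candidate_haplotypes(bad, [], RealignConfig(), locus)


# ---------------------------------------------------------------------------
# read assignment and calling
# ---------------------------------------------------------------------------

class TestAssignAndCall:
    def test_noiseless_reads_assign_to_origin(self, locus, frameshift):
        pos = frameshift.pos + 12
        ev = left_align(
            SecondaryEvent(pos, locus.slice(pos, pos + 2), locus.base(pos)), locus
        )
        cfg = RealignConfig()
        haps = enumerate_candidate_haplotypes(frameshift, [ev], cfg, locus)
        assert len(haps) == 3
        reads = sim_reads(
            [(haps[0].sequence, 0.5), (haps[2].sequence, 0.5)],
            depth=400, err=0.0, seed=3, labels=["ref", "rev"], anchor=frameshift.pos,
        )
        table = assign_reads(reads, haps, cfg)
        # every assigned read lands on its origin haplotype
        assert table.counts["pathogenic"] == 0
        assert table.counts["ref"] > 0 and table.counts[haps[2].name] > 0
        calls = call_reversions(table, cfg, locus)
        assert len(calls) == 1 and calls[0].events == (ev,)

    def test_tie_goes_unassigned(self, locus, frameshift):
        cfg = RealignConfig()
        haps = enumerate_candidate_haplotypes(frameshift, [], cfg, locus)
        # a read not covering the pathogenic site matches ref and pathogenic
        # equally; parsimony resolves to the least-specific (reference)
        far = frameshift.pos - 600
        seq = locus.slice(far, far + 99)
        read = Read("t1", far, seq, "I" * 100)
        table = assign_reads([read], haps, cfg)
        assert table.counts["ref"] == 1
        # a genuinely ambiguous read (two reversion haplotypes sharing no
        # subset relation) stays unassigned
        p1, p2 = frameshift.pos + 9, frameshift.pos + 9
        e1 = left_align(SecondaryEvent(p1, locus.slice(p1, p1 + 2), locus.base(p1)), locus)
        e2 = left_align(SecondaryEvent(p2, locus.slice(p2, p2 + 5), locus.base(p2)), locus)
        haps2 = enumerate_candidate_haplotypes(frameshift, [e1, e2], cfg, locus)
        rev_names = [h.name for h in haps2 if h.frame_restored]
        if len(rev_names) == 2:
            read2 = Read("t2", far, seq, "I" * 100)
            table2 = assign_reads([read2], haps2, cfg)
            assert table2.counts["ref"] == 1  # still resolved by parsimony

    def test_three_read_floor(self, locus, frameshift):
        """2 supporting reads -> no call; 3 -> call (the 3-read minimum filter)."""
        pos = frameshift.pos + 12
        ev = left_align(
            SecondaryEvent(pos, locus.slice(pos, pos + 2), locus.base(pos)), locus
        )
        cfg = RealignConfig()
        haps = enumerate_candidate_haplotypes(frameshift, [ev], cfg, locus)
        rev_hap = [h for h in haps if h.frame_restored][0]

        def reads_with_support(n):
            rds = sim_reads(
                [(haps[0].sequence, 1.0)], depth=50, err=0.0, seed=1,
                labels=["ref"], anchor=frameshift.pos,
            )
            rev = sim_reads(
                [(rev_hap.sequence, 1.0)], depth=n, err=0.0, seed=2,
                labels=["rev"], anchor=frameshift.pos,
            )
            return rds + rev

        t2 = assign_reads(reads_with_support(2), haps, cfg)
        assert call_reversions(t2, cfg, locus) == []
        t3 = assign_reads(reads_with_support(3), haps, cfg)
        calls = call_reversions(t3, cfg, locus)
        assert len(calls) == 1 and calls[0].support_reads == 3

    def test_complex_classification(self, locus, frameshift):
        p1, p2 = frameshift.pos + 10, frameshift.pos + 25
        e1 = left_align(SecondaryEvent(p1, locus.slice(p1, p1 + 1), locus.base(p1)), locus)
        e2 = left_align(SecondaryEvent(p2, locus.slice(p2, p2 + 1), locus.base(p2)), locus)
        assert net_frame_change(frameshift, [e1, e2]) == 0
        cfg = RealignConfig()
        haps = enumerate_candidate_haplotypes(frameshift, [e1, e2], cfg, locus)
        pair = [h for h in haps if len(h.events) == 2]
        if pair:
            reads = sim_reads(
                [(pair[0].sequence, 1.0)], depth=10, err=0.0, seed=4,
                labels=["c"], anchor=frameshift.pos,
            )
            table = assign_reads(reads, haps, cfg)
            calls = call_reversions(table, cfg, locus)
            assert any(c.klass == "complex" for c in calls)


class TestStopGain:
    def test_qualifying_codon_called(self):
        calls = classify_stopgain({"TTA": 5}, ref_codon="TGG", pathogenic_codon="TGA")
        assert len(calls) == 1 and calls[0].support_reads == 5

    def test_reference_codon_not_called(self):
        assert classify_stopgain({"TGG": 50}, "TGG", "TGA") == []

    def test_stop_codon_not_called(self):
        assert classify_stopgain({"TAA": 50}, "TGG", "TGA") == []

    def test_below_support_floor_not_called(self):
        assert classify_stopgain({"TTA": 2}, "TGG", "TGA") == []

    def test_non_stop_pathogenic_rejected(self):
        with pytest.raises(ValueError):
            classify_stopgain({}, "TGG", "TGC")


# ---------------------------------------------------------------------------
# end-to-end sensitivity / specificity
# ---------------------------------------------------------------------------

def test_specificity_no_false_calls(locus, frameshift):
    """Reads from reference + pathogenic haplotypes only: zero calls."""
    path_hap = apply_events(locus, [frameshift.as_event()])
    reads = sim_reads(
        [(locus.sequence, 0.5), (path_hap, 0.5)], depth=2000, err=0.0, seed=9,
        labels=["ref", "pathogenic"], anchor=frameshift.pos,
    )
    calls, table = detect_reversions(reads, locus, frameshift)
    assert calls == []
    assert table.counts["ref"] + table.counts["pathogenic"] == table.n_assigned
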