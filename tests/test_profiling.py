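from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retroterm.errors import EmptyProfileError
from retroterm.profiling import (
    Alignment,
    LengthProfile,
    align_read,
    compare_conditions,
    end_site_profile,
    length_profile,
    termination_span,
)
from retroterm.reads import TrimmedRead
from retroterm.reference import NcRNAReference, revcomp
from retroterm.simulate import (
    LibraryConfig,
    MoleculeConfig,
    preset_minus_rnaseh1,
    preset_plus_rnaseh1,
    simulate_library,
    simulate_molecules,
    synthetic_reference,
)


def _tr(seq, read_id="r", retron="x"):
    return TrimmedRead(read_id=read_id, rtdna_sequence=seq, trimmed_tail_len=0,
                       adapter_found=True, orientation="sense", retron=retron)


class TestLengthProfile:
    def test_frequencies_normalized_by_total(self):
        reads = [_tr("G" * 85), _tr("G" * 85), _tr("G" * 120)]
        prof = length_profile(reads, "x")
        assert prof.frequencies == {85: 2 / 3, 120: 1 / 3}
        assert prof.total_rtdna_reads == 3

    def test_single_length_single_bin(self):
        prof = length_profile([_tr("G" * 40)] * 5, "x")
        assert prof.frequencies == {40: 1.0}
        assert prof.modal_length == 40

    def test_zero_reads_raises(self):
        with pytest.raises(EmptyProfileError):
            length_profile([_tr("G" * 40, retron="other")], "x")

    def test_modal_length_matches_ground_truth_across_seeds(self):
        """Tight-termination libraries (error 0) yield the ground-truth
        modal molecule length in every one of 50 seeded replicates."""
        ref = synthetic_reference("modal", 64, seed=5)
        start, end = preset_plus_rnaseh1(ref)
        for seed in range(50):
            mols, truth = simulate_molecules(
                MoleculeConfig(30, start, end, seed=seed), ref)
            prof = length_profile([_tr(m, retron="modal") for m in mols],
                                  "modal")
            assert prof.modal_length == truth["length"].mode().iloc[0] == 64


def brute_force_best_placement(read: str, ref: str):
    """Minimal-Hamming placement over all offsets and both strands."""
    best = None
    for strand, seq in (("sense", read), ("antisense", revcomp(read))):
        for off in range(len(ref) - len(seq) + 1):
            mm = sum(a != b for a, b in zip(ref[off:off + len(seq)], seq))
            key = (mm, off, strand != "sense")
            if best is None or key < best[0]:
                best = (key, Alignment("r", off, off + len(seq), strand, mm))
    return best[1] if best else None


@pytest.fixture(scope="module")
def ref():
    return synthetic_reference("aln", 60, seed=9, exclude_t_in_msd=False)


class TestAlignRead:
    def test_antisense_placement(self, ref):
        read = revcomp(ref.sequence[10:50])
        aln = align_read(_tr(read), ref)
        assert (aln.ref_start, aln.ref_end, aln.strand, aln.mismatches) == \
            (10, 50, "antisense", 0)

    def test_sense_placement(self, ref):
        aln = align_read(_tr(ref.sequence[0:20]), ref)
        assert (aln.ref_start, aln.ref_end, aln.strand) == (0, 20, "sense")

    def test_mismatch_fraction_threshold(self, ref):
        read = "T" * 40  # nothing resembling the reference
        assert align_read(_tr(read), ref, max_mismatch_frac=0.1) is None

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_agrees_with_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        ref_seq = "".join(rng.choice(list("ACGT"), size=60))
        ref = NcRNAReference("fuzz", ref_seq, {"msd": (0, 60)})
        start = int(rng.integers(0, 40))
        length = int(rng.integers(15, 60 - start))
        read = revcomp(ref_seq[start:start + length])
        if rng.random() < 0.5:
            read = revcomp(read)
        got = align_read(_tr(read), ref, max_mismatch_frac=0.5)
        want = brute_force_best_placement(read, ref_seq)
        assert (got.ref_start, got.ref_end, got.strand, got.mismatches) == \
            (want.ref_start, want.ref_end, want.strand, want.mismatches)


@pytest.fixture(scope="module")
def tiny_ref():
    return NcRNAReference("tiny", "ACGT", {"msd": (0, 4)})


class TestEndSiteProfile:
    def test_two_overlapping_alignments(self, tiny_ref):
        alns = [Alignment("a", 0, 3, "antisense", 0),
                Alignment("b", 1, 3, "antisense", 0)]
        prof = end_site_profile(alns, tiny_ref)
        assert prof.coverage.tolist() == [0.5, 1.0, 1.0, 0.0]
        assert prof.n_aligned == 2
        assert sum(prof.start_hist.values()) == sum(prof.end_hist.values()) == 2
        # default orientation: 3' terminus at the low coordinate
        assert prof.end_hist == {0: 1, 1: 1}
        assert prof.start_hist == {2: 2}

    def test_single_alignment_indicator_coverage(self, tiny_ref):
        prof = end_site_profile([Alignment("a", 1, 4, "antisense", 0)], tiny_ref)
        assert prof.coverage.tolist() == [0.0, 1.0, 1.0, 1.0]

    def test_empty_alignments_raise(self, tiny_ref):
        with pytest.raises(EmptyProfileError):
            end_site_profile([], tiny_ref)

    def test_end_hist_matches_ground_truth_at_error_zero(self):
        """Broad-termination simulation, error 0: the recovered 3'-end
        histogram equals the ground-truth termini exactly."""
        ref = synthetic_reference("esp", 70, seed=13)
        start, end = preset_minus_rnaseh1(ref)
        mols, truth = simulate_molecules(
            MoleculeConfig(300, start, end, seed=14), ref)
        alns = [align_read(_tr(m, read_id=f"m{i}"), ref)
                for i, m in enumerate(mols)]
        prof = end_site_profile([a for a in alns if a], ref)
        assert prof.end_hist == dict(Counter(truth["three_prime_pos"]))
        assert prof.start_hist == dict(Counter(truth["five_prime_pos"]))

    def test_coverage_dominates_termini(self):
        """Coverage between the modal 5' and modal 3' positions is at least
        each individual terminus frequency (coverage accumulates)."""
        ref = synthetic_reference("dom", 70, seed=15)
        start, end = preset_minus_rnaseh1(ref)
        mols, _ = simulate_molecules(MoleculeConfig(300, start, end, seed=16), ref)
        alns = [align_read(_tr(m, read_id=f"m{i}"), ref)
                for i, m in enumerate(mols)]
        prof = end_site_profile([a for a in alns if a], ref)
        modal_end = max(prof.end_hist, key=prof.end_hist.get)
        modal_start = max(prof.start_hist, key=prof.start_hist.get)
        inner = prof.coverage[min(modal_end, modal_start):
                              max(modal_end, modal_start) + 1]
        max_end_freq = max(prof.end_hist.values()) / prof.n_aligned
        assert (inner >= max_end_freq - 1e-12).all()


class TestTerminationSpan:
    def test_dominant_single_site(self):
        assert termination_span({100: 60, 101: 30, 102: 10}) == (100, 1)

    def test_uniform_ten_positions_needs_width_six(self):
        hist = {p: 10 for p in range(10)}
        assert termination_span(hist) == (0, 6)

    def test_point_mass_width_one(self):
        assert termination_span({42: 999}) == (42, 1)

    def test_leftmost_tie_break(self):
        # both [0,1] and [1,2] hold 60%; leftmost window wins
        assert termination_span({0: 30, 1: 30, 2: 30, 10: 10}) == (0, 2)

    @settings(max_examples=150, deadline=None)
    @given(st.dictionaries(st.integers(0, 30), st.integers(1, 50),
                           min_size=1, max_size=12),
           st.floats(0.05, 0.95))
    def test_matches_window_enumeration(self, hist, mass):
        """The reported window is the smallest (then leftmost) contiguous
        window whose summed frequency strictly exceeds the mass threshold."""
        total = sum(hist.values())
        lo, hi = min(hist), max(hist)
        best = None
        for width in range(1, hi - lo + 2):
            for start in range(lo, hi - width + 2):
                s = sum(hist.get(p, 0) for p in range(start, start + width))
                if s > mass * total:
                    best = (start, width)
                    break
            if best:
                break
        assert termination_span(hist, mass) == best

    def test_monotone_in_modal_mass(self):
        """Adding mass at the modal position never widens the span."""
        hist = {10: 5, 11: 4, 12: 3, 13: 3}
        w0 = termination_span(hist)[1]
        hist[10] += 10
        assert termination_span(hist)[1] <= w0


class TestCompareConditions:
    def test_identical_profiles_have_zero_modal_difference(self):
        prof = LengthProfile("a", {85: 10, 90: 5})
        report = compare_conditions(prof, LengthProfile("b", {85: 10, 90: 5}))
        assert report.modal_difference == 0
        assert report.mann_whitney.p_two_sided > 0.9

    def test_translation_shifts_modal_length_exactly(self):
        a = LengthProfile("a", {80: 7, 85: 12, 90: 2})
        b = LengthProfile("b", {k + 10: v for k, v in a.counts.items()})
        report = compare_conditions(a, b)
        assert report.modal_difference == 10

    def test_tight_condition_has_narrower_span(self):
        a = LengthProfile("tight", {85: 95, 86: 5})
        b = LengthProfile("broad", {k: 10 for k in range(80, 95)})
        report = compare_conditions(a, b)
        assert report.majority_span_a < report.majority_span_b
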