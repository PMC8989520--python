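"""Quantitative RT-DNA read-outs.

Length profiles (reads per length / total RT-DNA reads), ungapped reference
placement, per-nucleotide coverage, 5'/3' end-site histograms, and the
majority-termination-span statistic: the smallest contiguous window of
3'-end positions holding a strict majority of aligned molecules. A precise
terminator concentrates the majority within a span of <= 3 bases; losing
RNase H1 broadens it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import EmptyProfileError, ValidationError
from .reads import TrimmedRead
from .reference import NcRNAReference, revcomp


@dataclass
class LengthProfile:
    """Per-length read counts and normalized frequencies for one retron."""

    retron: str
    counts: dict[int, int]
    total_rtdna_reads: int = 0

    def __post_init__(self) -> None:
        if not self.counts:
            raise EmptyProfileError(f"retron {self.retron!r}: no reads to profile")
        if self.total_rtdna_reads == 0:
            self.total_rtdna_reads = sum(self.counts.values())
        if self.total_rtdna_reads != sum(self.counts.values()):
            raise ValidationError("total_rtdna_reads does not match counts")

    @property
    def frequencies(self) -> dict[int, float]:
        return {k: v / self.total_rtdna_reads for k, v in sorted(self.counts.items())}

    @property
    def modal_length(self) -> int:
        """Most frequent length; ties resolved toward the shorter length."""
        return max(sorted(self.counts), key=lambda k: self.counts[k])

    def expand(self) -> np.ndarray:
        """Per-read length vector (order not meaningful)."""
        return np.repeat(
            np.array(sorted(self.counts)),
            [self.counts[k] for k in sorted(self.counts)],
        )


def length_profile(trimmed_reads: list[TrimmedRead], retron: str) -> LengthProfile:
    """Tally trimmed-read lengths for one retron, normalized by total reads."""
    counts: dict[int, int] = {}
    for t in trimmed_reads:
        if t.retron != retron:
            continue
        n = len(t.rtdna_sequence)
        counts[n] = counts.get(n, 0) + 1
    if not counts:
        raise EmptyProfileError(f"retron {retron!r}: no classified reads")
    return LengthProfile(retron=retron, counts=counts)


# ---------------------------------------------------------------------------
# ungapped placement
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    read_id: str
    ref_start: int
    ref_end: int  # half-open
    strand: str  # "sense" | "antisense" relative to the reference
    mismatches: int

    def __post_init__(self) -> None:
        if not (0 <= self.ref_start < self.ref_end):
            raise ValidationError(
                f"alignment {self.read_id!r}: bad interval "
                f"[{self.ref_start}, {self.ref_end})"
            )


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _offset_mismatches(ref: np.ndarray, read: np.ndarray) -> np.ndarray:
    """Mismatch count for the read at every full-length offset in ref."""
    windows = np.lib.stride_tricks.sliding_window_view(ref, read.size)
    return (windows != read).sum(axis=1)


def align_read(trimmed: TrimmedRead, ref: NcRNAReference,
               max_mismatch_frac: float = 0.1) -> Alignment | None:
    """Best ungapped placement of a read against the reference.

    Both the read (reference-sense placement) and its reverse complement
    (antisense placement; the usual case for RT-DNA-sense reads) are scanned
    over every offset; the placement with the fewest mismatches wins,
    reported only if mismatches / read length <= ``max_mismatch_frac``. Ties
    break toward the lowest ref_start, then the sense strand.
    """
    read = trimmed.rtdna_sequence
    if len(read) > len(ref):
        return None
    ref_arr = _encode(ref.sequence)
    m_sense = _offset_mismatches(ref_arr, _encode(read))
    m_anti = _offset_mismatches(ref_arr, _encode(revcomp(read)))
    best = int(min(m_sense.min(), m_anti.min()))
    if best > max_mismatch_frac * len(read):
        return None
    # candidates at the minimal mismatch count, ordered by (ref_start, sense-first)
    cand = []
    for off in np.flatnonzero(m_sense == best):
        cand.append((int(off), 0, "sense"))
    for off in np.flatnonzero(m_anti == best):
        cand.append((int(off), 1, "antisense"))
    off, _, strand = min(cand)
    return Alignment(
        read_id=trimmed.read_id,
        ref_start=off,
        ref_end=off + len(read),
        strand=strand,
        mismatches=best,
    )


# ---------------------------------------------------------------------------
# end-site profile
# ---------------------------------------------------------------------------

@dataclass
class EndSiteProfile:
    """Per-position coverage fraction plus RT-DNA 5'-start / 3'-end histograms."""

    coverage: np.ndarray
    start_hist: dict[int, int]
    end_hist: dict[int, int]
    n_aligned: int
    five_prime_at_high_coord: bool = True


def end_site_profile(alignments: list[Alignment], ref: NcRNAReference) -> EndSiteProfile:
    """Coverage fraction and termini histograms from ungapped placements.

    ``coverage[p]`` is the fraction of aligned RT-DNA reads covering
    reference position p. Alignment boundaries map to RT-DNA termini through
    the reference orientation flag: with the default flag the 3' terminus is
    ``ref_start`` and the 5' terminus ``ref_end - 1``.
    """
    if not alignments:
        raise EmptyProfileError("no alignments to profile")
    depth = np.zeros(len(ref) + 1, dtype=float)
    start_hist: dict[int, int] = {}
    end_hist: dict[int, int] = {}
    for aln in alignments:
        depth[aln.ref_start] += 1
        depth[aln.ref_end] -= 1
        if ref.rtdna_five_prime_at_high_coord:
            p5, p3 = aln.ref_end - 1, aln.ref_start
        else:
            p5, p3 = aln.ref_start, aln.ref_end - 1
        start_hist[p5] = start_hist.get(p5, 0) + 1
        end_hist[p3] = end_hist.get(p3, 0) + 1
    coverage = np.cumsum(depth[:-1]) / len(alignments)
    return EndSiteProfile(
        coverage=coverage,
        start_hist=start_hist,
        end_hist=end_hist,
        n_aligned=len(alignments),
        five_prime_at_high_coord=ref.rtdna_five_prime_at_high_coord,
    )


def termination_span(end_hist: dict[int, int], mass: float = 0.5) -> tuple[int, int]:
    """Smallest contiguous window of 3'-end positions holding > ``mass``.

    Returns (window_start, width); ties resolved toward the leftmost window.
    "Majority" means the window's summed frequency strictly exceeds ``mass``
    (default: more than half of the aligned molecules).
    """
    if not end_hist:
        raise EmptyProfileError("empty end-site histogram")
    total = sum(end_hist.values())
    lo, hi = min(end_hist), max(end_hist)
    counts = np.zeros(hi - lo + 1, dtype=float)
    for pos, c in end_hist.items():
        counts[pos - lo] = c
    csum = np.concatenate([[0.0], np.cumsum(counts)])
    for width in range(1, counts.size + 1):
        window_sums = csum[width:] - csum[:-width]
        ok = np.flatnonzero(window_sums > mass * total)
        if ok.size:
            return lo + int(ok[0]), width
    return lo, counts.size  # unreachable: the full window holds everything


# ---------------------------------------------------------------------------
# condition comparison
# ---------------------------------------------------------------------------

@dataclass
class ConditionComparison:
    """Structured comparison of two length profiles (e.g. +/- RNase H1)."""

    retron_a: str
    retron_b: str
    modal_length_a: int
    modal_length_b: int
    modal_difference: int
    majority_span_a: int
    majority_span_b: int
    mann_whitney: "object" = field(default=None)

    def to_dict(self) -> dict:
        d = {
            "retron_a": self.retron_a,
            "retron_b": self.retron_b,
            "modal_length_a": self.modal_length_a,
            "modal_length_b": self.modal_length_b,
            "modal_difference": self.modal_difference,
            "majority_span_a": self.majority_span_a,
            "majority_span_b": self.majority_span_b,
        }
        mw = self.mann_whitney
        if mw is not None:
            d["mann_whitney"] = {
                "U": mw.U, "p_two_sided": mw.p_two_sided,
                "method": mw.method, "nA": mw.nA, "nB": mw.nB,
            }
        return d


def compare_conditions(profile_a: LengthProfile,
                       profile_b: LengthProfile) -> ConditionComparison:
    """Compare two length profiles: modal lengths, majority spans, and a
    Mann-Whitney test on the underlying per-read lengths."""
    from .stats import mann_whitney_u

    lengths_a = profile_a.expand()
    lengths_b = profile_b.expand()
    span_a = termination_span({k: v for k, v in profile_a.counts.items()})[1]
    span_b = termination_span({k: v for k, v in profile_b.counts.items()})[1]
    return ConditionComparison(
        retron_a=profile_a.retron,
        retron_b=profile_b.retron,
        modal_length_a=profile_a.modal_length,
        modal_length_b=profile_b.modal_length,
        modal_difference=profile_b.modal_length - profile_a.modal_length,
        majority_span_a=span_a,
        majority_span_b=span_b,
        mann_whitney=mann_whitney_u(lengths_a.tolist(), lengths_b.tolist()),
    )


# ---------------------------------------------------------------------------
# output / plotting
# ---------------------------------------------------------------------------

def write_length_profile_tsv(profile: LengthProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("length\tcount\tfrequency\n")
        for k in sorted(profile.counts):
            fh.write(f"{k}\t{profile.counts[k]}\t"
                     f"{profile.counts[k] / profile.total_rtdna_reads:.6g}\n")


def write_coverage_tsv(prof: EndSiteProfile, path: str | Path) -> None:
    """Coverage track: 1-based positions, coverage fraction, termini counts."""
    with open(path, "w") as fh:
        fh.write("position_1based\tcoverage_fraction\tstart_count\tend_count\n")
        for p, cov in enumerate(prof.coverage):
            fh.write(f"{p + 1}\t{cov:.6g}\t{prof.start_hist.get(p, 0)}\t"
                     f"{prof.end_hist.get(p, 0)}\n")


def plot_length_profile(profile: LengthProfile, path: str | Path,
                        bin_width: int = 1) -> None:
    """Histogram of RT-DNA lengths (frequency scale), written to a file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lengths = profile.expand()
    lo, hi = lengths.min(), lengths.max()
    bins = np.arange(lo - 0.5, hi + bin_width + 0.5, bin_width)
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.hist(lengths, bins=bins, weights=np.full(lengths.size, 1 / lengths.size),
            color="#6a3d9a")
    ax.set_xlabel("RT-DNA length (nt)")
    ax.set_ylabel("relative frequency")
    ax.set_title(profile.retron)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_coverage(prof: EndSiteProfile, path: str | Path) -> None:
    """Coverage track across the reference, written to a file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3))
    ax.fill_between(np.arange(1, prof.coverage.size + 1), prof.coverage,
                    step="mid", color="#1f78b4", alpha=0.8)
    ax.set_xlabel("reference position (1-based)")
    ax.set_ylabel("coverage fraction")
    ax.set_ylim(0, 1.05)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
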