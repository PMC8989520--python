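"""Statistical procedures used by the pipeline.

Two procedures only: the Mann-Whitney U comparison of RT-DNA length
distributions, and the terminal-base bias tally for the spiked-oligo control
of the template-independent tailing chemistry. Two-sided p-values throughout;
no multiple-testing correction is applied across retrons (each comparison is
reported on its own).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import edlib
import numpy as np
from scipy.stats import chisquare, norm, rankdata

from .errors import ValidationError
from .reference import revcomp

#: Exact enumeration is used when nA * nB is at or below this product;
#: larger samples use the tie- and continuity-corrected normal approximation.
EXACT_THRESHOLD = 64


@dataclass
class MannWhitneyResult:
    U: float
    p_two_sided: float
    method: str  # "exact" | "normal-approximation"
    nA: int
    nB: int


def _u_statistic(ranks_a_sum: float, n_a: int) -> float:
    return ranks_a_sum - n_a * (n_a + 1) / 2


def mann_whitney_u(lengths_a: Sequence[float], lengths_b: Sequence[float],
                   exact_threshold: int = EXACT_THRESHOLD) -> MannWhitneyResult:
    """Mann-Whitney U with midranks for ties.

    Exact two-sided p by full enumeration of rank assignments when
    ``nA * nB <= exact_threshold``; otherwise the normal approximation with
    tie correction and a 0.5 continuity correction. The exact two-sided p is
    ``min(1, 2 * min(P(U <= u), P(U >= u)))``.
    """
    a = np.asarray(lengths_a, dtype=float)
    b = np.asarray(lengths_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("Mann-Whitney requires two non-empty samples")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks
    u = _u_statistic(ranks[:n_a].sum(), n_a)

    if n_a * n_b <= exact_threshold:
        # enumerate every C(n, nA) assignment of pooled ranks to group A
        n = n_a + n_b
        us = np.fromiter(
            (_u_statistic(sum(ranks[list(idx)]), n_a)
             for idx in combinations(range(n), n_a)),
            dtype=float,
        )
        le = np.mean(us <= u + 1e-9)
        ge = np.mean(us >= u - 1e-9)
        p = min(1.0, 2 * min(le, ge))
        method = "exact"
    else:
        mu = n_a * n_b / 2
        n = n_a + n_b
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
        var = n_a * n_b / 12 * ((n + 1) - tie_term)
        if var <= 0:
            # all observations tied: no evidence either way
            return MannWhitneyResult(U=float(u), p_two_sided=1.0,
                                     method="normal-approximation",
                                     nA=n_a, nB=n_b)
        # continuity correction toward the mean
        z = (u - mu - 0.5 * np.sign(u - mu)) / np.sqrt(var)
        p = min(1.0, 2 * float(norm.sf(abs(z))))
        method = "normal-approximation"
    return MannWhitneyResult(U=float(u), p_two_sided=float(p), method=method,
                             nA=n_a, nB=n_b)


# ---------------------------------------------------------------------------
# terminal-base bias
# ---------------------------------------------------------------------------

@dataclass
class TerminalBaseTally:
    """Counts of matched spike-in reads binned by observed terminal base."""

    counts: dict[str, int]
    n_matched: int
    chi_square_p: float

    @property
    def fractions(self) -> dict[str, float]:
        if self.n_matched == 0:
            return {b: 0.0 for b in "ACGT"}
        return {b: self.counts.get(b, 0) / self.n_matched for b in "ACGT"}


_N_EQUALITIES = [("N", b) for b in "ACGT"]


def _best_oligo_match(seq: str, query: str, max_edits: int) -> tuple[int, int] | None:
    """Best infix match of the N-wildcarded oligo in a read (either strand).

    Returns (edit distance, end index of the terminal base in the matched
    strand sequence) after picking the better strand, or None above
    ``max_edits``. The terminal base is read off the matched strand at the
    alignment end.
    """
    best = None
    for strand_seq in (seq, revcomp(seq)):
        res = edlib.align(query, strand_seq, mode="HW", task="locations",
                          k=max_edits, additionalEqualities=_N_EQUALITIES)
        if res["editDistance"] == -1:
            continue
        end = res["locations"][0][1]
        terminal = strand_seq[end] if end < len(strand_seq) else None
        if terminal is None:
            continue
        if best is None or res["editDistance"] < best[0]:
            best = (res["editDistance"], terminal)
    return best


def terminal_base_bias(reads: Iterable[str], oligo_templates: Sequence[str],
                       max_edits: int = 2) -> TerminalBaseTally:
    """Bin spike-in reads by terminal base via a fuzzy full-oligo search.

    The four templates must be identical except at the final base; the query
    is the common stem with the terminal position wildcarded, matched with
    Levenshtein distance <= ``max_edits`` (the wildcard terminal never counts
    as an edit). Matched reads are binned by the base observed at the
    terminal position; a chi-square test against the equimolar expectation is
    reported.
    """
    templates = [t.upper() for t in oligo_templates]
    if len(templates) != 4:
        raise ValidationError(f"expected 4 oligo templates, got {len(templates)}")
    if len({len(t) for t in templates}) != 1:
        raise ValidationError("oligo templates must have equal length")
    stems = {t[:-1] for t in templates}
    if len(stems) != 1:
        raise ValidationError("oligo templates must differ only at the final base")
    query = stems.pop() + "N"

    counts: dict[str, int] = {}
    n_matched = 0
    for read in reads:
        seq = read if isinstance(read, str) else str(read)
        hit = _best_oligo_match(seq.upper(), query, max_edits)
        if hit is None:
            continue
        _, terminal = hit
        if terminal not in "ACGT":
            continue
        counts[terminal] = counts.get(terminal, 0) + 1
        n_matched += 1
    if n_matched == 0:
        chi_p = 1.0
    else:
        observed = [counts.get(b, 0) for b in "ACGT"]
        chi_p = float(chisquare(observed).pvalue)
    return TerminalBaseTally(counts=counts, n_matched=n_matched,
                             chi_square_p=chi_p)


def write_tally_tsv(tally: TerminalBaseTally, path) -> None:
    with open(path, "w") as fh:
        fh.write("terminal_base\tcount\tfraction\n")
        for b in "ACGT":
            fh.write(f"{b}\t{tally.counts.get(b, 0)}\t{tally.fractions[b]:.6g}\n")
        fh.write(f"# n_matched={tally.n_matched}\tchi_square_p={tally.chi_square_p:.6g}\n")
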