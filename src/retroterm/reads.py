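"""Raw-read processing: adapter/poly-A trimming and retron classification.

Reads are canonicalized to RT-DNA sense: adapters are removed from both ends
(fuzzy, at most one substitution per 10 adapter bases; partial end matches of
>= 8 bases accepted), then the terminal poly-A run (or the leading poly-T run
of an antisense read, after reverse complementing) is trimmed. A read is then
assigned to a retron if at least one of that retron's three 10-base probes
occurs in it with at most ``max_mismatches`` substitutions, on either strand.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .errors import ValidationError
from .reference import ProbeSet, revcomp

#: Reads shorter than this after trimming are discarded (prevents spurious
#: probe hits on near-empty sequences).
MIN_LENGTH = 15

#: Terminal A runs must reach this length to be treated as a poly-A tail;
#: shorter runs are considered template-encoded.
POLYA_MIN_RUN = 5


@dataclass
class ReadRecord:
    read_id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValidationError(f"read {self.read_id!r}: empty sequence")
        if set(self.sequence) - set("ACGTN"):
            raise ValidationError(
                f"read {self.read_id!r}: alphabet outside A/C/G/T/N"
            )


@dataclass
class TrimmedRead:
    """A canonicalized RT-DNA-sense read plus trimming metadata."""

    read_id: str
    rtdna_sequence: str
    trimmed_tail_len: int
    adapter_found: bool
    orientation: str  # "sense" | "antisense"
    retron: str = "unassigned"


def find_fuzzy_matches(haystack: str, pattern: str, max_sub: int) -> list[int]:
    """All start offsets where the pattern matches with <= max_sub mismatches.

    Substitution-only (Hamming) matching over full-length windows, offsets
    ascending. ``N`` never matches anything.
    """
    if not pattern:
        raise ValidationError("empty pattern")
    m, n = len(pattern), len(haystack)
    if m > n:
        return []
    hay = np.frombuffer(haystack.encode(), dtype=np.uint8)
    pat = np.frombuffer(pattern.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(hay, m)
    mismatches = (windows != pat).sum(axis=1)
    return np.flatnonzero(mismatches <= max_sub).tolist()


def _adapter_tolerance(length: int) -> int:
    """At most one substitution per 10 adapter bases."""
    return length // 10


def _find_adapter(seq: str, adapter: str) -> tuple[int, int] | None:
    """Locate an adapter in a read; returns (start, end) or None.

    Looks for the full adapter anywhere (fuzzy), then for a >= 8-base adapter
    suffix at the read start or prefix at the read end (library molecules can
    begin/end mid-adapter).
    """
    hits = find_fuzzy_matches(seq, adapter, _adapter_tolerance(len(adapter)))
    if hits:
        start = hits[0]
        return start, start + len(adapter)
    # partial adapter hanging off the read start (adapter suffix)
    for k in range(min(len(adapter), len(seq)) - 1, 7, -1):
        tail = adapter[-k:]
        if _hamming(seq[:k], tail) <= _adapter_tolerance(k):
            return 0, k
    # partial adapter truncated at the read end (adapter prefix)
    for k in range(min(len(adapter), len(seq)) - 1, 7, -1):
        head = adapter[:k]
        if _hamming(seq[-k:], head) <= _adapter_tolerance(k):
            return len(seq) - k, len(seq)
    return None


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _trim_poly_a(seq: str, min_run: int = POLYA_MIN_RUN) -> tuple[str, int]:
    """Remove the best-scoring terminal poly-A suffix.

    Scans suffixes scoring +1 per A and -(min_run - 1) per non-A and removes
    the best-scoring suffix containing at least ``min_run`` adenosines (ties
    resolved toward the longer suffix). On error-free reads this reduces to
    removing the maximal terminal A run of length >= min_run; with
    substitution errors inside the tail it still removes the whole tail.
    """
    penalty = min_run - 1
    best_score = 0
    best_cut = len(seq)  # cut point: suffix seq[best_cut:] removed
    best_a = 0
    score = 0
    n_a = 0
    for i in range(len(seq) - 1, -1, -1):
        if seq[i] == "A":
            score += 1
            n_a += 1
        else:
            score -= penalty
        if n_a >= min_run and score >= best_score:
            best_score = score
            best_cut = i
            best_a = n_a
    if best_a < min_run:
        return seq, 0
    return seq[:best_cut], len(seq) - best_cut


def _leading_t_run(seq: str) -> int:
    k = 0
    while k < len(seq) and seq[k] == "T":
        k += 1
    return k


def _trailing_a_run(seq: str) -> int:
    k = 0
    while k < len(seq) and seq[-1 - k] == "A":
        k += 1
    return k


def trim_read(read: ReadRecord,
              adapters: tuple[str, str],
              polyA_min_run: int = POLYA_MIN_RUN,
              min_length: int = MIN_LENGTH) -> TrimmedRead | None:
    """Canonicalize a raw read to RT-DNA sense and strip adapters + tail.

    Orientation is called from adapter signatures (falling back to the
    poly-T-vs-poly-A run comparison), the read is reverse complemented if
    antisense, adapters are removed first, then the terminal poly-A tail.
    Returns None for reads shorter than ``min_length`` after trimming.
    """
    adapter_a, adapter_b = (a.upper() for a in adapters)
    seq = read.sequence

    def sense_evidence(s: str) -> int:
        score = 0
        if _find_adapter(s, adapter_a) is not None:
            score += 1
        if _find_adapter(s, adapter_b) is not None:
            score += 1
        return score

    fwd = sense_evidence(seq)
    rev = sense_evidence(revcomp(seq))
    if fwd > rev:
        orientation = "sense"
    elif rev > fwd:
        orientation = "antisense"
    elif (_leading_t_run(seq) >= 9  # the nine-T anchor image
          and _leading_t_run(seq) > _trailing_a_run(seq)):
        orientation = "antisense"
    else:
        orientation = "sense"
    if orientation == "antisense":
        seq = revcomp(seq)

    adapter_found = False
    loc = _find_adapter(seq, adapter_a)
    if loc is not None and loc[0] <= len(seq) // 2:
        seq = seq[loc[1]:]
        adapter_found = True
    loc = _find_adapter(seq, adapter_b)
    if loc is not None and loc[1] >= len(seq) // 2:
        seq = seq[:loc[0]]
        adapter_found = True

    seq, tail_len = _trim_poly_a(seq, polyA_min_run)
    if len(seq) < min_length:
        return None
    return TrimmedRead(
        read_id=read.read_id,
        rtdna_sequence=seq,
        trimmed_tail_len=tail_len,
        adapter_found=adapter_found,
        orientation=orientation,
    )


def classify_read(trimmed: TrimmedRead, probesets: Iterable[ProbeSet]) -> str:
    """Assign a retron label by fuzzy 10-mer probe matching on both strands.

    Returns the unique retron with >= 1 probe hit, ``"unassigned"`` if none,
    ``"ambiguous"`` if more than one retron matches. The label is also stored
    on the read.
    """
    seq = trimmed.rtdna_sequence
    rc = revcomp(seq)
    matched = []
    for ps in probesets:
        hit = any(
            find_fuzzy_matches(strand, probe, ps.max_mismatches)
            for probe in ps.probes
            for strand in (seq, rc)
            if len(probe) <= len(strand)
        )
        if hit:
            matched.append(ps.retron)
    if not matched:
        label = "unassigned"
    elif len(matched) > 1:
        label = "ambiguous"
    else:
        label = matched[0]
    trimmed.retron = label
    return label


# ---------------------------------------------------------------------------
# FASTQ-level pipeline
# ---------------------------------------------------------------------------

def iter_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Yield reads from a (possibly gzipped) FASTQ file."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()  # plus line
            qual = fh.readline().strip()
            yield ReadRecord(read_id=header.strip().lstrip("@").split()[0],
                             sequence=seq, quality=qual or None)


def process_reads(reads: Iterable[ReadRecord],
                  probesets: list[ProbeSet],
                  adapters: tuple[str, str],
                  polyA_min_run: int = POLYA_MIN_RUN,
                  min_length: int = MIN_LENGTH,
                  ) -> tuple[list[TrimmedRead], dict]:
    """Trim and classify a stream of reads; returns (trimmed reads, QC).

    QC counts satisfy ``n_in == classified + unassigned + ambiguous +
    discarded`` where ``classified`` sums the per-retron counts.
    """
    out: list[TrimmedRead] = []
    qc = {
        "n_in": 0,
        "adapter_found": 0,
        "discarded_short": 0,
        "unassigned": 0,
        "ambiguous": 0,
        "per_retron": {ps.retron: 0 for ps in probesets},
    }
    for read in reads:
        qc["n_in"] += 1
        trimmed = trim_read(read, adapters, polyA_min_run, min_length)
        if trimmed is None:
            qc["discarded_short"] += 1
            continue
        if trimmed.adapter_found:
            qc["adapter_found"] += 1
        label = classify_read(trimmed, probesets)
        if label == "unassigned":
            qc["unassigned"] += 1
        elif label == "ambiguous":
            qc["ambiguous"] += 1
        else:
            qc["per_retron"][label] += 1
        out.append(trimmed)
    qc["classified"] = sum(qc["per_retron"].values())
    return out, qc


def write_trimmed_tsv(trimmed: list[TrimmedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tretron\tlength\torientation\ttail_len\tadapter_found\n")
        for t in trimmed:
            fh.write(
                f"{t.read_id}\t{t.retron}\t{len(t.rtdna_sequence)}\t"
                f"{t.orientation}\t{t.trimmed_tail_len}\t"
                f"{str(t.adapter_found).lower()}\n"
            )


def write_trimmed_fasta(trimmed: list[TrimmedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in trimmed:
            fh.write(f">{t.read_id} retron={t.retron}\n{t.rtdna_sequence}\n")


def write_qc_json(qc: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(qc, fh, indent=2, sort_keys=True)
        fh.write("\n")
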