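"""Retron ncRNA reference model.

A retron non-coding RNA is represented here as its DNA-sense sequence (5'->3')
with named regions: the a1/a2 inverted repeats flanking the element, the msr
(not reverse transcribed) and the msd (the template that the retron reverse
transcriptase copies into single-stranded RT-DNA). Because the RT reads its
template 3'->5', the RT-DNA is the reverse complement of a contiguous slice of
the reference, with its 3' terminus at the *lower* reference coordinate by
default.

Coordinates are 0-based half-open internally; human-readable reports use
1-based inclusive coordinates (see :func:`to_report_interval`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigurationError, ValidationError

DNA_ALPHABET = frozenset("ACGT")

#: Region names that must be present in an annotation for a full retron
#: element; a minimal reference only needs ``msd``.
CANONICAL_REGIONS = ("a1", "msr", "msd", "a2")

#: Reserved single-position annotation names (stored as width-1 intervals in
#: the BED-like TSV, not as regions).
_POINT_ANNOTATIONS = ("term_site", "branch_g")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return str(Seq(seq).reverse_complement())


def to_report_interval(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive."""
    return start + 1, end


def from_report_interval(start1: int, end1: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval back to 0-based half-open."""
    return start1 - 1, end1


@dataclass
class NcRNAReference:
    """An annotated retron ncRNA template.

    Parameters
    ----------
    name
        Identifier (e.g. ``"Eco1"``).
    sequence
        DNA-sense ncRNA sequence, 5'->3', A/C/G/T only.
    regions
        Map of region name -> 0-based half-open interval. Must include
        ``msd``; typically also ``a1``, ``msr``, ``a2``.
    canonical_term_site
        Reference position of the RT-DNA 3' terminus (the precise termination
        point), if known. Must lie inside ``msd``.
    branch_g_pos
        Reference position of the branching guanosine whose 2'-OH primes
        reverse transcription (the 2'-5' linkage site), if known.
    rtdna_five_prime_at_high_coord
        Orientation flag: if True (default) the RT-DNA 5' terminus maps to the
        higher reference coordinate of its alignment, matching an RT that
        initiates near the msd 3' boundary and synthesises toward lower
        coordinates.
    """

    name: str
    sequence: str
    regions: dict[str, tuple[int, int]]
    canonical_term_site: int | None = None
    branch_g_pos: int | None = None
    rtdna_five_prime_at_high_coord: bool = True

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValidationError(
                f"reference {self.name!r}: sequence contains non-A/C/G/T "
                f"characters {sorted(bad)} (degenerate bases are rejected)"
            )
        if not self.sequence:
            raise ValidationError(f"reference {self.name!r}: empty sequence")
        n = len(self.sequence)
        self.regions = {k: (int(s), int(e)) for k, (s, e) in self.regions.items()}
        for rname, (s, e) in self.regions.items():
            if not (0 <= s < e <= n):
                raise ValidationError(
                    f"reference {self.name!r}: region {rname!r}=[{s},{e}) "
                    f"outside [0,{n}) or empty"
                )
        if "msd" not in self.regions:
            raise ConfigurationError(
                f"reference {self.name!r}: required region 'msd' missing"
            )
        if "msr" in self.regions:
            ms, me = self.regions["msr"]
            ds, de = self.regions["msd"]
            if max(ms, ds) < min(me, de):
                raise ValidationError(
                    f"reference {self.name!r}: msr {self.regions['msr']} and "
                    f"msd {self.regions['msd']} overlap"
                )
        if self.canonical_term_site is not None:
            s, e = self.regions["msd"]
            if not (s <= self.canonical_term_site < e):
                raise ValidationError(
                    f"reference {self.name!r}: canonical_term_site "
                    f"{self.canonical_term_site} outside msd [{s},{e})"
                )
        if self.branch_g_pos is not None and not (0 <= self.branch_g_pos < n):
            raise ValidationError(
                f"reference {self.name!r}: branch_g_pos {self.branch_g_pos} "
                f"outside the sequence"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def msd_interval(self) -> tuple[int, int]:
        return self.regions["msd"]

    def msd_sequence(self) -> str:
        s, e = self.msd_interval
        return self.sequence[s:e]

    def rtdna_sense_msd(self) -> str:
        """The msd region in RT-DNA sense (reverse complement of the template)."""
        return revcomp(self.msd_sequence())

    def canonical_rtdna(self) -> str:
        """The canonical full-length RT-DNA (termination site -> msd 3' edge).

        Requires ``canonical_term_site``; the 5' terminus is taken as the high
        edge of msd (or the low edge if the orientation flag is flipped).
        """
        if self.canonical_term_site is None:
            raise ConfigurationError(
                f"reference {self.name!r}: canonical_term_site not set"
            )
        s, e = self.msd_interval
        if self.rtdna_five_prime_at_high_coord:
            return revcomp(self.sequence[self.canonical_term_site:e])
        return self.sequence[s:self.canonical_term_site + 1]


@dataclass
class ProbeSet:
    """Three retron-specific 10-mers queried (fuzzily) to classify reads."""

    retron: str
    probes: list[str] = field(default_factory=list)
    max_mismatches: int = 1

    def __post_init__(self) -> None:
        self.probes = [p.upper() for p in self.probes]
        if len(self.probes) != 3:
            raise ValidationError(
                f"probe set {self.retron!r}: expected exactly 3 probes, "
                f"got {len(self.probes)}"
            )
        for p in self.probes:
            if len(p) != 10:
                raise ValidationError(
                    f"probe set {self.retron!r}: probe {p!r} has length "
                    f"{len(p)}, expected 10"
                )
            if set(p) - DNA_ALPHABET:
                raise ValidationError(
                    f"probe set {self.retron!r}: probe {p!r} contains "
                    f"non-A/C/G/T characters"
                )
        if self.max_mismatches < 0:
            raise ValidationError("max_mismatches must be >= 0")


def load_reference(fasta_path: str | Path, annotation_path: str | Path,
                   rtdna_five_prime_at_high_coord: bool = True) -> NcRNAReference:
    """Load a reference from a single-record FASTA plus a BED-like TSV.

    The annotation TSV has three columns (name, start, end), 0-based
    half-open, one row per region; the reserved names ``term_site`` and
    ``branch_g`` give single positions (width-1 intervals).
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ConfigurationError(
            f"{fasta_path}: expected exactly one FASTA record, got {len(records)}"
        )
    rec = records[0]
    regions: dict[str, tuple[int, int]] = {}
    term_site = None
    branch_g = None
    with open(annotation_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ConfigurationError(
                    f"{annotation_path}:{lineno}: expected 3 tab-separated "
                    f"columns (name, start, end)"
                )
            name, start, end = parts[0], int(parts[1]), int(parts[2])
            if name == "term_site":
                term_site = start
            elif name == "branch_g":
                branch_g = start
            else:
                regions[name] = (start, end)
    return NcRNAReference(
        name=rec.id,
        sequence=str(rec.seq),
        regions=regions,
        canonical_term_site=term_site,
        branch_g_pos=branch_g,
        rtdna_five_prime_at_high_coord=rtdna_five_prime_at_high_coord,
    )


def write_reference(ref: NcRNAReference, fasta_path: str | Path,
                    annotation_path: str | Path) -> None:
    """Write a reference back out as FASTA + BED-like TSV (round-trips)."""
    SeqIO.write([SeqRecord(Seq(ref.sequence), id=ref.name, description="")],
                str(fasta_path), "fasta")
    with open(annotation_path, "w") as fh:
        for name, (s, e) in sorted(ref.regions.items(), key=lambda kv: kv[1]):
            fh.write(f"{name}\t{s}\t{e}\n")
        if ref.canonical_term_site is not None:
            fh.write(f"term_site\t{ref.canonical_term_site}\t{ref.canonical_term_site + 1}\n")
        if ref.branch_g_pos is not None:
            fh.write(f"branch_g\t{ref.branch_g_pos}\t{ref.branch_g_pos + 1}\n")


def validate_probes(probeset: ProbeSet, ref: NcRNAReference) -> dict[str, list[int]]:
    """Locate each probe within the RT-DNA sense of the msd region.

    Returns a map probe -> list of 0-based offsets within
    ``ref.rtdna_sense_msd()`` (all exact occurrences). A probe that does not
    occur triggers a :class:`UserWarning` and maps to an empty list.
    """
    target = ref.rtdna_sense_msd()
    out: dict[str, list[int]] = {}
    for probe in probeset.probes:
        hits = []
        start = target.find(probe)
        while start != -1:
            hits.append(start)
            start = target.find(probe, start + 1)
        if not hits:
            warnings.warn(
                f"probe {probe!r} of retron {probeset.retron!r} not found in "
                f"the RT-DNA sense of reference {ref.name!r}",
                UserWarning,
                stacklevel=2,
            )
        out[probe] = hits
    return out
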