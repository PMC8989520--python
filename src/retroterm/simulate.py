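"""Ground-truth-labelled synthetic data for every pipeline stage.

The simulator emulates the library chemistry used to sequence retron RT-DNA:

1. single-stranded RT-DNA molecules are reverse complements of a slice of the
   ncRNA template, with configurable 5'-start and 3'-termination
   distributions ("+RNase H1" = near-point termination at the canonical
   site; "-RNase H1" = broad termination extended toward the template 5'
   end);
2. each molecule is 3'-tailed with ~25 adenosines by a template-independent
   polymerase, a complementary strand is primed from an adapter + nine T +
   non-T (V) anchor, and a second adapter is ligated, so a read is
   ``adapter_A + molecule + poly(A) + adapter_B`` in RT-DNA sense, or its
   reverse complement (which carries the poly(T)/anchor image up front);
3. substitution errors are applied at a configurable per-base rate; quality
   strings are constant (the downstream analysis uses no quality filtering).

Every generator is deterministic under a fixed seed and emits one ground-truth
record per read, enabling exact parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigurationError, ValidationError
from .reference import DNA_ALPHABET, NcRNAReference, revcomp

#: Default adapters (arbitrary Illumina-style sequences; configurable).
DEFAULT_ADAPTER_A = "AGATGTGTATAAGAGACAG"
DEFAULT_ADAPTER_B = "AGATCGGAAGAGCACACGTC"

#: Second-strand primer anchor: nine thymines plus a non-T (V) base.
ANCHOR = "TTTTTTTTTV"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# discrete distributions over reference positions / tail lengths
# ---------------------------------------------------------------------------

def point_mass(pos: int) -> dict[int, float]:
    """Degenerate distribution at a single position."""
    return {int(pos): 1.0}


def discretized_normal(mean: float, sd: float, low: int, high: int) -> dict[int, float]:
    """Normal(mean, sd) discretized to integers and truncated to [low, high].

    Each integer k gets the probability mass of (k-0.5, k+0.5], renormalized
    over the truncated support. ``sd == 0`` degenerates to a point mass at
    round(mean) clipped into the interval.
    """
    if high < low:
        raise ConfigurationError(f"empty support: [{low}, {high}]")
    if sd < 0:
        raise ConfigurationError(f"negative sd: {sd}")
    if sd == 0:
        return point_mass(int(np.clip(round(mean), low, high)))
    ks = np.arange(low, high + 1)
    mass = norm.cdf(ks + 0.5, mean, sd) - norm.cdf(ks - 0.5, mean, sd)
    total = mass.sum()
    if total <= 0:
        raise ConfigurationError(
            f"discretized normal(mean={mean}, sd={sd}) has no mass in [{low}, {high}]"
        )
    mass /= total
    return {int(k): float(m) for k, m in zip(ks, mass) if m > 0}


def mixture(components: list[tuple[float, dict[int, float]]]) -> dict[int, float]:
    """Weighted mixture of discrete distributions (weights renormalized)."""
    wtot = sum(w for w, _ in components)
    if wtot <= 0:
        raise ConfigurationError("mixture weights must sum to a positive value")
    out: dict[int, float] = {}
    for w, pmf in components:
        for k, p in pmf.items():
            out[k] = out.get(k, 0.0) + (w / wtot) * p
    return out


def _check_pmf(pmf: dict[int, float], what: str) -> None:
    total = sum(pmf.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"{what}: probabilities sum to {total}, not 1")
    if any(p < 0 for p in pmf.values()):
        raise ConfigurationError(f"{what}: negative probability mass")


def _sample_pmf(pmf: dict[int, float], n: int, rng: np.random.Generator) -> np.ndarray:
    keys = np.array(sorted(pmf))
    probs = np.array([pmf[k] for k in keys], dtype=float)
    probs /= probs.sum()
    return rng.choice(keys, size=n, p=probs)


# ---------------------------------------------------------------------------
# molecules
# ---------------------------------------------------------------------------

@dataclass
class MoleculeConfig:
    """Sampling scheme for RT-DNA molecules on one reference.

    ``start_dist`` is over the RT-DNA 5'-terminus reference position and
    ``end_dist`` over the 3'-terminus position (3' at the lower coordinate
    under the default orientation); both are {position: probability} maps.
    """

    n_molecules: int
    start_dist: dict[int, float]
    end_dist: dict[int, float]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules <= 0:
            raise ConfigurationError("n_molecules must be positive")
        _check_pmf(self.start_dist, "start_dist")
        _check_pmf(self.end_dist, "end_dist")


def preset_plus_rnaseh1(ref: NcRNAReference, end_sd: float = 0.0) -> tuple[dict[int, float], dict[int, float]]:
    """(start_dist, end_dist) for the '+RNase H1' condition.

    Initiation is fixed at the msd 3' boundary; termination is a point mass
    (or a near-point discretized normal if ``end_sd`` > 0) at the canonical
    termination site.
    """
    if ref.canonical_term_site is None:
        raise ConfigurationError(
            f"reference {ref.name!r}: presets require canonical_term_site"
        )
    s, e = ref.msd_interval
    start = point_mass(e - 1)
    if end_sd == 0:
        end = point_mass(ref.canonical_term_site)
    else:
        end = discretized_normal(ref.canonical_term_site, end_sd, s, e - 1)
    return start, end


def preset_minus_rnaseh1(ref: NcRNAReference, sd: float = 4.0,
                         extension: int = 12, extension_sd: float = 6.0,
                         extension_weight: float = 0.4) -> tuple[dict[int, float], dict[int, float]]:
    """(start_dist, end_dist) for the '-RNase H1' condition.

    Termination precision is lost: a broad component around the canonical site
    (sd defaults to 4 nt) mixed with a component shifted toward the template
    5' end (lower coordinates), emulating read-through past the canonical
    stop.
    """
    if ref.canonical_term_site is None:
        raise ConfigurationError(
            f"reference {ref.name!r}: presets require canonical_term_site"
        )
    s, e = ref.msd_interval
    start = point_mass(e - 1)
    lo = max(0, s - extension * 2)
    broad = discretized_normal(ref.canonical_term_site, sd, lo, e - 2)
    shifted = discretized_normal(ref.canonical_term_site - extension,
                                 extension_sd, lo, e - 2)
    return start, mixture([(1 - extension_weight, broad), (extension_weight, shifted)])


def simulate_molecules(cfg: MoleculeConfig, ref: NcRNAReference,
                       retron: str | None = None) -> tuple[list[str], pd.DataFrame]:
    """Sample RT-DNA molecules from a reference.

    Each molecule spanning reference interval [end, start] (inclusive) has
    sequence ``revcomp(ref[end:start+1])`` under the default orientation flag
    (5' at the high coordinate). Returns the molecule sequences plus a
    ground-truth table (molecule_id, retron, five_prime_pos, three_prime_pos,
    length).
    """
    n = len(ref)
    for what, pmf in (("start_dist", cfg.start_dist), ("end_dist", cfg.end_dist)):
        if min(pmf) < 0 or max(pmf) >= n:
            raise ConfigurationError(
                f"{what}: support [{min(pmf)}, {max(pmf)}] outside reference [0, {n})"
            )
    rng = np.random.default_rng(cfg.seed)
    starts = _sample_pmf(cfg.start_dist, cfg.n_molecules, rng)
    ends = _sample_pmf(cfg.end_dist, cfg.n_molecules, rng)
    if not ref.rtdna_five_prime_at_high_coord:
        starts, ends = ends, starts  # 5' maps to the low coordinate instead
    # resample the rare pairs that would define an empty molecule
    bad = ends > starts if ref.rtdna_five_prime_at_high_coord else starts > ends
    attempts = 0
    while bad.any():
        attempts += 1
        if attempts > 1000:
            raise ConfigurationError(
                "start_dist/end_dist overlap so strongly that non-empty "
                "molecules cannot be sampled"
            )
        k = int(bad.sum())
        starts[bad] = _sample_pmf(cfg.start_dist, k, rng)
        ends[bad] = _sample_pmf(cfg.end_dist, k, rng)
        bad = ends > starts if ref.rtdna_five_prime_at_high_coord else starts > ends
    seqs = []
    for p5, p3 in zip(starts, ends):
        lo, hi = (p3, p5) if ref.rtdna_five_prime_at_high_coord else (p5, p3)
        frag = ref.sequence[lo:hi + 1]
        seqs.append(revcomp(frag) if ref.rtdna_five_prime_at_high_coord else frag)
    truth = pd.DataFrame({
        "molecule_id": [f"mol_{i:06d}" for i in range(cfg.n_molecules)],
        "retron": retron or ref.name,
        "five_prime_pos": starts.astype(int),
        "three_prime_pos": ends.astype(int),
        "length": np.abs(starts - ends).astype(int) + 1,
    })
    return seqs, truth


# ---------------------------------------------------------------------------
# library prep
# ---------------------------------------------------------------------------

def default_tail_dist(mean: float = 25.0, sd: float = 5.0, floor: int = 5,
                      ceiling: int = 60) -> dict[int, float]:
    """Poly-A tail length distribution: discretized normal, mean ~25."""
    return discretized_normal(mean, sd, floor, ceiling)


@dataclass
class LibraryConfig:
    """Parameters of the sequencing library chemistry emulation."""

    tail_length_dist: dict[int, float] = field(default_factory=default_tail_dist)
    adapter_a: str = DEFAULT_ADAPTER_A
    adapter_b: str = DEFAULT_ADAPTER_B
    anchor: str = ANCHOR
    substitution_error_rate: float = 0.0
    sense_fraction: float = 0.5
    read_length: int | None = None
    untrimmed_5p_bases: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.substitution_error_rate <= 1.0):
            raise ConfigurationError(
                f"substitution_error_rate {self.substitution_error_rate} not in [0, 1]"
            )
        if not (0.0 <= self.sense_fraction <= 1.0):
            raise ConfigurationError(
                f"sense_fraction {self.sense_fraction} not in [0, 1]"
            )
        _check_pmf(self.tail_length_dist, "tail_length_dist")
        if min(self.tail_length_dist) < 0:
            raise ConfigurationError("tail lengths must be non-negative")
        for name in ("adapter_a", "adapter_b"):
            seq = getattr(self, name).upper()
            setattr(self, name, seq)
            if set(seq) - DNA_ALPHABET:
                raise ValidationError(f"{name} contains non-A/C/G/T characters")
        if self.read_length is not None and self.read_length < len(self.adapter_a):
            raise ConfigurationError(
                f"read_length {self.read_length} shorter than adapter_a "
                f"({len(self.adapter_a)} nt)"
            )


def _apply_substitutions(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0.0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    if hit.any():
        idx = np.flatnonzero(hit)
        # draw a base different from the original via an offset in 1..3
        offsets = rng.integers(1, 4, size=idx.size)
        base_idx = np.searchsorted(_BASES, arr[idx])
        # non-ACGT characters (N) are replaced by a uniform base
        known = (base_idx < 4) & (_BASES[np.minimum(base_idx, 3)] == arr[idx])
        new_idx = np.where(known, (base_idx + offsets) % 4, offsets % 4)
        arr[idx] = _BASES[new_idx]
    return arr.tobytes().decode()


def simulate_library(molecules: list[str], cfg: LibraryConfig,
                     truth: pd.DataFrame | None = None,
                     ) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Turn molecules into FASTQ-ready reads with per-read ground truth.

    Returns ``(reads, truth)`` where each read is a (read_id, sequence,
    quality) triple. A sense read is ``adapter_a + molecule + A*tail +
    adapter_b``; an antisense read is its reverse complement (poly-T/anchor
    image before the molecule complement). One ground-truth row is emitted per
    read; if a molecule-level ``truth`` table is given its columns are carried
    over.
    """
    if not molecules:
        raise ConfigurationError("simulate_library requires at least one molecule")
    rng = np.random.default_rng(cfg.seed)
    tails = _sample_pmf(cfg.tail_length_dist, len(molecules), rng)
    sense = rng.random(len(molecules)) < cfg.sense_fraction
    reads: list[tuple[str, str, str]] = []
    rows = []
    for i, mol in enumerate(molecules):
        mol = mol.upper()
        construct = cfg.adapter_a + mol + "A" * int(tails[i]) + cfg.adapter_b
        if not sense[i]:
            construct = revcomp(construct)
        construct = _apply_substitutions(construct, cfg.substitution_error_rate, rng)
        if cfg.read_length is not None:
            construct = construct[:cfg.read_length]
        read_id = f"read_{i:06d}"
        reads.append((read_id, construct, "I" * len(construct)))
        row = {
            "read_id": read_id,
            "orientation": "sense" if sense[i] else "antisense",
            "tail_length": int(tails[i]),
            "molecule_length": len(mol),
            "molecule_sequence": mol,
        }
        if truth is not None:
            for col in truth.columns:
                row[col] = truth.iloc[i][col]
        rows.append(row)
    return reads, pd.DataFrame(rows)


def write_fastq(reads: list[tuple[str, str, str]], path: str | Path) -> None:
    """Write (read_id, sequence, quality) triples as a 4-line FASTQ file."""
    with open(path, "w") as fh:
        for read_id, seq, qual in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# oligonucleotide spike-ins (terminal-base bias control)
# ---------------------------------------------------------------------------

def simulate_oligo_spike(oligos: list[str], n_reads: int,
                         proportions: list[float] | None = None,
                         bias: dict[str, float] | None = None,
                         seed: int = 0,
                         library: LibraryConfig | None = None,
                         ) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Emulate the equimolar 4-oligo spike-in used to test tailing bias.

    ``oligos`` are four equal-length sequences identical except at the final
    base. ``bias`` optionally maps terminal base -> relative tailing
    efficiency; emission probabilities are proportion x efficiency,
    renormalized. Reads pass through the same library chemistry as RT-DNA.
    """
    if len(oligos) != 4:
        raise ValidationError(f"expected 4 oligos, got {len(oligos)}")
    oligos = [o.upper() for o in oligos]
    if len({len(o) for o in oligos}) != 1:
        raise ValidationError("oligos must all have the same length")
    stems = {o[:-1] for o in oligos}
    if len(stems) != 1:
        raise ValidationError("oligos must be identical except at the final base")
    if len({o[-1] for o in oligos}) != 4:
        raise ValidationError("oligo terminal bases must be distinct")
    if proportions is None:
        proportions = [0.25] * 4
    if len(proportions) != 4:
        raise ConfigurationError("proportions must have 4 entries")
    props = np.asarray(proportions, dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ConfigurationError(f"proportions sum to {props.sum()}, not 1")
    if bias:
        eff = np.array([bias.get(o[-1], 1.0) for o in oligos], dtype=float)
        if (eff < 0).any():
            raise ConfigurationError("bias efficiencies must be non-negative")
        props = props * eff
        props /= props.sum()
    rng = np.random.default_rng(seed)
    which = rng.choice(4, size=n_reads, p=props)
    molecules = [oligos[k] for k in which]
    lib = library or LibraryConfig()
    lib.seed = int(np.random.default_rng(seed + 1).integers(0, 2**31 - 1))
    truth = pd.DataFrame({
        "oligo_index": which,
        "terminal_base": [oligos[k][-1] for k in which],
    })
    reads, full_truth = simulate_library(molecules, lib, truth=truth)
    return reads, full_truth


# ---------------------------------------------------------------------------
# phenotype tables
# ---------------------------------------------------------------------------

def simulate_phenotypes(design: list[dict], noise_cv: float = 0.1,
                        seed: int = 0, n_replicates: int = 3) -> pd.DataFrame:
    """Generate a tidy phenotype table from design means.

    Each design entry is a dict with a ``mean`` key plus identifying columns.
    OD entries (``kind='od'``, columns strain/construct/induced) get
    ``od600 = mean x lognormal`` noise with the requested coefficient of
    variation (mean-preserving parameterization); plaque entries
    (``kind='plaque'``, columns strain/construct/phage/lysate_volume_ul/
    dilution_factor) get Poisson counting noise around the mean count.
    ``noise_cv = 0`` returns the exact design means.
    """
    if noise_cv < 0:
        raise ConfigurationError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    sigma = float(np.sqrt(np.log1p(noise_cv ** 2)))
    for entry in design:
        entry = dict(entry)
        kind = entry.pop("kind")
        mean = float(entry.pop("mean"))
        if mean < 0:
            raise ConfigurationError(f"negative design mean: {mean}")
        reps = int(entry.pop("n_replicates", n_replicates))
        for rep in range(reps):
            row = dict(entry)
            row["replicate"] = rep + 1
            if kind == "od":
                if noise_cv == 0:
                    row["od600"] = mean
                else:
                    row["od600"] = mean * float(
                        rng.lognormal(-sigma ** 2 / 2, sigma))
            elif kind == "plaque":
                if noise_cv == 0:
                    row["plaque_count"] = int(round(mean))
                else:
                    row["plaque_count"] = int(rng.poisson(mean))
                row.setdefault("lysate_volume_ul", 45.0)
                row.setdefault("dilution_factor", 1.0)
            else:
                raise ConfigurationError(f"unknown design kind {kind!r}")
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synthetic study references
# ---------------------------------------------------------------------------

def synthetic_reference(name: str, rtdna_length: int, seed: int = 0,
                        msr_length: int = 80, ir_length: int = 12,
                        msd_padding: int = 20,
                        exclude_t_in_msd: bool = True) -> NcRNAReference:
    """Build a synthetic, randomly generated retron ncRNA reference.

    This is a synthetic stand-in for a real retron element: a random sequence
    with a1/msr/msd/a2 annotations laid out in order, sized so the canonical
    RT-DNA (msd 3' edge back to the termination site) is ``rtdna_length``
    bases, with ``msd_padding`` extra template bases beyond the termination
    site so read-through termination can be simulated. By default the msd
    region is drawn from {A,C,G} only, so the RT-DNA contains no adenosine and
    every poly-A tail junction is unambiguous (the same condition under which
    the V-anchor chemistry itself reads out lengths exactly).
    """
    if rtdna_length < 15:
        raise ConfigurationError("rtdna_length must be >= 15")
    rng = np.random.default_rng(seed)
    msd_len = rtdna_length + msd_padding

    def draw(k: int, alphabet: str) -> str:
        return "".join(rng.choice(list(alphabet), size=k))

    a1 = draw(ir_length, "ACGT")
    msr = draw(msr_length, "ACGT")
    msd = draw(msd_len, "ACG" if exclude_t_in_msd else "ACGT")
    a2 = revcomp(a1)  # inverted repeat
    seq = a1 + msr + msd + a2
    msd_start = ir_length + msr_length
    regions = {
        "a1": (0, ir_length),
        "msr": (ir_length, msd_start),
        "msd": (msd_start, msd_start + msd_len),
        "a2": (msd_start + msd_len, len(seq)),
    }
    term_site = msd_start + msd_len - rtdna_length
    return NcRNAReference(
        name=name,
        sequence=seq,
        regions=regions,
        canonical_term_site=term_site,
        branch_g_pos=msd_start + msd_len - 1,
        rtdna_five_prime_at_high_coord=True,
    )


def probes_for_reference(ref: NcRNAReference, retron: str | None = None,
                         offsets: tuple[int, int, int] | None = None,
                         max_mismatches: int = 1) -> "ProbeSet":
    """Pick three 10-mers from the 5' portion of the canonical RT-DNA.

    Offsets are measured from the RT-DNA 5' terminus, so the probes are
    present in every molecule whose termination lies at least
    ``max(offsets) + 10`` bases downstream of initiation. By default three
    offsets spread over the 5' three-quarters of the canonical RT-DNA are
    used.
    """
    from .reference import ProbeSet

    rtdna = ref.canonical_rtdna()
    if offsets is None:
        span = max(len(rtdna) - 10, 10)
        offsets = (min(5, span), span * 2 // 5, span * 3 // 4)
    probes = []
    for off in offsets:
        if off + 10 > len(rtdna):
            raise ConfigurationError(
                f"probe offset {off} outside the canonical RT-DNA "
                f"({len(rtdna)} nt)"
            )
        probes.append(rtdna[off:off + 10])
    return ProbeSet(retron=retron or ref.name, probes=probes,
                    max_mismatches=max_mismatches)
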