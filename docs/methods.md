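# Methods

`retroterm` quantifies how precisely a retron reverse transcriptase (RT)
terminates synthesis of its single-stranded RT-DNA, from multiplexed
sequencing reads of tailed, adapter-flanked libraries. This note documents
the model of the data, the algorithms, the tunable parameters, and the
limits of what the synthetic-data tests demonstrate.

## The measurement being modelled

A retron element is a non-coding RNA (ncRNA) with inverted repeats (a1/a2)
flanking a non-reverse-transcribed region (msr) and a template region (msd).
The RT initiates from a conserved branching guanosine and copies the msd
template 3'→5', producing an RT-DNA of roughly 40–160 nt whose 3' terminus
falls at a precise termination site when host RNase H1 removes the RNA from
the growing DNA:RNA hybrid. Without RNase H1, termination becomes imprecise
and reverse transcription runs on toward the template 5' end.

Sequencing libraries are built by tailing the RT-DNA 3' end with ~25
adenosines (terminal deoxynucleotidyl transferase, dATP only), priming the
complementary strand with an adapter + nine thymines + a non-T (V) anchor,
and ligating a second adapter. A read is therefore
`adapter_A + RT-DNA + poly(A) + adapter_B` in RT-DNA sense, or its reverse
complement, which carries the poly(T)/anchor image in front of the RT-DNA
complement.

## Coordinates and orientation

All intervals are 0-based half-open internally; reports use 1-based
inclusive coordinates. Because the RT reads its template 3'→5', the RT-DNA
3' terminus maps to the *lower* reference coordinate. Each reference carries
an explicit orientation flag (`rtdna_five_prime_at_high_coord`, default
true) that is recorded in every report, so a flipped reference cannot
silently swap the 5' and 3' histograms.

## Read processing

* **Fuzzy matching.** 10-mer probe queries use substitution-only (Hamming)
  matching, one mismatch allowed by default. Hamming is used because the
  probes are short, fixed-length anchors; an indel inside a 10-mer is far
  rarer than a substitution and would only demote a read to "unassigned".
  The full-oligo bias search instead uses Levenshtein distance (edlib) with
  the terminal base wildcarded, since that query spans a whole oligo.
* **Adapter removal** precedes poly-A trimming. Full adapters are located
  with at most one substitution per 10 adapter bases; partial adapter
  prefixes/suffixes of at least 8 nt at read ends are also removed.
* **Poly-A trimming** removes the best-scoring terminal suffix, scoring +1
  per A and −(`polyA_min_run` − 1) per non-A, and only if the suffix
  contains at least `polyA_min_run` (default 5) adenosines. On error-free
  reads this is exactly the maximal-terminal-A-run rule; with substitution
  errors inside the tail it still removes the whole tail instead of leaving
  an inflated stub. Known limitation (shared with the tailing chemistry
  itself): template-encoded adenosines adjacent to the tail junction are
  absorbed into the tail, shortening the called RT-DNA.
* **Orientation** is called from adapter signatures on both strands, falling
  back to a leading poly-T run of ≥ 9 nt (the nine-T anchor image). Reads
  shorter than 15 nt after trimming are discarded. Ambiguous reads (probes
  of more than one retron) are excluded from profiles and counted in QC.

## Profiling

Reads are placed on the reference by an exhaustive ungapped scan over every
offset and both strands, keeping the placement with the fewest mismatches
(ties: lowest start coordinate, then reference-sense). Ungapped placement is
justified because the RT-DNA is a contiguous reverse transcript without
duplications or deletions; reads with a mismatch fraction above
`max_mismatch_frac` (default 0.1) are counted as unaligned. Coverage at a
position is the fraction of aligned RT-DNA reads covering it.

The **majority termination span** is the smallest contiguous window of
3'-end positions whose summed frequency strictly exceeds 50% (leftmost
window on ties). "Majority" is operationalized as strictly > 50% because no
published threshold exists; a precise terminator gives a span of ≤ 3 nt,
a point terminator exactly 1.

**Length profiles** report reads per length divided by total RT-DNA reads
for that retron; histogram bins are 1 nt internally (plot-level rebinning is
cosmetic). Condition comparisons report modal lengths, majority spans and a
Mann–Whitney test on the underlying per-read lengths.

## Statistics

The Mann–Whitney U uses midranks for ties. When `nA·nB ≤ 64` the two-sided
p-value is exact by full enumeration of rank assignments,
`p = min(1, 2·min(P(U≤u), P(U≥u)))`; otherwise a normal approximation with
tie correction and 0.5 continuity correction is used, and the method is
recorded in the result. No multiple-testing correction is applied across
retrons; each comparison is reported per panel. The terminal-base tally is
tested against the equimolar expectation with a chi-square test.

## Synthetic data: what it emulates and what it does not

The generator's defaults encode the study conditions: 3' tail lengths are
discretized-normal (mean 25, sd 5, floor 5) matching the ~25-adenosine
tailing aim; substitution errors only (no indels, no quality-score realism,
no PCR duplicates); constant quality strings, because the analysis applies
no quality filtering; both read orientations at a configurable mix;
molecules are emitted debranched, with an optional parameter for residual
untrimmed 5' bases (default 0). The "+RNase H1" preset terminates at the
canonical site (point mass, or a small-sd discretized normal); the
"−RNase H1" preset mixes a broad component (sd 4 nt) around the canonical
site with a component shifted toward the template 5' end, emulating
read-through. The true in-vivo termination distribution without RNase H1 is
unknown, so the broad preset is illustrative: tests validate *parameter
recovery* under a known ground truth, not distributional realism, and
passing them shows the pipeline is faithful, not that real libraries are
error-free.

The synthetic study references (`synthetic_reference`) draw the msd region
from {A, C, G} by default, so the RT-DNA contains no adenosine and every
tail junction is unambiguous — the same condition under which the V-anchor
chemistry itself reads lengths exactly. The example study references carry
an 85-nt canonical RT-DNA (the refined Eco1 length: one base shorter than
the historically reported 86) and a 45-nt RT-DNA (Eco6, three bases shorter
than the literature's 48), with 20 nt of template padding beyond the
termination site so read-through can be simulated. A classification
guarantee (no cross-retron assignments) additionally requires that no probe
of one retron lies within Hamming distance 2 of any 10-mer of another
retron's RT-DNA; the probe helper does not enforce this across references,
so multiplexed designs should verify it.

All generators consume a single seeded NumPy generator with a fixed draw
order (tail lengths, then orientations, then per-read errors), so output is
byte-identical across machines for a fixed seed.

## Phenotype metrics

Toxin neutralization is `(OD600_full_ind / OD600_full_unind) /
(OD600_acc_ind / OD600_acc_unind)`; phage sensitivity is `PFU/mL(full
operon) / PFU/mL(ncRNA/RT)`, with `PFU/mL = plaques / (volume_mL ×
dilution_factor)`. Both are computed per paired biological replicate and
summarized as mean ± SD; pooling before ratio-taking would bias the ratio
and is deliberately avoided. Sensitivity above 1 is reported as-is.
Replicate pairing must be explicit in the input table (a `replicate`
column); OD noise is simulated as mean-preserving lognormal, plaque counts
as Poisson.

## Problem sizes and numerical choices

The validation suite runs 10,000-read round-trips (exact histogram recovery
at error 0; total-variation distance < 0.05 at error 0.01), 100 seeded
replicates of 200 molecules for the termination-span contrast, 4,000-read
spike-in tallies, and 200-replicate phenotype recoveries — sizes at which
every binomial/CLT bound in the tests is comfortably discriminating.
Degenerate inputs are rejected early with typed errors (configuration,
validation, empty input) that the CLI maps to distinct exit codes.

## Known limitations

* Terminal template adenosines are absorbed into the poly-A tail (above).
* Ungapped placement can differ from gapped assemblers at read edges for
  real, indel-containing reads; modal calls are robust, base-level edge
  coverage may not be.
* The probe sequences for real retrons are user configuration; they are not
  bundled, and classification quality depends on their specificity.
* No paired-end, UMI, or quality-based logic; the assay is single-read.
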