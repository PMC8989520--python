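# retroterm

Quantitative profiling of retron RT-DNA termination from multiplexed
sequencing reads.

Retrons are bacterial retroelements whose reverse transcriptase (RT) copies
part of a structured non-coding RNA (a1/msr/msd/a2) into a short
single-stranded RT-DNA (~40–160 nt) that terminates at a precise site —
precision that depends on host RNase H1 and matters for retron-based phage
defense. `retroterm` is for researchers who sequence these RT-DNA
populations (3'-poly-A tailed, adapter-flanked single-read libraries) and
want reproducible answers to: how long are the molecules, where do they
start and stop on the template, how tight is termination, is the tailing
chemistry biased, and how strong are the cellular phenotypes?

The package provides:

* **read processing** — adapter and poly-A trimming, canonicalization to
  RT-DNA sense, and retron assignment by three fuzzy 10-mer probes per
  retron (Hamming distance ≤ 1);
* **profiling** — length distributions normalized as reads-per-length /
  total RT-DNA reads; ungapped minimal-mismatch placement on the reference;
  per-nucleotide coverage fractions; 5'-start and 3'-end histograms; and the
  **majority termination span**: the smallest contiguous window of 3'-end
  positions holding a strict majority of molecules (≤ 3 nt for a precise
  terminator, 1 for a point terminator);
* **statistics** — Mann–Whitney U on length distributions (exact two-sided p
  by full enumeration when n<sub>A</sub>·n<sub>B</sub> ≤ 64, tie- and
  continuity-corrected normal approximation otherwise) and the terminal-base
  bias tally for equimolar 4-oligo spike-ins (Levenshtein ≤ 2 with the
  terminal base wildcarded, chi-square against equimolarity);
* **phenotype metrics** — toxin neutralization
  (OD600<sub>full,ind</sub>/OD600<sub>full,unind</sub>) /
  (OD600<sub>acc,ind</sub>/OD600<sub>acc,unind</sub>), PFU/mL conversion,
  and phage sensitivity PFU<sub>full operon</sub>/PFU<sub>ncRNA/RT</sub>
  (1 = no defense, 0 = total defense), per paired biological replicate;
* **a seeded synthetic-data generator** that emulates the library chemistry
  (configurable 5'-start/3'-end distributions, ~25-nt poly-A tails, nine-T +
  V-anchor second-strand image, both orientations, substitution errors) with
  per-read ground truth, so every stage is testable without downloads.

## Worked example

Simulate an Eco1-like element (85-nt canonical RT-DNA) under tight
("+RNase H1") and broad ("−RNase H1") termination, run the full pipeline,
and compare:

```python
from retroterm import *
from retroterm.simulate import (
    DEFAULT_ADAPTER_A, DEFAULT_ADAPTER_B, LibraryConfig, MoleculeConfig,
    preset_minus_rnaseh1, preset_plus_rnaseh1, probes_for_reference)
from retroterm.reads import ReadRecord, process_reads

ref = synthetic_reference("Eco1syn", 85, seed=7)
probes = probes_for_reference(ref)
profiles = {}
for label, (start, end) in [("plus", preset_plus_rnaseh1(ref, end_sd=0.8)),
                            ("minus", preset_minus_rnaseh1(ref))]:
    mols, truth = simulate_molecules(
        MoleculeConfig(2000, start, end, seed=42), ref)
    reads, _ = simulate_library(
        mols, LibraryConfig(substitution_error_rate=0.002, seed=43), truth=truth)
    trimmed, qc = process_reads([ReadRecord(i, s, q) for i, s, q in reads],
                                [probes], (DEFAULT_ADAPTER_A, DEFAULT_ADAPTER_B))
    profiles[label] = length_profile(trimmed, "Eco1syn")
    alns = [a for t in trimmed if t.retron == "Eco1syn"
            if (a := align_read(t, ref)) is not None]
    span_start, span_width = termination_span(end_site_profile(alns, ref).end_hist)
    print(f"{label}: modal length {profiles[label].modal_length} nt, "
          f"majority span {span_width} nt, "
          f"{qc['classified']}/{qc['n_in']} reads classified")

report = compare_conditions(profiles["plus"], profiles["minus"])
print(f"modal difference {report.modal_difference} nt, "
      f"Mann-Whitney p = {report.mann_whitney.p_two_sided:.3g} "
      f"({report.mann_whitney.method})")
```

prints

```
plus: modal length 85 nt, majority span 2 nt, 2000/2000 reads classified
minus: modal length 85 nt, majority span 10 nt, 2000/2000 reads classified
modal difference 0 nt, Mann-Whitney p = 5.97e-109 (normal-approximation)
```

Read this as: with tight termination the majority of molecules end within 2
bases; without it the majority span blows out to 10 bases and the length
distribution shifts (the modal length can stay put while the distribution
broadens — exactly why the span statistic, not the mode, measures
termination precision).

The same stages are available from the shell via the `retroterm` CLI
(`simulate`, `profile`, `compare`, `bias`, `phenotype`), which writes
plain-text TSV/JSON outputs plus a manifest (config snapshot, version,
seeds, input checksums) for bit-identical re-runs.

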