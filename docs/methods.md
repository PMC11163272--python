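# Methods

This note records the models, conventions and numerical choices behind
`amirkit`, and what the synthetic-data tests do and do not establish
about real data.

## Sequence model

Sequences are identified strings over {A, C, G, T, U} with an explicit
DNA/RNA alphabet. T and U are treated as equivalent for matching and
complementation: comparisons canonicalize RNA→DNA, and the duplex
consensus's `[AUT]` class collapses onto {A, T}. Coordinates are 0-based
half-open internally; 1-based positions appear only in reports (e.g. the
scaffold's "nt 10 and 11"). Lowercase input is accepted and uppercased.
IUPAC ambiguity codes are rejected rather than expanded.

## Candidate scan

A candidate is a 23-nt window whose 1-based positions 3, 12 and 21 carry
[CG], [AT], [AT] respectively, containing no homopolymer run ≥ 4 (checked
on the full window), with GC content inside 45–50% inclusive. GC is
computed on the 21-nt sense by default; a switch computes it on the full
window. Since 100·g/21 ∈ [45, 50] forces g = 10, every emitted candidate
has GC = 47.62% — the band is a one-point lattice at this length, which
the acceptance checks exploit.

Where the 21-mer sits inside the 23-nt window is a convention: default
offset 1 (centered), configurable 0–2. Published designs do not determine
the mapping (their flanks are unknown), so no consensus compliance is
asserted for them; conversely every filter is independently toggleable so
a known guide that violates a rule (one reference guide has GC = 42.9%)
can still be pushed through the downstream stages. Overlapping windows
are all reported; region restriction is by user-supplied target
intervals. `validate_candidate` re-derives every rule from the raw
sequence and serves as the scan's oracle in the tests.

## Terminal thermodynamics

Stack-only sums of RNA Watson–Crick nearest-neighbor ΔG°37 increments
(Xia et al. 1998; 16-entry table shipped as
`amirkit/data/nn_rna_dg37.tsv`, kcal/mol). `Es` sums the first
`terminal_window_bp` steps (default 5, spanning 6 bp) of the sense
strand read 5′→3′; `Eas` the same at the 5′ end of the reverse
complement. The acceptance rule is `Eas < Es` with
`Δ = Eas − Es ∈ [−5, −3]`: the antisense-5′ end of the duplex must be
the more stable (more negative) one by 3–5 kcal/mol. Δ is interpreted as
a free-energy difference; window length, units and parameter set are
explicit configuration, and the band is honored as a filter contract on
whatever Δ the configuration produces rather than as a calibrated
physical claim. Duplex initiation, terminal-AU penalties and dangling
ends are omitted — the filter compares two ends of one duplex, where the
initiation term cancels exactly. The table is symmetric under
reverse-complement of the dinucleotide (one stack, two reads), which the
tests assert; a consequence used in testing is that swapping strand roles
(reverse-complementing the sense) swaps Es↔Eas and negates Δ.

## Off-target screen

The screen measures the longest contiguous exact match between a
candidate and every transcript in a supplied FASTA, in two orientations:
the candidate itself and its reverse complement (the site a guide could
pair with). Gapped or mismatched alignment is deliberately not modelled;
the thresholds are phrased in contiguous nucleotides, and exact matching
is the conservative desk-scale reading. Candidates are discarded when the
match exceeds 17 nt (strict: 17 survives, 18 does not); intended target
transcripts are excluded by ID. Scrambled controls are seeded
permutations of the guide accepted when their match is strictly below
15 nt; the scramble loop also rejects runs ≥ 4 (not required of controls
but it prevents degenerate ones; toggleable) and reports the best failed
attempt if the budget (default 1000 draws) is exhausted.

The implementation is a diagonal-run dynamic program vectorised over the
subject (O(21·n) per subject, exact); a 50-kb screen takes milliseconds,
so no seeding heuristic is needed. Correctness is defined by equivalence
with a classic longest-common-substring DP, asserted on hundreds of
random instances.

## Scaffold assembly

Constructs follow `5′arm – antisense(21) – loop(19) – sense(19) – 3′arm`;
the sense strand is revcomp(antisense) with 1-based positions 10 and 11
deleted. The arms are defined *operationally* as the longest common
prefix (73 nt) and suffix (90 nt) of the three reference constructs
shipped in `amirkit/data/mir155_constructs.fasta`; whether they contain
vector cloning adapters is not resolved here — they are opaque verbatim
flanks. Construct length is constant at 222 nt.

`infer_deletion` recovers the deleted pair by trying all 20 adjacent
pairs. Sequence repeats make the answer ambiguous for all three reference
constructs (e.g. the `TGTG` repeat in one sense strand admits four valid
pairs, the smallest being (9, 10)); the tie-break therefore prefers the
scaffold's canonical pair (10, 11) whenever it is among the valid pairs
and falls back to the smallest otherwise. A pure smallest-pair rule would
misreport the canonical deletion for every shipped construct, which is
why preference, not order, is the primary criterion.

## Spike-train processing

* **Filter**: zero-phase (forward–backward) 3rd-order Butterworth
  band-pass, 300–6000 Hz, on ≥ 20 kHz traces.
* **Detection**: threshold at 5 SD from the mean of the filtered trace.
  Polarity is negative by default (extracellular somatic convention);
  an absolute-deviation mode covers positive-going events. Each
  supra-threshold excursion yields one event at its extremum; events
  within 1 ms of an accepted event are discarded. At 5 SD the Gaussian
  false-positive expectation on pure noise is ≈ 0 (the tests allow ≤ 2
  in 10 s).
* **Clustering**: seeded k-means on the leading 3 principal components
  of the waveform matrix. Aggregation/merging of clusters beyond k-means
  is out of scope; curated spike-to-unit labels can be passed in
  directly.
* **Trough-to-peak**: global trough to the maximum that follows it, with
  3-point parabolic sub-sample refinement (off → sample resolution);
  undefined (NaN) for flat/monotone waveforms or a peak not contained in
  the window. Classification is strict: > 440 μs → putative pyramidal,
  otherwise putative interneuron; NaN → unclassified.
* **Raster**: 1-ms binary bins, multiple spikes per bin collapse to 1.
* **Autocorrelogram**: pair counts at lags 1..50 ms on the raster. Lag 0
  is excluded — self-pairs are uninformative and would pin the half-mass
  lag at zero.
* **Burstiness**: Δt is the smallest lag whose cumulative count reaches
  half the 50-ms total (ties break toward smaller Δt, at the raster's
  native 1-ms resolution, no interpolation); BI = (50 − Δt)/50 ∈
  [0, 0.98]. BI is NaN (undefined, not 0) when no spike pairs fall
  within 50 ms. A flat autocorrelogram gives BI = 0.5 exactly; all mass
  at lag 1 gives 0.98.

## Synthetic data

Generators are pure functions of a plan with one explicit integer seed;
no global RNG state. Internal sub-streams are derived with non-zero
spawn constants so a plan seed never aliases a user's plain seed.

* **Transcriptomes**: uniform-composition background (configurable) with
  each plant inserted as the centered `match_len`-substring of its site
  and flanking bases forced to mismatch, so the planted match cannot
  extend; generation retries with a derived sub-seed until an
  exact-match oracle confirms every plant measures exactly its planned
  length.
* **Target genes**: compliant 23-nt windows planted at non-overlapping
  positions; a deterministic repair loop then breaks every spurious
  passing window by flipping one base's GC class outside planted
  footprints (windows shifted 1–2 nt into a plant are handled by
  redrawing that plant), so the scan recovers the plants exactly — with
  zero plants the loop guarantees an empty scan.
* **Recordings**: sum of per-unit biphasic templates (negative then
  positive lobe; half-sine lobes by default, quadratic-lobe option whose
  extrema parabolic refinement recovers exactly) at generated spike
  times, plus Gaussian noise. Firing models: homogeneous Poisson with a
  1.5-ms minimum gap, or Poisson burst onsets with fixed intra-burst
  spacing (default 3 spikes at 3 ms). Ground truth lists every spike
  with its unit, planned trough-to-peak and class.

Default study conditions used in the tests and the acceptance script:
20 kHz sampling, 60-s recordings, noise SD 1, two units at 8× and 12×
noise SD (SNR ≥ 8) with 300 μs/bursty and 550 μs/Poisson profiles, ≈ 5 Hz
mean rates; 2-kb design targets with 5 planted windows; 500-duplex pools
for the asymmetry stage; 50-kb transcriptomes for scramble screening.
These sizes make the whole suite run in seconds while leaving every
bound sharply testable; they are scaled-down stand-ins, not replicas of
any particular experiment.

What passing does **not** show about real data: real transcriptomes are
not composition-uniform (repeats and paralogs make long off-target
matches far likelier than in random backgrounds); real spike waveforms
vary within a unit, overlap, and drift, and real noise is not white
Gaussian — detection and clustering scores here are upper bounds on
field performance. The full published selection funnel (five candidates
from a real transcript, narrowed by BLAST against human and mouse) and
any wet-lab effect sizes are outside what synthetic inputs can
reproduce; the package substitutes sharp property contracts (bounds,
oracle equivalences, parameter recovery) for those endpoints, and
supports — but does not test — running the screen on real FASTA
transcriptomes.

## Numerical and policy details

* GC bounds inclusive; off-target discard strict (> 17); scramble bound
  strict (< 15); classification strict (> 440 μs).
* The classification sweep reports measured trough-to-peak rounded to
  0.1 μs before applying the strict boundary, which is twelve orders of
  magnitude above the refinement's float error and three below the
  sweep's 1-μs grid.
* `end_energy` requires `len ≥ terminal_window_bp + 1` (a w-step window
  spans w+1 bases).
* FASTA I/O via Biopython; duplicate IDs warn and keep both records;
  empty files are errors.
* k-means and PCA are seeded (`kmeans_seed`, default 0); identical
  inputs give identical labels.
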