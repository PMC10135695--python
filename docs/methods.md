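# Methods

## Model and procedure

The codec is transform coding with per-block subset selection. A signal
of length `L` is partitioned into `⌈L/N⌉` blocks of `N` samples, the
last block zero-padded (the pad count travels in the container header
and is stripped before any metric is computed). Each block is mapped to
Haar coefficients by `T = B Aᵀ` with the orthonormal `N×N` Haar matrix
`A`, `SS` coefficient positions are retained per block, the rest zeroed,
and the inverse `R = T A` reconstructs the block. The retained positions
minimize the block PRD; by Parseval this equals
`√(Σ_{i∉S} Tᵢ² / Σ B²) × 100`, so minimizing PRD is exactly maximizing
retained coefficient energy, and the `SS` largest-magnitude coefficients
are the global optimum. That identity is what makes the stochastic
selector verifiable: brute-force enumeration and magnitude thresholding
ship as first-class `selection_mode` oracles, and the test suite checks
that the metaheuristic reaches their optimum on small blocks rather than
trusting it.

### Haar normalization

Classical presentations of the Haar kernel differ in scaling (entries
like 1/8, 1/4, 1/2 appear when rows are normalized by `1/N` instead of
in Euclidean norm). This package uses the **orthonormal** convention —
constant row `1/√N`, wavelet amplitudes `±2^{j/2}/√N` — because it is
the only choice under which `T = B Aᵀ` and `R = T A` are exact mutual
inverses and coefficient energy equals signal energy; the sign/support
pattern of the rows is unaffected. Rows `i ≥ 2` are generated from the
dyadic decomposition `i = 2ʲ + k − 1` (dilation level `j`, translation
`k`), evaluated at cell midpoints `(x + ½)/N` to avoid boundary
ambiguity.

### The optimizer

COVIDOA is a population metaheuristic over the box `[lb, ub]^D`; in the
codec `D = SS`, `lb = 1`, `ub = N`, and a genome decodes to coefficient
positions. Per iteration, for each population slot: a parent is chosen
by tournament; `num_proteins` proteins are produced by +1 frameshifting
(first `shift_count` genes fresh uniform draws, the rest the leading
parent genes); uniform crossover merges them gene-by-gene into a virion;
per-gene mutation replaces each gene with a fresh uniform draw with
probability `MR`; the virion replaces the parent slot only on strict
improvement. Strict (not `≤`) replacement avoids neutral drift and makes
ties deterministic. The best-so-far trace is therefore non-increasing by
construction, and the evaluation budget is exactly
`popSize × (1 + MaxItr)`.

Open points resolved as package design choices:

- **Tournament size**: COVIDOA descriptions call for tournament
  selection without fixing a size; binary (size 2) is the conventional
  minimum and is configurable.
- **Mutation gating**: COVIDOA is variously described with a
  whole-virion mutation gate (`rand < MR`) or a per-gene replacement
  rule; the per-gene rule is implemented (every virion passes through
  per-gene mutation). At the default MR = 0.5 the two readings explore
  similarly.
- **Virions per parent**: one per population slot per iteration; the
  "millions of copies" replication narrative is biological flavor.
- **Degenerate frameshift (D = 1)**: a +1 shift would erase the entire
  genome, so the standalone operator rejects `shift ≥ D`; inside the
  main loop the protein degenerates to a fresh uniform draw — the
  natural limit of "first s genes random, rest shifted" — so that
  `SS = 1` compression is well defined.
- **Population update** is synchronous within an iteration: parents are
  drawn from the iteration-start snapshot; replacements land in the
  population as they occur but selection pressure within the iteration
  comes from the snapshot.

### Genome decoding

The genome-to-subset mapping is not dictated by the method definition
and is this package's choice: entries are rounded half-up, clipped to
`[1, N]`, and duplicates repaired deterministically by substituting the
smallest unused position, so every genome decodes to exactly `SS`
distinct sorted positions. Deterministic repair keeps the objective a
pure function of the genome, which the reproducibility guarantees rely
on.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `block_order N` | 64 (CLI) | block length; {2,4,8,16,32,64} supported |
| `subset_size SS` | — | retained coefficients per block, 1..N |
| `population_size` | 30 | optimizer population |
| `max_iterations` | 50 | optimizer iterations per block |
| `num_proteins` | 2 | proteins per parent |
| `shift_count` | 1 | frameshift magnitude |
| `mutation_rate` | 0.5 | per-gene mutation probability, valid range [0.005, 0.5] |
| `seed` | 0 | master seed |

Per-block optimizer seeds are derived as
`(master_seed XOR block_index·0x9E3779B1) mod 2³¹`, so blocks are
independent streams and a whole run is bit-reproducible from one seed;
identical seeds yield bit-identical containers.

## Metrics

- **PRD** uses the raw-signal baseline exactly — no mean removal and no
  amplitude offset. The mean-removed variant ("PRDN") common in the ECG
  literature is deliberately not provided, to keep a single unambiguous
  error number. An all-zero original makes PRD undefined (error); an
  all-zero *block* inside the optimizer objective is defined as PRD 0,
  since any subset reconstructs it perfectly.
- **CR** is reported as the sample-count ratio `N_O/N_R` (e.g. 64/2 = 32
  at the highest supported reduction). A real bitstream must also store
  the retained positions, so `bit_level_cr` provides a secondary
  accounting charging `index_bits + value_bits` per retained
  coefficient against 11-bit original samples (the common ECG ADC
  depth); it is clearly labeled and never mixed with the headline CR.
- **NCC** is the Pearson-form normalized cross-correlation, clipped to
  [−1, 1] against floating-point overshoot; constant inputs are an
  error (zero variance).
- **QS = CR/PRD**; undefined at PRD = 0, where the report says
  "lossless" instead.

## Synthetic data

`generate_ecg` sums five Gaussian bumps per beat (P, Q, R, S, T) at
fixed phase offsets within the beat period, plus white Gaussian noise;
beat centres sit at `(k + ½)·period` so R peaks are interior maxima and
exactly countable. Defaults: 360 Hz sampling, 60 bpm, noise σ = 0.02
(in R-amplitude units of 1) — enough to give every 64-sample block
nonzero energy so PRD denominators are safe. `generate_eeg` sums band
sinusoids (default 10 Hz alpha at amplitude 1 and a weaker 20 Hz beta
component) over `1/f^β` Gaussian noise (β = 1, the canonical EEG
background spectrum), 160 Hz sampling. Both are deterministic per seed.
Two short fixture CSVs generated by these models (filenames prefixed
`synthetic_`) are committed so I/O tests run without invoking the
generators.

What the generators do **not** emulate: arrhythmic or otherwise
pathological morphology, baseline wander, electrode artifacts,
multi-channel structure, quantization to an integer ADC grid, and
non-stationary spectra. Passing tests therefore demonstrate the codec's
transform/selection machinery and its optimality properties, not
clinical fidelity on real recordings; real data can be supplied as CSV
or (optionally) WFDB records.

## Numerical choices and degenerate inputs

- Orthonormality tolerance 1e−12; round-trip tolerance 1e−10 (both
  comfortably above double-precision error for N ≤ 64).
- Rounding is half-up everywhere a real becomes an index
  (`floor(x + 0.5)`), matching the subset-size formula's Round.
- Zero-padding for the final partial block; pad value 0.
- Container: little-endian binary, magic `HWCO`, u8 positions (1-based)
  and f8 coefficient values per block; an equivalent JSON dialect is
  read and written for debugging. Malformed containers (bad magic,
  truncation, out-of-range or duplicate positions) raise a format error
  naming the offending block.
- The problem sizes exercised by the default test run — 1000 random
  blocks per order for transform checks, 100 blocks per subset size at
  N = 8 for the optimizer-optimality sweep, a 10-second synthetic ECG
  for the N = 64 monotonicity sweep — were chosen so the whole suite
  completes in about two minutes on one CPU while still estimating the
  optimality rate to a few percent.

## Known limitations

- No entropy coding or coefficient quantization: the container stores
  raw float64 values, so the bit-level CR is poor even when the
  sample-count CR is high. Quantization is the natural next step and is
  out of scope here.
- The optimizer's optimality is verified exhaustively only for N = 8;
  at N = 64 the search space C(64, SS) is astronomically larger and the
  metaheuristic is best-effort (the magnitude selector provides the
  optimum there if desired — at which point the metaheuristic is a
  research baseline rather than the fastest route).
- Single-channel only; streaming and multi-lead compression are out of
  scope.
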