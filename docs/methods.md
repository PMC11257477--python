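# Methods

## The transcription-cycle model

A gene is discretized into 120 bp compartments: an optional UAS (STM class
only), a promoter, `n` transcript bins (default 10 → 1200 bp, the median
transcribed length in budding yeast), and a terminator. The state of a gene
is (UAS occupied?, promoter substate ∈ {empty, awaiting-TFIIH,
PIC-complete}, per-bin occupancy, terminator occupied?). Transitions and
their first-order rate constants (s⁻¹):

| transition | rate | gated by |
| --- | --- | --- |
| UAS association / dissociation | k1 / k−1 | STM only; UAS empty / occupied |
| UAS → promoter transfer | k2 | STM; UAS occupied, promoter empty |
| promoter → UAS reversal | k−2 | STM; awaiting-TFIIH, UAS empty |
| direct promoter recruitment | k3 | TFO only; promoter empty |
| promoter dissociation | k−3 | awaiting-TFIIH only |
| TFIIH arrival | k4 | awaiting-TFIIH |
| initiation | k5 | PIC-complete, first bin empty |
| per-bin hop | (k6/60)/120 | bin occupied, next bin (or terminator) empty |
| terminator release | k7 | terminator occupied |

Modeling commitments where the underlying biology leaves room:

- **Exclusion is disabling, not reject-and-retry.** A blocked move has
  propensity zero, the standard continuous-time Markov chain / TASEP
  convention; every enabled transition stays a Poisson process.
- **The promoter is a two-substate machine and k4–k7 are irreversible.**
  Dissociation (k−3) and reversal (k−2) act only while awaiting TFIIH.
  After TFIIH arrival the sole exit is initiation; if the first bin is
  occupied the polymerase waits (it does not abort).
- **Reversal requires an empty UAS** — a consequence of exclusion.
- **k6 is stored as a speed** (bp·min⁻¹) and converted per architecture;
  1000 bp/min over 120 bp gives a hop rate of 0.13889 s⁻¹.
- **Initial state is the empty gene**; the 1000 s burn-in (≫ the slowest
  relaxation time at the default rates) handles equilibration before the
  60 s recording window, which matches the duration of the cleavage
  reaction that produced the data this model class is compared to.
- **Occupancy attribution:** both promoter substates count as promoter
  occupancy; the terminator compartment is reported as the 3'UTR.

## Parameters

Fixed rates (published measurements): k1 = 0.002, k−1 = 0.003,
k3 = 0.002 (no direct measurement; the UAS association value is reused),
k5 = 0.1 (TFIIH residency), k6 = 1000 bp/min (midpoint of 1–3 kb/min),
k7 = 0.037 s⁻¹ (terminator dwell ~30 s, at the boundary of the published
0.009–0.034 range; 0.0614 in the amino-acid-starvation fitting context).
Free rates and their fitted functional ranges (cleavage-based fit): k2
0.03–0.2, k−2 0.0–0.15, k−3 0.0–0.03, k4 0.0075–0.09 s⁻¹. `RateSet.stm()` /
`.tfo()` default each free rate to a representative midpoint — geometric
for strictly positive ranges, arithmetic for ranges anchored at zero.

`SimulationProtocol` defaults: 1000 s total, 60 s recording window, 1000
genes. Publication-scale averages use 10⁵ genes; standard errors scale as
1/√n and nothing else changes, so desk and test runs use 500–2000 genes.

## Engines, random numbers, and the exact oracle

The hot path is a numba-compiled batch kernel; `gillespie_step` /
`simulate_gene` are a pure-Python reference implementation of the same
process kept for inspection and unit-level contracts. Per-gene substreams
derive deterministically from `master_seed + gene_index`, which makes
population averages independent of batching, lets every grid point share
one seed (common random numbers, so neighboring models differ through
their rates rather than through noise), and makes baseline/perturbed runs
exactly paired (the identity perturbation yields Δ = 0 bit-for-bit). The
two engines use different RNG streams and are validated against each other
through the oracle, not stream-matched.

The oracle (`analytic_steady_state`) enumerates the full state space
(2 × 3 × 2ⁿ × 2 states for STM; 12,288 at n = 10), restricts to states
reachable from the empty gene, finds the terminal communicating class and
solves πQ = 0 there. One probability is pinned to 1 and that state's
balance equation dropped, keeping the system sparse (the textbook
dense-normalization-row replacement causes catastrophic LU fill-in at this
size). Reducible chains (k7 = 0 with inflow) resolve to their absorbing
class; multiple terminal classes raise. Validation: at n = 60,000 genes
the kernel's per-compartment deviations from the oracle are all within
|z| < 2.5. Note that the per-compartment z statistic is only approximately
normal (60 s occupancy fractions are zero-inflated and skewed), so the
*maximum* |z| over many compartments and rate sets modestly exceeds
Gaussian expectations — around 3 is typical for 5 × 13 comparisons at
n = 2000.

## Fitting

Grids: log-spaced axes for strictly positive free rates, linear (anchored
at 0) for k−2 and k−3 whose fitted ranges include zero; 12 points per
dimension by default, 6 for desk-scale runs — the original analysis states
neither spacing nor resolution, so ensemble sizes are not comparable
across resolutions and are not a target. Model region vectors are L2-scaled
to the empirical vector (approximating the conversion to counts-per-million
units); cosine similarity is scale-invariant, so this affects reporting
only. Ensembles keep every model with similarity > 0.995; an empty
ensemble is returned with the ten best-scoring models attached as a
diagnostic (the behavior crosslinking-derived occupancy produces). The
transcript region value is the arithmetic mean over bins (equal-length
bins, so also the per-bp mean). Between-gene standard errors ignore
within-trace autocorrelation and inter-bin correlation; both are
conservative simplifications documented here rather than corrected.

TFO fits free k3 alongside k−3 and k4. k3 has no fitted functional range
of its own, so its sampling/grid range borrows the published UAS
association range (0.0019–0.0027 s⁻¹), mirroring the convention that set
its point value.

## Perturbation analysis

The catalog (`data/perturbations.json`) stores each published perturbation
row verbatim: point entries become overrides, range entries (re-fitted
free-rate ranges) become per-member multipliers via the ratio of
representative range midpoints, preserving ensemble diversity while
landing members inside the printed ranges. Δ agreement is quantified as
cosine similarity between signed Δ region vectors — the original analysis
judged agreement visually; the numeric ranking is this package's
extension.

A structural finding from the exact oracle: for TFO genes, changing k3
rescales the whole occupancy vector without changing its direction, so the
Δ signatures of "↓k3" and "↓k3 + ↑k−3" are exactly collinear (cosine
1.000). Steady-state Δ *shape* cannot distinguish those two mechanisms —
consistent with both being reported as acceptable fits — and closed-loop
ranking is therefore only meaningful for candidate sets whose generating
spec is directionally separated from the alternatives (pairwise analytic
cosine < 0.99), which is how the ranking validation is run.

## Minimal dwell-time model

With a single polymerase cycling promoter → transcript → terminator →
promoter, renewal-reward gives compartment occupancy = mean dwell / cycle
time, cycle = T_p + L/(v/60) + T_t. The stochastic variant (exponential
dwells) converges to the same fractions. The default grid spans the
literature ranges — T_p ∈ {5,10,15,20} s × v ∈ {1000,2000,3000} bp/min ×
T_t ∈ {5,70} s, 24 combinations — and on it 22/24 combinations predict
higher promoter-than-per-bin-transcript occupancy and 20/24 higher
terminator occupancy. The published counts (21/21 of 24) came from an
unstated grid; the module reports counts for whatever grid it is given and
the per-bin comparison flag is exactly T_p·v/60 > bin length. A
whole-region comparison variant is available via `per_bin=False`.

## Genomic binning conventions

Coordinates are 0-based half-open internally; BED stays 0-based half-open,
GFF3 converts at the boundary. Region offsets (UAS −500..−151 and promoter
−150..+25 from the TSS; transcript +26 from TSS to −76 from TES;
terminator −75..+150 from the TES) are interpreted with offset 0 = the
anchor base in transcription direction, giving constant widths 350 / 176 /
226 bp; minus-strand genes are mirrored. Worked example: TSS = 1000,
TES = 3000, + strand → UAS [500, 850), promoter [850, 1026), transcript
[1026, 2925), terminator [2925, 3151). Genes whose transcript region would
be empty are skipped with a log entry. When annotation lacks transcript
ends, the median yeast UTR lengths (47 bp 5', 118 bp 3') extend the coding
interval. CPM normalization scales a raw track to a genome-wide sum of
10⁶ and is guarded against double application; background subtraction
requires matching CPM/CPMn units and produces a signed "delta" track.
Metagene profiles average replicates per base pair first, then bin three
transcription-oriented segments (1 kb upstream, body, 1 kb downstream)
into 100 bins each, then average across genes. Metasite profiles align
oriented sites ±250 bp and smooth with a sliding mean (window 10, step 5)
using only windows fully inside the flank — 99 output points; partial edge
windows are not emitted. An optional per-gene count threshold implements
the minimum-expression filter as a parameter, not a hard-coded rule.

## Synthetic data

The generator emulates the *structure* of the real inputs: non-overlapping
genes with ±1 kb clearance on one contig, strands ~50/50, one TATA-like
site 50 bp upstream of each TSS; coverage placed multinomially over gene
regions ∝ weight × length, uniform within a region; region vectors =
model occupancy × lognormal multiplicative noise (σ default 0.1; region
CPMn means are positive with roughly scale-proportional dispersion) + an
optional additive floor, scaled by a CPMn-like factor of 100 (arbitrary;
cosine-invariant). It does **not** emulate nuclease sequence bias,
replicate batch structure, fragment-length effects, or between-gene rate
heterogeneity within a class — so passing closed-loop tests demonstrates
correctness of the inference machinery under the model's own noise
assumptions, not robustness to every artifact of real sequencing data.
Every generator records a manifest (seed, rates, protocol) sufficient to
regenerate its output bit-for-bit.

## Validation suite sizes

Desk-scale problem sizes used by the test suite and acceptance script:
oracle agreement over 5 rate sets at 2000 genes; closed-loop recovery over
10 replicates per class with 6-point grids at 500 genes (σ = 0.05,
threshold 0.995); perturbation directions at 2000 genes with paired seeds;
ranking over 10 seeds at 1000 genes; binning round trip at 200,000 reads
over 30 genes. These sizes keep every standard error small relative to the
effects being checked while the whole suite runs in a few minutes on one
CPU.

## Known limitations

- One polymerase per 120 bp compartment is coarser than the ~35 bp RNAPII
  footprint; jamming is therefore overestimated at very high initiation
  rates.
- No nucleosome dynamics, no gene-gene interactions, no mRNA fate after
  release.
- Error bars on occupancy are between-gene only.
- Ensemble sizes depend on grid resolution/spacing and are reported per
  grid, never compared across grids.
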