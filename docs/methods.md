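# Methods

## Swap model

Each simulated cluster draws a true sample from the pool (configurable
abundances, equal by default). Independently for each adapter end, a swap
event occurs with probability p_i7 or p_i5; on an event the end's index is
replaced by a draw from the pool's indexes weighted by sample abundance.
This is a "free adapter" model: the mass of stray index oligo available for
spurious extension is taken to track library mass, and replacement by the
read's own index is allowed. A self-replacement leaves no observable trace
— which reproduces two real phenomena at no extra cost: detectable swap
rates grow with pool size (more of the replacement mass belongs to other
samples), and the estimator can only ever see the detectable fraction
p·(1 − w_self), where w_self is the read's own abundance weight (1/S for S
equal-abundance samples).

The two ends are independent; double swaps arise as the product of the
per-end events rather than through any dedicated mechanism. Default per-end
rates are p_i5 = 0.0302 and p_i7 = 0.0131 — the i5:i7 ≈ 2.3 ratio
estimated for a PCR-free mixture pool — and both are freely configurable.

### Covariate link

Swapped reads in real pools skew toward shorter inserts, lower GC and more
chimeric pairs. Only the directions of these effects are established, so
the simulator uses a logistic link with free coefficients:

    logit(p_end | read) = logit(p_end) + c_len · z(log insert) + c_gc · z(gc)

with insert length lognormal(μ_log = ln 350, σ_log = 0.35) (a typical
ligation-library insert distribution), GC ~ Beta(6, 8.6) (mean ≈ 0.41,
human-like), and z the standardization under those configured
distributions. Defaults c_len = −0.3, c_gc = −0.2 encode the observed
directions with moderate effect size; both must be treated as free
parameters, not measurements. Chimerism is Bernoulli with rate 0.01 for
unswapped and 0.05 for swap-event reads (direction-only choice as well).
Setting the coefficients to zero gives the exchangeable model used for all
rate-recovery checks.

### Sequencing layer

Index reads are 8 bp by default. Per-base substitution errors occur at
`index_error_rate` (default 0.001); error bases get Phred quality 11 and
all others 37, a deliberately two-level model that is sufficient to
exercise the mean-Q30 filter without simulating per-cycle decay. Tiles are
uniform over a (2 surfaces × 3 swaths × 24 tiles) grid, matching the
observation that swapping is spatially uniform across a lane. All
randomness comes from one numpy Generator seeded once and consumed in a
fixed order, so a configuration is byte-reproducible.

## Demultiplexing

Filter precedence is quality → per-end match → pair consistency, because
the order fixes the denominator of every rate:

1. Reads whose i7 or i5 index read has **mean** Phred < 30 are
   LOW_QUALITY and excluded from everything downstream (mean, rather than
   per-base minimum, is the declared reading of a "Q30 or greater" filter).
2. Each end is resolved against the sheet's per-end list allowing
   `max_mismatch` (default 1, safe for distance-≥3 sets). A query with no
   candidate within tolerance is NO_MATCH; with two or more qualifying
   candidates, AMBIGUOUS. Both fold into UNDETERMINED — conservative, and
   what keeps foreign (outside-pool) indexes out of all swap statistics.
3. Both ends resolving to the same sample → MATCHED; to different samples
   → SWAPPED with the two owners recorded.

A double swap onto another sample's complete pair classifies MATCHED; it is
indistinguishable at demultiplexing by construction and only surfaces in
the two-organism design. The swap rate is swapped / (matched + swapped):
all passing-filter reads whose high-quality index reads both match an index
used within the pool.

When the sheet's per-end minimum pairwise distance exceeds 2·max_mismatch,
an exact dictionary hit is provably the unique qualifying candidate, so the
linear scan runs only for inexact observations; sheets without that margin
use the full scan per read so the ambiguity contract stays exact.

## Attribution estimator

See README for the formulas. Design choices:

- Double swaps count toward **both** end totals; consequently
  est_i7 + est_i5 = U + K7 + K5 + 2D, an identity enforced exactly by
  computing with rational numbers and rounding only in reports (half-up,
  4 d.p., nearest integer for totals).
- Undetermined-end swaps are allocated by the raw K7:K5 ratio — no
  smoothing or prior. Allocation is undefined (an error, not a guess) when
  U > 0 with no known-end swaps.
- Organism labels are taken from simulation truth or a user-supplied
  annotation; the package does not align reads, mirroring the working
  assumption that every read maps to its organism of origin. Exactly two
  organism labels are supported; more is an error.
- When independently tallied total-swapped / total-PF counts are supplied,
  p(Total Swap) uses them and the report also carries the component-based
  rate and the discrepancy between the two, rather than silently choosing.

The population contrast (insert length, chimerism, GC spectrum of swapped
vs. non-swapped reads) bins GC at width 0.05 over [0, 1], normalizes each
population's histogram to sum 1 and reports the ratio to the non-swapped
histogram; empty populations report NaN, never zero.

## Index set design

Validation checks, in order: per-end uniqueness, per-end minimum pairwise
Hamming distance (default 3, allowing confident single-mismatch
correction on 8-mers), GC within [0.25, 0.75], homopolymer runs ≤ 2, and —
opt-in — per-cycle color balance. Balance is evaluated per end (I1 and I2
are separate reads): two-color chemistry treats G as dark and requires at
least one base in {A, C} (red) and one in {A, T} (green) at every cycle;
four-color requires one of {A, C} and one of {G, T} (laser pairs). Balance
is off by default because it is a set-level property that small sets cannot
satisfy (a single 8-mer cannot cover both four-color laser pairs at any
cycle); the predicates are data, so other channel conventions can be
swapped in.

The designer is seeded rejection sampling with greedy accumulation
(budget 10,000 proposals per slot, whole-search restart if set-level
validation fails), designing the i7 and i5 lists independently since swaps
are within-end phenomena. Simple, reproducible, and ample for n ≤ 96 at
the default constraints.

## What the simulator does and does not emulate

It emulates: within-pool replacement (so foreign-index contamination is
absent by construction), per-end rates and their covariate tilt, index
sequencing error with quality, uniform tile geometry, and the two-organism
mixture design. It does not simulate genomic read sequences, alignment or
mapping error (organism truth is exact, so attribution results here are an
upper bound on real-data behaviour where mapping errors add noise),
amplification kinetics, per-cycle quality decay, flow-cell-to-flow-cell
rate variability, or outside-pool contamination. Passing recovery tests
therefore demonstrates correctness of the counting and allocation logic
under the stated model, not robustness to misalignment or instrument
artefacts.

## Problem sizes and numerical choices

Recovery checks run at n = 10⁶ reads with 12 + 12 samples over seeds 1–5;
at the default rates this gives binomial standard errors of about 1.7×10⁻⁴
on the detectable i5 probability, tight enough to resolve the 2:1 end
asymmetry cleanly. Unit and property tests use 10³–2×10⁵ reads. Count
tables use int64; estimator internals are `fractions.Fraction`; swap-rate
comparisons in tests use three-binomial-SE bounds rather than fixed
tolerances wherever the quantity is stochastic. Degenerate inputs are
errors, not defaults: empty index sets, zero qualifying reads for a rate,
allocation without known-end counts, and more than two organisms all raise.
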