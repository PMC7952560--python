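# Methods

## Fluctuation analysis

### Model

A culture grows from a small mutant-free inoculum N₀ to N_t cells.
Mutational events occur during growth at rate μ per division, so the
expected number of events per culture is m = μ(N_t − N₀) ≈ μN_t.  An event
at a random time founds a clone that keeps doubling until plating, so the
number of mutant *cells* per culture follows the Luria–Delbrück
distribution: a compound Poisson whose clone-size law is q_j = 1/(j(j+1)).
The package evaluates its pmf with the Ma–Sandri–Sarkar recursion

p₀ = e⁻ᵐ,  p_r = (m/r) Σ_{i=0}^{r−1} p_i/(r−i+1),

which is algebraically identical to that compound Poisson.

### Estimators

* **MSS-MLE** (`mss_mle`): maximises Σ_j log p_{r_j}(m).  The likelihood is
  unimodal in ln m; the optimum is located with bounded scalar minimisation
  (Brent) over [max(10⁻⁶, P₀ seed), 10·(mean count + 1)].  All-zero counts
  return the boundary maximum m̂ = 0 (a legitimate low-rate outcome, not an
  error).  Counts above a configurable cap (default 10,000) contribute the
  upper-tail mass 1 − Σp_r to the likelihood, so jackpot cultures stay
  finite to handle without evaluating an enormous pmf.
* **P₀ method** (`p0_estimate`): m̂ = −ln(fraction of zero-count cultures);
  undefined (raises) when no culture is mutant-free.

### Confidence intervals

Stewart's large-sample approximation: σ_ln m = 1.225 · m̂⁻⁰·³¹⁵ / √C, with
symmetric 95% bounds exp(ln m̂ ± 1.96 σ).  Some fluctuation calculators
apply an asymmetry correction that multiplies each half-width by
(e^{1.96σ})^{∓0.315}; this is available behind `asymmetric=True` but the
symmetric form is the default.  CI endpoints scale with m̂ when converted
to rates.  Simulated coverage at C = 24 sits near 0.95 across m ∈
{0.5, 2, 8} (checked in the test suite over 500 replicates per m).

### Rates and corrections

μ = m̂ / N_t (per division) by default; a per-generation variant
m̂/(N_t ln 2) is available behind `per_generation=True`.  The partial
plating correction is **off by default** — when only a fraction z of each
culture is plated, m̂ then estimates plated events and μ is a comparative
proxy.  When enabled, the Stewart (1990) factor m = m_plated·(z−1)/(z ln z)
is applied (→ 1 as z → 1).

## Synthetic fluctuation data

`simulate_fluctuation` draws Poisson(m) events per culture; each event's
clone size is ⌊1/U⌋ with U uniform — the discrete clone-size law
q_j = 1/(j(j+1)) that arises when event times are uniform with respect to
exponential population growth.  This matches the MSS pmf *exactly*, which
is what makes the generator a valid oracle for the estimators (empirical
total-variation distance < 0.01 at 10⁵ cultures).

A `synchronous=True` variant implements the textbook idealisation of
synchronous doublings, where clone sizes are exact powers of two.  It is
**not** the default because its count distribution deviates measurably
from the MSS pmf (total variation ≈ 0.09 at m = 2): the power-of-two
clone-size law puts weight 2⁻ʲ⁻¹ on size 2ʲ instead of spreading it as
1/(j(j+1)).  The asynchronous model is the one the MSS recursion actually
describes.

No cell death, no post-plating growth, and no variation of N_t across
cultures are modelled.

## Mutation spectra

### Pileups and frequencies

Base calls with Phred quality < 35 (configurable) are removed before
tallying; frequencies are f_B,i = N_B,i / (N_A,i + N_C,i + N_G,i + N_T,i).
Zero-coverage positions are masked, never zero-filled, so windowed means
are taken over observed positions only and are not deflated.  All counts
are reported on the reference strand: C>T and G>A are distinct classes
(the deaminase acts on different strands), never re-complemented.
Coordinates are 1-based and windows inclusive everywhere.

### Moving average

For each position, the up-to-(2w+1)-member window (w = 10 default) is
gathered, members further than k = 3 window-local standard deviations from
the window mean are excluded in a single pass, and the unweighted mean of
the survivors is the trend.  Windows shrink at the edges rather than pad
(no fabricated data); windows left with fewer than 3 members are masked.
A profile-global SD threshold is available behind `global_sd=True` for
sensitivity analysis; window-local is the default reading.

### Windowed statistics

* `mean_spb`: mean substitution frequency over a window, restricted to
  positions whose reference base matches the substitution type.
* `fold_enrichment`: ratio of target to control mean s.p.b. per type.  The
  control profile is shifted by a signed offset (default +23) before
  windowing, compensating for a landing-site insertion present in one
  strain only.  A zero control mean gives NaN unless the caller enables
  the pseudocount (adds one count to every base at every position before
  frequency computation; off by default so raw ratios are unchanged).
  Replicate SD is computed across biological replicate profile pairs.
* `background_subtract`: per-type corrected value
  max(0, spb_target − spb_control) and the renormalised fractions, the
  "fraction of substitutions occurring at each type"; all-zero corrected
  values leave fractions undefined (NaN).
* `detect_onset`: the plateau level is estimated by background subtraction
  over a downstream window; scanning downstream of the TSS, the first
  matching-reference position whose corrected frequency reaches 50% of the
  plateau is the onset.  With a hard-onset profile, coverage 10⁵ and error
  10⁻⁴ the detection noise (σ ≈ 10⁻⁴ per position) is an order of
  magnitude below the plateau, so the crossing is sharp.

### Synthetic pileups

The generator states a world with: a C>T plateau of 10⁻³ s.p.b. switching
on at an onset drawn uniformly 9–12 nt downstream of the TSS; minority A>G
and T>C plateaus of 10⁻⁴; a G>A component starting at 5 × 10⁻⁴ decaying
exponentially with a 300-nt length constant (the decay form is a modeling
choice — only the qualitative drop-off with distance is asserted by the
data it emulates); uniform sequencing error 10⁻⁴ spread equally over the
three alternatives; and a two-point Phred mixture (Q40/Q30 with 10% below
the filter) — only the filter boundary matters downstream, so a realistic
quality model would add nothing the pipeline can see.  Because the stated
world has its first rate increase at a cytosine, the random reference is
forced to carry a C at the drawn onset position (`ensure_onset_cytosine`).
The matched control strain lacks the 23-bp landing-site insertion, so its
coordinates run 23 lower downstream of the promoter; it sees sequencing
error only.

What a green recovery test establishes: the estimator chain (filter →
frequencies → background subtraction → windowed means) is unbiased at
stated coverage for step-like profiles with uniform error.  What it does
not establish: robustness to alignment artefacts, context-dependent error,
strand bias, or coverage heterogeneity — none of which the generator
emulates.

## Amplicon enrichment calling

Reads survive filtering iff mean Phred ≥ 20 (default; the filter
thresholds are declared defaults, not inferred values), length within the
configured window, and both the front and the back barcode match a single
well within Hamming distance 1; ties and disagreeing ends are discarded as
ambiguous.  Alignment is an input contract — the built-in aligner is
exact-offset gapless and intended for synthetic amplicons only.  Columns
that are gap-only within a well ("blanks" from external multiple
alignments) are removed per well.

A (position, alt) pair is significant iff its **global frequency** —
pooled alt reads over pooled covering reads across all wells, not averaged
per-well frequencies — is ≥ 10%, OR it is present in ≥ 4 wells.
"Present" requires a within-well frequency of at least the
`presence_floor`, default 0.10, chosen symmetric with the global
criterion; this floor is a package choice, is configurable, and should be
stated alongside any calls.  Raising either threshold can only remove
calls (monotonicity, property-tested).  Codon effects use the standard
genetic code via Biopython.

## Growth rates

rate = ln(OD600(t₁)/OD600(t₀)) / (t₁ − t₀), the only dimensionally
sensible parenthesisation of the ratio statistic (units h⁻¹), with the
default 4 → 16 h interval giving the divisor 12.  Missing endpoints are an
error — interpolation is refused rather than silently fabricated.
Replicates are summarised as per-replicate rates then mean ± SD (summary
after the ratio, not before).  Welch's t-test is exposed as a thin
convenience wrapper, documented as plumbing.  No logistic or Gompertz
fitting and no lag-phase estimation.

## Numerical notes

* The MSS recursion is evaluated with a vectorised dot product per step;
  cost is O(r_max²) and r_max is bounded by the tail cap.
* Likelihood tail mass 1 − Σp_r is clamped at 0; a capped count with zero
  tail mass yields −∞ log-likelihood and the optimiser moves away.
* `round_to_sig` rounds to significant figures via the decimal exponent;
  fold changes are reported both raw and at 2 s.f.
* Frequencies use masked arrays throughout; masked positions propagate
  through windowed statistics rather than becoming zeros.
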