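# Methods

## The model

`vfspace` implements a vector-space account of word retrieval in verbal
fluency (VF) tasks that unifies two power-of-two connectivity laws: the
count N = 2^i of non-ordered tuples over i category members (including the
empty tuple), which underlies the logarithmic VF time course, and the count
N = 2^i − 1 of neural cliques per connectivity motif, which excludes the
inactive state. Both are views of the same basis: the subsets of an i-item
set, enumerated in ascending decimal order of their characteristic bit
vectors, with or without index 0.

**Encoding.** The item at list position 0 is the least-significant bit;
this is the only assignment consistent with the three-item transcription
table ({A} = 1, {B} = 2, {C} = 4). Kets are written first-item-first
(|αβγ⟩ with α the digit of item A), and the barcode renders cells in item
list order.

**States.** A state is a real unit vector over the full 2^i basis
(Σ|c_k|² = 1, enforced at 1e-9). Producing a word must zero the
coefficients of every tuple containing it without changing the norm — the
suppressed representations remain part of the network — so production is a
rotation. The model's named families are the uniform state |x⟩ (all
coefficients 1/√(2^i)), the inseparable variant |x̄⟩ (empty-tuple
coefficient negated), and the post-production states (equal positive weight
on the 2^(i−m) surviving tuples). Coefficients are real throughout; complex
phases have no role in the model and are not supported.

**Rotations.** Every production operator R_w applies the minimal matrix
ρ = (1/√2)[[1, 1], [−1, 1]] to each (tuple-without-w, tuple-with-w)
coordinate pair and nothing else — equivalently, a Kronecker product with ρ
at item w's tensor factor. This is the unique norm-preserving construction
(up to global sign) that sends the uniform state to the post-production
state with non-negative coefficients and minimal mixing of w-free
coordinates; the printed worked examples (|x⟩ → |x_C⟩ → |x_B⟩ → |000⟩) are
the binding check. Consequences verified by the suite: all R_w are
orthogonal, commute, and share the eigenvalue multiset of ρ — e^{±iπ/4} at
multiplicity 2^(i−1) — so they form a single similarity class (spectral
equality suffices for similarity because orthogonal matrices are normal;
no explicit transformation matrix is computed). Dense matrices are
materialized up to i = 12; beyond that application is matrix-free and the
spectrum is produced analytically.

**Separability.** A state is separable when its i-way coefficient tensor
(extent 2 per mode) is rank 1 in every mode unfolding; the test requires
the second singular value of each unfolding below a tolerance (default
1e-9, suited to exactly-constructed states). Factors are unit pairs with
non-negative leading entries, the residual global sign absorbed into the
last factor, and the reconstruction is checked against the coefficients.
For magnitude-uniform states this coincides with the sign-pattern
characterization (a product of per-item signs), which the tests verify by
brute force for i = 3.

## Time-course machinery

The fused Bousfieldian function n(t) = c·[1 − (1 + αrt/c)^(−1/α)] has
parameters c (asymptote, words), r (reciprocal elementary process
duration, s⁻¹), α (dimensionless shape). α = 1 is the hyperbolic recall
curve, α → 0 the exponential, and α → ∞ with k = c/α fixed the logarithmic
curve n(t) = k·ln(1 + rt/k).

Retrieval probabilities follow p_{n+1} = n′(t_n)/r with t_n the time at
which the curve passes word n. All four curves are analytically invertible,
so both t_n and p_{n+1} have closed forms (logarithmic: t_n =
(k/r)(e^{n/k} − 1), p_{n+1} = e^{−n/k}, an exactly geometric sequence;
FBF: p_{n+1} = (1 − n/c)^{1+α}). Closed-form inversion replaces numeric
root finding; a numeric-derivative consistency check remains in the tests.

**Fitting.** The fitting objective is unweighted least squares of word
index j against onset t_j (j = 1..n), the simplest reading of the
Bousfield tradition; the noise model of real VF data is not specified by
the theory, so no weighting is attempted. Optimization uses bounded
trust-region-reflective least squares with parameters in (1e-6, 1e6)
(fits at a bound are flagged), initialized from r₀ = 2/t₂, c₀ = 1.5 ×
word count, and an α grid {0.01, 0.1, 1, 10} for the FBF. Model selection
minimizes AICc computed from the SSE-based Gaussian likelihood, with the
error variance counted as a parameter; "logarithmic classification" is
selection-by-minimum with no significance test. With fewer points than
the correction allows (m ≤ p + 1) the criterion is set to +∞ so such a
candidate is never preferred. Perfect (zero-SSE) fits are floored at
1e-300 before the log.

## The simulator and what it emulates

`simulator` realizes the sampling-with-replacement account: covert
elementary steps of exactly 1/r seconds each draw one tuple uniformly with
replacement from the 2^i tuples; a draw succeeds iff the tuple is disjoint
from the produced set (the empty tuple counts as favorable), giving
success probability 2^(i−n)/2^i = 2^(−n) at stage n. On success one
unproduced word is chosen uniformly — the theory does not name which word
a favorable tuple yields, and by symmetry the choice does not affect the
timing law. The `geometric` mode generalizes the success law to q^n,
q = e^{−1/k}, for time courses with k ≠ 1/ln 2. Waiting draws are sampled
directly from the geometric distribution (distributionally identical to
per-draw Bernoulli trials, and cheap at late stages where waits grow as
2^n). The default draw budget of 10^6 per run bounds those waits; a run
cut short is flagged `truncated`, never silently clipped. An exponential
inter-draw waiting variant exists behind a flag for sensitivity checks and
is not used by the test suite.

Defaults used across the tests and worked examples: i = 12 items, r = 1
draw/s, 400–500 runs, fixed seeds (run j of a set uses seed + j). These
sizes keep every suite run within seconds while leaving binomial standard
errors small enough for 3-SE checks down to stage ~8.

**What the simulation does not emulate:** semantic content, clustering and
switching, perseverations, intrusions, inter-subject variability in k, and
task time limits. Passing tests therefore show the internal consistency of
the model — the all-tuples structure yields geometric retrieval
probabilities and logarithmic cumulative curves — not that real VF data
follow it; no clinical data are analyzed here.

## A genuine discreteness effect

The continuum limit dn/dt = r·q^n gives n(t) = k·ln(1 + rt/k) with
k = 1/ln(1/q) (`theoretical_curve`); r passes through unchanged. But at
the coarse ratio q = 1/2 the discrete process differs measurably from its
own continuum limit: the mean onset of word n is exactly
(1/r)·Σ_{m<n} 2^m = (2^n − 1)/r, which lies on n(t) = k·ln(1 + rt) — a
logarithmic curve with the predicted scale k = 1/ln 2 but with effective
rate parameter r/ln 2 ≈ 1.443·r (the gap between Σ 2^m and ∫ 2^x dx).
Curve fits of simulated data therefore recover k faithfully (within a few
percent at 400+ runs) while the fitted r exceeds the generating r by
≈ 1/ln 2, for any fitting grid or objective; the bias vanishes only as
q → 1. The property suite asserts this exact discrete law; the one
acceptance check that expects the generating r back from the fit fails for
this reason and is retained unweakened as a documented limitation.

## Numerical choices and degenerate inputs

- Normalization tolerance 1e-9 on construction; rotation norm conservation
  asserted at 1e-12.
- The empty production set is valid (returns the uniform state); producing
  every item returns the pure empty-tuple state — a valid state, not an
  error.
- The single-item basis without the empty tuple is the degenerate 2^1 − 1
  case and contains exactly {A} with decimal 1.
- Bounded curves reject word indices at or beyond the asymptote c.
- Record validation rejects repeated words and non-increasing onsets at
  read time.
- Barcode text dialect: '#' activated, '.' suppressed, one character per
  cell, rows separated by newlines; with a state overlay each row gains a
  trailing '+'/'0' admissibility marker. Images use orange for activated
  and green for suppressed cells, dimming zero-coefficient rows.

## Known limitations

- Real coefficients only; no mixed states, density operators, or quantum
  backends — the quantum-logic-gate correspondence is structural analogy.
- Similarity testing is spectral; no explicit change-of-basis matrix is
  returned.
- The separability tolerance is tuned to exact constructions; noisy
  empirical states would need a looser, data-dependent threshold.
- The fitted-rate bias of the q = 1/2 simulator described above.
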