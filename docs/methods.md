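# Methods

## The model

`mitoinherit` iterates an exact, deterministic recursion for an infinite
population of diploid, isogamous, unicellular organisms whose mitochondrial
inheritance is under nuclear control. Each cell carries a fixed number *M* of
mitochondria, each either wild-type or mutant, so a cell class is summarised
by the count *j* ∈ {0, …, *M*} of mutants. The population state is a set of
nuclear genotype classes (unordered pairs of haplotypes), each with a
frequency and a conditional probability vector over *j*. One generation
applies, in order:

1. **Mutation.** Each wild-type organelle mutates independently with
   probability μ, so the state moves by *j* → *j* + Binomial(*M* − *j*, μ).
   In coadaptation mode mutation is symmetric (0 ↔ 1 at rate μ, plus nuclear
   flips at rate ν), applied nuclear-first.
2. **Selfish resampling** (only when *k* > 0). The *M* organelles are
   resampled with replacement, a mutant being drawn with probability
   *q* = *x*(1 + *k*)/(*M* + *xk*) from a cell with *x* mutants — a
   within-cell replicative advantage 1 + *k*. At *k* = 0 this step is
   skipped entirely (it is not the identity: it would add resampling
   variance the base model does not have).
3. **Selection.** Fitness is *f*(*j*) = 1 − (*j*/*M*)² (concave: few
   mutations are nearly neutral, decline sharpens with load). The convex
   alternative (1 − *j*/*M*)² is available. Each (genotype, *j*) mass is
   weighted by *f*(*j*) and the population renormalised by mean fitness.
4. **Meiosis.** The organelle population doubles exactly to 2*M* and is
   partitioned without replacement through two divisions into gametes of
   *M*/2. Two successive hypergeometric splits compose to a single
   Hypergeometric(2*M*, 2*j*, *M*/2) draw; the implementation uses the
   composed draw and the test suite checks the equivalence explicitly.
   Nuclear loci segregate 50/50; the mating-type locus recombines with the
   inheritance locus at fraction *r*; the mitonuclear locus is unlinked.
5. **Fusion.** Gametes pair by mass action over compatible pairs
   (mating-type alleles are self-incompatible, except index 0 which is
   universally compatible), renormalised by the total compatible mass — the
   source of the mating-rate disadvantage of self-incompatible alleles.
   *a* × *a* zygotes mix both parents' organelles (convolution, BPI);
   *A* × *a* zygotes inherit only the *A* gamete's organelles (UPI);
   *A* × *A* follows the configured rule (BPI by default, or inviable, or
   UPI with the transmitting role an equal-weight mixture).

There is no random number generator anywhere: every sampling step enters as
its exact transition matrix, and runs are bit-reproducible.

### UPI amplification

A uniparental zygote receives *M*/2 organelles and must restore the diploid
complement *M*. The default restores it by **binomial resampling**: *M*
draws with replacement at the gamete's mutant fraction, row *g* ↦
Binomial(*M*, 2*g*/*M*). Exact duplication (*g* ↦ 2*g*) is available as
`upi_amplification="duplicate"`. Resampling is the default because it is the
variant under which the package reproduces the published equilibria
(p_A ≈ 0.12 at M = 50, μ = 0.01, and genotype mean fitnesses
(0.447, 0.440, 0.447) at the merged equilibrium M = 100, μ = 0.1);
duplication gives p_A ≈ 0.144 and (0.373, 0.370) under otherwise identical
dynamics. Both variants preserve the expected mutant fraction and keep
homoplasmic gametes homoplasmic.

### Fitness census

Trajectory statistics (mean fitness per genotype and per allele) are
censused on the **zygote** distributions at the start of each generation,
before that generation's mutation step; allele means weight heterozygotes
once per allele copy. This census is what reproduces the printed merged-
equilibrium fitnesses. Note the mean population fitness that drives
selection (step 3) is computed after mutation, as it must be; only the
reported statistics use the zygote census.

## Experiments

- **Invasion** (`run_invasion`): the resident runs alone for `burn_in`
  generations (default 100) from a mutant-free start, approaching
  mutation–selection balance; the invader then enters the gamete pool at
  frequency `p0` (default 0.01) carrying the resident's aggregate gamete
  organelle distribution (a nuclear mutation arises on the resident
  cytoplasm), and the recursion iterates to convergence.
- **Convergence**: L∞ change of the concatenated genotype × state
  probability vector < `tol` (default 1e-12) for 10 consecutive
  generations; cap `max_gen` = 10⁶. Non-convergence is warned, never
  silent, and classified "other".
- **Classification** (half-width δ = 1e-3): loss (p_A < δ), E1 polymorphism
  (δ ≤ p_A < 0.5 − δ), merged E1/E2 (|p_A − 0.5| ≤ δ), fixation E3
  (p_A > 1 − δ).
- **Stability probing**: the allele frequency is shifted ±ε (default 1e-3)
  in the gamete pool, conditional distributions kept, and the recursion
  re-run to convergence; stable means every feasible direction returns to
  the starting classification (for E1, also to within 10ε of the starting
  frequency). No eigenvalue analysis is attempted — stability is purely by
  perturbation, matching the numerical character of the model.
- **Forced-frequency curves**: after every generation the nuclear genotype
  frequencies are reset to Hardy–Weinberg proportions at the target p_A
  (proportional reweighting of existing classes is available behind
  `rescale="proportional"`), organelles evolve freely, and stationary mean
  fitnesses are reported normalised by the stationary pure-BPI population
  mean. The two allele curves cross inside the grid interval containing the
  invasion equilibrium — the package's internal consistency check.
- **Mating-type scenarios**: invasion of a linked UPI + mating-type
  haplotype A₁ into (i) a universally compatible wild-type population,
  (ii) the resulting E1 polymorphism (by a second BPI mating type a₂),
  (iii) populations with n ≥ 2 pre-existing mating types. Initial
  populations for (iii) put the n resident types at equal gamete
  frequencies, mutant-free.

## Coadaptation mode

The two organelle states are reinterpreted as type 0/1 judged against a
biallelic nuclear locus. Fitness is the concave quadratic in the number *u*
of organelles unmatched to the nucleus, *F* = 1 − (*u*/*M*)²: *u* = *j* for
the 00 homozygote, *M* − *j* for 11, and the 01 heterozygote is treated as
half-matched to both types (*u* = *M*/2, so *F* = 0.75 independent of *j*).
This satisfies the relabelling symmetry *F*(00, *j*) = *F*(11, *M* − *j*),
which the whole dynamic inherits (tested exactly). The nuclear mutation
rate ν defaults to μ/10; configurations with ν ≥ μ trigger a warning.

Environmental switching periodically (every `period` generations) moves a
multiplicative penalty `cost` onto the currently dominant nuclear
homozygote, forcing re-adaptation. The study condition used in tests is
period = 500 generations, cost = 0.5 — long enough for re-coadaptation
between switches and strong enough to force every switch; the sustained
(post-transient) p_A under this schedule exceeds the no-switching
equilibrium, while weak or infrequent switching leaves p_A essentially at
E1.

## Numerical choices

- All state vectors are dense float64; probabilities below 1e-300 are
  clamped to zero and the vector renormalised, preventing denormal
  underflow over very long runs.
- The selfish-resampling success probability is clipped to [0, 1]; at
  *x* = *M* the exact value is 1 and floating-point evaluation can
  overshoot by 1 ulp, which scipy's binomial pmf rejects.
- Frequencies and conditional distributions are validated to 1e-10 in
  tests after every step of sampled runs.
- Ties in the switching controller (exactly equal homozygote frequencies)
  penalise state 0.

## Problem sizes and what the tests show

All standard runs use M ≤ 100 (state vectors ≤ 101 entries per genotype
class) and converge in 10²–10⁴ generations, seconds on one CPU. The slow
case is the decline of a redundant mating type (a₂), which is asymptotically
geometric with a rate near 1; its tests assert the per-generation monotone
decline over a 600-generation window rather than iterating ~10⁵ generations
to the tolerance floor.

The model is an idealised life cycle: infinite population (no drift), fixed
M, discrete non-overlapping generations, gamete-level control of
inheritance, no cost of UPI itself, no paternal-leakage fractions (each
fusion is all-or-none), at most two organelle allelic classes, and no
explicit environment. Passing tests therefore demonstrate properties of
this recursion, not of any particular protist; the biological reach of the
conclusions is limited accordingly.

## Known limitations

- Stability is probed along the inheritance-allele frequency only;
  perturbations of the conditional organelle distributions themselves are
  not probed (they relax quickly and are dragged along by the probe runs).
- The heterozygote matching rule in coadaptation mode (flat 0.75) is the
  simplest symmetric choice; alternatives (e.g. best-of-both) would change
  the strength, though not the direction, of the homozygote convergence.
- The forced-frequency a-allele curve rises with p_A only up to a maximum
  near p_A ≈ 0.15–0.2 before declining slightly; the leakage benefit to the
  biparental class itself (F̄_aa above baseline) holds throughout.
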