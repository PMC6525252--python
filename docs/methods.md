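# Methods

This note documents the models implemented in `cosem`, the defaults and the
numerical choices, in enough detail to reproduce or audit any number the
package computes.

## Ribosome-traffic model

State: the 1-based codon indices of the ribosomal A-sites, strictly
ascending with successive gaps ≥ *d* (footprint, default 10 codons).
Elementary transitions and rates:

| event        | rate                | condition                                  |
| ------------ | ------------------- | ------------------------------------------ |
| initiation   | α                   | no A-site at codon ≤ *d* (entry clear)     |
| elongation   | ω_i (codon at A-site) | A-site < n; target respects the gap      |
| termination  | β (default ω_n)     | A-site at the last codon n                 |
| drop-off     | γ                   | any codon except the last                  |

The Gillespie sampler picks a transition with probability rate/total and
advances time by an exponential waiting time with the total rate. A
fixed-increment sampler (event probability ≈ rate·dt per step, enforced
dt·max-rate ≤ 0.1, warning above 0.01) exists purely for cross-validation;
the two agree within sampling error on random systems (tested).

**Blocked attempts.** Two disciplines are implemented. The default rejects
an attempt by a sterically blocked ribosome (memoryless exclusion). The
alternative (`simultaneous_move=True`) flags a selected-but-blocked
ribosome — or the initiation site — and executes the pending move in the
same event in which the blocker next advances, so two adjacent ribosomes
move together; cascades are limited to the pair. The deferral measurably
accelerates dense traffic: at d = 1 the maximal current rises from the
classic 1/4 to ≈ 0.33, and the extended-footprint low-density current
exceeds α(1−α)/(1+(d−1)α) by ~18% at ᾱ = 0.03. Because every analytic
result the package quotes (LD/MC closed forms, the 1/(√d+1) corner) belongs
to the memoryless process, and because the two disciplines agree to ~1% in
the initiation-limited regime where translation operates (ᾱ ~ 10⁻³–10⁻²),
the memoryless discipline is the default; the pair rule is kept as an
explicit option and unit-tested at the single-event level.

**Known closed forms** (uniform rates, reduced units, used as oracles):
LD current J = ᾱ(1−ᾱ)/(1+(d−1)ᾱ); maximal current J\* = 1/(√d+1)²;
LD→MC corner ᾱ\* = β̄\* = 1/(√d+1). For d = 1 these reduce to the classic
α(1−α) and 1/4.

**Defaults.** Burn-in 10·n/⟨ω⟩ʰ seconds (ten harmonic-mean transit times);
measurement window sized for 500 expected completions at the LD current
(`target_completions` tunes the speed/noise trade-off; feature extraction
in benchmarks uses 60). Density is recorded as time-averaged A-site
occupancy per codon (not footprint coverage); the average density is its
mean over codons. Drop-off per-codon probability 3×10⁻⁴ converts to
γ = 3×10⁻⁴·ω; at organism-scale mean rates of 22, 33 and 6 s⁻¹ this gives
γ ∈ [0.0018, 0.0099] s⁻¹. All runs take explicit integer seeds; a run is
bit-reproducible given its seed.

**Synthesis-time estimate.** t_j ≈ 1/α + Σᵢ 1/ω_i + 1/β, valid
initiation-limited. In the simulator the last codon's elongation rate never
fires (termination replaces it), so a measured single-ribosome transit is
Σ_{i<n} 1/ω_i + 1/β; the estimate is checked against transit times on
systems whose final codon is fast (the biologically typical case — slow
codons are rare at the end of an mRNA), where the 1/ω_n discrepancy is well
inside sampling error.

## Rate tables

61 sense codons, elongation rate > 0 (1/s) and accuracy ∈ (0,1] each;
terminal stop codons are stripped from input CDSs, internal stops are hard
errors, U is accepted and mapped to T. The synthetic competition generator
maps a tRNA pool to a table via

    ω_c = base · C/(C + 0.1·N + 0.01·X),   a_c = C/(C + 0.1·N)

with C/N/X the aggregate cognate / near-cognate / non-cognate
concentrations and fixed discrimination weights 0.1 and 0.01 (configurable).
The map is deterministic and scale invariant; it is a deliberately simple
stand-in for detailed kinetic elongation models and is not fitted to any
measured kinetics.

## Features

x1 current (simulated), x2 arithmetic mean elongation rate (preferred over
the harmonic mean because it correlates less with the current and adds more
independent information; the harmonic mean is exposed separately), x3
bottleneck index = minimum 10-codon sliding-window mean rate, x4 accuracy
∏ a_i computed in the log domain (safe to 10⁵ codons), x5 5′ folding energy
and x9 hairpin count over the first 90 nt, x6 log₁₀ transcript abundance
(representable as absent — the design-time situation), x7 GC3, x8 ramp
index = mean rate over the first 30 codons, x10 length in codons.

Folding engines are pluggable. Default: ViennaRNA MFE when the bindings
import. Fallback: weighted base-pair maximization (GC = 3, AU = 2, GU = 1,
minimum loop 3 nt) with energies −2.0/−1.0/−0.5 kcal/mol per pair class and
a −0.5 stacking bonus per stacked pair — a documented heuristic, not a
nearest-neighbour parameter set. Hairpin convention for both engines: an
innermost pair whose contiguous closing stem has ≥ 3 stacked pairs.

## Expression score

Least-squares component-wise boosting. Base-learners: cubic B-splines with
20 interior knots and a second-order coefficient difference penalty whose
smoothing parameter is calibrated once per feature to ~4 effective degrees
of freedom (trace of the smoother matrix, solved by bisection on the
generalized eigenvalues); the hairpin count uses an ordinary least-squares
line (exactly 2 parameters). Step length ν = 0.1. Each iteration fits every
base-learner to the current residuals and applies the update whose ν-scaled
step most reduces the squared error; the loss is therefore non-increasing
by construction and the path stops early if no learner improves it.

Monotonicity (current, mean rate, log transcript abundance) is enforced by
projecting the accumulated B-spline coefficient vector onto the isotone
cone (pool-adjacent-violators) after every update; non-decreasing
coefficients imply a non-decreasing spline.

The stopping iteration is selected on 25 nonparametric bootstrap replicates
(in-bag fits, out-of-bag squared error, Eq-style mean loss) using the
**one-standard-error rule**: the smallest iteration whose mean OOB loss is
within one SE of the minimum. The plain argmin sits on a flat stretch of
the OOB curve and consistently lands ~20 iterations late, where pure-noise
base-learners start to be selected; the 1-SE rule stops before the first
noise entry at indistinguishable OOB loss. The offset is the outcome mean
(fitted jointly would be confounded with the base-learner intercepts).

Scoring clamps features to the training range (logged) because optimized
sequences can leave the observed range. The weighted score is
offset + Σ v_k f̂_k(x_k); an absent feature is only legal with weight 0.
A simplified variant (per-feature linear effects, quadratic for GC3)
linearizes a fitted model for quick interactive scoring.

Evaluation: 70/30 train/test split with a recorded seed, R² = 1 −
SS_res/SS_tot on the held-out part. The initiation rate can be calibrated
self-consistently by maximizing the Pearson correlation between simulated
currents and observed protein levels over an α grid (ties → smallest α; a
flat profile logs a warning).

## Optimizer

Proposal distribution per position: π_l ∝ s₁·(ω_l−ω_min)/(ω_max−ω_min) +
s₂·(a_l−a_min)/(a_max−a_min) + ε with defaults s₁ = s₂ = 1, ε = 0.05; a
family whose synonyms all share rate and accuracy normalizes both terms to
0 (continuity limit) and becomes uniform. The first candidate is the
locally optimal sequence (per-position argmax of the combined normalized
criterion, alphabetical tie-break); the wildtype is always in the candidate
set, so the best score brackets the wildtype score in the objective
direction by construction. Full-length resampling per proposal; frozen
positions copy the wildtype codon. Every candidate's protein identity is
asserted. Simulation seeds derive deterministically from the sequence
content (CRC32), so identical sequences always score identically — which
also makes termination on flat landscapes exact.

Termination: CV of the tracked m scores < 5% (m = 100 default). "Tracked"
defaults to the global top-m distinct scores (a bounded sorted buffer); the
alternative reading — the last m record-breaking scores — is available as
`score_buffer="recent"`. Relative scores are variant/wildtype; if the
wildtype score is ≤ 0 both are shifted by 1 − wildtype score (documented,
raw scores always reported). Design-time feature weights default to v = 1
except transcript abundance v = 0. A plain CAI utility (geometric mean of
relative adaptiveness) is included solely as a comparison baseline.

## Synthetic fixtures

`make_rate_table` draws per-codon rates uniformly in [4, 40] s⁻¹ (bracketing
the ~6–33 s⁻¹ organism-scale means of slow mammalian to fast microbial
translation) and accuracies in [0.90, 0.9999]; synonyms are independent so
every family has spread for the optimizer to exploit. `make_genes` emits
ATG-initiated stop-free random CDSs (default 40–90 codons — short, to keep
simulated feature extraction fast; the methods scale linearly in length).
`make_benchmark` pushes those genes through the *real* feature pipeline
(initiation rate 0.5 s⁻¹, γ = 0.0066 s⁻¹, 60 target completions per gene)
and generates outcomes y = offset + Σ g_k(z_k) + N(0, σ) on z-scored
features; defaults: monotone tanh on the current (amplitude 1.0), centred
quadratic on GC3 (0.6), linear on log transcript abundance (0.8), σ = 1.4,
putting the exact explainable fraction — recorded per benchmark — near 0.5.
Everything regenerates bit-identically from its seed.

What the generator does **not** emulate: real codon-usage bias, 5′ UTRs and
ribosome-binding-site strength, transcript-feature correlations found in
real transcriptomes, and measurement floors of proteomics data. Passing the
recovery tests therefore shows the estimator recovers known additive
structure through the simulation pipeline — not that any particular
organism reaches a given R².

## Problem sizes and tolerances

Stochastic checks compare currents within 3 standard errors on the Poisson
scale (√completions / measurement time). The phase-diagram scan runs a 6×6
grid at 300 codons, γ̄ = 1.7×10⁻⁴, 8000 s measurement per point; the
statistical recovery benchmark uses 2000 genes with 50 noise-refit seeds.
These sizes give comfortably resolvable contrasts for every asserted
effect; all of them are plain function arguments and scale up trivially.

## Known limitations

- tRNA recharging/recycling, density-dependent drop-off and gene-specific
  initiation rates are out of scope of the traffic model.
- The fallback folding engine ranks structures sensibly but its absolute
  energies are heuristic; use ViennaRNA where energies matter.
- Boosting gives point estimates only; no uncertainty bands for the
  partial functions are provided.
- Organism-scale predictive performance requires real proteome/transcriptome
  data and is deliberately not asserted by this package's tests.
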