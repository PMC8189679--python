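# Methods

## Model

Log2 expression of gene *i* in sample *k* is modeled as

    e_ik = b_i + Σ_j cs_ij · a_jk

with baseline *b_i* (the gene's expression when all of its regulators
have zero activity), control strength *cs_ij* (the condition-independent
potential of TF *j* to activate or repress gene *i*) and activity *a_jk*
(the condition-dependent extent to which TF *j* exerts that potential in
sample *k*). In matrix form `E = CS · TFA` with CS augmented by the
baseline column. The model is bilinear: linear in CS given TFA and vice
versa. It assumes additive, non-saturating regulation in log space, a
fixed sign of regulation per edge across all conditions, and no TF–TF
interactions; these assumptions are discussed under limitations.

Constraints make the parameters interpretable:

- `cs_ij = 0` unless the network map contains the edge j→i; on edges
  `cs_ij · sign_ij ≥ 0` where the sign matrix is derived from data;
- activities are non-negative: zero represents no activity (equivalent
  to deleting the TF's gene). In a deletion sample the perturbed TF's
  activity is fixed at exactly 0; in an overexpression sample it is
  constrained to be at least its activity in the unperturbed reference
  plus the floor (strict inequalities are not expressible in bounded
  least squares); all other activities are ≥ 10⁻⁴ (`floor`), which also
  keeps log-transformed activities finite during evaluation;
- when CS is being learned, each TF's mean activity across samples is
  rescaled to one after every iteration; this fixes the scale gauge
  (scaling a CS column by c and the TFA row by 1/c leaves E unchanged).
  Deletion samples are included in the mean (a literal reading of the
  convention); `normalize_mean_activity(..., include_deleted=False)`
  exposes the alternative.

## Fitting

The sum of squared reconstruction errors is minimized by alternating two
exact constrained least-squares blocks:

- **CS step** (per gene): regress the gene's expression on the fixed
  activities of its regulators plus an intercept. Columns are flipped by
  their constrained sign so the constraint becomes non-negativity, the
  unconstrained intercept is concentrated out by centering (for any
  coefficient vector the optimal intercept is the mean residual), and
  the reduced problem is solved exactly with NNLS.
- **TFA step** (per sample): regress the sample's baseline-subtracted
  expression on the fixed CS columns under per-entry lower bounds,
  solved by shifting (`a = lb + z, z ≥ 0`) and NNLS. Entries fixed at
  zero (deletions) are dropped from the design. Samples without
  overexpression bounds are solved first so that deferred bounds resolve
  against freshly fitted reference activities.

Because each block is an exact minimizer, training error is monotone
non-increasing across iterations (asserted in the tests). The fit runs
from `n_inits` (default 20) random initializations — CS magnitudes
uniform in [0.2, 2] with the constrained sign, baselines at per-gene
means — and the best run by the stopping-criterion R² is kept. The TFA
block is solved first, since CS holds the initialized values. Two
stopping rules are provided: `holdout_peak` (default) refits activities
and baselines to a held-out expression matrix after each iteration
(20 alternations by default) and stops after 3 iterations without
improvement, returning the parameters at the peak; `train_converge`
stops when the relative SSE change drops below `train_tol` (default
1e-6). After the winning run is selected, one final bounded TFA solve is
performed against the mean-one-normalized CS, so the returned activities
satisfy every bound exactly (the mean-one rescaling alone can push
floor-level activities marginally below the floor).

**Refitting** to a second dataset holds the non-baseline CS entries
fixed and alternates the bounded TFA step with the closed-form baseline
step (per-gene mean residual), without re-normalizing TF means — the
scale is inherited from CS. Baselines are per-dataset, absorbing
constant shifts between measurement platforms or conditions. In the
benchmark protocol the second dataset's refit uses only the generic
floor bound: its perturbation key is reserved for evaluation and is
structurally unavailable to the fit.

An independent **reference solver** (`tfactivity.reference`) minimizes
the identical objective over all parameters at once by multi-start
projected gradient descent with backtracking line search. It shares no
code with the alternating path and is used to cross-check final SSE
values on small instances (agreement within 1% is asserted).

## Networks and constraints

Given a globally ranked edge list, `build_network` walks the ranking
until `n_tfs` distinct TFs appear, adds lower-ranked edges of those TFs
down to `max_rank` (defaults 50 and 1250), then prunes: TFs with fewer
than two targets are dropped (their single target is indistinguishable
from baseline variation), and any group of TFs with identical target
sets is dropped together with the shared targets (such TFs are not
identifiable from expression). Since pruning can evict TFs, selection
returns to the list with evicted TFs excluded and repeats until the TF
set is stable (bounded at 25 rounds). Identical-set comparison is set
equality, re-checked after each removal round; removed targets may
re-enter as targets of other TFs. Rank ties keep input order; the
procedure is fully deterministic. `select_block` applies the same
procedure inside a fixed rank window (blocks of 2000 by default).
`merge_networks` unions signed networks, drops edges whose signs
conflict between inputs, and repeatedly removes single-target TFs along
with their orphaned target; it does not re-apply the identical-set rule.

Sign constraints come from either route:

- **perturbation signs**: Δ = target expression in the perturbation
  sample minus the unperturbed reference; a drop under deletion or a
  rise under overexpression means activation. Multiple samples for one
  TF vote through the mean of direction-oriented deltas.
- **correlation signs**: the sign of the Pearson correlation between the
  TF's mRNA and the target's expression across all samples, used even
  when not significant.

In both, an exact zero defaults to +1 with a logged warning (activation
is the majority class in the regulatory networks this models). When
several unperturbed samples exist, the first in sample order is the
reference (configurable).

## Evaluation

Three core metrics, computed against a perturbation key never seen by
the fit:

- **direction of perturbation** — the fraction of perturbation samples
  in which the perturbed TF's activity moved the right way relative to
  the unperturbed reference (down for deletion, up for overexpression);
  ties count as incorrect (conservative). Two-sided binomial test
  against 0.5.
- **median rank percentile** — activities are log2-transformed and
  z-scored per TF across samples; in a deletion sample TFs are sorted
  ascending by z (most negative first), in an overexpression sample
  descending; rank r of N maps to the percentile 100·(1 − (r−1)/N), so
  the top rank scores 100 and the chance median is 50. Ties share the
  mean rank. The median over samples is reported with a sign test
  (samples above vs below 50).
- **positive TFA–mRNA correlation** — for each bootstrap resample of the
  samples, the fraction of TFs whose raw (unlogged, unstandardized)
  activities correlate positively with their own mRNA; the median
  fraction across 1000 resamples is reported, with a binomial p-value
  from the non-resampled counts.

The protocol harness runs train→refit→evaluate in both directions and
combines the two directions by arithmetic means (fractions, percentiles)
and Fisher's combined probability test (p-values). Additional
operations: averaging standardized activities of TFs shared between
networks (rows re-standardized afterwards), regulator-recovery curves
(TFs ranked by |Δz| from the reference in each regulator-perturbation
sample; the curve reports the fraction of known regulator→TF edges whose
target ranks at or above each percentile threshold), and per-TF
bootstrap correlations between control strengths and a covariate (a
second CS matrix or per-target binding counts), restricted to TFs with
at least 5 targets.

## Time courses

Activity responses (log2 fold change versus time 0; series are anchored
at (0, 0)) are fit with

- a 4-parameter sigmoid `y0 + (A − y0)/(1 + exp(−k(t − t0)))`, k > 0,
  direction increasing iff A > y0; and
- a 6-parameter impulse, the product of a rising and a falling logistic
  sharing slope β, with ordered transition times t1 < t2 (enforced by
  parameterizing t2 = t1 + dt, dt > 0); direction compares fitted values
  at the last and first observed times.

Both use multi-start nonlinear least squares (trust-region reflective)
with data-driven starts — transition times from quantiles of the time
range, levels from the data extremes, two slope scales — so the fits are
deterministic. Model choice uses the Gaussian profile BIC,
`n·ln(SSE/n) + k·ln(n)`; ties go to fewer parameters. "Variance
explained" of a fit is 1 − SSE/SST around the series mean; constant
series (zero SST) are flagged low-information with undefined R².
Direction summaries drop fits below a configurable R² threshold
(0.85 by default).

A known behavior of this selection: the impulse family nests the sigmoid
exactly (h2 = h1), so with ~10 time points and appreciable noise the
impulse's SSE advantage on genuinely sigmoidal series exceeds the BIC
penalty (2·ln n) on a substantial fraction of series. In simulations at
the 9-point design with noise at 5% of amplitude, impulse-generated
series are identified essentially always, while about half of
sigmoid-generated series are (conservatively) assigned the impulse; the
ratio of nested least-squares SSEs is scale-free, so this rate does not
improve at lower noise. Direction classification is unaffected and is
exact on noiseless curves. When family identity matters more than shape
flexibility, fit only the sigmoid, or raise the R² threshold.

## Synthetic benchmark

The generator emulates single-TF perturbation compendia: one wild-type
sample (optionally several) plus one sample per TF deletion and per TF
overexpression. Defaults define the benchmark conditions used in the
tests: 20 TFs × 300 genes, 5–15 targets per TF, 70% activating edges, CS
magnitudes uniform in [0.5, 2], baselines uniform in [4, 10] log2 units,
expression noise 0.25 log2 units (homoscedastic Gaussian in log space,
matching the least-squares objective so recovery tests are
interpretable). Activities are lognormal (sdlog 0.5) per TF and sample,
with the perturbed entries imposed — 0 for deletions, 4× the wild-type
level for overexpression (strong but not degenerate induction;
configurable) — and rows rescaled to mean one, matching the fitting
convention. TF mRNA is generated as `c·z(TFA) + √(1−c²)·noise` with
coupling c = 0.9 by default, mapped to log2 expression units around 7;
TF-encoding genes are never target rows. `corrupt_signs` flips a stated
fraction of each TF's edge signs to emulate sign conflict between
perturbation datasets.

What the generator does **not** emulate: microarray platform artifacts,
batch effects, heteroscedastic or count-based noise, indirect regulatory
cascades (perturbing a TF only affects its direct targets), saturation,
or condition-dependent regulation. Passing tests therefore demonstrate
correctness and statistical behavior of the inference machinery under
the model's own assumptions, not performance on real compendia.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` run the full pipeline at
20 TFs × 300 genes × 41 samples (with 4–5 random initializations, which
is ample at these sizes since the alternating fit converges to nearly
identical optima from most starts), oracle comparisons at 3 TFs ×
12 genes × 8 samples with 20 projected-gradient restarts, 10 seeded
replicates for the sign-conflict analysis, and 100 series per family for
time-course selection. NNLS tolerances are scipy defaults; alternating
convergence uses relative SSE change (1e-6 production, 1e-10 in oracle
comparisons); reconstruction identities are asserted at 1e-10. All
randomness flows through explicit integer seeds (numpy `default_rng`);
identical seeds give bitwise-identical results.

## Limitations

Inherited from the model: no saturation; one sign per edge across all
conditions (condition-dependent activator/repressor switching appears as
sign conflict); no TF–TF interactions; no epigenetic accessibility
effects; variance explained is a poor guide to TFA accuracy because the
parameters are fit to the same objective. Practical: TFs with very few
or invariant targets are weakly identified; CS matrices transferred
across datasets explain less variance than in-dataset fits (per-dataset
baselines absorb only constant shifts); and the BIC sigmoid/impulse
selection is conservative toward the impulse at short series lengths, as
quantified above.
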