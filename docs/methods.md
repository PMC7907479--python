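# Methods

## Model

A pixel's discretized intensity trace is treated as a categorical process
`X(t)` on `n` categories. Its one-step law is factorized through a latent
categorical variable with `K` states, `Λ_K = λ_K γ_K`, for every
`K = 1..n`, and the candidates are combined by corrected-AIC posterior
weights into the averaged latent entropy `S̄` (predictability) and latent
dimension `K̄` (memory). The approach assumes stationarity of the
per-pixel dynamics over the recording, first-order (Markov) transition
statistics as the relevant summary, and pixel independence (each pixel,
or pooled patch, is analyzed on its own).

The sufficient statistic is the average contingency table
`C[j,i] = #(i→j)/N`, where `N` counts transition *pairs* — for a T-frame
trace `N = T−1`, and for pooled patches the member pixels' pair counts
add. All entropies are in nats.

### Affiliations are hard

The latent affiliation `γ_K` is formally a conditional probability, but
the direct-Bayesian-model-reduction fit used here assigns each input
category to exactly one latent state (0/1 columns), with the emission
`λ_K[:,k]` the count-weighted average of the member categories' empirical
conditional columns. This is the cross-entropy-optimal emission for a
given grouping, and it guarantees `S_K` is finite: every observed
transition retains positive model probability because a category's own
empirical column is part of its state's average.

### Parameter count

The complexity penalty uses `V_K = (n−1)K + n(K−1)` — the count for a
*stochastic* affiliation — even though the fitted affiliation is
deterministic. The weighting is deliberately kept in this form (and the
weight exponent is `−ΔAICc`, without the conventional ½, with the
likelihood term `N·S_K` rather than `2N·S_K`); these are the operative
definitions of the measures being implemented, not free choices, and
"correcting" them would change the measures.

## Optimization of the reduction

The cost of a hard partition decomposes over latent states:
`S = Σ_k f(M_k)` with `M_k` the sum of member columns of `C` and
`f(M) = −Σ_j M_j log(M_j/|M|)`. The fit therefore uses reassignment
sweeps with *exact* move deltas
(`Δ = f(M_a−c_i) + f(M_b+c_i) − f(M_a) − f(M_b)`), applying per column
the best strictly improving move until no move improves; sole members of
a state never move, so all `K` states stay nonempty. Ten starts are used:
one contiguous-blocks partition of the ordered categories (categories are
ordered intensity bins, so contiguous groupings are natural) plus nine
random assignments from a seeded generator (default seed 0; the fit is
deterministic). Ties break toward the lowest state index. The
`exhaustive_reduced_model` oracle enumerates all set partitions (sympy)
for `n ≤ 10` and the suite verifies the heuristic attains the exhaustive
optimum on random 4×4 and 5×5 tables to 1e−9.

### Degenerate inputs

- Categories absent from a sample (zero row *and* column of `C`) are
  dropped before fitting; `n_effective` bounds the K-sum and the `V_K`
  formula. A single-category pixel returns `S̄ = 0, K̄ = 1` exactly.
- Categories that occur only as final states (zero column) cannot anchor
  a latent state of their own; a requested `K` above the number of
  occupied columns returns the largest feasible model flagged `capped`,
  and the measure average excludes such duplicates (weight 0) rather than
  counting the same model twice.
- Models with `N − V_K − 1 ≤ 0` get `AICc = +∞` and zero weight, so short
  series degrade gracefully toward small-K models instead of failing.
- `N ≤ n²` triggers a warning (and the pipeline's `warnings_map`), not an
  error: the condition concerns estimation accuracy, not validity.

## Discretization

Default: 8 uniform-width bins between the global minimum and maximum of
the whole stack, one shared alphabet for all pixels, so entropy scales
are comparable across the image; the final interval is right-closed.
Integer-valued stacks with at most `n_bins` distinct levels use the
levels directly as categories (no empty bins). Constant traces collapse
to one category with a warning flag. Per-pixel alphabets are then reduced
to the categories actually observed at that pixel. Both the bin count and
binning scope are configurable because no canonical choice exists for
arbitrary video sources.

## The falling-toast model

`Λ(U_s, U_h)` deforms the fair-coin matrix; feasibility requires
`|U_s| + |U_h| ≤ 0.5`. Experiments are independent `(X, Y)` pairs with
the initial side drawn uniformly — a Bernoulli framing rather than a time
chain; the measures consume pair samples, so both regimes are supported.
Simulations default to 10,000 drops: the historically quoted 100-drop
experiment makes the limiting values visibly noisy, and 10,000 keeps the
sampling error well inside the bands discussed below while running in
milliseconds (100 remains available via `--n`).

Two finite-weight effects are worth stating precisely, because they bound
what "K̄ = 1" means operationally:

- **Population limit.** With `C` exactly the fair-coin table,
  `S_1 = S_2 = log 2`, so `ΔAICc = ΔV = 3` and
  `K̄ = 1 + (1 + e^{3+ε})^{-1} ≈ 1.047`: the two-state model always keeps
  ≈ 4.7 % posterior weight. The same holds in the always-butter-down case
  (`S_1 = S_2 = 0`).
- **Sampling bias.** On sampled fair-coin data the empirical mutual
  information makes `N(S_1 − S_2)` distributed like `χ²₁/2`, so `K̄`
  fluctuates above the population value — typically 1.05–1.10, with a
  heavy right tail. This is intrinsic to the weighting as defined; tests
  of the sampled no-memory case therefore assert a high-probability
  envelope rather than the population band. `S̄` is unaffected to O(1/N).

For the identity matrix (`U_h = 0.5`) the entropy of the *fitted* models
is zero (`S_2 = 0`) and `K̄ = 2` to machine precision; the sweep reports
the measured `S̄` surface without asserting any entropy claim for this
case, since the footnote-form entropy (zero) and a "maximal entropy"
reading of perfect memory cannot both hold.

## Synthetic stacks

The generator emulates the *structure* of the motivating data — a hidden
branching "capillary" network with distinct dynamics, a smooth parameter
gradient across columns, additive Gaussian observation noise before
discretization — with every pixel an independent two-state (or general
n-state) Markov chain started from its local stationary law. Defaults:
state intensities at consecutive integers, `noise_sd = 0.1` (states 10
SDs apart, so discretization is reliable; the noise knob probes
robustness), `T = 2000` frames at 64×64 for the recovery experiments.
What it does *not* emulate: spatial intensity correlations (optics/PSF),
photobleaching, drift or motion, compression artifacts, and non-Markov
or non-stationary dynamics. Passing the recovery tests therefore shows
the measures separate regions that differ in transition dynamics under
clean conditions; it does not certify performance on real microscopy.

The capillary mask is a seeded random-walk skeleton (branches start on
the existing skeleton, giving a connected network) dilated to a target
width, with an erosion fallback keeping the mask fraction below 40 %.

## Problem sizes and cost

Per-pixel cost is governed by the alphabet: fits for all K cost O(n⁴)
time and O(n²) memory, so 64×64×2000 stacks with binary dynamics map in
a few seconds on one core. Pixels are independent; the serial loop is an
implementation choice, not a contract. The test suite runs its recovery
experiments at 64×64, `T = 2000` (the same conditions as the acceptance
experiments) and completes in well under a minute.

## Known limitations

- Hard affiliations mean the fitted `γ` never realizes the stochastic
  `γ` its `V_K` pays for; the measures inherit this asymmetry by design.
- The reassignment search is a local method; global optimality is
  verified against enumeration only for small alphabets (the regime the
  maps actually use). For large `n` the 10-start heuristic is a
  heuristic.
- First-order statistics only: dynamics differing solely in higher-order
  temporal structure are invisible.
- Maps are emitted as raw values; normalization and color-scaling for
  display are left to the user.
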