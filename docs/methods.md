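# Methods

## Model

Organelle copy number `n(t)` is a continuous-time Markov jump process on the
non-negative integers with four elementary reactions: de novo synthesis
(constant propensity `k_denovo`), fission (`k_fission·n`), homotypic fusion
(`k_fusion·n(n−1)`, requiring a pair) and first-order decay (`γ·n`,
aggregating maturation, dilution at division, autophagy and heterotypic
fusion). Rates are in arbitrary reciprocal-time units; stationary
distributions depend only on rate ratios, and by convention the time unit is
1/γ where γ > 0. The fusion propensity is `n(n−1)` exactly (no 1/2 for
unordered pairs); a pair-counting convention would only rescale `k_fusion`.

The model deliberately omits spatial structure, organelle size and age, and
coupling between organelle types; copy number is the only state variable.

### Exact stationary solution

The process is a one-dimensional birth–death chain with birth rate
`b(n) = k_denovo + k_fission·n` and death rate `d(n) = γn + k_fusion·n(n−1)`,
so its stationary law satisfies detailed balance and is the product form
`p(n) ∝ Π b(i−1)/d(i)`. `cme_stationary` evaluates it in log space on
`0..n_max`, with `n_max` initialized at mean + 12 standard deviations and
doubled until a geometric bound on the discarded tail falls below 1e−8 (the
bound is reported as `tail_mass`). When γ = 0 the death rate at n = 1
vanishes, state 0 is transient, and the support starts at 1; with
`k_denovo = γ = 0` the chain is a zero-truncated Poisson with
λ = k_fission/k_fusion. Degenerate cases are rejected: no production, no
loss, absorption at zero (`k_denovo = 0, γ > 0`), and supercritical
branching (`k_fusion = 0, k_fission ≥ γ`). The test suite cross-checks the
product form against a least-squares null-space solve of the truncated
generator matrix.

### Fluctuation–dissipation approximation

The closed-form Fano factor is `σ²/⟨n⟩ = ⟨|δ|⟩/C` with unit step size and
dissipation `C` equal to the difference of logarithmic sensitivities of the
death and birth fluxes at the mean. For this scheme,

    σ²/⟨n⟩ = 1 / [ (k_fusion(2⟨n⟩−1)+γ)/(k_fusion(⟨n⟩−1)+γ)
                   − k_fission⟨n⟩/(k_denovo+k_fission⟨n⟩) ].

It is exact in two regimes: with `k_fusion = 0` both fluxes are affine in
`n` and the stationary law is negative-binomial with Fano `γ/(γ−k_fission)`,
which the formula reproduces; and it reduces exactly to 1 (Poisson) when
fission and fusion are both off, and to `1 − 1/⟨n⟩` when de novo and decay
are both off. Elsewhere it is an approximation whose error comes from the
moment closure `⟨n(n−1)⟩ ≈ ⟨n⟩(⟨n⟩−1)` in the fusion term, of relative size
~Fano/(⟨n⟩−1).

On the shifted-Poisson point: the exact stationary law of the pure
fission–fusion chain as written is a *zero-truncated* Poisson, whereas the
framework's distributional prediction for the vacuole is the *shifted*
Poisson `1 + Poisson(⟨n⟩−1)`, whose Fano factor `1 − 1/⟨n⟩` coincides with
the fluctuation-dissipation reduction. The two laws converge at large mean
but differ at the vacuole's mean of ~2 (exact-chain Fano ≈ 0.45 at
mean 1.65 for λ = 1.1 versus 0.52 for the shifted Poisson at mean 2.1).
Both distributions are implemented (`cme_stationary` vs
`shifted_poisson_distribution`) and the discrepancy is surfaced in the
tests rather than hidden; printed-value comparisons use the closed
formulas, as the framework does.

`fano_fusion_decay_balanced` implements the mixed fusion+decay expression
`(2k_denovo + 3k_fission⟨n⟩)/(3k_denovo + k_fission⟨n⟩)` verbatim; its
derivation condition ("similar rates") is loose and a naive large-n
fluctuation-dissipation calculation does not reproduce its numerator
coefficient, so it is excluded from oracle-equivalence tests.

### Mean-field mean and sweeps

`mean_field_steady_state` balances the fluxes under the same moment closure
and `gamma_for_target_mean` inverts it to hold the mean constant along
parameter sweeps (the construction behind the Fano-vs-fission/de novo-ratio
curves, with fusion rates in units of `k_denovo`). The exact CME mean is
authoritative when the closure disagrees with it; at strong fusion the
closure error reaches tens of percent, which is why the simulation's
stationarity diagnostic compares endpoint means against the exact solver
rather than the closure.

## Simulation

`simulate_trajectory` is a textbook exact SSA for one replicate.
Stationary samples are one endpoint per independent replicate (matching how
stationary histograms are built from repeated simulations, and giving
exactly independent draws), advanced in lock step across replicates with
vectorized draws from one seeded PCG64 stream. This is statistically exact:
each replicate's waiting times and reaction choices use its own draws, and
finished or absorbed replicates simply stop consuming theirs. Runs are
bit-reproducible for fixed `(rates, config, partition, seed)`; changing
`n_reps` reshuffles the stream assignment, a deliberate trade of
per-replicate stream stability for the vectorization that keeps
10,000-replicate studies at sub-second cost.

Burn-in guidance: the linearized relaxation rate is
`γ + k_fusion(2⟨n⟩−1) − k_fission`; horizons of ≥10 relaxation times with
the initial count near the stationary mean are used throughout, and a
warning fires when the endpoint mean sits more than 3 standard errors (and
15% relative) from the exact stationary mean.

### Division partitioning

Two variants replace first-order decay with partitioning at regular
intervals: deterministic halving (the followed mother cell retains
`ceil(n/2)`; "exactly one half" is impossible at odd counts and retaining
the larger half is the documented tie-break) and binomial partitioning
(`Binomial(n, p)`, p = 0.5 by default). The default period is one mean
organelle lifetime (1/γ of the matched decay model).

Binomial partitioning of a Poisson pool is Poisson-preserving (thinning),
so the binomial variant reproduces the decay model's Fano factor exactly —
confirmed by simulation. Deterministic halving is *not* noise-equivalent to
first-order decay: halving quarters the variance of the pool
(`Var(⌈n/2⌉) ≈ Var(n)/4`), and the stationary endpoint Fano of a de
novo-driven pool under halving sits near 1/2–2/3 (phase-dependent), not 1.
The acceptance-level check asserting equality for the halving variant is
retained as stated and fails by ~33 combined standard errors at matched
mean 3; we report the discrepancy rather than weaken the check. The
qualitative conclusion — fission-driven chains remain markedly
over-dispersed relative to de novo-driven chains under either partitioning
scheme — holds and is tested.

### Two-vesicle peroxisome biogenesis

The refined de novo pathway tracks Pex2/10-type and Pex13/14-type
pre-peroxisomal vesicles that fuse heterotypically (one of each per mature
organelle): reactions `∅→v1`, `∅→v2`, `v1+v2→m`, plus mature fission and
decay and optional vesicle decay. No numerical rates are published for this
model; defaults use symmetric vesicle production at the target mature mean,
`k_fuse = 10`, `γ_m = 1` and `γ_v = 0`, i.e. the mature mean is
`k_v/γ_m ≈ 3` on the haploid glucose scale. With vesicle decay off, the
`v1 − v2` imbalance is a null-recurrent random walk; as one pool comes to
dominate, fusion events track the minority vesicle arrivals (a Poisson
process), so the mature pool approaches Poisson statistics only
asymptotically (measured Fano 0.95 at t = 15 vs 0.996 at t = 300 with 10⁴
replicates). Horizons of 200–300 time units are therefore used as the
stationary horizon for this model; with mature fission off its Fano is then
statistically indistinguishable from the one-step de novo model at matched
means, which is the statistical-equivalence claim. Raising mature fission
inflates the Fano above 1, as in the single-species model.

## Inference

Point estimates use the sample mean and unbiased (n−1) variance; at the
experimental sample sizes (~100–300 cells) the estimator choice is below
the reported rounding, and the unbiased choice makes the Poisson Fano
property exact in expectation. Uncertainty is a nonparametric case
bootstrap (cells resampled with replacement, 1000 replicates by default,
percentile 95% intervals, deterministic given a seed); resamples with mean
zero are excluded from Fano statistics and counted. Both the SE of the mean
and the SE of the Fano estimate are reported; interval-based calls use the
Fano interval.

Regime calls follow interval rules against 1: entirely above 1 →
fission dominated; entirely below 1 → fission–fusion balance; covering 1 →
de novo dominated, unless the interval is wider than 1, which is reported
as indeterminate. The interval convention makes "significantly larger
than 1" reproducible. Calibration: on 200 synthetic Poisson datasets of 150
cells, ≥90% are called de novo dominated (tested).

`solve_k_denovo_ratio` inverts the γ = 0 form of the Fano relation for the
dimensionless ratio `k_denovo/(k_fission⟨n⟩)` via the fission birth-flux
fraction `B = (2⟨n⟩−1)/(⟨n⟩−1) − 1/Fano`, which must lie in (0, 1]; Fano
values at or above `(⟨n⟩−1)/⟨n⟩` are infeasible for a decay-free model and
rejected. Full four-rate estimation from a single stationary distribution
is deliberately out of scope (unidentifiable up to time rescaling).

`compare_to_reference` is a descriptive overlay: observed vs expected bin
proportions against a reference built from the sample mean alone (no other
fitted parameters), with a multinomial G statistic and a Monte-Carlo null
obtained by resampling from the reference at the observed sample size. Its
size is calibrated (≤10% rejections at nominal 5% over 100 Poisson
datasets) and it has ≥90% power against fission-dominated counts
(Fano ≈ 2.4) at 150 cells.

## Synthetic data

Because the per-cell organelle counts behind the measured yeast conditions
are not publicly deposited, the inference path is exercised on synthetic
analogues: Poisson counts (Golgi-like, diploid glucose peroxisomes),
shifted-Poisson counts at the measured vacuole means (2.1 haploid, 3.6
diploid, 4.0 oleic), and mechanistically generated over-dispersed counts
from the fusion-free SSA, parameterized by
`k_fission⟨n⟩/k_denovo = Fano − 1` (exact for this linear chain). Sample
sizes mirror the reported N (141, 95, 129, 153, 127, 154, 138). Means not
reported anywhere are placeholders: haploid Golgi 3.0, haploid glucose
peroxisome 3.4 (half the diploid 6.8), oleic peroxisome 7.0; none affects a
Fano-level claim. Per-condition seeds are spawned positionally from the
root seed so conditions use independent streams.

What passing on synthetic data does *not* show: robustness to detection
failures (missed or spurious spots), segmentation error, cell-cycle-phase
heterogeneity, or any real-data deviation from the four-process model.
Zero counts compared against a support-from-1 reference warn rather than
fail for exactly this reason.

## Validation-sweep study conditions

The percent error between the closed-form and simulated Fano factor,
`100·(calculated − simulated)/simulated`, is tracked along sweeps of each
rate constant that tune the mean from ~1 to ~4.6. The claim that the
approximation improves with the mean is regime-dependent: in weak-fusion
bases the error along a *fission* sweep grows toward criticality rather
than shrinking, while with fusion comparable to decay all three sweeps are
cleanly monotone (verified against the exact solver, Spearman −1). The
sweep tests therefore use a common strong-fusion base
(k_denovo 0.6, k_fission 0.8, k_fusion 0.6, γ 0.3); the complementary
claim — errors below a few percent at mean ≥ 2 — is tested in a
weak-fusion (peroxisome-like) base where the formula is near-exact. Sweep
simulations use 20,000 replicates per grid point, which keeps Monte-Carlo
noise (~1.5% on a Fano estimate) far below the systematic trends being
asserted while holding the full suite to a few minutes on one CPU.

## Known limitations

* The halving-partition equality check fails by construction (above); it is
  the one deliberately red check in the suite.
* The mixed fusion+decay Fano expression is implemented as printed, without
  an independent derivation.
* The fluctuation-dissipation predictor degrades near criticality
  (`k_fission → γ` with weak fusion) and at means below ~1.
* Endpoint sampling discards within-trajectory information; time-averaged
  estimators would be more efficient but are not what the histogram
  construction models.
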