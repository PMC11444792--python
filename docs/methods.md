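# Methods

## Model

The package is built around a single physical premise: in the burst range
a fish's drag scales as `F_D = Γ U_r^β` with the relative velocity, with
the exponent theoretically confined to `β ∈ [1.73, 2.0]` (pressure drag
alone gives 2; accounting for skin friction and body undulation lowers
the admissible floor to 1.73). The band is treated as a given constant
pair (`theory.BETA_MIN`, `theory.BETA_MAX`), overridable wherever it is
used as a check; its hydrodynamic derivation is outside the package's
scope. For pressure drag the lumped scale is `Γ = ρ L S` (density ×
length × body depth); for other drag mechanisms Γ has different internal
structure, but only the lumped value ever matters here, so viscosity,
drag coefficient and tail-beat amplitude are absorbed constants.

Swimming power is `F_D · U_r = Γ U_r^(β+1)`. A fish with anaerobic
reserve `E_i` (reserve × conversion efficiency, in arbitrary absorbed
units) fatigues at `T_fi = E_i / (Γ U_r^(β+1))`. Because `Γ` and the
distribution of `E` are velocity-independent for fish of one species and
size at one temperature, every moment of `T_f` inherits a pure power law
in `U_r`: slope `−(β+1)` for the mean, `−k(β+1)` for the k-th central
moment. All proportionalities are implemented as equalities with constant
1 — the package never uses an absolute drag or energy, only scaling, so
absolute magnitudes are explicitly not modelled.

In fixed-velocity flume tests the relative velocity is approximated by
the bulk flow velocity, `U_r ≈ U_f`; the estimation and design modules
are written in terms of `U_f` accordingly.

## Synthetic experiment generator

`simulate_experiment` emulates a fixed-velocity campaign: independent
fish (one trial per fish, never reused), a handful of test velocities,
trial failure, and occasional partly-aerobic trials.

Generator defaults, chosen once as the conditions the package's tests and
acceptance runs are performed under:

| parameter | default | rationale |
|---|---|---|
| fork length | truncated normal 4.87 ± 0.46 cm on [4.0, 6.6] | the riffle-dace row of the emulated campaign's summary table |
| body depth | `S = 0.22 L` | deep-bodied small cyprinid proportion; the true allometry is species-specific and config-exposed |
| mass | `m = K L³`, `K = 1.56/4.87³` | Fulton condition matching the table's mean mass; metadata only |
| energy reserve | lognormal, log-mean `ln 6.5e6`, log-sd 0.5 | strictly positive and right-skewed; places mean `T_f` at ≈ 8–22 s over 40–55 cm/s (the burst range) with the large inter-individual spread real data show; units are arbitrary since only velocity scaling matters |
| `beta_true` | 2.0 | upper band edge (pure pressure drag) |
| failure probability | 0 (presets: per-species observed rates, overall ≈ 26%) | unsuccessful trials carry no `T_f` |
| aerobic outliers | off by default; probability decays as `(U_min/U)^6`, inflation uniform on [5, 20]× | see below |
| temperature | metadata only | campaigns hold it within ±1 °C; no temperature effect is modelled |

Energy families: `lognormal` (default), `gamma` (matched mean and CV),
`point` (degenerate — the noiseless oracle for exactness tests). The
distribution of reserves is a generator choice, not something the theory
prescribes.

**Aerobic contamination.** Real burst campaigns occasionally record long
times caused by partly aerobic swimming, and these occur predominantly at
the *lower* test velocities. The generator therefore makes the outlier
probability decay with velocity, `p(U) = p₀ (U_min/U)^q` (default q = 6,
halving roughly every 11% of velocity; q = 0 gives uniform
contamination). The mechanism is a simple multiplicative inflation of
`T_f`, not a mechanistic aerobic-endurance model — the simplest mechanism
that reproduces the qualitative bias. Note that *uniform* multiplicative
contamination scales the per-velocity mean and variance by
velocity-independent constants and therefore does not bias the fitted
slopes at all; the documented upward bias of β̂ under contamination is a
consequence of the velocity preference, which is why the preference is
the default.

## Estimation pipeline

1. **Subsampling.** Moments must be taken over fish "of the same size".
   Successful trials are sorted by fork length and swept greedily: a
   window opens at the smallest unassigned length and absorbs fish while
   `max/min ≤ (1+tol)/(1−tol)` (tol = 0.10), the widest spread compatible
   with every member lying within ±10% of a common center. Windows are
   disjoint, cover all successful trials, and are deterministic (ties by
   row order). Overlapping or size-balanced windowings are plausible
   alternatives; the greedy disjoint sweep was chosen for reproducibility
   and because every group provably satisfies the ±10% rule.
2. **Moments.** Per group and velocity: arithmetic mean, and central
   moments with the population (divide-by-n) convention, matching the
   plain averaging operator of the derivation (`ddof=1` switches the
   variance to the sample convention). Velocities with a single
   successful trial contribute to the mean series only.
3. **Regression.** OLS of `ln(moment)` on `ln(U_f)`, one point per
   velocity level, unweighted (no weighting is prescribed; per-velocity
   sample sizes are near-equal by design). At least three usable levels
   are required; non-positive moments are dropped with a logged warning.
   Significance is the overall F-test of zero slope — with one predictor,
   the squared slope t-test — and fits with p ≥ 0.05 are screened out but
   still reported. No multiplicity correction is applied across groups.
4. **Exponent and reliability.** `β̂ = −slope/k − 1`; non-negative slopes
   are flagged non-physical rather than raised. Each fit carries
   `ReI = p ln(U_max/U_min)` with `p` the individual trials behind the
   used velocity levels (not the number of levels).

**Pooled summary.** A campaign yields one fit per (group, k). The
package's single-number summary, `PipelineResult.pooled(k)`, is the
ReI-weighted average of slopes/β̂ over physical fits — ReI is the
framework's own trust weight, and pooling uses all groups rather than
discarding all but the best one (empirically ~35% lower per-campaign
spread than the best-group choice at the default conditions).

**Densities and intervals.** Per-velocity `p(T_f)` is estimated with a
Gaussian KDE (Silverman bandwidth — the bandwidth rule is not prescribed,
and Silverman is the conventional default for unimodal-ish data) on a
grid over `[0, max + 3h]`; mass the kernels put below zero is excluded
and the raw integral reported, not renormalized. Bootstrap intervals are
percentile intervals over case resamples (≥100 replicates), reproducible
given a seed.

## Degenerate inputs and numerical choices

- Noiseless inputs make the regression residual exactly (to round-off)
  zero and the F statistic degenerate: a perfect fit with non-zero slope
  is assigned p = 0, a constant series (zero explained variation) p = 1
  and a zero-slope, non-physical flag.
- Degenerate samples elsewhere are handled, not raised: point-mass
  energies give zero variances (dropped from log fits with a warning),
  identical bootstrap samples give zero-width intervals, two identical
  values give a single narrow KDE peak.
- The closed-form maximum distance is asserted (in tests) against
  numerical maximization of the swim-distance function to a relative
  1e-6 across `β ∈ [1.5, 2.5]`.
- Moment order defaults to `k_max = 2`: third and higher central moments
  need far larger samples than realistic campaigns provide.

## Problem sizes

The test suite and acceptance script use campaign sizes a desk run
completes in seconds: the noiseless oracle uses 50 fish per velocity;
stochastic recovery uses 500 fish per velocity × 4 velocities × 20 seeds;
the reliability-trend study spans 10→500 fish per velocity and 3→4
velocity levels at 40 seeds per configuration. These are the package's
study conditions; the recovery tolerances quoted in the tests were sized
to the sampling error at exactly these sizes.

## Scope and limitations

- The generator emulates the *statistical* structure of fixed-velocity
  campaigns (individual spread, failures, aerobic outliers), not flume
  hydraulics, motivation/tapping behaviour, repeated-measures
  correlation, temperature effects, or lactate physiology. Passing tests
  show the estimator recovers exponents under the generator's
  assumptions; real data can violate them (e.g. non-lognormal reserves,
  size-dependent energy density, velocity-dependent motivation).
- The fitted `α̂₁ = exp(intercept)` mapping assumes the mean curve is
  exactly the power law; with few velocity levels the intercept is far
  less stable than the slope, and design distances inherit that
  uncertainty.
- Design algebra applies to the *average* fish; half the population
  fatigues earlier than `D_s_max` predicts. It also presumes the fish can
  actually reach `U_r_opt`; if not, the optimum sits at the fish's
  maximum attainable speed.
- Empirical β̂ for real species requires real trials tables; the package
  ships none and makes no species-specific empirical claims.
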