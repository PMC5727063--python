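# Methods

## The conductance model

The simulator treats ion transport through a low-aspect-ratio pore as
quasi-static and purely geometric: at every instant the system is a series
chain of thin conducting slices perpendicular to the pore axis.

* **Open pore.** Inside the membrane (thickness `L_pore`, diameter
  `d_pore`) each slice has area `π (d_pore/2)²`; integrating gives the
  cylindrical pore term `L_pore/(κ π (d_pore/2)²)`. The converging field
  outside the channel contributes the classical access (Hall) term
  `1/(2 κ d_pore)` per side. `open_pore_resistance` is their sum; for the
  reference device (3 µm × 40 nm, κ = 0.16 S/m) the access terms dominate
  60:1, which is what makes the sensor shape- rather than volume-sensitive.
* **Access discretization.** For the blocked integral the access regions are
  rendered as expanding discs of radius `d_pore/2 + |z − z_face|`, truncated
  at `5 d_pore` per side, with a constant far-field closure chosen so the
  unblocked total equals the analytic `R_open` *exactly, by construction,
  for any grid*. Only the particle-induced excess
  `∫ [1/(κ(A_open − A_particle)) − 1/(κ A_open)] dz` is then discretized.
* **Quadrature.** `blocked_resistance` uses the fixed region grids
  (`L_pore/20` inside the membrane, `d_pore/200` in the access cones), with
  subintervals additionally split at the particle's profile breakpoints and
  integrated by 2-point Gauss–Legendre. The splitting matters: the excess
  integrand has slope discontinuities at cap–body junctions and particle
  tips, and an unaligned midpoint rule leaves O(10 Ω) errors against the
  ~2 Ω scale of a 10⁻⁶ relative comparison. The test suite checks 20 random
  configurations against an independent 10×-finer kink-split midpoint
  quadrature at 10⁻⁶ relative.
* **Trace evaluation.** `resistance_profile` evaluates the same excess
  integral in the *particle frame* (the particle cross-section is sampled
  once; only the cheap open-area term varies with position), which makes
  whole-trace evaluation vectorizable. It agrees with the scalar path to
  ~10⁻⁵ relative — three orders below the 13 pA noise floor — and the
  simulator interpolates it from a `d_pore/400` position grid with a
  monotone cubic. Samples outside the particle's influence zone
  (`half_length + L_pore/2 + 5 d_pore`) are exactly baseline.

Not modeled (deliberately): electroosmosis, surface-charge (zeta) effects,
particle rotation and off-axis paths, flagellar motility, and the full
coupled electrokinetic (Poisson–Nernst–Planck–Navier–Stokes) problem. The
model is meant to reproduce pulse *shapes* — cap-roundness-dependent apex
bluntness, per-cocci corrugations, pre-entry current decrease — not absolute
transport coefficients.

## Particle geometries

* **RoundedRod** (`D = 800 nm`, `Lb = 2.6 µm`): cylindrical body with
  elliptical end caps of axial height `h = min(R, Lb/2)` and radial
  semi-axis `D/2`. A cap-roundness parameter must cover both `R ≪ D/2`
  (nearly flat ends) and `R > D/2` (strongly rounded); a circular fillet
  cannot reach the large-`R` end of that range and a spherical cap cannot
  reach the small-`R` end, so one smooth elliptical family is used for all
  `R`. `R = 10 nm` is an almost flat-ended cylinder and serves as the
  normalization reference for the bluntness-vs-roundness curve. In this
  geometry the normalized bluntness *decreases* strictly with `R` (rounder
  caps taper the excluded volume gradually, sharpening the apex); the
  package asserts strict monotonicity and records the direction rather than
  assuming one.
* **Volume matching.** When classes with different `R` are compared, the
  body length is extended by `2(h − h_ref)/3` so the total volume equals the
  reference particle's — the comparison then isolates shape from volume,
  and the `I_p`/`t_d` distributions of the two classes overlap by
  construction (exact to machine precision; the suite checks 0.1%).
* **CocciChain** (`b = 400 nm`, `a = 500 nm`, neck 280 nm): `n` identical
  prolate spheroids overlapping so the chain necks to `neck_diameter` at the
  junction planes; the center spacing follows as
  `s = 2a √(1 − (neck/2b)²)`. The radial profile has exactly `n` maxima,
  and a noise-free translocation through the bacterium-sized pore
  (1.4 µm × 40 nm) yields exactly `n` prominence-filtered apex maxima for
  `n = 1…4`.

## Synthetic data: what it emulates, what it does not

`generate_dataset` emulates the study conditions: two volume-matched rod
classes (cap roundness 200 nm vs 1100 nm), 179 pulses per class, 1 MHz
sampling, white Gaussian noise of 13 pA rms, zero drift by default. Each
particle carries multiplicative lognormal size jitter (CV 0.05, all linear
dimensions) and lognormal translocation velocity (mean 3 mm/s — giving the
ms-scale dwell times of the reference recordings — CV 0.3), one event per
trace. `generate_mixture` draws event labels with probability
∝ concentration × per-class capture rate (the capture-rate asymmetry is a
user parameter, default 1:1) and returns hidden truth separately.

The generator does **not** emulate: correlated (1/f or amplifier) noise,
baseline wander beyond a linear drift, multi-particle co-translocations,
off-axis or tumbling trajectories, pore clogging, or biological
within-species shape variation beyond isotropic scaling. Passing tests
therefore demonstrate that the pipeline recovers what this model encodes —
they bound algorithmic, not biological, generalization.

## Detection

Following the two-stage scheme: baseline removal by linear fits to 0.5 s
segments; candidate events where the depth (baseline − current) crosses
60 pA, with regions bounded by the 10 pA rising edge; boundaries refined to
where the signal holds beyond 5σ, minus/plus 256-sample margins
(`t_s` is 0.256 ms before the 5σ rise at 1 MHz). Choices the scheme itself
leaves open:

* **Event masking.** Baseline fits exclude samples inside *confirmed*
  candidate regions (grown by the margin). Masking every sample above the
  10 pA edge instead would clip the noise distribution one-sidedly
  (10 pA ≈ 0.77σ) and bias the baseline by ~0.4σ.
* **σ estimation.** Scaled median absolute deviation over event-free
  samples near the event; recovers a known rms within a few percent.
* **Onset confirmation.** An event must hold the 60 pA threshold for ≥ 2
  consecutive samples; 60 pA is only 4.6σ at the reference noise, and
  single-sample excursions would otherwise contribute ~0.1 false events per
  10⁵ samples.
* **Run definition.** Boundary crossings require ≥ 3 consecutive samples
  beyond/below 5σ, preventing single-sample triggers.
* **Fragment merging.** Confirmed events whose regions are closer than the
  margin are merged: noise dips below the 10 pA edge otherwise fragment a
  pulse's shallow tails into spurious duplicate events.
* **Polarity and ties.** Detection operates on positive-down depth; upward
  excursions are ignored; equal minima resolve to the earliest sample.
* **Noise-free traces.** σ estimates below 10⁻³ of the rising edge fall
  back to a fixed boundary level of half the rising edge.

One known bias, characterized rather than hidden: the access-resistance
tail of a pulse never fully returns to baseline within a finite trace, so
the fitted baseline absorbs a sub-pA fraction of it; on the very shallow
tail slope this shifts the 5σ boundary crossing by tens of samples relative
to an oracle that knows the true baseline. Boundaries are self-consistent
within the pipeline (the boundary *logic* is verified to ±2 samples against
the exact depth signal), and β_apex, which depends on `t_d` only through
normalization, is insensitive at the achieved accuracy.

## Features

All descriptors operate on the normalized pulse, so they are invariant to
depth scaling and time translation by construction. Conventions that had to
be fixed:

* **Level convention.** `Y_th` is measured down from the apex:
  crossings at `I_norm = 1 − Y_th/100` (a baseline-referenced flag exists).
  β_apex is reported at `Y_th ∈ {15, 30, 50}`.
* **Onset angle.** θ = arctan(1/r) with `r` the normalized apex position
  measured from the onset (symmetric pulse → arctan 2; apex at the end →
  π/4; at the onset → π/2).
* **Crossings.** Linear interpolation between bracketing samples —
  sub-sample precision with no model assumptions.
* **Partitions.** `n = 50` for areas and inertia. Section means integrate
  the piecewise-linear pulse exactly (sample grid merged with section
  boundaries), and the height-band widths of `I_w` are exact Lebesgue
  measures at band centers; both therefore converge at O(1/n²) and match
  10⁵-point dense recomputations (and the Fubini identity
  `I_w = ∫ i³/3 dt`) to 10⁻³.
* **Feature-vector catalog.** The 60-vector composition is declared in
  config and fully overridable (results always carry the catalog hash):
  10 scalars {`I_p`, `t_d`, β@15, β@30, β@50, θ, `A`, `r_m`, `I_m`, `I_w`}
  × 6 augmentation modes {scalar alone; + 64-point resampled `I_norm`;
  + first/last crossing times over a 5–95% `Y_th` ladder; + both;
  + first difference of the resampled current; + all three}.

## Classification

* **KDE classifier**: features standardized globally, per-class
  per-dimension Silverman bandwidths, product Gaussian kernels, equal
  priors by default. On the 1-D two-Gaussian toy problem its accuracy
  reaches the closed-form Bayes rate Φ(1) ≈ 0.841 within 0.03.
* **Rotation Forest**: per tree, features are partitioned into
  `min(3, n_features)` random disjoint subsets; each subset's rotation
  block is a full principal-axes transform fit on a 75% bootstrap of a
  random non-empty class subset; blocks assemble into an orthonormal
  rotation; majority vote over 10 trees. The base-learner roster is a
  configurable list over standard families (trees, nearest-neighbor,
  naive Bayes, discriminant, logistic, margin-based); `@k` aliasing
  provides grid-shape parity with rosters of any printed size (e.g. 67,
  giving the 60 × 67 = 4020-cell grid).
* **Cross validation**: stratified, seeded, aggregate metrics pooled from
  per-fold confusion counts (not fold-averaged). With 179 items per class
  and 10 folds, test folds hold at most 18 per class against 322 teachers.
  The positive class defaults to the first label alphabetically.
  Ill-defined precision/recall (TP = 0) is flagged, and F is reported as 0
  with the flag rather than silently.
* **Reduced grid**: the shipped default scores 4 feature vectors
  (β@30; β@30 + current; `I_p`; β@50 + current + crossings) × 3
  Rotation-Forest bases (tree, Gaussian NB, 1-NN) = 12 cells — enough to
  span scalar-only, waveform-augmented and size-only behavior at interactive
  runtimes. On the full study conditions the best cell reaches ≥ 97% CV
  accuracy across seeds while the KDE on (`I_p`, `t_d`) stays near chance
  (≈ 47–53%), as volume matching intends.

## Mixtures

`classify_mixture` assigns every pulse exactly one label and reports
`r_B = N_B/N_E` (flagged infinite when `N_E = 0`). Expected behavior under
error follows the closed identity
`E[r] = (ρ(1−ε)+ε)/(ρε+(1−ε))` for symmetric per-class error ε and true
ratio ρ, verified against simulation. Capture-rate asymmetry produces the
sublinear `r_B(C_B)` bending; no quantitative mixture value is asserted
beyond monotonicity, since capture physics is outside the model.

## Problem sizes

Defaults were chosen so the full chain stays interactive on one CPU: the
acceptance run (358 traces at 1 MHz, detection, featurization, 12-cell
10-fold grid) completes in about a minute; the analysis drivers default to
40 pulses per class (`--n 179` restores the full conditions); the test
suite runs in under a minute.

## Reproducibility

Every stochastic component (noise, jitter, label draws, CV shuffling,
forest construction) flows from explicit integer seeds; the pipeline
expands one root seed per stage. Identical seeds give bit-identical traces
and byte-identical run summaries; results carry seeds and the
feature-catalog hash.
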