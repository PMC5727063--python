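# porescope

Resistive-pulse **shape** discrimination of single bacteria in
ultra-low-aspect-ratio pores.

## The problem

A Coulter-type pore sensor reports each particle passing through it as a
transient dip in the cross-pore ionic current. Classically the dip height
`I_p` measures particle *volume* and the width `t_d` its time of flight —
which is useless for telling apart two rod-shaped bacteria of nearly equal
volume and surface charge (e.g. *E. coli* vs *B. subtilis*). In a pore whose
membrane is far thinner than its diameter (aspect ratio
`AR = L_pore/d_pore ≈ 0.01`), however, most of the sensing volume lies in the
*access* regions outside the channel, and the fine waveform of each pulse
encodes the local particle shape sliding past the orifice. `porescope`
implements the full analysis chain that turns that observation into a
single-cell shape classifier:

1. **`pulse_sim`** — a quasi-static conductance model: the pore + electrolyte
   is a series chain of thin slices,
   `R_open = L_pore/(κ π (d_pore/2)²) + 1/(κ d_pore)` (pore term + two Hall
   access terms), and an axisymmetric particle (a `RoundedRod` with
   cap-roundness `R`, or a `CocciChain` of spheroidal cells) raises the slice
   resistances it overlaps. Synthetic 1 MHz traces add seeded white noise
   (13 pA rms by default) and optional drift.
2. **`pulse_detect`** — two-stage event extraction: a 60 pA onset threshold
   and 10 pA rising edge find candidate events on the baseline-subtracted
   depth signal; boundaries are refined to the 5σ noise crossings with
   256-sample margins, defining `t_s`, `t_e`, `t_d = t_e − t_s` and `I_p`.
3. **`features`** — shape descriptors of the normalized pulse
   (`I_norm = I_ion/I_p`, `t_norm ∈ [0,1]`), chiefly the apex bluntness

       β_apex = 1/(m t_d²) · Σᵢ (tᵢ − t_s − t_ave)²,

   the variance of the m times `tᵢ` at which the pulse crosses a level
   `Y_th` percent below its apex (0 for a needle, 0.25 for a flat top), plus
   the onset angle θ, areas `A = A_L + A_R`, ratio `r_m = A_L/A_R` and the
   waveform inertia `I_m = Σ tᵢ² A_lat,i`, `I_w = Σ hᵢ² A_long,i`. A catalog
   composes these into 60 named feature vectors.
4. **`classify`** — two engines: a product-Gaussian kernel-density classifier
   on a feature pair, and Rotation-Forest ensembles (block-orthonormal
   principal-axes rotations per tree) over exchangeable base learners, scored
   on a (feature vector × classifier) grid by cross-validated
   `F_Meas = 2 P_pre P_rec/(P_pre + P_rec)`.
5. **`mixture`** — applies a trained classifier to mixed-population pulses
   and reports the assigned-class ratio `r_B` versus the nominal
   concentration ratio `C_B`.

## Worked example

The numbered drivers under `analysis/` walk the whole chain; computation
lives in `src/porescope/` so every step is importable and tested.

```
$ python analysis/01_pore_model.py
reference pore (d = 3 um, L = 40 nm, AR = 0.013): R_open = 2.119 MOhm, baseline I = 23.6 nA
beta_norm decreases with R: R=10nm -> 1.000, R=100nm -> 0.962, R=200nm -> 0.918,
  R=400nm -> 0.828, R=600nm -> 0.742, R=800nm -> 0.663, R=1100nm -> 0.565
1-cocci chain: depth 1224 pA, 1 apex maxima
...
4-cocci chain: depth 1376 pA, 4 apex maxima
size sensitivity: 2.08 nm/pA; resolution at 13 pA rms: 27 nm
```

The open-pore figures are the analytic access + pore decomposition; the
bluntness curve shows that rounder end caps produce *sharper* (lower-β)
apices in this geometry, strictly monotone in `R`; each cocci chain yields
exactly one apex corrugation per cell, and the ≈250 pA per-cocci step over
the (800 − 280) nm thick-to-neck difference implies ≈2 nm of radial size per
pA, i.e. a ≈26 nm shape resolution at the 13 pA noise floor.

```
$ python analysis/02_simulate_dataset.py && python analysis/03_detect_featurize.py
$ python analysis/04_classifier_grid.py
F_Max = 0.976 at ('beta_apex_50+curr+cross', 'rotation_forest(gaussian_nb)'); best CV accuracy 97.5%
size features only (KDE on I_p, t_d): 51.2% accuracy
```

On 40 volume-matched pulses per class (cap roundness 200 nm vs 1100 nm) the
waveform-shape grid discriminates the classes at ≈98% while the size-only
baseline is near chance — the volume matching removes exactly the
information a classical Coulter analysis relies on. `05_mixture_sweep.py`
then counts the two classes in simulated mixtures (`r_B` rises monotonically
with `C_B`).

The same pipeline is scriptable via the CLI
(`porescope run config.yaml`, or staged `simulate | detect | featurize |
classify | grid | mixture`).

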