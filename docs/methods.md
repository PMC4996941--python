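# Methods

This note documents the models, estimators and numerical choices behind
`trsfx`, and what its synthetic-data tests do and do not demonstrate about
real serial-crystallography data.

## Conventions

* Resolution variable `s = 1/d` everywhere. The isotropic Debye-Waller
  factor is `exp(−B s²/4)` on amplitudes and `exp(−B s²/2)` on intensities.
* Fractional symmetry operators act as `x' = R x + t`; the reciprocal
  (index) action is `h' = h·R`, under which `F(h') = F(h)·exp(−2πi h·t)`.
* Map synthesis: `ρ(x) = (1/V)·Σ_h F(h)·exp(−2πi h·x)` over the full sphere
  (ASU coefficients expanded through the space-group operators plus Friedel
  completion), evaluated by FFT on a 2,3,5-smooth grid with spacing
  ≤ d_min/3 per axis. Friedel-inconsistent input is rejected, not averaged.
* Space groups: P1 and P6₃ only, with hard-coded operators verified for
  closure and against gemmi in the test suite. P6₃'s Laue group is 6/m
  (order 12) and its unique nontrivial indexing-ambiguity operator is
  `(h,k,l) → (k,h,−l)`.

## Synthetic data (the study conditions)

The two-state toy is 30 atoms (C/N/O/S, electron-count form factors) in a
20 Å cell, 20% of them rigidly displaced by 1.5 Å to form the activated
state; structure factors are computed by direct summation to d_min = 2.3 Å
and mixed **coherently**, `F_mix = (1−α)F_dark + αF_M`, because both states
share one lattice (an incoherent intensity-mixing mode exists for
sensitivity tests). The default activated fraction is α = 0.13, matching the
low activation level of femtosecond-laser pumping. Atomic form factors are a
constant electron count times the Debye-Waller term — no angle-dependent
Cromer-Mann coefficients. This is sufficient (and exactly invertible) for
internal-consistency and recovery tests; absolute densities are not
physical electron densities.

Serial observations: each crystal carries a hidden log-normal scale
(spread 0.3 in log), a normal relative B (spread 8 Å²), a Bernoulli
indexing-setting flip, a random ~70% reflection subset, and 3% relative
Gaussian intensity noise (2–5% in specific tests, stated per test).
Saturation is a per-observation flag (intensity above a threshold), standing
in for pixel-level detector saturation, which would need images. The
simulator assumes a single global α — crystal-to-crystal variability of the
activated fraction is not modelled.

Photocycle: a sequential first-order chain `bR → K → L → M → N → bR` with
illustrative default rates (5·10⁶, 2.5·10⁴, 2.5·10³, 4·10², 10² s⁻¹) chosen
so the deprotonated, 412 nm-absorbing intermediate peaks near 1 ms with a
~40 µs step earlier in the cycle; they are not literature rate constants.
The last state is absorbing (recovered ground, Δε = 0), so populations sum
to the excited fraction at all times.

## Merging

Scaling runs a fixed number of cycles (default 3, per standard serial
practice, without any partiality model): merge everything into an unweighted
reference, then fit per crystal `ln(I_c/I_ref) = ln k_c − B_c s²/2` by
linear least squares and divide the correction out. After the final cycle:

* crystals with `|B_c| > 100 Å²` are rejected (the bound is symmetric);
* each crystal's **conservative resolution limit** — a quantity the field
  leaves loosely defined — is taken as the highest-resolution of 10
  equal-volume shells whose mean I/σ ≥ 1; its reflections are kept to that
  limit **plus 0.3 nm⁻¹ in 1/d**;
* saturated observations are excluded from every fit, reference and merge.

A single crystal scales to `k = 1, B = 0` exactly (its own merge is its
reference). Merged intensity is the unweighted mean per canonical index
(Monte-Carlo merging); merged sigma is `SD/√n` for multiplicity ≥ 2 and the
propagated single-observation sigma otherwise — a convention choice, stated
here because no standard exists. Completeness counts the full ASU sphere to
d_min. Half-data-set statistics split crystals by parity of their index
(even/odd crystal, not observation parity — the alternative would mix
within-crystal correlations into the halves). `CC*` is reported as undefined
(NaN) when `CC_1/2 ≤ 0` rather than imaginary.

Indexing-ambiguity resolution is the greedy iteration: random initial
labels, correlate every crystal with the current merged reference under both
indexings, take the better, repeat to convergence (ties keep the current
label; crystals sharing < 3 reflections with the reference are flagged
unassigned). The solution is defined modulo a global flip; an optional
external reference (model intensities or an oriented data set) pins the
global orientation — the pipeline uses the dark-model intensities so the
dark and light merges land in one common setting, which matters because a
difference map between oppositely-oriented merges is meaningless.

## Difference maps and the activated fraction

Wilson scaling between amplitude sets fits `ln(|F_ref|/|F_t|) = ln k − B s²/4`
on bin-averaged log ratios (equal-count bins, weighted by population,
≥ 3 populated bins required); scaling maps the target onto the reference.

Difference coefficients are unweighted `(|F_light| − |F_dark|)·exp(iφ_dark)`
(σ-based weighting is a possible future option). Peaks are 26-neighbour
local extrema of the periodic grid at |ρ| ≥ threshold·σ_map, merged within
1.0 Å (strongest wins) and annotated with the nearest model atom.

**Dark-subtraction sweep.** Maps of `|F_mix| − m·|F_dark|` (with dark model
phases) are synthesised over m = 0…0.95 in steps of 0.01. Residual dark
features are scored by projecting each swept map onto the component of the
dark reference density orthogonal to the activated reference density; this
unnormalised residual is exactly linear in m, so its zero crossing m* is
interpolated (or extrapolated from the boundary segment, clamped to [0,1])
exactly. Two systematic effects separate m* from 1−α and are corrected by
construction rather than by calibration constants:

1. amplitude-only difference coefficients carry about **half** the true
   state difference (the classic factor-of-two of isomorphous difference
   maps), and
2. the overall scale of the mixed data is not unity even after Wilson
   scaling, because coherent mixing itself lowers the mean amplitude
   (fitted k ≈ 1.02 at α = 0.13).

Modelling the mixed map as `k·(ρ_D + (α/2)(ρ_M − ρ_D))` (amplitude mode) or
`k·((1−α)ρ_D + αρ_M)` (complex mode) gives the scale-invariant estimator

    α = f·(1 − ρ) / (1 − ρ + ρ·g),   ρ = m*/q,   f = 2 (amplitude) | 1 (complex)

where q is the projection of the mixed map onto the dark map actually
subtracted and g is the dark projection of the activated reference density.
It is exact in the noiseless complex case and exact to first order in α in
amplitude mode; measured bias on the default toy is ≤ 0.005 for α ≤ 0.3 and
≈ 0.04 at α = 0.5, where the linearisation of |F_mix| degrades. The reported
`m_star` is the effective cancellation point `1 − α` (so the documented
invariant α = 1 − m* holds); the raw crossing is exposed separately.

**Occupancy refinement** minimises `Σ_h (|F_obs| − k·|(1−α)F_dark + αF_M|)²`
with k in closed form per α, a Δα = 0.01 grid scan, and bounded scalar
polishing to 1e-4. It needs no bias correction because it models the
coherent mixture exactly; identical dark and activated models raise a
"states indistinguishable" error. In the end-to-end pipeline the observed
amplitudes are first Wilson-scaled onto the calculated dark amplitudes —
the overall k/B step any refinement program applies — which removes the
resolution-dependent scale error left by merging.

## Kinetics

Chain populations use the closed-form Bateman solution for pairwise-distinct
decay constants; rates closer than 1e-6 relative switch to the matrix
exponential of the rate matrix — exact for a linear chain and free of the
catastrophic cancellation of the simple-pole form (a confluent closed form
would be equivalent; the matrix exponential is simpler and as accurate).
The peak time of an intermediate is found by bracketing the analytic
derivative of its exponential-sum population on a log grid and polishing
with Brent's method (≈ 1e-12 relative; for A→B→C it reproduces
`ln(k1/k2)/(k1−k2)` to machine precision).

Multi-exponential fitting is variable projection: amplitudes and the
(optional, default-on) offset are solved linearly for each trial set of log
time constants, and only the log-τ vector is optimised (Levenberg-Marquardt,
≥ 10 seeded multi-starts: one log-spaced, the rest uniform in the padded
log-time window). Time constants are reported sorted ascending. Offsets can
be pinned to zero by flag. `find_peak_time` interpolates a parabola through
the three points around the discrete maximum and flags boundary maxima.

## Structure metrics

PDB/mmCIF parsing is gemmi's; alternate locations keep the
highest-occupancy conformer (ties: first encountered); waters are residues
named HOH (plus common synonyms). Cα superposition pairs residues by chain
id + residue number (unpaired counts are reported, never silently dropped)
and uses Kabsch SVD with the proper-rotation determinant correction. Local
RMSD selects reference atoms within a radius of a named centre atom and
reports the atom count so selection conventions are auditable; the
superposition can be global (all-Cα transform), local (refit on the
selection) or none. Solvent content uses the standard protein partial
specific volume constant 1.230 Å³/Da; RMSDs are reported in Å.

## Pipeline and reproducibility

One top-level seed is stretched into per-stage streams by SHA-256 hashing of
the stage name (sub-seeds < 2³¹), so toggling one stage never changes
another stage's random numbers. All reductions run in fixed index order;
reruns with the same config and seed are byte-identical. Fixture sets:
`tiny` (12 atoms, 8 crystals, d_min 3 Å — seconds, < 1 MB) and `demo`
(the default study conditions above).

## Problem sizes

Defaults are desk-scale by design: ~1,400 unique reflections (P1 toy,
2.3 Å), 8–128 crystals in merging studies, 40 crystals in the demo pipeline,
50 crystals in the ambiguity study, 121-point time grids, and 20-seed
Monte-Carlo repeats in the bias tests.

## Known limitations

* Electron densities are toy densities: constant form factors, no solvent,
  no anomalous signal, no mosaicity or partiality physics (the merging model
  assumes Monte-Carlo averaging handles partiality, as the no-partiality
  scaling mode does in practice).
* Sharp atoms (B ≈ 15 Å²) at 2.3 Å band limit produce series-termination
  sidelobes up to ~2.5 Å from atoms at the 3σ level; difference-peak
  localisation tests therefore use ADPs typical of the resolution
  (B = 35 Å²), where the maps are sidelobe-clean. Real maps face the same
  physics.
* The sweep's bias correction is first order in α; above α ≈ 0.4 the
  refinement route is the more accurate estimator.
* Passing recovery tests on this generator shows the estimators are
  correct and unbiased **under the stated measurement model**; real data add
  indexing errors, non-isomorphism, beam fluctuations and detector artifacts
  that the generator does not emulate.
* Space-group support is intentionally limited to P1 and P6₃.
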