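# trsfx

A toy-scale, fully tested implementation of the computational analysis chain
behind a pump-probe **time-resolved serial femtosecond crystallography
(TR-SFX)** experiment, built for method developers and students who want to
study each stage of the pipeline against known ground truth rather than
against irreproducible raw detector data.

In a TR-SFX experiment, thousands of micro-crystals each contribute one noisy
snapshot diffraction pattern; an optical pump pulse converts a fraction α of
the molecules to a transient conformation before the X-ray probe arrives.
The analysis questions this package answers on synthetic data with known
truth are the real experiment's questions:

* **Merging.** Per-crystal intensities `I = k_c·exp(−B_c s²/2)·|F|²·(1+ε)`
  (with `s = 1/d`) must be scaled, outliers rejected (|relative B| > 100 Å²,
  saturated observations, per-crystal conservative resolution limits extended
  by 0.3 nm⁻¹ in 1/d), and Monte-Carlo averaged. Quality is measured by
  half-data-set statistics
  `R_split = (1/√2)·Σ|I_even−I_odd| / (½·Σ(I_even+I_odd))`,
  `CC_1/2` (Pearson) and `CC* = √(2·CC_1/2/(1+CC_1/2))`.
* **Indexing ambiguity.** In merohedral space groups such as P6₃ every
  snapshot can be indexed in either of two settings related by
  `(h,k,l) → (k,h,−l)`; an iterative correlation-with-reference algorithm
  assigns each crystal to one cluster (defined up to a global flip).
* **Difference maps.** Isomorphous difference Fourier maps with coefficients
  `(|F_light| − |F_dark|)·exp(iφ_dark)` reveal the conformational change
  without phase bias toward any intermediate model; peaks are contoured in
  units of the map RMSD (σ).
* **Activated fraction.** Dark-state-subtracted maps
  `n·F_obs(light) − m·F_obs(dark)` (n = 1, m swept over a grid) cancel
  residual dark features at `m* ≈ 1 − α`; independently, two-conformer
  occupancy refinement minimises
  `Σ_h (|F_obs| − k·|(1−α)F_dark + α·F_M|)²` over (α, k). The two estimates
  confirm each other.
* **Photocycle kinetics.** Pump-probe absorption traces
  `ΔA(λ,t) = Σ_s c_s(t)·(ε_s(λ) − ε_ground(λ))` follow a sequential
  first-order chain (Bateman populations); three-exponential fits and
  parabolic peak interpolation locate the delay of maximal intermediate
  accumulation.
* **Structure metrics.** Kabsch Cα superposition RMSD, local-selection RMSD,
  triclinic cell volume, Matthews coefficient `V_M = V/(Z·MW)` and solvent
  content `100·(1 − 1.230/V_M)`.

Everything is driven by a synthetic-data module with complete ground truth:
a two-state toy crystal (dark + displaced conformer sharing one lattice,
coherently mixed as complex structure factors), serial observation lists
with hidden per-crystal scales/relative-B/flip bits, and photocycle traces.

## Worked example

```bash
python examples/estimate_activation_fraction.py
```

prints (numbers from an actual run):

```
Wilson scaling of mixed onto dark: k = 1.0180, B = -0.60 A^2 over 1388 reflections
ground-truth activated fraction: 0.130
dark-subtraction sweep:          0.128 (residual dark features cancel near m = 0.951)
occupancy refinement:            0.126 (scale 1.029)
```

A 13% coherent mixture with 3% amplitude noise was scaled onto the dark
data; the map sweep and the occupancy refinement independently recover the
activated fraction to within ~0.005 of the truth. Note the Wilson `k`
slightly above 1 — coherent mixing lowers the mean amplitude, a real effect
the sweep estimator must be (and is) invariant to.

The other examples exercise the remaining stages:

```bash
python examples/merge_serial_dataset.py       # ambiguity + scaling + Rsplit/CC1/2/CC*
python examples/photocycle_kinetics.py        # 3-exponential fit, M-peak delay
python examples/compare_depositions.py A.pdb B.pdb   # Cα RMSD, waters, Matthews
```

For shell use, the same stages are exposed as a thin CLI:

```bash
trsfx fixtures --seed 0 --scale tiny --out fx
trsfx merge --obs fx/observations_dark.csv --cell 16,16,18,90,90,120 --spacegroup P63
trsfx run --seed 42 --out run42       # full simulate→merge→map→occupancy→kinetics chain
```

`trsfx run` is bit-reproducible: the same seed and config give byte-identical
CSV/JSON outputs.

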