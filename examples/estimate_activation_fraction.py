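"""Estimate the activated-state fraction of a partially photoactivated crystal.

A two-state toy structure (dark resting state + a conformer with part of the
atoms rigidly displaced) stands in for a light-activated protein crystal.
Structure-factor amplitudes of a coherent 13% mixture, with 3% measurement
noise, are analysed exactly as a time-resolved experiment would be: Wilson
scaling onto the dark data, a dark-state-subtraction map sweep, and
two-conformer occupancy refinement.
"""

import numpy as np

from trsfx import (
    AmplitudeSet,
    build_two_state_toy,
    calc_structure_factors,
    dark_subtraction_sweep,
    mix_states,
    occupancy_refine,
    wilson_scale,
)

ALPHA_TRUE = 0.13

dark, m_state = build_two_state_toy(seed=42, n_atoms=30, displacement_A=1.5,
                                    displaced_fraction=0.2)
f_dark = calc_structure_factors(dark, d_min=2.3)
f_m = calc_structure_factors(m_state, d_min=2.3)
f_mix = mix_states(f_dark, f_m, ALPHA_TRUE)

rng = np.random.default_rng(1)
amp_dark = f_dark.to_amplitude_set("dark")
noisy_mix = AmplitudeSet(
    hkl=f_mix.hkl, amp=np.abs(f_mix.f) * (1 + rng.normal(0, 0.03, len(f_mix))),
    sigma=0.03 * np.abs(f_mix.f), cell=f_mix.cell, spacegroup=f_mix.spacegroup,
    label="mix_1ms",
)
scale_model, scaled_mix = wilson_scale(amp_dark, noisy_mix)
print(f"Wilson scaling of mixed onto dark: k = {scale_model.k:.4f}, "
      f"B = {scale_model.b:+.2f} A^2 over {scale_model.n_common} reflections")

sweep = dark_subtraction_sweep(scaled_mix, amp_dark, phases=f_dark.to_phase_set(),
                               reference_m=m_state, reference_dark=dark,
                               d_min=2.3, mode="amplitude")
refine = occupancy_refine(scaled_mix, f_dark, f_m)

print(f"ground-truth activated fraction: {ALPHA_TRUE:.3f}")
print(f"dark-subtraction sweep:          {sweep.alpha:.3f} "
      f"(residual dark features cancel near m = {sweep.raw_crossing:.3f})")
print(f"occupancy refinement:            {refine.alpha:.3f} "
      f"(scale {refine.scale:.3f})")
print("Both estimates should sit within ~0.03 of the truth: the sweep reads the")
print("fraction off the map series, the refinement fits it against amplitudes.")
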