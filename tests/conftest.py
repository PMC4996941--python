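import numpy as np
import pytest

from trsfx import (
    UnitCell,
    build_two_state_toy,
    calc_structure_factors,
    mix_states,
    space_group,
)


@pytest.fixture(scope="session")
def toy_pair():
    """Standard two-state toy in P1: 30 atoms, 1.5 Å shift of 20%."""
    return build_two_state_toy(seed=42, n_atoms=30, displacement_A=1.5,
                               displaced_fraction=0.2)


@pytest.fixture(scope="session")
def toy_sf(toy_pair):
    """Structure factors of the toy pair to 2.3 Å."""
    dark, m = toy_pair
    return calc_structure_factors(dark, 2.3), calc_structure_factors(m, 2.3)


@pytest.fixture(scope="session")
def hex_toy():
    """Small two-state toy in P6_3 (hexagonal cell)."""
    cell = UnitCell(16.0, 16.0, 18.0, 90.0, 90.0, 120.0)
    return build_two_state_toy(seed=5, n_atoms=12, displacement_A=1.2,
                               displaced_fraction=0.25, cell=cell,
                               spacegroup="P63")


@pytest.fixture(scope="session")
def p63():
    return space_group("P63")


@pytest.fixture(scope="session")
def p1():
    return space_group("P1")


def brute_force_structure_factor(model, hkl):
    """Naive double-loop direct summation oracle (atoms x symops)."""
    out = np.zeros(len(hkl), dtype=complex)
    for i, h in enumerate(np.asarray(hkl, dtype=int)):
        d = model.cell.d_spacing(h)
        s2 = 1.0 / d**2
        total = 0.0 + 0.0j
        for op in model.spacegroup.symops:
            rot = op.rot_array
            trans = op.trans_array
            for atom in model.atoms:
                x = rot @ np.asarray(atom.frac) + trans
                f = atom.electrons * atom.occupancy * np.exp(-atom.b_iso * s2 / 4.0)
                total += f * np.exp(2j * np.pi * float(np.dot(h, x)))
        out[i] = total
    return out
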