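"""Two-state toy crystal structures and direct-summation structure factors.

The toy emulates a photoactivated crystal: a "dark" resting structure and an
activated "M" structure that differs by a rigid displacement of a subset of
atoms, sharing one lattice.  Scattering uses a deliberately simplified atomic
form factor — a constant electron count modulated by the isotropic
Debye-Waller term exp(-B s²/4) on amplitudes (s = 1/d) — which preserves
every property the downstream recovery tests rely on while avoiding
angle-dependent Cromer-Mann parameterisations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .reflections import ReflectionSet
from .symmetry import SpaceGroupInfo, UnitCell, reduce_to_asu, space_group

__all__ = [
    "Atom",
    "ToyModel",
    "build_two_state_toy",
    "calc_structure_factors",
    "mix_states",
]

# nominal electron counts for the elements the toy generator uses
_ELECTRONS = {"H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16, "FE": 26}


@dataclass(frozen=True)
class Atom:
    element: str
    frac: tuple  # fractional coordinates
    occupancy: float = 1.0
    b_iso: float = 0.0  # Å²
    electrons: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")
        if self.b_iso < 0:
            raise ValueError("isotropic B must be non-negative")
        if self.electrons is None:
            try:
                ne = float(_ELECTRONS[self.element.upper()])
            except KeyError:
                raise ValueError(f"unknown element {self.element!r}; pass electrons=")
            object.__setattr__(self, "electrons", ne)


@dataclass
class ToyModel:
    """Atomic model in a unit cell: the substrate for structure factors."""

    atoms: list
    cell: UnitCell
    spacegroup: SpaceGroupInfo
    label: str = "dark"

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("model must contain at least one atom")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def frac_coords(self) -> np.ndarray:
        return np.array([a.frac for a in self.atoms], dtype=float)

    @property
    def electron_counts(self) -> np.ndarray:
        return np.array([a.electrons for a in self.atoms], dtype=float)

    @property
    def occupancies(self) -> np.ndarray:
        return np.array([a.occupancy for a in self.atoms], dtype=float)

    @property
    def b_factors(self) -> np.ndarray:
        return np.array([a.b_iso for a in self.atoms], dtype=float)

    def with_label(self, label: str) -> "ToyModel":
        return replace(self, label=label)


def build_two_state_toy(
    seed: int,
    n_atoms: int = 30,
    displacement_A: float = 1.5,
    displaced_fraction: float = 0.2,
    cell: UnitCell | None = None,
    spacegroup: str = "P1",
    b_iso: float = 15.0,
    cluster: bool = False,
) -> tuple[ToyModel, ToyModel]:
    """Generate a dark/activated pair differing by a rigid displacement.

    A random ``displaced_fraction`` of the atoms is translated by a single
    random direction of length ``displacement_A`` (Cartesian Å) to form the
    activated state; identity and ordering of atoms are preserved, so the
    ground-truth correspondence is trivial.  With ``cluster=True`` the moved
    atoms are the ones closest to a random centre (mimicking a localised
    conformational change such as a helix shift); otherwise a random subset.
    """
    if n_atoms < 3:
        raise ValueError("n_atoms must be at least 3")
    if displacement_A < 0:
        raise ValueError("displacement must be non-negative")
    if not 0.0 < displaced_fraction <= 1.0:
        raise ValueError("displaced_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    if cell is None:
        cell = UnitCell(20.0, 20.0, 20.0)
    sg = space_group(spacegroup)
    # keep atoms inside a sub-volume so symmetry copies do not collide
    frac = rng.uniform(0.05, 0.45, size=(n_atoms, 3))
    elements = rng.choice(["C", "N", "O", "S"], size=n_atoms, p=[0.55, 0.2, 0.2, 0.05])
    b = np.clip(rng.normal(b_iso, 3.0, size=n_atoms), 2.0, None)

    n_disp = max(1, int(round(displaced_fraction * n_atoms)))
    if cluster:
        centre = frac[rng.integers(n_atoms)]
        order = np.argsort(np.linalg.norm(cell.frac_to_cart(frac - centre), axis=1))
        idx = np.sort(order[:n_disp])
    else:
        idx = np.sort(rng.choice(n_atoms, size=n_disp, replace=False))
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    shift_cart = displacement_A * direction
    shift_frac = np.linalg.solve(cell.orthogonalization, shift_cart)

    dark_atoms, m_atoms = [], []
    moved = np.zeros(n_atoms, dtype=bool)
    moved[idx] = True
    for i in range(n_atoms):
        pos = frac[i]
        dark_atoms.append(Atom(elements[i], tuple(pos), 1.0, float(b[i])))
        mpos = pos + shift_frac if moved[i] else pos
        m_atoms.append(Atom(elements[i], tuple(mpos), 1.0, float(b[i])))
    dark = ToyModel(dark_atoms, cell, sg, label="dark")
    m = ToyModel(m_atoms, cell, sg, label="M")
    return dark, m


def unique_asu_hkl(cell: UnitCell, spacegroup: SpaceGroupInfo, d_min: float) -> np.ndarray:
    """All ASU-unique Miller indices with d >= d_min ((0,0,0) excluded)."""
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    axes = cell.orthogonalization.T  # rows = real-space axis vectors
    lims = [int(np.ceil(np.linalg.norm(ax) / d_min)) for ax in axes]
    grids = np.meshgrid(*[np.arange(-m, m + 1) for m in lims], indexing="ij")
    hkl = np.stack([g.ravel() for g in grids], axis=1)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    d = cell.d_spacing(hkl)
    hkl = hkl[d >= d_min - 1e-9]
    canon = reduce_to_asu(hkl, spacegroup)
    uniq = np.unique(canon, axis=0)
    # stable ordering: sort by (h, k, l)
    order = np.lexsort((uniq[:, 2], uniq[:, 1], uniq[:, 0]))
    return uniq[order]


def calc_structure_factors(model: ToyModel, d_min: float,
                           hkl: np.ndarray | None = None) -> ReflectionSet:
    """Direct-summation structure factors on the ASU-unique index set.

    F(h) = Σ_ops Σ_j occ_j · n_e,j · exp(-B_j s²/4) · exp(2πi h·(R x_j + t)),
    with s = 1/d.  Friedel mates are not duplicated (for the real scattering
    factors used here F(-h) = conj F(h)).
    """
    if model is None or len(model) == 0:
        raise ValueError("empty model")
    if hkl is None:
        hkl = unique_asu_hkl(model.cell, model.spacegroup, d_min)
    hkl = np.asarray(hkl, dtype=int)
    d = model.cell.d_spacing(hkl)
    s2 = 1.0 / d**2

    x = model.frac_coords  # (n_atoms, 3)
    weights = model.electron_counts * model.occupancies  # (n_atoms,)
    b = model.b_factors
    dw = np.exp(-np.outer(s2, b) / 4.0)  # (n_hkl, n_atoms)

    f = np.zeros(len(hkl), dtype=complex)
    for op in model.spacegroup.symops:
        h_rot = hkl @ op.rot_array  # reciprocal action, (n_hkl, 3)
        phase = 2.0 * np.pi * (h_rot @ x.T + (hkl @ op.trans_array)[:, None])
        f += np.sum(weights[None, :] * dw * np.exp(1j * phase), axis=1)
    return ReflectionSet(hkl=hkl, f=f, cell=model.cell,
                         spacegroup=model.spacegroup, d_min=d_min, d=d)


def mix_states(f_dark: ReflectionSet, f_m: ReflectionSet, alpha: float,
               mode: str = "coherent") -> ReflectionSet:
    """Two-conformer mixture F_mix = (1-α)·F_dark + α·F_M.

    Coherent (complex) combination is the physical default for two states
    sharing one lattice; ``mode="incoherent"`` combines intensities instead
    (|F|² mixed) for sensitivity tests.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if f_dark.hkl.shape != f_m.hkl.shape or np.any(f_dark.hkl != f_m.hkl):
        map_d, map_m = f_dark.index_map(), f_m.index_map()
        for h in map_d:
            if h not in map_m:
                raise ValueError(f"index sets differ: {h} present only in dark set")
        for h in map_m:
            if h not in map_d:
                raise ValueError(f"index sets differ: {h} present only in M set")
        raise ValueError("index sets ordered differently; reorder before mixing")
    if mode == "coherent":
        f = (1.0 - alpha) * f_dark.f + alpha * f_m.f
    elif mode == "incoherent":
        amp = np.sqrt((1.0 - alpha) * np.abs(f_dark.f) ** 2 + alpha * np.abs(f_m.f) ** 2)
        f = amp * np.exp(1j * np.angle(f_dark.f))
    else:
        raise ValueError("mode must be 'coherent' or 'incoherent'")
    return ReflectionSet(hkl=f_dark.hkl.copy(), f=f, cell=f_dark.cell,
                         spacegroup=f_dark.spacegroup, d_min=f_dark.d_min,
                         d=f_dark.d.copy())
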