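"""Unit cells, space-group operators and reflection-index symmetry.

Only the two space groups the toy pipeline needs are supported: triclinic
P1 and hexagonal P6_3 (the merohedral group in which serial snapshots carry
a twofold indexing ambiguity).  Operators are hard-coded and verified for
closure in the test suite rather than pulled from a symmetry library, so
that the reciprocal-space conventions used throughout the package are
explicit in one place.

Conventions
-----------
* Fractional real-space operators act as ``x' = R @ x + t``.
* The reciprocal-space (index) action of a rotational part ``R`` is
  ``h' = h @ R`` (row vector times matrix), under which ``|F(h')| = |F(h)|``
  and ``F(h') = F(h) * exp(-2*pi*i h.t)``.
* ``s = 1/d`` is used everywhere as the resolution variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import cos, radians, sin, sqrt

import numpy as np

__all__ = [
    "UnitCell",
    "SymOp",
    "SpaceGroupInfo",
    "space_group",
    "reduce_to_asu",
]


@dataclass(frozen=True)
class UnitCell:
    """Crystallographic unit cell (lengths in Å, angles in degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        if not np.isfinite(self.volume) or self.volume <= 0:
            raise ValueError("degenerate unit cell (non-positive volume)")

    @property
    def _cos_term(self) -> float:
        ca, cb, cg = (cos(radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg

    @property
    def volume(self) -> float:
        """Cell volume in Å³ (general triclinic formula)."""
        term = self._cos_term
        if term <= 0:
            return float("nan")
        return self.a * self.b * self.c * sqrt(term)

    @property
    def orthogonalization(self) -> np.ndarray:
        """3x3 matrix mapping fractional to Cartesian (Å) coordinates."""
        ca, cb, cg = (cos(radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = sin(radians(self.gamma))
        v = sqrt(self._cos_term)
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, self.c * v / sg],
            ]
        )

    @property
    def reciprocal_metric(self) -> np.ndarray:
        """Reciprocal metric tensor G* with 1/d² = h · G* · h."""
        m = self.orthogonalization
        return np.linalg.inv(m.T @ m)

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray:
        """Resolution d (Å) of Miller indices; hkl of shape (..., 3)."""
        hkl = np.asarray(hkl, dtype=float)
        inv_d2 = np.einsum("...i,ij,...j->...", hkl, self.reciprocal_metric, hkl)
        with np.errstate(divide="ignore"):
            return 1.0 / np.sqrt(inv_d2)

    def frac_to_cart(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.orthogonalization.T

    def min_image_distance(self, frac_a: np.ndarray, frac_b: np.ndarray) -> np.ndarray:
        """Minimum-image Cartesian distance between fractional positions.

        Exact for the modest cells used here (searches the 27 neighbouring
        cells explicitly, valid also for non-orthogonal cells).
        """
        delta = np.asarray(frac_a, float) - np.asarray(frac_b, float)
        delta -= np.round(delta)
        shifts = np.array(
            [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
        )
        cand = delta[..., None, :] + shifts
        dists = np.linalg.norm(cand @ self.orthogonalization.T, axis=-1)
        return dists.min(axis=-1)


@dataclass(frozen=True)
class SymOp:
    """Space-group operator: fractional rotation part and translation."""

    rot: tuple  # 3x3 nested tuple of ints
    trans: tuple = (0.0, 0.0, 0.0)

    @property
    def rot_array(self) -> np.ndarray:
        return np.array(self.rot, dtype=int)

    @property
    def trans_array(self) -> np.ndarray:
        return np.array(self.trans, dtype=float)


def _mat(*rows) -> tuple:
    return tuple(tuple(r) for r in rows)


_IDENTITY = _mat((1, 0, 0), (0, 1, 0), (0, 0, 1))
_INVERSION = _mat((-1, 0, 0), (0, -1, 0), (0, 0, -1))


@dataclass(frozen=True)
class SpaceGroupInfo:
    """Symmetry content needed by the pipeline.

    ``symops`` generate the crystal symmetry (used for structure factors and
    map expansion); ``laue_ops`` are the reciprocal rotation parts of the
    Laue group including Friedel inversion (used for ASU reduction);
    ``ambiguity_ops`` are index relabelings that preserve the lattice metric
    but are not Laue operations — the source of the serial indexing
    ambiguity in merohedral groups.
    """

    symbol: str
    symops: tuple = field(default_factory=tuple)
    laue_ops: tuple = field(default_factory=tuple)  # tuples of 3x3 int
    ambiguity_ops: tuple = field(default_factory=tuple)

    @property
    def laue_arrays(self) -> np.ndarray:
        return np.array([np.array(m) for m in self.laue_ops], dtype=int)

    @property
    def ambiguity_op(self) -> np.ndarray | None:
        if not self.ambiguity_ops:
            return None
        return np.array(self.ambiguity_ops[0], dtype=int)

    @property
    def n_symops(self) -> int:
        return len(self.symops)


def _laue_from_rotations(rots) -> tuple:
    """Close the set of rotation parts under Friedel inversion."""
    seen = {}
    inv = np.array(_INVERSION)
    for r in rots:
        arr = np.array(r, dtype=int)
        for m in (arr, arr @ inv):
            seen[_mat(*m.tolist())] = True
    return tuple(seen.keys())


def space_group(symbol: str) -> SpaceGroupInfo:
    """Return hard-coded symmetry for ``"P1"`` or ``"P63"``/``"P6_3"``."""
    key = symbol.replace(" ", "").replace("_", "").upper()
    if key == "P1":
        ops = (SymOp(_IDENTITY),)
        return SpaceGroupInfo(
            symbol="P1",
            symops=ops,
            laue_ops=_laue_from_rotations([_IDENTITY]),
            ambiguity_ops=(),
        )
    if key == "P63":
        half = (0.0, 0.0, 0.5)
        rots = [
            _IDENTITY,                                   # 1
            _mat((0, -1, 0), (1, -1, 0), (0, 0, 1)),     # 3+ (z)
            _mat((-1, 1, 0), (-1, 0, 0), (0, 0, 1)),     # 3- (z)
            _mat((-1, 0, 0), (0, -1, 0), (0, 0, 1)),     # 2 (z), screw
            _mat((1, -1, 0), (1, 0, 0), (0, 0, 1)),      # 6+ (z), screw
            _mat((0, 1, 0), (-1, 1, 0), (0, 0, 1)),      # 6- (z), screw
        ]
        trans = [(0, 0, 0), (0, 0, 0), (0, 0, 0), half, half, half]
        ops = tuple(SymOp(r, t) for r, t in zip(rots, trans))
        # Twofold index relabeling along a+b: (h,k,l) -> (k,h,-l); this is the
        # unique nontrivial coset of 6/m in the holohedral Laue group 6/mmm.
        amb = _mat((0, 1, 0), (1, 0, 0), (0, 0, -1))
        return SpaceGroupInfo(
            symbol="P6_3",
            symops=ops,
            laue_ops=_laue_from_rotations(rots),
            ambiguity_ops=(amb,),
        )
    raise ValueError(f"unsupported space group {symbol!r} (P1 and P6_3 only)")


def reduce_to_asu(hkl: np.ndarray, laue_ops) -> np.ndarray:
    """Map indices to a canonical asymmetric-unit representative.

    The representative of the orbit of ``h`` under the Laue group (Friedel
    mates included) is the lexicographically greatest equivalent index.
    Total and idempotent; shape-preserving for (..., 3) input.
    """
    if isinstance(laue_ops, SpaceGroupInfo):
        ops = laue_ops.laue_arrays
    else:
        ops = np.asarray(laue_ops, dtype=int)
        if ops.ndim == 2:
            ops = ops[None]
    hkl_in = np.asarray(hkl, dtype=int)
    single = hkl_in.ndim == 1
    hkl = np.atleast_2d(hkl_in)
    # (n_ops, n, 3) all equivalents, then lexicographic max per reflection
    equiv = np.einsum("nj,oji->oni", hkl, ops)
    # lexicographic key: compare h, then k, then l
    best = equiv[0].copy()
    for cand in equiv[1:]:
        c0, b0 = cand[:, 0], best[:, 0]
        c1, b1 = cand[:, 1], best[:, 1]
        c2, b2 = cand[:, 2], best[:, 2]
        better = (c0 > b0) | ((c0 == b0) & ((c1 > b1) | ((c1 == b1) & (c2 > b2))))
        best[better] = cand[better]
    return best[0] if single else best


def apply_index_op(hkl: np.ndarray, op: np.ndarray) -> np.ndarray:
    """Apply a reciprocal-space index operator: h' = h @ op."""
    return np.atleast_2d(np.asarray(hkl, dtype=int)) @ np.asarray(op, dtype=int)
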