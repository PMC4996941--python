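"""Wilson scaling, difference-Fourier coefficients, map synthesis and peaks.

Map synthesis follows the standard crystallographic convention
ρ(x) = (1/V)·Σ_h F(h)·exp(−2πi h·x), with ASU coefficients expanded to the
full sphere through the space-group operators (F(h·R) = F(h)·exp(−2πi h·t))
and Friedel completion, evaluated on an FFT grid whose spacing is at most
d_min/3 by default.  Map values are therefore in electrons/Å³ for true
structure-factor input; contouring and peak heights use σ_map, the RMSD of
the grid values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .reflections import AmplitudeSet, PhaseSet, ReflectionSet
from .symmetry import SpaceGroupInfo, UnitCell

__all__ = [
    "ScaleModel",
    "wilson_scale",
    "CoefficientSet",
    "difference_coefficients",
    "DensityMap",
    "synthesize_map",
    "Peak",
    "find_peaks",
    "map_correlation",
]


# ---------------------------------------------------------------------------
# Wilson scaling between amplitude sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScaleModel:
    """Linear scale and relative Wilson B mapping a target onto a reference."""

    k: float
    b: float  # Å²
    residual: float  # RMS of the binned log-linear fit
    n_common: int = 0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("scale must be positive")

    def apply_amplitudes(self, amp: np.ndarray, s2: np.ndarray) -> np.ndarray:
        return self.k * np.exp(-self.b * s2 / 4.0) * amp


def wilson_scale(
    reference: AmplitudeSet,
    target: AmplitudeSet,
    n_bins: int = 10,
    min_bins: int = 3,
) -> tuple[ScaleModel, AmplitudeSet]:
    """Fit (k, B) so that k·exp(−B s²/4)·|F_target| matches |F_reference|.

    The fit is a weighted linear least squares of the bin-averaged log ratio
    ln(|F_ref|/|F_t|) against s², over equal-count resolution bins; the
    scaled target (amplitudes and sigmas multiplied by the fitted factor) is
    returned alongside.
    """
    map_r = reference.index_map()
    rows = [(map_r[h], i) for i, h in enumerate(map(tuple, target.hkl)) if h in map_r]
    if len(rows) < 20:
        raise ValueError(f"only {len(rows)} common reflections; need at least 20")
    ri = np.array([r[0] for r in rows])
    ti = np.array([r[1] for r in rows])
    fr = reference.amp[ri]
    ft = target.amp[ti]
    s2 = 1.0 / target.d[ti] ** 2
    ok = (fr > 0) & (ft > 0)
    fr, ft, s2 = fr[ok], ft[ok], s2[ok]

    order = np.argsort(s2)
    n_bins_eff = min(n_bins, max(1, len(s2) // 5))
    bins = np.array_split(order, n_bins_eff)
    bins = [b for b in bins if len(b) > 0]
    if len(bins) < min_bins:
        raise ValueError(
            f"insufficient resolution coverage: {len(bins)} populated bins, need {min_bins}"
        )
    x = np.array([s2[b].mean() for b in bins])
    y = np.array([np.log(fr[b] / ft[b]).mean() for b in bins])
    w = np.array([len(b) for b in bins], dtype=float)
    # y = ln k − (B/4)·x, weighted by bin population
    design = np.stack([np.ones_like(x), -x / 4.0], axis=1)
    coef, *_ = np.linalg.lstsq(design * np.sqrt(w)[:, None], y * np.sqrt(w), rcond=None)
    ln_k, b_fit = coef
    resid = float(np.sqrt(np.average((design @ coef - y) ** 2, weights=w)))
    model = ScaleModel(k=float(np.exp(ln_k)), b=float(b_fit), residual=resid,
                       n_common=int(ok.sum()))

    s2_all = 1.0 / target.d**2
    factor = model.k * np.exp(-model.b * s2_all / 4.0)
    scaled = AmplitudeSet(
        hkl=target.hkl.copy(), amp=factor * target.amp, sigma=factor * target.sigma,
        cell=target.cell, spacegroup=target.spacegroup,
        label=f"{target.label}_scaled",
    )
    return model, scaled


# ---------------------------------------------------------------------------
# difference coefficients
# ---------------------------------------------------------------------------

@dataclass
class CoefficientSet:
    """Complex Fourier coefficients on an ASU index set."""

    hkl: np.ndarray
    values: np.ndarray  # complex
    cell: UnitCell
    spacegroup: SpaceGroupInfo
    n_dropped: int = 0  # reflections lacking a phase

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int)
        self.values = np.asarray(self.values, dtype=complex)

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def d(self) -> np.ndarray:
        return self.cell.d_spacing(self.hkl)

    @classmethod
    def from_reflection_set(cls, refl: ReflectionSet) -> "CoefficientSet":
        return cls(hkl=refl.hkl.copy(), values=refl.f.copy(),
                   cell=refl.cell, spacegroup=refl.spacegroup)

    def scaled(self, factor: complex) -> "CoefficientSet":
        return CoefficientSet(self.hkl.copy(), factor * self.values,
                              self.cell, self.spacegroup, self.n_dropped)


def difference_coefficients(
    f_light: AmplitudeSet, f_dark: AmplitudeSet, phases: PhaseSet
) -> CoefficientSet:
    """Isomorphous difference coefficients (|F_light| − |F_dark|)·exp(iφ_dark).

    The inputs must already be on a common scale (see :func:`wilson_scale`).
    Reflections missing a model phase are dropped and counted in
    ``n_dropped``.
    """
    map_d = f_dark.index_map()
    map_p = phases.index_map()
    hkl_out, vals = [], []
    n_dropped = 0
    n_common = 0
    for i, h in enumerate(map(tuple, f_light.hkl)):
        j = map_d.get(h)
        if j is None:
            continue
        n_common += 1
        p = map_p.get(h)
        if p is None:
            n_dropped += 1
            continue
        delta = f_light.amp[i] - f_dark.amp[j]
        vals.append(delta * np.exp(1j * np.radians(phases.phase_deg[p])))
        hkl_out.append(h)
    if n_common == 0:
        raise ValueError("light and dark amplitude sets share no reflections")
    if not hkl_out:
        raise ValueError("no common reflection carries a model phase")
    return CoefficientSet(
        hkl=np.array(hkl_out, int), values=np.array(vals, complex),
        cell=f_light.cell, spacegroup=f_light.spacegroup, n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# Fourier synthesis
# ---------------------------------------------------------------------------

@dataclass
class DensityMap:
    """Real-space density on a periodic fractional grid over the unit cell."""

    values: np.ndarray  # (n1, n2, n3)
    cell: UnitCell

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("map grid must be three-dimensional")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sigma(self) -> float:
        """Map RMSD about the mean — the σ used for contouring."""
        return float(self.values.std())

    def grid_fractions(self):
        return [np.arange(n) / n for n in self.shape]

    def __add__(self, other: "DensityMap") -> "DensityMap":
        return DensityMap(self.values + other.values, self.cell)

    def __sub__(self, other: "DensityMap") -> "DensityMap":
        return DensityMap(self.values - other.values, self.cell)

    def __mul__(self, scalar: float) -> "DensityMap":
        return DensityMap(self.values * scalar, self.cell)

    __rmul__ = __mul__

    def write_ccp4(self, path) -> None:
        """Write as a CCP4/MRC map (mode 2) via gemmi."""
        import gemmi

        grid = gemmi.FloatGrid(*self.shape)
        grid.set_unit_cell(gemmi.UnitCell(
            self.cell.a, self.cell.b, self.cell.c,
            self.cell.alpha, self.cell.beta, self.cell.gamma,
        ))
        arr = np.array(grid, copy=False)
        arr[...] = self.values.astype(np.float32)
        m = gemmi.Ccp4Map()
        m.grid = grid
        m.update_ccp4_header(2, True)
        m.write_ccp4_map(str(path))


def _fft_friendly(n: int) -> int:
    """Smallest 2,3,5-smooth integer >= n."""
    m = max(2, n)
    while True:
        r = m
        for p in (2, 3, 5):
            while r % p == 0:
                r //= p
        if r == 1:
            return m
        m += 1


def map_grid_shape(cell: UnitCell, d_min: float, factor: float = 3.0) -> tuple:
    """Grid with spacing <= d_min/factor along each cell axis."""
    return tuple(
        _fft_friendly(int(np.ceil(factor * length / d_min)))
        for length in (cell.a, cell.b, cell.c)
    )


def expand_to_sphere(coeffs: CoefficientSet, tol: float = 1e-6) -> dict:
    """Expand ASU coefficients to the full sphere (symmetry + Friedel).

    Raises if expansion produces conflicting values for one index — i.e. the
    input violates the symmetry it claims (including Friedel symmetry).
    """
    full: dict = {}

    def put(h: tuple, v: complex) -> None:
        prev = full.get(h)
        if prev is None:
            full[h] = v
        elif abs(prev - v) > tol * (abs(prev) + abs(v) + 1.0):
            raise ValueError(f"inconsistent coefficients for index {h} after expansion")

    for h, v in zip(coeffs.hkl, coeffs.values):
        for op in coeffs.spacegroup.symops:
            h_new = tuple(int(x) for x in (h @ op.rot_array))
            v_new = v * np.exp(-2j * np.pi * float(h @ op.trans_array))
            put(h_new, v_new)
            put(tuple(-x for x in h_new), np.conj(v_new))
    full.pop((0, 0, 0), None)
    return full


def synthesize_map(
    coeffs: CoefficientSet,
    d_min: float | None = None,
    grid_factor: float = 3.0,
    shape: tuple | None = None,
) -> DensityMap:
    """FFT Fourier synthesis ρ(x) = (1/V)·Σ_h F(h)·exp(−2πi h·x)."""
    if d_min is None:
        d_min = float(coeffs.d.min()) if len(coeffs) else 1.0
    if shape is None:
        shape = map_grid_shape(coeffs.cell, d_min, grid_factor)
    full = expand_to_sphere(coeffs)
    grid = np.zeros(shape, dtype=complex)
    n1, n2, n3 = shape
    for (h, k, l), v in full.items():
        if abs(h) >= n1 // 2 or abs(k) >= n2 // 2 or abs(l) >= n3 // 2:
            raise ValueError("grid too coarse for coefficient indices; lower d_min or raise grid_factor")
        grid[(-h) % n1, (-k) % n2, (-l) % n3] += v
    rho = np.fft.ifftn(grid) * (np.prod(shape) / coeffs.cell.volume)
    return DensityMap(values=rho.real, cell=coeffs.cell)


def map_correlation(a: DensityMap, b: DensityMap) -> float:
    """Pearson correlation of two maps on the same grid."""
    if a.shape != b.shape:
        raise ValueError("maps must share one grid")
    av = a.values.ravel() - a.mean
    bv = b.values.ravel() - b.mean
    na, nb = np.linalg.norm(av), np.linalg.norm(bv)
    if na == 0 or nb == 0:
        return float("nan")
    return float(av @ bv / (na * nb))


# ---------------------------------------------------------------------------
# peak search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Peak:
    frac: tuple            # fractional position
    height_sigma: float    # signed height in units of σ_map
    sign: int
    nearest_atom: str = ""
    nearest_distance: float = np.nan  # Å


def find_peaks(
    density: DensityMap,
    threshold_sigma: float = 3.0,
    model=None,
    merge_radius: float = 1.0,
) -> list:
    """Local extrema of the periodic map with |height| ≥ threshold·σ_map.

    Uses the 26-neighbour rule on the wrapped grid; peaks closer than
    ``merge_radius`` Å keep only the strongest.  If a
    :class:`~trsfx.toy.ToyModel` (or anything with ``frac_coords`` and
    ``atoms``) is given, each peak is annotated with its nearest atom.
    Returns peaks sorted by |height| descending.
    """
    sigma = density.sigma
    if sigma <= 0:
        return []
    v = density.values
    footprint = np.ones((3, 3, 3), bool)
    vmax = ndimage.maximum_filter(v, footprint=footprint, mode="wrap")
    vmin = ndimage.minimum_filter(v, footprint=footprint, mode="wrap")
    pos = (v >= vmax) & (v >= threshold_sigma * sigma)
    neg = (v <= vmin) & (v <= -threshold_sigma * sigma)

    shape = np.array(v.shape)
    raw = []
    for mask, sign in ((pos, 1), (neg, -1)):
        for idx in np.argwhere(mask):
            frac = idx / shape
            raw.append((float(v[tuple(idx)] / sigma), sign, tuple(frac)))
    raw.sort(key=lambda r: -abs(r[0]))

    kept = []
    cell = density.cell
    for height, sign, frac in raw:
        clash = False
        for other in kept:
            if cell.min_image_distance(np.array(frac), np.array(other[2])) < merge_radius:
                clash = True
                break
        if not clash:
            kept.append((height, sign, frac))

    peaks = []
    atom_frac = model.frac_coords if model is not None else None
    for height, sign, frac in kept:
        name, dist = "", np.nan
        if atom_frac is not None:
            dists = cell.min_image_distance(np.array(frac)[None, :], atom_frac)
            j = int(np.argmin(dists))
            atom = model.atoms[j]
            name = f"{atom.element}{j}"
            dist = float(dists[j])
        peaks.append(Peak(frac=frac, height_sigma=height, sign=sign,
                          nearest_atom=name, nearest_distance=dist))
    return peaks


def peaks_to_frame(peaks) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "x": p.frac[0], "y": p.frac[1], "z": p.frac[2],
                "height_sigma": p.height_sigma, "sign": p.sign,
                "nearest_atom": p.nearest_atom,
                "nearest_distance_A": p.nearest_distance,
            }
            for p in peaks
        ]
    )
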