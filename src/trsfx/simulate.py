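"""Synthetic serial-crystallography observations and pump-probe traces.

The measurement model for a serial experiment is deliberately minimal but
captures everything the merging stage must undo or reject:

* each crystal ``c`` carries a hidden multiplicative scale ``k_c``
  (log-normal) and a relative Debye-Waller factor ``B_c`` (normal), so the
  observed intensity is ``I = k_c · exp(-B_c s²/2) · |F|² · (1 + ε)`` with
  relative Gaussian noise ε (s = 1/d; the factor on intensities is the
  square of the amplitude convention exp(-B s²/4));
* each crystal may be indexed in the wrong merohedral setting, recorded by
  relabeling its indices through the space group's ambiguity operator;
* observations above a saturation threshold are flagged, never removed —
  downstream code must exclude them.

Ground truth (scales, relative Bs, flip bits) is returned alongside so
recovery can be tested quantitatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reflections import ReflectionSet
from .symmetry import SpaceGroupInfo, UnitCell, apply_index_op, reduce_to_asu

__all__ = [
    "SerialSimConfig",
    "ObservationList",
    "SerialGroundTruth",
    "simulate_serial_observations",
    "PhotocycleConfig",
    "TimeTrace",
    "simulate_photocycle_traces",
]


@dataclass(frozen=True)
class SerialSimConfig:
    n_crystals: int = 50
    fraction_observed: float = 0.6
    log_scale_spread: float = 0.3
    rel_b_spread: float = 10.0  # Å²
    noise: float = 0.05  # relative Gaussian sigma on intensities
    saturation_threshold: float = np.inf  # intensity units
    flip_probability: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_crystals < 1:
            raise ValueError("n_crystals must be at least 1")
        if not 0.0 < self.fraction_observed <= 1.0:
            raise ValueError("fraction_observed must lie in (0, 1]")
        if not 0.0 <= self.flip_probability <= 1.0:
            raise ValueError("flip_probability must lie in [0, 1]")
        if self.noise < 0 or self.log_scale_spread < 0 or self.rel_b_spread < 0:
            raise ValueError("spreads and noise must be non-negative")


@dataclass
class ObservationList:
    """Unmerged per-crystal intensity observations."""

    hkl: np.ndarray          # (n, 3) canonical ASU indices as recorded
    intensity: np.ndarray    # (n,)
    sigma: np.ndarray        # (n,) > 0
    crystal_id: np.ndarray   # (n,) dense integer ids
    saturated: np.ndarray    # (n,) bool
    cell: UnitCell
    spacegroup: SpaceGroupInfo

    def __post_init__(self) -> None:
        n = len(self.hkl)
        self.hkl = np.asarray(self.hkl, dtype=int)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.crystal_id = np.asarray(self.crystal_id, dtype=int)
        self.saturated = np.asarray(self.saturated, dtype=bool)
        for arr in (self.intensity, self.sigma, self.crystal_id, self.saturated):
            if len(arr) != n:
                raise ValueError("observation columns must have equal length")
        if np.any(self.sigma <= 0):
            raise ValueError("sigmas must be positive")

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def d(self) -> np.ndarray:
        return self.cell.d_spacing(self.hkl)

    @property
    def crystal_ids(self) -> np.ndarray:
        return np.unique(self.crystal_id)

    def subset(self, mask: np.ndarray) -> "ObservationList":
        return ObservationList(
            hkl=self.hkl[mask], intensity=self.intensity[mask],
            sigma=self.sigma[mask], crystal_id=self.crystal_id[mask],
            saturated=self.saturated[mask], cell=self.cell,
            spacegroup=self.spacegroup,
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "h": self.hkl[:, 0], "k": self.hkl[:, 1], "l": self.hkl[:, 2],
                "I": self.intensity, "sigma": self.sigma,
                "crystal_id": self.crystal_id,
                "saturated": self.saturated.astype(int),
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, cell: UnitCell, spacegroup: SpaceGroupInfo) -> "ObservationList":
        df = pd.read_csv(path)
        return cls(
            hkl=df[["h", "k", "l"]].to_numpy(dtype=int),
            intensity=df["I"].to_numpy(float), sigma=df["sigma"].to_numpy(float),
            crystal_id=df["crystal_id"].to_numpy(int),
            saturated=df["saturated"].to_numpy(int).astype(bool),
            cell=cell, spacegroup=spacegroup,
        )


@dataclass(frozen=True)
class SerialGroundTruth:
    """Hidden per-crystal parameters of a simulated serial data set."""

    scale: np.ndarray     # k_c
    rel_b: np.ndarray     # B_c, Å²
    flipped: np.ndarray   # bool


def simulate_serial_observations(
    f_true: ReflectionSet, cfg: SerialSimConfig
) -> tuple[ObservationList, SerialGroundTruth]:
    """Draw noisy per-crystal snapshot intensities from true structure factors."""
    rng = np.random.default_rng(cfg.seed)
    n_refl = len(f_true)
    if n_refl == 0:
        raise ValueError("empty reflection set")
    i_true = f_true.intensities
    s2 = 1.0 / f_true.d**2
    sg = f_true.spacegroup
    amb = sg.ambiguity_op

    scales = np.exp(rng.normal(0.0, cfg.log_scale_spread, size=cfg.n_crystals))
    rel_bs = rng.normal(0.0, cfg.rel_b_spread, size=cfg.n_crystals)
    flips = rng.random(cfg.n_crystals) < cfg.flip_probability
    if amb is None:
        flips[:] = False

    chunks = []
    for c in range(cfg.n_crystals):
        if cfg.fraction_observed >= 1.0:
            sel = np.arange(n_refl)
        else:
            mask = rng.random(n_refl) < cfg.fraction_observed
            if not mask.any():
                mask[rng.integers(n_refl)] = True
            sel = np.flatnonzero(mask)
        model_i = scales[c] * np.exp(-rel_bs[c] * s2[sel] / 2.0) * i_true[sel]
        eps = rng.normal(0.0, cfg.noise, size=len(sel)) if cfg.noise > 0 else 0.0
        obs_i = model_i * (1.0 + eps)
        sigma = np.maximum(cfg.noise * np.abs(model_i), 1e-6 * (np.abs(model_i) + 1e-12))
        hkl = f_true.hkl[sel]
        if flips[c]:
            hkl = reduce_to_asu(apply_index_op(hkl, amb), sg)
        chunks.append(
            (hkl, obs_i, sigma, np.full(len(sel), c), obs_i > cfg.saturation_threshold)
        )
    obs = ObservationList(
        hkl=np.concatenate([c[0] for c in chunks]),
        intensity=np.concatenate([c[1] for c in chunks]),
        sigma=np.concatenate([c[2] for c in chunks]),
        crystal_id=np.concatenate([c[3] for c in chunks]),
        saturated=np.concatenate([c[4] for c in chunks]),
        cell=f_true.cell, spacegroup=sg,
    )
    return obs, SerialGroundTruth(scale=scales, rel_b=rel_bs, flipped=flips)


# ---------------------------------------------------------------------------
# Pump-probe absorption traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhotocycleConfig:
    """Sequential photocycle and probe set-up for light-minus-dark traces.

    ``states`` is the ordered cycle starting from the photoexcited ground
    state; if the ground state is repeated at the end the cycle returns to
    it (the final state is always absorbing).  ``rates`` are the first-order
    rate constants (s⁻¹) of the ``len(states) - 1`` consecutive transitions.
    At t = 0 the excited fraction sits in the first state.  ``extinction``
    maps state name -> {wavelength nm: ε}; wavelengths present for the
    ground state define the probe channels (the photoexcited and recovered
    ground states contribute Δε = 0 by construction).  Default rates are
    illustrative, not literature values: they mimic a retinal-protein
    photocycle whose deprotonated, 412 nm-absorbing intermediate reaches
    maximal accumulation near 1 ms, with a ~40 µs step earlier in the cycle.
    """

    states: tuple = ("bR", "K", "L", "M", "N", "bR")
    rates: tuple = (5.0e6, 2.5e4, 2.5e3, 4.0e2, 1.0e2)  # s⁻¹, one per arrow
    extinction: dict = field(default_factory=lambda: {
        "bR": {412.0: 0.10, 570.0: 1.00},
        "K": {412.0: 0.15, 570.0: 1.10},
        "L": {412.0: 0.25, 570.0: 0.80},
        "M": {412.0: 1.00, 570.0: 0.05},
        "N": {412.0: 0.20, 570.0: 0.70},
    })
    excited_fraction: float = 0.13
    times: tuple = tuple(np.geomspace(1e-7, 1e-1, 121))
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise ValueError("need at least a ground state and one intermediate")
        if len(self.rates) != len(self.states) - 1:
            raise ValueError(
                f"expected {len(self.states) - 1} rates for {len(self.states)} states, "
                f"got {len(self.rates)}"
            )
        if any(k <= 0 for k in self.rates):
            raise ValueError("rates must be positive")
        if not 0.0 <= self.excited_fraction <= 1.0:
            raise ValueError("excited_fraction must lie in [0, 1]")
        if len(self.times) == 0:
            raise ValueError("empty time grid")
        t = np.asarray(self.times, float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        for st, spec in self.extinction.items():
            if any(v < 0 for v in spec.values()):
                raise ValueError(f"negative extinction for state {st}")

    @property
    def ground(self) -> str:
        return self.states[0]

    @property
    def state_columns(self) -> tuple:
        """Position-unique column names (duplicate names get a suffix)."""
        seen: dict = {}
        cols = []
        for name in self.states:
            if name in seen:
                seen[name] += 1
                cols.append(f"{name}_recovered" if name == self.ground
                            else f"{name}_{seen[name]}")
            else:
                seen[name] = 0
                cols.append(name)
        return tuple(cols)

    @property
    def cycle_closes(self) -> bool:
        return self.states[-1] == self.ground

    @property
    def wavelengths(self) -> tuple:
        return tuple(sorted(self.extinction[self.ground]))


@dataclass
class TimeTrace:
    """Light-minus-dark absorption traces ΔA(λ, t)."""

    times: np.ndarray                # s, strictly increasing
    delta_a: dict                    # wavelength -> np.ndarray
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        self.delta_a = {float(w): np.asarray(v, float) for w, v in self.delta_a.items()}
        for v in self.delta_a.values():
            if len(v) != len(self.times) or not np.all(np.isfinite(v)):
                raise ValueError("trace values must be finite and match the time grid")

    def to_csv(self, path) -> None:
        cols = {"time_s": self.times}
        for w in sorted(self.delta_a):
            cols[f"dA_{int(round(w))}"] = self.delta_a[w]
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TimeTrace":
        df = pd.read_csv(path)
        traces = {
            float(c.split("_", 1)[1]): df[c].to_numpy(float)
            for c in df.columns if c.startswith("dA_")
        }
        return cls(times=df["time_s"].to_numpy(float), delta_a=traces)


def simulate_photocycle_traces(cfg: PhotocycleConfig) -> TimeTrace:
    """Forward-model ΔA(λ, t) from the sequential photocycle.

    ΔA(λ, t) = Σ_s c_s(t) · (ε_s(λ) − ε_ground(λ)) + noise, where the
    populations c_s (including the recovered ground state, whose Δε is zero)
    sum to the excited fraction at every time.
    """
    from .kinetics import solve_chain_populations

    rng = np.random.default_rng(cfg.seed)
    times = np.asarray(cfg.times, float)
    pops = solve_chain_populations(cfg, times)  # DataFrame, one column per chain position
    eps_g = cfg.extinction[cfg.ground]
    traces = {}
    for w in cfg.wavelengths:
        da = np.zeros_like(times)
        for name, col in zip(cfg.states, cfg.state_columns):
            d_eps = cfg.extinction.get(name, eps_g).get(w, 0.0) - eps_g[w]
            if name == cfg.ground:
                d_eps = 0.0
            da += pops[col].to_numpy() * d_eps
        if cfg.noise_sd > 0:
            da = da + rng.normal(0.0, cfg.noise_sd, size=len(times))
        traces[w] = da
    return TimeTrace(times=times, delta_a=traces, noise_sd=cfg.noise_sd)
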