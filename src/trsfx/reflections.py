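"""Reflection containers: complex structure factors, amplitudes and phases.

CSV dialects (header required, one row per record):

* complex sets:   ``h,k,l,d,F_real,F_imag``
* amplitude sets: ``h,k,l,d,F,sigma``
* observations (see :mod:`trsfx.simulate`): ``h,k,l,I,sigma,crystal_id,saturated``
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .symmetry import SpaceGroupInfo, UnitCell

__all__ = ["ReflectionSet", "AmplitudeSet", "PhaseSet"]


def _check_hkl(hkl: np.ndarray) -> np.ndarray:
    hkl = np.asarray(hkl, dtype=int)
    if hkl.ndim != 2 or hkl.shape[1] != 3:
        raise ValueError("hkl must have shape (n, 3)")
    if np.any(np.all(hkl == 0, axis=1)):
        raise ValueError("(0,0,0) is not a valid reflection")
    return hkl


def _index_map(hkl: np.ndarray) -> dict:
    return {tuple(h): i for i, h in enumerate(hkl)}


@dataclass
class ReflectionSet:
    """ASU-unique complex structure factors with their resolution."""

    hkl: np.ndarray
    f: np.ndarray  # complex structure factors
    cell: UnitCell
    spacegroup: SpaceGroupInfo
    d_min: float
    d: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.hkl = _check_hkl(self.hkl)
        self.f = np.asarray(self.f, dtype=complex)
        if len(self.f) != len(self.hkl):
            raise ValueError("hkl and F length mismatch")
        if self.d is None:
            self.d = self.cell.d_spacing(self.hkl)
        seen = set(map(tuple, self.hkl))
        if len(seen) != len(self.hkl):
            raise ValueError("duplicate Miller indices in reflection set")
        if not np.all(np.isfinite(self.f)):
            raise ValueError("non-finite structure factors")

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.abs(self.f)

    @property
    def intensities(self) -> np.ndarray:
        return np.abs(self.f) ** 2

    def index_map(self) -> dict:
        return _index_map(self.hkl)

    def to_amplitude_set(self, label: str, sigma: np.ndarray | None = None) -> "AmplitudeSet":
        sig = np.zeros(len(self)) if sigma is None else np.asarray(sigma, float)
        return AmplitudeSet(
            hkl=self.hkl.copy(), amp=np.abs(self.f), sigma=sig,
            cell=self.cell, spacegroup=self.spacegroup, label=label,
        )

    def to_phase_set(self) -> "PhaseSet":
        phase = np.degrees(np.angle(self.f))
        phase = (phase + 180.0) % 360.0 - 180.0
        return PhaseSet(hkl=self.hkl.copy(), phase_deg=phase,
                        cell=self.cell, spacegroup=self.spacegroup)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "h": self.hkl[:, 0], "k": self.hkl[:, 1], "l": self.hkl[:, 2],
                "d": self.d, "F_real": self.f.real, "F_imag": self.f.imag,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, cell: UnitCell, spacegroup: SpaceGroupInfo,
                 d_min: float | None = None) -> "ReflectionSet":
        df = pd.read_csv(path)
        hkl = df[["h", "k", "l"]].to_numpy(dtype=int)
        f = df["F_real"].to_numpy() + 1j * df["F_imag"].to_numpy()
        d = df["d"].to_numpy(float) if "d" in df else None
        dm = d_min if d_min is not None else float(np.min(cell.d_spacing(hkl)))
        return cls(hkl=hkl, f=f, cell=cell, spacegroup=spacegroup, d_min=dm, d=d)


@dataclass
class AmplitudeSet:
    """ASU-unique structure-factor amplitudes with uncertainties."""

    hkl: np.ndarray
    amp: np.ndarray
    sigma: np.ndarray
    cell: UnitCell
    spacegroup: SpaceGroupInfo
    label: str

    def __post_init__(self) -> None:
        self.hkl = _check_hkl(self.hkl)
        self.amp = np.asarray(self.amp, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not self.label:
            raise ValueError("label must be nonempty")
        if np.any(self.amp < 0):
            raise ValueError("amplitudes must be non-negative")

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def d(self) -> np.ndarray:
        return self.cell.d_spacing(self.hkl)

    def index_map(self) -> dict:
        return _index_map(self.hkl)

    def relabeled(self, label: str) -> "AmplitudeSet":
        return replace(self, label=label)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "h": self.hkl[:, 0], "k": self.hkl[:, 1], "l": self.hkl[:, 2],
                "d": self.d, "F": self.amp, "sigma": self.sigma,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, cell: UnitCell, spacegroup: SpaceGroupInfo,
                 label: str) -> "AmplitudeSet":
        df = pd.read_csv(path)
        return cls(
            hkl=df[["h", "k", "l"]].to_numpy(dtype=int),
            amp=df["F"].to_numpy(float), sigma=df["sigma"].to_numpy(float),
            cell=cell, spacegroup=spacegroup, label=label,
        )


@dataclass
class PhaseSet:
    """Model phases (degrees in [-180, 180)) on an ASU index set."""

    hkl: np.ndarray
    phase_deg: np.ndarray
    cell: UnitCell
    spacegroup: SpaceGroupInfo

    def __post_init__(self) -> None:
        self.hkl = _check_hkl(self.hkl)
        self.phase_deg = np.asarray(self.phase_deg, dtype=float)
        if np.any(self.phase_deg < -180.0) or np.any(self.phase_deg >= 180.0):
            raise ValueError("phases must lie in [-180, 180) degrees")

    def __len__(self) -> int:
        return len(self.hkl)

    def index_map(self) -> dict:
        return _index_map(self.hkl)

    @property
    def phasors(self) -> np.ndarray:
        return np.exp(1j * np.radians(self.phase_deg))
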