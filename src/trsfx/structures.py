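"""Coordinate-file I/O and structural comparison metrics.

PDB/mmCIF parsing is delegated to gemmi; the comparison metrics — Kabsch
Cα superposition, local-selection RMSD, triclinic cell volume, Matthews
coefficient and solvent content — are implemented here.  Residue pairing
for RMSD uses the intersection of (chain id, residue number); unpaired
residues are reported, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .symmetry import UnitCell

__all__ = [
    "StructureAtom",
    "Residue",
    "StructureModel",
    "read_structure",
    "SuperpositionResult",
    "kabsch",
    "superpose_calpha",
    "local_rmsd",
    "cell_volume",
    "MatthewsResult",
    "matthews_solvent",
]

_WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}


@dataclass
class StructureAtom:
    name: str
    element: str
    xyz: np.ndarray  # Cartesian Å
    occupancy: float = 1.0
    b_iso: float = 0.0

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite coordinates")


@dataclass
class Residue:
    number: int
    name: str
    atoms: list = field(default_factory=list)

    @property
    def is_water(self) -> bool:
        return self.name.upper() in _WATER_NAMES

    def atom(self, name: str) -> StructureAtom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class StructureModel:
    """Chains of residues with Cartesian coordinates."""

    chains: dict                      # chain id -> list[Residue]
    cell: UnitCell | None = None
    spacegroup_symbol: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        for cid, residues in self.chains.items():
            nums = [r.number for r in residues]
            if len(nums) != len(set(nums)):
                raise ValueError(f"duplicate residue numbers in chain {cid!r}")

    def iter_atoms(self):
        for cid, residues in self.chains.items():
            for res in residues:
                for atom in res.atoms:
                    yield cid, res, atom

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    def water_count(self) -> int:
        """Number of water residues (residue name HOH and synonyms)."""
        return sum(
            1 for residues in self.chains.values() for r in residues if r.is_water
        )

    def protein_atom_count(self) -> int:
        return sum(
            len(r.atoms) for residues in self.chains.values()
            for r in residues if not r.is_water
        )

    def calpha_map(self) -> dict:
        """(chain id, residue number) -> Cα coordinates."""
        out = {}
        for cid, residues in self.chains.items():
            for res in residues:
                ca = res.atom("CA")
                if ca is not None:
                    out[(cid, res.number)] = ca.xyz
        return out

    def find_atom(self, chain: str, resnum: int, atom_name: str):
        for res in self.chains.get(chain, []):
            if res.number == resnum:
                a = res.atom(atom_name)
                if a is not None:
                    return res, a
        return None, None


def read_structure(path, label: str | None = None) -> StructureModel:
    """Load a PDB or mmCIF file (format detected by gemmi).

    ATOM and HETATM records are kept; alternate locations are collapsed to
    the highest-occupancy conformer (ties: first encountered); waters are
    identified by residue name HOH (and common synonyms).
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    model = st[0]
    chains: dict = {}
    for chain in model:
        residues = []
        for res in chain:
            atoms: dict = {}
            for atom in res:
                prev = atoms.get(atom.name)
                if prev is None or atom.occ > prev.occupancy:
                    atoms[atom.name] = StructureAtom(
                        name=atom.name, element=atom.element.name,
                        xyz=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=atom.occ, b_iso=atom.b_iso,
                    )
            residues.append(Residue(number=res.seqid.num, name=res.name,
                                    atoms=list(atoms.values())))
        if residues:
            chains[chain.name] = residues
    cell = None
    # a 1 Å cube is gemmi's placeholder for files without cell information
    if st.cell and st.cell.a > 2.0:
        cell = UnitCell(st.cell.a, st.cell.b, st.cell.c,
                        st.cell.alpha, st.cell.beta, st.cell.gamma)
    return StructureModel(
        chains=chains, cell=cell,
        spacegroup_symbol=st.spacegroup_hm or "",
        label=label or st.name or str(path),
    )


def write_pdb(model: StructureModel, path) -> None:
    """Minimal PDB writer (round-trip fixture support)."""
    lines = []
    serial = 1
    for cid, residues in model.chains.items():
        for res in residues:
            for a in res.atoms:
                record = "HETATM" if res.is_water else "ATOM  "
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                lines.append(
                    f"{record}{serial:>5d} {name:<4s}{res.name:>4s} {cid[:1]}"
                    f"{res.number:>4d}    {a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
                    f"{a.occupancy:6.2f}{a.b_iso:6.2f}          {a.element:>2s}"
                )
                serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# superposition and RMSD
# ---------------------------------------------------------------------------

@dataclass
class SuperpositionResult:
    rotation: np.ndarray     # 3x3, proper (det = +1)
    translation: np.ndarray
    rmsd: float              # Å
    n_atoms: int
    unpaired_a: int = 0
    unpaired_b: int = 0

    def transform(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, float) @ self.rotation.T + self.translation


def kabsch(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation + translation mapping ``moving`` onto ``fixed``."""
    p = np.asarray(moving, float)
    q = np.asarray(fixed, float)
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = qc - rot @ pc
    return rot, trans


def superpose_calpha(a: StructureModel, b: StructureModel) -> SuperpositionResult:
    """Least-squares Cα superposition of B onto A, paired by chain + residue number."""
    ca_a = a.calpha_map()
    ca_b = b.calpha_map()
    keys = sorted(set(ca_a) & set(ca_b))
    if len(keys) < 3:
        raise ValueError(f"only {len(keys)} Cα pairs; need at least 3")
    xa = np.array([ca_a[k] for k in keys])
    xb = np.array([ca_b[k] for k in keys])
    rot, trans = kabsch(xb, xa)
    moved = xb @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - xa) ** 2, axis=1))))
    return SuperpositionResult(
        rotation=rot, translation=trans, rmsd=rmsd, n_atoms=len(keys),
        unpaired_a=len(ca_a) - len(keys), unpaired_b=len(ca_b) - len(keys),
    )


def local_rmsd(
    a: StructureModel,
    b: StructureModel,
    center: tuple,
    radius: float,
    superposition: str = "global",
) -> tuple[float, int]:
    """RMSD over atoms of A within ``radius`` Å of a centre atom.

    ``center`` is (chain, residue number, atom name) naming an atom of A.
    Atoms are paired with B by chain / residue number / atom name.
    ``superposition``: "global" applies the all-Cα transform first, "local"
    refits Kabsch on the selection, "none" compares coordinates as given.
    The atom count is returned so the selection convention is auditable.
    """
    chain, resnum, atom_name = center
    _, centre_atom = a.find_atom(chain, int(resnum), atom_name)
    if centre_atom is None:
        raise ValueError(f"centre atom {center} not found in reference model")
    c = centre_atom.xyz

    pairs_a, pairs_b = [], []
    b_index = {
        (cid, res.number, atom.name): atom.xyz
        for cid, res, atom in b.iter_atoms()
    }
    for cid, res, atom in a.iter_atoms():
        if np.linalg.norm(atom.xyz - c) <= radius:
            key = (cid, res.number, atom.name)
            if key in b_index:
                pairs_a.append(atom.xyz)
                pairs_b.append(b_index[key])
    if not pairs_a:
        raise ValueError("no atoms selected within the radius")
    xa = np.array(pairs_a)
    xb = np.array(pairs_b)
    if superposition == "global":
        sup = superpose_calpha(a, b)
        xb = sup.transform(xb)
    elif superposition == "local":
        rot, trans = kabsch(xb, xa)
        xb = xb @ rot.T + trans
    elif superposition != "none":
        raise ValueError("superposition must be 'global', 'local' or 'none'")
    rmsd = float(np.sqrt(np.mean(np.sum((xb - xa) ** 2, axis=1))))
    return rmsd, len(xa)


# ---------------------------------------------------------------------------
# cell volume and Matthews coefficient
# ---------------------------------------------------------------------------

def cell_volume(cell: UnitCell) -> float:
    """Triclinic cell volume V = abc·√(1−cos²α−cos²β−cos²γ+2cosαcosβcosγ)."""
    v = cell.volume
    if not np.isfinite(v) or v <= 0:
        raise ValueError("degenerate unit cell")
    return v


# protein partial specific volume 0.74 cm³/g expressed in Å³/Da
_PROTEIN_VOLUME_PER_DALTON = 1.230


@dataclass(frozen=True)
class MatthewsResult:
    v_m: float            # Å³/Da
    solvent_percent: float
    cell_volume: float
    z: int
    molecular_weight: float


def matthews_solvent(cell: UnitCell, z: int, molecular_weight: float) -> MatthewsResult:
    """Matthews coefficient V_M = V/(Z·MW) and solvent content.

    Solvent % = 100·(1 − 1.230/V_M), with 1.230 Å³/Da the standard protein
    partial-specific-volume constant.
    """
    if z < 1:
        raise ValueError("Z must be at least 1")
    if molecular_weight <= 0:
        raise ValueError("molecular weight must be positive")
    v = cell_volume(cell)
    v_m = v / (z * molecular_weight)
    solvent = 100.0 * (1.0 - _PROTEIN_VOLUME_PER_DALTON / v_m)
    if not 0.0 < solvent < 100.0:
        raise ValueError(
            f"implausible solvent content {solvent:.1f}% (V_M = {v_m:.3f} Å³/Da)"
        )
    return MatthewsResult(v_m=float(v_m), solvent_percent=float(solvent),
                          cell_volume=float(v), z=int(z),
                          molecular_weight=float(molecular_weight))
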