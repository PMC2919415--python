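"""Shared lightweight containers used across the package.

The two workhorse representations are :class:`AtomicStructure` (atoms read
from a PDB file, plus the declared full sequence and crystal symmetry) and
:class:`SphereModel` (a shape-based coarse-grained model: a handful of
labelled spheres carrying position, radius and mass).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "AtomicStructure",
    "Sphere",
    "SphereModel",
    "SymOp",
    "UnitCell",
    "MassAccount",
]


@dataclass(frozen=True)
class UnitCell:
    """Crystallographic unit cell: lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def orthogonalization_matrix(self) -> np.ndarray:
        """Matrix M mapping fractional to Cartesian coordinates (x = M f)."""
        al, be, ga = np.radians([self.alpha, self.beta, self.gamma])
        cos_al, cos_be, cos_ga = np.cos([al, be, ga])
        sin_ga = np.sin(ga)
        v = np.sqrt(
            1 - cos_al**2 - cos_be**2 - cos_ga**2 + 2 * cos_al * cos_be * cos_ga
        )
        return np.array(
            [
                [self.a, self.b * cos_ga, self.c * cos_be],
                [0.0, self.b * sin_ga, self.c * (cos_al - cos_be * cos_ga) / sin_ga],
                [0.0, 0.0, self.c * v / sin_ga],
            ]
        )


@dataclass(frozen=True)
class SymOp:
    """Rigid symmetry operator x' = R x + t.

    ``fractional`` marks the convention of (R, t): REMARK 290 SMTRY rows are
    Cartesian (Å); user-supplied space-group operators are usually fractional.
    """

    rot: tuple  # 3x3 nested tuple, hashable
    trans: tuple  # length 3
    fractional: bool = False

    @property
    def R(self) -> np.ndarray:
        return np.asarray(self.rot, dtype=float)

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.trans, dtype=float)

    @staticmethod
    def identity(fractional: bool = False) -> "SymOp":
        return SymOp(
            rot=((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0)),
            trans=(0.0, 0.0, 0.0),
            fractional=fractional,
        )

    def is_identity(self, tol: float = 1e-6) -> bool:
        return bool(
            np.allclose(self.R, np.eye(3), atol=tol)
            and np.allclose(self.t, 0.0, atol=tol)
        )

    @staticmethod
    def make(R, t, fractional: bool = False) -> "SymOp":
        R = np.asarray(R, dtype=float)
        t = np.asarray(t, dtype=float)
        return SymOp(
            rot=tuple(tuple(float(x) for x in row) for row in R),
            trans=tuple(float(x) for x in t),
            fractional=fractional,
        )


@dataclass
class AtomicStructure:
    """Atoms of a (possibly incomplete) structure plus declared sequences.

    Per-atom arrays are parallel; ``chains`` maps chain id to the declared
    full one-letter sequence (from SEQRES or a user FASTA), which may be
    longer than what the coordinates cover.
    """

    elements: list  # element symbols, e.g. "C"
    atom_names: list
    res_names: list
    res_seq: np.ndarray  # residue sequence numbers (int)
    icodes: list  # insertion codes ('' if none)
    chain_ids: list
    coords: np.ndarray  # (N, 3) Cartesian Å
    chains: dict = field(default_factory=dict)  # chain id -> one-letter seq
    cell: UnitCell | None = None
    sym_ops: list | None = None  # list[SymOp]
    source: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.res_seq = np.asarray(self.res_seq, dtype=int)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def residue_keys(self) -> list:
        """Ordered unique (chain, res_seq, icode) keys of observed residues."""
        seen: dict = {}
        for ch, rs, ic in zip(self.chain_ids, self.res_seq, self.icodes):
            seen.setdefault((ch, int(rs), ic), None)
        return list(seen)

    def residue_names(self) -> dict:
        out: dict = {}
        for ch, rs, ic, rn in zip(
            self.chain_ids, self.res_seq, self.icodes, self.res_names
        ):
            out.setdefault((ch, int(rs), ic), rn)
        return out

    def heavy_mask(self) -> np.ndarray:
        return np.array([e.upper() != "H" for e in self.elements], dtype=bool)

    def atom_masses(self) -> np.ndarray:
        import gemmi

        return np.array([gemmi.Element(e).weight for e in self.elements])

    def center_of_mass(self) -> np.ndarray:
        m = self.atom_masses()
        return (self.coords * m[:, None]).sum(axis=0) / m.sum()

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "AtomicStructure":
        """Return a copy with coordinates x -> R x + t."""
        new = replace(self)
        new.coords = self.coords @ np.asarray(R, float).T + np.asarray(t, float)
        return new

    def subset(self, atom_idx: Sequence[int]) -> "AtomicStructure":
        idx = np.asarray(atom_idx, dtype=int)
        return AtomicStructure(
            elements=[self.elements[i] for i in idx],
            atom_names=[self.atom_names[i] for i in idx],
            res_names=[self.res_names[i] for i in idx],
            res_seq=self.res_seq[idx],
            icodes=[self.icodes[i] for i in idx],
            chain_ids=[self.chain_ids[i] for i in idx],
            coords=self.coords[idx],
            chains=dict(self.chains),
            cell=self.cell,
            sym_ops=self.sym_ops,
            source=self.source,
        )

    def ca_indices(self) -> np.ndarray:
        return np.array(
            [i for i, nm in enumerate(self.atom_names) if nm.strip() == "CA"],
            dtype=int,
        )


@dataclass(frozen=True)
class Sphere:
    """One coarse-grained sphere: a protein domain, subunit or missing mass."""

    label: str
    center: tuple  # (x, y, z) Å
    radius: float  # Å
    mass: float  # Da
    kind: str = "domain"  # domain | subunit | missing

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError(f"sphere {self.label!r}: radius must be > 0")
        if self.mass <= 0:
            raise ValueError(f"sphere {self.label!r}: mass must be > 0")


@dataclass
class SphereModel:
    """A shape-based coarse-grained model: a set of labelled spheres."""

    spheres: list  # list[Sphere]
    provenance: str = ""

    def __post_init__(self):
        if not all(isinstance(s, Sphere) for s in self.spheres):
            raise TypeError("spheres must be Sphere instances")

    def __len__(self) -> int:
        return len(self.spheres)

    @property
    def centers(self) -> np.ndarray:
        return np.array([s.center for s in self.spheres], dtype=float).reshape(-1, 3)

    @property
    def radii(self) -> np.ndarray:
        return np.array([s.radius for s in self.spheres], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([s.mass for s in self.spheres], dtype=float)

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    def center_of_mass(self) -> np.ndarray:
        m = self.masses
        return (self.centers * m[:, None]).sum(axis=0) / m.sum()

    def scaled_radii(self, factor: float) -> "SphereModel":
        return SphereModel(
            spheres=[replace(s, radius=s.radius * factor) for s in self.spheres],
            provenance=self.provenance,
        )

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "SphereModel":
        R = np.asarray(R, float)
        t = np.asarray(t, float)
        return SphereModel(
            spheres=[
                replace(s, center=tuple(R @ np.asarray(s.center) + t))
                for s in self.spheres
            ],
            provenance=self.provenance,
        )

    def with_sphere(self, sphere: Sphere) -> "SphereModel":
        return SphereModel(spheres=[*self.spheres, sphere], provenance=self.provenance)


@dataclass(frozen=True)
class MassAccount:
    """Bookkeeping of the mass present in, and absent from, a structure."""

    m_present: float  # Da
    m_full: float  # Da
    f_missing: float  # (m_full - m_present) / m_full
    missing_segments: tuple = ()  # ((chain, start, end), ...)

    def __post_init__(self):
        if not (self.m_full >= self.m_present > 0):
            raise ValueError("need m_full >= m_present > 0")
        expect = (self.m_full - self.m_present) / self.m_full
        if abs(expect - self.f_missing) > 1e-6:
            raise ValueError("inconsistent f_missing")
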