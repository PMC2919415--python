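"""Synthetic test structures, symmetry operators and planted CCS tables.

Everything the pipeline consumes can be generated here without any
database access: gapped poly-alanine PDB units at protein-like density
(globule, dumbbell or trilobe envelopes), REMARK 290 operator sets, and
experimental-style CCS tables computed from a *planted* oligomer topology
so that end-to-end topology recovery can be tested in a closed loop.

Units are Cα-only chains: one CA pseudo-atom per residue, placed by
dart-throwing inside the envelope at ~0.8 Da/Å³ with a minimum spacing.
A gap fraction removes the C-terminal tail's atoms while keeping its
SEQRES entries, mimicking a truncated crystal construct.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ccs as ccs_mod
from . import geometry, symmetry
from .models import AtomicStructure
from .structio import read_structure

__all__ = [
    "FixtureSpec",
    "make_unit_pdb",
    "make_unit",
    "make_planted_ccs_table",
    "planted_symmetry_series",
    "write_ccs_table",
    "read_ccs_table",
]

RESIDUE_MASS_ALA = 71.0788  # Da
PROTEIN_DENSITY = 0.8  # Da / Å³
MIN_CA_SPACING = 3.2  # Å
OPERATOR_SETS = ("identity", "p1", "orthorhombic4")
SHAPES = ("globule", "dumbbell", "trilobe")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic unit and its planted oligomer data."""

    seed: int = 0
    n_residues: int = 120
    shape: str = "globule"  # globule | dumbbell | trilobe
    gap_fraction: float = 0.0
    operators: str = "p1"  # identity | p1 | orthorhombic4
    planted_topology: str = "symmetry_mined"
    noise: float = 0.0  # bound of the uniform relative CCS perturbation

    def __post_init__(self):
        if not 0.0 <= self.gap_fraction <= 0.9:
            raise ValueError("gap fraction must be in [0, 0.9]")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if self.shape not in SHAPES:
            raise ValueError(f"shape must be one of {SHAPES}")
        if self.operators not in OPERATOR_SETS:
            raise ValueError(f"operators must be one of {OPERATOR_SETS}")


def _sphere_radius_for(n_residues: int) -> float:
    vol = n_residues * RESIDUE_MASS_ALA / PROTEIN_DENSITY
    return (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0)


def _dart_throw(
    n: int, radius: float, center: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """n points uniform in a sphere with minimum pairwise spacing."""
    pts: list = []
    attempts = 0
    spacing = MIN_CA_SPACING
    while len(pts) < n:
        attempts += 1
        if attempts > 200 * n:
            spacing *= 0.95  # relax if the envelope is unexpectedly tight
            attempts = 0
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        p = center + u * radius * rng.random() ** (1.0 / 3.0)
        if all(np.linalg.norm(p - q) >= spacing for q in pts):
            pts.append(p)
    return np.array(pts)


def _unit_coords(spec: FixtureSpec) -> np.ndarray:
    """Cα coordinates for the full-length chain, residue order = chain order."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    if spec.shape == "globule":
        r = _sphere_radius_for(n)
        return _dart_throw(n, r, np.zeros(3), rng)
    if spec.shape == "dumbbell":
        n_link = 5
        n_lobe = (n - n_link) // 2
        n_lobe2 = n - n_link - n_lobe
        r = _sphere_radius_for(n_lobe)
        gap = 2.6 * r  # lobes clearly separated, joined by the linker
        a = _dart_throw(n_lobe, r, np.array([-gap / 2, 0, 0]), rng)
        b = _dart_throw(n_lobe2, r, np.array([gap / 2, 0, 0]), rng)
        xs = np.linspace(-gap / 2 + r * 0.7, gap / 2 - r * 0.7, n_link)
        link = np.column_stack([xs, np.zeros(n_link), np.zeros(n_link)])
        return np.vstack([a, link, b])
    # trilobe: three touching lobes at triangle vertices, contiguous in sequence
    n_lobe = n // 3
    sizes = [n_lobe, n_lobe, n - 2 * n_lobe]
    r = _sphere_radius_for(max(sizes))
    d = 1.9 * r  # overlapping enough for a connected Cα network
    centers = [
        np.array([0.0, 0.0, 0.0]),
        np.array([d, 0.0, 0.0]),
        np.array([d / 2, d * np.sqrt(3) / 2, 0.0]),
    ]
    parts = [_dart_throw(sz, r, c, rng) for sz, c in zip(sizes, centers)]
    return np.vstack(parts)


def _operator_lines(spec: FixtureSpec, cell: tuple) -> list:
    """REMARK 290 SMTRY rows (Cartesian Å) for the requested operator set."""
    a, b, c = cell[:3]
    ops = [(np.eye(3), np.zeros(3))]
    if spec.operators == "orthorhombic4":
        # P2_1 2_1 2_1 - like screw operators, Cartesian for a 90° cell
        ops += [
            (np.diag([-1.0, -1.0, 1.0]), np.array([a / 2, 0.0, c / 2])),
            (np.diag([-1.0, 1.0, -1.0]), np.array([0.0, b / 2, c / 2])),
            (np.diag([1.0, -1.0, -1.0]), np.array([a / 2, b / 2, 0.0])),
        ]
    lines = []
    for iop, (R, t) in enumerate(ops, start=1):
        for irow in range(3):
            lines.append(
                f"REMARK 290   SMTRY{irow + 1} {iop:3d} "
                f"{R[irow, 0]:9.6f} {R[irow, 1]:9.6f} {R[irow, 2]:9.6f} "
                f"{t[irow]:14.5f}"
            )
    return lines


def make_unit_pdb(spec: FixtureSpec) -> str:
    """PDB text for one synthetic unit (SEQRES, CRYST1, REMARK 290, ATOM)."""
    coords = _unit_coords(spec)
    coords = coords - coords.mean(axis=0)
    n = spec.n_residues
    n_gap = int(round(spec.gap_fraction * n))
    n_obs = n - n_gap

    # distinct near-touching cell lengths per axis, so lattice neighbours
    # pack against each face without clashing and the three directions are
    # geometrically distinguishable
    extents = 2.0 * (np.abs(coords).max(axis=0) + 2.2)
    cell = (
        1.06 * extents[0], 1.13 * extents[1], 1.22 * extents[2],
        90.0, 90.0, 90.0,
    )
    # keep the unit away from the rotation axes for the screw-operator set
    offset = (
        np.array([0.30 * cell[0], 0.27 * cell[1], 0.22 * cell[2]])
        if spec.operators == "orthorhombic4"
        else np.zeros(3)
    )
    coords = coords + offset

    lines = ["REMARK 250 SYNTHETIC POLY-ALANINE UNIT (GENERATED FIXTURE)"]
    lines += _operator_lines(spec, cell)
    seq = ["ALA"] * n
    for i0 in range(0, n, 13):
        row = seq[i0 : i0 + 13]
        lines.append(
            f"SEQRES {i0 // 13 + 1:3d} A {n:4d}  " + " ".join(f"{r:>3s}" for r in row)
        )
    lines.append(
        f"CRYST1{cell[0]:9.3f}{cell[1]:9.3f}{cell[2]:9.3f}"
        f"{cell[3]:7.2f}{cell[4]:7.2f}{cell[5]:7.2f} P 1"
    )
    for i in range(n_obs):
        x, y, z = coords[i]
        lines.append(
            f"ATOM  {i + 1:5d}  CA  ALA A{i + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{20.00:6.2f}           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_unit(spec: FixtureSpec, path=None) -> AtomicStructure:
    """Generate a unit and parse it back through the standard PDB reader."""
    import tempfile
    from pathlib import Path

    text = make_unit_pdb(spec)
    if path is not None:
        Path(path).write_text(text)
        return read_structure(path)
    with tempfile.NamedTemporaryFile("w", suffix=".pdb", delete=False) as fh:
        fh.write(text)
        name = fh.name
    try:
        return read_structure(name)
    finally:
        Path(name).unlink(missing_ok=True)


def planted_symmetry_series(unit: AtomicStructure, n_max: int, shell: int = 1):
    """The geometrically preferred nested series of symmetry copies of a unit.

    This is the "planted" architecture for closed-loop tests: starting from
    the reference copy, each order adds the connected, clash-free copy whose
    assembly minimizes the sum of pairwise COM distances, with point-group
    symmetry of the arrangement as the secondary criterion — the same
    geometric preference the stepwise selector applies among candidates
    that fit the experimental CCS equally well.
    Returns (SymmetryBlock, [members_1, members_2, ...]).
    """
    block = symmetry.expand_symmetry(unit, shell=shell)
    coms = block.coms()
    cutoff = 1.2 * 2.0 * geometry.bounding_radius(unit)
    D = np.linalg.norm(coms[:, None, :] - coms[None, :, :], axis=2)
    neighbours = [set(np.where(D[i] <= cutoff)[0]) - {i} for i in range(len(block))]
    members = (0,)
    series = [members]
    for _ in range(2, n_max + 1):
        frontier = sorted(int(x) for x in set().union(*(neighbours[i] for i in members)) - set(members))

        def rank(v):
            mem = tuple(sorted((*members, v)))
            comp = symmetry.compactness_of(block, mem)
            sym = symmetry.point_group_score(coms[list(mem)])
            return (round(comp, 6), -sym[0], not sym[1], mem)

        best = int(min(frontier, key=rank))
        members = tuple(sorted((*members, best)))
        series.append(members)
    return block, series


def make_planted_ccs_table(
    unit: AtomicStructure,
    topology: str = "symmetry_mined",
    n_values=(1, 2, 3, 4),
    noise: float = 0.0,
    seed: int = 0,
    subunits_per_block: int = 1,
    n_rotations: int = 120,
    n_points: int = 2500,
) -> pd.DataFrame:
    """Experimental-style CCS table computed from a planted topology.

    For ``topology="symmetry_mined"`` the planted oligomers are the
    compactness-greedy nested series of crystal-symmetry copies of the
    unit; otherwise an archetype of that name is generated.  CCS values are
    perturbed multiplicatively by a uniform factor in [1-noise, 1+noise].
    Columns: species, n_subunits, ccs_A2, rel_error.
    """
    rng = np.random.default_rng(seed)
    n_values = sorted(n_values)
    rows = []
    if topology == "symmetry_mined":
        block, series = planted_symmetry_series(unit, max(n_values))
        for n in n_values:
            est = symmetry.assembly_ccs(
                block, series[n - 1], n_rotations=n_rotations, n_points=n_points,
                seed=seed + n,
            )
            rows.append((n, est.value))
    else:
        for n in n_values:
            model = geometry.generate_archetype(unit, n, topology, seed=seed)
            est = model.ccs(n_rotations=n_rotations, n_points=n_points, seed=seed + n)
            rows.append((n, est.value))
    # reported errors cover the injected noise plus a calibration margin,
    # capped at the typical 10% experimental uncertainty
    rel_error = min(max(0.03, noise + 0.02), 0.10)
    records = []
    for n, value in rows:
        factor = 1.0 + rng.uniform(-noise, noise)
        records.append(
            {
                "species": f"planted_{topology}_{n}",
                "n_subunits": n * subunits_per_block,
                "ccs_A2": value * factor,
                "rel_error": rel_error,
            }
        )
    return pd.DataFrame.from_records(records)


def write_ccs_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_ccs_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    required = {"species", "n_subunits", "ccs_A2", "rel_error"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"CCS table missing columns: {sorted(missing)}")
    return table
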