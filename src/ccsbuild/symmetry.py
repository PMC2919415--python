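"""Crystal-symmetry mining of candidate oligomer packings.

Applying a crystal's symmetry operators together with lattice translations
to a building block yields a "block" of symmetry-related copies.  Candidate
n-mers are connected n-subsets of that block that contain the reference
copy; they are ranked by compactness (the sum of pairwise center-of-mass
distances) and, when building a series of oligomer orders, selected
stepwise against experimental CCS values so that every n-mer contains the
chosen (n-1)-mer.  Candidates that fit the measurement equally well (within
one experimental tolerance of the best fit) are joint solutions, ranked by
compactness and then by point-group symmetry of the copy-center arrangement.
"""
from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field

import numpy as np

from . import ccs as ccs_mod
from .geometry import block_spheres, bounding_radius
from .models import AtomicStructure, SphereModel, SymOp

__all__ = [
    "SymmetryBlock",
    "CandidateAssembly",
    "expand_symmetry",
    "enumerate_candidates",
    "stepwise_series",
    "point_group_score",
    "assembly_congruent",
]

CLASH_VOLUME_FRACTION = 0.05


@dataclass(frozen=True)
class CopyPlacement:
    """One symmetry-related copy: operator index, lattice shift, transform."""

    copy_id: int
    op_index: int
    shift: tuple  # (i, j, k) lattice translation
    R: tuple  # 3x3 rotation (nested tuples)
    t: tuple  # translation, Å
    com: tuple  # center of mass after the transform, Å

    @property
    def transform(self) -> tuple:
        return np.asarray(self.R, float), np.asarray(self.t, float)


@dataclass
class SymmetryBlock:
    """All symmetry copies of a building unit within a lattice shell."""

    copies: list  # list[CopyPlacement]; copies[0] is the identity copy
    source: object  # AtomicStructure or SphereModel

    def __len__(self) -> int:
        return len(self.copies)

    def coms(self) -> np.ndarray:
        return np.array([c.com for c in self.copies])


@dataclass
class CandidateAssembly:
    """A connected subset of symmetry copies proposed as an n-mer."""

    members: tuple  # sorted copy ids, always containing 0
    compactness: float  # sum of pairwise COM distances, Å
    ccs: ccs_mod.CCSEstimate | None = None
    deviation: float | None = None
    nested_parent: tuple | None = None
    symmetry: tuple = (1, False)  # (rotational order, dihedral flag)

    @property
    def n(self) -> int:
        return len(self.members)


def expand_symmetry(
    structure,
    operators: list | None = None,
    shell: int = 1,
) -> SymmetryBlock:
    """Apply symmetry operators x lattice translations within +-shell cells.

    ``structure`` may be an AtomicStructure (operators default to its
    REMARK 290 set) or a SphereModel (operators must be supplied).
    Identical transforms are deduplicated; the identity copy is first.
    """
    if operators is None:
        operators = getattr(structure, "sym_ops", None)
    if not operators:
        raise ValueError("no symmetry operators available")
    cell = getattr(structure, "cell", None)
    needs_cell = shell > 0 or any(op.fractional for op in operators)
    if needs_cell and cell is None:
        raise ValueError("a unit cell is required for fractional operators "
                         "or nonzero lattice shells")
    M = cell.orthogonalization_matrix() if cell is not None else np.eye(3)
    Minv = np.linalg.inv(M) if cell is not None else np.eye(3)

    centers, _, masses = block_spheres(structure)
    com0 = (centers * masses[:, None]).sum(axis=0) / masses.sum()

    # put the identity operator first so copy 0 is the reference block
    ops = sorted(operators, key=lambda op: 0 if op.is_identity() else 1)
    if not ops[0].is_identity():
        ops.insert(0, SymOp.identity(fractional=ops[0].fractional))

    shifts = sorted(
        itertools.product(range(-shell, shell + 1), repeat=3),
        key=lambda s: (s != (0, 0, 0), s),
    )
    copies = []
    seen = set()
    for iop, op in enumerate(ops):
        if op.fractional:
            Rc = M @ op.R @ Minv
            base_t = M @ op.t
        else:
            Rc = op.R
            base_t = op.t
        for s in shifts:
            t = base_t + M @ np.asarray(s, float)
            key = (
                tuple(np.round(Rc, 4).ravel()),
                tuple(np.round(t, 3)),
            )
            if key in seen:
                continue
            seen.add(key)
            com = Rc @ com0 + t
            copies.append(
                CopyPlacement(
                    copy_id=len(copies),
                    op_index=iop,
                    shift=s,
                    R=tuple(tuple(float(x) for x in row) for row in Rc),
                    t=tuple(float(x) for x in t),
                    com=tuple(float(x) for x in com),
                )
            )
    return SymmetryBlock(copies=copies, source=structure)


def _pair_dists(coms: np.ndarray) -> np.ndarray:
    return np.linalg.norm(coms[:, None, :] - coms[None, :, :], axis=2)


def compactness_of(block: SymmetryBlock, members) -> float:
    """Sum of pairwise COM distances among the given copies."""
    coms = block.coms()[list(members)]
    d = _pair_dists(coms)
    return float(d[np.triu_indices(len(members), 1)].sum())


def _copy_volume_overlap(block: SymmetryBlock, id_a: int, id_b: int) -> float:
    """Fractional sphere-volume overlap between two copies (vs one copy's volume)."""
    centers, radii, _ = block_spheres(block.source)
    Ra, ta = block.copies[id_a].transform
    Rb, tb = block.copies[id_b].transform
    ca = centers @ Ra.T + ta
    cb = centers @ Rb.T + tb
    vol = (4.0 / 3.0) * np.pi * (radii**3).sum()
    d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
    ra = radii[:, None]
    rb = radii[None, :]
    touching = d < (ra + rb)
    if not touching.any():
        return 0.0
    dd = np.where(touching, d, 1.0)
    # sphere-sphere intersection volume (lens), clipped to containment
    inter = (
        np.pi
        * (ra + rb - dd) ** 2
        * (dd**2 + 2 * dd * (ra + rb) - 3 * (ra - rb) ** 2)
        / (12 * dd)
    )
    small = (4.0 / 3.0) * np.pi * np.minimum(ra, rb) ** 3
    contained = dd <= np.abs(ra - rb)
    inter = np.where(contained, small, inter)
    return float(np.where(touching, inter, 0.0).sum() / vol)


def _has_clash(block: SymmetryBlock, members, max_frac: float) -> bool:
    for a, b in itertools.combinations(members, 2):
        if _copy_volume_overlap(block, a, b) > max_frac:
            return True
    return False


def enumerate_candidates(
    block: SymmetryBlock,
    n: int,
    max_candidates: int = 500,
    cutoff: float | None = None,
    clash_fraction: float = CLASH_VOLUME_FRACTION,
) -> list:
    """Connected n-subsets of the block containing the reference copy.

    Copies are neighbours when their COM distance is at most ``cutoff``
    (default 1.2 x the block diameter).  Subsets are grown best-first on
    partial compactness — an admissible, monotone bound — so candidates are
    produced in ascending order of compactness and the first
    ``max_candidates`` completed subsets are exactly the most compact ones.
    Candidates whose copies interpenetrate by more than ``clash_fraction``
    of a copy's sphere volume are discarded.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if len(block) < n:
        return []
    coms = block.coms()
    if cutoff is None:
        cutoff = 1.2 * 2.0 * bounding_radius(block.source)
    D = _pair_dists(coms)
    neighbours = [set(np.where(D[i] <= cutoff)[0]) - {i} for i in range(len(block))]

    results = []
    counter = itertools.count()
    heap = [(0.0, next(counter), frozenset([0]))]
    visited = {frozenset([0])}
    while heap and len(results) < max_candidates:
        comp, _, S = heapq.heappop(heap)
        if len(S) == n:
            members = tuple(sorted(S))
            if not _has_clash(block, members, clash_fraction):
                results.append(
                    CandidateAssembly(members=members, compactness=comp)
                )
            continue
        frontier = set().union(*(neighbours[i] for i in S)) - S
        for v in sorted(int(x) for x in frontier):
            S2 = frozenset(S | {v})
            if S2 in visited:
                continue
            visited.add(S2)
            comp2 = comp + sum(D[v, u] for u in S)
            heapq.heappush(heap, (comp2, next(counter), S2))
    return results


def point_group_score(coms: np.ndarray, rmsd_tol: float = 1.0) -> tuple:
    """(rotational order, dihedral flag) of a copy-center point set.

    Checks whether rotating the centered point set by 2*pi/k (k = 3, 2)
    about a principal axis maps it onto itself within ``rmsd_tol`` Å per
    point; dihedral means an additional perpendicular 2-fold exists.
    """
    from scipy.spatial.transform import Rotation

    x = coms - coms.mean(axis=0)
    if len(x) < 2:
        return (1, False)
    cov = x.T @ x
    _, evecs = np.linalg.eigh(cov)
    axes = [evecs[:, i] for i in range(3)]

    def maps_onto(R: np.ndarray) -> bool:
        y = x @ R.T
        d = np.linalg.norm(y[:, None, :] - x[None, :, :], axis=2)
        # greedy one-to-one matching is enough at these sizes
        used = set()
        for i in range(len(x)):
            order = np.argsort(d[i])
            for j in order:
                if j not in used:
                    if d[i, j] > rmsd_tol:
                        return False
                    used.add(int(j))
                    break
        return True

    best_k, best_axis = 1, None
    for k in (3, 2):
        for ax in axes:
            R = Rotation.from_rotvec(ax * 2 * np.pi / k).as_matrix()
            if maps_onto(R):
                best_k, best_axis = k, ax
                break
        if best_k > 1:
            break
    dihedral = False
    if best_k > 1 and best_axis is not None:
        for ax in axes:
            if abs(ax @ best_axis) > 0.9:
                continue
            R = Rotation.from_rotvec(ax * np.pi).as_matrix()
            if maps_onto(R):
                dihedral = True
                break
    return (best_k, dihedral)


def assembly_ccs(
    block: SymmetryBlock,
    members,
    radii: ccs_mod.CollisionRadii | None = None,
    n_rotations: int = 100,
    n_points: int = 2000,
    seed: int = 0,
    scale: float = 1.0,
) -> ccs_mod.CCSEstimate:
    """PA CCS of the union of the given copies."""
    centers, r, _ = block_spheres(block.source, radii)
    all_c, all_r = [], []
    for i in members:
        R, t = block.copies[i].transform
        all_c.append(centers @ R.T + t)
        all_r.append(r)
    return ccs_mod.pa_ccs_points(
        np.vstack(all_c), np.concatenate(all_r),
        n_rotations=n_rotations, n_points=n_points, seed=seed, scale=scale,
    )


def assembly_to_sphere_model(
    block: SymmetryBlock,
    members,
    radii: ccs_mod.CollisionRadii | None = None,
) -> SphereModel:
    """Realize a candidate assembly as a multi-copy sphere model.

    Atomic sources become one pseudo-atom sphere per atom per copy, which
    round-trips through the sphere-model PDB writer.
    """
    from .models import Sphere

    centers, r, masses = block_spheres(block.source, radii)
    spheres = []
    for i in members:
        R, t = block.copies[i].transform
        moved = centers @ R.T + t
        for j, (c, rr, mm) in enumerate(zip(moved, r, masses)):
            spheres.append(
                Sphere(
                    label=f"copy{i}_s{j}",
                    center=tuple(float(x) for x in c),
                    radius=float(rr),
                    mass=float(mm),
                    kind="subunit",
                )
            )
    return SphereModel(
        spheres=spheres, provenance=f"assembly_{'_'.join(map(str, members))}"
    )


def assembly_congruent(
    block: SymmetryBlock, members_a, members_b, tol: float = 0.5
) -> bool:
    """True when two candidate assemblies are rigid images of each other.

    Compared by the sorted multiset of pairwise COM distances, which is a
    complete rigid invariant for the small point sets handled here.
    """
    coms = block.coms()
    da = np.sort(
        _pair_dists(coms[list(members_a)])[np.triu_indices(len(members_a), 1)]
    )
    db = np.sort(
        _pair_dists(coms[list(members_b)])[np.triu_indices(len(members_b), 1)]
    )
    return len(da) == len(db) and bool(np.all(np.abs(da - db) <= tol))


@dataclass
class StepwiseResult:
    """Nested series of selected assemblies plus per-order diagnostics."""

    series: list  # list[CandidateAssembly], orders 1..n reached
    complete: bool
    messages: list = field(default_factory=list)


def stepwise_series(
    block: SymmetryBlock,
    n_max: int,
    experimental: dict,
    tolerance: float = 0.10,
    cutoff: float | None = None,
    clash_fraction: float = CLASH_VOLUME_FRACTION,
    radii: ccs_mod.CollisionRadii | None = None,
    n_rotations: int = 100,
    n_points: int = 2000,
    seed: int = 0,
    scale: float = 1.0,
) -> StepwiseResult:
    """Select a nested series of assemblies against experimental CCS values.

    ``experimental`` maps the number of building blocks to (ccs, rel_error)
    (rel_error may be None).  At each order the extensions of the previously
    selected assembly by one connected copy are compared with the measured
    CCS; extensions outside the experimental tolerance are rejected, and
    among the joint solutions within one tolerance of the best fit the most
    compact packing wins, with point-group symmetry as the secondary
    criterion.  Orders with no experimental value are selected by
    (compactness, symmetry) alone.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if not experimental and n_max > 1:
        raise ValueError("need an experimental CCS for at least one oligomer order")
    coms = block.coms()
    if cutoff is None:
        cutoff = 1.2 * 2.0 * bounding_radius(block.source)
    D = _pair_dists(coms)
    neighbours = [set(np.where(D[i] <= cutoff)[0]) - {i} for i in range(len(block))]

    root = CandidateAssembly(members=(0,), compactness=0.0)
    series = [root]
    messages: list = []
    for n in range(2, n_max + 1):
        prev = series[-1].members
        frontier = sorted(int(x) for x in set().union(*(neighbours[i] for i in prev)) - set(prev))
        cands = []
        for v in frontier:
            members = tuple(sorted((*prev, v)))
            if _has_clash(block, members, clash_fraction):
                continue
            comp = compactness_of(block, members)
            cand = CandidateAssembly(
                members=members, compactness=comp, nested_parent=prev
            )
            cand.symmetry = point_group_score(coms[list(members)])
            cands.append(cand)
        if not cands:
            messages.append(f"n={n}: no connected clash-free extension")
            return StepwiseResult(series=series, complete=False, messages=messages)

        exp = experimental.get(n)
        rank_key = lambda c: (round(c.compactness, 6), -c.symmetry[0],
                              not c.symmetry[1], c.members)
        if exp is not None:
            exp_ccs, rel_err = exp
            for cand in cands:
                cand.ccs = assembly_ccs(
                    block, cand.members, radii=radii,
                    n_rotations=n_rotations, n_points=n_points, seed=seed,
                    scale=scale,
                )
                cand.deviation = (cand.ccs.value - exp_ccs) / exp_ccs
            tol = rel_err if rel_err is not None else tolerance
            feasible = [c for c in cands if abs(c.deviation) <= tol]
            if not feasible:
                chosen = min(cands, key=lambda c: abs(c.deviation))
                messages.append(
                    f"n={n}: best candidate deviates {chosen.deviation:+.1%}, "
                    f"outside the {tol:.0%} tolerance"
                )
                series.append(chosen)
                return StepwiseResult(series=series, complete=False, messages=messages)
            # candidates within one experimental uncertainty of the best fit
            # are joint solutions; prefer compact, then symmetric, packings
            best_abs = min(abs(c.deviation) for c in feasible)
            tied = [c for c in feasible if abs(c.deviation) <= best_abs + tol]
            chosen = min(tied, key=rank_key)
        else:
            chosen = min(cands, key=rank_key)
            messages.append(f"n={n}: no experimental CCS; selected by compactness/symmetry")
        series.append(chosen)
    return StepwiseResult(series=series, complete=True, messages=messages)
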