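"""Archetypal oligomer topologies and CCS-vs-n trend lines.

Candidate quaternary structures are bounded and classified with idealized
geometric arrangements of n copies of a building block: linear chains,
regular rings, double-tiered rings, face/end stacks, lateral edge-to-edge
chains, and a maximally collapsed packing.  The linear and collapsed
archetypes bracket the accessible CCS range at every oligomer order; the
others interpolate between them.  Nearest-neighbour copies are placed at
tangency of their bounding spheres, with a configurable fractional overlap
mimicking packed protein interfaces.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import ccs as ccs_mod
from .models import AtomicStructure, Sphere, SphereModel

__all__ = [
    "OligomerModel",
    "TrendLine",
    "TOPOLOGIES",
    "generate_archetype",
    "trend_lines",
    "block_spheres",
    "bounding_radius",
]

TOPOLOGIES = (
    "linear",
    "ring",
    "double_tiered_ring",
    "collapsed",
    "stack_face",
    "stack_end",
    "edge_to_edge",
)

DEFAULT_OVERLAP = 0.10  # fractional interpenetration of bounding spheres


def block_spheres(block, radii: ccs_mod.CollisionRadii | None = None) -> tuple:
    """(centers, radii, masses) of a block, whatever its representation."""
    if isinstance(block, AtomicStructure):
        rtab = radii or ccs_mod.CollisionRadii()
        return (
            block.coords,
            rtab.for_elements(block.elements),
            block.atom_masses(),
        )
    if hasattr(block, "centers") and hasattr(block, "radii"):
        # SphereModel or any sphere-model-like wrapper
        return (
            np.asarray(block.centers, float),
            np.asarray(block.radii, float),
            np.asarray(block.masses, float),
        )
    raise TypeError(f"unsupported block type {type(block).__name__}")


def _com(block) -> np.ndarray:
    c, _, m = block_spheres(block)
    return (c * m[:, None]).sum(axis=0) / m.sum()


def bounding_radius(block) -> float:
    """Radius of the tight bounding sphere around the block's center of mass."""
    centers, radii, _ = block_spheres(block)
    com = _com(block)
    return float((np.linalg.norm(centers - com, axis=1) + radii).max())


def _principal_axes(block) -> np.ndarray:
    """Rows: principal axes of the mass distribution, longest extent first."""
    centers, _, masses = block_spheres(block)
    com = _com(block)
    x = centers - com
    cov = (x * masses[:, None]).T @ x / masses.sum()
    evals, evecs = np.linalg.eigh(cov)
    axes = evecs[:, ::-1].T  # descending variance
    if np.allclose(evals, evals[0]):
        return np.eye(3)  # isotropic block: fixed frame
    return axes


def _axis_extent(block, axis: np.ndarray) -> float:
    centers, radii, _ = block_spheres(block)
    com = _com(block)
    proj = np.abs((centers - com) @ axis)
    return float(2.0 * (proj + radii).max())


@dataclass
class OligomerModel:
    """n rigid copies of a building block with a topology label."""

    block: object  # SphereModel or AtomicStructure
    placements: list  # [(R (3,3), t (3,)), ...] acting on COM-centered coords
    topology: str
    n: int

    def __post_init__(self):
        if self.n != len(self.placements) or self.n < 1:
            raise ValueError("n must equal the number of placements and be >= 1")
        for R, _ in self.placements:
            if not np.allclose(np.asarray(R) @ np.asarray(R).T, np.eye(3), atol=1e-8):
                raise ValueError("placements must be distance-preserving")

    def as_spheres(self, radii: ccs_mod.CollisionRadii | None = None) -> tuple:
        centers, r, masses = block_spheres(self.block, radii)
        com = _com(self.block)
        local = centers - com
        all_c, all_r, all_m = [], [], []
        for R, t in self.placements:
            all_c.append(local @ np.asarray(R).T + np.asarray(t))
            all_r.append(r)
            all_m.append(masses)
        return np.vstack(all_c), np.concatenate(all_r), np.concatenate(all_m)

    def copy_centers(self) -> np.ndarray:
        return np.array([np.asarray(t, float) for _, t in self.placements])

    def to_sphere_model(self, radii: ccs_mod.CollisionRadii | None = None) -> SphereModel:
        centers, r, masses = self.as_spheres(radii)
        spheres = [
            Sphere(
                label=f"copy{i // (len(r) // self.n)}_s{i % (len(r) // self.n)}",
                center=tuple(c),
                radius=float(rr),
                mass=float(mm),
                kind="subunit",
            )
            for i, (c, rr, mm) in enumerate(zip(centers, r, masses))
        ]
        return SphereModel(spheres=spheres, provenance=f"{self.topology}_{self.n}")

    def ccs(
        self,
        radii: ccs_mod.CollisionRadii | None = None,
        n_rotations: int = ccs_mod.DEFAULT_N_ROTATIONS,
        n_points: int = ccs_mod.DEFAULT_N_POINTS,
        seed: int = 0,
        scale: float = 1.0,
    ) -> ccs_mod.CCSEstimate:
        centers, r, _ = self.as_spheres(radii)
        return ccs_mod.pa_ccs_points(
            centers, r, n_rotations=n_rotations, n_points=n_points, seed=seed,
            scale=scale,
        )


def _rot_about(axis: np.ndarray, angle: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(np.asarray(axis) * angle).as_matrix()


def _collapsed_centers(n: int, spacing: float, seed: int) -> np.ndarray:
    """Greedy sphere packing minimizing the sum of pairwise center distances.

    Candidate positions are contact points on already-placed copies over a
    fixed direction set; a short repulsion/contraction refinement follows.
    Deterministic for a given seed.  This is a bound, not a candidate, so
    exact optimality is not required.
    """
    rng = np.random.default_rng(seed)
    # near-uniform directions (Fibonacci sphere) + a few random ones
    m = 40
    i = np.arange(m)
    phi = np.arccos(1 - 2 * (i + 0.5) / m)
    golden = np.pi * (1 + 5**0.5)
    dirs = np.column_stack(
        [np.sin(phi) * np.cos(golden * i), np.sin(phi) * np.sin(golden * i), np.cos(phi)]
    )
    dirs = np.vstack([dirs, rng.standard_normal((10, 3))])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

    placed = [np.zeros(3)]
    for _ in range(1, n):
        best, best_cost = None, np.inf
        P = np.array(placed)
        for p in placed:
            cands = p + spacing * dirs
            d = np.linalg.norm(cands[:, None, :] - P[None, :, :], axis=2)
            ok = (d >= spacing * (1 - 1e-9)).all(axis=1)
            if not ok.any():
                continue
            cost = d[ok].sum(axis=1)
            j = int(np.argmin(cost))
            if cost[j] < best_cost:
                best_cost = float(cost[j])
                best = cands[ok][j]
        placed.append(best)
    P = np.array(placed)
    # refinement: pull toward centroid, push apart overlaps
    for _ in range(60):
        centroid = P.mean(axis=0)
        P += 0.05 * (centroid - P)
        d = np.linalg.norm(P[:, None, :] - P[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        for a in range(n):
            for b in range(a + 1, n):
                if d[a, b] < spacing:
                    mid = 0.5 * (P[a] + P[b])
                    u = P[a] - P[b]
                    nu = np.linalg.norm(u)
                    u = u / nu if nu > 1e-12 else np.array([1.0, 0, 0])
                    P[a] = mid + 0.5 * spacing * u
                    P[b] = mid - 0.5 * spacing * u
    return P - P[0]


def generate_archetype(
    block,
    n: int,
    topology: str,
    overlap: float = DEFAULT_OVERLAP,
    seed: int = 0,
) -> OligomerModel:
    """Place n copies of a building block in an archetypal arrangement."""
    if topology not in TOPOLOGIES:
        raise ValueError(f"unknown topology {topology!r}; one of {TOPOLOGIES}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if topology == "ring" and 1 < n < 3:
        raise ValueError("a ring needs n >= 3")
    if topology == "double_tiered_ring" and n > 1 and (n % 2 or n < 6):
        raise ValueError("a double-tiered ring needs even n >= 6")

    R0 = bounding_radius(block)
    spacing = 2.0 * R0 * (1.0 - overlap)
    eye = np.eye(3)

    if n == 1:
        return OligomerModel(block, [(eye, np.zeros(3))], topology, 1)

    placements = []
    if topology == "linear":
        for i in range(n):
            placements.append((eye, np.array([i * spacing, 0.0, 0.0])))
    elif topology == "ring":
        rc = spacing / (2.0 * np.sin(np.pi / n))
        for i in range(n):
            th = 2.0 * np.pi * i / n
            placements.append((eye, rc * np.array([np.cos(th), np.sin(th), 0.0])))
    elif topology == "double_tiered_ring":
        m = n // 2
        rc = spacing / (2.0 * np.sin(np.pi / m))
        for tier, z in ((0, -spacing / 2), (1, spacing / 2)):
            for i in range(m):
                th = 2.0 * np.pi * i / m + tier * np.pi / m  # staggered tiers
                placements.append(
                    (eye, np.array([rc * np.cos(th), rc * np.sin(th), z]))
                )
    elif topology == "collapsed":
        # the lower bound packs at the tightest legitimate contact: the
        # block's smallest axis extent, not the bounding-sphere diameter
        axes = _principal_axes(block)
        tight = min(_axis_extent(block, ax) for ax in axes) * (1.0 - overlap)
        for t in _collapsed_centers(n, tight, seed):
            placements.append((eye, t))
    elif topology in ("stack_face", "stack_end", "edge_to_edge"):
        axes = _principal_axes(block)
        axis = {"stack_end": axes[0], "edge_to_edge": axes[1], "stack_face": axes[2]}[
            topology
        ]
        step = _axis_extent(block, axis) * (1.0 - overlap)
        for i in range(n):
            R = eye
            if topology == "stack_end" and i % 2 == 1:
                R = _rot_about(axis, np.pi)  # alternate head-to-head copies
            placements.append((R, i * step * axis))
    model = OligomerModel(block, placements, topology, n)
    # center the assembly on its copy centroid for tidy output
    centroid = model.copy_centers().mean(axis=0)
    model.placements = [(R, t - centroid) for R, t in model.placements]
    return model


@dataclass
class TrendLine:
    """CCS per (topology, n), with an optional experimental series."""

    series: dict  # topology -> list[(n, ccs, stderr)]
    experimental: dict = field(default_factory=dict)  # n -> (ccs, rel_error)

    def to_dataframe(self):
        import pandas as pd

        rows = [
            (topo, n, v, se)
            for topo, pts in self.series.items()
            for n, v, se in pts
        ]
        return pd.DataFrame(rows, columns=["topology", "n", "ccs_A2", "mc_stderr"])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def trend_lines(
    block,
    topologies=TOPOLOGIES,
    n_values=(1, 2, 3, 4, 5, 6, 7, 8),
    experimental: dict | None = None,
    overlap: float = DEFAULT_OVERLAP,
    radii: ccs_mod.CollisionRadii | None = None,
    n_rotations: int = ccs_mod.DEFAULT_N_ROTATIONS,
    n_points: int = ccs_mod.DEFAULT_N_POINTS,
    seed: int = 0,
    scale: float = 1.0,
) -> TrendLine:
    """CCS-vs-n curves for each archetypal topology of a building block."""
    if not topologies:
        raise ValueError("need at least one topology")
    series: dict = {}
    for topo in topologies:
        pts = []
        for n in sorted(n_values):
            try:
                model = generate_archetype(block, n, topo, overlap=overlap, seed=seed)
            except ValueError:
                continue  # unsupported (topology, n), e.g. odd double-tiered
            est = model.ccs(
                radii=radii, n_rotations=n_rotations, n_points=n_points, seed=seed,
                scale=scale,
            )
            pts.append((n, est.value, est.mc_stderr))
        series[topo] = pts
    return TrendLine(series=series, experimental=dict(experimental or {}))
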