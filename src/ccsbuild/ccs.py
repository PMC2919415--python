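"""Projection-approximation (PA) collision cross-section estimation.

The PA treats every atom (or coarse-grained sphere) as a hard sphere and
estimates the CCS as the orientationally averaged area of the projected
union of disks.  Orientations are sampled as uniform random rotations; the
projected area per orientation is measured by uniform point sampling over
the tight bounding box of the projection.  The PA systematically
underestimates the true CCS of large ions (it ignores scattering), so a
global multiplicative scale factor is carried with every estimate and a
least-squares calibration helper is provided.

A linear missing-mass correction implements the rule that structures
missing < 5% of their mass have their computed CCS scaled up by the
full/present mass ratio rather than being remodelled.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from .models import AtomicStructure, MassAccount, SphereModel

__all__ = [
    "CCSEstimate",
    "CollisionRadii",
    "Deviation",
    "pa_ccs_spheres",
    "pa_ccs_atoms",
    "pa_ccs_points",
    "linear_scale_ccs",
    "deviation",
    "calibrate_scale",
    "MissingMassRuleError",
]

MISSING_MASS_THRESHOLD = 0.05
DEFAULT_N_ROTATIONS = 300
DEFAULT_N_POINTS = 4000
DEFAULT_RADIUS = 2.2  # Å, generic heavy-atom collision radius


class MissingMassRuleError(ValueError):
    """Linear CCS scaling requested for a structure missing >= 5% of its mass."""


@dataclass(frozen=True)
class CCSEstimate:
    """A PA CCS value (Å²) with its Monte-Carlo standard error."""

    value: float
    mc_stderr: float
    n_rotations: int
    n_points: int
    scale: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("CCS must be positive")
        if self.mc_stderr < 0:
            raise ValueError("mc_stderr must be >= 0")


@dataclass(frozen=True)
class CollisionRadii:
    """Per-element hard-sphere collision radii (Å) with a fallback default."""

    table: tuple = ()  # ((element, radius), ...)
    default: float = DEFAULT_RADIUS

    def __post_init__(self):
        if self.default is not None and self.default <= 0:
            raise ValueError("default radius must be positive")
        for el, r in self.table:
            if r <= 0:
                raise ValueError(f"radius for {el} must be positive")

    def radius(self, element: str) -> float:
        for el, r in self.table:
            if el.upper() == element.upper():
                return r
        if self.default is None:
            raise KeyError(f"no collision radius for element {element!r}")
        return self.default

    def for_elements(self, elements) -> np.ndarray:
        return np.array([self.radius(e) for e in elements])

    @staticmethod
    def from_yaml(path) -> "CollisionRadii":
        data = yaml.safe_load(open(path)) or {}
        table = tuple((str(k), float(v)) for k, v in data.get("elements", {}).items())
        return CollisionRadii(table=table, default=float(data.get("default", DEFAULT_RADIUS)))


try:  # JIT point-in-union test; pure-numpy fallback below
    from numba import njit

    @njit(cache=True)
    def _count_hits(xs, xy, r2, pts, rmax):  # pragma: no cover - jitted
        hits = 0
        for i in range(pts.shape[0]):
            px = pts[i, 0]
            py = pts[i, 1]
            lo = np.searchsorted(xs, px - rmax)
            hi = np.searchsorted(xs, px + rmax)
            for j in range(lo, hi):
                dx = px - xy[j, 0]
                dy = py - xy[j, 1]
                if dx * dx + dy * dy <= r2[j]:
                    hits += 1
                    break
        return hits

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _hits_numpy(xy, r2, pts):
    max_pairs = 8_000_000
    chunk = max(1, min(len(pts), max_pairs // max(1, len(xy))))
    hits = 0
    for start in range(0, len(pts), chunk):
        p = pts[start : start + chunk]
        d2 = ((p[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
        hits += int((d2 <= r2[None, :]).any(axis=1).sum())
    return hits


def _projected_areas(
    centers: np.ndarray,
    radii: np.ndarray,
    n_rotations: int,
    n_points: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Monte-Carlo projected union-of-disks area for each random orientation."""
    rots = Rotation.random(n_rotations, random_state=rng).as_matrix()
    rmax = float(radii.max())
    areas = np.empty(n_rotations)
    for k in range(n_rotations):
        xy = centers @ rots[k].T[:, :2]  # (N, 2) projected centers
        lo = (xy - radii[:, None]).min(axis=0)
        hi = (xy + radii[:, None]).max(axis=0)
        span = hi - lo
        box = span[0] * span[1]
        pts = lo + rng.random((n_points, 2)) * span
        if _HAVE_NUMBA:
            order = np.argsort(xy[:, 0])
            xy_s = np.ascontiguousarray(xy[order])
            r2_s = np.ascontiguousarray(radii[order] ** 2)
            hits = _count_hits(xy_s[:, 0].copy(), xy_s, r2_s, pts, rmax)
        else:
            hits = _hits_numpy(xy, radii**2, pts)
        areas[k] = box * hits / n_points
    return areas


def pa_ccs_points(
    centers,
    radii,
    n_rotations: int = DEFAULT_N_ROTATIONS,
    n_points: int = DEFAULT_N_POINTS,
    seed: int | None = 0,
    scale: float = 1.0,
) -> CCSEstimate:
    """PA CCS of an arbitrary hard-sphere cloud (centers Å, radii Å)."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    radii = np.atleast_1d(np.asarray(radii, dtype=float))
    if centers.shape[0] != radii.shape[0]:
        raise ValueError("centers and radii length mismatch")
    if centers.shape[0] == 0:
        raise ValueError("need at least one sphere")
    if np.any(radii <= 0):
        raise ValueError("all radii must be positive")
    if n_rotations < 1:
        raise ValueError("n_rotations must be >= 1")
    if n_points < 100:
        raise ValueError("n_points must be >= 100")
    rng = np.random.default_rng(seed)
    areas = _projected_areas(centers, radii, n_rotations, n_points, rng)
    value = float(areas.mean())
    stderr = float(areas.std(ddof=1) / np.sqrt(n_rotations)) if n_rotations > 1 else 0.0
    return CCSEstimate(
        value=value * scale,
        mc_stderr=stderr * scale,
        n_rotations=n_rotations,
        n_points=n_points,
        scale=scale,
        seed=seed,
    )


def pa_ccs_spheres(
    model: SphereModel,
    n_rotations: int = DEFAULT_N_ROTATIONS,
    n_points: int = DEFAULT_N_POINTS,
    seed: int | None = 0,
    scale: float = 1.0,
) -> CCSEstimate:
    """PA CCS of a coarse-grained sphere model."""
    if len(model) == 0:
        raise ValueError("sphere model is empty")
    return pa_ccs_points(
        model.centers, model.radii, n_rotations, n_points, seed, scale
    )


def pa_ccs_atoms(
    structure: AtomicStructure,
    radii: CollisionRadii | None = None,
    scale: float = 1.0,
    n_rotations: int = DEFAULT_N_ROTATIONS,
    n_points: int = DEFAULT_N_POINTS,
    seed: int | None = 0,
) -> CCSEstimate:
    """PA CCS of an atomic structure using per-element collision radii."""
    if structure.n_atoms == 0:
        raise ValueError("structure has no atoms")
    radii = radii or CollisionRadii()
    r = radii.for_elements(structure.elements)
    return pa_ccs_points(structure.coords, r, n_rotations, n_points, seed, scale)


def linear_scale_ccs(
    ccs: CCSEstimate, account: MassAccount, exponent: float = 1.0
) -> CCSEstimate:
    """Correct a CCS computed from an incomplete structure for small missing mass.

    Allowed only when f_missing < 5%; the value (and its standard error) is
    multiplied by (m_full / m_present) ** exponent.  The default exponent of
    1 applies the correction linearly in the mass ratio; ``exponent=2/3``
    gives the constant-density geometric alternative.
    """
    if account.f_missing >= MISSING_MASS_THRESHOLD:
        raise MissingMassRuleError(
            f"missing mass fraction {account.f_missing:.3f} >= "
            f"{MISSING_MASS_THRESHOLD:.0%}: use the homology or "
            "coarse-grained modelling paths instead of linear scaling"
        )
    factor = (account.m_full / account.m_present) ** exponent
    return replace(
        ccs, value=ccs.value * factor, mc_stderr=ccs.mc_stderr * factor
    )


@dataclass(frozen=True)
class Deviation:
    """Signed relative deviation of a model CCS from a measurement."""

    value: float  # (model - exp) / exp
    within_error: bool
    tolerance: float


def deviation(
    model_ccs: CCSEstimate | float,
    exp_ccs: float,
    rel_error: float | None = None,
    tolerance: float = 0.10,
) -> Deviation:
    """Relative deviation (model − exp)/exp with a within-error flag.

    The flag tolerance defaults to 10% or, when supplied, the experimental
    relative error of the measurement.
    """
    if exp_ccs <= 0:
        raise ValueError("experimental CCS must be positive")
    value = model_ccs.value if isinstance(model_ccs, CCSEstimate) else float(model_ccs)
    tol = rel_error if rel_error is not None else tolerance
    dev = (value - exp_ccs) / exp_ccs
    return Deviation(value=dev, within_error=abs(dev) <= tol, tolerance=tol)


def calibrate_scale(pairs) -> float:
    """Least-squares PA scale factor from (computed_ccs, measured_ccs) pairs.

    Minimizes sum (s * computed - measured)^2 over s.
    """
    comp = np.array([float(c.value if isinstance(c, CCSEstimate) else c) for c, _ in pairs])
    meas = np.array([float(m) for _, m in pairs])
    if comp.size == 0:
        raise ValueError("need at least one calibration pair")
    return float((comp * meas).sum() / (comp * comp).sum())
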