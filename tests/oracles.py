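"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's Monte-Carlo machinery: the
two-disk union area is integrated by adaptive quadrature over the
orientation angle, and candidate enumeration is done by exhaustive
combination search with networkx connectivity.
"""
from __future__ import annotations

import itertools

import numpy as np
from scipy.integrate import quad


def two_disk_union_area(s: float, r: float) -> float:
    """Area of the union of two disks of radius r at center distance s."""
    if s >= 2 * r:
        return 2 * np.pi * r * r
    lens = 2 * r * r * np.arccos(s / (2 * r)) - (s / 2) * np.sqrt(4 * r * r - s * s)
    return 2 * np.pi * r * r - lens


def two_sphere_pa_ccs(d: float, r: float) -> float:
    """Orientation-averaged projected union area of two spheres of radius r.

    The projected center separation at polar angle theta between the
    center-line and the viewing axis is d*sin(theta); averaging over
    uniformly distributed orientations weights theta by sin(theta).
    """
    val, _ = quad(
        lambda th: two_disk_union_area(d * np.sin(th), r) * np.sin(th),
        0.0,
        np.pi / 2,
        limit=200,
    )
    return val


def sphere_overlap_volume(d: float, r1: float, r2: float) -> float:
    """Intersection volume of two spheres (lens formula)."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        rm = min(r1, r2)
        return 4.0 / 3.0 * np.pi * rm**3
    return (
        np.pi
        * (r1 + r2 - d) ** 2
        * (d**2 + 2 * d * (r1 + r2) - 3 * (r1 - r2) ** 2)
        / (12 * d)
    )


def brute_force_candidates(coms: np.ndarray, n: int, cutoff: float,
                           radius: float | None = None,
                           clash_fraction: float = 0.05) -> list:
    """All connected n-subsets containing copy 0, sorted by compactness.

    Connectivity via networkx; compactness is the plain pairwise-distance
    sum.  When ``radius`` is given, each copy is one sphere of that radius
    and subsets with a pairwise volume overlap above ``clash_fraction`` of
    a sphere's volume are discarded.
    Returns [(compactness, members), ...] ascending.
    """
    import networkx as nx

    m = len(coms)
    D = np.linalg.norm(coms[:, None, :] - coms[None, :, :], axis=2)
    out = []
    for S in itertools.combinations(range(m), n):
        if 0 not in S:
            continue
        G = nx.Graph()
        G.add_nodes_from(S)
        for a, b in itertools.combinations(S, 2):
            if D[a, b] <= cutoff:
                G.add_edge(a, b)
        if not nx.is_connected(G):
            continue
        if radius is not None:
            vol = 4.0 / 3.0 * np.pi * radius**3
            if any(
                sphere_overlap_volume(D[a, b], radius, radius) / vol > clash_fraction
                for a, b in itertools.combinations(S, 2)
            ):
                continue
        comp = float(sum(D[a, b] for a, b in itertools.combinations(S, 2)))
        out.append((round(comp, 6), tuple(sorted(S))))
    out.sort()
    return out
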