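"""Morphometry from SWC trees: Sholl profiles, apical length, spine density.

Sholl analysis counts the intersections of the dendritic arbour with
concentric spheres (circles after ``planar`` projection) at fixed radial
increments from the soma (default 5 um). Each parent-child segment is
treated as a straight line; crossings are counted exactly from the quadratic
distance-along-edge function, so a segment that dips below a radius and
comes back counts both crossings. A node lying exactly on a radius is
credited to its child edge (the crossing parameter t in (0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import Morphology, ParameterError

__all__ = ["ShollProfile", "sholl", "apical_length", "spine_density"]

DEFAULT_SHOLL_STEP_UM = 5.0
DEFAULT_SPINE_DENDRITE_UM = 10.0


@dataclass(frozen=True)
class ShollProfile:
    """Intersections per concentric radius (radii are multiples of step)."""

    radii_um: np.ndarray
    intersections: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "radii_um", np.asarray(self.radii_um, float))
        object.__setattr__(self, "intersections",
                           np.asarray(self.intersections, int))


def _edge_crossings(d0: float, a_dot_v: float, v2: float, r: float) -> int:
    """Number of crossings of |p0 + t v| = r for t in (0, 1].

    ``d0`` is |p0|^2; the squared distance along the edge is the quadratic
    q(t) = d0 + 2 t a_dot_v + t^2 v2. Transversal crossings are counted;
    tangencies are not.
    """
    if v2 == 0:
        return 0
    c = d0 - r * r
    disc = a_dot_v * a_dot_v - v2 * c
    if disc <= 0:
        return 0  # no real root or tangency
    sq = np.sqrt(disc)
    roots = ((-a_dot_v - sq) / v2, (-a_dot_v + sq) / v2)
    return sum(1 for t in roots if 0.0 < t <= 1.0)


def sholl(m: Morphology, step: float = DEFAULT_SHOLL_STEP_UM,
          planar: bool = False) -> ShollProfile:
    """Sholl profile: intersections with spheres at radii step, 2*step, ...

    With ``planar=True`` the tree is projected onto the xy plane first
    (matching image-derived morphologies); otherwise distances are 3-D
    Euclidean. A soma-only morphology yields an empty profile; radii beyond
    the farthest node are not reported (their count is zero by definition).
    """
    if step <= 0:
        raise ParameterError("step must be positive")
    edges = m.edges()
    if edges.size == 0:
        return ShollProfile(np.empty(0), np.empty(0, int))
    xyz = m.xyz[:, :2] if planar else m.xyz
    soma = (m.soma_xyz[:2] if planar else m.soma_xyz)
    p = xyz - soma
    d = np.linalg.norm(p, axis=1)
    max_r = d.max()
    n_radii = int(np.floor(max_r / step + 1e-9))
    if max_r > n_radii * step:
        n_radii += 1  # partial outer shell still crossable
    radii = step * np.arange(1, n_radii + 1)
    counts = np.zeros(radii.size, int)
    p0 = p[edges[:, 0]]
    v = p[edges[:, 1]] - p0
    d0 = np.einsum("ij,ij->i", p0, p0)
    adv = np.einsum("ij,ij->i", p0, v)
    v2 = np.einsum("ij,ij->i", v, v)
    for k, r in enumerate(radii):
        counts[k] = sum(_edge_crossings(d0[e], adv[e], v2[e], r)
                        for e in range(edges.shape[0]))
    # drop trailing all-zero shells beyond the arbour
    nz = np.flatnonzero(counts)
    if nz.size == 0:
        return ShollProfile(np.empty(0), np.empty(0, int))
    last = nz[-1] + 1
    return ShollProfile(radii[:last], counts[:last])


def apical_length(m: Morphology) -> float:
    """Maximum Euclidean distance from the soma to any node (um).

    Used as the soma-to-most-apical-point length; apical orientation is not
    encoded in SWC, so the farthest node stands in for the apical tip.
    """
    d = np.linalg.norm(m.xyz - m.soma_xyz, axis=1)
    return float(d.max())


def spine_density(spines: pd.DataFrame,
                  dendrite_length: float = DEFAULT_SPINE_DENDRITE_UM) -> float:
    """Spines per micrometre along the annotated dendritic segment.

    ``spines`` is the annotation table (one row per spine); the designated
    segment has length ``dendrite_length`` um (default 10 um of distal
    dendrite).
    """
    if dendrite_length <= 0:
        raise ParameterError("dendrite_length must be positive")
    return float(len(spines)) / dendrite_length
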