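"""Axial-compression / anterior-shear decomposition of intersegmental forces.

At L4L5 the axial direction runs through the two intervertebral joints of L5
(caudally oriented) and the anterior direction is its +90-degree orthogonal,
parallel to the L5 upper endplate. At L5S1 the anterior direction is parallel
to the sacral endplate at the configuration's sacral slope and the axial
direction is its caudal normal. Compression is positive for a caudally
transmitted standing load.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, ValidationError
from .posture import PostureConfig

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class ProjectionAxes:
    """Orthonormal (axial caudal, anterior) unit-vector pair."""

    axial: np.ndarray
    anterior: np.ndarray

    def __post_init__(self) -> None:
        for v in (self.axial, self.anterior):
            if abs(float(np.linalg.norm(v)) - 1.0) > _ORTHO_TOL:
                raise ValidationError("projection axes must be unit vectors")
        if abs(float(self.axial @ self.anterior)) > _ORTHO_TOL:
            raise ValidationError("projection axes must be orthogonal")


def _ccw90(v: np.ndarray) -> np.ndarray:
    return np.array([-v[1], v[0]])


def l4l5_axes(posture: PostureConfig) -> ProjectionAxes:
    """Axes at L4L5: axial through L5's two joints, anterior endplate-parallel."""
    d = posture.joint_positions["l5s1"] - posture.joint_positions["l4l5"]
    n = float(np.linalg.norm(d))
    if n < 1e-12:
        raise GeometryError("L4L5 and L5S1 joints coincide")
    axial = d / n
    return ProjectionAxes(axial=axial, anterior=_ccw90(axial))


def l5s1_axes(posture: PostureConfig) -> ProjectionAxes:
    """Axes at L5S1 from the sacral endplate direction at the posture's SS."""
    a = math.radians(posture.params.ss)
    anterior = np.array([math.cos(a), -math.sin(a)])
    axial = np.array([-math.sin(a), -math.cos(a)])
    return ProjectionAxes(axial=axial, anterior=anterior)


def decompose(force: np.ndarray, axes: ProjectionAxes) -> tuple[float, float]:
    """Project a world force onto (compression, anterior shear), in N."""
    force = np.asarray(force, dtype=float)
    return float(force @ axes.axial), float(force @ axes.anterior)


__all__ = ["ProjectionAxes", "l4l5_axes", "l5s1_axes", "decompose"]
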