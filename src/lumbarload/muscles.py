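"""Lumped sagittal trunk actuators and their moment-arm geometry.

The full fascicle anatomy is reduced to at most a dozen bilateral-summed
straight-line actuators: five mono-segmental multifidus fascicles (one per
lumbar joint, small posterior offset), one erector-spinae/longissimus
actuator from the thorax to the sacrum crossing every lumbar joint (larger
posterior offset), and one rectus-abdominis flexor from the thorax to the
pubic region of the pelvis (large anterior offset). Group force totals are
reported as F_MF, F_ES (equivalently F_LS) and F_RA.

Moment arms are signed so that a positive arm means tension produces an
extension (posterior) moment at the joint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .config import LUMBAR_JOINTS, ModelConstants, default_constants
from .errors import ConfigurationError, GeometryError
from .posture import PostureConfig, rotation_matrix

#: chain rank used to decide which joints a fascicle spans
_RANK = {"sacrum_pelvis": 0, "l5": 1, "l4": 2, "l3": 3, "l2": 4, "l1": 5, "thorax": 6}

#: joint -> rank of the segment immediately below it
_JOINT_RANK = {"l5s1": 0, "l4l5": 1, "l3l4": 2, "l2l3": 3, "l1l2": 4, "t12l1": 5}

EXTENSOR_GROUPS = frozenset({"multifidus", "erector_spinae"})
FLEXOR_GROUPS = frozenset({"rectus_abdominis"})


@dataclass(frozen=True)
class MuscleFascicle:
    """A straight-line bilateral-summed actuator.

    ``origin`` is the cranial attachment, ``insertion`` the caudal one; local
    coordinates are in the owning segment's frame (origin at the segment's
    caudal joint, or at the endplate midpoint for the sacrum).
    """

    name: str
    group: str
    origin_segment: str
    origin_local: tuple[float, float]
    insertion_segment: str
    insertion_local: tuple[float, float]
    strength: float
    spanned_joints: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.strength <= 0:
            raise ConfigurationError(f"{self.name}: strength must be positive")
        if self.origin_segment == self.insertion_segment:
            raise ConfigurationError(
                f"{self.name}: origin and insertion on the same segment"
            )
        if _RANK[self.origin_segment] <= _RANK[self.insertion_segment]:
            raise ConfigurationError(
                f"{self.name}: origin must be cranial to insertion"
            )


@dataclass(frozen=True)
class MuscleSet:
    fascicles: tuple[MuscleFascicle, ...]
    abdominal_pressure_enabled: bool = False

    def group(self, name: str) -> tuple[MuscleFascicle, ...]:
        return tuple(f for f in self.fascicles if f.group == name)


def _spanned(origin_segment: str, insertion_segment: str) -> tuple[str, ...]:
    lo = _RANK[insertion_segment]
    hi = _RANK[origin_segment]
    return tuple(j for j, r in _JOINT_RANK.items() if lo <= r < hi)


def _segment_frame(segment: str, posture: PostureConfig) -> tuple[np.ndarray, float]:
    """World base point and inclination of a segment's local frame."""
    joints = posture.joint_positions
    if segment == "sacrum_pelvis":
        # The sacrum's local frame stands at the default sacral slope; its
        # attachments rotate with the applied sacrum rotation, not the full SS.
        base = 0.5 * (posture.endplate_posterior_corner
                      + posture.endplate_anterior_corner)
        return np.asarray(base, dtype=float), posture.sacrum_rotation_deg
    elif segment == "thorax":
        base = joints["t12l1"]
    elif segment in ("l1", "l2", "l3", "l4", "l5"):
        inferior = {"l5": "l5s1", "l4": "l4l5", "l3": "l3l4",
                    "l2": "l2l3", "l1": "l1l2"}
        base = joints[inferior[segment]]
    else:
        raise GeometryError(f"segment {segment!r} carries no muscle attachments")
    return np.asarray(base, dtype=float), posture.segment_orientations[segment]


def attachment_point(segment: str, local: tuple[float, float],
                     posture: PostureConfig) -> np.ndarray:
    base, angle = _segment_frame(segment, posture)
    return base + rotation_matrix(angle) @ np.asarray(local, dtype=float)


def line_of_action(fascicle: MuscleFascicle,
                   posture: PostureConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit vector (origin -> insertion) and world attachment points."""
    p_o = attachment_point(fascicle.origin_segment, fascicle.origin_local, posture)
    p_i = attachment_point(fascicle.insertion_segment, fascicle.insertion_local,
                           posture)
    d = p_i - p_o
    n = float(np.linalg.norm(d))
    if n < 1e-12:
        raise GeometryError(f"{fascicle.name}: coincident attachment points")
    return d / n, p_o, p_i


def moment_arm(fascicle: MuscleFascicle, joint: str,
               posture: PostureConfig) -> float:
    """Signed perpendicular distance from the joint to the line of action.

    Positive arms give an extension moment for positive tension; a fascicle
    that does not span the joint contributes a zero arm.
    """
    if joint not in fascicle.spanned_joints:
        return 0.0
    u, p_o, _ = line_of_action(fascicle, posture)
    j = posture.joint_positions[joint]
    r = p_o - j
    return float(r[0] * u[1] - r[1] * u[0])


def build_muscle_set(constants: ModelConstants | None = None) -> MuscleSet:
    """Construct the default lumped actuator set from the constants file."""
    constants = constants or default_constants()
    heights = constants.anthropometry.vertebra_heights_m
    mf = constants.multifidus
    es = constants.erector_spinae
    ra = constants.rectus_abdominis
    off = -float(mf.posterior_offset_m or 0.0)

    def mid(level: str) -> tuple[float, float]:
        return (off, heights[level] / 2.0)

    fascicles = [
        MuscleFascicle("mf_l1l2", "multifidus", "l1", mid("l1"), "l2", mid("l2"),
                       mf.strength_n, _spanned("l1", "l2")),
        MuscleFascicle("mf_l2l3", "multifidus", "l2", mid("l2"), "l3", mid("l3"),
                       mf.strength_n, _spanned("l2", "l3")),
        MuscleFascicle("mf_l3l4", "multifidus", "l3", mid("l3"), "l4", mid("l4"),
                       mf.strength_n, _spanned("l3", "l4")),
        MuscleFascicle("mf_l4l5", "multifidus", "l4", mid("l4"), "l5", mid("l5"),
                       mf.strength_n, _spanned("l4", "l5")),
        MuscleFascicle("mf_l5s1", "multifidus", "l5", mid("l5"),
                       "sacrum_pelvis", tuple(mf.sacrum_local_m),  # type: ignore[arg-type]
                       mf.strength_n, _spanned("l5", "sacrum_pelvis")),
        MuscleFascicle("erector_spinae", "erector_spinae",
                       "thorax", tuple(es.thorax_local_m),  # type: ignore[arg-type]
                       "sacrum_pelvis", tuple(es.sacrum_local_m),  # type: ignore[arg-type]
                       es.strength_n, _spanned("thorax", "sacrum_pelvis")),
        MuscleFascicle("rectus_abdominis", "rectus_abdominis",
                       "thorax", tuple(ra.thorax_local_m),  # type: ignore[arg-type]
                       "sacrum_pelvis", tuple(ra.sacrum_local_m),  # type: ignore[arg-type]
                       ra.strength_n, _spanned("thorax", "sacrum_pelvis")),
    ]
    muscle_set = MuscleSet(
        fascicles=tuple(fascicles),
        abdominal_pressure_enabled=constants.abdominal_pressure.enabled,
    )
    validate_muscle_set(muscle_set)
    return muscle_set


def validate_muscle_set(muscle_set: MuscleSet) -> None:
    """Every lumbar joint needs extensor and flexor coverage to be balanceable."""
    for joint in LUMBAR_JOINTS:
        ext = any(joint in f.spanned_joints and f.group in EXTENSOR_GROUPS
                  for f in muscle_set.fascicles)
        flex = any(joint in f.spanned_joints and f.group in FLEXOR_GROUPS
                   for f in muscle_set.fascicles)
        if not ext:
            raise ConfigurationError(f"no extensor crosses joint {joint}")
        if not flex:
            raise ConfigurationError(f"no flexor crosses joint {joint}")


def muscle_geometry_json(muscle_set: MuscleSet, posture: PostureConfig,
                         **kwargs) -> str:
    """Resolved world-frame muscle geometry for one posture, as JSON."""
    out = []
    for f in muscle_set.fascicles:
        u, p_o, p_i = line_of_action(f, posture)
        out.append({
            "name": f.name,
            "group": f.group,
            "origin_world_m": [float(p_o[0]), float(p_o[1])],
            "insertion_world_m": [float(p_i[0]), float(p_i[1])],
            "unit_vector": [float(u[0]), float(u[1])],
            "strength_n": f.strength,
            "moment_arms_m": {j: moment_arm(f, j, posture) for j in LUMBAR_JOINTS},
        })
    return json.dumps(out, **kwargs)


__all__ = [
    "MuscleFascicle",
    "MuscleSet",
    "attachment_point",
    "line_of_action",
    "moment_arm",
    "build_muscle_set",
    "validate_muscle_set",
    "muscle_geometry_json",
    "EXTENSOR_GROUPS",
    "FLEXOR_GROUPS",
]
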