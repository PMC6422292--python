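"""Standing-posture construction from spinopelvic alignment parameters.

The skeleton is a planar (sagittal) chain: sacrum+pelvis, five lumbar
vertebrae, a lumped thorax+ribcage segment and the head. Coordinates are
x anterior, y up, in meters; angles are in degrees with flexion (anterior
rotation) positive, so the world inclination of the sacral endplate equals
the sacral slope SS and the fixed per-type lumbar inclinations are mostly
negative (extension).

Posture assembly follows the order SS, PI, RT, SVA:

1. the sacrum is rotated about the L5S1 joint so the endplate inclination
   equals SS (the unrotated segment stands at 30 degrees);
2. the hip centre is shifted horizontally, at fixed vertical drop below the
   endplate midpoint, until the pelvic incidence PI is reached;
3. the lumbar vertebrae L5..L1 take the fixed world inclinations of the
   requested Roussouly type;
4. the thorax is rotated about T12L1 until the C7 plumb line reproduces the
   requested SVA, with the head counter-rotated to stay level and the arms
   hanging vertically from the shoulder.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

from .config import (
    LUMBAR_LEVELS,
    RT_LABELS,
    SVA_CONDITIONS,
    ModelConstants,
    default_constants,
)
from .errors import GeometryError, ValidationError

# ---------------------------------------------------------------------------
# planar rotation helpers (flexion positive: +y rotates toward +x)

def rotation_matrix(angle_deg: float) -> np.ndarray:
    """World-from-local matrix for a segment inclined ``angle_deg`` in flexion."""
    a = math.radians(angle_deg)
    return np.array([[math.cos(a), math.sin(a)], [-math.sin(a), math.cos(a)]])


def up_vector(angle_deg: float) -> np.ndarray:
    """Cranial (local +y) direction of a segment at the given inclination."""
    a = math.radians(angle_deg)
    return np.array([math.sin(a), math.cos(a)])


def anterior_vector(angle_deg: float) -> np.ndarray:
    """Endplate-parallel anterior (local +x) direction at the given inclination."""
    a = math.radians(angle_deg)
    return np.array([math.cos(a), -math.sin(a)])


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class SpinopelvicParams:
    """One point of the (RT, SS, PI, SVA) design space.

    ``pt`` is derived from the pelvic identity PI = SS + PT.
    """

    rt: str
    ss: float
    pi: float
    sva: float  # cm, anterior positive
    sva_condition: str

    @property
    def pt(self) -> float:
        return self.pi - self.ss

    def validate(self, constants: ModelConstants | None = None,
                 strict: bool = True) -> None:
        constants = constants or default_constants()
        rt_def = constants.rt(self.rt)  # raises on unknown label
        if self.sva_condition not in SVA_CONDITIONS:
            raise ValidationError(
                f"unknown SVA condition {self.sva_condition!r}; "
                f"valid: {list(SVA_CONDITIONS)}"
            )
        if strict:
            lo, hi = rt_def.ss_range
            if not lo <= self.ss <= hi:
                raise ValidationError(
                    f"SS={self.ss} outside {self.rt} range [{lo}, {hi}]"
                )
            plo, phi = rt_def.pi_range
            if not plo <= self.pi <= phi:
                raise ValidationError(
                    f"PI={self.pi} outside {self.rt} range [{plo}, {phi}]"
                )
            expected = rt_def.sva_cm[self.sva_condition]
            if abs(self.sva - expected) > 1e-9:
                raise ValidationError(
                    f"SVA={self.sva} does not match the {self.rt}/"
                    f"{self.sva_condition} value {expected}"
                )


def make_params(rt: str, ss: float, pi: float, sva_condition: str,
                constants: ModelConstants | None = None,
                strict: bool = True) -> SpinopelvicParams:
    """Build a validated parameter point, filling SVA from the per-type table."""
    constants = constants or default_constants()
    rt_def = constants.rt(rt)
    if sva_condition not in rt_def.sva_cm:
        raise ValidationError(
            f"unknown SVA condition {sva_condition!r}; valid: {list(SVA_CONDITIONS)}"
        )
    params = SpinopelvicParams(
        rt=rt, ss=float(ss), pi=float(pi),
        sva=rt_def.sva_cm[sva_condition], sva_condition=sva_condition,
    )
    params.validate(constants, strict=strict)
    return params


@dataclass(frozen=True)
class LumbarOrientations:
    """Fixed world-frame inclinations of L1..L5 for one lumbar type."""

    angles_deg: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.angles_deg) != 5:
            raise ValidationError("exactly five lumbar inclinations required (L1..L5)")

    def angle(self, level: str) -> float:
        return self.angles_deg[LUMBAR_LEVELS.index(level)]


@dataclass(frozen=True)
class PostureConfig:
    """World-frame orientations, joint positions and COM positions."""

    params: SpinopelvicParams
    segment_orientations: Mapping[str, float]
    joint_positions: Mapping[str, np.ndarray]
    com_positions: Mapping[str, np.ndarray]
    ll_deg: float
    thoracic_rotation_deg: float
    sacrum_rotation_deg: float
    endplate_posterior_corner: np.ndarray = field(repr=False)
    endplate_anterior_corner: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "params": {
                "rt": self.params.rt, "ss": self.params.ss, "pi": self.params.pi,
                "sva": self.params.sva, "sva_condition": self.params.sva_condition,
                "pt": self.params.pt,
            },
            "segment_orientations_deg": dict(self.segment_orientations),
            "joint_positions_m": {k: list(map(float, v))
                                  for k, v in self.joint_positions.items()},
            "com_positions_m": {k: list(map(float, v))
                                for k, v in self.com_positions.items()},
            "ll_deg": self.ll_deg,
            "thoracic_rotation_deg": self.thoracic_rotation_deg,
            "sacrum_rotation_deg": self.sacrum_rotation_deg,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


# ---------------------------------------------------------------------------
# elementary alignment operations

def lumbar_orientations(rt: str,
                        constants: ModelConstants | None = None) -> LumbarOrientations:
    """Fixed L1..L5 world inclinations of the requested Roussouly type."""
    constants = constants or default_constants()
    return LumbarOrientations(constants.rt(rt).vertebral_rotation_deg)


def sacrum_rotation(ss_target: float, ss_default: float = 30.0,
                    strict: bool = True) -> float:
    """Anterior rotation applied to the sacrum-pelvis to reach ``ss_target``.

    The unrotated segment stands at ``ss_default`` (30 degrees), so a target
    of 40 degrees requires a 10-degree anterior rotation.
    """
    if strict and not 25.0 <= ss_target <= 55.0:
        raise ValidationError(
            f"SS={ss_target} outside the simulated union range [25, 55]"
        )
    return ss_target - ss_default


def hip_offset_for_pi(pi_target: float, ss: float, hip_drop_m: float) -> float:
    """Horizontal hip-centre position realizing the requested pelvic incidence.

    The hip stays at fixed vertical drop below the sacral endplate midpoint
    and only its horizontal coordinate moves. With PT-positive retroversion
    (PI = SS + PT) the hip sits anterior of the midpoint by
    ``hip_drop * tan(PI - SS)``; the offset is returned anterior-positive,
    relative to the plumb line through the midpoint.
    """
    if hip_drop_m <= 0:
        raise GeometryError("hip vertical drop must be positive")
    pt = pi_target - ss
    if abs(pt) >= 90.0:
        raise GeometryError(
            f"PI={pi_target} unreachable with SS={ss} at fixed drop "
            f"(|PI - SS| must be < 90 degrees)"
        )
    return hip_drop_m * math.tan(math.radians(pt))


def anterior_axis_angle_difference(rt: str, ss: float,
                                   constants: ModelConstants | None = None,
                                   strict: bool = True) -> float:
    """Angle between the anterior axes of L5 and S1 (degrees, nonnegative).

    The L5 anterior axis is parallel to its upper endplate (fixed per type);
    the S1 anterior axis is parallel to the sacral endplate at slope SS.
    """
    constants = constants or default_constants()
    rt_def = constants.rt(rt)
    if strict:
        lo, hi = rt_def.ss_range
        if not lo <= ss <= hi:
            raise ValidationError(f"SS={ss} outside {rt} range [{lo}, {hi}]")
    return abs(ss - rt_def.rotation("l5"))


def l5s1_wedge_angle(rt: str, ss: float,
                     constants: ModelConstants | None = None,
                     strict: bool = True) -> float:
    """Signed L5-to-S1 wedge angle (flexion positive; negative = extension)."""
    constants = constants or default_constants()
    rt_def = constants.rt(rt)
    if strict:
        lo, hi = rt_def.ss_range
        if not lo <= ss <= hi:
            raise ValidationError(f"SS={ss} outside {rt} range [{lo}, {hi}]")
    return rt_def.rotation("l5") - ss


def compute_ll(t12_inclination: float, ss: float) -> float:
    """Lumbar lordosis between the T12 and S1 endplates (lordosis positive)."""
    return ss - t12_inclination


# ---------------------------------------------------------------------------
# posture assembly

def _lumbar_joints(rt: str, constants: ModelConstants) -> dict[str, np.ndarray]:
    """Joint centres of the lumbar chain, L5S1 at the origin."""
    heights = constants.anthropometry.vertebra_heights_m
    rots = lumbar_orientations(rt, constants)
    joints = {"l5s1": np.zeros(2)}
    names_up = {"l5": "l4l5", "l4": "l3l4", "l3": "l2l3", "l2": "l1l2", "l1": "t12l1"}
    below = "l5s1"
    for level in ("l5", "l4", "l3", "l2", "l1"):
        sup = joints[below] + heights[level] * up_vector(rots.angle(level))
        joints[names_up[level]] = sup
        below = names_up[level]
    return joints


def _c7_x(t12l1: np.ndarray, thorax_rotation_deg: float,
          constants: ModelConstants) -> float:
    """Horizontal C7 position for a given thoracic rotation."""
    return float(
        t12l1[0]
        + constants.anthropometry.thorax_length_m
        * up_vector(thorax_rotation_deg)[0]
    )


def thoracic_rotation_for_sva(target_sva_cm: float, chain_template: PostureConfig,
                              constants: ModelConstants | None = None) -> float:
    """Thoracic (T12L1) rotation placing the C7 plumb line at the target SVA.

    ``chain_template`` is a posture built with zero thoracic rotation; only
    its T12L1 joint and sacral-corner positions are consulted. The C7
    horizontal offset is continuous and strictly monotone in the rotation
    over the +-45 degree bracket, so a bracketed root find converges to the
    1e-6 cm tolerance.
    """
    constants = constants or default_constants()
    t12l1 = chain_template.joint_positions["t12l1"]
    corner_x = float(chain_template.endplate_posterior_corner[0])
    target_x = corner_x + target_sva_cm / 100.0
    bracket = constants.posture.thoracic_bracket_deg

    def offset(t: float) -> float:
        return _c7_x(t12l1, t, constants) - target_x

    lo, hi = offset(-bracket), offset(bracket)
    if lo > 0 or hi < 0:
        lo_sva = (corner_x * -100.0 + _c7_x(t12l1, -bracket, constants) * 100.0)
        hi_sva = (corner_x * -100.0 + _c7_x(t12l1, bracket, constants) * 100.0)
        raise GeometryError(
            f"SVA={target_sva_cm} cm unreachable within +-{bracket} degrees of "
            f"thoracic rotation; achievable interval [{lo_sva:.2f}, {hi_sva:.2f}] cm"
        )
    return float(brentq(offset, -bracket, bracket, xtol=1e-10, rtol=8.9e-16))


def _assemble(params: SpinopelvicParams, thorax_rotation: float,
              constants: ModelConstants) -> PostureConfig:
    anth = constants.anthropometry
    post = constants.posture
    ss = params.ss

    mid = np.zeros(2)
    half_w = post.sacral_endplate_width_m / 2.0
    ant = anterior_vector(ss)
    post_corner = mid - half_w * ant
    ant_corner = mid + half_w * ant

    joints = _lumbar_joints(params.rt, constants)
    hip_x = hip_offset_for_pi(params.pi, ss, post.hip_drop_m)
    joints["hip"] = np.array([hip_x, -post.hip_drop_m])

    rots = lumbar_orientations(params.rt, constants)
    orientations = {"sacrum_pelvis": ss}
    coms: dict[str, np.ndarray] = {}
    inferior = {"l5": "l5s1", "l4": "l4l5", "l3": "l3l4", "l2": "l2l3", "l1": "l1l2"}
    superior = {"l5": "l4l5", "l4": "l3l4", "l3": "l2l3", "l2": "l1l2", "l1": "t12l1"}
    for level in ("l5", "l4", "l3", "l2", "l1"):
        a = rots.angle(level)
        orientations[level] = a
        centroid = 0.5 * (joints[inferior[level]] + joints[superior[level]])
        coms[level] = centroid + anth.com_anterior_offsets_m[level] * anterior_vector(a)

    thorax_orient = thorax_rotation  # default thorax inclination is vertical (0)
    orientations["thorax"] = thorax_orient
    orientations["head"] = 0.0  # neck counter-rotation keeps the head level
    rot_t = rotation_matrix(thorax_orient)
    t12l1 = joints["t12l1"]
    c7 = t12l1 + anth.thorax_length_m * up_vector(thorax_orient)
    joints["c7"] = c7
    coms["thorax"] = t12l1 + rot_t @ np.asarray(anth.thorax_com_local_m)
    shoulder = t12l1 + rot_t @ np.asarray(anth.shoulder_local_m)
    coms["arms"] = shoulder + np.array([0.0, -anth.arm_com_drop_m])
    coms["head"] = c7 + np.asarray(anth.head_com_offset_m)
    coms["sacrum_pelvis"] = mid + np.asarray(anth.pelvis_com_offset_m)

    t12_incl = thorax_orient + post.t12_offset_deg
    return PostureConfig(
        params=params,
        segment_orientations=orientations,
        joint_positions=joints,
        com_positions=coms,
        ll_deg=compute_ll(t12_incl, ss),
        thoracic_rotation_deg=thorax_rotation,
        sacrum_rotation_deg=sacrum_rotation(ss, post.default_ss_deg, strict=False),
        endplate_posterior_corner=post_corner,
        endplate_anterior_corner=ant_corner,
    )


def build_posture(params: SpinopelvicParams,
                  constants: ModelConstants | None = None,
                  strict: bool = True) -> PostureConfig:
    """Construct the full standing posture for one parameter point."""
    constants = constants or default_constants()
    params.validate(constants, strict=strict)
    template = _assemble(params, 0.0, constants)
    t = thoracic_rotation_for_sva(params.sva, template, constants)
    return _assemble(params, t, constants)


# ---------------------------------------------------------------------------
# forward measurement (independent of the construction path; used as oracles)

def measure_ss(posture: PostureConfig) -> float:
    """Sacral slope re-measured from the endplate corner positions."""
    e = posture.endplate_anterior_corner - posture.endplate_posterior_corner
    return math.degrees(math.atan2(-e[1], e[0]))


def measure_pi(posture: PostureConfig) -> float:
    """Pelvic incidence re-measured from the hip and endplate geometry."""
    mid = 0.5 * (posture.endplate_anterior_corner + posture.endplate_posterior_corner)
    ss = measure_ss(posture)
    a = math.radians(ss)
    normal = np.array([-math.sin(a), -math.cos(a)])  # caudal endplate normal
    u = posture.joint_positions["hip"] - mid
    nu = float(np.linalg.norm(u))
    if nu == 0:
        raise GeometryError("hip coincides with the endplate midpoint")
    u = u / nu
    return math.degrees(math.acos(max(-1.0, min(1.0, float(normal @ u)))))


def measure_sva(posture: PostureConfig) -> float:
    """SVA re-measured as the C7-to-sacral-corner horizontal offset, in cm."""
    return float(
        (posture.joint_positions["c7"][0] - posture.endplate_posterior_corner[0])
        * 100.0
    )


# ---------------------------------------------------------------------------
# sweep enumeration

def enumerate_sweep(constants: ModelConstants | None = None,
                    rts: tuple[str, ...] | None = None,
                    ss_values: tuple[int, ...] | None = None,
                    pi_values: tuple[int, ...] | None = None,
                    sva_conditions: tuple[str, ...] | None = None,
                    ) -> list[SpinopelvicParams]:
    """Enumerate the simulated design grid in (RT, SS, PI, SVA) order.

    Per type: SS and PI run over their closed ranges in 1-degree increments
    and all three SVA conditions are visited, giving 4 x 11 x 21 x 3 = 2772
    configurations for the unfiltered grid.
    """
    constants = constants or default_constants()
    out: list[SpinopelvicParams] = []
    for rt in (rts or RT_LABELS):
        rt_def = constants.rt(rt)
        ss_grid = range(rt_def.ss_range[0], rt_def.ss_range[1] + 1)
        pi_grid = range(rt_def.pi_range[0], rt_def.pi_range[1] + 1)
        for ss in ss_grid:
            if ss_values is not None and ss not in ss_values:
                continue
            for pi in pi_grid:
                if pi_values is not None and pi not in pi_values:
                    continue
                for cond in (sva_conditions or SVA_CONDITIONS):
                    out.append(make_params(rt, ss, pi, cond, constants))
    return out


__all__ = [
    "SpinopelvicParams",
    "LumbarOrientations",
    "PostureConfig",
    "make_params",
    "lumbar_orientations",
    "sacrum_rotation",
    "hip_offset_for_pi",
    "anterior_axis_angle_difference",
    "l5s1_wedge_angle",
    "compute_ll",
    "thoracic_rotation_for_sva",
    "build_posture",
    "measure_ss",
    "measure_pi",
    "measure_sva",
    "enumerate_sweep",
    "rotation_matrix",
    "up_vector",
    "anterior_vector",
]
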