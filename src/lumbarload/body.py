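"""Weighted rigid-segment chain and free-body gravity queries.

The chain carries the whole-body mass partition of the default 75 kg subject.
Arms enter as a lumped point mass hanging vertically from the shoulder and
the head+neck as a separate level-kept mass; the pelvis+legs mass sits below
the L5S1 joint and never enters a superincumbent free body.

Sign conventions: forces are world vectors (x anterior, y up, N); moments are
scalar and flexion-positive, so gravity acting anterior of a joint produces a
positive moment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .config import ModelConstants, SEGMENT_ORDER, default_constants
from .errors import ConfigurationError, ValidationError
from .posture import PostureConfig

#: chain rank of each segment (caudal -> cranial); head/arms ride on the thorax
_SEGMENT_RANK = {name: i for i, name in enumerate(
    ("sacrum_pelvis", "l5", "l4", "l3", "l2", "l1", "thorax")
)}
_SEGMENT_RANK["head"] = _SEGMENT_RANK["thorax"]
_SEGMENT_RANK["arms"] = _SEGMENT_RANK["thorax"]

#: joints usable for free-body queries, mapped to the rank of the segment
#: immediately below them
JOINT_BELOW_RANK = {
    "l5s1": 0, "l4l5": 1, "l3l4": 2, "l2l3": 3, "l1l2": 4, "t12l1": 5,
}


@dataclass(frozen=True)
class Segment:
    name: str
    mass: float
    com: np.ndarray
    inferior_joint: np.ndarray | None = None
    superior_joint: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise ConfigurationError(f"segment {self.name}: negative mass")
        if not np.all(np.isfinite(self.com)):
            raise ConfigurationError(f"segment {self.name}: non-finite COM")


@dataclass(frozen=True)
class BodyChain:
    """Rigid segments of one posture, ordered caudal to cranial."""

    posture: PostureConfig
    segments: tuple[Segment, ...]
    gravity: float
    total_suprapelvic_mass: float

    def segment(self, name: str) -> Segment:
        for seg in self.segments:
            if seg.name == name:
                return seg
        raise ValidationError(f"unknown segment {name!r}")

    def segments_above(self, level: str) -> tuple[Segment, ...]:
        if level not in JOINT_BELOW_RANK:
            raise ValidationError(
                f"unknown joint level {level!r}; valid: {sorted(JOINT_BELOW_RANK)}"
            )
        rank = JOINT_BELOW_RANK[level]
        return tuple(s for s in self.segments if _SEGMENT_RANK[s.name] > rank)


def build_chain(posture: PostureConfig,
                constants: ModelConstants | None = None) -> BodyChain:
    """Assemble the weighted chain for a posture.

    Raises ``ConfigurationError`` if the configured mass fractions do not sum
    to 1 within 1e-9 (the partition must conserve the total body mass).
    """
    constants = constants or default_constants()
    anth = constants.anthropometry
    fractions = anth.mass_fractions
    missing = set(SEGMENT_ORDER) - set(fractions)
    if missing:
        raise ConfigurationError(f"mass fractions missing segments: {sorted(missing)}")
    total_frac = sum(fractions.values())
    if abs(total_frac - 1.0) > 1e-9:
        raise ConfigurationError(
            f"mass fractions sum to {total_frac!r}, expected 1 within 1e-9"
        )

    joints = posture.joint_positions
    inferior = {"l5": "l5s1", "l4": "l4l5", "l3": "l3l4", "l2": "l2l3",
                "l1": "l1l2", "thorax": "t12l1"}
    superior = {"l5": "l4l5", "l4": "l3l4", "l3": "l2l3", "l2": "l1l2",
                "l1": "t12l1", "thorax": "c7"}
    segments = []
    for name in SEGMENT_ORDER:
        segments.append(Segment(
            name=name,
            mass=fractions[name] * anth.mass_kg,
            com=np.asarray(posture.com_positions[name], dtype=float),
            inferior_joint=joints.get(inferior.get(name, "")),
            superior_joint=joints.get(superior.get(name, "")),
        ))
    chain = BodyChain(
        posture=posture,
        segments=tuple(segments),
        gravity=anth.gravity_m_s2,
        total_suprapelvic_mass=sum(
            s.mass for s in segments if _SEGMENT_RANK[s.name] > 0
        ),
    )
    return chain


def superincumbent_load(chain: BodyChain, level: str) -> tuple[np.ndarray, float]:
    """Net gravity force and flexion-positive moment above a joint.

    Returns the vector sum of the segment weights strictly above ``level``
    and their net moment about the joint centre (N, N*m).
    """
    above = chain.segments_above(level)  # validates the level label
    joint = chain.posture.joint_positions[level]
    force = np.zeros(2)
    moment = 0.0
    for seg in above:
        w = seg.mass * chain.gravity
        force += np.array([0.0, -w])
        moment += w * (seg.com[0] - joint[0])  # flexion positive
    return force, moment


__all__ = [
    "Segment",
    "BodyChain",
    "build_chain",
    "superincumbent_load",
    "JOINT_BELOW_RANK",
]
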