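"""Model constants: loading, validation, and typed access.

All tunable quantities of the model live in one flat TOML file
(``defaults.toml``, packaged with the library). A user file with the same
layout can override any subset of keys; the result is frozen into immutable
dataclasses so that a constants object can be shared between postures and
perturbed copies can be derived without aliasing surprises.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

from .errors import ConfigurationError

LUMBAR_LEVELS = ("l1", "l2", "l3", "l4", "l5")
RT_LABELS = ("RT1", "RT2", "RT3", "RT4")
SVA_CONDITIONS = ("back", "med", "front")

#: segments ordered caudal -> cranial; "arms" is the lumped hanging-arm mass
SEGMENT_ORDER = ("sacrum_pelvis", "l5", "l4", "l3", "l2", "l1", "thorax", "head", "arms")

#: lumbar joints ordered cranial -> caudal (the recruitment constraint set)
LUMBAR_JOINTS = ("l1l2", "l2l3", "l3l4", "l4l5", "l5s1")


@dataclass(frozen=True)
class RTDefinition:
    """Table-row describing one Roussouly lumbar type."""

    name: str
    ss_range: tuple[int, int]
    pi_range: tuple[int, int]
    sva_cm: Mapping[str, float]
    vertebral_rotation_deg: tuple[float, float, float, float, float]  # L1..L5

    def rotation(self, level: str) -> float:
        return self.vertebral_rotation_deg[LUMBAR_LEVELS.index(level)]


@dataclass(frozen=True)
class PostureSettings:
    default_ss_deg: float
    sacral_endplate_width_m: float
    hip_drop_m: float
    t12_offset_deg: float
    thoracic_bracket_deg: float


@dataclass(frozen=True)
class Anthropometry:
    stature_m: float
    mass_kg: float
    gravity_m_s2: float
    thorax_length_m: float
    thorax_com_local_m: tuple[float, float]
    shoulder_local_m: tuple[float, float]
    head_com_offset_m: tuple[float, float]
    arm_com_drop_m: float
    pelvis_com_offset_m: tuple[float, float]
    vertebra_heights_m: Mapping[str, float]
    com_anterior_offsets_m: Mapping[str, float]
    mass_fractions: Mapping[str, float]


@dataclass(frozen=True)
class MuscleGroupSpec:
    strength_n: float
    posterior_offset_m: float | None = None
    thorax_local_m: tuple[float, float] | None = None
    sacrum_local_m: tuple[float, float] | None = None


@dataclass(frozen=True)
class AbdominalPressureSpec:
    enabled: bool
    pressure_kpa: float
    diaphragm_area_m2: float
    moment_arm_m: float

    @property
    def extension_moment_nm(self) -> float:
        """Extension moment contributed at each lumbar joint when enabled."""
        if not self.enabled:
            return 0.0
        return self.pressure_kpa * 1e3 * self.diaphragm_area_m2 * self.moment_arm_m


@dataclass(frozen=True)
class SolverSettings:
    criterion_power: float
    residual_tol_nm: float


@dataclass(frozen=True)
class ModelConstants:
    posture: PostureSettings
    anthropometry: Anthropometry
    solver: SolverSettings
    multifidus: MuscleGroupSpec
    erector_spinae: MuscleGroupSpec
    rectus_abdominis: MuscleGroupSpec
    abdominal_pressure: AbdominalPressureSpec
    table1: Mapping[str, RTDefinition] = field(repr=False)

    def rt(self, label: str) -> RTDefinition:
        from .errors import ValidationError

        if label not in self.table1:
            raise ValidationError(
                f"unknown Roussouly type {label!r}; valid labels: {sorted(self.table1)}"
            )
        return self.table1[label]


def _pair(value: Any) -> tuple[float, float]:
    x, y = value
    return (float(x), float(y))


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for key, val in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(val, Mapping):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = val
    return out


def _raw_defaults() -> dict:
    text = resources.files("lumbarload").joinpath("defaults.toml").read_text()
    return tomllib.loads(text)


def _build(raw: Mapping[str, Any]) -> ModelConstants:
    try:
        p = raw["posture"]
        a = raw["anthropometry"]
        s = raw["solver"]
        m = raw["muscles"]
        t1 = raw["table1"]
    except KeyError as exc:  # pragma: no cover - malformed user file
        raise ConfigurationError(f"missing constants section: {exc}") from exc

    table1 = {}
    for label, row in t1.items():
        rot = tuple(float(v) for v in row["vertebral_rotation_deg"])
        if len(rot) != 5:
            raise ConfigurationError(
                f"{label}: expected 5 vertebral rotations (L1..L5), got {len(rot)}"
            )
        lo, hi = row["ss_range_deg"]
        plo, phi = row["pi_range_deg"]
        table1[label] = RTDefinition(
            name=label,
            ss_range=(int(lo), int(hi)),
            pi_range=(int(plo), int(phi)),
            sva_cm={k: float(v) for k, v in row["sva_cm"].items()},
            vertebral_rotation_deg=rot,  # type: ignore[arg-type]
        )

    return ModelConstants(
        posture=PostureSettings(
            default_ss_deg=float(p["default_ss_deg"]),
            sacral_endplate_width_m=float(p["sacral_endplate_width_m"]),
            hip_drop_m=float(p["hip_drop_m"]),
            t12_offset_deg=float(p["t12_offset_deg"]),
            thoracic_bracket_deg=float(p["thoracic_bracket_deg"]),
        ),
        anthropometry=Anthropometry(
            stature_m=float(a["stature_m"]),
            mass_kg=float(a["mass_kg"]),
            gravity_m_s2=float(a["gravity_m_s2"]),
            thorax_length_m=float(a["thorax_length_m"]),
            thorax_com_local_m=_pair(a["thorax_com_local_m"]),
            shoulder_local_m=_pair(a["shoulder_local_m"]),
            head_com_offset_m=_pair(a["head_com_offset_m"]),
            arm_com_drop_m=float(a["arm_com_drop_m"]),
            pelvis_com_offset_m=_pair(a["pelvis_com_offset_m"]),
            vertebra_heights_m={k: float(v) for k, v in a["vertebra_heights_m"].items()},
            com_anterior_offsets_m={
                k: float(v) for k, v in a["com_anterior_offsets_m"].items()
            },
            mass_fractions={k: float(v) for k, v in a["mass_fractions"].items()},
        ),
        solver=SolverSettings(
            criterion_power=float(s["criterion_power"]),
            residual_tol_nm=float(s["residual_tol_nm"]),
        ),
        multifidus=MuscleGroupSpec(
            strength_n=float(m["multifidus"]["strength_n"]),
            posterior_offset_m=float(m["multifidus"]["posterior_offset_m"]),
            sacrum_local_m=_pair(m["multifidus"]["sacrum_local_m"]),
        ),
        erector_spinae=MuscleGroupSpec(
            strength_n=float(m["erector_spinae"]["strength_n"]),
            thorax_local_m=_pair(m["erector_spinae"]["thorax_local_m"]),
            sacrum_local_m=_pair(m["erector_spinae"]["sacrum_local_m"]),
        ),
        rectus_abdominis=MuscleGroupSpec(
            strength_n=float(m["rectus_abdominis"]["strength_n"]),
            thorax_local_m=_pair(m["rectus_abdominis"]["thorax_local_m"]),
            sacrum_local_m=_pair(m["rectus_abdominis"]["sacrum_local_m"]),
        ),
        abdominal_pressure=AbdominalPressureSpec(
            enabled=bool(m["abdominal_pressure"]["enabled"]),
            pressure_kpa=float(m["abdominal_pressure"]["pressure_kpa"]),
            diaphragm_area_m2=float(m["abdominal_pressure"]["diaphragm_area_m2"]),
            moment_arm_m=float(m["abdominal_pressure"]["moment_arm_m"]),
        ),
        table1=table1,
    )


_DEFAULTS: ModelConstants | None = None


def default_constants() -> ModelConstants:
    """The packaged default constants (cached; immutable)."""
    global _DEFAULTS
    if _DEFAULTS is None:
        _DEFAULTS = _build(_raw_defaults())
    return _DEFAULTS


def load_constants(path: str | Path | None = None,
                   overrides: Mapping[str, Any] | None = None) -> ModelConstants:
    """Load constants, optionally merging a user TOML file and/or a dict.

    Parameters
    ----------
    path
        TOML file with the same layout as ``defaults.toml``; keys present
        override the defaults, absent keys keep their default values.
    overrides
        Nested mapping merged on top of everything else.
    """
    raw = _raw_defaults()
    if path is not None:
        with open(path, "rb") as fh:
            raw = _deep_merge(raw, tomllib.load(fh))
    if overrides:
        raw = _deep_merge(raw, overrides)
    return _build(raw)


__all__ = [
    "LUMBAR_LEVELS",
    "RT_LABELS",
    "SVA_CONDITIONS",
    "SEGMENT_ORDER",
    "LUMBAR_JOINTS",
    "RTDefinition",
    "PostureSettings",
    "Anthropometry",
    "MuscleGroupSpec",
    "AbdominalPressureSpec",
    "SolverSettings",
    "ModelConstants",
    "default_constants",
    "load_constants",
]
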