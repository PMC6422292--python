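"""Randomized fixtures: parameter samples and perturbed anthropometries.

Everything here is test plumbing rather than science: it draws valid
spinopelvic parameter points on the same integer-degree grid the sweep uses,
and produces jittered copies of the model constants for robustness checks.
A single explicitly seeded generator (numpy ``default_rng``) drives all
randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .config import (
    ModelConstants,
    MuscleGroupSpec,
    RT_LABELS,
    SVA_CONDITIONS,
    default_constants,
)
from .errors import ValidationError
from .posture import SpinopelvicParams, make_params


@dataclass(frozen=True)
class SamplerConfig:
    seed: int
    n: int = 1
    rt_weights: Mapping[str, float] | None = None
    jitter: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.jitter <= 0.2:
            raise ValidationError("jitter must lie in [0, 0.2]")
        if self.rt_weights is not None:
            w = np.array([self.rt_weights.get(rt, 0.0) for rt in RT_LABELS])
            if np.any(w < 0) or not np.any(w > 0):
                raise ValidationError(
                    "rt_weights must be nonnegative and not all zero"
                )


def _weights(config: SamplerConfig) -> np.ndarray:
    if config.rt_weights is None:
        return np.full(len(RT_LABELS), 1.0 / len(RT_LABELS))
    w = np.array([config.rt_weights.get(rt, 0.0) for rt in RT_LABELS], dtype=float)
    return w / w.sum()


def sample_params(config: SamplerConfig,
                  constants: ModelConstants | None = None,
                  ) -> list[SpinopelvicParams]:
    """Draw ``n`` valid parameter points, reproducibly from the seed."""
    constants = constants or default_constants()
    rng = np.random.default_rng(config.seed)
    weights = _weights(config)
    out = []
    for _ in range(config.n):
        rt = RT_LABELS[int(rng.choice(len(RT_LABELS), p=weights))]
        rt_def = constants.rt(rt)
        ss = int(rng.integers(rt_def.ss_range[0], rt_def.ss_range[1] + 1))
        pi = int(rng.integers(rt_def.pi_range[0], rt_def.pi_range[1] + 1))
        cond = SVA_CONDITIONS[int(rng.integers(0, len(SVA_CONDITIONS)))]
        out.append(make_params(rt, ss, pi, cond, constants))
    return out


def _scale(rng: np.random.Generator, jitter: float) -> float:
    return float(rng.uniform(1.0 - jitter, 1.0 + jitter))


def _scale_pair(pair, rng, jitter) -> tuple[float, float]:
    return (pair[0] * _scale(rng, jitter), pair[1] * _scale(rng, jitter))


def perturb_anthropometry(constants: ModelConstants,
                          config: SamplerConfig) -> ModelConstants:
    """Multiply lengths, masses and attachment offsets by independent factors
    in [1 - jitter, 1 + jitter]; mass fractions are renormalized to sum 1."""
    if config.jitter == 0.0:
        return constants
    rng = np.random.default_rng(config.seed)
    j = config.jitter
    anth = constants.anthropometry

    fractions = {k: v * _scale(rng, j) for k, v in anth.mass_fractions.items()}
    total = sum(fractions.values())
    fractions = {k: v / total for k, v in fractions.items()}

    new_anth = replace(
        anth,
        mass_kg=anth.mass_kg * _scale(rng, j),
        thorax_length_m=anth.thorax_length_m * _scale(rng, j),
        thorax_com_local_m=_scale_pair(anth.thorax_com_local_m, rng, j),
        shoulder_local_m=_scale_pair(anth.shoulder_local_m, rng, j),
        head_com_offset_m=_scale_pair(anth.head_com_offset_m, rng, j),
        arm_com_drop_m=anth.arm_com_drop_m * _scale(rng, j),
        pelvis_com_offset_m=_scale_pair(anth.pelvis_com_offset_m, rng, j),
        vertebra_heights_m={k: v * _scale(rng, j)
                            for k, v in anth.vertebra_heights_m.items()},
        com_anterior_offsets_m={k: v * _scale(rng, j)
                                for k, v in anth.com_anterior_offsets_m.items()},
        mass_fractions=fractions,
    )

    def perturb_group(spec: MuscleGroupSpec) -> MuscleGroupSpec:
        return MuscleGroupSpec(
            strength_n=spec.strength_n * _scale(rng, j),
            posterior_offset_m=(None if spec.posterior_offset_m is None
                                else spec.posterior_offset_m * _scale(rng, j)),
            thorax_local_m=(None if spec.thorax_local_m is None
                            else _scale_pair(spec.thorax_local_m, rng, j)),
            sacrum_local_m=(None if spec.sacrum_local_m is None
                            else _scale_pair(spec.sacrum_local_m, rng, j)),
        )

    new_posture = replace(
        constants.posture,
        sacral_endplate_width_m=constants.posture.sacral_endplate_width_m
        * _scale(rng, j),
        hip_drop_m=constants.posture.hip_drop_m * _scale(rng, j),
    )
    return replace(
        constants,
        posture=new_posture,
        anthropometry=new_anth,
        multifidus=perturb_group(constants.multifidus),
        erector_spinae=perturb_group(constants.erector_spinae),
        rectus_abdominis=perturb_group(constants.rectus_abdominis),
    )


__all__ = ["SamplerConfig", "sample_params", "perturb_anthropometry"]
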