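"""Static muscle recruitment and intersegmental force extraction.

For one posture the recruitment problem is

    minimize   sum_i (f_i / S_i)^p
    subject to sum_i arm[j, i] * f_i = M_g[j]   for every lumbar joint j
               f_i >= 0

where ``arm`` are extension-positive moment arms, ``M_g`` the flexion-positive
net gravity moments of the superincumbent body, ``S_i`` the actuator
strengths and p the polynomial criterion power (3 by default). The objective
is strictly convex in activations for p > 1, so the minimizer is unique.

Moment balance is enforced at the five lumbar joints L1L2..L5S1; the planar
hinge joints carry all translational load, so the joint reactions follow
from free-body force balance once the tensions are known.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import linprog, minimize

from .body import BodyChain, build_chain, superincumbent_load
from .config import LUMBAR_JOINTS, ModelConstants, default_constants
from .errors import (
    InfeasibleProblemError,
    SolverConvergenceError,
    ValidationError,
)
from .muscles import MuscleSet, build_muscle_set, line_of_action, moment_arm
from .posture import PostureConfig, SpinopelvicParams, build_posture
from .projection import decompose, l4l5_axes, l5s1_axes

#: rank of the segment below each joint, for crossing tests
_JOINT_RANK = {"l5s1": 0, "l4l5": 1, "l3l4": 2, "l2l3": 3, "l1l2": 4, "t12l1": 5}
_SEG_RANK = {"sacrum_pelvis": 0, "l5": 1, "l4": 2, "l3": 3, "l2": 4, "l1": 5,
             "thorax": 6}


@dataclass(frozen=True)
class RecruitmentProblem:
    joints: tuple[str, ...]
    gravity_moments: np.ndarray           # N*m, flexion positive
    moment_arm_matrix: np.ndarray         # (n_joints, n_fascicles), m
    strengths: np.ndarray                 # N
    fascicle_names: tuple[str, ...]
    criterion_power: float = 3.0

    def __post_init__(self) -> None:
        nj, nf = self.moment_arm_matrix.shape
        if nj != len(self.joints) or nf != len(self.strengths) \
                or nf != len(self.fascicle_names) \
                or len(self.gravity_moments) != nj:
            raise ValidationError("inconsistent recruitment problem dimensions")
        if self.criterion_power <= 1:
            raise ValidationError("criterion power must exceed 1")


@dataclass(frozen=True)
class RecruitmentSolution:
    muscle_forces: np.ndarray
    activations: np.ndarray
    objective_value: float
    equilibrium_residual: float
    fascicle_names: tuple[str, ...]

    def force(self, name: str) -> float:
        return float(self.muscle_forces[self.fascicle_names.index(name)])


@dataclass(frozen=True)
class LoadResult:
    """Per-configuration outputs in the layout of the result tables."""

    params: SpinopelvicParams
    f_l4l5: np.ndarray
    f_l5s1: np.ndarray
    fl4l5c: float
    fl4l5s: float
    fl5s1c: float
    fl5s1s: float
    f_mf: float
    f_es: float
    f_ra: float
    ll_deg: float
    equilibrium_residual: float = 0.0

    @property
    def f_ls(self) -> float:
        """Longissimus-spinae alias of the erector-spinae group force."""
        return self.f_es

    def to_row(self) -> dict:
        p = self.params
        return {
            "rt": p.rt, "ss": p.ss, "pi": p.pi,
            "sva_condition": p.sva_condition, "sva_cm": p.sva, "pt": p.pt,
            "fl4l5c": self.fl4l5c, "fl4l5s": self.fl4l5s,
            "fl5s1c": self.fl5s1c, "fl5s1s": self.fl5s1s,
            "f_mf": self.f_mf, "f_es": self.f_es, "f_ra": self.f_ra,
            "ll_deg": self.ll_deg,
            "equilibrium_residual": self.equilibrium_residual,
            "f_l4l5_x": float(self.f_l4l5[0]), "f_l4l5_y": float(self.f_l4l5[1]),
            "f_l5s1_x": float(self.f_l5s1[0]), "f_l5s1_y": float(self.f_l5s1[1]),
        }


def assemble_problem(chain: BodyChain, muscles: MuscleSet,
                     posture: PostureConfig,
                     constants: ModelConstants | None = None) -> RecruitmentProblem:
    """Build the per-joint moment-balance system for one posture."""
    constants = constants or default_constants()
    joints = LUMBAR_JOINTS
    moments = np.array([superincumbent_load(chain, j)[1] for j in joints])
    if muscles.abdominal_pressure_enabled:
        # intra-abdominal pressure assists the extensors at every lumbar joint
        moments = moments - constants.abdominal_pressure.extension_moment_nm
    arms = np.array([[moment_arm(f, j, posture) for f in muscles.fascicles]
                     for j in joints])
    for k, j in enumerate(joints):
        row = arms[k]
        m = moments[k]
        if m > 0 and not np.any(row > 0):
            raise InfeasibleProblemError(
                f"joint {j}: flexion moment {m:.3f} N*m but no extensor arm"
            )
        if m < 0 and not np.any(row < 0):
            raise InfeasibleProblemError(
                f"joint {j}: extension moment {m:.3f} N*m but no flexor arm"
            )
    return RecruitmentProblem(
        joints=joints,
        gravity_moments=moments,
        moment_arm_matrix=arms,
        strengths=np.array([f.strength for f in muscles.fascicles]),
        fascicle_names=tuple(f.name for f in muscles.fascicles),
        criterion_power=constants.solver.criterion_power,
    )


def _feasible_start(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    res = linprog(c=np.ones(A.shape[1]), A_eq=A, b_eq=b,
                  bounds=[(0, None)] * A.shape[1], method="highs")
    if not res.success:
        raise InfeasibleProblemError(
            f"no nonnegative muscle forces balance the joint moments: {res.message}"
        )
    return np.maximum(res.x, 0.0)


def _repair(A: np.ndarray, b: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Least-norm projection back onto the equality constraints."""
    for _ in range(8):
        r = b - A @ f
        if float(np.max(np.abs(r))) < 1e-10:
            break
        f = f + np.linalg.pinv(A) @ r
        f = np.where(f < 0, np.where(f > -1e-9, 0.0, f), f)
    return f


def solve_recruitment(problem: RecruitmentProblem,
                      residual_tol: float = 1e-6) -> RecruitmentSolution:
    """Minimize the polynomial activation criterion under moment balance."""
    A = problem.moment_arm_matrix
    b = problem.gravity_moments
    S = problem.strengths
    p = problem.criterion_power

    f0 = _feasible_start(A, b)
    AS = A * S  # constraints in activation variables
    x0 = f0 / S

    def objective(x: np.ndarray) -> float:
        return float(np.sum(np.maximum(x, 0.0) ** p))

    def gradient(x: np.ndarray) -> np.ndarray:
        return p * np.maximum(x, 0.0) ** (p - 1.0)

    res = minimize(
        objective, x0, jac=gradient, method="SLSQP",
        bounds=[(0.0, None)] * len(S),
        constraints=[{"type": "eq", "fun": lambda x: AS @ x - b,
                      "jac": lambda x: AS}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    x = np.maximum(res.x, 0.0)
    f = _repair(A, b, x * S)
    f = np.maximum(f, 0.0)
    residual = float(np.max(np.abs(A @ f - b))) if len(b) else 0.0
    if residual > residual_tol:
        raise SolverConvergenceError(
            f"equilibrium residual {residual:.3e} N*m exceeds {residual_tol:.1e} "
            f"(solver status: {res.status}, {res.message})"
        )
    activations = f / S
    if np.any(activations > 1.0 + 1e-9):
        worst = problem.fascicle_names[int(np.argmax(activations))]
        warnings.warn(
            f"activation above 1 for {worst} "
            f"(max {float(np.max(activations)):.3f}); forces kept uncapped",
            RuntimeWarning, stacklevel=2,
        )
    return RecruitmentSolution(
        muscle_forces=f,
        activations=activations,
        objective_value=float(np.sum((f / S) ** p)),
        equilibrium_residual=residual,
        fascicle_names=problem.fascicle_names,
    )


def _crossing(fascicle, level: str) -> bool:
    rank = _JOINT_RANK[level]
    lo = _SEG_RANK[fascicle.insertion_segment]
    hi = _SEG_RANK[fascicle.origin_segment]
    return lo <= rank < hi


def intersegmental_force(chain: BodyChain, muscles: MuscleSet,
                         solution: RecruitmentSolution, level: str) -> np.ndarray:
    """World force transmitted to the element below ``level``.

    Free-body balance of the superincumbent body: the transmitted force is
    the sum of the gravity loads above the level plus the tensions of the
    crossing fascicles pulling the upper body toward their caudal
    attachments. In standing this resultant points downward (compressive).
    """
    if level not in _JOINT_RANK:
        raise ValidationError(
            f"unknown joint level {level!r}; valid: {sorted(_JOINT_RANK)}"
        )
    gravity, _ = superincumbent_load(chain, level)
    total = gravity.copy()
    for fascicle, force in zip(muscles.fascicles, solution.muscle_forces):
        if force > 0 and _crossing(fascicle, level):
            u, _, _ = line_of_action(fascicle, chain.posture)
            total += force * u  # pull toward the caudal attachment
    return total


def simulate_configuration(params: SpinopelvicParams,
                           constants: ModelConstants | None = None,
                           strict: bool = True) -> LoadResult:
    """Full pipeline for one parameter point: posture -> recruitment -> loads."""
    constants = constants or default_constants()
    posture = build_posture(params, constants, strict=strict)
    chain = build_chain(posture, constants)
    muscles = build_muscle_set(constants)
    problem = assemble_problem(chain, muscles, posture, constants)
    solution = solve_recruitment(problem, constants.solver.residual_tol_nm)

    f_l4l5 = intersegmental_force(chain, muscles, solution, "l4l5")
    f_l5s1 = intersegmental_force(chain, muscles, solution, "l5s1")
    c45, s45 = decompose(f_l4l5, l4l5_axes(posture))
    c51, s51 = decompose(f_l5s1, l5s1_axes(posture))

    def group_force(group: str) -> float:
        return float(sum(
            force for fascicle, force in zip(muscles.fascicles,
                                             solution.muscle_forces)
            if fascicle.group == group
        ))

    return LoadResult(
        params=params,
        f_l4l5=f_l4l5, f_l5s1=f_l5s1,
        fl4l5c=c45, fl4l5s=s45, fl5s1c=c51, fl5s1s=s51,
        f_mf=group_force("multifidus"),
        f_es=group_force("erector_spinae"),
        f_ra=group_force("rectus_abdominis"),
        ll_deg=posture.ll_deg,
        equilibrium_residual=solution.equilibrium_residual,
    )


__all__ = [
    "RecruitmentProblem",
    "RecruitmentSolution",
    "LoadResult",
    "assemble_problem",
    "solve_recruitment",
    "intersegmental_force",
    "simulate_configuration",
]
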