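"""Neck strength evaluation by static muscle optimization.

The strength of the model in one loading mode is the largest external force
(or axial moment) applied at a skull landmark that the muscles can balance
while holding the neutral posture. Following the standard static-
optimization formulation, muscle forces f solve the bound-constrained
convex quadratic program

    min_f  sum_i (f_i / f_i^max)^2  +  w_tau * || R^T f - tau ||^2,
    s.t.   0 <= f_i <= f_i^max,

where R holds tendon-excursion moment arms and tau the per-joint-DOF
torques the muscles must generate. The model "fails" once the RMS residual
torque exceeds a threshold; the maximum resistible magnitude is found by
bisection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import lsq_linear

from .model import GRAVITY, NeckModel
from .muscles import moment_arm_matrix
from . import tables

MODES = tables.MODES
DEFAULT_W_TAU = 100.0
DEFAULT_RESIDUAL_TOLERANCE = 0.1  # N*m RMS over the cervical DOFs
FORCE_BISECTION_TOL = 0.5  # N, for force modes
MOMENT_BISECTION_TOL = 0.01  # N*m, for the axial-rotation mode

#: per-mode application landmark and load direction at neutral posture.
#: In a maximal-effort test the subject pushes anteriorly at the forehead
#: (flexion), posteriorly at the opisthocranion (extension) and laterally at
#: the temple (bending); the external load on the head is the pad's
#: reaction, i.e. the opposite direction, so the agonists of the named mode
#: are the muscles that resist it. Axial rotation is a pure moment about z.
MODE_DEFINITIONS = {
    "flexion": ("forehead", np.array([-1.0, 0.0, 0.0]), "force"),
    "extension": ("opisthocranion", np.array([1.0, 0.0, 0.0]), "force"),
    "lateral_bending": ("temple", np.array([0.0, -1.0, 0.0]), "force"),
    "axial_rotation": (None, np.array([0.0, 0.0, 1.0]), "moment"),
}


@dataclass
class LoadCase:
    """An external head load: a force at a landmark, or a pure moment."""

    mode: str
    landmark: str | None
    direction: np.ndarray
    magnitude: float

    def __post_init__(self):
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if not np.isclose(n, 1.0, atol=1e-9):
            raise ValueError(f"load direction must be a unit vector (|d| = {n:g})")

    @property
    def is_moment(self) -> bool:
        return MODE_DEFINITIONS[self.mode][2] == "moment"


def default_load_case(mode: str, magnitude: float) -> LoadCase:
    if mode not in MODE_DEFINITIONS:
        raise ValueError(f"unknown loading mode {mode!r}; expected one of {list(MODES)}")
    landmark, direction, _kind = MODE_DEFINITIONS[mode]
    return LoadCase(mode=mode, landmark=landmark, direction=direction, magnitude=magnitude)


def required_joint_torques(
    model: NeckModel, load: LoadCase, include_gravity: bool = True
) -> np.ndarray:
    """Torques the muscles must generate at every cervical joint DOF.

    Returns a (n_joints * 3,) vector, joint-major like the moment-arm
    matrix columns. Each entry is the projection on the joint DOF axis of
    minus the moment of the external load (and, optionally, of the weights
    of all segments on the head side of the joint) about the joint centre.
    """
    if load.landmark is not None:
        lm = model.landmarks.get(load.landmark)
        if lm is None:
            raise ValueError(f"model has no landmark {load.landmark!r}")
        if lm.attached_segment != model.skull_segment():
            raise ValueError(
                f"load landmark {load.landmark!r} must lie on the skull segment"
            )
        point = model.world_landmark(load.landmark)
    tau = np.zeros(len(model.joints) * 3)
    for ji, joint in enumerate(model.joints):
        if load.is_moment:
            m = load.direction * load.magnitude
        else:
            force = load.direction * load.magnitude
            m = np.cross(point - joint.center, force)
        if include_gravity:
            w = np.array([0.0, 0.0, -GRAVITY])
            for seg_name in model.distal_segments(joint):
                seg = model.segments[seg_name]
                com_world = seg.origin + seg.com
                m = m + np.cross(com_world - joint.center, seg.mass * w)
        tau[3 * ji : 3 * ji + 3] = joint.dof_axes @ (-m)
    return tau


@dataclass
class InnerSolution:
    """Result of one static muscle optimization."""

    forces: np.ndarray
    residual: np.ndarray  # tau_sim - tau_target per DOF
    js: float
    converged: bool
    rms_residual: float = field(init=False)

    def __post_init__(self):
        self.rms_residual = float(np.sqrt(np.mean(self.residual**2)))


def _solve_box_qp(m: np.ndarray, tau: np.ndarray, fmax: np.ndarray, w_tau: float):
    """Solve min ||f/fmax||^2 + w ||m f - tau||^2, 0 <= f <= fmax.

    Uses a semismooth Newton iteration on the torque-residual fixed point:
    at the optimum, f = clip(w * fmax^2 * (m^T r), 0, fmax) with
    r = tau - m f, a piecewise-linear system in the (small) torque space.
    Returns (f, converged).
    """
    v = w_tau * fmax**2
    eye = np.eye(m.shape[0])
    scale = max(float(np.linalg.norm(tau)), 1.0)
    mt = np.ascontiguousarray(m.T)

    # The fixed point is the unique stationary point of the strictly convex,
    # piecewise-quadratic dual merit Phi(r) = |r|^2/2 - tau.r + sum_i
    # psi_i(q_i) with q = m^T r; its gradient is g below. Newton directions
    # are combined with an exact line search: Phi' along a ray is a
    # continuous increasing piecewise-linear function of t, whose zero is
    # found by bisection.
    r = tau.copy()
    q = mt @ r
    f = np.clip(v * q, 0.0, fmax)
    g = r - tau + m @ f

    def exact_step(d: np.ndarray, dq: np.ndarray, dphi0: float) -> float:
        """Zero of the increasing piecewise-linear derivative Phi'(t) along
        r + t d, found by walking the sorted muscle-state breakpoints."""
        qf = fmax / v  # q value at which a muscle saturates
        base_interior = (q > 0.0) & (q < qf)
        slope = float(d @ d) + float((v[base_interior] * dq[base_interior] ** 2).sum())
        moving = dq != 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            t_zero = np.where(moving, -q / dq, -1.0)
            t_sat = np.where(moving, (qf - q) / dq, -1.0)
        idx = np.arange(len(q))
        t_all = np.concatenate([t_zero, t_sat])
        i_all = np.concatenate([idx, idx])
        keep = t_all > 0.0
        t_all, i_all = t_all[keep], i_all[keep]
        order = np.argsort(t_all)
        t_all, i_all = t_all[order], i_all[order]
        phi_p, t_prev = dphi0, 0.0
        toggles = np.zeros(len(q), dtype=np.int64)
        for t_k, i in zip(t_all, i_all):
            phi_k = phi_p + slope * (t_k - t_prev)
            if phi_k >= 0.0:
                return t_prev - phi_p / slope
            inside = bool(base_interior[i]) ^ bool(toggles[i] % 2)
            slope += (-1.0 if inside else 1.0) * v[i] * dq[i] ** 2
            toggles[i] += 1
            phi_p, t_prev = phi_k, t_k
        return t_prev - phi_p / slope if slope > 0.0 else t_prev

    for _ in range(100):
        if float(np.linalg.norm(g)) <= 1e-10 * scale:
            return f, True
        w_active = np.where((q > 0.0) & (v * q < fmax), v, 0.0)
        jac = eye + (m * w_active) @ mt
        try:
            step = np.linalg.solve(jac, g)
        except np.linalg.LinAlgError:  # pragma: no cover
            return f, False
        d = -step
        dq = mt @ d
        dphi0 = float(g @ d)
        if dphi0 >= 0.0:  # pragma: no cover - PD Jacobian guarantees descent
            return f, False
        t = exact_step(d, dq, dphi0)
        if not t > 0.0:  # pragma: no cover
            return f, False
        r = r + t * d
        q = q + t * dq
        f = np.clip(v * q, 0.0, fmax)
        g = r - tau + m @ f
    return f, False


def static_muscle_optimization(
    model: NeckModel,
    tau_target: np.ndarray,
    w_tau: float = DEFAULT_W_TAU,
    moment_arms: np.ndarray | None = None,
    f_max: np.ndarray | None = None,
) -> InnerSolution:
    """Solve the inner static optimization for one torque target.

    ``moment_arms`` (fascicles x DOFs) and ``f_max`` may be precomputed /
    overridden so that repeated solves on fixed geometry are cheap. The
    bound-constrained convex QP is solved by a semismooth Newton method in
    torque space, falling back to bounded least squares (BVLS) on the rare
    non-convergence.
    """
    r = moment_arm_matrix(model) if moment_arms is None else moment_arms
    fmax = model.f_max_vector() if f_max is None else np.asarray(f_max, float)
    m = r.T  # (n_dof, n_muscles): tau = m @ f
    forces, ok = _solve_box_qp(m, tau_target, fmax, w_tau)
    if not ok:  # pragma: no cover - exercised only on degenerate inputs
        sqrt_w = np.sqrt(w_tau)
        a = np.vstack([sqrt_w * m, np.diag(1.0 / fmax)])
        b = np.concatenate([sqrt_w * tau_target, np.zeros(len(fmax))])
        res = lsq_linear(a, b, bounds=(np.zeros(len(fmax)), fmax), method="bvls", tol=1e-12)
        forces, ok = res.x, bool(res.success)
    residual = m @ forces - tau_target
    with np.errstate(divide="ignore", invalid="ignore"):
        effort = np.where(fmax > 0, (forces / fmax) ** 2, 0.0)
    js = float(effort.sum() + w_tau * np.sum(residual**2))
    return InnerSolution(forces=forces, residual=residual, js=js, converged=ok)


@dataclass
class StrengthResult:
    magnitudes: dict[str, float]
    diagnostics: dict[str, dict] = field(default_factory=dict)


def max_resistible_load(
    model: NeckModel,
    mode: str,
    residual_tolerance: float = DEFAULT_RESIDUAL_TOLERANCE,
    include_gravity: bool = True,
    w_tau: float = DEFAULT_W_TAU,
    moment_arms: np.ndarray | None = None,
    f_max: np.ndarray | None = None,
) -> float:
    """Largest load magnitude (N, or N*m for axial rotation) the model can
    resist at neutral posture, by deterministic bisection."""
    r = moment_arm_matrix(model) if moment_arms is None else moment_arms
    fmax = model.f_max_vector() if f_max is None else np.asarray(f_max, float)
    tol = MOMENT_BISECTION_TOL if MODE_DEFINITIONS[mode][2] == "moment" else FORCE_BISECTION_TOL

    def resists(magnitude: float) -> bool:
        tau = required_joint_torques(
            model, default_load_case(mode, magnitude), include_gravity=include_gravity
        )
        sol = static_muscle_optimization(
            model, tau, w_tau=w_tau, moment_arms=r, f_max=fmax
        )
        return sol.rms_residual <= residual_tolerance

    if not resists(0.0):
        warnings.warn(
            f"model cannot resist zero load in mode {mode!r} (gravity unsupported); "
            "reporting strength 0",
            stacklevel=2,
        )
        return 0.0
    lo, hi = 0.0, 16.0 * tol
    while resists(hi):
        lo, hi = hi, 2.0 * hi
        if hi > 1e6:
            raise RuntimeError(f"strength bisection failed to bracket in mode {mode!r}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if resists(mid):
            lo = mid
        else:
            hi = mid
    return lo


def evaluate_strengths(
    model: NeckModel,
    modes: tuple[str, ...] = MODES,
    residual_tolerance: float = DEFAULT_RESIDUAL_TOLERANCE,
    include_gravity: bool = True,
    w_tau: float = DEFAULT_W_TAU,
    moment_arms: np.ndarray | None = None,
    f_max: np.ndarray | None = None,
) -> StrengthResult:
    """Maximum resistible load for each requested mode."""
    r = moment_arm_matrix(model) if moment_arms is None else moment_arms
    mags = {
        mode: max_resistible_load(
            model,
            mode,
            residual_tolerance=residual_tolerance,
            include_gravity=include_gravity,
            w_tau=w_tau,
            moment_arms=r,
            f_max=f_max,
        )
        for mode in modes
    }
    return StrengthResult(magnitudes=mags)
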