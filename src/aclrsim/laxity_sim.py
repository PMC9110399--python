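"""Reduced-order quasi-static knee laxity simulation.

The FE continuum solve is replaced by a rigid-femur-on-spring-bundles
equilibrium: the tibia is fixed, the femur's six Grood-Suntay degrees of
freedom are split per protocol step into prescribed and free sets, and the
free DoFs minimize the total potential (spring strain energy + contact
penalty - work of the applied load) via a damped Newton iteration on the
generalized residual with a finite-difference Jacobian and a ramped load.
This reproduces the scalar outputs of interest -- anterior-posterior
displacement, graft tension and a graft stress proxy (axial force over
section area) -- but not continuum stress fields.

Protocols implemented: the two-step Lachman test (graft pretension at a
fixation angle, then 30 degrees of flexion with a 134 N posterior femoral
force, internal-external rotation locked) and anterior/posterior drawer
tests, plus the stiffness x prestrain sensitivity grid and the what-if
parameter sweeps (graft radius, pretension, fixation angle, SB vs DB).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConfigurationError,
    ConvergenceError,
    InvalidParameterError,
)
from .graft_meshing import GraftSpec
from .knee_assembly import JointPose, KneeModel
from .ligament_mechanics import (
    LigamentBundle,
    SpringLaw,
    slack_length,
    strain_at_force,
)

__all__ = [
    "DOF_NAMES",
    "DEFAULT_GRAFT_MODULI",
    "ProtocolStep",
    "Protocol",
    "SimResult",
    "SensitivityGrid",
    "graft_effective_bundle",
    "apply_pretension",
    "solve_equilibrium",
    "run_lachman",
    "run_drawer",
    "displacement_difference",
    "apply_multipliers",
    "sensitivity_grid",
    "sweep_what_if",
]

DOF_NAMES = (
    "flexion",
    "adduction",
    "external_rotation",
    "medial_lateral",
    "anterior_posterior",
    "superior_inferior",
)

#: Effective axial Young's moduli (MPa) per graft harvest site.  These are
#: package defaults drawn from tendon tensile-testing literature; override
#: per call for subject-specific values.
DEFAULT_GRAFT_MODULI = {
    "semitendinosus": 362.0,
    "patellar tendon": 307.0,
    "gracilis": 612.0,
}

_ANG = slice(0, 3)


@dataclass
class ProtocolStep:
    """One quasi-static step: prescribed DoFs, an applied femoral force.

    ``prescribed`` maps DoF names to target values (deg / mm); all other
    DoFs are free.  ``force`` (N, world) acts at the femoral frame origin
    and is ramped together with the prescribed values over
    ``ramp_substeps`` increments.
    """

    prescribed: dict = field(default_factory=dict)
    force: np.ndarray = field(default_factory=lambda: np.zeros(3))
    ramp_substeps: int = 10
    name: str = "step"

    def __post_init__(self):
        for k in self.prescribed:
            if k not in DOF_NAMES:
                raise ConfigurationError(f"unknown DoF {k!r}")
        self.force = np.asarray(self.force, dtype=float).reshape(3)
        if self.ramp_substeps < 1:
            raise InvalidParameterError("ramp_substeps must be >= 1")

    @property
    def free(self):
        return tuple(n for n in DOF_NAMES if n not in self.prescribed)


@dataclass
class Protocol:
    """An ordered list of protocol steps."""

    steps: list
    name: str = "protocol"


@dataclass
class SimResult:
    """Converged equilibrium of one protocol step."""

    pose: JointPose
    relative_ap_displacement: float
    tensions: dict  # bundle name -> per-spring tensions (N)
    graft_axial_force: float
    graft_stress_proxy: float  # MPa: axial force / graft section area
    residual_force: float  # N
    residual_moment: float  # N*mm
    converged: bool
    iterations: int = 0

    def total_tension(self, name: str) -> float:
        return float(np.sum(self.tensions.get(name, 0.0)))


# -- solver internals -------------------------------------------------------


class _System:
    """Flattened arrays for fast residual evaluation."""

    def __init__(self, model: KneeModel):
        self.tibia_axes = model.tibia_frame.axes
        self.tibia_origin = model.tibia_frame.origin
        origins, insertions, ks, epsls, L0s = [], [], [], [], []
        self.slices = {}
        for b in model.active_bundles:
            if b.L_0 is None:
                continue  # unresolved (e.g. graft before pretension)
            start = sum(len(o) for o in origins)
            origins.append(b.origins)
            insertions.append(b.insertions)
            ks.append(np.full(b.n_springs, b.per_spring_k))
            epsls.append(np.full(b.n_springs, b.law.eps_l))
            L0s.append(np.asarray(b.L_0, dtype=float))
            self.slices[b.name] = slice(start, start + b.n_springs)
        self.origins = np.vstack(origins) if origins else np.zeros((0, 3))
        self.insertions = np.vstack(insertions) if insertions else np.zeros((0, 3))
        self.k = np.concatenate(ks) if ks else np.zeros(0)
        self.eps_l = np.concatenate(epsls) if epsls else np.zeros(0)
        self.L0 = np.concatenate(L0s) if L0s else np.zeros(0)
        self.n_springs = len(self.origins)

        cpts, cpp, cn, ck = [], [], [], []
        for c in model.contacts:
            for p in c.points:
                cpts.append(p)
                cpp.append(c.plane_point)
                cn.append(c.normal)
                ck.append(c.stiffness)
        self.cpts = np.array(cpts).reshape(-1, 3)
        self.cpp = np.array(cpp).reshape(-1, 3)
        self.cn = np.array(cn).reshape(-1, 3)
        self.ck = np.array(ck)
        # femoral point block: spring origins, contact points, frame origin
        self.P = np.vstack([self.origins, self.cpts, np.zeros((1, 3))])

    def transforms_batch(self, Q):
        """Batched femur placements for internal pose vectors ``Q`` (B, 6).

        Returns ``(R, t)`` with shapes (B, 3, 3) and (B, 3).  Angles are in
        radians; translations are Grood-Suntay components along
        ``(e1, e2, e3)`` and are converted to Cartesian via Cramer's rule.
        """
        Q = np.atleast_2d(Q)
        a, b, c = Q[:, 0], Q[:, 1], Q[:, 2]
        ca, sa = np.cos(a), np.sin(a)
        cb, sb = np.cos(b), np.sin(b)
        cc, sc = np.cos(c), np.sin(c)
        R_rel = np.empty((len(Q), 3, 3))
        R_rel[:, 0, 0] = cb * cc
        R_rel[:, 0, 1] = -cb * sc
        R_rel[:, 0, 2] = sb
        R_rel[:, 1, 0] = sa * sb * cc + ca * sc
        R_rel[:, 1, 1] = -sa * sb * sc + ca * cc
        R_rel[:, 1, 2] = -sa * cb
        R_rel[:, 2, 0] = -ca * sb * cc + sa * sc
        R_rel[:, 2, 1] = ca * sb * sc + sa * cc
        R_rel[:, 2, 2] = ca * cb
        R = np.einsum("ij,bjk->bik", self.tibia_axes, R_rel)
        e1 = R[:, :, 0]
        e3 = np.broadcast_to(self.tibia_axes[:, 2], e1.shape)
        e2 = np.cross(e3, e1)
        n = np.linalg.norm(e2, axis=1, keepdims=True)
        if np.any(n < 1e-9):
            raise ConvergenceError("pose reached the gimbal-singular configuration")
        e2 = e2 / n
        # solve E^T H = d (rows e1, e2, e3) by Cramer's rule
        r23 = np.cross(e2, e3)
        r31 = np.cross(e3, e1)
        r12 = np.cross(e1, e2)
        det = np.einsum("bi,bi->b", e1, r23)
        d = Q[:, 3:6]
        H = (
            d[:, 0:1] * r23 + d[:, 1:2] * r31 + d[:, 2:3] * r12
        ) / det[:, None]
        return R, self.tibia_origin + H

    def world_points_batch(self, Q):
        R, t = self.transforms_batch(Q)
        return np.einsum("pk,bik->bpi", self.P, R) + t[:, None, :]

    def world_points(self, q):
        return self.world_points_batch(np.asarray(q)[None])[0]

    def spring_state(self, W):
        """(lengths, strains, tensions, unit chords) at world points ``W``."""
        chord = self.insertions - W[: self.n_springs]
        L = np.linalg.norm(chord, axis=1)
        eps = (L - self.L0) / self.L0
        F = np.where(
            eps < 0,
            0.0,
            np.where(
                eps <= 2 * self.eps_l,
                0.25 * self.k * eps**2 / self.eps_l,
                self.k * (eps - self.eps_l),
            ),
        )
        unit = chord / np.maximum(L, 1e-12)[:, None]
        return L, eps, F, unit

    def contact_state(self, W):
        if len(self.cpts) == 0:
            return np.zeros(0)
        pts = W[self.n_springs : self.n_springs + len(self.cpts)]
        gap = np.einsum("ij,ij->i", pts - self.cpp, self.cn)
        return np.maximum(-gap, 0.0)

    def energy(self, q, force):
        W = self.world_points(q)
        L, eps, F, _ = self.spring_state(W)
        e = np.where(
            eps < 0,
            0.0,
            np.where(
                eps <= 2 * self.eps_l,
                self.k * eps**3 / (12 * self.eps_l),
                0.5 * self.k * ((eps - self.eps_l) ** 2 - self.eps_l**2)
                + (2.0 / 3.0) * self.k * self.eps_l**2,
            ),
        )
        pen = self.contact_state(W)
        return (
            float(np.sum(self.L0 * e))
            + float(0.5 * np.sum(self.ck * pen**2))
            - float(force @ W[-1])
        )

    def residual_many(self, Q, free_idx, force, h=1e-6):
        """Generalized force residuals on the free DoFs for B pose vectors.

        For each pose the geometry derivative d(world point)/d(DoF) is
        taken by central differences of the pose map; spring tensions and
        contact pressures are exact, so the residual is accurate to the
        O(h^2) geometric truncation (~1e-12 relative here).
        Returns an array of shape (B, n_free) in N (translations) and
        N*mm (rotations, per radian).
        """
        Q = np.atleast_2d(Q)
        B = len(Q)
        n = len(free_idx)
        ns = self.n_springs
        nc = len(self.cpts)
        stack = np.repeat(Q[:, None, :], 1 + 2 * n, axis=1)
        for col, j in enumerate(free_idx):
            stack[:, 1 + 2 * col, j] += h
            stack[:, 2 + 2 * col, j] -= h
        W = self.world_points_batch(stack.reshape(-1, 6)).reshape(
            B, 1 + 2 * n, -1, 3
        )
        W0 = W[:, 0]
        chord = self.insertions[None] - W0[:, :ns]
        L = np.linalg.norm(chord, axis=2)
        eps = (L - self.L0[None]) / self.L0[None]
        F = np.where(
            eps < 0,
            0.0,
            np.where(
                eps <= 2 * self.eps_l[None],
                0.25 * self.k[None] * eps**2 / self.eps_l[None],
                self.k[None] * (eps - self.eps_l[None]),
            ),
        )
        unit = chord / np.maximum(L, 1e-12)[..., None]
        dW = (W[:, 1::2] - W[:, 2::2]) / (2 * h)  # (B, n, npts, 3)
        # dL = -unit . dW  (chord = insertion - origin)
        dPi = -np.einsum("bsi,bs,bnsi->bn", unit, F, dW[:, :, :ns])
        if nc:
            gap = np.einsum("bci,ci->bc", W0[:, ns : ns + nc] - self.cpp[None], self.cn)
            pen = np.maximum(-gap, 0.0)
            dpen = -np.einsum("ci,bnci->bnc", self.cn, dW[:, :, ns : ns + nc])
            dPi += np.einsum("bc,bnc->bn", self.ck[None] * pen, dpen)
        dPi -= np.einsum("i,bni->bn", force, dW[:, :, -1])
        return -dPi

    def residual(self, q, free_idx, force):
        return self.residual_many(np.asarray(q)[None], free_idx, force)[0]

    def residual_and_jacobian(self, q, free_idx, force, hj=1e-5):
        """Residual and its finite-difference Jacobian in one batched call."""
        n = len(free_idx)
        stack = np.repeat(np.asarray(q)[None], 1 + 2 * n, axis=0)
        for col, j in enumerate(free_idx):
            stack[1 + 2 * col, j] += hj
            stack[2 + 2 * col, j] -= hj
        rows = self.residual_many(stack, free_idx, force)
        r0 = rows[0]
        J = (rows[1::2] - rows[2::2]).T / (2 * hj)
        return r0, J


def _pose_to_q(pose: JointPose) -> np.ndarray:
    q = pose.as_array().astype(float)
    q[_ANG] = np.deg2rad(q[_ANG])
    return q


def _q_to_pose(q) -> JointPose:
    v = np.asarray(q, dtype=float).copy()
    v[_ANG] = np.rad2deg(v[_ANG])
    # wrap angles into (-180, 180]
    v[:3] = -((-v[:3] + 180.0) % 360.0 - 180.0)
    return JointPose.from_array(v)


def solve_equilibrium(
    model: KneeModel,
    step: ProtocolStep,
    start_pose: JointPose | None = None,
    tol_force: float = 1e-6,
    tol_moment: float = 1e-6,
    max_iterations: int = 60,
) -> SimResult:
    """Solve one protocol step to quasi-static equilibrium.

    Prescribed DoFs and the applied load are ramped linearly from the
    starting pose over the step's substeps; each increment is solved by a
    damped Newton iteration on the generalized residual (finite-difference
    Jacobian, backtracking line search on the residual norm), warm-started
    from the previous increment.
    """
    system = _System(model)
    q = _pose_to_q(start_pose or JointPose())
    free_idx = np.array([DOF_NAMES.index(n) for n in step.free], dtype=int)
    is_ang = free_idx < 3
    presc_idx = np.array(
        [DOF_NAMES.index(n) for n in step.prescribed], dtype=int
    )
    targets = np.array([float(step.prescribed[n]) for n in step.prescribed])
    t_int = targets.copy()
    if len(presc_idx):
        t_int[presc_idx < 3] = np.deg2rad(targets[presc_idx < 3])
    q0_presc = q[presc_idx] if len(presc_idx) else np.zeros(0)

    history = []
    total_iters = 0
    for s in np.linspace(1.0 / step.ramp_substeps, 1.0, step.ramp_substeps):
        if len(presc_idx):
            q[presc_idx] = (1 - s) * q0_presc + s * t_int
        force = s * step.force
        converged = False
        for _ in range(max_iterations):
            r, J = system.residual_and_jacobian(q, free_idx, force)
            rf = np.abs(r[~is_ang]).max() if (~is_ang).any() else 0.0
            rm = np.abs(r[is_ang]).max() if is_ang.any() else 0.0
            history.append((rf, rm))
            if rf < tol_force and rm < tol_moment:
                converged = True
                break
            total_iters += 1
            try:
                dq = np.linalg.solve(J, -r)
            except np.linalg.LinAlgError:
                dq = None
            # energy line search: the total potential decreases monotonically
            # along accepted steps (Armijo), with a steepest-descent fallback
            # when the Newton direction is not a descent direction
            if dq is None or float(r @ dq) <= 0.0:
                scale = max(np.abs(J).max(), 1.0)
                dq = r / scale
            if max(rf, rm) < 1e-2:
                # close to the root: full Newton steps converge quadratically
                # and energy differences are below float resolution anyway
                q[free_idx] += dq
                continue
            e0 = system.energy(q, force)
            slope = -float(r @ dq)  # directional derivative of the potential
            noise = 1e-12 * max(1.0, abs(e0))
            lam = 1.0
            accepted = False
            while lam > 1e-10:
                qt = q.copy()
                qt[free_idx] += lam * dq
                if system.energy(qt, force) <= e0 + 1e-4 * lam * slope + noise:
                    accepted = True
                    break
                lam *= 0.5
            if not accepted:
                lam = 1e-10
            q[free_idx] += lam * dq
        if not converged:
            raise ConvergenceError(
                f"step {step.name!r} did not converge at ramp fraction {s:.2f}",
                residual_history=history,
            )

    W = system.world_points(q)
    _, _, F, _ = system.spring_state(W)
    tensions = {name: F[sl].copy() for name, sl in system.slices.items()}
    graft_force = 0.0
    stress = 0.0
    area = 0.0
    for g in model.grafts:
        if g.bundle is not None and g.bundle.name in tensions:
            graft_force += float(np.sum(tensions[g.bundle.name]))
            area += g.spec.section_area
    if area > 0:
        stress = graft_force / area
    pose = _q_to_pose(q)
    r = system.residual(q, free_idx, step.force)
    rf = np.abs(r[~is_ang]).max() if (~is_ang).any() else 0.0
    rm = np.abs(r[is_ang]).max() if is_ang.any() else 0.0
    return SimResult(
        pose=pose,
        relative_ap_displacement=pose.anterior_posterior,
        tensions=tensions,
        graft_axial_force=graft_force,
        graft_stress_proxy=stress,
        residual_force=float(rf),
        residual_moment=float(rm),
        converged=True,
        iterations=total_iters,
    )


# -- graft handling ---------------------------------------------------------

def graft_effective_bundle(
    spec: GraftSpec,
    origins,
    insertions,
    moduli: dict | None = None,
    name: str | None = None,
) -> LigamentBundle:
    """Effective axial-spring bundle standing in for the 3D graft.

    Total stiffness is ``k = E_eff * A`` with ``A = n_bundles * pi * r_b^2``
    (the load-bearing section of the packed bundles) and ``E_eff`` selected
    by the spec's harvest-site material tag.  Slack lengths stay unresolved
    until pretension is applied.
    """
    moduli = dict(DEFAULT_GRAFT_MODULI, **(moduli or {}))
    if spec.material not in moduli:
        raise ConfigurationError(
            f"unknown graft material {spec.material!r}; known: {sorted(moduli)}"
        )
    E = moduli[spec.material]
    k = E * spec.section_area
    return LigamentBundle(
        name=name or f"graft-{spec.material}",
        origins=origins,
        insertions=insertions,
        law=SpringLaw(k=k),
    )


def apply_pretension(
    model: KneeModel,
    F_pre: float,
    fixation_angle: float = 20.0,
    ramp_substeps: int = 5,
) -> KneeModel:
    """Tension the graft(s) and fix their slack lengths.

    The knee is posed at the fixation flexion angle (graft springs inert,
    other structures at equilibrium), then each graft spring's slack
    length is set so its tension is exactly its share of ``F_pre``
    (closed-form inverse of the spring law).  Slack lengths are frozen
    afterwards; the knee may then return to extension carrying the graft
    preload.
    """
    if F_pre < 0:
        raise InvalidParameterError("pretension must be >= 0")
    if not model.grafts:
        raise InvalidParameterError("model has no graft to pretension")
    # the knee is held reduced while tensioning: translations in the joint
    # plane are prescribed to zero (without the ACL the anterior-posterior
    # direction would be nearly unconstrained), only the contact-supported
    # DoFs equilibrate
    step = ProtocolStep(
        prescribed={
            "flexion": fixation_angle,
            "external_rotation": 0.0,
            "medial_lateral": 0.0,
            "anterior_posterior": 0.0,
        },
        ramp_substeps=ramp_substeps,
        name="fixation pose",
    )
    res = solve_equilibrium(model, step)
    T = model.femur_transform(res.pose)
    for g in model.grafts:
        b = g.bundle
        if b is None:
            raise InvalidParameterError("graft has no effective bundle")
        L_cur = b.current_lengths(T)
        per_F = F_pre / b.n_springs
        if per_F == 0:
            eps_pre = 0.0
        else:
            eps_pre = strain_at_force(per_F, b.per_spring_k, b.law.eps_l)
        b.L_r = L_cur
        b.L_0 = L_cur / (1.0 + eps_pre)
        g.pretension = float(F_pre)
        g.fixation_angle = float(fixation_angle)
        g.fixation_pose = res.pose
    return model


# -- protocols --------------------------------------------------------------

def run_lachman(
    model: KneeModel,
    flexion: float = 30.0,
    force: float = 134.0,
    ramp_substeps: int = 8,
) -> SimResult:
    """Two-DoF-constrained Lachman maneuver.

    Flexion is prescribed, internal-external rotation locked at zero, the
    remaining four DoFs free; a posterior force of magnitude ``force`` acts
    at the femoral frame origin.  The reported relative displacement is the
    anterior-posterior translation change from the zero-force equilibrium
    at the same flexion (signed; posterior negative).
    """
    for g in model.grafts:
        if g.bundle is None or g.bundle.L_0 is None:
            raise InvalidParameterError(
                "apply_pretension must run before the Lachman maneuver on ACLR models"
            )
    return run_drawer(model, flexion, -abs(force), ramp_substeps=ramp_substeps)


def run_drawer(
    model: KneeModel,
    flexion: float,
    force: float,
    ramp_substeps: int = 8,
) -> SimResult:
    """Anterior (+) / posterior (-) drawer at a prescribed flexion angle.

    ``force`` is the signed anterior-posterior load (N) on the femur along
    the tibial AP axis.  Returns the equilibrium under load with
    ``relative_ap_displacement`` measured from the zero-force equilibrium.
    """
    prescribed = {"flexion": float(flexion), "external_rotation": 0.0}
    ref_step = ProtocolStep(prescribed=prescribed, ramp_substeps=ramp_substeps,
                            name="flex")
    ref = solve_equilibrium(model, ref_step)
    ap_axis = model.tibia_frame.ap
    load_step = ProtocolStep(
        prescribed=prescribed,
        force=float(force) * ap_axis,
        ramp_substeps=ramp_substeps,
        name="drawer",
    )
    res = solve_equilibrium(model, load_step, start_pose=ref.pose)
    res.relative_ap_displacement = (
        res.pose.anterior_posterior - ref.pose.anterior_posterior
    )
    return res


def displacement_difference(aclr: SimResult, rm: SimResult) -> float:
    """Absolute AP-displacement difference between an ACLR model and the RM."""
    return abs(aclr.relative_ap_displacement - rm.relative_ap_displacement)


# -- sensitivity analysis ---------------------------------------------------

def apply_multipliers(
    model: KneeModel,
    stiffness_multiplier: float,
    prestrain_multiplier: float,
    ligaments=("ACL", "PCL"),
) -> KneeModel:
    """Deep-copied model with cruciate stiffness/prestrain scaled.

    Slack lengths are re-derived from the stored reference lengths under
    the scaled prestrain, exactly as if the model had been assembled with
    the scaled parameters.
    """
    out = copy.deepcopy(model)
    for name in ligaments:
        try:
            b = out.bundle(name)
        except KeyError:
            continue
        law = b.law
        b.law = SpringLaw(
            k=law.k * stiffness_multiplier,
            eps_l=law.eps_l,
            eps_r=law.eps_r * prestrain_multiplier,
            L_r=law.L_r,
        )
        if getattr(b, "L_r", None) is not None:
            b.L_0 = slack_length(np.asarray(b.L_r), b.law.eps_r)
    return out


def multiplier_grid(
    stiffness_span: float = 0.30,
    prestrain_span: float = 0.15,
    step: float = 0.05,
):
    """Factorial multiplier grid: stiffness +/-30%, prestrain +/-15%, 5% step."""
    ns = int(round(stiffness_span / step))
    npr = int(round(prestrain_span / step))
    ms = np.round(1.0 + step * np.arange(-ns, ns + 1), 10)
    mp = np.round(1.0 + step * np.arange(-npr, npr + 1), 10)
    return ms, mp


@dataclass
class SensitivityGrid:
    """Full-factorial stiffness x prestrain sensitivity results."""

    stiffness_multipliers: np.ndarray
    prestrain_multipliers: np.ndarray
    records: list  # dicts: multipliers, per-condition displacements, mse

    @property
    def n_combinations(self) -> int:
        return len(self.stiffness_multipliers) * len(self.prestrain_multipliers)

    def ranked(self):
        """Records sorted by ascending MSE; ties prefer multipliers near 1."""
        return sorted(
            self.records,
            key=lambda r: (
                r["mse"],
                abs(r["stiffness_multiplier"] - 1.0),
                abs(r["prestrain_multiplier"] - 1.0),
            ),
        )

    @property
    def best(self):
        return self.ranked()[0]


def sensitivity_grid(
    model: KneeModel,
    experiments,
    stiffness_span: float = 0.30,
    prestrain_span: float = 0.15,
    step: float = 0.05,
    ligaments=("ACL", "PCL"),
    ramp_substeps: int = 3,
) -> SensitivityGrid:
    """Rank cruciate stiffness/prestrain combinations against laxity data.

    ``experiments`` is an iterable of ``(flexion_deg, force_N,
    displacement_mm)`` triples (signed anterior force).  Each grid
    combination -- by default 13 stiffness x 7 prestrain = 91 models, one
    multiplier pair applied jointly to ACL and PCL -- is simulated over the
    experimental conditions and scored by the mean squared displacement
    error (mm^2).
    """
    experiments = np.atleast_2d(np.asarray(experiments, dtype=float))
    if experiments.size == 0:
        raise InvalidParameterError("experiment set is empty")
    if experiments.shape[1] != 3:
        raise InvalidParameterError("experiments must be (flexion, force, displacement)")
    ms_list, mp_list = multiplier_grid(stiffness_span, prestrain_span, step)
    flexions = sorted({float(f) for f, _, _ in experiments})
    ap_axis = model.tibia_frame.ap
    records = []
    warm: dict = {}  # (kind, flexion[, force]) -> converged pose of previous combo
    first = True
    for ms in ms_list:
        for mp in mp_list:
            m = apply_multipliers(model, ms, mp, ligaments)
            system_substeps = ramp_substeps if first else 1
            refs = {}
            for f in flexions:
                s = ProtocolStep(
                    prescribed={"flexion": f, "external_rotation": 0.0},
                    ramp_substeps=system_substeps,
                    name="flex",
                )
                refs[f] = solve_equilibrium(m, s, start_pose=warm.get(("ref", f)))
                warm[("ref", f)] = refs[f].pose
            disp = np.empty(len(experiments))
            for i, (f, F, _) in enumerate(experiments):
                s = ProtocolStep(
                    prescribed={"flexion": float(f), "external_rotation": 0.0},
                    force=float(F) * ap_axis,
                    ramp_substeps=system_substeps,
                    name="drawer",
                )
                start = warm.get(("load", float(f), float(F)), refs[float(f)].pose)
                res = solve_equilibrium(m, s, start_pose=start)
                warm[("load", float(f), float(F))] = res.pose
                disp[i] = (
                    res.pose.anterior_posterior
                    - refs[float(f)].pose.anterior_posterior
                )
            first = False
            mse = float(np.mean((disp - experiments[:, 2]) ** 2))
            records.append(
                {
                    "stiffness_multiplier": float(ms),
                    "prestrain_multiplier": float(mp),
                    "displacements": disp,
                    "mse": mse,
                }
            )
    return SensitivityGrid(ms_list, mp_list, records)


# -- what-if sweeps ---------------------------------------------------------

def sweep_what_if(
    rm_result: SimResult,
    model_builder,
    radii=None,
    pretensions=None,
    fixation_angles=None,
    techniques=None,
    materials=None,
    flexion: float = 30.0,
    force: float = 134.0,
    defaults: dict | None = None,
) -> list:
    """Lachman sweeps over surgery parameters, compared against the RM.

    ``model_builder(technique, radius, material)`` must return a fresh
    ACLR :class:`KneeModel` with an unresolved graft bundle.  The supplied
    axes are combined factorially; omitted axes use the defaults
    (radius 4 mm, pretension 80 N, fixation 20 deg, SB, semitendinosus).
    Each row records the displacement difference to the reference model
    and the graft stress proxy.
    """
    base = {
        "radius": 4.0,
        "pretension": 80.0,
        "fixation_angle": 20.0,
        "technique": "SB",
        "material": "semitendinosus",
    }
    base.update(defaults or {})
    axes = {
        "radius": radii if radii is not None else [base["radius"]],
        "pretension": pretensions if pretensions is not None else [base["pretension"]],
        "fixation_angle": fixation_angles
        if fixation_angles is not None
        else [base["fixation_angle"]],
        "technique": techniques if techniques is not None else [base["technique"]],
        "material": materials if materials is not None else [base["material"]],
    }
    rows = []
    for tech in axes["technique"]:
        for R in axes["radius"]:
            for mat in axes["material"]:
                for pre in axes["pretension"]:
                    for ang in axes["fixation_angle"]:
                        model = model_builder(technique=tech, radius=R, material=mat)
                        apply_pretension(model, pre, fixation_angle=ang)
                        res = run_lachman(model, flexion=flexion, force=force)
                        rows.append(
                            {
                                "technique": tech,
                                "radius": float(R),
                                "material": mat,
                                "pretension": float(pre),
                                "fixation_angle": float(ang),
                                "displacement": res.relative_ap_displacement,
                                "difference": displacement_difference(res, rm_result),
                                "stress_proxy": res.graft_stress_proxy,
                                "graft_force": res.graft_axial_force,
                                "residual_force": res.residual_force,
                            }
                        )
    return rows


def equal_area_radius(radii) -> float:
    """Single-bundle radius matching the summed section area of ``radii``."""
    radii = np.asarray(radii, dtype=float)
    return float(np.sqrt(np.sum(radii**2)))
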