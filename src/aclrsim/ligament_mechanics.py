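"""Nonlinear spring ligament mechanics.

Knee ligaments (ACL, PCL, MCL, LCL) and grafts are modeled as bundles of
tension-only nonlinear springs following the piecewise force-strain law of
Blankevoort and Huiskes::

    F(eps) = 0                          eps < 0
           = (1/4) k eps^2 / eps_l      0 <= eps <= 2 eps_l
           = k (eps - eps_l)            eps > 2 eps_l

where ``k`` (N) is the total bundle stiffness, ``eps_l`` the linear strain
limit (default 0.03) and ``eps`` the engineering strain relative to the
zero-load slack length ``L_0``.  ``L_0`` is derived from the reference
length ``L_r`` (the chord length at the assembly pose) and the reference
prestrain ``eps_r`` via ``L_0 = L_r / (1 + eps_r)``.  Bundle stiffness is
the product of Young's modulus (MPa) and cross-sectional area (mm^2),
``k = E * A`` -- with lengths in mm and forces in N this is unit-exact --
and is distributed evenly over the springs of a bundle.

All lengths are in mm, forces in N, moduli in MPa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError, NumericalDegeneracyError

__all__ = [
    "SpringLaw",
    "LigamentBundle",
    "MaterialConstants",
    "MENISCAL_ROOT_STIFFNESS",
    "DEFAULT_LINEAR_STRAIN_LIMIT",
    "blankevoort_force",
    "blankevoort_energy_density",
    "strain_at_force",
    "slack_length",
    "spring_strain",
    "stiffness_from_EA",
    "round_for_report",
    "distribute_stiffness",
    "bundle_force",
]

#: Linear strain limit of the piecewise spring law (dimensionless).
DEFAULT_LINEAR_STRAIN_LIMIT = 0.03

#: Total stiffness of a meniscal-root linear spring bundle (N/mm).  Stored
#: as a named export constant; meniscal roots themselves are not simulated.
MENISCAL_ROOT_STIFFNESS = 2000.0


def blankevoort_force(eps, k, eps_l=DEFAULT_LINEAR_STRAIN_LIMIT):
    """Tension (N) of a nonlinear spring at strain ``eps``.

    Parameters
    ----------
    eps : float or array_like
        Engineering strain relative to the slack length.
    k : float
        Spring stiffness (N).
    eps_l : float
        Linear strain limit; the toe (quadratic) region spans
        ``0 <= eps <= 2 * eps_l``.

    Returns
    -------
    float or ndarray
        Non-negative tension; identically zero for slack springs.
    """
    if k <= 0:
        raise InvalidParameterError(f"stiffness k must be > 0, got {k}")
    if eps_l <= 0:
        raise InvalidParameterError(f"linear strain limit must be > 0, got {eps_l}")
    eps = np.asarray(eps, dtype=float)
    toe = 0.25 * k * eps**2 / eps_l
    lin = k * (eps - eps_l)
    out = np.where(eps < 0.0, 0.0, np.where(eps <= 2.0 * eps_l, toe, lin))
    return out if out.ndim else float(out)


def blankevoort_energy_density(eps, k, eps_l=DEFAULT_LINEAR_STRAIN_LIMIT):
    """Strain energy per unit slack length, ``int_0^eps F de`` (N).

    Multiplying by ``L_0`` gives the spring's stored energy in N*mm; this is
    the potential minimized by the quasi-static solver.
    """
    eps = np.asarray(eps, dtype=float)
    toe = k * eps**3 / (12.0 * eps_l)
    # continuation at eps = 2 eps_l where the toe integral equals (2/3) k eps_l^2
    lin = 0.5 * k * ((eps - eps_l) ** 2 - eps_l**2) + (2.0 / 3.0) * k * eps_l**2
    out = np.where(eps < 0.0, 0.0, np.where(eps <= 2.0 * eps_l, toe, lin))
    return out if out.ndim else float(out)


def strain_at_force(F, k, eps_l=DEFAULT_LINEAR_STRAIN_LIMIT):
    """Closed-form inverse of :func:`blankevoort_force` for ``F >= 0``.

    ``eps = F/k + eps_l`` on the linear branch (``F >= k * eps_l``) and
    ``eps = sqrt(4 F eps_l / k)`` on the toe branch.
    """
    if k <= 0 or eps_l <= 0:
        raise InvalidParameterError("k and eps_l must be > 0")
    F = np.asarray(F, dtype=float)
    if np.any(F < 0):
        raise InvalidParameterError("spring tension cannot be negative")
    out = np.where(F >= k * eps_l, F / k + eps_l, np.sqrt(4.0 * F * eps_l / k))
    return out if out.ndim else float(out)


def slack_length(L_r, eps_r):
    """Zero-load slack length ``L_0 = L_r / (1 + eps_r)`` (mm).

    ``L_r`` is the reference length (chord at the assembly pose) and
    ``eps_r`` the reference prestrain, so a spring at length ``L_r`` carries
    strain exactly ``eps_r``.
    """
    L_r = np.asarray(L_r, dtype=float)
    if np.any(L_r <= 0):
        raise InvalidParameterError("reference length must be > 0")
    if np.any(np.asarray(eps_r) <= -1.0):
        raise InvalidParameterError("reference strain must be > -1")
    out = L_r / (1.0 + np.asarray(eps_r, dtype=float))
    return out if out.ndim else float(out)


def spring_strain(L, L_0):
    """Engineering strain ``(L - L_0) / L_0`` of a spring of length ``L``."""
    L_0 = np.asarray(L_0, dtype=float)
    if np.any(L_0 <= 0):
        raise InvalidParameterError("slack length must be > 0")
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise InvalidParameterError("length cannot be negative")
    out = (L - L_0) / L_0
    return out if out.ndim else float(out)


def stiffness_from_EA(E, A):
    """Bundle stiffness ``k = E * A`` in N (MPa * mm^2)."""
    if E <= 0 or A <= 0:
        raise InvalidParameterError("Young's modulus and area must be > 0")
    return float(E) * float(A)


def round_for_report(value):
    """Round half away from zero to an integer, for reported stiffnesses.

    Internal computations keep full precision; only reported tables use
    integer newtons.
    """
    v = np.asarray(value, dtype=float)
    out = np.sign(v) * np.floor(np.abs(v) + 0.5)
    return int(out) if out.ndim == 0 else out.astype(int)


def distribute_stiffness(k, n_springs):
    """Per-spring stiffness when ``k`` is split evenly over ``n_springs``."""
    if n_springs < 1 or int(n_springs) != n_springs:
        raise InvalidParameterError("spring count must be a positive integer")
    if k <= 0:
        raise InvalidParameterError("stiffness must be > 0")
    return k / int(n_springs)


@dataclass(frozen=True)
class SpringLaw:
    """Parameters of the piecewise nonlinear spring law for one bundle.

    Attributes
    ----------
    k : float
        Total bundle stiffness (N).
    eps_l : float
        Linear strain limit (default 0.03).
    eps_r : float
        Reference prestrain at the assembly pose.
    L_r : float or None
        Reference length (mm); optional until the bundle is assembled.
    """

    k: float
    eps_l: float = DEFAULT_LINEAR_STRAIN_LIMIT
    eps_r: float = 0.0
    L_r: float | None = None

    def __post_init__(self):
        if self.k <= 0:
            raise InvalidParameterError(f"k must be > 0, got {self.k}")
        if self.eps_l <= 0:
            raise InvalidParameterError(f"eps_l must be > 0, got {self.eps_l}")
        if self.eps_r <= -1.0:
            raise InvalidParameterError(f"eps_r must be > -1, got {self.eps_r}")
        if self.L_r is not None and self.L_r <= 0:
            raise InvalidParameterError(f"L_r must be > 0, got {self.L_r}")

    @property
    def L_0(self) -> float | None:
        """Zero-load slack length ``L_r / (1 + eps_r)``, if ``L_r`` is set."""
        if self.L_r is None:
            return None
        return slack_length(self.L_r, self.eps_r)

    def force(self, eps):
        return blankevoort_force(eps, self.k, self.eps_l)

    def with_reference_length(self, L_r) -> "SpringLaw":
        return SpringLaw(self.k, self.eps_l, self.eps_r, float(L_r))


@dataclass
class MaterialConstants:
    """Young's modulus (MPa), cross-sectional area (mm^2) and harvest site."""

    E: float
    A: float
    harvest_site: str = "native ligament"

    def __post_init__(self):
        if self.E <= 0 or self.A <= 0:
            raise InvalidParameterError("E and A must be > 0")

    @property
    def k(self) -> float:
        return stiffness_from_EA(self.E, self.A)


@dataclass
class LigamentBundle:
    """A named bundle of point-to-point nonlinear springs.

    ``origins`` are femur-local attachment points, ``insertions`` tibia-local
    (the tibia is the fixed body so these are world coordinates).  The total
    stiffness of ``law`` is shared evenly by the springs; slack lengths are
    resolved per spring from the chord lengths at the assembly pose.
    """

    name: str
    origins: np.ndarray
    insertions: np.ndarray
    law: SpringLaw
    L_0: np.ndarray | None = field(default=None)
    L_r: np.ndarray | None = field(default=None)

    def __post_init__(self):
        self.origins = np.atleast_2d(np.asarray(self.origins, dtype=float))
        self.insertions = np.atleast_2d(np.asarray(self.insertions, dtype=float))
        if self.origins.shape != self.insertions.shape or self.origins.shape[1] != 3:
            raise InvalidParameterError("origins/insertions must be matching (n, 3) arrays")
        if len(self.origins) < 1:
            raise InvalidParameterError("a bundle needs at least one spring")
        chords = np.linalg.norm(self.origins - self.insertions, axis=1)
        if np.any(chords < 1e-12):
            raise InvalidParameterError("origin and insertion coincide for some spring")
        if self.L_0 is not None:
            self.L_0 = np.asarray(self.L_0, dtype=float)
        if self.L_r is not None:
            self.L_r = np.asarray(self.L_r, dtype=float)

    @property
    def n_springs(self) -> int:
        return len(self.origins)

    @property
    def per_spring_k(self) -> float:
        return distribute_stiffness(self.law.k, self.n_springs)

    def resolve_slack_lengths(self, transform=None):
        """Set per-spring slack lengths from chords at the assembly pose.

        ``transform`` is the 4x4 placement of the femur relative to the tibia
        (identity if omitted).  Chord lengths at this pose become the
        reference lengths ``L_r``; slack lengths follow from the bundle's
        reference prestrain.
        """
        L_r = self.current_lengths(transform)
        self.L_r = L_r
        self.L_0 = slack_length(L_r, self.law.eps_r)
        return self

    def current_lengths(self, transform=None) -> np.ndarray:
        pts = self.origins
        if transform is not None:
            T = np.asarray(transform, dtype=float)
            pts = pts @ T[:3, :3].T + T[:3, 3]
        return np.linalg.norm(pts - self.insertions, axis=1)

    def tensions(self, transform=None) -> np.ndarray:
        """Per-spring tensions (N) at the given femur placement."""
        if self.L_0 is None:
            raise InvalidParameterError(
                f"bundle {self.name!r} has unresolved slack lengths"
            )
        L = self.current_lengths(transform)
        eps = spring_strain(L, self.L_0)
        return blankevoort_force(eps, self.per_spring_k, self.law.eps_l)


def bundle_force(bundle: LigamentBundle, transform=None):
    """Net force, moment and per-spring tensions of a bundle on the femur.

    Each spring's tension acts along its current chord (femoral attachment
    toward tibial insertion); slack springs contribute nothing.  The moment
    is taken about the tibial frame origin.

    Returns
    -------
    (force, moment, tensions)
        Force (N) and moment (N*mm) vectors acting on the femur, plus the
        per-spring tension array.
    """
    T = np.eye(4) if transform is None else np.asarray(transform, dtype=float)
    world_origins = bundle.origins @ T[:3, :3].T + T[:3, 3]
    chord = bundle.insertions - world_origins
    L = np.linalg.norm(chord, axis=1)
    if np.any(L < 1e-12):
        raise NumericalDegeneracyError(
            f"bundle {bundle.name!r} has a zero-length spring chord"
        )
    tensions = bundle.tensions(T)
    unit = chord / L[:, None]
    forces = tensions[:, None] * unit
    net_force = forces.sum(axis=0)
    net_moment = np.cross(world_origins, forces).sum(axis=0)
    return net_force, net_moment, tensions
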