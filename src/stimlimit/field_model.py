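"""Static volume-conductor model of a current-injecting disk electrode.

The potential obeys ∇·(−σ∇V) = 0 in a homogeneous ohmic medium with the
stimulating disk as a current source and a distant return at ground;
E = −∇V. Two routes are provided:

* closed-form solutions (``analytic_disk_field``) for the idealized
  unbounded full-space / insulating half-space geometries, for both a
  uniform-current-density disk and an equipotential (primary-distribution)
  disk — these double as the oracle for the numerical solver;
* an axisymmetric finite-volume solver (``solve_field``) on a graded
  cylindrical grid with Neumann flux on the disk, an insulating array
  plane, and a grounded far boundary standing in for the distant return.

On-axis activation depth at a field criterion (default 1000 V/m) and its
inverse, the current required to reach a criterion field at a given height,
follow from either route by the linearity of the problem in I.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import ellipk

from .electrochem import ElectrodeGeometry
from .errors import DomainError, InvalidParameterError, SolverError

__all__ = [
    "VolumeConductorModel",
    "ActivationCriterion",
    "GridSpec",
    "FieldSolution",
    "analytic_disk_field",
    "solve_field",
    "activation_depth",
    "required_current",
]


@dataclass(frozen=True)
class VolumeConductorModel:
    """Geometry and conductivity of the passive medium.

    ``domain="sphere"`` mirrors the 18 mm conductive sphere with a distant
    return; ``domain="halfspace"`` is the semi-infinite medium above an
    insulating substrate plane. ``bc`` selects the disk boundary condition:
    fixed uniform current density ("uniform_j", the default) or an
    equipotential metal disk ("equipotential").
    """

    electrode: ElectrodeGeometry
    sigma_S_per_m: float = 0.2
    domain: Literal["sphere", "halfspace", "fullspace"] = "sphere"
    bc: Literal["uniform_j", "equipotential"] = "uniform_j"
    domain_diameter_mm: float = 18.0
    return_diameter_um: float = 200.0
    return_distance_mm: float = 7.5

    def __post_init__(self) -> None:
        if not self.sigma_S_per_m > 0:
            raise InvalidParameterError("conductivity must be positive")
        if self.electrode.radius_m >= 0.5 * self.domain_diameter_mm * 1e-3:
            raise InvalidParameterError("electrode does not fit inside the domain")

    @property
    def radius_m(self) -> float:
        return self.electrode.radius_m

    @property
    def solid_angle_factor(self) -> float:
        """2 for half-space (current confined above the insulating plane)."""
        return 2.0 if self.domain == "halfspace" else 1.0


@dataclass(frozen=True)
class ActivationCriterion:
    """Minimum field magnitude taken to elicit stimulation."""

    e_threshold_V_per_m: float = 1000.0
    pulse_width_s: float = 1e-3

    def __post_init__(self) -> None:
        if not self.e_threshold_V_per_m > 0:
            raise InvalidParameterError("e_threshold must be positive")


@dataclass(frozen=True)
class GridSpec:
    """Graded axisymmetric grid: fine cells across the disk, geometric
    coarsening out to the far boundary."""

    n_fine: int = 16          # cells across the electrode radius
    growth: float = 1.08      # geometric coarsening ratio
    extent_factor: float | None = None  # domain extent / radius; None = model

    def spacings(self, a: float, extent: float) -> np.ndarray:
        """1-D cell edges from 0 to `extent` for electrode radius `a`."""
        h = a / self.n_fine
        edges = [0.0]
        # uniform through 2 radii to resolve the rim singularity
        while edges[-1] < 2.0 * a - 0.5 * h:
            edges.append(edges[-1] + h)
        while edges[-1] < extent:
            h *= self.growth
            edges.append(edges[-1] + h)
        edges[-1] = extent
        return np.array(edges)


@dataclass
class FieldSolution:
    """Axisymmetric potential and field on the solver grid."""

    r_m: np.ndarray            # radial node coordinates
    z_m: np.ndarray            # axial node coordinates
    V: np.ndarray              # potential, shape (len(z), len(r))
    Emag: np.ndarray           # |E| in V/m, same shape
    current_A: float
    model: VolumeConductorModel

    @property
    def surface_current_density_A_m2(self) -> float:
        return self.current_A / (np.pi * self.model.radius_m**2)

    def on_axis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(z, V, |E|) profiles along the symmetry axis."""
        return self.z_m, self.V[:, 0], self.Emag[:, 0]


# ---------------------------------------------------------------------------
# Closed-form solutions
# ---------------------------------------------------------------------------

def _uniform_j_on_axis(a: float, sigma: float, I: float, z: np.ndarray):
    """Full-space uniform-current-density disk, on axis.

    V(z) = (I / 2πσa²)(√(z²+a²) − z);  E_z = (I / 2πσa²)(1 − z/√(z²+a²)).
    """
    k = I / (2.0 * np.pi * sigma * a**2)
    root = np.sqrt(z**2 + a**2)
    return k * (root - z), k * (1.0 - z / root)


def _uniform_j_potential(a: float, sigma: float, I: float, r: float, z: float) -> float:
    """Full-space uniform-J disk potential at (r, z) by elliptic quadrature."""
    if r == 0.0:
        return float(_uniform_j_on_axis(a, sigma, I, np.array([abs(z)]))[0][0])
    pref = I / (np.pi * a**2) / (4.0 * np.pi * sigma)

    def ring(rho: float) -> float:
        denom = np.sqrt((rho + r) ** 2 + z**2)
        m = 4.0 * rho * r / denom**2
        return rho * 4.0 * ellipk(m) / denom

    val, _ = quad(ring, 0.0, a, limit=200)
    return float(pref * val)


def _equipotential_potential(a: float, sigma: float, I: float, r: float, z: float) -> float:
    """Full-space equipotential-disk potential (oblate-spheroidal solution)."""
    za = abs(z)
    s = np.sqrt((r - a) ** 2 + za**2) + np.sqrt((r + a) ** 2 + za**2)
    return float(I / (2.0 * np.pi * sigma * a) * np.arcsin(2.0 * a / s) / 2.0)


def analytic_disk_field(
    model: VolumeConductorModel,
    I: float,
    point: tuple[float, float],
    *,
    grad_step: float | None = None,
) -> tuple[float, float, float]:
    """Closed-form (V, E_z, |E|) at ``point = (r, z)`` in meters.

    Uses the unbounded idealization of the model's geometry: full space for
    sphere mode (the 9 mm boundary is ~1800 radii away), doubled for
    half-space. ``z`` is height above the electrode plane. For the
    uniform-J variant the on-axis expressions are exact and off-axis values
    come from elliptic-integral quadrature; the equipotential variant is
    the oblate-spheroidal solution. Field components are exact on axis and
    obtained by central differences off axis.
    """
    r, z = point
    if z < 0:
        raise DomainError("point lies below the electrode plane (z < 0)")
    a = model.radius_m
    sigma = model.sigma_S_per_m
    factor = model.solid_angle_factor
    if I == 0.0:
        return 0.0, 0.0, 0.0

    if model.bc == "uniform_j":
        pot = _uniform_j_potential
    else:
        pot = _equipotential_potential

    V = factor * pot(a, sigma, I, abs(r), z)

    if r == 0.0 and model.bc == "uniform_j":
        _, ez = _uniform_j_on_axis(a, sigma, I, np.array([z]))
        e_z = factor * float(ez[0])
        return V, e_z, abs(e_z)
    if r == 0.0 and model.bc == "equipotential":
        e_z = factor * I / (4.0 * np.pi * sigma * (z**2 + a**2))
        return V, e_z, abs(e_z)

    h = grad_step if grad_step is not None else 1e-3 * a
    e_z = -factor * (pot(a, sigma, I, abs(r), z + h) - pot(a, sigma, I, abs(r), max(z - h, 0.0))) / (
        h + min(h, z)
    )
    e_r = -factor * (pot(a, sigma, I, abs(r) + h, z) - pot(a, sigma, I, max(abs(r) - h, 0.0), z)) / (
        h + min(h, abs(r))
    )
    return V, e_z, float(np.hypot(e_r, e_z))


# ---------------------------------------------------------------------------
# Finite-volume solver
# ---------------------------------------------------------------------------

def solve_field(
    model: VolumeConductorModel,
    I: float,
    grid: GridSpec | None = None,
) -> FieldSolution:
    """Axisymmetric finite-volume solution of ∇·(σ∇V) = 0.

    Discretizes the half-domain z ≥ 0 in cylindrical (r, z) on a graded
    tensor grid. Boundary conditions: prescribed flux J = I_half/(πa²)
    through the disk face at z = 0, zero flux on the rest of the plane
    (insulating substrate) and on the axis, V = 0 on the far boundary
    (the distant return). In sphere/full-space mode the plane z = 0 is a
    symmetry plane, so the half-domain carries I/2 and the solution equals
    the full-space field; in half-space mode it carries the full I.

    The disk itself always carries uniform current density; the
    ``equipotential`` variant is available analytically only.
    """
    grid = grid or GridSpec()
    a = model.radius_m
    sigma = model.sigma_S_per_m
    extent = (
        grid.extent_factor * a
        if grid.extent_factor is not None
        else 0.5 * model.domain_diameter_mm * 1e-3
    )
    if extent < 20 * a:
        raise InvalidParameterError("domain extent must be at least 20 electrode radii")
    if grid.n_fine < 5:
        raise InvalidParameterError("grid must resolve the electrode radius (n_fine >= 5)")

    r_edges = grid.spacings(a, extent)
    z_edges = grid.spacings(a, extent)
    r = 0.5 * (r_edges[:-1] + r_edges[1:])  # cell centers
    z = 0.5 * (z_edges[:-1] + z_edges[1:])
    # include boundary-adjacent representation by treating centers as nodes
    nr, nz = len(r), len(z)

    i_half = I / model.solid_angle_factor if model.domain != "halfspace" else I
    # note: solid_angle_factor is 1 for sphere/fullspace -> half-domain gets I/2
    if model.domain in ("sphere", "fullspace"):
        i_half = 0.5 * I

    # face areas (per full 2π revolution)
    rA = 2.0 * np.pi * r_edges  # radial faces: area = 2π r_face * dz
    zA = np.pi * (r_edges[1:] ** 2 - r_edges[:-1] ** 2)  # axial faces per cell ring

    dr_c = np.diff(r)  # center-to-center distances
    dz_c = np.diff(z)

    n = nr * nz

    def idx(iz: int, ir: int) -> int:
        return iz * nr + ir

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    b = np.zeros(n)

    dzs = np.diff(z_edges)

    def add(i: int, j: int, v: float) -> None:
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for iz in range(nz):
        for ir in range(nr):
            i0 = idx(iz, ir)
            diag = 0.0
            # radial neighbors
            if ir + 1 < nr:
                g = sigma * rA[ir + 1] * dzs[iz] / dr_c[ir]
                add(i0, idx(iz, ir + 1), -g)
                diag += g
            else:
                # Dirichlet V=0 at outer radial boundary (ghost at r_edges[-1])
                g = sigma * rA[-1] * dzs[iz] / (r_edges[-1] - r[-1])
                diag += g
            if ir > 0:
                g = sigma * rA[ir] * dzs[iz] / dr_c[ir - 1]
                add(i0, idx(iz, ir - 1), -g)
                diag += g
            # axis (ir == 0): zero-flux, nothing to add
            # axial neighbors
            if iz + 1 < nz:
                g = sigma * zA[ir] / dz_c[iz]
                add(i0, idx(iz + 1, ir), -g)
                diag += g
            else:
                g = sigma * zA[ir] / (z_edges[-1] - z[-1])
                diag += g
            if iz > 0:
                g = sigma * zA[ir] / dz_c[iz - 1]
                add(i0, idx(iz - 1, ir), -g)
                diag += g
            else:
                # plane z=0: insulating except the disk (Neumann source)
                lo, hi = r_edges[ir], r_edges[ir + 1]
                overlap = np.pi * (min(hi, a) ** 2 - min(lo, a) ** 2) if lo < a else 0.0
                if overlap > 0.0:
                    b[i0] += i_half * overlap / (np.pi * a**2)
            add(i0, i0, diag)

    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    try:
        V_flat = spla.spsolve(A, b)
    except Exception as exc:  # pragma: no cover - solver backend failure
        raise SolverError(f"sparse solve failed: {exc}") from exc

    residual = np.linalg.norm(A @ V_flat - b) / max(np.linalg.norm(b), 1e-300)
    if not np.isfinite(V_flat).all() or residual > 1e-8:
        raise SolverError(f"linear solve residual too large: {residual:.3g}")

    V = V_flat.reshape(nz, nr)
    if model.domain in ("sphere", "fullspace"):
        pass  # half-domain of the symmetric full-space problem: V already correct

    dVdz = np.gradient(V, z, axis=0)
    dVdr = np.gradient(V, r, axis=1)
    Emag = np.hypot(dVdr, dVdz)

    return FieldSolution(r_m=r, z_m=z, V=V, Emag=Emag, current_A=I, model=model)


# ---------------------------------------------------------------------------
# Activation depth and required current
# ---------------------------------------------------------------------------

def _on_axis_emag(model: VolumeConductorModel, I: float, z: float) -> float:
    return analytic_disk_field(model, I, (0.0, z))[2]


def activation_depth(
    model: VolumeConductorModel,
    I: float,
    criterion: ActivationCriterion | None = None,
    *,
    solution: FieldSolution | None = None,
    tol_m: float = 1e-8,
) -> tuple[float, str]:
    """Largest on-axis height z with |E| ≥ threshold, in meters.

    Uses bisection on the closed-form field, or linear interpolation on the
    on-axis profile of a supplied numerical ``solution``. Returns
    ``(depth, status)``; a current too small to reach the criterion
    anywhere gives ``(0.0, "subthreshold")``.
    """
    criterion = criterion or ActivationCriterion()
    eth = criterion.e_threshold_V_per_m

    if solution is not None:
        zax, _, eax = solution.on_axis()
        above = eax >= eth
        if not above.any():
            return 0.0, "subthreshold"
        k = int(np.nonzero(above)[0][-1])
        if k + 1 >= len(zax):
            return float(zax[-1]), "ok"
        z0, z1 = zax[k], zax[k + 1]
        e0, e1 = eax[k], eax[k + 1]
        depth = z0 + (e0 - eth) / (e0 - e1) * (z1 - z0)
        return float(depth), "ok"

    if I == 0.0 or _on_axis_emag(model, I, 0.0) < eth:
        return 0.0, "subthreshold"
    # bracket: expand until below threshold
    z_hi = 2.0 * model.radius_m
    while _on_axis_emag(model, I, z_hi) >= eth:
        z_hi *= 2.0
        if z_hi > 1.0:  # 1 m: criterion unreachable in practice
            raise InvalidParameterError("activation depth bracket exceeded 1 m")
    depth = brentq(
        lambda zz: _on_axis_emag(model, I, zz) - eth, 0.0, z_hi, xtol=tol_m
    )
    return float(depth), "ok"


def required_current(
    z: float,
    model: VolumeConductorModel,
    criterion: ActivationCriterion | None = None,
) -> float:
    """Current (A) producing the criterion field at on-axis height z.

    By linearity, I_req = E_threshold / |E|(z; I = 1 A).
    """
    criterion = criterion or ActivationCriterion()
    if z < 0:
        raise DomainError("z must be non-negative")
    e_unit = _on_axis_emag(model, 1.0, z)
    return float(criterion.e_threshold_V_per_m / e_unit)


def required_current_curve(
    model: VolumeConductorModel,
    z_m: np.ndarray,
    criterion: ActivationCriterion | None = None,
    *,
    i_max_A: float | None = None,
) -> np.ndarray:
    """Vectorized required-current curve, optionally truncated at the
    CIC-limited current for the criterion's phase width (NaN above it)."""
    out = np.array([required_current(float(zz), model, criterion) for zz in z_m])
    if i_max_A is not None:
        out = np.where(out <= i_max_A, out, np.nan)
    return out
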