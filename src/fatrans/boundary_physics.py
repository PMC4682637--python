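"""Binding equilibria and water-phospholipid boundary-zone permeability.

Free fatty acid (Fa) is the concentration potential for all diffusive
transfer.  In each aqueous compartment Fa binds a carrier protein Cp
(albumin or FABP) by mass action,

    [Fa][Cp] = K_CpFa [CpFa],

and the complex carries nearly all of the diffusive flux.  Next to a
membrane the complex cannot enter the lipid, so within a thin boundary zone
the flux hands over from CpFa to free Fa.  Linearizing the steady
reaction-diffusion system in the total flux gives an exponential hand-over
with decay length

    d_Fa = sqrt(D_Fa K_CpFa tau_CpFa / [Cp]0),

and an effective boundary permeability

    P_b = (1 + alpha) (1 - exp(-h/d_Fa)) (D_Fa/d_Fa) (1 + d_Cp/d_Fa),

where the d_Cp/d_Fa term is the "contact pathway": direct delivery of Fa
from CpFa touching the membrane, parameterized by the membrane reaction
rate length d_Cp.  The contact pathway is equivalent to shifting the
membrane face to x_b = -d_Fa ln(1 + d_Cp/d_Fa).

All quantities are SI (m, s, mol m^-3); note mmol l^-1 == mol m^-3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "CompartmentSpec",
    "MembraneSpec",
    "BindingState",
    "BoundaryZone",
    "BoundaryProfiles",
    "equilibrium_free_fa",
    "decay_length",
    "alpha_ratio",
    "boundary_shift",
    "boundary_zone",
    "boundary_profiles",
    "boundary_bvp_oracle",
    "boundary_permeability",
    "aqueous_permeability",
    "membrane_permeability",
    "series_permeability",
    "compartment_storage",
    "membrane_storage",
]

CompartmentName = Literal["cap", "ec", "is1", "myo"]
MembraneName = Literal["cap_ec", "ec_is1", "is1_myo"]


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be positive, got {value!r}")


def _require_nonnegative(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value < 0:
            raise ValueError(f"{name} must be nonnegative, got {value!r}")


@dataclass(frozen=True)
class CompartmentSpec:
    """Physicochemical parameters of one aqueous compartment.

    Parameters
    ----------
    name : {"cap", "ec", "is1", "myo"}
    D_Fa : free-Fa diffusion coefficient [m^2 s^-1].
    D_Cp : carrier-protein (and CpFa complex) diffusion coefficient [m^2 s^-1].
    K_CpFa : binding equilibrium constant [mol m^-3].
    tau_CpFa : CpFa dissociation time constant [s].
    Cp_total : total binding-site concentration [mol m^-3]; for albumin
        compartments this is n_Alb * [Alb] with n_Alb = 3.
    volume_fraction : compartment volume over total tissue volume.
    h_diff : effective diffusion thickness [m]; required for the thin, flat
        ec and is1 compartments.
    """

    name: CompartmentName
    D_Fa: float
    D_Cp: float
    K_CpFa: float
    tau_CpFa: float
    Cp_total: float
    volume_fraction: float
    h_diff: float | None = None

    def __post_init__(self) -> None:
        _require_positive(
            D_Fa=self.D_Fa,
            D_Cp=self.D_Cp,
            K_CpFa=self.K_CpFa,
            tau_CpFa=self.tau_CpFa,
            Cp_total=self.Cp_total,
        )
        if not 0 < self.volume_fraction < 1:
            raise ValueError("volume_fraction must be in (0, 1)")
        if self.name in ("ec", "is1") and self.h_diff is None:
            raise ValueError(f"h_diff is required for compartment {self.name!r}")
        if self.h_diff is not None:
            _require_positive(h_diff=self.h_diff)


@dataclass(frozen=True)
class MembraneSpec:
    """One phospholipid bilayer separating two aqueous compartments.

    S_per_Vall is the membrane surface density [m^2 per m^3 tissue], h_mem
    the bilayer thickness, C_lipid the lipid/water partition coefficient of
    Fa, D_mem the intramembrane Fa diffusion coefficient, and d_Cp_left /
    d_Cp_right the membrane reaction rate length on each face (a larger
    value emulates a transfer-facilitating membrane protein).
    """

    name: MembraneName
    S_per_Vall: float
    h_mem: float = 5e-9
    C_lipid: float = 8e5
    D_mem: float = 4e-12
    d_Cp_left: float = 5e-9
    d_Cp_right: float = 5e-9

    def __post_init__(self) -> None:
        _require_positive(
            S_per_Vall=self.S_per_Vall,
            h_mem=self.h_mem,
            C_lipid=self.C_lipid,
            D_mem=self.D_mem,
        )
        _require_nonnegative(d_Cp_left=self.d_Cp_left, d_Cp_right=self.d_Cp_right)

    @property
    def P_mem(self) -> float:
        """Intrinsic bilayer permeability C_lipid * D_mem / h_mem [m s^-1]."""
        return membrane_permeability(self.C_lipid, self.D_mem, self.h_mem)


@dataclass(frozen=True)
class BindingState:
    """Mass-action equilibrium of Fa, Cp and the CpFa complex [mol m^-3]."""

    Fa_free: float
    Cp_free: float
    CpFa: float

    @property
    def Fa_total(self) -> float:
        return self.Fa_free + self.CpFa

    @property
    def Cp_total(self) -> float:
        return self.Cp_free + self.CpFa


@dataclass(frozen=True)
class BoundaryZone:
    """Derived boundary-zone quantities for one membrane face."""

    d_Fa: float  # exponential decay length [m]
    alpha: float  # free vs carrier-mediated diffusion far from the boundary
    x_b: float  # virtual boundary shift [m], <= 0
    P_b: float  # boundary-zone permeability [m s^-1]


def equilibrium_free_fa(Cp_total: float, Fa_total: float, K_CpFa: float) -> BindingState:
    """Solve the mass-action equilibrium for given totals.

    Returns the unique nonnegative root of
    (Fa_total - b)(Cp_total - b) = K_CpFa * b for the bound concentration b.
    """
    _require_nonnegative(Cp_total=Cp_total, Fa_total=Fa_total)
    _require_positive(K_CpFa=K_CpFa)
    free = free_fa_from_total(Cp_total, Fa_total, K_CpFa)
    # cancellation-safe partition of the carrier: Cp_free/Cp_total = K/(K+u),
    # CpFa/Cp_total = u/(K+u) -- no subtractions, so both tails stay accurate
    denom = K_CpFa + free
    return BindingState(
        Fa_free=free,
        Cp_free=Cp_total * K_CpFa / denom,
        CpFa=Cp_total * free / denom,
    )


def free_fa_from_total(Cp_total: float, Fa_total: float, K_CpFa: float):
    """Free [Fa] from the binding quadratic; accepts scalars or arrays.

    u^2 + u (Cp_total - Fa_total + K) - K Fa_total = 0, taking the
    nonnegative root in a cancellation-safe form.
    """
    b = Cp_total - np.asarray(Fa_total) + K_CpFa
    c = -K_CpFa * np.asarray(Fa_total)
    disc = np.sqrt(b * b - 4.0 * c)
    # root = (-b + disc)/2; rewrite as -2c/(b + disc) when b > 0 to avoid
    # catastrophic cancellation (free Fa is ~1e-5 of the totals here).
    u = np.where(b > 0, -2.0 * c / (b + disc), 0.5 * (-b + disc))
    if np.ndim(Fa_total) == 0 and np.ndim(Cp_total) == 0:
        return float(u)
    return u


def dfree_dtotal(Cp_total: float, Fa_total: float, K_CpFa: float):
    """d(free Fa)/d(total Fa) at fixed Cp_total (implicit differentiation)."""
    u = free_fa_from_total(Cp_total, Fa_total, K_CpFa)
    b = Cp_total - np.asarray(Fa_total) + K_CpFa
    disc = np.sqrt(b * b + 4.0 * K_CpFa * np.asarray(Fa_total))
    return (u + K_CpFa) / disc


def decay_length(D_Fa: float, K_CpFa: float, tau_CpFa: float, Cp0_free: float) -> float:
    """Exponential decay length d_Fa of the free-Fa disturbance [m].

    d_Fa = sqrt(D_Fa K_CpFa tau_CpFa / [Cp]0): the classic reaction-diffusion
    boundary-layer length sqrt(D_Fa / k_on') with pseudo-first-order rebinding
    rate k_on' = [Cp]0 / (K_CpFa tau_CpFa).
    """
    _require_positive(D_Fa=D_Fa, K_CpFa=K_CpFa, tau_CpFa=tau_CpFa, Cp0_free=Cp0_free)
    return math.sqrt(D_Fa * K_CpFa * tau_CpFa / Cp0_free)


def alpha_ratio(
    D_Fa: float, K_CpFa: float, Cp_total: float, D_Cp: float, Cp0_free: float
) -> float:
    """Free-Fa over carrier-mediated diffusion far from the boundary.

    alpha = D_Fa K_CpFa [Cp_tot] / (D_Cp [Cp]0^2); much smaller than 1
    whenever the carrier dominates transport (in plasma < 0.002).
    """
    if D_Fa == 0:
        return 0.0
    _require_positive(
        D_Fa=D_Fa, K_CpFa=K_CpFa, Cp_total=Cp_total, D_Cp=D_Cp, Cp0_free=Cp0_free
    )
    return D_Fa * K_CpFa * Cp_total / (D_Cp * Cp0_free**2)


def boundary_shift(d_Fa: float, d_Cp: float) -> float:
    """Virtual boundary shift x_b = -d_Fa ln(1 + d_Cp/d_Fa) [m], <= 0."""
    _require_positive(d_Fa=d_Fa)
    _require_nonnegative(d_Cp=d_Cp)
    return -d_Fa * math.log1p(d_Cp / d_Fa)


def boundary_zone(spec: CompartmentSpec, Cp0_free: float, d_Cp: float, h: float) -> BoundaryZone:
    """All derived boundary quantities for one face of a membrane."""
    d = decay_length(spec.D_Fa, spec.K_CpFa, spec.tau_CpFa, Cp0_free)
    a = alpha_ratio(spec.D_Fa, spec.K_CpFa, spec.Cp_total, spec.D_Cp, Cp0_free)
    return BoundaryZone(
        d_Fa=d,
        alpha=a,
        x_b=boundary_shift(d, d_Cp),
        P_b=boundary_permeability(spec, Cp0_free, d_Cp, h),
    )


def boundary_permeability(
    spec: CompartmentSpec,
    Cp0_free: float,
    d_Cp: float,
    h: float,
    *,
    approximate: bool = False,
) -> float:
    """Boundary-zone permeability P_b [m s^-1].

    Full form (default):
        P_b = (1+alpha)(1 - exp(-h/d_Fa)) (D_Fa/d_Fa)(1 + d_Cp/d_Fa)
    with ``approximate=True`` the common short form (alpha << 1, h >> d_Fa):
        P_b ~= (D_Fa/d_Fa)(1 + d_Cp/d_Fa).
    """
    _require_positive(h=h)
    _require_nonnegative(d_Cp=d_Cp)
    d = decay_length(spec.D_Fa, spec.K_CpFa, spec.tau_CpFa, Cp0_free)
    base = (spec.D_Fa / d) * (1.0 + d_Cp / d)
    if approximate:
        return base
    a = alpha_ratio(spec.D_Fa, spec.K_CpFa, spec.Cp_total, spec.D_Cp, Cp0_free)
    return (1.0 + a) * (-math.expm1(-h / d)) * base


def aqueous_permeability(
    h: float, D_Fa: float, D_Cp: float, K_CpFa: float, Cp0_free: float, Cp_total: float
) -> float:
    """Permeability of an aqueous layer of thickness h [m s^-1].

    P_aqu = (D_Fa + D_Cp [Cp]0^2 / (K_CpFa [Cp_tot])) / h; the second term
    is carrier-mediated diffusion, referenced to the free-Fa potential.
    """
    _require_positive(h=h, D_Fa=D_Fa, D_Cp=D_Cp, K_CpFa=K_CpFa, Cp_total=Cp_total)
    _require_nonnegative(Cp0_free=Cp0_free)
    return (D_Fa + D_Cp * Cp0_free**2 / (K_CpFa * Cp_total)) / h


def membrane_permeability(C_lipid: float, D_mem: float, h_mem: float) -> float:
    """Intrinsic bilayer permeability P_mem = C_lipid D_mem / h_mem [m s^-1]."""
    _require_positive(C_lipid=C_lipid, D_mem=D_mem, h_mem=h_mem)
    return C_lipid * D_mem / h_mem


def series_permeability(perms) -> float:
    """Composite permeability of layers in series: 1 / sum(1/P_i)."""
    perms = list(perms)
    if not perms:
        raise ValueError("series_permeability needs at least one permeability")
    for p in perms:
        if not p > 0:
            raise ValueError(f"permeabilities must be positive, got {p!r}")
    return 1.0 / sum(1.0 / p for p in perms)


def compartment_storage(Cp_free: float, K_CpFa: float, volume_fraction: float) -> float:
    """Dimensionless Fa storage capacity of an aqueous compartment.

    V_Fa,c / V_all ~= [Cp] (V_c/V_all) / K_CpFa: the compartment stores
    bound Fa in proportion to its free-carrier concentration.
    """
    _require_nonnegative(Cp_free=Cp_free)
    _require_positive(K_CpFa=K_CpFa, volume_fraction=volume_fraction)
    return Cp_free * volume_fraction / K_CpFa


def membrane_storage(C_lipid: float, S_per_Vall: float, h_mem: float) -> float:
    """Dimensionless Fa storage capacity of a membrane: C_lipid S h / V_all."""
    _require_positive(C_lipid=C_lipid, h_mem=h_mem)
    _require_nonnegative(S_per_Vall=S_per_Vall)
    return C_lipid * S_per_Vall * h_mem


# ---------------------------------------------------------------------------
# Boundary-zone concentration/flux profiles (analytic and numerical oracle)
# ---------------------------------------------------------------------------


@dataclass
class BoundaryProfiles:
    """Profiles in the boundary zone; fluid occupies x <= 0."""

    x: np.ndarray  # position [m], <= 0, membrane face at x_b
    CpFa: np.ndarray  # complex concentration [mol m^-3]
    Fa: np.ndarray  # free Fa concentration [mol m^-3]
    phi_CpFa: np.ndarray  # complex-borne flux [mol m^-2 s^-1]
    phi_Fa: np.ndarray  # free-Fa flux [mol m^-2 s^-1]
    d_Fa: float = 0.0
    alpha: float = 0.0
    x_b: float = 0.0


def boundary_profiles(
    spec: CompartmentSpec,
    Cp0_free: float,
    flux_total: float,
    x_grid: np.ndarray,
    d_Cp: float = 0.0,
) -> BoundaryProfiles:
    """Analytic first-order (in flux) boundary-zone profiles.

    phi_CpFa(x) = flux_total (1 - e^{x/d_Fa}) / (1 + alpha)
    [CpFa](x)   = [Cp_tot] - [Cp]0 + flux_total(-x + d_Fa e^{x/d_Fa}) / (D_Cp (1+alpha))
    [Fa](x)     = K([Cp_tot]/[Cp]0 - 1) - flux_total (d_Fa e^{x/d_Fa} + alpha x)
                  / ((1+alpha) D_Fa)

    With the contact pathway active the physical membrane face sits at
    x_b = -d_Fa ln(1 + d_Cp/d_Fa); the remaining complex flux there is
    delivered by direct CpFa-membrane contact.
    """
    x = np.asarray(x_grid, dtype=float)
    if np.any(x > 0):
        raise ValueError("x_grid must satisfy x <= 0 (fluid side)")
    d = decay_length(spec.D_Fa, spec.K_CpFa, spec.tau_CpFa, Cp0_free)
    a = alpha_ratio(spec.D_Fa, spec.K_CpFa, spec.Cp_total, spec.D_Cp, Cp0_free)
    ex = np.exp(x / d)
    phi_c = flux_total * (1.0 - ex) / (1.0 + a)
    cpfa = spec.Cp_total - Cp0_free + flux_total * (-x + d * ex) / (spec.D_Cp * (1.0 + a))
    fa_eq = spec.K_CpFa * (spec.Cp_total / Cp0_free - 1.0)
    fa = fa_eq - flux_total * (d * ex + a * x) / ((1.0 + a) * spec.D_Fa)
    return BoundaryProfiles(
        x=x,
        CpFa=cpfa,
        Fa=fa,
        phi_CpFa=phi_c,
        phi_Fa=flux_total - phi_c,
        d_Fa=d,
        alpha=a,
        x_b=boundary_shift(d, d_Cp),
    )


def boundary_bvp_oracle(
    spec: CompartmentSpec,
    Cp0_free: float,
    flux_total: float,
    d_Cp: float = 0.0,
    h: float | None = None,
    n_nodes: int = 2000,
) -> BoundaryProfiles:
    """Finite-difference Newton solution of the boundary-zone BVP.

    Independent numerical solution of the full (nonlinear in concentrations)
    coupled steady reaction-diffusion system

        D_Fa  [Fa]''   = +r,   D_Cp [CpFa]'' = -r,
        r = ([Cp][Fa] - K [CpFa]) / (K tau),   [Cp] = [Cp_tot] - [CpFa],

    on x in [-h, 0] (membrane face at x = 0, so positions correspond to the
    analytic convention shifted by x_b).  Boundary conditions: far-field
    bulk values at x = -h (equilibrium plus the first-order linear ramps of
    the imposed flux), and at the membrane the total-flux condition together
    with the contact-pathway condition

        phi_CpFa(0) = -D_Cp [CpFa]'(0) = -d_Cp * r(0),

    i.e. the complex flux delivered by direct contact is proportional to the
    local excess of dissociation over association (zero for the pure detach
    pathway).  This sign reproduces the virtual-shift identity
    x_b = -d_Fa ln(1 + d_Cp/d_Fa).

    Used only as a cross-check in tests.
    """
    d = decay_length(spec.D_Fa, spec.K_CpFa, spec.tau_CpFa, Cp0_free)
    if h is None:
        h = 20.0 * d
    if n_nodes < 100:
        raise ValueError("n_nodes must be >= 100")
    if h < 10.0 * d:
        raise ValueError("h must be >= 10 * d_Fa for a clean far field")

    from scipy.sparse import lil_matrix
    from scipy.sparse.linalg import spsolve

    x = np.linspace(-h, 0.0, n_nodes)
    dx = x[1] - x[0]
    n = n_nodes
    K, tau, Ctot = spec.K_CpFa, spec.tau_CpFa, spec.Cp_total
    DF, DC = spec.D_Fa, spec.D_Cp
    ktau = K * tau
    fa_eq = K * (Ctot / Cp0_free - 1.0)
    cpfa_eq = Ctot - Cp0_free
    a = alpha_ratio(DF, K, Ctot, DC, Cp0_free)

    u_bc = fa_eq + flux_total * a * h / ((1.0 + a) * DF)
    w_bc = cpfa_eq + flux_total * h / (DC * (1.0 + a))

    u = np.full(n, fa_eq)
    w = np.full(n, cpfa_eq)
    c0, c1, c2 = 1.5 / dx, -2.0 / dx, 0.5 / dx  # one-sided derivative at x=0

    def residual(u, w):
        r = ((Ctot - w) * u - K * w) / ktau
        F = np.zeros(2 * n)
        F[0] = u[0] - u_bc
        F[n] = w[0] - w_bc
        lap_u = (u[:-2] - 2 * u[1:-1] + u[2:]) / dx**2
        lap_w = (w[:-2] - 2 * w[1:-1] + w[2:]) / dx**2
        F[1 : n - 1] = DF * lap_u - r[1:-1]
        F[n + 1 : 2 * n - 1] = DC * lap_w + r[1:-1]
        du0 = c0 * u[-1] + c1 * u[-2] + c2 * u[-3]
        dw0 = c0 * w[-1] + c1 * w[-2] + c2 * w[-3]
        F[n - 1] = -DF * du0 - DC * dw0 - flux_total
        F[2 * n - 1] = -DC * dw0 + d_Cp * r[-1]
        return F

    for it in range(30):
        F = residual(u, w)
        if np.max(np.abs(F)) == 0.0:
            break
        J = lil_matrix((2 * n, 2 * n))
        dr_du = (Ctot - w) / ktau
        dr_dw = (-u - K) / ktau
        J[0, 0] = 1.0
        J[n, n] = 1.0
        for i in range(1, n - 1):
            J[i, i - 1] = DF / dx**2
            J[i, i] = -2 * DF / dx**2 - dr_du[i]
            J[i, i + 1] = DF / dx**2
            J[i, n + i] = -dr_dw[i]
            J[n + i, n + i - 1] = DC / dx**2
            J[n + i, n + i] = -2 * DC / dx**2 + dr_dw[i]
            J[n + i, n + i + 1] = DC / dx**2
            J[n + i, i] = dr_du[i]
        for k, ck in zip((n - 1, n - 2, n - 3), (c0, c1, c2)):
            J[n - 1, k] = -DF * ck
            J[n - 1, n + k] = -DC * ck
            J[2 * n - 1, n + k] = -DC * ck
        J[2 * n - 1, n - 1] += d_Cp * dr_du[-1]
        J[2 * n - 1, 2 * n - 1] += d_Cp * dr_dw[-1]
        step = spsolve(J.tocsc(), -F)
        if not np.all(np.isfinite(step)):
            raise ArithmeticError("boundary BVP Newton step is non-finite")
        u = u + step[:n]
        w = w + step[n:]
        scale = max(abs(fa_eq), abs(flux_total) * d / DF, 1e-300)
        if np.max(np.abs(step[:n])) < 1e-12 * scale:
            break
    else:
        raise ArithmeticError(
            f"boundary BVP Newton did not converge; last residual {np.max(np.abs(F)):.3e}"
        )

    phi_fa = -DF * np.gradient(u, dx, edge_order=2)
    phi_cpfa = -DC * np.gradient(w, dx, edge_order=2)
    return BoundaryProfiles(
        x=x,
        CpFa=w,
        Fa=u,
        phi_CpFa=phi_cpfa,
        phi_Fa=phi_fa,
        d_Fa=d,
        alpha=a,
        x_b=boundary_shift(d, d_Cp),
    )
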