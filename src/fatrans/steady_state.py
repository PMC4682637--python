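"""Stationary nonlinear Fa transport and metabolic-rate tuning.

Unlabeled Fa enters the capillary bound to albumin, is advected along z,
exchanges with the endothelium (ec), pericapillary interstitium (is1) and
the cardiomyocyte pool (myo, a single well-mixed state because a myocyte is
shared by several capillaries), and is consumed in myo by a lumped
first-order sink g_met = R_met * A_myo * [Fa]_myo.

At steady state the thin ec/is1 compartments carry the trans-membrane flux
unchanged (no storage term), so at every z the chain

    g(z) = ([Fa]_cap(z) - [Fa]_myo) / (1/G1 + 1/G2 + 1/G3),
    G_m(z) = P_mem,composite(z) * dS_mem/dz,

holds, with each composite permeability the series combination of two
boundary-zone permeabilities and the bilayer itself.  The permeabilities
depend on the free carrier concentrations, which in turn depend on the Fa
fields, giving a mildly nonlinear fixed point solved by damped outer
iteration.  The converged state freezes all permeabilities for the linear
tracer system.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from fatrans.boundary_physics import (
    CompartmentSpec,
    MembraneSpec,
    aqueous_permeability,
    boundary_permeability,
    free_fa_from_total,
)
from fatrans.capillary_geometry import ZGrid, make_z_grid
from fatrans.config import ModelConfig

logger = logging.getLogger(__name__)

__all__ = ["SteadyState", "solve_steady_state", "tune_metabolic_rate"]

_MEMBRANES = ("cap_ec", "ec_is1", "is1_myo")
_SIDES = {"cap_ec": ("cap", "ec"), "ec_is1": ("ec", "is1"), "is1_myo": ("is1", "myo")}


@dataclass
class SteadyState:
    """Converged stationary state on the z-grid.

    Concentrations are mol m^-3; free carrier concentrations are per cell
    (myo entries are broadcast copies of the single myo value).
    """

    config: ModelConfig
    grid: ZGrid
    compartments: dict[str, CompartmentSpec]
    membranes: dict[str, MembraneSpec]
    R_met: float
    extraction: float
    cap_Fa_total: np.ndarray
    free_Fa: dict[str, np.ndarray]  # per compartment, per cell
    free_Cp: dict[str, np.ndarray]
    is2_free_Cp: float
    P_b: dict[tuple[str, str], np.ndarray]  # (membrane, compartment face)
    P_composite: dict[str, np.ndarray]
    P_aqu: dict[str, np.ndarray]
    g_exchange: np.ndarray  # mol s^-1 per m^3 tissue, per cell
    inflow: float
    outflow: float
    n_outer: int = 0

    @property
    def myo_free_Fa(self) -> float:
        return float(self.free_Fa["myo"][0])

    def conductances(self) -> dict[str, np.ndarray]:
        """Per-cell exchange conductances G_m = P_composite * dS_m [m^3 s^-1]."""
        w = self.grid.cell_fraction()
        return {
            m: self.P_composite[m] * self.membranes[m].S_per_Vall * w for m in _MEMBRANES
        }

    def mass_residual(self) -> float:
        """|inflow - outflow - metabolism| / inflow."""
        met = self.R_met * self.compartments["myo"].volume_fraction * self.myo_free_Fa
        return abs(self.inflow - self.outflow - met) / self.inflow

    def tracer_free_fraction(self, name: str) -> np.ndarray:
        """Labeled free / labeled total = K / (K + [Cp_free]) per cell."""
        K = self.compartments[name].K_CpFa
        return K / (K + self.free_Cp[name])

    def to_json(self, path=None) -> str:
        """Serialize the converged state (scalars + z-profiles) to JSON."""
        import json

        payload = {
            "R_met_per_s": self.R_met,
            "extraction": self.extraction,
            "inflow": self.inflow,
            "outflow": self.outflow,
            "is2_free_Cp": self.is2_free_Cp,
            "n_outer": self.n_outer,
            "z_m": self.grid.z.tolist(),
            "cap_Fa_total": self.cap_Fa_total.tolist(),
            "free_Fa": {k: v.tolist() for k, v in self.free_Fa.items()},
            "free_Cp": {k: v.tolist() for k, v in self.free_Cp.items()},
            "P_composite": {k: v.tolist() for k, v in self.P_composite.items()},
            "P_aqu": {k: v.tolist() for k, v in self.P_aqu.items()},
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text

    def storage_table(self):
        """Per-compartment and per-membrane storage capacities (z-averaged Cp)."""
        import pandas as pd

        from fatrans.boundary_physics import compartment_storage, membrane_storage

        rows = []
        for name, spec in self.compartments.items():
            rows.append(
                {
                    "item": name,
                    "kind": "compartment",
                    "P_aqu_m_per_s": float(np.mean(self.P_aqu[name])),
                    "storage_V_Fa_over_V_all": compartment_storage(
                        float(np.mean(self.free_Cp[name])), spec.K_CpFa, spec.volume_fraction
                    ),
                }
            )
        for name, mem in self.membranes.items():
            rows.append(
                {
                    "item": name,
                    "kind": "membrane",
                    "P_composite_m_per_s": float(np.mean(self.P_composite[name])),
                    "storage_V_Fa_over_V_all": membrane_storage(
                        mem.C_lipid, mem.S_per_Vall, mem.h_mem
                    ),
                }
            )
        return pd.DataFrame(rows)


def _free_cp_from_free_fa(spec: CompartmentSpec, fa_free) -> np.ndarray:
    """Free carrier when the free ligand concentration is fa_free."""
    return spec.Cp_total * spec.K_CpFa / (spec.K_CpFa + np.asarray(fa_free, dtype=float))


def _permeabilities(cfg, comps, mems, free_Cp):
    """Boundary-face, composite and aqueous permeabilities for given free Cp."""
    P_b: dict[tuple[str, str], np.ndarray] = {}
    P_comp: dict[str, np.ndarray] = {}
    for m in _MEMBRANES:
        left, right = _SIDES[m]
        mem = mems[m]
        pl = np.array(
            [
                boundary_permeability(
                    comps[left], c, mem.d_Cp_left, cfg.boundary_layer_thickness(left)
                )
                for c in np.atleast_1d(free_Cp[left])
            ]
        )
        pr = np.array(
            [
                boundary_permeability(
                    comps[right], c, mem.d_Cp_right, cfg.boundary_layer_thickness(right)
                )
                for c in np.atleast_1d(free_Cp[right])
            ]
        )
        P_b[(m, left)] = pl
        P_b[(m, right)] = pr
        P_comp[m] = 1.0 / (1.0 / pl + 1.0 / mem.P_mem + 1.0 / pr)
    P_aqu = {
        name: np.array(
            [
                aqueous_permeability(
                    cfg.boundary_layer_thickness(name),
                    comps[name].D_Fa,
                    comps[name].D_Cp,
                    comps[name].K_CpFa,
                    c,
                    comps[name].Cp_total,
                )
                for c in np.atleast_1d(free_Cp[name])
            ]
        )
        for name in comps
    }
    return P_b, P_comp, P_aqu


def _march_capillary(grid, cap_spec, G_series, C_in, u_myo):
    """Upwind finite-volume sweep: q_i (C_{i-1} - C_i) = G_i (u(C_i) - u_myo).

    Newton per cell on the binding quadratic, with a bisection fallback.
    Returns cell totals C, free u, and exchange fluxes g [mol/s per m^3].
    """
    n = grid.n
    C = np.empty(n)
    u = np.empty(n)
    g = np.empty(n)
    K = cap_spec.K_CpFa
    Ct = cap_spec.Cp_total
    qf = grid.q_faces
    C_prev = C_in
    for i in range(n):
        q = qf[i]
        G = G_series[i]

        def F(c):
            return q * (c - C_prev) + G * (free_fa_from_total(Ct, c, K) - u_myo)

        # Newton from the upstream value
        c = C_prev
        ok = False
        for _ in range(60):
            b = Ct - c + K
            disc = math.sqrt(b * b + 4.0 * K * c)
            ufree = 2.0 * K * c / (b + disc) if b > 0 else 0.5 * (-b + disc)
            dfree = (ufree + K) / disc
            f = q * (c - C_prev) + G * (ufree - u_myo)
            df = q + G * dfree
            step = f / df
            c_new = c - step
            if c_new < 0:
                c_new = 0.5 * c
            if abs(c_new - c) <= 1e-15 * max(abs(c), C_in, 1e-300):
                c = c_new
                ok = True
                break
            c = c_new
        if not ok:
            lo, hi = 0.0, max(C_prev, Ct * u_myo / (K + u_myo) + u_myo) * 2 + 1e-30
            c = brentq(F, lo, hi, xtol=1e-18, rtol=8.9e-16)
        C[i] = c
        u[i] = free_fa_from_total(Ct, c, K)
        g[i] = q * (C_prev - c)
        C_prev = c
    return C, u, g


def solve_steady_state(
    config: ModelConfig,
    R_met: float,
    grid: ZGrid | None = None,
    warm_start: dict[str, np.ndarray] | None = None,
) -> SteadyState:
    """Solve the stationary nonlinear transport problem at fixed R_met."""
    if R_met < 0:
        raise ValueError("R_met must be >= 0")
    cfg = config
    comps = {name: cfg.compartment_spec(name) for name in ("cap", "ec", "is1", "myo")}
    mems = {name: cfg.membrane_spec(name) for name in _MEMBRANES}
    grid = grid if grid is not None else make_z_grid(cfg.bed_spec(), cfg.numerics.n_z, cfg.numerics.area_cutoff)
    n = grid.n

    C_in = cfg.experiment.inlet_Fa_total
    if C_in >= comps["cap"].Cp_total:
        logger.warning(
            "inlet Fa total %.3g exceeds albumin binding sites %.3g; free Fa will be high",
            C_in,
            comps["cap"].Cp_total,
        )
    u_in = free_fa_from_total(comps["cap"].Cp_total, C_in, comps["cap"].K_CpFa)

    # initial guess: everything equilibrated with the inlet free Fa
    free_Cp = warm_start.copy() if warm_start else {
        name: _free_cp_from_free_fa(comps[name], np.full(n, u_in)) for name in comps
    }

    V_myo = comps["myo"].volume_fraction
    w = grid.cell_fraction()
    damping = cfg.numerics.damping
    tol = cfg.numerics.steady_tol

    C = u_cap = g = None
    u_comp: dict[str, np.ndarray] = {}
    for outer in range(cfg.numerics.max_outer):
        P_b, P_comp, P_aqu = _permeabilities(cfg, comps, mems, free_Cp)
        G = {m: P_comp[m] * mems[m].S_per_Vall * w for m in _MEMBRANES}
        G_series = 1.0 / (1.0 / G["cap_ec"] + 1.0 / G["ec_is1"] + 1.0 / G["is1_myo"])

        def net_uptake(u_myo):
            _, _, g_ = _march_capillary(grid, comps["cap"], G_series, C_in, u_myo)
            return float(np.sum(g_)) - R_met * V_myo * u_myo

        if R_met == 0.0:
            u_myo = u_in
        else:
            u_myo = brentq(net_uptake, 0.0, u_in, xtol=1e-22, rtol=8.9e-16)
        C, u_cap, g = _march_capillary(grid, comps["cap"], G_series, C_in, u_myo)

        u_comp = {
            "cap": u_cap,
            "ec": u_cap - g / G["cap_ec"],
            "is1": u_cap - g / G["cap_ec"] - g / G["ec_is1"],
            "myo": np.full(n, u_myo),
        }
        new_Cp = {name: _free_cp_from_free_fa(comps[name], u_comp[name]) for name in comps}
        rel = max(
            float(np.max(np.abs(new_Cp[k] - free_Cp[k]) / new_Cp[k])) for k in new_Cp
        )
        free_Cp = {
            k: (1.0 - damping) * free_Cp[k] + damping * new_Cp[k] for k in new_Cp
        }
        if rel < tol:
            break
    else:
        raise ArithmeticError(
            f"steady state did not converge in {cfg.numerics.max_outer} outer iterations "
            f"(last relative free-Cp change {rel:.3e})"
        )

    P_b, P_comp, P_aqu = _permeabilities(cfg, comps, mems, free_Cp)
    inflow = cfg.experiment.q_tot * C_in
    outflow = float(np.sum(grid.q_term * C) + grid.q_faces[-1] * C[-1])
    extraction = (inflow - outflow) / inflow

    # is2 albumin pool equilibrated with the myo free Fa (storage only)
    K_alb = comps["cap"].K_CpFa
    Cp_is2_tot = cfg.aux_volumes.is2_Cp_ratio_to_cap * comps["cap"].Cp_total
    is2_free_Cp = Cp_is2_tot * K_alb / (K_alb + u_comp["myo"][0])

    return SteadyState(
        config=cfg,
        grid=grid,
        compartments=comps,
        membranes=mems,
        R_met=R_met,
        extraction=extraction,
        cap_Fa_total=C,
        free_Fa=u_comp,
        free_Cp=free_Cp,
        is2_free_Cp=float(is2_free_Cp),
        P_b=P_b,
        P_composite=P_comp,
        P_aqu=P_aqu,
        g_exchange=g,
        inflow=inflow,
        outflow=outflow,
        n_outer=outer + 1,
    )


def tune_metabolic_rate(
    config: ModelConfig,
    target_extraction: float | None = None,
    grid: ZGrid | None = None,
    tol: float = 1e-4,
    R_max: float = 1e8,
) -> float:
    """Find R_met whose steady state reproduces the target extraction.

    Bracketing scalar root-find; |achieved - target| < tol (1e-4 default).
    Raises if the target exceeds the diffusion-limited maximum extraction.
    """
    if target_extraction is None:
        target_extraction = config.experiment.target_extraction
    if target_extraction is None:
        raise ValueError("no target extraction given")
    if not 0 <= target_extraction <= 0.95:
        raise ValueError("target_extraction must be in [0, 0.95]")
    if target_extraction == 0:
        return 0.0
    grid = grid if grid is not None else make_z_grid(
        config.bed_spec(), config.numerics.n_z, config.numerics.area_cutoff
    )
    warm: dict = {}

    def achieved(R):
        st = solve_steady_state(config, R, grid=grid, warm_start=warm or None)
        warm.update(st.free_Cp)
        return st.extraction

    e_max = achieved(R_max)
    if e_max < target_extraction:
        raise ValueError(
            f"target extraction {target_extraction} unreachable: diffusion-limited "
            f"maximum is {e_max:.4f} at R_met={R_max:.1e}"
        )
    R = brentq(
        lambda R: achieved(R) - target_extraction,
        0.0,
        R_max,
        xtol=1e-12,
        rtol=1e-10,
    )
    err = abs(achieved(R) - target_extraction)
    if err > tol:
        raise ArithmeticError(f"R_met tuning residual {err:.2e} exceeds {tol}")
    return float(R)
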