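"""Time-domain integration of the energy-metabolism models.

Two reduced three-variable systems are integrated:

* with AK equilibrium — state (G6P, F6P, E), E = 2 ATP + ADP; the adenylate
  triple is reconstructed algebraically at every right-hand-side evaluation,
  so trajectories stay on the AK equilibrium manifold exactly;
* without AK — state (G6P, F6P, ATP) with AMP clamped at its physiological
  value and ADP = A - ATP - AMP.

The AK reaction rate is not a state variable of the reduced model; it is
recovered along trajectories as V_AK = d[AMP]/dt = (dAMP/dE) * dE/dt.

For validating the equilibrium reduction, the module also integrates the
unreduced five-variable system (G6P, F6P, ATP, ADP, AMP) in which AK is an
explicit mass-action reaction 2 ADP <-> ATP + AMP with a finite rate
constant; as the rate constant grows the unreduced trajectories converge to
the reduced ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from . import adenylate as aden
from .kinetics import AtpaseSpec, v_atpase, v_gpi, v_hk, v_pfk
from .parameters import REFERENCE_STATE, ModelParams

__all__ = [
    "Trajectory",
    "StepReport",
    "IntegrationError",
    "rhs",
    "integrate",
    "ak_flux",
    "default_initial_state",
    "equilibrate",
    "step_response",
    "rhs_mass_action",
    "integrate_mass_action",
    "mass_action_rate_constant",
]

#: Terminal state counts as converged when every |d/dt| is below this (mM/h).
CONVERGENCE_TOL = 1e-6


class IntegrationError(RuntimeError):
    """Integration failed or was started from an infeasible state."""


def default_initial_state(p: ModelParams) -> np.ndarray:
    """Initial state near the physiological operating point of the cell type.

    Returns (G6P, F6P, E) in AK-equilibrium mode, (G6P, F6P, ATP) otherwise.
    """
    ref = REFERENCE_STATE.get(p.cell_type, REFERENCE_STATE["erythrocyte"])
    atp = min(ref["ATP"], 0.9 * p.A_pool)
    if p.ak_mode == "equilibrium":
        adp, _ = aden.adp_amp_from_atp(atp, p.A_pool, p.K_AK)
        third = 2 * atp + adp
    else:
        third = atp
    return np.array([ref["G6P"], ref["F6P"], third])


def rhs(state: Sequence[float], p: ModelParams, atpase: AtpaseSpec,
        atp_inhibition: bool = True) -> np.ndarray:
    """Time derivative of the reduced state.

    With AK equilibrium the state is (G6P, F6P, E) and
    dE/dt = -V_HK + 3 V_PFK - V_ATPase; without AK it is (G6P, F6P, ATP)
    with the same balance applied to ATP directly (AMP constant).
    """
    G6P, F6P, third = state
    if p.ak_mode == "equilibrium":
        try:
            ATP, ADP, AMP = aden.adenylates_from_E(third, p.A_pool, p.K_AK)
        except aden.InfeasibleStateError as exc:
            raise IntegrationError(f"infeasible state {state}: {exc}") from exc
    else:
        ATP = third
        AMP = p.fixed_AMP
        if ATP < 0 or ATP + AMP > p.A_pool * (1 + 1e-9):
            raise IntegrationError(f"infeasible state {state}: ATP outside [0, A - AMP]")
    vhk = v_hk(ATP, G6P, p)
    vgpi = v_gpi(G6P, F6P, p)
    vpfk = v_pfk(ATP, F6P, AMP, p.Pi, p, atp_inhibition=atp_inhibition)
    vatp = atpase.rate(ATP, p)
    return np.array([vhk - vgpi, vgpi - vpfk, -vhk + 3.0 * vpfk - vatp])


@dataclass
class Trajectory:
    """Integrated time course with reconstructed adenylates and fluxes."""

    mode: str  # 'equilibrium' or 'absent'
    t: np.ndarray
    G6P: np.ndarray
    F6P: np.ndarray
    ATP: np.ndarray
    ADP: np.ndarray
    AMP: np.ndarray
    E: np.ndarray
    V_HK: np.ndarray
    V_GPI: np.ndarray
    V_PFK: np.ndarray
    V_ATPase: np.ndarray
    V_AK: np.ndarray
    converged: bool

    @property
    def net_glycolytic_ATP(self) -> np.ndarray:
        return 3.0 * self.V_PFK - self.V_HK

    def final_state(self) -> np.ndarray:
        third = self.E[-1] if self.mode == "equilibrium" else self.ATP[-1]
        return np.array([self.G6P[-1], self.F6P[-1], third])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t, "G6P": self.G6P, "F6P": self.F6P,
                "ATP": self.ATP, "ADP": self.ADP, "AMP": self.AMP,
                "V_HK": self.V_HK, "V_GPI": self.V_GPI, "V_PFK": self.V_PFK,
                "V_ATPase": self.V_ATPase, "V_AK": self.V_AK,
            }
        )


def _attach(p: ModelParams, atpase: AtpaseSpec, t: np.ndarray, y: np.ndarray,
            atp_inhibition: bool, converged: bool) -> Trajectory:
    G6P, F6P, third = y
    if p.ak_mode == "equilibrium":
        ATP, ADP, AMP = aden.adenylates_from_E(third, p.A_pool, p.K_AK)
        E = third
    else:
        ATP = third
        AMP = np.full_like(ATP, p.fixed_AMP)
        ADP = p.A_pool - ATP - AMP
        E = 2 * ATP + ADP
    V_HK = v_hk(ATP, G6P, p)
    V_GPI = v_gpi(G6P, F6P, p)
    V_PFK = v_pfk(ATP, F6P, AMP, p.Pi, p, atp_inhibition=atp_inhibition)
    V_ATPase = np.asarray(atpase.rate(ATP, p), dtype=float)
    dE = -V_HK + 3.0 * V_PFK - V_ATPase
    if p.ak_mode == "equilibrium":
        V_AK = aden.damp_dE(E, p.A_pool, p.K_AK) * dE
    else:
        V_AK = np.zeros_like(dE)
    return Trajectory(
        mode=p.ak_mode, t=t, G6P=G6P, F6P=F6P, ATP=ATP, ADP=ADP, AMP=AMP, E=E,
        V_HK=V_HK, V_GPI=V_GPI, V_PFK=V_PFK, V_ATPase=V_ATPase, V_AK=V_AK,
        converged=converged,
    )


def integrate(p: ModelParams, init: Optional[Sequence[float]], t_end: float,
              atpase: Optional[AtpaseSpec] = None,
              t_eval: Optional[np.ndarray] = None,
              atp_inhibition: bool = True,
              rtol: float = 1e-8, atol: float = 1e-10,
              method: str = "LSODA") -> Trajectory:
    """Integrate the reduced model to ``t_end`` hours.

    ``init`` is (G6P, F6P, E) or (G6P, F6P, ATP) depending on ``p.ak_mode``;
    ``None`` starts near the physiological reference point.  The returned
    trajectory carries the adenylate triple, all fluxes and the AK rate at
    each sample, and a flag marking whether the terminal state is a steady
    state (all |d/dt| < 1e-6 mM/h).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    atpase = atpase or AtpaseSpec("linear")
    y0 = np.asarray(init if init is not None else default_initial_state(p), dtype=float)
    rhs(y0, p, atpase, atp_inhibition)  # feasibility check, raises if bad
    sol = solve_ivp(
        lambda t, y: rhs(y, p, atpase, atp_inhibition),
        (0.0, t_end), y0, method=method, t_eval=t_eval,
        rtol=rtol, atol=atol, dense_output=False,
    )
    if not sol.success:
        raise IntegrationError(
            f"solver failed: {sol.message}; last state {sol.y[:, -1] if sol.y.size else y0}"
        )
    deriv = rhs(sol.y[:, -1], p, atpase, atp_inhibition)
    converged = bool(np.max(np.abs(deriv)) < CONVERGENCE_TOL)
    return _attach(p, atpase, sol.t, sol.y, atp_inhibition, converged)


def ak_flux(traj: Trajectory, p: ModelParams) -> np.ndarray:
    """AK reaction rate along a with-AK trajectory,
    V_AK = (dAMP/dE) * dE/dt, positive when AK produces net ATP (and AMP)."""
    if traj.mode != "equilibrium":
        return np.zeros_like(traj.t)
    dE = -traj.V_HK + 3.0 * traj.V_PFK - traj.V_ATPase
    return aden.damp_dE(traj.E, p.A_pool, p.K_AK) * dE


def equilibrate(p: ModelParams, atpase: AtpaseSpec,
                init: Optional[Sequence[float]] = None,
                t_relax: float = 100.0,
                atp_inhibition: bool = True) -> np.ndarray:
    """Relax to the stable steady state reachable from ``init``.

    Integrates for ``t_relax`` hours and checks convergence; if drift
    remains, polishes with a direct root solve on the right-hand side.
    """
    traj = integrate(p, init, t_relax, atpase, atp_inhibition=atp_inhibition)
    y = traj.final_state()
    if traj.converged:
        return y
    sol = root(lambda s: rhs(s, p, atpase, atp_inhibition), y, method="hybr", tol=1e-12)
    resid = np.max(np.abs(rhs(sol.x, p, atpase, atp_inhibition)))
    if not sol.success or resid > CONVERGENCE_TOL:
        raise IntegrationError(
            f"pre-equilibration failed to converge (residual {resid:.2e})"
        )
    return sol.x


@dataclass
class StepReport:
    """Response to an instantaneous change in ATP-consuming activity.

    ``max_AK_share`` is the maximum over time of
    100 * V_AK+ / ((3 V_PFK - V_HK) + V_AK+), the instantaneous percentage of
    total ATP production contributed by the AK reaction (V_AK+ is the
    positive part of V_AK; intervals where AK consumes ATP are reported via
    ``min_V_AK``, never netted into the share).
    """

    trajectory: Trajectory
    activity_before: float
    activity_after: float
    atpase_kind: str
    max_AK_share: float
    min_V_AK: float
    t: np.ndarray = field(repr=False)
    total_production: np.ndarray = field(repr=False)
    production_ex_AK: np.ndarray = field(repr=False)
    V_AK: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "atpase_kind": self.atpase_kind,
            "activity_before": self.activity_before,
            "activity_after": self.activity_after,
            "max_AK_share_percent": self.max_AK_share,
            "min_V_AK": self.min_V_AK,
        }


def step_response(p: ModelParams, atpase_kind: str,
                  activity_before: float, activity_after: float,
                  t_end: float = 2.0, n_eval: int = 600) -> StepReport:
    """Pre-equilibrate at ``activity_before``, step the ATPase activity to
    ``activity_after`` at t = 0, and decompose ATP production over the
    transient."""
    before = AtpaseSpec(atpase_kind, activity=activity_before)
    after = AtpaseSpec(atpase_kind, activity=activity_after)
    y0 = equilibrate(p, before)
    t_eval = np.concatenate([[0.0], np.geomspace(1e-6, t_end, n_eval)])
    traj = integrate(p, y0, t_end, after, t_eval=t_eval)
    vak = traj.V_AK
    vak_pos = np.maximum(vak, 0.0)
    net = traj.net_glycolytic_ATP
    total = net + vak_pos
    with np.errstate(divide="ignore", invalid="ignore"):
        share = np.where(total > 0, 100.0 * vak_pos / total, 0.0)
    return StepReport(
        trajectory=traj,
        activity_before=activity_before,
        activity_after=activity_after,
        atpase_kind=atpase_kind,
        max_AK_share=float(np.max(share)),
        min_V_AK=float(np.min(vak)),
        t=traj.t,
        total_production=total,
        production_ex_AK=net,
        V_AK=vak,
    )


# ---------------------------------------------------------------------------
# Unreduced five-variable system with explicit mass-action AK
# ---------------------------------------------------------------------------

def mass_action_rate_constant(p: ModelParams, relative_activity: float) -> float:
    """Mass-action AK rate constant (1/(mM h)) such that the AK capacity
    k * ADP_ref^2 is ``relative_activity`` times the glycolytic flux scale
    (taken as the HK activity A_HK)."""
    adp_ref, _ = aden.adp_amp_from_atp(0.85 * p.A_pool, p.A_pool, p.K_AK)
    return relative_activity * p.A_HK / adp_ref**2


def rhs_mass_action(state: Sequence[float], p: ModelParams, atpase: AtpaseSpec,
                    ak_k: float, atp_inhibition: bool = True) -> np.ndarray:
    """Right-hand side of the unreduced (G6P, F6P, ATP, ADP, AMP) system.

    AK enters as the reversible mass-action reaction 2 ADP -> ATP + AMP with
    forward constant ``ak_k`` and equilibrium constant p.K_AK, i.e.
    V_AK = ak_k (ADP^2 - ATP * AMP / K_AK).
    """
    G6P, F6P, ATP, ADP, AMP = state
    vhk = v_hk(ATP, G6P, p)
    vgpi = v_gpi(G6P, F6P, p)
    vpfk = v_pfk(ATP, F6P, AMP, p.Pi, p, atp_inhibition=atp_inhibition)
    vatp = atpase.rate(ATP, p)
    vak = ak_k * (ADP**2 - ATP * AMP / p.K_AK)
    return np.array([
        vhk - vgpi,
        vgpi - vpfk,
        -vhk + 3.0 * vpfk - vatp + vak,
        vhk - 3.0 * vpfk + vatp - 2.0 * vak,
        vak,
    ])


def integrate_mass_action(p: ModelParams, init: Sequence[float], t_end: float,
                          atpase: Optional[AtpaseSpec] = None,
                          ak_relative_activity: float = 1e4,
                          t_eval: Optional[np.ndarray] = None,
                          rtol: float = 1e-8, atol: float = 1e-10,
                          atp_inhibition: bool = True) -> pd.DataFrame:
    """Integrate the unreduced five-variable system (stiff; Radau).

    ``init`` is (G6P, F6P, ATP, ADP, AMP).  Returns a tidy DataFrame of the
    five state variables versus time.  Used as the independent check of the
    AK equilibrium reduction: for large ``ak_relative_activity`` the result
    matches the reduced three-variable trajectories.
    """
    atpase = atpase or AtpaseSpec("linear")
    ak_k = mass_action_rate_constant(p, ak_relative_activity)
    y0 = np.asarray(init, dtype=float)
    sol = solve_ivp(
        lambda t, y: rhs_mass_action(y, p, atpase, ak_k, atp_inhibition),
        (0.0, t_end), y0, method="Radau", t_eval=t_eval, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"mass-action solver failed: {sol.message}")
    G6P, F6P, ATP, ADP, AMP = sol.y
    return pd.DataFrame(
        {"t": sol.t, "G6P": G6P, "F6P": F6P, "ATP": ATP, "ADP": ADP, "AMP": AMP}
    )
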