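"""Steady-state analysis: glycolysis characteristics, steady states,
stability, and bifurcation structure.

The *glycolysis characteristic* is the steady-state net glycolytic ATP
production rate as a function of a clamped ATP concentration.  For each
clamped [ATP] the adenylate complement is fixed (by AK equilibrium and pool
conservation, or by a constant AMP when AK is absent) and the two upper
metabolites solve

    V_HK(ATP, G6P) = V_GPI(G6P, F6P) = V_PFK(ATP, F6P, AMP).

Steady states of the full model are the intersections of this curve with the
ATPase load curve; with AK present the characteristic is bell-shaped and
intersections on its descending branch are stable, those on the ascending
branch unstable.  As the ATPase activity grows past the characteristic
maximum the two nonzero steady states merge and vanish in a saddle-node
(fold) bifurcation, leaving complete ATP depletion as the only attractor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, root

from . import adenylate as aden
from .dynamics import rhs as dynamics_rhs
from .kinetics import AtpaseSpec, v_gpi, v_hk, v_pfk
from .parameters import REFERENCE_STATE, ModelParams

__all__ = [
    "CharacteristicCurve",
    "SteadyStateRecord",
    "BifurcationDiagram",
    "PoolSweepResult",
    "ChargeCurve",
    "characteristic",
    "find_steady_states",
    "bifurcation_diagram",
    "stabilization_metrics",
    "pool_sweep",
    "characteristic_vs_charge",
    "solve_upper_glycolysis",
]

#: Flux-balance residual (mM/h) below which a characteristic point counts
#: as solved.
RESIDUAL_TOL = 1e-8
#: Eigenvalue real parts within this band (1/h) of zero are flagged marginal.
MARGINAL_EIG = 1e-9


def _complement(p: ModelParams, ATP: float) -> tuple[float, float]:
    """(ADP, AMP) for a clamped ATP in the current AK mode."""
    if p.ak_mode == "equilibrium":
        return aden.adp_amp_from_atp(ATP, p.A_pool, p.K_AK)
    amp = p.fixed_AMP
    return p.A_pool - ATP - amp, amp


def solve_upper_glycolysis(p: ModelParams, ATP: float, AMP: float,
                           guess: tuple[float, float],
                           atp_inhibition: bool = True
                           ) -> tuple[float, float, float, bool]:
    """Solve V_HK = V_GPI = V_PFK for (G6P, F6P) at clamped ATP and AMP.

    The solve runs in log-concentration space to keep iterates positive.
    Returns (G6P, F6P, residual, converged).
    """

    def balance(x):
        g6p, f6p = np.exp(x)
        vhk = v_hk(ATP, g6p, p)
        vgpi = v_gpi(g6p, f6p, p)
        vpfk = v_pfk(ATP, f6p, AMP, p.Pi, p, atp_inhibition=atp_inhibition)
        return [vhk - vgpi, vgpi - vpfk]

    x0 = np.log(np.maximum(guess, 1e-12))
    best = None
    for attempt, shift in enumerate(([0.0, 0.0], [0.5, 0.5], [-0.5, -0.5],
                                     [1.5, 1.5], [-1.5, -1.5], [3.0, 3.0])):
        sol = root(balance, x0 + np.asarray(shift), method="hybr", tol=1e-14)
        res = float(np.max(np.abs(balance(sol.x))))
        if best is None or res < best[1]:
            best = (sol.x, res)
        if res < RESIDUAL_TOL:
            break
    x, res = best
    g6p, f6p = np.exp(x)
    return float(g6p), float(f6p), res, res < RESIDUAL_TOL


@dataclass
class CharacteristicCurve:
    """Steady-state glycolysis characteristic over a clamped-ATP grid.

    ``production`` is the net glycolytic ATP production 3 V_PFK - V_HK,
    which equals 2 V_PFK at every solved point; ``gross_production`` is
    4 V_PFK.  Points where the root solve failed are flagged in
    ``converged`` rather than dropped.
    """

    mode: str
    A_pool: float
    ATP: np.ndarray
    ADP: np.ndarray
    AMP: np.ndarray
    G6P: np.ndarray
    F6P: np.ndarray
    V_HK: np.ndarray
    V_PFK: np.ndarray
    production: np.ndarray
    converged: np.ndarray
    atp_inhibition: bool = True

    @property
    def gross_production(self) -> np.ndarray:
        return 4.0 * self.V_PFK

    def production_at(self, ATP: float) -> float:
        ok = self.converged
        return float(np.interp(ATP, self.ATP[ok], self.production[ok]))

    def peak(self) -> tuple[float, float]:
        """(ATP, production) at the interior maximum, refined by a local
        quadratic fit through the three grid points around the maximum."""
        ok = self.converged
        atp, prod = self.ATP[ok], self.production[ok]
        i = int(np.argmax(prod))
        if 0 < i < len(prod) - 1:
            x, y = atp[i - 1:i + 2], prod[i - 1:i + 2]
            c = np.polyfit(x, y, 2)
            if c[0] < 0:
                xm = -c[1] / (2 * c[0])
                if x[0] <= xm <= x[-1]:
                    return float(xm), float(np.polyval(c, xm))
        return float(atp[i]), float(prod[i])

    def classify(self, operating_atp: Optional[float] = None,
                 rel_tol: float = 0.01, noise: float = 1e-6) -> str:
        """'bell' if the interior maximum exceeds both endpoints by more than
        ``rel_tol`` of the peak and the operating point (default: the cell
        type's physiological ATP) lies on the descending side; 'monotone' if
        production is non-decreasing within solver noise; else 'other'."""
        ok = self.converged
        atp, prod = self.ATP[ok], self.production[ok]
        atp_peak, peak = self.peak()
        if np.all(np.diff(prod) >= -noise):
            return "monotone"
        bell = (peak - prod[0] > rel_tol * peak) and (peak - prod[-1] > rel_tol * peak)
        if bell and operating_atp is not None:
            bell = operating_atp > atp_peak
        return "bell" if bell else "other"

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ATP": self.ATP, "ADP": self.ADP, "AMP": self.AMP,
                "G6P": self.G6P, "F6P": self.F6P,
                "V_PFK": self.V_PFK, "production": self.production,
                "gross_production": self.gross_production,
                "converged": self.converged,
            }
        )


def _default_grid(p: ModelParams, n: int) -> np.ndarray:
    return np.linspace(0.02 * p.A_pool, 0.995 * p.A_pool, n)


def characteristic(p: ModelParams, atp_grid: Optional[Sequence[float]] = None,
                   n: int = 400, atp_inhibition: bool = True) -> CharacteristicCurve:
    """Compute the glycolysis characteristic by natural-parameter
    continuation in the clamped ATP concentration.

    The first solve starts near the physiological reference point; the sweep
    then proceeds outward in both directions, each point warm-started from
    its neighbour.
    """
    grid = np.asarray(atp_grid if atp_grid is not None else _default_grid(p, n), dtype=float)
    if np.any(grid <= 0):
        raise ValueError("ATP grid must be positive")
    if p.ak_mode == "equilibrium" and np.any(grid >= p.A_pool):
        raise ValueError("ATP grid must lie inside (0, A_pool) with AK equilibrium")
    m = len(grid)
    G6P = np.empty(m)
    F6P = np.empty(m)
    conv = np.zeros(m, dtype=bool)

    ref = REFERENCE_STATE.get(p.cell_type, REFERENCE_STATE["erythrocyte"])
    start = int(np.argmin(np.abs(grid - min(ref["ATP"], 0.85 * p.A_pool))))
    guess0 = (ref["G6P"], ref["F6P"])

    order = list(range(start, m)) + list(range(start - 1, -1, -1))
    guesses: dict[int, tuple[float, float]] = {}
    for idx in order:
        if idx == start:
            guess = guess0
        elif idx > start:
            guess = guesses.get(idx - 1, guess0)
        else:
            guess = guesses.get(idx + 1, guess0)
        atp = grid[idx]
        _, amp = _complement(p, atp)
        g6p, f6p, res, ok = solve_upper_glycolysis(
            p, atp, amp, guess, atp_inhibition=atp_inhibition
        )
        G6P[idx], F6P[idx], conv[idx] = g6p, f6p, ok
        guesses[idx] = (g6p, f6p) if ok else guess

    ADP = np.empty(m)
    AMP = np.empty(m)
    for i, atp in enumerate(grid):
        ADP[i], AMP[i] = _complement(p, atp)
    VHK = v_hk(grid, G6P, p)
    VPFK = v_pfk(grid, F6P, AMP, p.Pi, p, atp_inhibition=atp_inhibition)
    return CharacteristicCurve(
        mode=p.ak_mode, A_pool=p.A_pool, ATP=grid, ADP=ADP, AMP=AMP,
        G6P=G6P, F6P=F6P, V_HK=np.asarray(VHK, dtype=float),
        V_PFK=np.asarray(VPFK, dtype=float),
        production=np.asarray(3.0 * VPFK - VHK, dtype=float),
        converged=conv, atp_inhibition=atp_inhibition,
    )


@dataclass
class SteadyStateRecord:
    """A located steady state of the full dynamic system."""

    ATP: float
    ADP: float
    AMP: float
    G6P: float
    F6P: float
    V_HK: float
    V_GPI: float
    V_PFK: float
    V_ATPase: float
    atpase: AtpaseSpec
    eigenvalues: Optional[np.ndarray]
    stability: str  # 'stable' | 'unstable' | 'marginal'
    branch: str     # 'descending' | 'ascending' | 'collapsed'

    @property
    def production(self) -> float:
        return 3.0 * self.V_PFK - self.V_HK


def _jacobian(fun, y, rel_step=1e-6, abs_step=1e-9):
    n = len(y)
    J = np.empty((n, n))
    for j in range(n):
        h = rel_step * abs(y[j]) + abs_step
        yp = y.copy(); yp[j] += h
        ym = y.copy(); ym[j] -= h
        J[:, j] = (fun(yp) - fun(ym)) / (2 * h)
    return J


def _classify_eigs(eigs: np.ndarray) -> str:
    re = np.real(eigs)
    if np.any(np.abs(re) <= MARGINAL_EIG):
        return "marginal"
    return "stable" if np.all(re < 0) else "unstable"


def _refine_record(p: ModelParams, atpase: AtpaseSpec, atp0: float,
                   curve: CharacteristicCurve,
                   atp_inhibition: bool = True) -> Optional[SteadyStateRecord]:
    """Polish an approximate intersection with a full 3-variable root solve
    and classify its stability from the Jacobian eigenvalues."""
    ok = curve.converged
    g6p0 = float(np.interp(atp0, curve.ATP[ok], curve.G6P[ok]))
    f6p0 = float(np.interp(atp0, curve.ATP[ok], curve.F6P[ok]))
    if p.ak_mode == "equilibrium":
        adp0, _ = aden.adp_amp_from_atp(atp0, p.A_pool, p.K_AK)
        third0 = 2 * atp0 + adp0
    else:
        third0 = atp0

    fun = lambda y: dynamics_rhs(y, p, atpase, atp_inhibition)
    sol = root(fun, [g6p0, f6p0, third0], method="hybr", tol=1e-14)
    resid = float(np.max(np.abs(fun(sol.x))))
    if resid > 1e-8:
        return None
    g6p, f6p, third = sol.x
    if p.ak_mode == "equilibrium":
        atp, adp, amp = aden.adenylates_from_E(third, p.A_pool, p.K_AK)
    else:
        atp, amp = third, p.fixed_AMP
        adp = p.A_pool - atp - amp
    eigs = np.linalg.eigvals(_jacobian(fun, sol.x))
    # branch from the slope of the characteristic at this ATP
    slope = float(np.gradient(curve.production[ok], curve.ATP[ok])[
        np.argmin(np.abs(curve.ATP[ok] - atp))])
    vhk = v_hk(atp, g6p, p)
    vgpi = v_gpi(g6p, f6p, p)
    vpfk = v_pfk(atp, f6p, amp, p.Pi, p, atp_inhibition=atp_inhibition)
    return SteadyStateRecord(
        ATP=float(atp), ADP=float(adp), AMP=float(amp),
        G6P=float(g6p), F6P=float(f6p),
        V_HK=float(vhk), V_GPI=float(vgpi), V_PFK=float(vpfk),
        V_ATPase=float(atpase.rate(atp, p)),
        atpase=atpase, eigenvalues=eigs, stability=_classify_eigs(eigs),
        branch="descending" if slope < 0 else "ascending",
    )


def _zero_record(p: ModelParams, atpase: AtpaseSpec) -> SteadyStateRecord:
    """The trivial ATP-depleted state (sole attractor past the fold)."""
    amp = p.A_pool if p.ak_mode == "equilibrium" else p.fixed_AMP
    return SteadyStateRecord(
        ATP=0.0, ADP=0.0 if p.ak_mode == "equilibrium" else p.A_pool - amp,
        AMP=amp, G6P=0.0, F6P=0.0,
        V_HK=0.0, V_GPI=0.0, V_PFK=0.0, V_ATPase=0.0,
        atpase=atpase, eigenvalues=None, stability="stable", branch="collapsed",
    )


def find_steady_states(p: ModelParams, atpase: AtpaseSpec,
                       curve: Optional[CharacteristicCurve] = None,
                       atp_inhibition: bool = True) -> list[SteadyStateRecord]:
    """All nonzero steady states as characteristic/ATPase intersections,
    each refined by a full root solve with eigenvalue classification.

    When no nonzero state exists the ATP-depleted state is returned as the
    only record.
    """
    if curve is None:
        curve = characteristic(p, atp_inhibition=atp_inhibition)
    ok = curve.converged
    atp = curve.ATP[ok]
    gap = curve.production[ok] - np.asarray(atpase.rate(atp, p), dtype=float)
    records: list[SteadyStateRecord] = []
    sign = np.sign(gap)
    for i in np.where(np.diff(sign) != 0)[0]:
        a, b = atp[i], atp[i + 1]
        try:
            atp_star = brentq(
                lambda x: curve.production_at(x) - float(atpase.rate(x, p)), a, b,
                xtol=1e-12, rtol=1e-12,
            )
        except ValueError:
            atp_star = 0.5 * (a + b)
        rec = _refine_record(p, atpase, atp_star, curve, atp_inhibition)
        if rec is not None and rec.ATP > 1e-6:
            if not any(abs(rec.ATP - r.ATP) < 1e-6 for r in records):
                records.append(rec)
    if not records:
        records.append(_zero_record(p, atpase))
    return records


@dataclass
class BifurcationDiagram:
    """Steady-state ATP versus ATPase activity, with stability labels."""

    atpase_kind: str
    activities: np.ndarray
    records: list[list[SteadyStateRecord]]
    fold_activity: Optional[float]

    def branch(self, stability: str) -> tuple[np.ndarray, np.ndarray]:
        acts, atps = [], []
        for a, recs in zip(self.activities, self.records):
            for r in recs:
                if r.stability == stability and r.branch != "collapsed":
                    acts.append(a)
                    atps.append(r.ATP)
        return np.array(acts), np.array(atps)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for a, recs in zip(self.activities, self.records):
            for r in recs:
                rows.append({"activity": a, "ATP": r.ATP,
                             "stability": r.stability, "branch": r.branch})
        return pd.DataFrame(rows)


def bifurcation_diagram(p: ModelParams, atpase_kind: str,
                        activity_grid: Sequence[float],
                        curve: Optional[CharacteristicCurve] = None
                        ) -> BifurcationDiagram:
    """Continuation of the steady states over an ascending ATPase-activity
    grid.  For hyperbolic loads the saddle-node (fold) activity is bracketed
    by bisection to 0.1% between the last activity with a nonzero state and
    the first without."""
    acts = np.asarray(activity_grid, dtype=float)
    if np.any(np.diff(acts) <= 0):
        raise ValueError("activity grid must be strictly ascending")
    if curve is None:
        curve = characteristic(p)
    records = [
        find_steady_states(p, AtpaseSpec(atpase_kind, activity=a), curve=curve)
        for a in acts
    ]
    has_nonzero = [any(r.branch != "collapsed" for r in recs) for recs in records]
    fold = None
    if any(has_nonzero) and not all(has_nonzero):
        lo = max(a for a, h in zip(acts, has_nonzero) if h)
        hi = min(a for a, h in zip(acts, has_nonzero) if not h)

        def exists(a: float) -> bool:
            recs = find_steady_states(p, AtpaseSpec(atpase_kind, activity=a), curve=curve)
            return any(r.branch != "collapsed" for r in recs)

        while (hi - lo) / hi > 1e-3:
            mid = 0.5 * (lo + hi)
            if exists(mid):
                lo = mid
            else:
                hi = mid
        fold = 0.5 * (lo + hi)
    return BifurcationDiagram(atpase_kind=atpase_kind, activities=acts,
                              records=records, fold_activity=fold)


def stabilization_metrics(p: ModelParams, atpase_kind: str = "linear",
                          activity: Optional[float] = None,
                          rel_step: float = 0.02,
                          curve: Optional[CharacteristicCurve] = None) -> dict:
    """Control coefficient C = d ln [ATP]_ST / d ln a of the ATPase activity
    over steady-state ATP, and the stabilization coefficient Q = -1/C,
    by central finite difference on the stable branch."""
    if activity is None:
        activity = (p.atpase_linear_a if atpase_kind == "linear"
                    else p.atpase_hyperbolic_Vmax)
    if curve is None:
        curve = characteristic(p)

    def stable_atp(a: float) -> float:
        recs = find_steady_states(p, AtpaseSpec(atpase_kind, activity=a), curve=curve)
        stable = [r for r in recs if r.stability == "stable" and r.branch != "collapsed"]
        if not stable:
            raise ValueError(f"no stable nonzero steady state at activity {a}")
        return max(r.ATP for r in stable)

    center = find_steady_states(p, AtpaseSpec(atpase_kind, activity=activity), curve=curve)
    if not any(r.stability == "stable" and r.branch != "collapsed" for r in center):
        raise ValueError("requested activity lies off the stable branch")
    h = np.log(1 + rel_step)
    up = stable_atp(activity * np.exp(h))
    dn = stable_atp(activity * np.exp(-h))
    C = (np.log(up) - np.log(dn)) / (2 * h)
    return {"C": float(C), "Q": float(-1.0 / C)}


@dataclass
class PoolSweepResult:
    """Characteristics at several adenine-pool sizes plus their overlay after
    normalization of both axes to each curve's maximum point."""

    pools: list[float]
    curves: list[CharacteristicCurve]
    x_common: np.ndarray
    normalized: np.ndarray  # one row per pool, production/peak on x_common
    max_deviation: float    # max pairwise |difference|, in units of the peak


def pool_sweep(p: ModelParams, pools: Sequence[float], n: int = 400,
               x_lo: float = 0.1, x_hi: float = 1.9,
               n_common: int = 200) -> PoolSweepResult:
    """Characteristics for each pool size and their normalized overlay.

    ``max_deviation`` is the largest pointwise difference between any two
    normalized curves, as a fraction of the (unit) peak height, over the
    overlay window [x_lo, x_hi] in peak-normalized ATP units (the window
    spans the ascending branch through the descending branch down to
    near-zero flux; the extreme tails beyond it are excluded).
    """
    curves = [characteristic(p.replace(A_pool=A), n=n) for A in pools]
    peaks = [c.peak() for c in curves]
    x_hi = min([x_hi] + [c.ATP[c.converged][-1] / pk[0]
                         for c, pk in zip(curves, peaks)])
    x_common = np.linspace(x_lo, x_hi, n_common)
    normalized = np.empty((len(curves), n_common))
    for i, (c, (atp_pk, prod_pk)) in enumerate(zip(curves, peaks)):
        ok = c.converged
        normalized[i] = np.interp(x_common, c.ATP[ok] / atp_pk, c.production[ok] / prod_pk)
    dev = 0.0
    for i in range(len(curves)):
        for j in range(i + 1, len(curves)):
            dev = max(dev, float(np.max(np.abs(normalized[i] - normalized[j]))))
    return PoolSweepResult(pools=list(pools), curves=curves, x_common=x_common,
                           normalized=normalized, max_deviation=dev)


@dataclass
class ChargeCurve:
    """The characteristic re-parameterized by energy charge and by relative
    ATP concentration."""

    phi: np.ndarray
    atp_rel: np.ndarray
    production: np.ndarray

    def production_at_phi(self, phi: float) -> float:
        return float(np.interp(phi, self.phi, self.production))

    def production_at_rel(self, rel: float) -> float:
        return float(np.interp(rel, self.atp_rel, self.production))


def characteristic_vs_charge(p: ModelParams,
                             curve: Optional[CharacteristicCurve] = None) -> ChargeCurve:
    """Re-express the with-AK characteristic as a function of Atkinson's
    energy charge and of ATP/A.  At high charge the two abscissae nearly
    coincide, so the curves overlay."""
    if p.ak_mode != "equilibrium":
        raise ValueError("charge re-parameterization requires AK equilibrium")
    if curve is None:
        curve = characteristic(p)
    ok = curve.converged
    phi = aden.energy_charge(curve.ATP[ok], curve.ADP[ok], curve.AMP[ok])
    return ChargeCurve(phi=np.asarray(phi, dtype=float),
                       atp_rel=curve.ATP[ok] / p.A_pool,
                       production=curve.production[ok])
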