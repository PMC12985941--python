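"""Adenylate pool algebra under adenylate-kinase (AK) equilibrium.

The AK reaction ATP + AMP <-> 2 ADP is far faster than glycolytic turnover,
so the three adenylates stay on the equilibrium manifold

    K = [ATP][AMP] / [ADP]^2        (K close to 1)

while the total pool A = [ATP] + [ADP] + [AMP] is conserved on metabolic
time scales.  On that manifold the pool has a single degree of freedom; the
natural coordinate is the composite variable

    E = 2 [ATP] + [ADP]

(the count of "high-energy" phosphoanhydride bonds), whose time derivative
contains no AK flux.  This module provides the closed-form split of E (or of
a clamped [ATP]) into the consistent (ATP, ADP, AMP) triple, the quadratic
small-AMP approximation, Atkinson's energy charge, and the sensitivity
dAMP/dE used to reconstruct the AK flux along trajectories.

All concentrations are mM.  Functions accept scalars or numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AdenylateState",
    "InfeasibleStateError",
    "split_from_E",
    "adenylates_from_E",
    "adp_amp_from_atp",
    "amp_quadratic_approx",
    "energy_charge",
    "damp_dE",
]

# Round-off guard at the boundaries of the feasible region (E = 0 or 2A):
# concentrations in [-_CLAMP_TOL, 0) are clamped to zero, anything more
# negative is a genuine infeasibility.
_CLAMP_TOL = 1e-12


class InfeasibleStateError(ValueError):
    """The requested adenylate state lies outside the physical region."""


@dataclass(frozen=True)
class AdenylateState:
    """A consistent (ATP, ADP, AMP) triple with its pool and E coordinate."""

    ATP: float
    ADP: float
    AMP: float
    A: float
    E: float
    K: float

    def validate(self, tol: float = 1e-9) -> None:
        """Check pool conservation, the E identity and (if on the AK manifold)
        the mass-action ratio; raises :class:`InfeasibleStateError` on failure."""
        if min(self.ATP, self.ADP, self.AMP) < -tol:
            raise InfeasibleStateError(f"negative concentration in {self}")
        if abs(self.ATP + self.ADP + self.AMP - self.A) > tol * max(self.A, 1.0):
            raise InfeasibleStateError(f"pool not conserved in {self}")
        if abs(2 * self.ATP + self.ADP - self.E) > tol * max(self.A, 1.0):
            raise InfeasibleStateError(f"E inconsistent in {self}")

    @property
    def energy_charge(self) -> float:
        return energy_charge(self.ATP, self.ADP, self.AMP)


def _clamp(x):
    """Clamp round-off-negative concentrations to zero; leave real negatives."""
    return np.where((x < 0) & (x >= -_CLAMP_TOL), 0.0, x)


def _q_discriminant(E, A, K):
    return A**2 - 2 * A * E + E**2 + 8 * A * E * K - 4 * E**2 * K


def adenylates_from_E(E, A, K=1.0):
    """Vector-friendly split of E into (ATP, ADP, AMP) on the AK manifold.

    Selects the root of the equilibrium quadratic for which all three
    concentrations are non-negative (the unique feasible root for
    0 <= E <= 2A and K > 0).
    """
    E = np.asarray(E, dtype=float)
    scalar = E.ndim == 0
    disc = _q_discriminant(E, A, K)
    if np.any(disc < -_CLAMP_TOL * max(A, 1.0) ** 2):
        raise InfeasibleStateError(
            f"negative discriminant for E={E}, A={A}, K={K}: E outside feasible range"
        )
    Q = np.sqrt(np.maximum(disc, 0.0))
    ATP = 0.5 * (E + (A - Q) / (4 * K - 1))
    ADP = (Q - A) / (4 * K - 1)
    AMP = A - ATP - ADP
    ATP, ADP, AMP = _clamp(ATP), _clamp(ADP), _clamp(AMP)
    if np.any(ATP < 0) or np.any(ADP < 0) or np.any(AMP < 0):
        raise InfeasibleStateError(
            f"negative concentration for E={E}, A={A}, K={K}"
        )
    if scalar:
        return float(ATP), float(ADP), float(AMP)
    return ATP, ADP, AMP


def split_from_E(E: float, A: float, K: float = 1.0) -> AdenylateState:
    """Split the composite variable E = 2 ATP + ADP into the unique
    non-negative adenylate triple consistent with pool A and AK constant K."""
    if not A > 0:
        raise InfeasibleStateError(f"pool A must be positive, got {A}")
    if not K > 0 or abs(K - 0.25) < 1e-12:
        raise InfeasibleStateError(f"K must be positive and != 0.25, got {K}")
    if E < -_CLAMP_TOL or E > 2 * A * (1 + _CLAMP_TOL):
        raise InfeasibleStateError(f"E={E} outside [0, 2A] for A={A}")
    ATP, ADP, AMP = adenylates_from_E(float(np.clip(E, 0.0, 2 * A)), A, K)
    state = AdenylateState(ATP=ATP, ADP=ADP, AMP=AMP, A=A, E=float(E), K=K)
    state.validate()
    return state


def adp_amp_from_atp(ATP, A, K=1.0):
    """ADP and AMP consistent with a clamped [ATP], pool A and AK constant K.

    Used to parameterize steady-state scans in which ATP itself is the
    control variable.  Returns ``(ADP, AMP)``.
    """
    ATP = np.asarray(ATP, dtype=float)
    scalar = ATP.ndim == 0
    if np.any(ATP < -_CLAMP_TOL) or np.any(ATP > A * (1 + 1e-12)):
        raise InfeasibleStateError(f"ATP outside [0, A={A}]")
    inner = ATP * (4 * K * A + ATP - 4 * K * ATP)
    if np.any(inner < -_CLAMP_TOL):
        raise InfeasibleStateError("no real ADP root for given (ATP, A, K)")
    ADP = (np.sqrt(np.maximum(inner, 0.0)) - ATP) / (2 * K)
    AMP = A - ATP - ADP
    ADP, AMP = _clamp(ADP), _clamp(AMP)
    if np.any(ADP < 0) or np.any(AMP < 0):
        raise InfeasibleStateError("negative ADP or AMP for given (ATP, A, K)")
    if scalar:
        return float(ADP), float(AMP)
    return ADP, AMP


def amp_quadratic_approx(ATP, A):
    """Quadratic approximation AMP ~ A (1 - ATP/A)^2, valid in the K = 1
    regime.  Kept separate from the exact algebra; never used in dynamics."""
    ATP = np.asarray(ATP, dtype=float)
    if np.any(ATP < 0) or np.any(ATP > A * (1 + 1e-12)):
        raise InfeasibleStateError(f"ATP outside [0, A={A}]")
    out = A * (1 - ATP / A) ** 2
    return float(out) if out.ndim == 0 else out


def energy_charge(ATP, ADP, AMP):
    """Atkinson's energy charge phi = (ATP + ADP/2) / (ATP + ADP + AMP)."""
    ATP = np.asarray(ATP, dtype=float)
    ADP = np.asarray(ADP, dtype=float)
    AMP = np.asarray(AMP, dtype=float)
    if np.any(ATP < 0) or np.any(ADP < 0) or np.any(AMP < 0):
        raise ValueError("concentrations must be non-negative")
    pool = ATP + ADP + AMP
    if np.any(pool == 0):
        raise ZeroDivisionError("energy charge undefined for an empty pool")
    out = (ATP + 0.5 * ADP) / pool
    return float(out) if out.ndim == 0 else out


def damp_dE(E, A, K=1.0):
    """Sensitivity d[AMP]/dE on the AK equilibrium manifold:
    (E - A - Q) / (2 Q), with Q the square root of the split discriminant.

    Multiplying by dE/dt gives the AK reaction rate V_AK = d[AMP]/dt.
    """
    E = np.asarray(E, dtype=float)
    disc = _q_discriminant(E, A, K)
    if np.any(disc <= 0):
        raise InfeasibleStateError("dAMP/dE undefined: discriminant <= 0")
    Q = np.sqrt(disc)
    out = (E - A - Q) / (2 * Q)
    return float(out) if out.ndim == 0 else out
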