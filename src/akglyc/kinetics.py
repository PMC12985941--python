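"""Rate laws of the upper-glycolysis enzymes and of ATP-consuming processes.

Stateless functions of concentrations (mM) and a :class:`ModelParams`,
returning fluxes in mM/h.

* Hexokinase (HK): irreversible, saturable in ATP, product-inhibited by G6P.
* Glucose-phosphate isomerase (GPI): reversible G6P <-> F6P isomerization
  with equilibrium ratio [G6P]/[F6P] = K_GPI1.
* Phosphofructokinase (PFK): irreversible, saturable in F6P and ATP, with a
  hyperbolic AMP-activation factor, a concerted allosteric suppression factor
  (constant L0 = 1e8, exponent 4) combining ATP inhibition with AMP and F6P
  relief, and a linear orthophosphate activation term.
* ATPase: total ATP-consuming activity, either linear in ATP or hyperbolic
  (Michaelis constant far below physiological [ATP]).

Only the first three glycolytic reactions are modelled explicitly; the
lower-glycolysis kinases are accounted for by the stoichiometric identity
V_PGK = V_PK = 2 V_PFK, so the ATP balance of the whole pathway is
-V_HK + 3 V_PFK - V_ATPase and the net glycolytic production is
3 V_PFK - V_HK (= 2 V_PFK in steady state).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .parameters import ModelParams

__all__ = [
    "v_hk",
    "v_gpi",
    "v_pfk",
    "v_atpase",
    "AtpaseSpec",
    "FluxVector",
    "flux_vector",
    "FROZEN_INHIBITORY_ATP",
]

#: ATP concentration (mM) frozen inside the PFK inhibitory term when
#: ATP-mediated allosteric inhibition is disabled.  Freezing (rather than
#: deleting) the term leaves the normal operating point unchanged.
FROZEN_INHIBITORY_ATP = 1.5


def v_hk(ATP, G6P, p: ModelParams):
    """Hexokinase rate: A_HK (ATP/K_HK1) / (1 + ATP/K_HK1 + G6P/K_HK2)."""
    return p.A_HK * (ATP / p.K_HK1) / (1.0 + ATP / p.K_HK1 + G6P / p.K_HK2)


def v_gpi(G6P, F6P, p: ModelParams):
    """GPI rate; zero at the equilibrium ratio G6P = K_GPI1 * F6P, positive
    toward F6P when G6P is in excess, negative otherwise."""
    return (
        p.A_GPI
        * ((G6P - p.K_GPI1 * F6P) / p.K_GPI2)
        / (1.0 + G6P / p.K_GPI2 + F6P / p.K_GPI3)
    )


def v_pfk(ATP, F6P, AMP, Pi, p: ModelParams, atp_inhibition: bool = True):
    """Phosphofructokinase rate.

    With ``atp_inhibition=False`` the ATP concentration inside the inhibitory
    factor (1 + ATP/K_PFK4) is frozen at :data:`FROZEN_INHIBITORY_ATP` while
    every other occurrence of ATP still varies.
    """
    atp_inhib = ATP if atp_inhibition else FROZEN_INHIBITORY_ATP
    amp_rel = AMP / p.K_PFK3
    activation = (1.0 + 2.0 * amp_rel) / (1.0 + amp_rel)
    ratio = (1.0 + atp_inhib / p.K_PFK4) / ((1.0 + amp_rel) * (1.0 + F6P / p.K_PFK5))
    suppression = 1.0 / (1.0 + p.L0 * ratio**p.n_allosteric)
    return (
        p.A_PFK
        * (1.0 + Pi / p.K_PFK6)
        * (F6P / (F6P + p.K_PFK1))
        * (ATP / (ATP + p.K_PFK2))
        * activation
        * suppression
    )


@dataclass(frozen=True)
class AtpaseSpec:
    """Specification of the ATP-consuming load.

    ``kind`` is 'linear' (rate = a * ATP) or 'hyperbolic'
    (rate = Vmax * ATP / (ATP + K_ATP)).  ``activity`` overrides the
    parameter-set default activity (a or Vmax); ``scale`` multiplies it.
    """

    kind: str = "linear"
    activity: Optional[float] = None
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "hyperbolic"):
            raise ValueError(f"ATPase kind must be 'linear' or 'hyperbolic', got {self.kind!r}")
        if self.scale <= 0:
            raise ValueError("ATPase scale must be positive")

    def resolved_activity(self, p: ModelParams) -> float:
        base = self.activity
        if base is None:
            base = p.atpase_linear_a if self.kind == "linear" else p.atpase_hyperbolic_Vmax
        return base * self.scale

    def rate(self, ATP, p: ModelParams):
        return v_atpase(ATP, p, kind=self.kind, activity=self.activity, scale=self.scale)

    def with_activity(self, activity: float) -> "AtpaseSpec":
        return AtpaseSpec(kind=self.kind, activity=activity, scale=1.0)


def v_atpase(ATP, p: ModelParams, kind: str = "linear",
             activity: Optional[float] = None, scale: float = 1.0):
    """Total ATP consumption rate, linear or hyperbolic in ATP."""
    spec_activity = activity
    if spec_activity is None:
        spec_activity = p.atpase_linear_a if kind == "linear" else p.atpase_hyperbolic_Vmax
    a = spec_activity * scale
    if kind == "linear":
        return a * np.asarray(ATP, dtype=float) * 1.0
    if kind == "hyperbolic":
        ATP = np.asarray(ATP, dtype=float) * 1.0
        return a * ATP / (ATP + p.atpase_K_ATP)
    raise ValueError(f"unknown ATPase kind {kind!r}")


@dataclass(frozen=True)
class FluxVector:
    """All reaction fluxes (mM/h) at one state."""

    V_HK: float
    V_GPI: float
    V_PFK: float
    V_ATPase: float

    @property
    def net_glycolytic_ATP(self) -> float:
        """ATP terms of the glycolytic balance, 3 V_PFK - V_HK."""
        return 3.0 * self.V_PFK - self.V_HK

    @property
    def gross_glycolytic_ATP(self) -> float:
        """Lower-glycolysis ATP production, 4 V_PFK."""
        return 4.0 * self.V_PFK


def flux_vector(ATP, G6P, F6P, AMP, p: ModelParams,
                atpase: Optional[AtpaseSpec] = None,
                atp_inhibition: bool = True) -> FluxVector:
    """Evaluate all rate laws at one state."""
    atpase = atpase or AtpaseSpec("linear")
    return FluxVector(
        V_HK=float(v_hk(ATP, G6P, p)),
        V_GPI=float(v_gpi(G6P, F6P, p)),
        V_PFK=float(v_pfk(ATP, F6P, AMP, p.Pi, p, atp_inhibition=atp_inhibition)),
        V_ATPase=float(atpase.rate(ATP, p)),
    )
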