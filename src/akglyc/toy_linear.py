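"""Conceptual linear production/consumption model of ATP turnover.

A minimal caricature of cellular energy metabolism: ATP consumption is
linear in [ATP], V_c = a [ATP], and ATP production is affine,
V_p = b [ATP] + b1, with negative slope b representing feedback activation
of production as ATP falls.  Closed forms exist for the steady state and for
the metabolic-control-analysis coefficients, making this the reference case
for the stabilization machinery used on the full kinetic models.

Quantities are in arbitrary units (concentration, rate and 1/time units are
mutually consistent but not tied to mM or hours).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LinearToyParams", "NoSteadyStateError", "toy_steady_state",
           "toy_coefficients", "toy_table"]


class NoSteadyStateError(ValueError):
    """No finite positive steady state exists (a <= b)."""


@dataclass(frozen=True)
class LinearToyParams:
    """Consumption slope a (> 0), production slope b (signed, negative for
    feedback), production intercept b1 (> 0)."""

    a: float = 1.0
    b: float = -9.0
    b1: float = 95.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("consumption slope a must be positive")
        if self.b1 <= 0:
            raise ValueError("production intercept b1 must be positive")


def toy_steady_state(p: LinearToyParams) -> float:
    """Steady-state ATP level b1 / (a - b); requires a > b."""
    if p.a - p.b <= 0:
        raise NoSteadyStateError(
            f"a - b = {p.a - p.b} <= 0: production outruns consumption, no steady state"
        )
    return p.b1 / (p.a - p.b)


def toy_coefficients(p: LinearToyParams) -> dict:
    """Control coefficient C = a/(b - a) of consumption activity over the
    steady-state ATP level, and stabilization coefficient Q = -1/C = 1 - b/a.

    Q = 1 for constant production (b = 0); Q > 1 exactly when production has
    negative slope, i.e. feedback improves ATP stabilization.
    """
    if p.a == p.b:
        raise NoSteadyStateError("a = b: control coefficient singular")
    C = p.a / (p.b - p.a)
    Q = 1.0 - p.b / p.a
    return {"C": C, "Q": Q}


def toy_table(a_grid=None, b1: float = 95.0, b_feedback: float = -9.0) -> pd.DataFrame:
    """Steady-state ATP versus consumption activity for constant production
    (b = 0) and for the negative-feedback production law, with Q for each."""
    if a_grid is None:
        a_grid = np.linspace(0.25, 4.0, 16)
    rows = []
    for a in np.asarray(a_grid, dtype=float):
        for b in (0.0, b_feedback):
            p = LinearToyParams(a=a, b=b, b1=b1)
            rows.append({
                "a": a, "b": b,
                "ATP_ST": toy_steady_state(p),
                "Q": toy_coefficients(p)["Q"],
            })
    return pd.DataFrame(rows)
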