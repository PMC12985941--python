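"""Scenario generation: reproducible perturbation experiments on the models.

A :class:`Scenario` is a fully serializable description of one model variant
— a base cell type, parameter overrides, the AK mode, whether PFK's ATP
inhibition is active, and (for random ensembles) the seed that produced it.
Scenario factories cover the published what-if analyses (HK inhibition
constant sweep, regulation knockouts, pool sweeps) and randomized enzyme
ensembles for robustness testing; running a scenario computes its glycolysis
characteristic and classifies the curve shape.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from .parameters import REFERENCE_STATE, ModelParams, load_params
from .steady_state import CharacteristicCurve, characteristic

__all__ = [
    "Scenario",
    "make_khk2_sweep",
    "make_regulation_knockouts",
    "make_pool_scenarios",
    "make_random_ensemble",
    "run_scenario",
    "ensemble_summary",
]

#: Pseudo-random generator recorded in scenario files; ensembles are
#: reproducible from (algorithm, seed) alone.
RNG_ALGORITHM = "numpy-PCG64"


@dataclass(frozen=True)
class Scenario:
    """One reproducible model variant."""

    name: str
    cell_type: str = "erythrocyte"
    overrides: dict[str, float] = field(default_factory=dict)
    ak_mode: str = "equilibrium"
    atp_inhibition: bool = True
    seed: Optional[int] = None
    rng_algorithm: str = RNG_ALGORITHM
    expected: Optional[str] = None  # qualitative tag, e.g. 'bell' / 'monotone'

    def build_params(self) -> ModelParams:
        return load_params(self.cell_type, ak_mode=self.ak_mode, **self.overrides)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "Scenario":
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text_or_path: str | Path) -> "Scenario":
        path = Path(text_or_path)
        text = path.read_text() if path.exists() else str(text_or_path)
        return cls.from_dict(yaml.safe_load(text))


def make_khk2_sweep() -> list[Scenario]:
    """Four (K_HK2, A_HK) pairs along which the HK activity is co-adjusted
    so every characteristic passes through the normal erythrocyte operating
    point; smaller inhibition constants give a steeper descending branch."""
    pairs = [  # (K_HK2 in mM, A_HK in mM/h)
        (0.55e-3, 102.0),
        (5.5e-3, 12.0),   # the default erythrocyte model
        (27.5e-3, 3.4),
        (220e-3, 2.2),
    ]
    return [
        Scenario(
            name=f"khk2_{1e3 * k:g}uM",
            overrides={"K_HK2": k, "A_HK": a},
            expected="bell",
        )
        for k, a in pairs
    ]


def make_regulation_knockouts(fixed_AMP: float = 0.040) -> list[Scenario]:
    """Baseline, PFK-ATP-inhibition frozen, and AK removed (AMP clamped).

    Removing ATP inhibition leaves the bell shape almost unchanged; removing
    AK equilibrium converts the characteristic into a monotonically
    increasing function of ATP.
    """
    return [
        Scenario(name="baseline", expected="bell"),
        Scenario(name="no_atp_inhibition", atp_inhibition=False, expected="bell"),
        Scenario(name="no_ak", ak_mode="absent",
                 overrides={"fixed_AMP": fixed_AMP}, expected="monotone"),
    ]


def make_pool_scenarios(pools=(0.9, 1.79, 3.58)) -> list[Scenario]:
    """Adenine-pool variants used for the pool-invariance analysis."""
    return [
        Scenario(name=f"pool_{A:g}mM", overrides={"A_pool": A}, expected="bell")
        for A in pools
    ]


def make_random_ensemble(n: int, spread: float, seed: int) -> list[Scenario]:
    """``n`` scenarios with the three enzyme activities jointly perturbed
    log-uniformly within [1/spread, spread]; deterministic given ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if spread < 1:
        raise ValueError("spread must be >= 1")
    rng = np.random.default_rng(seed)
    base = load_params("erythrocyte")
    out = []
    for i in range(n):
        factors = spread ** rng.uniform(-1.0, 1.0, size=3)
        out.append(
            Scenario(
                name=f"ensemble_{seed}_{i}",
                overrides={
                    "A_HK": float(base.A_HK * factors[0]),
                    "A_GPI": float(base.A_GPI * factors[1]),
                    "A_PFK": float(base.A_PFK * factors[2]),
                },
                seed=seed,
            )
        )
    return out


def run_scenario(sc: Scenario, n: int = 200,
                 atp_grid=None) -> dict[str, Any]:
    """Compute the scenario's characteristic and classify its shape.

    The operating ATP used for branch classification is the cell type's
    physiological value, rescaled with any pool override.
    """
    p = sc.build_params()
    curve = characteristic(p, atp_grid=atp_grid, n=n,
                           atp_inhibition=sc.atp_inhibition)
    ref = REFERENCE_STATE.get(p.cell_type, REFERENCE_STATE["erythrocyte"])
    base_pool = load_params(sc.cell_type).A_pool if sc.cell_type in ("erythrocyte", "muscle") else p.A_pool
    operating_atp = ref["ATP"] * p.A_pool / base_pool
    shape = curve.classify(operating_atp=operating_atp)
    return {
        "scenario": sc,
        "params": p,
        "curve": curve,
        "operating_ATP": operating_atp,
        "production_at_operating": curve.production_at(operating_atp),
        "classification": shape,
        "matches_expected": sc.expected is None or shape == sc.expected,
    }


def ensemble_summary(scenarios: list[Scenario], n: int = 120) -> dict[str, Any]:
    """Run every scenario and report the fraction whose characteristic keeps
    a descending branch through the (rescaled) operating point."""
    results = [run_scenario(sc, n=n) for sc in scenarios]
    n_bell = sum(1 for r in results if r["classification"] == "bell")
    return {
        "n": len(results),
        "n_bell": n_bell,
        "bell_fraction": n_bell / len(results),
        "classifications": [r["classification"] for r in results],
    }
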