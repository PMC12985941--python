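"""Parameter sets for the glycolytic energy-metabolism models.

Two built-in parameterizations are provided: human erythrocytes and resting
anaerobic (white) mammalian skeletal muscle.  The models share the same rate
laws for hexokinase (HK), glucose-phosphate isomerase (GPI) and
phosphofructokinase (PFK); the cell types differ in enzyme activities,
inorganic phosphate level, adenine nucleotide pool size and ATPase load.

Internal unit convention: every concentration is mM and every time is hours,
so activities are mM/h and first-order rate constants are 1/h.  Configuration
files may state values in µM (or µM-derived units); they are converted on
load.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "ModelParams",
    "ParameterError",
    "SingularityError",
    "load_params",
    "dump_params",
    "REFERENCE_STATE",
    "CELL_TYPES",
]


class ParameterError(ValueError):
    """A parameter value or key is invalid."""


class SingularityError(ParameterError):
    """A parameter value would make the adenylate algebra singular."""


#: Units of each field in the *internal* representation.
FIELD_UNITS: dict[str, str] = {
    "cell_type": "",
    "A_HK": "mM/h",
    "A_GPI": "mM/h",
    "A_PFK": "mM/h",
    "K_HK1": "mM",
    "K_HK2": "mM",
    "K_GPI1": "dimensionless",
    "K_GPI2": "mM",
    "K_GPI3": "mM",
    "K_PFK1": "mM",
    "K_PFK2": "mM",
    "K_PFK3": "mM",
    "K_PFK4": "mM",
    "K_PFK5": "mM",
    "K_PFK6": "mM",
    "L0": "dimensionless",
    "n_allosteric": "dimensionless",
    "Pi": "mM",
    "A_pool": "mM",
    "K_AK": "dimensionless",
    "atpase_linear_a": "1/h",
    "atpase_hyperbolic_Vmax": "mM/h",
    "atpase_K_ATP": "mM",
    "ak_mode": "",
    "fixed_AMP": "mM",
}

# Conversion factors into internal units, keyed by accepted unit spellings.
_UNIT_FACTORS: dict[str, float] = {
    "mM": 1.0,
    "uM": 1e-3,
    "µM": 1e-3,
    "mM/h": 1.0,
    "uM/h": 1e-3,
    "µM/h": 1e-3,
    "1/h": 1.0,
    "dimensionless": 1.0,
    "": 1.0,
}


@dataclass(frozen=True)
class ModelParams:
    """Complete parameter set of one cell-type model.

    All concentrations in mM, activities in mM/h, first-order constants in
    1/h.  ``ak_mode`` selects between the adenylate-kinase equilibrium model
    (ATP/ADP/AMP slaved to the composite variable E = 2 ATP + ADP) and the
    AK-free model in which AMP is clamped at ``fixed_AMP``.
    """

    cell_type: str
    # maximal activities
    A_HK: float
    A_GPI: float
    A_PFK: float
    # hexokinase: ATP half-saturation, G6P product-inhibition constant
    K_HK1: float = 1.0
    K_HK2: float = 5.5e-3
    # GPI: equilibrium ratio [G6P]/[F6P] and Michaelis constants
    K_GPI1: float = 3.0
    K_GPI2: float = 0.3
    K_GPI3: float = 0.2
    # PFK: F6P, ATP, AMP, inhibitory-ATP, allosteric-F6P and Pi constants
    K_PFK1: float = 0.1
    K_PFK2: float = 2.0
    K_PFK3: float = 0.01
    K_PFK4: float = 0.195
    K_PFK5: float = 0.37e-3
    K_PFK6: float = 10.0
    L0: float = 1e8
    n_allosteric: int = 4
    # environment
    Pi: float = 1.0
    A_pool: float = 1.79
    K_AK: float = 1.0
    # ATP-consuming processes
    atpase_linear_a: float = 1.57
    atpase_hyperbolic_Vmax: float = 2.36
    atpase_K_ATP: float = 0.010
    # adenylate handling
    ak_mode: str = "equilibrium"
    fixed_AMP: float = 0.040

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES and self.cell_type != "custom":
            raise ParameterError(
                f"unknown cell_type {self.cell_type!r}; "
                f"expected one of {sorted(CELL_TYPES)} or 'custom'"
            )
        if self.ak_mode not in ("equilibrium", "absent"):
            raise ParameterError(
                f"ak_mode must be 'equilibrium' or 'absent', got {self.ak_mode!r}"
            )
        for f in dataclasses.fields(self):
            if f.name in ("cell_type", "ak_mode", "n_allosteric"):
                continue
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)):
                raise ParameterError(f"parameter {f.name} must be numeric, got {v!r}")
            if not v > 0:
                raise ParameterError(f"parameter {f.name} must be strictly positive, got {v}")
        if self.n_allosteric < 1:
            raise ParameterError("n_allosteric must be >= 1")
        if abs(self.K_AK - 0.25) < 1e-12:
            raise SingularityError(
                "K_AK = 0.25 makes the adenylate split singular (division by 4K - 1)"
            )

    # -- serialization -----------------------------------------------------
    def to_dict(self, with_units: bool = True) -> dict[str, Any]:
        """Plain-dict form; with ``with_units`` each entry is {value, units}."""
        out: dict[str, Any] = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if with_units:
                out[f.name] = {"value": v, "units": FIELD_UNITS[f.name]}
            else:
                out[f.name] = v
        return out

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    def replace(self, **changes: Any) -> "ModelParams":
        if changes and "cell_type" not in changes:
            changes.setdefault("cell_type", self.cell_type)
        return replace(self, **changes)


_ERYTHROCYTE = dict(
    cell_type="erythrocyte",
    A_HK=12.0,
    A_GPI=360.0,
    A_PFK=380.0,
    Pi=1.0,
    A_pool=1.79,
    atpase_linear_a=1.57,
    atpase_hyperbolic_Vmax=2.36,
    fixed_AMP=0.040,
)

_MUSCLE = dict(
    cell_type="muscle",
    A_HK=100.0,
    A_GPI=20000.0,
    A_PFK=6000.0,
    Pi=2.0,
    A_pool=5.4,
    atpase_linear_a=5.16,
    atpase_hyperbolic_Vmax=25.7,
    fixed_AMP=0.030,
)

CELL_TYPES: dict[str, dict[str, Any]] = {
    "erythrocyte": _ERYTHROCYTE,
    "muscle": _MUSCLE,
}

#: Normal physiological operating point (mM) used for initial guesses and
#: consistency checks: G6P, F6P, ATP.
REFERENCE_STATE: dict[str, dict[str, float]] = {
    "erythrocyte": {"G6P": 0.0706, "F6P": 0.0231, "ATP": 1.5},
    "muscle": {"G6P": 0.181, "F6P": 0.060, "ATP": 4.98},
}

_VALID_KEYS = {f.name for f in dataclasses.fields(ModelParams)}


def _coerce_value(name: str, raw: Any) -> Any:
    """Convert a config entry (bare number or {value, units}) to internal units."""
    if name in ("cell_type", "ak_mode"):
        if isinstance(raw, Mapping):
            raw = raw.get("value")
        return raw
    if isinstance(raw, Mapping):
        if "value" not in raw:
            raise ParameterError(f"parameter {name}: mapping entry must contain 'value'")
        value = raw["value"]
        units = raw.get("units", FIELD_UNITS[name])
        if units not in _UNIT_FACTORS:
            raise ParameterError(f"parameter {name}: unknown units {units!r}")
        factor = _UNIT_FACTORS[units]
        # Guard: a µM unit on a field whose internal unit is mM converts; a µM
        # unit on a dimensionless field is a config error.
        if factor != 1.0 and FIELD_UNITS[name] not in ("mM", "mM/h"):
            raise ParameterError(
                f"parameter {name}: units {units!r} incompatible with {FIELD_UNITS[name]!r}"
            )
        raw = float(value) * factor
    if name == "n_allosteric":
        return int(raw)
    return float(raw)


def load_params(source: str | Path | Mapping[str, Any], **overrides: Any) -> ModelParams:
    """Build a validated :class:`ModelParams`.

    ``source`` is a built-in cell-type name (``"erythrocyte"`` or
    ``"muscle"``), a mapping, or a path to a YAML file.  Mappings and files
    may either name a ``cell_type`` to inherit its defaults or supply a
    complete parameter set.  Unknown keys are rejected.  Keyword
    ``overrides`` (in internal units) are applied last.
    """
    if isinstance(source, Mapping):
        data = dict(source)
    elif isinstance(source, (str, Path)) and str(source) in CELL_TYPES:
        data = {"cell_type": str(source)}
    else:
        path = Path(source)
        if not path.exists():
            raise ParameterError(
                f"unknown parameter source {source!r}: not a built-in cell type "
                "and no such file"
            )
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, Mapping):
            raise ParameterError(f"parameter file {path} must contain a mapping")
        data = dict(data)

    unknown = set(data) - _VALID_KEYS
    if unknown:
        raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")

    kwargs: dict[str, Any] = {}
    cell_type = _coerce_value("cell_type", data.get("cell_type", "custom"))
    if cell_type in CELL_TYPES:
        kwargs.update(CELL_TYPES[cell_type])
    else:
        kwargs["cell_type"] = cell_type
    for key, raw in data.items():
        if key == "cell_type":
            continue
        kwargs[key] = _coerce_value(key, raw)

    unknown = set(overrides) - _VALID_KEYS
    if unknown:
        raise ParameterError(f"unknown override keys: {sorted(unknown)}")
    kwargs.update(overrides)
    return ModelParams(**kwargs)


def dump_params(p: ModelParams, path: str | Path) -> None:
    """Write a parameter set to a YAML file (with a units field per entry)."""
    Path(path).write_text(p.to_yaml())
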