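"""Model configurations: parameter values, estimability, bounds, thresholds.

A :class:`ModelConfiguration` bundles everything needed to reproduce a
simulation/calibration setup: the full kinetic parameter vector, the subset
of parameters treated as estimable (with bounds), phase-detection
thresholds and solver tolerances. Which parameters are estimated is an
explicit per-configuration choice — biomass composition fractions, the
carbohydrate set point and the maximum specific growth rate are fixed from
independent measurements/literature in the shipped presets, structural
switches (must type ``delta``, production variants, decay) are never
estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .aminoacids import AMINO_ACID_NAMES
from .kinetics import (
    N_STATES,
    SECONDARY_PRODUCTS,
    KineticParameters,
    PhaseThresholds,
)

__all__ = ["ModelConfiguration", "uvarum_25c_config", "default_bounds"]

#: parameters held fixed in the shipped presets. lambda_c/lambda_p/theta_c
#: come from biomass-composition literature; mu_max_n is measured directly
#: from exponential-phase cell counts; k_d = 0 (parsimonious model) and
#: delta is a structural must-type switch.
FIXED_BY_DEFAULT = ("lambda_c", "lambda_p", "k_d", "delta", "theta_c", "mu_max_n")


def _estimable_names() -> tuple[str, ...]:
    names = ["yxn", "k_nh4"]
    names += [f"k_aa.{a}" for a in AMINO_ACID_NAMES]
    names += ["vmax_glx", "vmax_f", "ks_glx", "ks_f", "alpha", "k_sucrose",
              "tau_gns", "ks_c", "ks_s",
              "y_eth", "y_gly", "y_ace", "y_succ", "y_lac",
              "kc_ace", "kc_succ", "kc_mal", "a0", "phi_c"]
    names += [f"y_products.{m}" for m in SECONDARY_PRODUCTS]
    return tuple(names)


def default_bounds(
    params: KineticParameters, names: tuple[str, ...], span: float = 10.0
) -> dict[str, tuple[float, float]]:
    """Multiplicative bounds (default/span, default*span) per parameter.

    ``a0`` is capped at 1 (physiological-state fraction); zero-valued
    defaults get an absolute band instead.
    """
    out: dict[str, tuple[float, float]] = {}
    for name in names:
        v = params.get(name)
        if name == "a0":
            out[name] = (max(v / span, 1e-4), 1.0)
        elif v == 0.0:
            out[name] = (0.0, 1.0)
        else:
            out[name] = (v / span, v * span)
    return out


@dataclass
class ModelConfiguration:
    """A named, fully specified model setup."""

    name: str
    params: KineticParameters
    estimable: tuple[str, ...]
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    phase_thresholds: PhaseThresholds = field(default_factory=PhaseThresholds)
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self) -> None:
        self.params.validate()
        for name in self.estimable:
            self.params.get(name)  # raises for unknown names
        if not self.bounds:
            self.bounds = default_bounds(self.params, self.estimable)

    @property
    def n_odes(self) -> int:
        """Number of model ODEs: 40 independent states plus the aggregate
        biomass balance dX/dt = dXC/dt + dXP/dt + dXmRNA/dt (X itself is
        reported as the derived sum, never integrated independently)."""
        return N_STATES + 1

    @property
    def n_estimable(self) -> int:
        return len(self.estimable)

    # -- YAML round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        p = self.params
        return {
            "name": self.name,
            "params": {
                **{k: p.get(k) for k in (
                    "lambda_c", "lambda_p", "k_d", "phi_ed_eth50",
                    "phi_ed_steepness", "yxn", "k_nh4", "vmax_glx", "vmax_f",
                    "ks_glx", "ks_f", "alpha", "k_sucrose", "tau_gns", "ks_c",
                    "ks_s", "y_eth", "y_gly", "y_ace", "y_succ", "y_lac",
                    "kc_ace", "kc_succ", "kc_mal", "delta", "a0", "mu_max_n",
                    "theta_c", "phi_c")},
                "k_aa": dict(p.k_aa),
                "y_products": dict(p.y_products),
                "variants": dict(p.variants),
            },
            "estimable": list(self.estimable),
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "phase_thresholds": {
                "lag_threshold": self.phase_thresholds.lag_threshold,
                "yan_epsilon": self.phase_thresholds.yan_epsilon,
                "growth_epsilon": self.phase_thresholds.growth_epsilon,
            },
            "rtol": self.rtol,
            "atol": self.atol,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ModelConfiguration":
        pd = dict(data["params"])
        pd["delta"] = int(pd.get("delta", 1))
        params = KineticParameters(**pd)
        return cls(
            name=data["name"],
            params=params,
            estimable=tuple(data["estimable"]),
            bounds={k: tuple(v) for k, v in data.get("bounds", {}).items()},
            phase_thresholds=PhaseThresholds(**data.get("phase_thresholds", {})),
            rtol=data.get("rtol", 1e-8),
            atol=data.get("atol", 1e-10),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfiguration":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def uvarum_25c_config() -> ModelConfiguration:
    """Configuration for S. uvarum batch fermentation at 25 °C.

    The fermentation medium contained sucrose (hydrolysis active) and the
    data show net acetate and succinate consumption, so the natural-must
    acetate branch (delta = 0) and both consumption rate constants are on.
    This setup exposes 41 model ODEs and 46 estimable parameters.
    """
    params = KineticParameters(
        delta=0,
        k_sucrose=0.1,
        kc_ace=0.02,
        kc_succ=0.005,
    )
    return ModelConfiguration(
        name="uvarum_25c",
        params=params,
        estimable=_estimable_names(),
    )
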