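"""Synthetic fermentation data with the sampling structure of a real study.

Bioreactor campaigns of this kind sample each vessel five to seven times
over the fermentation and run three independent biological replicates;
the generator reproduces exactly that design: simulate a ground-truth
trajectory, sample it at the design times, and draw multiplicative
Gaussian replicate noise (coefficient-of-variation based, truncated at
zero — HPLC error scales roughly with signal and concentrations are
positive). Both the noisy dataset and the noise-free truth are returned
so parameter-recovery experiments can be scored.

The default initial condition mimics a synthetic must: two hexoses at
100 g/L each and 0.3 gN/L of assimilable nitrogen split over ammonium and
the 18 amino acids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aminoacids import AMINO_ACID_NAMES, AMMONIUM, NITROGEN_SOURCES
from .calibration import TimeSeriesDataset
from .kinetics import (
    KineticParameters,
    KineticTrajectory,
    SECONDARY_PRODUCTS,
    make_initial_state,
    simulate,
)
from .network import CompoundMap, MetabolicNetwork, toy_compound_map, toy_network

__all__ = [
    "SamplingDesign",
    "PROFILES",
    "preset_parameters",
    "synthetic_must",
    "generate_dataset",
    "generate_fermentation_fixture",
    "DEFAULT_OBSERVABLES",
    "FIXTURE_HORIZON",
]

#: simulation horizon (h) of the default fixture fermentation.
FIXTURE_HORIZON = 220.0

#: observables quantified at each sampling point (dry weight, residual
#: sugars and nitrogen sources, main by-products, volatiles).
DEFAULT_OBSERVABLES = (
    ("X", "Glx", "F", "NH4Cl", "Eth", "Glycerol", "Ace", "Succ", "Mal")
    + AMINO_ACID_NAMES
    + SECONDARY_PRODUCTS
)


@dataclass(frozen=True)
class SamplingDesign:
    """Sampling times, replicate count and noise model of one campaign."""

    times: tuple[float, ...] = (0.0, 12.0, 24.0, 48.0, 96.0, 150.0, 220.0)
    replicates: int = 3
    cv: float = 0.05  # per-observable coefficient of variation
    seed: int = 0
    observables: tuple[str, ...] = DEFAULT_OBSERVABLES

    def __post_init__(self) -> None:
        if len(self.times) < 5:
            raise ValueError("need at least 5 sampling times")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("sampling times must be strictly increasing")
        if self.replicates < 1:
            raise ValueError("need at least 1 replicate")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def synthetic_must(
    hexose: float = 100.0,
    yan: float = 0.3,
    nh4_nitrogen_fraction: float = 0.4,
    biomass: float = 0.02,
    sucrose: float = 0.0,
    lambda_c: float = 0.29,
    lambda_p: float = 0.59,
) -> np.ndarray:
    """Initial state of a synthetic-must fermentation.

    ``hexose`` g/L of each of glucose and fructose; ``yan`` gN/L of
    assimilable nitrogen with ``nh4_nitrogen_fraction`` of it as ammonium
    and the rest split equally (as nitrogen) over the 18 amino acids;
    ``biomass`` gDW/L of inoculum split by the composition fractions.
    """
    n_nh4 = yan * nh4_nitrogen_fraction
    n_per_aa = yan * (1.0 - nh4_nitrogen_fraction) / len(AMINO_ACID_NAMES)
    values = {
        "XC": lambda_c * biomass,
        "XP": lambda_p * biomass,
        "XmRNA": (1.0 - lambda_c - lambda_p) * biomass,
        "YAN": yan,
        "NH4Cl": n_nh4 / AMMONIUM.nitrogen_fraction,
        "Sucrose": sucrose,
        "Glx": hexose,
        "F": hexose,
        "GNS": 0.0,
    }
    for name in AMINO_ACID_NAMES:
        values[name] = n_per_aa / NITROGEN_SOURCES[name].nitrogen_fraction
    return make_initial_state(**values)


def _base_parameters() -> KineticParameters:
    """Kinetic parameters of the fixture fermentation (synthetic must,
    sucrose-free, magnitudes typical of a wine-yeast batch at 20-25 °C)."""
    return KineticParameters(
        yxn=6.0,
        k_nh4=0.18,
        k_aa={name: 0.15 for name in AMINO_ACID_NAMES},
        vmax_glx=1.8,
        vmax_f=1.5,
        ks_glx=25.0,
        ks_f=35.0,
        alpha=1.0,
        k_sucrose=0.0,
        tau_gns=0.05,
        ks_c=0.01,
        ks_s=8.0,
        y_eth=0.42,
        y_gly=0.035,
        y_ace=0.004,
        y_succ=0.003,
        y_lac=0.001,
        kc_ace=0.0,
        kc_succ=0.002,
        kc_mal=0.01,
        delta=1,
        a0=0.15,
        mu_max_n=0.3,
        theta_c=0.42,
        phi_c=0.2,
        y_products={"EthylA": 3e-4, "IamoA": 5e-5, "PEA": 2e-5,
                    "Iobut": 3e-4, "Iamo": 1.5e-3, "BDO": 2e-3, "PE": 3e-4},
    )


def _profile_fast() -> KineticParameters:
    return _base_parameters()


def _profile_slow() -> KineticParameters:
    """Slow fructose uptake, succinate-prone profile (fructophobic species
    with an active reductive branch)."""
    p = _base_parameters()
    return p.with_values({
        "vmax_glx": 1.2, "vmax_f": 0.6, "ks_f": 60.0,
        "y_succ": 0.009, "kc_succ": 0.0005, "mu_max_n": 0.2,
    })


def _profile_high_glycerol() -> KineticParameters:
    """Cryotolerant-style profile channelling more carbon to glycerol."""
    p = _base_parameters()
    return p.with_values({
        "vmax_glx": 1.5, "vmax_f": 1.3, "y_gly": 0.08, "y_eth": 0.40,
        "y_products.BDO": 4e-3, "y_products.PE": 6e-4,
    })


PROFILES = {
    "fast": _profile_fast,
    "slow": _profile_slow,
    "high_glycerol": _profile_high_glycerol,
}


def preset_parameters(profile: str) -> KineticParameters:
    """Deterministic, simulate-able parameter preset by profile name."""
    try:
        factory = PROFILES[profile]
    except KeyError:
        raise KeyError(
            f"unknown profile {profile!r}; known: {sorted(PROFILES)}") from None
    params = factory()
    params.validate()
    return params


def generate_dataset(
    params: KineticParameters,
    initial_state: np.ndarray,
    design: SamplingDesign,
    sigma_floor_frac: float = 0.05,
) -> tuple[TimeSeriesDataset, KineticTrajectory]:
    """Simulate, sample and perturb: one synthetic measurement campaign.

    Returns the replicate-resolved noisy dataset and the noise-free truth
    trajectory (dense grid over the sampling horizon). Fully deterministic
    given ``design.seed``.
    """
    t_final = design.times[-1]
    t_grid = np.union1d(np.linspace(0.0, t_final, 441), np.asarray(design.times))
    truth = simulate(params, initial_state, t_grid)

    from .kinetics import STATE_INDEX

    rng = np.random.default_rng(design.seed)
    rows = []
    for t in design.times:
        state = truth.state_at(t)
        x_total = float(state[0] + state[1] + state[2])
        for obs in design.observables:
            true_val = x_total if obs == "X" else float(state[STATE_INDEX[obs]])
            noise = rng.normal(0.0, design.cv, size=design.replicates)
            for r in range(design.replicates):
                value = max(true_val * (1.0 + noise[r]), 0.0)
                rows.append({"time": t, "observable": obs,
                             "replicate": r + 1, "value": value})
    dataset = TimeSeriesDataset(
        data=pd.DataFrame(rows),
        initial_state=np.asarray(initial_state, dtype=float).copy(),
        sigma_floor_frac=sigma_floor_frac,
    )
    return dataset, truth


def generate_fermentation_fixture(
    n_steps: int = 100,
) -> tuple[KineticTrajectory, MetabolicNetwork, CompoundMap]:
    """Matched end-to-end bundle: kinetic trajectory + toy network + map.

    The trajectory is the "fast" profile on the default synthetic must,
    whose derivative magnitudes keep every dFBA step within the toy
    network's capacity; ``n_steps + 1`` uniformly spaced grid points span
    the fermentation.
    """
    params = preset_parameters("fast")
    t_grid = np.linspace(0.0, FIXTURE_HORIZON, n_steps + 1)
    traj = simulate(params, synthetic_must(), t_grid)
    return traj, toy_network(), toy_compound_map()
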