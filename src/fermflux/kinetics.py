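"""Continuous multiphase kinetic model of yeast batch fermentation.

The model tracks 40 extracellular/biomass states: the three biomass
components (carbohydrate ``XC``, protein ``XP``, mRNA ``XmRNA``; total dry
weight ``X = XC + XP + XmRNA`` is derived, never integrated independently),
assimilable nitrogen ``YAN`` plus its constituents (ammonium and 18 amino
acids), sucrose and the two hexoses, a regulatory state ``GNS`` tracking the
nitrogen/sugar starvation programme, and the fermentation products (ethanol,
glycerol, acetate, succinate, lactate, malate and seven secondary
metabolites).

Phase structure is emergent rather than switched: a Baranyi–Roberts lag
factor gates uptake, primary growth is driven by nitrogen assimilation,
secondary growth (storage-carbohydrate accumulation) is activated by the
nitrogen-depletion regulator ``phi_NS``, and the transition to stationary
phase follows the product ``phi_NS * phi_sugar`` relaxed through ``GNS``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .aminoacids import AMINO_ACID_NAMES, AMMONIUM, NITROGEN_MW, NITROGEN_SOURCES

__all__ = [
    "STATE_NAMES",
    "SECONDARY_PRODUCTS",
    "PRODUCT_VARIANTS",
    "KineticParameters",
    "KineticTrajectory",
    "PhaseSchedule",
    "PhaseThresholds",
    "IntegrationError",
    "lag_factor",
    "phi_ns",
    "phi_sugar",
    "phi_ethanol_decay",
    "primary_growth_rate",
    "secondary_growth_rate",
    "rhs",
    "simulate",
    "detect_phases",
    "make_initial_state",
]

#: secondary metabolites with variant-dispatched production laws.
SECONDARY_PRODUCTS = ("EthylA", "IamoA", "PEA", "Iobut", "Iamo", "BDO", "PE")

#: recognised production-law variants. ``proportional`` tracks sugar uptake,
#: ``regulated_decline`` multiplies by (1 - GNS), ``nitrogen_delayed``
#: multiplies by phi_NS, ``nitrogen_delayed_repressed`` by phi_NS * (1 - GNS).
PRODUCT_VARIANTS = (
    "proportional",
    "regulated_decline",
    "nitrogen_delayed",
    "nitrogen_delayed_repressed",
)

STATE_NAMES: tuple[str, ...] = (
    ("XC", "XP", "XmRNA", "YAN", "NH4Cl")
    + AMINO_ACID_NAMES
    + ("Sucrose", "Glx", "F", "GNS")
    + ("Eth", "Glycerol", "Ace", "Succ", "Lac", "Mal")
    + SECONDARY_PRODUCTS
)

STATE_INDEX = {name: i for i, name in enumerate(STATE_NAMES)}
N_STATES = len(STATE_NAMES)

_AA_SLICE = slice(STATE_INDEX["Ala"], STATE_INDEX["Val"] + 1)
_AA_NFRAC = np.array([NITROGEN_SOURCES[a].nitrogen_fraction for a in AMINO_ACID_NAMES])
_NH4_NFRAC = AMMONIUM.nitrogen_fraction

_DEFAULT_VARIANTS = {
    "EthylA": "nitrogen_delayed",
    "IamoA": "nitrogen_delayed",
    "PEA": "nitrogen_delayed_repressed",
    "Iobut": "nitrogen_delayed",
    "Iamo": "nitrogen_delayed",
    "BDO": "nitrogen_delayed_repressed",
    "PE": "nitrogen_delayed_repressed",
}


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the time of failure."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


# ---------------------------------------------------------------------------
# constitutive closed forms
# ---------------------------------------------------------------------------

def lag_factor(t, a0: float, mu_max_n: float):
    """Baranyi–Roberts lag factor, a0 / (a0 + (1 - a0) e^{-mu_max_n t}).

    ``a0`` in (0, 1] is the physiological state of the inoculum and
    ``mu_max_n`` (1/h) the maximum specific growth rate. The factor starts
    at ``a0`` and saturates to 1, gating nitrogen uptake out of lag phase.
    """
    if not 0.0 < a0 <= 1.0:
        raise ValueError(f"a0 must be in (0, 1], got {a0}")
    if mu_max_n < 0:
        raise ValueError(f"mu_max_n must be >= 0, got {mu_max_n}")
    t = np.asarray(t, dtype=float)
    return a0 / (a0 + (1.0 - a0) * np.exp(-mu_max_n * t))


def phi_ns(yan, ks_c: float):
    """Nitrogen-starvation regulator, 1 - YAN/(YAN + ks_c) in [0, 1].

    Near 0 while assimilable nitrogen is plentiful; approaches 1 as YAN is
    depleted, switching on carbohydrate accumulation and the stationary
    transcriptional programme. ``ks_c`` (gN/L) is the half-saturation.
    """
    if ks_c <= 0:
        raise ValueError(f"ks_c must be > 0, got {ks_c}")
    yan = np.maximum(np.asarray(yan, dtype=float), 0.0)
    return ks_c / (yan + ks_c)


def phi_sugar(glx, f, ks_s: float):
    """Sugar-depletion regulator, 1 - (Glx+F)/(Glx+F+ks_s) in [0, 1]."""
    if ks_s <= 0:
        raise ValueError(f"ks_s must be > 0, got {ks_s}")
    total = np.maximum(np.asarray(glx, dtype=float), 0.0) + np.maximum(
        np.asarray(f, dtype=float), 0.0
    )
    return ks_s / (total + ks_s)


def phi_ethanol_decay(eth, eth50: float = 80.0, steepness: float = 0.2):
    """Logistic ethanol-stress modifier of the (optional) decay term.

    The decay law is k_d * X_i * phi_ED; the functional form of phi_ED is a
    package design choice (a logistic switch centred at ``eth50`` g/L
    ethanol). Only active when the decay rate k_d > 0; the parsimonious
    default model has k_d = 0.
    """
    eth = np.asarray(eth, dtype=float)
    return 1.0 / (1.0 + np.exp(-steepness * (eth - eth50)))


def primary_growth_rate(aa_rates: Mapping[str, float], yxn: float) -> float:
    """Volumetric primary growth rate mu_N (gDW/(L·h)) from nitrogen uptake.

    mu_N = -14.0067 * sum_i (NN_i / MW_i) * d[AA_i]/dt * Yx/N, summed over
    all nitrogen sources present in ``aa_rates`` (amino acids and ammonium;
    uptake rates are negative, so mu_N >= 0 under consumption).
    """
    total = 0.0
    for name, rate in aa_rates.items():
        spec = NITROGEN_SOURCES.get(name)
        if spec is None:
            raise KeyError(f"unknown nitrogen source {name!r}")
        total += spec.nn / spec.mw * rate
    return -NITROGEN_MW * total * yxn


def secondary_growth_rate(
    x: float, xc: float, phi_ns_value: float, theta_c: float, phi_c: float
) -> float:
    """Volumetric secondary growth rate mu_C (g/(L·h)).

    A proportional controller driving the carbohydrate fraction XC/X towards
    the set point ``theta_c``, gated by the nitrogen regulator:
    mu_C = phi_NS * X * Phi_C * (Theta_C - XC/X).
    """
    if x <= 0:
        raise ValueError(f"total biomass X must be > 0, got {x}")
    return phi_ns_value * x * phi_c * (theta_c - xc / x)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

def _default_k_aa() -> dict[str, float]:
    return {name: 0.2 for name in AMINO_ACID_NAMES}

def _default_y_products() -> dict[str, float]:
    return {name: 1e-4 for name in SECONDARY_PRODUCTS}

def _default_variants() -> dict[str, str]:
    return dict(_DEFAULT_VARIANTS)


@dataclass
class KineticParameters:
    """Full parameter vector of the kinetic model.

    Structural switches (``delta``, ``variants``, decay on/off via ``k_d``)
    live alongside the estimable rate/yield parameters; which parameters are
    *estimated* in a given configuration is decided by the calibration
    config, not here.
    """

    # biomass composition (mass fractions, dimensionless)
    lambda_c: float = 0.29
    lambda_p: float = 0.59
    # decay (off in the parsimonious model)
    k_d: float = 0.0  # 1/h
    phi_ed_eth50: float = 80.0  # g/L ethanol at half-maximal decay
    phi_ed_steepness: float = 0.2  # 1/(g/L)
    # nitrogen assimilation
    yxn: float = 25.0  # gDW / gN
    k_nh4: float = 0.25  # 1/(gprot·h)
    k_aa: dict[str, float] = field(default_factory=_default_k_aa)
    # sugar uptake
    vmax_glx: float = 0.8  # g/(gprot·h)
    vmax_f: float = 0.6
    ks_glx: float = 10.0  # g/L
    ks_f: float = 10.0
    alpha: float = 2.0  # transporter induction gain, (L·h)/gDW
    k_sucrose: float = 0.0  # 1/h
    # regulation
    tau_gns: float = 0.05  # 1/h
    ks_c: float = 0.01  # gN/L, phi_NS half-saturation
    ks_s: float = 10.0  # g/L, phi_sugar half-saturation
    # primary-metabolite yields (g per g sugar)
    y_eth: float = 0.45
    y_gly: float = 0.04
    y_ace: float = 0.004
    y_succ: float = 0.004
    y_lac: float = 0.002
    # consumption rate constants, 1/(gprot·h)
    kc_ace: float = 0.0
    kc_succ: float = 0.005
    kc_mal: float = 0.01
    # must type: 1 = synthetic, 0 = natural (acetate consumption branch)
    delta: int = 1
    # lag phase
    a0: float = 0.05
    mu_max_n: float = 0.25  # 1/h
    # secondary growth
    theta_c: float = 0.45
    phi_c: float = 0.02  # 1/h
    # secondary-metabolite yields (g per g sugar) and production variants
    y_products: dict[str, float] = field(default_factory=_default_y_products)
    variants: dict[str, str] = field(default_factory=_default_variants)

    def validate(self) -> None:
        if self.lambda_c < 0 or self.lambda_p < 0 or self.lambda_c + self.lambda_p > 1:
            raise ValueError("require lambda_c, lambda_p >= 0 and lambda_c + lambda_p <= 1")
        if not 0.0 < self.a0 <= 1.0:
            raise ValueError(f"a0 must be in (0, 1], got {self.a0}")
        if self.delta not in (0, 1):
            raise ValueError(f"delta must be 0 or 1, got {self.delta}")
        for nm in (
            "k_d", "yxn", "k_nh4", "vmax_glx", "vmax_f", "ks_glx", "ks_f",
            "alpha", "k_sucrose", "tau_gns", "ks_c", "ks_s", "y_eth", "y_gly",
            "y_ace", "y_succ", "y_lac", "kc_ace", "kc_succ", "kc_mal",
            "mu_max_n", "theta_c", "phi_c",
        ):
            if getattr(self, nm) < 0:
                raise ValueError(f"parameter {nm} must be >= 0")
        if set(self.k_aa) != set(AMINO_ACID_NAMES):
            raise ValueError("k_aa must cover exactly the 18 assimilated amino acids")
        if set(self.y_products) != set(SECONDARY_PRODUCTS):
            raise ValueError("y_products must cover exactly the secondary metabolites")
        for prod, var in self.variants.items():
            if var not in PRODUCT_VARIANTS:
                raise ValueError(f"unknown production variant {var!r} for {prod}")
        if any(v < 0 for v in self.k_aa.values()) or any(
            v < 0 for v in self.y_products.values()
        ):
            raise ValueError("rate/yield parameters must be >= 0")

    # -- flat named access (used by calibration and config I/O) ------------

    def get(self, name: str) -> float:
        if name.startswith("k_aa."):
            return self.k_aa[name[5:]]
        if name.startswith("y_products."):
            return self.y_products[name[11:]]
        return getattr(self, name)

    def with_values(self, values: Mapping[str, float]) -> "KineticParameters":
        """Return a copy with the given flat-named parameters replaced."""
        out = replace(self, k_aa=dict(self.k_aa), y_products=dict(self.y_products),
                      variants=dict(self.variants))
        for name, value in values.items():
            if name.startswith("k_aa."):
                key = name[5:]
                if key not in out.k_aa:
                    raise KeyError(name)
                out.k_aa[key] = float(value)
            elif name.startswith("y_products."):
                key = name[11:]
                if key not in out.y_products:
                    raise KeyError(name)
                out.y_products[key] = float(value)
            else:
                getattr(out, name)  # raise AttributeError for unknown names
                setattr(out, name, float(value))
        return out


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------

class _RhsContext:
    """Per-simulation cache of parameter arrays for fast RHS evaluation."""

    def __init__(self, p: KineticParameters):
        p.validate()
        self.p = p
        self.k_aa = np.array([p.k_aa[a] for a in AMINO_ACID_NAMES])
        self.y_sec = np.array([p.y_products[m] for m in SECONDARY_PRODUCTS])
        # variant gating encoded as (uses phi_NS, uses 1-GNS) flags
        self.sec_phi = np.array(
            [p.variants[m] in ("nitrogen_delayed", "nitrogen_delayed_repressed")
             for m in SECONDARY_PRODUCTS], dtype=float)
        self.sec_rep = np.array(
            [p.variants[m] in ("regulated_decline", "nitrogen_delayed_repressed")
             for m in SECONDARY_PRODUCTS], dtype=float)
        self.lambda_m = 1.0 - p.lambda_c - p.lambda_p

    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        p = self.p
        dy = np.zeros(N_STATES)
        xc, xp, xmrna = y[0], y[1], y[2]
        x = max(xc + xp + xmrna, 1e-12)
        xp_pos = max(xp, 0.0)
        yan = max(y[3], 0.0)
        nh4 = max(y[4], 0.0)
        aa = np.maximum(y[_AA_SLICE], 0.0)
        suc = max(y[STATE_INDEX["Sucrose"]], 0.0)
        glx = max(y[STATE_INDEX["Glx"]], 0.0)
        fru = max(y[STATE_INDEX["F"]], 0.0)
        gns = min(max(y[STATE_INDEX["GNS"]], 0.0), 1.0)

        lag = p.a0 / (p.a0 + (1.0 - p.a0) * np.exp(-p.mu_max_n * t))
        f_ns = p.ks_c / (yan + p.ks_c)
        f_sugar = p.ks_s / (glx + fru + p.ks_s)

        # nitrogen uptake (generalized mass action, lag-gated)
        d_nh4 = -lag * p.k_nh4 * nh4 * xp_pos
        d_aa = -lag * self.k_aa * aa * xp_pos
        # nitrogen_fraction already carries the 14.0067 * nn / mw prefactor
        mu_n = -p.yxn * (float(d_aa @ _AA_NFRAC) + _NH4_NFRAC * d_nh4)
        mu_c = f_ns * x * p.phi_c * (p.theta_c - xc / x)

        # decay (off unless k_d > 0)
        if p.k_d > 0.0:
            eth = max(y[STATE_INDEX["Eth"]], 0.0)
            decay = p.k_d / (1.0 + np.exp(-p.phi_ed_steepness * (eth - p.phi_ed_eth50)))
        else:
            decay = 0.0

        dy[0] = p.lambda_c * mu_n + mu_c - decay * xc
        dy[1] = p.lambda_p * mu_n - decay * xp
        dy[2] = self.lambda_m * mu_n - decay * xmrna
        dy[3] = -mu_n / p.yxn
        dy[4] = d_nh4
        dy[_AA_SLICE] = d_aa

        # sugars: sucrose hydrolysis feeds half into each hexose
        d_suc = -p.k_sucrose * suc
        induction = 1.0 + p.alpha * mu_n
        d_glx = -p.vmax_glx * xp_pos * glx / (glx + p.ks_glx) * induction - 0.5 * d_suc
        d_f = -p.vmax_f * xp_pos * fru / (fru + p.ks_f) * induction - 0.5 * d_suc
        dy[STATE_INDEX["Sucrose"]] = d_suc
        dy[STATE_INDEX["Glx"]] = d_glx
        dy[STATE_INDEX["F"]] = d_f

        dy[STATE_INDEX["GNS"]] = (f_ns * f_sugar - gns) * p.tau_gns

        d_sugar = d_glx + d_f
        dy[STATE_INDEX["Eth"]] = -p.y_eth * d_sugar
        dy[STATE_INDEX["Glycerol"]] = -p.y_gly * d_sugar * (1.0 - gns)
        dy[STATE_INDEX["Lac"]] = -p.y_lac * d_sugar * (1.0 - gns)
        ace = max(y[STATE_INDEX["Ace"]], 0.0)
        dy[STATE_INDEX["Ace"]] = (
            -p.delta * p.y_ace * d_sugar * (1.0 - gns)
            + (1 - p.delta)
            * (
                -p.y_ace * d_sugar * (1.0 - f_ns)
                - p.kc_ace * f_ns * xp_pos * ace * (1.0 - gns)
            )
        )
        succ = max(y[STATE_INDEX["Succ"]], 0.0)
        dy[STATE_INDEX["Succ"]] = (
            -p.y_succ * f_ns * d_sugar - p.kc_succ * (1.0 - f_ns) * succ * xp_pos
        )
        mal = max(y[STATE_INDEX["Mal"]], 0.0)
        dy[STATE_INDEX["Mal"]] = -p.kc_mal * mal * xp_pos

        gate = (self.sec_phi * f_ns + (1.0 - self.sec_phi)) * (
            1.0 - self.sec_rep * gns
        )
        dy[STATE_INDEX["EthylA"] :] = -self.y_sec * gate * d_sugar
        return dy

    def diagnostics(self, t: float, y: np.ndarray) -> dict[str, float]:
        """Regulatory/rate quantities at one state (lag, phi's, mu's)."""
        p = self.p
        xc, xp, xmrna = y[0], y[1], y[2]
        x = max(xc + xp + xmrna, 1e-12)
        yan = max(y[3], 0.0)
        glx = max(y[STATE_INDEX["Glx"]], 0.0)
        fru = max(y[STATE_INDEX["F"]], 0.0)
        dy = self(t, y)
        mu_n = -p.yxn * (
            float(dy[_AA_SLICE] @ _AA_NFRAC) + _NH4_NFRAC * dy[4]
        )
        f_ns = p.ks_c / (yan + p.ks_c)
        return {
            "lag": float(lag_factor(t, p.a0, p.mu_max_n)),
            "phi_ns": f_ns,
            "phi_sugar": p.ks_s / (glx + fru + p.ks_s),
            "mu_n": mu_n,
            "mu_c": f_ns * x * p.phi_c * (p.theta_c - xc / x),
            "x": x,
            "dx": float(dy[0] + dy[1] + dy[2]),
        }


def rhs(t: float, state: np.ndarray | Mapping[str, float],
        params: KineticParameters) -> np.ndarray:
    """Time derivatives of all 40 states at (t, state).

    The public entry point validates the state (NaN and negative entries
    beyond tolerance are rejected); the integrator uses the same kernel with
    soft clipping inside the rate laws only.
    """
    y = as_state_vector(state)
    if np.any(np.isnan(y)):
        raise ValueError("state contains NaN")
    if np.any(y < -1e-6):
        bad = [STATE_NAMES[i] for i in np.where(y < -1e-6)[0]]
        raise ValueError(f"negative state entries beyond tolerance: {bad}")
    return _RhsContext(params)(float(t), y)


def as_state_vector(state: np.ndarray | Mapping[str, float]) -> np.ndarray:
    if isinstance(state, Mapping):
        y = np.zeros(N_STATES)
        for name, value in state.items():
            if name not in STATE_INDEX:
                raise KeyError(f"unknown state {name!r}")
            y[STATE_INDEX[name]] = value
        return y
    y = np.asarray(state, dtype=float)
    if y.shape != (N_STATES,):
        raise ValueError(f"state vector must have shape ({N_STATES},), got {y.shape}")
    return y.copy()


def make_initial_state(**values: float) -> np.ndarray:
    """State vector with the given named entries and zeros elsewhere."""
    return as_state_vector(values)


# ---------------------------------------------------------------------------
# trajectory container and integration
# ---------------------------------------------------------------------------

@dataclass
class KineticTrajectory:
    """Dense solution of the kinetic model on a time grid.

    ``states``/``derivatives`` are (n_times, n_states) arrays; values at
    off-grid times are linearly interpolated (the default grid is dense
    enough that interpolation error is far below integration tolerance).
    """

    times: np.ndarray
    states: np.ndarray
    derivatives: np.ndarray
    params: KineticParameters

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def column(self, name: str) -> np.ndarray:
        return self.states[:, STATE_INDEX[name]]

    def deriv_column(self, name: str) -> np.ndarray:
        return self.derivatives[:, STATE_INDEX[name]]

    @property
    def total_biomass(self) -> np.ndarray:
        """X(t) = XC + XP + XmRNA (gDW/L)."""
        return self.states[:, 0] + self.states[:, 1] + self.states[:, 2]

    @property
    def total_biomass_rate(self) -> np.ndarray:
        return self.derivatives[:, 0] + self.derivatives[:, 1] + self.derivatives[:, 2]

    def state_at(self, t) -> np.ndarray:
        return self._interp(self.states, t)

    def deriv_at(self, t) -> np.ndarray:
        return self._interp(self.derivatives, t)

    def _interp(self, table: np.ndarray, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t < self.times[0] - 1e-9) or np.any(t > self.times[-1] + 1e-9):
            raise ValueError("time outside trajectory span")
        out = np.empty((t.size, table.shape[1]))
        for j in range(table.shape[1]):
            out[:, j] = np.interp(t, self.times, table[:, j])
        return out[0] if out.shape[0] == 1 else out

    def diagnostics(self) -> dict[str, np.ndarray]:
        """Per-time regulatory quantities (lag, phi_ns, phi_sugar, mu_n, mu_c)."""
        ctx = _RhsContext(self.params)
        rows = [ctx.diagnostics(t, y) for t, y in zip(self.times, self.states)]
        return {k: np.array([r[k] for r in rows]) for k in rows[0]}

    def to_frame(self):
        """Tidy (time, variable, value) DataFrame including derived X."""
        import pandas as pd

        nt = self.times.size
        frames = []
        for j, name in enumerate(STATE_NAMES):
            frames.append(pd.DataFrame(
                {"time": self.times, "variable": name, "value": self.states[:, j]}))
        frames.append(pd.DataFrame(
            {"time": self.times, "variable": "X", "value": self.total_biomass}))
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# units: time in h; biomass in gDW/L; YAN in gN/L; "
                     "all other concentrations in g/L\n")
            self.to_frame().to_csv(fh, index=False)


def simulate(
    params: KineticParameters,
    initial_state: np.ndarray | Mapping[str, float],
    t_grid: Sequence[float] | np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> KineticTrajectory:
    """Integrate the kinetic model over ``t_grid`` (strictly increasing, h).

    Uses a stiffness-capable adaptive solver; stored derivatives are the RHS
    re-evaluated at the stored states, so they are consistent by
    construction. Raises :class:`IntegrationError` (with the failure time)
    if the solver does not reach the end of the grid.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be a strictly increasing 1-D grid")
    y0 = as_state_vector(initial_state)
    if np.any(y0 < 0):
        raise ValueError("initial concentrations must be >= 0")
    ctx = _RhsContext(params)
    sol = solve_ivp(
        ctx, (t_grid[0], t_grid[-1]), y0, method=method, t_eval=t_grid,
        rtol=rtol, atol=atol,
    )
    if not sol.success or sol.t.size != t_grid.size:
        t_fail = float(sol.t[-1]) if sol.t.size else float(t_grid[0])
        raise IntegrationError(
            f"ODE integration failed at t = {t_fail:.3f} h: {sol.message}", t_fail
        )
    states = sol.y.T
    derivs = np.array([ctx(t, y) for t, y in zip(t_grid, states)])
    return KineticTrajectory(t_grid, states, derivs, params)


# ---------------------------------------------------------------------------
# phase detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseThresholds:
    """Numerical thresholds turning the qualitative phase definitions into
    grid crossings; all configurable."""

    lag_threshold: float = 0.99  # lag factor at which lag phase ends
    yan_epsilon: float = 1e-4  # gN/L, nitrogen considered depleted
    growth_epsilon: float = 1e-6  # gDW/(L·h), growth considered null


@dataclass(frozen=True)
class PhaseSchedule:
    """Fermentation phase boundaries (h): lag | growth | gng | stationary."""

    t_lag_end: float
    t_growth_end: float
    t_gng_end: float
    t_final: float
    yan_depleted: bool = True
    growth_ceased: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.t_lag_end <= self.t_growth_end
                <= self.t_gng_end <= self.t_final):
            raise ValueError("phase boundaries must be ordered")

    @property
    def intervals(self) -> dict[str, tuple[float, float]]:
        return {
            "lag": (0.0, self.t_lag_end),
            "growth": (self.t_lag_end, self.t_growth_end),
            "gng": (self.t_growth_end, self.t_gng_end),
            "stationary": (self.t_gng_end, self.t_final),
        }

    def duration(self, phase: str) -> float:
        a, b = self.intervals[phase]
        return b - a


def detect_phases(
    traj: KineticTrajectory, thresholds: PhaseThresholds = PhaseThresholds()
) -> PhaseSchedule:
    """Identify fermentation phases from a simulated trajectory.

    Lag ends when the Baranyi–Roberts factor first reaches
    ``lag_threshold``; primary growth ends when YAN first drops to
    ``yan_epsilon``; the growth/no-growth transition ends when the total
    growth rate dX/dt first becomes numerically null afterwards. If YAN
    never depletes (or growth never ceases) the corresponding boundary is
    the final time and a flag is cleared, with a warning.
    """
    t = traj.times
    t_final = float(t[-1])
    p = traj.params
    lag = lag_factor(t, p.a0, p.mu_max_n)
    hit = np.nonzero(lag >= thresholds.lag_threshold)[0]
    t_lag_end = float(t[hit[0]]) if hit.size else t_final

    yan = traj.column("YAN")
    hit = np.nonzero(yan <= thresholds.yan_epsilon)[0]
    if hit.size:
        t_growth_end = float(t[hit[0]])
        yan_depleted = True
    else:
        t_growth_end = t_final
        yan_depleted = False
        warnings.warn("YAN never depleted within the horizon", stacklevel=2)

    dx = traj.total_biomass_rate
    after = (t >= t_growth_end) & (dx <= thresholds.growth_epsilon)
    hit = np.nonzero(after)[0]
    if hit.size:
        t_gng_end = float(t[hit[0]])
        growth_ceased = True
    else:
        t_gng_end = t_final
        growth_ceased = False
        warnings.warn("growth rate never numerically null within the horizon",
                      stacklevel=2)

    t_lag_end = min(t_lag_end, t_growth_end)
    t_gng_end = max(t_gng_end, t_growth_end)
    return PhaseSchedule(t_lag_end, t_growth_end, t_gng_end, t_final,
                         yan_depleted, growth_ceased)
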