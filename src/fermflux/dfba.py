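"""Direct-approach dynamic flux balance analysis.

The calibrated kinetic trajectory fully determines the FBA constraints at
every time point (no feedback from fluxes to the kinetic states): each
mapped compound's exchange flux is pinned to the unit-converted kinetic
derivative, the biomass reaction to the specific growth rate, and the
growth-associated ATP maintenance demand enters as a lower bound on the
ATP hydrolysis reaction. The cellular objective shifts continuously from
ATP maximization to protein synthesis as nitrogen depletes,

    J(t) = max [ J_ATP * (1 - phi_NS(t)) + J_P * phi_NS(t) ],

and every LP is solved parsimoniously (two-stage pFBA: fix the objective
at its optimum, then minimize total absolute flux).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .kinetics import KineticTrajectory, STATE_INDEX, phi_ns as _phi_ns
from .network import CompoundMap, GamSpec, MetabolicNetwork, gam_total

__all__ = [
    "BoundSet",
    "ObjectiveWeights",
    "FluxTrajectory",
    "InfeasibleProblem",
    "exchange_bounds_at",
    "objective_at",
    "pfba",
    "fva",
    "run_dfba",
]

#: keep the pFBA stage-2 objective at essentially full stage-1 optimality.
DEFAULT_OPT_FRACTION = 1.0 - 1e-6


class InfeasibleProblem(RuntimeError):
    """LP infeasible after the relaxation ladder; carries the offending
    bounds for diagnosis."""

    def __init__(self, message: str, violated: dict | None = None):
        super().__init__(message)
        self.violated = violated or {}


@dataclass
class BoundSet:
    """Per-reaction flux bounds at one time point, with provenance.

    ``provenance`` tags each overridden reaction as "equality",
    "inequality" (noisy-compound relaxation) or leaves it "model-default".
    """

    lb: np.ndarray
    ub: np.ndarray
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        if np.any(self.lb > self.ub + 1e-12):
            raise ValueError("require lb <= ub in a BoundSet")


@dataclass(frozen=True)
class ObjectiveWeights:
    """Weights of the time-varying objective: (1 - phi_NS) on the ATP
    maintenance flux, phi_NS on the protein-synthesis flux."""

    atp: float
    protein: float
    atp_scale: float = 1.0
    protein_scale: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.atp <= 1.0 and 0.0 <= self.protein <= 1.0):
            raise ValueError("objective weights must lie in [0, 1]")
        if abs(self.atp + self.protein - 1.0) > 1e-9:
            raise ValueError("objective weights must sum to 1 before scaling")

    def vector(self, network: MetabolicNetwork) -> np.ndarray:
        c = np.zeros(network.n_reactions)
        c[network.reaction_index(network.atp_maintenance_reaction)] = (
            self.atp * self.atp_scale)
        c[network.reaction_index(network.protein_reaction)] = (
            self.protein * self.protein_scale)
        return c


@dataclass
class FluxTrajectory:
    """pFBA solutions along the kinetic trajectory.

    ``fluxes`` is (n_times, n_reactions) in mmol/(gDW·h); ``dw`` carries
    the kinetic dry-weight biomass (gDW/L — the constant broth volume
    cancels wherever DW enters a flux-score ratio).
    """

    times: np.ndarray
    fluxes: np.ndarray
    objective_values: np.ndarray
    statuses: tuple[str, ...]
    dw: np.ndarray
    reaction_ids: tuple[str, ...]
    relaxation_log: tuple[tuple[float, str], ...] = ()

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluxes = np.asarray(self.fluxes, dtype=float)
        self._index = {r: i for i, r in enumerate(self.reaction_ids)}

    def flux_series(self, reaction_id: str) -> np.ndarray:
        try:
            return self.fluxes[:, self._index[reaction_id]]
        except KeyError:
            raise KeyError(f"unknown reaction {reaction_id!r}") from None

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.fluxes, columns=list(self.reaction_ids))
        df.insert(0, "time", self.times)
        df["status"] = list(self.statuses)
        df["DW"] = self.dw
        return df

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# fluxes in mmol/(gDW·h); DW in gDW/L; time in h\n")
            self.to_frame().to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# constraint construction
# ---------------------------------------------------------------------------

def exchange_bounds_at(
    t: float,
    traj: KineticTrajectory,
    cmap: CompoundMap,
    network: MetabolicNetwork,
) -> BoundSet:
    """Exchange and biomass bounds at time ``t`` from the kinetic model.

    Each mapped compound's specific exchange flux is
    v = (d[compound]/dt) / (MW * X(t)) * 1000 (mmol/(gDW·h), uptake
    negative). Equality-class compounds get lb = ub = v; inequality-class
    compounds keep the direction but relax toward zero (secretion: (0, v);
    uptake: (v, 0)). The biomass reaction is pinned to the specific growth
    rate (dX/dt)/X.
    """
    state = traj.state_at(t)
    deriv = traj.deriv_at(t)
    x = float(state[0] + state[1] + state[2])
    if x <= 0:
        raise ValueError(f"biomass X(t) must be > 0, got {x} at t = {t}")

    lb, ub = network.copy_bounds()
    provenance: dict[str, str] = {}
    for entry in cmap:
        j = network.reaction_index(entry.reaction_id)
        v = float(deriv[STATE_INDEX[entry.state]]) / (entry.mw * x) * 1000.0
        if entry.bound_class == "equality":
            lb[j] = ub[j] = v
            provenance[entry.reaction_id] = "equality"
        else:
            lb[j], ub[j] = (0.0, v) if v >= 0 else (v, 0.0)
            provenance[entry.reaction_id] = "inequality"

    dx = float(deriv[0] + deriv[1] + deriv[2])
    mu = dx / x
    jb = network.reaction_index(network.biomass_reaction)
    lb[jb] = ub[jb] = mu
    provenance[network.biomass_reaction] = "equality"
    return BoundSet(lb, ub, provenance)


def objective_at(t: float, traj: KineticTrajectory,
                 atp_scale: float = 1.0, protein_scale: float = 1.0
                 ) -> ObjectiveWeights:
    """Time-varying objective weights from the nitrogen regulator at ``t``."""
    state = traj.state_at(t)
    f_ns = float(_phi_ns(state[STATE_INDEX["YAN"]], traj.params.ks_c))
    return ObjectiveWeights(atp=1.0 - f_ns, protein=f_ns,
                            atp_scale=atp_scale, protein_scale=protein_scale)


# ---------------------------------------------------------------------------
# LP solves
# ---------------------------------------------------------------------------

#: tight feasibility tolerances so LP optima agree with exact vertex
#: arithmetic to ~1e-10.
_LP_OPTIONS = {
    "primal_feasibility_tolerance": 1e-10,
    "dual_feasibility_tolerance": 1e-10,
}


def _solve_lp(c_min: np.ndarray, a_eq: np.ndarray, b_eq: np.ndarray,
              bounds: list[tuple[float, float]],
              a_ub: np.ndarray | None = None, b_ub: np.ndarray | None = None):
    res = linprog(c_min, A_ub=a_ub, b_ub=b_ub, A_eq=a_eq, b_eq=b_eq,
                  bounds=bounds, method="highs", options=_LP_OPTIONS)
    return res


def _stage1(network: MetabolicNetwork, lb: np.ndarray, ub: np.ndarray,
            c: np.ndarray):
    n = network.n_reactions
    res = _solve_lp(-c, network.s_matrix, np.zeros(network.n_metabolites),
                    list(zip(lb, ub)))
    return res


def pfba(
    network: MetabolicNetwork,
    bounds: BoundSet,
    weights: ObjectiveWeights,
    opt_fraction: float = DEFAULT_OPT_FRACTION,
) -> tuple[np.ndarray, float]:
    """Two-stage parsimonious FBA.

    Stage 1 maximizes the weighted objective subject to S·v = 0 and the
    bounds; stage 2 fixes the objective at >= opt_fraction of the optimum
    and minimizes total absolute flux via a positive/negative split.
    Returns (flux vector, stage-1 objective value).
    """
    if not 0.0 < opt_fraction <= 1.0:
        raise ValueError("opt_fraction must be in (0, 1]")
    c = weights.vector(network)
    res1 = _stage1(network, bounds.lb, bounds.ub, c)
    if res1.status != 0:
        raise InfeasibleProblem(
            f"stage-1 LP not optimal (status {res1.status}: {res1.message})",
            _irreducible_bounds(network, bounds))
    j_opt = -res1.fun

    n = network.n_reactions
    m = network.n_metabolites
    # variables z = [p; q], v = p - q, p, q >= 0
    a_eq = np.hstack([network.s_matrix, -network.s_matrix])
    b_eq = np.zeros(m)
    # original bounds on v and the objective floor as inequalities
    eye = np.eye(n)
    a_ub = np.vstack([
        np.hstack([eye, -eye]),       # v <= ub
        np.hstack([-eye, eye]),       # -v <= -lb
        np.hstack([-c, c])[None, :],  # -c·v <= -floor
    ])
    floor = j_opt - (1.0 - opt_fraction) * max(abs(j_opt), 1.0) - 1e-9
    b_ub = np.concatenate([bounds.ub, -bounds.lb, [-floor]])
    z_bounds = [(0.0, max(float(u), 0.0)) for u in bounds.ub] + [
        (0.0, max(-float(l), 0.0)) for l in bounds.lb]
    res2 = _solve_lp(np.ones(2 * n), a_eq, b_eq, z_bounds, a_ub, b_ub)
    if res2.status != 0:
        raise InfeasibleProblem(
            f"stage-2 LP not optimal (status {res2.status}: {res2.message})")
    v = res2.x[:n] - res2.x[n:]
    return v, float(j_opt)


def fva(
    network: MetabolicNetwork,
    bounds: BoundSet,
    weights: ObjectiveWeights,
    opt_fraction: float = DEFAULT_OPT_FRACTION,
) -> dict[str, tuple[float, float]]:
    """Flux variability analysis at >= opt_fraction of the optimum.

    Returns {reaction_id: (min flux, max flux)}; used as a sanity check
    that parsimony leaves little residual variability.
    """
    c = weights.vector(network)
    res1 = _stage1(network, bounds.lb, bounds.ub, c)
    if res1.status != 0:
        raise InfeasibleProblem(
            f"FVA base LP not optimal (status {res1.status}: {res1.message})")
    j_opt = -res1.fun
    floor = j_opt - (1.0 - opt_fraction) * max(abs(j_opt), 1.0) - 1e-9
    a_ub = (-c)[None, :]
    b_ub = np.array([-floor])
    out: dict[str, tuple[float, float]] = {}
    n = network.n_reactions
    for j, rid in enumerate(network.reaction_ids):
        obj = np.zeros(n)
        obj[j] = 1.0
        lo = _solve_lp(obj, network.s_matrix, np.zeros(network.n_metabolites),
                       list(zip(bounds.lb, bounds.ub)), a_ub, b_ub)
        hi = _solve_lp(-obj, network.s_matrix, np.zeros(network.n_metabolites),
                       list(zip(bounds.lb, bounds.ub)), a_ub, b_ub)
        if lo.status != 0 or hi.status != 0:
            raise InfeasibleProblem(f"FVA sub-LP failed for {rid}")
        out[rid] = (float(lo.fun), float(-hi.fun))
    return out


def _irreducible_bounds(network: MetabolicNetwork, bounds: BoundSet) -> dict:
    tagged = {}
    for rid, tag in bounds.provenance.items():
        j = network.reaction_index(rid)
        tagged[rid] = (tag, float(bounds.lb[j]), float(bounds.ub[j]))
    return tagged


def _relaxed(bounds: BoundSet, network: MetabolicNetwork, widen: float,
             eps: float) -> BoundSet:
    """One rung of the relaxation ladder: widen inequality-class bounds by
    ``widen``, open equality-class bounds to ±eps around the kinetic value."""
    lb, ub = bounds.lb.copy(), bounds.ub.copy()
    for rid, tag in bounds.provenance.items():
        j = network.reaction_index(rid)
        if tag == "inequality":
            lb[j] = lb[j] * widen if lb[j] < 0 else lb[j]
            ub[j] = ub[j] * widen if ub[j] > 0 else ub[j]
        elif tag == "equality" and eps > 0:
            lb[j] -= eps * max(abs(lb[j]), 1.0)
            ub[j] += eps * max(abs(ub[j]), 1.0)
    return BoundSet(lb, ub, dict(bounds.provenance))


def run_dfba(
    traj: KineticTrajectory,
    network: MetabolicNetwork,
    cmap: CompoundMap,
    gam: GamSpec = GamSpec(),
    times: np.ndarray | None = None,
    opt_fraction: float = DEFAULT_OPT_FRACTION,
    atp_scale: float = 1.0,
    protein_scale: float = 1.0,
    relax_widen: float = 1.5,
    relax_eps: float = 0.05,
) -> FluxTrajectory:
    """Solve one pFBA per output time over a calibrated kinetic trajectory.

    ``times`` defaults to a uniform 0.5 h grid over the trajectory span.
    At each step: build the kinetic exchange/biomass bounds, set the ATP
    maintenance lower bound from the GAM decomposition, build the
    phi_NS-weighted objective, and solve pFBA. Infeasible steps walk a
    logged relaxation ladder (widen inequality bounds, then open equality
    bounds to a small band) before giving up.
    """
    if times is None:
        times = np.arange(traj.times[0], traj.times[-1] + 1e-9, 0.5)
    times = np.asarray(times, dtype=float)

    flux_rows, obj_vals, statuses, log = [], [], [], []
    dw = np.empty(times.size)
    j_atpm = network.reaction_index(network.atp_maintenance_reaction)
    for k, t in enumerate(times):
        state = traj.state_at(t)
        deriv = traj.deriv_at(t)
        x = float(state[0] + state[1] + state[2])
        dw[k] = x
        bounds = exchange_bounds_at(t, traj, cmap, network)
        mu = float(deriv[0] + deriv[1] + deriv[2]) / x
        rates = {
            "protein": max(float(deriv[1]), 0.0) / x,
            "rna": max(float(deriv[2]), 0.0) / x,
            "carbohydrate": max(float(deriv[0]), 0.0) / x,
        }
        demand = gam_total(gam, rates, growth_rate=max(mu, 0.0))
        bounds.lb[j_atpm] = demand
        bounds.ub[j_atpm] = max(bounds.ub[j_atpm], demand)
        bounds.provenance[network.atp_maintenance_reaction] = "equality-floor"
        weights = objective_at(t, traj, atp_scale, protein_scale)

        attempt, status = bounds, "optimal"
        for rung in range(3):
            try:
                v, j_opt = pfba(network, attempt, weights, opt_fraction)
                break
            except InfeasibleProblem as err:
                if rung == 0:
                    attempt = _relaxed(bounds, network, relax_widen, 0.0)
                    status = "relaxed-inequality"
                    log.append((float(t), "widened inequality bounds"))
                elif rung == 1:
                    attempt = _relaxed(bounds, network, relax_widen, relax_eps)
                    status = "relaxed-equality"
                    log.append((float(t), "opened equality bounds"))
                else:
                    raise InfeasibleProblem(
                        f"dFBA step at t = {t:.3f} h infeasible after "
                        f"relaxation ladder", err.violated) from err
        flux_rows.append(v)
        obj_vals.append(j_opt)
        statuses.append(status)

    return FluxTrajectory(
        times=times,
        fluxes=np.array(flux_rows),
        objective_values=np.array(obj_vals),
        statuses=tuple(statuses),
        dw=dw,
        reaction_ids=network.reaction_ids,
        relaxation_log=tuple(log),
    )
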