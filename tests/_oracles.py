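"""Independent oracles used by the test suite.

These re-derive expected values by routes independent of the package
implementation: a literal, dictionary-based transcription of the kinetic
rate laws, and an exhaustive active-set enumeration for small LPs.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np

from fermflux.aminoacids import NITROGEN_MW, NITROGEN_SOURCES
from fermflux.kinetics import (
    AMINO_ACID_NAMES,
    SECONDARY_PRODUCTS,
    STATE_INDEX,
    STATE_NAMES,
)


def rhs_oracle(t: float, state: dict[str, float], p) -> dict[str, float]:
    """Term-by-term evaluation of the kinetic rate laws on plain dicts.

    Written directly from the constitutive equations, state by state, with
    no shared code with the package RHS.
    """
    s = {k: max(v, 0.0) for k, v in state.items()}
    xc, xp, xm = state["XC"], state["XP"], state["XmRNA"]
    x = xc + xp + xm

    lag = p.a0 / (p.a0 + (1 - p.a0) * np.exp(-p.mu_max_n * t))
    f_ns = 1.0 - s["YAN"] / (s["YAN"] + p.ks_c)
    f_sug = 1.0 - (s["Glx"] + s["F"]) / (s["Glx"] + s["F"] + p.ks_s)

    d = {}
    d["NH4Cl"] = -lag * p.k_nh4 * s["NH4Cl"] * max(xp, 0.0)
    for name in AMINO_ACID_NAMES:
        d[name] = -lag * p.k_aa[name] * s[name] * max(xp, 0.0)

    mu_n = 0.0
    for name in AMINO_ACID_NAMES + ("NH4Cl",):
        spec = NITROGEN_SOURCES[name]
        mu_n += spec.nn / spec.mw * d[name]
    mu_n = -NITROGEN_MW * mu_n * p.yxn

    mu_c = f_ns * x * p.phi_c * (p.theta_c - xc / x)
    if p.k_d > 0:
        phi_ed = 1.0 / (1.0 + np.exp(-p.phi_ed_steepness
                                     * (s["Eth"] - p.phi_ed_eth50)))
    else:
        phi_ed = 0.0
    d["XC"] = p.lambda_c * mu_n + mu_c - p.k_d * xc * phi_ed
    d["XP"] = p.lambda_p * mu_n - p.k_d * xp * phi_ed
    d["XmRNA"] = (1 - p.lambda_c - p.lambda_p) * mu_n - p.k_d * xm * phi_ed
    d["YAN"] = -mu_n / p.yxn

    d["Sucrose"] = -p.k_sucrose * s["Sucrose"]
    ind = 1.0 + p.alpha * mu_n
    d["Glx"] = (-p.vmax_glx * max(xp, 0.0) * s["Glx"] / (s["Glx"] + p.ks_glx)
                * ind - 0.5 * d["Sucrose"])
    d["F"] = (-p.vmax_f * max(xp, 0.0) * s["F"] / (s["F"] + p.ks_f)
              * ind - 0.5 * d["Sucrose"])
    gns = min(max(state["GNS"], 0.0), 1.0)
    d["GNS"] = (f_ns * f_sug - gns) * p.tau_gns

    dsug = d["Glx"] + d["F"]
    d["Eth"] = -p.y_eth * dsug
    d["Glycerol"] = -p.y_gly * dsug * (1 - gns)
    d["Lac"] = -p.y_lac * dsug * (1 - gns)
    d["Ace"] = (-p.delta * p.y_ace * dsug * (1 - gns)
                + (1 - p.delta) * (-p.y_ace * dsug * (1 - f_ns)
                                   - p.kc_ace * f_ns * max(xp, 0.0)
                                   * s["Ace"] * (1 - gns)))
    d["Succ"] = (-p.y_succ * f_ns * dsug
                 - p.kc_succ * (1 - f_ns) * s["Succ"] * max(xp, 0.0))
    d["Mal"] = -p.kc_mal * s["Mal"] * max(xp, 0.0)

    for name in SECONDARY_PRODUCTS:
        variant = p.variants[name]
        y = p.y_products[name]
        if variant == "proportional":
            d[name] = -y * dsug
        elif variant == "regulated_decline":
            d[name] = -y * dsug * (1 - gns)
        elif variant == "nitrogen_delayed":
            d[name] = -y * f_ns * dsug
        else:  # nitrogen_delayed_repressed
            d[name] = -y * f_ns * dsug * (1 - gns)
    return d


def state_vector_to_dict(y: np.ndarray) -> dict[str, float]:
    return {name: float(y[STATE_INDEX[name]]) for name in STATE_NAMES}


# ---------------------------------------------------------------------------
# LP vertex enumeration
# ---------------------------------------------------------------------------

def enumerate_lp_candidates(
    s_matrix: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    c: np.ndarray | None = None,
    c_rhs: float | None = None,
    tol: float = 1e-7,
) -> list[np.ndarray]:
    """All basic feasible points of {S v = 0, lb <= v <= ub}.

    Variables with lb == ub are substituted out. For the remaining free
    variables, every subset of size equal to the degrees of freedom is
    pinned to each combination of {lower bound, upper bound, 0} (zero only
    where the interval straddles it — |v| kinks there, so minimizers of
    total absolute flux can sit on v_i = 0 facets); the remaining square
    system is solved and feasibility checked. When ``c``/``c_rhs`` are
    given, candidates with the extra active constraint c·v = c_rhs
    (one fewer pin) are enumerated too, covering optima of second-stage
    problems restricted to an optimal face.
    """
    n = len(lb)
    fixed = np.isclose(lb, ub)
    free = np.where(~fixed)[0]
    v_fix = np.where(fixed, lb, 0.0)
    b = -s_matrix[:, fixed] @ v_fix[fixed]

    a = s_matrix[:, free]
    rank = np.linalg.matrix_rank(a, tol=1e-9)
    dof = len(free) - rank

    systems = [(a, b, dof)]
    if c is not None and c_rhs is not None and dof >= 1:
        a_aug = np.vstack([a, c[free]])
        b_aug = np.concatenate([b, [c_rhs - c[fixed] @ v_fix[fixed]]])
        rank_aug = np.linalg.matrix_rank(a_aug, tol=1e-9)
        systems.append((a_aug, b_aug, len(free) - rank_aug))

    candidates: list[np.ndarray] = []
    for a_sys, b_sys, d in systems:
        if d < 0:
            continue
        for pin_set in combinations(range(len(free)), d):
            rest = [i for i in range(len(free)) if i not in pin_set]
            pin_choices = []
            for i in pin_set:
                j = free[i]
                opts = [lb[j], ub[j]]
                if lb[j] < 0.0 < ub[j]:
                    opts.append(0.0)
                pin_choices.append(opts)
            a_rest = a_sys[:, rest]
            pinv = np.linalg.pinv(a_rest)
            for values in product(*pin_choices):
                rhs_vec = b_sys.copy()
                for i, val in zip(pin_set, values):
                    rhs_vec -= a_sys[:, i] * val
                x_rest = pinv @ rhs_vec
                if np.max(np.abs(a_rest @ x_rest - rhs_vec), initial=0.0) > tol:
                    continue
                x = np.empty(len(free))
                for i, val in zip(pin_set, values):
                    x[i] = val
                x[rest] = x_rest
                if np.any(x < lb[free] - tol) or np.any(x > ub[free] + tol):
                    continue
                v = v_fix.copy()
                v[free] = x
                candidates.append(v)
    return candidates


def pfba_oracle(
    s_matrix: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    c: np.ndarray,
    opt_fraction: float = 1.0 - 1e-6,
    tol: float = 1e-7,
) -> tuple[float, float]:
    """Brute-force (optimal objective, minimal total |flux|) of the
    two-stage parsimonious program.

    Stage 1: maximize c·v over the enumerated vertices. Stage 2: minimize
    sum |v| subject to c·v >= floor, where the floor allows the same tiny
    optimality slack as the implementation; its minimizer is either a
    vertex of the |v|-kink arrangement or sits on the active floor
    hyperplane, so both candidate families are enumerated.
    """
    first = enumerate_lp_candidates(s_matrix, lb, ub, tol=tol)
    if not first:
        raise ValueError("no feasible candidate found (infeasible instance?)")
    j_opt = max(float(c @ v) for v in first)
    floor = j_opt - (1.0 - opt_fraction) * max(abs(j_opt), 1.0) - 1e-9
    on_floor = enumerate_lp_candidates(s_matrix, lb, ub, c=c, c_rhs=floor,
                                       tol=tol)
    feasible = [v for v in first + on_floor
                if c @ v >= floor - tol * max(abs(j_opt), 1.0)]
    min_l1 = min(float(np.abs(v).sum()) for v in feasible)
    return j_opt, min_l1
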