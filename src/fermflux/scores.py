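"""Phase-resolved flux scores and differential-reaction selection.

The flux score of reaction r over an interval [tA, tB] is the trapezoidal
time integral of its flux times biomass, normalized by the total hexose
consumption over the same interval:

    FS_r = 100 * ∫ v_r(t)·DW(t) dt / ( ∫|v_Glx·DW| dt + ∫|v_F·DW| dt )

in mmol of compound per mmol of hexose × 100. The normalized flux score
NFS_r divides FS_r by the phase duration (per hour), so species with
different phase lengths remain comparable. Fluxes between dFBA grid points
are interpolated piecewise-linearly, consistent with the trapezoid rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dfba import FluxTrajectory
from .kinetics import PhaseSchedule

__all__ = [
    "FluxScoreTable",
    "flux_score",
    "normalized_flux_score",
    "compute_flux_scores",
    "differential_reactions",
]


def _segment(times: np.ndarray, series: np.ndarray, t_a: float, t_b: float
             ) -> tuple[np.ndarray, np.ndarray]:
    """Grid restricted to [t_a, t_b] with interpolated endpoints."""
    if not times[0] - 1e-9 <= t_a < t_b <= times[-1] + 1e-9:
        raise ValueError(
            f"interval [{t_a}, {t_b}] must be increasing and within the "
            f"trajectory span [{times[0]}, {times[-1]}]")
    inner = times[(times > t_a) & (times < t_b)]
    grid = np.concatenate([[t_a], inner, [t_b]])
    return grid, np.interp(grid, times, series)


def _hexose_denominator(fluxtraj: FluxTrajectory, glx_id: str, f_id: str,
                        t_a: float, t_b: float) -> float:
    total = 0.0
    for rid in (glx_id, f_id):
        grid, vals = _segment(fluxtraj.times,
                              fluxtraj.flux_series(rid) * fluxtraj.dw, t_a, t_b)
        total += float(np.trapezoid(np.abs(vals), grid))
    return total


def flux_score(
    fluxtraj: FluxTrajectory,
    reaction: str,
    t_a: float,
    t_b: float,
    glx_exchange: str = "EX_glc",
    fructose_exchange: str = "EX_fru",
) -> float:
    """Flux score of ``reaction`` over [t_a, t_b] (mmol/mmol hexose × 100).

    Signed: secretion-dominated reactions score positive, uptake negative.
    Raises if the interval consumes no hexose (score undefined).
    """
    denom = _hexose_denominator(fluxtraj, glx_exchange, fructose_exchange,
                                t_a, t_b)
    if denom <= 0.0:
        raise ValueError(
            f"zero hexose consumption over [{t_a}, {t_b}]: flux score undefined")
    grid, vals = _segment(fluxtraj.times,
                          fluxtraj.flux_series(reaction) * fluxtraj.dw, t_a, t_b)
    return 100.0 * float(np.trapezoid(vals, grid)) / denom


def normalized_flux_score(
    fluxtraj: FluxTrajectory,
    reaction: str,
    phase: tuple[float, float],
    **kwargs,
) -> float:
    """Flux score over one phase divided by the phase duration (per hour)."""
    t_a, t_b = phase
    duration = t_b - t_a
    if duration <= 0:
        raise ValueError(f"zero-length phase [{t_a}, {t_b}]")
    return flux_score(fluxtraj, reaction, t_a, t_b, **kwargs) / duration


@dataclass
class FluxScoreTable:
    """Tidy per-reaction, per-phase FS/NFS table with the phase schedule used."""

    table: pd.DataFrame  # columns: reaction, phase, FS, NFS
    phases: PhaseSchedule

    def __post_init__(self) -> None:
        required = {"reaction", "phase", "FS", "NFS"}
        if not required <= set(self.table.columns):
            raise ValueError(f"score table must have columns {sorted(required)}")

    def score(self, reaction: str, phase: str, column: str = "FS") -> float:
        row = self.table[(self.table.reaction == reaction)
                         & (self.table.phase == phase)]
        if row.empty:
            raise KeyError(f"no score for ({reaction!r}, {phase!r})")
        return float(row[column].iloc[0])

    @property
    def phase_names(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.table.phase))

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# FS in mmol per mmol hexose x 100; NFS = FS / phase "
                     "duration (1/h)\n")
            self.table.to_csv(fh, index=False)


def compute_flux_scores(
    fluxtraj: FluxTrajectory,
    phases: PhaseSchedule,
    reactions: tuple[str, ...] | None = None,
    **kwargs,
) -> FluxScoreTable:
    """FS and NFS for every reaction over every non-degenerate phase."""
    reactions = reactions or fluxtraj.reaction_ids
    rows = []
    for phase_name, (t_a, t_b) in phases.intervals.items():
        t_a = max(t_a, float(fluxtraj.times[0]))
        t_b = min(t_b, float(fluxtraj.times[-1]))
        if t_b - t_a <= 0:
            continue
        for rid in reactions:
            fs = flux_score(fluxtraj, rid, t_a, t_b, **kwargs)
            rows.append({"reaction": rid, "phase": phase_name, "FS": fs,
                         "NFS": fs / (t_b - t_a)})
    return FluxScoreTable(pd.DataFrame(rows), phases)


def differential_reactions(
    scores_a: FluxScoreTable,
    scores_b: FluxScoreTable,
    threshold: float = 1e-3,
    column: str = "FS",
) -> set[str]:
    """Reactions whose scores differ between two conditions.

    A reaction is selected when |log10(|S1/S2|)| >= threshold in any shared
    phase. One-sided zeros (S1·S2 = 0 but not both) are treated as
    infinitely different and always selected; both-zero pairs are identical
    and never selected. The two tables must cover the same phases.
    """
    phases_a, phases_b = set(scores_a.phase_names), set(scores_b.phase_names)
    if phases_a != phases_b:
        raise ValueError(
            f"phase mismatch between score tables: {sorted(phases_a)} vs "
            f"{sorted(phases_b)}")
    a = scores_a.table.set_index(["reaction", "phase"])[column]
    b = scores_b.table.set_index(["reaction", "phase"])[column]
    shared = a.index.intersection(b.index)
    selected: set[str] = set()
    for reaction, phase in shared:
        s1, s2 = float(a.loc[(reaction, phase)]), float(b.loc[(reaction, phase)])
        if s1 == 0.0 and s2 == 0.0:
            continue
        if s1 == 0.0 or s2 == 0.0:
            selected.add(reaction)
        elif abs(np.log10(abs(s1 / s2))) >= threshold:
            selected.add(reaction)
    return selected
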