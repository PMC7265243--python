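"""Time integration, experimental conditions and phenotype calls.

A :class:`Condition` expresses an experimental perturbation (degron-mediated
cyclin depletion, Wee1 inhibition, B55 knock-down, ...) as a set of
parameter overrides.  ``run_condition_atlas`` integrates every registered
condition from the interphase state and reduces each run to a row of final
species levels plus a phenotype label, mirroring the heat-map summary of the
model's predictions across the experimental panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (
    STATE_FIELDS,
    ConfigError,
    InvariantViolation,
    ModelParameters,
    ModelState,
    rhs,
)

__all__ = [
    "ATLAS_CONDITIONS",
    "Condition",
    "IntegrationError",
    "LEVEL_FIELDS",
    "PhenotypeCall",
    "Trajectory",
    "apply_condition",
    "builtin_conditions",
    "classify_phenotype",
    "final_levels",
    "initial_state",
    "integrate_trajectory",
    "run_condition_atlas",
]

logger = logging.getLogger(__name__)

#: Columns of a final-level row, in fixed order.
LEVEL_FIELDS = ("A", "Ba", "W", "C25", "G", "ET", "B55a", "Se", "Si", "Sl")

PHENOTYPE_LABELS = ("interphase", "prophase_arrest", "prometaphase_no_late", "mitosis")


class IntegrationError(RuntimeError):
    """Stiff-solver failure; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last good time: {last_time})")
        self.last_time = last_time


@dataclass(frozen=True)
class Condition:
    """A named perturbation as parameter overrides."""

    name: str
    overrides: dict[str, float] = field(default_factory=dict)


def builtin_conditions(p: ModelParameters) -> list[Condition]:
    """The registry of conditions making up the phenotype atlas.

    Scaled overrides (partial B55 depletion) are resolved against the base
    parameter set ``p``.
    """
    return [
        Condition("control", {}),
        Condition("dCycA", {"u_A": 0.0}),
        Condition("dCycB", {"u_B": 0.0}),
        Condition("dCycB_dENSA", {"u_B": 0.0, "ensa_tot": 0.0}),
        Condition("dCycB_dGwl", {"u_B": 0.0, "kag": 0.0}),
        Condition("dCycA_Wee1i", {"u_A": 0.0, "wee1_scale": 0.0}),
        # siRNA-style partial depletion: 10% of B55 remains
        Condition("dCycA_dB55", {"u_A": 0.0, "b55_tot": p.b55_tot * 0.1}),
    ]


#: Names in the built-in registry, in atlas order.
ATLAS_CONDITIONS = tuple(c.name for c in builtin_conditions(ModelParameters()))


def apply_condition(p: ModelParameters, c: Condition) -> ModelParameters:
    """Return a copy of ``p`` with the condition's overrides applied."""
    return p.with_overrides(**c.overrides)


def initial_state() -> ModelState:
    """The interphase initial condition: everything off, Wee1 fully active."""
    return ModelState(W=1.0)


@dataclass(frozen=True)
class Trajectory:
    """A time course: strictly increasing times and aligned state rows."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), len(STATE_FIELDS))
    params: ModelParameters

    def __post_init__(self) -> None:
        if len(self.times) == 0:
            raise ValueError("empty trajectory")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    def state_at(self, index: int) -> ModelState:
        return ModelState.from_array(self.states[index])

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: a time column plus one column per state field."""
        df = pd.DataFrame(self.states, columns=list(STATE_FIELDS))
        df.insert(0, "time", self.times)
        return df


def integrate_trajectory(
    p: ModelParameters,
    t_end: float = 300.0,
    initial: ModelState | None = None,
    rel_tol: float = 1e-8,
    abs_tol: float = 1e-10,
    n_points: int = 601,
) -> Trajectory:
    """Integrate the network over ``[0, t_end]`` with a stiff-capable solver.

    The output grid is evenly spaced (``n_points`` samples); integration is
    adaptive internally.  Every output state is checked against the model's
    physical bounds (tolerance 1e-6); a violation raises rather than being
    silently clamped.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if initial is None:
        initial = initial_state()
    initial.validate(p)
    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        initial.to_array(),
        args=(p,),
        method="LSODA",
        rtol=rel_tol,
        atol=abs_tol,
        t_eval=t_eval,
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else 0.0
        raise IntegrationError(f"integration failed: {sol.message}", last)
    traj = Trajectory(times=sol.t, states=sol.y.T, params=p)
    for i in range(len(traj.times)):
        try:
            traj.state_at(i).validate(p)
        except InvariantViolation as exc:
            raise InvariantViolation(f"at t={traj.times[i]:g}: {exc}") from exc
    return traj


def final_levels(traj: Trajectory) -> np.ndarray:
    """Final species levels ``(A, Ba, W, C25, G, ET, B55a, Se, Si, Sl)``."""
    s = traj.state_at(-1)
    return np.array(
        [s.A, s.Ba, s.W, s.C25, s.G, s.ET, s.b55_active(traj.params), s.Se, s.Si, s.Sl]
    )


@dataclass(frozen=True)
class PhenotypeCall:
    """Phenotype label derived from substrate phosphorylation flags."""

    label: str
    on_flags: tuple[bool, bool, bool]  # (early, intermediate, late)


def classify_phenotype(levels: np.ndarray, threshold: float = 0.5) -> PhenotypeCall:
    """Map final substrate levels to a cell-biological phenotype.

    Substrate classes switch on in order (early, intermediate, late);
    patterns where a later class is on while an earlier one is off are
    diagnostically inconsistent and raise.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if len(levels) != len(LEVEL_FIELDS):
        raise ValueError(f"expected {len(LEVEL_FIELDS)} levels, got {len(levels)}")
    se, si, sl = levels[7], levels[8], levels[9]
    early, inter, late = bool(se > threshold), bool(si > threshold), bool(sl > threshold)
    if (not early and inter) or (not inter and late):
        raise InvariantViolation(
            f"inconsistent substrate pattern (early={early}, intermediate={inter}, "
            f"late={late}): later substrate class on while an earlier one is off"
        )
    if not early:
        label = "interphase"
    elif not inter:
        label = "prophase_arrest"
    elif not late:
        label = "prometaphase_no_late"
    else:
        label = "mitosis"
    return PhenotypeCall(label=label, on_flags=(early, inter, late))


def run_condition_atlas(
    p: ModelParameters,
    conditions: list[Condition] | None = None,
    t_end: float = 300.0,
    threshold: float = 0.5,
    rel_tol: float = 1e-8,
    abs_tol: float = 1e-10,
) -> pd.DataFrame:
    """One final-level row plus phenotype label per condition.

    Deterministic: repeated runs give identical labels and final levels.
    """
    if conditions is None:
        conditions = builtin_conditions(p)
    rows = []
    for cond in conditions:
        pc = apply_condition(p, cond)
        traj = integrate_trajectory(pc, t_end=t_end, rel_tol=rel_tol, abs_tol=abs_tol)
        levels = final_levels(traj)
        call = classify_phenotype(levels, threshold=threshold)
        logger.info("condition %s -> %s", cond.name, call.label)
        rows.append(
            {"condition": cond.name, **dict(zip(LEVEL_FIELDS, levels)), "phenotype": call.label}
        )
    return pd.DataFrame(rows, columns=["condition", *LEVEL_FIELDS, "phenotype"])
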