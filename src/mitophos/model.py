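"""Core ODE network of mitotic entry.

The network couples two cyclin:Cdk1 activities to the phosphorylation state
of three classes of mitotic substrates:

* CycA:Cdk1 (``A``) is synthesised and degraded but carries no inhibitory
  phosphorylation.
* CycB:Cdk1 exists as a total pool (``BT``) of which a part (``BP``) is kept
  inactive by Wee1-mediated Tyr15 phosphorylation; Cdc25 reverses it.  The
  active form is ``Ba = BT - BP``.
* Wee1 (``W``) and Cdc25 (``C25``) are themselves switched by Cdk1 activity
  (Hill kinetics) and by the PP2A:B55 phosphatase, forming the classic
  double-negative / double-positive feedback pair.
* Greatwall kinase (``G``) is activated by cyclin:Cdk1 and phosphorylates
  ENSA (``ET``); phospho-ENSA sequesters PP2A:B55 into an inhibitory complex
  (``Cplx``) that turns over slowly ("unfair competition": pENSA is both
  inhibitor and substrate of the phosphatase).
* Early substrates (``Se``) respond to either cyclin via a Hill switch and a
  constant-activity phosphatase; intermediate substrates (``Si``) are
  phosphorylated by both cyclins and dephosphorylated by PP2A:B55; late
  substrates (``Sl``) strictly require active CycB:Cdk1.

All reactions follow mass action except the Wee1/Cdc25/early-substrate
switches, which use Hill kinetics.  Units are dimensionless concentrations
and "model minutes".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = [
    "ConfigError",
    "InvariantViolation",
    "ModelParameters",
    "ModelState",
    "STATE_FIELDS",
    "canonical_v1",
    "compute_derivatives",
    "hill",
    "load_parameters",
    "save_parameters",
]


class ConfigError(ValueError):
    """Invalid parameter set, condition or configuration file."""


class InvariantViolation(ValueError):
    """A model state left its physical bounds beyond tolerance."""


def hill(x: float, J: float, n: float) -> float:
    """Hill activation function ``x**n / (J**n + x**n)``.

    Strictly increasing in ``x`` with half-maximum at ``x == J``;
    returns 0 at ``x == 0``.

    Raises
    ------
    ValueError
        If ``x < 0``, ``J <= 0`` or ``n < 1``.
    """
    if x < 0:
        raise ValueError(f"hill: x must be non-negative, got {x}")
    if J <= 0:
        raise ValueError(f"hill: J must be positive, got {J}")
    if n < 1:
        raise ValueError(f"hill: n must be >= 1, got {n}")
    if x == 0.0:
        return 0.0
    # evaluate via the ratio to avoid overflow for large x**n
    r = (J / x) ** n
    return 1.0 / (1.0 + r)


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants, Hill constants, totals and condition switches.

    Rates are first-order (1/min) unless they multiply a second species.
    ``u_A``/``u_B`` gate cyclin synthesis (0 or 1); ``wee1_scale`` in [0, 1]
    models chemical Wee1 inhibition.
    """

    # cyclin synthesis / turnover
    ksa: float = 0.02
    kda: float = 0.02
    u_A: float = 1.0
    ksb: float = 0.02
    kdb: float = 0.02
    u_B: float = 1.0
    # Tyr15 modification of CycB:Cdk1
    kwee: float = 0.4
    wee1_scale: float = 1.0
    k25: float = 0.4
    # Wee1 activation/inactivation
    kaw0: float = 0.002
    kaw: float = 1.4
    kiw: float = 30.0
    Jw: float = 0.27
    nw: float = 4.0
    # Cdc25 activation/inactivation
    ka25: float = 1.0
    J25: float = 0.27
    n25: float = 4.0
    ki250: float = 0.02
    ki25: float = 4.0
    # Greatwall
    kag: float = 1.0
    gammaA: float = 1.0
    kig: float = 5.0
    # ENSA / PP2A:B55
    kpens: float = 2.0
    kass: float = 100.0
    kdiss: float = 1.0
    kcat: float = 0.5
    ensa_tot: float = 1.0
    b55_tot: float = 0.5
    gwl_tot: float = 1.0
    # early substrates
    kpe: float = 0.2
    Je: float = 0.3
    ne: float = 4.0
    kde: float = 0.05
    epsB: float = 0.5
    # intermediate substrates
    kpi: float = 0.1
    kdi: float = 1.0
    # late substrates
    kpl: float = 0.1
    kdl: float = 1.0
    # CycA weight in the Wee1/Cdc25 kinase input
    muA: float = 0.6

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ConfigError(f"parameter {f.name} must be a finite number, got {v!r}")
            if v < 0:
                raise ConfigError(f"parameter {f.name} must be >= 0, got {v}")
        for name in ("nw", "n25", "ne"):
            if getattr(self, name) < 1:
                raise ConfigError(f"Hill exponent {name} must be >= 1")
        for name in ("u_A", "u_B"):
            if getattr(self, name) not in (0.0, 1.0):
                raise ConfigError(f"{name} must be 0 or 1, got {getattr(self, name)}")
        if not 0.0 <= self.wee1_scale <= 1.0:
            raise ConfigError(f"wee1_scale must lie in [0, 1], got {self.wee1_scale}")

    def with_overrides(self, **overrides: float) -> "ModelParameters":
        """Return a copy with the given fields replaced; unknown names raise."""
        valid = {f.name for f in fields(self)}
        unknown = set(overrides) - valid
        if unknown:
            raise ConfigError(f"unknown parameter(s): {', '.join(sorted(unknown))}")
        return replace(self, **overrides)

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}


def canonical_v1() -> ModelParameters:
    """The shipped hand-calibrated parameter set ``canonical-v1``.

    Calibrated by grid refinement over the Wee1/Cdc25 switch constants
    (``kwee``, ``kiw``, ``kaw0``, ``Jw``), the Greatwall-ENSA arm
    (``kpens``, ``kig``) and the substrate rate ratios so that the seven
    registered depletion/inhibition conditions reproduce the observed
    cell-biological phenotypes (see :mod:`mitophos.simulate`).
    """
    return ModelParameters()


# Dynamic state variables, in integration order.
STATE_FIELDS = ("A", "BT", "BP", "W", "C25", "G", "ET", "Cplx", "Se", "Si", "Sl")

# fields bounded in [0, 1]
_UNIT_FIELDS = ("W", "C25", "G", "Se", "Si", "Sl")


@dataclass(frozen=True)
class ModelState:
    """Instantaneous values of all dynamic network species.

    ``Ba = BT - BP`` (active CycB:Cdk1) and ``B55a = b55_tot - Cplx``
    (free PP2A:B55) are derived, not stored.
    """

    A: float = 0.0
    BT: float = 0.0
    BP: float = 0.0
    W: float = 0.0
    C25: float = 0.0
    G: float = 0.0
    ET: float = 0.0
    Cplx: float = 0.0
    Se: float = 0.0
    Si: float = 0.0
    Sl: float = 0.0

    @property
    def Ba(self) -> float:
        """Active (Tyr15-unphosphorylated) CycB:Cdk1."""
        return self.BT - self.BP

    def b55_active(self, p: ModelParameters) -> float:
        """Free PP2A:B55, ``b55_tot - Cplx`` (exact by construction)."""
        return p.b55_tot - self.Cplx

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in STATE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ModelState":
        if len(y) != len(STATE_FIELDS):
            raise ValueError(f"expected {len(STATE_FIELDS)} values, got {len(y)}")
        return cls(**{f: float(v) for f, v in zip(STATE_FIELDS, y)})

    def __iter__(self) -> Iterator[float]:
        return iter(self.to_array())

    def validate(self, p: ModelParameters, tol: float = 1e-6) -> None:
        """Check physical bounds, raising :class:`InvariantViolation`.

        Bounds are enforced up to ``tol`` to accommodate integration error.
        """
        def bad(field: str, msg: str) -> None:
            raise InvariantViolation(f"state invariant violated for {field}: {msg}")

        for f in ("A", "BT", "BP", "ET", "Cplx"):
            if getattr(self, f) < -tol:
                bad(f, f"{getattr(self, f)} < 0")
        for f in _UNIT_FIELDS:
            v = getattr(self, f)
            if v < -tol or v > 1.0 + tol:
                bad(f, f"{v} outside [0, 1]")
        if self.BP > self.BT + tol:
            bad("BP", f"BP={self.BP} exceeds BT={self.BT}")
        if self.ET > p.ensa_tot + tol:
            bad("ET", f"ET={self.ET} exceeds ensa_tot={p.ensa_tot}")
        if self.Cplx > min(self.ET, p.b55_tot) + tol:
            bad("Cplx", f"Cplx={self.Cplx} exceeds min(ET, b55_tot)")


def compute_derivatives(state: ModelState, p: ModelParameters) -> np.ndarray:
    """Right-hand side of the network ODEs.

    Returns the time derivative of each dynamic field, ordered as
    :data:`STATE_FIELDS`.  The input state must satisfy its invariants
    (checked with the default 1e-6 tolerance).
    """
    state.validate(p)
    return rhs(0.0, state.to_array(), p)


def rhs(t: float, y: np.ndarray, p: ModelParameters) -> np.ndarray:
    """Unchecked RHS on a raw state vector (solver entry point)."""
    A, BT, BP, W, C25, G, ET, Cplx, Se, Si, Sl = y
    Ba = BT - BP
    B55a = p.b55_tot - Cplx
    # negative excursions within solver tolerance must not feed the Hill
    # terms, whose domain is x >= 0
    tyr_input = max(Ba + p.muA * A, 0.0)
    early_input = max(A + p.epsB * Ba, 0.0)

    dA = p.ksa * p.u_A - p.kda * A
    dBT = p.ksb * p.u_B - p.kdb * BT
    dBP = p.wee1_scale * p.kwee * W * Ba - p.k25 * C25 * BP - p.kdb * BP
    dW = (p.kaw0 + p.kaw * B55a) * (1.0 - W) - p.kiw * hill(tyr_input, p.Jw, p.nw) * W
    dC25 = (
        p.ka25 * hill(tyr_input, p.J25, p.n25) * (1.0 - C25)
        - (p.ki250 + p.ki25 * B55a) * C25
    )
    dG = p.kag * (Ba + p.gammaA * A) * (1.0 - G) - p.kig * B55a * G
    dET = p.kpens * p.gwl_tot * G * (p.ensa_tot - ET) - p.kcat * Cplx
    dCplx = p.kass * (ET - Cplx) * (p.b55_tot - Cplx) - (p.kdiss + p.kcat) * Cplx
    dSe = p.kpe * hill(early_input, p.Je, p.ne) * (1.0 - Se) - p.kde * Se
    dSi = p.kpi * (A + Ba) * (1.0 - Si) - p.kdi * B55a * Si
    dSl = p.kpl * Ba * (1.0 - Sl) - p.kdl * B55a * Sl
    return np.array([dA, dBT, dBP, dW, dC25, dG, dET, dCplx, dSe, dSi, dSl])


# ---------------------------------------------------------------------------
# flat key = value parameter files

def save_parameters(p: ModelParameters, path: str | Path) -> None:
    """Write a parameter set as a flat ``key = value`` text file."""
    lines = [f"{name} = {value!r}" for name, value in p.to_dict().items()]
    Path(path).write_text("\n".join(lines) + "\n")


def load_parameters(path: str | Path) -> ModelParameters:
    """Read a flat ``key = value`` parameter file; unknown keys are rejected."""
    valid = {f.name for f in fields(ModelParameters)}
    overrides: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in valid:
            raise ConfigError(f"{path}:{lineno}: unknown parameter {key!r}")
        try:
            overrides[key] = float(value.strip())
        except ValueError as exc:
            raise ConfigError(f"{path}:{lineno}: invalid number for {key}: {value.strip()!r}") from exc
    return ModelParameters(**overrides)
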