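"""FBA / FVA linear programs and reaction knockouts.

All reported quantities (``bm_max``, FVA min/max) are optima of explicit
LPs and therefore solver-independent; witness flux vectors are exposed for
diagnostics only and are never contractual.

The backend is a single "solve one LP" contract (:func:`solve_lp`) built on
``scipy.optimize.linprog`` with the HiGHS solvers, so another backend can
be swapped in without touching callers.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog

from .envelope import OrganismModule
from .model_core import MetabolicModel, stoichiometric_matrix

__all__ = [
    "LpStatus",
    "FbaResult",
    "FvaResult",
    "KnockoutSpec",
    "LpError",
    "FVA_EPSILON",
    "solve_lp",
    "solve_fba",
    "solve_fva",
    "flux_range",
    "apply_knockouts",
]

#: relative slack applied when fixing growth at its optimum for FVA
FVA_EPSILON = 1e-6

_TOL = 1e-9


class LpError(RuntimeError):
    """The LP solver failed in a way the caller cannot recover from."""


class LpStatus(enum.Enum):
    OPTIMAL = "optimal"
    INFEASIBLE = "infeasible"
    UNBOUNDED = "unbounded"


@dataclass
class FbaResult:
    status: LpStatus
    bm_max: Optional[float]
    flux_vector: Dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status is LpStatus.OPTIMAL


@dataclass(frozen=True)
class FvaResult:
    target_id: str
    v_min: float
    v_max: float

    def __post_init__(self) -> None:
        if self.v_min > self.v_max + 1e-6:
            raise ValueError(
                f"FVA of {self.target_id!r}: min {self.v_min} > max {self.v_max}"
            )


@dataclass(frozen=True)
class KnockoutSpec:
    """A (possibly empty) set of reaction ids whose bounds are nullified."""

    reaction_ids: frozenset = frozenset()

    @classmethod
    def of(cls, *ids: str) -> "KnockoutSpec":
        return cls(frozenset(ids))

    def __bool__(self) -> bool:
        return bool(self.reaction_ids)


# ---------------------------------------------------------------------------
# backend


def solve_lp(
    objective: np.ndarray,
    A_eq,
    b_eq: np.ndarray,
    bounds: Sequence[Tuple[float, float]],
    maximize: bool = True,
) -> Tuple[LpStatus, Optional[float], Optional[np.ndarray]]:
    """Solve max/min ``objective·v`` s.t. ``A_eq v = b_eq``, ``lb <= v <= ub``.

    Returns ``(status, optimum, witness)``; optimum is on the caller's scale
    (already negated back for maximization).
    """
    c = -objective if maximize else objective
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=list(bounds), method="highs")
    if res.status == 0:
        opt = -res.fun if maximize else res.fun
        return LpStatus.OPTIMAL, float(opt), np.asarray(res.x)
    if res.status == 2:
        return LpStatus.INFEASIBLE, None, None
    if res.status == 3:
        return LpStatus.UNBOUNDED, None, None
    raise LpError(f"LP solver failure: status={res.status} message={res.message!r}")


class _LpSystem:
    """Cached S·v = 0 system for one module's network."""

    def __init__(self, network: MetabolicModel):
        self.network = network
        self.S, self.met_rows = stoichiometric_matrix(network)
        self.rxn_index = {r.id: j for j, r in enumerate(network.reactions)}
        self.b = np.zeros(self.S.shape[0])

    def bounds(self, overrides: Optional[Dict[str, Tuple[float, float]]] = None):
        out = [(r.lower_bound, r.upper_bound) for r in self.network.reactions]
        if overrides:
            for rxn_id, bnd in overrides.items():
                out[self.rxn_index[rxn_id]] = bnd
        return out

    def objective(self, rxn_id: str) -> np.ndarray:
        c = np.zeros(len(self.network.reactions))
        c[self.rxn_index[rxn_id]] = 1.0
        return c


def _system(module: OrganismModule) -> _LpSystem:
    return _LpSystem(module.network)


def solve_fba(module: OrganismModule) -> FbaResult:
    """Maximize growth flux subject to mass balance, bounds and media feed.

    The media feed constraints are baked into the module (feed transporters
    carry equality bounds), so the LP is simply max growth over S·v = 0.
    """
    sys_ = _system(module)
    status, opt, x = solve_lp(
        sys_.objective(module.growth_reaction_id), sys_.S, sys_.b, sys_.bounds()
    )
    if status is not LpStatus.OPTIMAL:
        return FbaResult(status=status, bm_max=None)
    fluxes = {r.id: float(x[j]) for j, r in enumerate(module.network.reactions)}
    return FbaResult(status=LpStatus.OPTIMAL, bm_max=opt, flux_vector=fluxes)


def solve_fva(
    module: OrganismModule,
    target_reaction: str,
    bm_max: float,
    epsilon: float = FVA_EPSILON,
    extra_fixed: Optional[Dict[str, Tuple[float, float]]] = None,
) -> FvaResult:
    """Min and max of ``target_reaction`` with growth fixed at ``bm_max``.

    The growth lower bound is set to ``bm_max·(1−epsilon)`` (relative slack
    avoids spurious infeasibility in floating point).  If the LP still comes
    back infeasible the slack is widened tenfold, once.

    ``extra_fixed`` pins additional reactions (id → (lb, ub)), used by the
    serial pipeline to fix the product flux while ranging over uptakes.
    """
    sys_ = _system(module)
    growth = module.growth_reaction_id
    if target_reaction not in sys_.rxn_index:
        raise KeyError(f"unknown reaction {target_reaction!r}")

    for eps in (epsilon, epsilon * 10):
        overrides: Dict[str, Tuple[float, float]] = dict(extra_fixed or {})
        g_lo = bm_max - abs(bm_max) * eps
        g_hi = module.network.reaction(growth).upper_bound
        overrides[growth] = (min(g_lo, g_hi), g_hi)
        bounds = sys_.bounds(overrides)
        c = sys_.objective(target_reaction)
        st_min, v_min, _ = solve_lp(c, sys_.S, sys_.b, bounds, maximize=False)
        st_max, v_max, _ = solve_lp(c, sys_.S, sys_.b, bounds, maximize=True)
        if st_min is LpStatus.OPTIMAL and st_max is LpStatus.OPTIMAL:
            return FvaResult(target_reaction, min(v_min, v_max), max(v_min, v_max))
    raise LpError(
        f"FVA infeasible for {target_reaction!r} with growth fixed at {bm_max}"
    )


def flux_range(
    module: OrganismModule,
    target_reaction: str,
    fixed: Optional[Dict[str, Tuple[float, float]]] = None,
) -> FvaResult:
    """Min/max of a flux under arbitrary pinned bounds (no growth fixing)."""
    sys_ = _system(module)
    bounds = sys_.bounds(dict(fixed or {}))
    c = sys_.objective(target_reaction)
    st_min, v_min, _ = solve_lp(c, sys_.S, sys_.b, bounds, maximize=False)
    st_max, v_max, _ = solve_lp(c, sys_.S, sys_.b, bounds, maximize=True)
    if st_min is not LpStatus.OPTIMAL or st_max is not LpStatus.OPTIMAL:
        raise LpError(f"flux range infeasible for {target_reaction!r}")
    return FvaResult(target_reaction, min(v_min, v_max), max(v_min, v_max))


def apply_knockouts(module: OrganismModule, spec: KnockoutSpec) -> OrganismModule:
    """Copy of ``module`` with both bounds of each listed reaction set to 0."""
    out = module.copy()
    known = {r.id for r in out.network.reactions}
    missing = set(spec.reaction_ids) - known
    if missing:
        raise KeyError(
            f"knockout of unknown reaction(s): {', '.join(sorted(missing))}"
        )
    for rxn in out.network.reactions:
        if rxn.id in spec.reaction_ids:
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return out
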