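"""Flux balance analysis with shadow-price (dual) extraction.

FBA maximises an objective flux (typically biomass) subject to steady state
``S v = 0`` and flux bounds. The LP is solved with HiGHS through
``scipy.optimize.linprog``; the duals of the mass-balance rows are reported
as shadow prices.

Sign convention: the shadow price of metabolite ``m`` is the marginal change
of the maximal objective per unit of *extra availability* of ``m`` (one free
unit of ``m`` supplied to the network). A positive value means more of the
metabolite would raise the objective; zero means no effect; negative means
it would lower it. Solver-native duals are normalised to this convention and
verified against finite-difference re-solves in the test suite.

Boundary species (SBML ``boundaryCondition``) have no balance row and hence
no shadow price; reactions touching them act as uptake/secretion routes.

LP duals are not unique under degeneracy; solutions carry a
``degenerate_flag`` from a primal-degeneracy probe (more active constraints
at the vertex than the problem dimension requires), and comparisons between
models use a tolerance rather than exact dual equality.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.sparse import lil_matrix

from .model import Model

__all__ = [
    "ConditionPreset",
    "FluxSolution",
    "ShadowPriceComparison",
    "light_preset",
    "dark_preset",
    "apply_preset",
    "solve_fba",
    "classify_metabolite",
    "compare_shadow_prices",
    "radar_report",
]

_FEAS_TOL = 1e-9
_OPT_TOL = 1e-7


@dataclass(frozen=True)
class ConditionPreset:
    """Named set of exchange-bound overrides (growth-condition medium).

    ``light`` closes acetate uptake and leaves photon exchange open at the
    model-encoded maxima; ``dark`` closes photon exchange and opens acetate
    uptake at the model-encoded bound.
    """

    name: str
    exchange_overrides: dict = field(default_factory=dict)  # id -> (lb, ub)


def _find_exchanges(model: Model, pattern: str) -> list[str]:
    rx = re.compile(pattern, re.IGNORECASE)
    return [r.id for r in model.exchanges() if rx.search(r.id)]


def light_preset(
    model: Model,
    photon_pattern: str = r"photon|\bhnu\b",
    acetate_pattern: str = r"EX_ac(_|\b|\[)",
) -> ConditionPreset:
    """No acetate, photons open at model-encoded maxima."""
    overrides = {}
    for rid in _find_exchanges(model, acetate_pattern):
        overrides[rid] = (0.0, model.reactions[rid].upper_bound)
    for rid in _find_exchanges(model, photon_pattern):
        r = model.reactions[rid]
        overrides[rid] = (r.lower_bound, r.upper_bound)  # open as encoded
    return ConditionPreset("light", overrides)


def dark_preset(
    model: Model,
    photon_pattern: str = r"photon|\bhnu\b",
    acetate_pattern: str = r"EX_ac(_|\b|\[)",
) -> ConditionPreset:
    """Photons closed, acetate uptake open at the model-encoded bound."""
    overrides = {}
    for rid in _find_exchanges(model, photon_pattern):
        overrides[rid] = (0.0, model.reactions[rid].upper_bound)
    for rid in _find_exchanges(model, acetate_pattern):
        r = model.reactions[rid]
        overrides[rid] = (r.lower_bound, r.upper_bound)
    return ConditionPreset("dark", overrides)


def apply_preset(model: Model, preset: ConditionPreset | None) -> Model:
    if preset is None:
        return model
    out = model.copy()
    for rid, (lb, ub) in preset.exchange_overrides.items():
        if rid not in out.reactions:
            raise KeyError(f"preset {preset.name}: no such exchange {rid}")
        out.reactions[rid].lower_bound = lb
        out.reactions[rid].upper_bound = ub
    return out


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded | failed
    objective_value: float
    fluxes: dict
    shadow_prices: dict
    degenerate_flag: bool = False
    duality_gap: float = float("nan")
    condition: str = ""

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


_STATUS = {0: "optimal", 1: "failed", 2: "infeasible", 3: "unbounded", 4: "failed"}


def solve_fba(
    model: Model,
    objective: str | None = None,
    preset: ConditionPreset | None = None,
) -> FluxSolution:
    """Maximise ``objective`` (default: the model's objective reaction).

    Infeasibility/unboundedness is reported in ``status``, never raised.
    """
    objective = objective or model.objective
    if objective is None or objective not in model.reactions:
        raise KeyError(f"objective reaction not in model: {objective!r}")
    m = apply_preset(model, preset)

    rxn_ids = list(m.reactions)
    met_ids = [mid for mid, met in m.metabolites.items() if not met.boundary]
    met_index = {mid: i for i, mid in enumerate(met_ids)}
    n, nm = len(rxn_ids), len(met_ids)
    S = lil_matrix((nm, n))
    lb = np.empty(n)
    ub = np.empty(n)
    c = np.zeros(n)
    for j, rid in enumerate(rxn_ids):
        r = m.reactions[rid]
        lb[j], ub[j] = r.lower_bound, r.upper_bound
        for mid, coef in r.stoichiometry.items():
            if mid in met_index:
                S[met_index[mid], j] = coef
    c[rxn_ids.index(objective)] = -1.0  # maximise via minimisation

    res = linprog(
        c,
        A_eq=S.tocsr(),
        b_eq=np.zeros(nm),
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options={"primal_feasibility_tolerance": _FEAS_TOL,
                 "dual_feasibility_tolerance": _OPT_TOL},
    )
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return FluxSolution(status, float("nan"), {}, {},
                            condition=preset.name if preset else "")

    v = res.x
    fluxes = dict(zip(rxn_ids, map(float, v)))
    # scipy reports d(min fun)/d(b_eq); with fun = -objective and a supply of
    # one unit of m entering as b_eq[m] = -1, the availability-convention
    # shadow price equals the marginal as reported.
    duals = res.eqlin.marginals
    shadow = {mid: float(duals[i]) for mid, i in met_index.items()}

    # strong-duality audit: b_eq = 0, so the dual objective is the sum of
    # bound terms; scipy's lower/upper marginals are d(fun)/d(bound)
    dual_obj = float(np.dot(lb, res.lower.marginals) + np.dot(ub, res.upper.marginals))
    gap = abs(dual_obj - res.fun) / max(1.0, abs(res.fun))

    # primal-degeneracy probe: at a non-degenerate vertex exactly n - rank(S)
    # variables sit on a bound; more active constraints than that implies
    # alternate optimal bases and possibly non-unique duals
    at_bound = int(np.sum((v - lb < 1e-8) | (ub - v < 1e-8)))
    basis_slots = n - np.linalg.matrix_rank(S.toarray()) if n * nm <= 250_000 else n - nm
    degenerate = at_bound > max(basis_slots, 0)

    return FluxSolution(
        status="optimal",
        objective_value=float(-res.fun),
        fluxes=fluxes,
        shadow_prices=shadow,
        degenerate_flag=bool(degenerate),
        duality_gap=gap,
        condition=preset.name if preset else "",
    )


def classify_metabolite(sp: float, tol: float = 1e-9) -> str:
    """Map a shadow price to {excess, limiting, neutral}.

    Positive shadow prices mark metabolites whose extra availability raises
    the objective (reported as ``excess`` contributions in the study's
    terminology), negative ones lower it (``limiting``), and values at zero
    have no effect (``neutral``).
    """
    if not np.isfinite(sp):
        raise ValueError("shadow price must be finite")
    if sp > tol:
        return "excess"
    if sp < -tol:
        return "limiting"
    return "neutral"


@dataclass
class ShadowPriceComparison:
    """Per-metabolite shadow-price deltas between two solutions."""

    table: pd.DataFrame  # metabolite, sp_a, sp_b, differs
    n_differing: int
    tau: float


def compare_shadow_prices(
    sol_a: FluxSolution, sol_b: FluxSolution, tau: float = 1e-3
) -> ShadowPriceComparison:
    """Count metabolites whose duals differ by more than ``tau``.

    The union namespace is reported; metabolites absent from one solution
    appear with NaN and are not counted as differing (absent, not zero).
    """
    if not (sol_a.optimal and sol_b.optimal):
        raise ValueError("both solutions must be optimal to compare duals")
    union = sorted(set(sol_a.shadow_prices) | set(sol_b.shadow_prices))
    rows = []
    n_diff = 0
    for mid in union:
        a = sol_a.shadow_prices.get(mid, float("nan"))
        b = sol_b.shadow_prices.get(mid, float("nan"))
        shared = mid in sol_a.shadow_prices and mid in sol_b.shadow_prices
        differs = bool(shared and abs(a - b) > tau)
        n_diff += differs
        rows.append({"metabolite": mid, "sp_a": a, "sp_b": b, "differs": differs})
    return ShadowPriceComparison(
        table=pd.DataFrame(rows, columns=["metabolite", "sp_a", "sp_b", "differs"]),
        n_differing=n_diff,
        tau=tau,
    )


def radar_report(comparison: ShadowPriceComparison) -> pd.DataFrame:
    """Lossless tabular export of the per-metabolite dual pairs."""
    return comparison.table[["metabolite", "sp_a", "sp_b"]].copy()
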