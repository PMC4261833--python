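"""Root-gap detection: metabolites the network can never produce.

A *root gap* (the GapFind notion of a no-production metabolite) is a
metabolite with no production route: no reaction carries it as a product,
no reversible reaction consumes it (a reversible consumer can run backward),
and no exchange admits its uptake. Two detectors are provided:

* ``topological`` (default) — structural test per the definition above;
  reversible reactions count as bidirectional producers regardless of their
  current bounds.
* ``lp_producibility`` — respects bounds: metabolite ``m`` is unproducible
  iff the maximal flux through a temporary drain of ``m``, with all
  exchanges opened, is ~0.

Boundary species (mass balance not enforced) are never gap candidates, and
a reaction touching a boundary species on one side is an external route for
its other side. The two methods can disagree on bound-restricted models;
``find_root_gaps`` with ``method="both"`` reports each set so the
discrepancy is visible rather than silently resolved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import lil_matrix

from .model import Model

__all__ = ["GapReport", "find_root_gaps", "compare_gaps"]

_PRODUCIBILITY_TOL = 1e-9


@dataclass(frozen=True)
class GapReport:
    root_gaps: frozenset
    method: str

    def __len__(self):
        return len(self.root_gaps)


def _topological_gaps(model: Model) -> frozenset:
    producible = set()
    for r in model.reactions.values():
        boundary_touch = any(
            model.metabolites[mid].boundary for mid in r.stoichiometry
        )
        for mid, coef in r.stoichiometry.items():
            if model.metabolites[mid].boundary:
                continue
            if coef > 0:
                producible.add(mid)
            elif coef < 0 and r.reversible:
                producible.add(mid)
            elif coef < 0 and r.is_exchange and r.lower_bound < 0:
                # uptake-admitting exchange produces its species
                producible.add(mid)
            elif coef < 0 and boundary_touch:
                # consumes m while a boundary partner balances the other
                # side: running backward is still barred unless reversible,
                # so no production here
                pass
    candidates = {
        mid for mid, met in model.metabolites.items() if not met.boundary
    }
    return frozenset(candidates - producible)


def _lp_gaps(model: Model) -> frozenset:
    rxn_ids = list(model.reactions)
    met_ids = [mid for mid, met in model.metabolites.items() if not met.boundary]
    met_index = {mid: i for i, mid in enumerate(met_ids)}
    n, nm = len(rxn_ids), len(met_ids)
    S = lil_matrix((nm, n + 1))
    lb = np.empty(n + 1)
    ub = np.empty(n + 1)
    for j, rid in enumerate(rxn_ids):
        r = model.reactions[rid]
        if r.is_exchange:
            lb[j], ub[j] = -1000.0, 1000.0  # all exchanges opened
        else:
            lb[j], ub[j] = r.lower_bound, r.upper_bound
        for mid, coef in r.stoichiometry.items():
            if mid in met_index:
                S[met_index[mid], j] = coef
    # last column: the movable drain
    lb[n], ub[n] = 0.0, 1000.0
    c = np.zeros(n + 1)
    c[n] = -1.0
    S = S.tocsc()

    gaps = []
    b = np.zeros(nm)
    for mid in met_ids:
        i = met_index[mid]
        Si = S.tolil()
        Si[i, n] = -1.0
        res = linprog(
            c, A_eq=Si.tocsr(), b_eq=b,
            bounds=np.column_stack([lb, ub]), method="highs",
        )
        produced = -res.fun if res.status == 0 else 0.0
        if produced <= _PRODUCIBILITY_TOL:
            gaps.append(mid)
    return frozenset(gaps)


def find_root_gaps(model: Model, method: str = "topological"):
    """Detect no-production metabolites.

    ``method`` is ``"topological"``, ``"lp_producibility"`` or ``"both"``
    (returns a dict of both reports).
    """
    if method == "topological":
        return GapReport(_topological_gaps(model), method)
    if method in ("lp", "lp_producibility"):
        return GapReport(_lp_gaps(model), "lp_producibility")
    if method == "both":
        return {
            "topological": GapReport(_topological_gaps(model), "topological"),
            "lp_producibility": GapReport(_lp_gaps(model), "lp_producibility"),
        }
    raise ValueError(f"unknown gap method: {method!r}")


def compare_gaps(
    model_a: Model, model_b: Model, method: str = "topological"
) -> tuple[frozenset, frozenset, frozenset]:
    """Partition the union of root gaps: (shared, only_a, only_b)."""
    ga = find_root_gaps(model_a, method).root_gaps
    gb = find_root_gaps(model_b, method).root_gaps
    return ga & gb, ga - gb, gb - ga
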