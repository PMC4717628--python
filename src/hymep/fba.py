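"""Flux balance analysis: steady-state LP maximization of a target flux.

The primal problem is

    max  v_target
    s.t. S v = 0
         lb <= v <= ub

Two interchangeable LP backends are provided: ``scipy`` (HiGHS, the
default) and ``glpk`` (via optlang/swiglpk).  Degenerate optima are the
rule in metabolic LPs, so flux *distributions* are reported from a
secondary parsimonious step (minimize total absolute flux at the fixed
optimum) whenever a stable support is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import scipy.optimize

from .model import MetabolicModel, ModelError, set_bounds, stoichiometric_matrix

__all__ = [
    "FluxSolution",
    "ExchangeIds",
    "maximize_target",
    "parsimonious_fluxes",
    "apply_photomixotrophic_constraints",
]

#: |S v| infinity-norm allowed at a reported optimum
FEASIBILITY_TOL = 1e-9
#: relative agreement demanded between LP backends
OPTIMALITY_TOL = 1e-7
#: relative increase on the objective that counts as an improvement
IMPROVEMENT_TOL = 1e-6


@dataclass
class FluxSolution:
    status: Literal["optimal", "infeasible", "unbounded"]
    objective_value: Optional[float]
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def _solve_lp_scipy(S, c, lb, ub, maximize):
    sign = -1.0 if maximize else 1.0
    res = scipy.optimize.linprog(
        c=sign * c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    if res.status == 0:
        return "optimal", sign * res.fun, np.asarray(res.x)
    if res.status == 2:
        return "infeasible", None, None
    if res.status == 3:
        return "unbounded", None, None
    raise RuntimeError(f"LP solver failure: {res.message}")


def _solve_lp_glpk(S, c, lb, ub, maximize):
    from optlang import glpk_interface as gi

    n = S.shape[1]
    variables = []
    for j in range(n):
        variables.append(
            gi.Variable(
                f"v{j}",
                lb=None if np.isneginf(lb[j]) else float(lb[j]),
                ub=None if np.isposinf(ub[j]) else float(ub[j]),
            )
        )
    prob = gi.Model(name="fba")
    prob.add(variables)
    constraints = []
    for i in range(S.shape[0]):
        terms = [float(S[i, j]) * variables[j] for j in range(n) if S[i, j] != 0]
        if terms:  # an all-zero row is trivially satisfied
            constraints.append(gi.Constraint(sum(terms), lb=0, ub=0))
    prob.add(constraints)
    objective = sum(float(c[j]) * variables[j] for j in range(n) if c[j] != 0)
    prob.objective = gi.Objective(objective, direction="max" if maximize else "min")
    status = prob.optimize()
    if status == "optimal":
        x = np.array([variables[j].primal for j in range(n)])
        return "optimal", prob.objective.value, x
    if status in ("infeasible", "undefined"):
        return "infeasible", None, None
    if status == "unbounded":
        return "unbounded", None, None
    raise RuntimeError(f"GLPK solver failure: status {status}")


_BACKENDS = {"scipy": _solve_lp_scipy, "glpk": _solve_lp_glpk}


def _lp_arrays(model: MetabolicModel):
    S, _, rxn_ids = stoichiometric_matrix(model)
    lb = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([model.reactions[r].upper_bound for r in rxn_ids])
    return S, rxn_ids, lb, ub


def maximize_target(
    model: MetabolicModel,
    target_reaction_id: str,
    backend: str = "scipy",
    direction: str = "max",
) -> FluxSolution:
    """LP optimum of the target flux subject to S v = 0 and the bounds."""
    if target_reaction_id not in model.reactions:
        raise ModelError(f"unknown target reaction {target_reaction_id}")
    S, rxn_ids, lb, ub = _lp_arrays(model)
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(target_reaction_id)] = 1.0
    solve = _BACKENDS[backend]
    status, obj, x = solve(S, c, lb, ub, maximize=(direction == "max"))
    if status != "optimal":
        return FluxSolution(status=status, objective_value=None)
    return FluxSolution("optimal", float(obj), dict(zip(rxn_ids, map(float, x))))


def parsimonious_fluxes(
    model: MetabolicModel, target_reaction_id: str, backend: str = "scipy"
) -> FluxSolution:
    """Parsimonious FBA: minimize total |flux| at the fixed target optimum.

    The target optimum itself is unique; the minimizing flux vector
    stabilizes the reported support across solver vertices.
    """
    first = maximize_target(model, target_reaction_id, backend=backend)
    if not first.optimal:
        return first
    zstar = first.objective_value
    S, rxn_ids, lb, ub = _lp_arrays(model)
    n = len(rxn_ids)
    m = S.shape[0]
    j_t = rxn_ids.index(target_reaction_id)
    # variables [v; a], a_j >= |v_j|; minimize sum a
    A_eq = np.hstack([S, np.zeros((m, n))])
    A_ub = np.vstack(
        [
            np.hstack([np.eye(n), -np.eye(n)]),   #  v - a <= 0
            np.hstack([-np.eye(n), -np.eye(n)]),  # -v - a <= 0
        ]
    )
    b_ub = np.zeros(2 * n)
    # hold the objective at its optimum (tiny slack absorbs solver noise)
    row = np.zeros(2 * n)
    row[j_t] = -1.0
    A_ub = np.vstack([A_ub, row])
    b_ub = np.append(b_ub, -(zstar - 1e-9 * max(1.0, abs(zstar))))
    bounds = list(zip(lb, ub)) + [(0.0, None)] * n
    c = np.concatenate([np.zeros(n), np.ones(n)])
    res = scipy.optimize.linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=np.zeros(m), bounds=bounds, method="highs"
    )
    if res.status != 0:
        raise RuntimeError(f"parsimonious step failed: {res.message}")
    v = res.x[:n]
    return FluxSolution("optimal", float(zstar), dict(zip(rxn_ids, map(float, v))))


@dataclass
class ExchangeIds:
    """Names of the exchange reactions referenced by the simulation setup.

    ``None`` entries mean the model simply has no such exchange (the
    carbon-skeleton fixture omits O2, for instance); a *named* exchange
    missing from the model is an error.
    """

    source: str
    o2: Optional[str] = None
    co2: Optional[str] = None
    photon: tuple[str, ...] = ()


def apply_photomixotrophic_constraints(
    model: MetabolicModel,
    glycogen_uptake: float,
    exchanges: ExchangeIds,
    co2_policy: Literal["efflux_only", "free"] = "efflux_only",
) -> MetabolicModel:
    """Constrain a model to glycogen catabolism in the dark.

    Glycogen (glucose-equivalent) is the sole carbon source at the given
    uptake rate; O2 uptake and photosynthetic CO2 fixation are shut off.
    Under the default ``efflux_only`` policy CO2 may only leave the cell;
    ``free`` leaves the CO2 exchange untouched (the membrane-permeable
    reading), which never changes the succinate optimum on the shipped
    fixture because CO2 influx is not carbon-productive there.
    """
    if glycogen_uptake < 0:
        raise ModelError("uptake rate must be non-negative")
    named = [exchanges.source]
    if exchanges.o2:
        named.append(exchanges.o2)
    if exchanges.co2:
        named.append(exchanges.co2)
    named.extend(exchanges.photon)
    missing = [r for r in named if r not in model.reactions]
    if missing:
        raise ModelError(f"exchange reactions absent from model: {missing}")
    out = set_bounds(model, exchanges.source, -float(glycogen_uptake), 0.0)
    if exchanges.o2:
        rxn = out.reactions[exchanges.o2]
        out = set_bounds(out, exchanges.o2, 0.0, rxn.upper_bound)
    if exchanges.co2 and co2_policy == "efflux_only":
        rxn = out.reactions[exchanges.co2]
        out = set_bounds(out, exchanges.co2, 0.0, max(rxn.upper_bound, 0.0))
    for pid in exchanges.photon:
        out = set_bounds(out, pid, 0.0, 0.0)
    return out
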