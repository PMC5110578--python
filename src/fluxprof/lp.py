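"""Linear programming helpers over the steady-state flux polytope.

All LPs are of the form  optimize c'v  subject to  S v = 0, l <= v <= u,
solved with HiGHS through scipy.  Only what the sampler and the scan need:
single-reaction optima, flux variability (FVA), and a feasibility check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel, resolve_reaction_id, stoichiometric_matrix


class InfeasibleModelError(RuntimeError):
    """The steady-state polytope {v : S v = 0, l <= v <= u} is empty."""


@dataclass
class LPResult:
    objective: float
    fluxes: np.ndarray


def _solve(S: np.ndarray, l: np.ndarray, u: np.ndarray, c: np.ndarray) -> LPResult | None:
    kwargs = {}
    if S.shape[0] > 0:
        kwargs = {"A_eq": S, "b_eq": np.zeros(S.shape[0])}
    res = linprog(c, bounds=list(zip(l, u)), method="highs", **kwargs)
    if not res.success:
        return None
    return LPResult(objective=float(res.fun), fluxes=np.asarray(res.x))


def optimize_reaction(
    model: MetabolicModel, reaction: str, sense: str = "max"
) -> LPResult:
    """Maximize or minimize one reaction's flux over the polytope."""
    S = stoichiometric_matrix(model)
    l, u = model.lower_bounds, model.upper_bounds
    j = model.reaction_index(resolve_reaction_id(model, reaction))
    c = np.zeros(len(model.reactions))
    c[j] = -1.0 if sense == "max" else 1.0
    res = _solve(S, l, u, c)
    if res is None:
        raise InfeasibleModelError(
            f"LP for reaction {reaction!r} in model {model.id!r} is infeasible"
        )
    res.objective = float(res.fluxes[j])
    return res


def assert_feasible(model: MetabolicModel) -> np.ndarray:
    """Return one feasible flux vector, or raise :class:`InfeasibleModelError`."""
    S = stoichiometric_matrix(model)
    l, u = model.lower_bounds, model.upper_bounds
    res = _solve(S, l, u, np.zeros(len(model.reactions)))
    if res is None:
        raise InfeasibleModelError(
            f"model {model.id!r}: no flux vector satisfies S v = 0 with bounds "
            f"l in [{l.min()}, {l.max()}], u in [{u.min()}, {u.max()}]"
        )
    return res.fluxes


def flux_variability(
    model: MetabolicModel,
    reactions: list[str] | None = None,
    *,
    return_vertices: bool = False,
):
    """FVA: the LP minimum and maximum of each reaction's flux.

    Returns ``(mins, maxs)`` arrays; with ``return_vertices=True`` also the
    optimizing flux vectors (2 per reaction, min then max) as matrix columns
    -- these are the warm-up points of the sampler.
    """
    S = stoichiometric_matrix(model)
    l, u = model.lower_bounds, model.upper_bounds
    ids = reactions if reactions is not None else model.reaction_ids
    n = len(model.reactions)
    mins = np.empty(len(ids))
    maxs = np.empty(len(ids))
    vertices = []
    for k, rid in enumerate(ids):
        j = model.reaction_index(resolve_reaction_id(model, rid))
        c = np.zeros(n)
        for sense, sign in (("min", 1.0), ("max", -1.0)):
            c[j] = sign
            res = _solve(S, l, u, c)
            if res is None:
                raise InfeasibleModelError(
                    f"model {model.id!r}: FVA LP infeasible at reaction {rid!r}"
                )
            if sense == "min":
                mins[k] = res.fluxes[j]
            else:
                maxs[k] = res.fluxes[j]
            if return_vertices:
                vertices.append(res.fluxes)
        c[j] = 0.0
    if return_vertices:
        return mins, maxs, np.array(vertices).T
    return mins, maxs
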