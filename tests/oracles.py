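"""Independent oracles for the simulation methods.

Two routes, both independent of the package's solver path (which builds
problems through ``strainbench.solver.LinearProblem`` / ``scipy.optimize.milp``):

* **Vertex enumeration** — exhaustively enumerate the vertices of the flux
  polytope {S v = 0, A v <= b, lb <= v <= ub} (valid for small models); an
  LP optimum is attained at a vertex, so FBA optima are checked against the
  best vertex. Not used for pFBA/lMOMA: a convex piecewise-linear objective
  can attain its minimum off-vertex.
* **Second LP formulation** — scipy.optimize.linprog with a structurally
  different encoding: fluxes stay as single signed variables and absolute
  values are expressed with auxiliary t-variables (t >= v - w, t >= w - v),
  versus the package's split v+ / v- encoding.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog

from strainbench.model import ModelView, as_view, stoichiometric_matrix

_TOL = 1e-7


def _assemble(view: ModelView):
    model = view.model
    S = stoichiometric_matrix(model)
    n = len(model.reactions)
    lb = np.empty(n)
    ub = np.empty(n)
    for j, rid in enumerate(model.reaction_ids):
        lb[j], ub[j] = view.bounds(rid)
    A_ub = []
    b_ub = []
    idx = {rid: j for j, rid in enumerate(model.reaction_ids)}
    for con in view.extra_constraints:
        row = np.zeros(n)
        for rid, coef in con.coefficients:
            row[idx[rid]] = coef
        if con.sense == "<=":
            A_ub.append(row)
            b_ub.append(con.rhs)
        elif con.sense == ">=":
            A_ub.append(-row)
            b_ub.append(-con.rhs)
        else:
            S = np.vstack([S, row])  # equality: extend the equality system
    A_ub = np.array(A_ub) if A_ub else np.zeros((0, n))
    b_ub = np.array(b_ub)
    return S, A_ub, b_ub, lb, ub, idx


def polytope_vertices(view: ModelView) -> np.ndarray:
    """All vertices of {S v = 0, A v <= b, lb <= v <= ub} by enumerating
    active-constraint sets; intended for models with at most ~10 reactions."""
    S, A_ub, b_ub, lb, ub, _ = _assemble(view)
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S) if S.size else 0
    k = n - rank
    # candidate active constraints: each bound, each inequality row
    cands: list[tuple[np.ndarray, float]] = []
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        cands.append((e, lb[j]))
        if ub[j] != lb[j]:
            cands.append((e.copy(), ub[j]))
    for row, rhs in zip(A_ub, b_ub):
        cands.append((row, rhs))
    vertices = []
    eq_rhs = np.zeros(S.shape[0])
    for combo in itertools.combinations(range(len(cands)), k):
        A = np.vstack([S] + [cands[i][0] for i in combo]) if S.size else np.vstack(
            [cands[i][0] for i in combo]
        )
        b = np.concatenate([eq_rhs, [cands[i][1] for i in combo]])
        if np.linalg.matrix_rank(A) < n:
            continue
        v, res, rk, _ = np.linalg.lstsq(A, b, rcond=None)
        if np.max(np.abs(A @ v - b)) > 1e-8:
            continue
        if np.any(v < lb - _TOL) or np.any(v > ub + _TOL):
            continue
        if A_ub.size and np.any(A_ub @ v > b_ub + _TOL):
            continue
        vertices.append(np.round(v, 9))
    if not vertices:
        return np.zeros((0, n))
    return np.unique(np.array(vertices), axis=0)


def fba_vertex_oracle(view, objective_id: str, maximize: bool = True) -> float:
    """FBA optimum as the best objective value over all polytope vertices."""
    view = as_view(view)
    verts = polytope_vertices(view)
    assert len(verts) > 0, "empty polytope in vertex oracle"
    j = view.model.reaction_ids.index(objective_id)
    vals = verts[:, j]
    return float(vals.max() if maximize else vals.min())


def linprog_fba(view, objective_id: str, maximize: bool = True):
    """FBA through scipy.optimize.linprog directly (second formulation)."""
    view = as_view(view)
    S, A_ub, b_ub, lb, ub, idx = _assemble(view)
    n = len(lb)
    c = np.zeros(n)
    c[idx[objective_id]] = -1.0 if maximize else 1.0
    res = linprog(
        c, A_ub=A_ub if A_ub.size else None, b_ub=b_ub if b_ub.size else None,
        A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=list(zip(lb, ub)),
        method="highs",
    )
    if not res.success:
        return None
    return (-res.fun if maximize else res.fun), res.x


def linprog_min_l1(view, reference: dict, fix: dict | None = None):
    """Minimize sum |v - w| with t-variables; ``fix`` pins fluxes
    (reaction id -> value), e.g. the objective flux for a pFBA check.
    Returns (minimal L1 value, flux vector dict)."""
    view = as_view(view)
    S, A_ub, b_ub, lb, ub, idx = _assemble(view)
    n = len(lb)
    w = np.zeros(n)
    for rid, val in (reference or {}).items():
        if rid in idx:
            w[idx[rid]] = val
    # variables: [v (n), t (n)]
    c = np.concatenate([np.zeros(n), np.ones(n)])
    eye = np.eye(n)
    A_ub_full = [
        np.hstack([eye, -eye]),   # v - t <= w
        np.hstack([-eye, -eye]),  # -v - t <= -w
    ]
    b_ub_full = [w, -w]
    if A_ub.size:
        A_ub_full.append(np.hstack([A_ub, np.zeros_like(A_ub)]))
        b_ub_full.append(b_ub)
    A_eq = np.hstack([S, np.zeros((S.shape[0], n))])
    b_eq = np.zeros(S.shape[0])
    bounds = list(zip(lb, ub)) + [(0, None)] * n
    if fix:
        for rid, val in fix.items():
            j = idx[rid]
            bounds[j] = (val, val)
    res = linprog(
        c, A_ub=np.vstack(A_ub_full), b_ub=np.concatenate(b_ub_full),
        A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs",
    )
    if not res.success:
        return None
    fluxes = {rid: res.x[j] for rid, j in idx.items()}
    return res.fun, fluxes


def linprog_fva(view, reaction_id: str, objective_id: str, fraction: float = 1.0):
    """FVA min/max of one reaction at a fraction of the linprog FBA optimum."""
    view = as_view(view)
    opt = linprog_fba(view, objective_id)
    assert opt is not None
    S, A_ub, b_ub, lb, ub, idx = _assemble(view)
    n = len(lb)
    row = np.zeros(n)
    row[idx[objective_id]] = -1.0  # objective >= fraction * opt
    A = np.vstack([A_ub, row]) if A_ub.size else row.reshape(1, -1)
    b = np.concatenate([b_ub, [-fraction * opt[0]]])
    out = []
    for sign in (1.0, -1.0):
        c = np.zeros(n)
        c[idx[reaction_id]] = sign
        res = linprog(c, A_ub=A, b_ub=b, A_eq=S, b_eq=np.zeros(S.shape[0]),
                      bounds=list(zip(lb, ub)), method="highs")
        assert res.success
        out.append(sign * res.fun)
    return out[0], out[1]  # (min, max)
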