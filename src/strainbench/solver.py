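"""Backend-agnostic linear / mixed-integer problem container.

Simulation methods build a :class:`LinearProblem` — variables with bounds,
linear constraints, one linear objective, optional per-variable integrality —
and call :meth:`LinearProblem.solve`. The single shipped backend is scipy's
HiGHS interface (``scipy.optimize.milp``), which handles both LP and MILP.
A quadratic objective (needed for classical MOMA) is deliberately not part of
the contract; callers probe :func:`has_capability`.

Solver failures are returned as statuses, never raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import csr_matrix

__all__ = ["Status", "Solution", "LinearProblem", "has_capability"]


class Status:
    OPTIMAL = "optimal"
    INFEASIBLE = "infeasible"
    UNBOUNDED = "unbounded"
    ERROR = "error"


_MILP_STATUS = {0: Status.OPTIMAL, 2: Status.INFEASIBLE, 3: Status.UNBOUNDED}


def has_capability(name: str) -> bool:
    """Capabilities of the configured backend: 'lp' and 'milp' are available,
    'quadratic' is not."""
    return name in ("lp", "milp")


@dataclass
class Solution:
    status: str
    objective: Optional[float]
    values: dict[str, float] = field(default_factory=dict)


class LinearProblem:
    def __init__(self):
        self._names: list[str] = []
        self._index: dict[str, int] = {}
        self._lb: list[float] = []
        self._ub: list[float] = []
        self._integer: list[bool] = []
        # constraints as (coefs, sense, rhs)
        self._constraints: list[tuple[dict[str, float], str, float]] = []
        self._objective: dict[str, float] = {}
        self._maximize = True

    # -- construction ------------------------------------------------------
    def add_var(
        self, name: str, lb: float = 0.0, ub: float = np.inf, integer: bool = False
    ) -> str:
        if name in self._index:
            raise ValueError(f"duplicate variable '{name}'")
        self._index[name] = len(self._names)
        self._names.append(name)
        self._lb.append(lb)
        self._ub.append(ub)
        self._integer.append(integer)
        return name

    def has_var(self, name: str) -> bool:
        return name in self._index

    def set_var_bounds(self, name: str, lb: float, ub: float) -> None:
        i = self._index[name]
        self._lb[i] = lb
        self._ub[i] = ub

    def add_constraint(
        self, coefficients: Mapping[str, float], sense: str, rhs: float
    ) -> None:
        if sense not in ("<=", ">=", "=="):
            raise ValueError(f"bad constraint sense '{sense}'")
        for name in coefficients:
            if name not in self._index:
                raise ValueError(f"constraint references unknown variable '{name}'")
        self._constraints.append((dict(coefficients), sense, float(rhs)))

    def set_objective(self, coefficients: Mapping[str, float], maximize: bool = True) -> None:
        for name in coefficients:
            if name not in self._index:
                raise ValueError(f"objective references unknown variable '{name}'")
        self._objective = dict(coefficients)
        self._maximize = maximize

    # -- solving -----------------------------------------------------------
    def solve(self) -> Solution:
        n = len(self._names)
        c = np.zeros(n)
        for name, coef in self._objective.items():
            c[self._index[name]] = coef
        sign = -1.0 if self._maximize else 1.0

        constraints = []
        if self._constraints:
            rows, cols, data = [], [], []
            clb = np.empty(len(self._constraints))
            cub = np.empty(len(self._constraints))
            for i, (coefs, sense, rhs) in enumerate(self._constraints):
                for name, coef in coefs.items():
                    rows.append(i)
                    cols.append(self._index[name])
                    data.append(coef)
                if sense == "<=":
                    clb[i], cub[i] = -np.inf, rhs
                elif sense == ">=":
                    clb[i], cub[i] = rhs, np.inf
                else:
                    clb[i], cub[i] = rhs, rhs
            A = csr_matrix((data, (rows, cols)), shape=(len(self._constraints), n))
            constraints = [LinearConstraint(A, clb, cub)]

        res = milp(
            sign * c,
            constraints=constraints,
            bounds=Bounds(np.array(self._lb), np.array(self._ub)),
            integrality=np.array(self._integer, dtype=int),
        )
        status = _MILP_STATUS.get(res.status, Status.ERROR)
        if status != Status.OPTIMAL or res.x is None:
            return Solution(status=status, objective=None)
        values = {name: float(res.x[i]) for i, name in enumerate(self._names)}
        return Solution(status=Status.OPTIMAL, objective=float(sign * res.fun), values=values)
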