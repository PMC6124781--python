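"""Proximal operators and the proximal consensus (ADMM) solver.

The proximal operator of a function ``phi`` with penalty parameter ``rho`` is

    P_phi(v) = argmin_x  phi(x) + (rho / 2) ||x - v||^2 .

Several penalties of interest here (l1, squared-l2, nuclear norm,
non-negativity, fantope membership, linear terms) admit closed-form proximal
operators; smooth losses without a closed form are handled by an inner
quasi-Newton solve.  A sum of such terms is minimized by consensus ADMM:
each term gets its own variable copy driven by its proximal operator, and
the copies are averaged (with dual corrections) until they agree.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
import scipy.optimize


# ---------------------------------------------------------------------------
# closed-form proximal operators
# ---------------------------------------------------------------------------

def prox_l1(v: np.ndarray, threshold: float) -> np.ndarray:
    """Soft-threshold ``v`` elementwise (proximal operator of ``thr * ||x||_1``).

    ``threshold`` is the ratio gamma/rho of penalty weight to proximal
    penalty parameter.
    """
    v = np.asarray(v, dtype=float)
    if threshold < 0:
        raise ValueError(f"threshold must be non-negative, got {threshold}")
    return np.sign(v) * np.maximum(np.abs(v) - threshold, 0.0)


def prox_elementwise(v: np.ndarray, kind: str, threshold: float = 0.0) -> np.ndarray:
    """Elementwise proximal operators: ridge shrinkage (``l2``) or clamping (``nonneg``).

    The ``l2`` form is the scaling v / (1 + 1/rho') with the penalty weight
    gamma folded into rho' = rho / gamma, i.e. the proximal operator of
    (gamma/2) ||x||^2.  ``threshold`` again plays the role of gamma/rho.
    """
    v = np.asarray(v, dtype=float)
    if threshold < 0:
        raise ValueError(f"threshold must be non-negative, got {threshold}")
    if kind == "l2":
        # v / (1 + 1/rho') with rho' = rho/gamma  ==  v / (1 + gamma/rho)
        return v / (1.0 + threshold)
    if kind == "nonneg":
        return np.maximum(v, 0.0)
    raise ValueError(f"unknown elementwise prox kind: {kind!r}")


def prox_nuclear(V: np.ndarray, threshold: float) -> np.ndarray:
    """Singular-value soft thresholding (proximal operator of ``thr * ||X||_*``).

    Accepts stacks of matrices: the last two axes are treated as the matrix.
    """
    V = np.asarray(V, dtype=float)
    if threshold < 0:
        raise ValueError(f"threshold must be non-negative, got {threshold}")
    if not np.all(np.isfinite(V)):
        raise ValueError("non-finite entries in nuclear-norm prox input")
    if threshold == 0:
        return V.copy()
    U, s, Vt = np.linalg.svd(V, full_matrices=False)
    s = np.maximum(s - threshold, 0.0)
    return (U * s[..., None, :]) @ Vt


def project_capped_simplex(lam: np.ndarray, d: int, tol: float = 1e-10) -> np.ndarray:
    """Euclidean projection of ``lam`` onto {x : 0 <= x <= 1, sum(x) = d}.

    Solved by bisection on the scalar shift t in clip(lam - t, 0, 1); the
    trace constraint is met to ``tol``.
    """
    lam = np.asarray(lam, dtype=float)
    if not 0 < d <= lam.size:
        raise ValueError(f"d must be in [1, {lam.size}], got {d}")
    lo, hi = lam.min() - 1.0, lam.max()
    for _ in range(200):
        t = 0.5 * (lo + hi)
        total = np.clip(lam - t, 0.0, 1.0).sum()
        if abs(total - d) < tol:
            break
        if total > d:
            lo = t
        else:
            hi = t
    return np.clip(lam - t, 0.0, 1.0)


def prox_fantope(V: np.ndarray, d: int, sym_tol: float = 1e-8) -> np.ndarray:
    """Euclidean projection of a symmetric matrix onto the fantope.

    The fantope F_d = {X : 0 <= X <= I, trace(X) = d} is the convex hull of
    the rank-d orthogonal projection matrices.  The projection
    eigendecomposes V and projects its eigenvalues onto the capped simplex.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2 or V.shape[0] != V.shape[1]:
        raise ValueError("fantope projection requires a square matrix")
    asym = np.abs(V - V.T).max()
    if asym > sym_tol * max(1.0, np.abs(V).max()):
        raise ValueError(f"input is not symmetric (max asymmetry {asym:.2e})")
    Vs = 0.5 * (V + V.T)
    lam, Q = np.linalg.eigh(Vs)
    lam_proj = project_capped_simplex(lam, d)
    return (Q * lam_proj) @ Q.T


def prox_smooth_loss(
    v: np.ndarray,
    loss: Callable[[np.ndarray], float],
    grad: Callable[[np.ndarray], np.ndarray] | None,
    rho: float,
    x0: np.ndarray | None = None,
    maxiter: int = 50,
    gtol: float = 1e-6,
) -> np.ndarray:
    """Approximate proximal operator of a smooth loss via quasi-Newton (L-BFGS).

    Minimizes ``loss(x) + (rho/2) ||x - v||^2`` starting from ``x0`` (defaults
    to ``v``).  If ``grad`` is None, ``loss`` must return a ``(value,
    gradient)`` pair (one data pass per evaluation).  Raises on non-finite
    loss or gradient values.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    v = np.asarray(v, dtype=float)
    shape = v.shape

    def objective(xflat: np.ndarray):
        x = xflat.reshape(shape)
        if grad is None:
            f, g = loss(x)
        else:
            f, g = loss(x), grad(x)
        if not np.isfinite(f) or not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite loss or gradient in proximal step")
        diff = x - v
        return f + 0.5 * rho * float(diff.ravel() @ diff.ravel()), (g + rho * diff).ravel()

    start = v if x0 is None else np.asarray(x0, dtype=float)
    res = scipy.optimize.minimize(
        objective, start.ravel(), jac=True, method="L-BFGS-B",
        options={"maxiter": maxiter, "gtol": gtol},
    )
    return res.x.reshape(shape)


# ---------------------------------------------------------------------------
# penalty terms
# ---------------------------------------------------------------------------

def to_spacetime(v: np.ndarray, n_bars: int, n_lags: int) -> np.ndarray:
    """Reshape flattened filter vector(s) to (..., n_bars, n_lags) matrices.

    The flat layout is lag-major (oldest frame first), matching design-matrix
    rows; see :func:`lnlncascade.data.build_design_matrix`.
    """
    v = np.asarray(v)
    lead = v.shape[:-1]
    return v.reshape(lead + (n_lags, n_bars)).swapaxes(-1, -2)


def from_spacetime(M: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_spacetime`: flatten (..., n_bars, n_lags) matrices."""
    M = np.asarray(M)
    lead = M.shape[:-2]
    return M.swapaxes(-1, -2).reshape(lead + (-1,))


@dataclasses.dataclass
class PenaltyTerm:
    """Base class for consensus objective terms.

    Subclasses implement :meth:`prox`, the proximal operator with penalty
    parameter ``rho``, and optionally :meth:`value` (used for diagnostics
    only; indicator terms report 0 on their feasible set).
    """

    def prox(self, v: np.ndarray, rho: float) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def value(self, x: np.ndarray) -> float:
        return 0.0


@dataclasses.dataclass
class L1Penalty(PenaltyTerm):
    weight: float = 1.0

    def prox(self, v, rho):
        return prox_l1(v, self.weight / rho)

    def value(self, x):
        return self.weight * float(np.abs(x).sum())


@dataclasses.dataclass
class SquaredL2Penalty(PenaltyTerm):
    """Ridge penalty (gamma/2)||x||^2, the Table-form l2 scaling operator."""

    weight: float = 1.0

    def prox(self, v, rho):
        return prox_elementwise(v, "l2", self.weight / rho)

    def value(self, x):
        return 0.5 * self.weight * float(np.square(x).sum())


@dataclasses.dataclass
class NonnegativityConstraint(PenaltyTerm):
    def prox(self, v, rho):
        return prox_elementwise(v, "nonneg")


@dataclasses.dataclass
class SmoothnessPenalty(PenaltyTerm):
    """l2 penalty on first differences along the last axis (optional extra)."""

    weight: float = 1.0

    def prox(self, v, rho):
        # Solve (gamma D^T D + rho I) x = rho v with D the first-difference
        # operator; direct banded solve, exact.
        v = np.asarray(v, dtype=float)
        n = v.shape[-1]
        D = np.diff(np.eye(n), axis=0)
        A = self.weight * (D.T @ D) + rho * np.eye(n)
        return np.linalg.solve(A, rho * v[..., None]).reshape(v.shape)

    def value(self, x):
        return 0.5 * self.weight * float(np.square(np.diff(x, axis=-1)).sum())


@dataclasses.dataclass
class NuclearNormPenalty(PenaltyTerm):
    """Nuclear norm of each flattened filter reshaped to (n_bars, n_lags).

    Applied independently to every vector along the last axis of the
    variable, so a stack of filters (k, N) is penalized filter-by-filter.
    """

    weight: float
    n_bars: int
    n_lags: int

    def prox(self, v, rho):
        M = to_spacetime(v, self.n_bars, self.n_lags)
        return from_spacetime(prox_nuclear(M, self.weight / rho))

    def value(self, x):
        M = to_spacetime(x, self.n_bars, self.n_lags)
        s = np.linalg.svd(M, compute_uv=False)
        return self.weight * float(s.sum())


@dataclasses.dataclass
class FantopeConstraint(PenaltyTerm):
    """Indicator of the fantope F_d (for regularized STC)."""

    d: int

    def prox(self, v, rho):
        return prox_fantope(0.5 * (v + v.swapaxes(-1, -2)), self.d)


@dataclasses.dataclass
class LinearTerm(PenaltyTerm):
    """Linear objective <c, x>; prox is the exact shift v - c / rho."""

    c: np.ndarray

    def prox(self, v, rho):
        return v - self.c / rho

    def value(self, x):
        return float(np.vdot(self.c, x).real)


@dataclasses.dataclass
class SmoothLossTerm(PenaltyTerm):
    """A smooth loss (e.g. a Poisson negative log-likelihood) with gradient.

    ``loss`` either returns a scalar (with ``grad`` supplying the gradient)
    or, when ``grad`` is None, a ``(value, gradient)`` pair.  Successive
    prox calls warm-start the inner quasi-Newton solve from the previous
    solution.
    """

    loss: Callable[[np.ndarray], float]
    grad: Callable[[np.ndarray], np.ndarray] | None = None
    maxiter: int = 50
    gtol: float = 1e-6
    _last: np.ndarray | None = dataclasses.field(default=None, repr=False)

    def prox(self, v, rho):
        out = prox_smooth_loss(v, self.loss, self.grad, rho, x0=self._last,
                               maxiter=self.maxiter, gtol=self.gtol)
        self._last = out
        return out

    def value(self, x):
        out = self.loss(x)
        return float(out[0] if self.grad is None else out)


# ---------------------------------------------------------------------------
# consensus ADMM
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SolverState:
    """Diagnostics for a consensus-ADMM run."""

    iterations: int
    primal_residual: float
    dual_residual: float
    converged: bool
    history: list = dataclasses.field(default_factory=list)


def consensus_solve(
    terms: Sequence[PenaltyTerm],
    init: np.ndarray,
    rho: float = 1.0,
    tol: float = 1e-4,
    max_iter: int = 250,
    duals: list[np.ndarray] | None = None,
) -> tuple[np.ndarray, SolverState]:
    """Minimize a sum of terms by proximal consensus (ADMM).

    Each term keeps its own variable copy x_i, updated as
    ``x_i <- P_{phi_i}(xbar - u_i)``; the consensus variable ``xbar`` is the
    mean of the copies, and the duals accumulate the disagreement
    ``u_i <- u_i + x_i - xbar``.  Stops when both the scaled primal residual
    max_i ||x_i - xbar|| / sqrt(N) and the dual residual
    ||xbar - xbar_prev|| / sqrt(N) drop below ``tol``.

    ``duals`` may carry warm-start dual variables (mutated in place), which
    speeds up repeated solves of slowly changing problems.
    """
    if len(terms) == 0:
        raise ValueError("need at least one objective term")
    if rho <= 0:
        raise ValueError("rho must be positive")
    xbar = np.array(init, dtype=float)
    sqrt_n = np.sqrt(xbar.size)
    if duals is None or len(duals) == 0:
        us = [np.zeros_like(xbar) for _ in terms]
        if duals is not None:
            duals.extend(us)
    else:
        us = duals
    state = SolverState(0, np.inf, np.inf, False)
    for it in range(1, max_iter + 1):
        xs = [term.prox(xbar - u, rho) for term, u in zip(terms, us)]
        new_xbar = np.mean(xs, axis=0)
        if not np.all(np.isfinite(new_xbar)):
            raise FloatingPointError(
                f"consensus iterate diverged (non-finite) at iteration {it}")
        primal = max(float(np.linalg.norm(x - new_xbar)) for x in xs) / sqrt_n
        dual = float(np.linalg.norm(new_xbar - xbar)) / sqrt_n
        for u, x in zip(us, xs):
            u += x - new_xbar
        xbar = new_xbar
        state.iterations = it
        state.primal_residual = primal
        state.dual_residual = dual
        state.history.append({"iteration": it, "primal": primal, "dual": dual})
        if primal < tol and dual < tol:
            state.converged = True
            break
    return xbar, state


def penalties_from_config(config) -> list[PenaltyTerm]:
    """Build penalty terms from a configuration file or mapping.

    ``config`` is a path to a JSON or TOML file, or a dict, containing a
    ``penalties`` list of entries like ``{"kind": "l1", "weight": 0.02}``;
    matrix penalties additionally carry shape information
    (``n_bars``/``n_lags`` for ``nuclear``, ``d`` for ``fantope``).
    """
    import json as _json
    import pathlib as _pathlib

    if not isinstance(config, dict):
        path = _pathlib.Path(config)
        if path.suffix == ".toml":
            import tomllib
            config = tomllib.loads(path.read_text())
        else:
            config = _json.loads(path.read_text())
    terms: list[PenaltyTerm] = []
    for entry in config["penalties"]:
        kind = entry["kind"]
        if kind == "l1":
            terms.append(L1Penalty(entry.get("weight", 1.0)))
        elif kind == "l2":
            terms.append(SquaredL2Penalty(entry.get("weight", 1.0)))
        elif kind == "nonneg":
            terms.append(NonnegativityConstraint())
        elif kind == "smooth":
            terms.append(SmoothnessPenalty(entry.get("weight", 1.0)))
        elif kind == "nuclear":
            terms.append(NuclearNormPenalty(entry.get("weight", 1.0),
                                            entry["n_bars"], entry["n_lags"]))
        elif kind == "fantope":
            terms.append(FantopeConstraint(entry["d"]))
        else:
            raise ValueError(f"unknown penalty kind {kind!r}")
    return terms
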