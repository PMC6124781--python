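"""Two-layer linear-nonlinear (LN-LN) cascade encoding model.

The model maps a spatiotemporal stimulus vector x to a firing rate

    r(x) = g * log(1 + exp( sum_i h_i(w_i . x) - theta ))

where each of the k subunits has a unit-norm spatiotemporal filter w_i and a
flexible nonlinearity h_i expressed in a basis of evenly spaced Gaussian
bumps, and the output stage is a soft rectifier with gain g > 0 and
threshold theta.  The LN model is the k = 1 special case.  Parameters are
learned by alternating block minimization of a Poisson spiking negative
log-likelihood: the filter block is solved by proximal consensus with l1
and nuclear-norm penalties, the nonlinearity block by penalized Poisson
regression on bump activations, and the output block over (log g, theta).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import scipy.optimize
from scipy.special import expit, gammaln
from sklearn.base import BaseEstimator, RegressorMixin

from .proxops import (
    L1Penalty,
    NuclearNormPenalty,
    SmoothLossTerm,
    consensus_solve,
)

_RATE_FLOOR = 1e-300


def softplus(z: np.ndarray) -> np.ndarray:
    """Numerically stable log(1 + exp(z))."""
    return np.logaddexp(0.0, z)


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Logistic function, the derivative of :func:`softplus`."""
    return expit(z)


@dataclasses.dataclass
class BasisNonlinearity:
    """A scalar nonlinearity h(u) = sum_j a_j * exp(-(u - c_j)^2 / (2 s^2)).

    Centers tile the input range in units of the stimulus projection's
    standard deviation (unit-norm filters on unit-variance white noise give
    unit-s.d. inputs, so a fixed tiling of roughly [-5, 5] covers the mass).
    """

    centers: np.ndarray
    width: float
    weights: np.ndarray

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.centers.ndim != 1 or self.centers.size < 2:
            raise ValueError("need at least two bump centers")
        spacing = np.diff(self.centers)
        if np.any(spacing <= 0) or not np.allclose(spacing, spacing[0]):
            raise ValueError("centers must be strictly increasing and evenly spaced")
        if self.width <= 0:
            raise ValueError("bump width must be positive")
        if self.weights.shape != self.centers.shape:
            raise ValueError("weights and centers must have matching shape")

    @property
    def n_bumps(self) -> int:
        return self.centers.size

    def design(self, u: np.ndarray) -> np.ndarray:
        """Bump activations, shape u.shape + (p,)."""
        u = np.asarray(u, dtype=float)
        d = u[..., None] - self.centers
        return np.exp(-0.5 * (d / self.width) ** 2)

    def __call__(self, u: np.ndarray) -> np.ndarray:
        return self.design(u) @ self.weights

    def derivative(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        d = u[..., None] - self.centers
        phi = np.exp(-0.5 * (d / self.width) ** 2)
        return (phi * (-d / self.width**2)) @ self.weights

    @classmethod
    def make_basis(cls, n_bumps: int = 30, span: tuple[float, float] = (-5.0, 5.0)):
        """Evenly spaced centers over ``span``; width equals the spacing."""
        centers = np.linspace(span[0], span[1], n_bumps)
        width = centers[1] - centers[0]
        return centers, width

    @classmethod
    def from_function(cls, f, n_bumps: int = 30, span: tuple[float, float] = (-5.0, 5.0),
                      n_grid: int = 400) -> tuple["BasisNonlinearity", float]:
        """Least-squares projection of a scalar function onto the bump basis.

        Returns the nonlinearity and the relative projection residual
        (rms error over the grid divided by the dynamic range of f).
        """
        centers, width = cls.make_basis(n_bumps, span)
        grid = np.linspace(span[0], span[1], n_grid)
        target = np.asarray([f(u) for u in grid], dtype=float) \
            if not callable(getattr(f, "__call__", None)) else np.asarray(f(grid), dtype=float)
        phi = np.exp(-0.5 * ((grid[:, None] - centers) / width) ** 2)
        weights, *_ = np.linalg.lstsq(phi, target, rcond=None)
        nl = cls(centers=centers, width=width, weights=weights)
        rng_f = np.ptp(target)
        resid = float(np.sqrt(np.mean((phi @ weights - target) ** 2)))
        rel = resid / rng_f if rng_f > 0 else resid
        return nl, rel


@dataclasses.dataclass
class OutputNonlinearity:
    """Soft rectifier r(x) = g * log(1 + exp(x - theta)), g > 0."""

    gain: float
    threshold: float

    def __post_init__(self):
        if self.gain <= 0:
            raise ValueError("gain must be positive")

    def __call__(self, z: np.ndarray) -> np.ndarray:
        return self.gain * softplus(np.asarray(z, dtype=float) - self.threshold)


@dataclasses.dataclass
class LNLNModel:
    """Parameter container for a fitted or constructed LN-LN cascade."""

    filters: np.ndarray                      # (k, n_bars * n_lags), unit rows
    nonlinearities: list                     # k BasisNonlinearity objects
    output: OutputNonlinearity
    n_bars: int
    n_lags: int

    def __post_init__(self):
        self.filters = np.atleast_2d(np.asarray(self.filters, dtype=float))
        if len(self.nonlinearities) != self.filters.shape[0]:
            raise ValueError("one nonlinearity per subunit filter is required")
        if self.filters.shape[1] != self.n_bars * self.n_lags:
            raise ValueError("filter length must equal n_bars * n_lags")

    @property
    def n_subunits(self) -> int:
        return self.filters.shape[0]

    def filter_as_spacetime(self, i: int) -> np.ndarray:
        return self.filters[i].reshape(self.n_lags, self.n_bars).T


def subunit_activations(model: LNLNModel, X: np.ndarray) -> np.ndarray:
    """Project design-matrix rows onto each subunit filter, (n_samples, k).

    Under unit-variance white noise and unit-norm filters each column is
    standard normal, which fixes the input scale of the subunit
    nonlinearities.
    """
    X = np.atleast_2d(X)
    if X.shape[1] != model.filters.shape[1]:
        raise ValueError(
            f"design matrix has {X.shape[1]} columns but filters have "
            f"length {model.filters.shape[1]}")
    return np.asarray(X @ model.filters.T.astype(X.dtype), dtype=float)


def predict_rate(model: LNLNModel, X: np.ndarray) -> np.ndarray:
    """Predicted firing rate (spikes/bin) for each design-matrix row."""
    u = subunit_activations(model, X)
    z = sum(model.nonlinearities[i](u[:, i]) for i in range(model.n_subunits))
    r = model.output(z)
    return np.maximum(r, _RATE_FLOOR)


def poisson_nll(rates: np.ndarray, counts: np.ndarray,
                include_constant: bool = False) -> float:
    """Poisson negative log-likelihood, sum_t [r_t - y_t log r_t], nats."""
    rates = np.asarray(rates, dtype=float)
    counts = np.asarray(counts)
    if rates.shape != counts.shape:
        raise ValueError("rates and counts must have equal length")
    if np.any(rates <= 0):
        raise ValueError("rates must be strictly positive")
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    nll = float(rates.sum() - counts @ np.log(rates))
    if include_constant:
        nll += float(gammaln(np.asarray(counts, dtype=float) + 1.0).sum())
    return nll


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _bump_design(u, centers, width):
    d = u[:, None] - centers
    return np.exp(-0.5 * (d / width) ** 2)


class _Workspace:
    """Shared state for the alternating blocks of one fit.

    The filter-block loss is the Poisson NLL divided by the number of
    training spikes, which makes the penalty weights and the ADMM penalty
    parameter rho scale-free with respect to recording length and firing
    rate (the loss curvature is then O(1)).
    """

    def __init__(self, X, y, k, centers, width):
        self.X = X
        self.y = np.asarray(y, dtype=float)
        self.k = k
        self.centers = centers
        self.width = width
        self.p = centers.size
        self.scale = 1.0 / max(float(self.y.sum()), 1.0)

    def activations(self, W):
        u = self.X @ W.T.astype(self.X.dtype, copy=False)
        return np.asarray(u, dtype=float)

    def rate_terms(self, z, g):
        """Return (rate, s) where s = dNLL/dz."""
        sp = softplus(z)
        r = np.maximum(g * sp, _RATE_FLOOR)
        s = (1.0 - self.y / r) * g * expit(z)
        return r, s

    def nll_grad_filters(self, W, A, g, theta):
        """Per-spike NLL and its gradient with respect to the filters (k, N)."""
        u = self.activations(W)
        z = -theta * np.ones(u.shape[0])
        phis = []
        for i in range(self.k):
            phi = _bump_design(u[:, i], self.centers, self.width)
            phis.append(phi)
            z = z + phi @ A[i]
        r, s = self.rate_terms(z, g)
        nll = float(r.sum() - self.y @ np.log(r))
        S = np.empty((u.shape[0], self.k), dtype=self.X.dtype)
        for i in range(self.k):
            hp = (phis[i] * (-(u[:, i, None] - self.centers) / self.width**2)) @ A[i]
            S[:, i] = s * hp
        G = np.asarray(S.T @ self.X, dtype=float)  # single BLAS pass over X
        return nll * self.scale, G * self.scale


def _fit_nonlinearity_block(ws, Phi, y, g, theta, a0, ridge, smooth=0.0,
                            n_bumps=None, maxiter=150):
    """Penalized Poisson regression of bump weights (all subunits jointly).

    ``ridge`` is a small l2 weight for conditioning; ``smooth`` penalizes
    second differences of each subunit's bump weights, discouraging
    high-frequency wiggles in the learned nonlinearity (which would
    otherwise feed noisy derivatives back into the filter updates).
    """
    k = a0.size // n_bumps if n_bumps else 1
    p = n_bumps or a0.size
    D2 = np.diff(np.eye(p), n=2, axis=0)
    S = D2.T @ D2

    def smooth_terms(a):
        A = a.reshape(k, p)
        val = 0.5 * smooth * float(np.sum(A @ S * A))
        grad = smooth * (A @ S).ravel()
        return val, grad

    def obj(a):
        z = Phi @ a - theta
        sp = softplus(z)
        r = np.maximum(g * sp, _RATE_FLOOR)
        nll = float(r.sum() - y @ np.log(r))
        s = (1.0 - y / r) * g * expit(z)
        grad = Phi.T @ s + ridge * a
        sval, sgrad = (smooth_terms(a) if smooth > 0 else (0.0, 0.0))
        return nll + 0.5 * ridge * float(a @ a) + sval, grad + sgrad

    res = scipy.optimize.minimize(obj, a0, jac=True, method="L-BFGS-B",
                                  options={"maxiter": maxiter})
    return res.x


def _fit_output_block(hsum, y, g0, theta0, maxiter=100):
    """Quasi-Newton fit of (log g, theta); log-parameterization keeps g > 0."""

    def obj(params):
        logg, theta = params
        g = np.exp(logg)
        z = hsum - theta
        sp = softplus(z)
        r = np.maximum(g * sp, _RATE_FLOOR)
        nll = float(r.sum() - y @ np.log(r))
        resid = r - y          # dNLL/dlog g
        s = (1.0 - y / r) * g * expit(z)
        return nll, np.array([float(resid.sum()), -float(s.sum())])

    res = scipy.optimize.minimize(obj, np.array([np.log(g0), theta0]), jac=True,
                                  method="L-BFGS-B", options={"maxiter": maxiter})
    logg, theta = res.x
    return float(np.exp(logg)), float(theta)


class _ValTracker:
    """Early stopping for refinement trajectories.

    Evaluates held-out NLL at every quasi-Newton iterate, remembers the
    best one, and stops the solver once validation has not improved for
    ``patience`` iterations.  Unpenalized refinement descends the training
    likelihood past the point of generalization; the best-validation
    iterate is the implicitly regularized estimate.
    """

    def __init__(self, val_fn, z0, patience=25):
        self.val_fn = val_fn
        self.patience = patience
        self.best_val = val_fn(z0)
        self.best_z = z0.copy()
        self.stall = 0

    def __call__(self, zk):
        v = self.val_fn(zk)
        if v < self.best_val:
            self.best_val = v
            self.best_z = zk.copy()
            self.stall = 0
        else:
            self.stall += 1
            if self.stall >= self.patience:
                raise StopIteration


def _joint_refine(ws, W, A, g, theta, centers, width, maxiter=200,
                  val_fn=None):
    """Joint quasi-Newton refinement of all parameters.

    Alternating block minimization can stall at points that are optimal
    per block but not jointly (coupled filter/nonlinearity moves are
    unavailable to it).  This stage minimizes the unpenalized per-spike
    NLL over (W, A, log g, theta) together with L-BFGS.  Filter norms are
    left free during the refinement; the caller restores unit norms.
    With ``val_fn`` the trajectory is early-stopped at the best held-out
    likelihood.
    """
    k, N = W.shape
    p = centers.size

    def unpack(zf):
        Wx = zf[:k * N].reshape(k, N)
        Ax = zf[k * N:k * N + k * p].reshape(k, p)
        logg, th = zf[-2:]
        return Wx, Ax, logg, th

    def obj(zf):
        Wx, Ax, logg, th = unpack(zf)
        gx = np.exp(logg)
        u = ws.activations(Wx)
        z = -th * np.ones(u.shape[0])
        phis = []
        for i in range(k):
            phi = _bump_design(u[:, i], centers, width)
            phis.append(phi)
            z = z + phi @ Ax[i]
        r, s = ws.rate_terms(z, gx)
        nll = float(r.sum() - ws.y @ np.log(r))
        S = np.empty((u.shape[0], k), dtype=ws.X.dtype)
        gA = np.empty((k, p))
        for i in range(k):
            hp = (phis[i] * (-(u[:, i, None] - centers) / width**2)) @ Ax[i]
            S[:, i] = s * hp
            gA[i] = phis[i].T @ s
        gW = np.asarray(S.T @ ws.X, dtype=float)
        grad = np.concatenate([
            gW.ravel(), gA.ravel(),
            [float((r - ws.y).sum()), -float(s.sum())]]) * ws.scale
        return nll * ws.scale, grad

    z0 = np.concatenate([W.ravel(), A.ravel(), [np.log(g), theta]])
    if val_fn is None:
        res = scipy.optimize.minimize(obj, z0, jac=True, method="L-BFGS-B",
                                      options={"maxiter": maxiter})
        z_best = res.x
    else:
        tracker = _ValTracker(lambda z: val_fn(*unpack(z)), z0)
        scipy.optimize.minimize(obj, z0, jac=True, method="L-BFGS-B",
                                options={"maxiter": maxiter}, callback=tracker)
        z_best = tracker.best_z
    Wx, Ax, logg, th = unpack(z_best)
    return Wx, Ax, float(np.exp(logg)), float(th)


def _lowrank_refine(ws, W, A, g, theta, centers, width, shape, rank=2,
                    maxiter=300, val_fn=None, nl_smooth=0.0):
    """Refit with each filter constrained to a fixed-rank factorization.

    The nuclear-norm penalty that guides the search also shrinks the
    singular values of near-separable filters (their weaker space-time
    components most of all).  Refitting the unpenalized per-spike NLL over
    rank-``rank`` factors w_i = U_i V_i^T removes that bias while keeping
    the low-dimensional structure that made the penalty appropriate in the
    first place.  Factors are initialized from the truncated SVD of the
    current filters.
    """
    nbars, nlags = shape
    k, N = W.shape
    p = centers.size
    Us, Vs = [], []
    for i in range(k):
        F = W[i].reshape(nlags, nbars).T
        u, s, vt = np.linalg.svd(F, full_matrices=False)
        Us.append(u[:, :rank] * np.sqrt(s[:rank]))
        Vs.append(vt[:rank].T * np.sqrt(s[:rank]))
    nu, nv = nbars * rank, nlags * rank
    D2 = np.diff(np.eye(p), n=2, axis=0)
    Ssm = D2.T @ D2

    def unpack(zf):
        off = 0
        U = zf[off:off + k * nu].reshape(k, nbars, rank); off += k * nu
        V = zf[off:off + k * nv].reshape(k, nlags, rank); off += k * nv
        Ax = zf[off:off + k * p].reshape(k, p); off += k * p
        logg, th = zf[-2:]
        return U, V, Ax, logg, th

    def filters_from(U, V):
        return np.stack([(U[i] @ V[i].T).T.ravel() for i in range(k)])

    def obj(zf):
        U, V, Ax, logg, th = unpack(zf)
        gx = np.exp(logg)
        Wx = filters_from(U, V)
        u_act = ws.activations(Wx)
        z = -th * np.ones(u_act.shape[0])
        phis = []
        for i in range(k):
            phi = _bump_design(u_act[:, i], centers, width)
            phis.append(phi)
            z = z + phi @ Ax[i]
        r, s = ws.rate_terms(z, gx)
        nll = float(r.sum() - ws.y @ np.log(r))
        S = np.empty((u_act.shape[0], k), dtype=ws.X.dtype)
        gA = np.empty((k, p))
        for i in range(k):
            hp = (phis[i] * (-(u_act[:, i, None] - centers) / width**2)) @ Ax[i]
            S[:, i] = s * hp
            gA[i] = phis[i].T @ s
        gW = np.asarray(S.T @ ws.X, dtype=float)
        gU = np.empty((k, nbars, rank))
        gV = np.empty((k, nlags, rank))
        for i in range(k):
            G = gW[i].reshape(nlags, nbars).T       # (nbars, nlags)
            gU[i] = G @ V[i]
            gV[i] = G.T @ U[i]
        sm_val = 0.5 * nl_smooth * float(np.sum(Ax @ Ssm * Ax))
        gA = gA + nl_smooth * (Ax @ Ssm)
        grad = np.concatenate([
            gU.ravel(), gV.ravel(), gA.ravel(),
            [float((r - ws.y).sum()), -float(s.sum())]]) * ws.scale
        return (nll + sm_val) * ws.scale, grad

    z0 = np.concatenate([np.stack(Us).ravel(), np.stack(Vs).ravel(),
                         A.ravel(), [np.log(g), theta]])
    if val_fn is None:
        res = scipy.optimize.minimize(obj, z0, jac=True, method="L-BFGS-B",
                                      options={"maxiter": maxiter})
        z_best = res.x
    else:
        def vf(z):
            U, V, Ax, logg, th = unpack(z)
            return val_fn(filters_from(U, V), Ax, logg, th)
        tracker = _ValTracker(vf, z0)
        scipy.optimize.minimize(obj, z0, jac=True, method="L-BFGS-B",
                                options={"maxiter": maxiter}, callback=tracker)
        z_best = tracker.best_z
    U, V, Ax, logg, th = unpack(z_best)
    return filters_from(U, V), Ax, float(np.exp(logg)), float(th)


class LNLNCascade(RegressorMixin, BaseEstimator):
    """Scikit-learn style estimator for the LN-LN cascade.

    Parameters
    ----------
    n_subunits : int
        Number of hidden subunits k (k = 1 is the LN baseline).
    filter_shape : tuple (n_bars, n_lags)
        Spatiotemporal shape each filter reshapes to; required, since the
        nuclear-norm penalty acts on this reshape.
    gamma_l1, gamma_nuc : float
        Weights of the l1 (sparsity) and nuclear-norm (space-time
        separability) penalties on the subunit filters.
    n_bumps : int
        Gaussian bumps parameterizing each subunit nonlinearity.
    bump_span : tuple
        Input range tiled by the bumps, in stimulus-projection s.d. units.
    max_rounds : int
        Cap on alternating block rounds.
    round_tol : float
        Stop when the relative change of validation NLL is below this for
        two consecutive rounds.
    admm_iters, admm_tol, rho : ADMM settings for the filter block.
    prox_maxiter : L-BFGS iteration cap inside the smooth-loss prox.
    nl_ridge : ridge weight on bump coefficients (conditioning only).
    validation_fraction : trailing fraction of samples held out when no
        explicit validation set is passed to :meth:`fit`.
    random_state : seed for filter initialization.

    Attributes
    ----------
    filters_ : (k, N) array of unit-norm subunit filters.
    nonlinearities_ : list of :class:`BasisNonlinearity`.
    gain_, threshold_ : output soft-rectifier parameters.
    model_ : the fitted :class:`LNLNModel`.
    report_ : per-round list of dicts (train NLL, validation NLL, objective).
    uphill_flag_ : True if the regularized training objective increased by
        more than the allowed slack in any round.
    """

    def __init__(self, n_subunits=2, filter_shape=None, gamma_l1=0.02,
                 gamma_nuc=0.05, n_bumps=30, bump_span=(-5.0, 5.0),
                 max_rounds=20, round_tol=1e-4, admm_iters=20, admm_tol=1e-4,
                 rho=1.0, prox_maxiter=20, nl_ridge=1e-4, nl_smooth=0.0,
                 init="spectral",
                 polish_factor=0.25, polish_rounds=5, lowrank_rank=2,
                 joint_refine=True, prune_subunits=True,
                 validation_fraction=0.2, random_state=None):
        self.init = init
        self.polish_factor = polish_factor
        self.polish_rounds = polish_rounds
        self.lowrank_rank = lowrank_rank
        self.joint_refine = joint_refine
        self.prune_subunits = prune_subunits
        self.n_subunits = n_subunits
        self.filter_shape = filter_shape
        self.gamma_l1 = gamma_l1
        self.gamma_nuc = gamma_nuc
        self.n_bumps = n_bumps
        self.bump_span = bump_span
        self.max_rounds = max_rounds
        self.round_tol = round_tol
        self.admm_iters = admm_iters
        self.admm_tol = admm_tol
        self.rho = rho
        self.prox_maxiter = prox_maxiter
        self.nl_ridge = nl_ridge
        self.nl_smooth = nl_smooth
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------

    def _init_filters(self, X, y, k, rng):
        """Initial unit-norm filters.

        ``random``: i.i.d. Gaussian rows.  ``spectral`` (default): mixtures
        of the regularized spike-triggered average with leading regularized
        spike-triggered covariance eigenvectors.  For a multi-pathway cell
        the STA approximates the pathway-filter mean and the significant
        STC eigenvectors span the pathway differences, so seeding each
        filter with STA +/- a difference direction breaks the permutation
        symmetry that otherwise makes alternating minimization collapse
        all filters onto the population average.  An explicit (k, N) array
        is also accepted.
        """
        N = X.shape[1]
        if isinstance(self.init, np.ndarray):
            W = np.array(self.init, dtype=float)
            if W.shape != (k, N):
                raise ValueError("init array must have shape (k, N)")
        elif self.init == "random" or y.sum() < 10:
            W = rng.standard_normal((k, N))
        elif self.init == "spectral":
            from .sta import compute_stc, regularized_sta, regularized_stc, \
                suggested_sta_penalties
            nbars, nlags = self.filter_shape
            stats = compute_stc(X, y)
            g1, gn = suggested_sta_penalties(stats.n_spikes, (nbars, nlags))
            sta = regularized_sta(stats.sta, (nbars, nlags), g1, gn)
            if np.linalg.norm(sta) < 1e-9:
                sta = stats.sta
            basis = [sta / np.linalg.norm(sta)]
            if k > 1:
                res = regularized_stc(stats.stc, min(k, 3), gamma_nuc=0.1,
                                      shape=(nbars, nlags), max_iter=150)
                for j in range(res.eigenvectors.shape[1]):
                    v = res.eigenvectors[:, j].astype(float)
                    for b in basis:
                        v = v - (v @ b) * b
                    nrm = np.linalg.norm(v)
                    if nrm > 1e-8:
                        basis.append(v / nrm)
                    if len(basis) >= 3:
                        break
            b0 = basis[0]
            b1 = basis[1] if len(basis) > 1 else b0
            b2 = basis[2] if len(basis) > 2 else b1
            if k == 1:
                W = b0[None, :].copy()
            else:
                angles = 2 * np.pi * np.arange(k) / k
                W = np.vstack([b0 + np.cos(a) * b1 + np.sin(a) * b2
                               for a in angles])
            W = W + 0.05 * rng.standard_normal(W.shape) / np.sqrt(N)
        else:
            raise ValueError(f"unknown init scheme {self.init!r}")
        return W / np.linalg.norm(W, axis=1, keepdims=True)

    def _init_nonlinearity_weights(self, centers, width, rng):
        grid = np.linspace(centers[0], centers[-1], 400)
        target = softplus(grid - 1.0)
        phi = _bump_design(grid, centers, width)
        a0, *_ = np.linalg.lstsq(phi, target, rcond=None)
        A = np.tile(a0, (self.n_subunits, 1))
        A += 0.05 * np.abs(a0).mean() * rng.standard_normal(A.shape)
        return A

    def _rescale_nonlinearity(self, a, scale, centers, width):
        """Absorb a filter norm into the nonlinearity's input axis."""
        grid = np.linspace(centers[0], centers[-1], 400)
        phi = _bump_design(grid, centers, width)
        target = _bump_design(scale * grid, centers, width) @ a
        a_new, *_ = np.linalg.lstsq(phi, target, rcond=None)
        return a_new

    def _regularization_value(self, W, nbars, nlags):
        l1 = self.gamma_l1 * float(np.abs(W).sum())
        M = W.reshape(self.n_subunits, nlags, nbars).swapaxes(-1, -2)
        nuc = self.gamma_nuc * float(np.linalg.svd(M, compute_uv=False).sum())
        return l1 + nuc

    # -- estimator API ----------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.atleast_2d(np.asarray(X))
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have mismatched sample counts")
        if self.filter_shape is None:
            raise ValueError("filter_shape=(n_bars, n_lags) is required")
        nbars, nlags = self.filter_shape
        if nbars * nlags != X.shape[1]:
            raise ValueError("filter_shape does not match the design-matrix width")
        k = int(self.n_subunits)
        if k < 1:
            raise ValueError("n_subunits must be at least 1")
        if self.gamma_l1 < 0 or self.gamma_nuc < 0:
            raise ValueError("penalty weights must be non-negative")

        if X_val is None:
            n_val = int(round(self.validation_fraction * X.shape[0]))
            if n_val > 0:
                X, X_val = X[:-n_val], X[-n_val:]
                y, y_val = y[:-n_val], y[-n_val:]
        if y.sum() == 0:
            raise ValueError("no spikes in the training data")

        rng = np.random.default_rng(self.random_state)
        centers, width = BasisNonlinearity.make_basis(self.n_bumps, self.bump_span)
        ws = _Workspace(X, y, k, centers, width)

        W = self._init_filters(X, y, k, rng)
        A = self._init_nonlinearity_weights(centers, width, rng)

        # warm-up the output stage only.  The nonlinearities deliberately
        # start at a generic soft-rectifier shape even for warm restarts:
        # the resulting first filter block acts as a mild perturbation that
        # helps the alternation escape the previous stage's basin (the
        # best-validation-round rule protects against any damage).
        u = ws.activations(W)
        hsum = sum(_bump_design(u[:, i], centers, width) @ A[i]
                   for i in range(k))
        mean_rate = max(y.mean(), 1e-6)
        g, theta = _fit_output_block(hsum, ws.y, mean_rate, 1.0)

        report = []
        self.uphill_flag_ = False
        duals: list[np.ndarray] = []
        prev_obj = np.inf
        prev_val = None
        stall = 0
        best = None
        for rnd in range(1, self.max_rounds + 1):
            # ---- filter block: proximal consensus over NLL + l1 + nuclear
            terms = [
                SmoothLossTerm(
                    loss=lambda Wx, A=A, g=g, theta=theta:
                        ws.nll_grad_filters(Wx, A, g, theta),
                    maxiter=self.prox_maxiter,
                ),
                L1Penalty(self.gamma_l1),
                NuclearNormPenalty(self.gamma_nuc, nbars, nlags),
            ]
            W, admm_state = consensus_solve(
                terms, W, rho=self.rho, tol=self.admm_tol,
                max_iter=self.admm_iters, duals=duals)

            # ---- unit-norm rescaling, norm absorbed into the nonlinearity
            norms = np.linalg.norm(W, axis=1)
            for i in range(k):
                if norms[i] > 1e-6:
                    W[i] /= norms[i]
                    A[i] = self._rescale_nonlinearity(A[i], norms[i], centers, width)
                else:
                    W[i] = rng.standard_normal(W.shape[1])
                    W[i] /= np.linalg.norm(W[i])
                    A[i] = 0.0

            # ---- nonlinearity block
            u = ws.activations(W)
            Phi = np.concatenate(
                [_bump_design(u[:, i], centers, width) for i in range(k)], axis=1)
            A = _fit_nonlinearity_block(
                ws, Phi, ws.y, g, theta, A.ravel(), self.nl_ridge,
                smooth=self.nl_smooth, n_bumps=self.n_bumps).reshape(k, -1)

            # ---- output block
            hsum = Phi @ A.ravel()
            g, theta = _fit_output_block(hsum, ws.y, g, theta)

            # ---- diagnostics and stopping
            r_train = np.maximum(g * softplus(hsum - theta), _RATE_FLOOR)
            train_nll = float(r_train.sum() - ws.y @ np.log(r_train))
            obj = train_nll * ws.scale + self._regularization_value(W, nbars, nlags)
            if obj > prev_obj + 1e-3 * max(1.0, abs(prev_obj)):
                self.uphill_flag_ = True
            entry = {"round": rnd, "train_nll": train_nll, "objective": obj,
                     "admm_iterations": admm_state.iterations,
                     "admm_primal": admm_state.primal_residual}
            if X_val is not None:
                model = self._assemble(W, A, g, theta, centers, width, nbars, nlags)
                r_val = predict_rate(model, X_val)
                val_nll = float(r_val.sum() - np.asarray(y_val, float) @ np.log(r_val))
                entry["val_nll"] = val_nll
                if best is None or val_nll < best[0]:
                    best = (val_nll, W.copy(), A.copy(), g, theta)
                if prev_val is not None:
                    rel = abs(prev_val - val_nll) / max(1.0, abs(prev_val))
                    stall = stall + 1 if rel < self.round_tol else 0
                prev_val = val_nll
            report.append(entry)
            prev_obj = obj
            if stall >= 2:
                break

        if self.uphill_flag_:
            warnings.warn("regularized training objective increased beyond "
                          "solver slack during alternating minimization")
        if best is not None:
            # keep the round with the best held-out likelihood
            best_val, W, A, g, theta = best

        # ---- polish stage: shrinkage debiasing.  The penalties that make
        # the search reliable also bias the filters toward zero; a short
        # warm-started refit at reduced weights removes most of that bias.
        # Kept only if it improves the held-out likelihood.
        if (self.polish_rounds > 0 and best is not None
                and (self.gamma_l1 > 0 or self.gamma_nuc > 0)):
            sub = LNLNCascade(
                n_subunits=k, filter_shape=self.filter_shape,
                gamma_l1=self.gamma_l1 * self.polish_factor,
                gamma_nuc=self.gamma_nuc * self.polish_factor,
                n_bumps=self.n_bumps, bump_span=self.bump_span,
                max_rounds=self.polish_rounds, round_tol=self.round_tol,
                admm_iters=self.admm_iters, admm_tol=self.admm_tol,
                rho=self.rho, prox_maxiter=self.prox_maxiter,
                nl_ridge=self.nl_ridge, nl_smooth=self.nl_smooth,
                init=W.copy(), polish_rounds=0, lowrank_rank=0,
                joint_refine=False, prune_subunits=False,
                validation_fraction=0.0,
                random_state=self.random_state)
            sub.fit(X, y, X_val=X_val, y_val=y_val)
            polish_val = min((e["val_nll"] for e in sub.report_
                              if "val_nll" in e), default=np.inf)
            for e in sub.report_:
                report.append({**e, "stage": "polish"})
            if polish_val < best_val:
                W = sub.filters_
                A = np.vstack([nl.weights for nl in sub.nonlinearities_])
                g, theta = sub.gain_, sub.threshold_
                best_val = polish_val

        def _val_nll_params(Wx, Ax, logg, th):
            """Held-out NLL for raw (unnormalized) refinement parameters."""
            u = np.asarray(X_val @ Wx.T.astype(X_val.dtype), dtype=float)
            z = -th * np.ones(u.shape[0])
            for i in range(k):
                z = z + _bump_design(u[:, i], centers, width) @ Ax[i]
            r = np.maximum(np.exp(logg) * softplus(z), _RATE_FLOOR)
            return float(r.sum() - np.asarray(y_val, float) @ np.log(r))

        def _guarded_refine(stage, refine_fn):
            """Run a refinement stage; keep it only if validation improves.

            Returns True when the refined parameters were accepted.
            """
            nonlocal W, A, g, theta, best_val
            Wj, Aj, gj, thj = refine_fn()
            norms = np.linalg.norm(Wj, axis=1)
            for i in range(k):
                if norms[i] > 1e-6:
                    Wj[i] /= norms[i]
                    Aj[i] = self._rescale_nonlinearity(Aj[i], norms[i],
                                                       centers, width)
            model = self._assemble(Wj, Aj, gj, thj, centers, width,
                                   nbars, nlags)
            r_val = predict_rate(model, X_val)
            val = float(r_val.sum()
                        - np.asarray(y_val, float) @ np.log(r_val))
            report.append({"stage": stage, "val_nll": val})
            if val < best_val:
                W, A, g, theta = Wj, Aj, gj, thj
                best_val = val
                return True
            return False

        # ---- fixed-rank refinement: debias the nuclear-norm shrinkage.
        # Each cycle restarts the quasi-Newton state; repeat while the
        # held-out likelihood keeps improving.
        if self.lowrank_rank and best is not None \
                and self.lowrank_rank < min(nbars, nlags):
            for _ in range(3):
                accepted = _guarded_refine("lowrank", lambda: _lowrank_refine(
                    ws, W.copy(), A.copy(), g, theta, centers, width,
                    (nbars, nlags), rank=self.lowrank_rank,
                    val_fn=_val_nll_params, nl_smooth=self.nl_smooth))
                if not accepted:
                    break

        # ---- joint refinement: escape block-coordinate stalls
        if self.joint_refine and best is not None:
            _guarded_refine("joint", lambda: _joint_refine(
                ws, W.copy(), A.copy(), g, theta, centers, width,
                val_fn=_val_nll_params))

        # ---- subunit pruning: backward elimination of redundant subunits.
        # A subunit whose removal (flat nonlinearity) does not hurt the
        # held-out likelihood after refitting the remaining nonlinearities
        # is permanently silenced; superfluous subunits are thereby ignored
        # rather than left free to split the load of a real pathway.
        if self.prune_subunits and k > 1 and best is not None:
            u = ws.activations(W)
            phis = [_bump_design(u[:, i], centers, width) for i in range(k)]
            for i in range(k):
                if not np.any(A[i]):
                    continue
                keep = [j for j in range(k) if j != i and np.any(A[j])]
                if not keep:
                    break
                A_trial = A.copy()
                A_trial[i] = 0.0
                Phi_rest = np.concatenate([phis[j] for j in keep], axis=1)
                a_rest = _fit_nonlinearity_block(
                    ws, Phi_rest, ws.y, g, theta,
                    A_trial[keep].ravel(), self.nl_ridge,
                    smooth=self.nl_smooth, n_bumps=self.n_bumps)
                A_trial[keep] = a_rest.reshape(len(keep), -1)
                g_trial, th_trial = _fit_output_block(
                    Phi_rest @ a_rest, ws.y, g, theta)
                model = self._assemble(W, A_trial, g_trial, th_trial,
                                       centers, width, nbars, nlags)
                r_val = predict_rate(model, X_val)
                val = float(r_val.sum()
                            - np.asarray(y_val, float) @ np.log(r_val))
                report.append({"stage": "prune", "subunit": i,
                               "val_nll": val})
                if val < best_val:
                    A, g, theta = A_trial, g_trial, th_trial
                    best_val = val

        self.filters_ = W
        self.nonlinearities_ = [
            BasisNonlinearity(centers=centers, width=width, weights=A[i])
            for i in range(k)]
        self.gain_ = float(g)
        self.threshold_ = float(theta)
        self.model_ = self._assemble(W, A, g, theta, centers, width, nbars, nlags)
        self.report_ = report
        self.n_iter_ = sum(1 for e in report if "stage" not in e)
        return self

    @staticmethod
    def _assemble(W, A, g, theta, centers, width, nbars, nlags):
        nls = [BasisNonlinearity(centers=centers, width=width, weights=A[i])
               for i in range(W.shape[0])]
        return LNLNModel(filters=W.copy(), nonlinearities=nls,
                         output=OutputNonlinearity(gain=g, threshold=theta),
                         n_bars=nbars, n_lags=nlags)

    def predict(self, X):
        return predict_rate(self.model_, X)

    def score(self, X, y):
        """Log-likelihood improvement over the mean rate, bits/spike."""
        from .metrics import bits_per_spike
        return bits_per_spike(self.predict(X), y)


def fit_lnln(design_matrix, counts, k, gamma_l1=0.02, gamma_nuc=0.05,
             split=None, seed=None, rounds=20, **kwargs):
    """Fit an LN-LN cascade to a design matrix and aligned spike counts.

    Thin functional wrapper over :class:`LNLNCascade`.  ``design_matrix``
    is a :class:`~lnlncascade.data.DesignMatrix`; ``counts`` are per-frame
    spike counts (aligned automatically).  Returns (model, report).
    """
    X = design_matrix.X
    y = np.asarray(counts)
    if y.size == design_matrix.n_samples + design_matrix.offset:
        y = design_matrix.align_counts(y)
    est = LNLNCascade(
        n_subunits=k, filter_shape=(design_matrix.n_bars, design_matrix.n_lags),
        gamma_l1=gamma_l1, gamma_nuc=gamma_nuc, max_rounds=rounds,
        random_state=seed, **kwargs)
    if split is not None:
        est.fit(X[split.train], y[split.train],
                X_val=X[split.validation], y_val=y[split.validation])
    else:
        est.fit(X, y)
    return est.model_, est.report_


def select_num_subunits(design_matrix, counts, k_max, gamma_l1=0.02,
                        gamma_nuc=0.05, split=None, seed=None,
                        score_tol=1e-3, **kwargs):
    """Choose the subunit count by validation performance (bits/spike).

    Fits models with increasing k and stops as soon as held-out performance
    decreases below the running best (beyond ``score_tol``); among ties
    within ``score_tol`` the smallest k wins.  Returns (k_star, scores).
    """
    from .data import split_contiguous
    from .metrics import bits_per_spike

    X = design_matrix.X
    y = np.asarray(counts)
    if y.size == design_matrix.n_samples + design_matrix.offset:
        y = design_matrix.align_counts(y)
    if split is None:
        split = split_contiguous(X.shape[0])
    scores = {}
    best = -np.inf
    for k in range(1, k_max + 1):
        est = LNLNCascade(
            n_subunits=k,
            filter_shape=(design_matrix.n_bars, design_matrix.n_lags),
            gamma_l1=gamma_l1, gamma_nuc=gamma_nuc, random_state=seed, **kwargs)
        est.fit(X[split.train], y[split.train],
                X_val=X[split.validation], y_val=y[split.validation])
        rates = est.predict(X[split.validation])
        scores[k] = bits_per_spike(
            rates, y[split.validation],
            rate_baseline=float(np.mean(y[split.train])))
        if scores[k] > best:
            best = scores[k]
        elif scores[k] < best - score_tol:
            break
    k_star = min(k for k, s in scores.items() if s >= best - score_tol)
    return k_star, scores


def penalty_grid(center_l1=0.02, center_nuc=0.05, n=7):
    """Log-spaced (gamma_l1, gamma_nuc) pairs spanning 3 orders of magnitude.

    The grid scales both weights together around the package defaults,
    which is how held-out performance is typically swept.
    """
    factors = np.logspace(-1.5, 1.5, n)
    return [(center_l1 * f, center_nuc * f) for f in factors]


def cross_validate_penalties(design_matrix, counts, k, grid=None, split=None,
                             seed=None, **kwargs):
    """Pick (gamma_l1, gamma_nuc) by held-out bits/spike over a grid.

    Returns ((gamma_l1, gamma_nuc), scores) with scores keyed by pair.
    """
    from .data import split_contiguous
    from .metrics import bits_per_spike

    if grid is None:
        grid = penalty_grid()
    X = design_matrix.X
    y = np.asarray(counts)
    if y.size == design_matrix.n_samples + design_matrix.offset:
        y = design_matrix.align_counts(y)
    if split is None:
        split = split_contiguous(X.shape[0])
    scores = {}
    for g1, gn in grid:
        est = LNLNCascade(
            n_subunits=k,
            filter_shape=(design_matrix.n_bars, design_matrix.n_lags),
            gamma_l1=g1, gamma_nuc=gn, random_state=seed, **kwargs)
        est.fit(X[split.train], y[split.train],
                X_val=X[split.validation], y_val=y[split.validation])
        scores[(g1, gn)] = bits_per_spike(
            est.predict(X[split.validation]), y[split.validation],
            rate_baseline=float(np.mean(y[split.train])))
    best = max(scores, key=scores.get)
    return best, scores


def fit_subunit_subspace(design_matrix, counts, k, n_folds=3, seed=None,
                         **kwargs):
    """Ensemble estimate of the subunit filter subspace.

    Fits the cascade on ``n_folds`` rotated contiguous train/validation
    splits of the same recording and averages the orthogonal projectors
    onto each fit's filter span; the top-k eigenvectors of the averaged
    projector are the subspace estimate.  Individual fits sit at the
    data's likelihood-indifference set around the true filters, with
    partially independent errors across splits, so the fold average has
    visibly lower subspace error than any single fit.

    Returns ``(basis, fits)``: an (N, k) orthonormal basis and the list of
    per-fold fitted estimators (the first fold uses the trailing block as
    validation, matching the single-fit convention).
    """
    X = design_matrix.X
    y = np.asarray(counts)
    if y.size == design_matrix.n_samples + design_matrix.offset:
        y = design_matrix.align_counts(y)
    n = X.shape[0]
    vb = n // (n_folds + 2)
    starts = [n - vb] + [int(round(f * (n - vb) / max(n_folds - 1, 1)))
                         for f in range(n_folds - 1)]
    fits = []
    projector = 0.0
    for vstart in starts[:n_folds]:
        vidx = np.arange(vstart, vstart + vb)
        tidx = np.setdiff1d(np.arange(n), vidx)
        est = LNLNCascade(
            n_subunits=k,
            filter_shape=(design_matrix.n_bars, design_matrix.n_lags),
            random_state=seed, **kwargs)
        est.fit(X[tidx], y[tidx], X_val=X[vidx], y_val=y[vidx])
        fits.append(est)
        Q, _ = np.linalg.qr(est.filters_.T)
        projector = projector + Q @ Q.T
    lam, V = np.linalg.eigh(projector / n_folds)
    return V[:, np.argsort(lam)[-k:]], fits
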