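"""Spike-triggered statistics: raw, denoised, and fantope-regularized.

The spike-triggered average (STA) and covariance (STC) are the first two
moments of the stimulus distribution conditional on a spike.  For a
Gaussian white-noise stimulus they relate to the gradient and Hessian of
the neuron's response function, so the significant STC eigenvectors of a
multi-pathway cell span the pathway filters.  Both statistics can be
denoised without access to the spike-triggered ensemble: the STA by
proximal minimization of a least-squares term plus sparsity/low-rank
penalties, and the STC subspace by maximizing ``Tr(XC)`` over the fantope
(the convex hull of rank-d projection matrices) with column-wise penalties.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .proxops import (
    FantopeConstraint,
    L1Penalty,
    LinearTerm,
    NuclearNormPenalty,
    PenaltyTerm,
    SmoothLossTerm,
    consensus_solve,
    prox_fantope,
    prox_nuclear,
    to_spacetime,
    from_spacetime,
)


@dataclasses.dataclass
class SpikeTriggeredStats:
    """Raw spike-triggered moments of a recording."""

    sta: np.ndarray
    stc: np.ndarray | None
    n_spikes: int
    mean_spike_prob: float


@dataclasses.dataclass
class RegularizedSTCResult:
    """Solution of the fantope-constrained regularized STC problem."""

    X_hat: np.ndarray            # (N, N) matrix in the fantope F_d
    d: int
    eigenvectors: np.ndarray     # (N, d), orthonormal
    eigenvalues: np.ndarray      # (d,)
    solver_iterations: int
    converged: bool


def compute_sta(X: np.ndarray, counts: np.ndarray) -> SpikeTriggeredStats:
    """Spike-count-weighted mean of design-matrix rows."""
    counts = np.asarray(counts, dtype=float)
    n_spikes = counts.sum()
    if n_spikes <= 0:
        raise ValueError("need at least one spike to compute an STA")
    sta = np.asarray((counts.astype(X.dtype) @ X), dtype=float) / n_spikes
    return SpikeTriggeredStats(sta=sta, stc=None, n_spikes=int(n_spikes),
                               mean_spike_prob=float(counts.mean()))


def compute_stc(X: np.ndarray, counts: np.ndarray,
                center: bool = True) -> SpikeTriggeredStats:
    """Spike-count-weighted stimulus covariance (second moment minus STA outer).

    Only spiking bins enter the accumulation, so the cost scales with the
    number of distinct spike bins rather than the recording length.
    """
    counts = np.asarray(counts, dtype=float)
    n_spikes = counts.sum()
    if n_spikes <= 1:
        raise ValueError("need more than one spike to compute an STC")
    idx = np.nonzero(counts)[0]
    w = counts[idx]
    rows = np.asarray(X[idx], dtype=float)
    sta = (w @ rows) / n_spikes
    stc = (rows.T * w) @ rows / n_spikes
    if center:
        stc = stc - np.outer(sta, sta)
    stc = 0.5 * (stc + stc.T)
    return SpikeTriggeredStats(sta=sta, stc=stc, n_spikes=int(n_spikes),
                               mean_spike_prob=float(counts.mean()))


def regularized_sta(raw_sta: np.ndarray, shape: tuple[int, int],
                    gamma_l1: float = 0.0, gamma_nuc: float = 0.0,
                    rho: float = 1.0, tol: float = 1e-6,
                    max_iter: int = 250) -> np.ndarray:
    """Denoise a raw STA by sparse + low-rank proximal regression.

    Solves ``argmin_x ||x - sta||^2 + g1 ||x||_1 + g* ||reshape(x)||_*``
    with proximal consensus; only the raw STA is needed, never the
    spike-triggered ensemble.  With both weights zero the raw STA is
    returned exactly.
    """
    raw_sta = np.asarray(raw_sta, dtype=float)
    n_bars, n_lags = shape
    if raw_sta.size != n_bars * n_lags:
        raise ValueError("shape does not match the STA length")
    if gamma_l1 < 0 or gamma_nuc < 0:
        raise ValueError("penalty weights must be non-negative")
    if gamma_l1 == 0 and gamma_nuc == 0:
        return raw_sta.copy()
    terms: list[PenaltyTerm] = [
        SmoothLossTerm(loss=lambda x: (float(np.sum((x - raw_sta) ** 2)),
                                       2.0 * (x - raw_sta))),
    ]
    if gamma_l1 > 0:
        terms.append(L1Penalty(gamma_l1))
    if gamma_nuc > 0:
        terms.append(NuclearNormPenalty(gamma_nuc, n_bars, n_lags))
    x, _ = consensus_solve(terms, raw_sta, rho=rho, tol=tol, max_iter=max_iter)
    return x


def suggested_sta_penalties(n_spikes: int,
                            shape: tuple[int, int]) -> tuple[float, float]:
    """Noise-scale heuristic for STA denoising weights.

    Under unit-variance white noise the raw STA carries i.i.d. noise of
    standard deviation ``sigma = 1/sqrt(n_spikes)`` per coordinate.  The
    singular values of an (n_bars x n_lags) pure-noise matrix concentrate
    below ``sigma * (sqrt(n_bars) + sqrt(n_lags))``, so a nuclear-norm
    threshold at that edge suppresses noise while passing any structured
    (low-rank) component; the l1 weight is kept at the per-coordinate
    noise scale, a mild sparsity prior.  Since the data term of the STA
    denoiser is ``||x - sta||^2`` (curvature 2), the returned weights are
    twice the intended thresholds.
    """
    m, n = shape
    sigma = 1.0 / np.sqrt(n_spikes)
    return sigma, 2.0 * sigma * (np.sqrt(m) + np.sqrt(n))


class _ColumnwiseNuclear(PenaltyTerm):
    """Nuclear-norm penalty on each column of a square matrix variable."""

    def __init__(self, weight: float, n_bars: int, n_lags: int):
        self.weight = weight
        self.n_bars = n_bars
        self.n_lags = n_lags

    def prox(self, v, rho):
        cols = to_spacetime(v.T, self.n_bars, self.n_lags)
        return from_spacetime(prox_nuclear(cols, self.weight / rho)).T

    def value(self, x):
        s = np.linalg.svd(to_spacetime(x.T, self.n_bars, self.n_lags),
                          compute_uv=False)
        return self.weight * float(s.sum())


def regularized_stc(raw_stc: np.ndarray, d: int,
                    gamma_l1: float = 0.0, gamma_nuc: float = 0.0,
                    shape: tuple[int, int] | None = None,
                    suppressive: bool = False, rho: float = 1.0,
                    tol: float = 1e-5, max_iter: int = 250) -> RegularizedSTCResult:
    """Regularized significant STC subspace via fantope programming.

    Maximizes ``Tr(XC) - g1 |X|_1 - g* sum_j ||reshape(col_j X)||_*`` over
    the fantope F_d by proximal consensus (internally the negated trace
    term is minimized; its prox is the closed-form shift ``v + C/rho``).
    The solution may have rank above d, so a final eigendecomposition
    returns the top-d orthonormal eigenvectors.  Set ``suppressive`` to
    negate C and find suppressive rather than expansive directions.
    """
    C = np.asarray(raw_stc, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("STC matrix must be square")
    if np.abs(C - C.T).max() > 1e-8 * max(1.0, np.abs(C).max()):
        raise ValueError("STC matrix must be symmetric")
    N = C.shape[0]
    if not 1 <= d < N:
        raise ValueError(f"d must be in [1, {N - 1}]")
    if suppressive:
        C = -C
    terms: list[PenaltyTerm] = [LinearTerm(-C), FantopeConstraint(d)]
    if gamma_l1 > 0:
        terms.append(L1Penalty(gamma_l1))
    if gamma_nuc > 0:
        if shape is None:
            raise ValueError("shape=(n_bars, n_lags) is required for the "
                             "column-wise nuclear penalty")
        terms.append(_ColumnwiseNuclear(gamma_nuc, *shape))
    # start from the unregularized fantope solution (top-d projector)
    lam, Q = np.linalg.eigh(C)
    init = (Q[:, -d:] @ Q[:, -d:].T)
    X_hat, state = consensus_solve(terms, init, rho=rho, tol=tol,
                                   max_iter=max_iter)
    # report the feasible iterate: project the consensus average onto the
    # fantope so the box and trace constraints hold exactly
    X_hat = prox_fantope(0.5 * (X_hat + X_hat.T), d)
    lam, Q = np.linalg.eigh(X_hat)
    order = np.argsort(lam)[::-1][:d]
    return RegularizedSTCResult(
        X_hat=X_hat, d=d, eigenvectors=Q[:, order], eigenvalues=lam[order],
        solver_iterations=state.iterations, converged=state.converged)


def significant_stc_eigenvectors(X: np.ndarray, counts: np.ndarray,
                                 n_shifts: int = 100, seed: int = 0,
                                 center: bool = True):
    """Expansive/suppressive raw STC eigenvectors outside a shift null.

    The null distribution comes from ``n_shifts`` circular shifts of the
    spike train against the stimulus (destroying stimulus-locked structure
    while preserving count statistics); eigenvalues outside the null's
    min/max band are significant.  Returns (eigenvalues, eigenvectors,
    mask) with the mask flagging significant components.
    """
    counts = np.asarray(counts, dtype=float)
    stats = compute_stc(X, counts, center=center)
    lam, Q = np.linalg.eigh(stats.stc)
    rng = np.random.default_rng(seed)
    lo, hi = np.inf, -np.inf
    n = counts.size
    for _ in range(n_shifts):
        shift = int(rng.integers(n // 10, n - n // 10))
        null = compute_stc(X, np.roll(counts, shift), center=center)
        null_lam = np.linalg.eigvalsh(null.stc)
        lo = min(lo, null_lam.min())
        hi = max(hi, null_lam.max())
    mask = (lam < lo) | (lam > hi)
    return lam, Q, mask


class STCSubspace(TransformerMixin, BaseEstimator):
    """Estimator interface to (regularized) spike-triggered covariance.

    ``fit(X, y)`` computes raw spike-triggered statistics from a design
    matrix and aligned counts, then solves the fantope program for the
    top-d regularized subspace; ``transform`` projects stimuli onto it.

    Attributes
    ----------
    sta_, stc_ : raw spike-triggered moments.
    eigenvectors_, eigenvalues_ : regularized top-d subspace.
    result_ : the full :class:`RegularizedSTCResult`.
    """

    def __init__(self, d=5, gamma_l1=0.0, gamma_nuc=0.0, filter_shape=None,
                 suppressive=False, rho=1.0, tol=1e-5, max_iter=250):
        self.d = d
        self.gamma_l1 = gamma_l1
        self.gamma_nuc = gamma_nuc
        self.filter_shape = filter_shape
        self.suppressive = suppressive
        self.rho = rho
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        stats = compute_stc(X, y)
        self.sta_ = stats.sta
        self.stc_ = stats.stc
        self.n_spikes_ = stats.n_spikes
        self.result_ = regularized_stc(
            stats.stc, self.d, gamma_l1=self.gamma_l1,
            gamma_nuc=self.gamma_nuc, shape=self.filter_shape,
            suppressive=self.suppressive, rho=self.rho, tol=self.tol,
            max_iter=self.max_iter)
        self.eigenvectors_ = self.result_.eigenvectors
        self.eigenvalues_ = self.result_.eigenvalues
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float) @ self.eigenvectors_
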