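"""Model evaluation and descriptive statistics.

Includes the spike-prediction scores (bits/spike, rate correlation), the
principal-angle subspace overlap used to compare filter subspaces, the
stable (numerical) rank measuring space-time separability, the 40%-of-max
nonlinearity threshold statistic, and difference-of-Gaussians receptive
field sizing.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.optimize

from .lnln import poisson_nll


class FlatNonlinearityError(ValueError):
    """Raised when a threshold is requested for a (near-)constant nonlinearity."""


def bits_per_spike(rates_model, counts, rate_baseline: float | None = None) -> float:
    """Poisson log-likelihood improvement over a constant mean rate, bits/spike.

    ``rate_baseline`` defaults to the mean of ``counts``; pass the training
    mean when scoring held-out data.
    """
    counts = np.asarray(counts)
    n_spikes = counts.sum()
    if n_spikes == 0:
        raise ValueError("cannot compute bits/spike with zero spikes")
    if rate_baseline is None:
        rate_baseline = float(counts.mean())
    if rate_baseline <= 0:
        raise ValueError("baseline rate must be positive")
    nll_model = poisson_nll(rates_model, counts)
    nll_base = poisson_nll(np.full(counts.shape, rate_baseline), counts)
    return float((nll_base - nll_model) / (n_spikes * np.log(2.0)))


def rate_correlation(rates_model, rates_observed) -> float:
    """Pearson correlation between two rate traces."""
    a = np.asarray(rates_model, dtype=float)
    b = np.asarray(rates_observed, dtype=float)
    if a.shape != b.shape:
        raise ValueError("rate traces must have equal length")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("rate correlation undefined for constant input")
    return float(np.corrcoef(a, b)[0, 1])


def subspace_overlap(X: np.ndarray, Y: np.ndarray) -> float:
    """Mean cosine of the principal angles between span(X) and span(Y).

    Columns span the subspaces; both are orthonormalized by QR and the
    cosines are the singular values of Q_X^T Q_Y.  The average runs over
    the smaller dimension, so the overlap is 1 for identical spans and 0
    for orthogonal ones.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with matching ambient dimension")
    if X.shape[1] > Y.shape[1]:
        X, Y = Y, X
    for M, name in ((X, "X"), (Y, "Y")):
        if np.linalg.matrix_rank(M) < M.shape[1]:
            raise ValueError(f"{name} is rank deficient")
    qx, _ = np.linalg.qr(X)
    qy, _ = np.linalg.qr(Y)
    cosines = np.linalg.svd(qx.T @ qy, compute_uv=False)
    return float(np.clip(cosines, 0.0, 1.0).mean())


def stable_rank(M: np.ndarray) -> float:
    """Stable (numerical) rank ||M||_F^2 / ||M||_2^2.

    Equals the sum of squared singular values over the largest one; 1
    exactly when the matrix is rank one (space-time separable), and robust
    to small noise unlike the integer rank.
    """
    M = np.asarray(M, dtype=float)
    fro2 = float(np.square(M).sum())
    if fro2 == 0:
        raise ValueError("stable rank undefined for the zero matrix")
    top = float(np.linalg.norm(M, ord=2))
    return fro2 / top**2


def nonlinearity_threshold(h, fraction: float = 0.4,
                           domain: tuple[float, float] = (-5.0, 5.0),
                           step: float = 1e-3) -> float:
    """Input at which a nonlinearity reaches ``fraction`` of its maximum.

    Evaluated on a dense grid over ``domain``; the output is min-subtracted,
    so the threshold is the smallest u with
    ``h(u) - min(h) >= fraction * (max(h) - min(h))``.  Units are input
    standard deviations.
    """
    lo, hi = domain
    grid = np.arange(lo, hi + step / 2, step)
    vals = np.asarray(h(grid), dtype=float)
    rng = vals.max() - vals.min()
    if rng <= 1e-12 * max(1.0, abs(vals.max())):
        raise FlatNonlinearityError("nonlinearity is flat on the domain")
    idx = np.argmax(vals - vals.min() >= fraction * rng)
    return float(grid[idx])


@dataclasses.dataclass
class DoGFit:
    """Difference-of-Gaussians fit of a spatial receptive field profile.

    Sizes are reported as 2 sigma of the fitted Gaussians, micrometres.
    """

    center_amplitude: float
    center_sigma_um: float
    surround_amplitude: float
    surround_sigma_um: float
    position_um: float
    residual: float

    @property
    def center_size_um(self) -> float:
        return 2.0 * self.center_sigma_um

    @property
    def surround_size_um(self) -> float:
        return 2.0 * self.surround_sigma_um


def _dog(x, a, sc, b, ss, m):
    return a * np.exp(-0.5 * ((x - m) / sc) ** 2) - b * np.exp(-0.5 * ((x - m) / ss) ** 2)


def fit_difference_of_gaussians(spatial_profile: np.ndarray,
                                bar_width_um: float) -> DoGFit:
    """Nonlinear least-squares DoG fit of a 1-D spatial profile.

    The profile is sign-aligned so its dominant lobe is positive.  The
    surround width is parameterized as a multiple (> 1) of the center
    width, enforcing sigma_c < sigma_s structurally, and a very weak
    penalty on the surround amplitude resolves the degenerate case of a
    profile with no surround (a pure Gaussian would otherwise admit many
    center/surround decompositions).
    """
    profile = np.asarray(spatial_profile, dtype=float)
    if profile.ndim != 1 or profile.size < 5:
        raise ValueError("need a 1-D profile with at least 5 bars")
    if profile[np.argmax(np.abs(profile))] < 0:
        profile = -profile
    x = (np.arange(profile.size) + 0.5) * bar_width_um
    span = profile.size * bar_width_um
    m0 = x[np.argmax(profile)]
    a0 = max(profile.max(), 1e-12)
    scale = a0

    def residuals(params):
        a, sc, b, ratio, m = params
        model = _dog(x, a, sc, b, sc * ratio, m)
        return np.concatenate([model - profile, [1e-3 * scale * b / a0]])

    p0 = [a0, 1.5 * bar_width_um, 0.1 * a0, 3.0, m0]
    lower = [0, 0.2 * bar_width_um, 0, 1.05, 0]
    upper = [10 * a0, span, 10 * a0, 50.0, span]
    res = scipy.optimize.least_squares(residuals, p0, bounds=(lower, upper),
                                       max_nfev=20000)
    if not res.success:
        raise RuntimeError(f"difference-of-Gaussians fit failed: {res.message}")
    a, sc, b, ratio, m = res.x
    ss = sc * ratio
    resid = float(np.sqrt(np.mean((_dog(x, a, sc, b, ss, m) - profile) ** 2)))
    return DoGFit(center_amplitude=float(a), center_sigma_um=float(sc),
                  surround_amplitude=float(b), surround_sigma_um=float(ss),
                  position_um=float(m), residual=resid)


def spatial_profile(filter_matrix: np.ndarray) -> np.ndarray:
    """Spatial profile of an (n_bars, n_lags) filter.

    The leading left-singular vector, sign-aligned so the peak-magnitude
    bar is positive.
    """
    M = np.asarray(filter_matrix, dtype=float)
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    prof = U[:, 0]
    if prof[np.argmax(np.abs(prof))] < 0:
        prof = -prof
    return prof


def rf_center_um(filter_matrix: np.ndarray, bar_width_um: float) -> float:
    """Receptive-field center position from a DoG fit of the spatial profile."""
    prof = spatial_profile(filter_matrix)
    return fit_difference_of_gaussians(prof, bar_width_um).position_um
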