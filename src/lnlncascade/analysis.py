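"""Downstream computational analyses of fitted or ground-truth models.

These operate on the cascade's internal representations: pairwise
correlations of population activity at successive circuit stages
(decorrelation curves), level sets of firing probability in the plane of
two subunit activations (iso-response contours), principal components of
spike-triggered subunit activations, and PCA across a population of
subunit nonlinearities.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from sklearn.decomposition import PCA
from skimage import measure

from .data import Stimulus, build_design_matrix
from .lnln import LNLNModel, predict_rate, subunit_activations
from .metrics import rf_center_um

logger = logging.getLogger(__name__)

STAGES = ("stimulus", "post-filter", "post-nonlinearity", "ganglion-rate")


@dataclasses.dataclass
class DecorrelationCurve:
    """Binned correlation-versus-distance curve for one circuit stage."""

    stage: str
    bin_centers_um: np.ndarray
    mean_correlation: np.ndarray
    sem_correlation: np.ndarray
    bin_um: float


@dataclasses.dataclass
class ContourMap:
    """Iso-response geometry in the plane of two subunit activations."""

    grid: np.ndarray                 # 1-D axis, s.d. units (both axes)
    rate: np.ndarray                 # (n_grid, n_grid) firing rate surface
    levels: np.ndarray
    contours: list                   # per level: list of (m, 2) point arrays
    density_ellipse: np.ndarray      # (2, n_pts) 2-s.d. stimulus ellipse
    spike_histogram: np.ndarray | None


def _binned_correlation(series: np.ndarray, centers_um: np.ndarray,
                        bin_um: float, stage: str) -> DecorrelationCurve:
    """Pairwise Pearson correlations binned by pairwise distance."""
    n_units = series.shape[0]
    dists, corrs = [], []
    sd = series.std(axis=1)
    for i in range(n_units):
        for j in range(i + 1, n_units):
            if sd[i] == 0 or sd[j] == 0:
                logger.info("skipping constant pair (%d, %d) at stage %s",
                            i, j, stage)
                continue
            dists.append(abs(centers_um[i] - centers_um[j]))
            corrs.append(np.corrcoef(series[i], series[j])[0, 1])
    dists = np.asarray(dists)
    corrs = np.asarray(corrs)
    n_bins = max(1, int(np.ceil((dists.max() + 1e-9) / bin_um)))
    edges = np.arange(n_bins + 1) * bin_um
    centers, means, sems = [], [], []
    for a, b in zip(edges[:-1], edges[1:]):
        sel = (dists >= a) & (dists < b)
        if not np.any(sel):
            continue
        centers.append(0.5 * (a + b))
        means.append(corrs[sel].mean())
        sems.append(corrs[sel].std(ddof=1) / np.sqrt(sel.sum())
                    if sel.sum() > 1 else 0.0)
    return DecorrelationCurve(stage=stage, bin_centers_um=np.array(centers),
                              mean_correlation=np.array(means),
                              sem_correlation=np.array(sems), bin_um=bin_um)


def decorrelation_curves(models: list[LNLNModel], stimulus: Stimulus,
                         bin_um: float = 70.0,
                         sample_spikes: bool = False,
                         seed=None) -> list[DecorrelationCurve]:
    """Correlation-versus-distance at each stage of a model population.

    Every model sees the *same* stimulus realization, so differences
    between stages are not sampling artifacts.  Stages: raw stimulus bars,
    subunit activations before the nonlinearity, subunit outputs after it,
    and ganglion-cell firing rates (model rates by default; Poisson-sampled
    counts if ``sample_spikes``).  Unit positions are receptive-field
    centers from difference-of-Gaussians fits; distances are binned every
    ``bin_um`` micrometres with the s.e.m. within each bin.
    """
    if len(models) < 2:
        raise ValueError("need at least two model cells")
    n_lags = models[0].n_lags
    design = build_design_matrix(stimulus, n_lags)
    rng = np.random.default_rng(seed)

    stim_series = stimulus.luminance[:, design.offset:]
    stim_pos = stimulus.bar_positions_um()

    filt_series, nl_series, rate_series = [], [], []
    filt_pos, rate_pos = [], []
    for model in models:
        u = subunit_activations(model, design.X)
        cell_pos = []
        for i in range(model.n_subunits):
            filt_series.append(u[:, i])
            nl_series.append(model.nonlinearities[i](u[:, i]))
            pos = rf_center_um(model.filter_as_spacetime(i),
                               stimulus.bar_width_um)
            cell_pos.append(pos)
            filt_pos.append(pos)
        r = predict_rate(model, design.X)
        if sample_spikes:
            r = rng.poisson(r).astype(float)
        rate_series.append(r)
        rate_pos.append(float(np.mean(cell_pos)))

    return [
        _binned_correlation(np.asarray(stim_series), stim_pos, bin_um, "stimulus"),
        _binned_correlation(np.asarray(filt_series), np.asarray(filt_pos),
                            bin_um, "post-filter"),
        _binned_correlation(np.asarray(nl_series), np.asarray(filt_pos),
                            bin_um, "post-nonlinearity"),
        _binned_correlation(np.asarray(rate_series), np.asarray(rate_pos),
                            bin_um, "ganglion-rate"),
    ]


def iso_response_contours(model: LNLNModel, subunit_pair=(0, 1),
                          grid_halfwidth: float = 4.0, n_grid: int = 201,
                          levels=None, design_X=None,
                          counts=None) -> ContourMap:
    """Level sets of firing rate in the plane of two subunit activations.

    The model's composite rate is evaluated on a grid of the two chosen
    activations with all other subunits held at zero.  The returned map
    also carries the 2-s.d. stimulus-density ellipse implied by the filter
    pair's correlation under white noise, and (when a design matrix and
    counts are given) an empirical spike histogram over the same plane.
    """
    i, j = subunit_pair
    if model.n_subunits < 2:
        raise ValueError("iso-response contours need at least two subunits")
    grid = np.linspace(-grid_halfwidth, grid_halfwidth, n_grid)
    U1, U2 = np.meshgrid(grid, grid, indexing="ij")
    z = model.nonlinearities[i](U1) + model.nonlinearities[j](U2)
    rate = model.output(z)
    span = rate.max() - rate.min()
    if span <= 1e-12 * max(1.0, rate.max()):
        raise ValueError("model rate is flat over the activation plane")
    if levels is None:
        # set levels within the stimulus-density region (activations are
        # standard normal, so almost all stimuli fall within ~2.5 s.d.);
        # far outside it the nonlinearities run linear or saturated and the
        # contour geometry is uninformative
        r_core = min(2.5, grid_halfwidth)
        core = np.abs(grid) <= r_core
        sub = rate[np.ix_(core, core)]
        levels = sub.min() + np.array([0.2, 0.4, 0.6]) * (sub.max() - sub.min())
    levels = np.asarray(levels, dtype=float)

    step = grid[1] - grid[0]
    contours = []
    for lev in levels:
        segs = measure.find_contours(rate, lev)
        pts = [np.column_stack([grid[0] + seg[:, 0] * step,
                                grid[0] + seg[:, 1] * step]) for seg in segs]
        contours.append(pts)

    # stimulus density: activations (u_i, u_j) are bivariate normal with
    # unit variances and correlation w_i . w_j
    rho = float(model.filters[i] @ model.filters[j])
    t = np.linspace(0, 2 * np.pi, 200)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    L = np.linalg.cholesky(cov)
    ellipse = 2.0 * (L @ np.vstack([np.cos(t), np.sin(t)]))

    hist = None
    if design_X is not None and counts is not None:
        counts = np.asarray(counts, dtype=float)
        u = subunit_activations(model, design_X)[:, [i, j]]
        hist, _, _ = np.histogram2d(u[:, 0], u[:, 1], bins=40,
                                    range=[[-grid_halfwidth, grid_halfwidth]] * 2,
                                    weights=counts)
    return ContourMap(grid=grid, rate=rate, levels=levels, contours=contours,
                      density_ellipse=ellipse, spike_histogram=hist)


def classify_contour_curvature(cmap: ContourMap, model: LNLNModel,
                               subunit_pair=(0, 1), level_index: int = 1) -> str:
    """Classify an iso-rate contour as convex or concave toward the origin.

    Uses long chords: for points a, b a quarter-contour apart, the rate at
    the chord midpoint lies below the contour level iff the sublevel
    (origin-side) region is locally convex there, i.e. the contour bows
    toward the origin.  Median vote over chord positions; ``straight``
    when midpoint rates stay within 2% of the rate range.
    """
    i, j = subunit_pair
    level = cmap.levels[level_index]
    pts = max(cmap.contours[level_index], key=len, default=None)
    if pts is None or len(pts) < 8:
        raise ValueError("no usable contour at the requested level")
    lag = max(4, len(pts) // 4)
    a, b = pts[:-lag], pts[lag:]
    mid = 0.5 * (a + b)
    z = model.nonlinearities[i](mid[:, 0]) + model.nonlinearities[j](mid[:, 1])
    r_mid = model.output(z)
    span = cmap.rate.max() - cmap.rate.min()
    rel = (r_mid - level) / span
    if np.all(np.abs(rel) < 0.02):
        return "straight"
    return "convex" if np.median(rel) < 0 else "concave"


def subunit_ste_pca(model: LNLNModel, X: np.ndarray, counts: np.ndarray):
    """PCA of spike-triggered subunit activations with argmax labels.

    Projects spike-triggered stimuli onto the k subunit filters, runs PCA
    on those k-dimensional activation vectors (spike-count weighted by row
    repetition), and labels each spike by its maximally active subunit.
    Returns (scores, components, labels): top-2 PCA scores per spike,
    component loadings, and integer subunit labels.
    """
    counts = np.asarray(counts)
    n_spikes = int(counts.sum())
    if n_spikes <= model.n_subunits:
        raise ValueError("need more spikes than subunits")
    idx = np.repeat(np.arange(counts.size), counts)
    u = subunit_activations(model, X[np.unique(idx)])
    # expand back to one row per spike
    uniq, inverse = np.unique(idx, return_inverse=True)
    u_spikes = u[inverse]
    if np.linalg.matrix_rank(np.cov(u_spikes.T)) < min(2, model.n_subunits):
        raise ValueError("degenerate spike-triggered activation covariance")
    pca = PCA(n_components=min(2, model.n_subunits))
    scores = pca.fit_transform(u_spikes)
    labels = np.argmax(u_spikes, axis=1)
    return scores, pca.components_, labels


def nonlinearity_pca(nonlinearities, grid=None):
    """PCA across a population of subunit nonlinearity curves.

    Curves are evaluated on a common grid; returns (mean_curve, components,
    explained_variance_fractions, grid).  All components are kept, so the
    fractions sum to one.
    """
    if len(nonlinearities) < 2:
        raise ValueError("need at least two nonlinearities")
    if grid is None:
        grid = np.linspace(-5.0, 5.0, 200)
    curves = np.vstack([nl(grid) for nl in nonlinearities])
    pca = PCA()
    pca.fit(curves)
    return curves.mean(axis=0), pca.components_, pca.explained_variance_ratio_, grid
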