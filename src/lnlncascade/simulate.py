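"""Synthetic stimuli and ground-truth LN-LN responders.

The white-noise generator emulates a 100 Hz one-dimensional bars display
(50 bars of 55.5 um, each bar's luminance drawn independently from a
standard normal).  Ground-truth model cells combine difference-of-Gaussians
spatial profiles with biphasic temporal kernels into near-separable
spatiotemporal subunit filters, followed by high-threshold subunit
nonlinearities, summation, and a soft-rectifier output driving Poisson
spiking.  All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import scipy.optimize

from .data import SpikeTrain, Stimulus, build_design_matrix
from .lnln import (
    BasisNonlinearity,
    LNLNModel,
    OutputNonlinearity,
    predict_rate,
    softplus,
)


def generate_white_noise_bars(duration_s: float, n_bars: int = 50,
                              frame_rate_hz: float = 100.0,
                              bar_width_um: float = 55.5,
                              seed=None) -> Stimulus:
    """Gaussian white-noise bar stimulus (i.i.d. standard-normal luminance)."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n_frames = int(round(duration_s * frame_rate_hz))
    rng = np.random.default_rng(seed)
    lum = rng.standard_normal((n_bars, n_frames))
    return Stimulus(luminance=lum, bar_width_um=bar_width_um,
                    frame_rate_hz=frame_rate_hz)


def generate_pink_noise_stimulus(duration_s: float, n_bars: int = 50,
                                 frame_rate_hz: float = 100.0,
                                 temporal_cutoff_hz: float = 2.0,
                                 bar_width_um: float = 55.5,
                                 seed=None) -> Stimulus:
    """Spatially pink (1/f power) noise, low-pass filtered in time.

    Built in the frequency domain: white Gaussian noise is shaped so its
    spatial power spectrum falls as 1/f (DC zeroed, random phases), then a
    hard temporal low-pass at ``temporal_cutoff_hz`` is applied and the
    array is renormalized to unit variance.
    """
    if temporal_cutoff_hz >= frame_rate_hz / 2:
        raise ValueError("temporal cutoff must be below the Nyquist frequency")
    n_frames = int(round(duration_s * frame_rate_hz))
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((n_bars, n_frames))
    spec = np.fft.rfft(white, axis=0)
    f_space = np.fft.rfftfreq(n_bars)
    amp = np.zeros_like(f_space)
    amp[1:] = 1.0 / np.sqrt(f_space[1:])        # power ~ 1/f
    field = np.fft.irfft(spec * amp[:, None], n=n_bars, axis=0)
    tspec = np.fft.rfft(field, axis=1)
    f_time = np.fft.rfftfreq(n_frames, d=1.0 / frame_rate_hz)
    tspec[:, f_time > temporal_cutoff_hz] = 0.0
    field = np.fft.irfft(tspec, n=n_frames, axis=1)
    field -= field.mean()
    field /= field.std()
    return Stimulus(luminance=field, bar_width_um=bar_width_um,
                    frame_rate_hz=frame_rate_hz)


@dataclasses.dataclass
class SubunitSpec:
    """Geometry and nonlinearity of one ground-truth subunit.

    The spatial profile is a difference of Gaussians (center narrower than
    surround); the temporal kernel is biphasic with separate center and
    surround time courses, which gives the assembled filter a stable rank
    slightly above one.  ``threshold_sd`` is calibrated so the 40%-of-max
    statistic of the subunit nonlinearity lands at that many input s.d.
    """

    center_um: float
    sigma_c_um: float = 55.0
    sigma_s_um: float = 165.0
    surround_weight: float = 0.25
    polarity: int = -1                   # -1: Off-type, +1: On-type
    kernel_support_s: float = 0.2
    threshold_sd: float = 3.0
    slope: float = 2.0
    nonlinearity: str = "softplus"       # or "sigmoid" (saturating, low-threshold)


@dataclasses.dataclass
class GroundTruthSpec:
    """Full specification of a synthetic LN-LN responder."""

    subunits: list
    gain: float = 0.2
    theta: float = 2.5
    n_bars: int = 50
    n_lags: int = 40
    bar_width_um: float = 55.5
    frame_rate_hz: float = 100.0
    n_bumps: int = 30
    bump_span: tuple = (-5.0, 5.0)


def _temporal_kernel(n_lags: int, frame_rate_hz: float, support_s: float,
                     tau_center: float = 0.04, tau_surround: float = 0.075):
    """Biphasic kernel pair (center, delayed surround) over the lag window.

    Returned oldest-lag-first so column tau of the filter matrix multiplies
    stimulus frame t - n_lags + 1 + tau.
    """
    t = np.arange(n_lags) / frame_rate_hz      # time before the response bin
    t = t[::-1]                                # column 0 = oldest frame
    def lobe(tau, n=5.0):
        k = (t / tau) ** n * np.exp(-n * (t / tau - 1.0))
        k[t > support_s] = 0.0
        return k
    k_center = lobe(tau_center) - 0.55 * lobe(tau_surround)
    k_surround = lobe(tau_center * 1.4) - 0.55 * lobe(tau_surround * 1.4)
    return k_center, k_surround


def _softplus_shift(threshold_sd, slope, span):
    """Shift c so that softplus(slope*(u - c)) hits 40% of max at threshold."""
    lo, hi = span
    grid = np.linspace(lo, hi, 2001)

    def forty_point(c):
        vals = softplus(slope * (grid - c))
        target = vals.min() + 0.4 * (vals.max() - vals.min())
        return grid[np.argmax(vals >= target)] - threshold_sd

    return float(scipy.optimize.brentq(forty_point, lo, hi, xtol=1e-6))


def make_subunit_filter(sub: SubunitSpec, spec: GroundTruthSpec) -> np.ndarray:
    """Assemble one unit-norm (n_bars, n_lags) spatiotemporal filter."""
    x = (np.arange(spec.n_bars) + 0.5) * spec.bar_width_um
    gc = np.exp(-0.5 * ((x - sub.center_um) / sub.sigma_c_um) ** 2)
    gs = np.exp(-0.5 * ((x - sub.center_um) / sub.sigma_s_um) ** 2)
    k_c, k_s = _temporal_kernel(spec.n_lags, spec.frame_rate_hz,
                                sub.kernel_support_s)
    F = np.outer(gc, k_c) - sub.surround_weight * np.outer(gs, k_s)
    F *= sub.polarity
    return F / np.linalg.norm(F)


def make_ground_truth_model(spec: GroundTruthSpec) -> LNLNModel:
    """Deterministically build the LN-LN model a spec describes.

    Subunit nonlinearities are expressed in the bump basis by least-squares
    projection; a warning is raised if the projection residual exceeds 2%
    of the dynamic range.
    """
    filters = []
    nonlins = []
    for sub in spec.subunits:
        if not 0 <= sub.center_um <= spec.n_bars * spec.bar_width_um:
            raise ValueError("subunit center lies outside the stimulus span")
        F = make_subunit_filter(sub, spec)
        filters.append(F.T.ravel())          # lag-major flat layout
        if sub.nonlinearity == "softplus":
            shift = _softplus_shift(sub.threshold_sd, sub.slope, spec.bump_span)
            f = lambda u, s=sub.slope, c=shift: softplus(s * (u - c))
        elif sub.nonlinearity == "sigmoid":
            f = lambda u, s=sub.slope, c=sub.threshold_sd: \
                1.0 / (1.0 + np.exp(-s * (u - c)))
        else:
            raise ValueError(f"unknown nonlinearity kind {sub.nonlinearity!r}")
        nl, resid = BasisNonlinearity.from_function(
            f, n_bumps=spec.n_bumps, span=spec.bump_span)
        if resid > 0.02:
            warnings.warn(
                f"bump-basis projection residual {resid:.1%} exceeds 2% of range")
        nonlins.append(nl)
    return LNLNModel(
        filters=np.vstack(filters), nonlinearities=nonlins,
        output=OutputNonlinearity(gain=spec.gain, threshold=spec.theta),
        n_bars=spec.n_bars, n_lags=spec.n_lags)


def sample_poisson_spikes(model: LNLNModel, stimulus: Stimulus,
                          n_lags: int | None = None, seed=None,
                          design=None) -> SpikeTrain:
    """Sample Poisson spike counts from a model's predicted rate.

    Bins without complete stimulus history get zero counts, so the returned
    train has one bin per stimulus frame.  Pass a prebuilt ``design`` to
    avoid re-embedding the stimulus.
    """
    if design is None:
        design = build_design_matrix(stimulus, n_lags or model.n_lags)
    rates = predict_rate(model, design.X)
    rng = np.random.default_rng(seed)
    counts = np.zeros(stimulus.n_frames, dtype=np.int64)
    counts[design.offset:] = rng.poisson(rates)
    return SpikeTrain(counts=counts, bin_width_s=1.0 / stimulus.frame_rate_hz)


def two_subunit_spec(separation_bars: int = 10, n_bars: int = 20,
                     n_lags: int = 15, threshold_sd: float = 3.0,
                     gain: float = 0.18, theta: float = 2.5,
                     **kwargs) -> GroundTruthSpec:
    """The standard two-subunit fixture used throughout the test suite.

    Two Off-type subunits with 55/165 um center/surround widths, centers
    ``separation_bars`` bars apart and placed symmetrically around the
    middle of the bar array, high-threshold (3 s.d.) softplus
    nonlinearities, and an output stage producing roughly 1-2 spikes/s
    under white noise.  The 20-bar window and 150 ms temporal history keep
    the embedded dimension at 300, small enough that model fits on a
    hundred thousand bins run in minutes on one core while preserving the
    high-threshold, center-surround regime of interest.
    """
    bw = kwargs.pop("bar_width_um", 55.5)
    mid = n_bars / 2.0 * bw
    half = separation_bars / 2.0 * bw
    subs = [
        SubunitSpec(center_um=mid - half, threshold_sd=threshold_sd, **kwargs),
        SubunitSpec(center_um=mid + half, threshold_sd=threshold_sd, **kwargs),
    ]
    return GroundTruthSpec(subunits=subs, gain=gain, theta=theta,
                           n_bars=n_bars, n_lags=n_lags, bar_width_um=bw)
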