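"""Stimulus and spike-train containers and time embedding.

Conventions
-----------
Time indexing is 0-based and bins are half-open ``[t, t+1)`` (in frames).
The spike count in bin ``t`` is predicted from the stimulus history *ending*
at frame ``t`` (causal filtering), so design-matrix row ``t`` concatenates
stimulus frames ``t - n_lags + 1 .. t``, oldest first.  Frames with
incomplete history are dropped, not zero-padded.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclasses.dataclass
class Stimulus:
    """A 1-D spatiotemporal bar stimulus.

    Parameters
    ----------
    luminance : array, shape (n_bars, n_frames)
        Contrast values (nominally zero mean, unit variance).
    bar_width_um : float
        Width of each bar on the retina, micrometres.
    frame_rate_hz : float
        Stimulus update rate.
    """

    luminance: np.ndarray
    bar_width_um: float = 55.5
    frame_rate_hz: float = 100.0

    def __post_init__(self):
        self.luminance = np.atleast_2d(np.asarray(self.luminance, dtype=float))
        if self.luminance.size == 0:
            raise ValueError("stimulus must have at least one bar and one frame")
        if not np.all(np.isfinite(self.luminance)):
            raise ValueError("stimulus contains non-finite values")
        if self.bar_width_um <= 0 or self.frame_rate_hz <= 0:
            raise ValueError("bar width and frame rate must be positive")

    @property
    def n_bars(self) -> int:
        return self.luminance.shape[0]

    @property
    def n_frames(self) -> int:
        return self.luminance.shape[1]

    @property
    def span_um(self) -> float:
        """Physical extent covered by the bars, micrometres."""
        return self.n_bars * self.bar_width_um

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    def bar_positions_um(self) -> np.ndarray:
        """Centre position of each bar, micrometres from the left edge."""
        return (np.arange(self.n_bars) + 0.5) * self.bar_width_um


@dataclasses.dataclass
class SpikeTrain:
    """Binned spike counts aligned to stimulus frames."""

    counts: np.ndarray
    bin_width_s: float

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
            raise ValueError("spike counts must be non-negative integers")
        self.counts = counts.astype(np.int64)
        if self.bin_width_s <= 0:
            raise ValueError("bin width must be positive")

    @property
    def n_frames(self) -> int:
        return self.counts.size

    @property
    def n_spikes(self) -> int:
        return int(self.counts.sum())


def bin_spikes(spike_times, frame_rate_hz: float, n_frames: int) -> SpikeTrain:
    """Bin sorted spike times (seconds) into frame-aligned counts.

    Bin ``i`` is the half-open interval ``[i/f, (i+1)/f)``; every spike is
    counted exactly once, so ``sum(counts) == len(spike_times)``.
    """
    times = np.asarray(spike_times, dtype=float)
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("spike times must be sorted")
    duration = n_frames / frame_rate_hz
    if times.size and (times[0] < 0 or times[-1] >= duration):
        raise ValueError(f"spike times must lie in [0, {duration}) s")
    idx = np.floor(times * frame_rate_hz).astype(np.int64)
    counts = np.bincount(idx, minlength=n_frames)
    return SpikeTrain(counts=counts, bin_width_s=1.0 / frame_rate_hz)


@dataclasses.dataclass
class DesignMatrix:
    """Time-embedded stimulus rows aligned to spike-count bins.

    Row ``t`` holds frames ``t .. t + n_lags - 1`` of the stimulus,
    flattened lag-major (oldest frame first, bars contiguous within each
    lag), and predicts the spike count of frame ``offset + t`` where
    ``offset = n_lags - 1``.  Each row reshapes losslessly to an
    (n_bars, n_lags) spatiotemporal matrix via :meth:`row_as_spacetime`.
    """

    X: np.ndarray
    n_bars: int
    n_lags: int

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.n_bars * self.n_lags

    @property
    def offset(self) -> int:
        """Index of the first stimulus frame with complete history."""
        return self.n_lags - 1

    def row_as_spacetime(self, t: int) -> np.ndarray:
        """Row ``t`` as an (n_bars, n_lags) matrix; column tau is frame t+tau."""
        return self.X[t].reshape(self.n_lags, self.n_bars).T

    def align_counts(self, counts: np.ndarray) -> np.ndarray:
        """Drop the first ``offset`` bins so counts align with rows."""
        counts = np.asarray(counts)
        if counts.size != self.n_samples + self.offset:
            raise ValueError(
                f"expected {self.n_samples + self.offset} frame counts, got {counts.size}")
        return counts[self.offset:]


def build_design_matrix(stimulus: Stimulus, n_lags: int,
                        dtype=np.float64) -> DesignMatrix:
    """Time-embed a stimulus into design-matrix rows.

    Returns an (n_frames - n_lags + 1, n_bars * n_lags) matrix whose row t
    is the concatenation of frames t .. t + n_lags - 1 (oldest first).
    """
    if n_lags < 1:
        raise ValueError("n_lags must be at least 1")
    if n_lags > stimulus.n_frames:
        raise ValueError(
            f"n_lags={n_lags} exceeds the {stimulus.n_frames} stimulus frames")
    frames = np.ascontiguousarray(stimulus.luminance.T)  # (n_frames, n_bars)
    windows = sliding_window_view(frames, n_lags, axis=0)  # (n_samples, n_bars, n_lags)
    X = windows.swapaxes(1, 2).reshape(windows.shape[0], -1)
    return DesignMatrix(X=np.ascontiguousarray(X, dtype=dtype),
                        n_bars=stimulus.n_bars, n_lags=n_lags)


@dataclasses.dataclass
class DataSplit:
    """Contiguous train/validation/test sample blocks."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray


def split_contiguous(n_samples: int, fractions=(0.6, 0.2, 0.2)) -> DataSplit:
    """Split sample indices into contiguous train/validation/test blocks.

    Block boundaries are ``round(cumfrac * n)``, train first; every sample
    lands in exactly one block.  Contiguous blocks (rather than shuffled
    frames) respect the temporal correlation of embedded rows.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.size != 3 or np.any(fractions <= 0):
        raise ValueError("need three positive fractions")
    if not np.isclose(fractions.sum(), 1.0):
        raise ValueError("fractions must sum to 1")
    edges = np.round(np.cumsum(fractions) * n_samples).astype(int)
    edges[-1] = n_samples
    bounds = [0, *edges]
    blocks = [np.arange(a, b) for a, b in zip(bounds[:-1], bounds[1:])]
    if any(b.size == 0 for b in blocks):
        raise ValueError(f"degenerate split block for n_samples={n_samples}")
    return DataSplit(train=blocks[0], validation=blocks[1], test=blocks[2])
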