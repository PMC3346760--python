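"""Containers and preprocessing for extracellular recordings.

This module turns a raw recording — an LFP voltage trace, sorted spike times
for one unit and stimulus onset times — into the aligned, normalized inputs
used everywhere downstream: the three model features (LFP, its derivative and
the instantaneous phase of the derivative, each z-scored over all trials and
bins) and the 2-ms binarized spike response whose across-trial mean is the
PSTH.

Conventions
-----------
* All public windows and bin widths are in milliseconds; internal computation
  is in seconds and samples.
* Bins are half-open ``[t, t + bin_width)``, trial-relative, 0-based; a spike
  exactly on an edge belongs to the bin opening at that edge.
* z-scoring uses the population (divide-by-N) standard deviation computed
  jointly over all trials and bins of a feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as _sig


class InvalidBandError(ValueError):
    """Filter band incompatible with the trace's Nyquist frequency."""


class DegenerateFeatureError(ValueError):
    """A feature has zero variance and cannot be normalized."""


@dataclass(frozen=True)
class Trace:
    """A regularly sampled voltage trace.

    Parameters
    ----------
    samples : ndarray
        Signal values (volts or arbitrary units).
    fs : float
        Sampling rate in Hz; must be positive.
    t0 : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("trace requires a non-empty 1-D sample array")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (s) of a single unit; strictly increasing."""

    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class EventList:
    """Stimulus onset times (s) with an integer category label per event."""

    times: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        lab = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "labels", lab)
        if t.shape != lab.shape:
            raise ValueError("times and labels must have the same length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("event times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)

    def select(self, label: int) -> "EventList":
        m = self.labels == label
        return EventList(self.times[m], self.labels[m])


@dataclass(frozen=True)
class FeatureSet:
    """The three normalized model inputs, aligned on a trials x bins grid.

    ``x1`` is the (optionally STA-convolved) LFP, ``x2`` its time derivative
    and ``x3`` the Hilbert phase of the derivative; each is z-scored over all
    entries so that downstream weightings act on comparable scales.
    """

    x1: np.ndarray
    x2: np.ndarray
    x3: np.ndarray
    bin_width: float  # ms
    window: tuple[float, float]  # ms relative to stimulus onset

    def __post_init__(self) -> None:
        if not (self.x1.shape == self.x2.shape == self.x3.shape):
            raise ValueError("feature matrices must share one shape")

    @property
    def n_trials(self) -> int:
        return int(self.x1.shape[0])

    @property
    def n_bins(self) -> int:
        return int(self.x1.shape[1])

    def stacked(self) -> np.ndarray:
        """Features stacked on a leading axis: shape (3, trials, bins)."""
        return np.stack([self.x1, self.x2, self.x3])


@dataclass(frozen=True)
class BinaryResponse:
    """Trials x bins 0/1 spike matrix at a fixed bin width (default 2 ms)."""

    matrix: np.ndarray
    bin_width: float = 2.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2:
            raise ValueError("binary response must be 2-D (trials x bins)")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("binary response entries must be 0 or 1")
        object.__setattr__(self, "matrix", m.astype(np.int8))

    @property
    def n_trials(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def n_bins(self) -> int:
        return int(self.matrix.shape[1])

    @property
    def n_spikes(self) -> int:
        return int(self.matrix.sum())


# ---------------------------------------------------------------------------
# filtering / resampling


def bandpass_filter(trace: Trace, low: float, high: float, order: int = 4) -> Trace:
    """Zero-phase Butterworth band-pass (forward-backward), same length/fs.

    A 4th-order filter per pass (8th order effective) keeps the band edges the
    only tuning knobs while the filtfilt realization avoids latency distortion
    of the evoked response.
    """
    nyq = trace.fs / 2.0
    if not (0.0 < low < high < nyq):
        raise InvalidBandError(
            f"band ({low}, {high}) Hz invalid for Nyquist {nyq} Hz"
        )
    sos = _sig.butter(order, [low, high], btype="bandpass", fs=trace.fs, output="sos")
    return Trace(_sig.sosfiltfilt(sos, trace.samples), trace.fs, trace.t0)


def downsample(trace: Trace, target_fs: float) -> Trace:
    """Anti-aliased resampling to ``target_fs`` (polyphase FIR)."""
    if target_fs > trace.fs:
        raise ValueError("target rate exceeds the trace sampling rate")
    if np.isclose(target_fs, trace.fs):
        return trace
    ratio = Fraction(target_fs / trace.fs).limit_denominator(10000)
    out = _sig.resample_poly(trace.samples, ratio.numerator, ratio.denominator)
    return Trace(out, target_fs, trace.t0)


# ---------------------------------------------------------------------------
# STA and feature signals


def spike_triggered_average(
    lfp: Trace, spikes: SpikeTrain, half_window: float = 20.0
) -> np.ndarray:
    """Mean LFP segment centered on spike times.

    The 20-ms default half-window brackets the 15-20 ms evoked-response
    latency typical of these recordings. Spikes whose window would leave the
    trace are discarded; with no usable spike an error is raised.
    """
    n = int(round(half_window * lfp.fs / 1000.0))
    idx = np.round((spikes.times - lfp.t0) * lfp.fs).astype(int)
    idx = idx[(idx - n >= 0) & (idx + n < lfp.samples.size)]
    if idx.size == 0:
        raise ValueError("no spike with a full STA window inside the trace")
    segs = np.stack([lfp.samples[i - n : i + n + 1] for i in idx])
    return segs.mean(axis=0)


def convolve_sta(lfp: Trace, kernel: np.ndarray) -> Trace:
    """Centered ('same'-mode) convolution of the LFP with an STA kernel."""
    kernel = np.asarray(kernel, dtype=float)
    if kernel.size == 0:
        raise ValueError("empty convolution kernel")
    if kernel.size >= lfp.samples.size:
        raise ValueError("kernel must be shorter than the trace")
    out = _sig.fftconvolve(lfp.samples, kernel, mode="same")
    return Trace(out, lfp.fs, lfp.t0)


def derivative(trace: Trace) -> Trace:
    """Central-difference time derivative (units/s), one-sided at the edges."""
    if trace.samples.size < 2:
        raise ValueError("derivative requires at least two samples")
    return Trace(np.gradient(trace.samples) * trace.fs, trace.fs, trace.t0)


def hilbert_phase(trace: Trace) -> Trace:
    """Instantaneous phase of the analytic signal, radians in (-pi, pi]."""
    x = trace.samples
    if not np.isfinite(x).all():
        raise ValueError("trace contains non-finite values")
    if np.allclose(x, 0.0):
        raise ValueError("phase undefined for an all-zero trace")
    return Trace(np.angle(_sig.hilbert(x)), trace.fs, trace.t0)


def zscore(matrix: np.ndarray) -> np.ndarray:
    """Global z-score: subtract the grand mean, divide by the population SD."""
    a = np.asarray(matrix, dtype=float)
    sd = a.std()
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateFeatureError("zero-variance input cannot be z-scored")
    return (a - a.mean()) / sd


# ---------------------------------------------------------------------------
# trial alignment


def _bin_grid(window: tuple[float, float], bin_width: float) -> int:
    w0, w1 = window
    if not bin_width > 0:
        raise ValueError("bin width must be positive")
    if not w1 > w0:
        raise ValueError("empty analysis window")
    n_bins = int(round((w1 - w0) / bin_width))
    if n_bins < 1:
        raise ValueError("window shorter than one bin")
    return n_bins


def binarize_spikes(
    spikes: SpikeTrain,
    events: EventList,
    window: tuple[float, float],
    bin_width: float = 2.0,
) -> BinaryResponse:
    """Clip spikes into a trials x bins 0/1 matrix.

    Entry (k, j) is 1 iff at least one spike falls in the half-open 2-ms bin j
    of trial k; several spikes in one bin still yield a single 1 (the response
    is a binary signal, not a count). Overlapping trial windows would make the
    spike-to-trial assignment ambiguous and raise an error.
    """
    n_bins = _bin_grid(window, bin_width)
    w0, w1 = window[0] / 1000.0, window[1] / 1000.0
    starts = events.times + w0
    stops = events.times + w1
    if np.any(stops[:-1] > starts[1:] + 1e-12):
        raise ValueError("trial windows overlap; spike assignment ambiguous")
    mat = np.zeros((len(events), n_bins), dtype=np.int8)
    bw = bin_width / 1000.0
    for k, t_ev in enumerate(events.times):
        rel = spikes.times - (t_ev + w0)
        sel = (rel >= 0) & (rel < (w1 - w0))
        bins = np.floor(rel[sel] / bw).astype(int)
        bins = bins[bins < n_bins]
        mat[k, bins] = 1
    return BinaryResponse(mat, bin_width)


def psth(b: BinaryResponse) -> np.ndarray:
    """Across-trial mean of the binary response; spike probability per bin."""
    if b.n_trials < 1:
        raise ValueError("PSTH requires at least one trial")
    return b.matrix.mean(axis=0)


def slice_trials(
    trace: Trace,
    events: EventList,
    window: tuple[float, float],
    bin_width: float = 2.0,
) -> np.ndarray:
    """Sample a trace on the trial/bin grid: value at each bin start."""
    n_bins = _bin_grid(window, bin_width)
    w0 = window[0] / 1000.0
    bw = bin_width / 1000.0
    out = np.empty((len(events), n_bins))
    for k, t_ev in enumerate(events.times):
        idx = np.round((t_ev + w0 + np.arange(n_bins) * bw - trace.t0) * trace.fs)
        idx = idx.astype(int)
        if idx[0] < 0 or idx[-1] >= trace.samples.size:
            raise ValueError(f"trial {k} window extends outside the trace")
        out[k] = trace.samples[idx]
    return out


def extract_features(
    lfp: Trace,
    events: EventList,
    window: tuple[float, float],
    bin_width: float = 2.0,
    sta_kernel: np.ndarray | None = None,
) -> FeatureSet:
    """Build the three aligned, z-scored model inputs from an LFP trace.

    The feature signals are computed on the full trace — optional STA
    convolution, then derivative, then Hilbert phase of the derivative — and
    only afterwards cut into trials, so filter and phase estimates do not
    suffer per-trial edge effects.
    """
    base = convolve_sta(lfp, sta_kernel) if sta_kernel is not None else lfp
    deriv = derivative(base)
    phase = hilbert_phase(deriv)
    x1 = zscore(slice_trials(base, events, window, bin_width))
    x2 = zscore(slice_trials(deriv, events, window, bin_width))
    x3 = zscore(slice_trials(phase, events, window, bin_width))
    return FeatureSet(x1, x2, x3, bin_width, tuple(window))
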