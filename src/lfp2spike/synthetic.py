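"""Synthetic recording bundles with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* a couplet tactile-stimulation protocol — first pulses on an exact 500-ms
  grid, each second pulse following by a uniform 50-250 ms delay, 5-ms
  pulses cycling over five stimulus locations;
* an LFP made of 1/f background noise plus a stereotyped evoked deflection
  (difference of exponentials, 5-ms rise, 15-ms decay) appearing ~17 ms
  after each pulse with lognormal trial-to-trial gain;
* spikes produced by a known model genome of the package's own class applied
  to the pipeline-extracted features, thresholded to a target in-window
  rate, with optional per-bin flip noise and background Poisson spikes
  outside the analysis windows.

Because the spikes come from a genome in the search space, the full
pipeline can be tested for ground-truth recovery, not just for smoke.
All randomness flows from one master seed through named substreams so the
protocol, LFP and spikes can be varied independently.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .model import ModelGenome, OperatorSet, apply_model, threshold_prediction
from .signals import (
    BinaryResponse,
    EventList,
    FeatureSet,
    SpikeTrain,
    Trace,
    extract_features,
)

FORMAT_VERSION = "lfp2spike-bundle-1"


@dataclass(frozen=True)
class ProtocolSpec:
    """Couplet stimulation protocol parameters (times in ms)."""

    n_couplets: int = 500
    first_period: float = 500.0
    second_delay: tuple[float, float] = (50.0, 250.0)
    pulse_width: float = 5.0
    n_locations: int = 5
    t_start: float = 5000.0  # lead-in of spontaneous activity

    def __post_init__(self) -> None:
        lo, hi = self.second_delay
        if not (0.0 < lo < hi < self.first_period - self.pulse_width):
            raise ValueError("second-pulse delay range outside the couplet period")


@dataclass(frozen=True)
class LFPSimSpec:
    """LFP simulation parameters."""

    fs: float = 500.0
    alpha: float = 1.0  # background spectral exponent (1/f^alpha)
    background_amp: float = 1.0  # background SD, arbitrary units
    evoked_amp: float = 3.0  # mean evoked peak, same units
    latency: float = 17.0  # ms from pulse to deflection onset
    rise: float = 5.0  # ms
    decay: float = 15.0  # ms
    gain_sigma: float = 0.5  # lognormal sigma of per-trial gain
    tail: float = 1000.0  # ms of trace beyond the last event

    def __post_init__(self) -> None:
        if self.latency < 0:
            raise ValueError("latency must be nonnegative")
        if self.gain_sigma < 0:
            raise ValueError("gain sigma must be nonnegative")


def default_genome() -> ModelGenome:
    """Ground-truth genome: signed-square of the LFP dominating, linear
    derivative and phase contributions — weights (0.5, 0.3, 0.2)."""
    opset = OperatorSet()
    return ModelGenome(
        (opset.names.index("ssquare"), 0, 0), np.array([0.5, 0.3, 0.2])
    )


@dataclass(frozen=True)
class GroundTruth:
    """The spike-generating model plus its noise parameters.

    ``spike_noise`` flips each in-window bin with the given probability;
    ``base_rate`` adds background Poisson spikes (Hz) outside the analysis
    windows; ``target_rate`` is the in-window firing rate (Hz) the genome's
    threshold is calibrated to.
    """

    genome: ModelGenome = field(default_factory=default_genome)
    spike_noise: float = 0.1
    base_rate: float = 2.0
    target_rate: float = 20.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.spike_noise < 0.5:
            raise ValueError("flip probability must lie in [0, 0.5)")
        if self.base_rate < 0 or self.target_rate <= 0:
            raise ValueError("rates must be nonnegative (target positive)")


@dataclass(frozen=True)
class Recording:
    """An in-memory recording bundle: trace + spikes + events + manifest."""

    lfp: Trace
    spikes: SpikeTrain
    events: EventList
    manifest: dict


def _substream(seed: int, label: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), label]))


# ---------------------------------------------------------------------------
# protocol


def make_protocol(spec: ProtocolSpec, seed: int = 0) -> EventList:
    """Generate the couplet pulse train; every pulse is an event.

    Labels cycle over the locations couplet by couplet; both pulses of a
    couplet share the label.
    """
    rng = _substream(seed, 1)
    firsts = spec.t_start / 1000.0 + np.arange(spec.n_couplets) * (
        spec.first_period / 1000.0
    )
    delays = rng.uniform(*spec.second_delay, size=spec.n_couplets) / 1000.0
    times = np.empty(2 * spec.n_couplets)
    labels = np.empty(2 * spec.n_couplets, dtype=int)
    times[0::2] = firsts
    times[1::2] = firsts + delays
    labels[0::2] = np.arange(spec.n_couplets) % spec.n_locations
    labels[1::2] = labels[0::2]
    return EventList(times, labels)


def first_pulse_events(events: EventList) -> EventList:
    """The first pulse of each couplet (even indices of a protocol train).

    These are the analysis trials: 500 ms apart, so 50-ms pre and post
    windows never overlap a neighbouring trial.
    """
    return EventList(events.times[0::2], events.labels[0::2])


# ---------------------------------------------------------------------------
# LFP


def _one_over_f_noise(
    n: int, fs: float, alpha: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance 1/f^alpha noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(f)
    shape[1:] = f[1:] ** (-alpha / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def evoked_kernel(spec: LFPSimSpec) -> np.ndarray:
    """Difference-of-exponentials deflection, unit peak amplitude."""
    tau_r = spec.rise / 1000.0
    tau_d = spec.decay / 1000.0
    t = np.arange(0.0, 5.0 * tau_d, 1.0 / spec.fs)
    k = np.exp(-t / tau_d) - np.exp(-t / tau_r)
    peak = np.abs(k).max()
    return k / peak if peak > 0 else k


def simulate_lfp(events: EventList, spec: LFPSimSpec, seed: int = 0) -> Trace:
    """Background 1/f^alpha noise plus gain-jittered evoked deflections.

    The per-event gain is lognormal with mean ``evoked_amp`` (sigma
    ``gain_sigma``); the deflection is negative-going, as evoked LFPs
    typically are, though every downstream statistic is sign-blind.
    """
    rng = _substream(seed, 2)
    t_end = (events.times.max() if len(events) else 0.0) + spec.tail / 1000.0
    n = int(round(t_end * spec.fs)) + 1
    x = spec.background_amp * _one_over_f_noise(n, spec.fs, spec.alpha, rng)
    kern = evoked_kernel(spec)
    lat = spec.latency / 1000.0
    for t_ev in events.times:
        gain = spec.evoked_amp * rng.lognormal(
            mean=-0.5 * spec.gain_sigma**2, sigma=spec.gain_sigma
        )
        i0 = int(round((t_ev + lat) * spec.fs))
        i1 = min(i0 + kern.size, n)
        if i0 < n:
            x[i0:i1] -= gain * kern[: i1 - i0]
    return Trace(x, spec.fs, 0.0)


# ---------------------------------------------------------------------------
# spikes


def ground_truth_response(
    lfp: Trace,
    events: EventList,
    gt: GroundTruth,
    window: tuple[float, float] = (0.0, 50.0),
    bin_width: float = 2.0,
) -> tuple[FeatureSet, BinaryResponse]:
    """Noise-free response of the ground-truth genome on pipeline features.

    Features are extracted exactly as the analysis pipeline does (without the
    STA convolution, which would need the very spikes being generated); the
    genome's threshold is set so the total in-window spike count matches
    ``target_rate``.
    """
    feats = extract_features(lfp, events, window, bin_width)
    values = apply_model(gt.genome, feats)
    dur_s = (window[1] - window[0]) / 1000.0
    n_sp = int(round(gt.target_rate * dur_s * feats.n_trials))
    n_sp = min(n_sp, values.size)
    _, pred = threshold_prediction(values, n_sp)
    return feats, BinaryResponse(pred, bin_width)


def simulate_spikes(
    lfp: Trace,
    events: EventList,
    gt: GroundTruth,
    window: tuple[float, float] = (0.0, 50.0),
    seed: int = 0,
    bin_width: float = 2.0,
) -> SpikeTrain:
    """Spike times from the ground-truth model plus noise.

    In-window bins follow the thresholded genome output, each flipped with
    probability ``spike_noise``; spike times sit at bin centers so that
    re-binarizing with the same grid recovers the matrix bit for bit.
    Background Poisson spikes at ``base_rate`` fill the record outside the
    analysis windows.
    """
    rng = _substream(seed, 3)
    if len(events) == 0:
        mat = np.zeros((0, 0), dtype=np.int8)
    else:
        _, resp = ground_truth_response(lfp, events, gt, window, bin_width)
        mat = resp.matrix.copy()
    if gt.spike_noise > 0:
        flips = rng.random(mat.shape) < gt.spike_noise
        mat = np.where(flips, 1 - mat, mat)
    w0 = window[0] / 1000.0
    bw = bin_width / 1000.0
    times = []
    for k, t_ev in enumerate(events.times):
        bins = np.flatnonzero(mat[k])
        times.extend(t_ev + w0 + (bins + 0.5) * bw)
    # background activity outside the trial windows
    if gt.base_rate > 0:
        n_bg = rng.poisson(gt.base_rate * lfp.duration)
        bg = np.sort(rng.uniform(lfp.t0, lfp.t_end, size=n_bg))
        w1 = window[1] / 1000.0
        for t_ev in events.times:
            bg = bg[(bg < t_ev + w0) | (bg >= t_ev + w1)]
        times.extend(bg)
    t = np.unique(np.asarray(times, dtype=float))
    return SpikeTrain(t)


# ---------------------------------------------------------------------------
# full bundle


def make_dataset(
    protocol: ProtocolSpec = ProtocolSpec(),
    lfp_spec: LFPSimSpec = LFPSimSpec(),
    gt: GroundTruth = GroundTruth(),
    seed: int = 0,
    window: tuple[float, float] = (0.0, 50.0),
    bin_width: float = 2.0,
) -> Recording:
    """One call yields trace + spikes + events + a reproducibility manifest.

    The spike-generating trials are the first pulses of each couplet (see
    :func:`first_pulse_events`); the manifest records every spec and the
    master seed, so regenerating from the manifest reproduces the bundle
    exactly.
    """
    events = make_protocol(protocol, seed)
    lfp = simulate_lfp(events, lfp_spec, seed)
    trials = first_pulse_events(events)
    spikes = simulate_spikes(lfp, trials, gt, window, seed, bin_width)
    def plain(x):
        if isinstance(x, tuple):
            return [plain(v) for v in x]
        if isinstance(x, dict):
            return {k: plain(v) for k, v in x.items()}
        return x

    manifest = {
        "format_version": FORMAT_VERSION,
        "fs": lfp_spec.fs,
        "seed": int(seed),
        "window_ms": list(window),
        "bin_width_ms": bin_width,
        "protocol": asdict(protocol),
        "lfp": asdict(lfp_spec),
        "ground_truth": {
            "structure": list(gt.genome.structure),
            "weights": gt.genome.weights.tolist(),
            "spike_noise": gt.spike_noise,
            "base_rate": gt.base_rate,
            "target_rate": gt.target_rate,
        },
    }
    return Recording(lfp, spikes, events, plain(manifest))


def dataset_from_manifest(manifest: dict) -> Recording:
    """Regenerate a bundle from its manifest (exact reproduction)."""
    proto = dict(manifest["protocol"])
    proto["second_delay"] = tuple(proto["second_delay"])
    protocol = ProtocolSpec(**proto)
    lfp_spec = LFPSimSpec(**manifest["lfp"])
    g = manifest["ground_truth"]
    gt = GroundTruth(
        genome=ModelGenome(tuple(g["structure"]), np.array(g["weights"])),
        spike_noise=g["spike_noise"],
        base_rate=g["base_rate"],
        target_rate=g["target_rate"],
    )
    return make_dataset(
        protocol,
        lfp_spec,
        gt,
        seed=manifest["seed"],
        window=tuple(manifest["window_ms"]),
        bin_width=manifest["bin_width_ms"],
    )
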