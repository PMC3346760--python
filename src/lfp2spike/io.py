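"""Bundle readers/writers and run configuration.

A recording bundle is a directory of delimited-text files plus a JSON
manifest::

    trace.csv     time_s,value        (uniformly sampled LFP)
    spikes.txt    one spike time (s) per line
    events.csv    time_s,label
    manifest.json format version, fs, seeds, generator specs

Times are serialized in seconds as decimal text at 12 significant digits;
voltages are unit-agnostic because the analysis z-scores every feature.
"""

from __future__ import annotations

import json
from pathlib import Path
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .optimize import GAConfig
from .model import DEFAULT_OPERATOR_NAMES
from .signals import EventList, SpikeTrain, Trace
from .synthetic import FORMAT_VERSION, Recording

_REQUIRED_MANIFEST_KEYS = ("format_version", "fs")
_FMT = "%.12g"


class BundleError(ValueError):
    """A bundle file is missing or violates the schema."""


def write_bundle(rec: Recording, directory: str | Path) -> Path:
    """Write a recording bundle; returns the directory path."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    tr = np.column_stack([rec.lfp.times(), rec.lfp.samples])
    np.savetxt(d / "trace.csv", tr, fmt=_FMT, delimiter=",",
               header="time_s,value", comments="")
    np.savetxt(d / "spikes.txt", rec.spikes.times, fmt=_FMT)
    ev = np.column_stack([rec.events.times, rec.events.labels])
    np.savetxt(d / "events.csv", ev, fmt=[_FMT, "%d"], delimiter=",",
               header="time_s,label", comments="")
    (d / "manifest.json").write_text(
        json.dumps(rec.manifest, indent=2, sort_keys=True) + "\n"
    )
    return d


def read_bundle(directory: str | Path) -> Recording:
    """Load and validate a recording bundle."""
    d = Path(directory)
    for name in ("trace.csv", "spikes.txt", "events.csv", "manifest.json"):
        if not (d / name).exists():
            raise BundleError(f"missing bundle file: {name}")
    manifest = json.loads((d / "manifest.json").read_text())
    missing = [k for k in _REQUIRED_MANIFEST_KEYS if k not in manifest]
    if missing:
        raise BundleError(f"manifest missing required keys: {missing}")

    tr = np.loadtxt(d / "trace.csv", delimiter=",", skiprows=1)
    if tr.ndim != 2 or tr.shape[1] != 2:
        raise BundleError("trace.csv must have columns time_s,value")
    times, values = tr[:, 0], tr[:, 1]
    fs = float(manifest["fs"])
    dt = np.diff(times)
    if dt.size and not np.allclose(dt, 1.0 / fs, rtol=1e-6, atol=1e-9):
        raise BundleError("trace sampling interval disagrees with manifest fs")
    lfp = Trace(values, fs, float(times[0]))

    raw = np.loadtxt(d / "spikes.txt", ndmin=1)
    try:
        spikes = SpikeTrain(raw)
    except ValueError as e:
        bad = int(np.flatnonzero(np.diff(raw) <= 0)[0]) + 2
        raise BundleError(f"spikes.txt line {bad}: {e}") from e

    ev = np.loadtxt(d / "events.csv", delimiter=",", skiprows=1, ndmin=2)
    events = EventList(ev[:, 0], ev[:, 1].astype(int))
    if len(events) and (
        events.times[0] < lfp.t0 or events.times[-1] > lfp.t_end
    ):
        raise BundleError("event times fall outside the trace span")
    if len(spikes) and (
        spikes.times[0] < lfp.t0 or spikes.times[-1] > lfp.t_end
    ):
        raise BundleError("spike times fall outside the trace span")
    return Recording(lfp, spikes, events, manifest)


# ---------------------------------------------------------------------------
# run configuration


@dataclass(frozen=True)
class RunConfig:
    """All pipeline settings; every default is the reference protocol value.

    Attributes
    ----------
    bin_width : float
        Response bin width, ms.
    window : tuple
        Post-stimulus analysis window, ms.
    mi_windows : tuple
        Spike-count windows for the MI search, ms.
    ga : GAConfig
        Genetic-algorithm settings.
    operators : tuple
        Operator-set names defining the model class.
    use_sta : bool
        Convolve the LFP with the spike-triggered average before feature
        extraction.
    sta_half_window : float
        STA half-window, ms.
    trials : str
        ``"first_pulses"`` (couplet protocols) or ``"all"`` events as trials.
    bandpass : tuple or None
        Optional preprocessing band (low, high) Hz for raw traces.
    downsample_to : float or None
        Optional target rate (Hz) after filtering.
    mi_n_rep : int
        Shuffle repetitions for the MI bias correction.
    seed : int
        Master seed for every stochastic stage.
    """

    bin_width: float = 2.0
    window: tuple[float, float] = (0.0, 50.0)
    mi_windows: tuple[float, ...] = tuple(range(5, 55, 5))
    ga: GAConfig = field(default_factory=GAConfig)
    operators: tuple[str, ...] = DEFAULT_OPERATOR_NAMES
    use_sta: bool = True
    sta_half_window: float = 20.0
    trials: str = "first_pulses"
    bandpass: tuple[float, float] | None = None
    downsample_to: float | None = None
    mi_n_rep: int = 100
    seed: int = 0

    def to_dict(self) -> dict:
        """Plain-container form (lists, not tuples) safe for YAML/JSON."""

        def plain(x):
            if isinstance(x, tuple):
                return [plain(v) for v in x]
            if isinstance(x, dict):
                return {k: plain(v) for k, v in x.items()}
            return x

        d = asdict(self)
        d["ga"] = asdict(self.ga)
        return plain(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "ga" in d and isinstance(d["ga"], dict):
            ga = dict(d["ga"])
            if "objectives" in ga:
                ga["objectives"] = tuple(ga["objectives"])
            d["ga"] = GAConfig(**ga)
        for key in ("window", "mi_windows", "operators", "bandpass"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
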