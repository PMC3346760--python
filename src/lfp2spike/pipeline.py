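"""Single-command per-unit analysis: preprocess -> responsiveness -> fit.

``run_pipeline`` reproduces the whole per-neuron workflow on one recording
bundle and returns a plain JSON-serializable report: the MI table over the
window/location grid, the LFP responsiveness and Spectral Ratio, the fitted
Pareto fronts and the above-chance verdict. Reports are byte-reproducible
for a fixed bundle, config and seed (no timestamps in the body).
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd

from . import optimize, responsiveness as resp
from .io import RunConfig
from .model import OperatorSet, format_equation, genome_to_text
from .signals import (
    EventList,
    Trace,
    bandpass_filter,
    binarize_spikes,
    downsample,
    extract_features,
    spike_triggered_average,
)
from .synthetic import Recording, first_pulse_events

log = logging.getLogger("lfp2spike")


def _trial_events(cfg: RunConfig, rec: Recording) -> EventList:
    if cfg.trials == "first_pulses":
        return first_pulse_events(rec.events)
    if cfg.trials == "all":
        return rec.events
    raise ValueError(f"unknown trial selection: {cfg.trials!r}")


def preprocess(cfg: RunConfig, lfp: Trace) -> Trace:
    """Optional band-pass and downsampling for raw wideband traces."""
    if cfg.bandpass is not None:
        lfp = bandpass_filter(lfp, *cfg.bandpass)
        log.info("bandpass %s Hz applied (n=%d)", cfg.bandpass, lfp.samples.size)
    if cfg.downsample_to is not None:
        lfp = downsample(lfp, cfg.downsample_to)
        log.info("downsampled to %.6g Hz (n=%d)", lfp.fs, lfp.samples.size)
    return lfp


def responsiveness_table(cfg: RunConfig, rec: Recording) -> pd.DataFrame:
    """Corrected MI per (location, window), plus the arg-max summary row."""
    trials = _trial_events(cfg, rec)
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for loc in sorted(np.unique(trials.labels).tolist()):
        ev = trials.select(loc)
        for w in cfg.mi_windows:
            table = resp.count_spikes(rec.spikes, ev, w)
            est = resp.corrected_mi(table, cfg.mi_n_rep, rng)
            rows.append(
                {
                    "location": loc,
                    "window_ms": w,
                    "mi_bits": est.value,
                    "noise_bits": est.noise,
                    "reliable": est.reliable,
                }
            )
    df = pd.DataFrame(rows)
    reliable = df[df["reliable"]]
    pool = reliable if len(reliable) else df
    top = pool.sort_values(
        ["mi_bits", "window_ms", "location"], ascending=[False, True, True]
    ).iloc[0]
    # arg-max summary row, marked with location -1
    df = pd.concat(
        [df, pd.DataFrame([{**top.to_dict(), "location": -1}])],
        ignore_index=True,
    )
    return df


def run_pipeline(cfg: RunConfig, rec: Recording) -> dict:
    """Full per-unit analysis; returns the report as a plain dict."""
    lfp = preprocess(cfg, rec.lfp)
    trials = _trial_events(cfg, rec)
    log.info("trials=%d spikes=%d", len(trials), len(rec.spikes))

    # --- responsiveness ---------------------------------------------------
    mi_best = resp.best_mi(
        rec.spikes, trials, cfg.mi_windows, cfg.mi_n_rep, cfg.seed
    )
    rm = resp.response_matrix(lfp, trials, cfg.window)
    r_lfp = resp.lfp_responsiveness(rm)

    sr = None
    t_first = trials.times[0] if len(trials) else lfp.t_end
    spont_dur = t_first - lfp.t0
    if spont_dur >= 2.0 and lfp.t_end - t_first >= 2.0:
        n0 = int(round(spont_dur * lfp.fs))
        spont = Trace(lfp.samples[:n0], lfp.fs, lfp.t0)
        stim = Trace(lfp.samples[n0:], lfp.fs, t_first)
        sr = resp.spectral_ratio(resp.psd(stim), resp.psd(spont))

    # --- features and truth ----------------------------------------------
    sta = None
    if cfg.use_sta:
        sta = spike_triggered_average(lfp, rec.spikes, cfg.sta_half_window)
    feats = extract_features(lfp, trials, cfg.window, cfg.bin_width, sta)
    truth = binarize_spikes(rec.spikes, trials, cfg.window, cfg.bin_width)

    # --- model estimation -------------------------------------------------
    opset = OperatorSet(cfg.operators)
    result = optimize.fit(feats, truth, cfg.ga, opset)
    verdict = optimize.above_chance(result)

    def front_rows(front):
        return [
            {
                "equation": format_equation(m.genome, opset),
                "genome": genome_to_text(m.genome, opset),
                **{k: round(v, 12) for k, v in m.costs.items()},
            }
            for m in front
        ]

    report = {
        "config": cfg.to_dict(),
        "n_trials": len(trials),
        "n_spikes": len(rec.spikes),
        "responsiveness": {
            "mi_bits": mi_best.value,
            "mi_noise_bits": mi_best.noise,
            "mi_reliable": mi_best.reliable,
            "mi_window_ms": mi_best.window,
            "mi_location": mi_best.location,
            "r_lfp": None if not np.isfinite(r_lfp) else r_lfp,
            "spectral_ratio": sr,
        },
        "fit": {
            "train_front": front_rows(result.train_front),
            "val_front": front_rows(result.val_front),
            "generations": len(result.history),
            "final_min": result.history[-1] if result.history else None,
        },
        "above_chance": verdict,
    }
    return report


def report_to_json(report: dict) -> str:
    """Deterministic serialization: sorted keys, fixed float formatting."""
    return json.dumps(report, indent=2, sort_keys=True, allow_nan=False)
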