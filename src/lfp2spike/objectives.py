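"""Cost functions scoring a predicted binary response against the truth.

Three objectives, all minimized and all chance-anchored:

* **Spike Match (SM)** — local, trial-to-trial: the Hamming distance between
  prediction and truth over all bins, divided by the expected Hamming
  distance of a count-matched prediction placed uniformly at random. 0 means
  a perfect bin-for-bin match, 1 means chance-level prediction.
* **PSTH Fit (PF)** — global: RMSE between predicted and true PSTHs, divided
  by the root of the *expected* squared PSTH error of a random count-matched
  prediction. That expectation has two parts: the distance between the flat
  PSTH at the truth's mean rate (the chance prediction's expected PSTH) and
  the true PSTH, plus the sampling variance of the chance prediction's PSTH
  around flat. Same 0/1 anchoring: dividing by the flat-PSTH distance alone
  would ignore the variance term and push the chance mean well above 1.
* **Complexity Order (CO)** — parsimony: normalized entropy of the weight
  triple; 0 for a single-feature (one-hot) model, 1 for uniform weights.

For k ones placed uniformly at random among T bins against a truth with k
ones, the overlap is hypergeometric with mean k^2/T, so the expected Hamming
distance is ``E[H] = 2k(1 - k/T)`` — the closed-form chance normalizer used
by SM (cross-checked by exhaustive enumeration in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signals import BinaryResponse, psth

#: Finite sentinel for degenerate normalizations (k = 0 or k = T with a
#: mismatch): large enough to be dominated, without propagating inf/NaN.
SENTINEL = 1e3


@dataclass(frozen=True)
class CostVector:
    """(SM, PF, CO) for one genome; all entries finite and >= 0."""

    sm: float
    pf: float
    co: float

    def as_array(self) -> np.ndarray:
        return np.array([self.sm, self.pf, self.co])


def chance_hamming(k: int, T: int) -> float:
    """Expected Hamming distance of a uniform count-matched placement."""
    return 2.0 * k * (1.0 - k / T)


def spike_match(truth: BinaryResponse, pred: BinaryResponse) -> float:
    """Chance-normalized Hamming distance; 0 iff exact match, ~1 at chance."""
    if truth.matrix.shape != pred.matrix.shape:
        raise ValueError("truth and prediction shapes differ")
    h = int(np.count_nonzero(truth.matrix != pred.matrix))
    k = truth.n_spikes
    T = truth.matrix.size
    if k == 0 or k == T:
        return 0.0 if h == 0 else SENTINEL
    return h / chance_hamming(k, T)


def chance_psth_mse(truth: BinaryResponse) -> float:
    """Expected squared PSTH error of a uniform count-matched prediction.

    Placing k ones uniformly among the T = n_trials * n_bins cells makes the
    per-bin one-count hypergeometric; its PSTH scatters around the flat rate
    k/T with variance (k/T)(1-k/T)(T-n_tr)/(n_tr(T-1)) per bin. Adding the
    flat-to-truth distance gives the exact chance-level mean squared error,
    so E[PF^2] = 1 at chance (and the Monte-Carlo mean of PF sits within a
    few percent of 1 for response sizes of practical interest).
    """
    pt = psth(truth)
    n_tr = truth.n_trials
    T = truth.matrix.size
    k = truth.n_spikes
    rate = k / T
    var = 0.0
    if T > 1:
        var = rate * (1.0 - rate) * (T - n_tr) / (n_tr * (T - 1))
    return float(var + np.mean((rate - pt) ** 2))


def psth_fit(truth: BinaryResponse, pred: BinaryResponse) -> float:
    """Chance-normalized PSTH RMSE; 0 iff the PSTHs coincide, ~1 at chance."""
    if truth.matrix.shape != pred.matrix.shape:
        raise ValueError("truth and prediction shapes differ")
    pt = psth(truth)
    pp = psth(pred)
    num = float(np.sqrt(np.mean((pp - pt) ** 2)))
    den = float(np.sqrt(chance_psth_mse(truth)))
    if den == 0.0:
        return 0.0 if num == 0.0 else SENTINEL
    return num / den


def complexity_order(weights: np.ndarray) -> float:
    """Normalized weight entropy: 0 one-hot, 1 uniform.

    Any strictly Schur-concave function of the weights would preserve the two
    anchors; base-2 entropy over log2(3) is the simplest such choice and is
    isolated here so it can be swapped.
    """
    w = np.asarray(weights, dtype=float)
    p = w[w > 0]
    h = float(-(p * np.log2(p)).sum())
    return max(0.0, h / np.log2(3.0))


def dominates(a: CostVector | np.ndarray, b: CostVector | np.ndarray) -> bool:
    """Pareto dominance: a <= b everywhere and strictly better somewhere."""
    av = a.as_array() if isinstance(a, CostVector) else np.asarray(a, dtype=float)
    bv = b.as_array() if isinstance(b, CostVector) else np.asarray(b, dtype=float)
    if av.shape != bv.shape:
        raise ValueError("cost vectors must share dimensionality")
    return bool(np.all(av <= bv) and np.any(av < bv))


def evaluate_costs(
    truth: BinaryResponse, pred: BinaryResponse, weights: np.ndarray
) -> CostVector:
    """All three objectives for one (truth, prediction, genome-weights) triple."""
    return CostVector(
        sm=spike_match(truth, pred),
        pf=psth_fit(truth, pred),
        co=complexity_order(weights),
    )
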