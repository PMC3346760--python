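"""The LFP-to-spike model class.

A candidate model (genome) is a weighted combination of the three normalized
LFP features, each first passed through a unary operator drawn from a small
configurable operator set U:

    value(k, j) = w1*u_{j1}(x1) + w2*u_{j2}(x2) + w3*u_{j3}(x3)

with nonnegative weights summing to 1. The continuous output is converted to
a binary spike prediction by a Heaviside threshold calibrated so that the
prediction emits exactly as many spikes as the true response (``n_sp``). The
operator-index triple is the model *structure* (|U|^3 possibilities), the
weights are its *parameters*.

The default operator set holds four odd, sign-preserving nonlinearities
(identity, signed square, cube, signed square root) spanning compressive and
expansive transforms of z-scored inputs; it is configuration, not dogma.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .signals import BinaryResponse, FeatureSet

_SIMPLEX_TOL = 1e-9

#: Registry of available unary operators, keyed by name.
OPERATORS = {
    "identity": lambda x: x,
    "ssquare": lambda x: x * np.abs(x),
    "cube": lambda x: x**3,
    "ssqrt": lambda x: np.sign(x) * np.sqrt(np.abs(x)),
}

DEFAULT_OPERATOR_NAMES = ("identity", "ssquare", "cube", "ssqrt")


@dataclass(frozen=True)
class OperatorSet:
    """An ordered set of named unary operators."""

    names: tuple[str, ...] = DEFAULT_OPERATOR_NAMES

    def __post_init__(self) -> None:
        if len(self.names) < 1:
            raise ValueError("operator set must contain at least one operator")
        unknown = [n for n in self.names if n not in OPERATORS]
        if unknown:
            raise KeyError(f"unknown operators: {unknown}")

    def __len__(self) -> int:
        return len(self.names)

    def func(self, i: int):
        return OPERATORS[self.names[i]]


@dataclass(frozen=True)
class ModelGenome:
    """One candidate LFP-to-spike transformation.

    ``structure`` indexes three operators from an :class:`OperatorSet`;
    ``weights`` live on the 2-simplex; ``theta`` is the Heaviside threshold,
    set by spike-count calibration on whichever dataset the genome is being
    evaluated on — it is bookkeeping, not an evolved parameter.
    """

    structure: tuple[int, int, int]
    weights: np.ndarray
    theta: float | None = None

    def __post_init__(self) -> None:
        s = tuple(int(i) for i in self.structure)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "structure", s)
        object.__setattr__(self, "weights", w)
        if len(s) != 3 or w.shape != (3,):
            raise ValueError("genome needs 3 operator indices and 3 weights")
        if np.any(w < -_SIMPLEX_TOL) or abs(w.sum() - 1.0) > _SIMPLEX_TOL:
            raise ValueError("weights must be nonnegative and sum to 1")

    def with_theta(self, theta: float) -> "ModelGenome":
        return replace(self, theta=theta)


@dataclass(frozen=True)
class ModelOutput:
    """Continuous model values plus the thresholded binary prediction."""

    values: np.ndarray
    prediction: BinaryResponse
    theta: float


def normalize_weights(w: np.ndarray) -> np.ndarray:
    """Clip at zero and renormalize onto the simplex; raise if the sum is 0."""
    w = np.clip(np.asarray(w, dtype=float), 0.0, None)
    s = w.sum()
    if s <= 0:
        raise ValueError("cannot normalize an all-zero weight vector")
    return w / s


def enumerate_structures(opset: OperatorSet) -> list[tuple[int, int, int]]:
    """All |U|^3 ordered operator triples, in stable lexicographic order."""
    n = len(opset)
    return list(itertools.product(range(n), repeat=3))


def apply_model(
    genome: ModelGenome, features: FeatureSet, opset: OperatorSet = OperatorSet()
) -> np.ndarray:
    """Evaluate the weighted operator combination bin-wise."""
    n = len(opset)
    if any(not (0 <= i < n) for i in genome.structure):
        raise IndexError("structure index outside the operator set")
    xs = (features.x1, features.x2, features.x3)
    out = np.zeros_like(features.x1)
    for w, j, x in zip(genome.weights, genome.structure, xs):
        out += w * opset.func(j)(x)
    return out


def threshold_prediction(values: np.ndarray, n_sp: int) -> tuple[float, np.ndarray]:
    """Rank-based Heaviside calibration: exactly ``n_sp`` ones.

    theta is the (n_sp+1)-th largest value so that strictly greater entries
    fire; ties at theta are resolved by earlier (trial, bin) position so the
    spike-count match is deterministic even on degenerate value matrices.
    """
    flat = values.ravel()
    total = flat.size
    if not 0 <= n_sp <= total:
        raise ValueError("spike count outside [0, total bins]")
    pred = np.zeros(total, dtype=np.int8)
    if n_sp == 0:
        theta = float(flat.max())
    elif n_sp == total:
        theta = float(flat.min()) - 1.0
        pred[:] = 1
    else:
        order = np.argsort(-flat, kind="stable")
        theta = float(flat[order[n_sp]])
        pred[order[:n_sp]] = 1
    return theta, pred.reshape(values.shape)


def calibrate_threshold(values: np.ndarray, n_sp: int) -> float:
    """Threshold at which exactly ``n_sp`` entries exceed theta (up to ties)."""
    theta, _ = threshold_prediction(values, n_sp)
    return theta


def predict(
    genome: ModelGenome,
    features: FeatureSet,
    n_sp: int,
    opset: OperatorSet = OperatorSet(),
) -> ModelOutput:
    """Full transformation: model values -> calibrated Heaviside -> binary."""
    values = apply_model(genome, features, opset)
    theta, pred = threshold_prediction(values, n_sp)
    return ModelOutput(values, BinaryResponse(pred, features.bin_width), theta)


# ---------------------------------------------------------------------------
# serialization

def genome_to_text(genome: ModelGenome, opset: OperatorSet = OperatorSet()) -> str:
    """Loss-free (12 significant digits) structured-text serialization."""
    ops = ",".join(opset.names[i] for i in genome.structure)
    ws = ",".join(f"{w:.12g}" for w in genome.weights)
    th = "none" if genome.theta is None else f"{genome.theta:.12g}"
    return f"ops={ops}\nweights={ws}\ntheta={th}\n"


def genome_from_text(text: str, opset: OperatorSet = OperatorSet()) -> ModelGenome:
    fields: dict[str, str] = {}
    for line in text.strip().splitlines():
        key, _, val = line.partition("=")
        fields[key.strip()] = val.strip()
    names = fields["ops"].split(",")
    structure = tuple(opset.names.index(n) for n in names)
    weights = np.array([float(v) for v in fields["weights"].split(",")])
    theta = None if fields.get("theta", "none") == "none" else float(fields["theta"])
    return ModelGenome(structure, normalize_weights(weights), theta)


def format_equation(genome: ModelGenome, opset: OperatorSet = OperatorSet()) -> str:
    """Human-readable model law, e.g. ``0.50*ssquare(x1) + 0.30*x2 + ...``."""
    parts = []
    for w, j, name in zip(genome.weights, genome.structure, ("x1", "x2", "x3")):
        if w == 0:
            continue
        op = opset.names[j]
        term = name if op == "identity" else f"{op}({name})"
        parts.append(f"{w:.3g}*{term}")
    return " + ".join(parts) if parts else "0"
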