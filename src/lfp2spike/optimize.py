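"""Multi-objective search over model genomes: NSGA-II with restricted mating.

The genome mixes a discrete part (the operator-structure triple) with a
continuous one (the simplex weights). Crossover between different structures
would average parameters that mean different things, so mating is restricted
to parents sharing a structure — the one modification to the classic
elitist NSGA-II loop (fast non-dominated sorting, crowding distance, binary
tournament on (rank, crowding), merge of parents and offspring truncated by
rank then crowding).

Data are split into equal training and validation halves by alternating
trials. The training Pareto front is re-evaluated on the validation half —
with the Heaviside threshold recalibrated to the validation spike count —
and its validation-non-dominated subset is the fitted result.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import objectives as obj
from .model import ModelGenome, OperatorSet, apply_model, threshold_prediction
from .signals import BinaryResponse, FeatureSet

OBJECTIVE_NAMES = ("sm", "pf", "co")


class StructureMismatchError(ValueError):
    """Restricted mating refused: the parents' structures differ."""


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings.

    Defaults follow the reference protocol: population 320 (five individuals
    per structure on average, for |U| = 4), 50 generations, mutation
    probability 0.1 on both the structure and the parameters. ``mut_sigma``
    is the scale of the Gaussian weight perturbation.
    """

    pop_size: int = 320
    generations: int = 50
    p_mut: float = 0.1
    mut_sigma: float = 0.1
    seed: int = 0
    objectives: tuple[str, ...] = OBJECTIVE_NAMES

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("population size must be >= 2")
        if not 0.0 <= self.p_mut <= 1.0:
            raise ValueError("mutation probability must lie in [0, 1]")
        bad = [o for o in self.objectives if o not in OBJECTIVE_NAMES]
        if bad:
            raise ValueError(f"unknown objectives: {bad}")


@dataclass
class Population:
    genomes: list[ModelGenome]
    costs: np.ndarray  # (n, n_objectives)
    fronts: list[list[int]] = field(default_factory=list)
    crowding: np.ndarray | None = None


@dataclass(frozen=True)
class FrontMember:
    genome: ModelGenome
    costs: dict[str, float]


@dataclass(frozen=True)
class FitResult:
    """Training front, validation-selected front and per-generation history."""

    train_front: tuple[FrontMember, ...]
    val_front: tuple[FrontMember, ...]
    history: tuple[dict, ...]
    objectives: tuple[str, ...]


# ---------------------------------------------------------------------------
# NSGA-II building blocks


def init_population(
    cfg: GAConfig, opset: OperatorSet, rng: np.random.Generator | None = None
) -> list[ModelGenome]:
    """Random sample of parameter space with balanced structure coverage.

    The population is sized so every structure is represented, so the
    initializer deals structures out stratified — each of the |U|^3 triples
    appears floor(pop/|U|^3) or ceil(pop/|U|^3) times, in shuffled order —
    rather than sampling with replacement, which at one individual per
    structure would leave ~1/e of the structures uncovered. Weights are
    uniform on the 2-simplex (flat Dirichlet). Marginally each slot remains
    uniform over the operator set.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    from .model import enumerate_structures

    structures = enumerate_structures(opset)
    reps = -(-cfg.pop_size // len(structures))  # ceil
    deck = np.tile(np.arange(len(structures)), reps)
    rng.shuffle(deck)
    out = []
    for i in range(cfg.pop_size):
        weights = rng.dirichlet(np.ones(3))
        out.append(ModelGenome(structures[deck[i]], weights))
    return out


def nondominated_sort(costs: np.ndarray) -> list[list[int]]:
    """Fast non-dominated sorting: peel successive non-dominated fronts."""
    c = np.asarray(costs, dtype=float)
    if c.ndim != 2 or c.shape[0] < 1:
        raise ValueError("need at least one cost vector")
    n = c.shape[0]
    le = np.all(c[:, None, :] <= c[None, :, :], axis=2)
    lt = np.any(c[:, None, :] < c[None, :, :], axis=2)
    dom = le & lt  # dom[i, j]: i dominates j
    n_dom = dom.sum(axis=0)  # how many dominate each j
    fronts: list[list[int]] = []
    remaining = n_dom.copy()
    current = np.flatnonzero(remaining == 0)
    assigned = np.zeros(n, dtype=bool)
    while current.size:
        fronts.append(current.tolist())
        assigned[current] = True
        # removing the current front lowers domination counts of the rest
        remaining = remaining - dom[current].sum(axis=0)
        remaining[assigned] = -1
        current = np.flatnonzero(remaining == 0)
    return fronts


def crowding_distance(front_costs: np.ndarray) -> np.ndarray:
    """Standard crowding distance; boundary solutions get infinity."""
    c = np.asarray(front_costs, dtype=float)
    n, m = c.shape
    if n == 0:
        raise ValueError("empty front")
    d = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for j in range(m):
        order = np.argsort(c[:, j], kind="stable")
        span = c[order[-1], j] - c[order[0], j]
        d[order[0]] = d[order[-1]] = np.inf
        if span > 0:
            gaps = (c[order[2:], j] - c[order[:-2], j]) / span
            d[order[1:-1]] += gaps
    return d


def restricted_mate(
    parent_a: ModelGenome, parent_b: ModelGenome, rng: np.random.Generator
) -> ModelGenome:
    """Uniform parameter crossover between same-structure parents.

    Each weight is copied from a uniformly chosen parent and the triple is
    renormalized to the simplex; the rare all-zero draw is re-tossed.
    """
    if parent_a.structure != parent_b.structure:
        raise StructureMismatchError("parents must share a structure to mate")
    for _ in range(100):
        pick = rng.integers(0, 2, size=3)
        w = np.where(pick == 0, parent_a.weights, parent_b.weights)
        if w.sum() > 0:
            return ModelGenome(parent_a.structure, w / w.sum())
    # both parents must hold complementary zero patterns; fall back to a blend
    w = 0.5 * (parent_a.weights + parent_b.weights)
    return ModelGenome(parent_a.structure, w / w.sum())


def mutate(
    genome: ModelGenome,
    cfg: GAConfig,
    opset: OperatorSet,
    rng: np.random.Generator,
) -> ModelGenome:
    """Per-gene structure and parameter mutations, each with prob. 0.1.

    Every operator slot independently switches to a different uniformly
    chosen operator with probability ``p_mut``; every weight independently
    receives a Gaussian(0, sigma^2) nudge with the same probability, after
    which the triple is clipped at 0 and renormalized. The per-gene reading
    keeps the expected number of mutated genes per offspring proportional to
    genome length and sustains search pressure in small populations.
    """
    structure = list(genome.structure)
    n_ops = len(opset)
    if n_ops > 1:
        for slot in range(3):
            if rng.random() < cfg.p_mut:
                alternatives = [i for i in range(n_ops) if i != structure[slot]]
                structure[slot] = alternatives[int(rng.integers(0, len(alternatives)))]
    weights = genome.weights
    w = weights.copy()
    touched = False
    for slot in range(3):
        if rng.random() < cfg.p_mut:
            w[slot] += rng.normal(0.0, cfg.mut_sigma)
            touched = True
    if touched:
        w = np.clip(w, 0.0, None)
        if w.sum() > 0:
            weights = w / w.sum()
    return ModelGenome(tuple(structure), weights)


# ---------------------------------------------------------------------------
# evaluation helpers


def _subset(features: FeatureSet, truth: BinaryResponse, idx: slice):
    f = FeatureSet(
        features.x1[idx], features.x2[idx], features.x3[idx],
        features.bin_width, features.window,
    )
    t = BinaryResponse(truth.matrix[idx], truth.bin_width)
    return f, t


def _evaluate(
    genomes: list[ModelGenome],
    features: FeatureSet,
    truth: BinaryResponse,
    opset: OperatorSet,
    objective_names: tuple[str, ...],
) -> np.ndarray:
    n_sp = truth.n_spikes
    rows = np.empty((len(genomes), len(objective_names)))
    for i, g in enumerate(genomes):
        values = apply_model(g, features, opset)
        _, pred = threshold_prediction(values, n_sp)
        pred_b = BinaryResponse(pred, truth.bin_width)
        full = {
            "sm": obj.spike_match(truth, pred_b),
            "pf": obj.psth_fit(truth, pred_b),
            "co": obj.complexity_order(g.weights),
        }
        rows[i] = [full[name] for name in objective_names]
    return rows


def _rank_of(fronts: list[list[int]], n: int) -> np.ndarray:
    rank = np.empty(n, dtype=int)
    for r, front in enumerate(fronts):
        rank[front] = r
    return rank


def _crowding_of(costs: np.ndarray, fronts: list[list[int]]) -> np.ndarray:
    crowd = np.empty(costs.shape[0])
    for front in fronts:
        crowd[front] = crowding_distance(costs[front])
    return crowd


def _tournament(
    rng: np.random.Generator, rank: np.ndarray, crowd: np.ndarray,
    candidates: np.ndarray,
) -> int:
    i, j = rng.integers(0, candidates.size, size=2)
    a, b = int(candidates[i]), int(candidates[j])
    if rank[a] != rank[b]:
        return a if rank[a] < rank[b] else b
    if crowd[a] != crowd[b]:
        return a if crowd[a] > crowd[b] else b
    return a


def _truncate(
    costs: np.ndarray, pop_size: int
) -> list[int]:
    """Elitist environmental selection: fill by front, split ties by crowding."""
    fronts = nondominated_sort(costs)
    chosen: list[int] = []
    for front in fronts:
        if len(chosen) + len(front) <= pop_size:
            chosen.extend(front)
        else:
            crowd = crowding_distance(costs[front])
            order = np.argsort(-crowd, kind="stable")
            need = pop_size - len(chosen)
            chosen.extend([front[i] for i in order[:need]])
            break
    return chosen


# ---------------------------------------------------------------------------
# the full fit


def fit(
    features: FeatureSet,
    truth: BinaryResponse,
    cfg: GAConfig = GAConfig(),
    opset: OperatorSet = OperatorSet(),
) -> FitResult:
    """Estimate predictive models from an aligned (features, truth) pair.

    Trials are split 50/50 by alternation (even-indexed trials train,
    odd-indexed validate); the NSGA-II loop runs on the training half, and
    the resulting first front is re-scored on the validation half, whose
    non-dominated subset is returned. Fully reproducible under ``cfg.seed``.
    """
    if features.n_trials != truth.n_trials or features.n_bins != truth.n_bins:
        raise ValueError("features and truth are not aligned")
    if features.n_trials < 2:
        raise ValueError("need at least two trials to split train/validation")
    if truth.n_spikes == 0:
        raise ValueError("true response contains no spikes; nothing to fit")

    rng = np.random.default_rng(cfg.seed)
    train_f, train_t = _subset(features, truth, slice(0, None, 2))
    val_f, val_t = _subset(features, truth, slice(1, None, 2))
    if train_t.n_spikes == 0 or val_t.n_spikes == 0:
        raise ValueError("a data half contains no spikes; cannot calibrate")

    genomes = init_population(cfg, opset, rng)
    costs = _evaluate(genomes, train_f, train_t, opset, cfg.objectives)
    history: list[dict] = []

    for gen in range(cfg.generations):
        fronts = nondominated_sort(costs)
        rank = _rank_of(fronts, len(genomes))
        crowd = _crowding_of(costs, fronts)
        structures = [g.structure for g in genomes]

        children: list[ModelGenome] = []
        all_idx = np.arange(len(genomes))
        for _ in range(cfg.pop_size):
            a = _tournament(rng, rank, crowd, all_idx)
            same = np.flatnonzero(
                [s == structures[a] for s in structures]
            )
            if same.size > 1:
                b = _tournament(rng, rank, crowd, same)
                child = restricted_mate(genomes[a], genomes[b], rng)
            else:
                # singleton structure: offspring is a (possibly mutated) clone
                child = genomes[a]
            children.append(mutate(child, cfg, opset, rng))

        child_costs = _evaluate(children, train_f, train_t, opset, cfg.objectives)
        merged = genomes + children
        merged_costs = np.vstack([costs, child_costs])
        keep = _truncate(merged_costs, cfg.pop_size)
        genomes = [merged[i] for i in keep]
        costs = merged_costs[keep]
        history.append(
            {
                "generation": gen,
                **{
                    f"min_{name}": float(costs[:, j].min())
                    for j, name in enumerate(cfg.objectives)
                },
                "front1_size": len(nondominated_sort(costs)[0]),
            }
        )

    # training Pareto front, re-evaluated on the validation half
    first = nondominated_sort(costs)[0]
    train_front = [
        FrontMember(
            genomes[i],
            dict(zip(cfg.objectives, costs[i].tolist())),
        )
        for i in first
    ]
    front_genomes = [genomes[i] for i in first]
    val_costs = _evaluate(front_genomes, val_f, val_t, opset, cfg.objectives)
    val_first = nondominated_sort(val_costs)[0]
    val_front = [
        FrontMember(
            front_genomes[i],
            dict(zip(cfg.objectives, val_costs[i].tolist())),
        )
        for i in val_first
    ]
    return FitResult(
        tuple(train_front), tuple(val_front), tuple(history), cfg.objectives
    )


def above_chance(result: FitResult) -> bool:
    """Is the unit predicted above chance?

    True when the mean validation-front PSTH-Fit value minus its (population)
    standard deviation falls below unity — i.e. the global cost of the
    selected models sits reliably on the better-than-chance side of 1.
    """
    if "pf" not in result.objectives:
        raise ValueError("above-chance test requires the PSTH-Fit objective")
    if not result.val_front:
        raise ValueError("empty validation front")
    pf = np.array([m.costs["pf"] for m in result.val_front])
    return bool(pf.mean() - pf.std() < 1.0)


def knee_point(result: FitResult) -> FrontMember:
    """Convenience selector: front member closest to the origin in (SM, PF).

    An extension beyond the core procedure — a reproducible way to pick one
    trade-off model from the front rather than by eye.
    """
    if not ("sm" in result.objectives and "pf" in result.objectives):
        raise ValueError("knee point requires SM and PF objectives")
    members = result.val_front or result.train_front
    dist = [np.hypot(m.costs["sm"], m.costs["pf"]) for m in members]
    return members[int(np.argmin(dist))]
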