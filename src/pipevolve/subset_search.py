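"""Feature-subset search over binary inclusion masks.

Four searchers share one pluggable subset evaluator:

* ``ga``        — binary genetic algorithm (tournament selection, uniform
                  crossover, bit-flip mutation, elitism);
* ``bpso``      — binary particle swarm optimisation (real velocities,
                  sigmoid transfer, stochastic bit sampling);
* ``ep``        — evolutionary programming (mutation-only, (mu + mu)
                  truncation survival);
* ``best_first``— deterministic greedy best-first over the subset lattice.

The default evaluator is a correlation-based (CFS-style) merit

    merit(S) = k * mean|r_cf| / sqrt(k + k (k - 1) * mean|r_ff|)

with k selected features, r_cf the Pearson correlation of each selected
feature with the 0/1 class and r_ff the pairwise correlations among the
selected features: it rewards class relevance and penalises redundancy.
A cross-validated wrapper fitness (accuracy of a user-chosen classifier)
is provided as the alternative.

Reported attribute indices are 1-based opaque labels, matching how
feature-selection tables are usually printed.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .dataset import Dataset, make_stratified_folds
from .metrics import classification_metrics, confusion
from .primitives import make_classifier

__all__ = [
    "FeatureSubset",
    "SearchConfig",
    "SubsetSearchError",
    "CfsMerit",
    "cfs_merit",
    "wrapper_fitness",
    "ga_subset_search",
    "bpso_subset_search",
    "ep_subset_search",
    "best_first_search",
    "subset_overlap",
    "SubsetSearch",
    "SubsetSearchResults",
]


class SubsetSearchError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureSubset:
    """A binary inclusion mask with its merit and provenance."""

    mask: np.ndarray
    merit: float
    provenance: str

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", mask)
        if mask.ndim != 1:
            raise SubsetSearchError("mask must be a 1-D boolean vector")

    @property
    def indices(self) -> list[int]:
        """Selected attribute labels, 1-based."""
        return [int(i) + 1 for i in np.flatnonzero(self.mask)]

    @property
    def size(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class SearchConfig:
    """Settings shared by (and specific to) the four search methods."""

    method: str = "ga"
    population_size: int = 20
    iterations: int = 40
    seed: int = 0
    # GA
    crossover_rate: float = 0.9
    mutation_rate: float | None = None  # default 1/p, resolved at run time
    tournament_size: int = 3
    # BPSO
    inertia: float = 0.72
    c1: float = 1.49
    c2: float = 1.49
    velocity_clamp: float = 4.0
    # EP
    flip_rate: float | None = None  # default 1/p
    # best-first
    stale_limit: int = 5

    def __post_init__(self) -> None:
        if self.method not in ("ga", "bpso", "ep", "best_first"):
            raise SubsetSearchError(f"unknown method {self.method!r}")
        if self.method != "best_first" and self.population_size < 2:
            raise SubsetSearchError("population methods need population_size >= 2")
        if self.iterations < 1:
            raise SubsetSearchError("iterations must be >= 1")
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise SubsetSearchError("crossover_rate must lie in [0, 1]")
        if self.stale_limit < 1:
            raise SubsetSearchError("stale_limit must be >= 1")


# ---------------------------------------------------------------------------
# Subset evaluators


class CfsMerit:
    """Correlation-based subset merit with cached correlation structure.

    All feature-class and feature-feature Pearson correlations are
    computed once at construction, so evaluating a mask is O(k^2) on the
    cached matrix — cheap enough for population searches.
    """

    def __init__(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise SubsetSearchError("X and y have incompatible shapes")
        self.p = X.shape[1]
        stds = X.std(axis=0)
        self._zero_var = np.flatnonzero(stds == 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            # zero-variance columns yield NaN rows; they are rejected at
            # evaluation time rather than here
            full = np.corrcoef(np.column_stack([X, y]), rowvar=False)
        self._r_ff = np.abs(full[: self.p, : self.p])
        self._r_cf = np.abs(full[: self.p, self.p])

    def __call__(self, mask) -> float:
        mask = np.asarray(mask, dtype=bool)
        sel = np.flatnonzero(mask)
        if sel.size == 0:
            raise SubsetSearchError("mask selects no features")
        bad = np.intersect1d(sel, self._zero_var)
        if bad.size:
            raise SubsetSearchError(
                f"zero-variance feature(s) selected: {bad.tolist()}"
            )
        k = sel.size
        mean_rcf = float(self._r_cf[sel].mean())
        if k == 1:
            return mean_rcf
        sub = self._r_ff[np.ix_(sel, sel)]
        mean_rff = float((sub.sum() - k) / (k * (k - 1)))
        return k * mean_rcf / np.sqrt(k + k * (k - 1) * mean_rff)


def cfs_merit(X, y, mask) -> float:
    """One-shot CFS merit of a mask (see :class:`CfsMerit`)."""
    return CfsMerit(X, y)(mask)


def wrapper_fitness(X, y, classifier_name: str = "gnb", cv_folds: int = 5,
                    seed: int = 0):
    """CV-accuracy wrapper fitness: subsets scored by a learner's performance.

    Returns a callable mask -> mean stratified-CV accuracy of
    ``classifier_name`` trained on the selected columns.
    """
    X = np.asarray(X, dtype=float)
    ds = Dataset(X, y)
    folds = make_stratified_folds(ds, cv_folds, seed)

    def fitness(mask) -> float:
        sel = np.flatnonzero(np.asarray(mask, dtype=bool))
        if sel.size == 0:
            raise SubsetSearchError("mask selects no features")
        accs = []
        for train, test in folds:
            clf = make_classifier(classifier_name, random_state=seed)
            clf.fit(X[np.ix_(train, sel)], ds.y[train])
            cm = confusion(ds.y[test], clf.predict(X[np.ix_(test, sel)]))
            accs.append(classification_metrics(cm).acc)
        return float(np.mean(accs))

    return fitness


def _resolve_fitness(X, y, fitness):
    if fitness is not None:
        return fitness
    return CfsMerit(X, y)


def _repair(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Ensure at least one selected bit (searchers never report empty masks)."""
    if not mask.any():
        mask = mask.copy()
        mask[int(rng.integers(len(mask)))] = True
    return mask


def _safe_eval(fitness, mask) -> float:
    """Degenerate masks (e.g. zero-variance selections) score -inf."""
    try:
        return float(fitness(mask))
    except SubsetSearchError:
        return float("-inf")


# ---------------------------------------------------------------------------
# Population searchers


def ga_subset_search(X, y, config: SearchConfig | None = None,
                     fitness=None) -> FeatureSubset:
    """Binary genetic algorithm over feature masks.

    Uniform random initialisation, tournament selection, uniform
    crossover, per-bit flip mutation (default rate 1/p) and one elite.
    Deterministic under the config seed.
    """
    config = config or SearchConfig(method="ga")
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    fitness = _resolve_fitness(X, y, fitness)
    rng = np.random.default_rng(config.seed)
    mut_rate = config.mutation_rate if config.mutation_rate is not None else 1.0 / p

    pop = [_repair(rng.random(p) < 0.5, rng) for _ in range(config.population_size)]
    fits = [_safe_eval(fitness, m) for m in pop]

    def tournament() -> np.ndarray:
        contenders = rng.integers(len(pop), size=config.tournament_size)
        best = max(contenders, key=lambda i: (fits[i], -pop[i].sum()))
        return pop[best]

    for _ in range(config.iterations):
        elite_idx = int(np.argmax(fits))
        new_pop = [pop[elite_idx].copy()]
        while len(new_pop) < config.population_size:
            a, b = tournament(), tournament()
            if rng.random() < config.crossover_rate:
                swap = rng.random(p) < 0.5
                child = np.where(swap, a, b)
            else:
                child = a.copy()
            flip = rng.random(p) < mut_rate
            child = _repair(child ^ flip, rng)
            new_pop.append(child)
        pop = new_pop
        fits = [_safe_eval(fitness, m) for m in pop]

    best = int(np.argmax(fits))
    return FeatureSubset(pop[best], fits[best], "ga")


def bpso_subset_search(X, y, config: SearchConfig | None = None,
                       fitness=None) -> FeatureSubset:
    """Binary particle swarm optimisation over feature masks.

    Velocities are real-valued and clamped; a sigmoid transfer maps each
    velocity to a bit-inclusion probability sampled stochastically.
    Personal and global bests steer the swarm.  Deterministic under seed.
    """
    config = config or SearchConfig(method="bpso")
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    fitness = _resolve_fitness(X, y, fitness)
    rng = np.random.default_rng(config.seed)
    n = config.population_size
    clamp = config.velocity_clamp

    positions = [_repair(rng.random(p) < 0.5, rng) for _ in range(n)]
    velocities = rng.uniform(-1, 1, size=(n, p))
    pbest = [pos.copy() for pos in positions]
    pbest_fit = [_safe_eval(fitness, pos) for pos in positions]
    g = int(np.argmax(pbest_fit))
    gbest, gbest_fit = pbest[g].copy(), pbest_fit[g]

    for _ in range(config.iterations):
        for i in range(n):
            r1, r2 = rng.random(p), rng.random(p)
            velocities[i] = (
                config.inertia * velocities[i]
                + config.c1 * r1 * (pbest[i].astype(float) - positions[i])
                + config.c2 * r2 * (gbest.astype(float) - positions[i])
            )
            np.clip(velocities[i], -clamp, clamp, out=velocities[i])
            prob = 1.0 / (1.0 + np.exp(-velocities[i]))
            positions[i] = _repair(rng.random(p) < prob, rng)
            fit = _safe_eval(fitness, positions[i])
            if fit > pbest_fit[i]:
                pbest[i], pbest_fit[i] = positions[i].copy(), fit
                if fit > gbest_fit:
                    gbest, gbest_fit = positions[i].copy(), fit

    return FeatureSubset(gbest, gbest_fit, "bpso")


def ep_subset_search(X, y, config: SearchConfig | None = None,
                     fitness=None) -> FeatureSubset:
    """Evolutionary programming: mutation-only search, no crossover.

    Each of the mu parents spawns one offspring by per-bit flips (default
    rate 1/p); parents and offspring compete in (mu + mu) truncation
    survival.  Deterministic under seed.
    """
    config = config or SearchConfig(method="ep")
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    fitness = _resolve_fitness(X, y, fitness)
    rng = np.random.default_rng(config.seed)
    flip_rate = config.flip_rate if config.flip_rate is not None else 1.0 / p
    mu = config.population_size

    pop = [_repair(rng.random(p) < 0.5, rng) for _ in range(mu)]
    fits = [_safe_eval(fitness, m) for m in pop]

    for _ in range(config.iterations):
        offspring, off_fits = [], []
        for parent in pop:
            flips = rng.random(p) < flip_rate
            child = _repair(parent ^ flips, rng)
            offspring.append(child)
            off_fits.append(_safe_eval(fitness, child))
        merged = pop + offspring
        merged_fits = fits + off_fits
        order = sorted(range(len(merged)),
                       key=lambda i: (-merged_fits[i], merged[i].sum(), i))
        pop = [merged[i] for i in order[:mu]]
        fits = [merged_fits[i] for i in order[:mu]]

    return FeatureSubset(pop[0], fits[0], "ep")


def best_first_search(X, y, config: SearchConfig | None = None,
                      fitness=None) -> FeatureSubset:
    """Greedy best-first search over the subset lattice; fully deterministic.

    Starts from the empty set, expands the most promising open node by
    all single-bit additions and removals, and stops after
    ``stale_limit`` consecutive expansions that fail to improve the best
    merit found so far.
    """
    config = config or SearchConfig(method="best_first")
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    fitness = _resolve_fitness(X, y, fitness)

    def key(mask: np.ndarray) -> bytes:
        return np.packbits(mask).tobytes()

    start = np.zeros(p, dtype=bool)
    # (-merit, insertion order) priority; the empty set itself is not a
    # reportable subset, it only seeds the expansion
    heap: list[tuple[float, int, np.ndarray]] = [(0.0, 0, start)]
    seen = {key(start)}
    counter = 1
    best_mask, best_fit = None, float("-inf")
    stale = 0

    while heap and stale < config.stale_limit:
        _, _, node = heapq.heappop(heap)
        improved = False
        for j in range(p):
            child = node.copy()
            child[j] = not child[j]
            if not child.any():
                continue
            ck = key(child)
            if ck in seen:
                continue
            seen.add(ck)
            fit = _safe_eval(fitness, child)
            heapq.heappush(heap, (-fit, counter, child))
            counter += 1
            if fit > best_fit:
                best_mask, best_fit = child, fit
                improved = True
        stale = 0 if improved else stale + 1

    if best_mask is None:  # p == 0 cannot happen (Dataset enforces p >= 1)
        raise SubsetSearchError("search found no admissible subset")
    return FeatureSubset(best_mask, best_fit, "best_first")


_SEARCHERS = {
    "ga": ga_subset_search,
    "bpso": bpso_subset_search,
    "ep": ep_subset_search,
    "best_first": best_first_search,
}


# ---------------------------------------------------------------------------
# Overlap reporting


def subset_overlap(subsets: list[FeatureSubset],
                   groups: dict[str, list[str]] | None = None) -> dict:
    """Agreement statistics across subsets from different methods.

    Returns the attribute set common to all inputs, the common set within
    each named group of provenances, and pairwise Jaccard indices.
    Indices are reported as 1-based labels.
    """
    if len(subsets) < 2:
        raise SubsetSearchError("overlap needs at least two subsets")
    p = len(subsets[0].mask)
    for s in subsets[1:]:
        if len(s.mask) != p:
            raise SubsetSearchError("subsets cover different index universes")

    sets = {s.provenance: set(s.indices) for s in subsets}
    if len(sets) != len(subsets):
        raise SubsetSearchError("subset provenances must be unique")

    common_all = set.intersection(*sets.values())
    report = {
        "universe_size": p,
        "per_method": {name: sorted(vals) for name, vals in sets.items()},
        "common_all": sorted(common_all),
        "common_all_size": len(common_all),
        "pairwise_jaccard": {},
    }
    names = list(sets)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            union = sets[a] | sets[b]
            jac = len(sets[a] & sets[b]) / len(union) if union else 1.0
            report["pairwise_jaccard"][f"{a}|{b}"] = jac
    if groups:
        report["groups"] = {}
        for gname, members in groups.items():
            missing = [m for m in members if m not in sets]
            if missing:
                raise SubsetSearchError(f"group {gname!r} names unknown subsets {missing}")
            gcommon = set.intersection(*(sets[m] for m in members))
            report["groups"][gname] = {
                "common": sorted(gcommon),
                "size": len(gcommon),
            }
    return report


# ---------------------------------------------------------------------------
# Model-style entry point


class SubsetSearch:
    """Feature-subset selection as a fit-able model.

    ``evaluator`` is either ``"cfs"`` (filter merit, the default) or
    ``"wrapper"`` (CV accuracy of ``wrapper_classifier``); a custom
    callable mask -> float is also accepted.
    """

    def __init__(self, dataset: Dataset, config: SearchConfig | None = None,
                 evaluator="cfs", wrapper_classifier: str = "gnb",
                 wrapper_cv_folds: int = 5):
        self.dataset = dataset
        self.config = config or SearchConfig()
        if callable(evaluator):
            self.fitness = evaluator
        elif evaluator == "cfs":
            self.fitness = CfsMerit(dataset.X, dataset.y)
        elif evaluator == "wrapper":
            self.fitness = wrapper_fitness(
                dataset.X, dataset.y, wrapper_classifier,
                wrapper_cv_folds, self.config.seed,
            )
        else:
            raise SubsetSearchError(f"unknown evaluator {evaluator!r}")

    def fit(self) -> "SubsetSearchResults":
        searcher = _SEARCHERS[self.config.method]
        subset = searcher(self.dataset.X, self.dataset.y, self.config, self.fitness)
        return SubsetSearchResults(self, subset)


class SubsetSearchResults:
    def __init__(self, model: SubsetSearch, subset: FeatureSubset):
        self.model = model
        self.subset = subset

    @property
    def selected_indices(self) -> list[int]:
        return self.subset.indices

    @property
    def merit(self) -> float:
        return self.subset.merit

    @property
    def selected_names(self) -> list[str]:
        names = self.model.dataset.feature_names
        return [names[i - 1] for i in self.subset.indices]

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Feature-subset search results",
            "=" * 60,
            f"method {cfg.method}  seed {cfg.seed}  iterations {cfg.iterations}",
            f"merit: {self.merit:.6f}",
            f"selected ({self.subset.size} of {len(self.subset.mask)}): "
            + ", ".join(map(str, self.selected_indices)),
            "names: " + ", ".join(self.selected_names),
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<SubsetSearchResults method={self.model.config.method!r} "
                f"k={self.subset.size} merit={self.merit:.4f}>")
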