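"""Genetic-programming search over classification pipelines.

A pipeline genome is an ordered chain of 0..max_depth transform steps
(scalers, selectors, decomposers, in any order) followed by exactly one
classifier step, each step carrying bound hyperparameters.  Every
primitive here is single-input/single-output, so tree-shaped programs
degenerate to linear chains and the genome is represented as one.

Fitness is mean stratified k-fold cross-validated accuracy, with all
transform statistics fitted on each fold's training part only.  The
generational loop applies truncation selection (the top ``selection_size``
individuals), one-point crossover of transform prefixes at a configurable
rate, and a three-move mutation (resample a hyperparameter, insert a
transform, delete a transform).  One elite individual is carried over
unchanged each generation, so the best fitness is non-decreasing.
Pipelines that fail numerically (e.g. a robust scaler meeting a constant
column) are contained: they score fitness 0 and the run continues.

The model-style entry point is :class:`PipelineSearch`, whose ``fit()``
returns a :class:`PipelineSearchResults` carrying the best pipeline, the
per-generation history and a ``summary()`` table; the module-level
functions (``random_genome``, ``evaluate``, ``select``, ``crossover``,
``mutate``, ``evolve``) are the engine they drive.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import config_context as sklearn_config_context

from .dataset import Dataset, FoldAssignment, make_stratified_folds
from .metrics import confusion, classification_metrics
from .primitives import (
    DEFAULT_REGISTRY,
    PrimitiveError,
    Registry,
    make_classifier,
    make_transform,
    sample_hyperparameters,
)

__all__ = [
    "Step",
    "PipelineGenome",
    "Individual",
    "GPConfig",
    "GenomeError",
    "validate_genome",
    "random_genome",
    "build_pipeline",
    "evaluate",
    "select",
    "crossover",
    "mutate",
    "evolve",
    "export_pipeline",
    "load_pipeline",
    "PipelineSearch",
    "PipelineSearchResults",
]


class GenomeError(ValueError):
    """Raised for grammar-invalid genomes or malformed pipeline bundles."""


@dataclass(frozen=True)
class Step:
    name: str
    params: dict = field(default_factory=dict)

    def signature(self) -> str:
        return json.dumps({"name": self.name, "params": self.params}, sort_keys=True)


@dataclass(frozen=True)
class PipelineGenome:
    """0..T transform steps followed by exactly one classifier step."""

    steps: tuple[Step, ...]

    @property
    def transform_steps(self) -> tuple[Step, ...]:
        return self.steps[:-1]

    @property
    def classifier_step(self) -> Step:
        return self.steps[-1]

    def __len__(self) -> int:
        return len(self.steps)

    def signature(self) -> str:
        return "|".join(s.signature() for s in self.steps)

    def to_dict(self) -> dict:
        return {"steps": [{"name": s.name, "params": dict(s.params)} for s in self.steps]}

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineGenome":
        return cls(tuple(Step(s["name"], dict(s.get("params", {}))) for s in d["steps"]))


def validate_genome(genome: PipelineGenome, registry: Registry,
                    max_depth: int | None = None) -> None:
    """Raise :class:`GenomeError` unless the genome is grammar-valid."""
    if len(genome.steps) < 1:
        raise GenomeError("genome has no steps")
    for i, step in enumerate(genome.steps):
        if step.name not in registry:
            raise GenomeError(f"step {i}: unregistered primitive {step.name!r}")
        spec = registry.get(step.name)
        is_last = i == len(genome.steps) - 1
        if is_last and spec.stage != "classify":
            raise GenomeError("last step must be a classifier")
        if not is_last and spec.stage == "classify":
            raise GenomeError(f"step {i}: classifier before the end of the chain")
        try:
            spec.validate_params(step.params)
        except PrimitiveError as exc:
            raise GenomeError(f"step {i}: {exc}") from exc
    if max_depth is not None and len(genome.transform_steps) > max_depth:
        raise GenomeError(
            f"{len(genome.transform_steps)} transform steps exceed max_depth={max_depth}"
        )


def random_genome(registry: Registry, rng: np.random.Generator,
                  max_depth: int = 3) -> PipelineGenome:
    """Sample a grammar-valid genome; transform count uniform on 0..max_depth."""
    classifier_names = registry.names("classify")
    if not classifier_names:
        raise GenomeError("registry has no classifier primitives")
    transform_names = registry.transform_names()
    n_transforms = int(rng.integers(0, max_depth + 1)) if transform_names else 0
    steps = []
    for _ in range(n_transforms):
        name = transform_names[int(rng.integers(len(transform_names)))]
        steps.append(Step(name, sample_hyperparameters(registry.get(name), rng)))
    clf = classifier_names[int(rng.integers(len(classifier_names)))]
    steps.append(Step(clf, sample_hyperparameters(registry.get(clf), rng)))
    return PipelineGenome(tuple(steps))


# ---------------------------------------------------------------------------
# Building and evaluating pipelines


class PipelineModel:
    """A concrete, fittable pipeline built from a genome.

    Seed-derivation contract (part of the public reproducibility
    guarantee): transform step ``i`` receives ``seed + 1000 * i`` and the
    classifier receives ``seed % 2**31`` as its random state.
    """

    def __init__(self, genome: PipelineGenome, seed: int | None = None):
        self.genome = genome
        seed = 0 if seed is None else int(seed)
        self.transforms = [
            make_transform(s.name, s.params, seed=seed + 1000 * i)
            for i, s in enumerate(genome.transform_steps)
        ]
        clf = genome.classifier_step
        self.classifier = make_classifier(clf.name, random_state=seed % (2**31), **clf.params)

    def fit(self, X, y):
        Xt = np.asarray(X, dtype=float)
        for t in self.transforms:
            Xt = t.fit_transform(Xt, y)
        self.classifier.fit(Xt, y)
        return self

    def _apply(self, X) -> np.ndarray:
        Xt = np.asarray(X, dtype=float)
        for t in self.transforms:
            Xt = t.transform(Xt)
        return Xt

    def predict(self, X) -> np.ndarray:
        return self.classifier.predict(self._apply(X))

    def predict_proba(self, X) -> np.ndarray:
        return self.classifier.predict_proba(self._apply(X))

    def decision_scores(self, X) -> np.ndarray:
        return self.classifier.decision_scores(self._apply(X))


def build_pipeline(genome: PipelineGenome, seed: int | None = None) -> PipelineModel:
    return PipelineModel(genome, seed)


@dataclass
class Individual:
    genome: PipelineGenome
    fitness: float | None = None
    eval_record: dict | None = None
    creation_order: int = 0

    @property
    def failed(self) -> bool:
        return bool(self.eval_record and self.eval_record.get("failed"))


def evaluate(genome: PipelineGenome, dataset: Dataset, cv_folds: int = 10,
             seed: int = 0, folds: FoldAssignment | None = None) -> Individual:
    """Cross-validate a genome; numerical failures yield fitness 0, not errors.

    Each fold fits every step on the training part only, then scores
    accuracy on the held-out part; fitness is the mean over folds.  The
    fold partition derives from ``seed`` unless an explicit ``folds``
    assignment is supplied (as the evolutionary loop does, so all
    individuals in a run share one partition).
    """
    if folds is None:
        folds = make_stratified_folds(dataset, cv_folds, seed)
    t0 = time.perf_counter()
    fold_accuracies = []
    try:
        # inputs are validated finite at Dataset construction; skip sklearn's
        # per-estimator re-checks inside the hot evaluation loop
        with sklearn_config_context(assume_finite=True):
            for train, test in folds:
                model = PipelineModel(genome, seed)
                model.fit(dataset.X[train], dataset.y[train])
                y_pred = model.predict(dataset.X[test])
                cm = confusion(dataset.y[test], y_pred)
                fold_accuracies.append(classification_metrics(cm).acc)
        record = {
            "fold_accuracies": fold_accuracies,
            "failed": False,
            "error": None,
            "wall_time": time.perf_counter() - t0,
        }
        return Individual(genome, float(np.mean(fold_accuracies)), record)
    except Exception as exc:  # failure containment: the run must continue
        record = {
            "fold_accuracies": fold_accuracies,
            "failed": True,
            "error": f"{type(exc).__name__}: {exc}",
            "wall_time": time.perf_counter() - t0,
        }
        return Individual(genome, 0.0, record)


def _rank_key(ind: Individual):
    return (-ind.fitness, len(ind.genome), ind.creation_order)


def select(population: list[Individual], selection_size: int) -> list[Individual]:
    """Truncation selection: the ``selection_size`` fittest individuals.

    Ties break toward the shorter genome, then earlier creation order.
    """
    for ind in population:
        if ind.fitness is None:
            raise GenomeError("cannot select from an unevaluated population")
    return sorted(population, key=_rank_key)[:selection_size]


def crossover(parent_a: PipelineGenome, parent_b: PipelineGenome,
              rng: np.random.Generator, max_depth: int = 3,
              ) -> tuple[PipelineGenome, PipelineGenome]:
    """One-point crossover on transform prefixes; each child keeps its classifier.

    A cut point is drawn at a step boundary in each parent's transform
    prefix and the tails are exchanged; children are truncated to
    ``max_depth`` transforms.  Two bare classifiers cross to themselves.
    """
    pref_a, pref_b = parent_a.transform_steps, parent_b.transform_steps
    cut_a = int(rng.integers(0, len(pref_a) + 1))
    cut_b = int(rng.integers(0, len(pref_b) + 1))
    new_a = (pref_a[:cut_a] + pref_b[cut_b:])[:max_depth]
    new_b = (pref_b[:cut_b] + pref_a[cut_a:])[:max_depth]
    child_a = PipelineGenome(new_a + (parent_a.classifier_step,))
    child_b = PipelineGenome(new_b + (parent_b.classifier_step,))
    return child_a, child_b


def mutate(genome: PipelineGenome, rng: np.random.Generator, registry: Registry,
           max_depth: int = 3) -> PipelineGenome:
    """Apply one mutation move, chosen uniformly among the applicable ones.

    Moves: (i) resample one hyperparameter of one step; (ii) insert a
    random transform step at a random position (when below max_depth);
    (iii) delete a random transform step (never the classifier).
    """
    steps = list(genome.steps)
    n_transforms = len(steps) - 1
    tunable = [i for i, s in enumerate(steps)
               if registry.get(s.name).hyperparameters]
    transform_names = registry.transform_names()

    moves = []
    if tunable:
        moves.append("resample")
    if n_transforms < max_depth and transform_names:
        moves.append("insert")
    if n_transforms > 0:
        moves.append("delete")
    if not moves:
        return genome

    move = moves[int(rng.integers(len(moves)))]
    if move == "resample":
        idx = tunable[int(rng.integers(len(tunable)))]
        spec = registry.get(steps[idx].name)
        hp = spec.hyperparameters[int(rng.integers(len(spec.hyperparameters)))]
        params = dict(steps[idx].params)
        params[hp.name] = hp.sample(rng)
        steps[idx] = Step(steps[idx].name, params)
    elif move == "insert":
        pos = int(rng.integers(0, n_transforms + 1))
        name = transform_names[int(rng.integers(len(transform_names)))]
        steps.insert(pos, Step(name, sample_hyperparameters(registry.get(name), rng)))
    else:  # delete
        steps.pop(int(rng.integers(0, n_transforms)))
    return PipelineGenome(tuple(steps))


# ---------------------------------------------------------------------------
# The evolutionary loop


@dataclass(frozen=True)
class GPConfig:
    """Knobs of the evolutionary run.

    Defaults: truncation to the top 20, 5% crossover; population size,
    generation count and the mutation rate applied to non-crossover
    offspring are open choices exposed here.
    """

    population_size: int = 100
    generations: int = 20
    selection_size: int = 20
    crossover_rate: float = 0.05
    mutation_rate: float = 0.9
    max_depth: int = 3
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not 1 <= self.selection_size <= self.population_size:
            raise ValueError("selection_size must lie in [1, population_size]")
        for rate in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.max_depth < 0:
            raise ValueError("max_depth must be >= 0")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


class _EvalCache:
    """Memoizes fitness per genome signature within one evolutionary run."""

    def __init__(self, dataset: Dataset, folds: FoldAssignment, seed: int):
        self.dataset = dataset
        self.folds = folds
        self.seed = seed
        self._store: dict[str, Individual] = {}

    def evaluate(self, genome: PipelineGenome, creation_order: int) -> Individual:
        sig = genome.signature()
        hit = self._store.get(sig)
        if hit is None:
            hit = evaluate(genome, self.dataset, seed=self.seed, folds=self.folds)
            self._store[sig] = hit
        return Individual(genome, hit.fitness, hit.eval_record, creation_order)


def evolve(dataset: Dataset, config: GPConfig,
           registry: Registry | None = None,
           verbose: bool = False) -> tuple[Individual, list[dict]]:
    """Run the generational loop; returns the best individual and history.

    One fold partition (from ``config.seed``) is shared by every
    individual so fitnesses are comparable across the population.  The
    best individual is carried over unchanged each generation (elitism),
    making the best-fitness trajectory non-decreasing.  Fully
    deterministic given (dataset, config, registry).
    """
    registry = registry or DEFAULT_REGISTRY
    rng = np.random.default_rng(config.seed)
    folds = make_stratified_folds(dataset, config.cv_folds, config.seed)
    cache = _EvalCache(dataset, folds, config.seed)
    counter = 0

    def fresh(genome: PipelineGenome) -> Individual:
        nonlocal counter
        ind = cache.evaluate(genome, counter)
        counter += 1
        return ind

    population = [
        fresh(random_genome(registry, rng, config.max_depth))
        for _ in range(config.population_size)
    ]

    history: list[dict] = []

    def log_generation(gen: int) -> None:
        fitnesses = [ind.fitness for ind in population]
        entry = {
            "generation": gen,
            "best_fitness": float(max(fitnesses)),
            "mean_fitness": float(np.mean(fitnesses)),
            "failures": sum(ind.failed for ind in population),
        }
        history.append(entry)
        if verbose:
            print(
                f"gen {gen:3d}  best {entry['best_fitness']:.4f}  "
                f"mean {entry['mean_fitness']:.4f}  failures {entry['failures']}"
            )

    log_generation(0)
    for gen in range(1, config.generations + 1):
        parents = select(population, config.selection_size)
        elite = parents[0]
        offspring: list[Individual] = [elite]
        while len(offspring) < config.population_size:
            if (len(parents) >= 2 and
                    rng.random() < config.crossover_rate):
                i = int(rng.integers(len(parents)))
                j = int(rng.integers(len(parents) - 1))
                j = j if j < i else j + 1
                child_a, child_b = crossover(
                    parents[i].genome, parents[j].genome, rng, config.max_depth
                )
                offspring.append(fresh(child_a))
                if len(offspring) < config.population_size:
                    offspring.append(fresh(child_b))
            else:
                parent = parents[int(rng.integers(len(parents)))]
                if rng.random() < config.mutation_rate:
                    genome = mutate(parent.genome, rng, registry, config.max_depth)
                else:
                    genome = parent.genome
                offspring.append(fresh(genome))
        population = offspring
        log_generation(gen)

    best = min(population, key=_rank_key)
    return best, history


# ---------------------------------------------------------------------------
# Pipeline bundles (export / import)

_SCHEMA = "pipevolve-pipeline/1"


def export_pipeline(individual: Individual, path, config: GPConfig | None = None) -> None:
    """Write a JSON bundle sufficient to re-fit the pipeline exactly."""
    if individual.fitness is None:
        raise GenomeError("export requires an evaluated individual")
    bundle = {
        "schema": _SCHEMA,
        "genome": individual.genome.to_dict(),
        "fitness": individual.fitness,
        "eval_record": individual.eval_record,
        "config": None if config is None else vars(config) | {},
    }
    with open(path, "w") as fh:
        json.dump(bundle, fh, indent=2)


def load_pipeline(path, registry: Registry | None = None) -> Individual:
    """Read and validate a pipeline bundle; tampered step names fail loudly."""
    registry = registry or DEFAULT_REGISTRY
    with open(path) as fh:
        bundle = json.load(fh)
    if bundle.get("schema") != _SCHEMA:
        raise GenomeError(f"unrecognized pipeline schema {bundle.get('schema')!r}")
    genome = PipelineGenome.from_dict(bundle["genome"])
    validate_genome(genome, registry)
    return Individual(genome, bundle.get("fitness"), bundle.get("eval_record"))


# ---------------------------------------------------------------------------
# Model-style entry point


class PipelineSearch:
    """Evolutionary pipeline-structure search as a fit-able model.

    Parameters
    ----------
    dataset : Dataset
        The labelled table to search on.
    config : GPConfig, optional
        Evolution settings; defaults to :class:`GPConfig` defaults.
    registry : Registry, optional
        Primitive registry; defaults to the built-in one.

    Examples
    --------
    >>> from pipevolve import PipelineSearch, SynthSpec, generate_synthetic
    >>> data = generate_synthetic(SynthSpec(n=120, p_informative=3, seed=1))
    >>> res = PipelineSearch(data, GPConfig(population_size=10, generations=2,
    ...                                     selection_size=5, cv_folds=3)).fit()
    >>> 0.0 <= res.best_fitness <= 1.0
    True
    """

    def __init__(self, dataset: Dataset, config: GPConfig | None = None,
                 registry: Registry | None = None):
        self.dataset = dataset
        self.config = config or GPConfig()
        self.registry = registry or DEFAULT_REGISTRY

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "diagnosis",
                       positive="M", config: GPConfig | None = None,
                       registry: Registry | None = None) -> "PipelineSearch":
        """Build a search from a dataframe with one label column."""
        y = (df[label_col] == positive).astype(int).to_numpy()
        X = df.drop(columns=[label_col]).to_numpy(dtype=float)
        names = [c for c in df.columns if c != label_col]
        ds = Dataset(X, y, feature_names=names,
                     sample_ids=[str(i) for i in df.index])
        return cls(ds, config=config, registry=registry)

    def fit(self, verbose: bool = False) -> "PipelineSearchResults":
        best, history = evolve(self.dataset, self.config, self.registry, verbose)
        return PipelineSearchResults(self, best, history)


class PipelineSearchResults:
    """Outcome of a :class:`PipelineSearch` run."""

    def __init__(self, model: PipelineSearch, best: Individual, history: list[dict]):
        self.model = model
        self.best_individual = best
        self.history = pd.DataFrame(history)

    @property
    def best_genome(self) -> PipelineGenome:
        return self.best_individual.genome

    @property
    def best_fitness(self) -> float:
        return self.best_individual.fitness

    def refit(self, seed: int | None = None) -> PipelineModel:
        """Fit the best pipeline on the full dataset."""
        seed = self.model.config.seed if seed is None else seed
        return build_pipeline(self.best_genome, seed).fit(
            self.model.dataset.X, self.model.dataset.y
        )

    def reevaluate(self, seed: int) -> Individual:
        """Re-score the best genome on a fresh fold partition.

        Running with a seed different from the search seed exposes the
        optimistic bias of selecting on the search partition.
        """
        return evaluate(self.best_genome, self.model.dataset,
                        cv_folds=self.model.config.cv_folds, seed=seed)

    def export(self, path) -> None:
        export_pipeline(self.best_individual, path, self.model.config)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Pipeline evolution results",
            "=" * 60,
            f"population {cfg.population_size}  generations {cfg.generations}  "
            f"cv_folds {cfg.cv_folds}  seed {cfg.seed}",
            f"best CV accuracy: {self.best_fitness:.4f}",
            "best pipeline:",
        ]
        for step in self.best_genome.steps:
            params = ", ".join(f"{k}={v!r}" for k, v in sorted(step.params.items()))
            lines.append(f"  - {step.name}({params})")
        lines.append("history (best / mean fitness per generation):")
        for _, row in self.history.iterrows():
            lines.append(
                f"  gen {int(row.generation):3d}  best {row.best_fitness:.4f}"
                f"  mean {row.mean_fitness:.4f}  failures {int(row.failures)}"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<PipelineSearchResults best_fitness={self.best_fitness:.4f} "
                f"steps={[s.name for s in self.best_genome.steps]}>")
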