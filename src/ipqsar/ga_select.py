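"""Genetic-algorithm wrappers for feature selection (GEMPLS / GEMkNN).

A chromosome encodes a candidate feature subset plus one model
hyperparameter: the number of PLS latent variables (``lv``, GEMPLS) or the
number of neighbours (``k``, GEMkNN).  Fitness is the leave-one-out q2 of
the corresponding regressor restricted to the chromosome's features.

Mutation is biased toward Mahalanobis-significant features: a feature i with
significance M_i at or above the significance threshold (default 10) is
added with probability P_i proportional to M_i, replacing uniform mutation.
Crossover is a uniform set-crossover; selection is tournament (size 2) with
elitism, so the best fitness per generation is non-decreasing.  All
randomness flows through a single integer seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from typing import Mapping

import numpy as np

from . import metrics as _metrics
from . import regressors as _reg
from .profiles import FeatureMatrix

METHODS = ("gempls", "gemknn")

#: ceiling on lv and k regardless of data size
MAX_HYPER = 10


@dataclass
class Chromosome:
    """GA individual: a feature-index set plus one hyperparameter."""

    feature_idx: frozenset
    hyper: int
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.feature_idx = frozenset(int(i) for i in self.feature_idx)
        self.hyper = int(self.hyper)

    def key(self) -> tuple:
        return (tuple(sorted(self.feature_idx)), self.hyper)


@dataclass
class GAConfig:
    population_size: int = 50
    generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1
    min_features: int = 3
    max_features: int = 40
    elitism: int = 1
    tournament_size: int = 2
    significance_threshold: float = 10.0
    biased_mutation: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.min_features < 1:
            raise ValueError("min_features must be >= 1")
        if self.max_features < self.min_features:
            raise ValueError("max_features must be >= min_features")
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise ValueError("crossover_rate must be in [0, 1]")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.elitism < 1:
            raise ValueError("elitism must be >= 1")

    @classmethod
    def from_dict(cls, d: Mapping) -> "GAConfig":
        return cls(**dict(d))

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class ModelRecord:
    """Outcome of one GA run: the best-ever chromosome, resolved to ids."""

    method: str
    feature_ids: list[str]
    hyper: int
    q2_train: float
    seed: int
    config_digest: str = ""

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ModelRecord":
        with open(path) as fh:
            return cls(**json.load(fh))


def hyper_bounds(method: str, n_compounds: int, n_selected: int) -> tuple[int, int]:
    """Valid hyperparameter range: lv in 1..min(10, |features|, n-2) for
    GEMPLS, k in 1..min(10, n-2) for GEMkNN (n-2 keeps every LOO fold valid)."""
    if method == "gempls":
        hi = min(MAX_HYPER, n_selected, n_compounds - 2)
    elif method == "gemknn":
        hi = min(MAX_HYPER, n_compounds - 2)
    else:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    return 1, max(1, hi)


def _clip_hyper(method: str, hyper: int, n: int, n_selected: int) -> int:
    lo, hi = hyper_bounds(method, n, n_selected)
    return int(min(max(hyper, lo), hi))


# ---------------------------------------------------------------------------
# fitness
# ---------------------------------------------------------------------------

def _pls_fit_fn(lv: int) -> _metrics.FitFunction:
    def fit(Xt: np.ndarray, yt: np.ndarray):
        model = _reg.fit_pls(Xt, yt, lv=min(lv, Xt.shape[0] - 1, Xt.shape[1]))
        return model.predict
    return fit


def _knn_fit_fn(k: int) -> _metrics.FitFunction:
    def fit(Xt: np.ndarray, yt: np.ndarray):
        scorer = _reg.MahalanobisScorer.fit(Xt)
        return lambda Xq: _reg.knn_predict(Xt, yt, Xq, k=min(k, yt.size), scorer=scorer)
    return fit


def fitness(
    ch: Chromosome,
    X: FeatureMatrix | np.ndarray,
    y: np.ndarray,
    method: str,
    cache: dict | None = None,
) -> float:
    """Leave-one-out q2 of the chromosome's model; -inf on any fold failure.

    Memoised per (sorted feature tuple, hyper) when ``cache`` is given.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    if cache is not None and ch.key() in cache:
        return cache[ch.key()]
    Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    cols = sorted(ch.feature_idx)
    Xs = Xv[:, cols]
    fit_fn = _pls_fit_fn(ch.hyper) if method == "gempls" else _knn_fit_fn(ch.hyper)
    try:
        pred = _metrics.loo_predict(fit_fn, Xs, y)
        value = _metrics.q2(pred)
    except Exception:  # noqa: BLE001 - unfit chromosomes lose naturally
        value = float("-inf")
    if cache is not None:
        cache[ch.key()] = value
    return value


# ---------------------------------------------------------------------------
# variation operators
# ---------------------------------------------------------------------------

def _addition_probs(
    candidates: np.ndarray, M: np.ndarray, threshold: float, eps: float = 1e-12
) -> tuple[np.ndarray, np.ndarray]:
    """Restrict to significant candidates when any exist; P_i ~ max(M_i, eps)."""
    sig = candidates[M[candidates] >= threshold]
    pool = sig if sig.size else candidates
    w = np.maximum(M[pool], eps)
    total = w.sum()
    probs = w / total if total > 0 else np.full(pool.size, 1.0 / pool.size)
    return pool, probs


def biased_mutate(
    ch: Chromosome,
    M: np.ndarray,
    cfg: GAConfig,
    rng: np.random.Generator,
    n_compounds: int,
    method: str = "gempls",
    selectable: np.ndarray | None = None,
) -> Chromosome:
    """Mutate the feature set and hyperparameter.

    Each of |feature_idx| potential mutation events fires with probability
    ``mutation_rate``; a firing event removes a uniformly chosen selected
    feature or adds an unselected one drawn with probability proportional to
    its Mahalanobis significance (restricted to features above the
    significance threshold when any are available; uniform otherwise, or when
    ``cfg.biased_mutation`` is off).  The hyperparameter takes a +-1 step with
    probability ``mutation_rate``, clipped to its bounds.  Size bounds are
    always respected.
    """
    M = np.asarray(M, dtype=float)
    selected = set(ch.feature_idx)
    universe = (
        np.asarray(selectable, dtype=int)
        if selectable is not None
        else np.arange(M.size)
    )
    n_events = int(rng.binomial(max(len(selected), 1), cfg.mutation_rate))
    for _ in range(n_events):
        can_remove = len(selected) > cfg.min_features
        can_add = len(selected) < cfg.max_features
        if not (can_remove or can_add):
            break
        do_remove = (can_remove and not can_add) or (
            can_remove and can_add and rng.random() < 0.5
        )
        if do_remove:
            selected.remove(int(rng.choice(sorted(selected))))
        else:
            candidates = universe[~np.isin(universe, sorted(selected))]
            if candidates.size == 0:
                continue
            if cfg.biased_mutation:
                pool, probs = _addition_probs(
                    candidates, M, cfg.significance_threshold
                )
                selected.add(int(rng.choice(pool, p=probs)))
            else:
                selected.add(int(rng.choice(candidates)))
    hyper = ch.hyper
    if rng.random() < cfg.mutation_rate:
        hyper += int(rng.choice([-1, 1]))
    hyper = _clip_hyper(method, hyper, n_compounds, len(selected))
    return Chromosome(feature_idx=frozenset(selected), hyper=hyper)


def crossover(
    a: Chromosome,
    b: Chromosome,
    cfg: GAConfig,
    rng: np.random.Generator,
    selectable: np.ndarray | None = None,
) -> tuple[Chromosome, Chromosome]:
    """Uniform set-crossover: shared features kept by both children, each
    symmetric-difference feature goes to one child at random; hyperparameters
    swap with probability 1/2.  Children are repaired to the size bounds by
    random drop/add."""
    shared = a.feature_idx & b.feature_idx
    diff = sorted(a.feature_idx ^ b.feature_idx)
    child_a, child_b = set(shared), set(shared)
    for f in diff:
        (child_a if rng.random() < 0.5 else child_b).add(f)
    ha, hb = a.hyper, b.hyper
    if rng.random() < 0.5:
        ha, hb = hb, ha
    universe = (
        np.asarray(selectable, dtype=int)
        if selectable is not None
        else np.asarray(sorted(a.feature_idx | b.feature_idx), dtype=int)
    )

    def repair(sel: set, hyper: int) -> Chromosome:
        while len(sel) > cfg.max_features:
            sel.remove(int(rng.choice(sorted(sel))))
        while len(sel) < cfg.min_features:
            candidates = universe[~np.isin(universe, sorted(sel))]
            if candidates.size == 0:
                break
            sel.add(int(rng.choice(candidates)))
        return Chromosome(feature_idx=frozenset(sel), hyper=hyper)

    return repair(child_a, ha), repair(child_b, hb)


# ---------------------------------------------------------------------------
# GA driver
# ---------------------------------------------------------------------------

def _random_chromosome(
    rng: np.random.Generator,
    selectable: np.ndarray,
    cfg: GAConfig,
    method: str,
    n: int,
) -> Chromosome:
    hi = min(cfg.max_features, selectable.size)
    size = int(rng.integers(cfg.min_features, hi + 1))
    idx = frozenset(int(i) for i in rng.choice(selectable, size=size, replace=False))
    lo, hi_h = hyper_bounds(method, n, size)
    return Chromosome(feature_idx=idx, hyper=int(rng.integers(lo, hi_h + 1)))


def run_ga(
    X: FeatureMatrix,
    y: np.ndarray,
    method: str,
    cfg: GAConfig,
    significance: np.ndarray | None = None,
    history: list | None = None,
) -> ModelRecord:
    """Evolve feature subsets maximising LOO q2; return the best-ever model.

    Deterministic for a given config seed.  Zero-variance columns are
    excluded from the selectable pool.  ``history``, when given, collects the
    best fitness of each generation (non-decreasing under elitism).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    y = np.asarray(y, dtype=float).ravel()
    n = X.n_compounds
    if n < 5:
        raise ValueError("need at least 5 compounds")
    selectable = np.flatnonzero(~X.zero_variance_mask())
    if selectable.size < cfg.min_features:
        raise ValueError(
            f"only {selectable.size} usable (non-constant) features; "
            f"min_features={cfg.min_features}"
        )
    if significance is None:
        M = np.zeros(X.n_features)
        M[selectable] = _reg.feature_significance(X.values[:, selectable])
    else:
        M = np.asarray(significance, dtype=float)
        if M.size != X.n_features:
            raise ValueError("significance vector length must equal n_features")

    rng = np.random.default_rng(cfg.seed)
    cache: dict = {}
    pop = [
        _random_chromosome(rng, selectable, cfg, method, n)
        for _ in range(cfg.population_size)
    ]
    for ch in pop:
        ch.fitness = fitness(ch, X, y, method, cache)
    best = max(pop, key=lambda c: c.fitness)

    for _gen in range(cfg.generations):
        pop.sort(key=lambda c: c.fitness, reverse=True)
        next_pop = [replace(c) for c in pop[: cfg.elitism]]
        while len(next_pop) < cfg.population_size:
            pa = _tournament(pop, cfg, rng)
            pb = _tournament(pop, cfg, rng)
            if rng.random() < cfg.crossover_rate:
                ca, cb = crossover(pa, pb, cfg, rng, selectable=selectable)
            else:
                ca, cb = replace(pa), replace(pb)
            for child in (ca, cb):
                if len(next_pop) >= cfg.population_size:
                    break
                child = biased_mutate(
                    child, M, cfg, rng, n, method=method, selectable=selectable
                )
                child.fitness = fitness(child, X, y, method, cache)
                next_pop.append(child)
        pop = next_pop
        gen_best = max(pop, key=lambda c: c.fitness)
        if gen_best.fitness > best.fitness:
            best = gen_best
        if history is not None:
            history.append(best.fitness)

    return ModelRecord(
        method=method,
        feature_ids=[X.feature_ids[i] for i in sorted(best.feature_idx)],
        hyper=best.hyper,
        q2_train=float(best.fitness),
        seed=cfg.seed,
        config_digest=cfg.digest(),
    )


def _tournament(
    pop: list, cfg: GAConfig, rng: np.random.Generator
) -> Chromosome:
    picks = rng.integers(0, len(pop), size=cfg.tournament_size)
    return max((pop[i] for i in picks), key=lambda c: c.fitness)
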