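"""Genetic-algorithm wrapper feature selection with a bounded feature count.

Chromosomes carry a binary feature-inclusion mask plus one parametric gene
(the PLS component count of the default evaluator). Fitness is stratified
k-fold cross-validated MCC of the evaluator restricted to the masked
columns; a shared fold partition makes fitness comparable across
chromosomes and lets results be cached by (mask, parametric gene). The
population evolves by size-3 tournament selection, uniform crossover,
per-gene mutation, and repair of the selected-feature count into
[m_start, m_end] by random bit flips toward the nearer bound; single-elite
elitism makes the best-fitness history non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from peptidestack.evaluation import ConfusionCounts, mcc_from_counts
from peptidestack.features import FeatureMatrix
from peptidestack.learners import PLSClassifier
from peptidestack.stacking import PFVMatrix


@dataclass
class GAConfig:
    m_start: int = 5          # lower bound on selected feature count
    m_end: int = 20           # upper bound on selected feature count
    p_mutation: float = 0.05  # per-gene bit-flip probability
    population: int = 50
    generations: int = 100
    stagnation: int = 20      # stop after this many generations without improvement
    elitism: int = 1
    tournament: int = 3
    cv_folds: int = 10
    components_range: tuple[int, int] = (1, 8)  # parametric gene domain
    seed: int = 0

    def validate(self, n_features: int) -> None:
        if not 1 <= self.m_start <= self.m_end:
            raise ValueError("need 1 <= m_start <= m_end")
        if self.m_end > n_features:
            raise ValueError(
                f"m_end={self.m_end} exceeds feature count {n_features}"
            )
        if not 0.0 < self.p_mutation < 1.0:
            raise ValueError("mutation probability must be in (0, 1)")
        if self.population < 2:
            raise ValueError("population must be >= 2")


@dataclass
class GAChromosome:
    mask: np.ndarray           # boolean feature-inclusion genes
    n_components: int          # parametric gene
    fitness: float = -np.inf

    @property
    def m(self) -> int:
        return int(self.mask.sum())

    def key(self) -> tuple:
        return (self.mask.tobytes(), self.n_components)

    def sort_key(self) -> tuple:
        # higher fitness first; ties to fewer features, then lexicographic mask
        return (-self.fitness, self.m, tuple(self.mask.astype(int)))


def repair(mask: np.ndarray, m_start: int, m_end: int, rng) -> np.ndarray:
    """Flip random bits toward the nearer bound until the selected count
    lies in [m_start, m_end]. Never leaves the bounds once inside."""
    mask = mask.copy()
    m = int(mask.sum())
    if m < m_start:
        off = np.flatnonzero(~mask)
        add = rng.choice(off, size=m_start - m, replace=False)
        mask[add] = True
    elif m > m_end:
        on = np.flatnonzero(mask)
        drop = rng.choice(on, size=m - m_end, replace=False)
        mask[drop] = False
    return mask


def _as_array(X) -> np.ndarray:
    if isinstance(X, PFVMatrix):
        return X.values
    if isinstance(X, FeatureMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def _pls_cv_mcc(X: np.ndarray, y: np.ndarray, n_components: int, folds) -> float:
    oof = np.empty(len(y), dtype=float)
    for train_idx, test_idx in folds:
        clf = PLSClassifier(n_components=n_components).fit(X[train_idx], y[train_idx])
        oof[test_idx] = clf.predict_proba(X[test_idx])[:, 1]
    pred = (oof >= 0.5).astype(int)
    counts = ConfusionCounts(
        tp=int(((y == 1) & (pred == 1)).sum()),
        tn=int(((y == 0) & (pred == 0)).sum()),
        fp=int(((y == 0) & (pred == 1)).sum()),
        fn=int(((y == 1) & (pred == 0)).sum()),
    )
    return mcc_from_counts(counts)


def evaluate_mask(X, y, mask, k: int = 10, seed: int = 0, n_components: int = 2) -> float:
    """Stratified k-fold CV MCC of the PLS evaluator on the masked columns."""
    X = _as_array(X)
    y = np.asarray(y, dtype=int)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty feature mask")
    k = min(k, int(np.bincount(y).min()))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(len(y)), y))
    return _pls_cv_mcc(X[:, mask], y, n_components, folds)


def select_features(
    X,
    y,
    cfg: GAConfig | None = None,
    evaluator=None,
    feature_names: list[str] | None = None,
) -> tuple[GAChromosome, list[float]]:
    """Run the GA and return (all-time best chromosome, best-fitness history).

    ``evaluator(X_masked, y, n_components, folds) -> fitness`` may override
    the default PLS cross-validated MCC. The returned history has one entry
    per generation (including the initial population) and is non-decreasing
    thanks to elitism.
    """
    X = _as_array(X)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    cfg = cfg or GAConfig()
    n = X.shape[1]
    cfg.validate(n)
    rng = np.random.default_rng(cfg.seed)
    k = min(cfg.cv_folds, int(np.bincount(y).min()))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=cfg.seed)
    folds = list(skf.split(np.zeros(len(y)), y))  # shared by all chromosomes
    c_lo, c_hi = cfg.components_range

    if evaluator is None:
        evaluator = _pls_cv_mcc

    cache: dict[tuple, float] = {}

    def fitness(ch: GAChromosome) -> float:
        key = ch.key()
        if key not in cache:
            comps = min(ch.n_components, ch.m)
            try:
                cache[key] = evaluator(X[:, ch.mask], y, comps, folds)
            except Exception as exc:  # noqa: BLE001 - add chromosome context
                raise RuntimeError(
                    f"evaluator failed on mask with m={ch.m}, "
                    f"components={comps}: {exc}"
                ) from exc
        return cache[key]

    def random_chromosome() -> GAChromosome:
        m = int(rng.integers(cfg.m_start, cfg.m_end + 1))
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=m, replace=False)] = True
        return GAChromosome(mask, int(rng.integers(c_lo, c_hi + 1)))

    population = [random_chromosome() for _ in range(cfg.population)]
    for ch in population:
        ch.fitness = fitness(ch)

    def best_of(chroms) -> GAChromosome:
        return min(chroms, key=GAChromosome.sort_key)

    best = best_of(population)
    history = [best.fitness]
    stale = 0

    def tournament() -> GAChromosome:
        picks = [population[i] for i in rng.integers(0, len(population), cfg.tournament)]
        return best_of(picks)

    for _gen in range(cfg.generations):
        offspring: list[GAChromosome] = []
        elites = sorted(population, key=GAChromosome.sort_key)[: cfg.elitism]
        offspring.extend(GAChromosome(e.mask.copy(), e.n_components, e.fitness)
                         for e in elites)
        while len(offspring) < cfg.population:
            pa, pb = tournament(), tournament()
            take_a = rng.random(n) < 0.5  # uniform crossover
            mask = np.where(take_a, pa.mask, pb.mask)
            comps = pa.n_components if rng.random() < 0.5 else pb.n_components
            flips = rng.random(n) < cfg.p_mutation
            mask = mask ^ flips
            if rng.random() < cfg.p_mutation:
                comps = int(rng.integers(c_lo, c_hi + 1))
            mask = repair(mask, cfg.m_start, cfg.m_end, rng)
            child = GAChromosome(mask, comps)
            child.fitness = fitness(child)
            offspring.append(child)
        population = offspring
        gen_best = best_of(population)
        if gen_best.sort_key() < best.sort_key():
            if gen_best.fitness > best.fitness:
                stale = 0
            best = GAChromosome(gen_best.mask.copy(), gen_best.n_components,
                                gen_best.fitness)
        else:
            stale += 1
        history.append(best.fitness)
        if stale >= cfg.stagnation:
            break

    return best, history


def selected_report(best: GAChromosome, feature_names: list[str]) -> list[str]:
    """Names of the selected features, in column order."""
    return [name for name, keep in zip(feature_names, best.mask) if keep]
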