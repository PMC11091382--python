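"""Feature screening: univariate statistics and genetic-algorithm selection.

Candidate ratio features are first screened one at a time — log2 fold
change of group means, a two-group test (Mann-Whitney U by default) and
Benjamini-Hochberg FDR control — and the survivors are handed to a wrapper
search: a genetic algorithm over binary feature masks whose fitness is the
cross-validated AUC of the downstream SVC pipeline.  Because a single GA
run is stochastic, the algorithm is repeated many times and each feature's
appearance frequency across the per-run optimal subsets is tallied; the
top-k most frequent features become the marker panel.  Strong, reproducible
markers produce the steep frequency distributions this procedure expects.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .evaluation import cv_auc
from .features import FeatureMatrix, log2_ratio

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# univariate screening

def univariate_screen(
    features,
    labels: np.ndarray | None = None,
    alpha: float = 0.05,
    fc_min: float = 1.0,
    test: str = "mannwhitney",
) -> tuple[pd.DataFrame, list[str]]:
    """Per-feature differential statistics and the candidate feature set.

    Returns a table with columns ``feature_id``, ``log2fc`` (mean log2
    value in disease minus control), ``p`` (two-sided) and ``q`` (BH), and
    the list of candidates with ``q < alpha`` and ``|log2fc| >= fc_min``.
    Constant features get p = 1 by convention.
    """
    values = features.values if isinstance(features, FeatureMatrix) else features
    y = np.asarray(features.labels if labels is None else labels)
    if (y == 1).sum() < 3 or (y == 0).sum() < 3:
        raise ValueError("univariate screening needs >= 3 samples per group")
    X = log2_ratio(values.to_numpy(dtype=float))
    dis, ctl = X[y == 1], X[y == 0]
    lfc = dis.mean(axis=0) - ctl.mean(axis=0)

    pvals = np.ones(X.shape[1])
    n_const = 0
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.ptp(col) == 0:
            n_const += 1
            continue
        if test == "mannwhitney":
            pvals[j] = stats.mannwhitneyu(dis[:, j], ctl[:, j], alternative="two-sided").pvalue
        elif test == "welch":
            pvals[j] = stats.ttest_ind(dis[:, j], ctl[:, j], equal_var=False).pvalue
        else:
            raise ValueError(f"unknown test {test!r}")
    if n_const:
        logger.info("%d constant feature(s) assigned p = 1", n_const)

    qvals = multipletests(pvals, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "feature_id": list(values.columns),
            "log2fc": lfc,
            "p": pvals,
            "q": qvals,
        }
    )
    mask = (table["q"] < alpha) & (table["log2fc"].abs() >= fc_min)
    candidates = table.loc[mask, "feature_id"].tolist()
    return table, candidates


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# genetic algorithm

@dataclass
class GAConfig:
    population_size: int = 50
    generations: int = 40
    crossover_prob: float = 0.8
    mutation_prob: float | None = None  # None -> 1/chromosome_length
    tournament_size: int = 3
    elitism: int = 1
    fitness: str = "cv_auc"
    cv_folds: int = 5
    max_subset_penalty: float = 0.0
    init_bits: float = 8.0  # expected subset size in the initial population
    n_repeats: int = 100
    seed: int = 0
    C: float = 1.0

    def __post_init__(self) -> None:
        if self.population_size < self.tournament_size:
            raise ValueError("population_size must be >= tournament_size")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.tournament_size < 2:
            raise ValueError("tournament_size must be >= 2")
        if not 0 <= self.crossover_prob <= 1:
            raise ValueError("crossover_prob must be in [0, 1]")
        if self.max_subset_penalty < 0:
            raise ValueError("max_subset_penalty must be >= 0")


@dataclass
class FrequencyTable:
    """Per-feature count of membership in the optimal subset across runs."""

    counts: dict[str, int]
    n_repeats: int

    def as_series(self) -> pd.Series:
        s = pd.Series(self.counts, dtype=int)
        return s.sort_values(ascending=False)


class SubsetFitness:
    """Memoised fitness of a binary feature mask.

    fitness(mask) = mean stratified CV score of the SVC pipeline on the
    masked columns, minus ``max_subset_penalty * |subset| / n_features``;
    the empty mask scores 0 (worst).  The cache is shared between callers,
    so a GA and an exhaustive enumeration over the same instance see
    identical values.
    """

    def __init__(self, values: pd.DataFrame, labels: np.ndarray, config: GAConfig, cv_seed: int = 0):
        self.X = values.to_numpy(dtype=float)
        self.columns = list(values.columns)
        self.y = np.asarray(labels)
        self.config = config
        self.cv_seed = cv_seed
        self._cache: dict[bytes, float] = {}

    @property
    def n_features(self) -> int:
        return len(self.columns)

    def __call__(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        key = np.packbits(mask).tobytes()
        if key in self._cache:
            return self._cache[key]
        if not mask.any():
            fit = 0.0
        else:
            score = cv_auc(
                self.X[:, mask],
                self.y,
                C=self.config.C,
                folds=self.config.cv_folds,
                seed=self.cv_seed,
                metric=self.config.fitness,
            )
            fit = score - self.config.max_subset_penalty * mask.sum() / len(mask)
        self._cache[key] = fit
        return fit


def ga_select(
    candidates,
    labels: np.ndarray | None = None,
    config: GAConfig | None = None,
    run_seed: int | None = None,
    fitness_fn: SubsetFitness | None = None,
) -> tuple[frozenset[str], float, list[float]]:
    """One genetic-algorithm run over binary feature masks.

    Tournament selection, uniform crossover, per-bit mutation and elitism;
    returns (best feature-id subset, its fitness, best-so-far trace per
    generation).  With ``elitism >= 1`` the trace is non-decreasing.
    """
    values = candidates.values if isinstance(candidates, FeatureMatrix) else candidates
    y = np.asarray(candidates.labels if labels is None else labels)
    config = config or GAConfig()
    seed = config.seed if run_seed is None else run_seed
    # the CV split is re-randomised per run, so repeated runs probe the
    # sampling stability of each feature, not just GA search stochasticity
    fit = fitness_fn or SubsetFitness(values, y, config, cv_seed=seed)
    L = fit.n_features
    if L < 1:
        raise ValueError("need at least one candidate feature")
    rng = np.random.default_rng(seed)
    pmut = config.mutation_prob if config.mutation_prob is not None else 1.0 / L

    # sparse initialisation: feature-selection GAs converge faster from
    # small subsets than from expected-L/2 ones
    p_init = min(0.5, config.init_bits / L)
    pop = rng.random((config.population_size, L)) < p_init
    for row in pop:  # no dead chromosomes at start
        if not row.any():
            row[rng.integers(L)] = True

    def tournament(scores: np.ndarray) -> np.ndarray:
        contenders = rng.integers(len(pop), size=config.tournament_size)
        return pop[contenders[np.argmax(scores[contenders])]]

    best_mask, best_fit, trace = None, -np.inf, []
    for _ in range(config.generations + 1):
        scores = np.array([fit(row) for row in pop])
        gen_best = int(np.argmax(scores))
        if scores[gen_best] > best_fit:
            best_fit = float(scores[gen_best])
            best_mask = pop[gen_best].copy()
        trace.append(best_fit)

        order = np.argsort(scores)[::-1]
        elite = pop[order[: config.elitism]].copy()
        children = []
        while len(children) < config.population_size - config.elitism:
            p1, p2 = tournament(scores), tournament(scores)
            if rng.random() < config.crossover_prob:
                swap = rng.random(L) < 0.5
                c1, c2 = np.where(swap, p2, p1), np.where(swap, p1, p2)
            else:
                c1, c2 = p1.copy(), p2.copy()
            for c in (c1, c2):
                flip = rng.random(L) < pmut
                c = np.logical_xor(c, flip)
                children.append(c)
        pop = np.vstack([elite, *children])[: config.population_size]

    subset = frozenset(np.array(fit.columns)[best_mask])
    return subset, best_fit, trace


def repeat_ga(
    candidates,
    labels: np.ndarray | None = None,
    config: GAConfig | None = None,
) -> FrequencyTable:
    """Run the GA ``n_repeats`` times (seeds seed+0 ... seed+n-1) and tally
    how often each feature appears in the per-run optimal subset."""
    values = candidates.values if isinstance(candidates, FeatureMatrix) else candidates
    y = np.asarray(candidates.labels if labels is None else labels)
    config = config or GAConfig()
    counts = {c: 0 for c in values.columns}
    for i in range(config.n_repeats):
        subset, _, _ = ga_select(values, y, config, run_seed=config.seed + i)
        for f in subset:
            counts[f] += 1
    return FrequencyTable(counts=counts, n_repeats=config.n_repeats)


def top_k_markers(table: FrequencyTable, k: int = 3) -> list[str]:
    """Top-k features by (count desc, feature_id asc)."""
    if not table.counts:
        raise ValueError("empty frequency table")
    ranked = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if k > len(ranked):
        logger.warning("requested top %d of %d features; returning all", k, len(ranked))
    return [f for f, _ in ranked[:k]]


def exhaustive_best_subset(
    values: pd.DataFrame,
    labels: np.ndarray,
    config: GAConfig | None = None,
    fitness_fn: SubsetFitness | None = None,
) -> tuple[frozenset[str], float]:
    """Best non-empty subset by full enumeration (2^L - 1 masks).

    Feasible only for small L; serves as the ground-truth optimum the GA
    is checked against.
    """
    config = config or GAConfig()
    fit = fitness_fn or SubsetFitness(values, np.asarray(labels), config)
    L = fit.n_features
    if L > 20:
        raise ValueError("exhaustive search is limited to <= 20 features")
    best_mask, best_fit = None, -np.inf
    for bits in itertools.product([False, True], repeat=L):
        mask = np.array(bits)
        if not mask.any():
            continue
        f = fit(mask)
        if f > best_fit:
            best_fit, best_mask = f, mask
    return frozenset(np.array(fit.columns)[best_mask]), float(best_fit)
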