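"""GA-MLR QSAR modelling with a full validation suite.

The response is pIC50 = −log10(IC50 in mol/L). Candidate descriptors are
pruned (near-constant columns, then the later member of any highly
intercorrelated pair), a genetic algorithm searches fixed-size descriptor
subsets maximising leave-one-out Q², and the winning subset is fitted by
ordinary least squares. Validation covers:

* internal fit — R², adjusted R², per-descriptor t statistics and VIFs;
* leave-one-out cross-validation — Q² = 1 − PRESS/TSS with PRESS from n
  refits, TSS about the full-data mean;
* external validation — R²_test on a held-out split;
* Y-randomization — refitting on permuted responses to confirm the model
  beats chance;
* applicability domain — leverage h_i from the hat matrix of the
  intercept-augmented design against the critical value h* = 3(p+1)/n,
  with standardized residuals (residual / training RMSE) bounded at ±2.45
  by default, i.e. the Williams plot.

GA settings (population 50, generations 100, tournament size 3, uniform
crossover 0.8, per-gene mutation 0.05, elitism 1) are fixed, seeded
defaults; selection is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .exceptions import (
    DataError,
    SelectionError,
    SingularityError,
    UndefinedMetricError,
)

GA_DEFAULTS = dict(population=50, generations=100, crossover_rate=0.8,
                   mutation_rate=0.05, tournament=3, elitism=1)


def to_pic50(ic50_um: float) -> float:
    """pIC50 = −log10(IC50 in molar) for an IC50 given in µM."""
    if ic50_um <= 0:
        raise DataError(f"IC50 must be positive, got {ic50_um}")
    return -math.log10(ic50_um * 1e-6)


@dataclass
class QsarTable:
    """Compound ids, a named descriptor matrix, and the pIC50 response."""

    compound_ids: list[str]
    descriptors: pd.DataFrame
    response: np.ndarray

    def __post_init__(self):
        self.response = np.asarray(self.response, dtype=float)
        n = len(self.compound_ids)
        if self.descriptors.shape[0] != n or self.response.shape[0] != n:
            raise DataError("compound_ids, descriptors and response lengths differ")
        if self.descriptors.isna().any().any() or not np.all(np.isfinite(self.response)):
            raise DataError("QSAR table contains missing or non-finite cells")

    @property
    def n(self) -> int:
        return len(self.compound_ids)

    def select(self, columns) -> "QsarTable":
        return QsarTable(self.compound_ids, self.descriptors[list(columns)].copy(),
                         self.response)

    def take(self, indices) -> "QsarTable":
        idx = list(indices)
        return QsarTable([self.compound_ids[i] for i in idx],
                         self.descriptors.iloc[idx].reset_index(drop=True),
                         self.response[idx])


@dataclass
class QsarModel:
    descriptor_names: list[str]
    coefficients: np.ndarray
    intercept: float
    r2: float
    r2_adj: float
    t_values: np.ndarray
    std_errors: np.ndarray
    vif: np.ndarray
    q2_loo: float | None = None
    r2_test: float | None = None
    n_train: int = 0

    def predict(self, X) -> np.ndarray:
        """Predict pIC50 for a descriptor matrix (array or named frame)."""
        if isinstance(X, pd.DataFrame):
            X = X[self.descriptor_names].to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.descriptor_names):
            raise DataError(
                f"expected {len(self.descriptor_names)} descriptors, got {X.shape[1]}"
            )
        return self.intercept + X @ self.coefficients

    def to_dict(self) -> dict:
        return {
            "descriptor_names": list(self.descriptor_names),
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "r2": float(self.r2),
            "r2_adj": float(self.r2_adj),
            "t_values": [float(t) for t in self.t_values],
            "std_errors": [float(s) for s in self.std_errors],
            "vif": [float(v) for v in self.vif],
            "q2_loo": None if self.q2_loo is None else float(self.q2_loo),
            "r2_test": None if self.r2_test is None else float(self.r2_test),
            "n_train": int(self.n_train),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QsarModel":
        return cls(
            descriptor_names=list(d["descriptor_names"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            r2=float(d["r2"]),
            r2_adj=float(d["r2_adj"]),
            t_values=np.asarray(d["t_values"], dtype=float),
            std_errors=np.asarray(d["std_errors"], dtype=float),
            vif=np.asarray(d["vif"], dtype=float),
            q2_loo=d.get("q2_loo"),
            r2_test=d.get("r2_test"),
            n_train=int(d.get("n_train", 0)),
        )


@dataclass(frozen=True)
class AdAssessment:
    compound_id: str
    leverage: float
    std_residual: float
    h_star: float
    in_domain: bool
    subset: str = "train"  # "train" or "query"


@dataclass
class RandomizationSummary:
    n_trials: int
    mean_r2: float
    mean_q2: float
    max_r2: float
    max_q2: float
    original_r2: float
    original_q2: float
    n_failed: int
    seed: int


def prune_descriptors(table: QsarTable, constancy_frac: float = 0.95,
                      corr_limit: float = 0.90) -> QsarTable:
    """Drop near-constant columns, then the later column of any highly
    correlated pair (|Pearson r| > corr_limit), scanning in input order."""
    if not (0 < constancy_frac <= 1) or not (0 < corr_limit <= 1):
        raise DataError("pruning limits must lie in (0, 1]")
    X = table.descriptors
    keep = []
    for col in X.columns:
        modal_frac = X[col].value_counts(normalize=True).iloc[0]
        if modal_frac <= constancy_frac:
            keep.append(col)
    # greedy correlation prune, earlier column wins
    final: list[str] = []
    for col in keep:
        ok = True
        for prev in final:
            r = np.corrcoef(X[prev].to_numpy(float), X[col].to_numpy(float))[0, 1]
            if np.isfinite(r) and abs(r) > corr_limit:
                ok = False
                break
        if ok:
            final.append(col)
    if not final:
        raise SelectionError("all descriptor columns pruned; pool is empty")
    return table.select(final)


def _check_rank(X: np.ndarray, names) -> None:
    design = np.column_stack([np.ones(X.shape[0]), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # flag columns with vanishing contribution in a QR factorisation
        _, R = np.linalg.qr(design)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(design.shape) * np.finfo(float).eps
        bad = [names[i - 1] for i in range(1, design.shape[1]) if diag[i] < tol]
        raise SingularityError(
            f"rank-deficient design (rank {rank} < {design.shape[1]}); "
            f"dependent columns: {bad or names}", columns=bad or names)


def fit_mlr(X, y, names=None) -> QsarModel:
    """Ordinary least squares with intercept, plus t values and VIFs.

    ``X`` may be a named DataFrame or a plain matrix (columns then named
    x1..xp). Requires n > p + 1 and a full-rank design.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if names is None:
        names = [f"x{i+1}" for i in range(p)]
    if n <= p + 1:
        raise DataError(f"need n > p + 1 (n={n}, p={p})")
    _check_rank(X, names)
    design = sm.add_constant(X, has_constant="add")
    res = sm.OLS(y, design).fit()
    if p == 1:
        vif = np.array([1.0])
    else:
        vif = np.array([variance_inflation_factor(design, j)
                        for j in range(1, p + 1)])
    return QsarModel(
        descriptor_names=names,
        coefficients=res.params[1:].copy(),
        intercept=float(res.params[0]),
        r2=float(res.rsquared),
        r2_adj=float(res.rsquared_adj),
        t_values=res.tvalues[1:].copy(),
        std_errors=res.bse[1:].copy(),
        vif=vif,
        n_train=n,
    )


def loo_q2(X, y, names=None) -> float:
    """Leave-one-out Q² = 1 − PRESS/TSS; PRESS from n refits, TSS about the
    full-data mean."""
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 2:
        raise DataError(f"LOO needs n > p + 2 (n={n}, p={p})")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise UndefinedMetricError("Q² undefined: response has zero variance")
    press = 0.0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            model = fit_mlr(X[mask], y[mask], names=names)
        except SingularityError as exc:
            raise SingularityError(
                f"LOO refit singular when leaving out row {i}: {exc}",
                columns=exc.columns) from exc
        pred = model.predict(X[i:i + 1])[0]
        press += (y[i] - pred) ** 2
    return 1.0 - press / tss


def external_r2(model: QsarModel, X_test, y_test) -> float:
    """R²_test = 1 − RSS/TSS on held-out data, TSS about the test mean."""
    y_test = np.asarray(y_test, dtype=float)
    if y_test.size == 0:
        raise DataError("empty test set")
    pred = model.predict(X_test)
    tss = float(np.sum((y_test - y_test.mean()) ** 2))
    if tss == 0:
        raise UndefinedMetricError("R²_test undefined: test response constant")
    rss = float(np.sum((y_test - pred) ** 2))
    return 1.0 - rss / tss


def split_train_test(table: QsarTable, train_frac: float = 0.8,
                     seed: int = 0) -> tuple[QsarTable, QsarTable]:
    """Seeded random split; train size = round(n · train_frac)."""
    if not (0 < train_frac < 1):
        raise DataError("train_frac must be in (0, 1)")
    n = table.n
    n_train = int(np.floor(n * train_frac + 0.5))
    if n_train < table.descriptors.shape[1] + 2 or n_train >= n:
        raise DataError(f"split {n_train}/{n - n_train} leaves too few rows")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return table.take(np.sort(perm[:n_train])), table.take(np.sort(perm[n_train:]))


def _subset_fitness(table: QsarTable, cols: tuple, cache: dict) -> float:
    key = frozenset(cols)
    if key not in cache:
        sub = table.descriptors[list(cols)]
        try:
            cache[key] = loo_q2(sub, table.response)
        except (SingularityError, DataError, UndefinedMetricError):
            cache[key] = -np.inf
    return cache[key]


def ga_select(table: QsarTable, subset_size: int = 3, seed: int = 0,
              population: int = None, generations: int = None,
              crossover_rate: float = None, mutation_rate: float = None,
              tournament: int = None, elitism: int = None):
    """Genetic-algorithm descriptor selection maximising LOO Q².

    Returns ``(best_names, fitted QsarModel, trajectory)`` where trajectory
    is the best fitness per generation. Deterministic given the seed.
    """
    params = dict(GA_DEFAULTS)
    for k, v in dict(population=population, generations=generations,
                     crossover_rate=crossover_rate, mutation_rate=mutation_rate,
                     tournament=tournament, elitism=elitism).items():
        if v is not None:
            params[k] = v
    pool = list(table.descriptors.columns)
    if len(pool) < subset_size:
        raise SelectionError(
            f"pool of {len(pool)} descriptors smaller than subset size {subset_size}")
    if table.n <= subset_size + 2:
        raise DataError("too few compounds for LOO-scored selection")

    cache: dict = {}
    if len(pool) == subset_size:
        cols = tuple(pool)
        fit = _subset_fitness(table, cols, cache)
        if not np.isfinite(fit):
            raise SelectionError("the only available subset is rank deficient")
        model = fit_mlr(table.descriptors[list(cols)], table.response)
        model.q2_loo = fit
        return list(cols), model, [fit]

    rng = np.random.default_rng(seed)
    n_pool = len(pool)

    def random_subset():
        return tuple(sorted(rng.choice(n_pool, size=subset_size, replace=False)))

    def crossover(a, b):
        union = sorted(set(a) | set(b))
        child = rng.choice(len(union), size=subset_size, replace=False)
        return tuple(sorted(union[i] for i in child))

    def mutate(genes):
        genes = list(genes)
        for i in range(subset_size):
            if rng.random() < params["mutation_rate"]:
                choices = [g for g in range(n_pool) if g not in genes]
                genes[i] = int(rng.choice(choices))
        return tuple(sorted(genes))

    def fitness(genes):
        return _subset_fitness(table, tuple(pool[g] for g in genes), cache)

    pop = [random_subset() for _ in range(params["population"])]
    scores = [fitness(g) for g in pop]
    trajectory = []
    for _ in range(params["generations"]):
        order = np.argsort(scores)[::-1]
        next_pop = [pop[i] for i in order[:params["elitism"]]]
        while len(next_pop) < params["population"]:
            contenders = rng.choice(len(pop), size=params["tournament"], replace=False)
            pa = pop[max(contenders, key=lambda i: scores[i])]
            contenders = rng.choice(len(pop), size=params["tournament"], replace=False)
            pb = pop[max(contenders, key=lambda i: scores[i])]
            child = crossover(pa, pb) if rng.random() < params["crossover_rate"] else pa
            next_pop.append(mutate(child))
        pop = next_pop
        scores = [fitness(g) for g in pop]
        trajectory.append(float(max(scores)))
    best = pop[int(np.argmax(scores))]
    best_fit = max(scores)
    if not np.isfinite(best_fit):
        raise SelectionError("no full-rank subset found by the GA")
    names = [pool[g] for g in best]
    model = fit_mlr(table.descriptors[names], table.response)
    model.q2_loo = best_fit
    return names, model, trajectory


def y_randomization(X, y, n_trials: int = 200, seed: int = 0) -> RandomizationSummary:
    """Refit on seeded permutations of the response; a real model's R²/Q²
    should dwarf every randomized trial's."""
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_trials < 1:
        raise DataError("n_trials must be ≥ 1")
    original = fit_mlr(X, y)
    original_q2 = loo_q2(X, y)
    rng = np.random.default_rng(seed)
    r2s, q2s, n_failed = [], [], 0
    for _ in range(n_trials):
        y_perm = rng.permutation(y)
        try:
            r2s.append(fit_mlr(X, y_perm).r2)
            q2s.append(loo_q2(X, y_perm))
        except (SingularityError, UndefinedMetricError, DataError):
            n_failed += 1
    if not r2s:
        raise DataError("every randomization trial failed to fit")
    return RandomizationSummary(
        n_trials=n_trials,
        mean_r2=float(np.mean(r2s)),
        mean_q2=float(np.mean(q2s)),
        max_r2=float(np.max(r2s)),
        max_q2=float(np.max(q2s)),
        original_r2=float(original.r2),
        original_q2=float(original_q2),
        n_failed=n_failed,
        seed=seed,
    )


def critical_leverage(p: int, n: int) -> float:
    """Williams-plot critical leverage h* = 3(p+1)/n."""
    if n < 1 or p < 1:
        raise DataError("need p ≥ 1 descriptors and n ≥ 1 compounds")
    return 3.0 * (p + 1) / n


def applicability_domain(X_train, y_train, model: QsarModel,
                         X_query=None, y_query=None, query_ids=None,
                         train_ids=None, h_star: float = None,
                         n_reference: int = None,
                         residual_limit: float = 2.45) -> list[AdAssessment]:
    """Leverage / standardized-residual domain check (Williams plot data).

    Leverages are diagonal entries of the hat projection for the
    intercept-augmented training design; query compounds are mapped through
    x (XᵀX)⁻¹ xᵀ. h* defaults to 3(p+1)/n with n = all assessed compounds
    (train plus query). Standardized residuals divide by the training RMSE;
    query compounds without a measured response get a residual of 0 and are
    judged on leverage alone.
    """
    if isinstance(X_train, pd.DataFrame):
        X_train = X_train[model.descriptor_names].to_numpy(dtype=float)
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    y_train = np.asarray(y_train, dtype=float)
    n, p = X_train.shape
    A = np.column_stack([np.ones(n), X_train])
    gram = A.T @ A
    if np.linalg.matrix_rank(gram) < gram.shape[0]:
        raise SingularityError("singular training design in domain assessment")
    gram_inv = np.linalg.inv(gram)

    resid = y_train - model.predict(X_train)
    rmse = float(np.sqrt(np.mean(resid ** 2)))

    if X_query is not None:
        if isinstance(X_query, pd.DataFrame):
            X_query = X_query[model.descriptor_names].to_numpy(dtype=float)
        X_query = np.atleast_2d(np.asarray(X_query, dtype=float))
        n_query = X_query.shape[0]
    else:
        n_query = 0

    if h_star is None:
        n_ref = n_reference if n_reference is not None else n + n_query
        h_star = critical_leverage(p, n_ref)

    if train_ids is None:
        train_ids = [f"train{i+1}" for i in range(n)]

    def assess(cid, row, residual, subset):
        h = float(row @ gram_inv @ row)
        if rmse > 0 and residual is not None:
            std_res = float(residual / rmse)
        else:
            std_res = 0.0
        in_domain = (h < h_star) and (abs(std_res) <= residual_limit)
        return AdAssessment(cid, h, std_res, h_star, in_domain, subset)

    out = [assess(cid, A[i], resid[i], "train")
           for i, cid in enumerate(train_ids)]
    if n_query:
        if query_ids is None:
            query_ids = [f"query{i+1}" for i in range(n_query)]
        preds = model.predict(X_query)
        for i, cid in enumerate(query_ids):
            row = np.concatenate([[1.0], X_query[i]])
            residual = None if y_query is None else float(y_query[i] - preds[i])
            out.append(assess(cid, row, residual, "query"))
    return out
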