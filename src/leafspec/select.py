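"""Wavelength selection: sMC, iterative predictor weighting, regularized
backward elimination, and a genetic algorithm, behind one result contract.

All four return a :class:`SelectionResult` carrying per-band scores, the
boolean selected mask, the applied cutoff (where one exists) and the
hyperparameters used. Every method guarantees at least one selected band.

* ``smc`` -- significance multivariate correlation: each centered band is
  regressed on the unit vector along the PLSR prediction direction
  u = Xb/||Xb||; the F-like statistic SSreg/(SSres/(n-2)) is compared with
  the F(1, n-2) upper-alpha quantile. Under a pure-noise response the
  selected fraction calibrates to alpha.
* ``ipw`` -- iterative predictor weighting: refit PLSR on importance-weighted
  bands (importance = |coefficient| x band SD, normalized to mean 1),
  multiply the running weights, and keep bands whose final weight exceeds
  ``keep_threshold`` x the maximum weight.
* ``rep_elimination`` -- backward elimination dropping the lowest-VIP
  fraction each step, scoring every intermediate band set by 10-fold CV RMSE
  and returning the set with the smallest CV error.
* ``ga_select`` -- binary GA over contiguous 4-band windows with 5-fold
  RMSECV fitness, tournament selection (k=2), uniform crossover, per-bit
  mutation and single elitism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, InvalidParameterError
from .pls import fit_plsr, kfold_rmse, loo_select_ncomp, vip_scores

__all__ = ["SelectionResult", "smc", "ipw", "rep_elimination", "ga_select"]


@dataclass
class SelectionResult:
    method: str
    scores: np.ndarray
    selected: np.ndarray
    threshold: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.selected = np.asarray(self.selected, dtype=bool)
        if self.scores.shape != self.selected.shape:
            raise InvalidParameterError("scores and mask must have equal length")
        if not np.all(np.isfinite(self.scores)):
            raise InvalidParameterError("selection scores must be finite")
        if not self.selected.any():
            raise InvalidParameterError("at least one band must be selected")

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())


def _choose_ncomp(X, y, max_ncomp: int, ncomp: int | None) -> int:
    if ncomp is not None:
        return max(1, int(ncomp))
    best, _ = loo_select_ncomp(X, y, max_ncomp)
    return max(1, best)


def smc(
    X, y, max_ncomp: int = 10, alpha: float = 0.05, ncomp: int | None = None
) -> SelectionResult:
    """Significance multivariate correlation selection.

    The prediction direction is taken from a PLS fit at the full
    ``max_ncomp`` rank (not a CV-chosen rank): the statistic needs the least
    biased in-sample yhat available, since the F(1, n-2) reference assumes
    the direction is not aligned with any individual noise band -- a
    low-rank direction is dominated by the single-band covariances and
    over-selects under the null. If no band clears the F cutoff the single
    highest-scoring band is kept (with a warning) so the result is always
    usable downstream.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if not (0 < alpha < 1):
        raise InvalidParameterError(f"alpha must be in (0, 1), got {alpha}")
    k = max(1, int(ncomp) if ncomp is not None else min(max_ncomp, n - 1, X.shape[1]))
    model = fit_plsr(X, y, k)
    Xc = X - X.mean(axis=0)
    yhat = Xc @ model.regression_vector
    norm = np.linalg.norm(yhat)
    if norm <= 0:
        raise DegenerateDataError("PLSR prediction direction has zero norm")
    u = yhat / norm
    proj = Xc.T @ u
    ssreg = proj**2
    sstot = np.sum(Xc**2, axis=0)
    ssres = np.maximum(sstot - ssreg, 0.0)
    with np.errstate(divide="ignore"):
        scores = np.where(
            ssres > 0, ssreg / (ssres / (n - 2)), np.where(ssreg > 0, np.inf, 0.0)
        )
    scores = np.where(np.isfinite(scores), scores, np.nanmax(scores[np.isfinite(scores)], initial=0.0) * 10 + 1)
    threshold = float(stats.f.ppf(1.0 - alpha, 1, n - 2))
    selected = scores > threshold
    if not selected.any():
        warnings.warn("sMC: no band exceeded the F cutoff; keeping the top band",
                      stacklevel=2)
        selected[np.argmax(scores)] = True
    return SelectionResult(
        method="smc",
        scores=scores,
        selected=selected,
        threshold=threshold,
        provenance={"alpha": alpha, "ncomp": k, "max_ncomp": max_ncomp},
    )


def ipw(
    X,
    y,
    max_iter: int = 10,
    keep_threshold: float = 0.1,
    max_ncomp: int = 10,
    ncomp: int | None = None,
) -> SelectionResult:
    """Iterative predictor weighting selection."""
    if max_iter < 1:
        raise InvalidParameterError("max_iter must be >= 1")
    if not (0 < keep_threshold < 1):
        raise InvalidParameterError("keep_threshold must be in (0, 1)")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    p = X.shape[1]
    k = _choose_ncomp(X, y, max_ncomp, ncomp)
    weights = np.ones(p)
    prev = None
    for it in range(max_iter):
        Xw = X * weights
        model = fit_plsr(Xw, y, min(k, max(1, int(np.sum(weights > 0)) )))
        imp = np.abs(model.regression_vector) * Xw.std(axis=0, ddof=1)
        total = imp.sum()
        if total <= 0:
            break
        imp = imp / imp.mean()
        weights = weights * imp
        weights = weights / weights.max()
        selected = weights > keep_threshold
        if selected.sum() <= 1:
            warnings.warn("Ipw: weights collapsed to a single band", stacklevel=2)
            break
        if prev is not None and np.array_equal(selected, prev):
            break
        prev = selected
    selected = weights > keep_threshold
    if not selected.any():
        selected[np.argmax(weights)] = True
    return SelectionResult(
        method="ipw",
        scores=weights,
        selected=selected,
        threshold=float(keep_threshold),
        provenance={
            "max_iter": max_iter,
            "keep_threshold": keep_threshold,
            "ncomp": k,
            "iterations_run": it + 1,
        },
    )


def rep_elimination(
    X,
    y,
    drop_fraction: float = 0.1,
    min_bands: int = 10,
    max_ncomp: int = 10,
    ncomp: int | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """Regularized (VIP-ranked) backward elimination.

    Each step drops the ``drop_fraction`` lowest-VIP bands of the current
    set and records the 10-fold CV RMSE of the set before dropping; folds
    are shared across steps so the comparison is paired. The returned mask
    is the recorded set with the smallest CV RMSE. Scores report the step at
    which each band was eliminated (bands in the final surviving set share
    the top score), i.e. how long each band survived.
    """
    if not (0.0 < drop_fraction < 1.0):
        raise InvalidParameterError("drop_fraction must be in (0, 1)")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    p = X.shape[1]
    min_bands = max(1, min(min_bands, p))
    k = _choose_ncomp(X, y, max_ncomp, ncomp)
    active = np.arange(p)
    survival = np.zeros(p)
    recorded: list[tuple[np.ndarray, float]] = []
    step = 0
    while True:
        rng = np.random.default_rng(seed)  # identical folds at every step
        kk = min(k, active.size, X.shape[0] - 2)
        cv = kfold_rmse(X[:, active], y, kk, n_folds=n_folds, rng=rng)
        recorded.append((active.copy(), cv))
        if active.size <= min_bands:
            break
        model = fit_plsr(X[:, active], y, kk)
        vip = vip_scores(model)
        n_drop = max(1, int(round(drop_fraction * active.size)))
        n_drop = min(n_drop, active.size - min_bands)
        order = np.argsort(vip)
        dropped = active[order[:n_drop]]
        survival[dropped] = step
        active = np.sort(active[order[n_drop:]])
        step += 1
    survival[active] = step
    best_set, _ = min(recorded, key=lambda t: t[1])
    selected = np.zeros(p, dtype=bool)
    selected[best_set] = True
    return SelectionResult(
        method="rep",
        scores=survival,
        selected=selected,
        threshold=float("nan"),
        provenance={
            "drop_fraction": drop_fraction,
            "min_bands": min_bands,
            "ncomp": k,
            "n_folds": n_folds,
            "seed": seed,
            "n_steps": len(recorded),
            "cv_rmse_path": [float(c) for _, c in recorded],
        },
    )


def _expand_windows(chrom: np.ndarray, p: int, window: int) -> np.ndarray:
    mask = np.repeat(chrom, window)[:p]
    return mask.astype(bool)


def ga_select(
    X,
    y,
    pop_size: int = 64,
    n_generations: int = 100,
    mutation_rate: float = 0.01,
    seed: int = 0,
    window: int = 4,
    max_ncomp: int = 10,
    ncomp: int | None = None,
    n_folds: int = 5,
) -> SelectionResult:
    """Genetic-algorithm selection over contiguous ``window``-band blocks.

    Fitness is minus the ``n_folds``-fold CV RMSE of a PLS1 fit on the active
    windows; fold assignment is fixed once per call so fitnesses of different
    chromosomes are comparable, and fitness values are memoized. Elitism of
    one makes the best fitness non-decreasing across generations.
    """
    if pop_size < 4 or pop_size % 2:
        raise InvalidParameterError("pop_size must be even and >= 4")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    n_windows = int(np.ceil(p / window))
    rng = np.random.default_rng(seed)
    fold_rng_state = np.random.default_rng(rng.integers(2**31))
    fold_perm = fold_rng_state.permutation(n)
    k = _choose_ncomp(X, y, max_ncomp, ncomp)

    class _FixedRng:
        """Replays one fixed permutation so CV folds are shared."""

        def __init__(self, perm):
            self._perm = perm

        def permutation(self, m):
            return self._perm[:m].copy()

    cache: dict[bytes, float] = {}

    def fitness(chrom: np.ndarray) -> float:
        key = chrom.tobytes()
        if key in cache:
            return cache[key]
        mask = _expand_windows(chrom, p, window)
        if not mask.any():
            return -np.inf
        kk = min(k, int(mask.sum()), n - 2)
        rmse = kfold_rmse(X[:, mask], y, kk, n_folds=n_folds, rng=_FixedRng(fold_perm))
        val = -rmse
        cache[key] = val
        return val

    pop = (rng.random((pop_size, n_windows)) < 0.3).astype(np.uint8)
    for i in range(pop_size):  # repair empty chromosomes
        if not pop[i].any():
            pop[i, rng.integers(n_windows)] = 1
    fits = np.array([fitness(c) for c in pop])
    history = [float(fits.max())]

    for _gen in range(n_generations):
        elite = pop[np.argmax(fits)].copy()
        children = [elite]
        while len(children) < pop_size:
            parents = []
            for _ in range(2):
                i, j = rng.integers(pop_size, size=2)
                parents.append(pop[i] if fits[i] >= fits[j] else pop[j])
            swap = rng.random(n_windows) < 0.5
            c1 = np.where(swap, parents[0], parents[1]).astype(np.uint8)
            c2 = np.where(swap, parents[1], parents[0]).astype(np.uint8)
            for c in (c1, c2):
                mut = rng.random(n_windows) < mutation_rate
                c ^= mut.astype(np.uint8)
                if not c.any():
                    c[rng.integers(n_windows)] = 1
                children.append(c)
        pop = np.array(children[:pop_size], dtype=np.uint8)
        fits = np.array([fitness(c) for c in pop])
        history.append(float(fits.max()))

    best = pop[np.argmax(fits)]
    selected = _expand_windows(best, p, window)
    freq = _expand_windows_freq(pop, p, window)
    return SelectionResult(
        method="ga",
        scores=freq,
        selected=selected,
        threshold=float("nan"),
        provenance={
            "pop_size": pop_size,
            "n_generations": n_generations,
            "mutation_rate": mutation_rate,
            "seed": seed,
            "window": window,
            "ncomp": k,
            "n_folds": n_folds,
            "best_fitness": float(fits.max()),
            "fitness_history": history,
        },
    )


def _expand_windows_freq(pop: np.ndarray, p: int, window: int) -> np.ndarray:
    """Per-band selection frequency across the final population."""
    freq = pop.mean(axis=0)
    return np.repeat(freq, window)[:p]


SELECTORS = {
    "smc": smc,
    "ipw": ipw,
    "rep": rep_elimination,
    "ga": ga_select,
}
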