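"""Ant-colony-optimization selection of predictive MACCS fingerprint bits.

A colony of ants repeatedly assembles candidate bit subsets, sampling bits
with probability proportional to a pheromone trail (greedy with probability
``exploitation_prob``, roulette otherwise). Each subset is scored by a
transparent binary classifier: every selected bit gets a log-odds
enrichment weight (CNSp+ vs CNSp-, Haldane +0.5 correction), a molecule's
score is the sum of weights over its set bits, and fitness is a ROC-based
quality measure (AUC by default) of those scores. To guard against
overfitting the fitness is computed on pooled 10-fold cross-validation
scores: weights are always fitted on the nine training folds and applied to
the held-out fold. Pheromone evaporates each iteration and is reinforced on
the iteration-best subset proportionally to its fitness; the global best
subset is retained, so the best-fitness trace is monotone nondecreasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dti import CLASS_NEG, CLASS_POS
from .evaluation import ConfusionCounts, RocCurve, ccr, mcc, roc_curve, stratified_folds
from .fingerprints import N_KEYS


@dataclass
class AcoParams:
    """Colony-search and fitness settings."""

    n_ants: int = 50
    n_iterations: int = 100
    evaporation_rate: float = 0.1
    subset_min: int = 3
    subset_max: int = 15
    pheromone_init: float = 1.0
    exploitation_prob: float = 0.9
    fitness_metric: str = "AUC"  # "AUC" | "CCR" | "MCC"
    n_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.evaporation_rate < 1:
            raise ValueError("evaporation_rate must be in (0, 1)")
        if not 1 <= self.subset_min <= self.subset_max <= N_KEYS:
            raise ValueError("need 1 <= subset_min <= subset_max <= 166")
        self.fitness_metric = self.fitness_metric.upper()
        if self.fitness_metric not in ("AUC", "CCR", "MCC"):
            raise ValueError(f"unknown fitness metric {self.fitness_metric!r}")


@dataclass
class FeatureSubsetSolution:
    """An ACO-selected bit subset with its classifier and quality measures.

    ``selected_bits`` are 1-based MACCS key indices; ``bit_weights`` maps
    each to its signed log-odds enrichment (full-data fit, for reporting);
    ``cv_scores`` are the pooled cross-validated molecule scores the metrics
    were computed from.
    """

    selected_bits: tuple[int, ...]
    bit_weights: dict[int, float]
    fitness: float
    roc: RocCurve
    ccr: float
    mcc: float
    cutoff: float
    cv_scores: np.ndarray
    labels: np.ndarray
    confusion: ConfusionCounts
    degenerate: bool = False


@dataclass
class AcoResult:
    best: FeatureSubsetSolution
    trace: list[float] = field(default_factory=list)  # global-best fitness/iteration
    n_evaluations: int = 0
    pheromone: np.ndarray | None = None  # final trail, for diagnostics


def bit_weight(bit_column: np.ndarray, labels: np.ndarray) -> float:
    """Signed log-odds enrichment of a bit in CNSp+ vs CNSp- (+0.5 Haldane).

    log[ ((a+.5)/(n1-a+.5)) / ((b+.5)/(n0-b+.5)) ] with a/b the set-bit
    counts in the positive/negative class. A constant column carries no
    direction and gets weight 0.
    """
    bit_column = np.asarray(bit_column)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    if len(np.unique(bit_column)) < 2:
        return 0.0
    pos = labels == CLASS_POS
    a, n1 = float(bit_column[pos].sum()), float(pos.sum())
    b, n0 = float(bit_column[~pos].sum()), float((~pos).sum())
    return float(
        np.log(((a + 0.5) / (n1 - a + 0.5)) / ((b + 0.5) / (n0 - b + 0.5)))
    )


def _weight_matrix(X: np.ndarray, y: np.ndarray, train_mask: np.ndarray) -> np.ndarray:
    """Log-odds weights for every bit, fitted on ``train_mask`` rows."""
    Xt, yt = X[train_mask], y[train_mask]
    pos = yt == CLASS_POS
    n1, n0 = float(pos.sum()), float((~pos).sum())
    a = Xt[pos].sum(axis=0).astype(float)
    b = Xt[~pos].sum(axis=0).astype(float)
    w = np.log(((a + 0.5) / (n1 - a + 0.5)) / ((b + 0.5) / (n0 - b + 0.5)))
    constant = (Xt.min(axis=0) == Xt.max(axis=0))
    w[constant] = 0.0
    return w


def score_molecule(fp_bits: np.ndarray, sol: FeatureSubsetSolution) -> float:
    """Sum of the solution's bit weights over the fingerprint's set bits."""
    fp_bits = np.asarray(fp_bits)
    return float(
        sum(sol.bit_weights[b] for b in sol.selected_bits if fp_bits[b - 1])
    )


def classify_molecule(fp_bits: np.ndarray, sol: FeatureSubsetSolution) -> int:
    """CNSp+ iff the molecule's score reaches the solution's Youden cutoff."""
    return CLASS_POS if score_molecule(fp_bits, sol) >= sol.cutoff else CLASS_NEG


class _CvScorer:
    """Pooled cross-validated subset scores, vectorized for the ACO loop.

    Per-fold log-odds weight matrices (train rows only) are precomputed once;
    a subset's pooled CV score vector is then a single masked matrix
    contraction.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, n_folds: int, seed: int):
        self.X = np.asarray(X, dtype=np.float64)
        self.y = np.asarray(y)
        self.fold_of = stratified_folds(self.y, n_folds, seed, stratified=True)
        self.W = np.vstack(
            [
                _weight_matrix(self.X, self.y, self.fold_of != f)
                for f in range(n_folds)
            ]
        )  # (n_folds, 166)
        self.row_weights = self.W[self.fold_of]  # (n, 166): held-out weights per row

    def scores(self, bits: np.ndarray) -> np.ndarray:
        cols = np.asarray(bits, dtype=int) - 1
        return (self.X[:, cols] * self.row_weights[:, cols]).sum(axis=1)

    def auc(self, bits: np.ndarray) -> float:
        s = self.scores(bits)
        if np.ptp(s) == 0.0:
            return 0.5
        return roc_curve(s, self.y).auc


def evaluate_fitness(
    bits,
    X: np.ndarray,
    y: np.ndarray,
    params: AcoParams,
    _scorer: _CvScorer | None = None,
) -> FeatureSubsetSolution:
    """Fit and score one candidate subset.

    Weights are fitted per CV fold, pooled held-out scores give the ROC;
    the Youden cutoff sets the operating point for CCR/MCC; fitness is the
    configured metric. Degenerate (all-equal) scores yield AUC 0.5.
    """
    bits = tuple(sorted(int(b) for b in bits))
    if not params.subset_min <= len(bits) <= params.subset_max:
        raise ValueError(
            f"subset size {len(bits)} outside [{params.subset_min}, {params.subset_max}]"
        )
    X = np.asarray(X)
    y = np.asarray(y)
    scorer = _scorer or _CvScorer(X, y, params.n_folds, params.seed)
    scores = scorer.scores(np.array(bits))
    full_weights = {b: bit_weight(X[:, b - 1], y) for b in bits}
    if np.ptp(scores) == 0.0:
        conf = ConfusionCounts.from_predictions(y, np.full_like(y, CLASS_POS))
        flat = RocCurve(
            fpr=np.array([0.0, 1.0]), tpr=np.array([0.0, 1.0]),
            thresholds=np.array([np.inf, scores[0]]),
            auc=0.5, youden_cutoff=float(scores[0]), youden_j=0.0,
        )
        return FeatureSubsetSolution(
            selected_bits=bits, bit_weights=full_weights, fitness=0.5 if
            params.fitness_metric == "AUC" else 0.0,
            roc=flat, ccr=0.5, mcc=0.0, cutoff=float(scores[0]),
            cv_scores=scores, labels=y, confusion=conf, degenerate=True,
        )
    roc = roc_curve(scores, y)
    cutoff = roc.youden_cutoff
    y_pred = np.where(scores >= cutoff, CLASS_POS, CLASS_NEG)
    conf = ConfusionCounts.from_predictions(y, y_pred)
    sol_ccr = ccr(conf)
    sol_mcc = mcc(conf)
    fitness = {"AUC": roc.auc, "CCR": sol_ccr, "MCC": sol_mcc}[params.fitness_metric]
    return FeatureSubsetSolution(
        selected_bits=bits, bit_weights=full_weights, fitness=float(fitness),
        roc=roc, ccr=sol_ccr, mcc=sol_mcc, cutoff=float(cutoff),
        cv_scores=scores, labels=y, confusion=conf,
    )


def _build_subset(
    rng: np.random.Generator,
    tau: np.ndarray,
    eta: np.ndarray,
    size: int,
    q0: float,
) -> tuple[int, ...]:
    """One ant's subset, bit by bit.

    Desirability of bit i is tau_i * eta_i (pheromone times the heuristic
    univariate enrichment). With probability ``q0`` the ant exploits (argmax,
    random tie-break), otherwise it samples by roulette.
    """
    value = tau * eta
    available = np.ones(len(tau), dtype=bool)
    chosen: list[int] = []
    for _ in range(size):
        if rng.random() < q0:
            avail_idx = np.flatnonzero(available)
            v = value[avail_idx]
            best = avail_idx[np.flatnonzero(v == v.max())]
            idx = int(rng.choice(best))
        else:
            p = np.where(available, value, 0.0)
            p = p / p.sum()
            idx = int(rng.choice(len(tau), p=p))
        chosen.append(idx + 1)
        available[idx] = False
    return tuple(sorted(chosen))


def run_aco_selection(X: np.ndarray, y: np.ndarray, params: AcoParams) -> AcoResult:
    """Search for the bit subset with the best cross-validated fitness.

    Fully deterministic under ``params.seed``: the fold assignment, every
    ant's construction, and all pheromone updates derive from one generator.
    Returns the global-best solution (rebuilt through
    :func:`evaluate_fitness`) and the per-iteration best-fitness trace.
    """
    X = np.asarray(X, dtype=np.uint8)
    y = np.asarray(y)
    if len(y) < 20:
        raise ValueError("need at least 20 labeled fingerprints")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(params.seed)
    scorer = _CvScorer(X, y, params.n_folds, params.seed)
    # heuristic desirability: magnitude of each bit's class enrichment,
    # floored so no bit is unreachable by roulette
    eta = np.abs(_weight_matrix(X, y, np.ones(len(y), dtype=bool))) + 0.1
    tau = np.full(X.shape[1], float(params.pheromone_init))
    best_bits: tuple[int, ...] | None = None
    best_fitness = -np.inf
    trace: list[float] = []
    cache: dict[tuple[int, ...], float] = {}
    n_evals = 0
    for _iteration in range(params.n_iterations):
        iter_best_bits: tuple[int, ...] | None = None
        iter_best_fitness = -np.inf
        for _ant in range(params.n_ants):
            size = int(rng.integers(params.subset_min, params.subset_max + 1))
            bits = _build_subset(rng, tau, eta, size, params.exploitation_prob)
            if bits in cache:
                fitness = cache[bits]
            else:
                if params.fitness_metric == "AUC":
                    fitness = scorer.auc(np.array(bits))
                else:
                    fitness = evaluate_fitness(bits, X, y, params, _scorer=scorer).fitness
                cache[bits] = fitness
                n_evals += 1
            if fitness > iter_best_fitness:
                iter_best_bits, iter_best_fitness = bits, fitness
        # evaporation then reinforcement on the iteration-best subset
        tau *= 1.0 - params.evaporation_rate
        if iter_best_bits is not None:
            idx = np.array(iter_best_bits) - 1
            tau[idx] += params.evaporation_rate * max(iter_best_fitness, 0.0)
        np.clip(tau, 1e-12, None, out=tau)
        if iter_best_fitness > best_fitness:
            best_bits, best_fitness = iter_best_bits, iter_best_fitness
        trace.append(best_fitness)
    assert best_bits is not None
    best = evaluate_fitness(best_bits, X, y, params, _scorer=scorer)
    return AcoResult(best=best, trace=trace, n_evaluations=n_evals, pheromone=tau)


def nested_cv_auc(X: np.ndarray, y: np.ndarray, params: AcoParams) -> float:
    """Selection-honest cross-validated AUC of the whole ACO pipeline.

    The subset search itself is repeated inside each of ``params.n_folds``
    training partitions; weights are fitted on the training rows and the
    held-out rows are scored with them. The pooled held-out scores give an
    AUC free of feature-selection bias: on label-permuted data it
    concentrates at 0.5, whereas the AUC of a subset selected on the full
    data is optimistically inflated.
    """
    X = np.asarray(X, dtype=np.uint8)
    y = np.asarray(y)
    fold_of = stratified_folds(y, params.n_folds, params.seed + 1, stratified=True)
    pooled_scores = np.empty(len(y), dtype=float)
    for f in range(params.n_folds):
        train = fold_of != f
        inner = AcoParams(
            n_ants=params.n_ants,
            n_iterations=params.n_iterations,
            evaporation_rate=params.evaporation_rate,
            subset_min=params.subset_min,
            subset_max=params.subset_max,
            pheromone_init=params.pheromone_init,
            exploitation_prob=params.exploitation_prob,
            fitness_metric=params.fitness_metric,
            n_folds=params.n_folds,
            seed=params.seed + 10_000 + f,
        )
        result = run_aco_selection(X[train], y[train], inner)
        cols = np.array(result.best.selected_bits) - 1
        w = _weight_matrix(X, y, train)[cols]
        pooled_scores[~train] = X[~train][:, cols].astype(float) @ w
    if np.ptp(pooled_scores) == 0.0:
        return 0.5
    return roc_curve(pooled_scores, y).auc


def solution_summary(sol: FeatureSubsetSolution) -> dict:
    """JSON-ready report: bits, defining SMARTS, weights, cutoff, metrics."""
    from .fingerprints import key_smarts

    return {
        "selected_bits": list(sol.selected_bits),
        "smarts": {b: key_smarts(b)[0] for b in sol.selected_bits},
        "bit_weights": {b: sol.bit_weights[b] for b in sol.selected_bits},
        "cutoff": sol.cutoff,
        "fitness": sol.fitness,
        "auc": sol.roc.auc,
        "ccr": sol.ccr,
        "mcc": sol.mcc,
        "youden_j": sol.roc.youden_j,
        "degenerate": sol.degenerate,
    }
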