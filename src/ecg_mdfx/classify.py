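"""GA-optimized RBF-SVM classification and its evaluation metrics.

The classifier is a one-vs-one RBF support vector machine (LIBSVM via
scikit-learn) on the 24-dimensional multi-domain feature vectors, with
per-column z-scoring fitted on the training split. Its two
hyperparameters — penalty ``C`` in (0, 100] and kernel width ``delta``
in (0, 1000], with K(u, v) = exp(-||u-v||^2 / (2 delta^2)) — are tuned
by a binary-coded genetic algorithm whose fitness is stratified k-fold
cross-validated accuracy on the training set.

Evaluation follows the standard per-class decomposition of a 5-class
confusion matrix: sensitivity Se = TP/(TP+FN), specificity
Sp = TN/(TN+FP), positive predictivity Pp = TP/(TP+FP), and overall
accuracy Acc = (N_T - N_E)/N_T, all reported as percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .core import CLASSES


@dataclass
class SVMConfig:
    """RBF-SVM hyperparameters; one-vs-one multiclass scheme."""

    C: float = 1.0
    delta: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.C <= 100.0:
            raise ValueError("C must lie in (0, 100]")
        if not 0.0 < self.delta <= 1000.0:
            raise ValueError("delta must lie in (0, 1000]")

    @property
    def gamma(self) -> float:
        """scikit-learn gamma for K = exp(-gamma ||u-v||^2)."""
        return 1.0 / (2.0 * self.delta**2)


@dataclass
class SVMModel:
    """Fitted scaler + SVC bundle."""

    config: SVMConfig
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    svc: SVC

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.scaler_mean.shape[0]:
            raise ValueError("feature dimension mismatch")
        return (X - self.scaler_mean) / self.scaler_std


def _zscore_stats(X):
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=0)
    std = np.where(std == 0, 1.0, std)
    return mean, std


def svm_train(X, labels, config: SVMConfig) -> SVMModel:
    """Train a one-vs-one RBF-SVM on z-scored features."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if len(set(labels)) < 2:
        raise ValueError("need at least 2 classes to train")
    mean, std = _zscore_stats(X)
    svc = SVC(C=config.C, kernel="rbf", gamma=config.gamma,
              decision_function_shape="ovo")
    svc.fit((X - mean) / std, labels.astype(str))
    return SVMModel(config=config, scaler_mean=mean, scaler_std=std, svc=svc)


def predict(model: SVMModel, X) -> np.ndarray:
    """Predicted class label per feature row."""
    return model.svc.predict(model.transform(X)).astype(object)


def cv_fitness(X, labels, C: float, delta: float,
               folds: int = 5, seed: int = 0) -> float:
    """Stratified k-fold mean accuracy for one (C, delta) setting."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=object)
    _, counts = np.unique(labels.astype(str), return_counts=True)
    if folds > counts.min():
        raise ValueError(
            f"folds={folds} exceeds the smallest class count {counts.min()}"
        )
    config = SVMConfig(C=C, delta=delta)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    y = labels.astype(str)
    for tr, te in skf.split(X, y):
        model = svm_train(X[tr], labels[tr], config)
        accs.append(float(np.mean(predict(model, X[te]) == labels[te])))
    return float(np.mean(accs))


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------

@dataclass
class GAConfig:
    """Binary-coded GA settings (conventional defaults, elitist)."""

    max_iteration: int = 200
    population: int = 20
    cv_folds: int = 5
    bits_per_gene: int = 16
    crossover_rate: float = 0.7
    mutation_rate: float = 0.01
    seed: int = 0
    elitism: int = 1

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        for r in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


def _decode_gene(bits: np.ndarray, lo: float, hi: float) -> float:
    """Map a Gray-coded bit vector to (lo, hi].

    Gray decoding keeps single-bit mutations local in parameter space
    (no Hamming cliffs); the decoded value is lo + (int+1)/2^m * (hi-lo),
    half-open at lo.
    """
    v = 0
    for b in bits:  # Gray -> binary: b_i XOR-prefixed
        v = (v << 1) | ((v & 1) ^ int(b))
    return lo + (v + 1) / (1 << len(bits)) * (hi - lo)


def decode_chromosome(chrom: np.ndarray, c_range, delta_range,
                      bits_per_gene: int) -> tuple[float, float]:
    c = _decode_gene(chrom[:bits_per_gene], *c_range)
    d = _decode_gene(chrom[bits_per_gene:], *delta_range)
    return c, d


def ga_optimize(
    X,
    labels,
    ga: GAConfig,
    c_range: tuple[float, float] = (0.0, 100.0),
    delta_range: tuple[float, float] = (0.0, 1000.0),
    fitness_fn=None,
) -> tuple[float, float, list[float]]:
    """Evolve (C, delta) maximizing CV accuracy; returns the fitness trace.

    ``fitness_fn(C, delta) -> float`` may replace the default
    cross-validation fitness (useful for calibration studies). With
    elitism >= 1 the per-generation best fitness is non-decreasing.
    """
    if fitness_fn is None:
        Xa = np.asarray(X, dtype=float)
        la = np.asarray(labels, dtype=object)

        def fitness_fn(C, delta):
            return cv_fitness(Xa, la, C, delta,
                              folds=ga.cv_folds, seed=ga.seed)

    rng = np.random.default_rng(ga.seed)
    n_bits = 2 * ga.bits_per_gene
    pop = rng.integers(0, 2, size=(ga.population, n_bits), dtype=np.int8)
    cache: dict[bytes, float] = {}

    def evaluate(individual) -> float:
        key = individual.tobytes()
        if key not in cache:
            c, d = decode_chromosome(individual, c_range, delta_range,
                                     ga.bits_per_gene)
            cache[key] = float(fitness_fn(c, d))
        return cache[key]

    trace: list[float] = []
    best_chrom, best_fit = None, -np.inf
    for _ in range(ga.max_iteration):
        fits = np.array([evaluate(ind) for ind in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_chrom = pop[gen_best].copy()
        trace.append(best_fit)

        # fitness-proportional selection (uniform when degenerate)
        shifted = fits - fits.min()
        probs = (shifted / shifted.sum()) if shifted.sum() > 0 else \
            np.full(len(pop), 1.0 / len(pop))
        elite_idx = np.argsort(fits)[::-1][: ga.elitism]
        elite = pop[elite_idx].copy()
        n_children = ga.population - ga.elitism
        parents = pop[rng.choice(len(pop), size=2 * n_children, p=probs)]
        children = []
        for k in range(n_children):
            p1, p2 = parents[2 * k].copy(), parents[2 * k + 1].copy()
            if rng.random() < ga.crossover_rate:
                cut = int(rng.integers(1, n_bits))
                child = np.concatenate([p1[:cut], p2[cut:]])
            else:
                child = p1
            flip = rng.random(n_bits) < ga.mutation_rate
            child[flip] ^= 1
            children.append(child)
        pop = np.vstack([elite] + children)

    best_c, best_delta = decode_chromosome(best_chrom, c_range, delta_range,
                                           ga.bits_per_gene)
    return best_c, best_delta, trace


# ---------------------------------------------------------------------------
# Confusion matrix and metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """Counts[i, j] = true class i predicted as class j, in fixed order."""

    counts: np.ndarray
    class_order: tuple = CLASSES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square over the class order")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(true_labels, predicted_labels,
              class_order=CLASSES) -> ConfusionMatrix:
    """Count the confusion matrix in the canonical class order."""
    y_t = np.asarray(true_labels, dtype=object)
    y_p = np.asarray(predicted_labels, dtype=object)
    if len(y_t) != len(y_p):
        raise ValueError("label sequences must have equal length")
    unknown = (set(y_t) | set(y_p)) - set(class_order)
    if unknown:
        raise ValueError(f"unknown labels: {sorted(map(str, unknown))}")
    counts = _sk_confusion(y_t.astype(str), y_p.astype(str),
                           labels=list(class_order))
    return ConfusionMatrix(counts=counts, class_order=tuple(class_order))


@dataclass
class MetricsReport:
    """Per-class Se/Sp/Pp, their macro-averages, and overall accuracy (%)."""

    per_class: dict
    averages: dict
    accuracy: float
    class_order: tuple = CLASSES

    def summary(self) -> str:
        lines = [f"{'Type':>6} {'Se':>8} {'Sp':>8} {'Pp':>8}"]
        for cls in self.class_order:
            m = self.per_class[cls]
            lines.append(
                f"{cls:>6} {m['se']:8.2f} {m['sp']:8.2f} {m['pp']:8.2f}"
            )
        a = self.averages
        lines.append(
            f"{'Avg':>6} {a['se']:8.2f} {a['sp']:8.2f} {a['pp']:8.2f}"
        )
        lines.append(f"Accuracy: {self.accuracy:.2f}%")
        return "\n".join(lines)


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class Se/Sp/Pp and accuracy from the confusion counts.

    A metric with a zero denominator is reported as NaN and excluded
    from the macro-average.
    """
    counts = cm.counts
    n_t = cm.total
    if n_t == 0:
        raise ValueError("empty confusion matrix")
    per_class = {}
    for k, cls in enumerate(cm.class_order):
        tp = int(counts[k, k])
        fn = int(counts[k].sum()) - tp
        fp = int(counts[:, k].sum()) - tp
        tn = n_t - tp - fn - fp
        per_class[cls] = {
            "se": 100.0 * tp / (tp + fn) if tp + fn else float("nan"),
            "sp": 100.0 * tn / (tn + fp) if tn + fp else float("nan"),
            "pp": 100.0 * tp / (tp + fp) if tp + fp else float("nan"),
        }
    averages = {
        key: float(np.nanmean([per_class[c][key] for c in cm.class_order]))
        for key in ("se", "sp", "pp")
    }
    n_e = n_t - int(np.trace(counts))
    accuracy = 100.0 * (n_t - n_e) / n_t
    return MetricsReport(per_class=per_class, averages=averages,
                         accuracy=accuracy, class_order=cm.class_order)
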