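"""Frequency-domain beat features: db2 wavelet band statistics + LDA.

Each beat is decomposed into a 4-level db2 pyramid; the detail bands
cd1..cd4 and the level-4 approximation ca4 summarize the beat's energy
distribution across frequency octaves. Per band, four statistics —
max, min, mean, population standard deviation — give a 20-dimensional
vector (band order cd1, cd2, cd3, cd4, ca4; statistic order max, min,
mean, std). Fisher linear discriminant analysis then reduces the 20
statistics to at most ``n_classes - 1`` dimensions (4 for five beat
classes) by maximizing between-class over within-class scatter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import pywt

_BAND_ORDER = ("cd1", "cd2", "cd3", "cd4", "ca4")
_STAT_ORDER = ("max", "min", "mean", "std")


@dataclass
class BandDecomposition:
    """db2 pyramid bands of one beat."""

    ca4: np.ndarray
    cd1: np.ndarray
    cd2: np.ndarray
    cd3: np.ndarray
    cd4: np.ndarray

    def band(self, name: str) -> np.ndarray:
        return getattr(self, name)


def dwt_bands(beat, wavelet: str = "db2", levels: int = 4,
              mode: str = "symmetric") -> BandDecomposition:
    """4-level db2 decomposition into {cd1..cd4, ca4}."""
    beat = np.asarray(beat, dtype=float)
    if beat.ndim != 1 or len(beat) < 16:
        raise ValueError("beat must be 1-D with at least 16 samples")
    coeffs = pywt.wavedec(beat, wavelet, level=levels, mode=mode)
    ca4, cd4, cd3, cd2, cd1 = coeffs
    return BandDecomposition(ca4=np.asarray(ca4), cd1=np.asarray(cd1),
                             cd2=np.asarray(cd2), cd3=np.asarray(cd3),
                             cd4=np.asarray(cd4))


def band_statistics(bands: BandDecomposition) -> np.ndarray:
    """20 statistics: (cd1..cd4, ca4) x (max, min, mean, population std)."""
    out = []
    for name in _BAND_ORDER:
        c = bands.band(name)
        out.extend([c.max(), c.min(), c.mean(), c.std()])  # ddof=0
    return np.asarray(out, dtype=float)


def band_feature_names() -> list[str]:
    """Column names matching :func:`band_statistics` order."""
    return [f"{b}_{s}" for b in _BAND_ORDER for s in _STAT_ORDER]


def beat_band_features(data) -> np.ndarray:
    """Row-wise band statistics for a beat matrix."""
    X = np.asarray(getattr(data, "data", data), dtype=float)
    return np.vstack([band_statistics(dwt_bands(row)) for row in X])


# ---------------------------------------------------------------------------
# Fisher LDA
# ---------------------------------------------------------------------------

@dataclass
class LDAModel:
    """Fisher discriminant directions fitted on a labeled training set."""

    directions: np.ndarray      # (d, n_out)
    class_means: dict
    n_out: int
    grand_mean: np.ndarray
    eigenvalues: np.ndarray     # Fisher ratios along each direction


def _scatter_matrices(F, labels):
    F = np.asarray(F, dtype=float)
    labels = np.asarray(labels, dtype=object)
    classes = sorted(set(labels), key=str)
    mu = F.mean(axis=0)
    d = F.shape[1]
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    means = {}
    for cls in classes:
        Fc = F[labels == cls]
        if len(Fc) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        mc = Fc.mean(axis=0)
        means[cls] = mc
        Xc = Fc - mc
        Sw += Xc.T @ Xc
        diff = (mc - mu)[:, None]
        Sb += len(Fc) * (diff @ diff.T)
    return Sw, Sb, means, mu


def lda_fit(F, labels, n_out: int = 4) -> LDAModel:
    """Fisher LDA: directions maximizing between/within scatter ratio.

    The within-class scatter is ridge-regularized by ``1e-6 * trace``
    when numerically singular. Eigenvalue ties are resolved by the
    solver's input order.
    """
    Sw, Sb, means, mu = _scatter_matrices(F, labels)
    n_classes = len(means)
    if n_out > n_classes - 1:
        raise ValueError(
            f"n_out={n_out} exceeds n_classes - 1 = {n_classes - 1}"
        )
    d = Sw.shape[0]
    if np.linalg.matrix_rank(Sw) < d:
        Sw = Sw + 1e-6 * np.trace(Sw) / d * np.eye(d)
    evals, evecs = scipy.linalg.eigh(Sb, Sw)
    order = np.argsort(evals)[::-1][:n_out]
    return LDAModel(
        directions=evecs[:, order],
        class_means=means,
        n_out=n_out,
        grand_mean=mu,
        eigenvalues=evals[order],
    )


def lda_transform(F, model: LDAModel) -> np.ndarray:
    """Project (centered) features onto the discriminant directions."""
    F = np.asarray(F, dtype=float)
    if F.shape[1] != model.directions.shape[0]:
        raise ValueError("feature dimension does not match LDA model")
    return (F - model.grand_mean) @ model.directions


def fisher_ratio(X, labels) -> float:
    """trace(Sw^+ Sb) of a (projected) feature set — higher is better."""
    Sw, Sb, _, _ = _scatter_matrices(X, labels)
    return float(np.trace(np.linalg.pinv(Sw) @ Sb))


def combine_features(nonlinear: np.ndarray, frequency: np.ndarray) -> np.ndarray:
    """Concatenate 20 nonlinear + 4 frequency columns into the 24-dim vector."""
    nonlinear = np.asarray(nonlinear, dtype=float)
    frequency = np.asarray(frequency, dtype=float)
    if nonlinear.shape[0] != frequency.shape[0]:
        raise ValueError("row count mismatch between feature blocks")
    return np.hstack([nonlinear, frequency])
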