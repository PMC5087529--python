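"""Shared containers for the beat-classification pipeline.

The central exchange format is the :class:`BeatMatrix`: a stack of
fixed-length (250-sample), R-peak-aligned beat segments with one class
label per row. Every stage of the pipeline — denoising, nonlinear and
frequency-domain feature extraction, classification — consumes or
produces one of these.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical class order used everywhere (confusion matrices, reports).
CLASSES: tuple[str, ...] = ("N", "LBBB", "RBBB", "PVC", "APC")

#: Fixed beat segment length in samples.
BEAT_LENGTH: int = 250

#: Default sampling rate (Hz), the MIT-BIH convention.
DEFAULT_FS: float = 360.0


@dataclass
class BeatMatrix:
    """n_beats x 250 matrix of aligned beat segments with class labels.

    Parameters
    ----------
    data : ndarray, shape (n_beats, 250)
        Amplitude samples, one beat per row.
    labels : ndarray of str, shape (n_beats,)
        Class symbol per beat, drawn from :data:`CLASSES`.
    source_ids : ndarray of str, shape (n_beats,)
        Provenance strings (record name / beat index); empty strings when
        beats are synthetic.
    """

    data: np.ndarray
    labels: np.ndarray
    source_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("beat data must be 2-D (n_beats x n_samples)")
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} beats"
            )
        unknown = set(self.labels) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown class labels: {sorted(unknown)}")
        if self.source_ids is None:
            self.source_ids = np.asarray([""] * self.n_beats, dtype=object)
        else:
            self.source_ids = np.asarray(self.source_ids, dtype=object)
            if len(self.source_ids) != self.n_beats:
                raise ValueError("source_ids length mismatch")

    @property
    def n_beats(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset(self, idx) -> "BeatMatrix":
        """Row subset preserving labels and provenance."""
        idx = np.asarray(idx)
        return BeatMatrix(self.data[idx], self.labels[idx], self.source_ids[idx])


def stratified_split(
    labels, fraction: float = 0.5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Split row indices into (train, test), stratified by class.

    Each class contributes ``round(fraction * n_class)`` rows to the
    training split; assignment within a class is a seeded permutation.
    """
    labels = np.asarray(labels, dtype=object)
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in sorted(set(labels), key=lambda c: CLASSES.index(c) if c in CLASSES else 99):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        k = int(round(fraction * len(idx)))
        train.extend(idx[:k])
        test.extend(idx[k:])
    return np.sort(np.asarray(train, dtype=int)), np.sort(np.asarray(test, dtype=int))
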