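"""Reading ECG records and segmenting them into fixed-length beats.

Two on-disk dialects are supported:

* ``wfdb`` — MIT-style records: ``<base>.hea`` + ``<base>.dat`` signal
  files with a binary ``<base>.atr`` annotation stream;
* ``csv`` — a signal CSV with header ``sample,amplitude`` plus a sibling
  annotation CSV ``<base>.ann.csv`` with header ``index,symbol``.

Annotation symbols follow the MIT convention; only the five retained
beat symbols {N, L, R, V, A} are kept and mapped onto the class alphabet
{N, LBBB, RBBB, PVC, APC}. Everything else is dropped and counted in the
log.
"""

from __future__ import annotations

import csv as _csv
import logging
import os
from dataclasses import dataclass

import numpy as np

from . import _wfdb
from .core import BEAT_LENGTH, BeatMatrix

logger = logging.getLogger(__name__)

#: MIT annotation symbol -> class label for the five retained classes.
SYMBOL_MAP = {"N": "N", "L": "LBBB", "R": "RBBB", "V": "PVC", "A": "APC"}


@dataclass
class ECGRecord:
    """A single-channel ECG with per-beat fiducials and labels."""

    samples: np.ndarray
    sampling_rate: float
    r_peaks: np.ndarray
    labels: np.ndarray
    name: str = "record"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.r_peaks = np.asarray(self.r_peaks, dtype=int)
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.r_peaks) != len(self.labels):
            raise ValueError("r_peaks and labels must have equal length")
        if len(self.r_peaks) and (
            np.any(np.diff(self.r_peaks) <= 0)
            or self.r_peaks[0] < 0
            or self.r_peaks[-1] >= len(self.samples)
        ):
            raise ValueError("r_peaks must be strictly increasing and in range")


def _map_annotations(indices, symbols, name: str):
    keep_idx, keep_lab, dropped = [], [], 0
    for i, sym in zip(indices, symbols):
        cls = SYMBOL_MAP.get(sym)
        if cls is None:
            dropped += 1
        else:
            keep_idx.append(int(i))
            keep_lab.append(cls)
    if dropped:
        logger.info("%s: dropped %d beats with non-retained symbols", name, dropped)
    if not keep_idx:
        logger.warning("%s: no beats with retained symbols", name)
    return np.asarray(keep_idx, dtype=int), np.asarray(keep_lab, dtype=object)


def read_record(path: str, format: str = "csv") -> ECGRecord:
    """Read a signal + annotations into an :class:`ECGRecord`.

    For ``wfdb``, ``path`` is the record base (with or without ``.hea``);
    for ``csv``, ``path`` is the signal CSV and annotations come from the
    sibling ``<base>.ann.csv``.
    """
    if format == "wfdb":
        base = path[:-4] if path.endswith(".hea") else path
        try:
            samples, fs = _wfdb.read_signal(base)
            idx, syms = _wfdb.read_annotations(base + ".atr")
        except (OSError, ValueError, IndexError) as exc:
            raise ValueError(f"cannot parse WFDB record {base!r}: {exc}") from exc
        name = os.path.basename(base)
    elif format == "csv":
        base, _ = os.path.splitext(path)
        try:
            with open(path, newline="") as fh:
                reader = _csv.DictReader(fh)
                samples = np.asarray(
                    [float(row["amplitude"]) for row in reader], dtype=float
                )
            idx, syms = [], []
            with open(base + ".ann.csv", newline="") as fh:
                for row in _csv.DictReader(fh):
                    idx.append(int(row["index"]))
                    syms.append(row["symbol"].strip())
        except (OSError, KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"cannot parse CSV record {path!r}: {exc}") from exc
        fs = 360.0
        name = os.path.basename(base)
    else:
        raise ValueError(f"unknown format {format!r}")
    r_peaks, labels = _map_annotations(idx, syms, name)
    return ECGRecord(samples, fs, r_peaks, labels, name=name)


def segment_beats(
    record: ECGRecord,
    length: int = BEAT_LENGTH,
    pre_samples: int = 100,
) -> BeatMatrix:
    """Cut ``samples[r - pre_samples : r - pre_samples + length]`` per beat.

    Windows are half-open on 0-based indices. Beats whose window falls
    outside the signal are dropped and logged; the output row count is
    therefore at most the number of R peaks.
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    if not 0 < pre_samples < length:
        raise ValueError("pre_samples must satisfy 0 < pre_samples < length")
    n = len(record.samples)
    rows, labels, ids = [], [], []
    dropped = 0
    for k, (r, lab) in enumerate(zip(record.r_peaks, record.labels)):
        start = int(r) - pre_samples
        if start < 0 or start + length > n:
            dropped += 1
            continue
        rows.append(record.samples[start : start + length])
        labels.append(lab)
        ids.append(f"{record.name}/{k}")
    if dropped:
        logger.info("%s: dropped %d beats at signal boundaries", record.name, dropped)
    data = np.asarray(rows) if rows else np.empty((0, length))
    return BeatMatrix(data, np.asarray(labels, dtype=object),
                      np.asarray(ids, dtype=object))
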