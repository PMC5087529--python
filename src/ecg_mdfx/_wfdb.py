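"""Minimal MIT-dialect (WFDB) record and annotation I/O.

Supports the subset of the format family needed for single-channel
arrhythmia records: text ``.hea`` headers, signal formats 16 (little-
endian int16) and 212 (packed 12-bit pairs), and the standard binary
annotation stream (6-bit type code + 10-bit time increment words, with
SKIP/NUM/SUB/CHN/AUX escape codes).

Only single-signal records are handled; writing uses format 16.
"""

from __future__ import annotations

import os
import struct

import numpy as np

# MIT annotation type codes for the beat symbols we may encounter.
CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 8: "A", 9: "S",
    10: "E", 11: "J", 12: "/", 13: "Q", 38: "f", 31: "!", 34: "j",
}
SYMBOL_TO_CODE = {s: c for c, s in CODE_TO_SYMBOL.items()}

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


def read_header(hea_path: str) -> dict:
    """Parse a single-signal header file."""
    with open(hea_path) as fh:
        lines = [ln.strip() for ln in fh
                 if ln.strip() and not ln.startswith("#")]
    rec_fields = lines[0].split()
    name = rec_fields[0]
    n_sig = int(rec_fields[1])
    fs = float(rec_fields[2]) if len(rec_fields) > 2 else 250.0
    n_samp = int(rec_fields[3]) if len(rec_fields) > 3 else 0
    if n_sig != 1:
        raise ValueError(f"only single-signal records supported, got {n_sig}")
    sig = lines[1].split()
    fname, fmt = sig[0], sig[1].split("x")[0]
    gain, baseline = 200.0, None
    if len(sig) > 2:
        g = sig[2].split("/")[0]
        if "(" in g:
            g, base = g.split("(")
            baseline = int(base.rstrip(")"))
        gain = float(g) if float(g) != 0 else 200.0
    adc_zero = int(sig[4]) if len(sig) > 4 else 0
    if baseline is None:
        baseline = adc_zero
    return {
        "name": name, "fs": fs, "n_samp": n_samp, "dat_file": fname,
        "fmt": int(fmt), "gain": gain, "baseline": baseline,
    }


def _read_fmt16(path: str, n_samp: int) -> np.ndarray:
    raw = np.fromfile(path, dtype="<i2")
    return raw[:n_samp] if n_samp else raw


def _read_fmt212(path: str, n_samp: int) -> np.ndarray:
    raw = np.fromfile(path, dtype=np.uint8)
    n_pairs = len(raw) // 3
    raw = raw[: n_pairs * 3].reshape(-1, 3).astype(np.int32)
    first = raw[:, 0] | ((raw[:, 1] & 0x0F) << 8)
    second = raw[:, 2] | ((raw[:, 1] & 0xF0) << 4)
    out = np.empty(2 * n_pairs, dtype=np.int32)
    out[0::2], out[1::2] = first, second
    out = np.where(out > 2047, out - 4096, out)  # 12-bit two's complement
    return out[:n_samp] if n_samp else out


def read_signal(record_base: str) -> tuple[np.ndarray, float]:
    """Read samples (physical units) and sampling rate for a record.

    ``record_base`` is the path without extension; ``<base>.hea`` and the
    data file it names must exist side by side.
    """
    hdr = read_header(record_base + ".hea")
    dat = os.path.join(os.path.dirname(record_base), hdr["dat_file"])
    if hdr["fmt"] == 16:
        adc = _read_fmt16(dat, hdr["n_samp"])
    elif hdr["fmt"] == 212:
        adc = _read_fmt212(dat, hdr["n_samp"])
    else:
        raise ValueError(f"unsupported signal format {hdr['fmt']}")
    phys = (adc.astype(float) - hdr["baseline"]) / hdr["gain"]
    return phys, hdr["fs"]


def read_annotations(ann_path: str) -> tuple[np.ndarray, list[str]]:
    """Read (sample_indices, symbols) from a binary annotation file."""
    data = np.fromfile(ann_path, dtype=np.uint8)
    times, symbols = [], []
    t = 0
    i = 0
    while i + 1 < len(data):
        word = int(data[i]) | (int(data[i + 1]) << 8)
        i += 2
        code = word >> 10
        delta = word & 0x3FF
        if code == 0 and delta == 0:  # EOF
            break
        if code == _SKIP:
            hi = int(data[i]) | (int(data[i + 1]) << 8)
            lo = int(data[i + 2]) | (int(data[i + 3]) << 8)
            i += 4
            interval = (hi << 16) | lo
            if interval >= 1 << 31:
                interval -= 1 << 32
            t += interval
        elif code in (_NUM, _SUB, _CHN):
            continue  # payload is in `delta`; no time advance
        elif code == _AUX:
            n = delta
            i += n + (n & 1)  # aux string, padded to even length
        else:
            t += delta
            times.append(t)
            symbols.append(CODE_TO_SYMBOL.get(code, "?"))
    return np.asarray(times, dtype=int), symbols


def write_record(
    record_base: str,
    samples: np.ndarray,
    fs: float,
    gain: float = 200.0,
) -> None:
    """Write ``<base>.hea`` + ``<base>.dat`` in format 16."""
    samples = np.asarray(samples, dtype=float)
    adc = np.clip(np.round(samples * gain), -32768, 32767).astype("<i2")
    name = os.path.basename(record_base)
    with open(record_base + ".hea", "w") as fh:
        fh.write(f"{name} 1 {fs:g} {len(adc)}\n")
        fh.write(f"{name}.dat 16 {gain:g}(0)/mV 16 0 {int(adc[0]) if len(adc) else 0} 0 0 ECG\n")
    adc.tofile(record_base + ".dat")


def write_annotations(
    ann_path: str, sample_indices: np.ndarray, symbols: list[str]
) -> None:
    """Write a binary annotation stream (beat symbols only)."""
    order = np.argsort(sample_indices)
    out = bytearray()
    prev = 0
    for k in order:
        t, sym = int(sample_indices[k]), symbols[k]
        code = SYMBOL_TO_CODE.get(sym)
        if code is None:
            raise ValueError(f"no MIT code for symbol {sym!r}")
        delta = t - prev
        if delta >= 1 << 10:
            out += struct.pack("<H", (_SKIP << 10))
            out += struct.pack("<HH", (delta >> 16) & 0xFFFF, delta & 0xFFFF)
            delta = 0
        out += struct.pack("<H", (code << 10) | delta)
        prev = t
    out += struct.pack("<H", 0)  # EOF
    with open(ann_path, "wb") as fh:
        fh.write(bytes(out))
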