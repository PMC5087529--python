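"""Synthetic five-class ECG beat generator with a controllable noise model.

Templates are piecewise Gaussian-bump syntheses of P-QRS-T morphology:
a beat is a sum of Gaussian deflections placed relative to the R peak.
The five classes differ the way their clinical archetypes do —

* ``N``     narrow QRS, normal P and upright T;
* ``LBBB``  wide, notched, monophasic-positive QRS, discordant (negative) T;
* ``RBBB``  rSR' double-peaked QRS with a deep S and inverted T;
* ``PVC``   no P wave, very wide high-amplitude QRS, deep discordant T;
* ``APC``   early ectopic P close to a narrow, slightly smaller QRS.

Noise emulates the two contaminants of ambulatory recordings: additive
white Gaussian noise (electromyographic interference) and a 50 Hz
sinusoid (power-line interference) with per-beat random phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BEAT_LENGTH, CLASSES, DEFAULT_FS, BeatMatrix

#: Sample index of the R peak within each 250-sample beat.
R_OFFSET = 100


@dataclass
class JitterParams:
    """Per-class beat-to-beat variability, as dimensionless fractions.

    ``amp_sd``/``width_sd`` scale all bump amplitudes/widths by a factor
    drawn from N(1, sd^2); ``latency_sd_s`` shifts the whole beat in time
    (seconds, s.d. of a zero-mean normal).
    """

    amp_sd: float = 0.05
    width_sd: float = 0.05
    latency_sd_s: float = 0.006


@dataclass
class BeatTemplate:
    """Analytic beat morphology for one class.

    ``bumps`` is a list of ``(center_s, width_s, amplitude)`` Gaussian
    deflections with centers in seconds relative to the R peak.
    """

    class_label: str
    bumps: list[tuple[float, float, float]]
    jitter: JitterParams = field(default_factory=JitterParams)
    sampling_rate: float = DEFAULT_FS
    length: int = BEAT_LENGTH

    def __post_init__(self) -> None:
        if self.class_label not in CLASSES:
            raise ValueError(f"unknown class {self.class_label!r}")

    def waveform(
        self,
        amp_scale: float = 1.0,
        width_scale: float = 1.0,
        latency_s: float = 0.0,
    ) -> np.ndarray:
        """Evaluate the template on its sample grid, optionally jittered."""
        t = (np.arange(self.length) - R_OFFSET) / self.sampling_rate - latency_s
        y = np.zeros(self.length)
        for center, width, amp in self.bumps:
            w = width * width_scale
            y += amp * amp_scale * np.exp(-0.5 * ((t - center) / w) ** 2)
        return y


def default_templates() -> dict[str, BeatTemplate]:
    """The five built-in class templates, keyed by class symbol."""
    bumps = {
        # (center_s rel. R, width_s, amplitude mV-scale)
        "N": [
            (-0.170, 0.025, 0.15),   # P
            (-0.025, 0.010, -0.12),  # Q
            (0.000, 0.012, 1.00),    # R
            (0.025, 0.010, -0.20),   # S
            (0.160, 0.060, 0.30),    # T
        ],
        "LBBB": [
            (-0.175, 0.025, 0.12),   # P
            (-0.012, 0.030, 0.80),   # broad notched R (two lobes)
            (0.038, 0.030, 0.65),
            (0.195, 0.070, -0.25),   # discordant T
        ],
        "RBBB": [
            (-0.170, 0.025, 0.13),   # P
            (-0.022, 0.010, 0.30),   # r
            (0.004, 0.012, -0.35),   # deep S
            (0.042, 0.022, 0.85),    # R'
            (0.170, 0.060, -0.20),   # inverted T
        ],
        "PVC": [
            (-0.045, 0.022, -0.35),  # no P; wide bizarre QRS
            (-0.005, 0.038, 1.20),
            (0.055, 0.028, -0.50),
            (0.210, 0.080, -0.45),   # deep discordant T
        ],
        "APC": [
            (-0.085, 0.018, 0.30),   # early ectopic P, close to QRS
            (-0.018, 0.008, -0.10),
            (0.000, 0.009, 0.70),
            (0.020, 0.009, -0.18),
            (0.125, 0.045, 0.18),
        ],
    }
    return {cls: BeatTemplate(cls, bumps[cls]) for cls in CLASSES}


@dataclass
class NoiseSpec:
    """Additive noise model: white Gaussian + fixed-frequency sinusoid."""

    white_sigma: float = 0.0
    powerline_amp: float = 0.0
    powerline_freq: float = 50.0
    sampling_rate: float = DEFAULT_FS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.white_sigma < 0:
            raise ValueError("white_sigma must be >= 0")
        if self.powerline_amp < 0:
            raise ValueError("powerline_amp must be >= 0")
        if self.sampling_rate <= 2 * self.powerline_freq:
            raise ValueError(
                "sampling_rate must exceed twice the power-line frequency"
            )


def generate_beats(
    n_per_class: int,
    templates: dict[str, BeatTemplate] | None = None,
    seed: int = 0,
) -> BeatMatrix:
    """Generate ``5 * n_per_class`` labeled, jittered, noise-free beats.

    Beats are grouped by class in canonical order. The same seed yields
    bitwise-identical output.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    templates = templates if templates is not None else default_templates()
    missing = set(CLASSES) - set(templates)
    if missing:
        raise ValueError(f"missing templates for classes: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    rows, labels, ids = [], [], []
    for cls in CLASSES:
        tpl = templates[cls]
        j = tpl.jitter
        for i in range(n_per_class):
            amp = rng.normal(1.0, j.amp_sd) if j.amp_sd > 0 else 1.0
            wid = rng.normal(1.0, j.width_sd) if j.width_sd > 0 else 1.0
            lat = rng.normal(0.0, j.latency_sd_s) if j.latency_sd_s > 0 else 0.0
            # keep jitter factors physical
            amp = float(np.clip(amp, 0.5, 1.5))
            wid = float(np.clip(wid, 0.6, 1.4))
            rows.append(tpl.waveform(amp, wid, lat))
            labels.append(cls)
            ids.append(f"synth/{cls}/{i}")
    return BeatMatrix(np.asarray(rows), np.asarray(labels, dtype=object),
                      np.asarray(ids, dtype=object))


def add_noise(beats: BeatMatrix, spec: NoiseSpec) -> BeatMatrix:
    """Add white + power-line noise to every beat.

    The sinusoid phase is randomized per beat from the seeded RNG, so
    the interference is not phase-locked across beats.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = beats.data.shape
    out = beats.data.copy()
    if spec.white_sigma > 0:
        out += rng.normal(0.0, spec.white_sigma, size=(n, m))
    if spec.powerline_amp > 0:
        t = np.arange(m) / spec.sampling_rate
        phases = rng.uniform(0.0, 2 * np.pi, size=n)
        out += spec.powerline_amp * np.sin(
            2 * np.pi * spec.powerline_freq * t[None, :] + phases[:, None]
        )
    return BeatMatrix(out, beats.labels.copy(), beats.source_ids.copy())


def noise_spec_for_snr(
    beats: BeatMatrix,
    snr_db: float,
    seed: int = 0,
    powerline_fraction: float = 0.5,
    sampling_rate: float = DEFAULT_FS,
) -> NoiseSpec:
    """Build a :class:`NoiseSpec` targeting a given SNR over a beat set.

    Total noise power (per sample) is set to the mean per-sample beat
    power divided by ``10^(snr_db/10)`` and split between the white
    component and the 50 Hz sinusoid (a sinusoid of amplitude A carries
    power A^2/2).
    """
    if not 0.0 <= powerline_fraction <= 1.0:
        raise ValueError("powerline_fraction must be in [0, 1]")
    p_sig = float(np.mean(beats.data**2))
    p_noise = p_sig / 10.0 ** (snr_db / 10.0)
    white_sigma = float(np.sqrt(p_noise * (1.0 - powerline_fraction)))
    powerline_amp = float(np.sqrt(2.0 * p_noise * powerline_fraction))
    return NoiseSpec(
        white_sigma=white_sigma,
        powerline_amp=powerline_amp,
        sampling_rate=sampling_rate,
        seed=seed,
    )
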