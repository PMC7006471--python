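"""Synthetic motor-imagery neurofeedback sessions.

Generates sessions with the statistical structure the model assumes:
eight alternating 20 s rest / 20 s motor-imagery blocks (320 s total),
EEG whose alpha/beta oscillators over a C3-like channel desynchronize
during imagery (event-related desynchronization), NF scores produced as
<X, alpha*> from a known sparse ground-truth pattern plus Gaussian
noise, and HRF-delayed 1 Hz fMRI-like block responses.  Everything is
reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .design import (
    DesignTensor,
    EEGRecording,
    SCORE_RATE_HZ,
    hrf_kernel,
)
from .scores import NFScoreSeries

__all__ = [
    "Oscillator",
    "DEFAULT_GROUND_TRUTH",
    "DEFAULT_ELECTRODES",
    "SimulationConfig",
    "simulate_block_design",
    "simulate_eeg",
    "simulate_scores_from_pattern",
    "simulate_fmri_scores",
    "pattern_from_cells",
]

#: Reduced 10-20 montage: C3 with its four Laplacian neighbours plus a few
#: contralateral/midline channels, enough to exercise spatial selection.
DEFAULT_ELECTRODES: tuple[str, ...] = (
    "C3", "FC3", "CP3", "C1", "C5", "Cz", "C4", "Pz",
)


@dataclass(frozen=True)
class Oscillator:
    """A band-limited rhythm on one channel.

    ``task_modulation_depth`` scales the amplitude down by that fraction
    during task blocks (depth 0.5 halves the amplitude, i.e. quarters the
    band power — an ERD-like effect).  ``amplitude_fluct_sd`` adds slow
    spontaneous waxing and waning of the rhythm's envelope (relative
    standard deviation, correlation time ``fluct_corr_s``), independent
    across oscillators as in resting EEG.
    """

    channel: str
    center_hz: float
    amplitude: float = 5.0  # microvolts
    task_modulation_depth: float = 0.0
    amplitude_fluct_sd: float = 0.5
    fluct_corr_s: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.task_modulation_depth <= 1.0:
            raise ValueError("task_modulation_depth must lie in [0, 1]")
        if self.amplitude_fluct_sd < 0:
            raise ValueError("amplitude_fluct_sd must be non-negative")


def _default_oscillators() -> tuple[Oscillator, ...]:
    # alpha and low-beta rhythms over the sensorimotor channels, with the
    # strongest task modulation on C3 (contralateral to right-hand imagery)
    return (
        Oscillator("C3", 10.0, amplitude=5.0, task_modulation_depth=0.5),
        Oscillator("C3", 20.0, amplitude=2.5, task_modulation_depth=0.4),
        Oscillator("C1", 10.0, amplitude=3.0, task_modulation_depth=0.3),
        Oscillator("FC3", 10.0, amplitude=3.0, task_modulation_depth=0.2),
        Oscillator("CP3", 12.0, amplitude=3.0, task_modulation_depth=0.2),
        Oscillator("C4", 10.0, amplitude=4.0, task_modulation_depth=0.0),
        Oscillator("Cz", 10.0, amplitude=3.0, task_modulation_depth=0.1),
        Oscillator("Pz", 10.0, amplitude=3.0, task_modulation_depth=0.0),
    )


#: Default sparse ground truth for parameter-recovery studies: five cells
#: on five distinct (electrode, delay) rows, spanning the raw and delayed
#: blocks, with weights sized so each row contributes comparable signal
#: (the low-amplitude rhythms carry larger weights).
DEFAULT_GROUND_TRUTH: tuple[tuple[str, int, int, float], ...] = (
    ("C3", 0, 1, 2.0),
    ("C1", 0, 1, -4.0),
    ("FC3", 3, 1, 2.0),
    ("CP3", 4, 2, 2.0),
    ("C4", 0, 1, 2.5),
)


@dataclass
class SimulationConfig:
    n_blocks: int = 8
    rest_s: float = 20.0
    task_s: float = 20.0
    srate: float = 250.0
    electrodes: tuple[str, ...] = DEFAULT_ELECTRODES
    oscillators: tuple[Oscillator, ...] = field(default_factory=_default_oscillators)
    noise_sd: float = 1.0  # microvolts of white sensor noise per channel
    ground_truth: tuple[tuple[str, int, int, float], ...] = DEFAULT_GROUND_TRUTH
    score_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rest_s <= 0 or self.task_s <= 0:
            raise ValueError("block durations must be positive")
        unknown = [o.channel for o in self.oscillators
                   if o.channel not in self.electrodes]
        if unknown:
            raise ValueError(f"oscillator channels not in montage: {unknown}")

    @property
    def duration_s(self) -> float:
        return self.n_blocks * (self.rest_s + self.task_s)


def simulate_block_design(cfg: SimulationConfig) -> np.ndarray:
    """Boolean task indicator on the 4 Hz score grid, rest first.

    Sample i covers the interval ending at (i + 1) / 4 s, matching the
    design-tensor grid convention.
    """
    n = int(round(cfg.duration_s * SCORE_RATE_HZ))
    t_end = np.arange(1, n + 1) / SCORE_RATE_HZ
    phase = np.mod(t_end - 1e-9, cfg.rest_s + cfg.task_s)
    return phase >= cfg.rest_s


def _task_at_samples(cfg: SimulationConfig, n_samples: int) -> np.ndarray:
    t = np.arange(n_samples) / cfg.srate
    phase = np.mod(t, cfg.rest_s + cfg.task_s)
    return phase >= cfg.rest_s


def simulate_eeg(cfg: SimulationConfig) -> EEGRecording:
    """EEG with task-modulated oscillators plus white sensor noise."""
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.srate))
    t = np.arange(n) / cfg.srate
    task = _task_at_samples(cfg, n).astype(float)
    data = rng.normal(0.0, cfg.noise_sd, size=(len(cfg.electrodes), n))
    chan_index = {name: i for i, name in enumerate(cfg.electrodes)}
    for osc in cfg.oscillators:
        phase = rng.uniform(0, 2 * np.pi)
        envelope = osc.amplitude * (1.0 - osc.task_modulation_depth * task)
        if osc.amplitude_fluct_sd > 0:
            fluct = gaussian_filter1d(
                rng.standard_normal(n), osc.fluct_corr_s * cfg.srate
            )
            fluct /= fluct.std()
            envelope = envelope * np.clip(
                1.0 + osc.amplitude_fluct_sd * fluct, 0.0, None
            )
        data[chan_index[osc.channel]] += envelope * np.sin(
            2 * np.pi * osc.center_hz * t + phase
        )
    return EEGRecording(data=data, srate=cfg.srate,
                        channel_names=list(cfg.electrodes))


def pattern_from_cells(
    cells: list[tuple[str, int, int, float]],
    feature_labels: list[tuple[str, int]],
    n_bands: int,
) -> np.ndarray:
    """Build a sparse ground-truth alpha* from (electrode, delay, band, weight)."""
    alpha = np.zeros((len(feature_labels), n_bands))
    index = {lab: i for i, lab in enumerate(feature_labels)}
    for electrode, delay, band, weight in cells:
        key = (electrode, delay)
        if key not in index:
            raise KeyError(f"feature {key} not in design labels")
        if not 0 <= band < n_bands:
            raise IndexError(f"band index {band} out of range")
        alpha[index[key], band] = weight
    return alpha


def simulate_scores_from_pattern(
    xc: DesignTensor,
    alpha_star: np.ndarray,
    score_noise_sd: float = 0.0,
    seed: int = 0,
) -> NFScoreSeries:
    """Scores y(t) = <Xc(t), alpha*> + Gaussian noise."""
    alpha_star = np.asarray(alpha_star, dtype=float)
    if xc.values.shape[1:] != alpha_star.shape:
        raise ValueError(
            f"pattern shape {alpha_star.shape} does not match design "
            f"{xc.values.shape[1:]}"
        )
    rng = np.random.default_rng(seed)
    clean = np.einsum("tmb,mb->t", xc.values, alpha_star)
    noisy = clean + rng.normal(0.0, score_noise_sd, size=len(clean))
    return NFScoreSeries(values=noisy, kind="c", times=xc.times)


def simulate_fmri_scores(
    task: np.ndarray,
    kernel: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """HRF-delayed block response at 1 Hz, emulating an NF-fMRI score.

    ``task`` is the 4 Hz indicator; it is convolved with the kernel
    (default peak 4 s), downsampled to 1 Hz, and Gaussian noise is added.
    """
    task = np.asarray(task, dtype=float)
    if kernel is None:
        kernel = hrf_kernel(4.0)
    kernel = np.asarray(kernel, dtype=float)
    if kernel.size == 0:
        raise ValueError("empty HRF kernel")
    rng = np.random.default_rng(seed)
    bold = np.convolve(task, kernel)[: len(task)]
    step = int(round(SCORE_RATE_HZ))
    y_1hz = bold[step - 1 :: step]
    return y_1hz + rng.normal(0.0, noise_sd, size=len(y_1hz))
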