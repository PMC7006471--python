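"""Structured time-frequency-delay design tensors from multichannel EEG.

The model's features are sliding-window band powers per electrode
(the zero-delay block ``X0``), plus copies of that block convolved with
hemodynamic response kernels peaking at 3, 4 and 5 s (``X3``, ``X4``,
``X5``).  Concatenated along the feature axis these form the full design
tensor ``Xc`` with ``M = 4 * E`` rows per time point, or the delayed-only
tensor ``Xd`` with ``M = 3 * E``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

__all__ = [
    "EEGRecording",
    "FrequencyBandSet",
    "DesignTensor",
    "OutlierStats",
    "build_frequency_bands",
    "sliding_band_power",
    "hrf_kernel",
    "convolve_design",
    "assemble_design",
    "restrict_active_set",
    "clip_outliers",
    "drop_bad_samples",
    "DEFAULT_ACTIVE_SET",
]

SCORE_RATE_HZ = 4.0  # the neurofeedback score grid

#: Default 28-electrode active set used inside the MR scanner: the outer
#: ring (prone to contact noise against the scanner bed) is dropped and the
#: three central lines plus a few midline frontal/posterior channels are
#: kept.  The exact membership is a configurable choice, not a contract.
DEFAULT_ACTIVE_SET: tuple[str, ...] = (
    "F3", "Fz", "F4",
    "FC5", "FC3", "FC1", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
    "P1", "P3", "Pz", "P2", "P4",
)


@dataclass
class EEGRecording:
    """Multichannel EEG: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    srate: float
    channel_names: list[str]
    bad_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        if self.srate <= 0:
            raise ValueError(f"srate must be positive, got {self.srate}")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if self.bad_mask is not None:
            self.bad_mask = np.asarray(self.bad_mask, dtype=bool)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.srate

    def pick(self, names: Sequence[str]) -> "EEGRecording":
        """Return a copy restricted to ``names`` (in recording order)."""
        missing = [n for n in names if n not in self.channel_names]
        if missing:
            raise KeyError(f"channels not in recording: {missing}")
        keep = [i for i, n in enumerate(self.channel_names) if n in set(names)]
        return EEGRecording(
            data=self.data[keep],
            srate=self.srate,
            channel_names=[self.channel_names[i] for i in keep],
            bad_mask=self.bad_mask,
        )


@dataclass(frozen=True)
class FrequencyBandSet:
    """Ordered, possibly overlapping ``(low, high)`` frequency bands in Hz."""

    bands: tuple[tuple[float, float], ...]
    width_hz: float
    overlap_hz: float

    def __post_init__(self) -> None:
        for low, high in self.bands:
            if not np.isclose(high - low, self.width_hz):
                raise ValueError(
                    f"band ({low}, {high}) does not have width {self.width_hz}"
                )

    def __len__(self) -> int:
        return len(self.bands)

    @property
    def b_min(self) -> float:
        return self.bands[0][0]

    @property
    def b_max(self) -> float:
        return self.bands[-1][1]

    @classmethod
    def single(cls, low: float, high: float) -> "FrequencyBandSet":
        """A one-band set, e.g. the broad [8, 30] Hz feedback band."""
        return cls(bands=((low, high),), width_hz=high - low, overlap_hz=0.0)


@dataclass
class DesignTensor:
    """T x M x B array of (delayed) band powers on the 4 Hz score grid.

    ``feature_labels`` pairs each of the M feature rows with its
    ``(electrode, delay_s)`` origin; ``delay_s`` is 0 for raw band power
    and 3/4/5 for the HRF-convolved copies.
    """

    values: np.ndarray
    times: np.ndarray
    feature_labels: list[tuple[str, int]]
    band_set: FrequencyBandSet
    mode: str = "x0_only"
    n_prefix: int = 0  # leading rows whose window was shorter than window_s

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be T x M x B")
        T, M, B = self.values.shape
        if len(self.times) != T:
            raise ValueError("times length must equal T")
        if len(self.feature_labels) != M:
            raise ValueError("feature_labels length must equal M")
        if B != len(self.band_set):
            raise ValueError("band axis must match the band set")
        if self.mode not in ("full", "delayed_only", "x0_only"):
            raise ValueError(f"unknown design mode {self.mode!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_times(self) -> int:
        return self.values.shape[0]

    @property
    def delays(self) -> list[int]:
        seen: list[int] = []
        for _, d in self.feature_labels:
            if d not in seen:
                seen.append(d)
        return seen

    @property
    def electrodes(self) -> list[str]:
        seen: list[str] = []
        for e, _ in self.feature_labels:
            if e not in seen:
                seen.append(e)
        return seen

    def block(self, delay_s: int) -> np.ndarray:
        """View of the T x E x B sub-block for one delay."""
        rows = [i for i, (_, d) in enumerate(self.feature_labels) if d == delay_s]
        if not rows:
            raise KeyError(f"no features with delay {delay_s}")
        return self.values[:, rows, :]


def build_frequency_bands(
    b_min: float, b_max: float, width: float = 3.0, overlap: float = 1.0
) -> FrequencyBandSet:
    """Enumerate bands [b_min + i*step, ... + width] while they fit in b_max.

    ``step = width - overlap``.  With the defaults (8, 30, 3, 1) this gives
    ten bands, [8, 11] through [26, 29], covering the alpha and beta range.
    """
    if overlap < 0 or width <= overlap:
        raise ValueError(
            f"need width > overlap >= 0, got width={width}, overlap={overlap}"
        )
    if b_max < b_min + width:
        raise ValueError(f"no band of width {width} fits in [{b_min}, {b_max}]")
    step = width - overlap
    bands = []
    i = 0
    while b_min + i * step + width <= b_max + 1e-9:
        low = b_min + i * step
        bands.append((low, low + width))
        i += 1
    return FrequencyBandSet(bands=tuple(bands), width_hz=width, overlap_hz=overlap)


def _window_band_power(
    windows: np.ndarray, srate: float, band_set: FrequencyBandSet
) -> np.ndarray:
    """Band powers of Hamming-tapered periodograms, windows on last axis.

    Power spectral density scaling; band power is the mean PSD over the FFT
    bins whose centre frequency lies inside [low, high] (inclusive).
    """
    n = windows.shape[-1]
    freqs, pxx = sps.periodogram(
        windows, fs=srate, window="hamming", detrend=False, scaling="density",
        axis=-1,
    )
    out = np.empty(windows.shape[:-1] + (len(band_set),))
    for j, (low, high) in enumerate(band_set.bands):
        mask = (freqs >= low - 1e-12) & (freqs <= high + 1e-12)
        out[..., j] = pxx[..., mask].mean(axis=-1) if mask.any() else 0.0
    return out


def sliding_band_power(
    rec: EEGRecording,
    band_set: FrequencyBandSet,
    window_s: float = 2.0,
    shift_s: float = 0.25,
) -> DesignTensor:
    """Delay-0 design block X0: past-window band power on the 4 Hz grid.

    One output row per ``shift_s`` over the whole session (a 320 s session
    yields T = 1280 rows).  Row ``i`` summarises the window of the signal
    ending at ``(i + 1) * shift_s`` and extending ``window_s`` into the
    past; the first few rows, where the session is younger than
    ``window_s``, use the available prefix with the same Hamming taper and
    are counted in ``n_prefix``.
    """
    if rec.srate <= 2.0 * band_set.b_max:
        raise ValueError(
            f"srate {rec.srate} Hz too low for bands up to {band_set.b_max} Hz"
        )
    if rec.duration_s < window_s:
        raise ValueError(
            f"recording of {rec.duration_s:.2f}s shorter than the "
            f"{window_s}s analysis window"
        )
    fs = rec.srate
    n_out = int(round(rec.duration_s / shift_s))
    win = int(round(window_s * fs))
    ends = np.rint((np.arange(1, n_out + 1)) * shift_s * fs).astype(int)
    ends = np.minimum(ends, rec.n_samples)
    starts = np.maximum(ends - win, 0)
    full = ends - starts == win
    n_prefix = int(np.sum(~full))

    E, B = rec.n_channels, len(band_set)
    values = np.zeros((n_out, E, B))
    # full windows in one vectorized periodogram call per channel
    if full.any():
        idx = starts[full][:, None] + np.arange(win)[None, :]
        for e in range(E):
            values[full, e, :] = _window_band_power(rec.data[e][idx], fs, band_set)
    # short prefix windows one by one (their FFT lengths differ)
    for i in np.nonzero(~full)[0]:
        seg = rec.data[:, starts[i]:ends[i]]
        if seg.shape[1] < 2:
            continue  # sub-2-sample prefix carries no spectral content
        values[i] = _window_band_power(seg, fs, band_set)

    times = np.arange(1, n_out + 1) * shift_s
    labels = [(name, 0) for name in rec.channel_names]
    return DesignTensor(
        values=values,
        times=times,
        feature_labels=labels,
        band_set=band_set,
        mode="x0_only",
        n_prefix=n_prefix,
    )


def hrf_kernel(
    peak_s: float,
    srate: float = SCORE_RATE_HZ,
    duration_s: float = 32.0,
    undershoot_delay_s: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Causal double-gamma hemodynamic response kernel, peak-normalized.

    Response gamma (unit dispersion, mode at ``peak_s``) minus a scaled
    undershoot gamma; sampled on the score grid over ``duration_s``.
    """
    if peak_s <= 0:
        raise ValueError(f"peak_s must be positive, got {peak_s}")
    t = np.arange(0.0, duration_s + 0.5 / srate, 1.0 / srate)
    # gamma pdf with scale 1 has its mode at shape - 1
    response = spstats.gamma.pdf(t, peak_s + 1.0)
    undershoot = spstats.gamma.pdf(t, undershoot_delay_s + 1.0)
    kernel = response - undershoot_ratio * undershoot
    return kernel / kernel.max()


def convolve_design(x0: DesignTensor, kernel: np.ndarray, delay_s: int = 0) -> DesignTensor:
    """Causal temporal convolution of a delay-0 block with an HRF kernel.

    Output at time t depends only on inputs at times <= t and is truncated
    to the input length.  ``delay_s`` labels the resulting block.
    """
    kernel = np.asarray(kernel, dtype=float)
    if kernel.size == 0:
        raise ValueError("empty convolution kernel")
    if any(d != 0 for _, d in x0.feature_labels):
        raise ValueError("convolve_design expects a delay-0 (X0) block")
    T = x0.n_times
    out = sps.fftconvolve(x0.values, kernel[:, None, None], axes=0)[:T]
    labels = [(e, delay_s) for e, _ in x0.feature_labels]
    return replace(x0, values=out, feature_labels=labels)


def assemble_design(
    x0: DesignTensor,
    delays: Sequence[int] = (3, 4, 5),
    mode: str = "full",
    hrf_kwargs: dict | None = None,
) -> DesignTensor:
    """Concatenate X0 and/or its HRF-delayed copies along the feature axis.

    ``full`` -> [X0; X3; X4; X5] (M = 4E); ``delayed_only`` -> [X3; X4; X5]
    (M = 3E); ``x0_only`` -> X0 unchanged (M = E).
    """
    if mode not in ("full", "delayed_only", "x0_only"):
        raise ValueError(f"unknown design mode {mode!r}")
    if mode == "x0_only":
        return replace(x0, mode="x0_only")
    if not delays:
        raise ValueError("delays must be non-empty unless mode='x0_only'")
    srate = 1.0 / float(np.diff(x0.times).mean())
    kw = hrf_kwargs or {}
    blocks = [] if mode == "delayed_only" else [x0]
    for d in delays:
        blocks.append(convolve_design(x0, hrf_kernel(d, srate=srate, **kw), delay_s=d))
    values = np.concatenate([b.values for b in blocks], axis=1)
    labels = [lab for b in blocks for lab in b.feature_labels]
    return replace(x0, values=values, feature_labels=labels, mode=mode)


def restrict_active_set(x: DesignTensor, keep: Sequence[str]) -> DesignTensor:
    """Keep only the listed electrodes, consistently across delay blocks."""
    available = set(e for e, _ in x.feature_labels)
    unknown = [e for e in keep if e not in available]
    if unknown:
        raise KeyError(f"electrodes not in design: {unknown}")
    keep_set = set(keep)
    rows = [i for i, (e, _) in enumerate(x.feature_labels) if e in keep_set]
    return replace(
        x,
        values=x.values[:, rows, :],
        feature_labels=[x.feature_labels[i] for i in rows],
    )


@dataclass(frozen=True)
class OutlierStats:
    """Per-(feature, band) clipping statistics from a learning session."""

    mean: np.ndarray
    std: np.ndarray
    k: float


def clip_outliers(
    x: DesignTensor, k: float = 3.0, stats: OutlierStats | None = None
) -> tuple[DesignTensor, OutlierStats]:
    """Threshold each column to mean +/- k*std.

    Statistics are computed over the time axis of ``x`` unless ``stats``
    from a learning session is supplied, in which case those are reused
    (test sessions must not contribute to them).  Returns the clipped
    tensor and the statistics used.
    """
    if stats is None:
        if k <= 0:
            raise ValueError(f"k must be positive, got {k}")
        mean = x.values.mean(axis=0)
        std = x.values.std(axis=0)
        stats = OutlierStats(mean=mean, std=std, k=float(k))
    lo = stats.mean - stats.k * stats.std
    hi = stats.mean + stats.k * stats.std
    return replace(x, values=np.clip(x.values, lo, hi)), stats


def drop_bad_samples(x: DesignTensor, y, bad_mask: np.ndarray):
    """Remove annotated-bad time points from the design and its scores.

    Row pairing and temporal order are preserved.  ``y`` is an
    ``NFScoreSeries``; both outputs keep only the rows where the mask is
    False.
    """
    bad_mask = np.asarray(bad_mask, dtype=bool)
    if bad_mask.shape[0] != x.n_times:
        raise ValueError(
            f"mask length {bad_mask.shape[0]} != design length {x.n_times}"
        )
    if bad_mask.all():
        raise ValueError("all samples are marked bad; nothing left to fit")
    good = ~bad_mask
    x_out = replace(x, values=x.values[good], times=x.times[good])
    y_out = y.replace(values=np.asarray(y.values)[good], times=np.asarray(y.times)[good])
    return x_out, y_out
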