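"""Reference neurofeedback score series.

The EEG score ``y_e`` is minus the [8-30] Hz power of a Laplacian-filtered
C3 channel on the same sliding-window grid as the design tensor; the fMRI
score ``y_f`` arrives at 1 Hz and is resampled and Savitzky-Golay smoothed
to the 4 Hz grid; the hybrid score is the sum of the two after
standardization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import interp1d
from scipy.signal import savgol_filter

from .design import EEGRecording, FrequencyBandSet, SCORE_RATE_HZ, sliding_band_power

__all__ = [
    "NFScoreSeries",
    "laplacian_filter",
    "nf_eeg_score",
    "resample_smooth_fmri",
    "standardize",
    "combine_scores",
    "DEFAULT_LAPLACIAN_NEIGHBORS",
]

#: Default small-Laplacian montage around C3 (anterior, posterior, medial,
#: lateral neighbours); configurable because montages differ between caps.
DEFAULT_LAPLACIAN_NEIGHBORS: tuple[str, ...] = ("FC3", "CP3", "C1", "C5")

_KINDS = ("e", "f", "c", "predicted")


@dataclass
class NFScoreSeries:
    """A length-T neurofeedback score series on the 4 Hz grid."""

    values: np.ndarray
    kind: str
    times: np.ndarray | None = None
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("score series contains non-finite values")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.times is None:
            self.times = np.arange(1, len(self.values) + 1) / SCORE_RATE_HZ
        else:
            self.times = np.asarray(self.times, dtype=float)
            if len(self.times) != len(self.values):
                raise ValueError("times and values lengths differ")

    def __len__(self) -> int:
        return len(self.values)

    def replace(self, **kw) -> "NFScoreSeries":
        args = dict(
            values=self.values, kind=self.kind, times=self.times,
            standardized=self.standardized,
        )
        args.update(kw)
        return NFScoreSeries(**args)


def laplacian_filter(
    rec: EEGRecording,
    center: str = "C3",
    neighbors: Sequence[str] = DEFAULT_LAPLACIAN_NEIGHBORS,
) -> np.ndarray:
    """Spatial Laplacian: centre channel minus the mean of its neighbours.

    Sharpens the signal over the region of interest (sensorimotor cortex
    under C3 for right-hand motor imagery).  Returns a sample-rate series.
    """
    missing = [c for c in (center, *neighbors) if c not in rec.channel_names]
    if missing:
        raise KeyError(f"channels not in recording: {missing}")
    idx = {name: i for i, name in enumerate(rec.channel_names)}
    center_sig = rec.data[idx[center]]
    neigh = np.stack([rec.data[idx[n]] for n in neighbors])
    return center_sig - neigh.mean(axis=0)


def nf_eeg_score(
    rec: EEGRecording,
    center: str = "C3",
    neighbors: Sequence[str] = DEFAULT_LAPLACIAN_NEIGHBORS,
    window_s: float = 2.0,
    shift_s: float = 0.25,
    band: tuple[float, float] = (8.0, 30.0),
) -> NFScoreSeries:
    """NF-EEG score y_e: minus the band power of the Laplacian channel.

    Uses the same sliding-window band-power code path as the design
    tensor, so the output grid is identical.  The sign makes event-related
    desynchronization (power drop during imagery) push the score upward,
    in the same direction as the fMRI score.
    """
    lap = laplacian_filter(rec, center=center, neighbors=neighbors)
    lap_rec = EEGRecording(
        data=lap[None, :], srate=rec.srate, channel_names=[f"Lap({center})"]
    )
    x = sliding_band_power(
        lap_rec, FrequencyBandSet.single(*band), window_s=window_s, shift_s=shift_s
    )
    return NFScoreSeries(values=-x.values[:, 0, 0], kind="e", times=x.times)


def resample_smooth_fmri(
    y_raw: np.ndarray,
    in_rate: float = 1.0,
    out_rate: float = SCORE_RATE_HZ,
    window: int = 9,
    polyorder: int = 3,
) -> NFScoreSeries:
    """Bring 1 Hz NF-fMRI scores onto the 4 Hz grid.

    Linear interpolation to the score grid followed by a Savitzky-Golay
    filter (window 9 samples = 2.25 s, cubic), which removes the
    resampling staircase without distorting the 20 s block response.
    """
    y_raw = np.asarray(y_raw, dtype=float)
    if y_raw.ndim != 1:
        raise ValueError("y_raw must be one-dimensional")
    if len(y_raw) < window:
        raise ValueError(
            f"series of {len(y_raw)} samples shorter than the "
            f"{window}-sample smoothing window"
        )
    duration = len(y_raw) / in_rate
    n_out = int(round(duration * out_rate))
    t_in = np.arange(len(y_raw)) / in_rate
    t_out = np.arange(1, n_out + 1) / out_rate
    interp = interp1d(t_in, y_raw, kind="linear", fill_value="extrapolate")
    smoothed = savgol_filter(interp(t_out), window, polyorder)
    return NFScoreSeries(values=smoothed, kind="f", times=t_out)


def standardize(s: NFScoreSeries) -> NFScoreSeries:
    """Centre and scale to unit population variance within the session."""
    std = s.values.std()
    if std == 0:
        raise ValueError("cannot standardize a constant series")
    return s.replace(values=(s.values - s.values.mean()) / std, standardized=True)


def combine_scores(ye_std: NFScoreSeries, yf_std: NFScoreSeries) -> NFScoreSeries:
    """Hybrid score y_c = y_e + y_f (both inputs must be standardized)."""
    if not (ye_std.standardized and yf_std.standardized):
        raise ValueError("combine_scores requires standardized inputs")
    if len(ye_std) != len(yf_std):
        raise ValueError("score series lengths differ")
    return NFScoreSeries(
        values=ye_std.values + yf_std.values, kind="c", times=ye_std.times
    )
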