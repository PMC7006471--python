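"""Applying learned activation patterns to unseen sessions.

Three NF-predictors are supported: the pattern learned on the full design
against the hybrid score (variant ``c``), the pattern learned on the
delayed-only design against the fMRI score (variant ``f``), and the sum
of the measured EEG score with the predicted fMRI score
(variant ``e_plus_f``).  Also provides Pearson evaluation, Fisher-z
paired comparison of correlations, and activation-pattern summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats

from .design import DesignTensor
from .optimize import ActivationPattern
from .scores import NFScoreSeries, standardize

__all__ = [
    "PredictorSpec",
    "PatternSummary",
    "predict_scores",
    "run_predictor",
    "pearson_r",
    "compare_correlations",
    "summarize_patterns",
]

_REQUIRED_MODE = {"c": "full", "f": "delayed_only", "e_plus_f": "delayed_only"}


@dataclass
class PredictorSpec:
    """Which pattern to apply and which design mode it expects."""

    variant: str  # "c" | "f" | "e_plus_f"
    pattern: ActivationPattern

    def __post_init__(self) -> None:
        if self.variant not in _REQUIRED_MODE:
            raise ValueError(f"unknown predictor variant {self.variant!r}")

    @property
    def required_mode(self) -> str:
        return _REQUIRED_MODE[self.variant]


def _check_metadata(x: DesignTensor, alpha: ActivationPattern) -> None:
    if x.values.shape[1:] != alpha.weights.shape:
        raise ValueError(
            f"design features {x.values.shape[1:]} do not match "
            f"pattern {alpha.weights.shape}"
        )
    if alpha.feature_labels is not None and alpha.feature_labels != x.feature_labels:
        raise ValueError("design and pattern feature labels differ")
    if alpha.band_set is not None and alpha.band_set.bands != x.band_set.bands:
        raise ValueError("design and pattern band sets differ")


def predict_scores(x_test: DesignTensor, alpha: ActivationPattern) -> NFScoreSeries:
    """Predicted scores y~(t) = <X_test(t), alpha> for every t.

    Causal by construction: each prediction uses only the design row at
    time t, itself built from past EEG samples, so the map is usable in
    real time.
    """
    _check_metadata(x_test, alpha)
    values = np.einsum("tmb,mb->t", x_test.values, alpha.weights)
    return NFScoreSeries(values=values, kind="predicted", times=x_test.times)


def run_predictor(
    spec: PredictorSpec,
    x_test: DesignTensor,
    y_e: NFScoreSeries | None = None,
) -> NFScoreSeries:
    """Evaluate an NF-predictor on an unseen session.

    Variant ``c`` applies the pattern to the full design, ``f`` to the
    delayed-only design, and ``e_plus_f`` adds the standardized measured
    EEG score to the predicted fMRI score.
    """
    if x_test.mode != spec.required_mode:
        raise ValueError(
            f"variant {spec.variant!r} requires a {spec.required_mode!r} "
            f"design, got {x_test.mode!r}"
        )
    pred = predict_scores(x_test, spec.pattern)
    if spec.variant in ("c", "f"):
        return pred
    if y_e is None:
        raise ValueError("variant 'e_plus_f' needs the measured EEG score y_e")
    ye = y_e if y_e.standardized else standardize(y_e)
    if len(ye) != len(pred):
        raise ValueError("y_e and prediction lengths differ")
    return pred.replace(values=ye.values + pred.values)


def pearson_r(a, b) -> float:
    """Pearson correlation between two series."""
    av = np.asarray(getattr(a, "values", a), dtype=float)
    bv = np.asarray(getattr(b, "values", b), dtype=float)
    if len(av) != len(bv):
        raise ValueError("series lengths differ")
    if len(av) < 3:
        raise ValueError("need at least three samples")
    if av.std() == 0 or bv.std() == 0:
        raise ValueError("correlation undefined for a constant series")
    return float(spstats.pearsonr(av, bv).statistic)


def compare_correlations(
    r_list_1, r_list_2, paired: bool = True, alternative: str = "greater"
) -> tuple[float, float]:
    """Fisher-z transform then Student's t-test on two correlation samples.

    Each correlation is mapped through atanh before testing.  The default
    one-sided alternative tests whether the first sample's correlations
    exceed the second's; opposite-direction differences then yield p near
    1.  Returns ``(t, p)``.
    """
    r1 = np.asarray(r_list_1, dtype=float)
    r2 = np.asarray(r_list_2, dtype=float)
    if np.any(np.abs(r1) >= 1) or np.any(np.abs(r2) >= 1):
        raise ValueError("correlations must lie strictly inside (-1, 1)")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    if paired:
        if len(z1) != len(z2):
            raise ValueError("paired comparison needs equal-length samples")
        if np.std(z1 - z2) == 0:
            raise ValueError(
                "degenerate paired comparison: zero variance of z differences"
            )
        res = spstats.ttest_rel(z1, z2, alternative=alternative)
    else:
        res = spstats.ttest_ind(z1, z2, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


@dataclass
class PatternSummary:
    """Session-aggregated activation-pattern maps and sparsity figures."""

    zeta: np.ndarray  # sum over sessions of |alpha|, M x B
    gamma: np.ndarray  # sum over sessions of alpha, M x B
    electrode_maps: dict[int, np.ndarray]  # delay -> per-electrode sum_b zeta
    frequency_profiles: dict[int, np.ndarray]  # delay -> per-band sum_e gamma
    sparsity_by_block: dict[int, float]  # mean zero fraction per delay block
    sparsity_overall: float
    electrodes: list[str]


def summarize_patterns(patterns: list[ActivationPattern]) -> PatternSummary:
    """Aggregate patterns learned over sessions.

    ``zeta = sum_s |alpha(s)|`` is the absolute activation pattern,
    ``gamma = sum_s alpha(s)`` the average (signed) one.  Electrode heat
    maps sum zeta over bands per delay block; frequency profiles sum
    gamma over electrodes.  Sparsity is the mean (over sessions) fraction
    of exactly-zero coefficients, per block and overall.
    """
    if not patterns:
        raise ValueError("no patterns to summarize")
    first = patterns[0]
    for p in patterns[1:]:
        if p.weights.shape != first.weights.shape:
            raise ValueError("patterns have mixed shapes")
        if p.feature_labels != first.feature_labels:
            raise ValueError("patterns have mixed feature labels")
    stack = np.stack([p.weights for p in patterns])
    zeta = np.abs(stack).sum(axis=0)
    gamma = stack.sum(axis=0)

    labels = first.feature_labels or [
        (f"feat{i}", 0) for i in range(first.weights.shape[0])
    ]
    delays = []
    for _, d in labels:
        if d not in delays:
            delays.append(d)
    electrodes = []
    for e, _ in labels:
        if e not in electrodes:
            electrodes.append(e)

    electrode_maps, frequency_profiles, sparsity_by_block = {}, {}, {}
    for d in delays:
        rows = [i for i, (_, dd) in enumerate(labels) if dd == d]
        electrode_maps[d] = zeta[rows, :].sum(axis=1)
        frequency_profiles[d] = gamma[rows, :].sum(axis=0)
        sparsity_by_block[d] = float(np.mean(stack[:, rows, :] == 0))
    return PatternSummary(
        zeta=zeta,
        gamma=gamma,
        electrode_maps=electrode_maps,
        frequency_profiles=frequency_profiles,
        sparsity_by_block=sparsity_by_block,
        sparsity_overall=float(np.mean(stack == 0)),
        electrodes=electrodes,
    )
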