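"""ERP statistics: windowed contrasts as standardized differences, the
Simes improved-Bonferroni multiple-comparison procedure, median-split
grouping, and comparison of effect sizes between groups.

Contrasts between condition mean amplitudes are evaluated only in the time
window of interest but standardized by the spread of the pre-stimulus
baseline, so the standardized difference reads directly as an effect size in
the same metric as the waveforms.  All windows are half-open [start, stop)
in ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

__all__ = [
    "ContrastResult",
    "GroupSplit",
    "window_contrast",
    "simes_bonferroni",
    "median_split",
    "max_window_amplitude",
    "compare_effect_sizes",
]


@dataclass(frozen=True)
class ContrastResult:
    electrode: str
    window: tuple[float, float]
    mean_difference: float
    standardized_difference: float
    t_statistic: float
    df: int
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _window_mask(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if lo < times[0] or hi > times[-1] + (times[1] - times[0]):
        raise ValueError(f"window {window} outside epoch span [{times[0]}, {times[-1]}]")
    mask = (times >= lo) & (times < hi)
    if not mask.any():
        raise ValueError(f"window {window} contains no samples")
    return mask


def window_contrast(
    erpA: np.ndarray,
    erpB: np.ndarray,
    times: np.ndarray,
    window: tuple[float, float],
    electrode: str = "",
    baseline_window: tuple[float, float] | None = None,
) -> ContrastResult:
    """Paired contrast of two conditions at one electrode.

    ``erpA``/``erpB`` are per-subject waveforms (subjects x samples).  The t
    statistic is a paired t-test on per-subject window means; the
    standardized difference divides the mean difference by the across-subject
    spread of the baseline mean, making it an effect size in waveform units.
    """
    erpA = np.atleast_2d(np.asarray(erpA, dtype=float))
    erpB = np.atleast_2d(np.asarray(erpB, dtype=float))
    times = np.asarray(times, dtype=float)
    if erpA.shape != erpB.shape:
        raise ValueError(f"paired conditions must align: {erpA.shape} vs {erpB.shape}")
    n = erpA.shape[0]
    if n < 2:
        raise ValueError("need at least 2 paired subjects for a variance estimate")
    mask = _window_mask(times, window)
    meansA = erpA[:, mask].mean(axis=1)
    meansB = erpB[:, mask].mean(axis=1)
    diff = meansA - meansB
    if np.allclose(diff.std(ddof=1), 0.0):
        # degenerate paired test: no variability in the differences
        t_stat = 0.0 if diff.mean() == 0 else np.inf * np.sign(diff.mean())
        p_value = 1.0 if diff.mean() == 0 else 0.0
    else:
        t_stat, p_value = sstats.ttest_rel(meansA, meansB)

    if baseline_window is None:
        base_mask = times < 0
        if not base_mask.any():
            raise ValueError("no baseline samples; provide baseline_window explicitly")
    else:
        base_mask = _window_mask(times, baseline_window)
    baseline_means = np.concatenate([erpA[:, base_mask], erpB[:, base_mask]], axis=0).mean(axis=1)
    spread = float(baseline_means.std(ddof=1))
    standardized = float(diff.mean() / spread) if spread > 0 else float("inf") * np.sign(diff.mean())
    if diff.mean() == 0:
        standardized = 0.0
    return ContrastResult(
        electrode=electrode,
        window=tuple(window),
        mean_difference=float(diff.mean()),
        standardized_difference=standardized,
        t_statistic=float(t_stat),
        df=n - 1,
        p_value=float(p_value),
    )


def simes_bonferroni(
    p_values: np.ndarray, alpha: float = 0.05
) -> tuple[bool, np.ndarray, np.ndarray]:
    """Simes improved-Bonferroni global test with Hochberg step-up decisions.

    Global null rejected iff any ordered p-value satisfies
    ``p_(i) <= i * alpha / m``.  Per-hypothesis rejections use the Hochberg
    step-up rule (reject H_(1..k) for the largest k with
    ``p_(k) <= alpha / (m - k + 1)``); adjusted p-values are the Hochberg
    ones, monotone non-decreasing in the raw p-values.

    Returns ``(global_rejection, rejections, adjusted_p)`` in input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("need a 1-D vector of at least one p-value")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError(f"p-values must lie in [0, 1], got {p}")
    m = p.size
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    ranks = np.arange(1, m + 1)

    global_reject = bool(np.any(p_sorted <= ranks * alpha / m))

    # Hochberg step-up: largest k with p_(k) <= alpha / (m - k + 1).
    hochberg_ok = p_sorted <= alpha / (m - ranks + 1)
    rejections_sorted = np.zeros(m, dtype=bool)
    if hochberg_ok.any():
        k = int(np.max(np.flatnonzero(hochberg_ok)))
        rejections_sorted[: k + 1] = True

    adjusted_sorted = np.minimum.accumulate(((m - ranks + 1) * p_sorted)[::-1])[::-1]
    adjusted_sorted = np.clip(adjusted_sorted, 0.0, 1.0)

    rejections = np.empty(m, dtype=bool)
    adjusted = np.empty(m, dtype=float)
    rejections[order] = rejections_sorted
    adjusted[order] = adjusted_sorted
    return global_reject, rejections, adjusted


@dataclass(frozen=True)
class GroupSplit:
    """Low/high partition of subjects at the sample median of a score."""

    scores: dict[str, float]
    low: tuple[str, ...]
    high: tuple[str, ...]
    split_value: float

    def __post_init__(self) -> None:
        if set(self.low) & set(self.high):
            raise ValueError("groups must be disjoint")
        if set(self.low) | set(self.high) != set(self.scores):
            raise ValueError("groups must be exhaustive")
        if any(self.scores[s] > self.split_value for s in self.low) or any(
            self.scores[s] < self.split_value for s in self.high
        ):
            raise ValueError("every low score must be <= split value <= every high score")


def median_split(scores: dict[str, float]) -> GroupSplit:
    """Split subjects at the sample median.

    Even n gives equal halves; with odd n the median-valued subject joins the
    Low group.  Ties at the median are broken by subject-id order, so the
    result is identical across runs and input orderings.
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 subjects to split")
    values = np.array(list(scores.values()), dtype=float)
    if np.all(values == values[0]):
        raise ValueError("all scores equal; median split undefined")
    split_value = float(np.median(values))
    ordered = sorted(scores, key=lambda s: (scores[s], s))
    n_low = (len(ordered) + 1) // 2
    return GroupSplit(
        scores=dict(scores),
        low=tuple(sorted(ordered[:n_low])),
        high=tuple(sorted(ordered[n_low:])),
        split_value=split_value,
    )


def max_window_amplitude(
    waveform: np.ndarray,
    times: np.ndarray,
    window: tuple[float, float] = (0.0, 200.0),
) -> float:
    """Maximum signed amplitude over the half-open window (not the magnitude)."""
    waveform = np.asarray(waveform, dtype=float).ravel()
    times = np.asarray(times, dtype=float)
    if waveform.size != times.size:
        raise ValueError("waveform and time axis must align")
    mask = _window_mask(times, window)
    return float(waveform[mask].max())


def compare_effect_sizes(
    es1: float, n1: int, es2: float, n2: int, kind: str = "r"
) -> tuple[float, float]:
    """Standard-normal test on the difference of two effect sizes.

    Effect sizes are variance-stabilized with the Fisher transform
    (``kind="r"`` for correlation-scale effects; ``kind="d"`` first converts
    a standardized mean difference via ``r = d / sqrt(d**2 + 4)``), then

        Z = (z1 - z2) / sqrt(1/(n1-3) + 1/(n2-3))

    with a two-sided p-value.  Z = 0 when the effects are equal, and
    swapping the groups negates Z.
    """
    if n1 < 4 or n2 < 4:
        raise ValueError(f"group sizes must each exceed 3 (variance undefined): {n1}, {n2}")
    if kind == "d":
        es1 = es1 / np.sqrt(es1**2 + 4.0)
        es2 = es2 / np.sqrt(es2**2 + 4.0)
    elif kind != "r":
        raise ValueError(f"unknown effect-size kind {kind!r}")
    for es in (es1, es2):
        if not -1.0 < es < 1.0:
            raise ValueError(f"correlation-scale effect size {es} outside (-1, 1)")
    z1, z2 = np.arctanh(es1), np.arctanh(es2)
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    Z = float((z1 - z2) / se)
    p = float(2.0 * sstats.norm.sf(abs(Z)))
    return Z, p
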