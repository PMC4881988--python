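"""Disposition metrics and the prespecified similarity criteria.

Half-life comes from a log-linear ordinary-least-squares fit of the body
drug-count series; clearance is the standard dose/AUC construction with a
``last/k`` tail extrapolation.  Validation uses relative (treated/control)
forms, which are invariant to the count-to-concentration normalization.

Similarity criteria follow the validation style of prespecified bands:
values within +/- k standard deviations of the reference, within a fixed
percentage of it, or a minimum fraction of points inside such a band.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "half_life",
    "auc_and_clearance",
    "ClearanceSummary",
    "SimilarityCriterion",
    "SimilarityVerdict",
    "check_similarity",
]


def half_life(times, counts) -> float:
    """Half-life from a log-linear OLS fit over all post-dose points.

    Non-positive counts are excluded with a warning; at least three usable
    points are required, and the fitted slope must be negative.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(counts, dtype=float)
    if t.shape != y.shape:
        raise ValueError("times and counts must have equal length")
    ok = y > 0
    if not ok.all():
        warnings.warn(
            f"excluding {int((~ok).sum())} non-positive points from half-life fit",
            stacklevel=2,
        )
    t, y = t[ok], y[ok]
    if len(t) < 3:
        raise ValueError("need at least 3 positive points for a half-life fit")
    slope, _ = np.polyfit(t, np.log(y), 1)
    if slope >= -1e-12:  # flat or rising (within float noise)
        raise ValueError("series does not decay; half-life undefined")
    return math.log(2.0) / (-slope)


@dataclass(frozen=True)
class ClearanceSummary:
    half_life: float
    auc: float
    auc_observed: float
    k_elim: float
    clearance: float
    tail_extrapolated: bool


def auc_and_clearance(times, counts, dose: float) -> ClearanceSummary:
    """AUC by trapezoid plus ``last/k`` tail; clearance = dose / AUC(0-inf).

    ``dose`` should be the volume-of-distribution-adjusted dose where that
    correction applies (the intrinsic-clearance analog).  If the terminal
    slope is non-negative, no tail is added and the summary is flagged.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(counts, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 points for AUC")
    if dose <= 0:
        raise ValueError("dose must be positive")
    auc_obs = float(np.trapezoid(y, t))
    try:
        t_half = half_life(t, y)
        k = math.log(2.0) / t_half
    except (ValueError, Warning):
        t_half = float("nan")
        k = float("nan")
    if k > 0 and y[-1] > 0:
        auc_inf = auc_obs + float(y[-1]) / k
        tail = True
    else:
        auc_inf = auc_obs
        tail = False
    return ClearanceSummary(
        half_life=t_half,
        auc=auc_inf,
        auc_observed=auc_obs,
        k_elim=k,
        clearance=dose / auc_inf,
        tail_extrapolated=tail,
    )


@dataclass(frozen=True)
class SimilarityCriterion:
    """A prespecified quantitative band.

    kind = "sd_band": within ``k_sd`` standard deviations of the reference.
    kind = "pct_band": within ``pct`` percent of the reference.
    kind = "fraction_within": at least ``min_fraction`` of the points meet
    the inner band (given by ``pct``/``k_sd``), the multi-point rule used
    for time-course and disappearance-curve targets.
    """

    kind: str
    k_sd: float = 1.0
    pct: float = 25.0
    min_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("sd_band", "pct_band", "fraction_within"):
            raise ValueError(f"unknown criterion kind {self.kind!r}")
        if self.k_sd <= 0 or self.pct <= 0 or self.min_fraction <= 0:
            raise ValueError("criterion parameters must be positive")


@dataclass(frozen=True)
class SimilarityVerdict:
    passed: bool
    fraction: float
    point_pass: tuple[bool, ...]


def check_similarity(
    in_silico,
    reference,
    criterion: SimilarityCriterion,
    reference_sd=None,
    inner_kind: str = "pct_band",
) -> SimilarityVerdict:
    """Apply a similarity criterion point-by-point.

    For single-band kinds every point must fall in band; for
    "fraction_within" at least ``min_fraction`` of points must fall in the
    inner band (``inner_kind``).  Returns the verdict and the per-point
    pass pattern, mirroring the reporting style "X percent of values fall
    within acceptable similarity".
    """
    x = np.asarray(in_silico, dtype=float)
    r = np.asarray(reference, dtype=float)
    if x.shape != r.shape:
        raise ValueError("in_silico and reference must have matching lengths")
    kind = criterion.kind if criterion.kind != "fraction_within" else inner_kind
    if kind == "sd_band":
        if reference_sd is None:
            raise ValueError("sd_band criterion requires reference standard deviations")
        sd = np.asarray(reference_sd, dtype=float)
        ok = np.abs(x - r) <= criterion.k_sd * sd
    else:
        ok = np.abs(x - r) <= (criterion.pct / 100.0) * np.abs(r)
    fraction = float(ok.mean()) if ok.size else 0.0
    if criterion.kind == "fraction_within":
        passed = fraction >= criterion.min_fraction
    else:
        passed = bool(ok.all())
    return SimilarityVerdict(passed=passed, fraction=fraction, point_pass=tuple(ok))
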