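"""Stratified rare-event population estimation.

Estimates the number of positive survey units (image tiles containing a
facility) missed by a detection-driven review, from a stratified random
sample of the unreviewed units.  Per-stratum positive counts are treated as
binomial; because positives are rare (many strata observe zero), normal
approximations are inappropriate and the interval is built by combining
per-stratum exact (Clopper–Pearson style) binomial bounds with stratum
weights and a variance-ratio adjustment factor ``R`` — the stratified
exact-bound construction of Waller and colleagues.

For a category of ``L`` strata with weights ``w_i``, sample sizes ``n_i``
and positive counts ``x_i``::

    p_hat = sum_i w_i * x_i / n_i
    LB0   = sum_i w_i * CP_lower(x_i, n_i, alpha)
    UB0   = sum_i w_i * CP_upper(x_i, n_i, alpha)
    R     = sqrt(sum_i w_i^2 / n_i) / sum_i (w_i / sqrt(n_i))
    LB    = p_hat - (p_hat - LB0) * R
    UB    = p_hat + (UB0 - p_hat) * R

where CP_lower/CP_upper are the exact binomial limits expressed through
upper-tail F-distribution quantiles.  With a single stratum R = 1 and the
interval is exactly Clopper–Pearson.

Proportion intervals are converted to facility counts through the observed
ratio of positive images per facility and finally to a dataset-completeness
percentage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import f as f_dist

__all__ = [
    "Stratum",
    "ProportionInterval",
    "PopulationEstimate",
    "stratum_weights",
    "waller_interval",
    "estimate_unobserved_images",
    "images_per_facility_ratio",
    "estimate_total_facilities",
    "round_half_away",
]

CATEGORIES = ("no_detection", "low_confidence")


@dataclass(frozen=True)
class Stratum:
    """One cell of the survey design.

    Parameters
    ----------
    stratum_id : str
        Unique identifier, e.g. ``"no_detection/3"``.
    category : str
        Detection category, ``"no_detection"`` or ``"low_confidence"``.
    total : int
        N_i, total tiles in the stratum (labeled + unlabeled).
    labeled : int
        n_i, number of labeled tiles.
    positives : int
        x_i, number of labeled tiles with a positive label.
    """

    stratum_id: str
    category: str
    total: int
    labeled: int
    positives: int

    def __post_init__(self) -> None:
        if not (0 <= self.positives <= self.labeled <= self.total):
            raise ValueError(
                f"stratum {self.stratum_id}: need 0 <= x <= n <= N, "
                f"got x={self.positives}, n={self.labeled}, N={self.total}"
            )

    @property
    def unlabeled(self) -> int:
        return self.total - self.labeled


@dataclass(frozen=True)
class ProportionInterval:
    """A stratified exact-binomial confidence interval for a proportion."""

    p_hat: float
    lb: float
    ub: float
    lb0: float
    ub0: float
    r: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.lb <= self.p_hat <= self.ub <= 1.0):
            raise ValueError(
                f"interval ordering violated: LB={self.lb}, "
                f"p_hat={self.p_hat}, UB={self.ub}"
            )
        if self.r <= 0:
            raise ValueError("adjustment factor R must be positive")


@dataclass
class PopulationEstimate:
    """Facility-count and completeness estimate derived from tile intervals."""

    observed_facilities: int
    unobserved_images_point: int
    unobserved_images_ub: int
    images_per_facility: float
    unobserved_facilities_point: int = field(init=False)
    unobserved_facilities_ub: int = field(init=False)
    total_facilities_point: int = field(init=False)
    total_facilities_ub: int = field(init=False)
    completeness_point_pct: int = field(init=False)
    completeness_ci_pct: tuple[int, int] = field(init=False)

    def __post_init__(self) -> None:
        r = self.images_per_facility
        if r <= 0:
            raise ValueError("images-per-facility ratio must be positive")
        self.unobserved_facilities_point = round_half_away(
            self.unobserved_images_point / r
        )
        self.unobserved_facilities_ub = round_half_away(self.unobserved_images_ub / r)
        self.total_facilities_point = (
            self.observed_facilities + self.unobserved_facilities_point
        )
        self.total_facilities_ub = self.observed_facilities + self.unobserved_facilities_ub
        self.completeness_point_pct = round_half_away(
            100.0 * self.observed_facilities / self.total_facilities_point
        )
        lower = round_half_away(
            100.0 * self.observed_facilities / self.total_facilities_ub
        )
        # The unobserved count is bounded below by the point estimate's floor
        # of zero, so the interval's upper end is the point estimate itself.
        self.completeness_ci_pct = (lower, self.completeness_point_pct)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (not banker's)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def stratum_weights(strata: Sequence[Stratum]) -> np.ndarray:
    """Weights w_i = N_i / sum_j N_j for strata of a single category."""
    if len(strata) == 0:
        raise ValueError("cannot weight an empty category")
    cats = {s.category for s in strata}
    if len(cats) > 1:
        raise ValueError(f"strata span multiple categories: {sorted(cats)}")
    totals = np.array([s.total for s in strata], dtype=float)
    if np.any(totals <= 0):
        raise ValueError("all stratum totals must be positive")
    return totals / totals.sum()


def _cp_lower(x: int, n: int, alpha: float) -> float:
    """Exact binomial lower limit via the upper-tail F quantile; 0 at x=0."""
    if x == 0:
        return 0.0
    fq = f_dist.ppf(1.0 - alpha / 2.0, 2 * (n - x + 1), 2 * x)
    return x / (x + (n - x + 1) * fq)


def _cp_upper(x: int, n: int, alpha: float) -> float:
    """Exact binomial upper limit via the upper-tail F quantile; 1 at x=n."""
    if x == n:
        return 1.0
    fq = f_dist.ppf(1.0 - alpha / 2.0, 2 * (x + 1), 2 * (n - x))
    return (x + 1) * fq / ((n - x) + (x + 1) * fq)


def waller_interval(
    strata: Sequence[Stratum],
    alpha: float = 0.05,
    weights: np.ndarray | None = None,
) -> ProportionInterval:
    """Stratified exact-binomial confidence interval for one category.

    Per-stratum Clopper–Pearson bounds are weight-averaged into unadjusted
    bounds LB0/UB0, then pulled toward the point estimate by the adjustment
    factor R (ratio of the stratified standard error to the sum of
    per-stratum standard-error contributions).  Degenerate F-quantile
    arguments — x_i = 0 for the lower bound, x_i = n_i for the upper — use
    the exact-interval limits (term 0 and w_i respectively).

    Parameters
    ----------
    strata : sequence of Stratum
        All from one detection category; every n_i must be >= 1.
    alpha : float
        Two-sided significance level (default 0.05 for a 95% interval).
    weights : array, optional
        Override the default total-count weights (for sensitivity analysis,
        e.g. weighting by unlabeled counts).  Must sum to 1.

    Raises
    ------
    ValueError
        If any stratum has zero labeled tiles (names the stratum).
    """
    for s in strata:
        if s.labeled < 1:
            raise ValueError(f"stratum {s.stratum_id} has no labeled tiles")
    w = stratum_weights(strata) if weights is None else np.asarray(weights, float)
    if weights is not None and not math.isclose(w.sum(), 1.0, rel_tol=1e-9):
        raise ValueError("supplied weights must sum to 1")

    n = np.array([s.labeled for s in strata], dtype=float)
    x = np.array([s.positives for s in strata], dtype=float)

    p_hat = float(np.sum(w * x / n))
    lb0 = float(
        sum(
            wi * _cp_lower(s.positives, s.labeled, alpha)
            for wi, s in zip(w, strata)
        )
    )
    ub0 = float(
        sum(
            wi * _cp_upper(s.positives, s.labeled, alpha)
            for wi, s in zip(w, strata)
        )
    )
    r = float(np.sqrt(np.sum(w**2 / n)) / np.sum(w / np.sqrt(n)))
    lb = max(0.0, p_hat - (p_hat - lb0) * r)
    ub = min(1.0, p_hat + (ub0 - p_hat) * r)
    return ProportionInterval(
        p_hat=p_hat, lb=lb, ub=ub, lb0=lb0, ub0=ub0, r=r, alpha=alpha
    )


def estimate_unobserved_images(
    interval: ProportionInterval, unlabeled: int
) -> tuple[int, int]:
    """Convert a proportion interval to (point, upper-bound) image counts.

    Multiplies the point estimate and the upper bound by the number of
    unlabeled tiles in the category and rounds half away from zero.
    """
    if unlabeled < 0:
        raise ValueError("unlabeled count must be non-negative")
    return (
        round_half_away(interval.p_hat * unlabeled),
        round_half_away(interval.ub * unlabeled),
    )


def images_per_facility_ratio(
    positive_labeled_images: int, facilities_on_them: int
) -> float:
    """Images per facility among labeled positives.

    The ratio counts image sharing: ten facilities lying on the same two
    images give a ratio of 0.2 images per facility, even though each of
    those facilities occupies two images.
    """
    if facilities_on_them < 1:
        raise ValueError("need at least one facility to form the ratio")
    return positive_labeled_images / facilities_on_them


def estimate_total_facilities(
    observed_facilities: int,
    unobserved_images_point: int,
    unobserved_images_ub: int,
    images_per_facility: float,
) -> PopulationEstimate:
    """Combine observed facilities with estimated unobserved images.

    Unobserved image counts (summed across categories) are divided by the
    images-per-facility ratio to give unobserved facility counts; the
    completeness percentage is 100 * observed / total, reported as the
    point estimate and a lower bound derived from the image upper bound.
    """
    return PopulationEstimate(
        observed_facilities=observed_facilities,
        unobserved_images_point=unobserved_images_point,
        unobserved_images_ub=unobserved_images_ub,
        images_per_facility=images_per_facility,
    )


def estimate_population(
    strata: Iterable[Stratum],
    observed_facilities: int,
    images_per_facility: float,
    alpha: float = 0.05,
) -> dict:
    """End-to-end estimate over both detection categories.

    Applies the stratified interval separately to the ``no_detection`` and
    ``low_confidence`` strata (the variance-homogeneity assumption behind
    the adjustment factor holds within, not across, categories), scales by
    each category's unlabeled tile count, sums the two image estimates, and
    converts to facilities.  Returns a report dict with every intermediate
    quantity.
    """
    strata = list(strata)
    report: dict = {"alpha": alpha, "categories": {}}
    img_point = 0
    img_ub = 0
    for cat in CATEGORIES:
        cat_strata = [s for s in strata if s.category == cat]
        if not cat_strata:
            continue
        interval = waller_interval(cat_strata, alpha=alpha)
        unlabeled = sum(s.unlabeled for s in cat_strata)
        point, ub = estimate_unobserved_images(interval, unlabeled)
        img_point += point
        img_ub += ub
        report["categories"][cat] = {
            "n_strata": len(cat_strata),
            "unlabeled": unlabeled,
            "p_hat": interval.p_hat,
            "lb": interval.lb,
            "ub": interval.ub,
            "lb0": interval.lb0,
            "ub0": interval.ub0,
            "r": interval.r,
            "unobserved_images_point": point,
            "unobserved_images_ub": ub,
        }
    est = estimate_total_facilities(
        observed_facilities, img_point, img_ub, images_per_facility
    )
    report["estimate"] = {
        "observed_facilities": est.observed_facilities,
        "unobserved_images_point": est.unobserved_images_point,
        "unobserved_images_ub": est.unobserved_images_ub,
        "images_per_facility": est.images_per_facility,
        "unobserved_facilities_point": est.unobserved_facilities_point,
        "unobserved_facilities_ub": est.unobserved_facilities_ub,
        "total_facilities_point": est.total_facilities_point,
        "total_facilities_ub": est.total_facilities_ub,
        "completeness_point_pct": est.completeness_point_pct,
        "completeness_ci_pct": list(est.completeness_ci_pct),
    }
    return report
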