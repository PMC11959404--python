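"""Composite D studies: project G-study components onto hypothetical designs.

With composite weights ``w`` over the four score variables and ``n_p``
procedures in the decision design:

    universe score variance   tau   = w' sigma_t  w
    relative error variance   delta = w' sigma_tp w / n_p
    absolute error variance   Delta = w' (sigma_p + sigma_tp) w / n_p
    generalizability coeff.   Erho2 = tau / (tau + delta)
    index of dependability    Phi   = tau / (tau + Delta)
    SEM (absolute)            sqrt(Delta)

Rater and item are fixed facets: they contribute no error terms and are
averaged into the composite through the weights.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .errors import MvgtError, UndefinedStatisticError
from .gstudy import GStudyComponents


@dataclasses.dataclass
class CompositeWeights:
    """Nonnegative weights over the four variables, normalized to sum 1."""

    w: np.ndarray = dataclasses.field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self):
        w = np.asarray(self.w, dtype=float).reshape(-1)
        if w.size != 4:
            raise MvgtError("composite weights must have length 4")
        if np.any(w < 0):
            raise MvgtError("composite weights must be nonnegative")
        total = w.sum()
        if total <= 0:
            raise MvgtError("composite weights must not all be zero")
        self.w = w / total

    @classmethod
    def equal(cls) -> "CompositeWeights":
        return cls()

    @classmethod
    def single(cls, index: int) -> "CompositeWeights":
        w = np.zeros(4)
        w[index] = 1.0
        return cls(w)


@dataclasses.dataclass
class DStudyResult:
    """Composite D-study statistics at one facet size ``n_p``.

    ``ci95_margin`` follows the source convention of one SEM (labelled
    "paper-margin" in reports); ``ci95_margin_conventional`` is the usual
    1.96 * SEM half-width.
    """

    n_p: int
    universe_score_variance: float
    relative_error_variance: float
    absolute_error_variance: float
    gen_coefficient: float
    dependability: float
    sem_absolute: float
    ci95_margin: float
    ci95_margin_conventional: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def composite_dstudy(
    components: GStudyComponents, weights: CompositeWeights, n_p: int
) -> DStudyResult:
    """Compute the composite D-study statistics for ``n_p`` procedures."""
    if n_p < 1:
        raise MvgtError("n_p must be a positive integer")
    n_p = int(n_p)
    w = weights.w
    tau = float(w @ components.sigma_t @ w)
    delta = float(w @ components.sigma_tp @ w) / n_p
    big_delta = float(w @ (components.sigma_p + components.sigma_tp) @ w) / n_p
    if tau + big_delta == 0.0:
        raise UndefinedStatisticError(
            "universe-score and error variances are all zero; "
            "reliability coefficients are undefined"
        )
    erho2 = tau / (tau + delta)
    phi = tau / (tau + big_delta)
    sem = math.sqrt(big_delta)
    return DStudyResult(
        n_p=n_p,
        universe_score_variance=tau,
        relative_error_variance=delta,
        absolute_error_variance=big_delta,
        gen_coefficient=erho2,
        dependability=phi,
        sem_absolute=sem,
        ci95_margin=sem_margin(big_delta),
        ci95_margin_conventional=round(1.96 * sem, 2),
    )


def sem_margin(absolute_error_variance: float) -> float:
    """One-SEM margin on the rating scale, rounded to 2 decimals.

    This matches the source convention where the printed +/- margin of the
    95% interval equals a single standard error of measurement.
    """
    if absolute_error_variance < 0:
        raise MvgtError("absolute error variance must be nonnegative")
    return round(math.sqrt(absolute_error_variance), 2)


def min_procedures(
    components: GStudyComponents,
    weights: CompositeWeights,
    threshold: float,
    criterion: str = "dependability",
    n_max: int = 100,
) -> int | None:
    """Smallest ``n_p`` in [1, n_max] reaching the reliability threshold.

    Returns None when the threshold is not attainable within ``n_max``.
    Both criteria are monotone nondecreasing in ``n_p``, so a closed-form
    check followed by verification is exact:

        n* = ceil( threshold/(1-threshold) * E / tau )

    with E the per-procedure error variance of the chosen criterion.  The
    ceiling absorbs a 1e-9 relative slack so that a threshold like 0.8,
    which is not exactly representable in binary, still treats a
    coefficient of exactly 0.8 as attained.
    """
    if not 0.0 < threshold < 1.0:
        raise MvgtError("threshold must lie strictly in (0, 1)")
    if n_max < 1:
        raise MvgtError("n_max must be >= 1")
    if criterion not in ("dependability", "generalizability"):
        raise MvgtError(
            "criterion must be 'dependability' or 'generalizability'"
        )
    w = weights.w
    tau = float(w @ components.sigma_t @ w)
    if tau <= 0.0:
        return None
    if criterion == "dependability":
        err = float(w @ (components.sigma_p + components.sigma_tp) @ w)
    else:
        err = float(w @ components.sigma_tp @ w)
    if err == 0.0:
        return 1
    target = threshold / (1.0 - threshold) * err / tau
    n_star = max(math.ceil(target * (1.0 - 1e-9)), 1)
    if n_star > n_max:
        return None
    return n_star


def dstudy_curve(
    components: GStudyComponents, weights: CompositeWeights, n_range
) -> list[DStudyResult]:
    """One DStudyResult per facet size in the increasing ``n_range``."""
    n_range = [int(n) for n in n_range]
    if not n_range:
        raise MvgtError("n_range must be nonempty")
    if any(b <= a for a, b in zip(n_range, n_range[1:])):
        raise MvgtError("n_range must be strictly increasing")
    return [composite_dstudy(components, weights, n) for n in n_range]
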