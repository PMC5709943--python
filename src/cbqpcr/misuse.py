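"""Demonstration of why t-tests on raw expression ratios are invalid.

A tempting shortcut is to back-transform each replicate pair's ΔΔCq to a
ratio first and then t-test the ratios against 1.  Because ratios are
right-skewed (lognormal), the verdict of that test depends on which group
is called the numerator: A-vs-B and B-vs-A can disagree about significance
on the same data.  Working in log scale is immune — swapping the groups
merely negates the estimate, statistic and interval and inverts the ratio,
leaving the p-value untouched.  The functions here exist to exhibit the
failure, not for analysis use.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
import scipy.stats as st

from cbqpcr.core import DEFAULT_BASE


@dataclasses.dataclass(frozen=True)
class DirectionResult:
    """One direction of the improper ratio-scale t-test (mean tested vs 1)."""

    mean_ratio: float
    sd: float
    statistic: float
    p_value: float
    n: int

    @property
    def ratio(self) -> float:
        return self.mean_ratio


@dataclasses.dataclass(frozen=True)
class MisuseReport:
    """Both directions of the improper test on the same per-pair ΔΔ values."""

    direction_ab: DirectionResult
    direction_ba: DirectionResult
    alpha: float
    consistent: bool


def improper_ratio_test(
    pairs: Sequence[tuple[float, float]],
    base: float = DEFAULT_BASE,
    alpha: float = 0.05,
) -> MisuseReport:
    """Apply the (invalid) ratio-scale t-test in both directions.

    Per pair, the A-vs-B ratio is ``base^(−ΔΔ)`` and the B-vs-A ratio is
    ``base^(+ΔΔ)``; each direction gets a one-sample t-test with
    hypothesized mean 1.  ``consistent`` is True iff the two directions
    agree on significance at ``alpha`` — for skewed ratios they typically
    do not, which is the point of the demonstration.
    """
    warnings.warn(
        "improper_ratio_test applies a t-test on the ratio scale; this is a "
        "demonstration of invalid methodology, not an analysis tool",
        UserWarning,
        stacklevel=2,
    )
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (delta_cq_a, delta_cq_b)")
    if arr.shape[0] < 2:
        raise ValueError("need >= 2 pairs")
    ddcq = arr[:, 0] - arr[:, 1]

    def one_direction(sign: float) -> DirectionResult:
        ratios = np.power(base, sign * ddcq)
        n = ratios.size
        mean, sd = float(ratios.mean()), float(ratios.std(ddof=1))
        if sd == 0.0:
            t_stat = 0.0 if mean == 1.0 else math.inf * math.copysign(1, mean - 1)
            p = 1.0 if mean == 1.0 else 0.0
        else:
            t_stat = (mean - 1.0) / (sd / math.sqrt(n))
            p = 2.0 * st.t.sf(abs(t_stat), n - 1)
        return DirectionResult(
            mean_ratio=mean, sd=sd, statistic=float(t_stat), p_value=float(p), n=n
        )

    ab = one_direction(-1.0)
    ba = one_direction(+1.0)
    consistent = (ab.p_value < alpha) == (ba.p_value < alpha)
    return MisuseReport(
        direction_ab=ab, direction_ba=ba, alpha=alpha, consistent=consistent
    )


def reciprocity_check(result_ab, result_ba, tol: float = 1e-9) -> bool:
    """Do two opposite-direction results mirror each other exactly?

    True iff the p-values agree within ``tol``, the test statistics negate
    within ``tol``, and the ratios are multiplicative inverses within
    relative ``tol``.  A sound relative-quantification method passes this
    for any data; the ratio-scale t-test generically fails it.

    Accepts any objects exposing ``statistic``, ``p_value``, ``ratio`` and
    a sample size (``n`` or ``n_a``/``n_b``).
    """

    def sizes(res) -> tuple[int, ...]:
        if hasattr(res, "n"):
            return (int(res.n),)
        return (int(res.n_a), int(res.n_b))

    if sizes(result_ab) != sizes(result_ba):
        raise ValueError(
            f"results come from different sample sizes: {sizes(result_ab)} "
            f"vs {sizes(result_ba)}"
        )
    if abs(result_ab.p_value - result_ba.p_value) > tol:
        return False
    if abs(result_ab.statistic + result_ba.statistic) > tol:
        return False
    if not math.isclose(result_ab.ratio * result_ba.ratio, 1.0, rel_tol=tol):
        return False
    return True
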