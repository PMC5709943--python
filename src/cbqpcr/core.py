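"""Core log-scale arithmetic of the Common Base Method.

Every well contributes the efficiency-weighted quantification cycle
``log_b(E) * Cq`` (base ``b`` 10 by default).  Because ``b^(log_b(E)*Cq)
= E^Cq``, the weighted value is the initial template quantity expressed on
one shared logarithmic scale regardless of each well's amplification
efficiency.  Technical replicates are averaged on that scale, the gene of
interest is normalized by subtracting the arithmetic mean of the reference
genes (equivalent to dividing by their geometric mean in linear scale), and
the between-condition contrast ΔΔCq back-transforms to the relative
expression ratio R = b^(−ΔΔCq).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from cbqpcr.io import ExperimentTable, WellRecord

DEFAULT_BASE = 10.0


def _check_base(base: float) -> float:
    if not (math.isfinite(base) and base > 1.0):
        raise ValueError(f"log base must be finite and > 1, got {base!r}")
    return float(base)


@dataclasses.dataclass(frozen=True)
class WeightedCq:
    """Mean efficiency-weighted Cq for one (replicate, sample type, gene)."""

    replicate_id: str
    sample_type: str
    gene: str
    value: float
    n_wells: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"weighted Cq must be finite, got {self.value!r}")
        if self.n_wells < 1:
            raise ValueError("n_wells must be >= 1")


@dataclasses.dataclass(frozen=True)
class DeltaCq:
    """Normalized log-scale expression for one (replicate, sample type):
    GOI weighted Cq minus the mean reference-gene weighted Cq."""

    replicate_id: str
    sample_type: str
    value: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"delta Cq must be finite, got {self.value!r}")


def weight_cq(efficiency: float, cq: float, base: float = DEFAULT_BASE) -> float:
    """Efficiency-weighted quantification cycle, ``log_base(E) * Cq``.

    Wells with different amplification efficiencies are put on a common
    log-quantity scale; with E = base the weight is exactly Cq.
    """
    base = _check_base(base)
    if not (math.isfinite(efficiency) and efficiency > 1.0):
        raise ValueError(
            f"efficiency must be finite and > 1 (fold-amplification per "
            f"cycle), got {efficiency!r}"
        )
    if not math.isfinite(cq):
        raise ValueError(f"cq must be finite, got {cq!r}")
    return math.log(efficiency, base) * cq


def aggregate_technical(
    wells: Sequence[WellRecord], base: float = DEFAULT_BASE
) -> WeightedCq:
    """Average the efficiency-weighted Cq over the technical replicates of
    one (replicate, sample type, gene).

    The mean is taken in weighted (log) space — each well is weighted by its
    own efficiency before averaging, never the raw Cq values first.
    """
    if not wells:
        raise ValueError("aggregate_technical requires at least one well")
    keys = {(w.replicate_id, w.sample_type, w.gene) for w in wells}
    if len(keys) != 1:
        raise ValueError(
            f"wells must share (replicate, sample_type, gene); got {sorted(keys)}"
        )
    values = [weight_cq(w.efficiency, w.cq, base) for w in wells]
    rep, styp, gene = next(iter(keys))
    return WeightedCq(
        replicate_id=rep,
        sample_type=styp,
        gene=gene,
        value=float(np.mean(values)),
        n_wells=len(values),
    )


def delta_cq(goi_wcq: WeightedCq, ref_wcqs: Sequence[WeightedCq]) -> DeltaCq:
    """Normalize the gene of interest against one or more reference genes.

    Subtracting the arithmetic mean of the reference genes' weighted Cq in
    log scale is exactly division by their geometric mean in linear scale,
    so any number of reference genes combine without geometric means ever
    being computed explicitly.
    """
    if not ref_wcqs:
        raise ValueError("at least one reference-gene weighted Cq is required")
    key = (goi_wcq.replicate_id, goi_wcq.sample_type)
    for ref in ref_wcqs:
        if (ref.replicate_id, ref.sample_type) != key:
            raise ValueError(
                f"reference {ref.gene!r} has (replicate, sample_type) "
                f"{(ref.replicate_id, ref.sample_type)}, expected {key}"
            )
    value = goi_wcq.value - float(np.mean([r.value for r in ref_wcqs]))
    return DeltaCq(replicate_id=key[0], sample_type=key[1], value=value)


def delta_delta(
    dcq_a: Iterable[float] | float,
    dcq_b: Iterable[float] | float,
    *,
    paired: bool = False,
    labels_a: Sequence[str] | None = None,
    labels_b: Sequence[str] | None = None,
) -> float:
    """Point estimate of ΔΔCq between two sample types.

    Unpaired: difference of the group means.  Paired: mean of the per-pair
    differences (``labels_a``/``labels_b``, when given, must match pairwise).
    On balanced complete data the two coincide.
    """
    a = np.atleast_1d(np.asarray(dcq_a, dtype=float))
    b = np.atleast_1d(np.asarray(dcq_b, dtype=float))
    if paired:
        if a.shape != b.shape:
            raise ValueError(
                f"paired mode needs equal-length groups, got {a.size} and {b.size}"
            )
        if labels_a is not None and labels_b is not None and list(labels_a) != list(
            labels_b
        ):
            raise ValueError(
                f"paired mode requires matching replicate labels, got "
                f"{list(labels_a)} vs {list(labels_b)}"
            )
        return float(np.mean(a - b))
    return float(np.mean(a) - np.mean(b))


def ratio_from_ddcq(ddcq: float, base: float = DEFAULT_BASE) -> float:
    """Relative expression ratio ``R = base^(−ΔΔCq)``.

    The base cancels against the logarithms taken in :func:`weight_cq`, so
    R is invariant to the choice of base.
    """
    base = _check_base(base)
    if not math.isfinite(ddcq):
        raise ValueError(f"ddcq must be finite, got {ddcq!r}")
    return base ** (-ddcq)


def backtransform_interval(
    ci_log: tuple[float, float], base: float = DEFAULT_BASE
) -> tuple[float, float]:
    """Map a log-scale confidence interval onto the ratio scale.

    Because ``x -> base^(−x)`` is decreasing, the bounds swap:
    ``(lo, hi) -> (base^(−hi), base^(−lo))``.  The result is ordered low to
    high and asymmetric about the point ratio — as it should be after an
    exponential transformation.
    """
    base = _check_base(base)
    lo, hi = ci_log
    if lo > hi:
        raise ValueError(f"log-scale interval must be ordered, got ({lo}, {hi})")
    return (base ** (-hi), base ** (-lo))


# ---------------------------------------------------------------------------
# table-level pipeline


def weighted_cq_table(
    experiment: ExperimentTable, base: float = DEFAULT_BASE
) -> pd.DataFrame:
    """Aggregate every (replicate, sample_type, gene) of an experiment.

    Returns a DataFrame with columns ``replicate, sample_type, gene, plate,
    weighted_cq, n_wells``.  The plate label must be unique within each
    biological sample (all of a sample's wells sit on one plate).
    """
    base = _check_base(base)
    data = experiment.data.copy()
    data["_w"] = np.log(data["efficiency"].to_numpy()) / np.log(base) * data[
        "cq"
    ].to_numpy()
    grouped = (
        data.groupby(["replicate", "sample_type", "gene"], sort=False)
        .agg(
            weighted_cq=("_w", "mean"),
            n_wells=("_w", "size"),
            plate=("plate", lambda s: s.iloc[0]),
            n_plates=("plate", "nunique"),
        )
        .reset_index()
    )
    straddle = grouped[grouped["n_plates"] > 1]
    if len(straddle):
        row = straddle.iloc[0]
        raise ValueError(
            f"wells of (replicate={row['replicate']!r}, "
            f"sample_type={row['sample_type']!r}, gene={row['gene']!r}) span "
            f"multiple plates; technical replicates must share a plate"
        )
    return grouped.drop(columns="n_plates")


def delta_cq_table(
    experiment: ExperimentTable, base: float = DEFAULT_BASE
) -> pd.DataFrame:
    """Per-sample normalized log expression.

    Returns one row per (replicate, sample_type) with columns ``replicate,
    sample_type, plate, delta_cq``: the GOI weighted Cq minus the arithmetic
    mean of the reference genes' weighted Cq.
    """
    wtab = weighted_cq_table(experiment, base)
    goi = wtab[wtab["gene"] == experiment.goi].set_index(
        ["replicate", "sample_type"]
    )
    refs = (
        wtab[wtab["gene"].isin(experiment.refs)]
        .groupby(["replicate", "sample_type"], sort=False)["weighted_cq"]
        .mean()
    )
    out = goi[["plate", "weighted_cq"]].copy()
    out["delta_cq"] = goi["weighted_cq"] - refs
    out = out.drop(columns="weighted_cq").reset_index()
    if out["delta_cq"].isna().any():
        raise ValueError("missing reference-gene wells for some sample")
    return out
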