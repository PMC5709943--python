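"""Statistical inference on normalized log-scale expression (ΔCq values).

All testing happens in log scale, where lognormally distributed relative
expression becomes approximately normal: Welch or pooled two-sample t-tests
for unpaired designs, one-sample t-tests on per-pair differences for paired
designs, and one-factor ANOVA with additive blocking (plates or individuals
as randomized complete blocks) for more than two conditions.  Confidence
intervals are built with Student-t quantiles in log scale and back-
transformed to asymmetric ratio-scale intervals at the very end.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.formula.api import ols

from cbqpcr.core import DEFAULT_BASE, backtransform_interval, ratio_from_ddcq


class DesignError(ValueError):
    """The requested analysis is incompatible with the data layout."""


class AssumptionWarning(UserWarning):
    """Advisory: a parametric assumption (normality) looks doubtful."""


@dataclasses.dataclass(frozen=True)
class DesignSpec:
    """Analysis design: mode, blocking, confidence level and conventions.

    ``variance_assumption`` applies to the unpaired mode only: ``unequal``
    (Welch–Satterthwaite, the conservative default) or ``pooled``.
    ``adjust`` controls the post-hoc multiplicity correction.
    """

    mode: str = "unpaired"  # unpaired | paired | anova
    blocks: tuple[str, ...] = ()
    confidence: float = 0.95
    variance_assumption: str = "unequal"  # unequal | pooled
    adjust: str = "bonferroni"  # bonferroni | none
    check_assumptions: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("unpaired", "paired", "anova"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0.0 < self.confidence < 1.0):
            raise ValueError(f"confidence must be in (0, 1), got {self.confidence}")
        if self.variance_assumption not in ("unequal", "pooled"):
            raise ValueError(
                f"unknown variance assumption {self.variance_assumption!r}"
            )
        if self.adjust not in ("bonferroni", "none"):
            raise ValueError(f"unknown adjustment {self.adjust!r}")
        object.__setattr__(self, "blocks", tuple(self.blocks))


@dataclasses.dataclass(frozen=True)
class InferenceResult:
    """A two-group comparison in log scale with its ratio-scale translation.

    ``estimate`` is ΔΔCq (log scale); ``ratio = base^(−estimate)`` and
    ``ratio_ci`` is the back-transformed ``ci_log``.  ``df`` may be
    non-integer (Welch).  The p-value is two-tailed against ΔΔCq = 0,
    i.e. ratio = 1.
    """

    mode: str
    estimate: float
    se: float
    df: float
    statistic: float
    p_value: float
    ci_log: tuple[float, float]
    ratio: float
    ratio_ci: tuple[float, float]
    n_a: int
    n_b: int
    confidence: float = 0.95
    base: float = DEFAULT_BASE

    @property
    def n_pairs(self) -> int:
        if self.mode != "paired":
            raise AttributeError("n_pairs is defined for paired results only")
        return self.n_a


@dataclasses.dataclass(frozen=True)
class Comparison:
    """One post-hoc pairwise contrast from an ANOVA."""

    pair: tuple[str, str]
    diff: float
    se: float
    df: float
    statistic: float
    p_raw: float
    p_adjusted: float
    ci_log: tuple[float, float]
    ratio: float
    ratio_ci: tuple[float, float]
    harmonic_n: bool = False


@dataclasses.dataclass(frozen=True)
class AnovaSource:
    name: str
    df: float
    ss: float
    ms: float
    f: float  # nan when undefined (blocks, degenerate data)
    p: float  # nan when undefined


@dataclasses.dataclass(frozen=True)
class AnovaResult:
    """Additive-decomposition table plus the context post-hoc tests need."""

    sources: tuple[AnovaSource, ...]
    posthoc: tuple[Comparison, ...]
    factor: str
    level_means: dict[str, float]
    level_ns: dict[str, int]
    ms_error: float
    df_error: float
    confidence: float = 0.95
    base: float = DEFAULT_BASE

    @property
    def factor_source(self) -> AnovaSource:
        return next(s for s in self.sources if s.name == self.factor)


def _t_interval(
    estimate: float, se: float, df: float, confidence: float
) -> tuple[float, float]:
    q = st.t.ppf(0.5 + confidence / 2.0, df)
    return (estimate - q * se, estimate + q * se)


def _screen_normality(values: np.ndarray, label: str) -> None:
    # advisory only — small-sample Shapiro screens are weak, never a gate
    if 3 <= len(values) <= 5000 and np.ptp(values) > 0:
        p = st.shapiro(values).pvalue
        if p < 0.05:
            warnings.warn(
                f"{label}: Shapiro normality screen p = {p:.3g}; the t-test "
                f"assumes log-scale values are approximately normal",
                AssumptionWarning,
                stacklevel=3,
            )


def _finish(
    mode: str,
    estimate: float,
    se: float,
    df: float,
    n_a: int,
    n_b: int,
    spec: DesignSpec,
    base: float,
) -> InferenceResult:
    statistic = estimate / se
    p_value = 2.0 * st.t.sf(abs(statistic), df)
    ci_log = _t_interval(estimate, se, df, spec.confidence)
    return InferenceResult(
        mode=mode,
        estimate=estimate,
        se=se,
        df=df,
        statistic=statistic,
        p_value=p_value,
        ci_log=ci_log,
        ratio=ratio_from_ddcq(estimate, base),
        ratio_ci=backtransform_interval(ci_log, base),
        n_a=n_a,
        n_b=n_b,
        confidence=spec.confidence,
        base=base,
    )


def unpaired_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    spec: DesignSpec = DesignSpec(),
    base: float = DEFAULT_BASE,
) -> InferenceResult:
    """Two-sample t-test on ΔCq values from independent biological replicates.

    The estimate is mean(A) − mean(B).  With the default ``unequal``
    variance assumption the Welch–Satterthwaite degrees of freedom are kept
    as a real number; ``pooled`` gives the classical equal-variance test.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(
            f"each group needs >= 2 replicates for inference (got {a.size} "
            f"and {b.size}); use delta_delta for a point estimate alone"
        )
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        raise ValueError("both groups have zero variance; inference degenerate")
    if spec.check_assumptions:
        _screen_normality(a, "group A")
        _screen_normality(b, "group B")
    estimate = float(a.mean() - b.mean())
    if spec.variance_assumption == "pooled":
        df = a.size + b.size - 2.0
        sp2 = ((a.size - 1) * va + (b.size - 1) * vb) / df
        se = math.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
    else:
        qa, qb = va / a.size, vb / b.size
        se = math.sqrt(qa + qb)
        df = (qa + qb) ** 2 / (qa**2 / (a.size - 1) + qb**2 / (b.size - 1))
    return _finish("unpaired", estimate, se, df, a.size, b.size, spec, base)


def paired_test(
    pairs: Sequence[tuple[float, float]],
    spec: DesignSpec = DesignSpec(mode="paired"),
    base: float = DEFAULT_BASE,
) -> InferenceResult:
    """One-sample t-test on per-pair ΔCq differences against zero.

    ΔΔCq is the mean of the within-pair differences (A − B); the pairing
    acts as an implicit block absorbing between-replicate variation.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (value_a, value_b)")
    if arr.shape[0] < 2:
        raise ValueError("paired inference needs >= 2 pairs")
    diffs = arr[:, 0] - arr[:, 1]
    if diffs.var(ddof=1) == 0.0:
        raise ValueError("all pair differences identical; zero-variance inference")
    if spec.check_assumptions:
        _screen_normality(diffs, "pair differences")
    n = diffs.size
    estimate = float(diffs.mean())
    se = float(diffs.std(ddof=1) / math.sqrt(n))
    return _finish("paired", estimate, se, float(n - 1), n, n, spec, base)


def blocked_anova(
    data: pd.DataFrame,
    spec: DesignSpec = DesignSpec(mode="anova"),
    *,
    value: str = "delta_cq",
    factor: str = "sample_type",
    base: float = DEFAULT_BASE,
) -> AnovaResult:
    """One-factor ANOVA on ΔCq values with optional additive blocks.

    Blocks (``spec.blocks`` naming columns of ``data``, e.g. plates or
    individuals) enter as additive fixed effects with no interaction terms:
    a randomized-complete-block analysis that partitions nuisance variation
    out of the error term.  Block F and p values are reported for
    completeness but carry no inferential weight for the hypothesis of
    interest.  With no blocks this reduces to a one-way ANOVA.  Unbalanced
    data fall back to a marginal (each-term-after-all-others)
    decomposition with a warning; all worked examples here are balanced.
    """
    for col in (value, factor, *spec.blocks):
        if col not in data.columns:
            raise DesignError(f"column {col!r} not found in data")
    levels = list(dict.fromkeys(data[factor]))
    if len(levels) < 2:
        raise DesignError(f"factor {factor!r} needs >= 2 levels, got {levels}")
    for blk in spec.blocks:
        counts = pd.crosstab(data[factor], data[blk])
        if (counts == 0).any().any():
            lvl = counts.index[(counts == 0).any(axis=1)][0]
            b = counts.columns[(counts == 0).any(axis=0)][0]
            raise DesignError(
                f"factor level {lvl!r} is missing from block {blk}={b!r}; "
                f"a complete-block analysis needs every level in every block"
            )
    cell_sizes = data.groupby([factor, *spec.blocks], sort=False)[value].size()
    balanced = cell_sizes.nunique() == 1
    if not balanced:
        warnings.warn(
            "unbalanced design: using a marginal (each-term-after-all-others) "
            "sum-of-squares decomposition",
            UserWarning,
            stacklevel=2,
        )

    work = pd.DataFrame({"y": data[value].to_numpy(dtype=float)})
    work["f0"] = data[factor].astype(str).to_numpy()
    block_cols = []
    for i, blk in enumerate(spec.blocks):
        col = f"b{i}"
        work[col] = data[blk].astype(str).to_numpy()
        block_cols.append(col)

    n_total = len(work)
    df_factor = len(levels) - 1
    df_blocks = [work[c].nunique() - 1 for c in block_cols]
    df_error = n_total - 1 - df_factor - sum(df_blocks)
    if df_error <= 0:
        raise DesignError(
            f"zero residual degrees of freedom (N={n_total}, factor df "
            f"{df_factor}, block dfs {df_blocks})"
        )

    level_means = {
        lvl: float(work.loc[work["f0"] == lvl, "y"].mean()) for lvl in levels
    }
    level_ns = {lvl: int((work["f0"] == lvl).sum()) for lvl in levels}

    names = [factor, *spec.blocks, "Error"]
    if np.ptp(work["y"].to_numpy()) == 0.0:
        # constant response: the decomposition exists but F is undefined
        sources = tuple(
            AnovaSource(
                name=name,
                df=float(dfi),
                ss=0.0,
                ms=0.0,
                f=math.nan,
                p=math.nan,
            )
            for name, dfi in zip(
                names, [df_factor, *df_blocks, df_error], strict=True
            )
        )
        result = AnovaResult(
            sources=sources,
            posthoc=(),
            factor=factor,
            level_means=level_means,
            level_ns=level_ns,
            ms_error=0.0,
            df_error=float(df_error),
            confidence=spec.confidence,
            base=base,
        )
        return result

    formula = "y ~ C(f0)" + "".join(f" + C({c})" for c in block_cols)
    fit = ols(formula, work).fit()
    table = sm.stats.anova_lm(fit, typ=2)

    term_names = ["C(f0)"] + [f"C({c})" for c in block_cols]
    sources = []
    for name, term in zip(names[:-1], term_names, strict=True):
        row = table.loc[term]
        sources.append(
            AnovaSource(
                name=name,
                df=float(row["df"]),
                ss=float(row["sum_sq"]),
                ms=float(row["sum_sq"] / row["df"]),
                f=float(row["F"]),
                p=float(row["PR(>F)"]),
            )
        )
    resid = table.loc["Residual"]
    sources.append(
        AnovaSource(
            name="Error",
            df=float(resid["df"]),
            ss=float(resid["sum_sq"]),
            ms=float(resid["sum_sq"] / resid["df"]),
            f=math.nan,
            p=math.nan,
        )
    )
    result = AnovaResult(
        sources=tuple(sources),
        posthoc=(),
        factor=factor,
        level_means=level_means,
        level_ns=level_ns,
        ms_error=float(resid["sum_sq"] / resid["df"]),
        df_error=float(resid["df"]),
        confidence=spec.confidence,
        base=base,
    )
    return dataclasses.replace(result, posthoc=posthoc_pairwise(result, spec))


def posthoc_pairwise(
    anova: AnovaResult, spec: DesignSpec = DesignSpec(mode="anova")
) -> tuple[Comparison, ...]:
    """Pairwise t-contrasts of factor-level means after an ANOVA.

    Each contrast uses the pooled error mean square on the error degrees of
    freedom: se = sqrt(2·MS_error/n).  P-values are Bonferroni-multiplied
    by the number of pairs and capped at 1; confidence intervals use the
    unadjusted t quantile, so a comparison's CI matches its unadjusted
    test.  Unequal level sizes fall back to the harmonic-mean n, flagged on
    the comparison.
    """
    levels = list(anova.level_means)
    if len(levels) < 2:
        raise DesignError("post-hoc testing needs >= 2 factor levels")
    if anova.ms_error == 0.0:
        raise DesignError("zero error mean square; post-hoc tests undefined")
    pairs = list(itertools.combinations(levels, 2))
    m = len(pairs) if spec.adjust == "bonferroni" else 1
    q = st.t.ppf(0.5 + spec.confidence / 2.0, anova.df_error)
    out = []
    for lv_a, lv_b in pairs:
        n_a, n_b = anova.level_ns[lv_a], anova.level_ns[lv_b]
        harmonic = n_a != n_b
        n_eff = 2.0 / (1.0 / n_a + 1.0 / n_b) if harmonic else float(n_a)
        se = math.sqrt(2.0 * anova.ms_error / n_eff)
        diff = anova.level_means[lv_a] - anova.level_means[lv_b]
        t_stat = diff / se
        p_raw = 2.0 * st.t.sf(abs(t_stat), anova.df_error)
        ci_log = (diff - q * se, diff + q * se)
        out.append(
            Comparison(
                pair=(lv_a, lv_b),
                diff=diff,
                se=se,
                df=anova.df_error,
                statistic=t_stat,
                p_raw=p_raw,
                p_adjusted=min(1.0, p_raw * m),
                ci_log=ci_log,
                ratio=ratio_from_ddcq(diff, anova.base),
                ratio_ci=backtransform_interval(ci_log, anova.base),
                harmonic_n=harmonic,
            )
        )
    return tuple(out)


def analyze_pair(
    delta_table: pd.DataFrame,
    type_a: str,
    type_b: str,
    spec: DesignSpec,
    base: float = DEFAULT_BASE,
) -> InferenceResult:
    """Run the unpaired or paired comparison of two sample types taken from
    a ΔCq table (as produced by :func:`cbqpcr.core.delta_cq_table`)."""
    sub_a = delta_table[delta_table["sample_type"] == type_a]
    sub_b = delta_table[delta_table["sample_type"] == type_b]
    if sub_a.empty or sub_b.empty:
        raise DesignError(
            f"sample types {type_a!r}/{type_b!r} not both present in the table"
        )
    if spec.mode == "paired":
        a = sub_a.set_index("replicate")["delta_cq"]
        b = sub_b.set_index("replicate")["delta_cq"]
        if set(a.index) != set(b.index):
            raise DesignError(
                f"paired mode requires matching replicate labels; got "
                f"{sorted(a.index)} vs {sorted(b.index)}"
            )
        pairs = [(float(a[r]), float(b[r])) for r in a.index]
        return paired_test(pairs, spec, base)
    if spec.mode == "unpaired":
        return unpaired_test(
            sub_a["delta_cq"].to_numpy(),
            sub_b["delta_cq"].to_numpy(),
            spec,
            base,
        )
    raise DesignError(f"analyze_pair handles unpaired/paired, not {spec.mode!r}")
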