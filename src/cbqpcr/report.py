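"""Publication-style outputs: ratio plots with 95% CI bars and text reports.

Error bars are always back-transformed confidence intervals, never SD or
SEM: after the exponential transformation out of log scale only the
interval retains its interpretation, and the asymmetry of the bars is a
feature, not an artifact.  The presentation layer reads result objects
verbatim — nothing is recomputed here.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from cbqpcr.inference import AnovaResult, Comparison, InferenceResult


def _sig(x: float, figures: int = 3) -> str:
    return f"{x:.{figures}g}"


def format_inference_text(result: InferenceResult) -> str:
    lines = [
        f"{result.mode} analysis (log base {result.base:g})",
        f"  estimate (log scale)     {result.estimate:.4f}",
        f"  SE (log scale)           {result.se:.4f}",
        f"  t = {result.statistic:.2f} on df = {result.df:.4g}, "
        f"two-tailed p = {result.p_value:.3f}",
        f"  {result.confidence:.0%} CI (log scale)      "
        f"({result.ci_log[0]:.4f}, {result.ci_log[1]:.4f})",
        f"  expression ratio         {_sig(result.ratio)}",
        f"  {result.confidence:.0%} CI (ratio scale)    "
        f"({_sig(result.ratio_ci[0])}, {_sig(result.ratio_ci[1])})",
    ]
    if result.mode == "paired":
        lines.append(f"  n pairs                  {result.n_pairs}")
    else:
        lines.append(f"  n per group              {result.n_a}, {result.n_b}")
    return "\n".join(lines)


def format_anova_text(result: AnovaResult) -> str:
    lines = [f"ANOVA on {result.factor} (log base {result.base:g})"]
    lines.append(f"  {'source':<14}{'df':>6}{'SS':>10}{'MS':>10}{'F':>10}{'p':>8}")
    for s in result.sources:
        f_txt = f"{s.f:.3f}" if s.f == s.f else "-"
        p_txt = f"{s.p:.3f}" if s.p == s.p else "-"
        lines.append(
            f"  {s.name:<14}{s.df:>6.0f}{s.ss:>10.4f}{s.ms:>10.4f}"
            f"{f_txt:>10}{p_txt:>8}"
        )
    if result.posthoc:
        lines.append(
            "  post-hoc pairwise comparisons (Bonferroni-adjusted p; "
            "unadjusted CIs)"
        )
        for c in result.posthoc:
            lines.append(
                f"  {c.pair[0]} vs {c.pair[1]}: diff {c.diff:.4f}, "
                f"ratio {_sig(c.ratio)} "
                f"CI ({_sig(c.ratio_ci[0])}, {_sig(c.ratio_ci[1])}), "
                f"p_adj {c.p_adjusted:.3f}"
            )
    return "\n".join(lines)


def plot_ratios(
    results: Sequence[InferenceResult | Comparison],
    path: str | Path,
    *,
    log_scale: bool = False,
    labels: Sequence[str] | None = None,
    title: str | None = None,
) -> Path:
    """Plot expression ratios as points with asymmetric CI error bars.

    One point per result at its ratio, bars spanning the back-transformed
    confidence interval, and a horizontal reference line at ratio 1 (no
    change).  ``log_scale`` switches the y-axis to logarithmic, where the
    bars become symmetric again.
    """
    results = list(results)
    if not results:
        raise ValueError("no results to plot")
    if labels is None:
        labels = [
            f"{r.pair[0]} vs {r.pair[1]}" if isinstance(r, Comparison) else "A vs B"
            for r in results
        ]
    ratios = [r.ratio for r in results]
    lower = [r.ratio - r.ratio_ci[0] for r in results]
    upper = [r.ratio_ci[1] - r.ratio for r in results]

    fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(results), 4.0))
    x = range(len(results))
    ax.errorbar(
        x, ratios, yerr=[lower, upper], fmt="o", color="black", capsize=4,
        markersize=6,
    )
    ax.axhline(1.0, color="grey", linestyle="--", linewidth=1)
    ax.set_xticks(list(x))
    ax.set_xticklabels(labels)
    ax.set_ylabel("relative expression ratio")
    if log_scale:
        ax.set_yscale("log")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path
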