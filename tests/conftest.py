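"""Shared fixtures, including session-scoped Monte-Carlo summaries.

The Monte-Carlo fixtures are computed once per session and shared by the
property and acceptance tests; each uses a fixed seed ladder so results
are reproducible run to run.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

from cbqpcr import core, inference, simulate
from cbqpcr.io import ExperimentTable

FAST_SPEC = inference.DesignSpec(check_assumptions=False)
FAST_PAIRED = inference.DesignSpec(mode="paired", check_assumptions=False)


def simulate_delta(cfg: simulate.SimulationConfig):
    table, truth = simulate.simulate_experiment(cfg)
    return core.delta_cq_table(table), truth


def make_constant_e_table(
    rng: np.random.Generator,
    e_goi: float = 1.87,
    e_ref: float = 1.93,
    n_rep: int = 3,
    n_tech: int = 2,
) -> ExperimentTable:
    """Random single-reference experiment with gene-wise constant
    efficiencies — the regime where the classical efficiency-corrected
    formula applies exactly."""
    rows = []
    for t in ("A", "B"):
        for r in range(n_rep):
            for gene, role, e, loc in (
                ("goi", "target", e_goi, 30.0),
                ("ref", "reference", e_ref, 25.0),
            ):
                for _ in range(n_tech):
                    rows.append(
                        {
                            "replicate": f"r{r + 1}",
                            "sample_type": t,
                            "gene": gene,
                            "role": role,
                            "plate": "plate1",
                            "well": f"w{len(rows) + 1}",
                            "efficiency": e,
                            "cq": float(rng.normal(loc, 1.0)),
                        }
                    )
    return ExperimentTable(data=pd.DataFrame(rows), goi="goi", refs=("ref",))


def pipeline_ratio(table: ExperimentTable) -> float:
    """Common-base expression ratio A vs B from a per-well table
    (unpaired point estimate)."""
    dt = core.delta_cq_table(table)
    dd = core.delta_delta(
        dt[dt["sample_type"] == "A"]["delta_cq"],
        dt[dt["sample_type"] == "B"]["delta_cq"],
    )
    return core.ratio_from_ddcq(dd)


@pytest.fixture(scope="session")
def null_rejection() -> dict:
    """Type-I error of the pipeline under a true ratio of 1, 4 replicates
    per group, 2000 simulated experiments — alongside the rejection rate
    of the Welch test on ideal iid Gaussian samples of the same size (an
    independent oracle for the test's true finite-sample level, which at
    n = 4 per group sits slightly below the nominal 0.05)."""
    import scipy.stats as st

    cfg0 = simulate.SimulationConfig(sample_types={"A": 0.0, "B": 0.0})
    n, rej = 2000, 0
    for i in range(n):
        dt, _ = simulate_delta(dataclasses.replace(cfg0, seed=100_000 + i))
        res = inference.analyze_pair(dt, "A", "B", FAST_SPEC)
        rej += res.p_value < 0.05
    rej_oracle = 0
    for i in range(n):
        rng = np.random.default_rng(900_000 + i)
        a, b = rng.normal(0, 0.16, 4), rng.normal(0, 0.16, 4)
        rej_oracle += st.ttest_ind(a, b, equal_var=False).pvalue < 0.05
    return {"pipeline": rej / n, "oracle": rej_oracle / n, "n": n}


@pytest.fixture(scope="session")
def ci_coverage() -> dict:
    """Per design: 95% ratio-CI coverage of the true ratio and the mean
    log-scale estimate, over 1000 simulated experiments each."""
    out = {}
    for design, spec in (("unpaired", FAST_SPEC), ("paired", FAST_PAIRED)):
        cfg0 = simulate.SimulationConfig(design=design)
        n, covered, estimates = 1000, 0, []
        for i in range(n):
            dt, truth = simulate_delta(
                dataclasses.replace(cfg0, seed=200_000 + i)
            )
            res = inference.analyze_pair(dt, "A", "B", spec)
            lo, hi = res.ratio_ci
            covered += lo <= truth.true_ratio[("A", "B")] <= hi
            estimates.append(res.estimate)
        out[design] = {
            "coverage": covered / n,
            "mean_estimate": float(np.mean(estimates)),
            "true_ddcq": truth.true_ddcq[("A", "B")],
            "n": n,
        }
    return out


@pytest.fixture(scope="session")
def blocking_summary() -> dict:
    """Blocked vs. unblocked ANOVA on plate-confounded data: rejection
    rates at alpha 0.05 and mean error mean-squares, 400 simulations."""
    cfg0 = simulate.SimulationConfig(
        sample_types={"A": 0.0, "B": -0.25, "C": 0.0},
        n_plates=2,
        sd_plate=0.3,
        sd_biological=0.1,
    )
    n = 400
    rej = {"blocked": 0, "unblocked": 0}
    mse = {"blocked": [], "unblocked": []}
    spec_b = inference.DesignSpec(mode="anova", blocks=("plate",))
    spec_u = inference.DesignSpec(mode="anova")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for i in range(n):
            dt, _ = simulate_delta(dataclasses.replace(cfg0, seed=300_000 + i))
            for name, spec in (("blocked", spec_b), ("unblocked", spec_u)):
                res = inference.blocked_anova(dt, spec)
                rej[name] += res.factor_source.p < 0.05
                mse[name].append(res.ms_error)
    return {
        "rejection": {k: v / n for k, v in rej.items()},
        "mean_ms_error": {k: float(np.mean(v)) for k, v in mse.items()},
        "n": n,
    }
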