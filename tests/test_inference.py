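"""Unpaired/paired t-tests, blocked ANOVA and post-hoc comparisons."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from cbqpcr import datasets
from cbqpcr.inference import (
    AssumptionWarning,
    DesignError,
    DesignSpec,
    analyze_pair,
    blocked_anova,
    paired_test,
    posthoc_pairwise,
    unpaired_test,
)

A_VALUES = [1.1387, 0.845, 0.499, 0.699]
B_VALUES = [1.4077, 1.291, 1.496, 1.172]
SPEC = DesignSpec(check_assumptions=False)
SPEC_PAIRED = DesignSpec(mode="paired", check_assumptions=False)
SPEC_ANOVA = DesignSpec(mode="anova")


class TestUnpaired:
    def test_worked_example(self):
        res = unpaired_test(A_VALUES, B_VALUES, SPEC)
        assert res.estimate == pytest.approx(-0.546, abs=5e-4)
        assert res.statistic == pytest.approx(-3.60, abs=5e-3)
        assert res.p_value == pytest.approx(0.019, abs=5e-4)
        assert res.ci_log[0] == pytest.approx(-0.949, abs=5e-4)
        assert res.ci_log[1] == pytest.approx(-0.143, abs=5e-4)
        assert res.ratio == pytest.approx(3.52, abs=5e-3)
        # Welch df kept real-valued, not floored
        assert res.df == pytest.approx(4.53, abs=5e-3)

    def test_identical_groups(self):
        res = unpaired_test([0.1, 0.4, 0.9], [0.1, 0.4, 0.9], SPEC)
        assert res.statistic == 0.0
        assert res.ratio == 1.0
        assert res.ratio_ci[0] < 1.0 < res.ratio_ci[1]

    def test_pooled_matches_closed_form(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0.3, 0.2, 5), rng.normal(0.6, 0.2, 7)
        res = unpaired_test(a, b, DesignSpec(
            variance_assumption="pooled", check_assumptions=False
        ))
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t_expected = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
        assert res.statistic == pytest.approx(t_expected, rel=1e-12)
        assert res.df == na + nb - 2
        # cross-check against scipy's pooled implementation
        ref = st.ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_welch_matches_scipy(self):
        ref = st.ttest_ind(A_VALUES, B_VALUES, equal_var=False)
        res = unpaired_test(A_VALUES, B_VALUES, SPEC)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_small_or_degenerate_groups_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            unpaired_test([1.0], [1.0, 2.0], SPEC)
        with pytest.raises(ValueError, match="zero variance"):
            unpaired_test([1.0, 1.0], [2.0, 2.0], SPEC)

    def test_normality_screen_warns(self):
        skewed = [0.0, 0.001, 0.002, 0.003, 0.004, 50.0, 90.0, 95.0]
        with pytest.warns(AssumptionWarning):
            unpaired_test(skewed, [1.0, 1.2, 1.4, 1.6, 1.8, 2.0, 2.2, 2.4],
                          DesignSpec())


class TestPaired:
    def test_worked_example(self):
        res = paired_test(list(zip(A_VALUES, B_VALUES)), SPEC_PAIRED)
        assert res.estimate == pytest.approx(-0.546, abs=5e-4)
        assert res.statistic == pytest.approx(-3.48, abs=5e-3)
        assert res.p_value == pytest.approx(0.040, abs=5e-4)
        assert res.ci_log[0] == pytest.approx(-1.046, abs=5e-4)
        assert res.ci_log[1] == pytest.approx(-0.047, abs=5e-4)
        assert res.ratio == pytest.approx(3.52, abs=5e-3)
        assert res.ratio_ci[0] == pytest.approx(1.11, abs=5e-3)
        assert res.ratio_ci[1] == pytest.approx(11.1, abs=5e-2)
        assert res.df == 3
        assert res.n_pairs == 4

    def test_symmetric_noise_gives_ratio_one(self):
        pairs = [(0.5 + d, 0.5) for d in (-0.2, 0.2, -0.1, 0.1)]
        res = paired_test(pairs, SPEC_PAIRED)
        assert res.estimate == pytest.approx(0.0, abs=1e-15)
        assert res.ratio == pytest.approx(1.0, rel=1e-15)

    def test_swapping_groups_negates_everything_but_p(self):
        fwd = paired_test(list(zip(A_VALUES, B_VALUES)), SPEC_PAIRED)
        rev = paired_test(list(zip(B_VALUES, A_VALUES)), SPEC_PAIRED)
        assert rev.estimate == pytest.approx(-fwd.estimate, rel=1e-12)
        assert rev.statistic == pytest.approx(-fwd.statistic, rel=1e-12)
        assert rev.ci_log[0] == pytest.approx(-fwd.ci_log[1], rel=1e-12)
        assert rev.ci_log[1] == pytest.approx(-fwd.ci_log[0], rel=1e-12)
        assert rev.p_value == pytest.approx(fwd.p_value, rel=1e-12)
        assert rev.ratio == pytest.approx(1.0 / fwd.ratio, rel=1e-12)
        assert rev.ratio_ci[0] == pytest.approx(1.0 / fwd.ratio_ci[1], rel=1e-12)
        assert rev.ratio_ci[1] == pytest.approx(1.0 / fwd.ratio_ci[0], rel=1e-12)

    def test_degenerate_pairs_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            paired_test([(1.0, 2.0)], SPEC_PAIRED)
        with pytest.raises(ValueError, match="zero-variance"):
            paired_test([(1.0, 0.5), (2.0, 1.5), (3.0, 2.5)], SPEC_PAIRED)

    def test_matches_scipy_one_sample(self):
        diffs = np.array(A_VALUES) - np.array(B_VALUES)
        ref = st.ttest_1samp(diffs, 0.0)
        res = paired_test(list(zip(A_VALUES, B_VALUES)), SPEC_PAIRED)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-12)


class TestBlockedAnova:
    def test_plate_blocked_worked_example(self):
        res = blocked_anova(
            datasets.plate_blocked_delta_cq(),
            DesignSpec(mode="anova", blocks=("plate",)),
        )
        factor = res.factor_source
        assert factor.ms == pytest.approx(0.096, abs=5e-4)
        assert factor.df == 2
        assert res.df_error == 8
        assert res.ms_error == pytest.approx(0.007, abs=5e-4)
        # printed F values stem from unrounded source data; reproducible
        # from the printed inputs only to a few tenths of a percent
        assert factor.f == pytest.approx(12.864, rel=5e-3)
        assert res.sources[1].f == pytest.approx(20.487, rel=5e-3)
        assert factor.p == pytest.approx(0.003, abs=5e-4)

    def test_unblocked_contrast(self):
        res = blocked_anova(datasets.plate_blocked_delta_cq(), SPEC_ANOVA)
        factor = res.factor_source
        assert factor.f == pytest.approx(4.064, abs=2e-3)
        assert (factor.df, res.df_error) == (2, 9)
        assert factor.p == pytest.approx(0.055, abs=5e-4)

    def test_individual_blocked_worked_example(self):
        res = blocked_anova(
            datasets.individual_blocked_delta_cq(),
            DesignSpec(mode="anova", blocks=("replicate",)),
        )
        assert res.factor_source.f == pytest.approx(20.222, abs=5e-4)
        assert res.sources[1].f == pytest.approx(2.237, abs=5e-4)
        assert res.ms_error == pytest.approx(0.017, abs=5e-4)
        assert res.factor_source.p == pytest.approx(0.002, abs=5e-4)

    def test_balanced_decomposition_sums(self):
        data = datasets.individual_blocked_delta_cq()
        res = blocked_anova(
            data, DesignSpec(mode="anova", blocks=("replicate",))
        )
        total_ss = float(((data["delta_cq"] - data["delta_cq"].mean()) ** 2).sum())
        assert sum(s.ss for s in res.sources) == pytest.approx(total_ss, rel=1e-9)
        n = len(data)
        assert res.df_error == n - 1 - sum(
            s.df for s in res.sources if s.name != "Error"
        )

    def test_constant_response_undefined_f(self):
        data = pd.DataFrame(
            {"sample_type": ["A", "A", "B", "B", "C", "C"], "delta_cq": [0.7] * 6}
        )
        res = blocked_anova(data, SPEC_ANOVA)
        assert all(s.ss == 0.0 for s in res.sources)
        assert math.isnan(res.factor_source.f)
        assert math.isnan(res.factor_source.p)

    def test_missing_cell_names_it(self):
        data = datasets.plate_blocked_delta_cq()
        data = data[~((data.sample_type == "C") & (data.plate == "plate2"))]
        with pytest.raises(DesignError, match="'C'.*plate"):
            blocked_anova(data, DesignSpec(mode="anova", blocks=("plate",)))

    def test_zero_residual_df_rejected(self):
        data = pd.DataFrame(
            {
                "sample_type": ["A", "B", "A", "B"],
                "replicate": ["r1", "r1", "r2", "r2"],
                "delta_cq": [0.1, 0.2, 0.3, 0.25],
            }
        ).iloc[:3]
        with pytest.raises(DesignError):
            blocked_anova(
                data, DesignSpec(mode="anova", blocks=("replicate",))
            )

    def test_unbalanced_warns_and_uses_marginal_ss(self):
        data = pd.concat(
            [
                datasets.plate_blocked_delta_cq(),
                pd.DataFrame(
                    {
                        "replicate": ["r5"],
                        "sample_type": ["A"],
                        "plate": ["plate1"],
                        "delta_cq": [0.8],
                    }
                ),
            ],
            ignore_index=True,
        )
        with pytest.warns(UserWarning, match="unbalanced"):
            res = blocked_anova(
                data, DesignSpec(mode="anova", blocks=("plate",))
            )
        assert res.df_error == len(data) - 1 - 2 - 1

    def test_paired_t_equivalence_two_levels(self):
        """Two sample types with the replicate as block: the ANOVA factor
        test is exactly the paired t-test (F = t^2, same p)."""
        frame = datasets.unpaired_delta_cq()
        res_anova = blocked_anova(
            frame, DesignSpec(mode="anova", blocks=("replicate",))
        )
        res_t = paired_test(list(zip(A_VALUES, B_VALUES)), SPEC_PAIRED)
        assert res_anova.factor_source.f == pytest.approx(
            res_t.statistic**2, rel=1e-9
        )
        assert res_anova.factor_source.p == pytest.approx(res_t.p_value, rel=1e-9)
        # the single post-hoc comparison reproduces the t-test too
        (comp,) = res_anova.posthoc
        assert comp.statistic**2 == pytest.approx(
            res_anova.factor_source.f, rel=1e-9
        )
        assert comp.p_raw == pytest.approx(res_anova.factor_source.p, rel=1e-9)


class TestPosthoc:
    def test_plate_blocked_comparisons(self):
        res = blocked_anova(
            datasets.plate_blocked_delta_cq(),
            DesignSpec(mode="anova", blocks=("plate",)),
        )
        by_pair = {c.pair: c for c in res.posthoc}
        ab = by_pair[("A", "B")]
        assert ab.ratio == pytest.approx(1.86, abs=5e-3)
        assert ab.ratio_ci[0] == pytest.approx(1.34, abs=5e-3)
        assert ab.ratio_ci[1] == pytest.approx(2.57, abs=5e-3)
        assert ab.p_adjusted == pytest.approx(0.007, abs=5e-4)
        ac = by_pair[("A", "C")]
        assert ac.p_adjusted == 1.0  # Bonferroni capping exercised
        # published 1.00 derives from unrounded source data; the printed
        # inputs give 1.005
        assert ac.ratio == pytest.approx(1.00, abs=1e-2)

    def test_individual_blocked_comparisons(self):
        res = blocked_anova(
            datasets.individual_blocked_delta_cq(),
            DesignSpec(mode="anova", blocks=("replicate",)),
        )
        bc = {c.pair: c for c in res.posthoc}[("B", "C")]
        assert bc.diff == pytest.approx(0.506, abs=5e-4)
        assert bc.ratio == pytest.approx(0.31, abs=5e-3)
        assert bc.ratio_ci[0] == pytest.approx(0.19, abs=5e-3)
        assert bc.ratio_ci[1] == pytest.approx(0.52, abs=5e-3)
        assert bc.p_adjusted == pytest.approx(0.005, abs=5e-4)

    def test_adjustment_none(self):
        res = blocked_anova(
            datasets.plate_blocked_delta_cq(),
            DesignSpec(mode="anova", blocks=("plate",), adjust="none"),
        )
        for comp in res.posthoc:
            assert comp.p_adjusted == pytest.approx(comp.p_raw, rel=1e-15)

    def test_harmonic_n_flagged_when_unbalanced(self):
        data = pd.concat(
            [
                datasets.plate_blocked_delta_cq(),
                pd.DataFrame(
                    {
                        "replicate": ["r5"],
                        "sample_type": ["A"],
                        "plate": ["plate1"],
                        "delta_cq": [0.8],
                    }
                ),
            ],
            ignore_index=True,
        )
        with pytest.warns(UserWarning, match="unbalanced"):
            res = blocked_anova(
                data, DesignSpec(mode="anova", blocks=("plate",))
            )
        flags = {c.pair: c.harmonic_n for c in res.posthoc}
        assert flags[("A", "B")] and flags[("A", "C")]
        assert not flags[("B", "C")]

    def test_posthoc_rejects_degenerate_context(self):
        data = pd.DataFrame(
            {"sample_type": ["A", "A", "B", "B", "C", "C"], "delta_cq": [0.7] * 6}
        )
        res = blocked_anova(data, SPEC_ANOVA)
        with pytest.raises(DesignError, match="zero error"):
            posthoc_pairwise(res, SPEC_ANOVA)


class TestInvariants:
    def test_ci_excludes_zero_iff_significant(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            a = rng.normal(0.0, 0.3, 4)
            b = rng.normal(rng.normal(0, 0.3), 0.3, 4)
            for alpha in (0.05, 0.2):
                spec = DesignSpec(confidence=1 - alpha, check_assumptions=False)
                res = unpaired_test(a, b, spec)
                excludes = res.ci_log[0] > 0 or res.ci_log[1] < 0
                assert excludes == (res.p_value < alpha)

    def test_scale_equivariance(self):
        shift = 2.75
        base_res = unpaired_test(A_VALUES, B_VALUES, SPEC)
        shifted = unpaired_test(
            [v + shift for v in A_VALUES], [v + shift for v in B_VALUES], SPEC
        )
        assert shifted.statistic == pytest.approx(base_res.statistic, rel=1e-9)
        assert shifted.p_value == pytest.approx(base_res.p_value, rel=1e-9)
        assert shifted.ratio == pytest.approx(base_res.ratio, rel=1e-9)
        data = datasets.plate_blocked_delta_cq()
        shifted_data = data.assign(delta_cq=data["delta_cq"] + shift)
        res0 = blocked_anova(data, DesignSpec(mode="anova", blocks=("plate",)))
        res1 = blocked_anova(
            shifted_data, DesignSpec(mode="anova", blocks=("plate",))
        )
        assert res1.factor_source.f == pytest.approx(res0.factor_source.f, rel=1e-9)

    def test_result_internal_consistency(self):
        res = unpaired_test(A_VALUES, B_VALUES, SPEC)
        assert res.ci_log[0] <= res.estimate <= res.ci_log[1]
        assert res.ratio == pytest.approx(10.0**-res.estimate, rel=1e-15)
        assert res.ratio_ci[0] == pytest.approx(10.0**-res.ci_log[1], rel=1e-15)


class TestAnalyzePair:
    def test_paired_requires_matching_labels(self):
        frame = datasets.unpaired_delta_cq()
        frame = frame.assign(
            replicate=["r1", "r2", "r3", "r4", "r1", "r2", "r3", "r5"]
        )
        with pytest.raises(DesignError, match="matching replicate"):
            analyze_pair(frame, "A", "B", SPEC_PAIRED)

    def test_missing_sample_type_rejected(self):
        with pytest.raises(DesignError, match="not both present"):
            analyze_pair(datasets.unpaired_delta_cq(), "A", "Z", SPEC)
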