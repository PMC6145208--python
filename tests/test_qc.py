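"""Detection p-values, failed-probe/sample rules, the MU intensity
statistic, and specificity threshold learning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methval import qc
from methval.methio import IntensityTable


def _table(probe_totals, mu=200.0, sd=20.0, n_controls=2000, seed=0):
    """Intensity table with given probe totals (split evenly M/U) and
    controls drawn so the estimated background is ~(mu, sd)."""
    rng = np.random.default_rng(seed)
    n = len(probe_totals)
    totals = np.asarray(probe_totals, dtype=float)
    ctrl = rng.normal(mu, sd, size=(n_controls, 2))
    frame = pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(n)]
            + [f"c{i}" for i in range(n_controls)],
            "M": np.concatenate([totals / 2, ctrl[:, 0]]),
            "U": np.concatenate([totals / 2, ctrl[:, 1]]),
            "is_background_control": [False] * n + [True] * n_controls,
        }
    )
    return IntensityTable(frame)


def _exact_background_table(probe_totals, mu=200.0, sd=20.0):
    """Controls constructed to have exactly mean mu and sd (ddof=1) after
    per-channel pooling, so p-values can be checked in closed form."""
    # pooled values mu ± sd * sqrt((k-1)/k)-style: use a symmetric pair
    # construction: half at mu+delta, half at mu-delta with delta chosen
    # so the sample sd (ddof=1) equals sd exactly.
    k = 100
    delta = sd * np.sqrt((2 * k - 1) / (2 * k))
    ctrl_m = np.concatenate([np.full(k // 2, mu + delta),
                             np.full(k // 2, mu - delta)])
    ctrl_u = ctrl_m[::-1].copy()
    n = len(probe_totals)
    totals = np.asarray(probe_totals, dtype=float)
    frame = pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(n)]
            + [f"c{i}" for i in range(k)],
            "M": np.concatenate([totals / 2, ctrl_m]),
            "U": np.concatenate([totals / 2, ctrl_u]),
            "is_background_control": [False] * n + [True] * k,
        }
    )
    return IntensityTable(frame)


class TestDetectionPValues:
    def test_closed_form_points(self):
        """p = 1 - Phi((total - 2 mu)/(sqrt(2) sd)): symmetric point, a
        3-sigma point, and the z = sqrt(2) point."""
        totals = [400.0, 400.0 + 3 * 20 * np.sqrt(2), 440.0]
        pvals = qc.detection_pvalues(_exact_background_table(totals))
        assert pvals.iloc[0] == pytest.approx(0.5, abs=1e-9)
        assert pvals.iloc[1] == pytest.approx(0.00135, abs=2e-5)
        assert pvals.iloc[2] == pytest.approx(0.0786, abs=2e-4)

    def test_z_sqrt2_point_fails_at_cutoff(self):
        pvals = qc.detection_pvalues(_exact_background_table([440.0]))
        mask, frac = qc.failed_probe_mask(pvals, cutoff=0.01)
        assert bool(mask.iloc[0]) is True
        assert frac == 1.0

    def test_requires_background_controls(self):
        frame = pd.DataFrame(
            {"probe_id": ["p1"], "M": [100.0], "U": [100.0],
             "is_background_control": [False]}
        )
        with pytest.raises(ValueError, match="background-control"):
            qc.detection_pvalues(IntensityTable(frame))

    def test_degenerate_controls_rejected(self):
        frame = pd.DataFrame(
            {
                "probe_id": [f"c{i}" for i in range(12)] + ["p1"],
                "M": [200.0] * 12 + [500.0],
                "U": [200.0] * 12 + [500.0],
                "is_background_control": [True] * 12 + [False],
            }
        )
        with pytest.raises(ValueError, match="degenerate"):
            qc.detection_pvalues(IntensityTable(frame))

    def test_strong_signal_has_tiny_pvalue(self):
        pvals = qc.detection_pvalues(_table([5000.0]))
        assert pvals.iloc[0] < 1e-6


class TestFailureRules:
    def test_boundary_p_is_not_failed(self):
        pvals = pd.Series([0.01, 0.0099, 0.0101])
        mask, frac = qc.failed_probe_mask(pvals, cutoff=0.01)
        assert list(mask) == [False, False, True]
        assert frac == pytest.approx(1 / 3)

    def test_three_of_sixty_failing(self):
        pvals = pd.Series([0.5] * 3 + [0.001] * 57)
        _, frac = qc.failed_probe_mask(pvals)
        assert frac == pytest.approx(0.05)

    @pytest.mark.parametrize("fraction,passes", [
        (0.0, True), (0.05, True), (0.051, False), (1.0, False),
    ])
    def test_sample_rule_boundary(self, fraction, passes):
        assert qc.sample_sensitivity_pass(fraction) is passes

    def test_empty_pvalues_rejected(self):
        with pytest.raises(ValueError, match="no probes"):
            qc.failed_probe_mask(pd.Series([], dtype=float))


class TestMUStatistic:
    def test_equal_medians(self):
        table = _table([2048.0] * 11)  # M = U = 1024 per probe
        assert qc.mu_statistic(table) == pytest.approx(10.0)

    def test_geometric_mean_symmetry(self):
        frame = pd.DataFrame(
            {
                "probe_id": ["p1", "p2", "p3", "c1"],
                "M": [512.0, 512.0, 512.0, 200.0],
                "U": [2048.0, 2048.0, 2048.0, 200.0],
                "is_background_control": [False, False, False, True],
            }
        )
        assert qc.mu_statistic(IntensityTable(frame)) == pytest.approx(10.0)

    def test_monotone_in_both_medians(self, rng):
        base = _table(rng.uniform(500, 1500, 101))
        brighter = IntensityTable(
            base.frame.assign(M=base.frame["M"] * 2, U=base.frame["U"] * 2)
        )
        assert qc.mu_statistic(brighter) > qc.mu_statistic(base)


class TestNormalAberrantRange:
    def test_worked_example(self):
        counts = [10, 12, 14, 9, 11, 13, 10, 12]
        lo, hi = qc.normal_aberrant_range(counts)
        assert lo == pytest.approx(7.03, abs=0.01)
        assert hi == pytest.approx(15.72, abs=0.01)
        assert not (lo <= 40 <= hi)  # a clearly contaminated count is outside

    def test_constant_counts_zero_width(self):
        lo, hi = qc.normal_aberrant_range([7, 7, 7, 7])
        assert lo == hi == 7.0

    def test_lower_bound_floored_at_zero(self):
        lo, _ = qc.normal_aberrant_range([0, 1, 0, 2, 1])
        assert lo == 0.0

    def test_needs_three_counts(self):
        with pytest.raises(ValueError, match=">= 3"):
            qc.normal_aberrant_range([1, 2])


class TestMUThreshold:
    def test_midpoint(self):
        assert qc.learn_mu_threshold([9.0, 9.5], [10.4, 11.0]) == pytest.approx(
            9.95
        )

    def test_symmetric_gap(self):
        eps = 0.01
        assert qc.learn_mu_threshold(
            [9.96 - eps], [9.96 + eps]
        ) == pytest.approx(9.96)

    def test_classifies_training_data_perfectly(self, rng):
        failed = rng.uniform(8.0, 9.4, 10)
        passed = rng.uniform(9.8, 11.0, 10)
        thr = qc.learn_mu_threshold(failed, passed)
        assert (failed < thr).all() and (passed >= thr).all()

    def test_non_separable_rejected_with_overlap(self):
        with pytest.raises(ValueError, match="not separable"):
            qc.learn_mu_threshold([9.0, 10.1], [10.0, 11.0])

    @given(
        st.lists(st.floats(5, 9.49, allow_nan=False), min_size=1, max_size=20),
        st.lists(st.floats(9.51, 14, allow_nan=False), min_size=1, max_size=20),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_brute_force_margin_search(self, failed, passed):
        thr = qc.learn_mu_threshold(failed, passed)
        # brute force: scan midpoints of adjacent sorted values, keep the
        # perfectly separating cut with the widest margin
        values = np.sort(np.array(failed + passed))
        best, best_margin = None, -1.0
        for cut in (values[:-1] + values[1:]) / 2:
            if all(f < cut for f in failed) and all(p >= cut for p in passed):
                margin = min(cut - max(failed), min(passed) - cut)
                if margin > best_margin:
                    best, best_margin = cut, margin
        assert best is not None
        assert thr == pytest.approx(best, abs=1e-9)
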