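"""Replicate-similarity statistics and proficiency-testing pass rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methval import calling, precision, reference
from methval.calling import AberrantCallSet
from methval.simulate import (SimConfig, draw_locus_means,
                              gen_reference_population,
                              gen_technical_replicates)


def _calls_from_matrix(aberrant: np.ndarray, t=0.2) -> list[AberrantCallSet]:
    """Column j of the 0/1 matrix -> replicate j's calls."""
    loci = [f"cg{i}" for i in range(aberrant.shape[0])]
    return [
        AberrantCallSet(
            f"rep{j}",
            pd.Series(np.where(aberrant[:, j], "hyper", "normal"),
                      index=loci, dtype=object),
            t,
        )
        for j in range(aberrant.shape[1])
    ]


class TestLocusSimilarity:
    @pytest.mark.parametrize("x,n,expected", [
        (6, 6, 1.0),
        (0, 6, 1.0),
        (3, 6, 0.5),
        (1, 6, 5 / 6),
    ])
    def test_values(self, x, n, expected):
        assert precision.locus_similarity(x, n) == pytest.approx(expected)

    @given(st.integers(1, 50), st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetry(self, n, data):
        x = data.draw(st.integers(0, n))
        assert precision.locus_similarity(x, n) == precision.locus_similarity(
            n - x, n
        )
        assert 0.5 <= precision.locus_similarity(x, n) <= 1.0

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            precision.locus_similarity(3, 0)
        with pytest.raises(ValueError):
            precision.locus_similarity(7, 6)


class TestSampleSimilarity:
    def test_mean_of_per_locus_values(self):
        # loci with S = {1, 1, 1, 0.5} -> S_jt = 0.875
        aberrant = np.array([
            [0, 0], [1, 1], [0, 0], [1, 0],
        ])
        report = precision.sample_similarity(_calls_from_matrix(aberrant))
        assert report.s_jt == pytest.approx(0.875)
        assert report.m == 4

    def test_identical_replicates_give_one(self, rng):
        aberrant = rng.integers(0, 2, 50)[:, None].repeat(5, axis=1)
        report = precision.sample_similarity(_calls_from_matrix(aberrant))
        assert report.s_jt == 1.0

    @given(st.integers(2, 8), st.integers(1, 40), st.data())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_brute_force(self, n_reps, m, data):
        flat = data.draw(
            st.lists(st.integers(0, 1), min_size=m * n_reps,
                     max_size=m * n_reps)
        )
        aberrant = np.array(flat).reshape(m, n_reps)
        report = precision.sample_similarity(_calls_from_matrix(aberrant))
        brute = np.mean([
            max(row.sum(), n_reps - row.sum()) / n_reps for row in aberrant
        ])
        assert report.s_jt == pytest.approx(brute)

    def test_pairwise_matrix_symmetric_zero_diagonal(self, rng):
        aberrant = rng.integers(0, 2, (30, 4))
        mat = precision.pairwise_difference_matrix(
            _calls_from_matrix(aberrant)
        )
        assert np.array_equal(mat, mat.T)
        assert np.all(np.diag(mat) == 0)

    def test_pairwise_mean_bounded_by_twice_dissimilarity(self, rng):
        """Mean pairwise set difference <= 2 m (1 - S_jt), deterministically."""
        for _ in range(10):
            aberrant = rng.integers(0, 2, (40, 6))
            calls = _calls_from_matrix(aberrant)
            report = precision.sample_similarity(calls)
            pw = precision.pairwise_difference_matrix(calls)
            mean_pw = pw[np.triu_indices(6, 1)].mean()
            assert mean_pw <= 2 * report.m * (1 - report.s_jt) + 1e-9


@pytest.fixture(scope="module")
def ref_and_config():
    config = SimConfig(n_loci=800, n_reference_samples=80, seed=21)
    table = reference.build_reference(gen_reference_population(config))
    return config, table


class TestThresholdSweep:
    def test_zero_noise_similarity_is_one(self, ref_and_config):
        config, table = ref_and_config
        quiet = SimConfig(**{**config.to_dict(), "replicate_noise_sd": 0.0,
                             "outlier_rate": 0.0})
        means, sds = draw_locus_means(quiet)
        truth = np.clip(means, 0, 1)
        mats = {"s": gen_technical_replicates(truth, 4, quiet)}
        sweep = precision.threshold_sweep(mats, table, [0.1, 0.2, 0.4], 0.052)
        assert (sweep["mean"] == 1.0).all()

    def test_degenerate_threshold_gives_one(self, ref_and_config, rng):
        config, table = ref_and_config
        means, sds = draw_locus_means(config)
        truth = np.clip(means + sds * rng.standard_normal(means.size), 0, 1)
        mats = {"s": gen_technical_replicates(truth, 4, config)}
        sweep = precision.threshold_sweep(mats, table, [0.999], 0.052)
        assert sweep["mean"].iloc[0] == 1.0

    def test_mean_curve_nondecreasing_in_t(self, ref_and_config, rng):
        config, table = ref_and_config
        means, sds = draw_locus_means(config)
        mats = {}
        for s in range(3):
            truth = np.clip(means + sds * rng.standard_normal(means.size),
                            0, 1)
            mats[f"s{s}"] = gen_technical_replicates(
                truth, 6, config, rng=np.random.default_rng(s)
            )
        grid = [0.05, 0.1, 0.2, 0.3, 0.4]
        sweep = precision.threshold_sweep(mats, table, grid, 0.052)
        assert (np.diff(sweep["mean"].to_numpy()) >= -1e-12).all()

    def test_empty_grid_rejected(self, ref_and_config):
        _, table = ref_and_config
        with pytest.raises(ValueError, match="empty"):
            precision.threshold_sweep({}, table, [], 0.052)


class TestProficiencyTesting:
    def test_allowance_is_floored(self):
        """m=6690, rate 0.3%, slack 20% -> floor(24.084) = 24 allowed."""
        base = np.zeros((6690, 1), dtype=int)
        calls = _calls_from_matrix(np.hstack([base, base]))
        outcome = precision.pt_evaluate(calls, 0.003, 0.2, 0.8, 6690)
        assert outcome.allowance == 24

    @pytest.mark.parametrize("n_diff,passes", [(24, True), (25, False)])
    def test_boundary_replicate(self, n_diff, passes):
        first = np.zeros((6690, 1), dtype=int)
        second = np.zeros((6690, 1), dtype=int)
        second[:n_diff] = 1
        calls = _calls_from_matrix(np.hstack([first, second]))
        outcome = precision.pt_evaluate(calls, 0.003, 0.2, 1.0, 6690)
        assert outcome.per_replicate["passed"].iloc[0] == passes
        assert outcome.passed == passes

    def test_four_of_five_replicates_pass_at_80pct(self):
        m = 1000
        base = np.zeros((m, 1), dtype=int)
        bad = np.zeros((m, 1), dtype=int)
        bad[:500] = 1  # way over any allowance
        aberrant = np.hstack([base, base, base, base, base, bad])
        outcome = precision.pt_evaluate(
            _calls_from_matrix(aberrant), 0.003, 0.2, 0.8, m
        )
        # replicates 2..5 pass, the last fails: 4/5 = 0.8 passes the run
        assert outcome.pass_fraction_observed == pytest.approx(0.8)
        assert outcome.passed

    def test_zero_differences_pass(self):
        base = np.zeros((100, 1), dtype=int)
        calls = _calls_from_matrix(np.hstack([base] * 4))
        assert precision.pt_evaluate(calls, 0.003, 0.2, 0.8, 100).passed

    def test_needs_prior_replicates(self):
        calls = _calls_from_matrix(np.zeros((10, 1), dtype=int))
        with pytest.raises(ValueError, match="prior"):
            precision.pt_evaluate(calls, 0.003, 0.2, 0.8, 10)


class TestLongRunEmulation:
    def test_long_run_mean_differences_below_allowed_rate(self):
        """14- and 18-replicate series at m = 6690 loci: pooled mean
        pairwise differences stay under 20 when the per-call
        inconsistency is at the 0.3% operating point."""
        config = SimConfig(seed=0)
        table = reference.build_reference(gen_reference_population(config))
        means, sds = draw_locus_means(config)
        total, count = 0.0, 0
        for k_idx, n_long in enumerate((14, 18)):
            rng = np.random.default_rng([config.seed, 7, k_idx])
            truth = np.clip(means + sds * rng.standard_normal(means.size),
                            0, 1)
            mat = gen_technical_replicates(truth, n_long, config, rng=rng)
            calls = [
                calling.call_sample(mat.sample(r), table, 0.2, 0.052)
                for r in mat.sample_ids
            ]
            pw = precision.pairwise_difference_matrix(calls)
            off = pw[np.triu_indices(n_long, 1)]
            report = precision.sample_similarity(calls)
            assert 1 - report.s_jt <= 0.003
            total += off.sum()
            count += off.size
        assert total / count < 20
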