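"""Interaction-matrix resampling and diet-breadth classification."""

import numpy as np
import pytest

from prefperf import (
    DiversityEstimate,
    ResamplingPlan,
    aggregate_survival,
    alpha_distributions,
    classify_by_alpha,
    load_roster,
    resample_matrices,
)

from conftest import tiny_dataset


def _deterministic_dataset():
    """One oviposition replicate and exactly five cups per cell."""
    eggs = {("a", 1): [10], ("a", 2): [5], ("b", 1): [3], ("b", 2): [3]}
    cups = {k: [1, 1, 0, 1, 0] for k in eggs}
    return tiny_dataset(eggs, cups)


class TestResampleMatrices:
    def test_deterministic_dataset_gives_identical_matrices(self):
        ds = _deterministic_dataset()
        plan = ResamplingPlan(n_matrices=5, seed=1)
        pairs = resample_matrices(ds, plan)
        for eggs, surv in pairs[1:]:
            np.testing.assert_array_equal(eggs.values, pairs[0][0].values)
            np.testing.assert_array_equal(surv.values, pairs[0][1].values)
        assert pairs[0][1].values[0, 0] == pytest.approx(3 / 5)

    def test_same_seed_reproduces_exactly(self, default_dataset):
        plan = ResamplingPlan(n_matrices=4, seed=9)
        a = resample_matrices(default_dataset, plan)
        b = resample_matrices(default_dataset, plan)
        for (ea, sa), (eb, sb) in zip(a, b):
            assert ea.values.tobytes() == eb.values.tobytes()
            assert sa.values.tobytes() == sb.values.tobytes()

    def test_extending_b_keeps_earlier_matrices(self, default_dataset):
        short = resample_matrices(default_dataset, ResamplingPlan(n_matrices=3, seed=9))
        long = resample_matrices(default_dataset, ResamplingPlan(n_matrices=6, seed=9))
        for (ea, sa), (eb, sb) in zip(short, long):
            np.testing.assert_array_equal(ea.values, eb.values)
            np.testing.assert_array_equal(sa.values, sb.values)

    def test_every_resample_has_full_design_shape(self, default_dataset):
        for eggs, surv in resample_matrices(default_dataset, ResamplingPlan(n_matrices=3, seed=0)):
            assert eggs.shape == (29, 6)
            assert surv.shape == (29, 6)

    def test_survival_sampling_matches_hypergeometric_mean(self):
        # 2 pupae in 10 cups, k = 5 sampled without replacement: mean 0.2
        eggs = {("a", 1): [1], ("b", 1): [1]}
        cups = {("a", 1): [1, 1] + [0] * 8, ("b", 1): [1] * 5}
        ds = tiny_dataset(eggs, cups)
        pairs = resample_matrices(ds, ResamplingPlan(n_matrices=2000, seed=3))
        vals = np.array([surv.values[0, 0] for _, surv in pairs])
        # per-draw variance p(1-p)(N-k)/(k(N-1)); 3 standard errors of the mean
        se = np.sqrt(0.2 * 0.8 * 5 / (5 * 9) / 2000)
        assert abs(vals.mean() - 0.2) < 3 * se

    def test_full_cup_count_reproduces_aggregate_proportions(self):
        eggs = {("a", 1): [4, 2], ("a", 2): [1, 7]}
        cups = {("a", 1): [1, 0, 1, 0], ("a", 2): [1, 1, 1, 0]}
        ds = tiny_dataset(eggs, cups)
        plan = ResamplingPlan(n_matrices=10, k_survival=4, seed=0)
        agg = aggregate_survival(ds.survival).set_index(["species", "fruit_id"])["survival"]
        for _, surv in resample_matrices(ds, plan):
            assert surv.values[0, 0] == pytest.approx(agg[("a", 1)])
            assert surv.values[1, 0] == pytest.approx(agg[("a", 2)])

    def test_monte_carlo_mean_converges_to_cell_mean(self):
        eggs = {("a", 1): [0, 3, 6, 9, 12, 30], ("a", 2): [1, 1]}
        cups = {("a", 1): [1, 0], ("a", 2): [1, 0]}
        ds = tiny_dataset(eggs, cups)
        pairs = resample_matrices(ds, ResamplingPlan(n_matrices=5000, seed=2))
        vals = np.array([e.values[0, 0] for e, _ in pairs])
        pool = np.array([0, 3, 6, 9, 12, 30])
        se = pool.std() / np.sqrt(5000)
        assert abs(vals.mean() - pool.mean()) < 3 * se


class TestAlphaDistributions:
    def test_deterministic_dataset_has_zero_variance(self):
        ds = _deterministic_dataset()
        ests = alpha_distributions(ds, ResamplingPlan(n_matrices=50, seed=1))
        assert all(e.var_alpha == 0.0 for e in ests)

    def test_single_host_species_alpha_one(self):
        eggs = {("a", 1): [10, 12], ("a", 2): [0, 0], ("b", 1): [1], ("b", 2): [1]}
        cups = {k: [1, 0, 1] for k in eggs}
        ds = tiny_dataset(eggs, cups)
        ests = alpha_distributions(
            ds, ResamplingPlan(n_matrices=40, k_survival=3, seed=0), measures=("eggs",)
        )
        a = next(e for e in ests if e.species == "a")
        assert a.mean_alpha == pytest.approx(1.0)
        assert a.var_alpha == 0.0

    def test_uniform_species_recovers_host_count(self):
        # large equal counts over 6 hosts: alpha must sit within 5% of 6
        rng = np.random.default_rng(5)
        eggs = {("a", f): list(rng.poisson(500, size=4)) for f in range(1, 7)}
        cups = {("a", f): [1, 0, 1, 0, 1] for f in range(1, 7)}
        ds = tiny_dataset(eggs, cups)
        ests = alpha_distributions(
            ds, ResamplingPlan(n_matrices=100, seed=1), measures=("eggs",)
        )
        assert ests[0].mean_alpha == pytest.approx(6.0, rel=0.05)

    def test_all_zero_species_rejected(self):
        eggs = {("a", 1): [1, 2], ("b", 1): [0, 0]}
        cups = {("a", 1): [1, 0], ("b", 1): [1, 0]}
        ds = tiny_dataset(eggs, cups)
        with pytest.raises(ValueError, match="degenerate"):
            alpha_distributions(ds, ResamplingPlan(n_matrices=5, seed=0), measures=("eggs",))

    def test_mean_and_variance_consistent_with_samples(self, default_dataset):
        ests = alpha_distributions(
            default_dataset, ResamplingPlan(n_matrices=30, seed=4), measures=("eggs",)
        )
        for e in ests:
            assert e.mean_alpha == pytest.approx(np.nanmean(e.samples))
            assert e.var_alpha == pytest.approx(np.nanvar(e.samples, ddof=1))


def _fake_estimates(means, spread=0.0, b=8):
    rng = np.random.default_rng(0)
    out = []
    for i, m in enumerate(means):
        samples = np.full(b, float(m)) + (rng.normal(0, spread, b) if spread else 0.0)
        out.append(
            DiversityEstimate(
                species=f"sp{i}", measure="eggs", mean_alpha=float(np.mean(samples)),
                var_alpha=float(np.var(samples, ddof=1)) if spread else 0.0,
                samples=samples,
            )
        )
    return out


class TestClassification:
    def test_largest_gap_split(self):
        ests = _fake_estimates([1.2, 1.5, 9, 10, 11, 12])
        res = classify_by_alpha(ests)
        by = {a.species: a.assigned_guild for a in res.assignments}
        assert by["sp0"] == by["sp1"] == "specialist"
        assert all(by[f"sp{i}"] == "generalist" for i in (2, 3, 4, 5))
        assert res.separation_score == 1.0
        assert not res.degenerate

    def test_equal_means_flagged_degenerate(self):
        res = classify_by_alpha(_fake_estimates([3.0, 3.0, 3.0]))
        assert res.degenerate
        assert 0.0 <= res.separation_score <= 1.0

    def test_single_species_rejected(self):
        with pytest.raises(ValueError, match="two species"):
            classify_by_alpha(_fake_estimates([2.0]))

    def test_agreement_with_a_priori_roster(self, default_dataset):
        ests = alpha_distributions(
            default_dataset, ResamplingPlan(n_matrices=30, seed=4), measures=("eggs", "survival")
        )
        res = classify_by_alpha(ests, load_roster())
        assert res.agreement
        assert res.separation_score > 0.9
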