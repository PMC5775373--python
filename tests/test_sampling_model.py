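import math

import numpy as np
import pytest

from alteredself import (
    PeptideRecord,
    RepertoirePair,
    SamplingConfig,
    enumerate_category_frequencies,
    fold_change,
    ligand_density,
    run_sampling,
    sample_ligand_set,
    specificity_sweep,
)
from alteredself.exceptions import EmptyInputError, ParameterError, UndefinedCategoryError
from alteredself.sampling_model import derive_seed
from alteredself.synthetic_data import GeneratorParams, generate_repertoire_pair

CATEGORIES = ("increase", "equal", "decrease", "novel", "decrease_ge50", "disappeared")


def assert_within_3se(mc: dict, exact: dict, replicates: int):
    for key in CATEGORIES:
        se = math.sqrt(max(exact[key] * (1 - exact[key]), 1e-12) / replicates)
        assert abs(mc[f"frac_{key}" if f"frac_{key}" in mc else key] - exact[key]) <= 3 * se + 1e-12, key


class TestSampleLigandSet:
    def test_p_one_returns_full_pool(self, toy_pair):
        rng = np.random.default_rng(0)
        subset = sample_ligand_set(toy_pair, 1.0, rng)
        assert set(subset) == set(toy_pair.records)

    def test_p_zero_is_parameter_error(self, toy_pair):
        with pytest.raises(ParameterError):
            sample_ligand_set(toy_pair, 0.0, np.random.default_rng(0))

    def test_empty_pool_is_error(self):
        with pytest.raises(EmptyInputError):
            sample_ligand_set(RepertoirePair("e", {}), 0.5, np.random.default_rng(0))

    def test_subset_size_matches_binomial_expectation(self):
        pair = generate_repertoire_pair(
            GeneratorParams(n_self_pre=1000, frac_novel_self=0.0, n_viral=0, seed=1)
        )
        rng = np.random.default_rng(123)
        n, p, reps = 1000, 0.2, 10_000
        sizes = [len(sample_ligand_set(pair, p, rng)) for _ in range(reps)]
        se = math.sqrt(n * p * (1 - p) / reps)
        assert abs(np.mean(sizes) - n * p) <= 3 * se


class TestLigandDensity:
    def test_full_pool_gives_totals(self, small_pair):
        subset = tuple(small_pair.records)
        assert ligand_density(subset, small_pair, "uninfected") == small_pair.T_H
        assert ligand_density(subset, small_pair, "infected") == pytest.approx(
            small_pair.T_HI + small_pair.T_MV
        )

    def test_empty_subset_is_zero(self, small_pair):
        assert ligand_density((), small_pair, "uninfected") == 0.0

    def test_single_peptide(self, toy_pair):
        assert ligand_density(("AAAAAAAAA",), toy_pair, "uninfected") == 2.0
        assert ligand_density(("AAAAAAAAA",), toy_pair, "infected") == 0.0


class TestFoldChange:
    @pytest.mark.parametrize("lu,li,expected", [(10, 5, -0.5), (5, 5, 0.0), (2, 3, 0.5)])
    def test_values(self, lu, li, expected):
        assert fold_change(lu, li) == pytest.approx(expected)

    def test_novel_sentinel_and_undefined(self):
        assert fold_change(0.0, 2.0) == math.inf
        with pytest.raises(UndefinedCategoryError):
            fold_change(0.0, 0.0)


class TestRunSampling:
    def test_toy_pool_matches_enumeration(self, toy_pair):
        """Seven equally weighted nonempty subsets at p=1/2: decrease 4/7,
        increase 2/7, equal 1/7 (frozen from exhaustive enumeration)."""
        exact = enumerate_category_frequencies(toy_pair, 0.5)
        assert exact["decrease"] == pytest.approx(4 / 7)
        assert exact["increase"] == pytest.approx(2 / 7)
        assert exact["equal"] == pytest.approx(1 / 7)
        reps = 100_000
        result = run_sampling(toy_pair, SamplingConfig(p=0.5, replicates=reps, seed=7))
        assert_within_3se(result.frequencies, exact, reps)

    def test_random_small_pool_matches_enumeration(self):
        pair = generate_repertoire_pair(
            GeneratorParams(n_self_pre=8, frac_disappear=0.5, frac_novel_self=0.25,
                            n_viral=2, seed=5)
        )
        assert len(pair) == 12
        exact = enumerate_category_frequencies(pair, 0.3)
        reps = 50_000
        result = run_sampling(pair, SamplingConfig(p=0.3, replicates=reps, seed=21))
        assert_within_3se(result.frequencies, exact, reps)

    def test_p_one_degenerates_to_total_fold_change(self):
        pair = generate_repertoire_pair(GeneratorParams(n_self_pre=50, seed=3, n_viral=2))
        expected = (pair.T_HI + pair.T_MV - pair.T_H) / pair.T_H
        result = run_sampling(pair, SamplingConfig(p=1.0, replicates=200, seed=1))
        assert np.all(result.fold_changes == expected)
        assert result.n_pool == len(pair)

    def test_same_seed_is_bit_identical(self, toy_pair):
        config = SamplingConfig(p=0.3, replicates=500, seed=99)
        a = run_sampling(toy_pair, config)
        b = run_sampling(toy_pair, config)
        assert np.array_equal(a.l_u, b.l_u) and np.array_equal(a.l_i, b.l_i)
        assert a.frequencies == b.frequencies and a.n_redraws == b.n_redraws

    def test_skip_policy_reports_skipped_draws(self, toy_pair):
        config = SamplingConfig(p=0.05, replicates=2000, seed=4, empty_policy="skip")
        result = run_sampling(toy_pair, config)
        assert result.n_skipped > 0
        assert len(result.categories) == 2000 - result.n_skipped
        top = sum(result.frequencies[k] for k in ("increase", "equal", "decrease"))
        assert top == pytest.approx(1.0, abs=1e-9)

    def test_kir_pool_mode_restricts_before_sampling(self, small_pair):
        config = SamplingConfig(p=1.0, replicates=1, seed=0, pool_mode="kir_epitopes")
        result = run_sampling(small_pair, config)
        assert result.n_pool == 3  # A*02:01 and NA peptides excluded

    def test_small_p_approaches_single_peptide_disappearance(self):
        # at p -> 0 a nonempty draw is almost surely one peptide, so the
        # disappearance frequency approaches the per-peptide disappear fraction
        pair = generate_repertoire_pair(
            GeneratorParams(n_self_pre=10, frac_disappear=0.5, frac_novel_self=0.0,
                            n_viral=0, seed=2)
        )
        exact = enumerate_category_frequencies(pair, 1e-4)
        assert exact["disappeared"] == pytest.approx(0.5, abs=1e-3)


class TestSpecificitySweep:
    def test_singleton_grid_matches_run_sampling(self, toy_pair):
        sweep = specificity_sweep(toy_pair, p_values=[1.0], replicates=100, seed=13)
        single = run_sampling(
            toy_pair, SamplingConfig(p=1.0, replicates=100, seed=derive_seed(13, 0))
        )
        row = sweep.iloc[0]
        for key in CATEGORIES:
            assert row[f"frac_{key}"] == single.frequencies[key]

    def test_everything_disappears_at_every_p(self):
        pair = RepertoirePair.from_records(
            "gone",
            [
                PeptideRecord("AAAAAAAAA", 2.0, 0.0),
                PeptideRecord("CCCCCCCCC", 5.0, 0.0),
                PeptideRecord("DDDDDDDDD", 1.0, 0.0),
            ],
        )
        sweep = specificity_sweep(pair, p_values=[0.1, 0.5, 1.0], replicates=300, seed=8)
        assert (sweep["frac_disappeared"] == 1.0).all()

    def test_disappearance_detection_decreases_with_degeneracy(self):
        # 6 disappearing + 6 unchanged peptides: exact enumeration over the
        # standard grid must be monotonically non-increasing, and the
        # Monte-Carlo sweep must agree within 3 standard errors
        records = [PeptideRecord(f"AAAAAA{a}{b}A", 1.0, 0.0) for a, b in
                   zip("CDEFGH", "CDEFGH")]
        records += [PeptideRecord(f"AAAAAA{a}{b}A", 1.0, 1.0) for a, b in
                    zip("IKLMNQ", "IKLMNQ")]
        pair = RepertoirePair.from_records("half", records)
        grid = (0.0025, 0.01, 0.04, 0.0625, 0.125, 0.25, 0.5, 0.75, 1.0)
        exact = [enumerate_category_frequencies(pair, p)["disappeared"] for p in grid]
        assert all(a >= b - 1e-12 for a, b in zip(exact, exact[1:]))
        assert exact[0] > exact[-1]
        reps = 20_000
        sweep = specificity_sweep(pair, p_values=grid, replicates=reps, seed=3)
        for mc, ex in zip(sweep["frac_disappeared"], exact):
            se = math.sqrt(max(ex * (1 - ex), 1e-12) / reps)
            assert abs(mc - ex) <= 3 * se + 1e-12

    def test_order_independent_substreams(self, toy_pair):
        full = specificity_sweep(toy_pair, p_values=[0.25, 0.75], replicates=400, seed=5)
        # the second grid entry alone, seeded by its index, reproduces its row
        single = run_sampling(
            toy_pair, SamplingConfig(p=0.75, replicates=400, seed=derive_seed(5, 1))
        )
        assert full.iloc[1]["frac_decrease"] == single.frequencies["decrease"]
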