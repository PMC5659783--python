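"""Tests for the quantile summary, chi-square objective, benchmarks,
information criteria, likelihood-ratio tests and the parity split."""

import numpy as np
import pandas as pd
import pytest

from vssm import (
    FITTED_PARAMS,
    SimConfig,
    chi2_statistic,
    information_criteria,
    lr_test,
    null_predict,
    parity_split,
    saturated_predict,
    summarize,
)
from vssm.fitting import (
    EmpiricalPredictor,
    FitResult,
    QuantileCell,
    QuantileTable,
    summarize_arrays,
)
from vssm.simulate import simulate_dataset, simulate_pairs
from vssm.design import value_pairs


def toy_dataset(rows):
    """Trial table from (v_left, v_right, choice, rt_ms) tuples."""
    df = pd.DataFrame(rows, columns=["v_left", "v_right", "choice", "rt_ms"])
    df.insert(0, "trial", np.arange(1, len(df) + 1))
    df.insert(0, "subject", 1)
    return df


@pytest.fixture(scope="module")
def sim_dataset(config):
    design = [(p, 120) for p in value_pairs()]
    return simulate_dataset(FITTED_PARAMS["SCA"], design, config, seed=42)


class TestSummarize:
    def test_choice_frequencies(self):
        rows = [(1, 3, "R", 500)] * 6 + [(1, 3, "L", 500)] * 4
        table = summarize(toy_dataset(rows))
        freqs = {c.cat: c.freq for c in table.cells}
        assert freqs[1] == pytest.approx(0.6)  # greater value chosen
        assert freqs[0] == pytest.approx(0.4)

    def test_fast_contaminants_are_dropped(self):
        rows = [(1, 3, "R", 400 + 10 * i) for i in range(10)]
        rows.append((1, 3, "R", 250))  # contaminant below 300 ms
        table = summarize(toy_dataset(rows))
        assert table.n_responded == 10
        cell = next(c for c in table.cells if c.cat == 1)
        assert cell.n == 10
        assert np.all(cell.edges >= 300)

    def test_quantiles_use_linear_interpolation(self):
        rows = [(2, 4, "R", rt) for rt in range(400, 1301, 100)]
        table = summarize(toy_dataset(rows))
        cell = next(c for c in table.cells if c.cat == 1)
        # frozen sort-and-interpolate oracle for 400..1300 by 100
        assert cell.edges[2] == pytest.approx(850.0)
        assert cell.edges[0] == pytest.approx(490.0)
        assert np.all(np.diff(cell.edges) >= 0)

    def test_sparse_choices_contribute_frequency_only(self):
        rows = [(1, 3, "R", 500 + i) for i in range(20)]
        rows += [(1, 3, "L", 700), (1, 3, "L", 800)]  # 2 < 5 trials
        table = summarize(toy_dataset(rows))
        lo_cell = next(c for c in table.cells if c.cat == 0)
        assert lo_cell.edges is None
        assert lo_cell.props == pytest.approx([2 / 22])

    def test_props_sum_to_one_per_vector(self, sim_dataset):
        table = summarize(sim_dataset)
        for pair in table.pairs:
            total = sum(c.props.sum() for c in table.cells if c.pair == pair)
            assert total == pytest.approx(1.0)

    def test_empty_dataset_is_rejected(self):
        with pytest.raises(ValueError):
            summarize(toy_dataset([]))


class _FixedPredictor:
    def __init__(self, props_by_cat):
        self.props_by_cat = props_by_cat

    def predict_props(self, cell):
        return np.asarray(self.props_by_cat[cell.cat], dtype=float)


class TestChiSquare:
    def test_identical_distributions_give_zero(self, sim_dataset):
        table = summarize(sim_dataset)
        assert chi2_statistic(table, sim_dataset) == pytest.approx(0.0)

    def test_two_bin_hand_worked_example(self):
        """p_obs=(0.3,0.7) vs p_pred=(0.5,0.5) at N_eff=100 gives 16.0."""
        cells = (
            QuantileCell(pair=(1.0, 2.0), cat=0, n=30, freq=0.3,
                         edges=None, props=np.array([0.3])),
            QuantileCell(pair=(1.0, 2.0), cat=1, n=70, freq=0.7,
                         edges=None, props=np.array([0.7])),
        )
        table = QuantileTable(cells=cells, n_responded=100,
                              pairs=((1.0, 2.0),))
        predictor = _FixedPredictor({0: [0.5], 1: [0.5]})
        assert chi2_statistic(table, predictor) == pytest.approx(16.0)

    def test_invariant_to_left_right_relabeling(self, sim_dataset, config):
        """Summaries key on value-pair identity, not presentation side."""
        flipped = sim_dataset.copy()
        flipped["v_left"] = sim_dataset["v_right"]
        flipped["v_right"] = sim_dataset["v_left"]
        flipped["choice"] = sim_dataset["choice"].map(
            {"L": "R", "R": "L", "NONE": "NONE"})
        design = [(p, 200) for p in value_pairs()]
        predicted = simulate_dataset(FITTED_PARAMS["SCA"], design, config,
                                     seed=77)
        a = chi2_statistic(summarize(sim_dataset), predicted)
        b = chi2_statistic(summarize(flipped), predicted)
        # equal-value pairs relabel their arbitrary side split, so compare
        # the unequal-pair contribution exactly via full-table equality
        assert a == pytest.approx(b)

    def test_invariant_to_record_order(self, sim_dataset):
        shuffled = sim_dataset.sample(frac=1.0, random_state=0)
        predicted = sim_dataset.iloc[::-1]
        a = chi2_statistic(summarize(sim_dataset), predicted)
        b = chi2_statistic(summarize(shuffled), predicted)
        assert a == pytest.approx(b)

    def test_additive_over_vectors(self, sim_dataset, config):
        table = summarize(sim_dataset)
        design = [(p, 150) for p in value_pairs()]
        predictor = EmpiricalPredictor.from_dataset(
            simulate_dataset(FITTED_PARAMS["SCA"], design, config, seed=9))
        total = chi2_statistic(table, predictor)
        parts = 0.0
        for pair in table.pairs:
            cells = tuple(c for c in table.cells if c.pair == pair)
            # keep the full table's pair bookkeeping so N_eff is unchanged
            sub = QuantileTable(cells=cells,
                                n_responded=table.n_responded,
                                pairs=table.pairs)
            parts += chi2_statistic(sub, predictor)
        assert total == pytest.approx(parts)


class TestBenchmarks:
    def test_saturated_in_sample_chi2_is_zero(self, sim_dataset):
        table = summarize(sim_dataset)
        predictor = saturated_predict(sim_dataset)
        assert chi2_statistic(table, predictor) == 0.0

    def test_null_choice_frequency_is_flat_across_vectors(self, sim_dataset):
        predictor = null_predict(sim_dataset)
        table = summarize(sim_dataset)
        freqs = {c.pair: predictor.predict_props(c).sum()
                 for c in table.cells if c.cat == 1 and c.pair[0] != c.pair[1]}
        assert len(set(np.round(list(freqs.values()), 12))) == 1

    def test_null_rt_density_integrates_to_one(self, sim_dataset):
        predictor = null_predict(sim_dataset)
        table = summarize(sim_dataset)
        for pair in table.pairs:
            total = sum(predictor.predict_props(c).sum()
                        for c in table.cells if c.pair == pair)
            assert total == pytest.approx(1.0)

    def test_null_is_dominated_by_the_generating_model(self, sim_dataset,
                                                       config):
        table = summarize(sim_dataset)
        chi2_null = chi2_statistic(table, null_predict(sim_dataset))
        pairs = np.asarray(table.pairs, dtype=float)
        sim = simulate_pairs(FITTED_PARAMS["SCA"], pairs, 2000, config, 123)
        chi2_truth = chi2_statistic(table, EmpiricalPredictor(pairs, *sim))
        assert chi2_truth < chi2_null


class TestInformationCriteria:
    def test_frozen_hand_computed_values(self):
        # oracles: 153.26 + 12 + 84/113 and 153.26 + 6*ln(120)
        aicc, bic = information_criteria(153.26, k=6, n_cells=120)
        assert aicc == pytest.approx(166.0033628318584)
        assert bic == pytest.approx(181.98495045669227)

    def test_zero_parameters_reduce_to_chi2(self):
        aicc, bic = information_criteria(42.0, k=0, n_cells=50)
        assert aicc == 42.0 and bic == 42.0

    def test_bic_penalty_exceeds_aicc_penalty_at_large_n(self):
        chi2 = 100.0
        for k in (3, 6):
            aicc, bic = information_criteria(chi2, k, n_cells=120)
            assert bic > aicc  # ln(120) > 2 + 2(k+1)/(120-k-1)

    def test_undefined_below_minimum_cell_count(self):
        with pytest.raises(ValueError):
            information_criteria(10.0, k=6, n_cells=7)


def _fit_result(model_id, chi2):
    params = FITTED_PARAMS[model_id]
    return FitResult(params=params, chi2=chi2, df=params.df, n_cells=120,
                     aicc=np.nan, bic=np.nan)


class TestLikelihoodRatio:
    def test_identical_fits_give_zero_statistic_unit_p(self):
        stat, ddf, p = lr_test(_fit_result("SCA", 189.5),
                               _fit_result("SSCA", 189.5))
        assert (stat, ddf, p) == (0.0, 1, 1.0)

    def test_critical_value_at_one_df(self):
        stat, ddf, p = lr_test(_fit_result("SCA", 190.84),
                               _fit_result("SSCA", 187.0))
        assert ddf == 1
        assert p == pytest.approx(0.05004352124870519)  # chi2 sf oracle

    def test_negative_statistic_clamps_with_warning(self):
        with pytest.warns(UserWarning):
            stat, _, p = lr_test(_fit_result("SCA", 180.0),
                                 _fit_result("SSCA", 185.0))
        assert stat == 0.0 and p == 1.0

    def test_non_nested_pair_is_refused(self):
        with pytest.raises(ValueError, match="information criteria"):
            lr_test(_fit_result("DNFI", 422.0), _fit_result("SSCA", 153.0))


class TestParitySplit:
    def test_odd_subject_keeps_odd_trials_for_training(self):
        df = toy_dataset([(1, 2, "L", 500)] * 720)
        training, test = parity_split(df)
        assert len(training) == len(test) == 360
        assert (training["trial"] % 2 == 1).all()
        assert (test["trial"] % 2 == 0).all()

    def test_even_subject_swaps_the_roles(self):
        df = toy_dataset([(1, 2, "L", 500)] * 10)
        df["subject"] = 2
        training, test = parity_split(df)
        assert (training["trial"] % 2 == 0).all()
        assert (test["trial"] % 2 == 1).all()

    def test_split_is_disjoint_exhaustive_and_idempotent(self, sim_dataset):
        training, test = parity_split(sim_dataset)
        assert len(training) + len(test) == len(sim_dataset)
        assert not set(training.index) & set(test.index)
        again, empty = parity_split(training)
        assert again.equals(training) and len(empty) == 0

    def test_missing_indices_are_rejected(self):
        with pytest.raises(ValueError):
            parity_split(pd.DataFrame({"trial": [1, 2]}))
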