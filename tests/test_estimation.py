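import math

import numpy as np
import pytest

from fractcm import (
    SolverConfig,
    TumorDataset,
    compute_aic,
    compute_rmse,
    fit_model,
    select_n_by_rmse,
    subset_experiment,
)
from fractcm.synthetic_data import StudyDesign, generate_dataset
from fractcm import ErlangTCMParameters


@pytest.fixture(scope="module")
def cfg_fit():
    """Coarse but adequate grid for cheap fitting tests (generation and
    fitting share the grid, so recovery is exact up to optimizer tolerance)."""
    return SolverConfig(0.0, 60.0, 2.0**-3)


@pytest.fixture(scope="module")
def erlang_dataset(growth, pk_params, cfg_fit):
    """Noise-free synthetic data from a mild Erlang truth, coarse grid."""
    truth = ErlangTCMParameters(growth=growth, eta=0.3, k1=0.6, n=4)
    return generate_dataset(truth, StudyDesign(), pk_params, seed=5,
                            cfg=cfg_fit)


class TestRMSE:
    def test_zero_iff_identical(self):
        d = TumorDataset([0, 1, 2], [1.0, 2.0, 3.0])
        assert compute_rmse(d, np.array([1.0, 2.0, 3.0])) == 0.0
        assert compute_rmse(d, np.array([1.0, 2.0, 3.1])) > 0.0

    def test_hand_example(self):
        d = TumorDataset([0, 1], [1.0, 2.0])
        assert compute_rmse(d, np.array([0.0, 2.0])) == pytest.approx(
            math.sqrt(0.5))

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        obs = rng.uniform(0.1, 2.0, 8)
        w = rng.uniform(0.1, 2.0, 8)
        d1 = TumorDataset(np.arange(8.0), obs)
        d5 = TumorDataset(np.arange(8.0), 5 * obs)
        assert compute_rmse(d5, 5 * w) == pytest.approx(5 * compute_rmse(d1, w))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_rmse(TumorDataset([0, 1], [1, 2]), np.array([1.0]))


class TestAIC:
    def test_printed_model_comparison_values(self):
        # the reference comparison: Erlang (N=10, RMSE=0.3139, k=2) vs
        # fractional (N=10, RMSE=0.3392, k=3)
        assert compute_aic(10, 0.3139, 2) == pytest.approx(11.2023, abs=0.01)
        assert compute_aic(10, 0.3392, 3) == pytest.approx(14.7538, abs=0.01)

    def test_closed_form_single_point(self):
        assert compute_aic(1, 1.0, 1) == pytest.approx(math.log(2 * math.pi) + 5)

    def test_parameter_penalty_is_exactly_two(self):
        a3 = compute_aic(10, 0.5, 3)
        a2 = compute_aic(10, 0.5, 2)
        assert a3 - a2 == pytest.approx(2.0, abs=1e-12)

    def test_zero_rmse_undefined(self):
        with pytest.raises(ValueError):
            compute_aic(10, 0.0, 2)


class TestDataset:
    def test_file_round_trip(self, tmp_path):
        d = TumorDataset([0.0, 7.0, 13.0], [0.01, 0.07, 0.31])
        path = tmp_path / "d.csv"
        d.to_file(path)
        back = TumorDataset.from_file(path)
        assert np.allclose(back.times, d.times)
        assert np.allclose(back.masses, d.masses)

    def test_invariants(self):
        with pytest.raises(ValueError):
            TumorDataset([1.0, 1.0], [0.1, 0.2])
        with pytest.raises(ValueError):
            TumorDataset([0.0, 1.0], [0.1, -0.2])


class TestFitModel:
    def test_perfect_start_returns_start(self, erlang_dataset, growth,
                                         pk_params, cfg_fit):
        # data generated at the start parameters: objective is 0 at the start
        design = StudyDesign()
        fit = fit_model(erlang_dataset, "erlang", pk=pk_params,
                        doses=design.dose_schedule, growth=growth, n=4,
                        start=(0.6, 0.3), cfg=cfg_fit)
        assert fit.parameters["k1"] == pytest.approx(0.6, abs=1e-9)
        assert fit.parameters["eta"] == pytest.approx(0.3, abs=1e-9)
        assert fit.rmse < 1e-12

    def test_erlang_recovery_from_reference_start(self, erlang_dataset,
                                                  growth, pk_params, cfg_fit):
        design = StudyDesign()
        fit = fit_model(erlang_dataset, "erlang", pk=pk_params,
                        doses=design.dose_schedule, growth=growth, n=4,
                        cfg=cfg_fit)
        assert fit.converged
        assert fit.parameters["k1"] == pytest.approx(0.6, rel=1e-3)
        assert fit.parameters["eta"] == pytest.approx(0.3, rel=1e-3)

    def test_deterministic(self, erlang_dataset, growth, pk_params, cfg_fit):
        design = StudyDesign()
        kw = dict(pk=pk_params, doses=design.dose_schedule, growth=growth,
                  n=4, cfg=cfg_fit)
        f1 = fit_model(erlang_dataset, "erlang", **kw)
        f2 = fit_model(erlang_dataset, "erlang", **kw)
        assert f1.parameters == f2.parameters  # bit-identical

    def test_too_few_points_rejected(self, growth, pk_params, cfg_fit):
        with pytest.raises(ValueError):
            fit_model(TumorDataset([1.0], [0.1]), "erlang", pk=pk_params,
                      doses=StudyDesign().dose_schedule, growth=growth,
                      cfg=cfg_fit)

    def test_unknown_model_rejected(self, erlang_dataset):
        with pytest.raises(ValueError):
            fit_model(erlang_dataset, "gompertz")


class TestSubsetExperiment:
    def test_full_size_matches_full_fit(self, erlang_dataset, growth,
                                        pk_params, cfg_fit):
        design = StudyDesign()
        kw = dict(model="erlang", pk=pk_params, doses=design.dose_schedule,
                  growth=growth, n=4, cfg=cfg_fit)
        table = subset_experiment(erlang_dataset, sizes=(10,), seed=1, **kw)
        full = fit_model(erlang_dataset, "erlang", pk=pk_params,
                         doses=design.dose_schedule, growth=growth, n=4,
                         cfg=cfg_fit)
        assert table.loc[0, "rmse_full"] == pytest.approx(full.rmse, abs=1e-9)

    def test_reproducible_and_flags_small_subsets(self, erlang_dataset, growth,
                                                  pk_params, cfg_fit):
        design = StudyDesign()
        kw = dict(model="erlang", pk=pk_params, doses=design.dose_schedule,
                  growth=growth, n=4, cfg=cfg_fit)
        t1 = subset_experiment(erlang_dataset, sizes=(2, 5), seed=42, **kw)
        t2 = subset_experiment(erlang_dataset, sizes=(2, 5), seed=42, **kw)
        assert t1["indices"].tolist() == t2["indices"].tolist()
        assert np.allclose(t1["rmse_full"], t2["rmse_full"])
        assert not t1.loc[t1["size"] == 2, "reliable"].item()
        assert t1.loc[t1["size"] == 5, "reliable"].item()

    def test_rmse_improves_with_more_data(self, erlang_dataset, growth,
                                          pk_params, cfg_fit):
        # noise-free truth: more points pin the parameters down
        design = StudyDesign()
        kw = dict(model="erlang", pk=pk_params, doses=design.dose_schedule,
                  growth=growth, n=4, cfg=cfg_fit)
        table = subset_experiment(erlang_dataset, sizes=(3, 10), seed=2, **kw)
        assert (table.loc[table["size"] == 10, "rmse_full"].item()
                <= table.loc[table["size"] == 3, "rmse_full"].item() + 1e-9)

    def test_oversized_subset_rejected(self, erlang_dataset):
        with pytest.raises(ValueError):
            subset_experiment(erlang_dataset, sizes=(11,))


class TestSelectN:
    def test_single_candidate_returned(self, erlang_dataset, growth,
                                       pk_params, cfg_fit):
        design = StudyDesign()
        best, table = select_n_by_rmse(erlang_dataset, [3], pk=pk_params,
                                       doses=design.dose_schedule,
                                       growth=growth, cfg=cfg_fit)
        assert best == 3
        assert len(table) == 1

    def test_recovers_generating_compartment_count(self, erlang_dataset,
                                                   growth, pk_params, cfg_fit):
        design = StudyDesign()
        best, table = select_n_by_rmse(erlang_dataset, [2, 3, 4, 5],
                                       pk=pk_params,
                                       doses=design.dose_schedule,
                                       growth=growth, cfg=cfg_fit)
        assert best == 4

    def test_tie_breaks_toward_smaller_n_without_treatment(
            self, growth, pk_params, cfg_fit):
        # eta = 0 truth: the delay chain is unidentifiable, RMSE flat in n
        truth = ErlangTCMParameters(growth=growth, eta=0.0, k1=0.6, n=4)
        data = generate_dataset(truth, StudyDesign(), pk_params, seed=5,
                                cfg=cfg_fit)
        design = StudyDesign()
        best, table = select_n_by_rmse(data, [2, 3, 4], pk=pk_params,
                                       doses=design.dose_schedule,
                                       growth=growth, cfg=cfg_fit)
        assert best == 2

    def test_empty_candidates_rejected(self, erlang_dataset):
        with pytest.raises(ValueError):
            select_n_by_rmse(erlang_dataset, [])
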