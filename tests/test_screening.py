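"""Random-scale screening: evaluation, selection, consensus."""

import numpy as np
import pytest

from dsekit.constants import STANDARD_AA
from dsekit.scales import PropensityScale, builtin_scale
from dsekit.screening import (RhDataset, ScaleMetrics, consensus,
                              evaluate_scale, random_scale, run_screening,
                              select_best)
from dsekit.synthetic import SyntheticTruth, generate_idp_dataset

HILSER = builtin_scale("hilser_ppii")


def make_dataset(noise_sd=0.0, seed=42, n=30, charge=(0.26, -0.29)):
    truth = SyntheticTruth(true_scale=HILSER, charge_slope=charge[0],
                           charge_intercept=charge[1], noise_sd=noise_sd,
                           seed=seed)
    return generate_idp_dataset(n, (50, 200), truth=truth)[0]


class TestRandomScale:
    def test_reproducible_from_seed_state(self):
        a = random_scale(np.random.default_rng(3))
        b = random_scale(np.random.default_rng(3))
        assert a.values == b.values

    def test_values_uniform_in_unit_interval(self):
        rng = np.random.default_rng(0)
        draws = np.array([list(random_scale(rng).values.values())
                          for _ in range(2000)])
        assert draws.min() >= 0 and draws.max() <= 1
        # mean of 2000*20 uniforms: 3 sigma ~ 0.5 +/- 3/sqrt(12*40000)
        assert abs(draws.mean() - 0.5) < 3 / np.sqrt(12 * draws.size)


class TestEvaluateScale:
    def test_noiseless_truth_recovers_charge_coefficients(self):
        metrics = evaluate_scale(HILSER, make_dataset(noise_sd=0.0))
        assert metrics.slope == pytest.approx(0.26, abs=1e-6)
        assert metrics.intercept == pytest.approx(-0.29, abs=1e-6)
        assert metrics.mean_abs_err < 1e-9
        assert 0 <= metrics.r2_pred <= 1

    def test_chargefree_data_fits_exactly(self):
        ds = make_dataset(noise_sd=0.0, charge=(0.0, 0.0))
        # strip charged residues' effect by zeroing coefficients at source:
        metrics = evaluate_scale(HILSER, ds)
        assert metrics.mean_abs_err < 1e-9

    def test_degenerate_dataset_errors(self):
        ds = RhDataset(ids=("a", "b", "c"),
                       sequences=("AAAAAAAAAA",) * 3,
                       rh_exp=(12.0, 12.0, 12.0),
                       temperatures=(298.15,) * 3)
        with pytest.raises(ValueError, match="constant"):
            evaluate_scale(HILSER, ds)

    def test_too_few_entries(self):
        ds = RhDataset(ids=("a", "b"), sequences=("AAAAAAAAAA",) * 2,
                       rh_exp=(12.0, 13.0), temperatures=(298.15,) * 2)
        with pytest.raises(ValueError, match=">= 3"):
            evaluate_scale(HILSER, ds)

    def test_recovery_degrades_with_noise(self):
        errs = []
        for sd in (0.0, 0.5, 1.0, 2.0):
            vals = [evaluate_scale(HILSER, make_dataset(sd, seed=s)).mean_abs_err
                    for s in (1, 2, 3, 4)]
            errs.append(np.mean(vals))
        assert errs[0] < errs[1] < errs[2] < errs[3]

    def test_builtin_scale_beats_median_random_scale(self):
        ds = make_dataset(noise_sd=0.5, seed=8)
        hil_err = evaluate_scale(HILSER, ds).mean_abs_err
        rng = np.random.default_rng(8)
        rand_errs = [evaluate_scale(random_scale(rng), ds).mean_abs_err
                     for _ in range(200)]
        assert hil_err < np.median(rand_errs)


def metrics(err, r2p=0.9, r2c=0.8):
    return ScaleMetrics(r2_pred=r2p, slope=0.2, intercept=-0.3,
                        r2_charge=r2c, mean_abs_err=err)


class TestSelectBest:
    def test_all_failing_thresholds(self):
        with pytest.warns(UserWarning, match="no scale"):
            mask = select_best([metrics(0.1, r2p=0.2), metrics(0.1, r2c=0.1)])
        assert not mask.any()

    def test_threshold_straddle(self):
        ms = [metrics(0.04, r2p=0.71, r2c=0.41), metrics(0.04, r2p=0.69),
              metrics(0.04, r2c=0.39)]
        mask = select_best(ms)
        assert mask.tolist() == [True, False, False]

    def test_bimodal_error_set_keeps_low_lobe(self):
        low = [metrics(e) for e in np.linspace(0.11, 0.19, 5)]
        high = [metrics(e) for e in np.linspace(0.56, 0.59, 20)]
        mask = select_best(low + high)
        assert mask[:5].all() and not mask[5:].any()


class TestConsensus:
    def test_single_scale_identity(self):
        s = random_scale(np.random.default_rng(1))
        cons, sd = consensus([s], np.array([True]))
        for aa in STANDARD_AA:
            assert cons[aa] == pytest.approx(s[aa])
            assert sd[aa] == 0.0

    def test_two_scales_midpoint(self):
        a = PropensityScale("a", {aa: 0.2 for aa in STANDARD_AA}, 298.15)
        b = PropensityScale("b", {aa: 0.6 for aa in STANDARD_AA}, 298.15)
        cons, _ = consensus([a, b], np.array([True, True]))
        assert cons["A"] == pytest.approx(0.4)

    def test_rank_constraint_filters(self):
        a = PropensityScale("a", {aa: 0.5 for aa in STANDARD_AA} | {
            "P": 0.9, "A": 0.7, "G": 0.2}, 298.15)
        b = PropensityScale("b", {aa: 0.5 for aa in STANDARD_AA} | {
            "P": 0.1, "A": 0.7, "G": 0.9}, 298.15)
        cons, _ = consensus([a, b], np.array([True, True]),
                            rank_constraint=["P", "A", "G"])
        assert cons["P"] == pytest.approx(0.9)

    def test_all_scales_violate_rank_order(self):
        s = PropensityScale("s", {aa: 0.5 for aa in STANDARD_AA} | {
            "P": 0.1, "A": 0.9}, 298.15)
        with pytest.raises(ValueError, match="rank"):
            consensus([s], np.array([True]), rank_constraint=["P", "A"])

    def test_empty_selection(self):
        with pytest.raises(ValueError, match="empty"):
            consensus([random_scale(np.random.default_rng(0))],
                      np.array([False]))


class TestRunScreening:
    def test_deterministic_given_seed(self):
        ds = make_dataset(noise_sd=0.5, seed=4)
        a = run_screening(200, ds, seed=9)
        b = run_screening(200, ds, seed=9)
        assert a.metrics == b.metrics
        assert np.array_equal(a.best_mask, b.best_mask)

    def test_zero_scales_rejected(self):
        with pytest.raises(ValueError):
            run_screening(0, make_dataset(), seed=1)

    def test_composes_selection_and_consensus(self):
        res = run_screening(400, make_dataset(noise_sd=0.5, seed=1), seed=101)
        assert res.n_scales == 400
        assert len(res.metrics) == 400
        if res.best_mask.any():
            assert res.consensus is not None
            assert set(res.consensus.values) == set(STANDARD_AA)
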