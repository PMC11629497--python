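"""Metrics, fold assignment, cross-validation, bootstrap, model comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from solcurate import baseline_model as bm
from solcurate import evaluation as ev
from solcurate import synthetic_data as sd

from conftest import prediction_table


class TestMetrics:
    def test_rmse_two_equal_errors(self):
        assert ev.rmse(prediction_table([0.6, 0.6])) == pytest.approx(0.6)

    def test_rmse_perfect_predictions(self):
        assert ev.rmse(prediction_table([0.0, 0.0, 0.0])) == 0.0

    def test_rmse_hand_arithmetic(self):
        assert ev.rmse(prediction_table([3.0, 4.0])) == pytest.approx(math.sqrt(12.5))

    def test_weighted_metric_halves_split_molecule(self):
        table = prediction_table([0.6, 0.6], weights=[0.5, 0.5])
        assert ev.curmse(table) == pytest.approx(0.3)
        assert ev.rmse(table) == pytest.approx(0.6)

    def test_weighted_metric_zero_weights_degenerate(self):
        assert ev.curmse(prediction_table([1.0, 2.0], weights=[0.0, 0.0])) == 0.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ev.rmse(prediction_table([]))

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            ev.curmse(prediction_table([1.0], weights=[-0.5]))

    @given(
        st.lists(
            st.floats(min_value=-5, max_value=5, allow_nan=False),
            min_size=1,
            max_size=40,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_unit_weights_reduce_to_rmse(self, errors):
        table = prediction_table(errors)
        assert ev.curmse(table) == pytest.approx(ev.rmse(table), abs=1e-12)

    def test_weighted_metric_monotone_in_single_weight(self):
        rng = np.random.default_rng(0)
        errors = rng.normal(size=20)
        weights = rng.uniform(0.1, 1.0, size=20)
        base = ev.curmse(prediction_table(errors, weights))
        bumped = weights.copy()
        bumped[7] += 0.3
        assert ev.curmse(prediction_table(errors, bumped)) >= base

    @pytest.mark.parametrize("r, expected", [(2.0, 0.0), (0.0, 2_000_000.0), (0.6, 1_400_000.0)])
    def test_challenge_score(self, r, expected):
        assert ev.challenge_score(r) == pytest.approx(expected)


def _toy_records(n, seed=0, n_molecules=40):
    universe = sd.generate_universe(n_molecules, seed=seed)
    truth = sd.build_ground_truth(universe)
    spec = sd.SourceSpec("t", n, noise_sd=0.5)
    tables, _ = sd.generate_sources(universe, truth, [spec], seed=seed + 1)
    from solcurate.standardize import standardize_table

    return standardize_table(tables["t"]), truth


class TestAssignFolds:
    def test_every_record_evaluated_exactly_once(self):
        records, _ = _toy_records(200)
        folds = ev.assign_folds(records, 10, "by_record", seed=0)
        seen = []
        for k in range(10):
            seen += folds.roles(k)["eval"]
        assert sorted(seen) == sorted(records["record_id"])

    def test_molecule_policy_keeps_connectivity_together(self):
        from solcurate.standardize import standardize_table

        df = standardize_table(
            pd.DataFrame(
                {
                    "record_id": [f"r{i}" for i in range(24)],
                    "smiles": (["C[C@H](O)CC", "CC(O)CC"] + ["CCO", "CCN", "CCC",
                               "c1ccccc1", "CCCl", "CCBr", "CC=C", "CC#N"])
                    + [f"{'C' * i}O" for i in range(3, 17)],
                    "logS": np.linspace(-3, 0, 24),
                }
            )
        )
        folds = ev.assign_folds(df, 3, "by_molecule", seed=5)
        assert folds.fold_of("r0") == folds.fold_of("r1")  # stereo pair

    def test_role_fractions_near_nominal_split(self):
        records, _ = _toy_records(400)
        folds = ev.assign_folds(records, 10, "by_record", seed=3)
        for k in range(10):
            roles = folds.roles(k)
            n = sum(len(v) for v in roles.values())
            assert n == 400
            assert len(roles["eval"]) == 40
            assert len(roles["early_stop"]) == round(0.1 * 360)
            assert len(roles["train"]) == 360 - round(0.1 * 360)

    def test_order_insensitive_and_deterministic(self):
        records, _ = _toy_records(100)
        shuffled = records.sample(frac=1.0, random_state=9).reset_index(drop=True)
        f1 = ev.assign_folds(records, 5, "by_molecule", seed=2)
        f2 = ev.assign_folds(shuffled, 5, "by_molecule", seed=2)
        assert f1.folds == f2.folds

    def test_too_few_molecules_rejected(self):
        from solcurate.standardize import standardize_table

        df = standardize_table(
            pd.DataFrame(
                {"record_id": ["a", "b"], "smiles": ["CCO", "OCC"], "logS": [0, 1]}
            )
        )
        with pytest.raises(ValueError):
            ev.assign_folds(df, 3, "by_molecule", seed=0)


class TestCrossValidate:
    def test_constant_data_mean_predictor_is_perfect(self):
        records, _ = _toy_records(60)
        records = records.assign(logS=-1.25)
        folds = ev.assign_folds(records, 5, "by_record", seed=0)
        table = ev.cross_validate(records, bm.memorizer_factory(), folds)
        assert ev.rmse(table) == pytest.approx(0.0, abs=1e-12)

    def test_deterministic(self):
        records, _ = _toy_records(80)
        folds = ev.assign_folds(records, 5, "by_molecule", seed=1)
        t1 = ev.cross_validate(records, bm.ridge_factory(), folds)
        t2 = ev.cross_validate(records, bm.ridge_factory(), folds)
        pd.testing.assert_frame_equal(t1, t2)

    def test_memorizer_exploits_by_record_split_on_duplicated_data(self):
        """With every record duplicated, a by-record split leaks the answer."""
        records, _ = _toy_records(60)
        twin = records.copy()
        twin["record_id"] = twin["record_id"] + "-twin"
        doubled = pd.concat([records, twin], ignore_index=True)
        f_rec = ev.assign_folds(doubled, 5, "by_record", seed=0)
        f_mol = ev.assign_folds(doubled, 5, "by_molecule", seed=0)
        rmse_rec = ev.rmse(ev.cross_validate(doubled, bm.memorizer_factory(), f_rec))
        rmse_mol = ev.rmse(ev.cross_validate(doubled, bm.memorizer_factory(), f_mol))
        assert rmse_rec < rmse_mol


class TestBootstrap:
    def test_constant_errors_zero_width(self):
        table = prediction_table([0.5] * 50)
        res = ev.bootstrap_ci(table, "rmse", B=200, seed=0)
        assert res.ci_low == res.ci_high == pytest.approx(0.5)

    def test_same_seed_identical(self):
        table = prediction_table(np.random.default_rng(1).normal(size=100))
        r1 = ev.bootstrap_ci(table, "rmse", B=200, seed=4)
        r2 = ev.bootstrap_ci(table, "rmse", B=200, seed=4)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)

    def test_ci_narrows_with_sample_size(self):
        """Average CI width at n=4000 is below the width at n=400."""
        widths = {400: [], 4000: []}
        for seed in range(20):
            rng = np.random.default_rng(seed)
            for n in widths:
                table = prediction_table(rng.normal(0, 0.5, size=n))
                res = ev.bootstrap_ci(table, "rmse", B=200, seed=seed)
                widths[n].append(res.ci_high - res.ci_low)
        assert np.mean(widths[4000]) < np.mean(widths[400])

    def test_small_replicate_count_rejected(self):
        with pytest.raises(ValueError):
            ev.bootstrap_ci(prediction_table([1.0, 2.0]), B=10)


class TestCompareModels:
    def test_self_comparison_not_significant(self):
        table = prediction_table(np.random.default_rng(0).normal(size=50))
        res = ev.compare_models(table, table)
        assert res.delta == 0.0
        assert res.p_value == 1.0
        assert not res.significant

    def test_constant_shift_is_significant(self):
        rng = np.random.default_rng(2)
        errors = rng.normal(0, 0.3, size=80)
        a = prediction_table(errors)
        b = prediction_table(errors + 0.5)
        res = ev.compare_models(a, b)
        assert res.better == "A"
        assert res.significant

    def test_mismatched_record_sets_rejected(self):
        a = prediction_table([1.0, 2.0])
        b = prediction_table([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            ev.compare_models(a, b)

    def test_type_i_error_calibrated(self):
        """Independent same-process error draws reject at roughly the 5% level."""
        rejections = 0
        reps = 20
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            a = prediction_table(rng.normal(0, 0.5, size=200))
            b = prediction_table(rng.normal(0, 0.5, size=200))
            if ev.compare_models(a, b).significant:
                rejections += 1
        assert rejections <= 4  # ≈ 0.05 nominal; binomial slack at 20 reps


class TestNestedValidation:
    def test_no_tuning_builder_matches_plain_cv(self):
        """With nothing to tune, the two-step protocol IS plain n-fold CV."""
        records, _ = _toy_records(80)

        def builder(dev):
            return bm.memorizer(dev)

        def factory(train, early):
            return bm.memorizer(pd.concat([train, early]))

        res, table = ev.nested_validation(
            records, builder, n_subsets=5, policy="by_molecule", seed=3,
            bootstrap_B=100,
        )
        folds = ev.assign_folds(records, 5, "by_molecule", seed=3)
        plain = ev.cross_validate(records, factory, folds)
        assert res.point == pytest.approx(ev.rmse(plain), abs=1e-12)

    def test_honest_tuner_estimate_tracks_fresh_data_error(self):
        """A tuner that only peeks at its own training data is not punished:
        the nested estimate agrees with error on freshly generated data."""
        records, truth = _toy_records(240, seed=5, n_molecules=60)

        def builder(dev):
            return bm.fit_ridge(dev, dev.sample(frac=0.2, random_state=0))

        res, _ = ev.nested_validation(
            records, builder, n_subsets=5, policy="by_molecule", seed=1,
            bootstrap_B=200,
        )
        fresh, _ = _toy_records(240, seed=77, n_molecules=60)
        model = builder(records)
        fresh_table = pd.DataFrame(
            {
                "record_id": fresh["record_id"],
                "y_pred": model.predict(fresh),
                "y_obs": fresh["logS"],
                "weight": 1.0,
                "fold": 0,
            }
        )
        fresh_rmse = ev.rmse(fresh_table)
        # agreement within a generous band around the bootstrap CI
        assert res.ci_low - 0.1 <= fresh_rmse <= res.ci_high + 0.1

    def test_too_few_subsets_rejected(self):
        records, _ = _toy_records(30)
        with pytest.raises(ValueError):
            ev.nested_validation(records, lambda dev: bm.memorizer(dev), n_subsets=1)
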