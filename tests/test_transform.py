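"""Law-bank fitting and the LLT feature transform."""

import numpy as np
import pandas as pd
import pytest

import naive_llt
from linlaw import (
    ConfigurationError,
    DataError,
    LabeledPanel,
    aggregate,
    fit,
    law_of_series,
    load_bank,
    project,
    save_bank,
    select_min_variance,
    transform,
)
from linlaw.synthetic import arem_mimic_panel, make_class_models, simulate_panel
from linlaw.transform import SelectedColumns, feature_names

RAMP_LAW = np.array([1.0, -2.0, 1.0]) / np.sqrt(6.0)


def ramp_panel(n_per_class=2):
    """Two-class panel: class 1 = arithmetic ramps, class 2 = period-4 waves."""
    t = np.arange(1.0, 41.0)
    series, labels = [], []
    for i in range(n_per_class):
        series.append([(i + 1) * t + i, (i + 2) * t])
        labels.append(1)
    for i in range(n_per_class):
        series.append([np.sin(np.pi * t / 2 + i), np.cos(np.pi * t / 2) * (i + 1)])
        labels.append(2)
    return LabeledPanel(series=series, labels=np.array(labels))


class TestFit:
    def test_law_count_is_tau_times_m(self, clean_panel):
        bank = fit(clean_panel, order=3)
        assert bank.n_train == 18 and bank.n_channels == 2
        total = sum(V.shape[1] for V in bank.channel_banks)
        assert total == 18 * 2
        for V in bank.channel_banks:
            np.testing.assert_allclose(np.linalg.norm(V, axis=0), 1.0, atol=1e-12)

    def test_class_partition_covers_columns(self, clean_panel):
        bank = fit(clean_panel, order=3)
        covered = np.concatenate([bank.class_columns(c) for c in (1, 2, 3)])
        assert sorted(covered.tolist()) == list(range(bank.n_train))

    def test_ramp_class_columns_are_second_difference(self):
        bank = fit(ramp_panel(), order=3)
        for col in bank.class_columns(1):
            for V in bank.channel_banks:
                assert abs(np.dot(V[:, col], RAMP_LAW)) > 1 - 1e-10

    def test_columns_match_law_of_series(self, noisy_small_panel):
        bank = fit(noisy_small_panel, order=4)
        for i in range(bank.n_train):
            for j in range(bank.n_channels):
                law = law_of_series(noisy_small_panel.series[i][j], 4)
                np.testing.assert_allclose(
                    bank.channel_banks[j][:, i], law.coefficients, atol=1e-12
                )

    def test_arem_scale_bank_has_246_columns(self):
        panel = arem_mimic_panel(seed=0)
        from linlaw.benchmark import arem_paper_split

        split = arem_paper_split(panel)
        bank = fit(panel.subset(split.train_indices), order=30)
        assert bank.n_train == 41
        assert bank.n_train * bank.n_channels == 246

    def test_short_series_error_names_instance_and_channel(self):
        panel = ramp_panel()
        with pytest.raises(DataError, match="channel 1"):
            fit(panel, order=45)


class TestProject:
    def test_annihilated_column_is_zero(self):
        t = np.arange(1.0, 31.0)
        bank = np.column_stack([RAMP_LAW, [0.6, 0.8, 0.0]])
        out = project(3 * t + 2, bank, order=3)
        np.testing.assert_allclose(out[:, 0], 0.0, atol=1e-8)
        assert np.abs(out[:, 1]).max() > 1.0

    def test_identity_bank_returns_gram(self, rng):
        z = rng.normal(size=20)
        from linlaw import embed, gram

        out = project(z, np.eye(4), order=4)
        np.testing.assert_allclose(out, gram(embed(z, 4)), atol=1e-12)

    def test_matches_brute_force_multiply(self, rng):
        z = rng.normal(size=25)
        V = rng.normal(size=(4, 3))
        from linlaw import embed, gram

        S = gram(embed(z, 4))
        expected = np.array(
            [[sum(S[a, b] * V[b, q] for b in range(4)) for q in range(3)] for a in range(4)]
        )
        np.testing.assert_allclose(project(z, V, order=4), expected, atol=1e-10)

    def test_order_mismatch_is_configuration_error(self, rng):
        with pytest.raises(ConfigurationError, match="rows"):
            project(rng.normal(size=20), np.eye(5), order=4)


class TestSelectMinVariance:
    def test_zero_column_wins(self):
        prod = np.column_stack([[0.0, 0, 0], [1.0, 2, 3]])
        sel = select_min_variance(prod, [1, 1])
        np.testing.assert_array_equal(sel.columns[0][1], [0, 0, 0])
        assert sel.variances[0][1] == 0.0

    def test_tie_broken_by_lowest_index(self):
        col = np.array([1.0, 2, 3])
        prod = np.column_stack([col + 5, col])  # equal variance
        sel = select_min_variance(prod, [1, 1])
        np.testing.assert_array_equal(sel.columns[0][1], col + 5)

    def test_matches_exhaustive_enumeration(self, rng):
        prod = rng.normal(size=(5, 6))
        classes = np.array([1, 1, 1, 2, 2, 2])
        sel = select_min_variance(prod, classes)
        for cls in (1, 2):
            members = np.flatnonzero(classes == cls)
            variances = [prod[:, i].var(ddof=1) for i in members]
            best = members[int(np.argmin(variances))]
            np.testing.assert_array_equal(sel.columns[0][cls], prod[:, best])

    def test_empty_class_group_rejected(self, rng):
        with pytest.raises(ConfigurationError, match="class 1"):
            select_min_variance(rng.normal(size=(4, 3)), [2, 2, 2])


class TestAggregate:
    @pytest.mark.parametrize(
        "column, mode, absolute, expected",
        [
            (np.zeros(3), "mean", True, 0.0),
            (np.zeros(3), "variance", True, 0.0),
            (np.array([1.0, 2, 3]), "mean", False, 2.0),
            (np.array([1.0, 2, 3]), "variance", True, 1.0),
            (np.array([-1.0, -2, -3]), "mean", True, 2.0),
            (np.array([-1.0, -2, -3]), "mean", False, -2.0),
        ],
    )
    def test_hand_arithmetic(self, column, mode, absolute, expected):
        sel = SelectedColumns(columns=[{1: column}], variances=[{1: 0.0}])
        out = aggregate(sel, mode, absolute_mean=absolute)
        assert out[0] == pytest.approx(expected)

    def test_bad_mode_rejected(self):
        sel = SelectedColumns(columns=[{1: np.zeros(2)}], variances=[{1: 0.0}])
        with pytest.raises(ConfigurationError):
            aggregate(sel, "median")


class TestTransform:
    def test_feature_shape_m6_c7_is_42(self):
        panel = arem_mimic_panel(seed=2, k=120)
        from linlaw.benchmark import arem_paper_split

        split = arem_paper_split(panel)
        bank = fit(panel.subset(split.train_indices), order=8)
        means, variances = transform(panel.subset(split.test_indices), bank)
        assert means.shape == (47, 42 + 1)  # + label column
        assert variances.shape == (47, 42 + 1)
        assert means.columns[:-1].is_unique

    def test_feature_names_channel_major_then_class(self):
        names = feature_names(2, 3, "mean")
        assert names == [
            "mean_ch1_cls1",
            "mean_ch1_cls2",
            "mean_ch1_cls3",
            "mean_ch2_cls1",
            "mean_ch2_cls2",
            "mean_ch2_cls3",
        ]

    def test_exact_annihilation_of_true_class(self):
        panel = ramp_panel()
        bank = fit(panel, order=3)
        t = np.arange(1.0, 41.0)
        test = LabeledPanel(series=[[7 * t - 3, 2 * t + 9]], labels=np.array([1]))
        means, variances = transform(test, bank)
        for j in (1, 2):
            assert means.iloc[0][f"mean_ch{j}_cls1"] < 1e-8
            assert variances.iloc[0][f"var_ch{j}_cls1"] < 1e-8
            assert means.iloc[0][f"mean_ch{j}_cls2"] > 1e-3

    def test_stacked_raw_table_shape(self, rng):
        models = make_class_models(c=2, m=1, order=2, seed=11)
        train = simulate_panel(models, counts=[3, 3], k=40, seed=11)
        test = simulate_panel(models, counts=[2, 2], k=40, seed=12)
        bank = fit(train, order=5)
        means, variances, raw = transform(test, bank, return_selected=True)
        assert raw.shape == (4 * 5, 1 * 2)  # (n-tau)*l rows, m*c columns

    def test_separation_true_class_minimal(self, clean_panel, clean_models):
        from linlaw.benchmark import stratified_split

        split = stratified_split(clean_panel, 0.5, seed=1)
        bank = fit(clean_panel.subset(split.train_indices), order=3)
        test = clean_panel.subset(split.test_indices)
        means, variances = transform(test, bank)
        for i in range(test.n_instances):
            true = int(test.labels[i])
            for table, prefix in ((means, "mean"), (variances, "var")):
                for j in (1, 2):
                    own = table.iloc[i][f"{prefix}_ch{j}_cls{true}"]
                    for other in {1, 2, 3} - {true}:
                        assert own <= table.iloc[i][f"{prefix}_ch{j}_cls{other}"]

    def test_permutation_within_class_leaves_output_unchanged(self, noisy_small_panel):
        order = 4
        bank = fit(noisy_small_panel, order=order)
        perm = [1, 2, 0, 5, 3, 4]  # shuffles within each 3-member class
        permuted = noisy_small_panel.subset(perm)
        bank_p = fit(permuted, order=order)
        test = noisy_small_panel.subset([0, 3])
        m1, v1 = transform(test, bank)
        m2, v2 = transform(test, bank_p)
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(v1, v2)

    def test_amplitude_scaling_scales_selected_columns(self):
        panel = ramp_panel()
        bank = fit(panel, order=3)
        t = np.arange(1.0, 41.0)
        base = LabeledPanel(series=[[3 * t, t + 1]], labels=np.array([1]))
        scaled = LabeledPanel(series=[[2 * 3 * t, 2 * (t + 1)]], labels=np.array([1]))
        _, _, raw_base = transform(base, bank, return_selected=True)
        _, _, raw_scaled = transform(scaled, bank, return_selected=True)
        np.testing.assert_allclose(
            raw_scaled.to_numpy(), 4.0 * raw_base.to_numpy(), rtol=1e-8, atol=1e-10
        )

    def test_extending_one_class_leaves_other_classes_unchanged(self, clean_panel, clean_models):
        bank = fit(clean_panel, order=3)
        extra = simulate_panel(clean_models, counts=[1, 1, 1], k=120, seed=99)
        extended = LabeledPanel(
            series=clean_panel.series + [extra.series[0]],
            labels=np.concatenate([clean_panel.labels, [1]]),
        )
        bank_ext = fit(extended, order=3)
        test = simulate_panel(clean_models, counts=[2, 2, 2], k=120, seed=55)
        m1, _ = transform(test, bank)
        m2, _ = transform(test, bank_ext)
        for j in (1, 2):
            for cls in (2, 3):  # classes whose bank columns did not change
                col = f"mean_ch{j}_cls{cls}"
                np.testing.assert_allclose(m1[col], m2[col], atol=1e-12)

    def test_channel_mismatch_rejected(self, clean_panel):
        bank = fit(clean_panel, order=3)
        one_channel = LabeledPanel(
            series=[[s[0]] for s in clean_panel.series[:4]],
            labels=clean_panel.labels[:4],
        )
        with pytest.raises(ConfigurationError, match="channels"):
            transform(one_channel, bank)

    def test_pipeline_matches_naive_reimplementation(self, noisy_small_panel):
        order = 4
        train_idx, test_idx = [0, 1, 3, 4], [2, 5]
        train = noisy_small_panel.subset(train_idx)
        test = noisy_small_panel.subset(test_idx)
        bank = fit(train, order=order)
        means, variances = transform(test, bank)
        naive_m, naive_v = naive_llt.naive_transform(
            [train.series[i] for i in range(train.n_instances)],
            train.labels.tolist(),
            [test.series[i] for i in range(test.n_instances)],
            order,
        )
        np.testing.assert_allclose(
            means.drop(columns="label").to_numpy(), naive_m, atol=1e-10
        )
        np.testing.assert_allclose(
            variances.drop(columns="label").to_numpy(), naive_v, atol=1e-10
        )


class TestBankSerialization:
    def test_round_trip_is_bit_exact(self, tmp_path, noisy_small_panel):
        bank = fit(noisy_small_panel, order=5)
        path = tmp_path / "bank.zip"
        save_bank(bank, path)
        loaded = load_bank(path)
        assert loaded.order == bank.order
        np.testing.assert_array_equal(loaded.column_classes, bank.column_classes)
        for V, W in zip(bank.channel_banks, loaded.channel_banks):
            np.testing.assert_array_equal(V, W)  # bit-exact
        np.testing.assert_array_equal(loaded.residuals, bank.residuals)

    def test_loaded_bank_transforms_identically(self, tmp_path, noisy_small_panel):
        bank = fit(noisy_small_panel, order=5)
        path = tmp_path / "bank.zip"
        save_bank(bank, path)
        test = noisy_small_panel.subset([0, 5])
        m1, v1 = transform(test, bank)
        m2, v2 = transform(test, load_bank(path))
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(v1, v2)
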