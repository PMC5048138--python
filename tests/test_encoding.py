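"""Feature encoders, the dimension formula and the window-size sweep."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phosthr.encoding import (
    FeatureMatrix,
    PropertyTable,
    WindowConfig,
    assemble_features,
    assemble_features_loo,
    encode_group,
    encode_physchem,
    encode_structure,
    optimize_window_size,
)
from phosthr.errors import ParameterError
from phosthr.profiles import PWMPair, build_pwm

from conftest import make_window, random_windows, t_window

even_sizes = st.integers(min_value=1, max_value=15).map(lambda d: 2 * d)


@pytest.fixture(scope="module")
def pwm_pair():
    rng = np.random.default_rng(11)
    return PWMPair.from_windows(random_windows(rng, 8), random_windows(rng, 8))


class TestWindowConfig:
    def test_default_is_216(self):
        assert WindowConfig().n_features == 216

    @pytest.mark.parametrize("bad", [{"w1": 13}, {"w2": 0}, {"w3": 32}])
    def test_invalid_sizes_raise(self, bad):
        with pytest.raises(ParameterError):
            WindowConfig(**bad)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(even_sizes, even_sizes, even_sizes, even_sizes)
    def test_dimension_formula(self, w1, w2, w3, w4):
        cfg = WindowConfig(w1=w1, w2=w2, w3=w3, w4=w4)
        assert cfg.n_features == w1 + 2 * w2 + 3 * w3 + 6 * w4


class TestEncodeStructure:
    def test_all_coil_zero_acc(self):
        win = make_window("A" * 15 + "T" + "A" * 15, ss="C" * 31)
        np.testing.assert_allclose(
            encode_structure(win, 4), [1.0, 0, 1.0, 0, 1.0, 0, 1.0, 0]
        )

    def test_w12_gives_24_values(self):
        win = make_window("A" * 15 + "T" + "A" * 15)
        assert encode_structure(win, 12).size == 24

    def test_x_flanks_neutral(self):
        win = t_window("X" * 15, "X" * 15)
        vals = encode_structure(win, 6, max_acc=10.0)
        np.testing.assert_allclose(vals[0::2], 0.5)  # ss
        np.testing.assert_allclose(vals[1::2], 0.0)  # acc


class TestEncodePhyschem:
    def test_group_dimensions(self, property_table):
        win = make_window("A" * 15 + "T" + "A" * 15)
        f3 = encode_physchem(
            win, 24, ("rigidity", "flexibility", "irreplaceability"), property_table
        )
        assert f3.size == 72
        f4 = encode_physchem(
            win,
            18,
            ("hydrophobicity", "hydrophilicity", "mass", "pk1", "pk2", "pi"),
            property_table,
        )
        assert f4.size == 108

    def test_poly_g_constant_per_property(self, property_table):
        win = make_window("G" * 15 + "T" + "G" * 15)
        vals = encode_physchem(win, 8, ("mass", "pi"), property_table)
        np.testing.assert_allclose(
            vals[0::2], property_table.scaled_value("G", "mass")
        )
        np.testing.assert_allclose(vals[1::2], property_table.scaled_value("G", "pi"))

    def test_unknown_property_raises(self, property_table):
        win = make_window("G" * 15 + "T" + "G" * 15)
        with pytest.raises(ParameterError):
            encode_physchem(win, 4, ("charge",), property_table)


class TestAssembleFeatures:
    def test_default_config_is_216_columns(self, rng, pwm_pair, property_table):
        wins = random_windows(rng, 5)
        fm = assemble_features(wins, WindowConfig(), pwm_pair, property_table)
        assert fm.X.shape == (5, 216)
        assert len(set(fm.names)) == 216

    def test_small_config_dimension(self, rng, pwm_pair, property_table):
        wins = random_windows(rng, 3)
        fm = assemble_features(
            wins, WindowConfig(w1=2, w2=2, w3=2, w4=2), pwm_pair, property_table
        )
        assert fm.X.shape[1] == 2 + 4 + 6 + 12

    def test_identical_windows_identical_rows(self, rng, pwm_pair, property_table):
        w = random_windows(rng, 1)[0]
        fm = assemble_features([w, w], WindowConfig(), pwm_pair, property_table)
        np.testing.assert_array_equal(fm.X[0], fm.X[1])

    def test_determinism(self, rng, pwm_pair, property_table):
        wins = random_windows(rng, 4)
        a = assemble_features(wins, WindowConfig(), pwm_pair, property_table)
        b = assemble_features(wins, WindowConfig(), pwm_pair, property_table)
        np.testing.assert_array_equal(a.X, b.X)

    def test_widening_preserves_inner_columns(self, rng, pwm_pair, property_table):
        wins = random_windows(rng, 4)
        small = assemble_features(
            wins, WindowConfig(w1=4, w2=4, w3=4, w4=4), pwm_pair, property_table
        )
        big = assemble_features(
            wins, WindowConfig(w1=8, w2=8, w3=8, w4=8), pwm_pair, property_table
        )
        for name in small.names:
            i, j = small.names.index(name), big.names.index(name)
            np.testing.assert_array_equal(small.X[:, i], big.X[:, j])

    def test_vectorized_assembly_matches_per_window_encoders(
        self, rng, pwm_pair, property_table
    ):
        from phosthr.encoding import encode_scores

        wins = random_windows(rng, 6)
        cfg = WindowConfig(w1=6, w2=4, w3=6, w4=4)
        max_acc = max(w.acc.max() for w in wins)
        fm = assemble_features(wins, cfg, pwm_pair, property_table, max_acc=max_acc)
        for i, w in enumerate(wins):
            row = np.concatenate(
                [
                    encode_scores(w, pwm_pair, 6),
                    encode_structure(w, 4, max_acc),
                    encode_physchem(
                        w, 6, ("rigidity", "flexibility", "irreplaceability"),
                        property_table,
                    ),
                    encode_physchem(
                        w,
                        4,
                        ("hydrophobicity", "hydrophilicity", "mass", "pk1", "pk2", "pi"),
                        property_table,
                    ),
                ]
            )
            np.testing.assert_allclose(fm.X[i], row)

    def test_loo_encoding_excludes_own_window_from_f1(self, rng, property_table):
        pos = random_windows(rng, 6, label="positive")
        neg = random_windows(rng, 6, label="negative")
        wins = pos + neg
        cfg = WindowConfig(w1=4, w2=2, w3=2, w4=2)
        fm = assemble_features_loo(wins, cfg, property_table)
        # oracle: window 0's F1 must match a pair trained without window 0
        pair0 = PWMPair(
            pos=build_pwm(pos[1:]), neg=build_pwm(neg)
        )
        from phosthr.encoding import encode_scores

        np.testing.assert_allclose(
            fm.X[0, :4], encode_scores(wins[0], pair0, 4)
        )


class TestOptimizeWindowSize:
    def test_single_candidate_returned(self, rng, property_table):
        wins = random_windows(rng, 4, label="positive") + random_windows(
            rng, 4, label="negative"
        )
        best, curve = optimize_window_size(
            wins, "F2", [12], evaluator=lambda X, y: 0.5, table=property_table
        )
        assert best == 12 and curve == {12: 0.5}

    def test_constant_score_ties_break_small(self, rng, property_table):
        wins = random_windows(rng, 4, label="positive") + random_windows(
            rng, 4, label="negative"
        )
        best, _ = optimize_window_size(
            wins, "F3", [10, 12, 14], evaluator=lambda X, y: 0.7,
            table=property_table,
        )
        assert best == 10

    def test_evaluator_failure_names_size(self, rng, property_table):
        wins = random_windows(rng, 4)

        def boom(X, y):
            raise ValueError("nope")

        with pytest.raises(RuntimeError, match="window size 10"):
            optimize_window_size(wins, "F2", [10], evaluator=boom,
                                 table=property_table)


class TestFeatureMatrix:
    def test_duplicate_names_rejected(self):
        with pytest.raises(ParameterError):
            FeatureMatrix(X=np.zeros((2, 2)), names=["a", "a"], y=np.array([0, 1]))

    def test_subset_keeps_names(self):
        fm = FeatureMatrix(
            X=np.arange(6.0).reshape(2, 3), names=["a", "b", "c"], y=np.array([0, 1])
        )
        sub = fm.subset([2, 0])
        assert sub.names == ["c", "a"]
        np.testing.assert_array_equal(sub.X, [[2.0, 0.0], [5.0, 3.0]])


class TestPropertyTable:
    def test_covers_20_residues_and_9_properties(self, property_table):
        assert property_table.values.shape == (20, 9)
        assert set(property_table.properties) == {
            "rigidity", "flexibility", "irreplaceability", "hydrophobicity",
            "hydrophilicity", "mass", "pk1", "pk2", "pi",
        }

    def test_scaled_values_in_unit_interval(self, property_table):
        assert (property_table.scaled.to_numpy() >= 0).all()
        assert (property_table.scaled.to_numpy() <= 1).all()

    def test_x_maps_to_mean_raw_and_half_scaled(self, property_table):
        assert property_table.raw_value("X", "mass") == pytest.approx(
            property_table.values["mass"].mean()
        )
        assert property_table.scaled_value("X", "mass") == 0.5
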