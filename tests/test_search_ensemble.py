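import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.ensemble import RandomForestClassifier

from bbbp.descriptors import DescriptorMatrix
from bbbp.errors import AccessGuardError
from bbbp.models import ModelConfig, roc_auc
from bbbp.scaffold_split import SplitIndices, random_split
from bbbp.search_ensemble import (
    EnsembleSpec,
    RowAccessGuard,
    clip,
    forward_search,
    power_mean,
)

FAST_RF = ModelConfig(kind="rf", n_trees=30, max_depth=5)


def decisive_matrix(seed, n=150, n_noise=4):
    """One descriptor fully determines the label; the rest are noise."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_noise + 1))
    y = (X[:, 0] > 0).astype(int)
    names = ["driver"] + [f"noise{i}" for i in range(n_noise)]
    frame = pd.DataFrame(X, columns=names, index=[str(i) for i in range(n)])
    return DescriptorMatrix(frame=frame), y


class TestPowerMean:
    def test_arithmetic_mean_at_n_equal_one(self):
        out = power_mean([np.array([0.6]), np.array([0.8])], n=1)
        assert out[0] == pytest.approx(0.7, abs=1e-15)

    def test_idempotent_on_identical_members(self):
        p = np.array([0.1, 0.5, 0.9])
        for n in (1.0, 0.5, 1 / 32, 2.0):
            assert np.allclose(power_mean([p, p, p], n), p)

    def test_direct_formula_evaluation(self):
        # ((0.25^(1/32) + 1^(1/32)) / 2)^32, evaluated independently
        expected = ((0.25 ** (1 / 32) + 1.0) / 2.0) ** 32
        out = power_mean([np.array([0.25]), np.array([1.0])], n=1 / 32)
        assert out[0] == pytest.approx(expected, rel=1e-12)
        assert out[0] == pytest.approx(0.5038, abs=1e-4)

    def test_zero_member_with_fractional_exponent(self):
        out = power_mean([np.array([0.0]), np.array([1.0])], n=1 / 32)
        assert np.isfinite(out[0]) and 0.0 <= out[0] <= 1.0

    def test_n_zero_rejected(self):
        with pytest.raises(ValueError):
            power_mean([np.array([0.5])], n=0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(st.floats(0.0, 1.0), min_size=2, max_size=6),
        st.sampled_from([1 / 32, 0.25, 0.5, 0.999, 1.0, 2.0]),
    )
    def test_bounded_by_member_min_max(self, values, n):
        members = [np.array([v]) for v in values]
        out = power_mean(members, n)[0]
        assert min(values) - 1e-12 <= out <= max(values) + 1e-12

    def test_approaches_arithmetic_mean_as_n_to_one(self):
        members = [np.array([0.2, 0.7]), np.array([0.9, 0.4])]
        near = power_mean(members, n=0.999)
        exact = power_mean(members, n=1.0)
        assert np.allclose(near, exact, atol=1e-3)

    def test_monotone_in_each_member(self):
        base = [np.array([0.3]), np.array([0.6])]
        bumped = [np.array([0.35]), np.array([0.6])]
        assert power_mean(bumped, 1 / 32)[0] > power_mean(base, 1 / 32)[0]


class TestClip:
    @pytest.mark.parametrize("p, expected", [(0.01, 0.0), (0.99, 1.0), (0.5, 0.5)])
    def test_rules(self, p, expected):
        assert clip([p])[0] == expected

    def test_boundaries_not_clipped(self):
        assert list(clip([0.02, 0.98])) == [0.02, 0.98]

    def test_preserves_ordering_away_from_clipped_ties(self):
        scores = np.array([0.01, 0.015, 0.3, 0.6, 0.99])
        labels = np.array([0, 0, 0, 1, 1])
        assert roc_auc(labels, clip(scores)) >= roc_auc(labels, scores) - 1e-12


class TestEnsembleSpec:
    def test_power_mean_then_clip(self):
        # clipping acts on the combined vector: members 0.01/0.02 average to
        # 0.015 < 0.02 and snap to 0, though 0.02 itself would not clip
        members = [np.array([0.01, 0.4]), np.array([0.02, 0.6])]
        spec = EnsembleSpec(members=members, n=1.0, clipping=True)
        manual = clip(power_mean(members, 1.0))
        assert np.allclose(spec.combine(), manual)
        assert spec.combine()[0] == 0.0
        assert spec.combine()[1] == pytest.approx(0.5)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            EnsembleSpec(members=[])
        with pytest.raises(ValueError):
            EnsembleSpec(members=[np.array([0.5]), np.array([0.5, 0.5])])
        with pytest.raises(ValueError):
            EnsembleSpec(members=[np.array([1.5])])
        with pytest.raises(ValueError):
            EnsembleSpec(members=[np.array([0.5])], n=0)


class TestRowAccessGuard:
    def test_forbidden_rows_raise(self):
        guard = RowAccessGuard(np.arange(20).reshape(10, 2), forbidden=[7, 8])
        assert guard.rows([0, 1]).shape == (2, 2)
        with pytest.raises(AccessGuardError, match="7"):
            guard.rows([1, 7])

    def test_column_selection(self):
        guard = RowAccessGuard(np.arange(12).reshape(4, 3), forbidden=[])
        block = guard.rows([1, 2], columns=[2])
        assert block.tolist() == [[5], [8]]


class TestForwardSearch:
    def test_decisive_descriptor_selected_first(self):
        matrix, y = decisive_matrix(seed=0)
        split = random_split(len(y), seed=0)
        state = forward_search(
            matrix, y, split, config=FAST_RF, max_steps=1, repeats=1, base_seed=0
        )
        assert state.selected[0] == "driver"
        assert state.history[0] > 0.9

    def test_greedy_path_matches_exhaustive_oracle(self):
        """Step-by-step argmax agrees with brute-force enumeration of all
        candidate subsets scored by an identically configured forest."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(120, 3))
        y = ((X[:, 0] + 0.8 * X[:, 1]) > 0).astype(int)
        frame = pd.DataFrame(X, columns=["a", "b", "c"],
                             index=[str(i) for i in range(120)])
        matrix = DescriptorMatrix(frame=frame)
        split = random_split(len(y), seed=1)

        def oracle_score(cols):
            est = RandomForestClassifier(n_estimators=30, max_depth=5, random_state=0)
            est.fit(X[np.ix_(split.train, cols)], y[split.train])
            probs = est.predict_proba(X[np.ix_(split.valid, cols)])[:, 1]
            return roc_auc(y[split.valid], probs)

        # oracle greedy path over subsets of size <= 2
        first = max(range(3), key=lambda j: (oracle_score([j]), -j))
        second = max(
            (j for j in range(3) if j != first),
            key=lambda j: (oracle_score([first, j]), -j),
        )
        state = forward_search(
            matrix, y, split, config=ModelConfig(kind="rf", n_trees=30, max_depth=5, seed=0),
            max_steps=2, repeats=1, base_seed=0, epsilon=-1.0,
        )
        names = ["a", "b", "c"]
        assert state.selected == [names[first], names[second]]

    def test_saturation_stops_search(self):
        matrix, y = decisive_matrix(seed=1)
        split = random_split(len(y), seed=2)
        state = forward_search(
            matrix, y, split, config=FAST_RF, max_steps=5, repeats=1, base_seed=0,
            epsilon=0.001,
        )
        assert state.stopped_reason == "saturated"
        assert len(state.selected) < 5
        # history is non-decreasing
        assert all(b >= a for a, b in zip(state.history, state.history[1:]))

    def test_train_plus_validation_criterion_runs(self):
        matrix, y = decisive_matrix(seed=2)
        split = random_split(len(y), seed=3)
        for mode in ("pooled", "averaged"):
            state = forward_search(
                matrix, y, split, criterion="train_plus_validation",
                config=FAST_RF, max_steps=1, repeats=1, tv_mode=mode,
            )
            assert state.selected[0] == "driver"

    def test_never_reads_test_rows(self):
        """The guard is the only row accessor, so a completed search implies
        no test access; asking the same guard for test rows raises."""
        matrix, y = decisive_matrix(seed=4)
        split = random_split(len(y), seed=4)
        state = forward_search(matrix, y, split, config=FAST_RF, max_steps=2, repeats=1)
        assert state.selected
        guard = RowAccessGuard(matrix.values, forbidden=split.test)
        with pytest.raises(AccessGuardError):
            guard.rows(split.test[:1])
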