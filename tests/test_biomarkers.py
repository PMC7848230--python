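"""Stable-predictor criteria and PDP form classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phenomark.biomarkers import (
    PDPCurve,
    average_curves,
    classify_pdp_form,
    compute_pdp,
    group_mean_differences,
    identify_stable_predictors,
)


def curve(prob):
    return PDPCurve(grid=np.linspace(0, 1, 20), prob=np.asarray(prob, float))


STEP = curve([0.8] * 5 + [0.2] * 15)
LINEAR_UP = curve(np.linspace(0.2, 0.8, 20))


class TestStablePredictors:
    def variants(self, pattern):
        """7 variants; pattern gives per-variant importance of 'probe'."""
        out = {}
        for i, v in enumerate(pattern):
            out[f"V{i}"] = pd.Series({"probe": v, "other": 0.5})
        return out

    def diffs(self, signs):
        return {f"D{i}": pd.Series({"probe": s, "other": 0.1})
                for i, s in enumerate(signs)}

    def test_six_of_seven_with_consistent_sign_is_stable(self):
        reports = identify_stable_predictors(
            self.variants([0.1] * 6 + [0.0]), self.diffs([0.2, 0.3, 0.1])
        )
        names = {r.feature for r in reports}
        assert "probe" in names
        probe = next(r for r in reports if r.feature == "probe")
        assert probe.n_variants_nonzero == 6
        assert probe.direction == 1
        assert probe.mean_importance == pytest.approx(0.6 / 7)

    def test_five_of_seven_is_not_stable(self):
        reports = identify_stable_predictors(
            self.variants([0.1] * 5 + [0.0] * 2), self.diffs([0.2, 0.3, 0.1])
        )
        assert "probe" not in {r.feature for r in reports}

    def test_sign_flip_in_one_dataset_is_not_stable(self):
        reports = identify_stable_predictors(
            self.variants([0.1] * 7), self.diffs([0.2, -0.3, 0.1])
        )
        assert "probe" not in {r.feature for r in reports}

    def test_zero_difference_breaks_consistency(self):
        reports = identify_stable_predictors(
            self.variants([0.1] * 7), self.diffs([0.2, 0.0, 0.1])
        )
        assert "probe" not in {r.feature for r in reports}

    def test_zeroing_importance_never_creates_stability(self, rng):
        """Monotonicity of criterion (i) under importance removal."""
        for trial in range(30):
            vals = rng.random(7) * (rng.random(7) < 0.8)
            base = identify_stable_predictors(
                self.variants(vals), self.diffs([1.0, 1.0, 1.0])
            )
            was_stable = "probe" in {r.feature for r in base}
            drop = vals.copy()
            drop[rng.integers(7)] = 0.0
            after = identify_stable_predictors(
                self.variants(drop), self.diffs([1.0, 1.0, 1.0])
            )
            now_stable = "probe" in {r.feature for r in after}
            assert not (now_stable and not was_stable)


class TestPDPCurve:
    def test_deltas_definition(self):
        c = curve(np.arange(20) / 20)
        assert len(c.deltas) == 15
        assert c.deltas[0] == pytest.approx(c.prob[5] - c.prob[0])

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            PDPCurve(grid=np.linspace(0, 1, 10), prob=np.zeros(10))


class TestClassifyPDPForm:
    def test_step_curve_is_sharply_decreasing(self):
        """Drop of 0.6 against flat outer intervals."""
        assert classify_pdp_form(STEP) == "sharply_decreasing"

    def test_step_up_is_sharply_increasing(self):
        assert classify_pdp_form(curve([0.2] * 5 + [0.8] * 15)) == (
            "sharply_increasing"
        )

    def test_linear_ascent_is_smoothly_increasing(self):
        assert classify_pdp_form(LINEAR_UP) == "smoothly_increasing"

    def test_linear_descent_is_smoothly_decreasing(self):
        assert classify_pdp_form(curve(np.linspace(0.8, 0.2, 20))) == (
            "smoothly_decreasing"
        )

    def test_mixed_signs_with_ratio_below_two_unclassified(self):
        """Rise then fall with max|d+|/max|d-| = 1.5."""
        prob = np.concatenate([
            np.linspace(0.2, 0.5, 8),          # rise: max positive delta
            np.linspace(0.5, 0.05, 12),        # fall
        ])
        c = curve(prob)
        pos = c.deltas[c.deltas > 0]
        neg = c.deltas[c.deltas < 0]
        ratio = max(pos.max(), -neg.min()) / min(pos.max(), -neg.min())
        assert ratio < 2
        assert classify_pdp_form(c) == "unclassified"

    def test_flat_curve_unclassified(self):
        assert classify_pdp_form(curve([0.5] * 20)) == "unclassified"

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        probs=st.lists(st.floats(0.0, 1.0, allow_nan=False),
                       min_size=20, max_size=20),
        # powers of two and dyadic offsets keep the affine map exact in
        # floating point, so boundary ties cannot flip spuriously
        scale=st.sampled_from([0.25, 0.5, 2.0, 4.0]),
        offset=st.sampled_from([-0.5, 0.0, 0.25, 0.5, 1.0]),
    )
    def test_invariant_under_positive_affine_transforms(self, probs, scale, offset):
        base = classify_pdp_form(curve(probs))
        transformed = classify_pdp_form(
            PDPCurve(grid=np.linspace(0, 1, 20),
                     prob=np.asarray(probs) * scale + offset)
        )
        assert base == transformed

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(probs=st.lists(st.floats(0.0, 1.0, allow_nan=False),
                          min_size=20, max_size=20))
    def test_reversal_swaps_direction_preserves_form(self, probs):
        forward = classify_pdp_form(curve(probs))
        backward = classify_pdp_form(curve(probs[::-1]))
        swap = {
            "sharply_increasing": "sharply_decreasing",
            "sharply_decreasing": "sharply_increasing",
            "smoothly_increasing": "smoothly_decreasing",
            "smoothly_decreasing": "smoothly_increasing",
            "unclassified": "unclassified",
        }
        assert backward == swap[forward]

    def test_monotone_curve_never_labelled_against_its_trend(self, rng):
        for k in range(20):
            steps = rng.random(19)
            prob = np.concatenate([[0.0], np.cumsum(steps)])
            prob = prob / max(prob.max(), 1e-9)
            label = classify_pdp_form(curve(prob))
            assert "decreasing" not in label


class TestComputePDP:
    def test_model_ignoring_feature_gives_flat_curve(self, rng):
        from sklearn.tree import DecisionTreeClassifier

        X = pd.DataFrame({"used": rng.random(100), "ignored": rng.random(100)})
        y = (X["used"] > 0.5).astype(int)
        model = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X.to_numpy(), y)
        c = compute_pdp(model, X, "ignored")
        assert np.allclose(c.prob, c.prob[0])

    def test_stump_pdp_is_two_level_step(self, rng):
        """A depth-1 split at t yields PDP levels equal to the leaf
        disease probabilities on either side of t (closed form)."""
        from sklearn.tree import DecisionTreeClassifier

        x = rng.random(200)
        y = (x > 0.5).astype(int)
        X = pd.DataFrame({"x": x})
        model = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X.to_numpy(), y)
        threshold = model.tree_.threshold[0]
        c = compute_pdp(model, X, "x")
        left = c.prob[c.grid <= threshold]
        right = c.prob[c.grid > threshold]
        lo = y[x <= threshold].mean()
        hi = y[x > threshold].mean()
        assert np.allclose(left, lo) and np.allclose(right, hi)
        assert classify_pdp_form(c) == "sharply_increasing"

    def test_constant_feature_rejected(self, rng):
        from sklearn.tree import DecisionTreeClassifier

        X = pd.DataFrame({"x": rng.random(50), "const": np.ones(50)})
        y = (X["x"] > 0.5).astype(int)
        model = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X.to_numpy(), y)
        with pytest.raises(ValueError, match="degenerate"):
            compute_pdp(model, X, "const")

    def test_average_requires_common_grid(self):
        a = PDPCurve(np.linspace(0, 1, 20), np.zeros(20))
        b = PDPCurve(np.linspace(0, 2, 20), np.zeros(20))
        with pytest.raises(ValueError):
            average_curves([a, b])
        merged = average_curves([a, curve([1.0] * 20)])
        assert np.allclose(merged.prob, 0.5)

    @pytest.mark.parametrize("relation, expected_form", [
        ("threshold", "sharply"),
        ("linear", "smoothly"),
    ])
    def test_form_recovery_from_planted_relations(self, relation, expected_form):
        """RFs trained on a hard-threshold vs linear disease relation
        yield the matching sharp/smooth increasing label on the majority
        of seeds."""
        from phenomark.ml import RFParams

        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 300
            X = pd.DataFrame({
                "x": rng.random(n),
                "noise": rng.random(n),
            })
            if relation == "threshold":
                p = np.where(X["x"] > 0.5, 0.9, 0.1)
            else:
                p = 0.1 + 0.8 * X["x"]
            y = (rng.random(n) < p).astype(int)
            model = RFParams(n_estimators=50).make(seed).fit(X.to_numpy(), y)
            label = classify_pdp_form(compute_pdp(model, X, "x"))
            if label == f"{expected_form}_increasing":
                hits += 1
        assert hits >= 3


def test_group_mean_differences():
    features = {
        "A": pd.DataFrame({"f": [1.0, 1.0, 3.0, 3.0]},
                          index=["s1", "s2", "s3", "s4"]),
    }
    labels = {"A": pd.Series(["HC", "HC", "CD", "CD"],
                             index=["s1", "s2", "s3", "s4"])}
    diffs = group_mean_differences(features, labels, "CD")
    assert diffs["A"]["f"] == pytest.approx(2.0)
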