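"""Stable predictors and partial-dependence-plot form classification.

A feature is a *stable predictor* for one predictor set x contrast when
(i) it has nonzero mean importance in at least six of the seven
strategy-variant classifiers (a feature never extracted in an iteration
carries importance zero there) and (ii) the sign of the case-minus-control
mean difference of its values is the same in every cohort. Its reported
importance is the average across the seven variants.

Each stable predictor's influence is summarised by a single-feature
partial dependence plot (PDP): the model's mean predicted disease
probability as the feature is substituted to each of 20 grid values
spanning its observed training range, averaged over all training rows
(and, one level up, over classifier iterations on a common grid). The
curve's shape is then labelled by the step differences

    delta_i = prob[i+5] - prob[i]      (1-based i = 1..15)

* direction: sign of the delta with the largest magnitude; if both signs
  occur and the ratio max|delta+| : max|delta-| (larger over smaller) is
  below 2, the curve is unclassified (so is an all-zero/flat curve);
* sharpness: sharp when some |delta_i| is at least 3x the largest
  probability range (max - min) over the outer intervals [1, i) and
  (i+5, 20]; otherwise smooth.

Labels: sharply/smoothly increasing/decreasing, or unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

PDP_LABELS = (
    "sharply_decreasing",
    "sharply_increasing",
    "smoothly_decreasing",
    "smoothly_increasing",
    "unclassified",
)

#: minimum number of strategy-variant classifiers with nonzero importance
STABILITY_MIN_VARIANTS = 6
#: opposite-sign delta ratio below which direction is ambiguous
DIRECTION_RATIO = 2.0
#: sharpness multiple of the outer-interval probability range
SHARPNESS_FACTOR = 3.0


@dataclass
class StablePredictorReport:
    feature: str
    predictor_set: str
    contrast: str
    mean_importance: float
    direction: int  # +1 case-enriched, -1 case-depleted
    n_variants_nonzero: int


@dataclass
class PDPCurve:
    """A 20-step partial dependence curve."""

    grid: np.ndarray  # ascending feature values
    prob: np.ndarray  # predicted disease probabilities

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.prob = np.asarray(self.prob, dtype=float)
        if self.grid.shape != self.prob.shape:
            raise ValueError("grid and prob lengths differ")
        if len(self.grid) != 20:
            raise ValueError(f"PDP curve needs 20 steps, got {len(self.grid)}")
        if np.any(np.diff(self.grid) < 0):
            raise ValueError("grid must be ascending")

    @property
    def deltas(self) -> np.ndarray:
        """delta_i = prob[i+5] - prob[i] for 1-based i = 1..15."""
        return self.prob[5:] - self.prob[:-5]


def identify_stable_predictors(
    importances_by_variant: Mapping[str, pd.Series],
    diffs_by_dataset: Mapping[str, pd.Series],
    predictor_set: str = "",
    contrast: str = "",
    min_variants: int = STABILITY_MIN_VARIANTS,
) -> list[StablePredictorReport]:
    """Apply the two stability criteria across the 7 classifier variants.

    ``importances_by_variant`` maps each strategy-variant key to a
    feature -> mean-importance series (missing features are zero);
    ``diffs_by_dataset`` maps each cohort to a feature -> (case mean -
    control mean) series. Stability needs >= ``min_variants`` nonzero
    importances and a strictly consistent difference sign in every cohort.
    """
    variants = list(importances_by_variant)
    features = sorted(
        set().union(*(s.index for s in importances_by_variant.values()))
    )
    imp = pd.DataFrame(
        {v: importances_by_variant[v].reindex(features, fill_value=0.0)
         for v in variants}
    )
    reports = []
    for f in features:
        nonzero = int((imp.loc[f] > 0).sum())
        if nonzero < min_variants:
            continue
        signs = {
            int(np.sign(diffs.get(f, 0.0))) for diffs in diffs_by_dataset.values()
        }
        if len(signs) != 1 or 0 in signs:
            continue
        reports.append(
            StablePredictorReport(
                feature=f,
                predictor_set=predictor_set,
                contrast=contrast,
                mean_importance=float(imp.loc[f].mean()),
                direction=signs.pop(),
                n_variants_nonzero=nonzero,
            )
        )
    reports.sort(key=lambda r: -r.mean_importance)
    return reports


def compute_pdp(
    model,
    train_features: pd.DataFrame,
    feature: str,
    n_grid: int = 20,
    grid_range: tuple[float, float] | None = None,
) -> PDPCurve:
    """Single-feature PDP of a fitted binary classifier.

    The grid spans the feature's observed training range (endpoints
    included; a shared range may be passed for cross-iteration averaging).
    prob[j] is the mean predicted disease-class probability after
    substituting grid[j] into every training row.
    """
    if grid_range is None:
        lo, hi = float(train_features[feature].min()), float(
            train_features[feature].max()
        )
    else:
        lo, hi = grid_range
    if hi <= lo:
        raise ValueError(f"feature {feature!r} has a degenerate range [{lo}, {hi}]")
    grid = np.linspace(lo, hi, n_grid)
    X = train_features.to_numpy(dtype=float).copy()
    col = list(train_features.columns).index(feature)
    disease_col = list(model.classes_).index(1)
    prob = np.empty(n_grid)
    for j, v in enumerate(grid):
        X[:, col] = v
        prob[j] = model.predict_proba(X)[:, disease_col].mean()
    return PDPCurve(grid=grid, prob=prob)


def average_curves(curves: Sequence[PDPCurve]) -> PDPCurve:
    """Pointwise mean of curves computed on a common grid."""
    grids = np.stack([c.grid for c in curves])
    if not np.allclose(grids, grids[0]):
        raise ValueError("curves must share a common grid")
    return PDPCurve(grid=grids[0], prob=np.mean([c.prob for c in curves], axis=0))


def classify_pdp_form(curve: PDPCurve) -> str:
    """Label a PDP curve by the delta rules described in the module docs."""
    deltas = curve.deltas
    absd = np.abs(deltas)
    if np.all(absd == 0):
        return "unclassified"

    max_abs = absd.max()
    best_signs = set(np.sign(deltas[absd == max_abs]).astype(int))
    if len(best_signs) > 1:
        return "unclassified"  # exact tie between a positive and negative delta
    direction = best_signs.pop()

    pos = deltas[deltas > 0]
    neg = deltas[deltas < 0]
    if len(pos) and len(neg):
        a, b = pos.max(), np.abs(neg).max()
        ratio = max(a, b) / min(a, b)
        if ratio < DIRECTION_RATIO:
            return "unclassified"

    sharp = False
    prob = curve.prob
    for i in range(1, 16):  # 1-based step index
        d = absd[i - 1]
        if d == 0:
            continue
        lower = prob[: i - 1]  # steps [1, i)
        upper = prob[i + 5 :]  # steps (i+5, 20]
        outer = 0.0
        if len(lower) > 1:
            outer = max(outer, lower.max() - lower.min())
        if len(upper) > 1:
            outer = max(outer, upper.max() - upper.min())
        if d >= SHARPNESS_FACTOR * outer:
            sharp = True
            break

    form = "sharply" if sharp else "smoothly"
    trend = "increasing" if direction > 0 else "decreasing"
    return f"{form}_{trend}"


def group_mean_differences(
    features_by_dataset: Mapping[str, pd.DataFrame],
    labels_by_dataset: Mapping[str, pd.Series],
    contrast: str,
) -> dict[str, pd.Series]:
    """Per cohort, the (case mean - control mean) of every feature."""
    out = {}
    for d, table in features_by_dataset.items():
        lab = labels_by_dataset[d].loc[table.index]
        case = table.loc[lab == contrast].mean(axis=0)
        ctrl = table.loc[lab == "HC"].mean(axis=0)
        out[d] = case - ctrl
    return out


def reports_to_frame(reports: Sequence[StablePredictorReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "predictor_set": r.predictor_set,
                "contrast": r.contrast,
                "mean_importance": r.mean_importance,
                "direction": r.direction,
                "n_variants_nonzero": r.n_variants_nonzero,
            }
            for r in reports
        ],
        columns=[
            "feature",
            "predictor_set",
            "contrast",
            "mean_importance",
            "direction",
            "n_variants_nonzero",
        ],
    )
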