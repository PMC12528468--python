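"""Binned aggregation of patch predictions and slide-level forest regression.

A slide yields a variable-length set of patch predictions (y_1 .. y_n).
The Freedman-Diaconis rule picks a bin count

    m = round( n^(1/3) * (max - min) / (2 * IQR) )

with the interquartile range computed by linear-interpolation quantiles;
the slide is then summarized by the per-bin means of its predictions over
m equal-width bins spanning [min, max].  Because a random forest needs a
fixed-length input, the bin count actually used is a single global value
chosen from the training slides (median of their per-slide counts,
rounded up, clamped to >= 2).  A 10-tree random forest with an
absolute-error split criterion regresses slide survival from the binned
features, and a patient's prediction is the unweighted mean over their
slides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestRegressor


@dataclass
class SlideFeatureVector:
    """Fixed-length summary of one slide's patch predictions."""

    slide_id: str
    m: int
    values: np.ndarray
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        if self.values.shape != (self.m,):
            raise ValueError(f"expected {self.m} values, got {self.values.shape}")


@dataclass
class PredictionRecord:
    """A predicted survival time (days) at patch, slide, or patient level."""

    level: str
    id: str
    predicted_days: float

    def __post_init__(self) -> None:
        if self.level not in ("patch", "slide", "patient"):
            raise ValueError(f"level must be patch/slide/patient, got {self.level!r}")
        if not np.isfinite(self.predicted_days):
            raise ValueError(f"non-finite prediction for {self.id!r}")


def fd_bin_count(values: Sequence[float]) -> int:
    """Freedman-Diaconis bin count for one slide's patch predictions.

    m = n^(1/3) * (max - min) / (2 * IQR), rounded half-away-from-zero and
    clamped to >= 1.  Quartiles use linear interpolation between order
    statistics.  Degenerate inputs (IQR = 0 or max = min) give m = 1.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("fd_bin_count needs at least one value")
    vmax, vmin = v.max(), v.min()
    iqr = np.subtract(*np.percentile(v, [75, 25]))
    if iqr == 0 or vmax == vmin:
        return 1
    m = v.size ** (1.0 / 3.0) * (vmax - vmin) / (2.0 * iqr)
    return max(1, int(math.floor(m + 0.5)))


def binned_features(
    values: Sequence[float], m: int, slide_id: str = ""
) -> SlideFeatureVector:
    """Per-bin means of ``values`` over m equal-width bins on [min, max].

    The last bin is right-closed so the maximum is counted.  Empty bins
    are filled with the overall mean of ``values`` (keeps the feature
    vector finite and on the same scale).  A degenerate range (max = min)
    yields the single value repeated to length m.
    """
    if m <= 0:
        raise ValueError(f"bin count must be positive, got {m}")
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("binned_features needs at least one value")
    vmin, vmax = v.min(), v.max()
    if vmin == vmax:
        return SlideFeatureVector(
            slide_id=slide_id,
            m=m,
            values=np.full(m, vmin),
            bin_edges=np.linspace(vmin - 0.5, vmax + 0.5, m + 1),
        )
    edges = np.linspace(vmin, vmax, m + 1)
    means, edges, _ = stats.binned_statistic(v, v, statistic="mean", bins=edges)
    means = np.where(np.isnan(means), v.mean(), means)
    return SlideFeatureVector(slide_id=slide_id, m=m, values=means, bin_edges=edges)


def choose_global_bin_count(
    training_slides: Sequence[Sequence[float]],
) -> int:
    """One bin count for the whole model: median of per-slide counts.

    The per-slide Freedman-Diaconis rule gives each slide its own m, but
    the forest needs a fixed-length input; the median over training
    slides, rounded up and clamped to >= 2, is stored with the model and
    reused for test slides.
    """
    if len(training_slides) == 0:
        raise ValueError("need at least one training slide")
    ms = [fd_bin_count(vals) for vals in training_slides]
    return max(2, int(math.ceil(np.median(ms))))


@dataclass
class SlideRegressor:
    """Random forest mapping binned slide features to survival days.

    Predictions are averages over tree-leaf training times, so they always
    lie within [min, max] of the training survival times.
    """

    forest: RandomForestRegressor
    feature_length: int
    m_global: int
    train_time_range: tuple[float, float]
    n_trees: int = 10
    split_criterion: str = "absolute_error"
    _train_times: np.ndarray = field(default=None, repr=False)


def fit_slide_regressor(
    features: Sequence[SlideFeatureVector],
    times: Sequence[float],
    n_trees: int = 10,
    seed: int = 0,
    bootstrap: bool = True,
    max_depth: int | None = None,
    min_samples_split: int = 2,
) -> SlideRegressor:
    """Fit the slide-level random forest (10 trees, absolute-error splits).

    One survival time per slide (a slide inherits its patient's time).
    Bootstrap sampling and tree construction are seeded.
    """
    if len(features) != len(times):
        raise ValueError(
            f"{len(features)} feature vectors but {len(times)} survival times"
        )
    if len(features) < 2:
        raise ValueError("need at least two slides to fit the forest")
    lengths = {f.m for f in features}
    if len(lengths) != 1:
        raise ValueError(f"feature vectors have mixed lengths {sorted(lengths)}")
    X = np.stack([f.values for f in features])
    y = np.asarray(times, dtype=np.float64)
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        criterion="absolute_error",
        bootstrap=bootstrap,
        random_state=seed,
        max_depth=max_depth,
        min_samples_split=min_samples_split,
    )
    forest.fit(X, y)
    return SlideRegressor(
        forest=forest,
        feature_length=X.shape[1],
        m_global=X.shape[1],
        train_time_range=(float(y.min()), float(y.max())),
        n_trees=n_trees,
        _train_times=y,
    )


def predict_slide_survival(
    model: SlideRegressor, feature: SlideFeatureVector
) -> PredictionRecord:
    """Predict one slide's survival time SV_i from its binned features."""
    if feature.m != model.feature_length:
        raise ValueError(
            f"feature length {feature.m} does not match the fitted length "
            f"{model.feature_length}"
        )
    pred = float(model.forest.predict(feature.values[None, :])[0])
    return PredictionRecord(level="slide", id=feature.slide_id, predicted_days=pred)


def aggregate_patient(
    slide_predictions: Sequence[PredictionRecord] | Sequence[float],
    patient_id: str = "",
) -> PredictionRecord:
    """Patient survival SV_p: unweighted mean of the slide predictions SV_i."""
    if len(slide_predictions) == 0:
        raise ValueError("a patient needs at least one slide prediction")
    vals = [
        p.predicted_days if isinstance(p, PredictionRecord) else float(p)
        for p in slide_predictions
    ]
    return PredictionRecord(
        level="patient", id=patient_id, predicted_days=float(np.mean(vals))
    )
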