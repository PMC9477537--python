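"""The wide-and-deep peak scorer.

Three components, trained in stages so each stays independently useful:

1. ``ShapeModel`` — a small 1-D convolutional network over the 2000-point
   max-normalized signal window, emitting a shape score in [0, 1].
2. ``EnrichmentModel`` — logistic regression over the 11 log-transformed
   enrichment ratios, emitting an enrichment score in [0, 1].
3. ``CombinerModel`` — a one-hidden-layer perceptron over 13 inputs (shape
   score, enrichment score, the 11 log-features), emitting the final peak
   score: the probability that the region's signal arises from a real event.

Stages 1 and 2 are fit first and frozen; the combiner is fit on their
outputs.  Everything is deterministic given the training seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression

from peakshaper import _nn
from peakshaper.candidate_detection import CandidatePeak
from peakshaper.coverage_io import GenomicRegion
from peakshaper.features import (
    EPSILON,
    N_ENRICHMENT_FEATURES,
    SIGNAL_WINDOW_BP,
    FeatureBundle,
)

FORMAT_VERSION = 1
FEATURE_ORDER = "bg10k..bg100k,chromwide"

# fixed small architectures; any net passing the recovery suite is conformant
SHAPE_ARCH = [
    ("conv", 1, 8, 11),
    ("relu",),
    ("maxpool", 10),
    ("conv", 8, 16, 9),
    ("relu",),
    ("maxpool", 5),
    ("conv", 16, 16, 5),
    ("relu",),
    ("maxpool", 4),
    ("flatten",),
    ("dense", 160, 16),
    ("relu",),
    ("dense", 16, 1),
]
COMBINER_ARCH = [
    ("dense", 13, 16),
    ("relu",),
    ("dense", 16, 1),
]


class TrainingError(ValueError):
    pass


class ModelLoadError(ValueError):
    pass


def _build_net(arch: list[tuple], rng: np.random.Generator) -> _nn.SequentialNet:
    layers: list[_nn.Layer] = []
    for spec in arch:
        kind = spec[0]
        if kind == "conv":
            layers.append(_nn.Conv1d(spec[1], spec[2], spec[3], rng))
        elif kind == "relu":
            layers.append(_nn.ReLU())
        elif kind == "maxpool":
            layers.append(_nn.MaxPool1d(spec[1]))
        elif kind == "flatten":
            layers.append(_nn.Flatten())
        elif kind == "dense":
            layers.append(_nn.Dense(spec[1], spec[2], rng))
        else:
            raise ModelLoadError(f"unknown layer kind {kind!r}")
    return _nn.SequentialNet(layers)


@dataclass
class ShapeModel:
    """CNN over the 2000-point signal window."""

    net: _nn.SequentialNet
    arch: list[tuple] = field(default_factory=lambda: list(SHAPE_ARCH))

    def predict(self, windows: np.ndarray) -> np.ndarray:
        windows = np.asarray(windows, dtype=np.float64)
        if windows.ndim == 1:
            windows = windows[None, :]
        if windows.shape[1] != SIGNAL_WINDOW_BP:
            raise ValueError(f"signal windows must have {SIGNAL_WINDOW_BP} points")
        return self.net.predict(windows[:, None, :])


@dataclass
class EnrichmentModel:
    """Logistic regression over log-transformed enrichment ratios."""

    coef: np.ndarray  # shape (11,)
    intercept: float

    def predict(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=np.float64)
        if features.ndim == 1:
            features = features[None, :]
        if features.shape[1] != N_ENRICHMENT_FEATURES:
            raise ValueError(f"expected {N_ENRICHMENT_FEATURES} enrichment features")
        return _nn.sigmoid(np.log(features) @ self.coef + self.intercept)


@dataclass
class CombinerModel:
    """MLP over (shape score, enrichment score, 11 log-features)."""

    net: _nn.SequentialNet
    arch: list[tuple] = field(default_factory=lambda: list(COMBINER_ARCH))

    def predict(self, inputs: np.ndarray) -> np.ndarray:
        inputs = np.asarray(inputs, dtype=np.float64)
        if inputs.ndim == 1:
            inputs = inputs[None, :]
        if inputs.shape[1] != 2 + N_ENRICHMENT_FEATURES:
            raise ValueError("combiner expects 13 inputs per region")
        return self.net.predict(inputs)


@dataclass
class PeakScorer:
    """The trained three-part model."""

    shape_model: ShapeModel
    enrichment_model: EnrichmentModel
    combiner_model: CombinerModel
    seed: int = 0

    def __iter__(self):
        return iter((self.shape_model, self.enrichment_model, self.combiner_model))


@dataclass(frozen=True)
class ScoredPeak:
    """A candidate plus its three scores and optional input-control P-value."""

    region: GenomicRegion
    shape_score: float
    enrichment_score: float
    peak_score: float
    height: float
    n_definitions: int = 0
    saturated: bool = False
    pvalue: float | None = None


def _stack(bundles: list[FeatureBundle]) -> tuple[np.ndarray, np.ndarray]:
    windows = np.stack([b.signal_window for b in bundles])
    feats = np.stack([b.enrichment_features for b in bundles])
    return windows, feats


def _as_binary(labels) -> np.ndarray:
    mapping = {"peak": 1, "noise": 0, 1: 1, 0: 0, True: 1, False: 0}
    try:
        return np.array([mapping[l] for l in labels], dtype=np.float64)
    except KeyError as exc:
        raise TrainingError(f"unknown label {exc.args[0]!r}") from exc


def train(
    bundles: list[FeatureBundle],
    labels,
    seed: int = 0,
) -> PeakScorer:
    """Staged training: CNN on windows, logistic regression on features,
    then the combiner on the frozen components' outputs.

    Deterministic given ``seed``.  Raises :class:`TrainingError` unless both
    classes have at least two examples.
    """
    y = _as_binary(labels)
    if len(bundles) != y.size:
        raise TrainingError("bundles and labels differ in length")
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise TrainingError("need at least 2 examples per class")
    windows, feats = _stack(bundles)
    logf = np.log(feats)

    # stage 1: shape CNN on signal windows only
    rng = np.random.default_rng(seed)
    shape_net = _build_net(SHAPE_ARCH, rng)
    _nn.train_binary(shape_net, windows[:, None, :], y, rng)
    shape_model = ShapeModel(shape_net)

    # stage 2: logistic regression on log enrichment features only
    lr = LogisticRegression(max_iter=1000)
    lr.fit(logf, y)
    enrichment_model = EnrichmentModel(
        coef=lr.coef_.ravel().astype(np.float64), intercept=float(lr.intercept_[0])
    )

    # stage 3: combiner on the frozen components' outputs + features
    shape_scores = shape_model.predict(windows)
    enr_scores = enrichment_model.predict(feats)
    combo_in = np.column_stack([shape_scores, enr_scores, logf])
    comb_net = _build_net(COMBINER_ARCH, rng)
    _nn.train_binary(comb_net, combo_in, y, rng, max_epochs=200, patience=20)
    combiner_model = CombinerModel(comb_net)

    return PeakScorer(shape_model, enrichment_model, combiner_model, seed=seed)


def score_bundles(scorer: PeakScorer, bundles: list[FeatureBundle]) -> np.ndarray:
    """Score many bundles at once; returns an (n, 3) array of
    (shape_score, enrichment_score, peak_score) rows."""
    if not bundles:
        return np.zeros((0, 3))
    windows, feats = _stack(bundles)
    shape_scores = scorer.shape_model.predict(windows)
    enr_scores = scorer.enrichment_model.predict(feats)
    combo_in = np.column_stack([shape_scores, enr_scores, np.log(feats)])
    peak_scores = scorer.combiner_model.predict(combo_in)
    return np.column_stack([shape_scores, enr_scores, peak_scores])


def score(scorer: PeakScorer, bundle: FeatureBundle) -> tuple[float, float, float]:
    """Score one region: (shape_score, enrichment_score, peak_score)."""
    row = score_bundles(scorer, [bundle])[0]
    return float(row[0]), float(row[1]), float(row[2])


def score_candidate(
    scorer: PeakScorer,
    candidate: CandidatePeak,
    bundle: FeatureBundle,
    pvalue: float | None = None,
) -> ScoredPeak:
    s, e, p = score(scorer, bundle)
    return ScoredPeak(
        region=candidate.region,
        shape_score=s,
        enrichment_score=e,
        peak_score=p,
        height=candidate.height,
        n_definitions=candidate.n_definitions,
        saturated=candidate.saturated,
        pvalue=pvalue,
    )


def save_models(scorer: PeakScorer, path: str | Path) -> None:
    """Write a model bundle directory: plain-text descriptor + JSON weights.

    Floats are serialized with ``repr`` precision so loading reproduces
    bit-identical scores.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    descriptor = {
        "format_version": FORMAT_VERSION,
        "feature_order": FEATURE_ORDER,
        "epsilon": EPSILON,
        "signal_window_bp": SIGNAL_WINDOW_BP,
        "n_enrichment_features": N_ENRICHMENT_FEATURES,
        "signal_normalization": "divide-by-max",
        "feature_transform": "log",
        "shape_arch": [list(t) for t in scorer.shape_model.arch],
        "combiner_arch": [list(t) for t in scorer.combiner_model.arch],
        "seed": scorer.seed,
    }
    weights = {
        "shape": [w.tolist() for w in scorer.shape_model.net.get_weights()],
        "enrichment_coef": scorer.enrichment_model.coef.tolist(),
        "enrichment_intercept": scorer.enrichment_model.intercept,
        "combiner": [w.tolist() for w in scorer.combiner_model.net.get_weights()],
    }
    (path / "descriptor.json").write_text(json.dumps(descriptor, indent=1))
    (path / "weights.json").write_text(json.dumps(weights))


def load_models(path: str | Path) -> PeakScorer:
    """Load a bundle written by :func:`save_models`.

    Raises :class:`ModelLoadError` on a missing, corrupted or incompatible
    bundle (wrong format version, feature order, or weight shapes).
    """
    path = Path(path)
    try:
        descriptor = json.loads((path / "descriptor.json").read_text())
        weights = json.loads((path / "weights.json").read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelLoadError(f"cannot read model bundle at {path}: {exc}") from exc
    if descriptor.get("format_version") != FORMAT_VERSION:
        raise ModelLoadError(f"unsupported format version {descriptor.get('format_version')}")
    if descriptor.get("feature_order") != FEATURE_ORDER:
        raise ModelLoadError(f"incompatible feature order {descriptor.get('feature_order')!r}")
    if descriptor.get("n_enrichment_features") != N_ENRICHMENT_FEATURES:
        raise ModelLoadError("incompatible enrichment feature count")
    shape_arch = [tuple(t) for t in descriptor["shape_arch"]]
    combiner_arch = [tuple(t) for t in descriptor["combiner_arch"]]
    rng = np.random.default_rng(0)  # weights are overwritten below
    try:
        shape_net = _build_net(shape_arch, rng)
        shape_net.set_weights([np.asarray(w, dtype=np.float64) for w in weights["shape"]])
        comb_net = _build_net(combiner_arch, rng)
        comb_net.set_weights([np.asarray(w, dtype=np.float64) for w in weights["combiner"]])
        enrichment = EnrichmentModel(
            coef=np.asarray(weights["enrichment_coef"], dtype=np.float64),
            intercept=float(weights["enrichment_intercept"]),
        )
    except (KeyError, ValueError) as exc:
        raise ModelLoadError(f"corrupted model bundle at {path}: {exc}") from exc
    if enrichment.coef.size != N_ENRICHMENT_FEATURES:
        raise ModelLoadError("enrichment coefficient length mismatch")
    return PeakScorer(
        ShapeModel(shape_net, list(shape_arch)),
        enrichment,
        CombinerModel(comb_net, list(combiner_arch)),
        seed=int(descriptor.get("seed", 0)),
    )
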