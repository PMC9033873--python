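"""Frozen feature extraction plus a small trainable regression head.

The pipeline mirrors transfer-learning regression: a frozen, deterministic
feature extractor maps each well image to a fixed-length vector, and only a
one-hidden-layer head (10 ReLU units, linear output) is trained to predict
the continuous viability label by mean squared error.

The default extractor is a built-in tile-statistics transform (per-tile mean
intensity, intensity SD, and mean gradient magnitude over a 16 x 16 grid,
plus a 32-bin global luminance histogram; D = 3*16^2 + 32 = 800).  It needs
no downloaded weights and carries genuine cell-density and texture signal.
ImageNet-pretrained CNN backbones plug in behind the same contract when a
deep-learning runtime with local weights is installed.

Splitting is series-aware: a series (one full dose ladder of one replicate
in one experiment set) is never divided across train and test, so the test
set always contains whole 11-concentration curves for IC50 fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .augment import AugmentationPolicy, center_crop
from .simulate import PlateImage, WellRecord, load_image

__all__ = [
    "FeatureExtractor",
    "RegressionHead",
    "RegressionModel",
    "DatasetSplit",
    "TrainConfig",
    "builtin_extractor",
    "builtin_extract",
    "pretrained_extract",
    "split_dataset",
    "kfold_series_split",
    "train_head",
    "predict_viability",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# feature extraction


@dataclass(frozen=True)
class FeatureExtractor:
    """A frozen, deterministic image -> D-vector transform."""

    name: str
    dimension: int
    transform: Callable[[PlateImage], np.ndarray]

    def __call__(self, image: PlateImage) -> np.ndarray:
        vec = self.transform(image)
        if vec.shape != (self.dimension,):
            raise ValueError(
                f"extractor {self.name!r} produced {vec.shape}, "
                f"expected ({self.dimension},)"
            )
        return vec


def builtin_extract(image: PlateImage, tiles_per_side: int = 16) -> np.ndarray:
    """Tile-statistics features: mean, SD, gradient per tile + histogram.

    The image is reduced to luminance, divided into a tiles_per_side^2 grid
    (trailing rows/columns beyond a multiple of the grid are dropped), and
    per-tile mean intensity, intensity SD, and mean gradient magnitude are
    concatenated with a 32-bin global luminance histogram normalized to sum
    one.  D = 3 * tiles_per_side^2 + 32.
    """
    px = image.pixels
    h, w = px.shape[:2]
    t = tiles_per_side
    if h < t or w < t:
        raise ValueError(f"image {h}x{w} smaller than {t}x{t} tile grid")
    gray = px @ np.array([0.299, 0.587, 0.114])

    gy, gx = np.gradient(gray)
    grad = np.hypot(gy, gx)

    th, tw = h // t, w // t
    g = gray[: th * t, : tw * t].reshape(t, th, t, tw)
    gr = grad[: th * t, : tw * t].reshape(t, th, t, tw)
    tile_mean = g.mean(axis=(1, 3))
    tile_sd = g.std(axis=(1, 3))
    tile_grad = gr.mean(axis=(1, 3))

    hist, _ = np.histogram(gray, bins=32, range=(0.0, 1.0))
    hist = hist / hist.sum()

    return np.concatenate(
        [tile_mean.ravel(), tile_sd.ravel(), tile_grad.ravel(), hist]
    )


def builtin_extractor(tiles_per_side: int = 16) -> FeatureExtractor:
    return FeatureExtractor(
        name=f"tilestats{tiles_per_side}",
        dimension=3 * tiles_per_side**2 + 32,
        transform=lambda img: builtin_extract(img, tiles_per_side),
    )


def pretrained_extract(image: PlateImage, backbone_name: str) -> np.ndarray:
    """Pooled penultimate features of an ImageNet-pretrained backbone.

    Optional plug-in: requires a deep-learning runtime with locally cached
    weights.  Raises ``RuntimeError`` when the plug-in is not installed —
    never a silent fallback to another extractor.
    """
    extractor = get_pretrained_extractor(backbone_name)
    return extractor(image)


def get_pretrained_extractor(backbone_name: str) -> FeatureExtractor:
    try:
        import torch  # noqa: F401
        import torchvision  # noqa: F401
    except ImportError as exc:
        raise RuntimeError(
            f"pretrained backbone {backbone_name!r} plug-in not installed: "
            "a deep-learning runtime with local weights is required"
        ) from exc
    raise RuntimeError(
        f"no pretrained backbone registered under {backbone_name!r}"
    )


def get_extractor(name: str) -> FeatureExtractor:
    """Resolve an extractor by name; built-in ``tilestatsN`` or a plug-in."""
    if name.startswith("tilestats"):
        t = int(name[len("tilestats"):] or 16)
        return builtin_extractor(t)
    return get_pretrained_extractor(name)


# ---------------------------------------------------------------------------
# series-aware splitting


def series_key(record: WellRecord) -> tuple[int, int]:
    return (record.set_index, record.replicate_index)


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train / validation / test well-id sets (whole series only)."""

    train_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        tr, va, te = map(set, (self.train_ids, self.validation_ids, self.test_ids))
        if tr & va or tr & te or va & te:
            raise ValueError("split sets must be pairwise disjoint")


def _series_map(records: Sequence[WellRecord]) -> dict[tuple[int, int], list[WellRecord]]:
    series: dict[tuple[int, int], list[WellRecord]] = {}
    for r in records:
        series.setdefault(series_key(r), []).append(r)
    return series


def split_dataset(
    records: Sequence[WellRecord],
    test_series: int = 6,
    validation_fraction: float = 0.2,
    seed: int = 0,
) -> DatasetSplit:
    """Hold out whole series for test; split the rest by series.

    On the standard 264-well plate (24 series of 11 doses) with
    ``test_series=6`` this yields 66 test wells and 198 train+validation
    wells, and every test series is a complete dose ladder.
    """
    series = _series_map(records)
    keys = sorted(series)
    if test_series > len(keys):
        raise ValueError(
            f"test_series={test_series} exceeds the {len(keys)} available series"
        )
    rng = np.random.Generator(np.random.PCG64(seed))
    order = [keys[i] for i in rng.permutation(len(keys))]
    test_keys = set(order[:test_series])
    rest = order[test_series:]
    n_val = int(round(validation_fraction * len(rest)))
    val_keys = set(rest[:n_val])

    train, val, test = [], [], []
    for k in keys:
        ids = [r.well_id for r in series[k]]
        if k in test_keys:
            test.extend(ids)
        elif k in val_keys:
            val.extend(ids)
        else:
            train.extend(ids)
    return DatasetSplit(tuple(train), tuple(val), tuple(test))


def kfold_series_split(
    records: Sequence[WellRecord], k: int = 4, seed: int = 0,
    validation_fraction: float = 0.2,
) -> list[DatasetSplit]:
    """k folds partitioning the series; each well tests in exactly one fold.

    With 24 series and k=4 each fold holds out 6 series (66 wells) and
    trains on the remaining 18 (198 wells).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    series = _series_map(records)
    keys = sorted(series)
    rng = np.random.Generator(np.random.PCG64(seed))
    order = [keys[i] for i in rng.permutation(len(keys))]
    fold_keys = [order[i::k] for i in range(k)]

    splits = []
    for i in range(k):
        test_keys = set(fold_keys[i])
        rest = [kk for kk in order if kk not in test_keys]
        n_val = int(round(validation_fraction * len(rest)))
        val_keys = set(rest[:n_val])
        train, val, test = [], [], []
        for kk in keys:
            ids = [r.well_id for r in series[kk]]
            if kk in test_keys:
                test.extend(ids)
            elif kk in val_keys:
                val.extend(ids)
            else:
                train.extend(ids)
        splits.append(DatasetSplit(tuple(train), tuple(val), tuple(test)))
    return splits


# ---------------------------------------------------------------------------
# regression head


@dataclass
class RegressionHead:
    """One hidden layer (default 10 ReLU units) and a linear output unit."""

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: float

    @property
    def input_dimension(self) -> int:
        return self.w1.shape[0]

    @property
    def hidden_width(self) -> int:
        return self.w1.shape[1]

    def forward(self, features: np.ndarray) -> np.ndarray:
        hidden = np.maximum(features @ self.w1 + self.b1, 0.0)
        return hidden @ self.w2 + self.b2


@dataclass
class RegressionModel:
    """Frozen extractor identity + trained head + training metadata."""

    extractor_name: str
    extractor_dimension: int
    head: RegressionHead
    seed: int
    epochs_trained: int
    loss_history: list[tuple[float, float]] = field(default_factory=list)
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None
    crop_fraction: float = 0.7

    def __post_init__(self) -> None:
        if self.head.input_dimension != self.extractor_dimension:
            raise ValueError(
                f"head input dimension {self.head.input_dimension} != "
                f"extractor dimension {self.extractor_dimension}"
            )


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters for the regression head."""

    hidden_width: int = 10
    learning_rate: float = 3e-3
    batch_size: int = 16
    max_epochs: int = 800
    patience: int = 60
    views_per_image: int = 16


def _adam_train(
    x_train: np.ndarray, y_train: np.ndarray,
    x_val: np.ndarray, y_val: np.ndarray,
    cfg: TrainConfig, rng: np.random.Generator,
) -> tuple[RegressionHead, int, list[tuple[float, float]]]:
    d = x_train.shape[1]
    hw = cfg.hidden_width
    w1 = rng.standard_normal((d, hw)) * math.sqrt(2.0 / d)
    b1 = np.zeros(hw)
    w2 = rng.standard_normal(hw) * math.sqrt(1.0 / hw)
    b2 = 0.0

    params = [w1, b1, w2, np.array(b2)]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0

    def val_loss() -> float:
        hidden = np.maximum(x_val @ params[0] + params[1], 0.0)
        pred = hidden @ params[2] + params[3]
        return float(np.mean((pred - y_val) ** 2))

    best_loss = math.inf
    best_params = [p.copy() for p in params]
    best_epoch = 0
    history: list[tuple[float, float]] = []
    n = len(x_train)

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        train_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            z1 = xb @ params[0] + params[1]
            a1 = np.maximum(z1, 0.0)
            pred = a1 @ params[2] + params[3]
            err = pred - yb
            loss = float(np.mean(err**2))
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(lr={cfg.learning_rate}, batch={cfg.batch_size})"
                )
            train_losses.append(loss)
            bsz = len(idx)
            g_pred = 2.0 * err / bsz
            g_w2 = a1.T @ g_pred
            g_b2 = np.array(g_pred.sum())
            g_a1 = np.outer(g_pred, params[2]) * (z1 > 0)
            g_w1 = xb.T @ g_a1
            g_b1 = g_a1.sum(axis=0)
            grads = [g_w1, g_b1, g_w2, g_b2]
            t += 1
            for i, g in enumerate(grads):
                m[i] = beta1 * m[i] + (1 - beta1) * g
                v[i] = beta2 * v[i] + (1 - beta2) * g * g
                mh = m[i] / (1 - beta1**t)
                vh = v[i] / (1 - beta2**t)
                params[i] = params[i] - cfg.learning_rate * mh / (np.sqrt(vh) + eps)

        vl = val_loss()
        history.append((float(np.mean(train_losses)), vl))
        if vl < best_loss - 1e-12:
            best_loss = vl
            best_params = [p.copy() for p in params]
            best_epoch = epoch
        elif epoch - best_epoch >= cfg.patience:
            break

    head = RegressionHead(
        w1=best_params[0], b1=best_params[1],
        w2=best_params[2], b2=float(best_params[3]),
    )
    return head, len(history), history


def fit_head_on_features(
    x_train: np.ndarray, y_train: np.ndarray,
    x_val: np.ndarray, y_val: np.ndarray,
    config: TrainConfig | None = None, seed: int = 0,
) -> tuple[RegressionHead, list[tuple[float, float]]]:
    """Train the head directly on precomputed feature matrices.

    Lower-level entry point behind :func:`train_head`; useful when features
    come from somewhere other than images.
    """
    config = config or TrainConfig()
    rng = np.random.Generator(np.random.PCG64(seed))
    head, _, history = _adam_train(
        np.asarray(x_train, float), np.asarray(y_train, float),
        np.asarray(x_val, float), np.asarray(y_val, float), config, rng,
    )
    return head, history


def _record_index(records: Sequence[WellRecord]) -> dict[str, WellRecord]:
    return {r.well_id: r for r in records}


def extract_features(
    records: Sequence[WellRecord],
    extractor: FeatureExtractor,
    policy: AugmentationPolicy | None,
    views: int,
    rng: np.random.Generator | None,
    images: dict[str, PlateImage] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Feature matrix for records: augmented views or a single center crop.

    With a policy, ``views`` stochastic augmented views per image are
    extracted (training).  Without, one deterministic center-cropped view
    per image (evaluation).  Returns (X, y, well_ids-per-row).
    """
    from .augment import augment_image

    xs, ys, ids = [], [], []
    for r in records:
        img = images[r.well_id] if images is not None else load_image(r.image_path)
        if policy is None:
            crop = center_crop(img, 0.7)
            xs.append(extractor(crop))
            ys.append(r.measured_viability)
            ids.append(r.well_id)
        else:
            for _ in range(views):
                view = augment_image(img, policy, rng)
                xs.append(extractor(view))
                ys.append(r.measured_viability)
                ids.append(r.well_id)
    return np.asarray(xs), np.asarray(ys), ids


def train_head(
    records: Sequence[WellRecord],
    split: DatasetSplit,
    extractor: FeatureExtractor,
    policy: AugmentationPolicy,
    config: TrainConfig | None = None,
    seed: int = 0,
    images: dict[str, PlateImage] | None = None,
) -> RegressionModel:
    """Train the regression head on frozen features of augmented views.

    Training wells contribute ``views_per_image`` stochastic augmented
    views each (features extracted once, up front); validation wells
    contribute one center-cropped view and drive early stopping on
    validation MSE.  Features are standardized by training statistics
    stored on the model.  Identical seeds give identical final weights.
    """
    config = config or TrainConfig()
    index = _record_index(records)
    train_recs = [index[i] for i in split.train_ids]
    val_recs = [index[i] for i in split.validation_ids]
    if not train_recs:
        raise ValueError("empty training set")
    if not val_recs:
        raise ValueError("empty validation set (early stopping needs one)")

    rng = np.random.Generator(np.random.PCG64(seed))
    x_train, y_train, _ = extract_features(
        train_recs, extractor, policy, config.views_per_image, rng, images
    )
    x_val, y_val, _ = extract_features(val_recs, extractor, None, 1, None, images)

    mean = x_train.mean(axis=0)
    scale = x_train.std(axis=0)
    scale[scale < 1e-12] = 1.0
    xt = (x_train - mean) / scale
    xv = (x_val - mean) / scale

    head, epochs, history = _adam_train(xt, y_train, xv, y_val, config, rng)
    return RegressionModel(
        extractor_name=extractor.name,
        extractor_dimension=extractor.dimension,
        head=head,
        seed=seed,
        epochs_trained=epochs,
        loss_history=history,
        feature_mean=mean,
        feature_scale=scale,
        crop_fraction=policy.crop_fraction,
    )


def predict_viability(
    model: RegressionModel,
    records: Sequence[WellRecord],
    extractor: FeatureExtractor | None = None,
    images: dict[str, PlateImage] | None = None,
) -> "pd.DataFrame":
    """Predict per-well viability from center-cropped views.

    Returns a DataFrame with ``predicted_viability`` clipped to the [0, 2]
    label scale (for IC50 fitting) and ``predicted_raw`` unclipped.  A
    missing image file yields a per-well ``error`` entry; the run continues.
    """
    import pandas as pd

    extractor = extractor or get_extractor(model.extractor_name)
    if extractor.dimension != model.extractor_dimension:
        raise ValueError(
            f"extractor dimension {extractor.dimension} does not match "
            f"model dimension {model.extractor_dimension}"
        )
    rows = []
    for r in records:
        try:
            img = images[r.well_id] if images is not None else load_image(r.image_path)
            crop = center_crop(img, model.crop_fraction)
            feat = extractor(crop)
            if model.feature_mean is not None:
                feat = (feat - model.feature_mean) / model.feature_scale
            raw = float(model.head.forward(feat[None, :])[0])
            rows.append(
                {
                    "well_id": r.well_id,
                    "cell_line": r.cell_line,
                    "concentration_um": r.concentration_um,
                    "replicate": r.replicate_index,
                    "set": r.set_index,
                    "measured_viability": r.measured_viability,
                    "predicted_viability": float(np.clip(raw, 0.0, 2.0)),
                    "predicted_raw": raw,
                    "error": "",
                }
            )
        except FileNotFoundError as exc:
            rows.append(
                {
                    "well_id": r.well_id,
                    "cell_line": r.cell_line,
                    "concentration_um": r.concentration_um,
                    "replicate": r.replicate_index,
                    "set": r.set_index,
                    "measured_viability": r.measured_viability,
                    "predicted_viability": math.nan,
                    "predicted_raw": math.nan,
                    "error": str(exc),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# persistence


def save_model(model: RegressionModel, path: str | Path) -> None:
    """Persist head weights + extractor identity + seed as a single NPZ."""
    np.savez(
        path,
        w1=model.head.w1, b1=model.head.b1,
        w2=model.head.w2, b2=np.array(model.head.b2),
        extractor_name=np.array(model.extractor_name),
        extractor_dimension=np.array(model.extractor_dimension),
        seed=np.array(model.seed),
        epochs_trained=np.array(model.epochs_trained),
        feature_mean=model.feature_mean if model.feature_mean is not None else np.empty(0),
        feature_scale=model.feature_scale if model.feature_scale is not None else np.empty(0),
        crop_fraction=np.array(model.crop_fraction),
        loss_history=np.array(model.loss_history) if model.loss_history else np.empty((0, 2)),
    )


def load_model(path: str | Path) -> RegressionModel:
    """Load a persisted model; refuses a head/extractor dimension mismatch."""
    with np.load(path, allow_pickle=False) as z:
        head = RegressionHead(
            w1=z["w1"], b1=z["b1"], w2=z["w2"], b2=float(z["b2"]),
        )
        fm = z["feature_mean"]
        fs = z["feature_scale"]
        return RegressionModel(
            extractor_name=str(z["extractor_name"]),
            extractor_dimension=int(z["extractor_dimension"]),
            head=head,
            seed=int(z["seed"]),
            epochs_trained=int(z["epochs_trained"]),
            loss_history=[tuple(row) for row in z["loss_history"]],
            feature_mean=fm if fm.size else None,
            feature_scale=fs if fs.size else None,
            crop_fraction=float(z["crop_fraction"]),
        )
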