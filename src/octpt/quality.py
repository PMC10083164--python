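"""Referenceless image-quality assessment and checkpoint selection.

Three estimator families are provided:

* **ENL** (equivalent number of looks), ``mean^2 / variance`` over a
  homogeneous background region — for fully developed multi-look speckle this
  recovers the number of averaged looks.
* **CNR** (contrast-to-noise ratio), ``(mean_ROI - mean_BG) / sd_BG``.
* A natural-scene-statistics score in the BRISQUE family: 36 features (18 per
  scale at two scales) built from mean-subtracted contrast-normalised (MSCN)
  coefficients — a generalised Gaussian fit of the coefficients plus
  asymmetric generalised Gaussian fits of four orientation pairwise products —
  mapped to a scalar by a pluggable regressor.  Lower score = higher
  perceptual quality.  No pretrained regressor is shipped; the default is a
  synthetic scorer trained at run time on speckle phantoms with graded look
  counts (see :class:`SyntheticSpeckleScorer`).

Checkpoint selection scores the images generated by every saved checkpoint
and picks the epoch with the lowest mean score for the model generating the
clean preset, and the highest for the model generating the noisy preset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import gamma as _gamma
from scipy.stats import skew as _skew

from .phantom import (BScanImage, PresetProfile, sample_phantom_spec,
                      make_reflectivity_map, simulate_bscan)

__all__ = [
    "UndefinedMetricError", "ConfigurationError", "ROIAnnotation",
    "QualityReport", "enl", "cnr", "brisque_features", "brisque_score",
    "SyntheticSpeckleScorer", "train_synthetic_scorer", "evaluate_checkpoints",
    "select_checkpoint", "summarize_scores", "plot_score_histograms",
]


class UndefinedMetricError(ValueError):
    """Metric undefined on this input (e.g. constant region)."""


class ConfigurationError(RuntimeError):
    """Missing scorer model or invalid configuration."""


# --------------------------------------------------------------------------
# region metrics
# --------------------------------------------------------------------------

Rect = tuple[int, int, int, int]  # (row, col, height, width)


@dataclass(frozen=True)
class ROIAnnotation:
    """Homogeneous tissue ROI and tissue-free background rectangles."""

    roi_rect: Rect
    bg_rect: Rect
    image_id: str = ""

    def validate(self, shape: tuple[int, int]) -> None:
        for name, (r, c, h, w) in (("roi", self.roi_rect), ("bg", self.bg_rect)):
            if h < 1 or w < 1 or r < 0 or c < 0 or r + h > shape[0] or c + w > shape[1]:
                raise ValueError(f"{name} rectangle {(r, c, h, w)} outside "
                                 f"image of shape {shape}")
        r1, c1, h1, w1 = self.roi_rect
        r2, c2, h2, w2 = self.bg_rect
        if r1 < r2 + h2 and r2 < r1 + h1 and c1 < c2 + w2 and c2 < c1 + w1:
            raise ValueError("ROI and background rectangles overlap")


def _pixels(image) -> np.ndarray:
    return image.pixels if isinstance(image, BScanImage) else np.asarray(image, float)


def _crop(arr: np.ndarray, rect: Rect) -> np.ndarray:
    r, c, h, w = rect
    if r < 0 or c < 0 or r + h > arr.shape[0] or c + w > arr.shape[1]:
        raise ValueError(f"rectangle {rect} outside image of shape {arr.shape}")
    return arr[r:r + h, c:c + w]


def enl(image, bg: Rect) -> float:
    """Equivalent number of looks of a background region: mean^2 / variance
    (variance with denominator n-1)."""
    region = _crop(_pixels(image), bg)
    if region.size < 2:
        raise ValueError("background region needs at least 2 pixels")
    var = region.var(ddof=1)
    if var == 0.0:
        raise UndefinedMetricError("ENL undefined: background region is constant")
    return float(region.mean() ** 2 / var)


def cnr(image, roi: Rect, bg: Rect) -> float:
    """Contrast-to-noise ratio: (mean_ROI - mean_BG) / sd_BG."""
    arr = _pixels(image)
    roi_px = _crop(arr, roi)
    bg_px = _crop(arr, bg)
    if bg_px.size < 2:
        raise ValueError("background region needs at least 2 pixels")
    sd = bg_px.std(ddof=1)
    if sd == 0.0:
        raise UndefinedMetricError("CNR undefined: background region is constant")
    return float((roi_px.mean() - bg_px.mean()) / sd)


# --------------------------------------------------------------------------
# natural-scene-statistics features
# --------------------------------------------------------------------------

_GGD_GRID = None


def _ggd_grid():
    global _GGD_GRID
    if _GGD_GRID is None:
        alphas = np.arange(0.2, 10.001, 0.001)
        ratios = _gamma(2.0 / alphas) ** 2 / (_gamma(1.0 / alphas) *
                                              _gamma(3.0 / alphas))
        _GGD_GRID = (alphas, ratios)
    return _GGD_GRID


def _fit_ggd(x: np.ndarray) -> tuple[float, float]:
    """Moment-matched generalised Gaussian: returns (alpha, sigma^2)."""
    alphas, ratios = _ggd_grid()
    sigma_sq = float(np.mean(x ** 2))
    e_abs = float(np.mean(np.abs(x)))
    rho = e_abs ** 2 / sigma_sq
    alpha = alphas[np.argmin((ratios - rho) ** 2)]
    return float(alpha), sigma_sq


def _fit_aggd(x: np.ndarray) -> tuple[float, float, float, float]:
    """Moment-matched asymmetric generalised Gaussian fit of a pairwise
    product: returns (alpha, mean eta, beta_left^2, beta_right^2)."""
    alphas, ratios = _ggd_grid()
    left = x[x < 0]
    right = x[x > 0]
    if left.size == 0 or right.size == 0:
        raise UndefinedMetricError("degenerate pairwise-product distribution")
    bl = np.sqrt(np.mean(left ** 2))
    br = np.sqrt(np.mean(right ** 2))
    gamma_hat = bl / br
    r_hat = np.mean(np.abs(x)) ** 2 / np.mean(x ** 2)
    R_hat = r_hat * (gamma_hat ** 3 + 1) * (gamma_hat + 1) / (gamma_hat ** 2 + 1) ** 2
    alpha = alphas[np.argmin((ratios - R_hat) ** 2)]
    conv = np.sqrt(_gamma(1.0 / alpha) / _gamma(3.0 / alpha))
    beta_l = bl * conv
    beta_r = br * conv
    eta = (beta_r - beta_l) * _gamma(2.0 / alpha) / _gamma(1.0 / alpha)
    return float(alpha), float(eta), float(beta_l ** 2), float(beta_r ** 2)


def _mscn(img: np.ndarray, c: float = 1.0 / 255.0) -> np.ndarray:
    mu = gaussian_filter(img, 7.0 / 6.0, truncate=2.571, mode="nearest")
    sigma = np.sqrt(np.abs(gaussian_filter(img * img, 7.0 / 6.0,
                                           truncate=2.571, mode="nearest")
                           - mu * mu))
    return (img - mu) / (sigma + c)


def _scale_features(img: np.ndarray) -> list[float]:
    m = _mscn(img)
    feats = list(_fit_ggd(m.ravel()))
    shifts = [(0, 1), (1, 0), (1, 1), (1, -1)]  # H, V, D1, D2
    for dr, dc in shifts:
        prod = m[:m.shape[0] - dr, max(0, -dc):m.shape[1] - max(0, dc)] * \
            m[dr:, max(0, dc):m.shape[1] - max(0, -dc)]
        feats.extend(_fit_aggd(prod.ravel()))
    return feats


def brisque_features(image) -> np.ndarray:
    """36-element natural-scene-statistics feature vector (18 per scale,
    computed at full and half resolution)."""
    img = _pixels(image)
    if img.shape[0] < 32 or img.shape[1] < 32:
        raise ValueError("image must be at least 32x32")
    if img.std() == 0.0:
        raise UndefinedMetricError("constant image: contrast normalisation "
                                   "is degenerate")
    feats = _scale_features(img)
    h2, w2 = img.shape[0] // 2, img.shape[1] // 2
    half = img[:2 * h2, :2 * w2].reshape(h2, 2, w2, 2).mean(axis=(1, 3))
    feats.extend(_scale_features(half))
    return np.asarray(feats, dtype=np.float64)


def brisque_score(image, scorer) -> float:
    """Map the 36 NSS features to a scalar via a pluggable regressor
    (lower = higher perceptual quality).  Deterministic given the scorer."""
    if scorer is None:
        raise ConfigurationError("no scorer model provided; train or supply one")
    return float(scorer(brisque_features(image)))


class SyntheticSpeckleScorer:
    """Synthetic stand-in for a pretrained perceptual-quality regressor.

    A linear ridge regression is fitted, at run time, on NSS features of
    speckle phantoms simulated with graded look counts; the regression target
    is ``100 / sqrt(looks)`` so that heavier averaging (higher perceptual
    quality) maps to a lower score, matching the lower-is-better convention.
    A linear model is used deliberately: checkpoint-generated images can sit
    outside the training feature distribution, where a kernel regressor
    collapses to a constant while a linear one stays monotone in the
    speckle-sensitive features.  It captures speckle-driven quality only —
    not blur, compression or other distortions a scorer trained on natural
    images would rank.
    """

    def __init__(self, model, feature_scaler):
        self._model = model
        self._scaler = feature_scaler
        self.is_synthetic = True

    def __call__(self, features: np.ndarray) -> float:
        feats = np.asarray(features, float).reshape(1, -1)
        return float(self._model.predict(self._scaler.transform(feats))[0])


def train_synthetic_scorer(seed: int = 0, n_per_level: int = 10,
                           looks_levels: tuple[int, ...] = (1, 2, 4, 9, 16, 25, 49),
                           size: int = 64) -> SyntheticSpeckleScorer:
    """Fit the synthetic speckle-quality scorer (deterministic given seed)."""
    from sklearn.linear_model import Ridge
    from sklearn.preprocessing import StandardScaler

    rng = np.random.default_rng(seed)
    X, y = [], []
    for looks in looks_levels:
        preset = PresetProfile(f"train_{looks}", looks=looks, slices=1,
                               field_deg=(1.0, 1.0))
        for _ in range(n_per_level):
            spec = sample_phantom_spec(rng, size, size)
            refl = make_reflectivity_map(spec)
            img = simulate_bscan(refl, preset,
                                 int(rng.integers(0, 2 ** 31 - 1)),
                                 log_compress=True)
            X.append(brisque_features(img))
            y.append(100.0 / np.sqrt(looks))
    scaler = StandardScaler().fit(np.asarray(X))
    model = Ridge(alpha=1.0).fit(scaler.transform(np.asarray(X)),
                                 np.asarray(y))
    return SyntheticSpeckleScorer(model, scaler)


# --------------------------------------------------------------------------
# distribution summaries and checkpoint selection
# --------------------------------------------------------------------------

def summarize_scores(scores) -> tuple[float, float, float]:
    """Sample mean, sample sd (n-1) and adjusted Fisher-Pearson skewness
    (0 by convention for constant samples)."""
    arr = np.asarray(scores, dtype=np.float64)
    if arr.size < 2:
        raise ValueError("need at least 2 scores to summarise")
    sd = arr.std(ddof=1)
    skewness = 0.0 if sd == 0.0 else float(_skew(arr, bias=False))
    return float(arr.mean()), float(sd), skewness


@dataclass
class QualityReport:
    """Per-image scores plus recomputable per-set summaries."""

    per_image: dict[str, dict[str, float]] = field(default_factory=dict)

    def add(self, image_id: str, metric: str, value: float) -> None:
        self.per_image.setdefault(image_id, {})[metric] = value

    def scores_for(self, metric: str) -> list[float]:
        return [m[metric] for m in self.per_image.values() if metric in m]

    def summary(self) -> pd.DataFrame:
        rows = []
        metrics = sorted({k for m in self.per_image.values() for k in m})
        for metric in metrics:
            vals = self.scores_for(metric)
            mean, sd, skw = summarize_scores(vals)
            rows.append({"metric": metric, "mean": mean, "sd": sd,
                         "skewness": skw, "count": len(vals)})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        rows = [{"image_id": iid, "metric": m, "value": v}
                for iid, metrics in self.per_image.items()
                for m, v in metrics.items()]
        pd.DataFrame(rows).to_csv(path, index=False)


def evaluate_checkpoints(checkpoints, images, score_fn, convert) -> pd.DataFrame:
    """Score every image as converted by every checkpoint.

    ``convert(checkpoint, image) -> BScanImage`` abstracts the generator;
    ``score_fn(image) -> float`` is the quality metric.  Returns one row per
    checkpoint epoch with the mean and sd of the scores.
    """
    checkpoints = list(checkpoints)
    images = list(images)
    if not checkpoints or not images:
        raise ValueError("need at least one checkpoint and one image")
    rows = []
    for ckpt in checkpoints:
        scores = [score_fn(convert(ckpt, img)) for img in images]
        arr = np.asarray(scores, float)
        rows.append({"epoch": int(ckpt.epoch), "mean": float(arr.mean()),
                     "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                     "n": int(arr.size)})
    return pd.DataFrame(rows)


def select_checkpoint(score_table: pd.DataFrame, mode: str) -> int:
    """Epoch with the minimal (``lowest``) or maximal (``highest``) mean
    score; ties broken by the earliest epoch.  ``lowest`` is used for the
    model generating the clean Seven-Lines style, ``highest`` for the model
    generating the noisy Macular-Cube style."""
    if mode not in ("lowest", "highest"):
        raise ValueError(f"mode must be lowest|highest, got {mode!r}")
    table = pd.DataFrame(score_table)
    if table.empty:
        raise ValueError("score table is empty")
    table = table.sort_values("epoch", kind="stable").reset_index(drop=True)
    means = table["mean"].to_numpy()
    idx = int(np.argmin(means) if mode == "lowest" else np.argmax(means))
    return int(table.loc[idx, "epoch"])


def plot_score_histograms(score_sets: dict[str, list[float]], path) -> None:
    """Histogram panel per score set with its mean marked (dashed line)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(score_sets)
    ncols = 2
    nrows = (n + 1) // 2
    fig, axes = plt.subplots(nrows, ncols, figsize=(5 * ncols, 3 * nrows),
                             squeeze=False)
    for ax, (name, scores) in zip(axes.ravel(), score_sets.items()):
        ax.hist(scores, bins=20, color="steelblue", alpha=0.8)
        ax.axvline(np.mean(scores), linestyle="--", color="black")
        ax.set_title(name)
        ax.set_xlabel("score")
    for ax in axes.ravel()[n:]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
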