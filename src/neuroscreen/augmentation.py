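"""Class-conditional kernel-density data augmentation.

A pilot cohort of a few dozen subjects is far too small to train
classifiers on directly. The expansion strategy is to fit a Gaussian
kernel density estimate to each class's feature vectors and draw
synthetic subjects from it — by default 200 per class on top of the
originals, so a 23-subject cohort becomes a 423-row training set.

The KDE uses a diagonal product-Gaussian kernel: each synthetic draw is a
uniformly chosen training point plus independent Gaussian noise with
per-dimension bandwidth. Features are standardized before the fit and the
draws are mapped back to the original scale. Bandwidth follows Scott's
rule by default (``n**(-1/(d+4))`` on standardized data).

:class:`KDEAugmenter` is the scikit-learn-style estimator;
:func:`fit_kde` / :func:`sample_kde` / :func:`augment_dataset` are the
functional surface over it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .cohort import LABELS, NEGATIVE_LABEL, POSITIVE_LABEL, CohortDataset


@dataclass
class KdeModel:
    """Gaussian product-kernel density over one class's feature space.

    ``points`` are the training vectors (n, d); ``bandwidth`` the
    per-dimension kernel scale in the same units as ``points``.
    """

    points: np.ndarray
    bandwidth: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.bandwidth = np.broadcast_to(
            np.asarray(self.bandwidth, dtype=float), (self.points.shape[1],)
        ).copy()
        if self.points.shape[0] < 2:
            raise ValueError("KDE requires at least 2 training points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("KDE training points must be finite")
        if np.any(self.bandwidth <= 0):
            raise ValueError("KDE bandwidth must be positive in every dimension")

    @property
    def n_dim(self) -> int:
        return self.points.shape[1]

    def pdf(self, x) -> np.ndarray:
        """Mixture density: mean of product Gaussians centred on the points."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        z = (x[:, None, :] - self.points[None, :, :]) / self.bandwidth
        log_norm = -0.5 * self.n_dim * np.log(2 * np.pi) - np.sum(np.log(self.bandwidth))
        kernel = np.exp(-0.5 * np.sum(z * z, axis=2) + log_norm)
        return kernel.mean(axis=1)

    def mean(self) -> np.ndarray:
        """Mixture mean (= training-point mean; the kernel is centred)."""
        return self.points.mean(axis=0)

    def var(self) -> np.ndarray:
        """Per-dimension mixture variance: point variance + bandwidth²."""
        return self.points.var(axis=0) + self.bandwidth**2


def _bandwidth_factor(rule, n: int, d: int) -> float:
    if isinstance(rule, (int, float)) and not isinstance(rule, bool):
        if rule <= 0:
            raise ValueError("fixed bandwidth must be positive")
        return float(rule)
    if rule == "scott":
        return n ** (-1.0 / (d + 4))
    if rule == "silverman":
        return (n * (d + 2) / 4.0) ** (-1.0 / (d + 4))
    raise ValueError(f"bandwidth_rule must be 'scott', 'silverman' or a number, got {rule!r}")


def fit_kde(points, bandwidth_rule="scott") -> KdeModel:
    """Fit a Gaussian KDE to one class's feature matrix.

    With ``scott``/``silverman`` the per-dimension bandwidth is the rule's
    factor times the dimension's standard deviation; a numeric rule is an
    absolute bandwidth applied to every dimension. Zero-variance features
    are rejected (drop or jitter them first) because the scaled kernel
    would collapse.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] < 2:
        raise ValueError("KDE requires at least 2 points")
    n, d = points.shape
    factor = _bandwidth_factor(bandwidth_rule, n, d)
    if isinstance(bandwidth_rule, (int, float)) and not isinstance(bandwidth_rule, bool):
        bandwidth = np.full(d, factor)
    else:
        sd = points.std(axis=0, ddof=1)
        if np.any(sd == 0):
            dead = list(np.flatnonzero(sd == 0))
            raise ValueError(
                f"constant (zero-variance) feature(s) at column(s) {dead}: "
                "drop or jitter them before fitting the KDE"
            )
        bandwidth = factor * sd
    return KdeModel(points, bandwidth)


def sample_kde(model: KdeModel, n: int, seed) -> np.ndarray:
    """Draw ``n`` synthetic vectors: uniform training point + scaled Gaussian noise."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    rng = np.random.default_rng(seed)
    if n == 0:
        return np.empty((0, model.n_dim))
    idx = rng.integers(0, model.points.shape[0], size=n)
    noise = rng.standard_normal((n, model.n_dim)) * model.bandwidth
    return model.points[idx] + noise


class KDEAugmenter(BaseEstimator):
    """Per-class Gaussian-KDE oversampler for small labelled cohorts.

    Parameters
    ----------
    n_negative, n_positive:
        Synthetic draws to add for the negative (no neuropathy) and
        positive (neuropathy) class. Defaults 200 + 200.
    bandwidth_rule:
        ``"scott"``, ``"silverman"`` or a fixed numeric bandwidth applied
        on the standardized scale.
    random_state:
        Seed for the draws.

    After :meth:`fit`, ``kde_models_`` maps each class label to its fitted
    :class:`KdeModel` on the standardized scale and ``scalers_`` to the
    per-class (mean, sd) used for standardization.
    """

    def __init__(self, n_negative: int = 200, n_positive: int = 200,
                 bandwidth_rule="scott", random_state=None):
        self.n_negative = n_negative
        self.n_positive = n_positive
        self.bandwidth_rule = bandwidth_rule
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (subjects x features)")
        if np.isnan(X).any():
            raise ValueError("X contains missing values")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(f"expected a binary cohort, got classes {self.classes_}")
        self.kde_models_ = {}
        self.scalers_ = {}
        for cls in self.classes_:
            pts = X[y == cls]
            if pts.shape[0] < 2:
                raise ValueError(f"class {cls!r} has fewer than 2 members; cannot fit its KDE")
            mean = pts.mean(axis=0)
            sd = pts.std(axis=0, ddof=1)
            if np.any(sd == 0):
                dead = list(np.flatnonzero(sd == 0))
                raise ValueError(
                    f"class {cls!r} has constant feature(s) at column(s) {dead}: "
                    "drop or jitter them before augmentation"
                )
            self.scalers_[cls] = (mean, sd)
            self.kde_models_[cls] = fit_kde((pts - mean) / sd, self.bandwidth_rule)
        self.n_features_in_ = X.shape[1]
        return self

    def sample(self, cls, n: int, seed=None) -> np.ndarray:
        """Draw ``n`` synthetic subjects of class ``cls`` on the original scale."""
        check_is_fitted(self, "kde_models_")
        seed = self.random_state if seed is None else seed
        z = sample_kde(self.kde_models_[cls], n, seed)
        mean, sd = self.scalers_[cls]
        return z * sd + mean

    def fit_resample(self, X, y):
        """Fit, then return originals plus the synthetic rows of both classes."""
        self.fit(X, y)
        counts = dict(zip(self._ordered_classes(), (self.n_negative, self.n_positive)))
        rng = np.random.default_rng(self.random_state)
        parts_X = [np.asarray(X, dtype=float)]
        parts_y = [np.asarray(y)]
        for cls in self._ordered_classes():
            n = counts[cls]
            synth = self.sample(cls, n, seed=rng.integers(0, 2**31 - 1))
            parts_X.append(synth)
            parts_y.append(np.full(n, cls, dtype=parts_y[0].dtype))
        return np.vstack(parts_X), np.concatenate(parts_y)

    def _ordered_classes(self):
        cls = list(self.classes_)
        # put the negative label first whichever encoding is used
        if NEGATIVE_LABEL in cls:
            return [NEGATIVE_LABEL, POSITIVE_LABEL]
        return sorted(cls)


def augment_dataset(
    cohort: CohortDataset,
    n_negative: int = 200,
    n_positive: int = 200,
    seed=None,
    bandwidth_rule="scott",
) -> CohortDataset:
    """Expand a cohort with per-class KDE draws.

    Original rows pass through bit-identical and keep their provenance;
    synthetic rows are labelled ``provenance="synthetic"`` with generated
    subject ids. Row count = originals + ``n_negative`` + ``n_positive``.
    """
    counts = cohort.class_counts()
    for label, cnt in counts.items():
        if cnt < 2:
            raise ValueError(f"class {label!r} has {cnt} member(s); need at least 2")
    if n_negative == 0 and n_positive == 0:
        return CohortDataset(cohort.frame.copy(), seed=seed)

    feats = cohort.feature_columns
    aug = KDEAugmenter(
        n_negative=n_negative,
        n_positive=n_positive,
        bandwidth_rule=bandwidth_rule,
        random_state=seed,
    )
    aug.fit(cohort.frame[feats].to_numpy(dtype=float), cohort.labels.to_numpy())

    rng = np.random.default_rng(seed)
    blocks = [cohort.frame.copy()]
    for label, n in ((NEGATIVE_LABEL, n_negative), (POSITIVE_LABEL, n_positive)):
        synth = aug.sample(label, n, seed=rng.integers(0, 2**31 - 1))
        block = pd.DataFrame(synth, columns=feats)
        block.insert(0, "subject_id", [f"syn_{label}_{i:04d}" for i in range(n)])
        block.insert(1, "label", label)
        block.insert(2, "provenance", "synthetic")
        blocks.append(block)
    frame = pd.concat(blocks, ignore_index=True)
    return CohortDataset(frame, seed=seed)
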