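"""Feature-distribution shift between image collections.

Quadrants are embedded as fixed-length 64-element feature vectors; the
shift between two collections is summarized as the average
Kullback-Leibler divergence over feature dimensions (per-dimension
univariate Gaussian closed form by default, a Kozachenko-Leonenko
style k-NN estimator as an alternative), and visualized with t-SNE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import digamma

from .score import MorphometryClassifier, _segment_nuclei

__all__ = [
    "FEATURE_LENGTH",
    "FeatureVector",
    "FeatureSet",
    "DivergenceEstimate",
    "BaselineFeatureExtractor",
    "extract_features",
    "estimate_kl",
    "embed_2d",
]

FEATURE_LENGTH = 64


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    source: str = ""
    dataset_label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (FEATURE_LENGTH,):
            raise ValueError(f"feature vector must have length {FEATURE_LENGTH}")
        if not np.isfinite(v).all():
            raise ValueError("feature values must be finite")
        object.__setattr__(self, "values", v)


@dataclass
class FeatureSet:
    vectors: list[FeatureVector]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.vectors:
            raise ValueError("feature set must be nonempty")

    def matrix(self) -> np.ndarray:
        return np.stack([v.values for v in self.vectors])

    def __len__(self) -> int:
        return len(self.vectors)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix(),
                          columns=[f"f{i:02d}" for i in range(FEATURE_LENGTH)])
        df["source"] = [v.source for v in self.vectors]
        df["dataset_label"] = [v.dataset_label or self.label
                               for v in self.vectors]
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = "") -> "FeatureSet":
        cols = [f"f{i:02d}" for i in range(FEATURE_LENGTH)]
        vecs = [
            FeatureVector(
                values=row[cols].to_numpy(dtype=float),
                source=str(row.get("source", "")),
                dataset_label=str(row.get("dataset_label", label)),
            )
            for _, row in df.iterrows()
        ]
        return cls(vectors=vecs, label=label or str(
            df["dataset_label"].iloc[0] if "dataset_label" in df else ""))


class BaselineFeatureExtractor:
    """Morphometry / intensity / texture descriptors, zero-padded to 64.

    The first block repeats the classifier's morphometry features
    (nuclear area fraction, count density, mean and spread of nucleus
    area, contrast); then intensity statistics, a 16-bin intensity
    histogram, gradient statistics, and block means on a 4x4 grid.
    Deterministic for identical inputs.
    """

    def __init__(self, min_area_px: int = 4) -> None:
        self._clf = MorphometryClassifier(min_area_px=min_area_px)

    def __call__(self, quadrant: np.ndarray) -> np.ndarray:
        q = np.asarray(quadrant, dtype=float)
        if q.size == 0:
            raise ValueError("empty quadrant")
        feats: list[float] = []
        m = self._clf.features(q)
        feats += [m["area_fraction"], m["count_density"], m["mean_area"],
                  m["contrast"]]
        labeled, n = _segment_nuclei(q, self._clf.min_area_px)
        if n:
            areas = np.bincount(labeled.ravel())[1:]
            feats += [float(np.std(areas)), float(np.median(areas))]
        else:
            feats += [0.0, 0.0]
        feats += [float(q.mean()), float(q.std()), float(np.median(q)),
                  float(np.percentile(q, 10)), float(np.percentile(q, 90))]
        hist, _ = np.histogram(q, bins=16, range=(0.0, 1.0))
        feats += list(hist / q.size)
        gy, gx = np.gradient(q)
        grad = np.hypot(gy, gx)
        feats += [float(grad.mean()), float(grad.std()),
                  float(np.percentile(grad, 90))]
        # coarse 4x4 spatial layout
        h, w = q.shape
        for by in range(4):
            for bx in range(4):
                block = q[by * h // 4:(by + 1) * h // 4,
                          bx * w // 4:(bx + 1) * w // 4]
                feats.append(float(block.mean()) if block.size else 0.0)
        out = np.zeros(FEATURE_LENGTH)
        out[:len(feats)] = feats[:FEATURE_LENGTH]
        return out


def extract_features(quadrant: np.ndarray, extractor=None,
                     source: str = "", dataset_label: str = "") -> FeatureVector:
    """Embed one quadrant as a 64-element feature vector."""
    ext = extractor or BaselineFeatureExtractor()
    values = np.asarray(ext(quadrant), dtype=float)
    if values.shape != (FEATURE_LENGTH,):
        raise ValueError(
            f"extractor returned shape {values.shape}, "
            f"contract requires ({FEATURE_LENGTH},)")
    return FeatureVector(values=values, source=source,
                         dataset_label=dataset_label)


@dataclass
class DivergenceEstimate:
    value: float
    estimator: str
    per_dimension: np.ndarray | None = None


def _gaussian_kl_per_dim(a: np.ndarray, b: np.ndarray,
                         var_floor: float = 1e-8) -> np.ndarray:
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    v1 = np.maximum(a.var(axis=0), var_floor)
    v2 = np.maximum(b.var(axis=0), var_floor)
    return 0.5 * (np.log(v2 / v1) + (v1 + (m1 - m2) ** 2) / v2 - 1.0)


def _knn_kl(a: np.ndarray, b: np.ndarray, k: int = 1) -> float:
    """Kozachenko-Leonenko style k-NN KL divergence estimate (nats)."""
    n, d = a.shape
    m = b.shape[0]
    # jitter-free: distances of each a-point to its k-NN within a (excluding
    # itself) and within b
    tree_a = cKDTree(a)
    tree_b = cKDTree(b)
    rho, _ = tree_a.query(a, k=[k + 1])
    nu, _ = tree_b.query(a, k=[k])
    rho = np.maximum(rho[:, 0], 1e-12)
    nu = np.maximum(nu[:, 0], 1e-12)
    return float(d * np.mean(np.log(nu / rho)) + np.log(m / (n - 1.0)))


def estimate_kl(a: FeatureSet | np.ndarray, b: FeatureSet | np.ndarray,
                estimator: str = "gaussian-per-dim",
                standardize: bool = False,
                var_floor: float = 1e-8, k: int = 1) -> DivergenceEstimate:
    """Average K-L divergence KL(a || b) between two feature collections.

    The default fits a univariate Gaussian per dimension per set and
    averages the closed-form divergences over the 64 dimensions; the
    "knn" alternative estimates the joint divergence directly.  The
    direction is asymmetric: ``a`` is the query set, ``b`` the
    reference.  ``standardize`` rescales both sets by the reference
    set's per-dimension location/scale first.
    """
    A = a.matrix() if isinstance(a, FeatureSet) else np.atleast_2d(
        np.asarray(a, dtype=float))
    B = b.matrix() if isinstance(b, FeatureSet) else np.atleast_2d(
        np.asarray(b, dtype=float))
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("both sets need at least 2 vectors")
    if A.shape[1] != B.shape[1]:
        raise ValueError("dimensionality mismatch")
    if standardize:
        loc = B.mean(axis=0)
        scale = np.maximum(B.std(axis=0), np.sqrt(var_floor))
        A = (A - loc) / scale
        B = (B - loc) / scale
    if estimator == "gaussian-per-dim":
        per_dim = _gaussian_kl_per_dim(A, B, var_floor)
        return DivergenceEstimate(value=float(per_dim.mean()),
                                  estimator=estimator, per_dimension=per_dim)
    if estimator == "knn":
        return DivergenceEstimate(value=_knn_kl(A, B, k=k), estimator=estimator)
    raise ValueError(f"unknown estimator {estimator!r}")


def embed_2d(sets: list[FeatureSet], perplexity: float = 30.0,
             seed: int = 0, n_iter: int = 500):
    """t-SNE embedding of the pooled feature sets, labeled by dataset.

    Visualization only; returns (coords (n, 2), labels list).  The
    total vector count must exceed 3x the perplexity.
    """
    from sklearn.manifold import TSNE

    X = np.vstack([s.matrix() for s in sets])
    labels = [s.label for s in sets for _ in range(len(s))]
    if X.shape[0] <= 3 * perplexity:
        raise ValueError(
            f"need more than {int(3 * perplexity)} vectors for perplexity "
            f"{perplexity}")
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                init="pca", max_iter=n_iter)
    coords = tsne.fit_transform(X)
    return coords, labels
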