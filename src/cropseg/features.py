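"""Spectral feature engineering: the 12-feature cube and its PCA reduction.

The feature cube stacks the ten reflectance bands with two vegetation
indices:

    NDVI = (NIR − R) / (NIR + R)
    EVI  = 2.5 (NIR − R) / (NIR + 6 R − 7.5 B + 1)

where NIR is Sentinel-2 band 8, R band 4 and B band 2.  The cube is then
z-scored per feature and projected onto its first three principal
components, which form the 3-channel network input after per-channel
min–max scaling to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .raster_io import BAND_NAMES, SceneBundle

FEATURE_NAMES = tuple(BAND_NAMES) + ("ndvi", "evi")


def _check_same_shape(*rasters: np.ndarray) -> None:
    shapes = {r.shape for r in rasters}
    if len(shapes) != 1:
        raise ValueError(f"rasters must share a shape, got {sorted(map(str, shapes))}")


def _safe_ratio(num: np.ndarray, den: np.ndarray, return_mask: bool):
    bad = den == 0
    out = np.zeros(np.broadcast(num, den).shape, dtype=np.float64)
    np.divide(num, den, out=out, where=~bad)
    out = out.astype(np.float32)
    if return_mask:
        return out, bad
    return out


def compute_ndvi(nir: np.ndarray, red: np.ndarray, return_mask: bool = False):
    """Normalized difference vegetation index (NIR − R)/(NIR + R).

    Pixels where NIR + R == 0 are set to 0; pass ``return_mask=True`` to
    also get the boolean mask of those degenerate pixels.
    """
    _check_same_shape(nir, red)
    return _safe_ratio(
        np.asarray(nir, np.float64) - red, np.asarray(nir, np.float64) + red, return_mask
    )


def compute_evi(nir: np.ndarray, red: np.ndarray, blue: np.ndarray,
                return_mask: bool = False):
    """Enhanced vegetation index 2.5 (NIR − R)/(NIR + 6R − 7.5B + 1)."""
    _check_same_shape(nir, red, blue)
    nir = np.asarray(nir, np.float64)
    den = nir + 6.0 * np.asarray(red, np.float64) - 7.5 * np.asarray(blue, np.float64) + 1.0
    return _safe_ratio(2.5 * (nir - np.asarray(red, np.float64)), den, return_mask)


@dataclass
class FeatureCube:
    """H×W×12 feature stack: ten bands plus NDVI and EVI, in that order."""

    values: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self):
        if self.values.ndim != 3 or self.values.shape[2] != len(self.feature_names):
            raise ValueError(
                f"feature cube must be H×W×{len(self.feature_names)}, "
                f"got {self.values.shape}"
            )

    @property
    def shape(self):
        return self.values.shape[:2]


def assemble_feature_cube(scene: SceneBundle) -> FeatureCube:
    """Stack the 10 bands with NDVI and EVI (NIR = band 8, R = band 4, B = band 2)."""
    nir = scene.band("nir")
    red = scene.band("red")
    blue = scene.band("blue")
    ndvi = compute_ndvi(nir, red)
    evi = compute_evi(nir, red, blue)
    values = np.concatenate(
        [scene.bands.astype(np.float32), ndvi[..., None], evi[..., None]], axis=2
    )
    return FeatureCube(values=values)


@dataclass
class PCAReduced:
    """First principal components of the standardized feature cube.

    ``loadings`` is the 12×n matrix of feature loadings (orthonormal
    columns); ``scaler`` holds the per-feature mean and scale applied
    before projection.
    """

    values: np.ndarray  # H×W×n
    explained_variance_ratio: np.ndarray  # (n,)
    loadings: np.ndarray  # 12×n
    scaler: tuple[np.ndarray, np.ndarray]  # (mean, scale), each (12,)

    def to_dict(self) -> dict:
        return {
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "loadings": self.loadings.tolist(),
            "mean": self.scaler[0].tolist(),
            "scale": self.scaler[1].tolist(),
        }


def pca_reduce(cube: FeatureCube, n_components: int = 3) -> PCAReduced:
    """Z-score each feature over all pixels, then project onto the top
    ``n_components`` principal axes.

    The sign of each component is fixed deterministically: the loading of
    largest magnitude is made positive.  A zero-variance feature gets unit
    scale (with a warning) so it simply contributes nothing.
    """
    n_feat = cube.values.shape[2]
    if n_components > n_feat:
        raise ValueError(f"n_components={n_components} exceeds {n_feat} features")
    h, w = cube.shape
    x = cube.values.reshape(-1, n_feat).astype(np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("feature cube contains non-finite values")

    scaler = StandardScaler()
    xs = scaler.fit_transform(x)
    if np.any(scaler.var_ == 0):
        zero = [cube.feature_names[i] for i in np.flatnonzero(scaler.var_ == 0)]
        warnings.warn(f"zero-variance features scaled by 1: {zero}", stacklevel=2)

    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(xs)
    components = pca.components_  # (n, 12)
    # deterministic sign: largest-magnitude loading of each component positive
    for i in range(n_components):
        j = np.argmax(np.abs(components[i]))
        if components[i, j] < 0:
            components[i] *= -1.0
            scores[:, i] *= -1.0

    return PCAReduced(
        values=scores.reshape(h, w, n_components).astype(np.float32),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        loadings=components.T.copy(),
        scaler=(scaler.mean_.copy(), scaler.scale_.copy()),
    )


def scale_for_model(pca: PCAReduced) -> np.ndarray:
    """Per-channel min–max scaling of the PCA scores to [0, 1].

    A constant channel maps to 0.5 everywhere.
    """
    v = pca.values.astype(np.float64)
    lo = v.min(axis=(0, 1))
    hi = v.max(axis=(0, 1))
    span = hi - lo
    out = np.empty_like(v)
    for c in range(v.shape[2]):
        if span[c] == 0:
            out[:, :, c] = 0.5
        else:
            out[:, :, c] = (v[:, :, c] - lo[c]) / span[c]
    return out.astype(np.float32)


def scene_to_model_input(scene: SceneBundle, n_components: int = 3) -> np.ndarray:
    """Full feature pipeline: cube → PCA → [0, 1] scaling.  Returns H×W×n."""
    return scale_for_model(pca_reduce(assemble_feature_cube(scene), n_components))
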