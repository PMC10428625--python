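"""Synthetic multispectral crop scenes for end-to-end testing.

Real agricultural scenes in this problem are mosaics of contiguous field
plots, each planted with one crop, with sharp boundaries between plots and
modest within-field reflectance variability.  The generator emulates that
structure: a Voronoi tessellation of random seed points defines the plot
map, each plot draws a crop class (or is left as unlabeled background),
and every pixel's 10-band spectrum is the class's mean signature plus
i.i.d. Gaussian noise (optionally spatially smoothed).

The default class signatures are vegetation-like — low blue/red, a
red-edge rise, a NIR plateau, moderate SWIR — with corn and soybean
deliberately closer to each other than either is to rice, mirroring the
corn/soybean confusion observed in real imagery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .features import scene_to_model_input
from .raster_io import BAND_ROLES, IGNORE_LABEL, SceneBundle
from .tiling import PatchSet

N_BANDS = len(BAND_ROLES)
N_CLASSES = 3  # corn, rice, soybean

#: Spectrum used for unlabeled background plots (bare soil: flat visible,
#: no red-edge rise, reflectance growing into SWIR).
SOIL_SIGNATURE = np.array(
    [0.10, 0.13, 0.16, 0.18, 0.20, 0.22, 0.24, 0.25, 0.30, 0.28], dtype=np.float64
)


def default_signatures() -> np.ndarray:
    """Mean 10-band reflectance per class (rows: corn, rice, soybean).

    Band order: blue, green, red, red-edge ×3, NIR, red-edge, SWIR ×2.
    Corn and soybean are spectrally close; rice stands apart (wet paddies:
    stronger NIR plateau, depressed SWIR).
    """
    corn = [0.040, 0.070, 0.050, 0.100, 0.250, 0.330, 0.380, 0.390, 0.220, 0.120]
    rice = [0.060, 0.090, 0.040, 0.120, 0.350, 0.480, 0.550, 0.560, 0.150, 0.070]
    soy_ = [0.045, 0.080, 0.055, 0.110, 0.280, 0.370, 0.430, 0.440, 0.240, 0.130]
    return np.array([corn, rice, soy_], dtype=np.float64)


@dataclass
class SceneParams:
    """Parameters of the synthetic scene generator.

    ``signature_sd`` is the per-band Gaussian noise standard deviation in
    reflectance units (default 0.02, i.e. ~2% within-field variability);
    ``background_fraction`` the probability that a plot stays unlabeled;
    ``spatial_smooth_sigma`` an optional Gaussian smoothing (pixels) of the
    noise field.
    """

    height: int = 256
    width: int = 256
    n_plots: int = 60
    class_signatures: np.ndarray = field(default_factory=default_signatures)
    signature_sd: float = 0.02
    spatial_smooth_sigma: float = 0.0
    class_probs: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    background_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        self.class_signatures = np.asarray(self.class_signatures, dtype=np.float64)
        k = self.class_signatures.shape[0]
        if self.class_signatures.shape != (k, N_BANDS):
            raise ValueError(f"class_signatures must be K×{N_BANDS}")
        if np.any(self.class_signatures < 0) or np.any(self.class_signatures > 1):
            raise ValueError("signatures must lie in [0, 1]")
        if len(self.class_probs) != k:
            raise ValueError("class_probs length must match signature rows")
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")
        if self.n_plots < k:
            raise ValueError("need at least one plot per class")
        if not (0 <= self.background_fraction < 1):
            raise ValueError("background_fraction must be in [0, 1)")

    @property
    def n_classes(self) -> int:
        return self.class_signatures.shape[0]


def generate_scene(params: SceneParams) -> SceneBundle:
    """Generate one labeled scene, fully reproducible from ``params.seed``.

    A Voronoi mosaic of ``n_plots`` seed points defines the plot map (ids
    1..n_plots); each plot is either background (label −1, soil spectrum)
    or a crop class drawn from ``class_probs``.  Band values are the plot
    class's signature plus Gaussian noise.
    """
    h, w = params.height, params.width
    if h < 8 or w < 8:
        raise ValueError(f"scene size {h}×{w} is degenerate; need at least 8×8")
    rng = np.random.default_rng(params.seed)

    # Voronoi mosaic: nearest seed point claims each pixel
    seeds = rng.uniform([0, 0], [h, w], size=(params.n_plots, 2))
    rr, cc = np.mgrid[0:h, 0:w]
    pts = np.column_stack([rr.ravel() + 0.5, cc.ravel() + 0.5])
    _, owner = cKDTree(seeds).query(pts)
    plots = (owner.reshape(h, w) + 1).astype(np.int64)

    # per-plot class assignment; every class seeded at least once
    k = params.n_classes
    plot_class = rng.choice(k, size=params.n_plots, p=np.asarray(params.class_probs))
    is_bg = rng.random(params.n_plots) < params.background_fraction
    plot_class = np.where(is_bg, -1, plot_class)
    if set(range(k)) - set(plot_class[plot_class >= 0]):
        for cls in range(k):
            if cls not in plot_class:
                plot_class[rng.integers(0, params.n_plots)] = cls

    labels = plot_class[plots - 1]

    means = np.vstack([params.class_signatures, SOIL_SIGNATURE[None, :]])
    bands = means[np.where(labels < 0, k, labels)]  # H×W×10 mosaic of means
    if params.signature_sd > 0:
        noise = rng.normal(0.0, params.signature_sd, size=(h, w, N_BANDS))
        if params.spatial_smooth_sigma > 0:
            for b in range(N_BANDS):
                noise[:, :, b] = gaussian_filter(
                    noise[:, :, b], params.spatial_smooth_sigma
                )
        bands = bands + noise
    bands = np.clip(bands, 0.0, 1.0).astype(np.float32)

    return SceneBundle(
        bands=bands,
        labels=labels.astype(np.int64),
        plots=plots,
    )


def generate_patchset(params: SceneParams, patch: int, n: int) -> PatchSet:
    """Sample ``n`` patches, each from a fresh scene, through the feature
    pipeline (feature cube → PCA → [0, 1] scaling).

    Scene i uses seed ``params.seed + i``; the crop position within each
    scene is random.  Plot ids are offset per scene so they stay globally
    unique across the patch set.
    """
    if patch > min(params.height, params.width):
        raise ValueError("patch size exceeds scene dimensions")
    rng = np.random.default_rng(params.seed)
    inputs, labels, plot_ids, plot_rasters = [], [], [], []
    for i in range(n):
        p = SceneParams(**{**params.__dict__, "seed": params.seed + i})
        scene = generate_scene(p)
        x = scene_to_model_input(scene)
        r = int(rng.integers(0, params.height - patch + 1))
        c = int(rng.integers(0, params.width - patch + 1))
        inputs.append(x[r : r + patch, c : c + patch])
        labels.append(scene.labels[r : r + patch, c : c + patch])
        offset = i * (params.n_plots + 1)
        pl = scene.plots[r : r + patch, c : c + patch] + offset
        plot_rasters.append(pl)
        plot_ids.append(frozenset(int(v) for v in np.unique(pl)))
    return PatchSet(
        inputs=np.stack(inputs).astype(np.float32),
        labels=np.stack(labels).astype(np.int64),
        plot_ids=plot_ids,
        plots=np.stack(plot_rasters).astype(np.int64),
    )
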