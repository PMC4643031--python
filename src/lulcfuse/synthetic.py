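"""Fully synthetic multispectral scenes for end-to-end testing.

The generator emulates the inputs of a composite-VI land-cover
classification study: a spatially autocorrelated 9-class label map, a
16-day NDVI/EVI time series per pixel driven by class-specific seasonal
curves (asymmetric Gaussians) with Gaussian noise and cloud-contaminated QA
flags, band reflectances back-solved from the vegetation-index definitions,
and a smooth DEM shifted by per-class elevation affinity.  Everything is
seeded and deterministic.

The default class parameters sketch the phenological contrasts of a
temperate agro-pastoral mosaic: crops with a narrow intense season,
deciduous forest with a broad one, evergreen forest with high base
greenness and low amplitude, shrublands and grassland in between, and
spectrally flat bare ground, urban and water classes separated by
brightness and NDVI sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .features import asymmetric_gaussian, compute_evi, compute_ndvi
from .types import (
    ClassScheme,
    GeoTransform,
    LULCMap,
    SampleSet,
    TimeSeriesCube,
)

__all__ = [
    "ClassSignature",
    "SceneConfig",
    "default_scene_config",
    "simulate_scene",
    "sample_reference_points",
]

#: 16-day composite days-of-year (23 composites per year).
COMPOSITE_DOYS = tuple(range(9, 366, 16))


@dataclass(frozen=True)
class ClassSignature:
    """Seasonal and spectral parameters of one land-cover class.

    ``base``/``amplitude`` describe the NDVI seasonal curve (asymmetric
    Gaussian peaking at ``peak_doy`` with widths ``sigma_left``/
    ``sigma_right`` in days); ``brightness`` is the NIR+red total
    reflectance; ``elevation_affinity`` (m) shifts the DEM under the class.
    """

    base: float
    amplitude: float
    peak_doy: float
    sigma_left: float
    sigma_right: float
    brightness: float
    elevation_affinity: float

    @property
    def curve_params(self) -> np.ndarray:
        return np.array(
            [self.base, self.amplitude, self.peak_doy, self.sigma_left, self.sigma_right]
        )


DEFAULT_SIGNATURES: dict[str, ClassSignature] = {
    "AGRI": ClassSignature(0.25, 0.45, 210.0, 22.0, 18.0, 0.42, -150.0),
    "BARE": ClassSignature(0.08, 0.03, 200.0, 40.0, 40.0, 0.55, 0.0),
    "CLSH": ClassSignature(0.25, 0.30, 195.0, 35.0, 30.0, 0.38, 100.0),
    "DBLF": ClassSignature(0.32, 0.42, 190.0, 42.0, 38.0, 0.35, 250.0),
    "ENLF": ClassSignature(0.55, 0.12, 185.0, 50.0, 45.0, 0.30, 500.0),
    "GRAS": ClassSignature(0.18, 0.33, 200.0, 30.0, 28.0, 0.40, 50.0),
    "OPSH": ClassSignature(0.14, 0.14, 195.0, 35.0, 32.0, 0.50, 150.0),
    "URBN": ClassSignature(0.12, 0.06, 200.0, 40.0, 40.0, 0.60, -100.0),
    "WATR": ClassSignature(-0.15, 0.02, 200.0, 40.0, 40.0, 0.15, -300.0),
}


@dataclass
class SceneConfig:
    """Configuration of one simulated scene."""

    shape: tuple[int, int] = (192, 192)
    signatures: dict[str, ClassSignature] = field(
        default_factory=lambda: dict(DEFAULT_SIGNATURES)
    )
    noise_sd: float = 0.02
    cloud_probability: float = 0.15
    marginal_probability: float = 0.10
    correlation_length: float = 5.0
    elevation_mean: float = 1200.0
    elevation_sd: float = 200.0
    dates: tuple[float, ...] = COMPOSITE_DOYS
    geotransform: GeoTransform = (500000.0, 250.0, 0.0, 4500000.0, 0.0, -250.0)
    crs: str = "EPSG:32650"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cloud_probability <= 1.0:
            raise ValueError("cloud_probability must lie in [0, 1]")
        if not 0.0 <= self.marginal_probability <= 1.0:
            raise ValueError("marginal_probability must lie in [0, 1]")
        if self.correlation_length < 1.0:
            raise ValueError("correlation_length must be >= 1 pixel")
        if any(sig.amplitude < 0 for sig in self.signatures.values()):
            raise ValueError("amplitudes must be non-negative")

    def scheme(self) -> ClassScheme:
        return ClassScheme(
            classes=tuple(
                (i + 1, name) for i, name in enumerate(sorted(self.signatures))
            )
        )


def default_scene_config(**overrides) -> SceneConfig:
    """The study-condition scene: 9 classes, noise sd 0.02, 15% clouds."""
    return replace(SceneConfig(), **overrides) if overrides else SceneConfig()


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def simulate_scene(
    config: SceneConfig, seed: int | None = None
) -> tuple[TimeSeriesCube, np.ndarray, LULCMap]:
    """Generate (time-series cube, DEM, truth label map) from a config.

    The label map is the per-pixel argmax of independent smoothed Gaussian
    random fields (one per class), giving contiguous patches; per pixel the
    NDVI trajectory is the class seasonal curve plus Gaussian noise, cloud
    composites (QA 3, drawn independently per composite) are biased
    downward by a random fraction of up to 50%, and reflectances are
    back-solved from the NDVI definition at the class brightness
    (blue = red/2, MIR tracks red).  The DEM is a smooth random surface
    shifted by each class's elevation affinity.
    """
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    names = sorted(config.signatures)
    sigs = [config.signatures[n] for n in names]
    scheme = config.scheme()
    r, c = config.shape
    n_cls = len(names)

    params = np.stack([s.curve_params for s in sigs])
    dup = len({tuple(p) for p in params}) < n_cls
    if dup:
        warnings.warn("some classes share identical seasonal parameters; "
                      "they are inseparable by construction")

    # label map: argmax of per-class smoothed fields
    fields = np.stack(
        [_smooth_field(rng, (r, c), config.correlation_length) for _ in range(n_cls)]
    )
    label_idx = fields.argmax(axis=0)
    labels = np.asarray(scheme.codes)[label_idx]
    truth = LULCMap(
        labels=labels.astype(np.int64),
        scheme=scheme,
        geotransform=config.geotransform,
        crs=config.crs,
    )

    # DEM: smooth surface + class affinity
    base_surface = _smooth_field(rng, (r, c), config.correlation_length * 3)
    affinity = np.array([s.elevation_affinity for s in sigs])
    dem = (
        config.elevation_mean
        + config.elevation_sd * base_surface
        + affinity[label_idx]
    )

    # NDVI trajectories
    dates = np.asarray(config.dates, dtype=float)
    t = dates.size
    curves = asymmetric_gaussian(dates, params)  # (n_cls, T)
    ndvi = curves[label_idx].transpose(2, 0, 1)  # (T, R, C)
    ndvi = ndvi + rng.normal(0.0, config.noise_sd, size=(t, r, c))

    # QA flags and cloud contamination
    u = rng.random((t, r, c))
    cloud = u < config.cloud_probability
    marginal = (~cloud) & (
        u < config.cloud_probability + config.marginal_probability
    )
    qa = np.zeros((t, r, c))
    qa[marginal] = rng.integers(1, 3, size=int(marginal.sum()))
    qa[cloud] = 3
    bias = rng.uniform(0.0, 0.5, size=(t, r, c))
    ndvi = np.where(cloud, ndvi * (1.0 - bias), ndvi)
    ndvi = np.clip(ndvi, -0.95, 0.95)

    # back-solve reflectances at the class brightness
    brightness = np.array([s.brightness for s in sigs])[label_idx]
    b = np.clip(
        brightness[None] + rng.normal(0.0, config.noise_sd / 2.0, size=(t, r, c)),
        0.05,
        0.95,
    )
    red = np.clip(b * (1.0 - ndvi) / 2.0, 1e-4, 1.0)
    nir = np.clip(b * (1.0 + ndvi) / 2.0, 1e-4, 1.0)
    blue = 0.5 * red
    mir = np.clip(red + rng.normal(0.0, config.noise_sd, size=(t, r, c)), 0.0, 1.0)

    values = np.stack(
        [blue, red, nir, mir, compute_ndvi(red, nir), compute_evi(blue, red, nir), qa],
        axis=1,
    )
    cube = TimeSeriesCube(
        values=values,
        bands=("blue", "red", "nir", "mir", "ndvi", "evi", "qa"),
        dates=dates,
        geotransform=config.geotransform,
        crs=config.crs,
    )
    cube.validate()
    return cube, dem, truth


def sample_reference_points(
    truth: LULCMap,
    n_per_class: int,
    homogeneity_window: int = 3,
    seed: int = 0,
) -> SampleSet:
    """Stratified random reference points from spatially homogeneous pixels.

    A pixel qualifies when its ``homogeneity_window``-sized neighbourhood is
    single-class (window 1 disables the filter, mimicking the practice of
    discarding reference points in heterogeneous neighbourhoods).  Exactly
    ``n_per_class`` points are drawn per class without replacement; a class
    with too few homogeneous pixels raises an error naming it.
    """
    if homogeneity_window < 1 or homogeneity_window % 2 == 0:
        raise ValueError("homogeneity_window must be a positive odd integer")
    labels = truth.labels
    if homogeneity_window == 1:
        homogeneous = np.ones(labels.shape, dtype=bool)
    else:
        mx = ndimage.maximum_filter(labels, size=homogeneity_window, mode="nearest")
        mn = ndimage.minimum_filter(labels, size=homogeneity_window, mode="nearest")
        homogeneous = mx == mn
    rng = np.random.default_rng(seed)
    rows_all, cols_all, codes_all = [], [], []
    for code, name in zip(truth.scheme.codes, truth.scheme.names):
        rr, cc = np.nonzero((labels == code) & homogeneous)
        if rr.size < n_per_class:
            raise ValueError(
                f"class {name}: only {rr.size} homogeneous pixels, "
                f"need {n_per_class}"
            )
        pick = rng.choice(rr.size, size=n_per_class, replace=False)
        rows_all.append(rr[pick])
        cols_all.append(cc[pick])
        codes_all.append(np.full(n_per_class, code))
    return SampleSet(
        rows=np.concatenate(rows_all),
        cols=np.concatenate(cols_all),
        codes=np.concatenate(codes_all),
    )
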