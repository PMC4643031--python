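"""Shared domain types for the classification pipeline.

The pipeline's contracts are carried by a small set of containers: a
:class:`ClassScheme` naming the land-cover legend, a :class:`TimeSeriesCube`
of composite reflectances/vegetation indices, per-sample
:class:`FeatureTable`/:class:`SampleSet` objects, per-pixel
:class:`ProbabilityCube` and :class:`LULCMap` layers, and the count/area
cross-tabulations used for accuracy and change assessment.

Conventions
-----------
* class codes are small unsigned integers; ``0`` is reserved for
  "unclassified" and ``255`` for nodata,
* pixel coordinates are 0-based ``(row, col)``; georeferenced ``(x, y)``
  appears only at I/O boundaries,
* missing float values are NaN in memory and mapped to the declared nodata
  value on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClassScheme",
    "DEFAULT_CLASS_NAMES",
    "default_scheme",
    "TimeSeriesCube",
    "FeatureTable",
    "SampleSet",
    "ProbabilityCube",
    "LULCMap",
    "VoteMap",
    "ConfusionMatrix",
    "ConversionMatrix",
    "GeoTransform",
]

#: GDAL-style affine geotransform (x0, dx, rx, y0, ry, dy).
GeoTransform = tuple[float, float, float, float, float, float]

#: Land-cover legend of the agro-pasture transition study region, in
#: alphabetical order: agriculture, bare ground, closed shrubland, deciduous
#: broad-leaved forest, evergreen needle-leaved forest, grassland, open
#: shrubland, urban, water.
DEFAULT_CLASS_NAMES = (
    "AGRI",
    "BARE",
    "CLSH",
    "DBLF",
    "ENLF",
    "GRAS",
    "OPSH",
    "URBN",
    "WATR",
)

REFLECTANCE_BANDS = ("blue", "red", "nir", "mir")
VI_BANDS = ("ndvi", "evi")
CUBE_BANDS = REFLECTANCE_BANDS + VI_BANDS + ("qa",)

IDENTITY_TRANSFORM: GeoTransform = (0.0, 1.0, 0.0, 0.0, 0.0, -1.0)


@dataclass(frozen=True)
class ClassScheme:
    """Ordered land-cover legend with reserved unclassified/nodata codes."""

    classes: tuple[tuple[int, str], ...]
    unclassified_code: int = 0
    nodata_code: int = 255

    def __post_init__(self) -> None:
        codes = [c for c, _ in self.classes]
        if len(set(codes)) != len(codes):
            raise ValueError("class codes must be unique")
        if any(c < 0 for c in codes):
            raise ValueError("class codes must be non-negative")
        reserved = {self.unclassified_code, self.nodata_code}
        if len(reserved) != 2:
            raise ValueError("unclassified and nodata codes must differ")
        if reserved & set(codes):
            raise ValueError("reserved codes must not collide with class codes")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def codes(self) -> tuple[int, ...]:
        return tuple(c for c, _ in self.classes)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for _, n in self.classes)

    def code_of(self, name: str) -> int:
        for code, n in self.classes:
            if n == name:
                return code
        raise KeyError(f"unknown class name: {name!r}")

    def name_of(self, code: int) -> str:
        for c, n in self.classes:
            if c == code:
                return n
        if code == self.unclassified_code:
            return "UNCE"
        if code == self.nodata_code:
            return "NODATA"
        raise KeyError(f"unknown class code: {code}")

    def index_of(self, code: int) -> int:
        """Position of ``code`` in the legend order."""
        try:
            return self.codes.index(code)
        except ValueError:
            raise KeyError(f"code {code} not in scheme") from None

    def is_valid_label(self, labels: np.ndarray) -> np.ndarray:
        valid = np.isin(labels, self.codes)
        valid |= labels == self.unclassified_code
        valid |= labels == self.nodata_code
        return valid


def default_scheme() -> ClassScheme:
    """The 9-class legend with codes 1..9 in alphabetical order."""
    return ClassScheme(
        classes=tuple((i + 1, name) for i, name in enumerate(DEFAULT_CLASS_NAMES))
    )


@dataclass
class TimeSeriesCube:
    """Multi-band composite time series on a common grid.

    ``values`` is indexed ``(composite, band, row, col)``; ``dates`` holds the
    day-of-year of each composite.  Reflectance bands live in [0, 1],
    vegetation indices in [-1, 1], and the ``qa`` band in {0, 1, 2, 3}
    (0 good .. 3 cloudy); missing data are NaN.
    """

    values: np.ndarray
    bands: tuple[str, ...]
    dates: np.ndarray
    geotransform: GeoTransform = IDENTITY_TRANSFORM
    crs: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.dates = np.asarray(self.dates, dtype=np.float64)
        self.bands = tuple(self.bands)
        if self.values.ndim != 4:
            raise ValueError("cube values must be 4-D (time, band, row, col)")
        if self.values.shape[0] != self.dates.size:
            raise ValueError("number of composites does not match dates")
        if self.values.shape[1] != len(self.bands):
            raise ValueError("number of band planes does not match band names")
        if len(set(self.bands)) != len(self.bands):
            raise ValueError("band names must be unique")
        if np.unique(self.dates).size != self.dates.size:
            raise ValueError("composite dates must be distinct")
        if np.any(np.diff(self.dates) < 0):  # sort composites by date
            order = np.argsort(self.dates)
            self.values = self.values[order]
            self.dates = self.dates[order]

    @property
    def n_composites(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[2], self.values.shape[3]

    def band(self, name: str) -> np.ndarray:
        """The ``(time, row, col)`` plane of one band."""
        if name not in self.bands:
            raise KeyError(f"band {name!r} not in cube (have {self.bands})")
        return self.values[:, self.bands.index(name)]

    def validate(self) -> None:
        """Check band-domain invariants; raises ``ValueError`` on violation."""
        for name in self.bands:
            plane = self.band(name)
            finite = plane[np.isfinite(plane)]
            if name == "qa":
                if finite.size and not np.isin(finite, (0, 1, 2, 3)).all():
                    bad = sorted(set(finite[~np.isin(finite, (0, 1, 2, 3))]))
                    raise ValueError(f"qa band contains values outside 0..3: {bad}")
            elif name in VI_BANDS:
                if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
                    raise ValueError(f"band {name!r} outside [-1, 1]")
            elif name in REFLECTANCE_BANDS:
                if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
                    raise ValueError(f"band {name!r} outside [0, 1]")

    def sorted_by_date(self) -> "TimeSeriesCube":
        order = np.argsort(self.dates)
        if np.array_equal(order, np.arange(self.dates.size)):
            return self
        return replace(self, values=self.values[order], dates=self.dates[order])


@dataclass
class FeatureTable:
    """Named per-sample (or per-pixel) feature vectors."""

    values: np.ndarray
    feature_names: tuple[str, ...]
    combo: str = ""

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        self.feature_names = tuple(self.feature_names)
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature count does not match names")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.feature_names))

    def select(self, names: Sequence[str]) -> "FeatureTable":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureTable(self.values[:, idx], tuple(names), combo=self.combo)


@dataclass
class SampleSet:
    """Labelled reference points with optional train/test split tags."""

    rows: np.ndarray
    cols: np.ndarray
    codes: np.ndarray
    split: np.ndarray | None = None  # "train" | "test" per point
    features: FeatureTable | None = None
    xs: np.ndarray | None = None
    ys: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.intp)
        self.cols = np.asarray(self.cols, dtype=np.intp)
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if not (self.rows.size == self.cols.size == self.codes.size):
            raise ValueError("rows, cols and codes must have equal length")
        if self.split is not None:
            self.split = np.asarray(self.split, dtype=object)
            if self.split.size != self.codes.size:
                raise ValueError("split tags must match number of points")

    def __len__(self) -> int:
        return self.codes.size

    def class_counts(self, scheme: ClassScheme) -> dict[str, int]:
        return {
            scheme.name_of(c): int((self.codes == c).sum()) for c in scheme.codes
        }

    def subset(self, mask: np.ndarray) -> "SampleSet":
        return SampleSet(
            rows=self.rows[mask],
            cols=self.cols[mask],
            codes=self.codes[mask],
            split=None if self.split is None else self.split[mask],
            features=None
            if self.features is None
            else FeatureTable(
                self.features.values[mask],
                self.features.feature_names,
                combo=self.features.combo,
            ),
            xs=None if self.xs is None else self.xs[mask],
            ys=None if self.ys is None else self.ys[mask],
        )

    def split_part(self, tag: str) -> "SampleSet":
        if self.split is None:
            raise ValueError("sample set has no split tags")
        return self.subset(self.split == tag)


def _check_simplex(probs: np.ndarray, axis: int, tol: float = 1e-6) -> None:
    finite = np.isfinite(probs).all(axis=axis)
    if not finite.any():
        return
    p = np.moveaxis(probs, axis, -1)[finite]
    if p.size == 0:
        return
    if p.min() < -tol or p.max() > 1 + tol:
        raise ValueError("probabilities outside [0, 1]")
    sums = p.sum(axis=-1)
    if np.abs(sums - 1.0).max() > tol:
        raise ValueError("probability vectors do not sum to 1 within 1e-6")


@dataclass
class ProbabilityCube:
    """Per-pixel (or per-sample) class-membership probabilities.

    ``probs`` is ``(class, row, col)`` for maps or ``(class, sample)`` for
    point sets, ordered as ``scheme.classes``.  Each valid pixel's vector
    lies on the probability simplex; pixels with NaN in any class are
    nodata.
    """

    probs: np.ndarray
    scheme: ClassScheme
    source: str = ""
    geotransform: GeoTransform = IDENTITY_TRANSFORM
    crs: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim not in (2, 3):
            raise ValueError("probs must be (class, sample) or (class, row, col)")
        if self.probs.shape[0] != self.scheme.n_classes:
            raise ValueError("first axis must equal the number of classes")

    def validate(self, tol: float = 1e-6) -> None:
        _check_simplex(self.probs, axis=0, tol=tol)

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.probs).all(axis=0)


@dataclass
class LULCMap:
    """Hard land-cover labels on a grid (may contain unclassified/nodata)."""

    labels: np.ndarray
    scheme: ClassScheme
    geotransform: GeoTransform = IDENTITY_TRANSFORM
    crs: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label map must hold integers")

    def validate(self) -> None:
        ok = self.scheme.is_valid_label(self.labels)
        if not ok.all():
            bad = sorted(set(np.asarray(self.labels)[~ok].tolist()))
            raise ValueError(f"label map contains codes outside scheme: {bad}")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.labels != self.scheme.nodata_code

    def pixel_area_km2(self) -> float:
        """Pixel footprint from the geotransform, assuming metric units."""
        _, dx, _, _, _, dy = self.geotransform
        return abs(dx * dy) / 1e6


@dataclass
class VoteMap:
    """Per-pixel count of classifiers agreeing with the fused label."""

    counts: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("vote map must be 2-D")

    def validate(self) -> None:
        c = self.counts[self.counts >= 0]  # negative marks nodata
        if c.size and (c.min() < 1 or c.max() > self.k):
            raise ValueError(f"vote counts must lie in 1..{self.k}")


@dataclass
class ConfusionMatrix:
    """Predicted-by-reference count cross-tabulation.

    Rows are predicted classes in scheme order, optionally followed by one
    "UNCE" row for unclassified predictions; columns are reference classes
    in scheme order.
    """

    counts: np.ndarray
    scheme: ClassScheme
    include_unclassified: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        m = self.scheme.n_classes
        expected_rows = m + 1 if self.include_unclassified else m
        if self.counts.shape != (expected_rows, m):
            raise ValueError(
                f"confusion matrix must be {expected_rows}x{m}, got {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise ValueError("confusion matrix counts must be non-negative")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_names(self) -> tuple[str, ...]:
        names = self.scheme.names
        return names + ("UNCE",) if self.include_unclassified else names

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.row_names), columns=list(self.scheme.names)
        )


@dataclass
class ConversionMatrix:
    """Class-by-class area cross-tabulation between two dates (km²)."""

    areas: np.ndarray
    scheme: ClassScheme
    pixel_area_km2: float = 1.0
    dates: tuple[str, str] = ("t1", "t2")
    excluded_km2: float = 0.0  # area unclassified/nodata at either date

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=np.float64)
        m = self.scheme.n_classes
        if self.areas.shape != (m, m):
            raise ValueError(f"conversion matrix must be {m}x{m}")
        if (self.areas < -1e-9).any():
            raise ValueError("areas must be non-negative")

    def to_dataframe(self) -> pd.DataFrame:
        names = list(self.scheme.names)
        return pd.DataFrame(self.areas, index=names, columns=names)

    @property
    def total_km2(self) -> float:
        return float(self.areas.sum())
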