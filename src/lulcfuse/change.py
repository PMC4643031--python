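"""Post-classification change detection between two dated land-cover maps.

The conversion matrix cross-tabulates the area (km²) moving from each class
at the first date to each class at the second; net flows and per-class area
changes derive from it.  Pixels unclassified or nodata at either date are
excluded from the matrix and reported as a remainder, so total matrix area
equals the commonly valid overlap.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .types import ClassScheme, ConversionMatrix, LULCMap

__all__ = ["conversion_matrix", "net_conversion", "class_area_change"]


def conversion_matrix(
    map_t1: LULCMap,
    map_t2: LULCMap,
    pixel_area_km2: float | None = None,
    dates: tuple[str, str] = ("t1", "t2"),
) -> ConversionMatrix:
    """Area cross-tabulation between two maps on the same grid.

    ``areas[i, j]`` is the area labelled class *i* at the first date and
    class *j* at the second.  ``pixel_area_km2`` defaults to the footprint
    implied by the first map's geotransform (e.g. a 250 m grid gives
    0.0625 km²).
    """
    if map_t1.labels.shape != map_t2.labels.shape:
        raise ValueError(
            f"grid mismatch: {map_t1.labels.shape} vs {map_t2.labels.shape}"
        )
    if map_t1.scheme.classes != map_t2.scheme.classes:
        raise ValueError("maps use different class schemes")
    if pixel_area_km2 is None:
        pixel_area_km2 = map_t1.pixel_area_km2()
    if pixel_area_km2 <= 0:
        raise ValueError("pixel_area_km2 must be positive")
    scheme = map_t1.scheme
    a = map_t1.labels.ravel()
    b = map_t2.labels.ravel()
    valid = np.isin(a, scheme.codes) & np.isin(b, scheme.codes)
    idx = {c: i for i, c in enumerate(scheme.codes)}
    m = scheme.n_classes
    counts = np.zeros((m, m), dtype=np.int64)
    ai = np.array([idx[v] for v in a[valid]])
    bi = np.array([idx[v] for v in b[valid]])
    np.add.at(counts, (ai, bi), 1)
    return ConversionMatrix(
        areas=counts * float(pixel_area_km2),
        scheme=scheme,
        pixel_area_km2=float(pixel_area_km2),
        dates=dates,
        excluded_km2=float((~valid).sum() * pixel_area_km2),
    )


def _to_codes(scheme: ClassScheme, classes: Iterable[int | str] | int | str) -> set[int]:
    if isinstance(classes, (int, str)):
        classes = [classes]
    return {
        scheme.code_of(c) if isinstance(c, str) else int(c) for c in classes
    }


def net_conversion(
    cm: ConversionMatrix,
    from_class: int | str,
    to_classes: Iterable[int | str] | int | str,
) -> float:
    """Signed net area (km²) converted from one class into a set of classes.

    Forward conversions minus the reverse flow:
    ``Σ_j areas[from, j] − Σ_j areas[j, from]`` over ``j`` in
    ``to_classes``.  Positive means a net loss of the source class to the
    targets.  ``from_class`` must not appear in ``to_classes``.
    """
    scheme = cm.scheme
    src = _to_codes(scheme, from_class)
    if len(src) != 1:
        raise ValueError("from_class must be a single class")
    dst = _to_codes(scheme, to_classes)
    if src & dst:
        raise ValueError("from_class and to_classes overlap")
    i = scheme.index_of(next(iter(src)))
    js = [scheme.index_of(c) for c in dst]
    return float(cm.areas[i, js].sum() - cm.areas[js, i].sum())


def class_area_change(cm: ConversionMatrix) -> pd.DataFrame:
    """Per-class area at each date and the percent change between them.

    Areas at the first date are row sums, at the second column sums; the
    percent change is relative to the first date (NaN for classes absent
    then).
    """
    t1 = cm.areas.sum(axis=1)
    t2 = cm.areas.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(t1 > 0, 100.0 * (t2 - t1) / t1, np.nan)
    return pd.DataFrame(
        {
            "class": list(cm.scheme.names),
            f"area_{cm.dates[0]}_km2": t1,
            f"area_{cm.dates[1]}_km2": t2,
            "change_pct": pct,
        }
    )
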