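"""Per-pixel feature extraction from composite time series and a DEM.

Three feature combinations feed the classifiers:

* **C1** — growing-season statistics (mean, sd, min, max, range) of the four
  reflectance bands (blue, red, NIR, MIR) and two vegetation indices
  (NDVI, EVI), plus terrain (elevation, slope, aspect): 33 features.
* **C2** — eleven phenology metrics of the EVI seasonal curve plus terrain:
  14 features.
* **C3** — the union of C1 and C2 (terrain counted once): 44 features.

Phenology is extracted from a QA-weighted upper-envelope fit of a per-season
asymmetric Gaussian, the classical approach for cloud-contaminated composite
VI series: cloud contamination biases vegetation indices downward, so points
falling below the fitted curve are progressively down-weighted and the curve
converges onto the upper envelope of the good observations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .types import FeatureTable, TimeSeriesCube

log = logging.getLogger(__name__)

__all__ = [
    "compute_ndvi",
    "compute_evi",
    "qa_to_weight",
    "fit_upper_envelope",
    "fit_seasonal_model",
    "asymmetric_gaussian",
    "PhenoMetrics",
    "extract_phenology",
    "seasonal_statistics",
    "terrain_derivatives",
    "assemble_features",
    "GROWING_SEASON_WINDOW",
    "FLAT_ASPECT_SENTINEL",
    "STAT_NAMES",
    "PHENO_NAMES",
    "TERRAIN_NAMES",
    "feature_names_for_combo",
]

#: Default growing-season DOY window (April–October) for the C1 statistics.
GROWING_SEASON_WINDOW = (97.0, 297.0)

#: Aspect value assigned to flat cells.
FLAT_ASPECT_SENTINEL = -1.0

STAT_NAMES = ("mean", "sd", "min", "max", "range")
STAT_BANDS = ("blue", "red", "nir", "mir", "ndvi", "evi")
PHENO_NAMES = (
    "pheno_start_doy",
    "pheno_mid_doy",
    "pheno_end_doy",
    "pheno_season_length",
    "pheno_base",
    "pheno_peak",
    "pheno_amplitude",
    "pheno_rate_increase",
    "pheno_rate_decrease",
    "pheno_integral_large",
    "pheno_integral_small",
)
TERRAIN_NAMES = ("elevation", "slope", "aspect")

# EVI coefficients of the standard two-band-plus-blue formulation.
_EVI_G, _EVI_C1, _EVI_C2, _EVI_L = 2.5, 6.0, 7.5, 1.0

_QA_WEIGHTS = {0: 1.0, 1: 0.5, 2: 0.5, 3: 0.1}


def compute_ndvi(red: np.ndarray, nir: np.ndarray) -> np.ndarray:
    """Normalized difference vegetation index (NIR − red)/(NIR + red).

    Zero denominators yield NaN; output is clipped to [-1, 1].
    """
    red = np.asarray(red, dtype=np.float64)
    nir = np.asarray(nir, dtype=np.float64)
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(np.abs(denom) > 0, (nir - red) / denom, np.nan)
    return np.clip(out, -1.0, 1.0)


def compute_evi(blue: np.ndarray, red: np.ndarray, nir: np.ndarray) -> np.ndarray:
    """Enhanced vegetation index with the standard coefficients.

    EVI = G (NIR − red) / (NIR + C1 red − C2 blue + L) with G=2.5, C1=6,
    C2=7.5, L=1.  Near-zero denominators (≤ 1e-6) yield NaN; output clipped
    to [-1, 1].
    """
    blue = np.asarray(blue, dtype=np.float64)
    red = np.asarray(red, dtype=np.float64)
    nir = np.asarray(nir, dtype=np.float64)
    denom = nir + _EVI_C1 * red - _EVI_C2 * blue + _EVI_L
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(np.abs(denom) > 1e-6, _EVI_G * (nir - red) / denom, np.nan)
    return np.clip(out, -1.0, 1.0)


def qa_to_weight(qa: np.ndarray | int) -> np.ndarray | float:
    """Fitting weight of a QA flag: 0→1.0 (good), 1–2→0.5, 3→0.1 (cloudy)."""
    arr = np.asarray(qa)
    finite = arr[np.isfinite(arr.astype(float))]
    if finite.size and not np.isin(finite, (0, 1, 2, 3)).all():
        bad = sorted(set(np.asarray(finite[~np.isin(finite, (0, 1, 2, 3))]).tolist()))
        raise ValueError(f"qa values outside 0..3: {bad}")
    out = np.select(
        [arr == 0, arr == 1, arr == 2, arr == 3],
        [1.0, 0.5, 0.5, 0.1],
        default=np.nan,
    )
    if np.isscalar(qa) or arr.ndim == 0:
        return float(out)
    return out


def asymmetric_gaussian(t: np.ndarray, params: np.ndarray) -> np.ndarray:
    """Evaluate the seasonal model ``base + A·exp(-((t-tp)/σ)²/2)``.

    ``params`` is ``(..., 5)`` = (base, amplitude, peak_doy, sigma_left,
    sigma_right); σ_left applies before the peak, σ_right after.
    """
    params = np.asarray(params, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    scalar = params.ndim == 1
    p = np.atleast_2d(params)
    b, a, tp, sl, sr = (p[:, i][:, None] for i in range(5))
    dt = t[None, :] - tp
    sig = np.where(dt < 0, sl, sr)
    out = b + a * np.exp(-0.5 * (dt / sig) ** 2)
    return out[0] if scalar else out


def _ag_jacobian(t: np.ndarray, params: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of the asymmetric Gaussian, shape (n, T, 5)."""
    b, a, tp, sl, sr = (params[:, i][:, None] for i in range(5))
    dt = t[None, :] - tp
    left = dt < 0
    sig = np.where(left, sl, sr)
    e = np.exp(-0.5 * (dt / sig) ** 2)
    j = np.empty(params.shape[:1] + t.shape + (5,))
    j[..., 0] = 1.0
    j[..., 1] = e
    j[..., 2] = a * e * dt / sig**2
    ds = a * e * dt**2 / sig**3
    j[..., 3] = np.where(left, ds, 0.0)
    j[..., 4] = np.where(~left, ds, 0.0)
    return j


_SIGMA_BOUNDS = (4.0, 400.0)


def _lm_fit(
    y: np.ndarray,
    w: np.ndarray,
    t: np.ndarray,
    max_iter: int = 40,
) -> np.ndarray:
    """Batch weighted Levenberg–Marquardt fit of the asymmetric Gaussian.

    ``y`` and ``w`` are (n, T) with NaN/zero-weight entries ignored; returns
    parameters (n, 5).  All pixels iterate in lockstep with per-pixel
    damping.
    """
    n, nt = y.shape
    w = np.where(np.isfinite(y), w, 0.0)
    ysafe = np.where(np.isfinite(y), y, 0.0)

    # moment-based initial guess
    wsum = w.sum(axis=1, keepdims=True)
    wsum = np.where(wsum > 0, wsum, 1.0)
    base0 = np.nanmin(np.where(w > 0, ysafe, np.nan), axis=1)
    base0 = np.where(np.isfinite(base0), base0, 0.0)
    peak_idx = np.argmax(np.where(w > 0, ysafe, -np.inf), axis=1)
    tp0 = t[peak_idx]
    amp0 = np.maximum(ysafe[np.arange(n), peak_idx] - base0, 0.0)
    span = (t[-1] - t[0]) if nt > 1 else 1.0
    sig0 = np.full(n, max(span / 6.0, _SIGMA_BOUNDS[0]))

    theta = np.column_stack([base0, amp0, tp0, sig0, sig0])
    lam = np.full(n, 1e-3)

    def cost(th: np.ndarray) -> np.ndarray:
        r = ysafe - asymmetric_gaussian(t, th)
        return (w * r**2).sum(axis=1)

    c = cost(theta)
    eye = np.eye(5)
    for _ in range(max_iter):
        f = asymmetric_gaussian(t, theta)
        r = (ysafe - f) * w  # weighted residual (w here is weight, not sqrt)
        j = _ag_jacobian(t, theta)
        jw = j * w[..., None]
        g = np.einsum("ntp,nt->np", jw, ysafe - f)
        h = np.einsum("ntp,ntq->npq", jw, j)
        hd = h + lam[:, None, None] * (np.abs(np.einsum("npp->np", h))[:, :, None] * eye + 1e-12 * eye)
        try:
            step = np.linalg.solve(hd, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            hd = hd + 1e-6 * eye
            step = np.linalg.solve(hd, g[..., None])[..., 0]
        cand = theta + step
        cand[:, 1] = np.maximum(cand[:, 1], 0.0)
        cand[:, 3] = np.clip(cand[:, 3], *_SIGMA_BOUNDS)
        cand[:, 4] = np.clip(cand[:, 4], *_SIGMA_BOUNDS)
        c_new = cost(cand)
        accept = c_new <= c
        theta = np.where(accept[:, None], cand, theta)
        c = np.where(accept, c_new, c)
        lam = np.where(accept, lam * 0.4, lam * 3.0)
        lam = np.clip(lam, 1e-9, 1e6)
    return theta


def fit_seasonal_model(
    values: np.ndarray,
    weights: np.ndarray,
    dates: np.ndarray,
    n_envelope: int = 2,
    min_valid: int = 6,
) -> tuple[np.ndarray, np.ndarray]:
    """Upper-envelope asymmetric-Gaussian fit of VI series.

    Parameters
    ----------
    values, weights
        ``(n, T)`` (or ``(T,)``) VI series and QA-derived weights.
    dates
        Composite day-of-year values, strictly increasing, length T.
    n_envelope
        Number of envelope-adaptation passes after the initial fit; each
        pass halves the weight of points lying below the current curve.
    min_valid
        Pixels with fewer valid (finite, positively weighted) composites
        than this are returned as NaN.

    Returns
    -------
    params, smoothed
        ``(n, 5)`` fitted parameters (base, amplitude, peak_doy, sigma_left,
        sigma_right) and the ``(n, T)`` smoothed series.
    """
    values = np.atleast_2d(np.asarray(values, dtype=np.float64))
    weights = np.atleast_2d(np.asarray(weights, dtype=np.float64))
    dates = np.asarray(dates, dtype=np.float64)
    if values.shape != weights.shape or values.shape[1] != dates.size:
        raise ValueError("values, weights and dates have inconsistent shapes")
    if np.any(np.diff(dates) <= 0):
        raise ValueError("dates must be strictly increasing")

    w = np.where(np.isfinite(values), weights, 0.0)
    n_valid = (w > 0).sum(axis=1)
    fit_mask = n_valid >= min_valid
    all_min = fit_mask & (
        np.isclose(np.where(w > 0, w, np.nan), 0.1).all(axis=1, where=w > 0)
        & (n_valid > 0)
    )
    if np.any(all_min):
        warnings.warn(
            f"{int(all_min.sum())} series have all weights at the cloud minimum; "
            "fit proceeds on low-confidence data"
        )

    params = np.full((values.shape[0], 5), np.nan)
    if fit_mask.any():
        yv, wv = values[fit_mask], w[fit_mask]
        th = _lm_fit(yv, wv, dates)
        for _ in range(n_envelope):
            curve = asymmetric_gaussian(dates, th)
            below = yv < curve
            wv = np.where(below, wv * 0.5, wv)
            th = _lm_fit(yv, wv, dates)
        params[fit_mask] = th
    smoothed = np.full_like(values, np.nan)
    if fit_mask.any():
        smoothed[fit_mask] = asymmetric_gaussian(dates, params[fit_mask])
    return params, smoothed


def evaluate_seasonal_model(
    params: np.ndarray, dates_out: np.ndarray
) -> np.ndarray:
    """Evaluate fitted seasonal curves on an arbitrary date grid.

    Rows with NaN parameters (pixels that could not be fitted) come back as
    NaN series.
    """
    params = np.atleast_2d(np.asarray(params, dtype=np.float64))
    dates_out = np.asarray(dates_out, dtype=np.float64)
    out = np.full((params.shape[0], dates_out.size), np.nan)
    ok = np.isfinite(params).all(axis=1)
    if ok.any():
        out[ok] = asymmetric_gaussian(dates_out, params[ok])
    return out


def fit_upper_envelope(
    vi_series: np.ndarray,
    weights: np.ndarray,
    dates: np.ndarray,
    n_envelope: int = 2,
) -> np.ndarray:
    """Smoothed upper-envelope series (same shape as the input)."""
    arr = np.asarray(vi_series, dtype=np.float64)
    _, smoothed = fit_seasonal_model(arr, weights, dates, n_envelope=n_envelope)
    return smoothed.reshape(arr.shape) if arr.ndim == 1 else smoothed


@dataclass
class PhenoMetrics:
    """Seasonal-curve metrics, one entry per series (NaN = no season).

    Dates are day-of-year; ``amplitude = peak − base``; rates are VI units
    per composite interval; integrals are VI·days between season start and
    end (``integral_small`` is the area above the base level).
    """

    start_doy: np.ndarray
    mid_doy: np.ndarray
    end_doy: np.ndarray
    season_length: np.ndarray
    base: np.ndarray
    peak: np.ndarray
    amplitude: np.ndarray
    rate_increase: np.ndarray
    rate_decrease: np.ndarray
    integral_large: np.ndarray
    integral_small: np.ndarray
    no_season: np.ndarray

    def to_array(self) -> np.ndarray:
        """Stack the 11 metrics as columns, ordered as ``PHENO_NAMES``."""
        return np.column_stack(
            [
                self.start_doy,
                self.mid_doy,
                self.end_doy,
                self.season_length,
                self.base,
                self.peak,
                self.amplitude,
                self.rate_increase,
                self.rate_decrease,
                self.integral_large,
                self.integral_small,
            ]
        )


def _daily_interp_matrix(dates: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linear-interpolation weights from composite dates to a daily grid."""
    grid = np.arange(dates[0], dates[-1] + 1.0)
    w = np.zeros((grid.size, dates.size))
    idx = np.clip(np.searchsorted(dates, grid, side="right") - 1, 0, dates.size - 2)
    frac = (grid - dates[idx]) / (dates[idx + 1] - dates[idx])
    w[np.arange(grid.size), idx] = 1.0 - frac
    w[np.arange(grid.size), idx + 1] = frac
    return grid, w


def extract_phenology(
    smoothed_series: np.ndarray,
    dates: np.ndarray,
    season_fraction: float = 0.2,
    min_amplitude: float = 0.05,
) -> PhenoMetrics:
    """Phenology metrics of smoothed seasonal curves.

    Season start/end are the first/last days where the linearly interpolated
    curve crosses ``base + season_fraction·amplitude``; the mid-season date
    is the curve maximum; rates of increase/decrease are slopes between the
    start/end crossings and the half-amplitude crossings (VI per composite
    interval); the large integral is the area under the curve between start
    and end, the small integral the area above the base level.  Series whose
    amplitude falls below ``min_amplitude`` carry no season: all metrics NaN
    and the ``no_season`` flag set.
    """
    y = np.atleast_2d(np.asarray(smoothed_series, dtype=np.float64))
    dates = np.asarray(dates, dtype=np.float64)
    if y.shape[1] != dates.size:
        raise ValueError("series length does not match dates")
    n = y.shape[0]
    grid, wmat = _daily_interp_matrix(dates)
    daily = np.where(np.isfinite(y), y, 0.0) @ wmat.T
    invalid = ~np.isfinite(y).all(axis=1)
    d = grid.size

    peak_idx = np.argmax(daily, axis=1)
    rng = np.arange(d)[None, :]
    left_mask = rng <= peak_idx[:, None]
    base_left = np.min(np.where(left_mask, daily, np.inf), axis=1)
    base_right = np.min(np.where(~left_mask | (rng == peak_idx[:, None]), daily, np.inf), axis=1)
    base = 0.5 * (base_left + base_right)
    peak = daily[np.arange(n), peak_idx]
    amplitude = peak - base
    no_season = invalid | (amplitude < min_amplitude)

    def first_at_or_above(v: np.ndarray, mask: np.ndarray) -> np.ndarray:
        hit = (daily >= v[:, None]) & mask
        any_hit = hit.any(axis=1)
        idx = np.argmax(hit, axis=1)
        return np.where(any_hit, idx, 0)

    def last_at_or_above(v: np.ndarray, mask: np.ndarray) -> np.ndarray:
        hit = (daily >= v[:, None]) & mask
        any_hit = hit.any(axis=1)
        idx = d - 1 - np.argmax(hit[:, ::-1], axis=1)
        return np.where(any_hit, idx, d - 1)

    right_mask = rng >= peak_idx[:, None]
    v_thr = base + season_fraction * amplitude
    v_mid = base + 0.5 * amplitude
    i_start = first_at_or_above(v_thr, left_mask)
    i_end = last_at_or_above(v_thr, right_mask)
    i_mid_l = first_at_or_above(v_mid, left_mask)
    i_mid_r = last_at_or_above(v_mid, right_mask)

    t = grid
    start, end = t[i_start], t[i_end]
    mid = t[peak_idx]
    spacing = float(np.median(np.diff(dates))) if dates.size > 1 else 1.0

    def slope(v_hi_idx, v_lo_idx, hi_val, lo_val):
        dt = t[v_hi_idx] - t[v_lo_idx]
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where(np.abs(dt) > 0, (hi_val - lo_val) / dt, 0.0)
        return s * spacing

    rate_inc = np.abs(slope(i_mid_l, i_start, v_mid, v_thr))
    rate_dec = np.abs(slope(i_mid_r, i_end, v_mid, v_thr))

    season_mask = (rng >= i_start[:, None]) & (rng <= i_end[:, None])
    integral_large = (daily * season_mask).sum(axis=1)
    integral_small = (np.clip(daily - base[:, None], 0.0, None) * season_mask).sum(
        axis=1
    )

    def mask_ns(a: np.ndarray) -> np.ndarray:
        return np.where(no_season, np.nan, a.astype(np.float64))

    return PhenoMetrics(
        start_doy=mask_ns(start),
        mid_doy=mask_ns(mid),
        end_doy=mask_ns(end),
        season_length=mask_ns(end - start),
        base=mask_ns(base),
        peak=mask_ns(peak),
        amplitude=mask_ns(amplitude),
        rate_increase=mask_ns(rate_inc),
        rate_decrease=mask_ns(rate_dec),
        integral_large=mask_ns(integral_large),
        integral_small=mask_ns(integral_small),
        no_season=no_season,
    )


def seasonal_statistics(
    values: np.ndarray,
    dates: np.ndarray,
    window: tuple[float, float] = GROWING_SEASON_WINDOW,
) -> np.ndarray:
    """Growing-season statistics (mean, sd, min, max, range) per series.

    ``values`` is ``(..., T)`` with time last; statistics run over valid
    (finite) composites whose date falls inside ``window`` (inclusive).
    Series with no valid composite in the window are all-NaN.
    """
    values = np.asarray(values, dtype=np.float64)
    dates = np.asarray(dates, dtype=np.float64)
    in_win = (dates >= window[0]) & (dates <= window[1])
    sub = values[..., in_win]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(sub, axis=-1) if sub.shape[-1] else np.full(values.shape[:-1], np.nan)
        if sub.shape[-1]:
            nvalid = np.isfinite(sub).sum(axis=-1)
            sd = np.nanstd(sub, axis=-1, ddof=1)
            sd = np.where(nvalid >= 2, sd, np.where(nvalid == 1, 0.0, np.nan))
            mn = np.nanmin(sub, axis=-1)
            mx = np.nanmax(sub, axis=-1)
        else:
            sd = mn = mx = np.full(values.shape[:-1], np.nan)
    return np.stack([mean, sd, mn, mx, mx - mn], axis=-1)


def terrain_derivatives(
    dem: np.ndarray,
    cell_size: float | tuple[float, float] = 1.0,
    flat_sentinel: float = FLAT_ASPECT_SENTINEL,
) -> tuple[np.ndarray, np.ndarray]:
    """Slope (degrees) and aspect (degrees clockwise from north) of a DEM.

    Uses Horn's 3×3 finite differences with edge replication at the border.
    Flat cells receive ``flat_sentinel`` as aspect.  Rows are assumed to run
    north→south (standard raster orientation).
    """
    dem = np.asarray(dem, dtype=np.float64)
    if dem.ndim != 2:
        raise ValueError("DEM must be 2-D")
    if not np.isfinite(dem).any():
        raise ValueError("DEM contains no valid cells")
    dx, dy = (cell_size, cell_size) if np.isscalar(cell_size) else cell_size
    z = np.pad(dem, 1, mode="edge")
    nw, n_, ne = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    w_, e_ = z[1:-1, :-2], z[1:-1, 2:]
    sw, s_, se = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    dzdx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8.0 * dx)
    dzdy = ((nw + 2 * n_ + ne) - (sw + 2 * s_ + se)) / (8.0 * dy)  # toward north
    grad = np.hypot(dzdx, dzdy)
    slope = np.degrees(np.arctan(grad))
    aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    aspect = np.where(grad < 1e-12, flat_sentinel, aspect)
    nan_in = ~np.isfinite(dem)
    slope[nan_in] = np.nan
    aspect[nan_in] = np.nan
    return slope, aspect


def feature_names_for_combo(combo: str) -> tuple[str, ...]:
    """Stable, documented feature names of a combination C1/C2/C3."""
    stats = tuple(f"{b}_{s}" for b in STAT_BANDS for s in STAT_NAMES)
    if combo == "C1":
        return stats + TERRAIN_NAMES
    if combo == "C2":
        return PHENO_NAMES + TERRAIN_NAMES
    if combo == "C3":
        return stats + PHENO_NAMES + TERRAIN_NAMES
    raise ValueError(f"unknown combination {combo!r}; expected C1, C2 or C3")


def _impute_columns(x: np.ndarray) -> np.ndarray:
    """Replace NaNs with per-column medians (0 if a column is all-NaN)."""
    x = x.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(x, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    nan_mask = ~np.isfinite(x)
    if nan_mask.any():
        x[nan_mask] = np.take(med, np.nonzero(nan_mask)[1])
    return x


def assemble_features(
    cube: TimeSeriesCube,
    dem: np.ndarray,
    combo: str,
    points: tuple[np.ndarray, np.ndarray] | None = None,
    window: tuple[float, float] = GROWING_SEASON_WINDOW,
    season_fraction: float = 0.2,
    min_amplitude: float = 0.05,
    include_quality_flag: bool = False,
    dem_cell_size: float | tuple[float, float] | None = None,
) -> FeatureTable:
    """Assemble the per-pixel feature table for a combination.

    If ``points`` (rows, cols) is given, features are extracted at those
    pixels; otherwise for every pixel in row-major order.  Composites are
    sorted by date internally, so feature values do not depend on input
    order.  Pixels without a detectable season get phenology imputed
    (amplitude, rates and integrals 0; dates at the window midpoint; base
    and peak at the series mean); any remaining NaNs are imputed with
    per-feature medians so the table is rectangular and NaN-free.
    """
    names = feature_names_for_combo(combo)
    cube = cube.sorted_by_date()
    nrow, ncol = cube.shape
    if points is None:
        rows, cols = np.divmod(np.arange(nrow * ncol), ncol)
    else:
        rows = np.asarray(points[0], dtype=np.intp)
        cols = np.asarray(points[1], dtype=np.intp)
    n = rows.size

    if dem_cell_size is None:
        _, gdx, _, _, _, gdy = cube.geotransform
        dem_cell_size = (abs(gdx), abs(gdy))
    dem = np.asarray(dem, dtype=np.float64)
    if dem.shape != (nrow, ncol):
        raise ValueError("DEM grid does not match the cube grid")
    slope, aspect = terrain_derivatives(dem, cell_size=dem_cell_size)
    terrain = np.column_stack(
        [dem[rows, cols], slope[rows, cols], aspect[rows, cols]]
    )

    blocks: list[np.ndarray] = []
    if combo in ("C1", "C3"):
        stat_cols = []
        for band in STAT_BANDS:
            series = cube.band(band)[:, rows, cols].T  # (n, T)
            stat_cols.append(seasonal_statistics(series, cube.dates, window))
        blocks.append(np.concatenate(stat_cols, axis=1))
    quality = None
    if combo in ("C2", "C3"):
        evi = cube.band("evi")[:, rows, cols].T
        qa = cube.band("qa")[:, rows, cols].T
        wts = np.where(np.isfinite(qa), qa_to_weight(np.nan_to_num(qa)), 0.0)
        params, _ = fit_seasonal_model(evi, wts, cube.dates)
        # metrics come off the continuous fitted curve sampled daily, which
        # avoids the chord error of the 16-day composite spacing
        daily = np.arange(cube.dates[0], cube.dates[-1] + 1.0)
        metrics = extract_phenology(
            evaluate_seasonal_model(params, daily),
            daily,
            season_fraction=season_fraction,
            min_amplitude=min_amplitude,
        )
        pheno = metrics.to_array()
        ns = metrics.no_season
        if ns.any():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                series_mean = np.nanmean(evi, axis=1)
            midpoint = 0.5 * (window[0] + window[1])
            fill = np.column_stack(
                [
                    np.full(n, midpoint),  # start
                    np.full(n, midpoint),  # mid
                    np.full(n, midpoint),  # end
                    np.zeros(n),  # season length
                    series_mean,  # base
                    series_mean,  # peak
                    np.zeros(n),  # amplitude
                    np.zeros(n),  # rates
                    np.zeros(n),
                    np.zeros(n),  # integrals
                    np.zeros(n),
                ]
            )
            pheno = np.where(ns[:, None], fill, pheno)
        blocks.append(pheno)
        quality = (~ns).astype(np.float64)
    blocks.append(terrain)
    values = np.concatenate(blocks, axis=1)
    if include_quality_flag and quality is not None:
        values = np.column_stack([values, quality])
        names = names + ("pheno_valid",)
    values = _impute_columns(values)
    return FeatureTable(values, names, combo=combo)
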