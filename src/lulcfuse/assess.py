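"""Accuracy assessment and uncertainty diagnostics.

Covers the standard map-accuracy toolkit — confusion matrix with an
optional "unclassified" predicted row, producer's/user's accuracies,
overall accuracy and Cohen's kappa — plus the experiments used to compare
and diagnose classifiers: training-sample-size sensitivity curves,
class-proportion ratios inside high-uncertainty subsets, the correlation
between mean class-membership probability and per-class accuracy, and CMP
histograms.

Accuracy conventions (all switchable): unclassified predictions count in
the producer's-accuracy denominators (a reference point left unclassified
is an omission) but have no user's accuracy; kappa is computed on the full
matrix with the unclassified row as a predicted category whose reference
margin is zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import predict_proba, train_backend
from .types import ClassScheme, ConfusionMatrix, LULCMap, ProbabilityCube

log = logging.getLogger(__name__)

__all__ = [
    "confusion_matrix",
    "AccuracyReport",
    "accuracy_report",
    "round_half_up",
    "SensitivityCurve",
    "sample_size_sensitivity",
    "proportion_ratio",
    "cmp_accuracy_correlation",
    "cmp_histogram",
]


def round_half_up(x, decimals: int = 1):
    """Decimal rounding with ties away from zero (report style)."""
    factor = 10.0**decimals
    x = np.asarray(x, dtype=np.float64)
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return float(out) if out.ndim == 0 else out


def confusion_matrix(
    predicted: np.ndarray | LULCMap,
    reference: np.ndarray,
    scheme: ClassScheme,
    include_unclassified: bool = True,
    points: tuple[np.ndarray, np.ndarray] | None = None,
) -> ConfusionMatrix:
    """Cross-tabulate predicted against reference labels.

    ``predicted`` is a label vector, or a map with ``points`` (rows, cols)
    giving the evaluation pixels.  Reference labels must be scheme classes;
    unclassified predictions fill a dedicated final row when
    ``include_unclassified`` (otherwise they raise).
    """
    if isinstance(predicted, LULCMap):
        if points is None:
            raise ValueError("points are required to evaluate a map")
        predicted = predicted.labels[points]
    pred = np.asarray(predicted).ravel()
    ref = np.asarray(reference).ravel()
    if pred.size != ref.size:
        raise ValueError("predicted and reference lengths differ")
    bad_ref = ~np.isin(ref, scheme.codes)
    if bad_ref.any():
        raise ValueError(
            f"reference contains codes outside the scheme: {sorted(set(ref[bad_ref].tolist()))}"
        )
    m = scheme.n_classes
    rows = m + 1 if include_unclassified else m
    counts = np.zeros((rows, m), dtype=np.int64)
    code_to_idx = {c: i for i, c in enumerate(scheme.codes)}
    pred_idx = np.array(
        [
            code_to_idx.get(p, m if p == scheme.unclassified_code else -1)
            for p in pred
        ]
    )
    if (pred_idx == -1).any():
        bad = sorted({int(p) for p in pred if p not in code_to_idx and p != scheme.unclassified_code})
        raise ValueError(f"predictions contain codes outside the scheme: {bad}")
    if not include_unclassified and (pred_idx == m).any():
        raise ValueError("unclassified predictions present but excluded from matrix")
    ref_idx = np.array([code_to_idx[r] for r in ref])
    np.add.at(counts, (pred_idx, ref_idx), 1)
    return ConfusionMatrix(counts, scheme, include_unclassified=include_unclassified)


@dataclass
class AccuracyReport:
    """Per-class and summary accuracies, in percent (full precision).

    NaN marks undefined entries (empty reference column or classified row).
    """

    pa: np.ndarray  # producer's accuracy per class
    ua: np.ndarray  # user's accuracy per class
    average_pa: float
    average_ua: float
    oa: float
    kappa: float
    scheme: ClassScheme

    def summary(self, decimals: int = 1) -> pd.DataFrame:
        """Rounded report table (half-up, report style)."""
        df = pd.DataFrame(
            {
                "class": list(self.scheme.names),
                "PA_pct": round_half_up(self.pa, decimals),
                "UA_pct": round_half_up(self.ua, decimals),
            }
        )
        footer = pd.DataFrame(
            {
                "class": ["average", "overall"],
                "PA_pct": [round_half_up(self.average_pa, decimals), round_half_up(self.oa, decimals)],
                "UA_pct": [round_half_up(self.average_ua, decimals), round_half_up(self.kappa, decimals)],
            }
        )
        df = pd.concat([df, footer], ignore_index=True)
        return df


def accuracy_report(cm: ConfusionMatrix, kappa_with_unclassified: bool = True) -> AccuracyReport:
    """Producer's/user's accuracies, overall accuracy and Cohen's kappa.

    PA_j = diagonal/column total (unclassified predictions included in the
    denominator); UA_i = diagonal/row total over classified rows; OA =
    trace/N.  Kappa uses p_e = Σ_i row_i·col_i / N² over predicted
    categories — with the unclassified row included by default (it has a
    zero reference margin, so it dilutes p_e slightly); set
    ``kappa_with_unclassified=False`` to drop unclassified samples first.
    """
    counts = cm.counts.astype(np.float64)
    m = cm.scheme.n_classes
    if not kappa_with_unclassified and cm.include_unclassified:
        counts = counts[:m]
    n = counts.sum()
    if n <= 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(counts[:m, :m]).astype(np.float64)
    col = counts.sum(axis=0)
    row = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = np.where(col > 0, 100.0 * diag / col, np.nan)
        ua = np.where(row[:m] > 0, 100.0 * diag / row[:m], np.nan)
    oa = 100.0 * diag.sum() / n
    # chance agreement over matched categories (extra predicted rows have
    # zero reference margin and contribute nothing to p_e's numerator)
    pe = float(row[:m] @ col) / n**2
    po = diag.sum() / n
    kappa = 100.0 * (po - pe) / (1.0 - pe) if pe < 1.0 else 100.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN means
        avg_pa, avg_ua = float(np.nanmean(pa)), float(np.nanmean(ua))
    return AccuracyReport(
        pa=pa,
        ua=ua,
        average_pa=avg_pa,
        average_ua=avg_ua,
        oa=float(oa),
        kappa=float(kappa),
        scheme=cm.scheme,
    )


@dataclass
class SensitivityCurve:
    """Replicate accuracies per training fraction for one classifier."""

    kind: str
    fractions: np.ndarray
    oa: np.ndarray  # (n_fractions, n_replicates)
    kappa: np.ndarray

    @property
    def oa_mean(self) -> np.ndarray:
        return self.oa.mean(axis=1)

    @property
    def oa_sd(self) -> np.ndarray:
        return self.oa.std(axis=1, ddof=1) if self.oa.shape[1] > 1 else np.zeros(self.oa.shape[0])

    @property
    def kappa_mean(self) -> np.ndarray:
        return self.kappa.mean(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for i, f in enumerate(self.fractions):
            for r in range(self.oa.shape[1]):
                recs.append(
                    {
                        "kind": self.kind,
                        "fraction": float(f),
                        "replicate": r,
                        "oa_pct": float(self.oa[i, r]),
                        "kappa_pct": float(self.kappa[i, r]),
                    }
                )
        return pd.DataFrame.from_records(recs)


def _stratified_subsample(
    codes: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Indices of a per-class subsample without replacement (≥1 per class)."""
    keep: list[np.ndarray] = []
    for code in np.unique(codes):
        idx = np.nonzero(codes == code)[0]
        n_keep = max(int(round(fraction * idx.size)), 1)
        if n_keep < 1:
            log.info("class %s floored to 1 training sample", code)
        keep.append(rng.choice(idx, size=min(n_keep, idx.size), replace=False))
    return np.concatenate(keep)


def sample_size_sensitivity(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    y_test: np.ndarray,
    scheme: ClassScheme,
    kinds=("rf", "svm", "wknn", "ann", "nb"),
    fractions=tuple(np.round(np.arange(0.1, 1.01, 0.1), 2)),
    replicates: int = 50,
    seed: int = 0,
    hyperparams: dict | None = None,
) -> dict[str, SensitivityCurve]:
    """Training-sample-size sensitivity experiment.

    For every replicate and fraction an independent stratified subsample of
    the training set (without replacement, at least one point per class)
    trains each classifier; overall accuracy and kappa are evaluated on the
    fixed test set.  Fully seeded: the subsample of (replicate, fraction)
    is identical across classifier kinds so curves are comparable.
    """
    fractions = np.asarray(sorted(fractions), dtype=float)
    if np.any(fractions <= 0) or np.any(fractions > 1):
        raise ValueError("fractions must lie in (0, 1]")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    hyperparams = hyperparams or {}
    oa = {k: np.zeros((fractions.size, replicates)) for k in kinds}
    kp = {k: np.zeros((fractions.size, replicates)) for k in kinds}
    root = np.random.default_rng(seed)
    rep_seeds = root.integers(0, 2**31 - 1, size=replicates)
    for r, rs in enumerate(rep_seeds):
        rng = np.random.default_rng(rs)
        for i, f in enumerate(fractions):
            idx = (
                np.arange(y_train.size)
                if f >= 1.0
                else _stratified_subsample(y_train, float(f), rng)
            )
            for kind in kinds:
                model = train_backend(
                    kind,
                    x_train[idx],
                    codes=y_train[idx],
                    hyperparams=hyperparams.get(kind),
                    seed=int(rs % (2**31 - 1)),
                )
                probs = predict_proba(model, x_test, scheme=scheme)
                pred = np.asarray(scheme.codes)[probs.argmax(axis=1)]
                cm = confusion_matrix(pred, y_test, scheme, include_unclassified=False)
                rep = accuracy_report(cm)
                oa[kind][i, r] = rep.oa
                kp[kind][i, r] = rep.kappa
    return {
        k: SensitivityCurve(kind=k, fractions=fractions, oa=oa[k], kappa=kp[k])
        for k in kinds
    }


def proportion_ratio(
    subset_labels: np.ndarray,
    full_map: LULCMap | np.ndarray,
    scheme: ClassScheme,
    flag_threshold: float = 3.0,
) -> pd.DataFrame:
    """Class proportions in an uncertain subset versus the whole map.

    Returns one row per class with the subset proportion (%), the full-map
    proportion (%), their ratio, and a flag for ratios above
    ``flag_threshold`` (classes over-represented among uncertain pixels are
    the ones the ensemble struggles to recognize).  Classes absent from the
    full map get a NaN ratio.
    """
    subset = np.asarray(subset_labels).ravel()
    subset = subset[np.isin(subset, scheme.codes)]
    if subset.size == 0:
        raise ValueError("uncertain subset holds no classified pixels")
    full = full_map.labels if isinstance(full_map, LULCMap) else np.asarray(full_map)
    full = full.ravel()
    full = full[np.isin(full, scheme.codes)]
    rows = []
    for code, name in zip(scheme.codes, scheme.names):
        p_sub = 100.0 * (subset == code).sum() / subset.size
        p_full = 100.0 * (full == code).sum() / full.size if full.size else np.nan
        ratio = p_sub / p_full if p_full and np.isfinite(p_full) else np.nan
        rows.append(
            {
                "class": name,
                "subset_pct": p_sub,
                "map_pct": p_full,
                "ratio": ratio,
                "flagged": bool(np.isfinite(ratio) and ratio > flag_threshold),
            }
        )
    return pd.DataFrame(rows)


def cmp_accuracy_correlation(
    fused_probs: np.ndarray | ProbabilityCube,
    reference: np.ndarray,
    scheme: ClassScheme,
) -> tuple[float, float, pd.DataFrame]:
    """Correlate per-class mean CMP with producer's and user's accuracy.

    For each class, the mean fused maximum probability (CMP) is computed
    over the test samples *belonging* to the class (paired with PA) and
    over those *assigned* to it (paired with UA); the Pearson correlations
    of those means with the PA/UA vectors are returned along with the
    per-class table.  Requires at least 3 classes with defined accuracy;
    zero CMP variance yields NaN correlations.
    """
    probs = fused_probs.probs.T if isinstance(fused_probs, ProbabilityCube) else np.asarray(fused_probs)
    if probs.ndim != 2 or probs.shape[1] != scheme.n_classes:
        raise ValueError("fused probabilities must be (n_samples, n_classes)")
    ref = np.asarray(reference).ravel()
    if ref.size != probs.shape[0]:
        raise ValueError("reference length does not match probabilities")
    codes = np.asarray(scheme.codes)
    pred = codes[probs.argmax(axis=1)]
    cmp_val = probs.max(axis=1)
    report = accuracy_report(
        confusion_matrix(pred, ref, scheme, include_unclassified=False)
    )
    rows = []
    for j, (code, name) in enumerate(zip(scheme.codes, scheme.names)):
        in_ref = ref == code
        in_pred = pred == code
        rows.append(
            {
                "class": name,
                "mean_cmp_reference": float(cmp_val[in_ref].mean()) if in_ref.any() else np.nan,
                "mean_cmp_assigned": float(cmp_val[in_pred].mean()) if in_pred.any() else np.nan,
                "pa_pct": report.pa[j],
                "ua_pct": report.ua[j],
            }
        )
    table = pd.DataFrame(rows)

    def _corr(a: pd.Series, b: pd.Series) -> float:
        ok = a.notna() & b.notna()
        if ok.sum() < 3:
            raise ValueError("fewer than 3 classes with defined accuracy")
        av, bv = a[ok].to_numpy(), b[ok].to_numpy()
        if av.std() == 0 or bv.std() == 0:
            return float("nan")
        return float(np.corrcoef(av, bv)[0, 1])

    r_pa = _corr(table["mean_cmp_reference"], table["pa_pct"])
    r_ua = _corr(table["mean_cmp_assigned"], table["ua_pct"])
    return r_pa, r_ua, table


def cmp_histogram(
    cmp_values: np.ndarray,
    bin_width: float = 0.05,
    thresholds: tuple[float, ...] = (0.4, 0.5),
) -> pd.DataFrame:
    """Histogram of CMP over valid pixels plus above-threshold fractions.

    ``bin_width`` must divide 1 evenly.  The returned frame carries a
    ``frac_above_<t>`` attribute per threshold in ``DataFrame.attrs``.
    """
    vals = np.asarray(cmp_values, dtype=np.float64).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("empty CMP map")
    nbins = round(1.0 / bin_width)
    if abs(nbins * bin_width - 1.0) > 1e-9:
        raise ValueError("bin_width must evenly divide (0, 1]")
    edges = np.linspace(0.0, 1.0, nbins + 1)
    hist, _ = np.histogram(vals, bins=edges)
    df = pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "count": hist}
    )
    for t in thresholds:
        df.attrs[f"frac_above_{t:g}"] = float((vals > t).mean())
    return df
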