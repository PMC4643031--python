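"""Benchmark accuracy and change tables for validating the statistics code.

These fixtures come from a regional 9-class MODIS-based land-cover mapping
study of an agro-pastoral ecotone: test-set confusion matrices for the
random-forest, SVM and weighted-kNN classifiers and for their majority-vote
and Bayesian-average integrations (rows = predicted, columns = reference,
both in the legend order AGRI..WATR; the majority-vote matrix carries a
final unclassified row), and a decadal land-conversion matrix in km²
(rows = earlier date).  Together with their published summary statistics
they pin down the accuracy and change arithmetic end to end.
"""

from __future__ import annotations

import numpy as np

from .types import ConfusionMatrix, ConversionMatrix, default_scheme

__all__ = [
    "benchmark_confusion_matrix",
    "benchmark_summary_statistics",
    "benchmark_conversion_matrix",
    "BENCHMARK_NET_FLOWS",
]

# fmt: off
_RF = [
    [548,   5,  10,   0,   0,  19,   9,   2,   0],
    [  0,  52,   3,   0,   0,   0,   8,   0,   1],
    [  5,   3, 248,   6,   0,  11,  22,   7,   0],
    [  0,   0,  10, 184,   1,   0,   0,   0,   0],
    [  0,   0,   1,   0,  55,   0,   0,   0,   0],
    [ 26,   3,  17,   0,   0, 159,   4,   4,   1],
    [  0,   9,   9,   0,   0,   0,  35,   0,   0],
    [  4,   2,   1,   0,   0,   0,   2, 151,   4],
    [  1,   0,   0,   0,   0,   0,   0,   0,  38],
]

_SVM = [
    [555,   4,   8,   0,   0,  15,   6,   6,   0],
    [  2,  48,   1,   0,   0,   0,  10,   0,   1],
    [  3,   5, 264,  11,   0,   7,  17,   3,   1],
    [  0,   0,   6, 178,   0,   0,   0,   0,   0],
    [  0,   0,   1,   0,  55,   0,   0,   0,   0],
    [ 18,   4,  11,   1,   0, 166,   6,   2,   1],
    [  1,  11,   6,   0,   0,   1,  40,   0,   0],
    [  4,   1,   1,   0,   0,   0,   1, 153,   0],
    [  1,   1,   1,   0,   1,   0,   0,   0,  41],
]

_WKNN = [
    [547,   3,   5,   0,   0,  11,   7,   5,   0],
    [  2,  50,   3,   0,   0,   0,  10,   0,   0],
    [ 12,   6, 263,  11,   0,  16,  16,   7,   4],
    [  0,   0,   7, 179,   0,   1,   0,   0,   0],
    [  0,   0,   0,   0,  56,   0,   0,   0,   0],
    [ 19,   1,  11,   0,   0, 161,   4,   3,   1],
    [  1,  12,   9,   0,   0,   0,  43,   0,   0],
    [  2,   2,   1,   0,   0,   0,   0, 149,   3],
    [  1,   0,   0,   0,   0,   0,   0,   0,  36],
]

_MAJORITY = [
    [558,   2,   8,   0,   0,  11,   8,   4,   0],
    [  1,  49,   2,   0,   0,   0,  11,   0,   0],
    [  5,   3, 262,   8,   0,  10,  19,   5,   2],
    [  0,   0,   7, 182,   0,   0,   0,   0,   0],
    [  0,   0,   1,   0,  56,   0,   0,   0,   0],
    [ 14,   2,  11,   0,   0, 164,   2,   2,   1],
    [  0,  12,   6,   0,   0,   0,  37,   0,   0],
    [  3,   1,   0,   0,   0,   0,   0, 152,   1],
    [  1,   0,   0,   0,   0,   0,   0,   0,  38],
    [  2,   5,   2,   0,   0,   4,   3,   1,   2],  # unclassified
]

_BAYES = [
    [556,   3,   5,   0,   0,   9,   7,   6,   0],
    [  1,  53,   3,   0,   0,   0,  11,   0,   0],
    [  3,   2, 265,   8,   0,  11,  20,   3,   2],
    [  0,   0,   7, 182,   0,   0,   0,   0,   0],
    [  0,   0,   0,   0,  56,   0,   0,   0,   0],
    [ 17,   3,   9,   0,   0, 169,   5,   2,   1],
    [  1,  11,   9,   0,   0,   0,  37,   0,   0],
    [  5,   2,   1,   0,   0,   0,   0, 153,   1],
    [  1,   0,   0,   0,   0,   0,   0,   0,  40],
]

# published summary lines (percent): average PA, average UA, OA, kappa
_SUMMARIES = {
    "rf":       {"average_pa": 83.2, "average_ua": 86.5, "oa": 87.5, "kappa": 84.4},
    "svm":      {"average_pa": 84.9, "average_ua": 87.2, "oa": 89.3, "kappa": 86.7},
    "wknn":     {"average_pa": 83.9, "average_ua": 87.2, "oa": 88.3, "kappa": 85.5},
    "majority": {"average_pa": 84.1, "average_ua": 88.4, "oa": 89.2, "kappa": 86.5},
    "bayes":    {"average_pa": 85.7, "average_ua": 87.9, "oa": 89.9, "kappa": 87.5},
}

# decadal conversion matrix, km²; rows = earlier date; classes as listed.
_CONVERSION_CLASSES = ("AGRI", "BARE", "CLSH", "DBLF", "ENLF", "GRAS", "OPSH")
_CONVERSION = [
    [236821.0, 6421.0, 43901.0,  2583.0,  592.0, 60392.0, 4870.0],
    [  2225.0, 4670.0,  4810.0,     0.0,    0.0,  1824.0, 2219.0],
    [  8930.0,  303.0, 73201.0, 12497.0,  997.0, 16079.0, 2289.0],
    [   336.0,    0.1,  5985.0, 50959.0,  535.0,  1098.0,    0.8],
    [    14.0,    0.0,   314.0,   736.0, 1897.0,    10.0,    0.2],
    [ 34385.0,  479.0, 29696.0,  5219.0,  281.0, 56823.0, 1469.0],
    [  2674.0, 1671.0, 10794.0,     2.0,   11.0,  3218.0, 6296.0],
]
# fmt: on

#: Published net conversion flows (km², positive = net loss of the source
#: class to the targets). Two entries carry a 1 km² rounding inconsistency
#: against the matrix arithmetic in the original report.
BENCHMARK_NET_FLOWS = {
    ("AGRI", ("CLSH",)): 34971.0,
    ("AGRI", ("GRAS",)): 26007.0,
    ("AGRI", ("DBLF", "ENLF")): 2825.0,
    ("AGRI", ("BARE",)): 4196.0,
    ("AGRI", ("OPSH",)): 2195.0,  # matrix arithmetic gives 2196
    ("GRAS", ("CLSH",)): 13617.0,
    ("GRAS", ("DBLF", "ENLF")): 4392.0,
    ("OPSH", ("CLSH",)): 8505.0,
    ("OPSH", ("GRAS",)): 1749.0,
    ("CLSH", ("DBLF", "ENLF")): 7195.0,
    ("BARE", ("CLSH",)): 4507.0,
    ("BARE", ("GRAS",)): 1344.0,  # matrix arithmetic gives 1345
}

_MATRICES = {
    "rf": (_RF, False),
    "svm": (_SVM, False),
    "wknn": (_WKNN, False),
    "majority": (_MAJORITY, True),
    "bayes": (_BAYES, False),
}


def benchmark_confusion_matrix(which: str) -> ConfusionMatrix:
    """One of the benchmark confusion matrices.

    ``which`` is ``rf``, ``svm``, ``wknn``, ``majority`` or ``bayes``; the
    majority-vote matrix includes the unclassified predicted row.
    """
    try:
        counts, with_unce = _MATRICES[which]
    except KeyError:
        raise KeyError(
            f"unknown benchmark {which!r}; expected one of {sorted(_MATRICES)}"
        ) from None
    return ConfusionMatrix(
        np.asarray(counts, dtype=np.int64),
        default_scheme(),
        include_unclassified=with_unce,
    )


def benchmark_summary_statistics(which: str) -> dict[str, float]:
    """Published summary accuracies (percent) for one benchmark matrix."""
    return dict(_SUMMARIES[which])


def benchmark_conversion_matrix() -> ConversionMatrix:
    """The benchmark decadal conversion matrix (km²).

    Urban and water were absent from the published table; they remain as
    zero rows/columns so the matrix keeps the full 9-class shape.
    """
    scheme = default_scheme()
    m = scheme.n_classes
    areas = np.zeros((m, m))
    idx = [scheme.index_of(scheme.code_of(n)) for n in _CONVERSION_CLASSES]
    for i, ci in enumerate(idx):
        for j, cj in enumerate(idx):
            areas[ci, cj] = _CONVERSION[i][j]
    return ConversionMatrix(
        areas=areas, scheme=scheme, pixel_area_km2=0.0625, dates=("2003", "2013")
    )
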