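"""Posterior fusion of multiple classifiers.

Two integration schemes:

* **Bayesian averaging** — the fused membership probability of class *i* is
  the equally weighted mean of the K classifiers' probabilities,
  ``P(X∈C_i) = (1/K) Σ_k P_k(X∈C_i)``; the fused label is the argmax of the
  averaged vector and the per-pixel maximum (the class membership
  probability, CMP) is the confidence layer.
* **Majority vote** — a hard-label vote: the fused label is the class with
  the strictly largest vote count of at least 2; pixels where no two
  classifiers agree (or where the top count is tied) are left unclassified.
  The vote-count layer is the uncertainty map (K = full consensus,
  1 = no common vote).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .types import LULCMap, ProbabilityCube, VoteMap

log = logging.getLogger(__name__)

__all__ = [
    "bayesian_average",
    "argmax_label",
    "majority_vote",
    "cmp_map",
    "FusionResult",
    "fuse_bayesian",
    "fuse_majority",
]


@dataclass
class FusionResult:
    """Fused map plus the uncertainty layer of the chosen method."""

    fused_map: LULCMap
    fused_probs: ProbabilityCube | None = None  # Bayesian only
    vote_map: VoteMap | None = None  # majority only
    cmp: np.ndarray | None = None  # Bayesian only
    n_ties: int = 0


def _check_same_grids(shapes: Sequence[tuple], what: str) -> None:
    if len(set(shapes)) != 1:
        raise ValueError(f"{what} are on different grids: {sorted(set(shapes))}")


def bayesian_average(prob_cubes: Sequence[ProbabilityCube]) -> ProbabilityCube:
    """Equal-weight linear average of K probability cubes.

    Output is simplex-valid wherever every input is valid and NaN where any
    input is nodata.  Schemes and grids must match.
    """
    if len(prob_cubes) < 2:
        raise ValueError("Bayesian averaging needs at least 2 classifiers")
    schemes = {c.scheme.classes for c in prob_cubes}
    if len(schemes) != 1:
        raise ValueError("probability cubes use different class schemes")
    _check_same_grids([c.probs.shape for c in prob_cubes], "probability cubes")
    stack = np.stack([c.probs for c in prob_cubes])
    fused = stack.mean(axis=0)  # NaN in any input propagates
    out = ProbabilityCube(
        probs=fused,
        scheme=prob_cubes[0].scheme,
        source="fused",
        geotransform=prob_cubes[0].geotransform,
        crs=prob_cubes[0].crs,
    )
    out.validate()
    return out


def argmax_label(probs: ProbabilityCube) -> tuple[LULCMap, int]:
    """Hard label of maximal membership probability per pixel.

    Exact ties go to the lowest class code (the number of tied pixels is
    returned and logged); nodata pixels map to the scheme's nodata code.
    Sample-shaped cubes ``(class, n)`` are labelled as a 1×n map.
    """
    p = probs.probs
    if p.ndim == 2:
        p = p[:, None, :]
    valid = np.isfinite(p).all(axis=0)
    idx = np.argmax(np.where(np.isfinite(p), p, -np.inf), axis=0)
    codes = np.asarray(probs.scheme.codes)
    labels = np.where(valid, codes[idx], probs.scheme.nodata_code).astype(np.int64)
    pmax = np.max(np.where(np.isfinite(p), p, -np.inf), axis=0)
    n_max = (np.isclose(p, pmax[None], rtol=0.0, atol=0.0) & np.isfinite(p)).sum(axis=0)
    n_ties = int(((n_max > 1) & valid).sum())
    if n_ties:
        log.info("argmax_label: %d tied pixels resolved to the lowest code", n_ties)
    lulc = LULCMap(
        labels=labels if probs.probs.ndim == 3 else labels,
        scheme=probs.scheme,
        geotransform=probs.geotransform,
        crs=probs.crs,
    )
    return lulc, n_ties


def majority_vote(label_maps: Sequence[LULCMap]) -> tuple[LULCMap, VoteMap]:
    """Fuse K hard maps by strict plurality with a minimum of 2 votes.

    A pixel keeps the class with the single largest vote count when that
    count is at least 2; otherwise (no common vote, or a tie among top
    counts) it is unclassified and its vote count recorded as 1.  Nodata in
    any input makes the pixel nodata (vote count -1).
    """
    k = len(label_maps)
    if k < 2:
        raise ValueError("majority vote needs at least 2 classifiers")
    schemes = {m.scheme.classes for m in label_maps}
    if len(schemes) != 1:
        raise ValueError("label maps use different class schemes")
    _check_same_grids([m.labels.shape for m in label_maps], "label maps")
    scheme = label_maps[0].scheme
    stack = np.stack([m.labels for m in label_maps])  # (K, R, C)
    nodata = (stack == scheme.nodata_code).any(axis=0)
    codes = np.asarray(scheme.codes)
    counts = (stack[None] == codes[:, None, None, None]).sum(axis=1)  # (M, R, C)
    top = counts.max(axis=0)
    n_top = (counts == top[None]).sum(axis=0)
    winner_idx = counts.argmax(axis=0)
    decided = (top >= 2) & (n_top == 1)
    labels = np.where(decided, codes[winner_idx], scheme.unclassified_code)
    labels = np.where(nodata, scheme.nodata_code, labels).astype(np.int64)
    votes = np.where(decided, top, 1)
    votes = np.where(nodata, -1, votes)
    fused = LULCMap(
        labels=labels,
        scheme=scheme,
        geotransform=label_maps[0].geotransform,
        crs=label_maps[0].crs,
    )
    vm = VoteMap(counts=votes.astype(np.int64), k=k)
    vm.validate()
    return fused, vm


def cmp_map(fused_probs: ProbabilityCube) -> np.ndarray:
    """Per-pixel maximum fused probability (class membership probability)."""
    p = fused_probs.probs
    out = np.max(p, axis=0)
    out[~np.isfinite(p).all(axis=0)] = np.nan
    return out


def fuse_bayesian(prob_cubes: Sequence[ProbabilityCube]) -> FusionResult:
    """Bayesian-average fusion: fused probabilities, argmax map and CMP."""
    fused = bayesian_average(prob_cubes)
    lulc, n_ties = argmax_label(fused)
    return FusionResult(
        fused_map=lulc, fused_probs=fused, cmp=cmp_map(fused), n_ties=n_ties
    )


def fuse_majority(label_maps: Sequence[LULCMap]) -> FusionResult:
    """Majority-vote fusion: fused map plus vote-count uncertainty layer."""
    fused, votes = majority_vote(label_maps)
    return FusionResult(fused_map=fused, vote_map=votes)
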