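"""Desk-scale study protocols on simulated scenes.

These helpers run the full classification protocol — simulate a scene at
the default study conditions, sample homogeneous reference points, extract
C3 features, split 70/30 per class, train the selected backends, fuse — and
return the accuracy and uncertainty summaries.  They are the reusable
building blocks behind the replicated ensemble and phenology-recovery
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assess import accuracy_report, cmp_accuracy_correlation, confusion_matrix
from .classify import predict_proba, stratified_split, train_backend
from .features import (
    asymmetric_gaussian,
    assemble_features,
    evaluate_seasonal_model,
    extract_phenology,
    fit_seasonal_model,
    qa_to_weight,
)
from .fusion import fuse_bayesian, fuse_majority
from .synthetic import (
    default_scene_config,
    sample_reference_points,
    simulate_scene,
)
from .types import LULCMap, ProbabilityCube

__all__ = ["EnsembleTrial", "ensemble_trial", "phenology_recovery"]

#: Points per class so a 70% split yields 400 training points per class.
DEFAULT_POINTS_PER_CLASS = 572


@dataclass
class EnsembleTrial:
    """Held-out accuracies of one seeded ensemble run."""

    seed: int
    member_oa: dict[str, float]
    bayes_oa: float
    bayes_kappa: float
    vote_oa: float
    consensus_frac: float
    unclassified_frac: float
    cmp_frac_above_05: float
    r_pa: float
    r_ua: float
    n_test: int

    @property
    def mean_member_oa(self) -> float:
        return float(np.mean(list(self.member_oa.values())))


def ensemble_trial(
    seed: int,
    kinds: tuple[str, ...] = ("rf", "svm", "wknn"),
    n_per_class: int = DEFAULT_POINTS_PER_CLASS,
    shape: tuple[int, int] = (192, 192),
    combo: str = "C3",
    hyperparams: dict | None = None,
) -> EnsembleTrial:
    """One seeded run of the ensemble protocol at the study conditions.

    Simulates a default-condition scene (noise sd 0.02, cloud probability
    0.15), samples ``n_per_class`` homogeneous points per class, splits
    70/30, trains the backends on the training part and evaluates single
    and fused classifications on the held-out points.
    """
    cfg = default_scene_config(seed=seed, shape=shape)
    cube, dem, truth = simulate_scene(cfg)
    scheme = truth.scheme
    samples = sample_reference_points(truth, n_per_class, 3, seed=seed + 1)
    samples.features = assemble_features(
        cube, dem, combo, points=(samples.rows, samples.cols)
    )
    samples = stratified_split(samples, 0.7, seed=seed + 2)
    train, test = samples.split_part("train"), samples.split_part("test")
    hyperparams = hyperparams or {}
    codes = np.asarray(scheme.codes)

    member_oa: dict[str, float] = {}
    prob_cubes: list[ProbabilityCube] = []
    hard_maps: list[LULCMap] = []
    for kind in kinds:
        model = train_backend(
            kind, train, hyperparams=hyperparams.get(kind), seed=seed + 3,
            scheme=scheme,
        )
        probs = predict_proba(model, test.features, scheme=scheme)
        pred = codes[probs.argmax(axis=1)]
        rep = accuracy_report(
            confusion_matrix(pred, test.codes, scheme, include_unclassified=False)
        )
        member_oa[kind] = rep.oa
        prob_cubes.append(ProbabilityCube(probs.T, scheme, source=kind))
        hard_maps.append(LULCMap(pred[None, :], scheme))

    bayes = fuse_bayesian(prob_cubes)
    bayes_pred = bayes.fused_map.labels.ravel()
    bayes_rep = accuracy_report(
        confusion_matrix(bayes_pred, test.codes, scheme, include_unclassified=False)
    )
    vote = fuse_majority(hard_maps)
    vote_pred = vote.fused_map.labels.ravel()
    vote_rep = accuracy_report(
        confusion_matrix(vote_pred, test.codes, scheme, include_unclassified=True)
    )
    counts = vote.vote_map.counts.ravel()
    try:
        r_pa, r_ua, _ = cmp_accuracy_correlation(
            bayes.fused_probs.probs.T, test.codes, scheme
        )
    except ValueError:
        r_pa = r_ua = float("nan")
    cmp_vals = bayes.cmp.ravel()
    return EnsembleTrial(
        seed=seed,
        member_oa=member_oa,
        bayes_oa=bayes_rep.oa,
        bayes_kappa=bayes_rep.kappa,
        vote_oa=vote_rep.oa,
        consensus_frac=float((counts == len(kinds)).mean()),
        unclassified_frac=float((counts == 1).mean()),
        cmp_frac_above_05=float((cmp_vals > 0.5).mean()),
        r_pa=r_pa,
        r_ua=r_ua,
        n_test=len(test),
    )


def phenology_recovery(
    seed: int,
    class_names: tuple[str, ...] = ("AGRI", "DBLF", "GRAS"),
    n_pixels: int = 150,
    cloud_probability: float = 0.15,
) -> dict[str, dict[str, float]]:
    """Mean phenology-recovery errors per class on one simulated scene.

    Fits the QA-weighted upper envelope to the simulated NDVI series of
    ``n_pixels`` random pixels of each class and compares the extracted
    season start/mid/end (days) and amplitude (relative) against the
    metrics of the noiseless generating curve sampled daily.
    """
    cfg = default_scene_config(
        seed=seed, shape=(96, 96), cloud_probability=cloud_probability
    )
    cube, _, truth = simulate_scene(cfg)
    dates = cube.dates
    rng = np.random.default_rng(seed + 77)
    out: dict[str, dict[str, float]] = {}
    daily = np.arange(dates[0], dates[-1] + 1.0)
    for name in class_names:
        sig = cfg.signatures[name]
        truth_curve = asymmetric_gaussian(daily, sig.curve_params[None])[0]
        true_m = extract_phenology(truth_curve, daily)
        rr, cc = np.nonzero(truth.labels == truth.scheme.code_of(name))
        pick = rng.choice(rr.size, size=min(n_pixels, rr.size), replace=False)
        series = cube.band("ndvi")[:, rr[pick], cc[pick]].T
        qa = cube.band("qa")[:, rr[pick], cc[pick]].T
        params, _ = fit_seasonal_model(series, qa_to_weight(qa), dates)
        m = extract_phenology(evaluate_seasonal_model(params, daily), daily)
        errs = {}
        for field in ("start_doy", "mid_doy", "end_doy"):
            est = getattr(m, field)
            errs[field + "_mae_days"] = float(
                np.nanmean(np.abs(est - float(getattr(true_m, field)[0])))
            )
        true_amp = float(true_m.amplitude[0])
        errs["amplitude_rel_err"] = float(
            np.nanmean(np.abs(m.amplitude - true_amp)) / true_amp
        )
        out[name] = errs
    return out
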