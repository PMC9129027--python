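"""Mediation scans across candidate mediators, LOD scans, and ROC harnesses."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .comparators import lod_drop, lod_score, sobel_test
from .core import (GROUPS, EffectPriorSpec, MediationData, ModelPrior,
                   model_posterior, standardize_trait)

logger = logging.getLogger("medbayes")

#: Disjoint groups whose probabilities sum to 1 in a scan row ("mediation"
#: overlaps complete + partial and is reported on top).
DISJOINT_GROUPS = ("complete", "partial", "colocal", "other_non_mediation",
                   "reactive")


def mediation_scan(y, candidates, X, priors: EffectPriorSpec = None,
                   model_prior: ModelPrior = None, covariates=None,
                   weights=None, include_comparators: bool = False) -> pd.DataFrame:
    """Posterior model-group summaries for every candidate mediator.

    ``candidates`` is a DataFrame (columns = candidate ids) or a 2-D array of
    mediator columns sharing row alignment with y and X.  Each candidate is
    standardized independently and scored with :func:`model_posterior`;
    zero-variance candidates are skipped with a warning.  Rows are sorted by
    the summed complete + partial (mediation) log posterior odds, descending.
    With ``include_comparators`` the Sobel p-value (single-column X only) and
    the scaled LOD drop are appended per candidate.
    """
    priors = priors or EffectPriorSpec()
    model_prior = model_prior or ModelPrior.default()
    if isinstance(candidates, pd.DataFrame):
        ids = [str(c) for c in candidates.columns]
        cand = candidates.to_numpy(dtype=float)
    else:
        cand = np.asarray(candidates, dtype=float)
        if cand.ndim == 1:
            cand = cand[:, None]
        ids = [f"candidate_{j}" for j in range(cand.shape[1])]
    y = np.asarray(y, float).ravel()
    X = np.asarray(X, float)
    if cand.shape[0] != y.size:
        raise ValueError("candidates are not row-aligned with y")

    rows = []
    for j, cid in enumerate(ids):
        col = cand[:, j]
        if np.std(col, ddof=1) == 0:
            logger.warning("candidate %s has zero variance; skipped", cid)
            continue
        data = MediationData.from_arrays(y, col, X, Z_m=covariates,
                                         Z_y=covariates, w_m=weights, w_y=weights)
        result = model_posterior(data, priors, model_prior)
        row = {"candidate": cid}
        for g in DISJOINT_GROUPS + ("mediation",):
            row[f"p_{g}"] = result.group_probabilities[g]
            row[f"log_odds_{g}"] = result.group_log_odds[g]
        if include_comparators:
            if X.ndim == 1 or X.shape[1] == 1:
                row["sobel_p"] = sobel_test(y, col, X, covariates=covariates).p
            row["scaled_lod_drop"] = lod_drop(y, col, X,
                                              covariates=covariates).scaled_drop
        rows.append(row)

    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values("log_odds_mediation", ascending=False,
                                  kind="mergesort").reset_index(drop=True)
    return table


def qtl_lod_scan(y, loci, covariates=None) -> np.ndarray:
    """Fixed-effects LOD score of each locus design matrix for the trait."""
    y = np.asarray(y, float).ravel()
    lods = []
    for X in loci:
        X = np.asarray(X, float)
        if X.shape[0] != y.size:
            raise ValueError("locus design not aligned with trait")
        lods.append(lod_score(y, X, covariates=covariates))
    return np.asarray(lods)


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    tpr: float
    fpr: float


def roc_curves(scores_positive, scores_negative):
    """Empirical ROC curve and trapezoidal AUC from two score samples.

    Higher scores must indicate a more mediation-like call (negate p-values
    before passing them in).  The threshold sweep visits every pooled unique
    score, so ties are averaged and the AUC equals the Mann-Whitney U
    statistic divided by n_pos * n_neg.
    """
    pos = np.asarray(scores_positive, float).ravel()
    neg = np.asarray(scores_negative, float).ravel()
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be nonempty")
    if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(neg))):
        raise ValueError("non-finite scores")
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    points = [RocPoint(threshold=float("inf"), tpr=0.0, fpr=0.0)]
    for t in thresholds:
        points.append(RocPoint(threshold=float(t),
                               tpr=float(np.mean(pos >= t)),
                               fpr=float(np.mean(neg >= t))))
    fpr = np.array([p.fpr for p in points])
    tpr = np.array([p.tpr for p in points])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc
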