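"""Replicable simulation benchmarks: scenario grids, ROC and calibration runs.

These harnesses wire the simulator, the Bayesian model posterior and the
comparator tests together the way the benchmarking study is set up: balanced
bi-allelic variants, a grid of effect sizes on M and Y, optional fitting with
a tag variant in LD instead of the true variant, and ROC comparisons of
complete mediation against co-local generation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .comparators import lod_drop, sobel_test
from .core import EffectPriorSpec, MediationData, ModelPrior, model_posterior
from .scan import DISJOINT_GROUPS, roc_curves
from .simulate import (GenotypeDesign, SimulationSpec, make_genotypes,
                       make_tag_variant, simulate_mediation_triple)

def _cell_rng(seed, *path):
    # one independent, reproducible stream per (scenario, cell, rep); the
    # data stream does not depend on whether a tag variant is also drawn
    return np.random.default_rng([int(seed)] + [int(p) for p in path])


def simulate_cell(scenario: str, effect_m: float, effect_y: float, n: int,
                  seed, rep: int, scenario_idx: int = 0,
                  genotype: GenotypeDesign = None):
    """One replicate of a scenario cell: (X, labels, m, y)."""
    spec = SimulationSpec(model=scenario, n=n, effect_m=effect_m,
                          effect_y=effect_y, genotype=genotype or GenotypeDesign(),
                          seed=0)
    rng = _cell_rng(seed, scenario_idx, round(effect_m * 1000),
                    round(effect_y * 1000), rep)
    X, labels = make_genotypes(spec.genotype, n, rng)
    m, y = simulate_mediation_triple(spec, X, rng)
    return X, labels, m, y


def scenario_grid(scenarios, effects, n: int = 200, reps: int = 20,
                  seed: int = 0, tag_r: float = None,
                  priors: EffectPriorSpec = None,
                  model_prior: ModelPrior = None) -> pd.DataFrame:
    """Mean posterior mass per model group over an effect-size grid.

    With ``tag_r`` the fit uses a tag variant in LD at that correlation with
    the simulated variant instead of the variant itself; the underlying data
    streams are identical with and without the tag, so the two fits are
    paired replicate by replicate.
    """
    priors = priors or EffectPriorSpec()
    model_prior = model_prior or ModelPrior.default()
    rows = []
    for s_idx, scenario in enumerate(scenarios):
        for em in effects:
            for ey in effects:
                acc = {g: 0.0 for g in DISJOINT_GROUPS + ("mediation",)}
                for rep in range(reps):
                    X, labels, m, y = simulate_cell(scenario, em, ey, n, seed,
                                                    rep, s_idx)
                    if tag_r is not None:
                        tag_rng = _cell_rng(seed, s_idx, round(em * 1000),
                                            round(ey * 1000), rep, 999)
                        fit_X, _ = make_tag_variant(labels, target_r=tag_r,
                                                    rng=tag_rng)
                        fit_X = fit_X[:, None]
                    else:
                        fit_X = X
                    data = MediationData.from_arrays(y, m, fit_X)
                    result = model_posterior(data, priors, model_prior)
                    for g in acc:
                        acc[g] += result.group_probabilities[g]
                row = {"scenario": scenario, "effect_m": em, "effect_y": ey}
                row.update({f"p_{g}": acc[g] / reps for g in acc})
                rows.append(row)
    return pd.DataFrame(rows)


def roc_benchmark(n: int = 24, reps: int = 500, effect: float = 0.5,
                  seed: int = 0, priors: EffectPriorSpec = None,
                  model_prior: ModelPrior = None) -> dict:
    """AUCs for distinguishing complete mediation from co-local generation.

    Scores per replicate: the summed complete + partial posterior
    probability, the scaled LOD drop, and the negated Sobel and IV p-values.
    """
    from .comparators import iv_2sls

    priors = priors or EffectPriorSpec()
    model_prior = model_prior or ModelPrior.default()
    scores = {"posterior": {}, "lod_drop": {}, "sobel": {}, "iv": {}}
    for cls_idx, scenario in enumerate(("complete", "colocal")):
        post, ld, sob, iv = [], [], [], []
        for rep in range(reps):
            X, _, m, y = simulate_cell(scenario, effect, effect, n, seed, rep,
                                       cls_idx)
            data = MediationData.from_arrays(y, m, X)
            result = model_posterior(data, priors, model_prior)
            post.append(result.group_probabilities["mediation"])
            ld.append(lod_drop(y, m, X).scaled_drop)
            sob.append(-sobel_test(y, m, X).p)
            iv.append(-iv_2sls(y, m, X).p)
        key = "pos" if scenario == "complete" else "neg"
        scores["posterior"][key] = post
        scores["lod_drop"][key] = ld
        scores["sobel"][key] = sob
        scores["iv"][key] = iv
    return {name: roc_curves(s["pos"], s["neg"])[1]
            for name, s in scores.items()}


def sobel_rejection_rate(scenario: str = "y_only", n: int = 200,
                         reps: int = 2000, effect_m: float = 0.5,
                         effect_y: float = 0.5, tag_r: float = None,
                         alpha: float = 0.05, seed: int = 0) -> float:
    """Fraction of replicates where the Sobel test rejects at level alpha."""
    hits = 0
    for rep in range(reps):
        X, labels, m, y = simulate_cell(scenario, effect_m, effect_y, n, seed,
                                        rep)
        if tag_r is not None:
            tag_rng = _cell_rng(seed, 0, round(effect_m * 1000),
                                round(effect_y * 1000), rep, 999)
            X = make_tag_variant(labels, target_r=tag_r, rng=tag_rng)[0][:, None]
        hits += sobel_test(y, m, X).p < alpha
    return hits / reps
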