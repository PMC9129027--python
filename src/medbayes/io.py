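"""Tabular I/O, run configuration and the single-mediator pipeline.

Inputs are CSV/TSV matrices with a header row and an id column; genotype
dosage extraction from VCF/PLINK is upstream of this tool.  Files are aligned
by intersecting their row ids, with dropped ids logged, so y, m, X and
covariates may come from differently ordered sources.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (MODELS, EffectPriorSpec, MediationData, ModelPrior,
                   empirical_phi, model_posterior)

logger = logging.getLogger("medbayes")

FLOAT_FORMAT = "%.10g"


def read_matrix(path, sep: str = None, orientation: str = "rows") -> pd.DataFrame:
    """Numeric matrix from CSV/TSV with an id column.

    The delimiter is taken from the extension (.tsv/.txt -> tab, else comma)
    unless forced.  ``orientation="columns"`` transposes, for files storing
    individuals as columns.  Raises on duplicate or missing ids and on
    non-numeric cells.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "columns":
        df = df.T
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicated id(s): {sorted(set(map(str, dup)))}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from None
    df.index = df.index.map(str)
    return df


def write_matrix(df: pd.DataFrame, path, sep: str = "\t") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, float_format=FLOAT_FORMAT)


def align_ids(frames: list[pd.DataFrame], names: list[str] = None) -> list[pd.DataFrame]:
    """Restrict all frames to their common row ids (original order of the first)."""
    names = names or [f"matrix{i}" for i in range(len(frames))]
    common = frames[0].index
    for df in frames[1:]:
        common = common.intersection(df.index)
    if len(common) == 0:
        raise ValueError("no shared ids across input files")
    common = [i for i in frames[0].index if i in set(common)]
    for df, name in zip(frames, names):
        dropped = sorted(set(df.index) - set(common))
        if dropped:
            logger.warning("%s: dropped %d id(s) not shared by all inputs: %s",
                           name, len(dropped), dropped[:10])
    return [df.loc[common] for df in frames]


@dataclass
class RunConfig:
    """Configuration of a single-mediator (or scan) run."""

    y: str
    m: str
    x: str
    covar: str = None
    weights: str = None
    prior: str = "default"          # preset name or path to a 12-weight file
    phi: str = "1,1,1"              # comma triple or "empirical"
    kappa: float = None
    lamb: float = None
    tau_mu_sq: float = None
    tau_z_sq: float = None
    log_base: str = "e"
    seed: int = 0
    out_dir: str = "medbayes_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def model_prior(self) -> ModelPrior:
        if self.prior in ("default", "reduced", "expanded"):
            return ModelPrior.preset(self.prior)
        weights = np.loadtxt(self.prior, ndmin=1)
        if weights.size != len(MODELS):
            raise ValueError(f"prior weight file must contain {len(MODELS)} values")
        return ModelPrior(tuple(weights))

    def effect_priors(self, data: MediationData = None) -> EffectPriorSpec:
        kwargs = {}
        if self.kappa is not None:
            kwargs["kappa"] = (self.kappa, self.kappa)
        if self.lamb is not None:
            kwargs["lamb"] = (self.lamb, self.lamb)
        if self.tau_mu_sq is not None:
            kwargs["tau_mu_sq"] = (self.tau_mu_sq, self.tau_mu_sq)
        if self.tau_z_sq is not None:
            kwargs["tau_z_sq"] = (self.tau_z_sq, self.tau_z_sq)
        spec = EffectPriorSpec(**kwargs)
        if self.phi == "empirical":
            if data is None:
                raise ValueError("empirical phi requires data")
            return spec.with_phi(empirical_phi(data))
        return spec.with_phi(tuple(float(x) for x in self.phi.split(",")))

    def base(self) -> float:
        return {"e": math.e, "10": 10.0}[str(self.log_base)]


def load_mediation_data(config: RunConfig):
    """Read and align the y/m/X (and covariate, weight) matrices."""
    frames = [read_matrix(config.y), read_matrix(config.m), read_matrix(config.x)]
    names = ["y", "m", "x"]
    if config.covar:
        frames.append(read_matrix(config.covar))
        names.append("covar")
    if config.weights:
        frames.append(read_matrix(config.weights))
        names.append("weights")
    frames = align_ids(frames, names)
    y = frames[0].iloc[:, 0].to_numpy()
    m = frames[1].iloc[:, 0].to_numpy()
    X = frames[2].to_numpy()
    Z = frames[names.index("covar")].to_numpy() if config.covar else None
    w = frames[names.index("weights")].iloc[:, 0].to_numpy() if config.weights else None
    data = MediationData.from_arrays(y, m, X, Z_m=Z, Z_y=Z, w_m=w, w_y=w)
    return data, list(frames[0].index)


def run_mediation(config: RunConfig) -> dict:
    """Single-mediator pipeline: read, fit, and write result tables.

    Writes ``posterior.tsv`` (per-model log marginal likelihood, prior and
    posterior), ``groups.tsv`` (group probabilities and log posterior odds)
    and ``provenance.json`` (hyperparameters, seed, package version, N).
    Outputs are deterministic given the config.
    """
    data, ids = load_mediation_data(config)
    priors = config.effect_priors(data)
    model_prior = config.model_prior()
    result = model_posterior(data, priors, model_prior, log_base=config.base())

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    per_model = pd.DataFrame({
        "model": result.labels,
        "theta_a": [m.theta_a for m in MODELS],
        "theta_b": [str(m.theta_b) for m in MODELS],
        "theta_c": [m.theta_c for m in MODELS],
        "log_marginal_lik": result.log_marginal,
        "prior": np.exp(result.log_prior),
        "posterior": result.posterior,
    }).set_index("model")
    write_matrix(per_model, out / "posterior.tsv")
    groups = pd.DataFrame({
        "probability": result.group_probabilities,
        "log_posterior_odds": result.group_log_odds,
    })
    groups.index.name = "group"
    write_matrix(groups, out / "groups.tsv")
    provenance = {
        "package": "medbayes",
        "version": __version__,
        "n": data.n,
        "n_input_ids": len(ids),
        "seed": config.seed,
        "log_base": config.log_base,
        "model_prior": dict(zip([m.label for m in MODELS],
                                config.model_prior().normalized.tolist())),
        "effect_priors": {
            "kappa": priors.kappa, "lamb": priors.lamb,
            "tau_mu_sq": priors.tau_mu_sq, "tau_z_sq": priors.tau_z_sq,
            "phi_sq": priors.phi_sq,
        },
        "config": dataclasses.asdict(config),
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("run_mediation: N=%d, outputs in %s", data.n, out)
    return {"result": result, "out_dir": str(out)}
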