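"""End-to-end orchestration of the courtship analysis stages.

Runs: observation parsing -> per-male transition matrices -> variance
decomposition of the MMP score and the 25 transition phenotypes ->
noninitiator mixture comparison -> factor analysis of line means ->
optional line-means association scan; writes tab-separated outputs plus a
JSON run manifest recording the configuration hash and seeds so a rerun
with the same inputs is bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .assoc import LineMeansScan, filter_variants, read_genotypes
from .ethogram import export_dot, line_mean_table, phenotype_names, transition_table
from .factors import TransitionFactorModel
from .heritability import VarianceComponents, decompose_table
from .mixtures import ExponentialModel, TwoNormalMixture, compare_fits
from .observations import read_observations

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Serializable configuration for a full pipeline run."""

    observations: str
    outdir: str
    genotypes: str | None = None
    covariates: str | None = None
    T: int = 30
    strict: bool = True
    arcsin: bool = False
    alpha: float = 0.05
    n_tests_transitions: int = 25
    mixture_seed: int = 0
    mixture_tol: float = 1e-9
    mixture_var_floor: float = 1e-6
    n_factors: int | None = None
    min_minor_lines: int = 4
    suggestive_p: float = 1e-5
    exclude_noninitiators: bool = False
    dot_min_edge: float = 0.01
    extra: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = pathlib.Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns the run manifest (also written).

    Stage failures raise with the stage name; the assoc stage is skipped
    with a notice when no genotype file is configured.
    """
    out = pathlib.Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stages": {},
    }

    obs = read_observations(config.observations, T=config.T,
                            strict=config.strict)
    summary = obs.summary()
    summary.to_csv(out / "male_summary.tsv", sep="\t", index=False)
    manifest["stages"]["score"] = {"n_males": len(obs),
                                   "dropped": len(obs.dropped_males)}

    # noninitiator proportions are always computed on the full male set;
    # the exclusion switch only affects the downstream phenotypes
    props = obs.noninitiator_proportions()
    if config.exclude_noninitiators:
        from .observations import ObservationTable

        obs = ObservationTable(
            [m for m in obs if not m.noninitiator], T=config.T)
        summary = obs.summary()
        manifest["stages"]["score"]["n_after_noninitiator_exclusion"] = \
            len(obs)

    per_male = transition_table(obs)
    per_male.to_csv(out / "transitions_per_male.tsv", sep="\t")
    line_means = line_mean_table(per_male)
    line_means.to_csv(out / "transitions_line_means.tsv", sep="\t")
    export_dot(
        line_means.mean(axis=0).to_numpy().reshape(5, 5),
        out / "ethogram_mean.dot",
        min_edge=config.dot_min_edge,
    )
    manifest["stages"]["etho"] = {"n_lines": len(line_means)}

    # variance decomposition: MMP plus the 25 transition phenotypes
    mmp_res = VarianceComponents(
        summary["mmp"].to_numpy(), summary["line"].to_numpy(),
        summary["block"].to_numpy(), trait="MMP",
    ).fit()
    trans_df = per_male.reset_index()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vc = decompose_table(
            trans_df, phenotype_names(),
            arcsin=config.arcsin, alpha=config.alpha,
            n_tests=config.n_tests_transitions,
        )
    vc = pd.concat([pd.DataFrame([mmp_res.as_row()]).set_index("trait"), vc])
    vc.to_csv(out / "variance_components.tsv", sep="\t")
    manifest["stages"]["h2"] = {
        "n_traits": len(vc),
        "mmp_H2_pct": float(mmp_res.H2 * 100.0),
    }

    # noninitiator mixture
    props.to_csv(out / "noninitiator_proportions.tsv", sep="\t")
    mix_report: dict = {"n_lines": int(props.size)}
    try:
        fits = [
            ExponentialModel(props.to_numpy()).fit(),
            TwoNormalMixture(
                props.to_numpy(), var_floor=config.mixture_var_floor
            ).fit(seed=config.mixture_seed, tol=config.mixture_tol),
        ]
        ranking = compare_fits(fits)
        mix_report["ranking"] = ranking
        mix_report["fits"] = {
            f.model_name: {"params": f.params, "logL": f.loglik,
                           "AIC": f.aic, "converged": f.converged,
                           "n_iter": f.n_iter}
            for f in fits
        }
    except ValueError as exc:  # e.g. all-zero proportions
        mix_report["error"] = str(exc)
    (out / "mixture_fits.json").write_text(json.dumps(mix_report, indent=1))
    manifest["stages"]["mixture"] = {
        k: v for k, v in mix_report.items() if k != "fits"
    }

    # factor analysis
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fa = TransitionFactorModel(line_means).fit(n_factors=config.n_factors)
    lf = fa.loadings_frame()
    lf.columns = [
        f"{c} ({v:.2f})" for c, v in zip(lf.columns, fa.variance_explained)
    ]
    lf.to_csv(out / "factor_loadings.tsv", sep="\t")
    fa.scores().to_csv(out / "factor_scores.tsv", sep="\t")
    manifest["stages"]["fa"] = {
        "n_factors": fa.n_factors,
        "variance_explained": [float(v) for v in fa.variance_explained],
    }

    # association scan on the most heritable transition phenotype
    if config.genotypes:
        trans_only = vc.drop(index="MMP")
        top_trait = trans_only["H2_pct"].idxmax()
        pheno = line_means[top_trait]
        gm = filter_variants(read_genotypes(config.genotypes),
                             min_minor_lines=config.min_minor_lines)
        cov = None
        if config.covariates:
            cov = pd.read_csv(config.covariates, sep="\t", index_col=0)
        scan = LineMeansScan(pheno, gm, covariates=cov).fit()
        scan.table.to_csv(out / "assoc_results.tsv", sep="\t", index=False)
        scan.hits(alpha=config.alpha,
                  suggestive=config.suggestive_p).to_csv(
            out / "assoc_hits.tsv", sep="\t", index=False)
        scan.qq_points().to_csv(out / "assoc_qq.tsv", sep="\t", index=False)
        manifest["stages"]["assoc"] = {
            "phenotype": top_trait,
            "n_variants": int(len(scan.table)),
            "lambda_gc": scan.lambda_gc(),
        }
    else:
        manifest["stages"]["assoc"] = {"skipped": "no genotypes configured"}

    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=1, default=str))
    return manifest
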