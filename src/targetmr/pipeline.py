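"""End-to-end orchestration of the drug-target MR workflow.

Stages: simulate (optional) -> exposure GWAS in the discovery sample ->
metabolite and disease GWAS in the non-overlapping outcome sample ->
cis instrument selection against the reference sample -> disease MR per
target (with a 50-kb sensitivity pass) -> metabolome-wide screen with
per-target FDR -> cross-target concordance -> individual-level GRS strata.
Every stage writes plain-text tables into the output directory and the run
is summarised in a JSON manifest (config echo, seeds, per-stage row counts)
so reruns with the same config are bitwise identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .assoc import count_gwas_hits, gwas_scan_many
from .concordance import all_pairs, scatter_table
from .grs import GRSWeights, build_grs, strata_regression
from .instruments import DrugTargetDefinition, harmonise, select_instruments
from .mr import MRInput, ivw_correlated, orient, to_odds_ratio
from .screen import bh_fdr, run_screen, signatures_long_table
from .simulate import LocusSpec, PhenotypeModel, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "demo_config"]

MR_COLUMNS = [
    "target", "outcome", "method", "n_snps", "theta", "se",
    "ci_low", "ci_high", "p", "f_stat", "or", "or_low", "or_high",
]


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, loadable from a YAML file."""

    n_individuals: int
    seed: int
    loci: list[LocusSpec]
    model: PhenotypeModel
    targets: list[DrugTargetDefinition]
    fractions: dict[str, float] = field(
        default_factory=lambda: {"discovery": 0.45, "outcome": 0.45, "reference": 0.10}
    )
    window_kb: float = 100.0
    p_threshold: float = 1e-6
    r2_threshold: float = 0.1
    fdr_q: float = 0.05
    gwas_threshold: float = 5e-8
    sensitivity_50kb: bool = True
    random_effects: bool = False
    drop_palindromic: bool = False
    covariate_names: list[str] = field(default_factory=lambda: ["age", "sex", "fasting", "chip"])
    grs_covariates: list[str] = field(
        default_factory=lambda: ["age", "sex"] + [f"PC{k}" for k in range(1, 11)]
    )
    grs_strata: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"youngest": (40, 54), "oldest": (61, 71)}
    )
    baseline_target: str | None = None
    write_vcf: bool = True

    def __post_init__(self) -> None:
        for name, value in (("window_kb", self.window_kb), ("fdr_q", self.fdr_q)):
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if not (0 < self.p_threshold <= 1 and 0 < self.r2_threshold <= 1):
            raise ValueError("p_threshold and r2_threshold must lie in (0, 1]")
        for t in self.targets:
            t.window_kb = self.window_kb
            t.p_threshold = self.p_threshold
            t.r2_threshold = self.r2_threshold

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        raw = io.load_yaml(path)
        raw["loci"] = [LocusSpec(**d) for d in raw["loci"]]
        model = raw["model"]
        for key in ("metabolite_loadings", "disease_intercepts", "disease_log_odds_per_exposure"):
            if key in model and model[key] is not None:
                model[key] = np.asarray(model[key], float)
        for key in ("exposure_names", "metabolite_names", "disease_names"):
            if key in model:
                model[key] = tuple(model[key])
        raw["model"] = PhenotypeModel(**model)
        raw["targets"] = [DrugTargetDefinition(**d) for d in raw["targets"]]
        if "grs_strata" in raw:
            raw["grs_strata"] = {k: tuple(v) for k, v in raw["grs_strata"].items()}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["model"] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in asdict(self.model).items()
        }
        return json.loads(json.dumps(d, default=lambda o: list(o) if hasattr(o, "__iter__") else str(o)))


def demo_config(seed: int = 7) -> PipelineConfig:
    """A small but complete configuration (3 targets, 12 metabolite traits)."""
    from .study import multi_target_design  # design builders double as config factories

    loci, model, targets = multi_target_design(seed=seed, n_metabolites=12)
    return PipelineConfig(
        n_individuals=20_000, seed=seed, loci=loci, model=model, targets=targets
    )


def _disease_mr(config, targets, exposure_stats, disease_stats, ref_dosages, window_kb=None):
    rows = []
    estimates = {}
    instrument_sets = {}
    for target in targets:
        iset = select_instruments(
            exposure_stats[target.exposure_trait], target, ref_dosages, window_kb=window_kb
        )
        instrument_sets[target.target_name] = iset
        for disease, stats_ in disease_stats.items():
            table = harmonise(
                iset.variants, stats_, iset.variant_ids,
                drop_palindromic=config.drop_palindromic,
            )
            est = orient(
                ivw_correlated(
                    MRInput.from_harmonised(table, iset.ld),
                    random_effects=config.random_effects,
                ),
                target,
            )
            or_, or_lo, or_hi = to_odds_ratio(est)
            rows.append({
                "target": target.target_name, "outcome": disease, "method": est.method,
                "n_snps": est.n_instruments, "theta": est.theta, "se": est.se,
                "ci_low": est.ci_low, "ci_high": est.ci_high, "p": est.p_value,
                "f_stat": est.f_statistic, "or": or_, "or_low": or_lo, "or_high": or_hi,
            })
            estimates[(target.target_name, disease)] = est
    df = pd.DataFrame(rows, columns=MR_COLUMNS)
    # FDR family: the set of targets, separately per disease
    df["q"] = np.nan
    for disease in disease_stats:
        mask = df["outcome"] == disease
        q, _ = bh_fdr(df.loc[mask, "p"].clip(lower=1e-300).to_numpy(), alpha=config.fdr_q)
        df.loc[mask, "q"] = q
    return df, estimates, instrument_sets


def run_pipeline(config: PipelineConfig, out_dir: str) -> dict:
    """Execute every stage and return the manifest (also written as JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}}

    def stage(name: str, **counts):
        manifest["stages"][name] = counts
        logger.info("stage %s: %s", name, counts)

    cohort = simulate_cohort(
        config.loci, config.model, config.n_individuals, config.seed, fractions=config.fractions
    )
    io.write_cohort(cohort, out / "cohort", vcf_partition="reference" if config.write_vcf else None)
    truth = {"seed": config.seed, "n_individuals": config.n_individuals}
    io.dump_yaml({**truth, "model": config.to_dict()["model"]}, str(out / "cohort" / "truth.yaml"))
    stage("simulate", individuals=cohort.n_individuals, variants=len(cohort.variant_table))

    discovery = cohort.partition("discovery")
    outcome = cohort.partition("outcome")
    reference = cohort.partition("reference")

    exposures = list(config.model.exposure_names)
    metabolites = list(config.model.metabolite_names)
    diseases = list(config.model.disease_names)

    (out / "gwas").mkdir(exist_ok=True)
    exposure_stats = gwas_scan_many(discovery, exposures, config.covariate_names, family="linear")
    outcome_linear = gwas_scan_many(
        outcome, exposures + metabolites, config.covariate_names, family="linear"
    )
    disease_stats = gwas_scan_many(outcome, diseases, config.covariate_names, family="logistic")
    for name, st in {**exposure_stats, **outcome_linear, **disease_stats}.items():
        st.write_tsv(out / "gwas" / f"{name}.tsv")
    hits = {
        name: count_gwas_hits(st, threshold=config.gwas_threshold)
        for name, st in outcome_linear.items()
    }
    stage(
        "gwas",
        traits=len(exposure_stats) + len(outcome_linear) + len(disease_stats),
        rows=sum(len(s.records) for s in outcome_linear.values()),
        gwas_hits=int(sum(h for h, _ in hits.values())),
        gwas_loci=int(sum(l for _, l in hits.values())),
    )

    mr_df, disease_estimates, isets = _disease_mr(
        config, config.targets, exposure_stats, disease_stats, reference.dosages
    )
    (out / "instruments").mkdir(exist_ok=True)
    for name, iset in isets.items():
        v = iset.variants.copy()
        v.insert(0, "target", name)
        v.to_csv(out / "instruments" / f"{name}.tsv", sep="\t", index=False)
        iset.ld.write_tsv(out / "instruments" / f"{name}_ld.tsv")
    mr_df.to_csv(out / "mr_disease.tsv", sep="\t", index=False)
    stage("mr_disease", rows=len(mr_df), instruments=sum(len(i.variant_ids) for i in isets.values()))

    if config.sensitivity_50kb:
        mr50_df, _, isets50 = _disease_mr(
            config, config.targets, exposure_stats, disease_stats, reference.dosages, window_kb=50.0
        )
        mr50_df.to_csv(out / "mr_disease_50kb.tsv", sep="\t", index=False)
        subset_ok = all(
            set(isets50[n].variant_ids) <= set(isets[n].variant_ids) for n in isets50
        )
        stage("mr_disease_50kb", rows=len(mr50_df), subset_of_100kb=bool(subset_ok))

    signatures = {}
    if metabolites:
        met_stats = {m: outcome_linear[m] for m in metabolites}
        signatures = run_screen(
            config.targets, exposure_stats, met_stats, reference.dosages, fdr_q=config.fdr_q
        )
        (out / "screen").mkdir(exist_ok=True)
        for name, sig in signatures.items():
            sig.write_tsv(out / "screen" / f"{name}.tsv")
        long = signatures_long_table(signatures)
        long.to_csv(out / "screen" / "all_targets.tsv", sep="\t", index=False)
        stage("screen", rows=len(long), discoveries=int(long["discovery"].sum()))

    if signatures and len(signatures) >= 2 and diseases:
        baseline = config.baseline_target or config.targets[0].target_name
        d0 = diseases[0]
        disease_for_scaling = {
            name: disease_estimates[(name, d0)] for name in signatures
        }
        baseline_results, matrix = all_pairs(signatures, disease_for_scaling, baseline)
        (out / "concordance").mkdir(exist_ok=True)
        matrix.to_csv(out / "concordance" / "r2_matrix.tsv", sep="\t")
        pd.DataFrame([asdict(r) for r in baseline_results]).to_csv(
            out / "concordance" / "baseline_comparisons.tsv", sep="\t", index=False
        )
        for res in baseline_results:
            scatter_table(signatures[res.target_a], signatures[res.target_b]).to_csv(
                out / "concordance" / f"scatter_{res.target_a}_vs_{res.target_b}.tsv",
                sep="\t", index=False,
            )
        stage("concordance", pairs=len(baseline_results))

    grs_rows = []
    for target in config.targets:
        iset = isets[target.target_name]
        weights = GRSWeights(
            target_name=target.target_name,
            variant_ids=iset.variant_ids,
            weights=target.therapeutic_direction * iset.variants["BETA"].to_numpy(),
            effect_alleles=list(iset.variants["EA"]),
        )
        score = build_grs(outcome.dosages, weights)
        for pheno in exposures:
            results, z_diff = strata_regression(
                score, outcome.phenotypes[pheno], outcome.covariates,
                config.grs_covariates, config.grs_strata,
            )
            for res in results.values():
                grs_rows.append({
                    "target": target.target_name, "phenotype": pheno, "stratum": res.stratum,
                    "n": res.n, "beta": res.beta, "se": res.se, "p": res.p, "z_diff": z_diff,
                })
    grs_df = pd.DataFrame(grs_rows)
    grs_df.to_csv(out / "grs_strata.tsv", sep="\t", index=False)
    stage("grs", rows=len(grs_df))

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
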