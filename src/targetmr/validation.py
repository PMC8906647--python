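"""Replicated end-to-end validation experiments on synthetic cohorts.

Each helper runs the real pipeline stages (simulate -> GWAS -> instrument
selection -> harmonisation -> correlated-instrument IVW) on a fresh seeded
cohort and returns the quantities a calibration study needs: the causal
estimate and its SE for parameter-recovery and type-I-error studies, the
false-discovery proportion of a global-null metabolome screen, same- and
cross-pathway signature concordance, and the GRS-versus-IVW cross-method
comparison. The experiment code lives here so the test suite and the
reproduction script exercise the identical path.
"""

from __future__ import annotations

import numpy as np

from .assoc import gwas_scan, gwas_scan_many
from .grs import GRSWeights, build_grs, strata_regression
from .instruments import harmonise, select_instruments
from .mr import MREstimate, MRInput, ivw_correlated, orient
from .screen import screen_target
from .study import multi_target_study, single_locus_study

__all__ = [
    "single_target_replicate",
    "fdr_null_replicate",
    "concordance_run",
    "grs_vs_ivw",
]

COVARIATES = ["age", "sex", "fasting", "chip"]


def single_target_replicate(
    seed: int,
    n_individuals: int = 50_000,
    theta: float = -0.25,
) -> MREstimate:
    """One full two-sample MR replicate for a single-locus cohort.

    Returns the raw (unoriented) correlated-instrument IVW estimate of the
    disease log-odds per 1 SD higher exposure; the cohort's true value is
    ``theta``.
    """
    cohort, target, _, _ = single_locus_study(
        n_individuals=n_individuals, seed=seed, theta=theta
    )
    discovery = cohort.partition("discovery")
    outcome = cohort.partition("outcome")
    reference = cohort.partition("reference")
    exposure_stats = gwas_scan(discovery, target.exposure_trait, COVARIATES)
    disease_stats = gwas_scan(outcome, "CAD", COVARIATES, family="logistic")
    iset = select_instruments(exposure_stats, target, reference.dosages)
    table = harmonise(iset.variants, disease_stats, iset.variant_ids)
    return ivw_correlated(MRInput.from_harmonised(table, iset.ld))


def fdr_null_replicate(
    seed: int,
    n_individuals: int = 50_000,
    n_traits: int = 200,
    fdr_q: float = 0.05,
) -> tuple[int, float]:
    """Screen one target against a global-null metabolome.

    All metabolite loadings are zero, so every discovery is false; returns
    ``(n_discoveries, false_discovery_proportion)`` for the target's FDR
    family (FDP is 0 when nothing is discovered).
    """
    cohort, targets, _, model = multi_target_study(
        n_individuals=n_individuals, seed=seed, n_metabolites=n_traits, null_metabolome=True
    )
    target = targets[0]
    discovery = cohort.partition("discovery")
    outcome = cohort.partition("outcome")
    reference = cohort.partition("reference")
    exposure_stats = gwas_scan(discovery, target.exposure_trait, COVARIATES)
    met_stats = gwas_scan_many(outcome, list(model.metabolite_names), COVARIATES)
    iset = select_instruments(exposure_stats, target, reference.dosages)
    sig = screen_target(iset, met_stats, fdr_q=fdr_q)
    n_disc = int(sig.rows["discovery"].sum())
    return n_disc, (1.0 if n_disc > 0 else 0.0)


def _signatures_and_disease(cohort, targets, model, fdr_q=0.05):
    discovery = cohort.partition("discovery")
    outcome = cohort.partition("outcome")
    reference = cohort.partition("reference")
    exposure_stats = gwas_scan_many(discovery, list(model.exposure_names), COVARIATES)
    met_stats = gwas_scan_many(outcome, list(model.metabolite_names), COVARIATES)
    disease_stats = gwas_scan(outcome, "CAD", COVARIATES, family="logistic")
    signatures, disease_estimates = {}, {}
    for target in targets:
        iset = select_instruments(
            exposure_stats[target.exposure_trait], target, reference.dosages
        )
        signatures[target.target_name] = screen_target(iset, met_stats, fdr_q=fdr_q)
        table = harmonise(iset.variants, disease_stats, iset.variant_ids)
        disease_estimates[target.target_name] = orient(
            ivw_correlated(MRInput.from_harmonised(table, iset.ld)), target
        )
    return signatures, disease_estimates


def concordance_run(
    seed: int,
    n_individuals: int = 50_000,
    n_traits: int = 60,
) -> tuple[float, float]:
    """Same-pathway and cross-pathway signature r^2 on one cohort.

    GENE1 and GENE2 instrument the same (LDL-like) exposure; GENE3 the
    TG-like one. Returns (r2 same-pathway, r2 cross-pathway) of the scaled
    signatures.
    """
    from .concordance import pairwise_r2, scale_by_disease_effect

    cohort, targets, _, model = multi_target_study(
        n_individuals=n_individuals, seed=seed, n_metabolites=n_traits
    )
    signatures, disease = _signatures_and_disease(cohort, targets, model)
    scaled = {
        name: scale_by_disease_effect(sig, disease[name]) for name, sig in signatures.items()
    }
    r2_same = pairwise_r2(scaled["GENE1"], scaled["GENE2"]).r_squared
    r2_cross = pairwise_r2(scaled["GENE1"], scaled["GENE3"]).r_squared
    return r2_same, r2_cross


def grs_vs_ivw(
    seed: int,
    n_individuals: int = 50_000,
    trait: str = "met000",
) -> tuple[float, float, float]:
    """Cross-method check: summary-level IVW vs individual-level GRS ratio.

    The IVW estimate of the GENE1 effect on ``trait`` (per 1 SD higher
    exposure) is compared with the individual-level ratio of
    covariate-adjusted slopes, score -> trait over score -> exposure, in the
    non-overlapping outcome sample. Returns (theta_ivw, se_ivw, theta_grs).
    """
    cohort, targets, _, model = multi_target_study(
        n_individuals=n_individuals, seed=seed, n_metabolites=4
    )
    target = targets[0]
    discovery = cohort.partition("discovery")
    outcome = cohort.partition("outcome")
    reference = cohort.partition("reference")
    exposure_stats = gwas_scan(discovery, target.exposure_trait, COVARIATES)
    trait_stats = gwas_scan(outcome, trait, COVARIATES)
    iset = select_instruments(exposure_stats, target, reference.dosages)
    table = harmonise(iset.variants, trait_stats, iset.variant_ids)
    est = ivw_correlated(MRInput.from_harmonised(table, iset.ld))

    weights = GRSWeights(
        target_name=target.target_name,
        variant_ids=iset.variant_ids,
        weights=iset.variants["BETA"].to_numpy(),
        effect_alleles=list(iset.variants["EA"]),
    )
    score = build_grs(outcome.dosages, weights)
    strata = {"all": (-np.inf, np.inf)}
    covars = ["age", "sex"] + [f"PC{k}" for k in range(1, 11)]
    trait_fit, _ = strata_regression(
        score, outcome.phenotypes[trait], outcome.covariates, covars, strata
    )
    expo_fit, _ = strata_regression(
        score, outcome.phenotypes[target.exposure_trait], outcome.covariates, covars, strata
    )
    theta_grs = trait_fit["all"].beta / expo_fit["all"].beta
    return est.theta, est.se, float(theta_grs)
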