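"""Canonical synthetic study designs.

These builders fix the conditions under which the pipeline is exercised and
validated: locus architecture (30 variants per locus, AR(1) latent LD with
decay 0.6, a handful of causal variants explaining ~2% of exposure variance,
the scale of a strong lipid locus), unit-variance exposures, a metabolite
panel with pathway-shared loadings, and logistic disease outcomes at
realistic prevalence. Sample size defaults to 50,000 individuals split
45% / 45% / 10% into discovery (instrument GWAS), outcome (metabolite and
disease GWAS) and reference (LD panel) samples.
"""

from __future__ import annotations

import numpy as np

from .instruments import DrugTargetDefinition
from .simulate import CohortData, LocusSpec, PhenotypeModel, simulate_cohort

__all__ = [
    "single_locus_study",
    "multi_target_design",
    "multi_target_study",
    "DEFAULT_FRACTIONS",
]

DEFAULT_FRACTIONS = {"discovery": 0.45, "outcome": 0.45, "reference": 0.10}

# one strong lipid-like locus: ~2% of exposure variance across 3 causal variants
_CAUSAL_IDX = (4, 14, 24)
_CAUSAL_EFF = (0.14, -0.12, 0.10)


def _locus(locus_id: str, chrom: str, exposure: str, n_variants: int = 30,
           ld_decay_rho: float = 0.6) -> LocusSpec:
    return LocusSpec(
        locus_id=locus_id,
        chromosome=chrom,
        start_bp=1_000_000,
        end_bp=1_000_000 + (n_variants - 1) * 2_000,
        n_variants=n_variants,
        maf_range=(0.1, 0.5),
        ld_decay_rho=ld_decay_rho,
        causal_indices=_CAUSAL_IDX,
        causal_effects=_CAUSAL_EFF,
        exposure_name=exposure,
    )


def _target_for(spec: LocusSpec, direction: int = -1, **kwargs) -> DrugTargetDefinition:
    return DrugTargetDefinition(
        target_name=spec.locus_id,
        chromosome=spec.chromosome,
        gene_start=spec.start_bp,
        gene_end=spec.end_bp,
        exposure_trait=spec.exposure_name,
        therapeutic_direction=direction,
        **kwargs,
    )


def single_locus_study(
    n_individuals: int = 50_000,
    seed: int = 0,
    theta: float = -0.25,
    disease_intercept: float = -1.5,
    n_variants: int = 30,
    ld_decay_rho: float = 0.6,
    fractions: dict[str, float] | None = None,
) -> tuple[CohortData, DrugTargetDefinition, LocusSpec, PhenotypeModel]:
    """One locus, one exposure, one disease with known effect ``theta``.

    ``theta`` is the true disease log-odds per 1 SD of the exposure; the
    default intercept gives roughly 20% prevalence. Setting ``theta=0``
    severs the exposure-outcome path for type-I-error studies.
    """
    spec = _locus("GENE1", "1", "LDL", n_variants=n_variants, ld_decay_rho=ld_decay_rho)
    model = PhenotypeModel(
        exposure_names=("LDL",),
        disease_names=("CAD",),
        disease_intercepts=np.array([disease_intercept]),
        disease_log_odds_per_exposure=np.array([[theta]]),
    )
    cohort = simulate_cohort(
        [spec], model, n_individuals, seed, fractions=fractions or DEFAULT_FRACTIONS
    )
    return cohort, _target_for(spec), spec, model


def multi_target_design(
    seed: int = 0,
    n_metabolites: int = 40,
    metabolite_loading_sd: float = 0.5,
    null_metabolome: bool = False,
    disease_theta: tuple[float, float] = (0.35, 0.25),
    disease_intercept: float = -2.0,
) -> tuple[list[LocusSpec], PhenotypeModel, list[DrugTargetDefinition]]:
    """Design for three drug targets on two exposure pathways.

    GENE1 and GENE2 both act through the LDL-like exposure (a same-pathway
    pair, like two LDL-lowering drug targets); GENE3 acts through the
    TG-like exposure (cross-pathway relative to the first two). Metabolite
    loadings on the two exposures are independent draws of SD
    ``metabolite_loading_sd`` (zero when ``null_metabolome`` for FDR
    calibration), and the CAD outcome depends on both exposures through
    ``disease_theta`` (log-odds per SD of higher LDL/TG, both harmful).
    """
    specs = [
        _locus("GENE1", "1", "LDL"),
        _locus("GENE2", "2", "LDL"),
        _locus("GENE3", "3", "TG"),
    ]
    rng = np.random.default_rng(np.random.SeedSequence((seed, 915)).generate_state(1)[0])
    names = tuple(f"met{t:03d}" for t in range(n_metabolites))
    loadings = (
        np.zeros((n_metabolites, 2))
        if null_metabolome
        else rng.normal(0.0, metabolite_loading_sd, size=(n_metabolites, 2))
    )
    model = PhenotypeModel(
        exposure_names=("LDL", "TG"),
        metabolite_names=names,
        metabolite_loadings=loadings,
        metabolite_noise_sd=1.0,
        disease_names=("CAD",),
        disease_intercepts=np.array([disease_intercept]),
        disease_log_odds_per_exposure=np.array([list(disease_theta)]),
    )
    targets = [_target_for(s) for s in specs]
    return specs, model, targets


def multi_target_study(
    n_individuals: int = 50_000,
    seed: int = 0,
    fractions: dict[str, float] | None = None,
    **design_kwargs,
) -> tuple[CohortData, list[DrugTargetDefinition], list[LocusSpec], PhenotypeModel]:
    """Simulate a cohort under the three-target, two-pathway design."""
    specs, model, targets = multi_target_design(seed=seed, **design_kwargs)
    cohort = simulate_cohort(
        specs, model, n_individuals, seed, fractions=fractions or DEFAULT_FRACTIONS
    )
    return cohort, targets, specs, model
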