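"""Synthetic two-sample cohort generator with known ground truth.

Simulates genotype dosages with autoregressive linkage disequilibrium,
lipoprotein-lipid exposures driven by locus-specific variant effects, a
metabolite panel with pathway-shared loadings on those exposures, covariates,
and binary disease outcomes generated from the exposures through a logistic
model. The cohort is split into non-overlapping discovery / outcome /
reference samples so that instrument discovery, outcome association, and LD
estimation never share individuals (the two-sample design).

The generative model
--------------------
Each locus carries ``n_variants`` biallelic variants. Per haplotype, a latent
standard-normal vector follows an AR(1) process with correlation
``ld_decay_rho**|i-j|`` between variants *i* and *j*; the effect allele is
carried where the latent value falls below the per-variant MAF quantile.
Dosages are the sum of two independent haplotypes, so Hardy-Weinberg
proportions hold by construction and the latent pairwise correlation has the
closed form ``rho**|i-j|`` used by the tests.

Exposures are ``E = (sum_j gamma_j (G_j - 2 p_j) + eps) / s`` where *s* is the
model-implied standard deviation computed analytically from the effect sizes,
allele frequencies and latent LD, so each exposure has unit variance in
expectation and downstream causal effects are expressed exactly per 1 SD.

Metabolites are linear in the exposures plus optional direct (pleiotropic)
variant effects plus independent noise; diseases are Bernoulli draws from a
logistic model in the exposures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LocusSpec",
    "PhenotypeModel",
    "CohortData",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_covariates",
    "simulate_cohort",
    "split_cohort",
    "latent_ld_matrix",
    "dosage_covariance",
]


@dataclass
class LocusSpec:
    """Definition of one simulated locus.

    ``causal_effects`` are per-allele effects (gamma, in raw exposure SD
    units before standardisation) of the variants listed in
    ``causal_indices`` on the exposure named ``exposure_name``.
    """

    locus_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_variants: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_decay_rho: float = 0.0
    causal_indices: tuple[int, ...] = ()
    causal_effects: tuple[float, ...] = ()
    exposure_name: str = "exposure"

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError(f"n_variants must be >= 1, got {self.n_variants}")
        if self.end_bp - self.start_bp + 1 < self.n_variants:
            raise ValueError(
                f"locus {self.locus_id}: region [{self.start_bp}, {self.end_bp}] "
                f"cannot hold {self.n_variants} distinct positions"
            )
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(
                f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range}"
            )
        if not (0.0 <= self.ld_decay_rho < 1.0):
            raise ValueError(f"ld_decay_rho must be in [0, 1), got {self.ld_decay_rho}")
        if len(self.causal_indices) != len(self.causal_effects):
            raise ValueError("causal_indices and causal_effects must have equal length")
        if any(j < 0 or j >= self.n_variants for j in self.causal_indices):
            raise ValueError("causal_indices out of range [0, n_variants)")

    @property
    def positions(self) -> np.ndarray:
        pos = np.linspace(self.start_bp, self.end_bp, self.n_variants)
        return np.round(pos).astype(np.int64)

    @property
    def variant_ids(self) -> list[str]:
        return [f"{self.locus_id}_v{j}" for j in range(self.n_variants)]


@dataclass
class PhenotypeModel:
    """Ground-truth phenotype model shared by all loci.

    ``metabolite_loadings`` has shape (n_metabolites, n_exposures) and
    ``disease_log_odds_per_exposure`` has shape (n_diseases, n_exposures);
    the latter holds the causal effects theta (log-odds per SD of exposure)
    that mendelian-randomisation estimation should recover.
    """

    exposure_names: tuple[str, ...]
    metabolite_names: tuple[str, ...] = ()
    metabolite_loadings: np.ndarray | None = None
    metabolite_noise_sd: np.ndarray | float = 1.0
    disease_names: tuple[str, ...] = ()
    disease_intercepts: np.ndarray | None = None
    disease_log_odds_per_exposure: np.ndarray | None = None
    exposure_noise_sd: np.ndarray | float = 1.0
    pleiotropy_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    confounding_strength: float = 0.0

    def __post_init__(self) -> None:
        k = len(self.exposure_names)
        m, d = len(self.metabolite_names), len(self.disease_names)
        if m:
            self.metabolite_loadings = np.atleast_2d(np.asarray(self.metabolite_loadings, float))
            if self.metabolite_loadings.shape != (m, k):
                raise ValueError(
                    f"metabolite_loadings shape {self.metabolite_loadings.shape} "
                    f"!= (n_metabolites={m}, n_exposures={k})"
                )
            self.metabolite_noise_sd = np.broadcast_to(
                np.asarray(self.metabolite_noise_sd, float), (m,)
            ).copy()
            if np.any(self.metabolite_noise_sd <= 0):
                raise ValueError("metabolite_noise_sd must be > 0")
        if d:
            self.disease_intercepts = np.broadcast_to(
                np.asarray(self.disease_intercepts, float), (d,)
            ).copy()
            self.disease_log_odds_per_exposure = np.atleast_2d(
                np.asarray(self.disease_log_odds_per_exposure, float)
            )
            if self.disease_log_odds_per_exposure.shape != (d, k):
                raise ValueError(
                    f"disease_log_odds_per_exposure shape "
                    f"{self.disease_log_odds_per_exposure.shape} != ({d}, {k})"
                )
        self.exposure_noise_sd = np.broadcast_to(
            np.asarray(self.exposure_noise_sd, float), (k,)
        ).copy()
        if np.any(self.exposure_noise_sd <= 0):
            raise ValueError("exposure_noise_sd must be > 0")


@dataclass
class CohortData:
    """Individual-level simulated data plus partition labels."""

    dosages: pd.DataFrame  # individuals x variants, values in {0,1,2}
    variant_table: pd.DataFrame  # SNP CHR POS EA NEA EAF
    phenotypes: pd.DataFrame
    covariates: pd.DataFrame
    sample_labels: pd.Series  # partition tag per individual

    @property
    def n_individuals(self) -> int:
        return len(self.dosages)

    def partition(self, label: str) -> "CohortData":
        """Return the sub-cohort carrying one partition tag."""
        mask = (self.sample_labels == label).to_numpy()
        if not mask.any():
            raise ValueError(f"no individuals carry partition label {label!r}")
        return CohortData(
            dosages=self.dosages.loc[mask],
            variant_table=self.variant_table,
            phenotypes=self.phenotypes.loc[mask],
            covariates=self.covariates.loc[mask],
            sample_labels=self.sample_labels.loc[mask],
        )


def latent_ld_matrix(spec: LocusSpec) -> np.ndarray:
    """Closed-form AR(1) correlation rho^|i-j| of the latent haplotype field."""
    idx = np.arange(spec.n_variants)
    return spec.ld_decay_rho ** np.abs(idx[:, None] - idx[None, :])


def _haplotypes(spec: LocusSpec, thresholds: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """One allele matrix (n x m) from a latent AR(1) Gaussian field."""
    m = spec.n_variants
    rho = spec.ld_decay_rho
    z = np.empty((n, m))
    eps = rng.standard_normal((n, m))
    z[:, 0] = eps[:, 0]
    innov_sd = np.sqrt(1.0 - rho * rho)
    for j in range(1, m):
        z[:, j] = rho * z[:, j - 1] + innov_sd * eps[:, j]
    return (z < thresholds).astype(np.int8)


def simulate_genotypes(
    spec: LocusSpec, n_individuals: int, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate dosages for one locus.

    Returns ``(dosages, variant_table)`` where dosages is an
    individuals x variants DataFrame with values in {0, 1, 2} and the
    variant table carries ``SNP CHR POS EA NEA EAF`` (EAF is the specified
    effect-allele frequency, not the realised one). Deterministic given
    ``seed``.
    """
    if n_individuals < 2:
        raise ValueError(f"n_individuals must be >= 2, got {n_individuals}")
    rng = np.random.default_rng(seed)
    lo, hi = spec.maf_range
    mafs = rng.uniform(lo, hi, size=spec.n_variants)
    thresholds = stats.norm.ppf(mafs)
    h1 = _haplotypes(spec, thresholds, n_individuals, rng)
    h2 = _haplotypes(spec, thresholds, n_individuals, rng)
    dosages = pd.DataFrame(h1 + h2, columns=spec.variant_ids)
    variant_table = pd.DataFrame(
        {
            "SNP": spec.variant_ids,
            "CHR": spec.chromosome,
            "POS": spec.positions,
            "EA": "A",
            "NEA": "G",
            "EAF": mafs,
        }
    )
    return dosages, variant_table


def dosage_covariance(spec: LocusSpec, mafs: np.ndarray) -> np.ndarray:
    """Analytic covariance of the dosage vector implied by the latent model.

    Per haplotype, Cov(allele_i, allele_j) = Phi2(t_i, t_j; rho^|i-j|) -
    p_i p_j with t = Phi^{-1}(p); the dosage covariance is twice that
    (independent haplotypes).
    """
    m = spec.n_variants
    t = stats.norm.ppf(mafs)
    cov = np.empty((m, m))
    for i in range(m):
        cov[i, i] = 2.0 * mafs[i] * (1.0 - mafs[i])
        for j in range(i + 1, m):
            r = spec.ld_decay_rho ** (j - i)
            if r == 0.0:
                joint = mafs[i] * mafs[j]
            else:
                joint = stats.multivariate_normal(
                    mean=[0.0, 0.0], cov=[[1.0, r], [r, 1.0]]
                ).cdf([t[i], t[j]])
            cov[i, j] = cov[j, i] = 2.0 * (joint - mafs[i] * mafs[j])
    return cov


def exposure_sd(
    specs: list[LocusSpec], model: PhenotypeModel, variant_table: pd.DataFrame
) -> dict[str, float]:
    """Model-implied SD of each raw exposure (genetic + noise variance)."""
    eaf = variant_table.set_index("SNP")["EAF"]
    genetic_var = {name: 0.0 for name in model.exposure_names}
    for spec in specs:
        if not spec.causal_indices:
            continue
        idx = np.asarray(spec.causal_indices)
        sub = LocusSpec(
            locus_id=spec.locus_id,
            chromosome=spec.chromosome,
            start_bp=spec.start_bp,
            end_bp=spec.end_bp,
            n_variants=spec.n_variants,
            maf_range=spec.maf_range,
            ld_decay_rho=spec.ld_decay_rho,
        )
        mafs = eaf.loc[spec.variant_ids].to_numpy()
        cov = dosage_covariance(sub, mafs)[np.ix_(idx, idx)]
        gamma = np.asarray(spec.causal_effects, float)
        genetic_var[spec.exposure_name] = genetic_var.get(spec.exposure_name, 0.0) + float(
            gamma @ cov @ gamma
        )
    noise = dict(zip(model.exposure_names, np.atleast_1d(model.exposure_noise_sd)))
    return {
        name: float(np.sqrt(genetic_var.get(name, 0.0) + noise[name] ** 2))
        for name in model.exposure_names
    }


def simulate_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Age, sex, fasting time, genotyping chip and 10 principal components."""
    cov = {
        "age": rng.integers(40, 72, size=n).astype(float),
        "sex": rng.integers(0, 2, size=n).astype(float),
        "fasting": rng.uniform(0.0, 12.0, size=n),
        "chip": rng.integers(0, 2, size=n).astype(float),
    }
    for k in range(1, 11):
        cov[f"PC{k}"] = rng.standard_normal(n)
    return pd.DataFrame(cov)


def simulate_phenotypes(
    dosages: pd.DataFrame,
    variant_table: pd.DataFrame,
    specs: list[LocusSpec],
    model: PhenotypeModel,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate exposures, metabolites, diseases and covariates.

    Returns ``(phenotypes, covariates)``. Exposures have unit variance in
    expectation (analytic standardisation), so the disease log-odds
    coefficients of the model are exactly per 1 SD of exposure.
    """
    for spec in specs:
        missing = [v for v in spec.variant_ids if v not in dosages.columns]
        if missing:
            raise ValueError(f"genotypes missing variants for locus {spec.locus_id}: {missing[:3]}")
    rng = np.random.default_rng(seed)
    n = len(dosages)
    k = len(model.exposure_names)
    eaf = variant_table.set_index("SNP")["EAF"]

    confounder = rng.standard_normal(n) if model.confounding_strength > 0 else None

    raw = np.zeros((n, k))
    for spec in specs:
        if not spec.causal_indices:
            continue
        col = model.exposure_names.index(spec.exposure_name)
        ids = [spec.variant_ids[j] for j in spec.causal_indices]
        g = dosages[ids].to_numpy(float)
        centred = g - 2.0 * eaf.loc[ids].to_numpy()
        raw[:, col] += centred @ np.asarray(spec.causal_effects, float)
    noise_sd = np.atleast_1d(model.exposure_noise_sd)
    raw += rng.standard_normal((n, k)) * noise_sd
    if confounder is not None:
        raw += model.confounding_strength * confounder[:, None]
    sds = exposure_sd(specs, model, variant_table)
    scale = np.array([sds[name] for name in model.exposure_names])
    exposures = raw / scale

    pheno = {name: exposures[:, i] for i, name in enumerate(model.exposure_names)}

    if model.metabolite_names:
        m = len(model.metabolite_names)
        metab = exposures @ model.metabolite_loadings.T
        metab += rng.standard_normal((n, m)) * np.atleast_1d(model.metabolite_noise_sd)
        for t, trait in enumerate(model.metabolite_names):
            direct = model.pleiotropy_effects.get(trait)
            if direct:
                for vid, delta in direct.items():
                    metab[:, t] += delta * dosages[vid].to_numpy(float)
            pheno[trait] = metab[:, t]

    if model.disease_names:
        eta = model.disease_intercepts + exposures @ model.disease_log_odds_per_exposure.T
        prob = 1.0 / (1.0 + np.exp(-eta))
        draws = rng.uniform(size=prob.shape) < prob
        for d, disease in enumerate(model.disease_names):
            pheno[disease] = draws[:, d].astype(float)

    covariates = simulate_covariates(n, rng)
    if confounder is not None:
        # age-linked confounding for negative-control analyses
        covariates["age"] += 8.0 * model.confounding_strength * confounder
    phenotypes = pd.DataFrame(pheno, index=dosages.index)
    covariates.index = dosages.index
    return phenotypes, covariates


def split_cohort(
    cohort: CohortData,
    fractions: dict[str, float],
    seed: int,
) -> CohortData:
    """Assign each individual to exactly one partition.

    Partition sizes are the largest-remainder apportionment of
    ``n * fraction`` (so (0.7, 0.2, 0.1) at n=1000 gives 700/200/100
    exactly); membership is a seeded permutation, disjoint and exhaustive.
    """
    fracs = np.asarray(list(fractions.values()), float)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError(f"partition fractions must sum to 1, got {fracs.sum()!r}")
    n = cohort.n_individuals
    base = np.floor(fracs * n).astype(int)
    remainder = fracs * n - base
    short = n - base.sum()
    for i in np.argsort(-remainder, kind="stable")[:short]:
        base[i] += 1
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    labels = np.empty(n, dtype=object)
    offset = 0
    for name, size in zip(fractions, base):
        labels[order[offset : offset + size]] = name
        offset += size
    return CohortData(
        dosages=cohort.dosages,
        variant_table=cohort.variant_table,
        phenotypes=cohort.phenotypes,
        covariates=cohort.covariates,
        sample_labels=pd.Series(labels, index=cohort.dosages.index, name="partition"),
    )


def simulate_cohort(
    specs: list[LocusSpec],
    model: PhenotypeModel,
    n_individuals: int,
    seed: int,
    fractions: dict[str, float] | None = None,
) -> CohortData:
    """Simulate genotypes at every locus, phenotypes, and partition labels."""
    seq = np.random.SeedSequence(seed)
    geno_seeds, pheno_seed, split_seed = (
        seq.spawn(1)[0].generate_state(len(specs)) % (2**31),
        int(seq.spawn(1)[0].generate_state(1)[0] % (2**31)),
        int(seq.spawn(1)[0].generate_state(1)[0] % (2**31)),
    )
    dose_blocks, var_blocks = [], []
    for spec, s in zip(specs, geno_seeds):
        d, v = simulate_genotypes(spec, n_individuals, int(s))
        dose_blocks.append(d)
        var_blocks.append(v)
    dosages = pd.concat(dose_blocks, axis=1)
    variant_table = pd.concat(var_blocks, ignore_index=True)
    if variant_table["SNP"].duplicated().any():
        raise ValueError("duplicate variant IDs across loci")
    phenotypes, covariates = simulate_phenotypes(dosages, variant_table, specs, model, pheno_seed)
    cohort = CohortData(
        dosages=dosages,
        variant_table=variant_table,
        phenotypes=phenotypes,
        covariates=covariates,
        sample_labels=pd.Series("all", index=dosages.index, name="partition"),
    )
    if fractions is None:
        fractions = {"discovery": 0.45, "outcome": 0.45, "reference": 0.10}
    return split_cohort(cohort, fractions, split_seed)
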