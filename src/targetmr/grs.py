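"""Genetic risk scores and age-stratified regression.

Individual-level sensitivity analysis: a target's instruments are combined
into a weighted genetic risk score (GRS) and the score is regressed on each
phenotype within age strata with covariate adjustment. Comparing the
youngest and oldest strata probes whether age-linked contingent factors
(such as statin use) distort the effect estimates, without conditioning on
those factors directly — conditioning would induce collider bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .assoc import rank_inverse_normal

logger = logging.getLogger(__name__)

__all__ = ["GRSWeights", "build_grs", "strata_regression", "StratumResult"]


@dataclass
class GRSWeights:
    """Per-variant weights (exposure betas, oriented) for one target's score."""

    target_name: str
    variant_ids: list[str]
    weights: np.ndarray
    effect_alleles: list[str]

    def __post_init__(self) -> None:
        self.weights = np.atleast_1d(np.asarray(self.weights, float))
        if not (len(self.variant_ids) == len(self.weights) == len(self.effect_alleles)):
            raise ValueError("variant_ids, weights and effect_alleles must have equal length")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")


def build_grs(
    dosages: pd.DataFrame,
    weights: GRSWeights,
    counted_alleles: pd.Series | None = None,
    max_missing_fraction: float = 0.1,
) -> pd.Series:
    """Per-individual weighted allele score ``score_i = sum_j w_j dosage_ij``.

    Dosages are flipped (2 - dosage) for variants whose counted allele
    differs from the weight's effect allele. Missing dosages contribute the
    variant's mean dosage; a variant entirely absent from the genotype table
    counts toward the 10% absence cap, beyond which scoring is refused.
    """
    present = [v in dosages.columns for v in weights.variant_ids]
    n_absent = present.count(False)
    if n_absent > max_missing_fraction * len(weights.variant_ids):
        raise ValueError(
            f"{weights.target_name}: {n_absent}/{len(weights.variant_ids)} "
            "weight variants absent from genotypes"
        )
    score = np.zeros(len(dosages))
    n_imputed = 0
    for vid, w, ea, ok in zip(
        weights.variant_ids, weights.weights, weights.effect_alleles, present
    ):
        if not ok:
            continue
        g = dosages[vid].to_numpy(float)
        if counted_alleles is not None and counted_alleles[vid] != ea:
            g = 2.0 - g
        miss = ~np.isfinite(g)
        if miss.any():
            g = np.where(miss, np.nanmean(g), g)
            n_imputed += int(miss.sum())
        score += w * g
    if n_imputed:
        logger.info("%s: mean-imputed %d missing dosages", weights.target_name, n_imputed)
    return pd.Series(score, index=dosages.index, name=f"{weights.target_name}_grs")


@dataclass
class StratumResult:
    stratum: str
    n: int
    beta: float
    se: float
    p: float


def _ols_slope(y: np.ndarray, x: np.ndarray, C: np.ndarray) -> tuple[float, float, float]:
    X = np.column_stack([np.ones(len(y)), x, C])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    z = coef[1] / se
    return float(coef[1]), se, float(2.0 * special.ndtr(-abs(z)))


def strata_regression(
    scores: pd.Series,
    phenotype: pd.Series,
    covariates: pd.DataFrame,
    covariate_names: list[str],
    strata: dict[str, tuple[float, float]],
    normalise: bool = True,
) -> tuple[dict[str, StratumResult], float]:
    """Covariate-adjusted score-phenotype slope within each age stratum.

    Within each stratum the score is standardised to unit SD and the
    phenotype is inverse-normal transformed (so slopes are phenotype-SD per
    score-SD), then regressed with covariate adjustment. Returns the
    per-stratum results and the two-sample z-statistic for the difference
    between the first two strata.
    """
    results: dict[str, StratumResult] = {}
    for name, (lo, hi) in strata.items():
        mask = (covariates["age"] >= lo) & (covariates["age"] <= hi)
        n = int(mask.sum())
        if n < len(covariate_names) + 2:
            raise ValueError(f"stratum {name!r} has too few individuals (n={n})")
        s = scores[mask].to_numpy(float)
        if s.std(ddof=0) == 0:
            raise ValueError(f"score constant within stratum {name!r}")
        s = (s - s.mean()) / s.std(ddof=0)
        y = phenotype[mask].to_numpy(float)
        if normalise:
            y = rank_inverse_normal(y)
        C = np.column_stack([covariates.loc[mask, c].to_numpy(float) for c in covariate_names])
        beta, se, p = _ols_slope(y, s, C)
        results[name] = StratumResult(stratum=name, n=n, beta=beta, se=se, p=p)
    names = list(results)
    z_diff = np.nan
    if len(names) >= 2:
        a, b = results[names[0]], results[names[1]]
        z_diff = (a.beta - b.beta) / np.sqrt(a.se**2 + b.se**2)
    return results, float(z_diff)
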