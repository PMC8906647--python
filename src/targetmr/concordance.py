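"""Cross-target comparison of metabolome-wide signatures.

Signatures are first rescaled so that every target corresponds to the same
genetically predicted reduction in disease (CAD) risk: each trait estimate
and SE is divided by the absolute value of the target's oriented disease
log-odds effect, giving trait-SD change per unit of CAD log-odds lowering.
Pairs of scaled signatures are then compared by least-squares regression of
the comparator on the baseline over shared traits; the coefficient of
determination r^2 = var(fitted)/var(observed) measures concordance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .mr import MREstimate
from .screen import MetabolicSignature

__all__ = [
    "ConcordanceResult",
    "scale_by_disease_effect",
    "pairwise_r2",
    "all_pairs",
]


@dataclass
class ConcordanceResult:
    """Concordance of two scaled signatures (b regressed on a)."""

    target_a: str
    target_b: str
    n_traits: int
    r_squared: float
    slope: float
    intercept: float
    scaling_factor_a: float
    scaling_factor_b: float


def scale_by_disease_effect(
    signature: MetabolicSignature, disease_estimate: MREstimate
) -> MetabolicSignature:
    """Divide every trait estimate and SE by |disease log-odds effect|.

    The disease estimate must already be oriented to the target's
    therapeutic direction; a zero disease effect leaves the scaling
    undefined and is an error.
    """
    d = abs(disease_estimate.theta)
    if d == 0.0:
        raise ValueError(
            f"disease effect for {signature.target_name} is 0; scaling undefined"
        )
    rows = signature.rows.copy()
    for col in ("theta", "se", "ci_low", "ci_high"):
        rows[col] = rows[col] / d
    return replace(signature, rows=rows)


def pairwise_r2(a: MetabolicSignature, b: MetabolicSignature) -> ConcordanceResult:
    """Regress b's scaled estimates on a's over traits present in both.

    r^2 is the coefficient of determination (variance of fitted over
    variance of observed values of the dependent variable); slope and
    intercept are from the same fit with an intercept term.
    """
    merged = a.rows[["trait", "theta"]].merge(
        b.rows[["trait", "theta"]], on="trait", suffixes=("_a", "_b")
    ).dropna()
    if len(merged) < 3:
        raise ValueError(
            f"need >= 3 shared traits between {a.target_name} and {b.target_name}, "
            f"got {len(merged)}"
        )
    x = merged["theta_a"].to_numpy()
    y = merged["theta_b"].to_numpy()
    if np.ptp(x) == 0.0:
        raise ValueError(f"{a.target_name} estimates are constant; regression undefined")
    fit = stats.linregress(x, y)
    return ConcordanceResult(
        target_a=a.target_name,
        target_b=b.target_name,
        n_traits=len(merged),
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        scaling_factor_a=np.nan,
        scaling_factor_b=np.nan,
    )


def all_pairs(
    signatures: dict[str, MetabolicSignature],
    disease_estimates: dict[str, MREstimate],
    baseline: str,
) -> tuple[list[ConcordanceResult], pd.DataFrame]:
    """Baseline-vs-each and all-pairs concordance on scaled signatures.

    Returns the list of baseline comparisons (comparator regressed on the
    baseline) and a symmetric r^2 matrix over all unordered target pairs
    (stored as b-on-a in row a, column b order).
    """
    if len(signatures) < 2:
        raise ValueError("need at least 2 signatures")
    if baseline not in signatures:
        raise ValueError(f"baseline target {baseline!r} has no signature")
    scaled = {}
    factors = {}
    for name, sig in signatures.items():
        est = disease_estimates[name]
        scaled[name] = scale_by_disease_effect(sig, est)
        factors[name] = abs(est.theta)
    names = list(signatures)
    baseline_results = []
    for name in names:
        if name == baseline:
            continue
        res = pairwise_r2(scaled[baseline], scaled[name])
        res.scaling_factor_a = factors[baseline]
        res.scaling_factor_b = factors[name]
        baseline_results.append(res)
    matrix = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            r2 = pairwise_r2(scaled[na], scaled[nb]).r_squared
            matrix.loc[na, nb] = matrix.loc[nb, na] = r2
    return baseline_results, matrix


def scatter_table(
    a: MetabolicSignature, b: MetabolicSignature
) -> pd.DataFrame:
    """Plot-ready paired estimates (`trait subcategory est_a est_b`)."""
    merged = a.rows[["trait", "subcategory", "theta"]].merge(
        b.rows[["trait", "theta"]], on="trait", suffixes=("_a", "_b")
    ).dropna()
    return merged.rename(columns={"theta_a": "est_a", "theta_b": "est_b"})
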