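"""Causal-effect estimation from summary statistics.

Implements the Wald ratio, the standard fixed-effect inverse-variance
weighted (IVW) estimator, and the correlated-instrument IVW as a generalised
weighted regression: with outcome-side covariance
``Omega_jk = se_y_j * se_y_k * rho_jk`` built from the signed reference-panel
LD, the causal effect of a 1 SD change in the exposure is

    theta = (bx' Omega^-1 bx)^-1  bx' Omega^-1 by
    se    = sqrt((bx' Omega^-1 bx)^-1)

which reduces exactly to the standard IVW when rho is the identity and to
the Wald ratio for a single instrument. Exposure-side uncertainty enters
only through the instrument-strength F-statistic, following standard
two-sample practice. Estimates can be oriented to the therapeutic direction
of a drug target (effects per 1 SD *lower* LDL or triglycerides, *higher*
HDL) and converted to odds ratios for binary outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import special

from .instruments import DrugTargetDefinition, LDMatrix

Z95 = 1.959963984540054  # scipy.stats.norm.ppf(0.975)

__all__ = [
    "MRInput",
    "MREstimate",
    "wald_ratio",
    "ivw_standard",
    "ivw_correlated",
    "f_statistic",
    "orient",
    "to_odds_ratio",
]


@dataclass
class MRInput:
    """Harmonised instrument-exposure and instrument-outcome effects."""

    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    rho: LDMatrix | np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("beta_x", "se_x", "beta_y", "se_y"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), float)))
        k = len(self.beta_x)
        if not all(len(getattr(self, n)) == k for n in ("se_x", "beta_y", "se_y")):
            raise ValueError("beta/se vectors must have equal length")
        if k < 1:
            raise ValueError("at least one instrument required")
        if np.any(self.se_x <= 0) or np.any(self.se_y <= 0):
            raise ValueError("standard errors must be positive")
        if self.rho is None:
            self.rho = np.eye(k)
        rho = self.rho.r if isinstance(self.rho, LDMatrix) else np.asarray(self.rho, float)
        if rho.shape != (k, k):
            raise ValueError(f"rho shape {rho.shape} does not match {k} instruments")
        self._rho = rho

    @property
    def rho_matrix(self) -> np.ndarray:
        return self._rho

    @property
    def n_instruments(self) -> int:
        return len(self.beta_x)

    @classmethod
    def from_harmonised(cls, table, ld: LDMatrix | None = None) -> "MRInput":
        rho = ld.subset(list(table["SNP"])) if ld is not None else None
        return cls(
            beta_x=table["beta_x"].to_numpy(),
            se_x=table["se_x"].to_numpy(),
            beta_y=table["beta_y"].to_numpy(),
            se_y=table["se_y"].to_numpy(),
            rho=rho,
        )


@dataclass
class MREstimate:
    """A causal estimate with its uncertainty and provenance."""

    theta: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_instruments: int
    f_statistic: float
    method: str
    orientation_applied: int = 1

    @classmethod
    def from_theta_se(cls, theta: float, se: float, n: int, f: float, method: str) -> "MREstimate":
        p = float(2.0 * special.ndtr(-abs(theta) / se)) if se > 0 else (1.0 if theta == 0 else 0.0)
        return cls(
            theta=float(theta),
            se=float(se),
            ci_low=float(theta - Z95 * se),
            ci_high=float(theta + Z95 * se),
            p_value=p,
            n_instruments=int(n),
            f_statistic=float(f),
            method=method,
        )


def f_statistic(beta_x, se_x) -> float:
    """Mean per-instrument squared z-score of the exposure associations."""
    beta_x = np.atleast_1d(np.asarray(beta_x, float))
    se_x = np.atleast_1d(np.asarray(se_x, float))
    if beta_x.size == 0:
        raise ValueError("empty instrument vector")
    return float(np.mean((beta_x / se_x) ** 2))


def wald_ratio(mr_input: MRInput) -> MREstimate:
    """Single-instrument ratio estimate with first-order delta-method SE."""
    if mr_input.n_instruments != 1:
        raise ValueError("wald_ratio requires exactly one instrument")
    bx, by = mr_input.beta_x[0], mr_input.beta_y[0]
    if bx == 0.0:
        raise ValueError("beta_x = 0: Wald ratio undefined")
    theta = by / bx
    se = mr_input.se_y[0] / abs(bx)
    return MREstimate.from_theta_se(theta, se, 1, f_statistic(mr_input.beta_x, mr_input.se_x), "wald")


def ivw_standard(mr_input: MRInput) -> MREstimate:
    """Fixed-effect IVW assuming independent instruments.

    The inverse-variance weighted average of per-instrument Wald ratios
    with weights beta_x_j^2 / se_y_j^2; instruments with beta_x = 0 are
    rejected.
    """
    if mr_input.n_instruments < 2:
        raise ValueError("ivw_standard requires >= 2 instruments")
    if np.any(mr_input.beta_x == 0.0):
        bad = np.nonzero(mr_input.beta_x == 0.0)[0].tolist()
        raise ValueError(f"instrument(s) {bad} have beta_x = 0; ratio undefined")
    ratios = mr_input.beta_y / mr_input.beta_x
    weights = (mr_input.beta_x / mr_input.se_y) ** 2
    theta = float(np.sum(weights * ratios) / np.sum(weights))
    se = float(1.0 / np.sqrt(np.sum(weights)))
    return MREstimate.from_theta_se(
        theta, se, mr_input.n_instruments, f_statistic(mr_input.beta_x, mr_input.se_x), "ivw"
    )


def ivw_correlated(mr_input: MRInput, random_effects: bool = False) -> MREstimate:
    """Correlated-instrument IVW by generalised least squares.

    ``random_effects=True`` inflates the SE by the square root of the
    residual mean square when it exceeds 1 (multiplicative overdispersion);
    the default is the plain fixed-effect model. A near-singular Omega is an
    error naming the most correlated instrument pair: it signals that LD
    pruning was insufficient.
    """
    rho = mr_input.rho_matrix
    omega = np.outer(mr_input.se_y, mr_input.se_y) * rho
    eigvals = np.linalg.eigvalsh(omega)
    if eigvals[0] < 1e-10 * eigvals[-1]:
        k = len(rho)
        off = np.abs(rho - np.eye(k))
        i, j = np.unravel_index(np.argmax(off), off.shape)
        raise ValueError(
            "near-singular instrument covariance: instruments "
            f"{i} and {j} have |rho| = {abs(rho[i, j]):.4f}; prune more aggressively"
        )
    wx = np.linalg.solve(omega, mr_input.beta_x)
    precision = float(mr_input.beta_x @ wx)
    theta = float(wx @ mr_input.beta_y) / precision
    se = 1.0 / np.sqrt(precision)
    if random_effects and mr_input.n_instruments > 1:
        resid = mr_input.beta_y - theta * mr_input.beta_x
        msr = float(resid @ np.linalg.solve(omega, resid)) / (mr_input.n_instruments - 1)
        se *= max(1.0, np.sqrt(msr))
    return MREstimate.from_theta_se(
        theta, se, mr_input.n_instruments,
        f_statistic(mr_input.beta_x, mr_input.se_x), "ivw_correlated",
    )


def orient(estimate: MREstimate, target: DrugTargetDefinition) -> MREstimate:
    """Express the effect per 1 SD exposure change in the therapeutic direction.

    A raw estimate is per 1 SD *higher* exposure; for a target whose drug
    lowers the exposure (direction -1) the sign is flipped and the CI
    bounds are negated and swapped, so reported effects mimic pharmacological
    modulation (per 1 SD lower LDL / lower triglycerides, or higher HDL).
    P-value and SE are unchanged. Applying the same orientation twice is the
    identity.
    """
    d = target.therapeutic_direction
    if d == 1:
        return replace(estimate, orientation_applied=1)
    return replace(
        estimate,
        theta=-estimate.theta,
        ci_low=-estimate.ci_high,
        ci_high=-estimate.ci_low,
        orientation_applied=-estimate.orientation_applied,
    )


def to_odds_ratio(estimate: MREstimate) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate: (OR, 95% CI low, 95% CI high)."""
    return (
        float(np.exp(estimate.theta)),
        float(np.exp(estimate.theta - Z95 * estimate.se)),
        float(np.exp(estimate.theta + Z95 * estimate.se)),
    )
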