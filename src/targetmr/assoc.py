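"""Per-variant association scans and phenotype normalisation.

Produces the per-trait summary statistics consumed by instrument selection
and mendelian-randomisation estimation. Quantitative traits are rank-based
inverse-normal transformed (mean 0, SD 1) before the scan so that effect
sizes are in trait-SD units per effect allele; binary traits are analysed by
logistic regression and effects are log-odds per effect allele. All scans
adjust for covariates in a joint regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special, stats

SUMMARY_COLUMNS = ["SNP", "CHR", "POS", "EA", "NEA", "EAF", "BETA", "SE", "P", "N"]

__all__ = [
    "SummaryStats",
    "SUMMARY_COLUMNS",
    "rank_inverse_normal",
    "gwas_scan",
    "gwas_scan_many",
    "count_gwas_hits",
]


@dataclass
class SummaryStats:
    """Per-variant association results for one trait.

    ``records`` carries the columns ``SNP CHR POS EA NEA EAF BETA SE P N``;
    rows whose SE is not a positive finite number are flagged (monomorphic
    or non-converged variants) and are excluded by downstream consumers.
    """

    trait_name: str
    records: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in SUMMARY_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns {missing}")
        if self.records["SNP"].duplicated().any():
            dupes = self.records.loc[self.records["SNP"].duplicated(), "SNP"].tolist()
            raise ValueError(f"duplicate variant IDs in {self.trait_name}: {dupes[:3]}")

    @property
    def usable(self) -> pd.DataFrame:
        """Records with a valid (positive, finite) standard error."""
        se = self.records["SE"]
        return self.records[np.isfinite(se) & (se > 0)]

    def write_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, trait_name: str | None = None) -> "SummaryStats":
        records = pd.read_csv(path, sep="\t")
        name = trait_name if trait_name is not None else str(path)
        return cls(trait_name=name, records=records[SUMMARY_COLUMNS])


def rank_inverse_normal(values, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transformation (Blom offset by default).

    Maps values to standard-normal quantiles of ``(rank - c) / (n - 2c + 1)``
    with ties receiving the mean of their tied ranks. Missing values are
    passed through. The result has mean ~0 and SD ~1.
    """
    x = np.asarray(values, dtype=float)
    mask = np.isfinite(x)
    n = int(mask.sum())
    if n < 3:
        raise ValueError(f"need >= 3 non-missing values, got {n}")
    obs = x[mask]
    if np.all(obs == obs[0]):
        raise ValueError("all values identical; rank-based transform undefined")
    ranks = stats.rankdata(obs, method="average")
    out = np.full_like(x, np.nan)
    out[mask] = special.ndtri((ranks - offset) / (n - 2.0 * offset + 1.0))
    return out


def _residualise(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(covariates)
    return y - q @ (q.T @ y)


def _linear_scan(
    G: np.ndarray, Y: np.ndarray, C: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Joint-regression dosage coefficients for every (variant, trait) pair.

    Equivalent (Frisch-Waugh) to fitting trait ~ dosage + covariates per
    variant: both dosage and trait are residualised on the covariates and
    the simple slope of the residuals is the joint coefficient. Returns
    (beta, se), each variants x traits.
    """
    n = G.shape[0]
    Gr = _residualise(G, C)
    Yr = _residualise(Y, C)
    gg = np.einsum("ij,ij->j", Gr, Gr)
    cross = Gr.T @ Yr  # variants x traits
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = cross / gg[:, None]
        yy = np.einsum("ij,ij->j", Yr, Yr)
        rss = yy[None, :] - beta**2 * gg[:, None]
        dof = n - C.shape[1] - 1
        sigma2 = np.clip(rss, 0.0, None) / dof
        se = np.sqrt(sigma2 / gg[:, None])
    degenerate = gg <= n * 1e-12
    beta[degenerate] = 0.0
    se[degenerate] = np.nan
    return beta, se


def _logistic_scan(
    G: np.ndarray, y: np.ndarray, C: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant logistic regression coefficients of the dosage."""
    n_var = G.shape[1]
    beta = np.zeros(n_var)
    se = np.full(n_var, np.nan)
    exog = np.column_stack([C, np.zeros(len(y))])
    for j in range(n_var):
        g = G[:, j]
        if np.ptp(g) == 0:
            continue
        exog[:, -1] = g
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, exog).fit(disp=0, maxiter=50)
            if not fit.mle_retvals.get("converged", False):
                continue
            beta[j] = fit.params[-1]
            se[j] = fit.bse[-1]
        except Exception:
            continue  # separation or singular fit: row stays flagged
    return beta, se


def _design(covariates: pd.DataFrame, names: list[str]) -> np.ndarray:
    missing = [c for c in names if c not in covariates.columns]
    if missing:
        raise ValueError(f"covariates not found: {missing}")
    return np.column_stack([np.ones(len(covariates))] + [covariates[c].to_numpy(float) for c in names])


def gwas_scan(
    cohort,
    trait: str,
    covariates: list[str],
    family: str = "linear",
    normalise: bool = True,
) -> SummaryStats:
    """Scan every variant in a cohort partition against one trait.

    For ``family='linear'`` the trait is inverse-normal transformed first
    (unless ``normalise=False``) and the reported BETA is the dosage
    coefficient of a joint least-squares fit with the covariates, in
    trait-SD per effect allele. For ``family='logistic'`` BETA is the
    log-odds per effect allele from a per-variant logistic fit.
    """
    res = gwas_scan_many(cohort, [trait], covariates, family=family, normalise=normalise)
    return res[trait]


def gwas_scan_many(
    cohort,
    traits: list[str],
    covariates: list[str],
    family: str = "linear",
    normalise: bool = True,
) -> dict[str, SummaryStats]:
    """Scan every variant against many traits sharing one covariate set.

    The covariate projection is computed once, so scanning a metabolite
    panel costs little more than a single-trait scan.
    """
    if family not in ("linear", "logistic"):
        raise ValueError(f"family must be 'linear' or 'logistic', got {family!r}")
    for t in traits:
        if t not in cohort.phenotypes.columns:
            raise ValueError(f"trait {t!r} not present in cohort phenotypes")
    G = cohort.dosages.to_numpy(float)
    C = _design(cohort.covariates, covariates)
    n = len(G)
    out: dict[str, SummaryStats] = {}
    if family == "linear":
        Y = np.column_stack(
            [
                rank_inverse_normal(cohort.phenotypes[t]) if normalise else cohort.phenotypes[t].to_numpy(float)
                for t in traits
            ]
        )
        beta, se = _linear_scan(G, Y, C)
    else:
        betas, ses = [], []
        for t in traits:
            y = cohort.phenotypes[t].to_numpy(float)
            classes = np.unique(y)
            if not np.isin(classes, [0.0, 1.0]).all() or len(classes) < 2:
                raise ValueError(f"logistic family requires a binary trait with both classes: {t!r}")
            b, s = _logistic_scan(G, y, C)
            betas.append(b)
            ses.append(s)
        beta, se = np.column_stack(betas), np.column_stack(ses)
    eaf = cohort.dosages.mean(axis=0).to_numpy() / 2.0
    for i, t in enumerate(traits):
        with np.errstate(invalid="ignore", divide="ignore"):
            z = beta[:, i] / se[:, i]
            p = 2.0 * special.ndtr(-np.abs(z))
        records = cohort.variant_table.copy()
        records["EAF"] = eaf
        records["BETA"] = beta[:, i]
        records["SE"] = se[:, i]
        records["P"] = p
        records["N"] = n
        out[t] = SummaryStats(trait_name=t, records=records[SUMMARY_COLUMNS])
    return out


def count_gwas_hits(
    stats_: SummaryStats, threshold: float = 5e-8, locus_window_bp: int = 500_000
) -> tuple[int, int]:
    """Count genome-wide significant variants and independent loci.

    Loci are formed greedily: the remaining hit with the smallest P seeds a
    locus and absorbs every hit within ``locus_window_bp`` either side on
    the same chromosome; repeat until no hits remain.
    """
    hits = stats_.usable.query("P < @threshold").copy()
    n_hits = len(hits)
    n_loci = 0
    hits = hits.sort_values(["P", "POS", "SNP"])
    while not hits.empty:
        seed_row = hits.iloc[0]
        n_loci += 1
        near = (hits["CHR"] == seed_row["CHR"]) & (
            (hits["POS"] - seed_row["POS"]).abs() <= locus_window_bp
        )
        hits = hits[~near]
    return n_hits, n_loci
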