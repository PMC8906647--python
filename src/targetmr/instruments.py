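"""cis instrument selection, LD matrices and allele harmonisation.

Instruments for a drug target are variants within a flanking window either
side of the encoding gene (default 100 kb, closed interval, 1-based
coordinates) that pass a P-value threshold (default 1e-6) in the exposure
GWAS, greedily LD-pruned so every retained pair has r^2 below a threshold
(default 0.1) in a reference genotype panel. Signed LD r relative to each
variant's stated effect allele is retained for the correlated-instrument
causal model; the pruning rule uses its square.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import SummaryStats

logger = logging.getLogger(__name__)

__all__ = [
    "DrugTargetDefinition",
    "LDMatrix",
    "InstrumentSet",
    "select_cis_variants",
    "compute_ld",
    "greedy_ld_prune",
    "select_instruments",
    "harmonise",
]


@dataclass
class DrugTargetDefinition:
    """Gene region, exposure trait and selection thresholds for one target.

    ``therapeutic_direction`` is -1 when the drug lowers the exposure
    (LDL-lowering and triglyceride-lowering targets) and +1 when it raises
    it (HDL-raising via CETP inhibition).
    """

    target_name: str
    chromosome: str
    gene_start: int
    gene_end: int
    exposure_trait: str
    therapeutic_direction: int = -1
    window_kb: float = 100.0
    p_threshold: float = 1e-6
    r2_threshold: float = 0.1
    min_instruments: int = 2

    def __post_init__(self) -> None:
        if self.window_kb <= 0:
            raise ValueError(f"window_kb must be > 0, got {self.window_kb}")
        if not (0.0 < self.p_threshold < 1.0) and self.p_threshold != 1.0:
            raise ValueError(f"p_threshold must be in (0, 1], got {self.p_threshold}")
        if not (0.0 < self.r2_threshold <= 1.0):
            raise ValueError(f"r2_threshold must be in (0, 1], got {self.r2_threshold}")
        if self.therapeutic_direction not in (-1, 1):
            raise ValueError(f"therapeutic_direction must be -1 or +1, got {self.therapeutic_direction}")

    def window_interval(self, window_kb: float | None = None) -> tuple[int, int]:
        w = int(round(1000 * (self.window_kb if window_kb is None else window_kb)))
        return self.gene_start - w, self.gene_end + w


@dataclass
class LDMatrix:
    """Signed pairwise dosage correlations, aligned to stated effect alleles."""

    variant_ids: list[str]
    r: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, float)
        k = len(self.variant_ids)
        if self.r.shape != (k, k):
            raise ValueError(f"LD matrix shape {self.r.shape} does not match {k} variants")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("LD matrix must have unit diagonal")
        if np.any(np.abs(self.r) > 1.0 + 1e-8):
            raise ValueError("LD entries must lie in [-1, 1]")

    def subset(self, ids: list[str]) -> "LDMatrix":
        idx = [self.variant_ids.index(v) for v in ids]
        return LDMatrix(variant_ids=list(ids), r=self.r[np.ix_(idx, idx)])

    def flip(self, variant_id: str) -> "LDMatrix":
        """LD matrix after relabelling one variant's effect allele."""
        j = self.variant_ids.index(variant_id)
        r = self.r.copy()
        r[j, :] *= -1.0
        r[:, j] *= -1.0
        return LDMatrix(variant_ids=list(self.variant_ids), r=r)

    def write_tsv(self, path) -> None:
        pd.DataFrame(self.r, index=self.variant_ids, columns=self.variant_ids).to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(variant_ids=list(df.columns), r=df.to_numpy(float))


@dataclass
class InstrumentSet:
    """The pruned cis instruments for one target plus their LD matrix."""

    target: DrugTargetDefinition
    variants: pd.DataFrame  # exposure-side summary records, ascending P
    ld: LDMatrix

    def __post_init__(self) -> None:
        if list(self.variants["SNP"]) != self.ld.variant_ids:
            raise ValueError("instrument records and LD matrix must list the same variants in order")

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants["SNP"])


def select_cis_variants(
    stats_: SummaryStats, target: DrugTargetDefinition, window_kb: float | None = None
) -> pd.DataFrame:
    """Candidate instruments: in-window, below the P threshold, ascending P.

    The window is the closed interval [gene_start - w, gene_end + w] in
    1-based coordinates. Ties in P break by (position, variant ID).
    """
    lo, hi = target.window_interval(window_kb)
    rec = stats_.usable
    mask = (
        (rec["CHR"].astype(str) == str(target.chromosome))
        & (rec["POS"] >= lo)
        & (rec["POS"] <= hi)
        & (rec["P"] < target.p_threshold)
    )
    out = rec[mask].sort_values(["P", "POS", "SNP"]).reset_index(drop=True)
    if out.empty:
        logger.warning(
            "no candidate instruments for %s in [%d, %d] at P < %g",
            target.target_name, lo, hi, target.p_threshold,
        )
    return out


def compute_ld(
    reference_dosages: pd.DataFrame,
    variant_ids: list[str],
    effect_alleles: pd.Series | None = None,
    panel_alleles: pd.Series | None = None,
) -> LDMatrix:
    """Signed Pearson correlation of dosages in a reference panel.

    ``reference_dosages`` columns are counted alleles per variant; when
    ``effect_alleles`` and ``panel_alleles`` are given, any variant whose
    stated effect allele differs from the panel's counted allele has its
    dosage reflected (2 - dosage) so the returned r is aligned to the
    effect alleles, and flipping a variant's labels negates its row and
    column.
    """
    missing = [v for v in variant_ids if v not in reference_dosages.columns]
    if missing:
        raise ValueError(f"variants absent from reference panel: {missing[:5]}")
    X = reference_dosages[variant_ids].to_numpy(float)
    mono = [v for v, s in zip(variant_ids, X.std(axis=0)) if s == 0.0]
    if mono:
        raise ValueError(f"monomorphic in reference panel: {mono[:5]}")
    if effect_alleles is not None and panel_alleles is not None:
        flip = np.array([effect_alleles[v] != panel_alleles[v] for v in variant_ids])
        X = np.where(flip[None, :], 2.0 - X, X)
    r = np.corrcoef(X, rowvar=False)
    r = np.atleast_2d(r)
    np.fill_diagonal(r, 1.0)
    return LDMatrix(variant_ids=list(variant_ids), r=r)


def greedy_ld_prune(
    candidates: pd.DataFrame, ld: LDMatrix, r2_threshold: float
) -> list[str]:
    """Greedy pruning in ascending-P order.

    Keeps a candidate iff its squared correlation with every already-kept
    variant is below the threshold; the best-P candidate is always kept.
    """
    if candidates.empty:
        raise ValueError("no candidates to prune")
    order = candidates.sort_values(["P", "POS", "SNP"])["SNP"].tolist()
    kept: list[str] = []
    for vid in order:
        i = ld.variant_ids.index(vid)
        ok = all(ld.r[i, ld.variant_ids.index(k)] ** 2 < r2_threshold for k in kept)
        if ok:
            kept.append(vid)
    return kept


def select_instruments(
    stats_: SummaryStats,
    target: DrugTargetDefinition,
    reference_dosages: pd.DataFrame,
    panel_alleles: pd.Series | None = None,
    window_kb: float | None = None,
) -> InstrumentSet:
    """Full selection: cis window + P filter, LD computation, greedy pruning."""
    candidates = select_cis_variants(stats_, target, window_kb=window_kb)
    if candidates.empty:
        raise ValueError(f"no instruments found for {target.target_name}")
    in_panel = candidates["SNP"].isin(reference_dosages.columns)
    if (~in_panel).any():
        logger.info(
            "%s: %d candidate(s) absent from the reference panel, excluded",
            target.target_name, int((~in_panel).sum()),
        )
        candidates = candidates[in_panel]
    if candidates.empty:
        raise ValueError(f"no panel-covered instruments for {target.target_name}")
    effect_alleles = candidates.set_index("SNP")["EA"]
    ld_all = compute_ld(
        reference_dosages, list(candidates["SNP"]), effect_alleles, panel_alleles
    )
    kept = greedy_ld_prune(candidates, ld_all, target.r2_threshold)
    if len(kept) < target.min_instruments:
        raise ValueError(
            f"{target.target_name}: only {len(kept)} instrument(s) after pruning "
            f"(minimum {target.min_instruments}); single-instrument cis scores are "
            "vulnerable to confounding by neighbouring genes"
        )
    variants = candidates.set_index("SNP").loc[kept].reset_index()
    return InstrumentSet(target=target, variants=variants, ld=ld_all.subset(kept))


def harmonise(
    exposure: pd.DataFrame,
    outcome: SummaryStats,
    variant_ids: list[str] | None = None,
    drop_palindromic: bool = False,
) -> pd.DataFrame:
    """Align outcome effect alleles to the exposure side.

    Returns one row per retained instrument with columns ``SNP, EA, NEA,
    beta_x, se_x, beta_y, se_y``. If the outcome's effect/other alleles are
    swapped relative to the exposure, the outcome beta is negated and its
    frequency complemented; irreconcilable allele pairs and instruments
    missing from the outcome are dropped with a logged reason. Dropping
    every instrument is an error.
    """
    if variant_ids is None:
        variant_ids = list(exposure["SNP"])
    exp = exposure.set_index("SNP").loc[variant_ids]
    out = outcome.usable.set_index("SNP")
    rows = []
    for vid in variant_ids:
        e = exp.loc[vid]
        if drop_palindromic and {e["EA"], e["NEA"]} in ({"A", "T"}, {"C", "G"}):
            logger.info("dropping palindromic variant %s", vid)
            continue
        if vid not in out.index:
            logger.info("instrument %s missing from outcome %s, dropped", vid, outcome.trait_name)
            continue
        o = out.loc[vid]
        if (o["EA"], o["NEA"]) == (e["EA"], e["NEA"]):
            beta_y, eaf_y = o["BETA"], o["EAF"]
        elif (o["EA"], o["NEA"]) == (e["NEA"], e["EA"]):
            beta_y, eaf_y = -o["BETA"], 1.0 - o["EAF"]
        else:
            logger.info(
                "instrument %s alleles %s/%s irreconcilable with outcome %s/%s, dropped",
                vid, e["EA"], e["NEA"], o["EA"], o["NEA"],
            )
            continue
        rows.append(
            {
                "SNP": vid,
                "EA": e["EA"],
                "NEA": e["NEA"],
                "eaf_x": e["EAF"],
                "eaf_y": eaf_y,
                "beta_x": e["BETA"],
                "se_x": e["SE"],
                "beta_y": beta_y,
                "se_y": o["SE"],
            }
        )
    if not rows:
        raise ValueError(f"no instruments could be harmonised with outcome {outcome.trait_name}")
    return pd.DataFrame(rows)
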