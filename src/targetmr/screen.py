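"""Metabolome-wide screening with per-target FDR control.

Runs the correlated-instrument IVW model for one drug target against every
trait in a metabolite panel, orients the estimates to the therapeutic
direction, and applies a Benjamini-Hochberg correction *within* each
target's family of traits (families are never pooled across targets).
Instruments are selected once per target and reused across traits, since
selection depends only on the exposure side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .assoc import SummaryStats
from .instruments import DrugTargetDefinition, InstrumentSet, harmonise, select_instruments
from .mr import MRInput, ivw_correlated, orient

logger = logging.getLogger(__name__)

__all__ = ["MetabolicSignature", "bh_fdr", "screen_target", "run_screen"]

SIGNATURE_COLUMNS = [
    "trait", "subcategory", "theta", "se", "ci_low", "ci_high", "p", "q", "discovery",
]


@dataclass
class MetabolicSignature:
    """Oriented MR estimates for one target across a metabolite panel."""

    target_name: str
    rows: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in SIGNATURE_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValueError(f"signature missing columns {missing}")
        if self.rows["trait"].duplicated().any():
            raise ValueError("one row per trait required")

    def write_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def bh_fdr(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and discovery flags.

    Returns ``(q, discovery)`` with q monotone in sorted p and capped at 1;
    discoveries are q < alpha. Empty input returns empty arrays.
    """
    p = np.atleast_1d(np.asarray(p_values, float))
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, q < alpha


def screen_target(
    instruments: InstrumentSet,
    outcome_stats: dict[str, SummaryStats],
    fdr_q: float = 0.05,
    subcategories: dict[str, str] | None = None,
    min_instrument_fraction: float = 0.5,
) -> MetabolicSignature:
    """MR of one target against every outcome trait, with per-target FDR.

    A trait retaining no more than ``min_instrument_fraction`` of the
    target's instruments after harmonisation is flagged missing (theta NaN)
    and excluded from the FDR family.
    """
    target = instruments.target
    k = len(instruments.variant_ids)
    rows = []
    for trait, stats_ in outcome_stats.items():
        sub = (subcategories or {}).get(trait, "")
        try:
            table = harmonise(instruments.variants, stats_, instruments.variant_ids)
        except ValueError:
            table = None
        if table is None or len(table) < min_instrument_fraction * k:
            kept = 0 if table is None else len(table)
            logger.warning(
                "%s vs %s: %d/%d instruments harmonised; cell flagged missing",
                target.target_name, trait, kept, k,
            )
            rows.append({"trait": trait, "subcategory": sub, "theta": np.nan, "se": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "p": np.nan})
            continue
        est = orient(ivw_correlated(MRInput.from_harmonised(table, instruments.ld)), target)
        rows.append({
            "trait": trait, "subcategory": sub, "theta": est.theta, "se": est.se,
            "ci_low": est.ci_low, "ci_high": est.ci_high, "p": est.p_value,
        })
    df = pd.DataFrame(rows)
    df["q"] = np.nan
    df["discovery"] = False
    ok = df["p"].notna()
    if ok.any():
        q, disc = bh_fdr(df.loc[ok, "p"].to_numpy(), alpha=fdr_q)
        df.loc[ok, "q"] = q
        df.loc[ok, "discovery"] = disc
    return MetabolicSignature(target_name=target.target_name, rows=df[SIGNATURE_COLUMNS])


def run_screen(
    targets: list[DrugTargetDefinition],
    exposure_stats: dict[str, SummaryStats],
    outcome_stats: dict[str, SummaryStats],
    reference_dosages: pd.DataFrame,
    fdr_q: float = 0.05,
    subcategories: dict[str, str] | None = None,
    window_kb: float | None = None,
) -> dict[str, MetabolicSignature]:
    """Screen every target against every outcome trait.

    Instrument selection runs exactly once per target (on its exposure
    trait's summary statistics) and the resulting set is reused for every
    outcome trait; the output is one signature per target.
    """
    signatures: dict[str, MetabolicSignature] = {}
    for target in targets:
        if target.exposure_trait not in exposure_stats:
            raise ValueError(
                f"no exposure summary statistics for {target.exposure_trait!r} "
                f"(needed by {target.target_name})"
            )
        iset = select_instruments(
            exposure_stats[target.exposure_trait], target, reference_dosages, window_kb=window_kb
        )
        signatures[target.target_name] = screen_target(
            iset, outcome_stats, fdr_q=fdr_q, subcategories=subcategories
        )
    return signatures


def signatures_long_table(signatures: dict[str, MetabolicSignature]) -> pd.DataFrame:
    """Combined long-format table across targets (one row per target x trait)."""
    frames = []
    for name, sig in signatures.items():
        df = sig.rows.copy()
        df.insert(0, "target", name)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
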