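import numpy as np
import pandas as pd
import pytest

from targetmr.simulate import LocusSpec, simulate_genotypes
from targetmr.study import multi_target_study, single_locus_study

COVARIATES = ["age", "sex", "fasting", "chip"]


@pytest.fixture(scope="session")
def ld_locus():
    """A 10-variant AR(1) locus with strong LD for instrument tests."""
    return LocusSpec(
        locus_id="L1",
        chromosome="1",
        start_bp=1_000_000,
        end_bp=1_018_000,
        n_variants=10,
        maf_range=(0.1, 0.5),
        ld_decay_rho=0.8,
    )


@pytest.fixture(scope="session")
def big_genotypes(ld_locus):
    """50k individuals at the LD locus (shared across LD-accuracy tests)."""
    return simulate_genotypes(ld_locus, 50_000, seed=42)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest three-target cohort with metabolites, for integration tests."""
    cohort, targets, specs, model = multi_target_study(
        n_individuals=20_000, seed=11, n_metabolites=8
    )
    return cohort, targets, specs, model


@pytest.fixture(scope="session")
def single_cohort():
    """Single-locus disease cohort (true theta = -0.25 log-odds/SD)."""
    cohort, target, spec, model = single_locus_study(n_individuals=20_000, seed=3)
    return cohort, target, spec, model


def toy_summary(positions, p_values, chrom="1", betas=None, eaf=0.3):
    """Hand-built summary statistics for selection/pruning tests."""
    from targetmr.assoc import SummaryStats

    n = len(positions)
    betas = betas if betas is not None else np.full(n, 0.1)
    records = pd.DataFrame(
        {
            "SNP": [f"rs{i}" for i in range(n)],
            "CHR": chrom,
            "POS": positions,
            "EA": "A",
            "NEA": "G",
            "EAF": eaf,
            "BETA": betas,
            "SE": 0.01,
            "P": p_values,
            "N": 10_000,
        }
    )
    return SummaryStats(trait_name="toy", records=records)
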