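"""Genotype, phenotype and partitioning behaviour of the cohort generator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from targetmr.simulate import (
    CohortData,
    LocusSpec,
    PhenotypeModel,
    simulate_cohort,
    simulate_genotypes,
    simulate_phenotypes,
    split_cohort,
)


def _spec(**kwargs):
    defaults = dict(
        locus_id="L",
        chromosome="1",
        start_bp=1_000_000,
        end_bp=1_020_000,
        n_variants=10,
        maf_range=(0.1, 0.5),
        ld_decay_rho=0.0,
        exposure_name="E",
    )
    defaults.update(kwargs)
    return LocusSpec(**defaults)


class TestSimulateGenotypes:
    def test_seed_determinism_is_bitwise(self):
        spec = _spec(ld_decay_rho=0.5)
        d1, v1 = simulate_genotypes(spec, 500, seed=9)
        d2, v2 = simulate_genotypes(spec, 500, seed=9)
        pd.testing.assert_frame_equal(d1, d2)
        pd.testing.assert_frame_equal(v1, v2)

    def test_dosages_in_range_and_hwe_frequencies(self):
        spec = _spec()
        dosages, variants = simulate_genotypes(spec, 20_000, seed=1)
        assert set(np.unique(dosages.to_numpy())) <= {0, 1, 2}
        # empirical allele frequency within 3 binomial SEs of specification
        p = variants["EAF"].to_numpy()
        freq = dosages.to_numpy().mean(axis=0) / 2.0
        se = np.sqrt(p * (1 - p) / (2 * 20_000))
        assert np.all(np.abs(freq - p) < 3.5 * se)

    def test_independent_variants_are_uncorrelated(self):
        spec = _spec(ld_decay_rho=0.0, n_variants=6)
        dosages, _ = simulate_genotypes(spec, 50_000, seed=2)
        r = np.corrcoef(dosages.to_numpy(), rowvar=False)
        off = r[~np.eye(6, dtype=bool)]
        assert np.max(np.abs(off)) < 0.02

    def test_ld_matches_monte_carlo_oracle(self):
        """Adjacent-dosage correlation agrees with a direct bivariate-normal
        threshold simulation, averaged over 10 replicate seeds."""
        rho, maf = 0.8, 0.3
        t = stats.norm.ppf(maf)
        rng = np.random.default_rng(2024)
        oracle = []
        for _ in range(10):
            z1 = rng.standard_normal((100_000, 2))
            z2 = rng.standard_normal((100_000, 2))
            d = np.zeros(100_000)
            e = np.zeros(100_000)
            for z in (z1, z2):  # two haplotypes
                d += z[:, 0] < t
                e += (rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1]) < t
            oracle.append(np.corrcoef(d, e)[0, 1])
        oracle_r = float(np.mean(oracle))

        spec = _spec(ld_decay_rho=rho, maf_range=(maf, maf), n_variants=4)
        dosages, _ = simulate_genotypes(spec, 50_000, seed=7)
        g = dosages.to_numpy()
        sim_r = np.mean([np.corrcoef(g[:, j], g[:, j + 1])[0, 1] for j in range(3)])
        assert sim_r == pytest.approx(oracle_r, abs=0.03)

    def test_ld_decays_with_distance(self):
        spec = _spec(ld_decay_rho=0.7, maf_range=(0.3, 0.3), n_variants=8)
        dosages, _ = simulate_genotypes(spec, 50_000, seed=5)
        r = np.corrcoef(dosages.to_numpy(), rowvar=False)
        by_dist = [np.mean([r[i, i + d] for i in range(8 - d)]) for d in (1, 2, 3, 4)]
        assert all(a > b for a, b in zip(by_dist, by_dist[1:]))

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(maf_range=(0.0, 0.5)), "maf_range"),
            (dict(maf_range=(0.1, 0.6)), "maf_range"),
            (dict(ld_decay_rho=1.0), "ld_decay_rho"),
            (dict(causal_indices=(99,), causal_effects=(0.1,)), "causal_indices"),
        ],
    )
    def test_invalid_spec_rejected_naming_field(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            _spec(**kwargs)

    def test_too_few_individuals_rejected(self):
        with pytest.raises(ValueError, match="n_individuals"):
            simulate_genotypes(_spec(), 1, seed=0)


class TestSimulatePhenotypes:
    def test_null_gamma_leaves_exposure_independent_of_genotypes(self):
        spec = _spec(n_variants=5)
        dosages, variants = simulate_genotypes(spec, 50_000, seed=3)
        model = PhenotypeModel(exposure_names=("E",))
        pheno, _ = simulate_phenotypes(dosages, variants, [spec], model, seed=4)
        for col in dosages.columns:
            assert abs(np.corrcoef(dosages[col], pheno["E"])[0, 1]) < 0.02

    def test_exposure_has_unit_variance_and_known_effects(self):
        spec = _spec(n_variants=5, causal_indices=(1, 3), causal_effects=(0.3, -0.2))
        dosages, variants = simulate_genotypes(spec, 50_000, seed=6)
        model = PhenotypeModel(exposure_names=("E",))
        pheno, _ = simulate_phenotypes(dosages, variants, [spec], model, seed=7)
        assert pheno["E"].std() == pytest.approx(1.0, abs=0.02)

    def test_prevalence_matches_logistic_normal_oracle(self):
        """Realised prevalence over 10 seeds matches Monte-Carlo integration
        of the logistic-normal mean (theta = 0.5, intercept for ~20%)."""
        rng = np.random.default_rng(99)
        intercept = -1.5
        # oracle: E[sigmoid(intercept + 0.5 Z)], Z ~ N(0, 1)
        z = rng.standard_normal(2_000_000)
        expected = float(np.mean(1 / (1 + np.exp(-(intercept + 0.5 * z)))))
        spec = _spec(n_variants=4, causal_indices=(0,), causal_effects=(0.15,))
        model = PhenotypeModel(
            exposure_names=("E",),
            disease_names=("D",),
            disease_intercepts=np.array([intercept]),
            disease_log_odds_per_exposure=np.array([[0.5]]),
        )
        prevalences = []
        for seed in range(10):
            dosages, variants = simulate_genotypes(spec, 20_000, seed=seed)
            pheno, _ = simulate_phenotypes(dosages, variants, [spec], model, seed=seed + 100)
            prevalences.append(pheno["D"].mean())
        assert np.mean(prevalences) == pytest.approx(expected, abs=0.01)

    def test_metabolite_tracks_exposure_in_noise_free_limit(self):
        spec = _spec(n_variants=4, causal_indices=(0,), causal_effects=(0.2,))
        dosages, variants = simulate_genotypes(spec, 5_000, seed=8)
        model = PhenotypeModel(
            exposure_names=("E",),
            metabolite_names=("M",),
            metabolite_loadings=np.array([[1.0]]),
            metabolite_noise_sd=1e-8,
        )
        pheno, _ = simulate_phenotypes(dosages, variants, [spec], model, seed=9)
        assert np.corrcoef(pheno["M"], pheno["E"])[0, 1] > 0.999999

    def test_no_pleiotropy_means_no_genotype_effect_beyond_exposures(self):
        """Partial correlation of metabolite and dosage given the exposure
        is null when direct variant effects are absent."""
        spec = _spec(n_variants=4, causal_indices=(0,), causal_effects=(0.3,))
        dosages, variants = simulate_genotypes(spec, 50_000, seed=10)
        model = PhenotypeModel(
            exposure_names=("E",),
            metabolite_names=("M",),
            metabolite_loadings=np.array([[0.8]]),
            metabolite_noise_sd=1.0,
        )
        pheno, _ = simulate_phenotypes(dosages, variants, [spec], model, seed=11)
        e = pheno["E"].to_numpy()
        for col in dosages.columns:
            g = dosages[col].to_numpy(float)
            m = pheno["M"].to_numpy()
            rg = g - np.polyval(np.polyfit(e, g, 1), e)
            rm = m - np.polyval(np.polyfit(e, m, 1), e)
            assert abs(np.corrcoef(rg, rm)[0, 1]) < 0.02

    def test_pleiotropy_effects_add_direct_variant_path(self):
        spec = _spec(n_variants=4)
        dosages, variants = simulate_genotypes(spec, 20_000, seed=12)
        model = PhenotypeModel(
            exposure_names=("E",),
            metabolite_names=("M",),
            metabolite_loadings=np.array([[0.0]]),
            metabolite_noise_sd=0.5,
            pleiotropy_effects={"M": {"L_v0": 0.5}},
        )
        pheno, _ = simulate_phenotypes(dosages, variants, [spec], model, seed=13)
        assert np.corrcoef(dosages["L_v0"], pheno["M"])[0, 1] > 0.3

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="metabolite_loadings"):
            PhenotypeModel(
                exposure_names=("A", "B"),
                metabolite_names=("M",),
                metabolite_loadings=np.ones((1, 3)),
            )


class TestSplitCohort:
    def _cohort(self, n):
        idx = pd.RangeIndex(n)
        return CohortData(
            dosages=pd.DataFrame({"v": np.zeros(n, dtype=np.int8)}, index=idx),
            variant_table=pd.DataFrame(
                {"SNP": ["v"], "CHR": ["1"], "POS": [1], "EA": ["A"], "NEA": ["G"], "EAF": [0.3]}
            ),
            phenotypes=pd.DataFrame({"t": np.zeros(n)}, index=idx),
            covariates=pd.DataFrame({"age": np.zeros(n)}, index=idx),
            sample_labels=pd.Series("all", index=idx),
        )

    def test_exact_partition_sizes(self):
        out = split_cohort(self._cohort(1000), {"a": 0.7, "b": 0.2, "c": 0.1}, seed=1)
        counts = out.sample_labels.value_counts()
        assert counts["a"] == 700 and counts["b"] == 200 and counts["c"] == 100

    def test_partitions_disjoint_and_exhaustive(self):
        out = split_cohort(self._cohort(100), {"x": 0.5, "y": 0.5}, seed=2)
        assert len(out.partition("x").dosages) == 50
        assert len(out.partition("y").dosages) == 50
        assert not set(out.partition("x").dosages.index) & set(out.partition("y").dosages.index)

    def test_membership_deterministic_given_seed(self):
        a = split_cohort(self._cohort(500), {"x": 0.6, "y": 0.4}, seed=3)
        b = split_cohort(self._cohort(500), {"x": 0.6, "y": 0.4}, seed=3)
        pd.testing.assert_series_equal(a.sample_labels, b.sample_labels)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            split_cohort(self._cohort(10), {"x": 0.6, "y": 0.5}, seed=0)


def test_simulate_cohort_unique_variants_and_partition_tags(small_cohort):
    cohort, _, _, _ = small_cohort
    assert cohort.variant_table["SNP"].is_unique
    assert set(cohort.sample_labels.unique()) == {"discovery", "outcome", "reference"}
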