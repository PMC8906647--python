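"""cis-window selection, LD computation, greedy pruning, harmonisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from targetmr.assoc import SummaryStats
from targetmr.instruments import (
    DrugTargetDefinition,
    LDMatrix,
    compute_ld,
    greedy_ld_prune,
    harmonise,
    select_cis_variants,
    select_instruments,
)

from conftest import toy_summary


def _target(**kwargs):
    defaults = dict(
        target_name="T",
        chromosome="1",
        gene_start=1_000_000,
        gene_end=1_050_000,
        exposure_trait="LDL",
        therapeutic_direction=-1,
    )
    defaults.update(kwargs)
    return DrugTargetDefinition(**defaults)


class TestSelectCisVariants:
    def test_100kb_window_boundaries_are_closed(self):
        stats_ = toy_summary([899_999, 900_000, 1_150_000, 1_150_001], [1e-8] * 4)
        kept = select_cis_variants(stats_, _target())
        assert set(kept["POS"]) == {900_000, 1_150_000}

    def test_50kb_window_is_narrower(self):
        stats_ = toy_summary([900_000, 950_000, 1_100_000, 1_150_000], [1e-8] * 4)
        kept = select_cis_variants(stats_, _target(), window_kb=50)
        assert set(kept["POS"]) == {950_000, 1_100_000}

    def test_p_threshold_filters(self):
        stats_ = toy_summary([1_000_000, 1_010_000], [1e-8, 1e-5])
        kept = select_cis_variants(stats_, _target())
        assert list(kept["POS"]) == [1_000_000]

    def test_vacuous_threshold_keeps_all_in_window(self):
        stats_ = toy_summary([1_000_000, 1_010_000], [0.9, 0.5])
        kept = select_cis_variants(stats_, _target(p_threshold=1.0))
        assert len(kept) == 2

    def test_sorted_by_ascending_p(self):
        stats_ = toy_summary([1_000_000, 1_010_000, 1_020_000], [1e-7, 1e-9, 1e-8])
        kept = select_cis_variants(stats_, _target())
        assert list(kept["P"]) == sorted(kept["P"])

    def test_other_chromosome_excluded(self):
        stats_ = toy_summary([1_000_000], [1e-9], chrom="2")
        assert select_cis_variants(stats_, _target()).empty


class TestComputeLD:
    def test_unit_diagonal_and_symmetry(self, big_genotypes):
        dosages, _ = big_genotypes
        ld = compute_ld(dosages, list(dosages.columns[:4]))
        np.testing.assert_allclose(np.diag(ld.r), 1.0)
        np.testing.assert_allclose(ld.r, ld.r.T)

    def test_independent_variants_near_zero(self):
        rng = np.random.default_rng(3)
        panel = pd.DataFrame(rng.binomial(2, 0.3, size=(50_000, 2)), columns=["a", "b"])
        ld = compute_ld(panel, ["a", "b"])
        assert abs(ld.r[0, 1]) < 0.02

    def test_ar1_locus_adjacent_ld_positive_and_decaying(self, big_genotypes):
        dosages, _ = big_genotypes
        ld = compute_ld(dosages, list(dosages.columns))
        adj = np.array([ld.r[i, i + 1] for i in range(9)])
        far = np.array([ld.r[i, i + 5] for i in range(5)])
        assert adj.mean() > 0.5
        assert far.mean() < adj.mean()

    def test_monomorphic_variant_rejected_by_id(self):
        panel = pd.DataFrame({"a": [0, 1, 2, 1], "b": [1, 1, 1, 1]})
        with pytest.raises(ValueError, match="b"):
            compute_ld(panel, ["a", "b"])

    def test_allele_flip_negates_row_and_column(self):
        rng = np.random.default_rng(4)
        g = rng.binomial(2, 0.4, size=(1_000, 3))
        g[:, 1] = np.clip(g[:, 0] + rng.binomial(1, 0.2, 1_000) - rng.binomial(1, 0.2, 1_000), 0, 2)
        panel = pd.DataFrame(g, columns=["a", "b", "c"])
        effect = pd.Series({"a": "A", "b": "G", "c": "A"})  # b counted on other allele
        counted = pd.Series({"a": "A", "b": "A", "c": "A"})
        ld = compute_ld(panel, ["a", "b", "c"], effect, counted)
        plain = compute_ld(panel, ["a", "b", "c"])
        np.testing.assert_allclose(ld.r[0, 1], -plain.r[0, 1], atol=1e-12)
        np.testing.assert_allclose(ld.r[0, 2], plain.r[0, 2], atol=1e-12)


def _random_instance(rng, k):
    """Random candidates + valid correlation matrix for pruning properties."""
    f = rng.standard_normal((k, max(2, k // 2)))
    cov = f @ f.T + np.diag(rng.uniform(0.1, 1.0, k))
    d = np.sqrt(np.diag(cov))
    r = cov / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    ids = [f"rs{i}" for i in range(k)]
    cand = toy_summary(np.arange(k) * 100 + 1, rng.uniform(1e-12, 1e-7, k)).records
    return cand, LDMatrix(variant_ids=ids, r=r)


class TestGreedyPrune:
    def test_hand_example(self):
        cand = toy_summary([100, 200, 300], [1e-10, 1e-8, 1e-7]).records
        r = np.eye(3)
        r[0, 1] = r[1, 0] = np.sqrt(0.5)
        r[0, 2] = r[2, 0] = np.sqrt(0.05)
        r[1, 2] = r[2, 1] = np.sqrt(0.02)
        ld = LDMatrix(variant_ids=["rs0", "rs1", "rs2"], r=r)
        assert greedy_ld_prune(cand, ld, 0.1) == ["rs0", "rs2"]

    def test_single_candidate_kept(self):
        cand = toy_summary([100], [1e-9]).records
        ld = LDMatrix(variant_ids=["rs0"], r=np.eye(1))
        assert greedy_ld_prune(cand, ld, 0.1) == ["rs0"]

    def test_vacuous_threshold_keeps_all(self):
        rng = np.random.default_rng(5)
        cand, ld = _random_instance(rng, 6)
        assert len(greedy_ld_prune(cand, ld, 1.0 + 1e-12)) == 6

    def test_best_p_candidate_always_kept(self):
        rng = np.random.default_rng(6)
        cand, ld = _random_instance(rng, 8)
        best = cand.sort_values("P")["SNP"].iloc[0]
        assert best in greedy_ld_prune(cand, ld, 0.1)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 10_000), k=st.integers(2, 20))
    def test_pruned_sets_are_valid_and_greedy_maximal(self, seed, k):
        """Kept pairs all satisfy r^2 < threshold; every dropped candidate
        conflicts with some kept variant (checked by enumeration)."""
        rng = np.random.default_rng(seed)
        cand, ld = _random_instance(rng, k)
        thr = 0.1
        kept = greedy_ld_prune(cand, ld, thr)
        idx = {v: i for i, v in enumerate(ld.variant_ids)}
        for a in kept:
            for b in kept:
                if a != b:
                    assert ld.r[idx[a], idx[b]] ** 2 < thr
        for v in ld.variant_ids:
            if v not in kept:
                assert any(ld.r[idx[v], idx[kv]] ** 2 >= thr for kv in kept)


class TestHarmonise:
    def _exposure(self):
        rec = toy_summary([100, 200], [1e-9, 1e-8], betas=np.array([0.3, 0.2])).records
        rec["EA"], rec["NEA"] = ["A", "C"], ["G", "T"]
        return rec

    def _outcome(self, ea, nea, betas):
        rec = toy_summary([100, 200], [0.5, 0.5], betas=np.asarray(betas)).records
        rec["EA"], rec["NEA"] = ea, nea
        return SummaryStats(trait_name="out", records=rec)

    def test_swapped_alleles_negate_beta_and_complement_frequency(self):
        out = self._outcome(["G", "C"], ["A", "T"], [0.2, 0.1])
        table = harmonise(self._exposure(), out)
        assert table.loc[table["SNP"] == "rs0", "beta_y"].iloc[0] == pytest.approx(-0.2)
        assert table.loc[table["SNP"] == "rs0", "eaf_y"].iloc[0] == pytest.approx(0.7)
        assert table.loc[table["SNP"] == "rs1", "beta_y"].iloc[0] == pytest.approx(0.1)

    def test_identical_alleles_pass_through(self):
        out = self._outcome(["A", "C"], ["G", "T"], [0.2, 0.1])
        table = harmonise(self._exposure(), out)
        np.testing.assert_allclose(table["beta_y"], [0.2, 0.1])

    def test_irreconcilable_alleles_dropped(self):
        out = self._outcome(["C", "C"], ["T", "T"], [0.2, 0.1])
        table = harmonise(self._exposure(), out)
        assert list(table["SNP"]) == ["rs1"]

    def test_missing_instrument_dropped(self):
        out = self._outcome(["A", "C"], ["G", "T"], [0.2, 0.1])
        out.records.drop(index=0, inplace=True)
        table = harmonise(self._exposure(), out, ["rs0", "rs1"])
        assert list(table["SNP"]) == ["rs1"]

    def test_all_dropped_is_hard_error(self):
        out = self._outcome(["C", "C"], ["T", "T"], [0.2, 0.1])
        out.records["EA"] = "C"
        out.records["NEA"] = "C"
        with pytest.raises(ValueError, match="harmonised"):
            harmonise(self._exposure(), out, ["rs0"])

    def test_drop_palindromic_flag(self):
        rec = self._exposure()
        rec.loc[0, ["EA", "NEA"]] = ["A", "T"]
        out = self._outcome(["A", "C"], ["T", "T"], [0.2, 0.1])
        table = harmonise(rec, out, drop_palindromic=True)
        assert "rs0" not in set(table["SNP"])


class TestEndToEndSelection:
    def test_50kb_instruments_subset_of_100kb(self, small_cohort):
        from targetmr.assoc import gwas_scan

        cohort, targets, _, _ = small_cohort
        disc = cohort.partition("discovery")
        ref = cohort.partition("reference")
        stats_ = gwas_scan(disc, "LDL", ["age", "sex", "fasting", "chip"])
        target = targets[0]
        full = select_instruments(stats_, target, ref.dosages)
        narrow = select_instruments(stats_, target, ref.dosages, window_kb=50)
        assert set(narrow.variant_ids) <= set(full.variant_ids)

    def test_instrument_set_respects_r2_threshold(self, small_cohort):
        from targetmr.assoc import gwas_scan

        cohort, targets, _, _ = small_cohort
        disc = cohort.partition("discovery")
        ref = cohort.partition("reference")
        stats_ = gwas_scan(disc, "LDL", ["age", "sex", "fasting", "chip"])
        iset = select_instruments(stats_, targets[0], ref.dosages)
        off = iset.ld.r[~np.eye(len(iset.variant_ids), dtype=bool)]
        assert np.all(off**2 < targets[0].r2_threshold)

    def test_min_instrument_count_enforced(self):
        stats_ = toy_summary([1_000_000], [1e-9])
        rng = np.random.default_rng(8)
        panel = pd.DataFrame({"rs0": rng.binomial(2, 0.3, 200)})
        with pytest.raises(ValueError, match="minimum"):
            select_instruments(stats_, _target(), panel)
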