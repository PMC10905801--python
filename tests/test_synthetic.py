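"""Tests for the synthetic-data generator and its planted generative law."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr, spearmanr

from synprof import synthetic as syn
from synprof.synthetic import AblationMode, Requirement, SynergyMotif


class TestCompoundLibrary:
    def test_empty_library(self):
        lib = syn.simulate_compound_library(n_compounds=0, seed=0)
        assert lib.n_compounds == 0
        assert lib.latent_inhibition.shape == (0, 13)

    def test_determinism(self):
        a = syn.simulate_compound_library(30, 128, 13, 0.2, seed=7)
        b = syn.simulate_compound_library(30, 128, 13, 0.2, seed=7)
        assert a.compound_ids == b.compound_ids
        np.testing.assert_array_equal(a.fingerprints, b.fingerprints)
        np.testing.assert_array_equal(a.latent_inhibition, b.latent_inhibition)

    @pytest.mark.parametrize(
        "kwargs", [{"n_bits": 4}, {"n_targets": 0}, {"n_compounds": -1}, {"sparsity": 1.5}]
    )
    def test_parameter_validation(self, kwargs):
        with pytest.raises(ValueError):
            syn.simulate_compound_library(**{"n_compounds": 10, **kwargs})

    def test_structure_profile_coupling(self):
        """Similar fingerprints must give similar profiles (positive rank
        correlation between Jaccard similarity and profile closeness),
        verified against a direct brute-force pairwise computation."""
        lib = syn.simulate_compound_library(50, 128, 13, 0.2, seed=3)
        fp = lib.fingerprints.astype(bool)
        lat = lib.latent_inhibition
        jaccard, closeness = [], []
        for i, j in itertools.combinations(range(50), 2):  # 1225 pairs
            inter = np.sum(fp[i] & fp[j])
            union = np.sum(fp[i] | fp[j])
            jaccard.append(inter / union)
            closeness.append(-np.linalg.norm(lat[i] - lat[j]))
        rho = spearmanr(jaccard, closeness).statistic
        assert rho > 0

    def test_shared_profile_model_gives_consistent_law(self):
        lib = syn.simulate_compound_library(20, 128, 13, 0.2, seed=1)
        other = syn.simulate_compound_library(
            35, 128, 13, 0.2, seed=2, profile_model=lib.profile_model
        )
        expected = lib.profile_model.profiles(other.fingerprints)
        np.testing.assert_allclose(other.latent_inhibition, expected)


class TestBioactivityScreen:
    def test_noise_free_extremes(self):
        """With no label noise the clearly-inhibiting compound gets an
        IC50 record and the clearly-inert one the inactive flag."""
        lib = syn.simulate_compound_library(2, 128, 13, 0.2, seed=0)
        lib.latent_inhibition[:, 0] = [0.99, 0.01]
        records = syn.simulate_bioactivity_screen(
            lib, 0, active_fraction=0.5, label_noise=0.0, seed=0
        )
        by_id = {r.compound_id: r for r in records}
        high, low = lib.compound_ids
        assert by_id[high].ic50_um is not None and by_id[high].ic50_um <= 10.0
        assert by_id[low].inactive_flag

    def test_class_imbalance_monte_carlo(self):
        lib = syn.simulate_compound_library(2000, 128, 13, 0.2, seed=5)
        records = syn.simulate_bioactivity_screen(
            lib, 0, active_fraction=0.1, label_noise=0.05, seed=6
        )
        frac = np.mean([r.ic50_um is not None for r in records])
        assert 0.05 <= frac <= 0.15

    def test_target_index_out_of_range(self, small_library):
        with pytest.raises(IndexError):
            syn.simulate_bioactivity_screen(small_library, 13, 0.1, 0.0, seed=0)

    def test_record_invariant(self):
        with pytest.raises(ValueError):
            syn.ActivityRecord("c", 0, ic50_um=1.0, inactive_flag=True)
        with pytest.raises(ValueError):
            syn.ActivityRecord("c", 0, ic50_um=-1.0)


class TestCellLines:
    def test_panel_shape_and_codes(self):
        p = syn.simulate_cell_lines(5, 7, seed=0)
        assert p.mutation_codes.shape == (5, 7)
        assert set(np.unique(p.mutation_codes)).issubset({0, 1, 2})
        assert len(set(p.line_ids)) == 5

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_cell_lines(5, 0, seed=0)
        with pytest.raises(ValueError):
            syn.simulate_cell_lines(0, 7, seed=0)

    def test_determinism(self):
        a = syn.simulate_cell_lines(5, 7, seed=9)
        b = syn.simulate_cell_lines(5, 7, seed=9)
        np.testing.assert_array_equal(a.mutation_codes, b.mutation_codes)


class TestTrueSynergy:
    def _motif(self, **kw):
        defaults = dict(
            requirements={0: Requirement.ONE, 1: Requirement.BOTH},
            effect_size=5.0,
            line_weights=(1.0,),
        )
        defaults.update(kw)
        return SynergyMotif(**defaults)

    def test_uncovered_is_exactly_zero(self):
        m = self._motif()
        a = np.zeros(13)
        b = np.zeros(13)
        assert syn.true_synergy(a, b, 0, [m], noise_sd=0.0) == 0.0

    def test_single_covered_motif_sums_to_beta(self):
        m = self._motif()
        a = np.zeros(13)
        a[0] = 0.9
        a[1] = 0.8
        b = np.zeros(13)
        b[1] = 0.7
        assert syn.true_synergy(a, b, 0, [m], noise_sd=0.0) == pytest.approx(5.0)

    def test_one_vs_both_semantics(self):
        m = self._motif()
        a = np.zeros(13)
        a[0] = 0.9
        a[1] = 0.8  # partner does not inhibit target 1 -> BOTH unmet
        b = np.zeros(13)
        assert syn.true_synergy(a, b, 0, [m], noise_sd=0.0) == 0.0

    def test_noisy_mean_matches_noise_free_value(self):
        """Monte-Carlo oracle: the sample mean over many draws approaches
        the noise-free score within 3 standard errors."""
        m = self._motif()
        a = np.full(13, 0.9)
        b = np.full(13, 0.9)
        rng = np.random.default_rng(42)
        draws = [syn.true_synergy(a, b, 0, [m], noise_sd=1.0, rng=rng) for _ in range(10_000)]
        assert abs(np.mean(draws) - 5.0) < 3.0 / np.sqrt(10_000)

    def test_motif_validation(self):
        with pytest.raises(ValueError):
            SynergyMotif({0: Requirement.ONE}, 5.0, (1.0,))
        with pytest.raises(ValueError):
            self._motif(effect_size=-1.0)

    def test_coverage_law_matches_closed_form(self):
        """For a 2-target all-ONE motif under independent Bernoulli(p)
        thresholding the coverage fraction converges to (1-(1-p)^2)^2."""
        p = 0.4
        rng = np.random.default_rng(0)
        m = SynergyMotif(
            {0: Requirement.ONE, 1: Requirement.ONE}, 1.0, (1.0,), inhibition_threshold=0.5
        )
        n = 20_000
        # profiles thresholded i.i.d.: value 0.9 w.p. p else 0.1
        a = np.where(rng.random((n, 13)) < p, 0.9, 0.1)
        b = np.where(rng.random((n, 13)) < p, 0.9, 0.1)
        covered = np.array(
            [syn.true_synergy(a[i], b[i], 0, [m], noise_sd=0.0) > 0 for i in range(n)]
        )
        analytic = (1 - (1 - p) ** 2) ** 2
        assert covered.mean() == pytest.approx(analytic, abs=0.01)


class TestSynergyTable:
    def test_exhaustive_two_compound_case(self):
        lib = syn.simulate_compound_library(2, 128, 13, 0.2, seed=0)
        one_line = syn.simulate_cell_lines(1, 7, seed=12)
        t = syn.simulate_synergy_table(lib, one_line, [], 1, noise_sd=0.0, seed=0)
        assert len(t) == 1

    def test_counts_per_line(self, small_library, panel, motifs):
        t = syn.simulate_synergy_table(small_library, panel, motifs, 100, 0.5, seed=1)
        assert len(t) == 500
        assert (t.groupby("cell_line").size() == 100).all()

    def test_no_self_pairs_and_unordered_uniqueness(self, small_table):
        assert (small_table["drug_a"] != small_table["drug_b"]).all()
        key = small_table.apply(
            lambda r: (tuple(sorted((r.drug_a, r.drug_b))), r.cell_line), axis=1
        )
        assert key.is_unique

    def test_too_many_pairs_rejected(self, panel, motifs):
        lib = syn.simulate_compound_library(4, 128, 13, 0.2, seed=0)
        with pytest.raises(ValueError):
            syn.simulate_synergy_table(lib, panel, motifs, 7, 0.5, seed=0)

    def test_sign_semantics_noise_free(self, small_library, panel, motifs):
        """With only positive-effect motifs and no noise, no pair is
        antagonistic: every score is >= 0."""
        t = syn.simulate_synergy_table(small_library, panel, motifs, 200, 0.0, seed=2)
        assert (t["zip_score"] >= 0).all()


class TestAblationProfiles:
    def test_shuffled_is_derangement(self, small_library):
        base = syn.make_ablation_profiles(small_library, "true_profile")
        shuf = syn.make_ablation_profiles(small_library, "shuffled", seed=0)
        moved = (base.to_numpy() != shuf.to_numpy()).any(axis=1)
        assert moved.all()  # no drug keeps its own profile
        # same multiset of rows
        assert sorted(map(tuple, base.to_numpy().round(9))) == sorted(
            map(tuple, shuf.to_numpy().round(9))
        )

    def test_random_weight_determinism(self, small_library):
        a = syn.make_ablation_profiles(small_library, AblationMode.RANDOM_WEIGHT, seed=5)
        b = syn.make_ablation_profiles(small_library, AblationMode.RANDOM_WEIGHT, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_shuffling_decorrelates_structure(self):
        """After shuffling, profile similarity no longer tracks fingerprint
        similarity (|r| < 0.1 over 500 drugs), by direct pairwise
        computation on a random subsample of pairs."""
        lib = syn.simulate_compound_library(500, 128, 13, 0.2, seed=21)
        shuf = syn.make_ablation_profiles(lib, "shuffled", seed=22).to_numpy()
        fp = lib.fingerprints.astype(bool)
        rng = np.random.default_rng(23)
        ii = rng.integers(0, 500, 4000)
        jj = rng.integers(0, 500, 4000)
        keep = ii != jj
        ii, jj = ii[keep], jj[keep]
        jac = np.array(
            [np.sum(fp[i] & fp[j]) / np.sum(fp[i] | fp[j]) for i, j in zip(ii, jj)]
        )
        close = -np.linalg.norm(shuf[ii] - shuf[jj], axis=1)
        assert abs(pearsonr(jac, close).statistic) < 0.1

    def test_fingerprint_mode_returns_bits(self, small_library):
        fpdf = syn.make_ablation_profiles(small_library, "fingerprint")
        assert fpdf.shape == (40, 128)
        np.testing.assert_array_equal(
            fpdf.to_numpy(), small_library.fingerprints.astype(float)
        )

    def test_unknown_mode_rejected(self, small_library):
        with pytest.raises(ValueError):
            syn.make_ablation_profiles(small_library, "nonsense")
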