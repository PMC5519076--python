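import itertools
import math

import numpy as np
import pytest

import oracles
from conftest import random_matrix
from corecollect import (
    MISSING,
    GenotypeMatrix,
    SelectionConfig,
    SyntheticSpec,
    allele_frequency_spectrum,
    build_allele_table,
    build_class_table,
    cv,
    evaluate_core,
    generate,
    modified_rogers,
    select_core,
    shannon,
    spectrum_max_difference,
)


def matrix(rows):
    calls = np.array(rows, dtype=object)
    n, m = calls.shape
    return GenotypeMatrix([f"S{j}" for j in range(n)], [f"M{i}" for i in range(m)], calls)


def tables(G):
    return build_class_table(G), build_allele_table(G)


class TestCoverage:
    def test_entire_collection_covers_everything(self, triplicated_matrix):
        T, _ = tables(triplicated_matrix)
        assert cv(triplicated_matrix.sample_ids, triplicated_matrix, T) == 100.0

    def test_single_sample_on_two_class_markers_covers_half(self):
        G = matrix([["AA", "GG", "AG"], ["AG", "CC", "AA"]])
        T, _ = tables(G)
        assert cv(["S0"], G, T) == pytest.approx(50.0)

    def test_empty_subset_is_zero(self, triplicated_matrix):
        T, _ = tables(triplicated_matrix)
        assert cv([], triplicated_matrix, T) == 0.0

    def test_monotone_under_subset_growth(self):
        rng = np.random.default_rng(8)
        G = random_matrix(rng, n_samples=8, n_markers=10)
        T, _ = tables(G)
        values = [cv(list(range(k)), G, T) for k in range(1, 9)]
        assert all(b >= a for a, b in zip(values, values[1:]))


class TestShannon:
    def test_monomorphic_markers_give_zero(self):
        G = matrix([["AA", "GG"], ["AA", "GG"]])
        T, A = tables(G)
        assert shannon(G.sample_ids, G, A) == 0.0

    def test_half_frequency_closed_form(self):
        G = matrix([["AA", "GG"], ["CC", "TT"]])
        _, A = tables(G)
        expected = 2 * (-0.5 * math.log(0.5))
        assert shannon(G.sample_ids, G, A) == pytest.approx(expected, abs=1e-6)

    def test_absent_reference_allele_contributes_zero(self):
        # within the subset {S1} the collection-major allele A has p=0
        G = matrix([["AA"], ["AA"], ["GG"]])
        _, A = tables(G)
        assert A.ref_allele == ["A"]
        assert shannon(["S2"], G, A) == 0.0

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(4)
        G = random_matrix(rng, n_samples=9, n_markers=11)
        _, A = tables(G)
        subset = ["S1", "S4", "S7"]
        assert shannon(subset, G, A) == pytest.approx(shannon(subset[::-1], G, A))


class TestModifiedRogers:
    def test_self_distance_zero(self):
        rng = np.random.default_rng(0)
        G = random_matrix(rng)
        _, A = tables(G)
        for j in range(G.n_samples):
            assert modified_rogers(j, j, A) == 0.0

    def test_opposite_homozygotes_at_distance_one(self):
        G = matrix([["AA", "CC", "GG"], ["GG", "TT", "AA"]])
        _, A = tables(G)
        assert modified_rogers(0, 1, A) == pytest.approx(1.0)

    def test_hom_vs_het_single_marker(self):
        G = matrix([["AA"], ["AG"]])
        _, A = tables(G)
        assert modified_rogers(0, 1, A) == pytest.approx(0.5)

    def test_no_shared_marker_raises(self):
        G = matrix([["AA", MISSING], [MISSING, "GG"]])
        _, A = tables(G)
        with pytest.raises(ValueError, match="MR undefined"):
            modified_rogers(0, 1, A)

    @pytest.mark.parametrize("seed", range(10))
    def test_symmetry_and_range(self, seed):
        rng = np.random.default_rng(seed)
        G = random_matrix(rng, n_samples=6, n_markers=8, missing_rate=0.1)
        _, A = tables(G)
        for x, y in itertools.combinations(range(G.n_samples), 2):
            d = modified_rogers(x, y, A)
            assert d == pytest.approx(modified_rogers(y, x, A))
            assert 0.0 <= d <= 1.0 + 1e-12


class TestEvaluateCore:
    def test_identical_pair_has_zero_distances(self):
        G = matrix([["AA", "AG"], ["AA", "AG"], ["GG", "GG"]])
        T, A = tables(G)
        cm = evaluate_core(["S0", "S1"], G, T, A)
        assert cm.mr_mean == cm.mr_min == 0.0

    def test_entire_collection_row(self, triplicated_matrix):
        T, A = tables(triplicated_matrix)
        cm = evaluate_core(triplicated_matrix.sample_ids, triplicated_matrix, T, A)
        assert cm.cv_percent == 100.0
        assert cm.n_samples == 15
        assert cm.mr_min <= cm.mr_mean <= 1.0

    def test_three_sample_min_is_smallest_pairwise(self):
        G = matrix([["AA", "AA"], ["AG", "AA"], ["GG", "GG"]])
        T, A = tables(G)
        cm = evaluate_core(["S0", "S1", "S2"], G, T, A)
        pairs = [modified_rogers(x, y, A) for x, y in itertools.combinations(range(3), 2)]
        assert cm.mr_min == pytest.approx(min(pairs))
        assert cm.mr_mean == pytest.approx(np.mean(pairs))

    def test_singleton_has_undefined_mr(self):
        G = matrix([["AA"], ["AG"]])
        T, A = tables(G)
        cm = evaluate_core(["S0"], G, T, A)
        assert cm.mr_mean is None and cm.mr_min is None


class TestNaiveOracleEquivalence:
    @pytest.mark.parametrize("seed", range(25))
    def test_cv_sh_mr_match_loop_implementations(self, seed):
        rng = np.random.default_rng(seed)
        G = random_matrix(rng)
        T, A = tables(G)
        calls = [list(row) for row in G.calls]
        subset = sorted(rng.choice(G.n_samples, size=max(2, G.n_samples // 2), replace=False))
        assert cv(list(subset), G, T) == pytest.approx(
            oracles.coverage_cv(calls, subset), abs=1e-12
        )
        assert shannon(list(subset), G, A) == pytest.approx(
            oracles.shannon_sh(calls, subset), abs=1e-12
        )
        for x, y in itertools.combinations(subset, 2):
            expect = oracles.modified_rogers_mr(calls, x, y)
            if expect is None:
                with pytest.raises(ValueError):
                    modified_rogers(x, y, A)
            else:
                assert modified_rogers(x, y, A) == pytest.approx(expect, abs=1e-12)


class TestSelectionConsistency:
    def test_metrics_cv_equals_final_trace_cv(self):
        spec = SyntheticSpec(n_founders=6, dups_per_founder=4, n_markers=60,
                             missing_rate=0.05, mutation_rate=0.02, seed=9)
        G, _ = generate(spec)
        res = select_core(G, SelectionConfig(target_cv_percent=100, delta_percent=0))
        T, _ = tables(G)
        assert cv(res.core_ids, G, T) == pytest.approx(res.final_cv_percent, abs=1e-9)


class TestSpectrum:
    def test_subset_against_itself_is_identical(self, triplicated_matrix):
        _, A = tables(triplicated_matrix)
        d = spectrum_max_difference(
            triplicated_matrix.sample_ids, triplicated_matrix.sample_ids,
            triplicated_matrix, A,
        )
        assert d == 0.0

    def test_monomorphic_data_occupies_one_bin(self):
        G = matrix([["AA", "GG"], ["AA", "GG"]])
        _, A = tables(G)
        counts, edges = allele_frequency_spectrum(G.sample_ids, G, A, bin_width=0.05)
        assert counts.sum() == 2
        assert (counts > 0).sum() == 1

    def test_bad_bin_width_rejected(self, triplicated_matrix):
        _, A = tables(triplicated_matrix)
        with pytest.raises(ValueError):
            allele_frequency_spectrum(triplicated_matrix.sample_ids,
                                      triplicated_matrix, A, bin_width=0.0)

    def test_core_spectrum_tracks_entire_collection(self):
        spec = SyntheticSpec(n_founders=60, dups_per_founder=2, n_markers=800,
                             maf_dist=(0.8, 0.8), missing_rate=0.02, seed=12)
        G, _ = generate(spec)
        res = select_core(G)
        _, A = tables(G)
        d = spectrum_max_difference(res.core_ids, G.sample_ids, G, A, bin_width=0.05)
        assert d <= 0.15
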