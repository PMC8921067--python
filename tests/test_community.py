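import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import braycurtis as scipy_braycurtis
from scipy.stats import rankdata

from phenocomm import (
    bray_curtis,
    bray_curtis_matrix,
    classify_modulation,
    differential_table,
    mann_whitney_exact,
    pcoa,
    shannon_diversity,
    summarize_modulation,
)


def closed(values):
    a = np.asarray(values, dtype=float)
    return a / a.sum()


class TestShannon:
    def test_uniform_is_log_richness(self):
        assert shannon_diversity([0.25] * 4) == pytest.approx(math.log(4))

    def test_single_taxon_is_zero(self):
        assert shannon_diversity([1.0]) == 0.0

    def test_hand_computed_mixture(self):
        assert shannon_diversity([0.5, 0.25, 0.25]) == pytest.approx(1.0397, abs=1e-4)

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError):
            shannon_diversity([1.5, -0.5])

    @given(st.lists(st.floats(min_value=0.01, max_value=1.0), min_size=2, max_size=12))
    @settings(deadline=None, max_examples=50)
    def test_uniform_maximizes_entropy(self, raw):
        a = closed(raw)
        assert shannon_diversity(a) <= shannon_diversity([1 / a.size] * a.size) + 1e-12


class TestBrayCurtis:
    def test_identical_samples_are_zero(self):
        a = pd.Series(closed([1, 2, 3]))
        assert bray_curtis(a, a) == pytest.approx(0.0)

    def test_disjoint_supports_are_one(self):
        a = pd.Series([0.6, 0.4, 0.0, 0.0])
        b = pd.Series([0.0, 0.0, 0.3, 0.7])
        assert bray_curtis(a, b) == pytest.approx(1.0)

    def test_hand_computed_overlap(self):
        a = pd.Series([0.6, 0.4, 0.0])
        b = pd.Series([0.2, 0.4, 0.4])
        assert bray_curtis(a, b) == pytest.approx(0.4)

    def test_mismatched_taxa_rejected(self):
        a = pd.Series({"x": 1.0})
        b = pd.Series({"y": 1.0})
        with pytest.raises(ValueError, match="taxa"):
            bray_curtis(a, b)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=3, max_size=8),
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=3, max_size=8),
    )
    @settings(deadline=None, max_examples=50)
    def test_agrees_with_scipy_on_closed_compositions(self, raw_a, raw_b):
        n = min(len(raw_a), len(raw_b))
        a = closed(np.asarray(raw_a[:n]) + 1e-3)
        b = closed(np.asarray(raw_b[:n]) + 1e-3)
        assert bray_curtis(pd.Series(a), pd.Series(b)) == pytest.approx(
            scipy_braycurtis(a, b)
        )


class TestPcoa:
    def test_identical_samples_coincide(self):
        d = pd.DataFrame([[0.0, 0.0, 0.5], [0.0, 0.0, 0.5], [0.5, 0.5, 0.0]],
                         index=list("abc"), columns=list("abc"))
        coords = pcoa(d).coordinates
        assert np.allclose(coords.loc["a"], coords.loc["b"], atol=1e-9)

    def test_equidistant_triple_embeds_symmetrically(self):
        d = pd.DataFrame(0.7 * (1 - np.eye(3)), index=list("abc"), columns=list("abc"))
        coords = pcoa(d).coordinates.to_numpy()
        dists = [np.linalg.norm(coords[i] - coords[j]) for i, j in combinations(range(3), 2)]
        assert np.allclose(dists, dists[0], atol=1e-9)

    def test_euclidean_distances_are_reproduced(self):
        rng = np.random.default_rng(7)
        points = rng.normal(size=(6, 3))
        d = np.linalg.norm(points[:, None] - points[None, :], axis=2)
        result = pcoa(pd.DataFrame(d))
        coords = result.coordinates.to_numpy()
        embedded = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        assert np.allclose(embedded, d, atol=1e-6)
        assert result.proportion_explained.sum() == pytest.approx(1.0)

    def test_asymmetric_matrix_rejected(self):
        d = pd.DataFrame([[0.0, 0.2], [0.4, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(d)

    def test_negative_eigenvalues_are_reported_for_non_euclidean_input(self):
        # Bray-Curtis on sparse compositions is generally non-Euclidean
        rng = np.random.default_rng(3)
        data = rng.dirichlet(np.full(12, 0.2), size=10)
        result = pcoa(bray_curtis_matrix(pd.DataFrame(data)))
        assert result.eigenvalues.min() < 0

    def test_matches_skbio_embedding_distances(self):
        skbio_pcoa = pytest.importorskip("skbio.stats.ordination").pcoa
        rng = np.random.default_rng(5)
        data = pd.DataFrame(rng.dirichlet(np.ones(6), size=5))
        d = bray_curtis_matrix(data)
        ours = pcoa(d).coordinates.to_numpy()
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            theirs = skbio_pcoa(d.to_numpy()).samples.to_numpy()
        k = ours.shape[1]
        ours_d = np.linalg.norm(ours[:, None] - ours[None, :], axis=2)
        theirs_d = np.linalg.norm(theirs[:, None, :k] - theirs[None, :, :k], axis=2)
        assert np.allclose(ours_d, theirs_d, atol=1e-6)


def enumeration_oracle(a, b):
    """Two-tailed exact Mann-Whitney p by direct pairwise-comparison counting.

    Independent of the implementation under test: U is computed from the
    definitional count of (i, j) pairs with a_i > b_j (ties count 1/2),
    and the null distribution enumerates every group labeling.
    """
    pooled = list(a) + list(b)
    n_a = len(a)

    def u_of(subset):
        inside = [pooled[i] for i in subset]
        outside = [pooled[i] for i in range(len(pooled)) if i not in subset]
        return sum(
            1.0 if x > y else 0.5 if x == y else 0.0 for x in inside for y in outside
        )

    observed = u_of(tuple(range(n_a)))
    mean_u = n_a * (len(pooled) - n_a) / 2.0
    labelings = list(combinations(range(len(pooled)), n_a))
    if observed <= mean_u:
        tail = sum(u_of(s) <= observed + 1e-9 for s in labelings)
    else:
        tail = sum(u_of(s) >= observed - 1e-9 for s in labelings)
    return observed, min(1.0, 2.0 * tail / len(labelings))


class TestMannWhitneyExact:
    def test_complete_separation_at_4v4_gives_2_over_70(self):
        u, p = mann_whitney_exact([1, 2, 3, 4], [5, 6, 7, 8])
        assert u == 0.0
        assert p == pytest.approx(2 / 70)
        assert round(p, 2) == 0.03

    def test_identical_groups_give_p_one(self):
        _, p = mann_whitney_exact([1, 1, 1], [1, 1, 1])
        assert p == 1.0

    def test_one_crossing_pair_gives_4_over_70(self):
        u, p = mann_whitney_exact([1, 2, 3, 5], [4, 6, 7, 8])
        assert u == 1.0
        assert p == pytest.approx(4 / 70)

    def test_groups_below_two_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_exact([1], [2, 3])

    def test_matches_enumeration_oracle_with_ties(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            n_a, n_b = rng.integers(2, 5, 2)
            values = rng.integers(0, 4, n_a + n_b)  # heavy ties on purpose
            u, p = mann_whitney_exact(values[:n_a], values[n_a:])
            u_exp, p_exp = enumeration_oracle(values[:n_a], values[n_a:])
            assert u == pytest.approx(u_exp)
            assert p == pytest.approx(p_exp)

    def test_large_samples_fall_back_to_asymptotic(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        from scipy.stats import mannwhitneyu

        u, p = mann_whitney_exact(a, b)
        expected = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(expected.statistic)
        assert p == pytest.approx(expected.pvalue)

    def test_tie_free_p_floor_reached_only_at_separation(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n_a, n_b = rng.integers(2, 5, 2)
            values = rng.permutation(np.arange(1.0, n_a + n_b + 1))
            _, p = mann_whitney_exact(values[:n_a], values[n_a:])
            floor = 2 / math.comb(n_a + n_b, n_a)
            assert p >= floor - 1e-12
            separated = (max(values[:n_a]) < min(values[n_a:])) or (
                min(values[:n_a]) > max(values[n_a:])
            )
            assert (abs(p - floor) < 1e-12) == separated


class TestClassifyModulation:
    def test_sixfold_increase_is_increased(self):
        call = classify_modulation(0.01, 0.06)
        assert call.direction == "increased"
        assert call.fold_ratio == pytest.approx(6.0)

    def test_unchanged_is_unaltered(self):
        assert classify_modulation(0.02, 0.02).direction == "unaltered"

    def test_exactly_fivefold_is_unaltered(self):
        assert classify_modulation(0.01, 0.05).direction == "unaltered"

    def test_new_taxon_counts_as_increased(self):
        call = classify_modulation(0.0, 0.046)
        assert call.direction == "increased"
        assert call.marker == "new"

    def test_lost_taxon_counts_as_decreased(self):
        call = classify_modulation(0.046, 0.0)
        assert call.direction == "decreased"
        assert call.marker == "lost"

    def test_negative_means_rejected(self):
        with pytest.raises(ValueError):
            classify_modulation(-0.1, 0.2)

    @given(
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(deadline=None)
    def test_antisymmetric_in_control_and_treatment(self, c, t):
        forward = classify_modulation(c, t).direction
        backward = classify_modulation(t, c).direction
        swap = {"increased": "decreased", "decreased": "increased", "unaltered": "unaltered"}
        assert backward == swap[forward]


class TestDifferentialTable:
    def make_inputs(self):
        rng = np.random.default_rng(4)
        samples = [f"{c}_r{i}" for c in ["control", "butyrate", "valerate"] for i in range(4)]
        metadata = pd.DataFrame(
            {"condition": [s.rsplit("_", 1)[0] for s in samples],
             "replicate": [int(s[-1]) for s in samples]},
            index=samples,
        )
        values = pd.DataFrame(
            {"flat": 0.5, "shifted": np.r_[rng.uniform(0.01, 0.02, 4),
                                           rng.uniform(0.2, 0.3, 4),
                                           rng.uniform(0.01, 0.02, 4)]},
            index=samples,
        )
        return values, metadata

    def test_flat_feature_is_unaltered_with_p_one(self):
        values, metadata = self.make_inputs()
        diff = differential_table(values, metadata)
        flat = diff[diff.feature == "flat"]
        assert (flat.direction == "unaltered").all()
        assert (flat.p == 1.0).all()

    def test_separated_tenfold_feature_hits_the_exact_floor(self):
        values, metadata = self.make_inputs()
        diff = differential_table(values, metadata)
        row = diff[(diff.feature == "shifted") & (diff.condition == "butyrate")].iloc[0]
        assert row.direction == "increased"
        assert row.p == pytest.approx(2 / 70)

    def test_row_count_is_features_times_noncontrol_conditions(self):
        values, metadata = self.make_inputs()
        diff = differential_table(values, metadata)
        assert len(diff) == values.shape[1] * 2

    def test_missing_control_errors(self):
        values, metadata = self.make_inputs()
        with pytest.raises(ValueError, match="control"):
            differential_table(values, metadata, control="absent")

    def test_summary_counts_add_up(self):
        values, metadata = self.make_inputs()
        summary = summarize_modulation(differential_table(values, metadata))
        assert (summary[["altered", "unaltered"]].sum(axis=1) == values.shape[1]).all()
        assert summary.loc["butyrate", "increased"] == 1
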