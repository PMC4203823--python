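import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bgctype.association import CorrelationMatrix
from bgctype.clustering import PCAResult, TypingResult, cluster_bgc_types, pca_decompose
from bgctype.ingest import FeatureTable
from bgctype.profiling import (
    collapse_taxonomy,
    community_distribution,
    extract_chemical_profile,
    pair_stdevp,
    scale_unit_variance_nocenter,
    select_explaining_pc,
)


class TestScaling:
    def test_constant_vector(self):
        assert np.allclose(scale_unit_variance_nocenter([2, 2, 2]), [1, 1, 1])

    def test_hand_computed(self):
        rms = np.sqrt((9 + 16) / 2)  # population RMS of (3, -4)
        got = scale_unit_variance_nocenter([3, -4])
        assert np.allclose(got, [3 / rms, -4 / rms])

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            scale_unit_variance_nocenter([0.0, 0.0])

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=20), st.floats(0.01, 50))
    def test_mean_square_one_and_scale_free(self, v, c):
        if not any(abs(x) > 1e-6 for x in v):
            return
        scaled = scale_unit_variance_nocenter(v)
        assert np.mean(scaled**2) == pytest.approx(1.0, abs=1e-9)
        # positively homogeneous of degree 0
        assert np.allclose(scale_unit_variance_nocenter(np.asarray(v) * c), scaled)


class TestPairStdevp:
    @pytest.mark.parametrize(
        "a,b,want", [(1, 0, 0.5), (0.9, 0.1, 0.4), (0.3, 0.3, 0.0), (-1, 1, 1.0)]
    )
    def test_values(self, a, b, want):
        assert pair_stdevp(a, b) == pytest.approx(want)
        assert pair_stdevp(b, a) == pytest.approx(want)

    @given(st.floats(-10, 10), st.floats(-10, 10))
    def test_symmetric_nonnegative_zero_iff_equal(self, a, b):
        s = pair_stdevp(a, b)
        assert s >= 0
        assert s == pair_stdevp(b, a)
        assert (s == 0) == (a == b)
        # matches the two-point population standard deviation
        assert s == pytest.approx(np.std([a, b]), abs=1e-12)


def _typing_with_scores(labels: dict, scores: np.ndarray, loadings=None) -> TypingResult:
    n_comp = scores.shape[1]
    loadings = loadings if loadings is not None else np.eye(max(3, n_comp))[:, :n_comp]
    pca = PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance=np.arange(n_comp, 0, -1, dtype=float),
        centering="mean",
    )
    return TypingResult(
        labels=labels,
        k=len(set(labels.values())),
        curve=None,
        pca=pca,
        cluster_space="corr_rows",
        seed=0,
    )


def _rel_table(values, ids, samples=None, taxonomy=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return FeatureTable(
        pd.DataFrame(values, index=ids, columns=samples),
        "fused_community",
        "relative_abundance",
        taxonomy,
    )


class TestCommunityDistribution:
    def test_single_type_equals_domain_column_sums(self):
        ids = ["16S|a", "16S|b"]
        table = _rel_table([[0.1, 0.2], [0.3, 0.1]], ids)
        t = _typing_with_scores({i: 1 for i in ids}, np.zeros((2, 2)))
        dist = community_distribution(t, table)
        assert np.allclose(dist[1].loc["16S"], [0.4, 0.3])

    def test_partition_conserves_column_sums(self, filtered_corr):
        fused, _, kept, _ = filtered_corr
        res = cluster_bgc_types(kept, 4, seed=0, n_init=10)
        dist = community_distribution(res, fused.community)
        total = sum(frame.sum(axis=0) for frame in dist.values())
        member_sum = fused.community.data.loc[list(res.labels)].sum(axis=0)
        assert np.abs(total - member_sum).max() < 1e-12

    def test_missing_member_rejected(self):
        table = _rel_table([[0.1, 0.2]], ["16S|a"])
        t = _typing_with_scores({"16S|a": 1, "16S|ghost": 1}, np.zeros((2, 2)))
        with pytest.raises(KeyError, match="ghost"):
            community_distribution(t, table)


class TestCollapseTaxonomy:
    def test_same_class_collapses_to_100_percent(self):
        ids = ["16S|a", "16S|b"]
        tax = {
            "16S|a": ("Bacteria", "Pa", "Actinobacteria"),
            "16S|b": ("Bacteria", "Pb", "Actinobacteria"),
        }
        table = _rel_table([[0.1], [0.3]], ids)
        t = _typing_with_scores({i: 1 for i in ids}, np.zeros((2, 2)))
        out = collapse_taxonomy(t, tax, table)
        assert out[1].to_dict() == pytest.approx({"Actinobacteria": 100.0})

    def test_truncated_lineage_falls_back_to_deepest_rank(self):
        ids = ["16S|a", "16S|b"]
        tax = {"16S|a": ("Bacteria", "Chloroflexi"), "16S|b": ()}
        table = _rel_table([[0.2], [0.2]], ids)
        t = _typing_with_scores({i: 1 for i in ids}, np.zeros((2, 2)))
        out = collapse_taxonomy(t, tax, table)
        assert out[1].to_dict() == pytest.approx({"Chloroflexi": 50.0, "Unassigned": 50.0})

    def test_equal_abundance_four_classes(self):
        ids = [f"16S|{i}" for i in "abcd"]
        tax = {f"16S|{c}": ("Bacteria", "P", f"Class_{c}") for c in "abcd"}
        table = _rel_table([[0.1]] * 4, ids)
        t = _typing_with_scores({i: 1 for i in ids}, np.zeros((4, 2)))
        out = collapse_taxonomy(t, tax, table)
        assert all(v == pytest.approx(25.0) for v in out[1].to_dict().values())

    def test_percentages_sum_to_100_per_type(self, filtered_corr):
        fused, _, kept, _ = filtered_corr
        res = cluster_bgc_types(kept, 4, seed=0, n_init=10)
        out = collapse_taxonomy(res, fused.community.taxonomy, fused.community)
        for series in out.values():
            assert series.sum() == pytest.approx(100.0, abs=1e-6)


class TestExplainingPC:
    def test_centroid_magnitude_picks_pc(self):
        labels = {"a": 1, "b": 1, "c": 2, "d": 2}
        scores = np.array([[5.0, 0.2], [4.8, 0.1], [0.1, -3.0], [0.2, -2.8]])
        t = _typing_with_scores(labels, scores)
        assert select_explaining_pc(t) == {1: 1, 2: 2}

    def test_exact_tie_warns_and_uses_pc1(self):
        labels = {"a": 1, "b": 1}
        scores = np.array([[2.0, -2.0], [2.0, -2.0]])
        t = _typing_with_scores(labels, scores)
        with pytest.warns(UserWarning, match="PC1"):
            assert select_explaining_pc(t) == {1: 1}

    def test_cross_geometry_maps_two_types_per_pc(self, filtered_corr):
        _, _, kept, truth = filtered_corr
        res = cluster_bgc_types(kept, 4, seed=0, n_init=20)
        mapping = select_explaining_pc(res)
        assert sorted(mapping.values()) == [1, 1, 2, 2]


class TestChemicalProfile:
    def test_negative_average_correlation_never_extracted(self, filtered_corr):
        _, _, kept, _ = filtered_corr
        res = cluster_bgc_types(kept, 4, seed=0, n_init=10)
        profiles = extract_chemical_profile(kept, res, cut=0.0)
        for frame in profiles.values():
            neg = frame[frame["avg_correlation"] <= 0]
            assert not neg["extracted"].any()

    def test_extracted_requires_stdevp_at_cut(self, filtered_corr):
        _, _, kept, _ = filtered_corr
        res = cluster_bgc_types(kept, 4, seed=0, n_init=10)
        profiles = extract_chemical_profile(kept, res, cut=0.20)
        for frame in profiles.values():
            assert (frame.loc[frame["extracted"], "stdevp"] >= 0.20).all()

    def test_planted_variables_recovered(self, filtered_corr):
        _, _, kept, truth = filtered_corr
        res = cluster_bgc_types(kept, 4, seed=0, n_init=20)
        profiles = extract_chemical_profile(kept, res)
        hits = 0
        for bgc, frame in profiles.items():
            members = [
                truth.otu_to_type[o] for o in res.members(bgc) if o in truth.otu_to_type
            ]
            planted = max(set(members), key=members.count)
            extracted = set(frame.index[frame["extracted"]])
            hits += len(extracted & set(truth.chems_of_type(planted)))
        assert hits >= 16  # out of 20 planted chemical variables

    def test_empty_cluster_rejected(self):
        m = CorrelationMatrix(
            otu_ids=["a", "b"],
            chem_ids=["c1", "c2"],
            rho=np.array([[0.9, 0.1], [0.8, 0.2]]),
            n_samples=14,
            undefined_mask=np.zeros((2, 2), dtype=bool),
        )
        t = _typing_with_scores({"a": 1, "b": 1}, np.array([[1.0, 0.0], [1.0, 0.1]]))
        t.k = 2  # declare a second, empty type
        with pytest.raises(ValueError, match="no member"):
            extract_chemical_profile(m, t)
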