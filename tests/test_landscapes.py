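"""Multi-sample landscape comparison: unions, unique bases, trees, PCA."""

import numpy as np
import pytest

import _oracles as oracle
from dhskit.intervals import GenomicInterval, IntervalSet, total_bases
from dhskit.landscapes import (
    bootstrap_dendrogram,
    build_union,
    large_dhs_set,
    pca_landscape,
    saturation_curve,
    unique_bases,
)
from dhskit.quantify import CutTrack, DhsMatrix, SampleProfile
from dhskit.synthetic import generate_grouped_matrix

CHROM_LEN = 10_000


def iv(c, s, e):
    return GenomicInterval(c, s, e)


def profile(name, intervals, cuts_per_dhs=100, rng=None):
    """A sample whose track carries ``cuts_per_dhs`` cuts in each hotspot."""
    positions = []
    for v in intervals:
        if rng is None:
            positions.extend(np.linspace(v.start, v.end - 1, cuts_per_dhs).astype(int))
        else:
            positions.extend(rng.integers(v.start, v.end, cuts_per_dhs))
    track = CutTrack.from_positions({"chr1": np.array(positions, dtype=np.int64)})
    return SampleProfile(name, track, IntervalSet(list(intervals)))


def random_profiles(rng, n_samples=5, n_dhs=40):
    out = []
    for i in range(n_samples):
        ivs = oracle.random_interval_set(rng, n=n_dhs, length=CHROM_LEN)
        out.append(profile(f"s{i}", list(ivs), rng=rng))
    return out


class TestBuildUnion:
    def test_identical_samples_union_equals_either(self):
        ivs = [iv("chr1", 100, 300), iv("chr1", 500, 700)]
        ls = build_union([profile("a", ivs), profile("b", ivs)])
        assert ls.union_dhss.intervals == ivs
        assert ls.union_bases == 400

    def test_disjoint_samples_add_bases(self):
        a = profile("a", [iv("chr1", 100, 300)])
        b = profile("b", [iv("chr1", 500, 700)])
        ls = build_union([a, b])
        assert ls.union_bases == 400

    def test_low_count_dhss_are_excluded(self):
        a = profile("a", [iv("chr1", 100, 300)], cuts_per_dhs=30)  # <= 50 gate
        b = profile("b", [iv("chr1", 500, 700)], cuts_per_dhs=100)
        assert large_dhs_set(a).intervals == []
        assert build_union([a, b]).union_bases == 200

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            build_union([profile("a", [iv("chr1", 0, 10)])])

    def test_union_bases_match_per_base_oracle(self):
        rng = np.random.default_rng(41)
        for _ in range(10):
            profiles = random_profiles(rng)
            ls = build_union(profiles)
            expected = oracle.union_bases(
                [ls.large_sets[p.name] for p in profiles], {"chr1": CHROM_LEN})
            assert ls.union_bases == expected


class TestUniqueBases:
    def test_fully_covered_sample_contributes_nothing(self):
        shared = [iv("chr1", 100, 300)]
        ls = build_union([profile("a", shared), profile("b", shared),
                          profile("c", shared + [iv("chr1", 600, 800)])])
        ub = unique_bases(ls)
        assert ub.unique_bp == {"a": 0, "b": 0, "c": 200}
        assert ub.unique_fraction["c"] == pytest.approx(200 / 400)

    def test_private_dhs_counted_exactly(self):
        a = profile("a", [iv("chr1", 100, 300), iv("chr1", 4000, 5000)])
        b = profile("b", [iv("chr1", 100, 300)])
        assert unique_bases(build_union([a, b])).unique_bp["a"] == 1_000

    def test_matches_per_base_ownership_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            profiles = random_profiles(rng)
            ls = build_union(profiles)
            ub = unique_bases(ls)
            covs = {p.name: oracle.coverage(ls.large_sets[p.name], "chr1", CHROM_LEN)
                    for p in profiles}
            stack = np.array(list(covs.values()))
            owners = stack.sum(axis=0)
            for name in covs:
                expected = int((covs[name] & (owners == 1)).sum())
                assert ub.unique_bp[name] == expected
            # partition identity: unique + multiply-covered == union
            assert sum(ub.unique_bp.values()) + int((owners >= 2).sum()) \
                == ls.union_bases

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(43)
        profiles = random_profiles(rng, n_samples=4)
        ub1 = unique_bases(build_union(profiles))
        ub2 = unique_bases(build_union(profiles[::-1]))
        assert ub1.unique_bp == ub2.unique_bp


class TestSaturation:
    def test_identical_samples_flat_after_first(self):
        ivs = [iv("chr1", 100, 300)]
        ls = build_union([profile(n, ivs) for n in "abc"])
        _, cum = saturation_curve(ls)
        assert cum == [200, 200, 200]

    def test_disjoint_samples_linear(self):
        ls = build_union([profile("a", [iv("chr1", 0, 100)]),
                          profile("b", [iv("chr1", 200, 300)]),
                          profile("c", [iv("chr1", 400, 500)])])
        _, cum = saturation_curve(ls)
        assert cum == [100, 200, 300]

    def test_prefixes_match_oracle_and_curve_monotone(self):
        rng = np.random.default_rng(44)
        profiles = random_profiles(rng)
        ls = build_union(profiles)
        order, cum = saturation_curve(ls)
        for i in range(len(order)):
            expected = oracle.union_bases(
                [ls.large_sets[n] for n in order[: i + 1]], {"chr1": CHROM_LEN})
            assert cum[i] == expected
        assert cum == sorted(cum)
        assert cum[-1] == ls.union_bases


class TestDendrogram:
    def test_two_planted_clades_fully_supported(self):
        m = generate_grouped_matrix(n_dhs=2_000, seed=45)
        d = bootstrap_dendrogram(m, n_trees=50, subsample=500, seed=46)
        clade = frozenset({"B1", "B2", "B3"})  # == {A*} on the unrooted tree
        assert d.support[clade] >= 0.95
        assert all(0 <= s <= 1 for s in d.support.values())

    def test_three_samples_have_no_internal_bipartitions(self):
        m = generate_grouped_matrix(n_dhs=500, group_sizes=(2, 1), seed=47)
        d = bootstrap_dendrogram(m, n_trees=10, subsample=200, seed=48)
        assert d.support == {}
        assert d.to_newick().endswith(";")

    def test_row_permutation_leaves_tree_unchanged(self):
        m = generate_grouped_matrix(n_dhs=800, seed=49)
        rng = np.random.default_rng(50)
        perm = rng.permutation(800)
        m2 = DhsMatrix(IntervalSet([m.dhss[i] for i in perm]), m.samples,
                       m.counts[perm])
        d1 = bootstrap_dendrogram(m, n_trees=5, subsample=800, seed=51)
        d2 = bootstrap_dendrogram(m2, n_trees=5, subsample=800, seed=51)
        # full-matrix subsample: identical data, so identical topology
        assert set(d1.support) == set(d2.support)

    def test_subsample_larger_than_rows_rejected(self):
        m = generate_grouped_matrix(n_dhs=100, seed=52)
        with pytest.raises(ValueError):
            bootstrap_dendrogram(m, n_trees=5, subsample=101, seed=0)

    def test_same_seed_is_deterministic(self):
        m = generate_grouped_matrix(n_dhs=600, seed=53)
        d1 = bootstrap_dendrogram(m, n_trees=20, subsample=200, seed=9)
        d2 = bootstrap_dendrogram(m, n_trees=20, subsample=200, seed=9)
        assert d1.support == d2.support and d1.to_newick() == d2.to_newick()


class TestPca:
    def test_pc1_separates_planted_groups(self):
        m = generate_grouped_matrix(n_dhs=2_000, seed=54)
        scores, evr = pca_landscape(m)
        pc1 = scores["PC1"]
        a = pc1[[s for s in m.samples if s.startswith("A")]]
        b = pc1[[s for s in m.samples if s.startswith("B")]]
        assert (np.sign(a) == np.sign(a.iloc[0])).all()
        assert (np.sign(b) == -np.sign(a.iloc[0])).all()
        assert evr[0] > evr[1] >= 0

    def test_duplicated_sample_scores_coincide(self):
        m = generate_grouped_matrix(n_dhs=500, seed=55)
        dup = DhsMatrix(m.dhss, m.samples + ["A1_copy"],
                        np.column_stack([m.counts, m.counts[:, 0]]))
        scores, _ = pca_landscape(dup)
        assert np.allclose(scores.loc["A1"], scores.loc["A1_copy"], atol=1e-8)

    def test_excluded_dhss_are_removed(self):
        m = generate_grouped_matrix(n_dhs=300, seed=56)
        # exclusion mask covering everything leaves nothing: error
        with pytest.raises(ValueError, match="no DHSs"):
            pca_landscape(m, exclude=IntervalSet([iv("chr1", 0, 10 ** 7)]))
        # masking a prefix region still yields scores
        scores, _ = pca_landscape(m, exclude=IntervalSet([iv("chr1", 0, 50_000)]))
        assert scores.shape[0] == len(m.samples)

    def test_constant_matrix_rejected(self):
        m = DhsMatrix(IntervalSet([iv("chr1", 0, 100), iv("chr1", 200, 300)]),
                      ["a", "b"], np.full((2, 2), 7.0))
        with pytest.raises(ValueError, match="degenerate"):
            pca_landscape(m)
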