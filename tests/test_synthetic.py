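"""Synthetic landscape generator: determinism, calibration, planted truth."""

import numpy as np
import pytest

from dhskit.intervals import merge
from dhskit.quantify import DhsMatrix, tally_cuts, write_bedgraph
from dhskit.synthetic import (
    LandscapeSpec,
    generate_annotation,
    generate_grouped_matrix,
    generate_landscape,
)

SMALL = dict(chrom_lengths={"chr1": 120_000, "chr2": 120_000},
             n_shared_dhs=60, n_specific_dhs=5, n_dynamic_dhs=20)


class TestGenerateLandscape:
    def test_same_seed_gives_byte_identical_tracks(self, tmp_path):
        spec = LandscapeSpec(**SMALL, seed=3)
        p1, _ = generate_landscape(spec)
        p2, _ = generate_landscape(spec)
        for a, b in zip(p1, p2):
            f1, f2 = tmp_path / "a.bg", tmp_path / "b.bg"
            write_bedgraph(a.track, f1)
            write_bedgraph(b.track, f2)
            assert f1.read_bytes() == f2.read_bytes()

    def test_different_seeds_differ(self):
        a, _ = generate_landscape(LandscapeSpec(**SMALL, seed=1))
        b, _ = generate_landscape(LandscapeSpec(**SMALL, seed=2))
        assert a[0].track != b[0].track

    def test_no_dynamic_dhss_means_equal_timepoint_means(self):
        spec = LandscapeSpec(chrom_lengths={"chr1": 120_000}, n_shared_dhs=40,
                             n_specific_dhs=0, n_dynamic_dhs=0, seed=4)
        _, truth = generate_landscape(spec)
        assert (truth.dhs["mu_t1"] == truth.dhs["mu_t2"]).all()

    def test_planted_intervals_do_not_overlap(self):
        spec = LandscapeSpec(**SMALL, seed=5)
        _, truth = generate_landscape(spec)
        ivs = truth.intervals()
        assert ivs.is_normalized()
        assert len(merge(ivs)) == len(ivs)

    def test_every_planted_dhs_has_exactly_one_class(self):
        spec = LandscapeSpec(**SMALL, n_samples=3, seed=6)
        _, truth = generate_landscape(spec)
        assert len(truth.dhs) == 60 + 3 * 5 + 20
        assert truth.dhs[["chrom", "start", "end"]].duplicated().sum() == 0

    def test_realized_cuts_match_spec_rate(self):
        # mean cuts over shared DHSs ~ dhs_rate; Poisson s.d. of the mean
        spec = LandscapeSpec(**SMALL, dhs_rate=500.0, seed=7)
        profiles, truth = generate_landscape(spec)
        shared = truth.intervals("shared")
        counts = tally_cuts(profiles[0].track, shared)
        sd_mean = np.sqrt(500.0 / len(shared))
        # background cuts inside DHSs add ~ width * bg_rate (~2) per DHS
        assert abs(counts.mean() - 500.0) < 3 * sd_mean + 3

    def test_spot_fraction_below_one_due_to_background(self):
        spec = LandscapeSpec(**SMALL, seed=8)
        profiles, _ = generate_landscape(spec)
        assert 0.5 < profiles[0].spot_fraction < 1.0

    def test_negative_binomial_noise_is_overdispersed(self):
        base = dict(chrom_lengths={"chr1": 1_000_000}, n_shared_dhs=300,
                    n_specific_dhs=0, n_dynamic_dhs=0, background_rate=0.0,
                    dhs_rate=500.0, seed=9)
        prof_p, truth_p = generate_landscape(LandscapeSpec(**base, noise="poisson"))
        prof_nb, truth_nb = generate_landscape(
            LandscapeSpec(**base, noise="negative_binomial", dispersion=5.0))
        var_p = tally_cuts(prof_p[0].track, truth_p.intervals()).var()
        var_nb = tally_cuts(prof_nb[0].track, truth_nb.intervals()).var()
        assert var_nb > 3 * var_p

    def test_infeasible_placement_raises(self):
        with pytest.raises(ValueError, match="too small"):
            generate_landscape(LandscapeSpec(
                chrom_lengths={"chr1": 5_000}, n_shared_dhs=500,
                n_specific_dhs=0, n_dynamic_dhs=0, seed=0))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            LandscapeSpec(n_samples=1)
        with pytest.raises(ValueError):
            LandscapeSpec(fold_change=1.0)
        with pytest.raises(ValueError):
            LandscapeSpec(noise="gamma")


class TestGenerateAnnotation:
    def test_full_concordance_tracks_dhs_direction(self):
        spec = LandscapeSpec(**SMALL, seed=10)
        _, truth = generate_landscape(spec)
        genes, tes, expr = generate_annotation(spec, truth, concordance_p=1.0)
        status = dict(zip(truth.genes["gene_id"], truth.genes["de_status"]))
        ratio = expr.frame["t2"] / expr.frame["t1"]
        for gid, st in status.items():
            if st == "up":
                assert ratio[gid] == 2.0
            elif st == "down":
                assert ratio[gid] == 0.5
            else:
                assert ratio[gid] == 1.0
        assert (truth.genes["de_status"] != "none").any()

    def test_zero_concordance_means_no_de_genes(self):
        spec = LandscapeSpec(**SMALL, seed=11)
        _, truth = generate_landscape(spec)
        _, _, expr = generate_annotation(spec, truth, concordance_p=0.0)
        assert (expr.frame["t1"] == expr.frame["t2"]).all()

    def test_half_concordance_within_binomial_bounds(self):
        # the eligible genes are those made DE at concordance 1; at 0.5 the
        # DE count among them should fall within 99% binomial bounds
        de_half, eligible = 0, 0
        for seed in range(5):
            spec = LandscapeSpec(chrom_lengths={"chr1": 600_000},
                                 n_shared_dhs=50, n_specific_dhs=0,
                                 n_dynamic_dhs=150, seed=seed)
            _, truth_full = generate_landscape(spec)
            generate_annotation(spec, truth_full, concordance_p=1.0)
            eligible += int((truth_full.genes["de_status"] != "none").sum())

            _, truth_half = generate_landscape(spec)
            generate_annotation(spec, truth_half, concordance_p=0.5)
            de_half += int((truth_half.genes["de_status"] != "none").sum())
        sd = np.sqrt(eligible * 0.25)
        assert abs(de_half - 0.5 * eligible) < 2.576 * sd

    def test_genes_do_not_overlap_planted_dhss(self):
        spec = LandscapeSpec(**SMALL, seed=12)
        _, truth = generate_landscape(spec)
        genes, tes, _ = generate_annotation(spec, truth)
        dhs_ivs = truth.intervals()
        for g in genes:
            for iv in dhs_ivs:
                if iv.chrom == g.chrom:
                    assert g.end <= iv.start or g.start >= iv.end


class TestGroupedMatrix:
    def test_shapes_and_names(self):
        m = generate_grouped_matrix(n_dhs=100, group_sizes=(2, 3), seed=13)
        assert m.counts.shape == (100, 5)
        assert m.samples == ["A1", "A2", "B1", "B2", "B3"]

    def test_informative_rows_are_higher_in_second_group(self):
        m = generate_grouped_matrix(n_dhs=1_000, informative_frac=0.2,
                                    fold=4.0, seed=14)
        inf = m.counts[:200]
        assert inf[:, 3:].mean() > 3 * inf[:, :3].mean()
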