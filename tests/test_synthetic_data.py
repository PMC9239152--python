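import numpy as np
import pytest

from multihic.chip_quant import enrichment, peak_score
from multihic.foci_analysis import colocalization_fraction, focus_count_matrix
from multihic.hic_pipeline import bin_contacts
from multihic.interaction_quant import (
    alignment_region,
    alignment_score,
    ori_interaction_score,
    region_membership,
    relative_interaction,
)
from multihic.synthetic_data import (
    ChipModelParams,
    FociModelParams,
    MapModelParams,
    expected_contact_map,
    simulate_chip_tracks,
    simulate_contact_map,
    simulate_contact_records,
    simulate_foci,
)


def quiet_params(**kw):
    base = dict(interarm_strength=0.0, ori_cluster_strength=0.0, alignment_strength=0.0)
    base.update(kw)
    return MapModelParams(**base)


class TestSimulateContactMap:
    def test_decay_only_block_diagonal(self, c58_layout):
        # steep decay -> negligible long-range signal; with no background or
        # features the interreplicon blocks are zero and the alignment area
        # (whose only intra-replicon row is the last Ch1 bin, y=285, at large
        # bin distances) scores ~0
        cm = simulate_contact_map(c58_layout, quiet_params(background=0.0, decay_exponent=50.0))
        m = cm.matrix
        assert m[:285, 286:].max() == 0.0
        assert np.array_equal(m, m.T)
        assert alignment_score(cm) == pytest.approx(0.0, abs=1e-30)

    def test_background_only_in_alignment_region(self, c58_layout):
        bgv = 0.02
        cm = simulate_contact_map(c58_layout, quiet_params(background=bgv, decay_exponent=50.0))
        n_pairs = len(region_membership(alignment_region(), cm.n_bins))
        assert alignment_score(cm) == pytest.approx(2 * n_pairs * bgv)

    def test_alignment_linearity(self, c58_layout):
        a = 0.05
        s_wt = alignment_score(simulate_contact_map(c58_layout, quiet_params(alignment_strength=a)))
        s_bg = alignment_score(simulate_contact_map(c58_layout, quiet_params()))
        for f in (0.15, 0.35, 0.6):
            s = alignment_score(
                simulate_contact_map(c58_layout, quiet_params(alignment_strength=f * a))
            )
            assert relative_interaction(s, s_wt, s_bg) == pytest.approx(100 * f, abs=1e-8)

    def test_ori_cluster_additivity(self, c58_layout):
        s = 0.7
        hi = ori_interaction_score(simulate_contact_map(c58_layout, quiet_params(ori_cluster_strength=s)))
        lo = ori_interaction_score(simulate_contact_map(c58_layout, quiet_params()))
        # ori1 block (143 +/- 20 = bins 123..163) x ori2 block (382 +/- 20 =
        # 362..402) overlaps the quantification rectangle in 41 x 40 cells
        assert hi - lo == pytest.approx(2 * 41 * 40 * s)

    def test_strengths_act_only_in_band(self, c58_layout):
        a = expected_contact_map(c58_layout, quiet_params())
        b = expected_contact_map(c58_layout, quiet_params(alignment_strength=0.5))
        diff = b - a
        assert set(np.unique(diff)) == {0.0, 0.5}
        # the band lives only in the Ch1 x Ch2 blocks
        assert diff[:285, :285].max() == 0.0
        assert diff[286:, 286:].max() == 0.0

    def test_seeded_reproducibility(self, c58_layout):
        p = quiet_params(alignment_strength=0.05, noise_pairs=10_000, seed=9)
        m1 = simulate_contact_map(c58_layout, p).matrix
        m2 = simulate_contact_map(c58_layout, p).matrix
        assert np.array_equal(m1, m2)

    def test_noise_map_is_symmetric_counts(self, c58_layout):
        p = quiet_params(noise_pairs=5000, seed=3)
        m = simulate_contact_map(c58_layout, p).matrix
        assert np.array_equal(m, m.T)
        assert m.sum() == 2 * 5000

    def test_sampling_unbiased(self, mini_layout):
        p = quiet_params(background=0.01)
        expected = expected_contact_map(mini_layout, p)
        acc = np.zeros_like(expected)
        k, n = 40, 20_000
        for s in range(k):
            acc += simulate_contact_map(
                mini_layout, quiet_params(background=0.01, noise_pairs=n, seed=s)
            ).matrix
        est = acc / acc.sum()
        ref = expected / expected.sum()
        assert np.abs(est - ref).max() < 5e-4

    def test_negative_params_rejected(self, mini_layout):
        with pytest.raises(ValueError):
            simulate_contact_map(mini_layout, MapModelParams(background=-0.1))


class TestSimulateContactRecords:
    def test_zero_pairs(self, mini_layout):
        cm = simulate_contact_map(mini_layout, quiet_params(background=0.01))
        assert simulate_contact_records(cm, 0) == []

    def test_seeded_identity(self, mini_layout):
        cm = simulate_contact_map(mini_layout, quiet_params(background=0.01))
        r1 = simulate_contact_records(cm, 500, seed=7)
        r2 = simulate_contact_records(cm, 500, seed=7)
        assert r1 == r2

    def test_zero_total_errors(self, mini_layout):
        cm = simulate_contact_map(mini_layout, quiet_params(background=0.0))
        cm.matrix[:] = 0.0
        with pytest.raises(ValueError):
            simulate_contact_records(cm, 10)

    def test_binned_records_converge_to_map(self, mini_layout):
        cm = simulate_contact_map(mini_layout, quiet_params(background=0.05))
        ref = cm.matrix / cm.matrix.sum()

        def deviation(n, seed):
            recs = simulate_contact_records(cm, n, seed=seed)
            binned = bin_contacts(recs, mini_layout).matrix
            return np.abs(binned / binned.sum() - ref).max()

        d_small, d_big = deviation(4_000, 11), deviation(400_000, 12)
        assert d_big < d_small  # concentration with n
        assert d_big < 4.0 / np.sqrt(400_000)  # ~ n^(-1/2) scale

    def test_ch1_coordinates_native(self, c58_layout):
        # records on the rotated chromosome re-bin to the bins they were drawn from
        cm = simulate_contact_map(c58_layout, quiet_params(background=0.01))
        recs = simulate_contact_records(cm, 2_000, seed=1)
        rebinned = bin_contacts(recs, c58_layout)
        assert rebinned.total == 2 * 2_000
        for rec in recs[:50]:
            for rep, pos in ((rec.replicon1, rec.pos1), (rec.replicon2, rec.pos2)):
                assert 1 <= pos <= c58_layout.replicon(rep).length


class TestSimulateChipTracks:
    def test_no_peaks_enrichment_near_one(self, mini_layout):
        chip, inp = simulate_chip_tracks(
            mini_layout, ChipModelParams(background_rate=5.0, library_sizes=(2e6, 2e6), seed=4)
        )
        e = enrichment(chip, inp)
        vals = np.concatenate([v[np.isfinite(v)] for v in e.values.values()])
        # ratio of Poissons has mean > 1 (1/input inflation); median is ~1
        assert abs(np.median(vals) - 1.0) < 0.05

    def test_peak_score_linear_in_height(self):
        from multihic.genome_model import RepliconSpec, build_layout

        lay = build_layout([RepliconSpec("chr", 1_000_000, "circular")], 10_000, 0)

        def score(h):
            params = ChipModelParams(
                peak_sites=(("chr", 500_000, h, 200.0),),
                background_rate=5.0,
                library_sizes=(2e7, 2e7),
                seed=21,
            )
            chip, inp = simulate_chip_tracks(lay, params)
            return peak_score(enrichment(chip, inp), ("chr", 499_000, 501_000))

        s1, s2 = score(50.0), score(100.0)
        assert s2 / s1 == pytest.approx(2.0, abs=0.15)

    def test_seeded_identity(self, mini_layout):
        p = ChipModelParams(library_sizes=(1e5, 1e5), seed=2)
        c1, i1 = simulate_chip_tracks(mini_layout, p)
        c2, i2 = simulate_chip_tracks(mini_layout, p)
        for name in c1.counts:
            assert np.array_equal(c1.counts[name], c2.counts[name])
            assert np.array_equal(i1.counts[name], i2.counts[name])

    def test_counts_nonnegative_integers(self, mini_layout):
        chip, inp = simulate_chip_tracks(mini_layout, ChipModelParams(library_sizes=(1e5, 1e5)))
        for t in (chip, inp):
            for arr in t.counts.values():
                assert (arr >= 0).all()
                assert np.array_equal(arr, np.round(arr))

    def test_param_validation(self, mini_layout):
        with pytest.raises(ValueError):
            simulate_chip_tracks(mini_layout, ChipModelParams(background_rate=0.0))
        with pytest.raises(ValueError):
            simulate_chip_tracks(
                mini_layout, ChipModelParams(peak_sites=(("chrA", 10, 1.0, 0.0),))
            )


class TestSimulateFoci:
    def test_full_coloc_zero_jitter(self):
        cells = simulate_foci(FociModelParams(n_cells=200, coloc_prob=1.0, coloc_jitter_px=0.0, seed=5))
        assert colocalization_fraction(cells, threshold=1e-9) == 1.0

    def test_chance_level_below_point_two(self):
        cells = simulate_foci(FociModelParams(n_cells=1000, coloc_prob=0.0, seed=6))
        assert colocalization_fraction(cells) < 0.2

    def test_zero_focus_fraction(self):
        dist = ((0, 0.4), (1, 0.6))
        cells = simulate_foci(FociModelParams(n_cells=1000, count_dist=dist, seed=8))
        frac = focus_count_matrix(cells).zero_fraction["green"]
        assert frac == pytest.approx(0.40, abs=3 * np.sqrt(0.4 * 0.6 / 1000))

    def test_seeded_identity(self):
        p = FociModelParams(n_cells=50, seed=13)
        c1, c2 = simulate_foci(p), simulate_foci(p)
        assert [c.foci for c in c1] == [c.foci for c in c2]

    def test_polar_bias(self):
        from multihic.foci_analysis import distance_to_nearest_pole

        p = FociModelParams(n_cells=500, polar_sigma_px=5.0, seed=14)
        cells = simulate_foci(p)
        dists = [
            distance_to_nearest_pole(c, f) for c in cells for f in c.foci_of("green")
        ]
        # half-normal with sigma 5 keeps foci near poles of a 120 px cell
        assert np.median(dists) < 15.0

    def test_param_validation(self):
        with pytest.raises(ValueError):
            simulate_foci(FociModelParams(coloc_prob=1.5))
        with pytest.raises(ValueError):
            simulate_foci(FociModelParams(count_dist=((1, 0.5),)))
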