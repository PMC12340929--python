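"""Generator-level checks: determinism, planted-effect bookkeeping, and
agreement of simulated data with the closed-form expectations recorded
as ground truth."""

import numpy as np
import pandas as pd
import pytest

from cortexpheno.config import (
    CalciumConfig,
    CountsConfig,
    HypnogramConfig,
    LatentFactor,
    MarkersConfig,
    SimConfig,
    TissueConfig,
    load_sim_config,
)
from cortexpheno.errors import ConfigurationError
from cortexpheno.synthetic import (
    gen_calcium_traces,
    gen_hypnogram,
    gen_nuclei_markers,
    gen_pseudobulk_counts,
    gen_tissue,
    stationary_distribution,
)


class TestDeterminism:
    def test_counts_bit_identical(self):
        cfg = SimConfig(seed=42)
        a, _ = gen_pseudobulk_counts(cfg)
        b, _ = gen_pseudobulk_counts(cfg)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_all_generators_stable_under_reuse(self):
        """Streams are independent: running one generator does not shift another."""
        cfg = SimConfig(seed=7)
        cfg.calcium.n_frames = 200
        first_tissue = gen_tissue(cfg)
        gen_calcium_traces(cfg)
        gen_nuclei_markers(cfg)
        second_tissue = gen_tissue(cfg)
        np.testing.assert_array_equal(first_tissue.centers, second_tissue.centers)

    def test_calcium_and_hypnogram_identical(self):
        cfg = SimConfig(seed=3)
        cfg.calcium.n_frames = 500
        t1, _ = gen_calcium_traces(cfg)
        t2, _ = gen_calcium_traces(cfg)
        np.testing.assert_array_equal(t1.traces, t2.traces)
        pd.testing.assert_frame_equal(gen_hypnogram(cfg), gen_hypnogram(cfg))


class TestCountsGenerator:
    def test_no_planted_effect_means_empty_truth(self):
        cfg = SimConfig(seed=1)
        cfg.counts.fraction_de = 0.0
        _, truth = gen_pseudobulk_counts(cfg)
        assert truth.de_genes == {}

    def test_counts_are_nonnegative_integers(self):
        cm, _ = gen_pseudobulk_counts(SimConfig(seed=2))
        assert np.issubdtype(cm.counts.dtype, np.integer)
        assert cm.counts.min() >= 0

    def test_planted_logfc_reflected_in_group_means(self):
        """At vanishing dispersion and large libraries the HET/WT mean CPM
        ratio of a +1 log2FC gene approaches 2 (Monte-Carlo over ~1e4 draws)."""
        cfg = SimConfig(seed=5)
        cfg.counts = CountsConfig(
            n_genes=2000, fraction_de=0.5, logfc_de=1.0, dispersion=0.0,
            n_batches=1, batch_effect_sd=0.0, lib_size_range=(2e6, 2e6),
        )
        cm, truth = gen_pseudobulk_counts(cfg)
        cpm = cm.counts / cm.counts.sum(axis=0) * 1e6
        het = cm.unit_meta["genotype"].to_numpy() == "HET"
        ratios = []
        for gene, lfc in truth.de_genes.items():
            i = cm.genes.index(gene)
            m_het, m_wt = cpm[i, het].mean(), cpm[i, ~het].mean()
            if m_wt > 5:  # skip near-zero-count genes with huge MC error
                ratios.append((m_het / m_wt) ** np.sign(lfc))
        assert 1.9 < np.median(ratios) < 2.1

    def test_invalid_dispersion_rejected(self):
        cfg = SimConfig(seed=1)
        cfg.counts.dispersion = -1.0
        with pytest.raises(ConfigurationError):
            gen_pseudobulk_counts(cfg)

    def test_module_genes_marked_in_truth(self):
        from cortexpheno.config import PlantedModule

        cfg = SimConfig(seed=4)
        cfg.counts.modules = [PlantedModule("M1", n_genes=50, genotype_shift=0.5)]
        _, truth = gen_pseudobulk_counts(cfg)
        members = [g for g, m in truth.module_membership.items() if m == "M1"]
        assert len(members) == 50
        assert all(truth.de_genes[g] == pytest.approx(0.5) for g in members)


class TestMarkersGenerator:
    def test_zero_nuclei_gives_empty_matrix(self):
        cfg = SimConfig(seed=1)
        cfg.markers.n_nuclei = 0
        cm, truth = gen_nuclei_markers(cfg)
        assert cm.n_units == 0 and len(truth.sex) == 0

    def test_no_dropout_males_have_y_counts(self):
        """With Y-mean 5 per gene and no dropout, a male nucleus lacks Y
        counts entirely only with probability e^-20."""
        cfg = SimConfig(seed=2)
        cfg.markers = MarkersConfig(n_nuclei=3000, dropout=0.0, y_mean=5.0)
        cm, truth = gen_nuclei_markers(cfg)
        y_total = cm.counts[:4].sum(axis=0)
        male = (truth.sex == "M").to_numpy()
        assert (y_total[male] >= 1).all()
        assert (y_total[~male] == 0).all()

    def test_dropout_out_of_range_rejected(self):
        cfg = SimConfig(seed=1)
        cfg.markers.dropout = 1.5
        with pytest.raises(ConfigurationError):
            gen_nuclei_markers(cfg)

    def test_pool_design_pairs_opposite_genotypes(self):
        cfg = SimConfig(seed=3)
        _, truth = gen_nuclei_markers(cfg)
        for mapping in truth.pool_design.values():
            assert {mapping["M"], mapping["F"]} == {"WT", "HET"}


class TestCalciumGenerator:
    def test_noise_free_trace_is_kernel_convolution(self):
        """Without noise and neuropil the trace is exactly baseline * (1 +
        raster convolved with the decay kernel)."""
        cfg = SimConfig(seed=6)
        cfg.calcium = CalciumConfig(n_neurons=3, n_frames=400, noise_sd_dff=0.0, neuropil_scale=0.0)
        ts, truth = gen_calcium_traces(cfg)
        for i in range(3):
            expected = np.convolve(truth.raster[i].astype(float), truth.kernel)[:400]
            np.testing.assert_allclose(ts.traces[i], cfg.calcium.baseline_f * (1 + expected), rtol=1e-12)

    def test_zero_loading_means_zero_expected_correlation(self):
        cfg = SimConfig(seed=6)
        cfg.calcium = CalciumConfig(
            n_neurons=4, n_frames=500,
            latent_factors=[LatentFactor(rate_hz=0.5, loadings=(0,) * 8)],
        )
        _, truth = gen_calcium_traces(cfg)
        assert truth.expected_correlation(0, 1) == pytest.approx(0.0, abs=1e-12)

    def test_shared_latent_correlation_matches_closed_form(self):
        """Two neurons fully loaded on one latent factor: the mean empirical
        raster correlation over independent replicates sits within 3
        replicate-based standard errors of the analytic value for jointly
        thinned Bernoulli frames."""
        cfg = SimConfig(seed=8)
        cfg.calcium = CalciumConfig(
            n_neurons=6, n_frames=20_000, depth_range_um=(0.0, 600.0),
            event_rate_hz=0.02,
            latent_factors=[LatentFactor(rate_hz=0.5, loadings=(1.0,) * 8)],
        )
        emps, expected = [], None
        for rep in range(12):
            _, truth = gen_calcium_traces(cfg, stream_index=rep)
            emps.append(np.corrcoef(truth.raster[0], truth.raster[1])[0, 1])
            expected = truth.expected_correlation(0, 1)
        se = np.std(emps, ddof=1) / np.sqrt(len(emps))
        assert abs(np.mean(emps) - expected) < 3 * se

    def test_negative_rate_rejected(self):
        cfg = SimConfig(seed=1)
        cfg.calcium.event_rate_hz = -0.1
        with pytest.raises(ConfigurationError):
            gen_calcium_traces(cfg)

    def test_depths_within_range(self):
        cfg = SimConfig(seed=9)
        cfg.calcium.n_frames = 200
        ts, _ = gen_calcium_traces(cfg)
        assert ts.depths_um.min() >= 0 and ts.depths_um.max() < 600


class TestHypnogramGenerator:
    def test_absorbing_wake_gives_full_day_wake(self):
        absorbing = ((1.0, 0.0, 0.0),) * 3
        cfg = SimConfig(seed=1)
        hyp = gen_hypnogram(cfg, light_transition=absorbing, dark_transition=absorbing)
        assert (hyp["state"] == "Wake").all()
        assert hyp["duration_s"].sum() == 86_400

    def test_epoch_count(self):
        cfg = SimConfig(seed=1)
        cfg.hypnogram.epoch_s = 10
        assert len(gen_hypnogram(cfg)) == 8640

    def test_tiles_day_without_gaps(self):
        hyp = gen_hypnogram(SimConfig(seed=2))
        ends = (hyp["start_s"] + hyp["duration_s"]).to_numpy()
        assert ends[-1] == 86_400
        np.testing.assert_array_equal(ends[:-1], hyp["start_s"].to_numpy()[1:])

    def test_long_run_occupancy_matches_stationary_distribution(self):
        """NREM occupancy over 50 stationary (light-matrix-all-day) replicates
        lies within 3 SE of the transition matrix's stationary entry."""
        cfg = SimConfig(seed=3)
        light = cfg.hypnogram.light_transition
        occ = []
        for i in range(50):
            hyp = gen_hypnogram(cfg, stream_index=i, dark_transition=light)
            occ.append((hyp["state"] == "NREM").mean())
        target = stationary_distribution(np.asarray(light))[1]
        se = np.std(occ, ddof=1) / np.sqrt(len(occ))
        assert abs(np.mean(occ) - target) < 3 * se

    def test_bad_transition_matrix_rejected(self):
        bad = ((0.5, 0.2, 0.2), (0.1, 0.8, 0.1), (0.1, 0.1, 0.8))
        with pytest.raises(ConfigurationError):
            gen_hypnogram(SimConfig(seed=1), light_transition=bad)


class TestTissueGenerator:
    def test_single_cell_inside_box(self):
        cfg = SimConfig(seed=1)
        cfg.tissue.n_cells = 1
        t = gen_tissue(cfg)
        assert t.true_count == 1
        assert (t.centers >= 0).all() and (t.centers <= np.array(cfg.tissue.box_um)).all()

    def test_density_uniform_in_subbox(self):
        """Count inside a random sub-box is Poisson-consistent with N/V."""
        cfg = SimConfig(seed=2)
        cfg.tissue = TissueConfig(box_um=(400.0, 400.0, 200.0), n_cells=10_000)
        t = gen_tissue(cfg)
        inside = (
            (t.centers[:, 0] < 200) & (t.centers[:, 1] < 200) & (t.centers[:, 2] < 100)
        ).sum()
        expected = 10_000 / 8
        assert abs(inside - expected) < 4 * np.sqrt(expected)

    def test_negative_radius_support_rejected(self):
        cfg = SimConfig(seed=1)
        cfg.tissue.radius_mean_um = -2.0
        with pytest.raises(ConfigurationError):
            gen_tissue(cfg)


class TestConfigLoading:
    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("seed: 11\ncounts:\n  n_genes: 500\n  fraction_de: 0.2\n")
        cfg = load_sim_config(p)
        assert cfg.seed == 11 and cfg.counts.n_genes == 500

    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigurationError):
            load_sim_config({"counts": {"n_genez": 10}})
        with pytest.raises(ConfigurationError):
            load_sim_config({"not_a_section": {}})
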