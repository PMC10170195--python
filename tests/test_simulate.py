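"""Generator correctness: spatial statistics, binding kinetics, determinism."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from scipy import stats

from qpaintlib import (
    AcquisitionParams,
    GeneratorConfig,
    KineticsModel,
    expected_localizations_per_site,
    frames_from_events,
    simulate_binding_timeseries,
    simulate_dataset,
    simulate_localizations,
    simulate_protein_map,
)


class TestProteinMap:
    def test_poisson_mean_protein_count(self):
        """Mean count over many seeds matches density * area (23 * 12.25)."""
        cfg = GeneratorConfig()
        n_rep = 400
        counts = [simulate_protein_map(cfg, seed=s).n_proteins for s in range(n_rep)]
        expected = 23.0 * 12.25  # analytic Poisson mean
        se = np.sqrt(expected / n_rep)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_tiny_density_empty_map_permitted(self):
        cfg = GeneratorConfig(density_per_um2=1e-4, area_um=(0.5, 0.5))
        m = simulate_protein_map(cfg, seed=0)
        assert m.n_proteins >= 0  # zero proteins is a valid map

    def test_fully_clustered_degenerate_mixture(self):
        cfg = GeneratorConfig(fraction_clustered=1.0, size_class_weights=(1.0, 0.0, 0.0))
        m = simulate_protein_map(cfg, seed=3)
        ids, sizes = np.unique(m.cluster_assignment[m.cluster_assignment > 0], return_counts=True)
        assert (sizes >= 3).all() and (sizes <= 5).all()
        # at most a sub-cluster remainder (< 3 proteins) may stay unclustered
        assert (m.cluster_assignment == 0).sum() < 3

    def test_positions_inside_roi(self):
        m = simulate_protein_map(GeneratorConfig(), seed=11)
        w, h = 3500.0, 3500.0
        assert (m.protein_positions[:, 0] >= 0).all() and (m.protein_positions[:, 0] < w).all()
        assert (m.protein_positions[:, 1] >= 0).all() and (m.protein_positions[:, 1] < h).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="density"):
            GeneratorConfig(density_per_um2=0.0)
        with pytest.raises(ValueError, match="area"):
            GeneratorConfig(area_um=(0.0, 1.0))
        with pytest.raises(ValueError, match="sum to 1"):
            GeneratorConfig(size_class_weights=(0.5, 0.2, 0.1))


class TestBindingKinetics:
    def test_localization_yield_matches_closed_form(self, acq, kin):
        """Per-site localization yield agrees with n_frames*tau_b*k_on*[I]."""
        ev = simulate_binding_timeseries(500, acq, kin, seed=1)
        locs = [len(frames_from_events(e, acq, "threshold")) for e in ev.site_events]
        expected = expected_localizations_per_site(acq, kin)  # 40.5
        se = np.std(locs) / np.sqrt(len(locs))
        assert abs(np.mean(locs) - expected) < 3 * se

    def test_zero_imager_concentration_gives_no_events(self, acq):
        kin0 = KineticsModel(imager_conc=0.0)
        ev = simulate_binding_timeseries(20, acq, kin0, seed=2)
        assert all(len(e) == 0 for e in ev.site_events)

    def test_mean_bright_duration(self, acq, kin):
        """Sampled bright times average to tau_bright = 0.27 s."""
        ev = simulate_binding_timeseries(800, acq, kin, seed=3)
        d = ev.all_durations()
        assert len(d) >= 10_000
        assert abs(d.mean() - 0.27) / 0.27 < 0.05

    def test_dark_times_exponential(self, kin):
        """KS test: waiting times between bindings ~ Exp(k_on*[I]).

        Uses an acquisition much longer than the mean dark time so that the
        finite-window truncation of the last intervals (which slightly
        depletes long gaps in a short acquisition) is negligible.
        """
        long_acq = AcquisitionParams(n_frames=3_000_000, frame_time=0.1)
        ev = simulate_binding_timeseries(4, long_acq, kin, seed=4)
        darks = []
        for e in ev.site_events:
            ends = e[:-1, 0] + e[:-1, 1]
            darks.append(e[1:, 0] - ends)
        darks = np.concatenate(darks)
        assert len(darks) >= 10_000
        p = stats.kstest(darks, "expon", args=(0, 1.0 / kin.binding_rate)).pvalue
        assert p > 0.01

    def test_site_count_validation(self, acq, kin):
        with pytest.raises(ValueError):
            simulate_binding_timeseries(0, acq, kin, seed=0)


class TestDiscretization:
    def test_three_frame_event_three_rows(self, acq):
        """An aligned 3-frame bright event occupies exactly 3 consecutive frames."""
        frames = frames_from_events(np.array([[1.0, 0.3]]), acq, "threshold")
        assert frames.tolist() == [10, 11, 12]

    def test_overlap_model_sees_every_event(self, acq):
        # far sub-frame event: invisible to the detection-threshold model,
        # recorded by the overlap model
        ev = np.array([[1.001, 0.02]])
        assert len(frames_from_events(ev, acq, "threshold")) == 0
        assert len(frames_from_events(ev, acq, "overlap")) == 1

    def test_clipped_to_acquisition(self):
        acq = AcquisitionParams(n_frames=10, frame_time=0.1)
        frames = frames_from_events(np.array([[0.85, 5.0]]), acq, "overlap")
        assert frames.max() == 9

    @pytest.mark.parametrize("model", ["threshold", "overlap", "round"])
    def test_models_give_sorted_valid_frames(self, acq, kin, model):
        ev = simulate_binding_timeseries(5, acq, kin, seed=9)
        for e in ev.site_events:
            fr = frames_from_events(e, acq, model)
            assert (np.diff(fr) > 0).all()
            assert (fr >= 0).all() and (fr < acq.n_frames).all()


class TestLocalizations:
    def _simple(self, sigma, seed=0, density=30.0, background=0.0):
        acq = dataclasses.replace(AcquisitionParams(), loc_precision_sigma=sigma)
        cfg = GeneratorConfig(
            density_per_um2=density,
            fraction_clustered=0.0,
            background_rate_per_um2_per_frame=background,
            nonspecific_site_density_per_um2=1e-9,
        )
        kin = KineticsModel()
        truth = simulate_protein_map(cfg, seed)
        ev = simulate_binding_timeseries(truth.n_proteins, acq, kin, seed + 1)
        table = simulate_localizations(truth, ev, acq, seed + 2)
        return truth, table

    def test_noiseless_localizations_at_true_positions(self):
        truth, table = self._simple(sigma=0.0)
        src = table.df["source"].to_numpy()
        ok = src >= 0
        assert ok.all()
        np.testing.assert_allclose(table.xy[ok], truth.protein_positions[src[ok]])

    def test_scatter_sd_matches_precision(self):
        truth, table = self._simple(sigma=9.0, density=60.0)
        src = table.df["source"].to_numpy()
        resid = table.xy - truth.protein_positions[src]
        assert len(resid) >= 10_000
        for axis in range(2):
            assert abs(np.std(resid[:, axis]) - 9.0) / 9.0 < 0.05

    def test_background_rate(self):
        _, table = self._simple(sigma=9.0, background=0.02)
        n_bg = int((table.df["source"] == -1).sum())
        expected = 0.02 * 12.25 * 15_000
        assert abs(n_bg - expected) < 4 * np.sqrt(expected)

    def test_persistent_site_mean_frame_near_half_acquisition(self, acq, kin):
        ev = simulate_binding_timeseries(300, acq, kin, seed=5)
        mf = []
        for e in ev.site_events:
            fr = frames_from_events(e, acq, "threshold")
            if len(fr):
                mf.append(fr.mean())
        assert abs(np.mean(mf) - 7500) / 7500 < 0.02


class TestDeterminism:
    def test_identical_tables_for_identical_seed(self, acq, kin, gen_config, tmp_path):
        a = simulate_dataset(gen_config, acq, kin, seed=123)
        b = simulate_dataset(gen_config, acq, kin, seed=123)
        a.table.to_csv(tmp_path / "a.csv")
        b.table.to_csv(tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()
        np.testing.assert_array_equal(a.truth.protein_positions, b.truth.protein_positions)

    def test_different_seeds_differ(self, acq, kin, gen_config):
        a = simulate_dataset(gen_config, acq, kin, seed=1)
        b = simulate_dataset(gen_config, acq, kin, seed=2)
        assert len(a.table) != len(b.table) or not np.array_equal(a.table.xy, b.table.xy)
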