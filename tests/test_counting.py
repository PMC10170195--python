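"""qPAINT counting: dark-time extraction and fitting, calibration, copy
numbers."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qpaintlib import (
    AcquisitionParams,
    Calibration,
    KineticsModel,
    calibrate,
    count_proteins,
    extract_dark_times,
    fit_dark_time,
    frames_from_events,
    qpaint_index,
    simulate_binding_timeseries,
)

#: kinetics whose per-site binding rate equals the measured single-protein
#: qPAINT index of 0.012 Hz (mean dark time 83.3 s)
KIN_CAL = KineticsModel(k_on=1.0e7, imager_conc=1.2e-9, tau_bright=0.27)


def _cluster_qpaint_index(n_sites, acq, kin, seed):
    """Simulate one cluster of independent sites; return its fitted q_i."""
    ev = simulate_binding_timeseries(n_sites, acq, kin, seed)
    frames = np.unique(
        np.concatenate([frames_from_events(e, acq, "overlap") for e in ev.site_events])
    )
    dark = extract_dark_times(frames, acq.frame_time)
    if len(dark) == 0:
        return None
    return qpaint_index(fit_dark_time(dark).tau_d)


class TestExtractDarkTimes:
    def test_nine_empty_frames_give_point_nine_seconds(self):
        assert extract_dark_times([10, 20], 0.1).tolist() == [pytest.approx(0.9)]

    def test_contiguous_run_has_no_dark_time(self):
        assert len(extract_dark_times([3, 4, 5], 0.1)) == 0

    def test_single_frame_hole_treated_as_dropout(self):
        # frames {0, 2}: one empty frame, indistinguishable from a lost
        # localization inside a bright run -> ignored by default
        assert len(extract_dark_times([0, 2], 0.1)) == 0
        assert extract_dark_times([0, 2], 0.1, min_dark_frames=1).tolist() == [
            pytest.approx(0.1)
        ]

    def test_boundary_gaps_censored(self):
        # only the inner gap is reported regardless of acquisition span
        out = extract_dark_times([100, 200], 0.1)
        assert len(out) == 1

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            out = extract_dark_times([], 0.1)
        assert len(out) == 0

    def test_simulated_site_mean_dark_time(self):
        """Single site at 0.01 s^-1 over a long acquisition: mean gap ~ 100 s."""
        acq = AcquisitionParams(n_frames=1_500_000, frame_time=0.1)
        kin = KineticsModel()  # k_on * [I] = 0.01 s^-1
        ev = simulate_binding_timeseries(1, acq, kin, seed=10)
        frames = frames_from_events(ev.site_events[0], acq, "overlap")
        dark = extract_dark_times(frames, acq.frame_time)
        assert len(dark) >= 1000
        se = dark.std() / np.sqrt(len(dark))
        assert abs(dark.mean() - 100.0) < 3 * se


class TestFitDarkTime:
    def test_single_gap_returned_exactly(self):
        est = fit_dark_time(np.array([50.0]))
        assert est.tau_d == 50.0 and est.method in ("degenerate", "sample_mean")

    def test_identical_gaps_returned_exactly(self):
        est = fit_dark_time(np.full(20, 7.0))
        assert est.tau_d == 7.0

    def test_cdf_fit_matches_mle_on_exponential_data(self):
        """ECDF least-squares agrees with the sample-mean MLE within 5%."""
        rng = np.random.default_rng(0)
        t = rng.exponential(83.3, 10_000)
        est = fit_dark_time(t)
        assert est.method == "cdf_fit"
        assert abs(est.tau_d - t.mean()) / t.mean() < 0.05
        assert abs(est.tau_d - 83.3) / 83.3 < 0.05

    @given(c=st.floats(0.01, 1000.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_scale_equivariance(self, c):
        rng = np.random.default_rng(1)
        base = rng.exponential(1.0, 200)
        tau0 = fit_dark_time(base).tau_d
        tau1 = fit_dark_time(c * base).tau_d
        assert tau1 == pytest.approx(c * tau0, rel=1e-3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fit_dark_time(np.array([]))


class TestQpaintIndex:
    def test_reciprocal_values(self):
        assert qpaint_index(100.0) == pytest.approx(0.01)
        assert qpaint_index(1 / 0.012) == pytest.approx(0.012)

    def test_round_trip(self):
        assert qpaint_index(qpaint_index(83.3)) == pytest.approx(83.3)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            qpaint_index(0.0)


class TestCountProteins:
    CAL = Calibration(q_i1=0.01, peak_sigma=0.003, counting_precision=0.3, n_calibration_clusters=100)

    def test_identity_case(self):
        assert count_proteins(0.01, self.CAL).n_proteins == 1

    def test_dark_time_25s_gives_four(self):
        # tau_off 25 s at k_on [I] = 0.01 s^-1: N = 1/(0.01 * 25) = 4
        assert count_proteins(1 / 25.0, self.CAL).n_proteins == 4

    def test_proportionality(self):
        assert count_proteins(0.05, self.CAL).n_proteins == 5

    def test_rounding_half_away_from_zero_minimum_one(self):
        assert count_proteins(0.025, self.CAL).n_proteins == 3
        assert count_proteins(0.002, self.CAL).n_proteins == 1


class TestCalibration:
    def test_mixture_recovers_single_protein_index(self, acq):
        """60/30/10% clusters of 1/2/3 sites: first peak lands at ~0.012 Hz
        and fitted peak amplitudes rank-order like the planted mixture."""
        rng = np.random.default_rng(2)
        ks = rng.choice([1, 2, 3], p=[0.6, 0.3, 0.1], size=320)
        qs = [
            _cluster_qpaint_index(int(k), acq, KIN_CAL, seed=1000 + i)
            for i, k in enumerate(ks)
        ]
        qs = np.array([x for x in qs if x is not None])
        cal = calibrate(qs, np.zeros(len(qs)), n_peaks=4)
        assert cal.method == "multi_gauss"
        assert abs(cal.q_i1 - 0.012) / 0.012 < 0.10
        assert cal.counting_precision > 0

    def test_pure_monomers_match_inverse_mean_dark_time(self, acq):
        darks = []
        qs = []
        for i in range(250):
            ev = simulate_binding_timeseries(1, acq, KIN_CAL, seed=5000 + i)
            frames = frames_from_events(ev.site_events[0], acq, "overlap")
            d = extract_dark_times(frames, acq.frame_time)
            if len(d) == 0:
                continue
            darks.append(d)
            qs.append(qpaint_index(fit_dark_time(d).tau_d))
        pooled = np.concatenate(darks)
        cal = calibrate(np.array(qs), np.zeros(len(qs)), n_peaks=2)
        assert abs(cal.q_i1 - 1.0 / pooled.mean()) / (1.0 / pooled.mean()) < 0.10

    def test_too_few_clusters_rejected(self):
        with pytest.raises(ValueError, match=">= 50"):
            calibrate(np.full(10, 0.01), np.zeros(10))

    def test_extent_gate(self):
        # clusters larger than the extent cut never enter the calibration
        q = np.concatenate([np.full(60, 0.01), np.full(60, 0.5)])
        ext = np.concatenate([np.full(60, 20.0), np.full(60, 500.0)])
        cal = calibrate(q, ext, max_extent=100.0)
        assert cal.n_calibration_clusters == 60
        assert cal.q_i1 < 0.1


class TestCountingRecovery:
    def test_additivity_of_merged_sites(self):
        """q_i of two merged independent sites ~ sum of individual q_i."""
        acq = AcquisitionParams(n_frames=60_000)
        ratios = []
        for i in range(20):
            ev = simulate_binding_timeseries(2, acq, KIN_CAL, seed=300 + i)
            fa = frames_from_events(ev.site_events[0], acq, "overlap")
            fb = frames_from_events(ev.site_events[1], acq, "overlap")
            qa = qpaint_index(fit_dark_time(extract_dark_times(fa, acq.frame_time)).tau_d)
            qb = qpaint_index(fit_dark_time(extract_dark_times(fb, acq.frame_time)).tau_d)
            fm = np.unique(np.concatenate([fa, fb]))
            qm = qpaint_index(fit_dark_time(extract_dark_times(fm, acq.frame_time)).tau_d)
            ratios.append(qm / (qa + qb))
        assert abs(np.mean(ratios) - 1.0) < 0.05

    def test_planted_copy_numbers_recovered_within_one(self, acq):
        """Counts match planted 1-12 site clusters within +-1 for >= 80%."""
        cal_qs = []
        for i in range(120):
            qi = _cluster_qpaint_index(1, acq, KIN_CAL, seed=7000 + i)
            if qi is not None:
                cal_qs.append(qi)
        cal = calibrate(np.array(cal_qs), np.zeros(len(cal_qs)), n_peaks=2)
        hits = {}
        for n_true in range(1, 13):
            ok = 0
            n_rep = 15
            for i in range(n_rep):
                qi = _cluster_qpaint_index(n_true, acq, KIN_CAL, seed=9000 + 50 * n_true + i)
                n_est = count_proteins(qi, cal).n_proteins
                ok += abs(n_est - n_true) <= 1
            hits[n_true] = ok / n_rep
        assert np.mean(list(hits.values())) >= 0.80

    def test_longer_acquisition_tightens_dark_time_estimates(self):
        """tau_d estimator variance strictly decreases with n_frames."""
        variances = []
        for n_frames in (5_000, 15_000, 45_000):
            acq = AcquisitionParams(n_frames=n_frames)
            taus = []
            for i in range(60):
                ev = simulate_binding_timeseries(1, acq, KIN_CAL, seed=40_000 + n_frames + i)
                fr = frames_from_events(ev.site_events[0], acq, "overlap")
                d = extract_dark_times(fr, acq.frame_time)
                if len(d) >= 2:
                    taus.append(fit_dark_time(d).tau_d)
            variances.append(np.var(taus))
        assert variances[0] > variances[1] > variances[2]
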