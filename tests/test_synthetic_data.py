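"""Generator contracts: layout, planted signals, behavior model."""

import numpy as np
import pandas as pd
import pytest

import tonepred.stimuli as st
import tonepred.synthetic_data as sd


class TestLayout:
    def test_grid_layout_roles_are_contiguous_quadrants(self):
        lay = sd.make_grid_layout(n_side=12)
        assert lay.n_sensors == 144
        assert {*lay.roles} == set(sd.ROLES)
        for role in sd.ROLES:
            assert len(lay.role_idx(role)) == 36
            # contiguity: the role's sensors form one connected component
            from scipy.sparse.csgraph import connected_components
            idx = lay.role_idx(role)
            sub = lay.adjacency[np.ix_(idx, idx)]
            n_comp, _ = connected_components(sub, directed=False)
            assert n_comp == 1

    def test_adjacency_symmetric_no_self_loops(self):
        lay = sd.make_grid_layout(n_side=5)
        a = lay.adjacency
        assert (a != a.T).nnz == 0
        assert a.diagonal().sum() == 0


class TestGroundTruth:
    def test_temporal_count_scales_with_duration(self):
        truth = sd.GroundTruth(roles=np.array(["temporal"]), t_int_ms=1200.0)
        assert [truth.k_temporal(d) for d in (150, 300, 600)] == [8, 4, 2]

    def test_sub_duration_span_degenerates_with_warning(self):
        truth = sd.GroundTruth(roles=np.array(["temporal"]), t_int_ms=100.0)
        with pytest.warns(UserWarning, match="degenerate"):
            assert truth.k_temporal(600) == 1

    def test_history_weights_decay_geometrically(self):
        truth = sd.GroundTruth(roles=np.array([]), lam=0.7)
        w = truth.history_weights(7)
        assert w[0] == 1.0
        assert np.allclose(w[1:] / w[:-1], 0.7)


class TestSimulateSession:
    def test_deterministic_given_seed(self, stimset, trials, tiny_session):
        lay, truth = tiny_session["layout"], tiny_session["truth"]
        r1, b1 = sd.simulate_session(trials, stimset, lay, truth, seed=3)
        assert np.array_equal(r1[300].activity,
                              tiny_session["recordings"][300].activity)
        assert b1.equals(tiny_session["behavior"])

    def test_noiseless_window_means_match_generative_model(self, stimset,
                                                           trials):
        lay = sd.make_grid_layout(n_side=4)
        truth = sd.make_ground_truth(lay)
        quiet = sd.NoiseConfig(white_sd=0.0, drift_sd=0.0)
        recs, _ = sd.simulate_session(trials, stimset, lay, truth,
                                      noise=quiet, seed=3)
        rec = recs[300]
        feats = sd.sequence_features(stimset)
        sub = trials[trials.tone_duration == 300].reset_index(drop=True)
        n_tone = rec.onset_samples[1] - rec.onset_samples[0]
        i = 19  # a mid-sequence tone (1-based tone 20)
        win = rec.activity[:, :, rec.onset_samples[i]:
                           rec.onset_samples[i] + n_tone].mean(axis=2)
        z34 = sd._z_standardizer(stimset.grid)(sub.presented_final.to_numpy())
        z = np.stack([np.r_[feats[s]["z"], 0.0] for s in sub.sequence_id])
        z[:, 33] = z34
        h7 = np.stack([sd._history_values(z[t], 7, truth.history_weights(7))
                       for t in range(len(sub))])
        pred = np.stack([feats[s]["zpred"] for s in sub.sequence_id])
        info0 = lay.role_idx("informational")[0]
        expected = truth.history_gain * h7[:, i] + \
            truth.predictive_gain * pred[:, i]
        assert np.allclose(win[:, info0], expected, atol=1e-5)
        noise0 = lay.role_idx("noise")[0]
        assert np.allclose(win[:, noise0], 0.0, atol=1e-6)

    def test_white_noise_window_means_within_3_sem(self, stimset, trials):
        lay = sd.make_grid_layout(n_side=4)
        truth = sd.make_ground_truth(lay)
        white = sd.NoiseConfig(white_sd=1.0, drift_sd=0.0)
        recs, _ = sd.simulate_session(trials, stimset, lay, truth,
                                      noise=white, seed=8)
        rec = recs[300]
        feats = sd.sequence_features(stimset)
        sub = trials[trials.tone_duration == 300].reset_index(drop=True)
        n_tone = rec.onset_samples[1] - rec.onset_samples[0]
        i = 24
        win = rec.activity[:, :, rec.onset_samples[i]:
                           rec.onset_samples[i] + n_tone].mean(axis=2)
        temp0 = lay.role_idx("temporal")[0]
        k = truth.k_temporal(300)
        z = np.stack([np.r_[feats[s]["z"], 0.0] for s in sub.sequence_id])
        h = np.stack([sd._history_values(z[t], k, truth.history_weights(k))
                      for t in range(len(sub))])
        resid = win[:, temp0] - truth.history_gain * h[:, i]
        sem = 1.0 / np.sqrt(n_tone) / np.sqrt(len(sub))
        assert abs(resid.mean()) < 3 * sem

    def test_noise_sensor_regression_slope_ci_covers_zero(self, tiny_session,
                                                          stimset, trials):
        rec = tiny_session["recordings"][300]
        lay = tiny_session["layout"]
        sub = trials[trials.tone_duration == 300].reset_index(drop=True)
        n_tone = rec.onset_samples[1] - rec.onset_samples[0]
        logp = {s.seq_id: np.log(s.pitches) for s in stimset.sequences}
        i = 20
        y = rec.activity[:, lay.role_idx("noise"),
                         rec.onset_samples[i]:rec.onset_samples[i] + n_tone
                         ].mean(axis=2)
        x = np.array([logp[s][i] for s in sub.sequence_id])
        xc = x - x.mean()
        slope = xc @ y / (xc ** 2).sum()
        resid = y - np.outer(x, slope / 1.0) - (y.mean(0) - slope * x.mean())
        se = np.sqrt(resid.var(axis=0, ddof=2) / (xc ** 2).sum())
        assert np.all(np.abs(slope) < 2.6 * se)

    def test_ols_recovers_history_weights_on_clean_data(self, stimset,
                                                        trials):
        """Closed-form check: regressing noiseless informational activity on
        the current + 6 previous pitches recovers the geometric weights."""
        lay = sd.make_grid_layout(n_side=4)
        truth = sd.make_ground_truth(lay, predictive_gain=0.0)
        quiet = sd.NoiseConfig(white_sd=0.0, drift_sd=0.0)
        recs, _ = sd.simulate_session(trials, stimset, lay, truth,
                                      noise=quiet, seed=1)
        rec = recs[150]
        sub = trials[trials.tone_duration == 150].reset_index(drop=True)
        feats = sd.sequence_features(stimset)
        n_tone = rec.onset_samples[1] - rec.onset_samples[0]
        rows_x, rows_y = [], []
        info0 = lay.role_idx("informational")[0]
        for t in range(len(sub)):
            z = feats[sub.sequence_id[t]]["z"]
            for i in range(15, 32):
                rows_x.append(z[i - 6:i + 1][::-1])
                a, b = rec.onset_samples[i], rec.onset_samples[i] + n_tone
                rows_y.append(rec.activity[t, info0, a:b].mean())
        coef, *_ = np.linalg.lstsq(np.asarray(rows_x), np.asarray(rows_y),
                                   rcond=None)
        assert np.allclose(coef, truth.history_weights(7), atol=1e-4)


class TestBehavior:
    def test_ratings_within_scale_and_deterministic(self, tiny_session):
        b = tiny_session["behavior"]
        assert b.likelihood_rating.between(1, 5).all()
        assert b.trend_rating.between(1, 3).all()
        assert len(b) == 324

    def test_gamma_zero_ratings_ignore_the_stimulus(self, stimset, trials):
        lay = sd.make_grid_layout(n_side=4)
        truth = sd.make_ground_truth(lay, gamma=0.0)
        b = sd.simulate_behavior(trials, stimset, truth, seed=5)
        cell_means = b.groupby(["pstar_bin", "presented_final"])[
            "likelihood_rating"].mean()
        assert cell_means.max() - cell_means.min() < 0.6

    def test_crossover_with_default_gamma(self, stimset, trials):
        lay = sd.make_grid_layout(n_side=4)
        truth = sd.make_ground_truth(lay, gamma=1.0)
        b = sd.simulate_behavior(trials, stimset, truth, seed=6)
        m = b.groupby(["pstar_bin", "presented_final"])[
            "likelihood_rating"].mean()
        # low p34 rated more likely when p34* was low, and vice versa
        assert m[("low", 220.0)] > m[("high", 220.0)]
        assert m[("high", 880.0)] > m[("low", 880.0)]

    def test_rating_monotone_in_prediction_error_before_clamp(self, stimset,
                                                              trials):
        lay = sd.make_grid_layout(n_side=4)
        truth = sd.make_ground_truth(lay, gamma=1.0)
        noise = sd.NoiseConfig(rating_noise_sd=0.0)
        b = sd.simulate_behavior(trials, stimset, truth, noise=noise, seed=0)
        zf = sd._z_standardizer(stimset.grid)
        # reconstruct the per-trial prediction error and check monotonicity
        r = st.autocovariance(stimset.sequences[0].beta, truth.k_subj + 2)
        errs, ratings = [], []
        for seq in stimset.sequences:
            a = st.blp_weights(r if seq.beta == stimset.sequences[0].beta
                               else st.autocovariance(seq.beta,
                                                      truth.k_subj + 2),
                               truth.k_subj, truth.k_subj + 1)
            z = zf(seq.pitches)[-truth.k_subj:]
            zhat = z.mean() + a @ (z - z.mean())
            rows = b[b.predicted_final == seq.predicted_final]
            rows = rows[rows.pstar_bin == seq.pstar_bin]
            for _, row in rows.iterrows():
                errs.append(abs(zf(row.presented_final) - zhat))
                ratings.append(row.likelihood_rating)
        errs, ratings = np.array(errs), np.array(ratings)
        order = np.argsort(errs)
        # ratings are a non-increasing step function of the error
        assert np.all(np.diff(ratings[order]) <= 0) or \
            np.corrcoef(errs, ratings)[0, 1] < -0.9


class TestIO:
    def test_recording_roundtrip(self, tiny_session, tmp_path):
        rec = tiny_session["recordings"][150]
        path = tmp_path / "rec.h5"
        sd.save_recording(rec, str(path))
        back = sd.load_recording(str(path))
        assert np.array_equal(back.activity, rec.activity)
        assert np.array_equal(back.onset_samples, rec.onset_samples)
        assert back.tone_duration == 150 and back.sample_rate == 300.0
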