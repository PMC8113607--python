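"""Windowed activity and cross-validated k' estimation."""

import numpy as np
import pandas as pd
import pytest

import tonepred.shi as shi
import tonepred.stimuli as st
import tonepred.synthetic_data as sd


def _manual_wa(trials, stimset, fill, tone_duration=300):
    """WindowedActivity built directly from a per-(trial, tone) function."""
    sub = trials[trials.tone_duration == tone_duration].reset_index(drop=True)
    logp = {s.seq_id: np.log(s.pitches) for s in stimset.sequences}
    n = len(sub)
    data = np.zeros((n, 1, 34, 1))
    for t in range(n):
        lp = logp[sub.sequence_id[t]]
        for i in range(34):
            data[t, 0, i, 0] = fill(lp, i)
    return shi.WindowedActivity(
        data=data, tone_duration=tone_duration,
        sequence_ids=sub.sequence_id.to_numpy(),
        trial_index=sub.trial_index.to_numpy())


class TestWindowAverage:
    @pytest.mark.parametrize("dur,n_windows", [(150, 3), (300, 6), (600, 12)])
    def test_window_count_scales_with_tone_duration(self, tiny_session,
                                                    trials, dur, n_windows):
        wa = shi.window_average(tiny_session["recordings"][dur], trials)
        assert wa.n_windows == n_windows
        assert wa.data.shape[2] == 34

    def test_constant_recording_gives_constant_windows(self, tiny_session,
                                                       trials):
        rec = tiny_session["recordings"][150]
        const = sd.Recording(
            subject=0, tone_duration=150,
            activity=np.full_like(rec.activity, 7.25),
            sample_rate=rec.sample_rate, onset_samples=rec.onset_samples,
            trial_index=rec.trial_index)
        wa = shi.window_average(const, trials)
        assert np.allclose(wa.data, 7.25)

    def test_ramp_window_means_match_sample_averages(self, tiny_session,
                                                     trials):
        rec = tiny_session["recordings"][150]
        n_samples = rec.activity.shape[2]
        ramp = np.arange(n_samples, dtype=np.float32)
        act = np.broadcast_to(ramp, rec.activity.shape).copy()
        r2 = sd.Recording(subject=0, tone_duration=150, activity=act,
                          sample_rate=rec.sample_rate,
                          onset_samples=rec.onset_samples,
                          trial_index=rec.trial_index)
        wa = shi.window_average(r2, trials)
        # oracle: arithmetic mean of the known ramp samples per window
        w_len = int(round(rec.sample_rate * 0.05))
        for i in (0, 10, 33):
            for w in range(3):
                a = rec.onset_samples[i] + w * w_len
                expected = ramp[a:a + w_len].mean()
                assert wa.data[0, 0, i, w] == pytest.approx(expected)

    def test_onset_past_recording_end_raises(self, tiny_session, trials):
        rec = tiny_session["recordings"][150]
        bad = sd.Recording(subject=0, tone_duration=150,
                           activity=rec.activity[:, :, :rec.onset_samples[-1]],
                           sample_rate=rec.sample_rate,
                           onset_samples=rec.onset_samples,
                           trial_index=rec.trial_index)
        with pytest.raises(IndexError):
            shi.window_average(bad, trials)


class TestFitKPrime:
    def test_fold_balance_two_reps_per_sequence(self, trials, stimset):
        wa = _manual_wa(trials, stimset, lambda lp, i: 0.0)
        km = shi.fit_kprime(wa, stimset, seed=4)
        sub = trials[trials.tone_duration == 300].reset_index(drop=True)
        df = pd.DataFrame({"fold": km.fold_assignment,
                           "seq": sub.sequence_id})
        counts = df.groupby(["fold", "seq"]).size()
        assert (counts == 2).all()
        assert df.groupby("fold").size().eq(18).all()

    def test_noiseless_current_tone_activity_selects_k_zero(self, trials,
                                                            stimset):
        wa = _manual_wa(trials, stimset, lambda lp, i: lp[min(i, 32)])
        km = shi.fit_kprime(wa, stimset, seed=4)
        # SSE is exactly zero for every model; ties resolve to the smallest
        assert np.all(km.fold_winners == 0)
        assert np.all(km.kprime == 0.0)

    def test_noiseless_two_tone_history_selects_k_one(self, trials, stimset):
        wa = _manual_wa(trials, stimset,
                        lambda lp, i: lp[min(i, 32)] + 0.7 * lp[max(i - 1, 0)])
        km = shi.fit_kprime(wa, stimset, seed=4)
        assert np.all(km.kprime == 1.0)

    def test_kprime_bounds_and_determinism(self, fixed_study):
        for d, maps in fixed_study["kmaps"].items():
            for km in maps:
                assert km.kprime.min() >= 0 and km.kprime.max() <= 15
        km0 = fixed_study["kmaps"][300][0]
        wa = fixed_study["was300"][0]
        again = shi.fit_kprime(wa, fixed_study["study"].stimset, seed=100,
                               windows=np.arange(3))
        assert np.array_equal(again.kprime, km0.kprime)

    def test_trial_order_exchangeability_with_fixed_folds(self, trials,
                                                          stimset):
        rng = np.random.default_rng(7)
        wa = _manual_wa(trials, stimset,
                        lambda lp, i: lp[min(i, 32)] + rng.normal(0, 0.3))
        km = shi.fit_kprime(wa, stimset, seed=4)
        perm = np.random.default_rng(0).permutation(len(wa.sequence_ids))
        wa2 = shi.WindowedActivity(
            data=wa.data[perm], tone_duration=300,
            sequence_ids=wa.sequence_ids[perm],
            trial_index=wa.trial_index[perm])
        km2 = shi.fit_kprime(wa2, stimset, seed=4,
                             fold_assignment=km.fold_assignment[perm])
        assert np.array_equal(km.kprime, km2.kprime)

    def test_k_max_beyond_pool_boundary_rejected(self, trials, stimset):
        wa = _manual_wa(trials, stimset, lambda lp, i: 0.0)
        with pytest.raises(ValueError, match="k_max"):
            shi.fit_kprime(wa, stimset, k_max=16)

    def test_unbalanced_trials_rejected(self, trials, stimset):
        wa = _manual_wa(trials, stimset, lambda lp, i: 0.0)
        wa_bad = shi.WindowedActivity(
            data=wa.data[:-1], tone_duration=300,
            sequence_ids=wa.sequence_ids[:-1],
            trial_index=wa.trial_index[:-1])
        with pytest.raises(ValueError, match="folds"):
            shi.fit_kprime(wa_bad, stimset)


class TestShuffledNull:
    def test_null_dimensions_and_prefold_count(self, fixed_study):
        kn = fixed_study["knulls"][300][0]
        assert kn.kshuff.shape == (64, 3, 100)
        # 100 repetitions x 6 folds = 600 winners before fold-averaging
        assert kn.kshuff.shape[-1] * 6 == 600

    def test_shuffle_orders_shared_across_conditions(self):
        a = shi._shuffle_perm(11, "b1.5_low", rep=3, fold=2)
        b = shi._shuffle_perm(11, "b1.5_low", rep=3, fold=2)
        c = shi._shuffle_perm(11, "b1.5_low", rep=4, fold=2)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)
        assert sorted(a) == list(range(32))

    def test_identity_permutation_reproduces_observed(self, trials, stimset):
        rng = np.random.default_rng(5)
        wa = _manual_wa(trials, stimset,
                        lambda lp, i: lp[min(i, 32)] + rng.normal(0, 0.5))
        eng = shi._CVEngine(wa, stimset, 15, 6, 4, None)
        observed = eng.fit_rep(lambda f: None)
        ident = eng.fit_rep(lambda f: [np.arange(32)] * 9)
        assert np.array_equal(observed, ident)

    def test_history_sensors_exceed_their_shuffled_null(self, fixed_study):
        lay = fixed_study["layout"]
        idx = lay.role_idx("informational")
        obs = np.mean([m.kprime[idx].mean()
                       for m in fixed_study["kmaps"][300]])
        null = np.mean([n.kshuff[idx].mean()
                        for n in fixed_study["knulls"][300]])
        assert obs > null + 1.0


class TestGroupTest:
    def test_null_vector_length_and_p_range(self, fixed_study):
        res = shi.group_kprime_test(fixed_study["kmaps"][300],
                                    fixed_study["knulls"][300],
                                    n_draws=1000, seed=2)
        assert res["null"].shape[0] == 1000
        assert res["p"].min() >= 0 and res["p"].max() <= 1

    def test_informational_sensors_significant_noise_not(self, fixed_study):
        res = shi.group_kprime_test(fixed_study["kmaps"][300],
                                    fixed_study["knulls"][300],
                                    n_draws=1000, seed=2)
        lay = fixed_study["layout"]
        assert res["p"][lay.role_idx("informational")].max() < 0.05
        assert res["p"][lay.role_idx("noise")].mean() > 0.2

    def test_observed_above_every_null_reports_zero(self):
        km = shi.KPrimeMap(kprime=np.full((2, 1), 15.0),
                           fold_winners=np.zeros((6, 2, 1), int),
                           fold_assignment=np.zeros(108, int),
                           windows=np.arange(1), tone_duration=300, seed=0)
        kn = shi.KPrimeNull(kshuff=np.random.default_rng(0).uniform(
            0, 5, (2, 1, 100)), fold_assignment=np.zeros(108, int),
            windows=np.arange(1), tone_duration=300, seed=0, shuffle_seed=0)
        res = shi.group_kprime_test([km, km], [kn, kn], n_draws=200)
        assert np.all(res["p"] == 0.0)

    def test_mismatched_subject_sets_rejected(self, fixed_study):
        with pytest.raises(ValueError):
            shi.group_kprime_test(fixed_study["kmaps"][300],
                                  fixed_study["knulls"][300][:-1])


def test_kprime_hdf5_roundtrip(fixed_study, tmp_path):
    km = fixed_study["kmaps"][300][0]
    kn = fixed_study["knulls"][300][0]
    path = tmp_path / "kprime.h5"
    shi.save_kprime(str(path), km, kn)
    km2, kn2 = shi.load_kprime(str(path))
    assert np.array_equal(km2.kprime, km.kprime)
    assert np.array_equal(kn2.kshuff, kn.kshuff)
    assert km2.tone_duration == 300
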