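"""Semi-Markov state generator and signal synthesis."""

import math

import numpy as np
import pytest

from oxsleep import (
    CATAPLEXY,
    NREM,
    REM,
    WAKE,
    SimConfig,
    apply_drug_effect,
    simulate_states,
    synthesize_signals,
)
from oxsleep.sim import ConfigError, track_runs
from oxsleep.spectral import epoch_features

from oracles import run_lengths, state_bout_means


def short_config(**kw) -> SimConfig:
    defaults = dict(duration_s=600.0, sampling_rate=250.0)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestSimulateStates:
    def test_forced_single_state_chain(self):
        cfg = short_config(
            mean_bout={WAKE: math.inf, NREM: 100.0, REM: 60.0}, cataplexy_hazard=0.0
        )
        track = simulate_states(cfg, seed=0)
        assert len(track.labels) == 600
        assert set(track.labels) == {WAKE}

    def test_deterministic_for_fixed_seed(self, oxko_config):
        a = simulate_states(oxko_config, seed=7)
        b = simulate_states(oxko_config, seed=7)
        assert np.array_equal(a.labels, b.labels)
        c = simulate_states(oxko_config, seed=8)
        assert not np.array_equal(a.labels, c.labels)

    def test_wake_bout_mean_matches_config(self, oxko_config):
        """Empirical wake bout mean (independent run-length scan) within 15%.

        Pooled over the six study-arm seeds: a single 3-h track holds only
        ~50 wake bouts, so its sample mean alone carries ~10% standard error.
        """
        durs = []
        for seed in range(1, 7):
            track = simulate_states(oxko_config, seed=seed)
            durs += [d for _, d, lab in run_lengths(track.labels) if lab == WAKE]
        target = oxko_config.mean_bout[WAKE]
        assert abs(np.mean(durs) - target) / target < 0.15

    def test_track_length_and_alphabet(self, oxko_config):
        track = simulate_states(oxko_config, seed=3)
        assert track.duration_s == int(oxko_config.duration_s)
        assert set(track.labels) <= {WAKE, NREM, REM, CATAPLEXY}

    def test_run_length_means_within_three_se(self):
        """Sample bout means within 3 SE of configured means (>=100 bouts).

        Checked without the cataplexy hazard, which by design truncates
        wake bouts (a competing risk, not part of the bout distribution).
        """
        cfg = SimConfig(duration_s=180000.0, cataplexy_hazard=0.0)
        track = simulate_states(cfg, seed=11)
        byst: dict[str, list[int]] = {}
        for _, dur, lab in run_lengths(track.labels):
            byst.setdefault(lab, []).append(dur)
        for st in (WAKE, NREM, REM):
            durs = np.array(byst[st], float)
            assert len(durs) >= 100, st
            se = durs.std(ddof=1) / np.sqrt(len(durs))
            assert abs(durs.mean() - cfg.mean_bout[st]) < 3 * se, st

    def test_rem_never_directly_follows_wake(self, oxko_config):
        for seed in range(5):
            runs = track_runs(simulate_states(oxko_config, seed=seed).labels)
            for prev, cur in zip(runs[:-1], runs[1:]):
                assert not (prev[2] == WAKE and cur[2] == REM)

    def test_cataplexy_entered_only_from_wake(self, oxko_config):
        runs = track_runs(simulate_states(oxko_config, seed=2).labels)
        for prev, cur in zip(runs[:-1], runs[1:]):
            if cur[2] == CATAPLEXY:
                assert prev[2] == WAKE

    def test_decoy_events_have_short_prior_wake(self):
        """With decoy_fraction 1, every theta-atonia event has <40 s prior wake."""
        cfg = SimConfig(duration_s=10800.0, decoy_fraction=1.0, cataplexy_hazard=12.0)
        runs = track_runs(simulate_states(cfg, seed=5).labels)
        n_events = 0
        for prev, cur in zip(runs[:-1], runs[1:]):
            if cur[2] == CATAPLEXY:
                n_events += 1
                assert prev[2] == WAKE and 10 <= prev[1] < 40
        assert n_events > 5


class TestApplyDrugEffect:
    def test_identity_multipliers(self, oxko_config):
        cfg = apply_drug_effect(oxko_config, 1.0, 1.0)
        assert cfg.mean_bout[WAKE] == oxko_config.mean_bout[WAKE]
        assert cfg.cataplexy_hazard == oxko_config.cataplexy_hazard

    def test_scaling_arithmetic(self, oxko_config):
        cfg = apply_drug_effect(oxko_config, 3.0, 0.2)
        assert cfg.mean_bout[WAKE] == pytest.approx(3 * oxko_config.mean_bout[WAKE])
        assert cfg.cataplexy_hazard == pytest.approx(0.2 * oxko_config.cataplexy_hazard)
        assert cfg.mean_bout[NREM] == oxko_config.mean_bout[NREM]
        assert cfg.rem_entry_prob == oxko_config.rem_entry_prob

    @pytest.mark.parametrize("mult", [(0.0, 1.0), (1.0, -2.0)])
    def test_nonpositive_multiplier_rejected(self, oxko_config, mult):
        with pytest.raises(ConfigError):
            apply_drug_effect(oxko_config, *mult)

    def test_drug_reduces_transitions_and_cataplexy(self, track_pairs):
        """Monte-Carlo: fewer wake<->NREM switches and fewer cataplexy-like
        bouts under the drug configuration (seed-matched means)."""

        def wn_transitions(labels):
            runs = track_runs(labels)
            return sum(
                1
                for a, b in zip(runs[:-1], runs[1:])
                if {a[2], b[2]} == {WAKE, NREM}
            )

        def n_cataplexy(labels):
            return sum(1 for r in track_runs(labels) if r[2] == CATAPLEXY)

        veh_t = [wn_transitions(v.labels) for v, _ in track_pairs]
        drug_t = [wn_transitions(d.labels) for _, d in track_pairs]
        veh_c = [n_cataplexy(v.labels) for v, _ in track_pairs]
        drug_c = [n_cataplexy(d.labels) for _, d in track_pairs]
        assert np.mean(drug_t) < np.mean(veh_t)
        assert np.mean(drug_c) < np.mean(veh_c)

    def test_transition_count_monotone_in_wake_multiplier(self, oxko_config):
        """Wake<->NREM transitions per 3 h non-increasing over multipliers
        1, 2, 4 (seed-matched means, 10 seeds)."""

        def wn_per_track(mult, seed):
            cfg = apply_drug_effect(oxko_config, mult, 1.0)
            runs = track_runs(simulate_states(cfg, seed=seed).labels)
            return sum(
                1 for a, b in zip(runs[:-1], runs[1:]) if {a[2], b[2]} == {WAKE, NREM}
            )

        means = [
            np.mean([wn_per_track(m, s) for s in range(10)]) for m in (1.0, 2.0, 4.0)
        ]
        assert means[0] >= means[1] >= means[2]


class TestSynthesizeSignals:
    def test_all_nrem_track_is_delta_dominant(self):
        cfg = short_config(mean_bout={WAKE: 100.0, NREM: math.inf, REM: 60.0})
        track = simulate_states(
            SimConfig(
                duration_s=600.0,
                mean_bout={WAKE: 1.0, NREM: math.inf, REM: 60.0},
                cataplexy_hazard=0.0,
            ),
            seed=0,
        )
        # force a pure-NREM track
        track = type(track)(labels=np.full(600, NREM, dtype="<U9"))
        rec = synthesize_signals(track, cfg, seed=1)
        for f in epoch_features(rec, 20):
            assert f.delta_power > f.theta_power
            assert f.delta_power > f.fast_power

    def test_all_rem_track_has_atonia(self, oxko_config):
        track = type(simulate_states(short_config(), seed=0))(
            labels=np.full(300, REM, dtype="<U9")
        )
        rec = synthesize_signals(track, short_config(), seed=2)
        rms = np.sqrt(np.mean(rec.emg**2))
        assert rms < 0.5 * short_config().emg_level_uv["nrem"]

    def test_byte_identical_across_runs(self):
        cfg = short_config()
        track = simulate_states(cfg, seed=3)
        a = synthesize_signals(track, cfg, seed=4)
        b = synthesize_signals(track, cfg, seed=4)
        assert a.eeg.tobytes() == b.eeg.tobytes()
        assert a.emg.tobytes() == b.emg.tobytes()

    def test_signal_length_matches_track(self):
        cfg = short_config()
        track = simulate_states(cfg, seed=5)
        rec = synthesize_signals(track, cfg, seed=6)
        assert len(rec.eeg) == len(rec.emg) == 600 * 250


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"duration_s": -10.0},
            {"duration_s": 10.5},
            {"mean_bout": {WAKE: 120.0, NREM: -1.0, REM: 60.0}},
            {"mean_bout": {WAKE: 120.0, NREM: 100.0, REM: 60.0, "Limbo": 5.0}},
            {"rem_entry_prob": 1.5},
            {"emg_level_uv": {"wake": 10.0, "nrem": 12.0, "atonia": 4.0}},
            {
                "band_weights": {
                    WAKE: (0.5, 0.5, 0.5),
                    NREM: (0.6, 0.15, 0.25),
                    REM: (0.15, 0.65, 0.2),
                    CATAPLEXY: (0.15, 0.65, 0.2),
                }
            },
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigError):
            SimConfig(**kw)
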