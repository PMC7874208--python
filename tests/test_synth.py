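"""Stimulus layout and the phenomenological resource model of the generator."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vsrkit import (
    PhenotypeParams,
    StimulusProtocol,
    make_stimulus,
    phenotype_preset,
    simulate_trace,
)
from vsrkit.metrics import analyze_trace


class TestStimulusProtocol:
    def test_default_cycle_has_56_frames(self):
        assert StimulusProtocol().frames_per_cycle == 56

    @pytest.mark.parametrize(
        "frequency,fps,expected",
        [(0.53, 30, 56), (1.0, 30, 30), (0.25, 10, 40)],
    )
    def test_frames_per_cycle_is_floor_of_fps_over_frequency(
        self, frequency, fps, expected
    ):
        p = StimulusProtocol(frequency=frequency, fps=fps, frames_per_recording=2 * expected)
        assert p.frames_per_cycle == expected

    def test_interval_protocol_totals_302_seconds(self):
        assert StimulusProtocol.defined_interval().total_duration_s() == pytest.approx(302.0)

    def test_prolonged_protocol_totals_252_seconds(self):
        assert StimulusProtocol.prolonged().total_duration_s() == pytest.approx(252.0)

    @pytest.mark.parametrize("bad", [dict(frequency=0), dict(frequency=-1), dict(fps=0)])
    def test_invalid_protocol_rejected(self, bad):
        with pytest.raises(ValueError):
            StimulusProtocol(**bad)

    def test_recording_must_cover_two_cycles(self):
        with pytest.raises(ValueError):
            StimulusProtocol(frames_per_recording=60)


class TestMakeStimulus:
    def test_platform_starts_at_zero_and_follows_sine(self):
        p = StimulusProtocol(frequency=1.0, fps=30, frames_per_recording=120)
        sched = make_stimulus(p)
        assert sched.platform_deg[0] == pytest.approx(0.0)
        t = np.arange(120) / 30.0
        np.testing.assert_allclose(
            sched.platform_deg, p.amplitude * np.sin(2 * np.pi * t), atol=1e-9
        )

    def test_black_frames_every_cycle_from_frame_zero(self):
        p = StimulusProtocol(frequency=0.25, fps=10, frames_per_recording=120)
        sched = make_stimulus(p)
        assert p.frames_per_cycle == 40
        np.testing.assert_array_equal(sched.black_frames, [0, 40, 80])

    def test_rest_periods_contain_no_frames(self):
        p = StimulusProtocol(epochs=((10.0, 5.0), (10.0, 0.0)))
        sched = make_stimulus(p)
        assert sched.n_frames == 2 * 300
        e0, e1 = sched.epochs
        assert (e0.stop, e1.start) == (300, 300)
        assert e1.t0_s == pytest.approx(10.0 + 5.0)


class TestSimulateTrace:
    def test_deterministic_for_fixed_seed(self, protocol):
        params = phenotype_preset("wild_type", seed=42)
        a = simulate_trace(params, protocol)
        b = simulate_trace(params, protocol)
        assert np.array_equal(a.angles, b.angles)
        assert np.array_equal(a.black_frames, b.black_frames)

    def test_seed_changes_trace(self, protocol):
        a = simulate_trace(phenotype_preset("wild_type", seed=1), protocol)
        b = simulate_trace(phenotype_preset("wild_type", seed=2), protocol)
        assert not np.array_equal(a.angles, b.angles)

    def test_null_phenotype_has_no_active_cycles(self, protocol):
        """No evoked signal and ≤1° noise: the pipeline finds zero activity."""
        failures = 0
        for seed in range(20):
            params = phenotype_preset("mechanotransduction_null", seed=seed)
            cy = analyze_trace(simulate_trace(params, protocol))
            if cy.loc[~cy["excluded"], "active"].any():
                failures += 1
        assert failures <= 1  # ≥95% of seeds fully inactive

    def test_no_depletion_keeps_every_cycle_active(self, protocol):
        params = phenotype_preset(
            "wild_type",
            bout_prob=1.0,
            adaptation_rate=0.0,
            depletion_per_cycle=0.0,
            startle_rate=0.0,
            seed=7,
        )
        cy = analyze_trace(simulate_trace(params, protocol))
        assert cy.loc[~cy["excluded"], "active"].all()

    @pytest.mark.parametrize("seed", [0, 5, 9])
    def test_depletion_confines_activity_to_prefix_matching_recursion(
        self, protocol, seed
    ):
        """Active cycles form an initial prefix whose length a hand-rolled
        simulation of the resource recursion predicts exactly."""
        delta, thr = 0.25, 0.2
        params = phenotype_preset(
            "synj1_like",
            bout_amplitude_deg=40.0,  # keeps the last firing cycle clearly above 5°
            depletion_per_cycle=delta,
            response_threshold=thr,
            bout_prob=1.0,
            startle_rate=0.0,
            noise_sd_deg=0.3,
            seed=seed,
        )
        # Independent oracle: step the recursion by hand over all cycles.
        n_cycles = 23  # 22 complete + 1 partial in a 1280-frame recording
        R, fired = 1.0, []
        for _ in range(n_cycles):
            if R >= thr:
                fired.append(True)
                R = max(0.0, R - delta)
            else:
                fired.append(False)
        cy = analyze_trace(simulate_trace(params, protocol))
        kept = cy[~cy["excluded"]]
        expected = [fired[int(i)] for i in kept["cycle_index"]]
        assert list(kept["active"]) == expected

    def test_resource_pool_stays_in_unit_interval(self):
        """Depletion and recovery can never push R outside [0, 1]."""
        rng = np.random.default_rng(3)
        for _ in range(200):
            R = rng.random()
            for _ in range(50):
                if rng.random() < 0.5:
                    R = max(0.0, R - rng.uniform(0, 1.5))
                else:
                    R = 1.0 - (1.0 - R) * np.exp(-rng.uniform(0, 60) / rng.uniform(1, 40))
                assert 0.0 <= R <= 1.0

    @given(st.integers(0, 30))
    def test_more_depletion_never_adds_active_cycles(self, seed):
        protocol = StimulusProtocol()
        counts = []
        for delta in (0.1, 0.2, 0.35, 0.6):
            params = phenotype_preset(
                "synj1_like",
                depletion_per_cycle=delta,
                bout_prob=1.0,
                startle_rate=0.0,
                seed=seed,
            )
            cy = analyze_trace(simulate_trace(params, protocol))
            counts.append(int(cy.loc[~cy["excluded"], "active"].sum()))
        assert counts == sorted(counts, reverse=True)

    def test_startles_exceed_45_degrees(self, protocol):
        params = phenotype_preset("wild_type", startle_rate=1.0, seed=13)
        trace = simulate_trace(params, protocol)
        assert np.max(np.abs(trace.angles)) > 45.0

    def test_rest_recovery_restores_response(self):
        """After depletion, a long rest brings activity back in the next epoch."""
        proto = StimulusProtocol(epochs=((42.0, 30.0), (42.0, 0.0)))
        params = phenotype_preset(
            "synj1_like", bout_prob=1.0, startle_rate=0.0, recovery_tau_s=10.0, seed=4
        )
        cy = analyze_trace(simulate_trace(params, proto))
        by_epoch = cy[~cy["excluded"]].groupby("epoch")["active"].sum()
        assert by_epoch[1] >= 1

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PhenotypeParams(bout_prob=1.5)
        with pytest.raises(ValueError):
            PhenotypeParams(depletion_per_cycle=-0.1)
        with pytest.raises(ValueError):
            phenotype_preset("no_such_phenotype")

    def test_black_frames_marked_invalid(self, wt_trace):
        assert not wt_trace.valid[wt_trace.black_frames].any()
        assert wt_trace.valid.sum() == wt_trace.n_frames - len(wt_trace.black_frames)
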