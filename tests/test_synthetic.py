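import dataclasses
import filecmp

import numpy as np
import pytest

from edgecode.data_model import save_dataset, segment_trials
from edgecode.features import mean_rate
from edgecode.synthetic import (
    ConfigError,
    DEFAULT_HYPERPARAMS,
    SimConfig,
    SubfieldModel,
    TypeHyperparams,
    edge_drive,
    generate_dataset,
    sample_neuron_model,
    simulate_trial,
)


def _single_subfield_model(**kw):
    defaults = dict(
        neuron_type="FA-1",
        centers_um=[[0.0, 0.0]],
        amplitudes=[1.0],
        sigmas_um=[100.0],
        gain_hz=300.0,
        background_hz=0.0,
        refractory_s=0.0005,
        beta=0.5,
        jitter_um=0.0,
        pattern_seed=9,
    )
    defaults.update(kw)
    return SubfieldModel(**defaults)


class TestModelSampling:
    def test_same_seed_identical_models(self):
        hp = DEFAULT_HYPERPARAMS["FA-1"]
        m1 = sample_neuron_model("FA-1", hp, np.random.default_rng(3))
        m2 = sample_neuron_model("FA-1", hp, np.random.default_rng(3))
        assert np.array_equal(m1.centers_um, m2.centers_um)
        assert np.array_equal(m1.amplitudes, m2.amplitudes)
        assert m1.gain_hz == m2.gain_hz and m1.pattern_seed == m2.pattern_seed

    def test_fa_subfield_count_about_twice_sa(self):
        # Monte-Carlo check of the configured ratio: E[FA]=17, E[SA]=8.5
        rng = np.random.default_rng(0)
        n_fa = np.mean(
            [
                sample_neuron_model("FA-1", DEFAULT_HYPERPARAMS["FA-1"], rng).n_subfields
                for _ in range(1000)
            ]
        )
        n_sa = np.mean(
            [
                sample_neuron_model("SA-1", DEFAULT_HYPERPARAMS["SA-1"], rng).n_subfields
                for _ in range(1000)
            ]
        )
        assert n_fa / n_sa == pytest.approx(2.0, rel=0.1)

    def test_forced_single_subfield_geometry(self):
        hp = TypeHyperparams(
            subfield_count=(1, 1),
            gain_range_hz=(300.0, 300.0),
            beta=0.5,
            amplitude_range=(1.0, 1.0),
            sigma_range_um=(100.0, 100.0),
            ellipse_semi_x_um=1e-9,
            ellipse_semi_y_um=1e-9,
        )
        m = sample_neuron_model("FA-1", hp, np.random.default_rng(1))
        assert m.n_subfields == 1
        assert np.allclose(m.centers_um, 0.0, atol=1e-6)
        assert m.sigmas_um[0] == 100.0 and m.amplitudes[0] == 1.0

    def test_degenerate_ellipse_rejected(self):
        hp = dataclasses.replace(DEFAULT_HYPERPARAMS["FA-1"], ellipse_semi_x_um=0.0)
        with pytest.raises(ConfigError):
            sample_neuron_model("FA-1", hp, np.random.default_rng(0))

    def test_refractory_floor_enforced(self):
        with pytest.raises(ConfigError):
            _single_subfield_model(refractory_s=0.0001)


class TestEdgeDrive:
    def test_line_through_centre_gives_unit_drive(self):
        m = _single_subfield_model()
        assert edge_drive(m, 0.0, 0.0) == pytest.approx(1.0)

    def test_one_sigma_off_centre(self):
        m = _single_subfield_model()
        assert edge_drive(m, 0.0, 100.0) == pytest.approx(np.exp(-0.5), rel=1e-12)

    @pytest.mark.parametrize("theta,y0", [(5.0, 400.0), (-10.0, 250.0), (8.0, -300.0)])
    def test_drive_maximal_where_line_passes_centre(self, theta, y0):
        # analytic maximiser x* = -y0 tan(theta), checked against a numeric scan
        m = _single_subfield_model(centers_um=[[0.0, y0]])
        x = np.linspace(-500.0, 500.0, 20001)
        d = edge_drive(m, theta, x)
        x_star = x[np.argmax(d)]
        assert x_star == pytest.approx(-y0 * np.tan(np.deg2rad(theta)), abs=0.1)


class TestSpikeGeneration:
    def test_zero_gain_zero_background_silent(self):
        m = _single_subfield_model(gain_hz=0.0)
        st = simulate_trial(m, 5.0, 30.0, np.random.default_rng(0))
        assert st.times_s.size == 0

    def test_spike_times_strictly_increasing_and_refractory(self):
        m = _single_subfield_model(gain_hz=800.0, background_hz=5.0, jitter_um=20.0)
        st = simulate_trial(m, -5.0, 30.0, np.random.default_rng(1))
        isi = np.diff(st.times_s)
        assert np.all(isi > 0)
        assert isi.min() >= m.refractory_s - 1e-12

    def test_speed_invariant_positions_in_deterministic_limit(self):
        # j = 0, beta = 1 (no thinning with speed), long refractory, high gain:
        # the expressed pattern is identical across speeds, so the surviving
        # spike positions agree to within the sampling bin
        m = _single_subfield_model(gain_hz=2000.0, beta=1.0, refractory_s=0.05)
        rng = np.random.default_rng(2)
        pos = {}
        for v in (15.0, 180.0):
            st = simulate_trial(m, 5.0, v, rng)
            pos[v] = st.times_s * v * 1000.0 - 6000.0
        assert pos[15.0].size == pos[180.0].size > 0
        # refractory in time censors distances differently per speed: compare
        # only the first spike, which is speed-invariant
        assert pos[15.0][0] == pytest.approx(pos[180.0][0], abs=2.0)

    def test_expected_count_scaling_with_speed(self):
        # mean count ratio between 15 and 180 mm/s ~ (180/15)^(1-beta) for
        # beta = 0.5; averaged over models to integrate out the frozen
        # recruitment strengths
        rng = np.random.default_rng(3)
        hp = TypeHyperparams(
            subfield_count=(40, 40),
            gain_range_hz=(120.0, 120.0),
            beta=0.5,
            sigma_range_um=(20.0, 30.0),
            background_hz=0.0,
            refractory_s=0.0005,
            jitter_um=0.0,
        )
        counts = {15.0: 0, 180.0: 0}
        for _ in range(25):
            m = sample_neuron_model("FA-1", hp, rng)
            for v in counts:
                counts[v] += sum(
                    simulate_trial(m, 5.0, v, rng).times_s.size for _ in range(20)
                )
        assert counts[15.0] / counts[180.0] == pytest.approx(np.sqrt(180.0 / 15.0), rel=0.07)

    def test_spike_sets_nested_across_speeds(self):
        # with no jitter/background the fast-scan pattern is a subset of the
        # slow-scan pattern (speed invariance by construction)
        rng0 = np.random.default_rng(40)
        m = _single_subfield_model(
            centers_um=rng0.normal(0.0, 800.0, size=(30, 2)),
            amplitudes=np.ones(30),
            sigmas_um=np.full(30, 40.0),
            gain_hz=120.0,
            beta=0.5,
        )
        rng = np.random.default_rng(4)
        slow = simulate_trial(m, 5.0, 15.0, rng).times_s * 15000.0
        fast = simulate_trial(m, 5.0, 180.0, rng).times_s * 180000.0
        assert slow.size > fast.size > 0
        matched = sum(np.min(np.abs(slow - p)) < 1e-6 for p in fast)
        # expression noise (p=0.9 per spike per trial) breaks exact subset
        # membership for a few spikes; the bulk must coincide exactly
        assert matched >= 0.7 * fast.size

    def test_jitter_knob_increases_measured_scatter(self):
        rng = np.random.default_rng(5)
        scatter = []
        for j in (0.0, 20.0, 80.0):
            m = _single_subfield_model(gain_hz=600.0, jitter_um=j, pattern_seed=11)
            trials = [
                simulate_trial(m, 5.0, 30.0, rng).times_s * 30000.0 for _ in range(30)
            ]
            # nearest-spike displacement between trial pairs
            diffs = []
            for a, b in zip(trials[:-1], trials[1:]):
                if a.size and b.size:
                    diffs += [np.min(np.abs(b - x)) for x in a]
            scatter.append(np.std(diffs))
        assert scatter[0] < scatter[1] < scatter[2]


class TestDatasetGeneration:
    def test_factorial_bookkeeping_full_design(self):
        cfg = SimConfig(n_fa=2, n_sa=2, seed=1)
        records, truth = generate_dataset(cfg)
        assert len(records) == 4 and len(truth) == 4
        for rec in records:
            assert len(rec.spike_trains) == 4 * 8 * 15  # 480 trials
        assert {truth[r.neuron_id].neuron_type for r in records} == {"FA-1", "SA-1"}

    def test_identical_seeds_byte_identical_files(self, tmp_path):
        cfg = SimConfig(n_fa=1, n_sa=1, seed=9, speeds_mm_s=(20.0, 60.0), trace_hz=600.0)
        r1, _ = generate_dataset(cfg)
        r2, _ = generate_dataset(cfg)
        save_dataset(r1, tmp_path / "a")
        save_dataset(r2, tmp_path / "b")
        for da in sorted((tmp_path / "a").iterdir()):
            db = tmp_path / "b" / da.name
            for f in ("meta.json", "spikes.csv", "drum.csv"):
                assert filecmp.cmp(da / f, db / f, shallow=False), f"{da.name}/{f}"

    def test_rate_up_count_down_with_speed(self):
        # population-level Fig 2-style trends: mean firing rate increases and
        # spike count decreases with speed for 0 < beta < 1 (averaged over
        # many models, where the subfield-recruitment steps of single neurons
        # wash out); the mean rate over the simulated span is proportional to
        # mean count x speed
        rng = np.random.default_rng(13)
        speeds = (15.0, 20.0, 30.0, 45.0, 60.0, 90.0, 120.0, 180.0)
        counts = {v: 0 for v in speeds}
        for t, base in DEFAULT_HYPERPARAMS.items():
            hp = dataclasses.replace(base, beta=0.5, background_hz=0.0)
            for _ in range(100):
                m = sample_neuron_model(t, hp, rng)
                for v in speeds:
                    counts[v] += sum(
                        simulate_trial(m, 5.0, v, rng).times_s.size for _ in range(3)
                    )
        mean_counts = np.array([counts[v] for v in speeds], dtype=float)
        mean_rates = mean_counts * np.asarray(speeds)
        assert np.all(np.diff(mean_rates) > 0)
        assert np.all(np.diff(mean_counts) < 0)

    def test_seed_recorded_in_truth(self, tmp_path):
        cfg = SimConfig(n_fa=1, n_sa=0, seed=5, speeds_mm_s=(30.0,), trace_hz=600.0)
        records, truth = generate_dataset(cfg)
        from edgecode.synthetic import save_truth
        import json

        save_truth(tmp_path, truth, cfg)
        payload = json.loads((tmp_path / "truth.json").read_text())
        assert payload["seed"] == 5
        assert set(payload["models"]) == {r.neuron_id for r in records}
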