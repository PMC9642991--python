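import numpy as np
import pytest

from edgecode.data_model import (
    DrumTrace,
    NeuronRecord,
    SpikeTrain,
    default_layout,
    segment_trials,
)
from edgecode.synthetic import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def mini_dataset():
    """Small but complete factorial dataset: 2 FA + 1 SA, 3 speeds."""
    cfg = SimConfig(
        n_fa=2, n_sa=1, seed=7, speeds_mm_s=(20.0, 60.0, 120.0), trace_hz=1200.0
    )
    records, truth = generate_dataset(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def mini_trials(mini_dataset):
    _, records, _ = mini_dataset
    return {rec.neuron_id: segment_trials(rec) for rec in records}


@pytest.fixture()
def manual_record():
    """Hand-built single-speed record with known geometry for windowing tests.

    One neuron, constant 30 mm/s, spikes placed symmetrically around each
    nominal line position so the alignment centre of mass is the nominal
    position itself.
    """
    layout = default_layout(rotations=1)
    circ = layout.circumference_mm
    v = 30.0
    trace = DrumTrace.constant_speed(v, circ / v, sample_hz=600.0)
    v_um_s = v * 1000.0
    trains = []
    counters = {}
    for pos_mm, theta in zip(layout.line_positions_mm, layout.line_orientations_deg):
        counters[theta] = counters.get(theta, 0) + 1
        center = pos_mm * 1000.0
        offsets = np.linspace(-1000.0, 1000.0, 11)  # symmetric -> CoM at nominal
        times = (center + offsets) / v_um_s
        trains.append(
            SpikeTrain(
                times_s=times,
                neuron_id="N1",
                orientation_deg=theta,
                speed_mm_s=v,
                rotation=0,
                presentation=counters[theta],
            )
        )
    rec = NeuronRecord(
        neuron_id="N1",
        neuron_type="FA-1",
        spike_trains=trains,
        drum_traces={v: trace},
        layout=layout,
    )
    rec.validate()
    return rec
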