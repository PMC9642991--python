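"""Generative model of FA-1/SA-1 afferents with Gaussian subfields.

Each synthetic afferent is a set of Gaussian-profile subfields scattered in an
elliptical receptive field.  An oriented edge scanning the field drives the
neuron by the sum of subfield activations at the edge's current position; the
spatial layout is fixed per neuron, so the spatial structure of the response
is speed invariant by construction, up to a per-trial Gaussian position jitter
of SD ``jitter_um``.  Spiking follows a frozen-pattern scheme: each subfield
draws, once per neuron, a set of burst events (a Poisson count at Gaussian
offsets around its centre) and a recruitment strength; a trial at speed v
expresses the bursts of the subfields whose strength falls below
(v/v_ref)^(β-1), shifted by the trial's jitter, plus an unrepeatable Poisson
background, then thinned by the absolute refractory period.  Marginally every
trial is an inhomogeneous Poisson process with rate g·(v/v0)^β·drive +
background, but — as in real afferents, whose spike patterns repeat closely
across passes of the same stimulus — spike positions repeat across trials and
speeds up to the configured jitter, so the jitter knob, not sampling noise,
controls the spatial precision of the response.  Firing rates increase and
spike counts decrease with scanning speed for 0 < beta < 1.

All parameter defaults are choices of this package (the factorial design —
4 orientations × 8 speeds × 15 trials, FA-1 with roughly twice the subfield
count of SA-1 — follows the recording study the analysis targets).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .data_model import (
    DrumTrace,
    NeuronRecord,
    SpikeTrain,
    StimulusLayout,
    default_layout,
)

__all__ = [
    "ConfigError",
    "SubfieldModel",
    "TypeHyperparams",
    "SimConfig",
    "sample_neuron_model",
    "edge_drive",
    "simulate_trial",
    "generate_dataset",
    "simulate_record",
    "save_truth",
]


class ConfigError(ValueError):
    """Invalid simulator configuration."""


@dataclass
class SubfieldModel:
    """Ground-truth generative parameters of one synthetic afferent."""

    neuron_type: str
    centers_um: np.ndarray  # (n, 2): x along scan direction, y across it
    amplitudes: np.ndarray  # (n,) dimensionless gains
    sigmas_um: np.ndarray  # (n,) isotropic subfield SDs
    gain_hz: float  # firing rate per unit drive at v0
    background_hz: float
    refractory_s: float
    beta: float  # velocity exponent (FA-1 > 0, SA-1 ~ 0)
    jitter_um: float  # trial-to-trial spatial jitter SD
    v0_mm_s: float = 30.0
    ellipse_semi_x_um: float = 2500.0
    ellipse_semi_y_um: float = 1500.0
    pattern_seed: int = 0  # seeds the frozen master spike pattern

    def __post_init__(self) -> None:
        self.centers_um = np.atleast_2d(np.asarray(self.centers_um, dtype=float))
        self.amplitudes = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        self.sigmas_um = np.atleast_1d(np.asarray(self.sigmas_um, dtype=float))
        if np.any(self.sigmas_um <= 0):
            raise ConfigError("subfield SDs must be positive")
        if self.refractory_s < 0.0005:
            raise ConfigError("absolute refractory period must be >= 0.5 ms")

    @property
    def n_subfields(self) -> int:
        return len(self.amplitudes)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return d


@dataclass(frozen=True)
class TypeHyperparams:
    """Sampling ranges for one neuron type (uniform unless noted)."""

    subfield_count: tuple[int, int]
    gain_range_hz: tuple[float, float]
    beta: float
    amplitude_range: tuple[float, float] = (0.3, 1.0)
    sigma_range_um: tuple[float, float] = (40.0, 90.0)
    background_hz: float = 2.0
    refractory_s: float = 0.001
    jitter_um: float = 30.0
    v0_mm_s: float = 30.0
    ellipse_semi_x_um: float = 2500.0
    ellipse_semi_y_um: float = 1500.0


#: FA-1 afferents innervate roughly twice as many end organs as SA-1 and fire
#: at higher, more speed-sensitive rates.
DEFAULT_HYPERPARAMS: dict[str, TypeHyperparams] = {
    "FA-1": TypeHyperparams(subfield_count=(10, 24), gain_range_hz=(200.0, 350.0), beta=0.6),
    "SA-1": TypeHyperparams(subfield_count=(5, 12), gain_range_hz=(130.0, 230.0), beta=0.2),
}


@dataclass
class SimConfig:
    """Full factorial design of a synthetic dataset."""

    n_fa: int = 30
    n_sa: int = 23
    speeds_mm_s: tuple[float, ...] = (15.0, 20.0, 30.0, 45.0, 60.0, 90.0, 120.0, 180.0)
    orientations_deg: tuple[float, ...] = (-10.0, -5.0, 5.0, 10.0)
    rotations: int = 3
    presentations_per_rotation: int = 5
    seed: int = 0
    trace_hz: float = 2400.0
    hyperparams: dict[str, TypeHyperparams] = field(
        default_factory=lambda: dict(DEFAULT_HYPERPARAMS)
    )

    @property
    def trials_per_condition(self) -> int:
        return self.rotations * self.presentations_per_rotation

    def validate(self) -> None:
        if any(v <= 0 for v in self.speeds_mm_s):
            raise ConfigError("speeds must be positive")
        if self.trials_per_condition < 2:
            raise ConfigError("need at least 2 trials per condition")
        for t, hp in self.hyperparams.items():
            if hp.ellipse_semi_x_um <= 0 or hp.ellipse_semi_y_um <= 0:
                raise ConfigError(f"degenerate receptive-field ellipse for {t}")


# ---------------------------------------------------------------------------
# model sampling and drive
# ---------------------------------------------------------------------------


def sample_neuron_model(
    neuron_type: str, hp: TypeHyperparams, rng: np.random.Generator
) -> SubfieldModel:
    """Draw one subfield model; fully reproducible given the generator state."""
    if hp.ellipse_semi_x_um <= 0 or hp.ellipse_semi_y_um <= 0:
        raise ConfigError("degenerate receptive-field ellipse")
    lo, hi = hp.subfield_count
    n = int(rng.integers(lo, hi + 1))
    # uniform in the ellipse via the unit-disc polar method
    r = np.sqrt(rng.random(n))
    phi = rng.random(n) * 2 * np.pi
    centers = np.column_stack(
        [r * np.cos(phi) * hp.ellipse_semi_x_um, r * np.sin(phi) * hp.ellipse_semi_y_um]
    )
    amplitudes = rng.uniform(*hp.amplitude_range, size=n)
    sigmas = rng.uniform(*hp.sigma_range_um, size=n)
    gain = float(rng.uniform(*hp.gain_range_hz))
    pattern_seed = int(rng.integers(2**31))
    return SubfieldModel(
        pattern_seed=pattern_seed,
        neuron_type=neuron_type,
        centers_um=centers,
        amplitudes=amplitudes,
        sigmas_um=sigmas,
        gain_hz=gain,
        background_hz=hp.background_hz,
        refractory_s=hp.refractory_s,
        beta=hp.beta,
        jitter_um=hp.jitter_um,
        v0_mm_s=hp.v0_mm_s,
        ellipse_semi_x_um=hp.ellipse_semi_x_um,
        ellipse_semi_y_um=hp.ellipse_semi_y_um,
    )


def edge_drive(model: SubfieldModel, orientation_deg: float, x_um) -> np.ndarray | float:
    """Total subfield activation by an infinite edge crossing the scan axis at x.

    The edge is a zero-width line tilted ``orientation_deg`` away from the
    axis perpendicular to the scan direction.  Each subfield contributes a
    Gaussian of its amplitude in the perpendicular distance from its centre to
    the line, so the drive is smooth in both x and orientation.
    """
    x = np.atleast_1d(np.asarray(x_um, dtype=float))
    th = np.deg2rad(orientation_deg)
    cx = model.centers_um[:, 0][:, None]
    cy = model.centers_um[:, 1][:, None]
    d = (cx - x[None, :]) * np.cos(th) - cy * np.sin(th)
    out = np.sum(
        model.amplitudes[:, None]
        * np.exp(-(d**2) / (2.0 * model.sigmas_um[:, None] ** 2)),
        axis=0,
    )
    return out if np.ndim(x_um) else float(out[0])


# ---------------------------------------------------------------------------
# spike generation
# ---------------------------------------------------------------------------

#: half-width of the simulated neighbourhood around each line crossing, µm
SIM_HALFSPAN_UM = 6000.0
#: spatial bin for Poisson sampling of the master pattern, µm
SIM_BIN_UM = 2.0
#: reference speed at which the master pattern is fully expressed, mm/s;
#: below every used speed, so the per-trial retention (v/v_ref)^(beta-1) <= 1
MASTER_REF_SPEED_MM_S = 10.0


#: per-spike expression probability within an active subfield burst; < 1 so
#: that spike counts vary from trial to trial (intensity decoders need a
#: stochastic count), while spatial structure stays subfield-locked
BURST_EXPRESSION_P = 0.9


def _subfield_bursts(model: SubfieldModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Frozen per-subfield burst events, drawn once per neuron.

    Subfield i contributes a Poisson number of spike events (mean set by its
    amplitude, width and the neuron's gain at the reference speed) at Gaussian
    perpendicular-distance offsets from its centre.  Each *subfield* carries a
    frozen recruitment strength in [0, 1): a trial at speed v expresses the
    bursts of the subfields whose strength falls below the speed-dependent
    retention, so spike sets are nested across speeds at burst granularity and
    shared bursts match exactly across speeds (up to the trial jitter).
    Returns (subfield index per spike, offsets, per-subfield strengths);
    deterministic given ``model.pattern_seed``.
    """
    cache = getattr(model, "_burst_cache", None)
    if cache is None:
        prng = np.random.default_rng(model.pattern_seed)
        mu = (
            model.gain_hz
            * (MASTER_REF_SPEED_MM_S / model.v0_mm_s) ** model.beta
            * model.amplitudes
            * model.sigmas_um
            * math.sqrt(2.0 * math.pi)
            / (MASTER_REF_SPEED_MM_S * 1000.0 * BURST_EXPRESSION_P)
        )  # expected events per subfield at the reference speed
        counts = prng.poisson(mu)
        idx = np.repeat(np.arange(model.n_subfields), counts)
        offsets = prng.normal(0.0, 1.0, idx.size) * model.sigmas_um[idx]
        strength = prng.random(model.n_subfields)
        cache = (idx, offsets, strength)
        object.__setattr__(model, "_burst_cache", cache)
    return cache


def _master_pattern(
    model: SubfieldModel, orientation_deg: float, halfspan_um: float
) -> tuple[np.ndarray, np.ndarray]:
    """Master spike positions and strengths for one (neuron, orientation).

    The same frozen burst events are reused for every orientation; only each
    subfield's crossing position (and the 1/cosθ stretch of the offsets)
    changes with the edge orientation, so spike trains evoked by different
    orientations share fine structure exactly as the subfield drive predicts.
    """
    cache = getattr(model, "_pattern_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(model, "_pattern_cache", cache)
    key = (orientation_deg, halfspan_um)
    if key not in cache:
        idx, offsets, strength = _subfield_bursts(model)
        th = math.radians(orientation_deg)
        crossings = model.centers_um[:, 0] - model.centers_um[:, 1] * math.tan(th)
        pos = crossings[idx] + offsets / math.cos(th)
        keep = (pos >= -halfspan_um) & (pos <= halfspan_um)
        order = np.argsort(pos[keep], kind="stable")
        cache[key] = (pos[keep][order], strength[idx[keep]][order])
    return cache[key]


def simulate_trial(
    model: SubfieldModel,
    orientation_deg: float,
    speed_mm_s: float,
    rng: np.random.Generator,
    halfspan_um: float = SIM_HALFSPAN_UM,
) -> SpikeTrain:
    """One edge passage: frozen-pattern Poisson spiking with refractory thinning.

    The receptive-field centre sits at local scan position 0; the trial spans
    local positions [-halfspan, +halfspan] and spike times are measured from
    the moment the edge enters that span.  The trial expresses the bursts of
    the subfields whose frozen recruitment strength falls below
    ``(v / v_ref) ** (beta - 1)`` (capped at 1), each spike independently with
    probability ``BURST_EXPRESSION_P``, so the expected spike count scales as
    ``(v / v0) ** (beta - 1)``, spike sets are nested across speeds at burst
    granularity, and the positions of expressed spikes repeat across trials up
    to the per-trial jitter shift.
    """
    if speed_mm_s <= 0:
        raise ConfigError("speed must be positive")
    v_um_s = speed_mm_s * 1000.0
    delta = float(rng.normal(0.0, model.jitter_um)) if model.jitter_um > 0 else 0.0

    pattern, strength = _master_pattern(model, orientation_deg, halfspan_um)
    retention = min(1.0, (speed_mm_s / MASTER_REF_SPEED_MM_S) ** (model.beta - 1.0))
    active = strength < retention
    expressed = active & (rng.random(pattern.size) < BURST_EXPRESSION_P)
    pos = pattern[expressed] + delta

    if model.background_hz > 0:
        n_bg = rng.poisson(model.background_hz * 2.0 * halfspan_um / v_um_s)
        pos = np.concatenate([pos, rng.uniform(-halfspan_um, halfspan_um, n_bg)])
    pos = np.sort(pos[(pos >= -halfspan_um) & (pos <= halfspan_um)])
    times = _refractory_thin((pos + halfspan_um) / v_um_s, model.refractory_s)
    return SpikeTrain(
        times_s=times,
        neuron_id="",
        orientation_deg=orientation_deg,
        speed_mm_s=speed_mm_s,
        rotation=0,
        presentation=1,
    )


def _refractory_thin(times: np.ndarray, refractory_s: float) -> np.ndarray:
    if times.size == 0:
        return times
    keep = [times[0]]
    for t in times[1:]:
        if t - keep[-1] >= refractory_s:
            keep.append(t)
    return np.asarray(keep)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


def generate_dataset(
    cfg: SimConfig,
) -> tuple[list[NeuronRecord], dict[str, SubfieldModel]]:
    """Simulate the full factorial design; reproducible from ``cfg.seed``.

    Returns the records plus the ground-truth subfield models keyed by neuron
    id (for parameter-recovery tests).  Drum traces are shared across neurons
    per speed, as in the physical apparatus.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    layout = default_layout(
        cfg.orientations_deg, cfg.presentations_per_rotation, cfg.rotations
    )
    circ_um = layout.circumference_mm * 1000.0
    total_um = cfg.rotations * circ_um

    traces = {
        v: DrumTrace.constant_speed(v, total_um / (v * 1000.0), cfg.trace_hz)
        for v in cfg.speeds_mm_s
    }

    names = [f"FA-{i + 1:03d}" for i in range(cfg.n_fa)] + [
        f"SA-{i + 1:03d}" for i in range(cfg.n_sa)
    ]
    types = ["FA-1"] * cfg.n_fa + ["SA-1"] * cfg.n_sa

    records: list[NeuronRecord] = []
    truth: dict[str, SubfieldModel] = {}
    for name, ntype in zip(names, types):
        model = sample_neuron_model(ntype, cfg.hyperparams[ntype], rng)
        truth[name] = model
        records.append(simulate_record(model, name, layout, traces, rng))
    return records, truth


def simulate_record(
    model: SubfieldModel,
    neuron_id: str,
    layout: StimulusLayout,
    traces: dict[float, DrumTrace],
    rng: np.random.Generator,
) -> NeuronRecord:
    """Simulate one neuron's full factorial recording from a given model.

    Useful for controlled experiments that reuse one subfield layout while
    varying a single model parameter (e.g. the trial jitter).
    """
    circ_um = layout.circumference_mm * 1000.0
    trains: list[SpikeTrain] = []
    for v in sorted(traces):
        v_um_s = v * 1000.0
        t_max = traces[v].time_s[-1]
        for rot in range(layout.rotations):
            for theta, pres_pos, pres_idx in _lines(layout):
                local = simulate_trial(model, theta, v, rng)
                cross_um = pres_pos * 1000.0 + rot * circ_um
                t_offset = (cross_um - SIM_HALFSPAN_UM) / v_um_s
                times = local.times_s + t_offset
                times = times[(times >= 0.0) & (times <= t_max)]
                trains.append(
                    SpikeTrain(
                        times_s=times,
                        neuron_id=neuron_id,
                        orientation_deg=theta,
                        speed_mm_s=v,
                        rotation=rot,
                        presentation=pres_idx,
                    )
                )
    rec = NeuronRecord(
        neuron_id=neuron_id,
        neuron_type=model.neuron_type,
        spike_trains=trains,
        drum_traces=traces,
        layout=layout,
    )
    rec.validate()
    return rec


def _lines(layout: StimulusLayout):
    """Yield (orientation, nominal position mm, presentation index) per line."""
    counters: dict[float, int] = {}
    for pos, theta in zip(layout.line_positions_mm, layout.line_orientations_deg):
        counters[theta] = counters.get(theta, 0) + 1
        yield theta, pos, counters[theta]


def save_truth(path: str | Path, models: dict[str, SubfieldModel], cfg: SimConfig) -> None:
    """Write ground-truth models, seed and hyperparameters next to a dataset."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    payload = {
        "seed": cfg.seed,
        "config": {
            "n_fa": cfg.n_fa,
            "n_sa": cfg.n_sa,
            "speeds_mm_s": list(cfg.speeds_mm_s),
            "orientations_deg": list(cfg.orientations_deg),
            "rotations": cfg.rotations,
            "presentations_per_rotation": cfg.presentations_per_rotation,
            "trace_hz": cfg.trace_hz,
            "hyperparams": {k: dataclasses.asdict(v) for k, v in cfg.hyperparams.items()},
        },
        "models": {k: m.to_jsonable() for k, m in models.items()},
    }
    (path / "truth.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
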