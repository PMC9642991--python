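"""Ideal-observer classification of edge orientation from single-neuron responses.

Two families of decoders are implemented, both leave-one-trial-out:

* intensity decoders compare a held-out trial's peak or mean firing rate with
  the average rate of reference trials per orientation (nearest mean wins);
* profile decoders compare a held-out firing-rate profile (or Gaussian-smoothed
  spike train) with reference profiles via zero-lag Pearson correlation
  (highest mean correlation wins).

Within a speed, references are means over the remaining 14 same-orientation
trials and over 14-trial subsets of each other orientation (the trial with the
same rotation/presentation index is dropped), so every reference has the same
sample size and the held-out trial never contributes to any reference.
Across speeds, the trial is compared against the full 15-trial references at
each *other* speed; the temporal-domain variant start-aligns profiles on an
absolute time grid, zero-padded to the longer window duration (no rescaling of
time, which would covertly re-create the spatial domain), whereas the spatial
domain shares one position grid across speeds.

Ties under the strict argmax/argmin rule count as incorrect (relevant only
for degenerate, e.g. spikeless, trials).  Chance is 0.25 for the four-way
decoders and 0.5 for pairwise orientation differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import TrialResponse
from .features import (
    DEFAULT_SPATIAL_STEP_UM,
    DEFAULT_TEMPORAL_STEP_S,
    mean_rate,
    peak_rate,
    rate_profile,
)

__all__ = [
    "ClassificationResult",
    "SpeedIntensityFit",
    "NeuronSignals",
    "intensity_signals",
    "profile_signals",
    "pearson_rows",
    "intensity_classify_within",
    "profile_classify_within",
    "intensity_classify_across",
    "profile_classify_across",
    "fit_population_speed_function",
    "pairwise_accuracy",
    "delta_theta_pairs",
    "confusion_matrix",
    "shuffle_labels",
    "classify_within_detailed",
    "results_to_frame",
]


@dataclass
class ClassificationResult:
    neuron_id: str
    neuron_type: str
    scheme: str  # intensity-peak | intensity-mean | profile-temporal | profile-spatial | convolved
    scope: str  # 'within' | 'across' | 'pair'
    core_speed: float | None
    chance: float
    accuracy: float
    n_decisions: int
    delta_theta: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.accuracy <= 1.0):
            raise ValueError("accuracy outside [0, 1]")
        if self.n_decisions <= 0:
            raise ValueError("no decisions")


@dataclass
class SpeedIntensityFit:
    """Population-level linear speed→intensity relationship (per neuron type)."""

    neuron_type: str
    kind: str
    slope: float  # Hz per mm/s
    intercept: float  # Hz
    speed_range: tuple[float, float]

    def __call__(self, speed_mm_s) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(speed_mm_s, dtype=float)

    def validate(self) -> None:
        lo, hi = self.speed_range
        if min(self(lo), self(hi)) <= 0:
            raise ValueError("fitted intensity not positive over the speed range")


@dataclass
class NeuronSignals:
    """Per-neuron response signals arranged for classification.

    ``data[speed]`` is an array of shape (n_orientations, n_trials) for scalar
    intensities or (n_orientations, n_trials, n_samples) for profiles /
    smoothed trains; trials are ordered by (rotation, presentation) so the
    same index refers to the same drum passage across orientations.
    """

    neuron_id: str
    neuron_type: str
    orientations: tuple[float, ...]
    speeds: tuple[float, ...]
    data: dict[float, np.ndarray]
    scheme: str = ""

    def restricted(self, speeds: Sequence[float]) -> "NeuronSignals":
        speeds = tuple(v for v in self.speeds if v in set(speeds))
        return NeuronSignals(
            self.neuron_id,
            self.neuron_type,
            self.orientations,
            speeds,
            {v: self.data[v] for v in speeds},
            self.scheme,
        )


# ---------------------------------------------------------------------------
# signal builders
# ---------------------------------------------------------------------------


def group_trials(
    trials: Sequence[TrialResponse],
) -> tuple[tuple[float, ...], tuple[float, ...], dict[float, list[list[TrialResponse]]]]:
    """Arrange one neuron's trials as [speed][orientation][trial index]."""
    speeds = tuple(sorted({t.speed_mm_s for t in trials}))
    orientations = tuple(sorted({t.orientation_deg for t in trials}))
    out: dict[float, list[list[TrialResponse]]] = {}
    for v in speeds:
        per_orient = []
        for th in orientations:
            sel = [t for t in trials if t.speed_mm_s == v and t.orientation_deg == th]
            sel.sort(key=lambda t: (t.rotation, t.presentation))
            per_orient.append(sel)
        n = {len(s) for s in per_orient}
        if len(n) != 1:
            raise ValueError(f"unbalanced trial counts at {v} mm/s: {sorted(n)}")
        out[v] = per_orient
    return orientations, speeds, out


def intensity_signals(trials: Sequence[TrialResponse], kind: str) -> NeuronSignals:
    """(n_orientations, n_trials) peak or mean firing rates per speed."""
    if kind not in ("peak", "mean"):
        raise ValueError(f"unknown intensity kind {kind!r}")
    fn = peak_rate if kind == "peak" else mean_rate
    orientations, speeds, grouped = group_trials(trials)
    data = {
        v: np.array([[fn(t).value_hz for t in row] for row in grouped[v]])
        for v in speeds
    }
    t0 = trials[0]
    return NeuronSignals(
        t0.neuron_id, t0.neuron_type, orientations, speeds, data, f"intensity-{kind}"
    )


def profile_signals(
    trials: Sequence[TrialResponse],
    domain: str = "spatial",
    grid_step: float | None = None,
) -> NeuronSignals:
    """(n_orientations, n_trials, n_samples) rate profiles per speed.

    Spatial profiles share the 8 mm window grid at every speed; temporal
    profiles use a common absolute time grid per speed (the longest measured
    window duration at that speed).
    """
    orientations, speeds, grouped = group_trials(trials)
    data = {}
    for v in speeds:
        rows = grouped[v]
        if domain == "temporal":
            length = max(t.duration_s for row in rows for t in row)
        else:
            length = rows[0][0].window_um
        data[v] = np.array(
            [
                [
                    rate_profile(t, domain, grid_step, grid_length=length).values_hz
                    for t in row
                ]
                for row in rows
            ]
        )
    t0 = trials[0]
    return NeuronSignals(
        t0.neuron_id, t0.neuron_type, orientations, speeds, data, f"profile-{domain}"
    )


# ---------------------------------------------------------------------------
# correlation and score machinery
# ---------------------------------------------------------------------------


def pearson_rows(a: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    """Pearson correlation between all row pairs; zero-variance rows yield 0."""
    a = np.asarray(a, dtype=float)
    b = a if b is None else np.asarray(b, dtype=float)
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    na = np.linalg.norm(ac, axis=1)
    nb = np.linalg.norm(bc, axis=1)
    denom = np.outer(na, nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (ac @ bc.T) / denom
    c[denom == 0] = 0.0
    return np.clip(c, -1.0, 1.0)


def _within_scores_profile(p: np.ndarray) -> np.ndarray:
    """Hold-out mean correlations M[o, i, o2] for profiles p of shape (O, T, S)."""
    n_o, n_t, _ = p.shape
    c = pearson_rows(p.reshape(n_o * n_t, -1)).reshape(n_o, n_t, n_o, n_t)
    sums = c.sum(axis=3)
    same_idx = c[:, np.arange(n_t), :, np.arange(n_t)]  # (T, O, O2)
    return (sums - same_idx.transpose(1, 0, 2)) / (n_t - 1)


def _within_scores_intensity(v: np.ndarray) -> np.ndarray:
    """Hold-out distances M[o, i, o2] for intensities v of shape (O, T)."""
    n_o, n_t = v.shape
    refs = (v.sum(axis=1, keepdims=True) - v) / (n_t - 1)  # (O, T): drop index i
    return np.abs(v[:, :, None] - refs.T[None, :, :])


def _across_scores_profile(p_core: np.ndarray, p_other: np.ndarray) -> np.ndarray:
    """Mean correlation of core trials with each orientation's trials at another speed.

    Signals are start-aligned and zero-padded to the longer common length
    (profiles are zero outside the response anyway), which is a no-op for
    spatial-domain signals sharing one grid.  Padding, rather than truncating
    to the shorter window, avoids reducing slow-speed trials to degenerate
    spikeless segments when compared against fast-speed references.
    """
    m = max(p_core.shape[2], p_other.shape[2])

    def pad(p: np.ndarray) -> np.ndarray:
        if p.shape[2] == m:
            return p
        out = np.zeros(p.shape[:2] + (m,))
        out[:, :, : p.shape[2]] = p
        return out

    a, b = pad(p_core), pad(p_other)
    n_o, n_t = a.shape[:2]
    n_t2 = b.shape[1]
    c = pearson_rows(a.reshape(n_o * n_t, m), b.reshape(n_o * n_t2, m)).reshape(
        n_o, n_t, n_o, n_t2
    )
    return c.mean(axis=3)


def _across_scores_intensity(v_core: np.ndarray, refs: np.ndarray) -> np.ndarray:
    return np.abs(v_core[:, :, None] - refs[None, None, :])


def _strict_correct(scores: np.ndarray, maximize: bool) -> np.ndarray:
    """Per-trial correctness under the strict argmax/argmin rule.

    ``scores[o, i, o2]`` is the match of trial i of orientation o against the
    reference for orientation o2; ties count as incorrect.
    """
    n_o = scores.shape[0]
    own = scores[np.arange(n_o), :, np.arange(n_o)]  # (O, T)
    if maximize:
        others = np.where(np.eye(n_o, dtype=bool)[:, None, :], -np.inf, scores).max(axis=2)
        return own > others
    others = np.where(np.eye(n_o, dtype=bool)[:, None, :], np.inf, scores).min(axis=2)
    return own < others


def _result(sig, scheme, scope, core_speed, chance, correct, delta_theta=None):
    correct = np.asarray(correct, dtype=float).ravel()
    return ClassificationResult(
        neuron_id=sig.neuron_id,
        neuron_type=sig.neuron_type,
        scheme=scheme or sig.scheme,
        scope=scope,
        core_speed=core_speed,
        chance=chance,
        accuracy=float(correct.mean()),
        n_decisions=int(correct.size),
        delta_theta=delta_theta,
    )


# ---------------------------------------------------------------------------
# within-speed classification
# ---------------------------------------------------------------------------


def intensity_classify_within(sig: NeuronSignals, speed: float) -> ClassificationResult:
    """Four-way orientation classification from peak/mean rate at one speed."""
    if speed not in sig.data:
        raise KeyError(f"speed {speed} mm/s not present for neuron {sig.neuron_id}")
    correct = _strict_correct(_within_scores_intensity(sig.data[speed]), maximize=False)
    return _result(sig, None, "within", speed, 1.0 / len(sig.orientations), correct)


def profile_classify_within(sig: NeuronSignals, speed: float) -> ClassificationResult:
    """Four-way orientation classification from rate-profile correlations."""
    if speed not in sig.data:
        raise KeyError(f"speed {speed} mm/s not present for neuron {sig.neuron_id}")
    correct = _strict_correct(_within_scores_profile(sig.data[speed]), maximize=True)
    return _result(sig, None, "within", speed, 1.0 / len(sig.orientations), correct)


# ---------------------------------------------------------------------------
# across-speed classification
# ---------------------------------------------------------------------------


def intensity_classify_across(
    sig: NeuronSignals,
    core_speed: float,
    fits: dict[str, SpeedIntensityFit] | None = None,
) -> ClassificationResult:
    """Classify each core-speed trial against orientation means at every other speed.

    With ``fits`` given, every intensity is first divided by the fitted
    population speed→intensity function for the neuron's type — the control
    asking whether intensities signal orientation once the overall speed
    scaling is discounted.
    """
    if len(sig.speeds) < 2:
        raise ValueError("across-speed classification needs at least 2 speeds")
    if core_speed not in sig.data:
        raise KeyError(f"speed {core_speed} mm/s not present")
    fit = None
    if fits is not None:
        fit = fits[sig.neuron_type]
        fit.validate()
    x = sig.data[core_speed] / (fit(core_speed) if fit else 1.0)
    blocks = []
    for v2 in sig.speeds:
        if v2 == core_speed:
            continue
        refs = sig.data[v2].mean(axis=1) / (fit(v2) if fit else 1.0)
        blocks.append(_strict_correct(_across_scores_intensity(x, refs), maximize=False))
    scheme = sig.scheme + ("-normalized" if fit else "")
    return _result(
        sig, scheme, "across", core_speed, 1.0 / len(sig.orientations), np.concatenate(blocks)
    )


def profile_classify_across(sig: NeuronSignals, core_speed: float) -> ClassificationResult:
    """Across-speed classification from profile (or smoothed-train) correlations."""
    if len(sig.speeds) < 2:
        raise ValueError("across-speed classification needs at least 2 speeds")
    if core_speed not in sig.data:
        raise KeyError(f"speed {core_speed} mm/s not present")
    blocks = [
        _strict_correct(_across_scores_profile(sig.data[core_speed], sig.data[v2]), maximize=True)
        for v2 in sig.speeds
        if v2 != core_speed
    ]
    return _result(
        sig, None, "across", core_speed, 1.0 / len(sig.orientations), np.concatenate(blocks)
    )


def fit_population_speed_function(
    features: pd.DataFrame, kind: str
) -> dict[str, SpeedIntensityFit]:
    """OLS of per-speed population mean intensity on speed, per neuron type.

    ``features`` is a tidy table with columns ``type``, ``speed`` and
    ``{kind}_hz`` (as produced by :func:`edgecode.features.feature_table`).
    """
    col = f"{kind}_hz"
    if col not in features.columns:
        raise KeyError(f"missing column {col!r}")
    fits = {}
    for ntype, g in features.groupby("type"):
        means = g.groupby("speed")[col].mean()
        if len(means) < 2:
            raise ValueError("need at least 2 speeds to fit the speed function")
        slope, intercept = np.polyfit(means.index.to_numpy(float), means.to_numpy(), 1)
        fits[ntype] = SpeedIntensityFit(
            str(ntype),
            kind,
            float(slope),
            float(intercept),
            (float(means.index.min()), float(means.index.max())),
        )
    return fits


# ---------------------------------------------------------------------------
# pairwise orientation differences and confusion matrix
# ---------------------------------------------------------------------------


def delta_theta_pairs(orientations: Sequence[float]) -> dict[float, list[tuple[float, float]]]:
    """Unordered orientation pairs grouped by angular difference."""
    pairs: dict[float, list[tuple[float, float]]] = {}
    os = sorted(orientations)
    for i, a in enumerate(os):
        for b in os[i + 1 :]:
            pairs.setdefault(round(abs(b - a), 9), []).append((a, b))
    return pairs


def pairwise_accuracy(
    sig: NeuronSignals,
    delta_theta: float,
    core_speed: float | None = None,
    scope: str = "across",
) -> ClassificationResult:
    """Two-way classification pooled over the orientation pairs at one Δθ.

    Chance is 0.5.  The across scope classifies each core-speed trial against
    the two orientations' references at every other speed; within restricts
    the hold-out rule to the pair at one speed.
    """
    pairs = delta_theta_pairs(sig.orientations).get(round(float(delta_theta), 9))
    if not pairs:
        raise ValueError(f"no orientation pairs with Δθ = {delta_theta}°")
    is_profile = sig.data[sig.speeds[0]].ndim == 3
    core_speeds = [core_speed] if core_speed is not None else list(sig.speeds)
    correct = []
    for a, b in pairs:
        idx = [sig.orientations.index(a), sig.orientations.index(b)]
        for v in core_speeds:
            x = sig.data[v][idx]
            if scope == "within":
                scores = (
                    _within_scores_profile(x) if is_profile else _within_scores_intensity(x)
                )
                correct.append(_strict_correct(scores, maximize=is_profile))
                continue
            if len(sig.speeds) < 2:
                raise ValueError("across scope needs at least 2 speeds")
            for v2 in sig.speeds:
                if v2 == v:
                    continue
                if is_profile:
                    scores = _across_scores_profile(x, sig.data[v2][idx])
                else:
                    scores = _across_scores_intensity(x, sig.data[v2][idx].mean(axis=1))
                correct.append(_strict_correct(scores, maximize=is_profile))
    return _result(
        sig,
        None,
        scope if scope == "within" else "pair",
        core_speed,
        0.5,
        np.concatenate([c.ravel() for c in correct]),
        delta_theta=float(delta_theta),
    )


def _assignment_probs(scores: np.ndarray, maximize: bool) -> np.ndarray:
    """P[o, i, o2]: probability of assigning orientation o2 (ties split evenly)."""
    if not maximize:
        scores = -scores
    best = scores.max(axis=2, keepdims=True)
    mask = (scores == best).astype(float)
    return mask / mask.sum(axis=2, keepdims=True)


def confusion_matrix(
    signal_sets: Sequence[NeuronSignals],
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """(speed × orientation) confusion matrix averaged across neurons.

    Entry at row (v, θ), column (v′, θ′) is the probability that a trial of
    orientation θ at speed v, classified against the orientation references at
    speed v′ (hold-out rule when v′ = v), is assigned θ′.  Each 4-column block
    of each row sums to 1; strict-rule ties split their mass evenly.
    """
    ref = signal_sets[0]
    orientations, speeds = ref.orientations, ref.speeds
    n_o, n_v = len(orientations), len(speeds)
    labels = [(v, th) for v in speeds for th in orientations]
    total = np.zeros((n_o * n_v, n_o * n_v))
    for sig in signal_sets:
        if sig.orientations != orientations or sig.speeds != speeds:
            raise ValueError("all neurons must share the factorial design")
        is_profile = sig.data[speeds[0]].ndim == 3
        for i, v in enumerate(speeds):
            for j, v2 in enumerate(speeds):
                if v2 == v:
                    scores = (
                        _within_scores_profile(sig.data[v])
                        if is_profile
                        else _within_scores_intensity(sig.data[v])
                    )
                else:
                    if is_profile:
                        scores = _across_scores_profile(sig.data[v], sig.data[v2])
                    else:
                        scores = _across_scores_intensity(
                            sig.data[v], sig.data[v2].mean(axis=1)
                        )
                probs = _assignment_probs(scores, maximize=is_profile).mean(axis=1)
                total[i * n_o : (i + 1) * n_o, j * n_o : (j + 1) * n_o] += probs
    return total / len(signal_sets), labels


# ---------------------------------------------------------------------------
# utilities
# ---------------------------------------------------------------------------


def shuffle_labels(
    signal_sets: Sequence[NeuronSignals], rng: np.random.Generator
) -> list[NeuronSignals]:
    """Permute orientation labels within each speed (null-calibration control).

    One permutation of the trial slots per (neuron, speed) is shared across
    all signal sets of that neuron, so intensity and profile views of the same
    neuron stay consistent.
    """
    by_neuron: dict[str, list[NeuronSignals]] = {}
    for s in signal_sets:
        by_neuron.setdefault(s.neuron_id, []).append(s)
    out: dict[int, NeuronSignals] = {}
    for sigs in by_neuron.values():
        base = sigs[0]
        perms = {v: rng.permutation(base.data[v].shape[0] * base.data[v].shape[1])
                 for v in base.speeds}
        for s in sigs:
            data = {}
            for v in s.speeds:
                arr = s.data[v]
                flat = arr.reshape(arr.shape[0] * arr.shape[1], *arr.shape[2:])
                data[v] = flat[perms[v]].reshape(arr.shape)
            out[id(s)] = NeuronSignals(
                s.neuron_id, s.neuron_type, s.orientations, s.speeds, data, s.scheme
            )
    return [out[id(s)] for s in signal_sets]


def classify_within_detailed(sig: NeuronSignals, speed: float) -> tuple[float, list[dict]]:
    """Plain-loop within-speed classifier exposing every reference set.

    Returns the accuracy and one record per decision listing, for each
    candidate orientation, the trial indices that entered its reference —
    an audit trail proving the hold-out discipline.  Used as an independent
    cross-check of the vectorized classifiers.
    """
    arr = sig.data[speed]
    is_profile = arr.ndim == 3
    n_o, n_t = arr.shape[:2]
    decisions = []
    for o in range(n_o):
        for i in range(n_t):
            x = arr[o, i]
            refs: dict[float, list[int]] = {}
            scores = []
            for o2 in range(n_o):
                used = [j for j in range(n_t) if j != i]
                refs[sig.orientations[o2]] = used
                if is_profile:
                    cs = [float(pearson_rows(x[None], arr[o2, j][None])[0, 0]) for j in used]
                    scores.append(float(np.mean(cs)))
                else:
                    scores.append(abs(float(x) - float(np.mean([arr[o2, j] for j in used]))))
            own = scores[o]
            others = [s for k, s in enumerate(scores) if k != o]
            correct = own > max(others) if is_profile else own < min(others)
            decisions.append(
                {
                    "orientation": sig.orientations[o],
                    "trial": i,
                    "correct": bool(correct),
                    "references": refs,
                }
            )
    acc = float(np.mean([d["correct"] for d in decisions]))
    return acc, decisions


def results_to_frame(results: Iterable[ClassificationResult]) -> pd.DataFrame:
    rows = [
        {
            "neuron_id": r.neuron_id,
            "type": r.neuron_type,
            "scheme": r.scheme,
            "scope": r.scope,
            "core_speed": r.core_speed,
            "delta_theta": r.delta_theta,
            "chance": r.chance,
            "accuracy": r.accuracy,
            "n_decisions": r.n_decisions,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
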