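"""Aggregation, above-chance statistics, and the end-to-end pipeline.

Per-neuron classification accuracies are summarised as type × speed (× scheme
× Δθ) means with SEM across neurons, optionally chance-subtracted and
arcsine-square-root transformed for downstream ANOVA tooling.  The only
inferential statistic computed here is the one-tailed one-sample t-test
(Bonferroni-corrected over the 8 speeds) asking at which speeds the finest
orientation difference (Δθ = 5°) is discriminated above chance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import classify as cls
from . import features as feat
from . import kernel_precision as kp
from .data_model import NeuronRecord, save_dataset, segment_trials
from .synthetic import SimConfig, generate_dataset, save_truth

__all__ = [
    "PipelineError",
    "PipelineConfig",
    "aggregate",
    "above_chance_test",
    "run_pipeline",
]

log = logging.getLogger("edgecode")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def aggregate(
    results: pd.DataFrame | Sequence[cls.ClassificationResult],
    by: Sequence[str] = ("type", "scheme", "scope", "core_speed"),
) -> pd.DataFrame:
    """Group per-neuron accuracies: mean, SEM across neurons, n, chance.

    Adds chance-subtracted and arcsine-square-root-transformed columns.
    Groups with a single neuron report SEM 0 and are flagged (``n_is_1``).
    """
    df = results if isinstance(results, pd.DataFrame) else cls.results_to_frame(results)
    by = [c for c in by if c in df.columns and df[c].notna().any()]
    rows = []
    for key, g in df.groupby(by, dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        accs = g["accuracy"].to_numpy()
        n = accs.size
        row = dict(zip(by, key))
        row.update(
            mean_accuracy=float(accs.mean()),
            sem=float(accs.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
            n_neurons=int(g["neuron_id"].nunique()),
            n_is_1=bool(n == 1),
            chance=float(g["chance"].iloc[0]),
            mean_minus_chance=float(accs.mean() - g["chance"].iloc[0]),
            arcsine_mean=float(np.mean(np.arcsin(np.sqrt(np.clip(accs, 0, 1))))),
        )
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values(by).reset_index(drop=True) if len(out) else out


def above_chance_test(
    results: pd.DataFrame,
    chance: float = 0.5,
    n_comparisons: int = 8,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-tailed one-sample t-test against chance, per type × core speed.

    ``results`` holds one accuracy per neuron × core speed (e.g. the Δθ = 5°
    pairwise accuracies).  p-values are Bonferroni-corrected for the number of
    speeds.  Zero-variance groups are decided by the sign of the mean
    difference and flagged degenerate.
    """
    rows = []
    for (ntype, speed), g in results.groupby(["type", "core_speed"]):
        accs = g["accuracy"].to_numpy()
        if accs.size < 2:
            raise ValueError("need at least 2 neurons per group")
        if np.allclose(accs, accs[0]):
            mean = float(accs.mean())
            rows.append(
                {
                    "type": ntype,
                    "core_speed": speed,
                    "n": accs.size,
                    "mean_accuracy": mean,
                    "t": np.nan,
                    "p_corrected": np.nan,
                    "significant": bool(mean > chance),
                    "degenerate": True,
                }
            )
            continue
        t, p = stats.ttest_1samp(accs, chance, alternative="greater")
        p_corr = min(1.0, float(p) * n_comparisons)
        rows.append(
            {
                "type": ntype,
                "core_speed": speed,
                "n": accs.size,
                "mean_accuracy": float(accs.mean()),
                "t": float(t),
                "p_corrected": p_corr,
                "significant": bool(p_corr < alpha),
                "degenerate": False,
            }
        )
    return pd.DataFrame(rows).sort_values(["type", "core_speed"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """End-to-end run: simulate (or load) a dataset and analyse it."""

    sim: SimConfig = field(default_factory=SimConfig)
    data_dir: str | None = None  # load a canonical dataset instead of simulating
    sigmas_um: tuple[float, ...] = kp.DEFAULT_SIGMAS_UM
    common_speeds: tuple[float, ...] = (15.0, 20.0, 30.0, 45.0)
    spatial_step_um: float = feat.DEFAULT_SPATIAL_STEP_UM
    temporal_step_s: float = feat.DEFAULT_TEMPORAL_STEP_S
    stages: tuple[str, ...] = (
        "features",
        "within",
        "across",
        "kernels",
        "convolved",
        "pairwise",
        "confusion",
    )
    save_inputs: bool = False  # also write the canonical dataset + truth.json

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every configured stage; deterministic given the dataset and seed.

    Writes tidy CSVs under ``out_dir`` and returns the manifest (also written
    as ``manifest.json``).  A stage failure raises :class:`PipelineError`
    naming the stage; outputs of completed stages are preserved.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "seed": cfg.sim.seed}

    def stage(name):
        if name not in cfg.stages and name not in ("dataset", "segment"):
            log.info("stage %s not configured; skipped", name)
            return False
        log.info("running stage %s", name)
        manifest["stages"].append(name)
        return True

    try:
        if cfg.data_dir is not None:
            from .data_model import load_dataset

            records = load_dataset(cfg.data_dir)
            manifest["dataset"] = {"source": str(cfg.data_dir), "n_neurons": len(records)}
        else:
            records, truth = generate_dataset(cfg.sim)
            manifest["dataset"] = {
                "source": "synthetic",
                "n_neurons": len(records),
                "seed": cfg.sim.seed,
            }
            if cfg.save_inputs:
                save_dataset(records, out / "dataset")
                save_truth(out / "dataset", truth, cfg.sim)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("dataset", e) from e

    try:
        trials = {rec.neuron_id: segment_trials(rec) for rec in records}
        types = {rec.neuron_id: rec.neuron_type for rec in records}
    except Exception as e:  # noqa: BLE001
        raise PipelineError("segment", e) from e

    speeds = records[0].speeds

    features_df = None
    if stage("features"):
        try:
            features_df = pd.concat(
                [feat.feature_table(trials[n], types[n]) for n in trials], ignore_index=True
            )
            (out / "features").mkdir(exist_ok=True)
            features_df.to_csv(out / "features" / "features.csv", index=False)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("features", e) from e

    results: list[cls.ClassificationResult] = []
    sig_cache: dict[str, dict[str, cls.NeuronSignals]] = {}
    for n in trials:
        sig_cache[n] = {
            "peak": cls.intensity_signals(trials[n], "peak"),
            "mean": cls.intensity_signals(trials[n], "mean"),
            "profile-temporal": cls.profile_signals(trials[n], "temporal", cfg.temporal_step_s),
            "profile-spatial": cls.profile_signals(trials[n], "spatial", cfg.spatial_step_um),
        }

    if stage("within"):
        try:
            for n, sigs in sig_cache.items():
                for v in speeds:
                    results.append(cls.intensity_classify_within(sigs["peak"], v))
                    results.append(cls.intensity_classify_within(sigs["mean"], v))
                    results.append(cls.profile_classify_within(sigs["profile-temporal"], v))
        except Exception as e:  # noqa: BLE001
            raise PipelineError("within", e) from e

    if stage("across"):
        try:
            if features_df is None:
                features_df = pd.concat(
                    [feat.feature_table(trials[n], types[n]) for n in trials], ignore_index=True
                )
            fits = {k: cls.fit_population_speed_function(features_df, k) for k in ("peak", "mean")}
            valid_fit: dict[tuple[str, str], bool] = {}
            for kind, by_type in fits.items():
                for ntype, fit in by_type.items():
                    try:
                        fit.validate()
                        valid_fit[(kind, ntype)] = True
                    except ValueError:
                        valid_fit[(kind, ntype)] = False
                        log.info(
                            "speed-normalized %s-rate classification skipped for %s: "
                            "fitted intensity not positive over the speed range",
                            kind,
                            ntype,
                        )
            for n, sigs in sig_cache.items():
                for v in speeds:
                    for kind in ("peak", "mean"):
                        results.append(cls.intensity_classify_across(sigs[kind], v))
                        if valid_fit[(kind, types[n])]:
                            results.append(
                                cls.intensity_classify_across(sigs[kind], v, fits[kind])
                            )
                    results.append(cls.profile_classify_across(sigs["profile-temporal"], v))
                    results.append(cls.profile_classify_across(sigs["profile-spatial"], v))
        except Exception as e:  # noqa: BLE001
            raise PipelineError("across", e) from e

    best_by_type: dict[str, float] = {}
    if stage("kernels"):
        try:
            curve_frames, best_rows = [], []
            for n in trials:
                curves = kp.correlation_curves(trials[n], cfg.sigmas_um)
                curve_frames.append(kp.kernel_curves_frame(curves))
                bk = kp.best_kernel(curves)
                best_rows.append(
                    {
                        "neuron_id": n,
                        "type": types[n],
                        **{f"best_um_at_{v:g}": b for v, b in zip(bk.speeds, bk.per_speed_um)},
                        "mean_best_um": bk.mean_um,
                        "flagged": bk.flagged,
                    }
                )
            (out / "kernels").mkdir(exist_ok=True)
            pd.concat(curve_frames, ignore_index=True).to_csv(
                out / "kernels" / "curves.csv", index=False
            )
            best_df = pd.DataFrame(best_rows)
            best_df.to_csv(out / "kernels" / "best_kernels.csv", index=False)
            grp = best_df[~best_df["flagged"]].groupby("type")["mean_best_um"].mean()
            best_by_type = {t: float(s) for t, s in grp.items()}
            manifest["mean_best_kernel_um"] = best_by_type
            manifest["equivalent_period_mm"] = {
                t: kp.gaussian_to_period(s) / 1000.0 for t, s in best_by_type.items()
            }
        except Exception as e:  # noqa: BLE001
            raise PipelineError("kernels", e) from e

    smoothed: dict[str, cls.NeuronSignals] = {}
    if stage("convolved"):
        try:
            for n in trials:
                sigma = best_by_type.get(types[n]) or float(np.mean(cfg.sigmas_um[2:4]))
                smoothed[n] = kp.smoothed_signals(trials[n], sigma, grid_step=cfg.spatial_step_um)
                for v in speeds:
                    results.append(cls.profile_classify_across(smoothed[n], v))
                common = smoothed[n].restricted(cfg.common_speeds)
                for v in common.speeds:
                    r = cls.profile_classify_across(common, v)
                    r.scheme = "convolved-common"
                    results.append(r)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("convolved", e) from e

    if stage("pairwise"):
        try:
            if not smoothed:
                raise ValueError("pairwise stage requires the convolved stage")
            pair_results = []
            for n, sig in smoothed.items():
                for dth in sorted(cls.delta_theta_pairs(sig.orientations)):
                    for v in speeds:
                        pair_results.append(cls.pairwise_accuracy(sig, dth, core_speed=v))
            results.extend(pair_results)
            pair_df = cls.results_to_frame(pair_results)
            finest = min(p.delta_theta for p in pair_results)
            (out / "summary").mkdir(exist_ok=True)
            sub = pair_df[pair_df["delta_theta"] == finest]
            if sub.groupby("type")["neuron_id"].nunique().min() >= 2:
                tests = above_chance_test(sub, chance=0.5, n_comparisons=len(speeds))
                tests.to_csv(out / "summary" / "above_chance_dtheta_min.csv", index=False)
            else:
                log.info("above-chance test skipped: fewer than 2 neurons in a type")
        except Exception as e:  # noqa: BLE001
            raise PipelineError("pairwise", e) from e

    conf = None
    if stage("confusion"):
        try:
            conf = cls.confusion_matrix(list(smoothed.values()) or
                                        [sig_cache[n]["profile-spatial"] for n in trials])
            mat, labels = conf
            cols = [f"v{v:g}_th{th:g}" for v, th in labels]
            pd.DataFrame(mat, index=cols, columns=cols).to_csv(out / "confusion.csv")
        except Exception as e:  # noqa: BLE001
            raise PipelineError("confusion", e) from e

    try:
        (out / "results").mkdir(exist_ok=True)
        res_df = cls.results_to_frame(results)
        res_df.to_csv(out / "results" / "classification.csv", index=False)
        (out / "summary").mkdir(exist_ok=True)
        summary = aggregate(res_df)
        summary.to_csv(out / "summary" / "accuracy_summary.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    except Exception as e:  # noqa: BLE001
        raise PipelineError("summaries", e) from e

    if stage("figures"):
        try:
            from . import figures

            fig_dir = out / "figures"
            fig_dir.mkdir(exist_ok=True)
            for scheme in summary["scheme"].unique():
                figures.plot_accuracy_vs_speed(
                    summary, scheme, fig_dir / f"accuracy_{scheme}.png"
                )
            curves_csv = out / "kernels" / "curves.csv"
            if curves_csv.exists():
                figures.plot_kernel_curves(pd.read_csv(curves_csv), fig_dir / "kernels.png")
            if conf is not None:
                figures.plot_confusion(conf[0], conf[1], fig_dir / "confusion.png")
        except Exception as e:  # noqa: BLE001
            raise PipelineError("figures", e) from e
    return manifest
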