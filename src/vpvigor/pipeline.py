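"""End-to-end session analysis.

Orchestrates segmentation -> kinematic features -> spike responses ->
regressor selection -> per-neuron GLMs -> population statistics (and,
for sessions with an infusion marker, the pre/post epoch regression),
producing a results bundle of plain tables.

Stage order and trial filtering mirror the analysis contract: excitation
detection and the GLMs see only DS trials in which the animal was still at
cue onset; the GLM additionally requires a correct response and complete
features, and sessions whose DS response ratio is below 0.80 are excluded
from encoding analysis.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import glm as glm_mod
from . import kinematics as km
from . import locomotion as loco
from . import spike_response as sr
from .epochs import EpochSlopeRegression, build_epoch_pairs
from .io import SessionBundle
from .selection import FactorRegressorSelector

WINDOWS_MS: dict[str, tuple[int, int]] = {
    "overall": (40, 400),
    "early": (40, 180),
    "late": (180, 400),
}

FOCUSED_REGRESSORS = ["radial_velocity_max", "path_efficiency", "lever_distance"]


@dataclass
class AnalysisConfig:
    seed: int = 0
    front_led: str = "red"
    half_window: int = 4
    windows_ms: dict = field(default_factory=lambda: dict(WINDOWS_MS))
    regressors: Optional[list[str]] = None  # None -> factor-based selection
    state_regressors: list[str] = field(
        default_factory=lambda: ["lever_distance", "time_since_cue", "time_since_reward"]
    )
    strong: float = 0.6
    independent: float = 0.4
    smc_tolerance: float = 0.8
    excitation_criterion: str = "normal"
    min_response_ratio: float = glm_mod.MIN_RESPONSE_RATIO
    min_trials_per_neuron: int = 10

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ResultsBundle:
    trials: pd.DataFrame
    features: pd.DataFrame
    excitation: pd.DataFrame
    selection: Optional[object]
    glm_effects: pd.DataFrame
    population: pd.DataFrame
    epoch_pairs: Optional[pd.DataFrame]
    epoch_regression: Optional[pd.DataFrame]
    summary: dict
    metadata: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.trials.to_csv(out / "trials.csv", index=False)
        self.features.to_csv(out / "features.csv", index=False)
        self.excitation.to_csv(out / "excitation.csv", index=False)
        self.glm_effects.to_csv(out / "glm_effects.csv", index=False)
        self.population.to_csv(out / "population.csv", index=False)
        if self.epoch_pairs is not None:
            self.epoch_pairs.to_csv(out / "epoch_pairs.csv", index=False)
        if self.epoch_regression is not None:
            self.epoch_regression.to_csv(out / "epoch_regression.csv", index=False)
        (out / "summary.json").write_text(
            json.dumps({"summary": self.summary, "metadata": self.metadata}, indent=2, default=str)
        )


def summarize_behavior(trials: pd.DataFrame) -> dict:
    """Per-cue-type response ratios and vigor summaries.

    Response ratio = responded / presented.  Latency and mean approach speed
    summaries cover responded trials with measured movement (speed column is
    joined in by the caller when features are available).
    """
    out: dict = {}
    for cue in ("DS", "NS"):
        sub = trials[trials["cue_type"] == cue]
        if not len(sub):
            out[cue] = None
            continue
        responded = sub["responded"].astype(bool)
        lat = sub.loc[responded, "movement_onset_latency"].astype(float).dropna()
        entry: dict = {
            "n_presented": int(len(sub)),
            "n_responded": int(responded.sum()),
            "response_ratio": float(responded.mean()),
            "latency_mean_s": float(lat.mean()) if len(lat) else np.nan,
            "latency_sd_s": float(lat.std(ddof=1)) if len(lat) > 1 else np.nan,
        }
        if "speed_mean" in sub.columns:
            sp = sub.loc[responded, "speed_mean"].astype(float).dropna()
            entry["speed_mean_mm_s"] = float(sp.mean()) if len(sp) else np.nan
            entry["speed_sd_mm_s"] = float(sp.std(ddof=1)) if len(sp) > 1 else np.nan
        out[cue] = entry
    return out


def compute_trial_features(
    bundle: SessionBundle, trials: pd.DataFrame, pose: km.PoseSeries
) -> pd.DataFrame:
    """Movement + state feature row per analyzable trial."""
    lever = bundle.manifest.lever_xy_mm
    rows = []
    for _, t in trials.iterrows():
        row = {"trial_id": t["trial_id"], "cue_type": t["cue_type"]}
        state = km.state_features(pose, bundle.events, float(t["cue_onset_time"]), lever)
        row.update(state)
        if (
            t["excluded_reason"] is None
            and np.isfinite(t.get("movement_start_time", np.nan))
            and np.isfinite(t.get("movement_end_time", np.nan))
            and t["movement_end_time"] > t["movement_start_time"]
        ):
            feats = km.movement_features(
                pose,
                float(t["movement_start_time"]),
                float(t["movement_end_time"]),
                lever,
                onset_latency=float(t["movement_onset_latency"]),
            )
            row.update(feats)
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_session(
    bundle: SessionBundle, config: AnalysisConfig | None = None
) -> ResultsBundle:
    """Run the full analysis on one session bundle."""
    cfg = config or AnalysisConfig()

    # 1. segmentation
    pose = km.head_pose(bundle.tracking, front_led=cfg.front_led)
    li = loco.locomotor_index(pose, half_window=cfg.half_window)
    thresholds = loco.fit_li_mixture(li.li[li.valid], seed=cfg.seed)
    bouts = loco.detect_bouts(li, thresholds)
    records = loco.classify_trials(bouts, bundle.events, li, thresholds)
    trials = loco.trials_to_frame(records)
    trials.insert(0, "trial_id", np.arange(len(trials)))

    # 2. kinematic + state features
    features = compute_trial_features(bundle, trials, pose)
    drop_cols = [c for c in ("cue_type", "movement_onset_latency") if c in features.columns]
    trials_full = trials.merge(features.drop(columns=drop_cols), on="trial_id")
    trials_full["movement_onset_latency"] = trials["movement_onset_latency"]

    # 3. spike responses on still-at-cue DS trials
    ds = trials_full[(trials_full["cue_type"] == "DS") & trials_full["still_at_cue"]]
    ds_onsets = ds["cue_onset_time"].to_numpy(dtype=float)
    exc_rows = []
    counts_by_neuron = {}
    for neuron in bundle.neurons:
        counts = sr.align_counts(
            neuron, ds_onsets, window_ms=(-1000, 400), trial_ids=ds["trial_id"].to_numpy()
        )
        counts_by_neuron[neuron.neuron_id] = counts
        if counts.n_trials >= sr.MIN_TRIALS:
            prof = sr.detect_excitation(counts, criterion=cfg.excitation_criterion)
            exc_rows.append(
                {
                    "neuron_id": prof.neuron_id,
                    "excited": prof.excited,
                    "onset_ms": prof.onset_bin_ms,
                    "baseline_mean_hz": prof.baseline_mean_hz,
                    "baseline_sd_hz": prof.baseline_sd_hz,
                    "z_early": prof.z_early,
                    "z_late": prof.z_late,
                    "rate_overall_hz": prof.rate_overall_hz,
                }
            )
    excitation = pd.DataFrame(
        exc_rows,
        columns=[
            "neuron_id", "excited", "onset_ms", "baseline_mean_hz",
            "baseline_sd_hz", "z_early", "z_late", "rate_overall_hz",
        ],
    )

    # 4. regressor selection on correct, still DS trials (complete cases)
    summary = summarize_behavior(trials_full)
    selection = None
    ds_ratio = summary["DS"]["response_ratio"] if summary["DS"] else 0.0
    glm_eligible = ds_ratio >= cfg.min_response_ratio
    if cfg.regressors is not None:
        regressors = list(cfg.regressors)
    else:
        pool = ds[ds["responded"].astype(bool)]
        movement_table = pool[km.MOVEMENT_VARIABLES].dropna(axis=1, how="all")
        complete = movement_table.dropna()
        regressors = []
        if glm_eligible and complete.shape[0] > complete.shape[1] + 2:
            selector = FactorRegressorSelector(
                smc_tolerance=cfg.smc_tolerance,
                strong=cfg.strong,
                independent=cfg.independent,
            )
            try:
                selector.fit(complete)
                selection = selector.report_
                regressors = list(selector.selected_)
            except ValueError:
                regressors = []
        regressors = regressors + [
            r for r in cfg.state_regressors if r not in regressors
        ]

    # 5. per-neuron GLMs on excited neurons, per window
    excited_ids = set(excitation.loc[excitation["excited"], "neuron_id"])
    effect_frames = []
    subj = {n.neuron_id: n.subject_id for n in bundle.neurons}
    if glm_eligible and regressors:
        for neuron_id in sorted(excited_ids):
            counts = counts_by_neuron[neuron_id]
            for wname, wms in cfg.windows_ms.items():
                design = glm_mod.build_design(trials_full, counts, wms, regressors)
                if not design.fittable:
                    continue
                try:
                    fit = glm_mod.fit_poisson_glm(design)
                except Exception:
                    continue
                if not fit.converged_:
                    continue
                frame = fit.effects_frame(neuron_id, wname)
                frame["subject_id"] = subj.get(neuron_id, "")
                effect_frames.append(frame)
    glm_effects = (
        pd.concat(effect_frames, ignore_index=True)
        if effect_frames
        else pd.DataFrame(
            columns=[
                "neuron_id", "window", "regressor", "beta", "se", "p",
                "idr", "ifd_percent", "converged", "subject_id",
            ]
        )
    )

    # 6. population tests per window
    pop_frames = []
    for wname in cfg.windows_ms:
        sub = glm_effects[glm_effects["window"] == wname]
        if not len(sub):
            continue
        ifd = sub.pivot(index="neuron_id", columns="regressor", values="ifd_percent")
        ifd = ifd.reindex(columns=[r for r in regressors if r in ifd.columns])
        if ifd.shape[0] >= 3:
            pop_frames.append(glm_mod.population_ifd_tests(ifd, window=wname))
    population = (
        pd.concat(pop_frames, ignore_index=True)
        if pop_frames
        else pd.DataFrame(
            columns=[
                "regressor", "mean_ifd", "se", "df", "t", "p_raw",
                "window", "p_holm", "significant", "n_neurons",
            ]
        )
    )

    # 7. optional infusion epoch comparison
    epoch_pairs = None
    epoch_regression = None
    inf_t = bundle.manifest.infusion_time_s
    if inf_t is not None:
        excited_neurons = [n for n in bundle.neurons if n.neuron_id in excited_ids]
        epoch_pairs = build_epoch_pairs(
            excited_neurons,
            bundle.events,
            inf_t,
            {"early": (40, 180), "late": (180, 400)},
            min_trials=cfg.min_trials_per_neuron,
        )
        rows = []
        for wname in ("early", "late"):
            sub = epoch_pairs[epoch_pairs["window"] == wname]
            if len(sub) >= 5:
                reg = EpochSlopeRegression().fit(sub["z_q1"], sub["z_q2"])
                rows.append(
                    reg.summary_row(
                        condition=bundle.manifest.infusion_condition or "infusion",
                        window=wname,
                    )
                )
        epoch_regression = pd.DataFrame(rows)

    summary["n_neurons"] = len(bundle.neurons)
    summary["n_excited"] = len(excited_ids)
    summary["ds_ratio_glm_eligible"] = bool(glm_eligible)
    metadata = {
        "config_hash": cfg.content_hash(),
        "seed": cfg.seed,
        "regressors": regressors,
        "onset_threshold": float(thresholds.onset_threshold_),
        "offset_threshold": float(thresholds.offset_threshold_),
        "n_bouts": len(bouts),
    }
    return ResultsBundle(
        trials=trials_full,
        features=features,
        excitation=excitation,
        selection=selection,
        glm_effects=glm_effects,
        population=population,
        epoch_pairs=epoch_pairs,
        epoch_regression=epoch_regression,
        summary=summary,
        metadata=metadata,
    )
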