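"""End-to-end validation pipeline.

Orchestrates simulate/read -> gap fill -> zero-lag filtering -> planar
kinematics -> force-based cycle segmentation -> parameter extraction ->
agreement statistics, and emits the five report tables of a
method-comparison study:

1. ICC(1,3) trial reproducibility per parameter, side and source;
2. waveform MAE (95% CI) per joint and side, right vs left;
3. parameter means (SD), markerless vs reference;
4. Pearson correlations per parameter and side;
5. CMC waveform similarity per joint and side, right vs left.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import io as gio
from .events import build_cycles, detect_events
from .kinematics import joint_angles
from .parameters import (
    PARAMETER_JOINT,
    PARAMETER_NAMES,
    aggregate,
    extract_parameters,
    parameter_table,
)
from .preprocess import fill_gaps, lowpass
from .stats import cmc, icc_1_3, interpret, mae, mae_ci, paired_t, pearson
from .synthetic import GaitProfile, GroundTruthTrial, make_trial
from .types import JOINTS, SIDES

log = logging.getLogger(__name__)


class CohortSpec(BaseModel):
    """Simulated study design: participants, trials, variability.

    Between-participant standard deviations default to values typical of
    healthy adult cohorts; trial-to-trial jitter models natural stride
    variability within a session.
    """

    n_participants: int = Field(21, ge=2)
    n_trials: int = Field(3, ge=1)
    n_cycles: int = Field(4, ge=1)
    base: GaitProfile = Field(default_factory=GaitProfile)
    amplitude_sd: dict = Field(
        default_factory=lambda: {
            "hip_peak_flex": 6.0,
            "hip_peak_ext": 5.0,
            "knee_stance_peak_flex": 8.6,
            "knee_swing_peak_flex": 7.6,
            "ankle_peak_dorsi": 4.2,
            "ankle_peak_plantar": 6.1,
        }
    )
    cycle_duration_sd: float = 0.07
    stance_fraction_sd: float = 0.015
    body_weight_sd: float = 100.0
    trial_jitter_sd: float = Field(1.0, description="within-participant amplitude jitter, degrees")
    noise_sd: float = Field(0.0, ge=0, description="keypoint noise, pixels")
    dropout_prob_crossing: float = Field(0.0, ge=0, le=1)
    seed: int = 0


class RunConfig(BaseModel):
    """Configuration of one validation run (fully serializable)."""

    simulate: CohortSpec | None = None
    trial_paths: list[dict] | None = None  # rows: participant, trial, pose_dir, reference_csv, grf_right_csv, grf_left_csv
    cutoff_hz: float = 6.0
    filter_order: int = 4
    filter_convention: str = "effective"
    max_gap_frames: int = 10
    event_threshold_n: float = 20.0
    mae_granularity: str = Field("waveform", pattern="^(waveform|parameters)$")
    video_rate_hz: float = 120.0
    image_height_px: float = 720.0
    keypoint_map_json: str | None = None
    output_dir: str | None = None
    seed: int = 0


@dataclass
class TrialResult:
    """Per-trial agreement measures and parameter values."""

    participant: int
    trial: int
    mae_by_joint: dict  # (side, joint) -> mean over cycles
    cmc_by_joint: dict  # (side, joint) -> mean over defined cycles (NaN if none)
    cmc_undefined: int
    params_ai: dict  # side -> {parameter: mean over cycles}
    params_ref: dict
    n_cycles: dict  # side -> cycles used
    exclusions: list


@dataclass
class AgreementReport:
    """The five aggregated report tables plus bookkeeping."""

    table1_icc: pd.DataFrame
    table2_mae: pd.DataFrame
    table3_parameters: pd.DataFrame
    table4_pearson: pd.DataFrame
    table5_cmc: pd.DataFrame
    parameter_rows: pd.DataFrame
    exclusions: list
    cmc_undefined_count: int
    manifest: dict = field(default_factory=dict)

    def write(self, directory) -> Path:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        tables = {
            "table1_icc": self.table1_icc,
            "table2_mae": self.table2_mae,
            "table3_parameters": self.table3_parameters,
            "table4_pearson": self.table4_pearson,
            "table5_cmc": self.table5_cmc,
            "parameters_tidy": self.parameter_rows,
        }
        for name, df in tables.items():
            df.to_csv(d / f"{name}.csv", index=False, float_format="%.10g")
        with open(d / "report.txt", "w") as fh:
            for name, df in tables.items():
                if name == "parameters_tidy":
                    continue
                fh.write(f"== {name} ==\n")
                fh.write(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
                fh.write("\n\n")
            fh.write(f"undefined CMC cycles excluded from means: {self.cmc_undefined_count}\n")
            fh.write(f"exclusions ({len(self.exclusions)}):\n")
            for e in self.exclusions:
                fh.write(f"  - {e}\n")
        with open(d / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True, default=str)
        return d


def simulate_cohort(spec: CohortSpec) -> list[tuple[int, int, GroundTruthTrial]]:
    """Draw a cohort of synthetic trials.

    Per-participant gait profiles are sampled around the base profile
    with the configured between-subject SDs; each trial adds a small
    amplitude jitter and a fresh noise seed.  Returns a list of
    (participant, trial, GroundTruthTrial).
    """
    if spec.n_participants < 2:
        raise ValueError("a cohort needs at least 2 participants")
    rng = np.random.default_rng(spec.seed)
    base = spec.base.model_dump()
    trials = []
    for p in range(spec.n_participants):
        subject = dict(base)
        for name, sd in spec.amplitude_sd.items():
            subject[name] = max(0.2 * base[name], base[name] + sd * rng.standard_normal())
        subject["cycle_duration"] = float(
            np.clip(base["cycle_duration"] + spec.cycle_duration_sd * rng.standard_normal(), 0.9, 1.4)
        )
        subject["stance_fraction"] = float(
            np.clip(base["stance_fraction"] + spec.stance_fraction_sd * rng.standard_normal(), 0.55, 0.65)
        )
        subject["body_weight_n"] = float(
            max(300.0, base["body_weight_n"] + spec.body_weight_sd * rng.standard_normal())
        )
        subject["n_cycles"] = spec.n_cycles
        subject["noise_sd"] = spec.noise_sd
        subject["dropout_prob_crossing"] = spec.dropout_prob_crossing
        for t in range(spec.n_trials):
            prof = dict(subject)
            for name in spec.amplitude_sd:
                prof[name] = max(0.1, prof[name] + spec.trial_jitter_sd * rng.standard_normal())
            prof["seed"] = int(rng.integers(2**31))
            trials.append((p, t, make_trial(GaitProfile(**prof))))
    return trials


def _matched_cycles(events, ai_angles, ref_angles, side, force_rate, video_rate):
    ai_cycles = build_cycles(events, {j: ai_angles[(side, j)] for j in JOINTS}, force_rate, video_rate)
    ref_cycles = build_cycles(events, {j: ref_angles[(side, j)] for j in JOINTS}, force_rate, video_rate)
    ref_by_ic = {c.ic_frame: c for c in ref_cycles}
    return [(c, ref_by_ic[c.ic_frame]) for c in ai_cycles if c.ic_frame in ref_by_ic]


def analyze_trial(
    pose,
    reference,
    grf_right,
    grf_left,
    config: RunConfig,
    participant: int = 0,
    trial: int = 0,
) -> TrialResult:
    """Run the full per-trial pipeline and return agreement measures.

    Both streams are filtered with the same zero-lag Butterworth, the
    force-derived cycle bounds are applied to both, and per-cycle MAE /
    CMC / parameters are averaged within the trial.
    """
    exclusions: list[str] = []
    pose = fill_gaps(pose, config.max_gap_frames)
    pose = lowpass(pose, config.cutoff_hz, config.filter_order, config.filter_convention)
    reference = lowpass(reference, config.cutoff_hz, config.filter_order, config.filter_convention)
    ai_angles = joint_angles(pose, source="ai")
    ref_angles = joint_angles(reference, source="reference")

    video_rate = pose.rate
    mae_by_joint: dict = {}
    cmc_by_joint: dict = {}
    cmc_undefined = 0
    params_ai: dict = {}
    params_ref: dict = {}
    n_cycles: dict = {}

    for side, grf in (("right", grf_right), ("left", grf_left)):
        if side in pose.unusable_sides:
            exclusions.append(f"p{participant} t{trial} {side}: side unusable (gap too long)")
            continue
        events = detect_events(grf, config.event_threshold_n)
        pairs = _matched_cycles(events, ai_angles, ref_angles, side, grf.rate, video_rate)
        if not pairs:
            exclusions.append(f"p{participant} t{trial} {side}: no usable cycles")
            continue
        n_cycles[side] = len(pairs)
        p_ai: list[dict] = []
        p_ref: list[dict] = []
        for joint in JOINTS:
            maes, cmcs = [], []
            for c_ai, c_ref in pairs:
                a = c_ai.normalized_angles[joint]
                r = c_ref.normalized_angles[joint]
                maes.append(mae(a, r))
                v = cmc(np.vstack([a, r]))
                if np.isnan(v):
                    cmc_undefined += 1
                else:
                    cmcs.append(v)
            mae_by_joint[(side, joint)] = float(np.mean(maes))
            cmc_by_joint[(side, joint)] = float(np.mean(cmcs)) if cmcs else float("nan")
        for c_ai, c_ref in pairs:
            p_ai.append(extract_parameters(c_ai))
            p_ref.append(extract_parameters(c_ref))
        params_ai[side] = {k: float(np.mean([d[k] for d in p_ai])) for k in PARAMETER_NAMES}
        params_ref[side] = {k: float(np.mean([d[k] for d in p_ref])) for k in PARAMETER_NAMES}
        if config.mae_granularity == "parameters":
            for joint in JOINTS:
                names = [n for n in PARAMETER_NAMES if PARAMETER_JOINT[n] == joint]
                mae_by_joint[(side, joint)] = float(
                    np.mean([abs(params_ai[side][n] - params_ref[side][n]) for n in names])
                )
    return TrialResult(
        participant=participant,
        trial=trial,
        mae_by_joint=mae_by_joint,
        cmc_by_joint=cmc_by_joint,
        cmc_undefined=cmc_undefined,
        params_ai=params_ai,
        params_ref=params_ref,
        n_cycles=n_cycles,
        exclusions=exclusions,
    )


def _participant_metric(results: list[TrialResult], attr: str, side: str, joint: str) -> dict:
    """participant -> mean over trials of a per-trial (side, joint) metric."""
    per: dict[int, list[float]] = {}
    for r in results:
        v = getattr(r, attr).get((side, joint))
        if v is not None and np.isfinite(v):
            per.setdefault(r.participant, []).append(v)
    return {p: float(np.mean(v)) for p, v in per.items()}


def _aggregate_report(results: list[TrialResult], config: RunConfig) -> AgreementReport:
    exclusions = [e for r in results for e in r.exclusions]
    cmc_undefined = sum(r.cmc_undefined for r in results)

    # Tidy parameter rows (participant, trial, side, source, parameter, value).
    raw_rows = []
    for r in results:
        for source, params in (("ai", r.params_ai), ("reference", r.params_ref)):
            for side, values in params.items():
                raw_rows.append(
                    {"participant": r.participant, "trial": r.trial, "side": side,
                     "source": source, **values}
                )
    if not raw_rows:
        raise ValueError("no usable trials: cannot aggregate a report")
    tidy = parameter_table(raw_rows)

    # Table 1: ICC(1,3) per parameter x side x source.
    t1 = []
    for side in SIDES:
        for source in ("ai", "reference"):
            sub = tidy[(tidy["side"] == side) & (tidy["source"] == source)]
            for name in PARAMETER_NAMES:
                wide = (
                    sub[sub["parameter"] == name]
                    .pivot(index="participant", columns="trial", values="value")
                    .dropna()
                )
                if len(wide) >= 3 and wide.shape[1] >= 2:
                    icc, lo, hi = icc_1_3(wide.to_numpy())
                else:
                    icc = lo = hi = float("nan")
                t1.append(
                    {"side": side, "source": source, "parameter": name, "icc_1_3": icc,
                     "ci_low": lo, "ci_high": hi, "n_participants": len(wide),
                     "interpretation": interpret("ICC", icc)}
                )
    table1 = pd.DataFrame(t1)

    # Table 2: waveform MAE mean (95% CI) per joint x side + right-vs-left t.
    t2 = []
    for joint in JOINTS:
        per_side = {s: _participant_metric(results, "mae_by_joint", s, joint) for s in SIDES}
        common = sorted(set(per_side["right"]) & set(per_side["left"]))
        if len(common) >= 3:
            _, p_rl = paired_t([per_side["right"][p] for p in common], [per_side["left"][p] for p in common])
        else:
            p_rl = float("nan")
        for side in SIDES:
            vals = [per_side[side][p] for p in sorted(per_side[side])]
            if len(vals) >= 2:
                m, lo, hi = mae_ci(vals)
            elif vals:
                m, lo, hi = vals[0], float("nan"), float("nan")
            else:
                m = lo = hi = float("nan")
            t2.append(
                {"joint": joint, "side": side, "mae_deg": m, "ci_low": lo, "ci_high": hi,
                 "n_participants": len(vals), "p_right_vs_left": p_rl,
                 "interpretation": interpret("AE", m)}
            )
    table2 = pd.DataFrame(t2)

    # Table 3: parameter means (SD) AI vs reference + paired t.
    means = aggregate(tidy)
    t3 = []
    for side in SIDES:
        for name in PARAMETER_NAMES:
            cell = {}
            for source in ("ai", "reference"):
                sub = means[(means["side"] == side) & (means["source"] == source) & (means["parameter"] == name)]
                sub = sub.sort_values("participant")
                cell[source] = sub.set_index("participant")["value"]
            common = cell["ai"].index.intersection(cell["reference"].index)
            if len(common) >= 3:
                _, p_val = paired_t(cell["ai"].loc[common].to_numpy(), cell["reference"].loc[common].to_numpy())
            else:
                p_val = float("nan")
            t3.append(
                {"side": side, "parameter": name,
                 "ai_mean": float(cell["ai"].mean()) if len(cell["ai"]) else float("nan"),
                 "ai_sd": float(cell["ai"].std(ddof=1)) if len(cell["ai"]) > 1 else float("nan"),
                 "reference_mean": float(cell["reference"].mean()) if len(cell["reference"]) else float("nan"),
                 "reference_sd": float(cell["reference"].std(ddof=1)) if len(cell["reference"]) > 1 else float("nan"),
                 "p_ai_vs_reference": p_val, "n_participants": int(len(common))}
            )
    table3 = pd.DataFrame(t3)

    # Table 4: Pearson r between AI and reference participant means.
    t4 = []
    for side in SIDES:
        for name in PARAMETER_NAMES:
            ai = means[(means["side"] == side) & (means["source"] == "ai") & (means["parameter"] == name)]
            ref = means[(means["side"] == side) & (means["source"] == "reference") & (means["parameter"] == name)]
            merged = ai.merge(ref, on="participant", suffixes=("_ai", "_ref"))
            if len(merged) >= 3:
                r, p = pearson(merged["value_ai"].to_numpy(), merged["value_ref"].to_numpy())
            else:
                r = p = float("nan")
            t4.append({"side": side, "parameter": name, "pearson_r": r, "p_value": p,
                       "n_participants": len(merged)})
    table4 = pd.DataFrame(t4)

    # Table 5: CMC mean (SD) per joint x side + right-vs-left t.
    t5 = []
    for joint in JOINTS:
        per_side = {s: _participant_metric(results, "cmc_by_joint", s, joint) for s in SIDES}
        common = sorted(set(per_side["right"]) & set(per_side["left"]))
        if len(common) >= 3:
            _, p_rl = paired_t([per_side["right"][p] for p in common], [per_side["left"][p] for p in common])
        else:
            p_rl = float("nan")
        for side in SIDES:
            vals = np.array([per_side[side][p] for p in sorted(per_side[side])])
            m = float(np.mean(vals)) if len(vals) else float("nan")
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")
            t5.append({"joint": joint, "side": side, "cmc_mean": m, "cmc_sd": sd,
                       "n_participants": len(vals), "p_right_vs_left": p_rl,
                       "interpretation": interpret("CMC", m)})
    table5 = pd.DataFrame(t5)

    return AgreementReport(
        table1_icc=table1,
        table2_mae=table2,
        table3_parameters=table3,
        table4_pearson=table4,
        table5_cmc=table5,
        parameter_rows=tidy,
        exclusions=exclusions,
        cmc_undefined_count=cmc_undefined,
        manifest={"config": config.model_dump(), "n_trials_analyzed": len(results)},
    )


def run_validation(config: RunConfig) -> AgreementReport:
    """Run the full validation study described by ``config``.

    Either simulates a cohort (``config.simulate``) or reads trials from
    disk (``config.trial_paths``).  Per-trial failures are logged and
    skipped, never abort the run; a missing input stream is an error
    before any computation starts.
    """
    if (config.simulate is None) == (config.trial_paths is None):
        raise ValueError("exactly one of 'simulate' or 'trial_paths' must be provided")
    results: list[TrialResult] = []
    if config.simulate is not None:
        for p, t, trial in simulate_cohort(config.simulate):
            try:
                results.append(
                    analyze_trial(trial.pose, trial.reference, trial.grf_right, trial.grf_left,
                                  config, participant=p, trial=t)
                )
            except Exception as exc:  # pragma: no cover - defensive
                log.warning("participant %d trial %d failed: %s", p, t, exc)
    else:
        kp_map = gio.load_keypoint_map(config.keypoint_map_json) if config.keypoint_map_json else None
        for row in config.trial_paths:
            for key in ("pose_dir", "reference_csv", "grf_right_csv", "grf_left_csv"):
                if key not in row or not Path(row[key]).exists():
                    raise FileNotFoundError(f"trial input {key} missing: {row.get(key)}")
        for row in config.trial_paths:
            p, t = int(row.get("participant", 0)), int(row.get("trial", 0))
            try:
                pose = gio.read_openpose_dir(row["pose_dir"], video_rate=config.video_rate_hz,
                                             image_height_px=config.image_height_px,
                                             keypoint_map=kp_map)
                reference = gio.read_reference_csv(row["reference_csv"])
                grf_r = gio.read_grf_csv(row["grf_right_csv"], "right")
                grf_l = gio.read_grf_csv(row["grf_left_csv"], "left")
                results.append(analyze_trial(pose, reference, grf_r, grf_l, config,
                                             participant=p, trial=t))
            except Exception as exc:
                log.warning("participant %d trial %d failed: %s", p, t, exc)
    report = _aggregate_report(results, config)
    if config.output_dir:
        report.write(config.output_dir)
    return report
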