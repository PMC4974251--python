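"""End-to-end orchestration: simulate -> preprocess -> measure -> stats.

Experiment profiles bind the option sets of the two studies this package
models: ``exp1`` (young adults: 23 subjects, 2000 ms mean inter-trial
interval, P300 window 200-500 ms) and ``exp2`` (older adults: 37 subjects
split 21/16 over a between-subject stimulation-hemisphere factor, 3000 ms
mean ITI, P300 window 250-650 ms).  Every run is reproducible from its
master seed; a manifest records the configuration hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .anova import AnovaResult, rm_anova, simple_effects
from .bayes import BayesFactorResult, model_comparison
from .components import (
    ComponentSpec, derive_lrp, lowpass_lrp, lrp_onset_latency, mean_amplitude,
    peak_measure,
)
from .io import ContinuousRecording, write_tables
from .montage import Montage, compact_montage, default_montage
from .preprocess import (
    average_condition, baseline, behavioral_measures, extract_epochs,
    filter_recording, parse_trials, reject_artifacts, rereference_mastoids,
)
from .simulate import (
    CohortSpec, SubjectParams, StimEffect, exp1_params, exp2_params,
    exp2_groups, default_between_subject_sd, generate_cohort,
)
from .task import TaskConfig

log = logging.getLogger(__name__)

# epoch geometry (ms): cue-locked epochs span 300 ms before fixation to
# 800 ms after the target; the remaining epochs are component-specific
CUE_EPOCH = (-800.0, 2300.0)
TARGET_EPOCH = (-300.0, 800.0)
TLRP_EPOCH = (-200.0, 700.0)
RLRP_EPOCH = (-800.0, 200.0)

TLRP_WINDOW = (100.0, 600.0)
RLRP_WINDOW = (-300.0, -100.0)
RLRP_BASELINE = (-700.0, -500.0)


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    profile: str = "exp1"
    task: TaskConfig = field(default_factory=TaskConfig)
    params: SubjectParams = field(default_factory=exp1_params)
    cohort: CohortSpec = field(default_factory=lambda: CohortSpec(
        n_subjects=23, seed=0,
        between_subject_sd=default_between_subject_sd()))
    fs: float = 256.0
    montage: Montage = field(default_factory=default_montage)
    # preprocessing
    band: tuple[float, float] | None = (0.02, 30.0)
    notch: float | None = 50.0
    artifact_threshold: float = 100.0
    max_rejected_fraction: float = 0.4
    # component measurement
    p300_window: tuple[float, float] = (200.0, 500.0)
    fal_fraction: float = 0.25
    area_reference: str = "window_mean"
    # statistics
    between: str | None = None        # e.g. "group" for exp2
    bf_draws: int = 10_000
    r_fixed: float = 0.5
    r_random: float = 1.0
    # LRP measures collapse hand by construction; listing "hand" among the
    # LRP factors is a configuration error caught by validate_config
    lrp_factors: tuple[str, ...] = ("stimulation", "cue")
    erp_factors: tuple[str, ...] = ("stimulation", "cue", "hand")

    @property
    def cnv_window(self) -> tuple[float, float]:
        return (self.task.cue_dur - 200.0, self.task.cue_dur)

    @property
    def cnv_baseline(self) -> tuple[float, float]:
        # 200 ms preceding fixation onset, on the cue-locked time base
        return (-self.task.fixation_dur - 200.0, -self.task.fixation_dur)

    def component_specs(self) -> list[ComponentSpec]:
        return [
            ComponentSpec("CNV", "Cz", self.cnv_window, self.cnv_baseline,
                          "negative", "mean_amplitude"),
            ComponentSpec("P300", "Pz", self.p300_window, (-200.0, 0.0),
                          "positive", "peak"),
            ComponentSpec("tLRP", None, TLRP_WINDOW, (-200.0, 0.0),
                          "negative", "fractional_area_latency",
                          self.fal_fraction),
            ComponentSpec("rLRP", None, RLRP_WINDOW, RLRP_BASELINE,
                          "negative", "fractional_area_latency",
                          self.fal_fraction),
        ]


def exp1_config(seed: int = 0, **overrides) -> RunConfig:
    cfg = RunConfig(
        profile="exp1",
        task=TaskConfig(),
        params=exp1_params(),
        cohort=CohortSpec(n_subjects=23, seed=seed,
                          between_subject_sd=default_between_subject_sd()),
        p300_window=(200.0, 500.0),
    )
    return replace(cfg, **overrides)


def exp2_config(seed: int = 0, **overrides) -> RunConfig:
    cfg = RunConfig(
        profile="exp2",
        task=TaskConfig(iti_mean=3000.0, iti_min=2500.0, iti_max=3500.0),
        params=exp2_params(),
        cohort=CohortSpec(n_subjects=37, seed=seed,
                          group_assignment=exp2_groups(),
                          between_subject_sd=default_between_subject_sd()),
        p300_window=(250.0, 650.0),
        between="group",
    )
    return replace(cfg, **overrides)


def desk_scale_exp1_config(seed: int, stim_effect: StimEffect | None = None,
                           bf_draws: int = 2000) -> RunConfig:
    """Desk-scale variant of the first experiment's profile.

    Keeps the cohort size (23 subjects, two sessions) and all printed
    component parameters, but runs 5 blocks of 40 trials (half the study's
    80) at 128 Hz on the compact montage so that a full
    simulate-measure-analyse replicate completes in well under a minute.
    """
    params = exp1_params() if stim_effect is None \
        else exp1_params(stim_effect=stim_effect)
    cfg = exp1_config(seed=seed)
    return replace(
        cfg,
        task=TaskConfig(trials_per_block=40),
        params=params,
        cohort=CohortSpec(n_subjects=23, seed=seed,
                          between_subject_sd=default_between_subject_sd()),
        montage=compact_montage(),
        fs=128.0,
        bf_draws=bf_draws,
    )


def validate_config(config: RunConfig) -> list[str]:
    """Aggregated, human-readable configuration checks (empty = ok)."""
    errors: list[str] = []
    try:
        config.montage.require("Cz", "Pz", "C3", "C4", "M1", "M2")
    except ValueError as e:
        errors.append(str(e))
    if len(config.montage.mastoids) != 2:
        errors.append("montage must tag exactly two mastoid channels")
    cw = config.cnv_window
    if not (CUE_EPOCH[0] <= cw[0] + config.task.fixation_dur
            and cw[1] + config.task.fixation_dur <= CUE_EPOCH[1]):
        errors.append(
            f"CNV window {cw} (post-cue) falls outside the cue-locked epoch "
            f"{CUE_EPOCH}")
    if not (TARGET_EPOCH[0] <= config.p300_window[0]
            and config.p300_window[1] <= TARGET_EPOCH[1]):
        errors.append(
            f"P300 window {config.p300_window} outside target-locked epoch "
            f"{TARGET_EPOCH}")
    if "hand" in config.lrp_factors:
        errors.append(
            "LRP measures are collapsed over hand by the double subtraction; "
            "'hand' cannot be an LRP analysis factor")
    if config.profile == "exp1":
        if config.p300_window != (200.0, 500.0):
            errors.append("profile exp1 binds the P300 window to 200-500 ms")
        if config.task.iti_mean != 2000.0:
            errors.append("profile exp1 binds the mean ITI to 2000 ms")
    if config.profile == "exp2":
        if config.p300_window != (250.0, 650.0):
            errors.append("profile exp2 binds the P300 window to 250-650 ms")
        if config.task.iti_mean != 3000.0:
            errors.append("profile exp2 binds the mean ITI to 3000 ms")
        if config.between is None:
            errors.append("profile exp2 requires the between-subject "
                          "hemisphere factor")
    if config.band is not None:
        nyq = config.fs / 2
        if not (0 < config.band[0] < config.band[1] < nyq):
            errors.append(f"band {config.band} invalid for fs {config.fs}")
    return errors


# ---------------------------------------------------------------------------
# per-session measurement


def preprocess_recording(rec: ContinuousRecording,
                         config: RunConfig) -> ContinuousRecording:
    """Reference and filter one continuous recording."""
    rec = rereference_mastoids(rec)
    if config.band is not None:
        rec = filter_recording(rec, band=config.band, notch=config.notch)
    return rec


def measure_session(
    rec: ContinuousRecording,
    config: RunConfig,
    subject: str,
    stimulation: str,
    group: str = "none",
    preprocessed: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """All component and behavioural measures of one session.

    Returns (long measure rows, info dict with rejection counts).
    """
    if not preprocessed:
        rec = preprocess_recording(rec, config)

    info: dict = {}
    rows: list[pd.DataFrame] = []

    # ---- cue-locked epochs: CNV
    cue_ep = extract_epochs(rec, "cue", *CUE_EPOCH)
    cue_ep, flagged = reject_artifacts(cue_ep, config.artifact_threshold,
                                       config.max_rejected_fraction)
    info["n_trials"] = cue_ep.n_trials
    info["n_rejected"] = int(cue_ep.reject_mask.sum())
    info["exclusion_flagged"] = flagged
    cue_ep = baseline(cue_ep, config.cnv_baseline)
    cnv_by_cell = average_condition(cue_ep, by=["cue", "target_dir"])
    cnv_waves = {}
    for (cue, hand), erp in cnv_by_cell.items():
        cnv_waves[(cue, hand)] = erp

    def add_row(cue, hand, measure, value):
        rows.append(pd.DataFrame([{
            "subject": subject, "group": group, "stimulation": stimulation,
            "cue": cue, "hand": hand, "measure": measure,
            "value": float(value)}]))

    for (cue, hand), erp in cnv_waves.items():
        # CNV windows are specified post-cue; the epoch is cue-locked
        add_row(cue, hand, "cnv_amp",
                mean_amplitude(erp, "Cz", config.cnv_window))

    # ---- target-locked epochs: P300
    tgt_ep = extract_epochs(rec, "target", *TARGET_EPOCH)
    tgt_ep, _ = reject_artifacts(tgt_ep, config.artifact_threshold,
                                 config.max_rejected_fraction)
    tgt_ep = baseline(tgt_ep, (-200.0, 0.0))
    for (cue, hand), erp in average_condition(
            tgt_ep, by=["cue", "target_dir"]).items():
        amp, lat = peak_measure(erp, "Pz", config.p300_window, "positive")
        add_row(cue, hand, "p300_amp", amp)
        add_row(cue, hand, "p300_lat", lat)

    # ---- LRPs: target- and response-locked double subtractions per cue
    tl_ep = extract_epochs(rec, "target", *TLRP_EPOCH)
    tl_ep, _ = reject_artifacts(tl_ep, config.artifact_threshold,
                                config.max_rejected_fraction)
    tl_ep = baseline(tl_ep, (-200.0, 0.0))
    rl_ep = extract_epochs(rec, "response", *RLRP_EPOCH)
    rl_ep, _ = reject_artifacts(rl_ep, config.artifact_threshold,
                                config.max_rejected_fraction)
    rl_ep = baseline(rl_ep, RLRP_BASELINE)

    lrp_waves = {}
    for name, ep, window in (("tlrp", tl_ep, TLRP_WINDOW),
                             ("rlrp", rl_ep, RLRP_WINDOW)):
        averages = average_condition(ep, by=["cue", "hand"])
        for cue in sorted({c for c, _h in averages}):
            by_hand = {h: averages[(cue, h)] for h in ("L", "R")
                       if (cue, h) in averages}
            if len(by_hand) < 2:
                log.warning("%s %s/%s: missing a hand cell, skipping LRP",
                            subject, stimulation, cue)
                continue
            lrp = lowpass_lrp(derive_lrp(by_hand), cutoff=30.0)
            lrp_waves[(name, cue)] = lrp
            onset = lrp_onset_latency(lrp, window,
                                      fraction=config.fal_fraction,
                                      area_reference=config.area_reference)
            add_row(cue, "collapsed", f"{name}_onset", onset)

    # ---- behaviour from the full trial list
    meta = parse_trials(rec.events)
    rows.append(behavioral_measures(meta, subject, stimulation, group))

    info["waveforms"] = {"cnv": cnv_waves, "lrp": lrp_waves}
    return pd.concat(rows, ignore_index=True), info


# ---------------------------------------------------------------------------
# cohort-level run


@dataclass
class RunResult:
    measures: pd.DataFrame
    anova: dict[str, AnovaResult]
    simple: dict[str, dict[str, AnovaResult]]
    bayes: dict[str, BayesFactorResult]
    exclusions: pd.DataFrame
    manifest: dict

    def anova_frame(self) -> pd.DataFrame:
        parts = []
        for measure, res in self.anova.items():
            t = res.table.copy()
            t.insert(0, "measure", measure)
            parts.append(t)
        return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()

    def bayes_frame(self) -> pd.DataFrame:
        parts = []
        for measure, res in self.bayes.items():
            t = res.as_frame()
            t.insert(0, "measure", measure)
            parts.append(t)
        return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()


# measures analysed with the full factor set vs the LRP (cue-only) set
ERP_MEASURES = ("rt", "cnv_amp", "p300_amp", "p300_lat")
LRP_MEASURES = ("tlrp_onset", "rlrp_onset")


def compute_measures(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the cohort and measure every session.

    Returns (long measure table, per-session exclusion log).
    """
    all_rows = []
    excl = []
    for item in generate_cohort(config.cohort, config.task, config.params,
                                montage=config.montage, fs=config.fs):
        m, info = measure_session(
            item.recording, config,
            subject=f"s{item.subject:02d}",
            stimulation=item.stimulation,
            group=item.group,
        )
        all_rows.append(m)
        excl.append({
            "subject": f"s{item.subject:02d}",
            "stimulation": item.stimulation,
            "n_trials": info["n_trials"],
            "n_rejected": info["n_rejected"],
            "exclusion_flagged": info["exclusion_flagged"],
        })
        log.info("measured subject %s session %s", item.subject,
                 item.stimulation)
    return (pd.concat(all_rows, ignore_index=True),
            pd.DataFrame(excl))


def analyse_measures(measures: pd.DataFrame, config: RunConfig,
                     stats_seed: int = 0) -> RunResult:
    """Frequentist and Bayesian factorial analyses of a measure table."""
    anova: dict[str, AnovaResult] = {}
    simple: dict[str, dict[str, AnovaResult]] = {}
    bayes: dict[str, BayesFactorResult] = {}

    for measure in list(ERP_MEASURES) + list(LRP_MEASURES):
        sub = measures[measures["measure"] == measure].copy()
        if sub.empty:
            continue
        is_lrp = measure in LRP_MEASURES
        within = [f for f in (config.lrp_factors if is_lrp
                              else config.erp_factors)
                  if f != config.between]
        if is_lrp:
            sub = sub[sub["hand"] == "collapsed"]
        if "hand" in within:
            sub = sub[sub["hand"].isin(["L", "R"])]
        anova[measure] = rm_anova(sub, within=within, between=config.between)
        if config.between:
            simple[measure] = simple_effects(sub, config.between,
                                             within=within)
        bf_factors = within + ([config.between] if config.between else [])
        bayes[measure] = model_comparison(
            sub, bf_factors, r_fixed=config.r_fixed,
            r_random=config.r_random, draws=config.bf_draws,
            seed=stats_seed)
    manifest = make_manifest(config)
    return RunResult(measures=measures, anova=anova, simple=simple,
                     bayes=bayes, exclusions=pd.DataFrame(), manifest=manifest)


def make_manifest(config: RunConfig) -> dict:
    payload = {
        "profile": config.profile,
        "seed": config.cohort.seed,
        "n_subjects": config.cohort.n_subjects,
        "fs": config.fs,
        "trials_per_block": config.task.trials_per_block,
        "version": __version__,
        "numpy": np.__version__,
    }
    blob = json.dumps(payload, sort_keys=True).encode()
    payload["config_hash"] = hashlib.sha256(blob).hexdigest()[:16]
    return payload


def run(config: RunConfig, out_dir: str | Path | None = None) -> RunResult:
    """Execute the full pipeline; optionally write the report bundle.

    If ``out_dir`` holds a measures.csv whose manifest hash matches the
    configuration, the simulation stage is resumed from it.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid configuration:\n- " + "\n- ".join(errors))
    manifest = make_manifest(config)

    measures = exclusions = None
    if out_dir is not None:
        out = Path(out_dir)
        mpath, manpath = out / "measures.csv", out / "manifest.json"
        if mpath.exists() and manpath.exists():
            old = json.loads(manpath.read_text())
            if old.get("config_hash") == manifest["config_hash"]:
                log.info("resuming from cached measures in %s", out)
                measures = pd.read_csv(mpath)
                epath = out / "exclusions.csv"
                exclusions = pd.read_csv(epath) if epath.exists() else pd.DataFrame()
    if measures is None:
        measures, exclusions = compute_measures(config)

    result = analyse_measures(measures, config,
                              stats_seed=config.cohort.seed + 1)
    result.exclusions = exclusions
    result.manifest = manifest

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_tables(measures, result.anova_frame(), result.bayes_frame(), out)
        exclusions.to_csv(out / "exclusions.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return result
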