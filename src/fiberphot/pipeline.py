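"""End-to-end orchestration: simulate -> preprocess -> quantify -> stats.

``run`` executes the full chain for one stimulus paradigm and writes a
deterministic result bundle (cohort CSV, stats JSON, per-timepoint heatmap
CSVs, and a run log embedding the seed and a hash of the configuration).
Identical configuration and seed produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import EventSchedule, RawTrace, validate_cohort, write_cohort, write_results
from .perievent import (
    F0_WINDOW,
    PerieventTrace,
    SUMMARY_MEASURES,
    align,
    average_perievents,
    dff,
    heatmap_matrix,
    qc_keep,
    summarize,
)
from .preprocess import preprocess
from .stats import pairwise_contrasts, rm_anova_two_way
from .synth import PARADIGMS, SimSession, simulate_cohort

__all__ = ["RunConfig", "RunBundle", "run", "quantify_session", "quantify_cohort"]

#: Peri-event window (s) used for alignment, per paradigm: 6 min of baseline
#: plus the summary window support.
ALIGN_PRE_S = 360.0


def _align_post(paradigm: str, window) -> float:
    default_end = SUMMARY_MEASURES[paradigm][2][1]
    return max(default_end, window[1] if window else 0.0)


@dataclass
class RunConfig:
    """Single source of truth for an end-to-end run."""

    paradigm: str = "presentation"
    seed: int = 0
    n_per_group: int = 10
    timepoints: tuple[str, ...] = ("baseline", "wk6", "wk10")
    n_trials: int = 3
    amplitude_sd: float = 0.05
    noise_sd: float = 0.2
    background: float = 0.5
    sample_rate: float = 250.0
    pre_duration: float = 600.0
    filter_cutoff_hz: float = 0.5
    filter_order: int = 2
    output_rate_hz: float = 10.0
    summary_window: tuple[float, float] | None = None
    contrast_family: str = "all"
    apply_qc: bool = True
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.paradigm not in PARADIGMS:
            raise ValueError(
                f"unknown paradigm {self.paradigm!r}; expected one of {PARADIGMS}"
            )
        self.timepoints = tuple(self.timepoints)
        if self.summary_window is not None:
            self.summary_window = tuple(self.summary_window)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            data = tomllib.loads(path.read_text())
        else:
            data = json.loads(path.read_text())
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunBundle:
    config: RunConfig
    cohort: pd.DataFrame
    anova: object
    contrasts: object
    perievents: dict
    excluded: list[str] = field(default_factory=list)
    paths: dict = field(default_factory=dict)


def quantify_session(
    traces: list[RawTrace],
    schedule: EventSchedule,
    paradigm: str,
    background: float = 0.0,
    cutoff: float = 0.5,
    order: int = 2,
    target_rate: float = 10.0,
    window: tuple[float, float] | None = None,
):
    """Preprocess, align and summarize one session (all trials averaged).

    Returns ``(SummaryStat, PerieventTrace)``; the peri-event trace is the
    trial-averaged percent dF/F.
    """
    onsets = schedule.of_type("stimulus_onset")
    if not onsets:
        raise ValueError("schedule contains no stimulus_onset event")
    post = _align_post(paradigm, window)
    pes: list[PerieventTrace] = []
    for i, trace in enumerate(traces):
        event_time = onsets[min(i, len(onsets) - 1)].time_s
        proc = preprocess(
            trace,
            background=background,
            cutoff=cutoff,
            order=order,
            target_rate=target_rate,
        )
        aligned = align(proc, event_time, pre=ALIGN_PRE_S, post=post)
        pes.append(dff(aligned))
    mean_pe = average_perievents(pes)
    stat = summarize(mean_pe, paradigm, window=window)
    return stat, mean_pe


def quantify_cohort(
    sessions: list[SimSession],
    paradigm: str,
    background: float = 0.0,
    cutoff: float = 0.5,
    order: int = 2,
    target_rate: float = 10.0,
    window: tuple[float, float] | None = None,
):
    """Quantify every session into a long-format cohort table.

    Returns ``(cohort_df, perievents)`` where ``perievents`` maps
    ``(mouse_id, timepoint)`` to the trial-averaged peri-event trace.
    """
    rows = []
    perievents: dict[tuple[str, str], PerieventTrace] = {}
    for s in sessions:
        stat, pe = quantify_session(
            s.traces,
            s.schedule,
            paradigm,
            background=background,
            cutoff=cutoff,
            order=order,
            target_rate=target_rate,
            window=window,
        )
        rows.append(
            {
                "mouse_id": s.mouse_id,
                "group": s.group,
                "timepoint": s.timepoint,
                "measure": stat.measure,
                "value": stat.value,
            }
        )
        perievents[(s.mouse_id, s.timepoint)] = pe
    return validate_cohort(pd.DataFrame(rows)), perievents


def _apply_qc(cohort: pd.DataFrame, paradigm: str):
    """Exclude mice failing the baseline sensory-response criterion.

    Only meaningful for the presentation paradigm, whose baseline measure is
    the 5-min post-presentation mean. Mice with no baseline measurement are
    flagged unevaluable (and excluded) rather than silently kept.
    """
    if paradigm != "presentation":
        return cohort, [], []
    excluded, unevaluable = [], []
    for mouse, sub in cohort.groupby("mouse_id"):
        base = sub[sub["timepoint"] == "baseline"]
        if base.empty:
            unevaluable.append(mouse)
        elif not qc_keep(float(base["value"].iloc[0])):
            excluded.append(mouse)
    keep = ~cohort["mouse_id"].isin(set(excluded) | set(unevaluable))
    return cohort[keep].reset_index(drop=True), excluded, unevaluable


def run(config: RunConfig, write: bool = True, log=print) -> RunBundle:
    """Execute the full pipeline for one paradigm."""
    log(f"[simulate] paradigm={config.paradigm} seed={config.seed}")
    sessions = simulate_cohort(
        paradigm=config.paradigm,
        n_per_group=config.n_per_group,
        timepoints=config.timepoints,
        amplitude_sd=config.amplitude_sd,
        seed=config.seed,
        noise_sd=config.noise_sd,
        background=config.background,
        sample_rate=config.sample_rate,
        pre_duration=config.pre_duration,
        n_trials=config.n_trials,
    )
    log(f"[simulate] {len(sessions)} sessions, {config.n_trials} trials each")

    cohort, perievents = quantify_cohort(
        sessions,
        config.paradigm,
        background=config.background,
        cutoff=config.filter_cutoff_hz,
        order=config.filter_order,
        target_rate=config.output_rate_hz,
        window=config.summary_window,
    )
    log(f"[quantify] {len(cohort)} cohort rows")

    excluded: list[str] = []
    if config.apply_qc:
        cohort, excluded, unevaluable = _apply_qc(cohort, config.paradigm)
        log(f"[qc] excluded={excluded} unevaluable={unevaluable}")

    anova = rm_anova_two_way(cohort)
    contrasts = pairwise_contrasts(cohort, family=config.contrast_family)
    log(f"[stats] {anova.design}")

    bundle = RunBundle(
        config=config,
        cohort=cohort,
        anova=anova,
        contrasts=contrasts,
        perievents=perievents,
        excluded=excluded,
    )
    if write:
        bundle.paths = _write_bundle(bundle, log=log)
    return bundle


def _write_bundle(bundle: RunBundle, log=print) -> dict:
    config = bundle.config
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort_path, stats_path = write_results(
        bundle.cohort,
        {"anova": bundle.anova, "contrasts": bundle.contrasts},
        out_dir,
        overwrite=True,
    )
    paths = {"cohort": str(cohort_path), "stats": str(stats_path)}
    for timepoint in config.timepoints:
        pes = [
            pe for (m, tp), pe in sorted(bundle.perievents.items()) if tp == timepoint
        ]
        if not pes:
            continue
        mice, t_rel, matrix = heatmap_matrix(pes)
        hm = pd.DataFrame(matrix, index=pd.Index(mice, name="mouse_id"),
                          columns=np.round(t_rel, 3))
        hm_path = out_dir / f"heatmap_{timepoint}.csv"
        hm.to_csv(hm_path)
        paths[f"heatmap_{timepoint}"] = str(hm_path)
    runlog = {
        "package_version": __version__,
        "python": sys.version.split()[0],
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_cohort_rows": int(len(bundle.cohort)),
        "excluded_mice": bundle.excluded,
        "f0_window_s": list(F0_WINDOW),
    }
    runlog_path = out_dir / "runlog.json"
    runlog_path.write_text(json.dumps(runlog, indent=1, sort_keys=True, default=list))
    paths["runlog"] = str(runlog_path)
    log(f"[write] {sorted(paths)} -> {out_dir}")
    return paths
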