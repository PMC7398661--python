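"""Peri-event quantification: alignment, F0, dF/F, summary windows, QC.

Time zero follows the stimulus convention of each paradigm (chamber opening
for food presentation and injections, pump start for infusions). The
normalization baseline F0 is the median fluorescence in the 2-minute window
flanking the -5 min time point, i.e. t_rel in [-360, -240] s, and

    dff(t) = 100 * (F(t) - F0) / F0        [percent]

Summary statistics are the window mean of dff (``mean ΔFa/F0``) or its
signed trapezoidal time integral in percent-minutes (AUC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import TraceMeta
from .preprocess import ProcessedTrace

__all__ = [
    "AlignedTrace",
    "PerieventTrace",
    "SummaryStat",
    "F0_WINDOW",
    "SUMMARY_MEASURES",
    "QC_THRESHOLD_PP",
    "align",
    "compute_f0",
    "dff",
    "window_mean_dff",
    "auc",
    "summarize",
    "qc_keep",
    "average_perievents",
    "heatmap_matrix",
]

#: F0 window in seconds relative to the event: the 2-min window centered on
#: ("flanking") the -5 min time point.
F0_WINDOW = (-360.0, -240.0)

#: Magnitude (percentage points) of the baseline chow sensory response below
#: which an implant is treated as a technical failure.
QC_THRESHOLD_PP = 20.0

#: Per-paradigm summary measure: name, statistic kind and default window (s).
#: presentation: mean over the 5 min after presentation; infusion: mean over
#: the final 2 min of the 12-min infusion; hormones: AUC over 20 min (CCK)
#: or 30 min (ghrelin) after injection.
SUMMARY_MEASURES = {
    "presentation": ("mean_dff_5min_post", "window_mean", (0.0, 300.0)),
    "infusion": ("mean_dff_end_infusion", "window_mean", (600.0, 720.0)),
    "cck": ("auc_20min", "auc", (0.0, 1200.0)),
    "ghrelin": ("auc_30min", "auc", (0.0, 1800.0)),
}


@dataclass
class AlignedTrace:
    """A processed trace re-expressed on a time axis relative to an event."""

    t_rel: np.ndarray
    fluorescence: np.ndarray
    sample_rate: float
    meta: TraceMeta = field(default_factory=TraceMeta)
    provenance: dict = field(default_factory=dict)


@dataclass
class PerieventTrace:
    """Event-aligned dF/F (percent) with the F0 it was normalized by."""

    t_rel: np.ndarray
    dff: np.ndarray
    f0: float
    stimulus: str = "sensory"
    meta: TraceMeta = field(default_factory=TraceMeta)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_rel = np.asarray(self.t_rel, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if self.f0 <= 0:
            raise ValueError("f0 must be > 0")
        if not np.all(np.isfinite(self.dff)):
            raise ValueError("dff contains non-finite values")


@dataclass(frozen=True)
class SummaryStat:
    """One per-mouse summary value (percent or percent-minutes)."""

    measure: str
    value: float
    window: tuple[float, float]


def align(
    trace: ProcessedTrace, event_time: float, pre: float, post: float
) -> AlignedTrace:
    """Window a trace around an event and re-zero its time axis.

    The window [event-pre, event+post] must lie within the trace support;
    sub-sample placement uses nearest-sample membership.
    """
    if pre < 0 or post < 0:
        raise ValueError("pre and post must be >= 0")
    t = np.asarray(trace.time, dtype=float)
    half_dt = 0.5 / trace.sample_rate
    lo, hi = event_time - pre, event_time + post
    if t[0] > lo + half_dt:
        raise ValueError(
            f"window starts {t[0] - lo:.3f} s before trace support "
            f"(need {pre:.0f} s pre-event)"
        )
    if t[-1] < hi - half_dt:
        raise ValueError(
            f"window ends {hi - t[-1]:.3f} s after trace support "
            f"(need {post:.0f} s post-event)"
        )
    mask = (t >= lo - half_dt) & (t <= hi + half_dt)
    prov = dict(getattr(trace, "provenance", {}))
    prov["event_time_s"] = float(event_time)
    return AlignedTrace(
        t_rel=t[mask] - event_time,
        fluorescence=np.asarray(trace.fluorescence)[mask],
        sample_rate=trace.sample_rate,
        meta=trace.meta,
        provenance=prov,
    )


def compute_f0(aligned: AlignedTrace, window: tuple[float, float] = F0_WINDOW) -> float:
    """Median fluorescence in the pre-event baseline window.

    Rejects traces whose F0 is non-positive (consistent with background
    over-subtraction) rather than producing an unusable normalization.
    """
    lo, hi = window
    if lo >= hi:
        raise ValueError("F0 window must have positive width")
    t = aligned.t_rel
    slack = 1.0 / aligned.sample_rate  # bin centers sit half a sample inward
    if t[0] > lo + slack or t[-1] < hi - slack:
        raise ValueError(
            f"aligned trace does not cover the F0 window [{lo}, {hi}] s"
        )
    mask = (t >= lo) & (t <= hi)
    f0 = float(np.median(aligned.fluorescence[mask]))
    if f0 <= 0:
        raise ValueError(
            f"F0 = {f0:.4g} <= 0; trace invalid (background over-subtraction?)"
        )
    return f0


def dff(aligned: AlignedTrace, f0: float | None = None) -> PerieventTrace:
    """Normalize an aligned trace to percent dF/F about F0."""
    if f0 is None:
        f0 = compute_f0(aligned)
    if f0 <= 0:
        raise ValueError("f0 must be > 0")
    values = 100.0 * (aligned.fluorescence - f0) / f0
    prov = dict(aligned.provenance)
    prov["f0"] = float(f0)
    return PerieventTrace(
        t_rel=aligned.t_rel,
        dff=values,
        f0=float(f0),
        stimulus=aligned.meta.stimulus,
        meta=aligned.meta,
        provenance=prov,
    )


def _window_mask(pe: PerieventTrace, t_start: float, t_end: float) -> np.ndarray:
    if t_start >= t_end:
        raise ValueError("window must have t_start < t_end")
    dt = float(np.median(np.diff(pe.t_rel))) if pe.t_rel.size > 1 else 0.0
    if pe.t_rel[0] > t_start + dt or pe.t_rel[-1] < t_end - dt:
        raise ValueError(
            f"window [{t_start}, {t_end}] s outside trace support "
            f"[{pe.t_rel[0]:.1f}, {pe.t_rel[-1]:.1f}] s"
        )
    mask = (pe.t_rel >= t_start) & (pe.t_rel <= t_end)
    if not mask.any():
        raise ValueError("window contains no samples")
    return mask


def window_mean_dff(pe: PerieventTrace, t_start: float, t_end: float) -> float:
    """Arithmetic mean dF/F (percent) over [t_start, t_end] s."""
    mask = _window_mask(pe, t_start, t_end)
    return float(pe.dff[mask].mean())


def auc(pe: PerieventTrace, t_start: float, t_end: float) -> float:
    """Signed trapezoidal integral of dF/F over the window, in percent-minutes."""
    mask = _window_mask(pe, t_start, t_end)
    if mask.sum() < 2:
        raise ValueError("AUC window must contain at least 2 samples")
    return float(np.trapezoid(pe.dff[mask], pe.t_rel[mask] / 60.0))


def summarize(
    pe: PerieventTrace, paradigm: str, window: tuple[float, float] | None = None
) -> SummaryStat:
    """Paradigm-appropriate summary statistic of a peri-event trace."""
    if paradigm not in SUMMARY_MEASURES:
        raise ValueError(
            f"unknown paradigm {paradigm!r}; expected one of {sorted(SUMMARY_MEASURES)}"
        )
    name, kind, default_window = SUMMARY_MEASURES[paradigm]
    w = window if window is not None else default_window
    value = window_mean_dff(pe, *w) if kind == "window_mean" else auc(pe, *w)
    return SummaryStat(measure=name, value=value, window=tuple(w))


def qc_keep(baseline_sensory_pp: float, threshold_pp: float = QC_THRESHOLD_PP) -> bool:
    """Implant QC on the baseline chow sensory response.

    Keep iff the response magnitude is at least ``threshold_pp`` percentage
    points (boundary inclusive); smaller responses are treated as technical
    failures of the implant.
    """
    if not np.isfinite(baseline_sensory_pp):
        raise ValueError("baseline sensory response is not finite")
    return abs(baseline_sensory_pp) >= threshold_pp


def average_perievents(pes: list[PerieventTrace]) -> PerieventTrace:
    """Pointwise mean dF/F across trials sharing one t_rel axis."""
    if not pes:
        raise ValueError("no peri-event traces to average")
    first = pes[0]
    for pe in pes[1:]:
        if len(pe.t_rel) != len(first.t_rel) or not np.allclose(
            pe.t_rel, first.t_rel, rtol=0, atol=1e-9
        ):
            raise ValueError("mismatched t_rel axes; cannot average trials")
    stacked = np.vstack([pe.dff for pe in pes])
    prov = dict(first.provenance)
    prov["n_trials_averaged"] = len(pes)
    return PerieventTrace(
        t_rel=first.t_rel,
        dff=stacked.mean(axis=0),
        f0=float(np.mean([pe.f0 for pe in pes])),
        stimulus=first.stimulus,
        meta=first.meta,
        provenance=prov,
    )


def heatmap_matrix(pes: list[PerieventTrace]):
    """Assemble a (mice x time) matrix of trial-averaged dF/F.

    Returns ``(mouse_ids, t_rel, matrix)`` with rows in stable mouse-id
    order, one row per mouse (trials averaged).
    """
    if not pes:
        raise ValueError("no peri-event traces")
    ref = pes[0].t_rel
    by_mouse: dict[str, list[PerieventTrace]] = {}
    for pe in pes:
        if len(pe.t_rel) != len(ref) or not np.allclose(
            pe.t_rel, ref, rtol=0, atol=1e-9
        ):
            raise ValueError("mismatched t_rel axes across traces")
        by_mouse.setdefault(pe.meta.mouse_id, []).append(pe)
    mouse_ids = sorted(by_mouse)
    rows = [average_perievents(by_mouse[m]).dff for m in mouse_ids]
    return mouse_ids, ref.copy(), np.vstack(rows)
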