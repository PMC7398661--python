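"""Synthetic photometry sessions and behavioral logs with known ground truth.

The generator produces the statistical structure the analysis assumes: a
positive baseline fluorescence plus a rig background, white Gaussian noise,
optional slow mono-exponential bleaching (off by default), and a parametric
stimulus-response kernel ``r(t)`` so that the noiseless signal is

    F(t) = F_b * (1 + k * r(t)) * bleach(t) + B

where ``k`` in [0, 1] is a multiplicative attenuation factor standing in for
the diet-induced-obese (DIO) state (k = 1: intact response; k < 1: blunted).

Four kernel shapes cover the study paradigms:

``sensory``
    rapid sustained inhibition after food presentation (negative amplitude,
    exponential approach, no recovery);
``infusion_ramp``
    progressive linear decline over an intragastric infusion, then sustained;
``cck_transient``
    inhibition that recovers (product of exponential approach and decay);
``ghrelin_rise``
    sustained activation (as ``sensory`` with positive amplitude).

Amplitudes are dimensionless fractional changes of the biological signal
F_b; the analysis pipeline reports them as percent dF/F.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .io import Event, EventSchedule, RawTrace, TraceMeta

__all__ = [
    "KernelSpec",
    "SimConfig",
    "GroundTruth",
    "InfusionProtocol",
    "KERNEL_KINDS",
    "PARADIGMS",
    "default_kernel",
    "default_config",
    "evaluate_kernel",
    "simulate_session",
    "simulate_cohort",
    "simulate_pellet_log",
    "infusion_protocol",
    "SimSession",
]

KERNEL_KINDS = ("sensory", "infusion_ramp", "cck_transient", "ghrelin_rise")


@dataclass(frozen=True)
class KernelSpec:
    """Parametric idealization of a stimulus-evoked fractional response.

    Parameters
    ----------
    kind : str
        One of ``KERNEL_KINDS``.
    amplitude : float
        Asymptotic fractional change A (negative = inhibition). For
        inhibitory kinds |A| must be < 1 so fluorescence stays positive.
    onset_latency : float
        Delay (s) between the event and the start of the response.
    tau_on : float
        Exponential approach time constant (s).
    tau_recover : float
        Recovery time constant (s); ``inf`` means sustained.
    ramp_duration : float or None
        Duration (s) of the linear decline; required for ``infusion_ramp``.
    """

    kind: str
    amplitude: float
    onset_latency: float = 0.0
    tau_on: float = 3.0
    tau_recover: float = math.inf
    ramp_duration: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_KINDS:
            raise ValueError(
                f"unknown kernel kind {self.kind!r}; expected one of {KERNEL_KINDS}"
            )
        if not math.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")
        if self.amplitude < 0 and abs(self.amplitude) >= 1:
            raise ValueError("|amplitude| must be < 1 for inhibitory kernels")
        if self.tau_on <= 0:
            raise ValueError("tau_on must be > 0")
        if self.tau_recover <= 0:
            raise ValueError("tau_recover must be > 0")
        if self.onset_latency < 0:
            raise ValueError("onset_latency must be >= 0")
        if self.kind == "infusion_ramp":
            if self.ramp_duration is None or self.ramp_duration <= 0:
                raise ValueError("infusion_ramp requires ramp_duration > 0")


def evaluate_kernel(spec: KernelSpec, t_rel) -> np.ndarray:
    """Evaluate the noiseless fractional response r(t) at times relative to onset.

    r(t) = 0 before ``onset_latency``. The noiseless fluorescence is
    ``F_b * (1 + r(t)) + B``.
    """
    t = np.asarray(t_rel, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    s = t - spec.onset_latency
    active = s >= 0
    sa = np.where(active, s, 0.0)
    A = spec.amplitude
    if spec.kind in ("sensory", "ghrelin_rise", "cck_transient"):
        r = A * (1.0 - np.exp(-sa / spec.tau_on))
        if math.isfinite(spec.tau_recover):
            r = r * np.exp(-sa / spec.tau_recover)
    elif spec.kind == "infusion_ramp":
        frac = np.minimum(sa / spec.ramp_duration, 1.0)
        r = A * frac
        if math.isfinite(spec.tau_recover):
            post = sa - spec.ramp_duration
            r = np.where(post > 0, A * np.exp(-post / spec.tau_recover), r)
    else:  # pragma: no cover - guarded in KernelSpec
        raise ValueError(f"unknown kernel kind {spec.kind!r}")
    r = np.where(active, r, 0.0)
    return float(r[0]) if scalar else r


@dataclass(frozen=True)
class SimConfig:
    """Conditions for one simulated session (one mouse, one paradigm, one day).

    ``pre_duration`` must be at least 360 s so the baseline F0 window
    ([-6, -4] min relative to the stimulus) is observable.
    """

    kernel: KernelSpec
    baseline_fluorescence: float = 10.0
    background: float = 0.5
    noise_sd: float = 0.2
    bleach_tau: float = math.inf
    sample_rate: float = 250.0
    pre_duration: float = 600.0
    post_duration: float = 360.0
    attenuation: float = 1.0
    n_trials: int = 3
    noise_smooth_tau: float | None = None

    def __post_init__(self) -> None:
        if self.baseline_fluorescence <= 0:
            raise ValueError("baseline_fluorescence must be > 0")
        if self.background < 0:
            raise ValueError("background must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.bleach_tau <= 0:
            raise ValueError("bleach_tau must be > 0 (or inf to disable)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if self.pre_duration < 360.0:
            raise ValueError(
                "pre_duration must be >= 360 s: the F0 window at [-6, -4] min "
                "before the stimulus would be unobservable"
            )
        if self.post_duration <= 0:
            raise ValueError("post_duration must be > 0")
        if not 0.0 <= self.attenuation <= 1.0:
            raise ValueError("attenuation must lie in [0, 1]")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    """What a simulated session was generated from, for parameter recovery."""

    kernel: KernelSpec
    effective_amplitude: float
    f0_true: float
    seed: int


def _session_times(config: SimConfig) -> np.ndarray:
    n = int(round((config.pre_duration + config.post_duration) * config.sample_rate)) + 1
    return np.arange(n) / config.sample_rate


def simulate_session(
    config: SimConfig, seed: int, meta: TraceMeta | None = None
) -> tuple[list[RawTrace], EventSchedule, GroundTruth]:
    """Simulate ``n_trials`` traces of one session.

    Each trial is a separate trace with its own time base starting at 0 and
    the stimulus at ``t = pre_duration``. Identical (config, seed) pairs give
    bit-identical output; all randomness flows through ``seed``.
    """
    rng = np.random.default_rng(seed)
    t = _session_times(config)
    t_rel = t - config.pre_duration
    r = evaluate_kernel(config.kernel, t_rel)
    k = config.attenuation
    signal = config.baseline_fluorescence * (1.0 + k * r)
    if math.isfinite(config.bleach_tau):
        signal = signal * np.exp(-t / config.bleach_tau)
    clean = signal + config.background

    base_meta = meta if meta is not None else TraceMeta(stimulus=config.kernel.kind)
    traces: list[RawTrace] = []
    events: list[Event] = []
    for trial in range(config.n_trials):
        noise = rng.normal(0.0, config.noise_sd, size=t.size) if config.noise_sd else 0.0
        if config.noise_smooth_tau and config.noise_sd:
            # optional first-order smoothing emulating the acquisition chain
            alpha = 1.0 - math.exp(-1.0 / (config.noise_smooth_tau * config.sample_rate))
            from scipy.signal import lfilter

            noise = lfilter([alpha], [1.0, -(1.0 - alpha)], noise)
        trace_meta = replace(base_meta, trial=trial)
        traces.append(
            RawTrace(
                time=t.copy(),
                fluorescence=clean + noise,
                sample_rate=config.sample_rate,
                meta=trace_meta,
            )
        )
        events.append(Event(config.pre_duration, "stimulus_onset", float(trial)))
        if config.kernel.kind == "infusion_ramp":
            onset = config.pre_duration + config.kernel.onset_latency
            events.append(Event(onset, "infusion_start", float(trial)))
            events.append(
                Event(onset + config.kernel.ramp_duration, "infusion_end", float(trial))
            )
    events.sort(key=lambda e: (e.time_s, e.value))
    schedule = EventSchedule(events=events)
    truth = GroundTruth(
        kernel=config.kernel,
        effective_amplitude=k * config.kernel.amplitude,
        f0_true=config.baseline_fluorescence + config.background,
        seed=int(seed),
    )
    return traces, schedule, truth


# ---------------------------------------------------------------------------
# paradigm defaults

#: Default kernels per stimulus paradigm. The source figures are qualitative,
#: so these magnitudes/time constants are package choices (see docs/methods.md).
_PARADIGM_KERNELS = {
    "presentation": KernelSpec("sensory", -0.25, onset_latency=2.0, tau_on=3.0),
    "infusion": KernelSpec("infusion_ramp", -0.30, tau_on=1.0, ramp_duration=720.0),
    "cck": KernelSpec("cck_transient", -0.30, onset_latency=30.0, tau_on=60.0,
                      tau_recover=420.0),
    "ghrelin": KernelSpec("ghrelin_rise", 0.30, onset_latency=60.0, tau_on=120.0),
}

#: Post-stimulus recording durations (s): 6 min after food presentation,
#: 12-min infusion + 15 min, and 35 min after hormone injections.
_PARADIGM_POST = {
    "presentation": 360.0,
    "infusion": 1620.0,
    "cck": 2100.0,
    "ghrelin": 2100.0,
}

PARADIGMS = tuple(_PARADIGM_KERNELS)


def default_kernel(paradigm: str) -> KernelSpec:
    if paradigm not in _PARADIGM_KERNELS:
        raise ValueError(f"unknown paradigm {paradigm!r}; expected one of {PARADIGMS}")
    return _PARADIGM_KERNELS[paradigm]


def default_config(paradigm: str, **overrides) -> SimConfig:
    """Session configuration with paradigm-appropriate kernel and windows."""
    kernel = overrides.pop("kernel", default_kernel(paradigm))
    post = overrides.pop("post_duration", _PARADIGM_POST[paradigm])
    return SimConfig(kernel=kernel, post_duration=post, **overrides)


# ---------------------------------------------------------------------------
# cohorts

#: Attenuation factor k per group and timepoint: the DIO response is blunted
#: at 6 weeks of high-fat diet and partially recovers after 4 weeks back on
#: chow; lean controls are stable.
DEFAULT_ATTENUATION = {
    "lean": {"baseline": 1.0, "wk6": 1.0, "wk10": 1.0},
    "DIO": {"baseline": 1.0, "wk6": 0.4, "wk10": 0.8},
}


@dataclass
class SimSession:
    mouse_id: str
    group: str
    timepoint: str
    traces: list[RawTrace]
    schedule: EventSchedule
    truth: GroundTruth


def simulate_cohort(
    paradigm: str = "presentation",
    n_per_group: int = 10,
    timepoints: tuple[str, ...] = ("baseline", "wk6", "wk10"),
    attenuation: dict | None = None,
    amplitude_sd: float = 0.05,
    seed: int = 0,
    **config_overrides,
) -> list[SimSession]:
    """Simulate a two-group longitudinal cohort.

    Each mouse carries its own response amplitude drawn once as
    ``A + Normal(0, amplitude_sd)`` (between-animal variability, constant
    across timepoints), then scaled by the group-by-timepoint attenuation
    factor. Session seeds are spawned deterministically from ``seed``.
    """
    attenuation = attenuation if attenuation is not None else DEFAULT_ATTENUATION
    base_kernel = config_overrides.pop("kernel", default_kernel(paradigm))
    rng = np.random.default_rng(seed)
    sessions: list[SimSession] = []
    for group in ("lean", "DIO"):
        for j in range(n_per_group):
            mouse_id = f"{group}{j:02d}"
            a = base_kernel.amplitude + rng.normal(0.0, amplitude_sd)
            # keep the sign and the positivity constraint
            if base_kernel.amplitude < 0:
                a = float(np.clip(a, -0.95, -0.01))
            else:
                a = float(np.clip(a, 0.01, 5.0))
            kernel = replace(base_kernel, amplitude=a)
            for timepoint in timepoints:
                k = attenuation[group][timepoint]
                config = default_config(
                    paradigm, kernel=kernel, attenuation=k, **config_overrides
                )
                session_seed = int(rng.integers(0, 2**31 - 1))
                meta = TraceMeta(
                    mouse_id=mouse_id,
                    session_id=f"{mouse_id}-{timepoint}",
                    stimulus=kernel.kind,
                    group=group,
                    timepoint=timepoint,
                )
                traces, schedule, truth = simulate_session(config, session_seed, meta)
                sessions.append(
                    SimSession(mouse_id, group, timepoint, traces, schedule, truth)
                )
    return sessions


def simulate_measure_cohort(
    n_per_group: int = 10,
    timepoints: tuple[str, ...] = ("baseline", "wk6", "wk10"),
    mean: float = -25.0,
    subject_sd: float = 5.0,
    residual_sd: float = 2.0,
    effects: dict | None = None,
    measure: str = "mean_dff_5min_post",
    seed: int = 0,
):
    """Simulate per-mouse summary measures directly (no trace pipeline).

    Each value is ``mean + effect[group][timepoint] + subject + residual``
    with a Normal(0, subject_sd) per-mouse offset constant across timepoints
    and independent Normal(0, residual_sd) session noise. With ``effects``
    omitted this is the null model (no group or timepoint effect), suitable
    for ANOVA calibration studies at full speed.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for group in ("lean", "DIO"):
        for j in range(n_per_group):
            mouse = f"{group}{j:02d}"
            subject = rng.normal(0.0, subject_sd)
            for tp in timepoints:
                delta = effects.get(group, {}).get(tp, 0.0) if effects else 0.0
                value = mean + delta + subject + rng.normal(0.0, residual_sd)
                rows.append((mouse, group, tp, measure, value))
    return pd.DataFrame(
        rows, columns=["mouse_id", "group", "timepoint", "measure", "value"]
    )


# ---------------------------------------------------------------------------
# behavioral logs


def simulate_pellet_log(
    n_delivered: int,
    removal_latency: float = 20.0,
    n_dropped: int = 0,
    seed: int = 0,
    last_removed: bool = True,
    redeliver_delay: float = 10.0,
) -> EventSchedule:
    """Simulate a pellet-dispenser event log.

    Deliveries and removals alternate: the dispenser issues the next pellet
    ``redeliver_delay`` seconds (10 s in the behavioral protocol) after each
    removal, so only the final pellet can remain unremoved
    (``last_removed=False``). Removal latencies are jittered uniformly in
    [0.5, 1.5] x ``removal_latency``. ``n_dropped`` pellets are recorded as
    the end-of-session drop count.
    """
    if n_delivered < 0 or n_dropped < 0:
        raise ValueError("counts must be >= 0")
    if removal_latency <= 0:
        raise ValueError("removal_latency must be > 0")
    n_removed = n_delivered if last_removed else max(n_delivered - 1, 0)
    if n_dropped > n_removed:
        raise ValueError(
            f"n_dropped ({n_dropped}) exceeds removal events ({n_removed})"
        )
    rng = np.random.default_rng(seed)
    events: list[Event] = []
    t = 0.0
    for i in range(n_delivered):
        events.append(Event(t, "pellet_delivery", float(i)))
        if i >= n_removed:
            break
        t += removal_latency * rng.uniform(0.5, 1.5)
        events.append(Event(t, "pellet_removal", float(i)))
        t += redeliver_delay
    return EventSchedule(events=events, drop_count=n_dropped)


# ---------------------------------------------------------------------------
# infusion protocol


@dataclass(frozen=True)
class InfusionProtocol:
    """Constant-rate intragastric infusion schedule."""

    rate_ul_per_min: float
    duration_min: float
    start_s: float = 0.0

    @property
    def total_volume_ml(self) -> float:
        return self.rate_ul_per_min * self.duration_min / 1000.0

    @property
    def schedule(self) -> EventSchedule:
        end = self.start_s + self.duration_min * 60.0
        return EventSchedule(
            events=[
                Event(self.start_s, "infusion_start", self.total_volume_ml),
                Event(end, "infusion_end", self.total_volume_ml),
            ]
        )


def infusion_protocol(
    rate_ul_per_min: float = 100.0, duration_min: float = 12.0, start_s: float = 0.0
) -> InfusionProtocol:
    """Build the standard infusion schedule (100 uL/min for 12 min -> 1.2 mL)."""
    if rate_ul_per_min <= 0 or duration_min <= 0:
        raise ValueError("rate and duration must be > 0")
    return InfusionProtocol(rate_ul_per_min, duration_min, start_s)
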