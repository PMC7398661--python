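"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from fiberphot.io import Event, EventSchedule, TraceMeta
from fiberphot.preprocess import ProcessedTrace

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_processed(values, sample_rate=10.0, t0=0.0, meta=None, steps=None):
    """Build a ProcessedTrace directly (bypassing the conditioning chain)."""
    values = np.asarray(values, dtype=float)
    time = t0 + np.arange(values.size) / sample_rate
    return ProcessedTrace(
        time=time,
        fluorescence=values,
        sample_rate=sample_rate,
        meta=meta or TraceMeta(),
        provenance={"steps": list(steps or ["background", "lowpass", "downsample"])},
    )


def pellet_log_from_string(pattern: str, drop_count: int = 0) -> EventSchedule:
    """Build a log from a compact pattern, e.g. 'drrdrdr' (d=delivery, r=removal)."""
    events = []
    for i, ch in enumerate(pattern):
        kind = "pellet_delivery" if ch == "d" else "pellet_removal"
        events.append(Event(float(i), kind, 0.0))
    return EventSchedule(events=events, drop_count=drop_count)


def exhaustive_pellet_oracle(log: EventSchedule, dropped: int) -> int:
    """Independent brute-force scorer implementing the consumption rule
    literally: a delivery is consumed iff at least one removal falls strictly
    between it and the next delivery (taking the first); the session drop
    count is subtracted at the end, floored at zero."""
    deliveries = sorted(
        e.time_s for e in log.events if e.event_type == "pellet_delivery"
    )
    removals = sorted(e.time_s for e in log.events if e.event_type == "pellet_removal")
    paired = 0
    for i, d in enumerate(deliveries):
        next_d = deliveries[i + 1] if i + 1 < len(deliveries) else float("inf")
        if any(d < r < next_d for r in removals):
            paired += 1
    return max(paired - dropped, 0)
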