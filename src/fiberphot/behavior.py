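"""Food-consumption scoring from pellet-dispenser logs and weighed sessions.

Consumption of a pellet is defined as the first removal event after its
delivery (and before the next delivery); pellets found dropped at the end of
a session are subtracted from the total at session level. Removal events
with no preceding unconsumed delivery are flagged as anomalies, not counted.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import EventSchedule

__all__ = [
    "PelletScore",
    "IntakeRecord",
    "score_pellet_log",
    "consumed_pellets",
    "intake_energy",
    "STIM_PROTOCOLS",
]

STIM_PROTOCOLS = ("no_stim", "pre_stim", "co_stim")


@dataclass(frozen=True)
class PelletScore:
    """Full accounting of a pellet session.

    ``consumed`` follows the first-removal pairing rule minus dropped
    pellets; ``removals_minus_dropped`` is the naive alternative (total
    removal events minus dropped), reported for comparison. The two agree on
    well-formed logs and can differ on pathological ones.
    """

    deliveries: int
    removals: int
    paired: int
    dropped: int
    anomalies: int

    @property
    def consumed(self) -> int:
        return max(self.paired - self.dropped, 0)

    @property
    def removals_minus_dropped(self) -> int:
        return max(self.removals - self.dropped, 0)


def score_pellet_log(log: EventSchedule, dropped: int | None = None) -> PelletScore:
    """Score a dispenser log by pairing each delivery with its first removal."""
    if dropped is None:
        dropped = log.drop_count
    if dropped < 0:
        raise ValueError("dropped must be >= 0")
    relevant = [
        e for e in log.events if e.event_type in ("pellet_delivery", "pellet_removal")
    ]
    relevant.sort(key=lambda e: e.time_s)
    deliveries = removals = paired = anomalies = 0
    pending = False  # an unconsumed pellet is available
    for e in relevant:
        if e.event_type == "pellet_delivery":
            if pending:
                # a new pellet while the previous one was never removed:
                # the previous delivery goes unconsumed
                pass
            deliveries += 1
            pending = True
        else:
            removals += 1
            if pending:
                paired += 1
                pending = False
            else:
                anomalies += 1
    if dropped > removals:
        raise ValueError(
            f"inconsistent session: dropped ({dropped}) exceeds removal "
            f"events ({removals})"
        )
    return PelletScore(
        deliveries=deliveries,
        removals=removals,
        paired=paired,
        dropped=dropped,
        anomalies=anomalies,
    )


def consumed_pellets(log: EventSchedule, dropped: int | None = None) -> int:
    """Number of pellets consumed in a session (pairing rule, floor at 0)."""
    return score_pellet_log(log, dropped).consumed


def intake_energy(mass_g: float, kcal_per_g: float) -> float:
    """Caloric intake of a weighed-food session."""
    if mass_g < 0 or kcal_per_g < 0:
        raise ValueError("mass and energy density must be >= 0")
    return mass_g * kcal_per_g


@dataclass
class IntakeRecord:
    """Per-session food intake under a diet / state / stimulation condition."""

    mouse_id: str
    diet: str = "chow"
    fasted: bool = False
    protocol: str = "no_stim"
    pellets: int = 0
    mass_g: float = 0.0
    kcal_per_g: float = 0.0
    energy_kcal: float | None = None

    def __post_init__(self) -> None:
        if self.protocol not in STIM_PROTOCOLS:
            raise ValueError(
                f"unknown protocol {self.protocol!r}; expected one of {STIM_PROTOCOLS}"
            )
        if self.pellets < 0:
            raise ValueError("pellet count must be >= 0")
        if self.energy_kcal is None:
            self.energy_kcal = intake_energy(self.mass_g, self.kcal_per_g)
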