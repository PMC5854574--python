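"""Task configuration and visual-feedback condition definitions.

The tracking paradigm: a monkey moves a manipulandum whose position is
mapped onto a screen cursor, and must keep the cursor inside a circular
target that travels along a pseudo-random path.  Two feedback
manipulations are modelled: a fixed 100 or 200 ms delay inserted between
hand and cursor movement, and a "hidden cursor" condition in which the
cursor is blanked whenever it lies inside the target.
"""
from __future__ import annotations

from dataclasses import dataclass, field

VALID_DELAYS_MS = (0, 100, 200)
CONDITION_LABELS = ("baseline", "delay100", "delay200", "hidden")

#: behavioral sampling rate (Hz) and spike clock (Hz)
BEHAVIOR_HZ = 200
SPIKE_HZ = 1000

#: width of one firing-rate bin (ms); all timing is kept commensurate with it
BIN_MS = 20


@dataclass(frozen=True)
class Condition:
    """A visual-feedback condition.

    ``delay_ms`` is the lag between hand and cursor movement (0, 100 or
    200 ms); ``hide_inside`` blanks the cursor whenever it is strictly
    inside the target.  ``hide_inside`` is true only for the ``hidden``
    label.
    """

    label: str
    delay_ms: int = 0
    hide_inside: bool = False

    def __post_init__(self) -> None:
        if self.label not in CONDITION_LABELS:
            raise ValueError(
                f"unknown condition label {self.label!r}; "
                f"valid labels: {CONDITION_LABELS}"
            )
        if self.delay_ms not in VALID_DELAYS_MS:
            raise ValueError(
                f"delay must be one of {VALID_DELAYS_MS} ms, got {self.delay_ms}"
            )
        if self.hide_inside and self.label != "hidden":
            raise ValueError("hide_inside is true only for the 'hidden' condition")

    @classmethod
    def from_label(cls, label: str) -> "Condition":
        if label == "baseline":
            return cls("baseline")
        if label == "delay100":
            return cls("delay100", delay_ms=100)
        if label == "delay200":
            return cls("delay200", delay_ms=200)
        if label == "hidden":
            return cls("hidden", hide_inside=True)
        raise ValueError(
            f"unknown condition label {label!r}; valid labels: {CONDITION_LABELS}"
        )


BASELINE = Condition.from_label("baseline")


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the tracking paradigm.

    ``target_diameter_cm`` is one of the two sizes used behaviorally
    (2.5 or 3.5 cm).  ``hold_range_ms`` bounds the random initial/final
    hold periods.  A trial tolerates cursor excursions outside the target
    shorter than ``excursion_limit_ms``; longer ones abort the trial.
    """

    target_diameter_cm: float = 2.5
    hold_range_ms: tuple[int, int] = (500, 3000)
    excursion_limit_ms: int = 700
    behavior_hz: int = BEHAVIOR_HZ
    spike_hz: int = SPIKE_HZ
    n_trajectories: int = 100

    def __post_init__(self) -> None:
        if self.target_diameter_cm not in (2.5, 3.5):
            raise ValueError("target diameter must be 2.5 or 3.5 cm")
        if self.excursion_limit_ms != 700:
            raise ValueError("the excursion limit of the paradigm is 700 ms")
        lo, hi = self.hold_range_ms
        if not (0 < lo <= hi):
            raise ValueError("hold_range_ms must be an increasing positive pair")

    @property
    def target_radius_cm(self) -> float:
        return self.target_diameter_cm / 2.0
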