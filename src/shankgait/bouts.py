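"""Walking-bout monitor for unsupervised deployment.

A battery-conscious state machine for a footwear-embedded gyroscope:
the device sleeps until three consecutive steps arrive within the
inter-step gap limit (arming), then records the walking bout.  A bout
is accepted for gait analysis only when it contains 20 to 30 steps —
shorter bouts are discarded as non-steady walking, and recording
stops at 30 steps because longer bouts add no information about
habitual gait while inviting fatigue effects.  Accepted bouts report
their cadence, ``60 * (n_steps - 1) / (t_last - t_first)`` steps/min.

The machine is a pure function of the time-ordered event sequence:
replaying the same events reproduces the same bout log.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = ["Bout", "BoutState", "update", "process_steps", "daily_summary",
           "DEFAULT_GAP_LIMIT_S", "MIN_STEPS", "MAX_STEPS", "ARM_STEPS"]

#: Steps below this count mean the walk stopped too early to analyse.
MIN_STEPS = 20
#: Recording stops here; longer walking adds no new gait information.
MAX_STEPS = 30
#: Consecutive steps required to wake the device.
ARM_STEPS = 3
#: Inter-step gap (s) beyond which walking counts as stopped.
DEFAULT_GAP_LIMIT_S = 2.5


@dataclass(frozen=True)
class Bout:
    start: float
    end: float
    n_steps: int
    accepted: bool

    @property
    def cadence(self) -> float | None:
        """Steps per minute over the bout; None for a single step."""
        if self.n_steps < 2 or self.end <= self.start:
            return None
        return 60.0 * (self.n_steps - 1) / (self.end - self.start)


@dataclass(frozen=True)
class BoutState:
    """Immutable monitor state; :func:`update` returns a new one."""

    mode: str = "sleep"  # sleep | armed | recording
    step_count: int = 0
    first_step_t: float | None = None
    last_step_t: float | None = None
    bout_log: tuple = field(default_factory=tuple)
    gap_limit_s: float = DEFAULT_GAP_LIMIT_S


def _close(state: BoutState) -> BoutState:
    """Close the current walk; log it if it reached recording mode."""
    if state.mode != "recording":
        return replace(state, mode="sleep", step_count=0,
                       first_step_t=None, last_step_t=None)
    bout = Bout(
        start=state.first_step_t,
        end=state.last_step_t,
        n_steps=state.step_count,
        accepted=MIN_STEPS <= state.step_count <= MAX_STEPS,
    )
    return replace(
        state,
        mode="sleep",
        step_count=0,
        first_step_t=None,
        last_step_t=None,
        bout_log=state.bout_log + (bout,),
    )


def update(state: BoutState, event: tuple) -> BoutState:
    """Advance the monitor by one event.

    ``event`` is ``("step", t)`` or ``("timeout", t)``.  Timestamps
    must be non-decreasing across calls.  A step later than the gap
    limit after the previous one implicitly closes the walk and starts
    a new tentative one.
    """
    kind, t = event
    if state.last_step_t is not None and t < state.last_step_t:
        raise ValueError(
            f"non-monotone timestamp {t} after {state.last_step_t}"
        )
    if kind == "timeout":
        return _close(state)
    if kind != "step":
        raise ValueError(f"unknown event kind {kind!r}")

    if state.mode == "sleep" or state.last_step_t is None:
        return replace(state, mode="armed", step_count=1,
                       first_step_t=t, last_step_t=t)

    if t - state.last_step_t > state.gap_limit_s:
        # Walking stopped; the incoming step opens a new tentative walk.
        closed = _close(state)
        return replace(closed, mode="armed", step_count=1,
                       first_step_t=t, last_step_t=t)

    count = state.step_count + 1
    mode = state.mode
    if mode == "armed" and count >= ARM_STEPS:
        mode = "recording"
    if mode == "recording" and count > MAX_STEPS:
        # Bout closed at the cap; this step is ignored (device asleep
        # until walking pauses and restarts).
        capped = _close(replace(state, step_count=MAX_STEPS))
        return capped
    return replace(state, mode=mode, step_count=count, last_step_t=t)


def process_steps(
    step_times: Sequence[float],
    gap_limit_s: float = DEFAULT_GAP_LIMIT_S,
) -> BoutState:
    """Run the monitor over a full day of step timestamps.

    The stream is closed with a final timeout so an in-progress bout
    is flushed to the log.
    """
    state = BoutState(gap_limit_s=gap_limit_s)
    for t in step_times:
        state = update(state, ("step", float(t)))
    if state.last_step_t is not None:
        state = update(state, ("timeout", state.last_step_t + gap_limit_s + 1e-9))
    return state


def daily_summary(bout_log: Iterable[Bout]) -> dict:
    """Counts and cadence statistics over a bout log."""
    bouts = list(bout_log)
    accepted = [b for b in bouts if b.accepted]
    cadences = [b.cadence for b in accepted if b.cadence is not None]
    return {
        "n_bouts_total": len(bouts),
        "n_bouts_accepted": len(accepted),
        "n_steps_accepted": sum(b.n_steps for b in accepted),
        "mean_cadence": (sum(cadences) / len(cadences)) if cadences else None,
        "min_cadence": min(cadences) if cadences else None,
        "max_cadence": max(cadences) if cadences else None,
    }
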