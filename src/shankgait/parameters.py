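"""The six sensor-derived gait parameters.

Per accepted gait cycle:

* **toe-off speed** — |omega_z| at toe-off (deg/s);
* **mid-swing speed** — |omega_z| at the mid-swing peak (deg/s);
* **mid-stance speed** — the maximum range (max minus min) of omega_z
  over the stance window (deg/s); by default the window is
  [heel-strike, heel-off], which keeps the value independent of the
  toe-off trough — a switch restores the literal
  [heel-strike, toe-off] window;
* **propulsion duration** — toe-off minus heel-off (s);
* **propulsion acceleration** — the average slope of omega_z over the
  propulsion phase (deg/s^2); by default the endpoint slope
  |omega_z(toe-off) - omega_z(heel-off)| / duration, with a
  least-squares alternative;
* **speed norm** — the per-cycle maximum of
  sqrt(omega_x^2 + omega_y^2), the magnitude of the angular velocity
  in the frontal and transverse planes (deg/s).

Cycles are then aggregated per subject-leg into mean, sample SD and
coefficient of variation; legs with fewer than two accepted cycles
are excluded from analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .segmentation import OK, GaitEvents
from .synthetic import GyroRecording

__all__ = ["GaitCycleParams", "SubjectGait", "cycle_parameters", "aggregate_leg"]

PARAM_FIELDS = (
    "toeoff_speed",
    "midswing_speed",
    "midstance_speed",
    "propulsion_duration",
    "propulsion_acceleration",
    "speed_norm",
)


@dataclass(frozen=True)
class GaitCycleParams:
    """The six gait parameters for one accepted cycle (magnitudes)."""

    toeoff_speed: float
    midswing_speed: float
    midstance_speed: float
    propulsion_duration: float
    propulsion_acceleration: float
    speed_norm: float
    cycle_index: int = 0


@dataclass(frozen=True)
class SubjectGait:
    """Per-subject-leg aggregate: mean, SD and CV of each parameter.

    ``included`` is False when fewer than two accepted cycles were
    available (the minimum for a subject-leg to enter analysis).
    """

    mean: dict
    sd: dict
    cv: dict
    n_cycles: int
    side: str = "right"
    included: bool = True


def cycle_parameters(
    recording: GyroRecording,
    events: GaitEvents,
    *,
    midstance_window: str = "heel_off",
    acceleration_method: str = "endpoint",
) -> list[GaitCycleParams]:
    """Compute the six parameters for every accepted cycle.

    Parameters
    ----------
    midstance_window : {'heel_off', 'toe_off'}
        End of the stance window for the mid-stance range: heel-off
        (default) or the full stance up to toe-off.
    acceleration_method : {'endpoint', 'least_squares'}
        Endpoint slope over the propulsion ramp, or the slope of a
        least-squares line fitted to the ramp samples.

    Cycles whose propulsion lasts one sample or less are dropped.
    """
    if midstance_window not in ("heel_off", "toe_off"):
        raise ValueError("midstance_window must be 'heel_off' or 'toe_off'")
    if acceleration_method not in ("endpoint", "least_squares"):
        raise ValueError("acceleration_method must be 'endpoint' or 'least_squares'")
    fs = recording.fs
    z = np.asarray(recording.omega_z, dtype=float)
    xy_norm = np.hypot(
        np.asarray(recording.omega_x, dtype=float),
        np.asarray(recording.omega_y, dtype=float),
    )

    out: list[GaitCycleParams] = []
    for i in range(events.n_cycles):
        if events.quality[i] != OK or not np.isfinite(events.heel_off[i]):
            continue
        hs = int(round(events.heel_strike[i] * fs))
        ho = int(round(events.heel_off[i] * fs))
        to = int(round(events.toe_off[i] * fs))
        ms = int(round(events.mid_swing[i] * fs))
        end = int(round(events.cycle_end[i] * fs))
        if to - ho <= 1:
            continue
        d_p = (to - ho) / fs
        stance_end = ho if midstance_window == "heel_off" else to
        stance = z[hs : stance_end + 1]
        ramp = z[ho : to + 1]
        if acceleration_method == "endpoint":
            accel = abs(z[to] - z[ho]) / d_p
        else:
            tt = np.arange(ramp.size) / fs
            accel = abs(np.polyfit(tt, ramp, 1)[0])
        out.append(
            GaitCycleParams(
                toeoff_speed=abs(z[to]),
                midswing_speed=abs(z[ms]),
                midstance_speed=float(stance.max() - stance.min()),
                propulsion_duration=d_p,
                propulsion_acceleration=float(accel),
                speed_norm=float(xy_norm[hs:end].max()),
                cycle_index=i,
            )
        )
    return out


def aggregate_leg(
    cycles: Sequence[GaitCycleParams],
    side: str = "right",
    min_cycles: int = 2,
) -> SubjectGait:
    """Aggregate per-cycle parameters into a subject-leg summary.

    Mean, sample SD (ddof=1) and CV = SD/mean per parameter.  With
    fewer than ``min_cycles`` accepted cycles the summary is returned
    with ``included=False`` rather than raising — exclusion is a
    data-quality outcome, not an error.
    """
    n = len(cycles)
    if n == 0:
        nan = {p: float("nan") for p in PARAM_FIELDS}
        return SubjectGait(nan, dict(nan), dict(nan), 0, side, included=False)
    mean, sd, cv = {}, {}, {}
    for p in PARAM_FIELDS:
        vals = np.array([getattr(c, p) for c in cycles], dtype=float)
        m = vals.mean()
        s = vals.std(ddof=1) if n > 1 else 0.0
        mean[p] = float(m)
        sd[p] = float(s)
        cv[p] = float(s / m) if m > 0 else float("nan")
    return SubjectGait(mean, sd, cv, n, side, included=n >= min_cycles)


def subject_table(subjects: dict) -> "object":
    """Tidy per-subject-leg parameter table (one row per subject-leg)."""
    import pandas as pd

    rows = []
    for sid, sg in subjects.items():
        row = {"subject_id": sid, "side": sg.side, "n_cycles": sg.n_cycles,
               "included": sg.included}
        for p in PARAM_FIELDS:
            row[f"{p}_mean"] = sg.mean[p]
            row[f"{p}_sd"] = sg.sd[p]
            row[f"{p}_cv"] = sg.cv[p]
        rows.append(row)
    return pd.DataFrame(rows)
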