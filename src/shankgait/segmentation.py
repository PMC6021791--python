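"""Gait-cycle and propulsion-phase segmentation.

Events are detected from the sagittal-plane (mediolateral-axis)
angular velocity of the shank by peak detection:

* **mid-swing** — prominent positive peaks above a threshold with a
  minimum temporal separation;
* **toe-off** — the most negative local minimum in a search window
  immediately before each mid-swing peak;
* **heel-strike** — the most negative local minimum immediately after
  a mid-swing peak (it opens the next cycle);
* **heel-off** — the onset of the propulsion ramp, found by locating
  the steepest descending slope between heel-strike and toe-off and
  extending backwards while the local slope keeps a configurable
  fraction of that steepest descent.

Cycles are delimited heel-strike to heel-strike; partial cycles at the
ends of a recording are discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks, savgol_filter

__all__ = ["GaitEvents", "lowpass", "detect_gait_events", "detect_heel_off"]

OK = "ok"
REJECTED = "rejected"


@dataclass
class GaitEvents:
    """Per-cycle event times in seconds, time-ordered and non-overlapping.

    ``heel_off`` entries are NaN until :func:`detect_heel_off` fills
    them.  ``cycle_end`` is the heel-strike closing the cycle.
    Rejected cycles keep their row but carry ``quality == 'rejected'``.
    """

    heel_strike: np.ndarray
    heel_off: np.ndarray
    toe_off: np.ndarray
    mid_swing: np.ndarray
    cycle_end: np.ndarray
    quality: list = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.heel_strike)
        for name in ("heel_off", "toe_off", "mid_swing", "cycle_end"):
            if len(getattr(self, name)) != n:
                raise ValueError("event arrays must have equal length")
        if not self.quality:
            self.quality = [OK] * n

    @property
    def n_cycles(self) -> int:
        return len(self.heel_strike)

    @property
    def accepted(self) -> np.ndarray:
        return np.array([q == OK for q in self.quality])

    def to_frame(self, subject_id: str = "", side: str = ""):
        import pandas as pd

        return pd.DataFrame(
            {
                "subject_id": subject_id,
                "side": side,
                "cycle_index": np.arange(self.n_cycles),
                "heel_strike_s": self.heel_strike,
                "heel_off_s": self.heel_off,
                "toe_off_s": self.toe_off,
                "mid_swing_s": self.mid_swing,
                "cycle_end_s": self.cycle_end,
                "quality": self.quality,
            }
        )

    @staticmethod
    def empty() -> "GaitEvents":
        z = np.empty(0)
        return GaitEvents(z, z.copy(), z.copy(), z.copy(), z.copy(), [])


def lowpass(signal: np.ndarray, fs: float, cutoff: float = 10.0, order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    Gait energy in shank angular velocity sits below ~10 Hz, so the
    default cutoff keeps the gait waveform intact while stripping
    sensor noise.  Output length equals input length; a constant input
    passes through unchanged (unit DC gain).
    """
    signal = np.asarray(signal, dtype=float)
    if not 0 < cutoff < fs / 2:
        raise ValueError(f"cutoff must lie in (0, fs/2) = (0, {fs / 2}), got {cutoff}")
    b, a = butter(order, cutoff / (fs / 2), btype="low")
    return filtfilt(b, a, signal)


def _local_minima(x: np.ndarray) -> np.ndarray:
    idx, _ = find_peaks(-x)
    return idx


def _most_negative_min(
    x: np.ndarray, minima: np.ndarray, lo: int, hi: int, anchor: int
) -> int | None:
    """Most negative local minimum in [lo, hi); ties go nearest the anchor."""
    cand = minima[(minima >= lo) & (minima < hi)]
    if cand.size == 0:
        return None
    vals = x[cand]
    best = vals.min()
    tied = cand[vals <= best + 1e-12]
    return int(tied[np.argmin(np.abs(tied - anchor))])


def detect_gait_events(
    omega_z: np.ndarray,
    fs: float,
    *,
    peak_height: float = 60.0,
    min_separation: float = 0.6,
    search_frac: float = 0.45,
    refine: np.ndarray | None = None,
    refine_halfwidth_s: float = 0.03,
) -> GaitEvents:
    """Detect cycles and the heel-strike/toe-off/mid-swing events.

    Parameters
    ----------
    omega_z : array
        Sagittal-plane angular velocity in deg/s (filter it with
        :func:`lowpass` first for noisy recordings).
    fs : float
        Sampling rate, Hz.
    peak_height : float
        Minimum mid-swing peak amplitude, deg/s.  The default sits a
        factor ~4 below the frail-group mean mid-swing speed.
    min_separation : float
        Minimum spacing between mid-swing peaks, s.
    search_frac : float
        Width of the toe-off / heel-strike search windows as a
        fraction of the local stride estimate.
    refine : array, optional
        A less-filtered version of the signal (typically the raw
        channel).  Zero-phase filtering rounds the asymmetric toe-off
        and heel-strike troughs and shifts their minima by a few
        samples; when given, each trough is re-located as the argmin
        of ``refine`` within ``refine_halfwidth_s`` of the filtered
        detection.

    Returns an empty :class:`GaitEvents` when fewer than two mid-swing
    peaks are found (no complete heel-strike-delimited cycle exists).
    """
    x = np.asarray(omega_z, dtype=float)
    if x.size < fs:
        raise ValueError("need at least one second of signal")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")

    def _refine(idx: int | None) -> int | None:
        if idx is None or refine is None:
            return idx
        w = max(1, int(round(refine_halfwidth_s * fs)))
        lo, hi = max(idx - w, 0), min(idx + w + 1, x.size)
        r = np.asarray(refine, dtype=float)
        return int(lo + np.argmin(r[lo:hi]))

    peaks, _ = find_peaks(
        x, height=peak_height, distance=max(1, int(round(min_separation * fs)))
    )
    if peaks.size < 2:
        return GaitEvents.empty()
    minima = _local_minima(x)
    spacings = np.diff(peaks)

    hs_list, to_list, ms_list, end_list, qual = [], [], [], [], []
    # heel-strike following each peak j opens the cycle whose mid-swing
    # is peak j+1; the heel-strike after peak j+1 closes it.
    hs_after = []
    for j, p in enumerate(peaks):
        stride = spacings[min(j, len(spacings) - 1)]
        w = max(2, int(round(search_frac * stride)))
        hs_after.append(
            _refine(_most_negative_min(x, minima, p + 1, min(p + 1 + w, x.size), p))
        )

    for j in range(len(peaks) - 1):
        hs = hs_after[j]
        end = hs_after[j + 1]
        p = peaks[j + 1]
        stride = spacings[j]
        w = max(2, int(round(search_frac * stride)))
        to = _refine(_most_negative_min(x, minima, max(p - w, 0), p, p))
        if hs is None or to is None or end is None:
            continue
        if not (hs < to < p < end):
            continue
        hs_list.append(hs / fs)
        to_list.append(to / fs)
        ms_list.append(p / fs)
        end_list.append(end / fs)
        qual.append(OK)

    n = len(hs_list)
    return GaitEvents(
        heel_strike=np.array(hs_list),
        heel_off=np.full(n, np.nan),
        toe_off=np.array(to_list),
        mid_swing=np.array(ms_list),
        cycle_end=np.array(end_list),
        quality=qual,
    )


def detect_heel_off(
    omega_z: np.ndarray,
    events: GaitEvents,
    fs: float,
    *,
    onset_frac: float = 0.10,
    slope_window_s: float = 0.15,
    max_gap_s: float = 0.05,
) -> GaitEvents:
    """Locate heel-off as the onset of the propulsion ramp.

    Within each stance interval [heel-strike, toe-off] the local slope
    of the sagittal angular velocity is estimated (Savitzky-Golay
    derivative over ``slope_window_s``).  The steepest descending
    slope marks the interior of the propulsion ramp; the ramp is then
    extended backwards in time while the local slope stays below
    ``-onset_frac`` times that steepest descent, tolerating brief
    interruptions up to ``max_gap_s``.  Heel-off is the first sample
    of that descending run — the latest point before toe-off at which
    the sustained descent begins.

    Stances shorter than three samples, or with no descending slope,
    are flagged ``rejected``.  Modifies a copy of ``events`` and
    returns it with ``heel_off`` filled.
    """
    x = np.asarray(omega_z, dtype=float)
    heel_off = events.heel_off.copy()
    quality = list(events.quality)

    for i in range(events.n_cycles):
        if quality[i] != OK:
            continue
        hs = int(round(events.heel_strike[i] * fs))
        to = int(round(events.toe_off[i] * fs))
        stance = x[hs : to + 1]
        if stance.size < 3:
            quality[i] = REJECTED
            continue
        win = int(round(slope_window_s * fs)) | 1  # odd
        if win >= stance.size:
            smooth = np.gradient(stance)
        else:
            smooth = savgol_filter(stance, win, polyorder=2, deriv=1)
        steepest = smooth.min()
        if steepest >= 0:
            quality[i] = REJECTED
            continue
        # Locate the steepest sustained descent on the smoothed slope,
        # then walk backwards on the raw per-sample difference so the
        # ramp onset lands on the exact corner for clean signals.
        d = np.diff(stance)
        thresh = onset_frac * abs(steepest)
        steepest_idx = min(int(np.argmin(smooth)), d.size - 1)
        max_gap = max(1, int(round(max_gap_s * fs)))
        j = steepest_idx
        gap = 0
        onset = steepest_idx
        while j > 0:
            if d[j - 1] <= -thresh:
                j -= 1
                onset = j
                gap = 0
            else:
                gap += 1
                if gap > max_gap:
                    break
                j -= 1
        ho = hs + onset
        if not hs <= ho < to:
            quality[i] = REJECTED
            continue
        heel_off[i] = ho / fs

    out = GaitEvents(
        heel_strike=events.heel_strike.copy(),
        heel_off=heel_off,
        toe_off=events.toe_off.copy(),
        mid_swing=events.mid_swing.copy(),
        cycle_end=events.cycle_end.copy(),
        quality=quality,
    )
    return out


def segment_recording(recording, *, cutoff: float | None = 10.0, **opts) -> GaitEvents:
    """Filter, detect cycle events and fill heel-off in one call.

    ``cutoff=None`` skips the low-pass stage (useful for clean
    synthetic signals where filtering would round the waveform).
    """
    if cutoff is None:
        filt = np.asarray(recording.omega_z, dtype=float)
    else:
        filt = lowpass(recording.omega_z, recording.fs, cutoff)
    opts.setdefault("refine", np.asarray(recording.omega_z, dtype=float))
    events = detect_gait_events(filt, recording.fs, **opts)
    if events.n_cycles == 0:
        return events
    return detect_heel_off(filt, events, recording.fs)
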