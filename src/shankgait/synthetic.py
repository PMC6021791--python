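"""Synthetic shank-gyroscope walks with exact ground truth.

This module fabricates the inputs the rest of the pipeline consumes:
single gait cycles, multi-cycle straight walks and whole cohorts.  The
sagittal-plane angular velocity of one gait cycle is rendered as a
smooth piecewise curve through the canonical shank-gyro anchor points

    heel-strike trough -> stance rise -> heel-off -> linear propulsion
    ramp -> toe-off trough -> mid-swing peak -> next heel-strike,

with the mid-swing peak positive and the toe-off trough negative (the
common shank-gyro sign convention; all downstream gait parameters are
magnitudes, so results do not depend on it).  Anchor values are chosen
so that re-measuring the six gait parameters on the noise-free signal
returns the requested :class:`CycleSpec` exactly up to sample
discretisation, which is what makes the generator usable as a
round-trip oracle for segmentation and parameter extraction.

The generator is a test fixture, not a biomechanical simulation: it
reproduces the morphology and the per-stage parameter distributions of
real shank-gyro gait, not its dynamics.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import butter, filtfilt

from . import reference

__all__ = [
    "CycleSpec",
    "GroundTruth",
    "GyroRecording",
    "GroupSpec",
    "InfeasibleCycleError",
    "make_cycle_waveform",
    "make_walk_recording",
    "make_cohort",
    "default_group_specs",
    "cycle_spec_for_stage",
]


class InfeasibleCycleError(ValueError):
    """The requested cycle geometry cannot be realised."""


@dataclass(frozen=True)
class CycleSpec:
    """Target values for one synthetic gait cycle.

    Parameters are the six sensor-derived gait parameters plus the
    stride duration, which is a generator-only control (it is not one
    of the extracted parameters).

    Attributes
    ----------
    stride_duration : float
        Heel-strike to heel-strike time, s.
    midswing_speed : float
        Magnitude of the sagittal angular velocity at the mid-swing
        peak, deg/s.
    toeoff_speed : float
        Magnitude of the sagittal angular velocity at the toe-off
        trough, deg/s.
    midstance_range : float
        Max-minus-min of the sagittal angular velocity between
        heel-strike and heel-off, deg/s.
    propulsion_duration : float
        Heel-off to toe-off time, s.
    propulsion_acceleration : float
        Mean absolute slope of the propulsion ramp, deg/s**2.
    speednorm_peak : float
        Per-cycle maximum of the Euclidean norm of the frontal and
        transverse angular-velocity components, deg/s.
    """

    stride_duration: float
    midswing_speed: float
    toeoff_speed: float
    midstance_range: float
    propulsion_duration: float
    propulsion_acceleration: float
    speednorm_peak: float

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise InfeasibleCycleError(
                    f"{f.name} must be strictly positive and finite, got {v!r}"
                )
        if self.propulsion_duration >= self.stride_duration:
            raise InfeasibleCycleError(
                "propulsion_duration must be shorter than stride_duration"
            )
        if self.toeoff_speed >= self.midswing_speed:
            raise InfeasibleCycleError(
                "toeoff_speed must be below midswing_speed"
            )
        # The propulsion ramp ends at -toeoff_speed after descending
        # propulsion_acceleration * propulsion_duration, so the ramp
        # start (heel-off value) must stay below the mid-swing peak
        # for the peak to remain the global maximum.
        if self.heeloff_value >= self.midswing_speed:
            raise InfeasibleCycleError(
                "propulsion ramp start exceeds the mid-swing peak; "
                "reduce propulsion_acceleration * propulsion_duration"
            )

    @property
    def toeoff_value(self) -> float:
        """Signed sagittal angular velocity at toe-off (trough)."""
        return -self.toeoff_speed

    @property
    def heeloff_value(self) -> float:
        """Signed sagittal angular velocity at heel-off (ramp start)."""
        return self.toeoff_value + (
            self.propulsion_acceleration * self.propulsion_duration
        )

    @property
    def heelstrike_value(self) -> float:
        """Signed sagittal angular velocity at heel-strike.

        The stance segment rises monotonically from the heel-strike
        trough to the heel-off value, so the mid-stance range equals
        heel-off minus heel-strike by construction.
        """
        return self.heeloff_value - self.midstance_range


@dataclass(frozen=True)
class GroundTruth:
    """Exact event times and realised parameters for one cycle.

    Times are in seconds on the recording clock; ``true_params`` holds
    the parameter values actually realised on the sample grid (they
    differ from the requested :class:`CycleSpec` only through snapping
    of event times to samples).
    """

    heel_strike: float
    heel_off: float
    toe_off: float
    mid_swing: float
    cycle_end: float
    true_params: CycleSpec

    def shifted(self, offset: float) -> "GroundTruth":
        return GroundTruth(
            self.heel_strike + offset,
            self.heel_off + offset,
            self.toe_off + offset,
            self.mid_swing + offset,
            self.cycle_end + offset,
            self.true_params,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class GyroRecording:
    """Three-axis shank angular-velocity recording for one leg.

    ``omega_x`` is the rotation about the tibia-aligned axis
    (transverse plane), ``omega_y`` about the anterior-posterior axis
    (frontal plane) and ``omega_z`` about the mediolateral axis — the
    sagittal-plane rotation that dominates gait.  All channels are in
    deg/s, sampled uniformly at ``fs`` Hz.
    """

    subject_id: str
    side: str
    fs: float
    t: np.ndarray
    omega_x: np.ndarray
    omega_y: np.ndarray
    omega_z: np.ndarray

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        n = len(self.t)
        for name in ("omega_x", "omega_y", "omega_z"):
            if len(getattr(self, name)) != n:
                raise ValueError("all channels must have equal length")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")

    @property
    def duration(self) -> float:
        return len(self.t) / self.fs


def _snap(t: float, fs: float) -> int:
    return int(round(t * fs))


def _stance_segment(n_ho: int, y0: float, y1: float) -> np.ndarray:
    """Monotone rise from heel-strike to heel-off over samples 0..n_ho.

    A shape-preserving cubic through unevenly spaced anchors gives the
    stance its gentle non-linear undulation without ever leaving the
    [y0, y1] band, so the mid-stance range stays exact.
    """
    if n_ho < 4:
        return np.linspace(y0, y1, n_ho + 1)
    xs = np.unique(np.round(np.array([0.0, 0.35, 0.72, 1.0]) * n_ho)).astype(float)
    fracs = np.interp(xs / n_ho, [0.0, 0.35, 0.72, 1.0], [0.0, 0.25, 0.72, 1.0])
    ys = y0 + fracs * (y1 - y0)
    interp = PchipInterpolator(xs, ys)
    return interp(np.arange(n_ho + 1, dtype=float))


def make_cycle_waveform(
    spec: CycleSpec,
    fs: float = 100.0,
    seed: int = 0,
    *,
    stance_share: float = 0.5,
    swing_peak_frac: float = 0.45,
    next_heelstrike_value: float | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Render one gait cycle as a (n, 3) sample block with ground truth.

    Columns are (omega_x, omega_y, omega_z).  The block covers samples
    ``[0, stride)``; the next heel-strike is the first sample of the
    following cycle.  ``stance_share`` is the fraction of the
    non-propulsion time allotted to early/mid stance (the rest is
    swing); ``swing_peak_frac`` places the mid-swing peak within the
    swing interval.

    Raises
    ------
    InfeasibleCycleError
        If the propulsion ramp plus minimal stance and swing intervals
        cannot fit inside the stride at this sampling rate.
    """
    if fs < 50:
        raise ValueError("sampling rate must be at least 50 Hz")
    n_stride = _snap(spec.stride_duration, fs)
    n_prop = _snap(spec.propulsion_duration, fs)
    free = n_stride - n_prop
    n_ho = int(round(stance_share * free))
    n_to = n_ho + n_prop
    n_swing = n_stride - n_to
    if n_ho < 3 or n_swing < 4 or n_prop < 2:
        raise InfeasibleCycleError(
            "propulsion ramp does not fit inside the stride with "
            f"minimal stance/swing at fs={fs}: stance={n_ho}, "
            f"propulsion={n_prop}, swing={n_swing} samples"
        )
    i_msw = n_to + max(1, int(round(swing_peak_frac * n_swing)))
    if i_msw >= n_stride - 1:
        i_msw = n_stride - 2

    d_p = n_prop / fs
    realised = CycleSpec(
        stride_duration=n_stride / fs,
        midswing_speed=spec.midswing_speed,
        toeoff_speed=spec.toeoff_speed,
        midstance_range=spec.midstance_range,
        propulsion_duration=d_p,
        propulsion_acceleration=spec.propulsion_acceleration,
        speednorm_peak=spec.speednorm_peak,
    )
    w_to = realised.toeoff_value
    w_ho = realised.heeloff_value
    w_hs = realised.heelstrike_value
    w_hs_next = w_hs if next_heelstrike_value is None else next_heelstrike_value

    omega_z = np.empty(n_stride)
    omega_z[: n_ho + 1] = _stance_segment(n_ho, w_hs, w_ho)
    omega_z[n_ho : n_to + 1] = np.linspace(w_ho, w_to, n_prop + 1)
    swing = PchipInterpolator(
        np.array([n_to, i_msw, n_stride], dtype=float),
        np.array([w_to, spec.midswing_speed, w_hs_next]),
    )
    omega_z[n_to:] = swing(np.arange(n_to, n_stride, dtype=float))

    # Frontal/transverse channels: two sinusoids at stride and
    # double-stride frequency with seeded phases, rescaled so the
    # per-cycle max Euclidean norm equals the requested speed norm.
    rng = np.random.default_rng(seed)
    ph = rng.uniform(0, 2 * np.pi, size=4)
    u = np.arange(n_stride) / n_stride
    raw_x = np.sin(2 * np.pi * u + ph[0]) + 0.5 * np.sin(4 * np.pi * u + ph[1])
    raw_y = np.cos(2 * np.pi * u + ph[2]) + 0.5 * np.cos(4 * np.pi * u + ph[3])
    norm = np.hypot(raw_x, raw_y)
    scale = spec.speednorm_peak / norm.max()
    samples = np.column_stack([raw_x * scale, raw_y * scale, omega_z])

    truth = GroundTruth(
        heel_strike=0.0,
        heel_off=n_ho / fs,
        toe_off=n_to / fs,
        mid_swing=i_msw / fs,
        cycle_end=n_stride / fs,
        true_params=realised,
    )
    return samples, truth


def make_walk_recording(
    specs: Sequence[CycleSpec],
    fs: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    subject_id: str = "synthetic",
    side: str = "right",
    pad: float = 0.3,
    noise_bandwidth: float = 15.0,
) -> tuple[GyroRecording, list[GroundTruth]]:
    """Concatenate cycles into a continuous straight-walk recording.

    Emulates a short free walking task: the requested cycles are
    rendered back to back, a quiet-stance pad is added at both ends so
    boundary cycles survive filtering, and band-limited Gaussian noise
    of standard deviation ``noise_sd`` (deg/s, low-passed at
    ``noise_bandwidth`` Hz) is added to all three channels.
    """
    if len(specs) == 0:
        raise ValueError("at least one cycle spec is required")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    ss = np.random.SeedSequence(seed)
    cycle_seeds = ss.spawn(len(specs) + 1)

    blocks: list[np.ndarray] = []
    truths: list[GroundTruth] = []
    offset_samples = 0
    n_pad = int(round(pad * fs))
    hs_values = [s.heelstrike_value for s in specs]
    for i, spec in enumerate(specs):
        nxt = hs_values[i + 1] if i + 1 < len(specs) else hs_values[i]
        block, truth = make_cycle_waveform(
            spec,
            fs,
            seed=int(cycle_seeds[i].generate_state(1)[0] % (2**31)),
            next_heelstrike_value=nxt,
        )
        truths.append(truth.shifted((n_pad + offset_samples) / fs))
        blocks.append(block)
        offset_samples += block.shape[0]

    body = np.vstack(blocks)
    lead = np.tile(body[0], (n_pad, 1)) if n_pad else np.empty((0, 3))
    # The tail rises like the start of one more stance so the closing
    # heel-strike forms a detectable trough (no mid-swing peak follows,
    # so no spurious cycle can be detected in the pad).
    if n_pad:
        last = specs[-1]
        rise = _stance_segment(
            n_pad, last.heelstrike_value,
            last.heelstrike_value + 0.5 * last.midstance_range,
        )[:n_pad]
        tail = np.column_stack([
            np.full(n_pad, body[-1, 0]),
            np.full(n_pad, body[-1, 1]),
            rise,
        ])
    else:
        tail = np.empty((0, 3))
    data = np.vstack([lead, body, tail])

    if noise_sd > 0:
        rng = np.random.default_rng(cycle_seeds[-1])
        white = rng.standard_normal(data.shape)
        b, a = butter(4, noise_bandwidth / (fs / 2), btype="low")
        coloured = filtfilt(b, a, white, axis=0)
        coloured *= noise_sd / coloured.std(axis=0, keepdims=True)
        data = data + coloured

    n = data.shape[0]
    rec = GyroRecording(
        subject_id=subject_id,
        side=side,
        fs=fs,
        t=np.arange(n) / fs,
        omega_x=data[:, 0],
        omega_y=data[:, 1],
        omega_z=data[:, 2],
    )
    return rec, truths


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass
class GroupSpec:
    """Distributional description of one frailty stage.

    ``means`` and ``sds`` map the six gait-parameter names to their
    group mean and SD; ``correlation`` is the 6x6 inter-parameter
    correlation matrix in the order :data:`shankgait.reference.PARAMETERS`.
    """

    label: str
    n: int
    means: dict[str, float]
    sds: dict[str, float]
    correlation: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be at least 2")
        missing = set(reference.PARAMETERS) - set(self.means)
        if missing:
            raise ValueError(f"means missing parameters: {sorted(missing)}")
        if any(self.sds[p] < 0 for p in reference.PARAMETERS):
            raise ValueError("SDs must be non-negative")
        if self.correlation is None:
            self.correlation = single_factor_correlation()
        corr = np.asarray(self.correlation, dtype=float)
        if corr.shape != (6, 6) or not np.allclose(corr, corr.T):
            raise ValueError("correlation must be a symmetric 6x6 matrix")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ValueError("correlation matrix is not positive semi-definite")
        self.correlation = corr


def single_factor_correlation(loading: float = 0.7) -> np.ndarray:
    """Single-factor correlation for the six gait parameters.

    One latent 'slowness' factor: propulsion duration loads positively
    (slower gait, longer push-off), the five speed/acceleration
    parameters load negatively.  Off-diagonals are products of the
    signed loadings.
    """
    signs = np.array([+1.0, -1.0, -1.0, -1.0, -1.0, -1.0])
    lam = loading * signs
    corr = np.outer(lam, lam)
    np.fill_diagonal(corr, 1.0)
    return corr


def default_group_specs(side: str = "right") -> list[GroupSpec]:
    """Group specs matching the reference cohort (49/92/20 subjects)."""
    table = reference.RIGHT_SENSOR if side == "right" else reference.LEFT_SENSOR
    specs = []
    for stage in reference.STAGES:
        specs.append(
            GroupSpec(
                label=stage,
                n=reference.GROUP_SIZES[stage],
                means={p: table[p][stage][0] for p in reference.PARAMETERS},
                sds={p: table[p][stage][1] for p in reference.PARAMETERS},
            )
        )
    return specs


def cycle_spec_for_stage(stage: str, side: str = "right") -> CycleSpec:
    """The reference group-mean cycle for a frailty stage."""
    table = reference.RIGHT_SENSOR if side == "right" else reference.LEFT_SENSOR
    return CycleSpec(
        stride_duration=reference.STRIDE_DURATION[stage],
        midswing_speed=table["midswing_speed"][stage][0],
        toeoff_speed=table["toeoff_speed"][stage][0],
        midstance_range=table["midstance_speed"][stage][0],
        propulsion_duration=table["propulsion_duration"][stage][0],
        propulsion_acceleration=table["propulsion_acceleration"][stage][0],
        speednorm_peak=table["speed_norm"][stage][0],
    )


def _feasible_vector(vec: np.ndarray, means: np.ndarray) -> np.ndarray:
    """Clip a drawn parameter vector to the generator's feasible region."""
    floor = 0.05 * means
    vec = np.maximum(vec, floor)
    idx = {p: i for i, p in enumerate(reference.PARAMETERS)}
    # Toe-off magnitude must stay below the mid-swing peak.
    if vec[idx["toeoff_speed"]] >= 0.95 * vec[idx["midswing_speed"]]:
        vec[idx["toeoff_speed"]] = 0.95 * vec[idx["midswing_speed"]]
    return vec


def subject_cycle_spec(row, jitter: float = 0.0, rng=None) -> CycleSpec:
    """Build a renderable CycleSpec from one cohort-table row.

    The stride duration is a generator control: it starts from the
    stage default and stretches when the drawn propulsion duration
    needs more room, keeping the cycle geometry feasible.  The
    propulsion acceleration is reduced when the drawn combination
    would push the ramp start above the mid-swing peak (rare tail
    draws); ground truth always stores the values actually rendered.
    """
    d_p = float(row["propulsion_duration"])
    stride = max(reference.STRIDE_DURATION[row["stage"]], d_p + 0.45)
    if jitter and rng is not None:
        stride *= float(rng.uniform(1 - jitter, 1 + jitter))
        stride = max(stride, d_p + 0.45)
    v_msw = float(row["midswing_speed"])
    v_to = float(row["toeoff_speed"])
    a_p = float(row["propulsion_acceleration"])
    # Keep the heel-off value safely below the mid-swing peak.
    a_max = (0.9 * v_msw + v_to) / d_p
    a_p = min(a_p, a_max)
    return CycleSpec(
        stride_duration=stride,
        midswing_speed=v_msw,
        toeoff_speed=min(v_to, 0.95 * v_msw),
        midstance_range=float(row["midstance_speed"]),
        propulsion_duration=d_p,
        propulsion_acceleration=a_p,
        speednorm_peak=float(row["speed_norm"]),
    )


def make_cohort(
    groups: Sequence[GroupSpec] | None = None,
    cycles_per_subject: int = 5,
    seed: int = 0,
    *,
    fs: float = 100.0,
    noise_sd: float = 0.0,
    make_recordings: bool = False,
    side: str = "right",
):
    """Draw a synthetic cohort; optionally render its recordings.

    Per subject, the six gait parameters are drawn from the group's
    correlated Gaussian and clipped to the feasible region;
    demographics are drawn from the reference per-stage distributions;
    the Fried phenotype measures are generated from a common gait
    latent so that slowness rises with propulsion duration and falls
    with the five speed parameters.  The frailty-stage label attached
    to each subject is the generating group's label.

    Returns
    -------
    table : pandas.DataFrame
        One row per subject with stage, gait parameters, demographics
        and phenotype measures.
    recordings : dict[str, GyroRecording] | None
        Rendered walks keyed by subject id when ``make_recordings``;
        ground-truth lists live in ``recordings_truth`` alongside.
    """
    import pandas as pd

    if groups is None:
        groups = default_group_specs(side)
    if len(groups) == 0:
        raise ValueError("at least one group is required")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    rows = []
    sid = 0
    for g in groups:
        mu = np.array([g.means[p] for p in reference.PARAMETERS])
        sd = np.array([g.sds[p] for p in reference.PARAMETERS])
        cov = g.correlation * np.outer(sd, sd)
        draws = rng.multivariate_normal(mu, cov, size=g.n, method="svd")
        demo = reference.DEMOGRAPHICS
        sex_counts = reference.SEX_COUNTS.get(
            g.label, {"M": g.n // 2, "F": g.n - g.n // 2}
        )
        p_male = sex_counts["M"] / max(1, sex_counts["M"] + sex_counts["F"])
        stage_key = g.label if g.label in reference.STAGES else "pre-frail"
        for k in range(g.n):
            vec = _feasible_vector(draws[k].copy(), mu)
            row = {"subject_id": f"S{sid:04d}", "stage": g.label}
            row.update(dict(zip(reference.PARAMETERS, vec)))
            row["age"] = float(
                np.clip(rng.normal(*demo["age"][stage_key]), 55, 100)
            )
            row["height_m"] = float(
                np.clip(rng.normal(*demo["height_m"][stage_key]), 1.35, 2.05)
            )
            row["bmi"] = float(
                np.clip(rng.normal(*demo["bmi"][stage_key]), 15, 50)
            )
            row["weight_kg"] = row["bmi"] * row["height_m"] ** 2
            row["sex"] = "M" if rng.random() < p_male else "F"
            rows.append(row)
            sid += 1
    table = pd.DataFrame(rows)
    _attach_phenotype_measures(table, rng)

    recordings = None
    truths = None
    if make_recordings:
        recordings, truths = {}, {}
        rec_seeds = ss.spawn(len(table))
        for i, (_, row) in enumerate(table.iterrows()):
            spec = subject_cycle_spec(row)
            rec, gt = make_walk_recording(
                [spec] * cycles_per_subject,
                fs=fs,
                noise_sd=noise_sd,
                seed=int(rec_seeds[i].generate_state(1)[0] % (2**31)),
                subject_id=row["subject_id"],
                side=side,
            )
            recordings[row["subject_id"]] = rec
            truths[row["subject_id"]] = gt
    if make_recordings:
        return table, recordings, truths
    return table


def _attach_phenotype_measures(table, rng) -> None:
    """Generate Fried phenotype measures tied to a common gait latent.

    The latent g is the standardized 'slowness' direction of the gait
    parameters (+ propulsion duration, - the five speeds).  Measures
    load on g with decreasing strength — slowness strongest, then
    weakness, exhaustion, low activity, shrinking near zero — which
    reproduces the sign structure seen between gait parameters and
    phenotypes in the reference cohort.
    """
    import pandas as pd  # noqa: F401

    z = {}
    for p in reference.PARAMETERS:
        col = table[p].to_numpy(dtype=float)
        s = col.std()
        z[p] = (col - col.mean()) / (s if s > 0 else 1.0)
    g = (
        z["propulsion_duration"]
        - z["propulsion_acceleration"]
        - z["midstance_speed"]
        - z["speed_norm"]
        - z["toeoff_speed"]
        - z["midswing_speed"]
    ) / 6.0
    gs = g.std()
    g = g / (gs if gs > 0 else 1.0)
    n = len(table)
    stage_shift = table["stage"].map(
        {"non-frail": -0.5, "pre-frail": 0.2, "frail": 1.0}
    ).fillna(0.0).to_numpy()

    # Walk time over the reference test distance: slower with g/stage.
    speed = np.clip(
        1.15 - 0.18 * g - 0.12 * stage_shift + 0.08 * rng.standard_normal(n),
        0.2,
        2.2,
    )
    table["walk_time_s"] = reference.WALK_DISTANCE_M / speed
    base_grip = np.where(table["sex"] == "M", 35.0, 22.0)
    table["grip_kg"] = np.clip(
        base_grip - 3.5 * (0.6 * g + 0.6 * stage_shift)
        + 4.0 * rng.standard_normal(n),
        2.0,
        60.0,
    )
    table["exhaustion_score"] = np.clip(
        np.round(8 + 3.0 * (0.35 * g + 0.8 * stage_shift)
                 + 3.0 * rng.standard_normal(n)),
        0,
        30,
    ).astype(int)
    table["activity_score"] = np.clip(
        1400 - 300 * (0.3 * g + 0.7 * stage_shift)
        + 350 * rng.standard_normal(n),
        0,
        None,
    )
    table["weight_loss_kg"] = np.clip(
        rng.exponential(1.2, size=n) + 1.8 * np.maximum(stage_shift, 0)
        + 0.3 * g,
        0,
        None,
    )


def ground_truth_to_json(truths: Sequence[GroundTruth]) -> str:
    """Serialise a per-cycle ground-truth list to a JSON sidecar."""
    return json.dumps([t.to_dict() for t in truths], indent=2)


def ground_truth_from_json(text: str) -> list[GroundTruth]:
    out = []
    for d in json.loads(text):
        d = dict(d)
        d["true_params"] = CycleSpec(**d["true_params"])
        out.append(GroundTruth(**d))
    return out
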