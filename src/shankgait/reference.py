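"""Reference cohort summary statistics.

Summary statistics (group means, SDs and sizes) for a 161-subject
geriatric-outpatient cohort staged by the Fried frailty phenotype:
49 non-frail, 92 pre-frail and 20 frail participants.  These tables
drive the defaults of the synthetic cohort generator and provide the
inputs for the summary-statistic entry points of
:mod:`shankgait.stats`, so the full pipeline is exercisable without
any raw recordings.

All angular velocities are in deg/s, accelerations in deg/s**2 and
durations in seconds.  ``RIGHT_SENSOR`` / ``LEFT_SENSOR`` hold the
per-stage gait-parameter summaries for the sensor worn on the right
and left lower shin respectively.
"""

from __future__ import annotations

STAGES = ("non-frail", "pre-frail", "frail")

#: Number of subjects per frailty stage in the reference cohort.
GROUP_SIZES = {"non-frail": 49, "pre-frail": 92, "frail": 20}

#: Canonical order of the six sensor-derived gait parameters.
PARAMETERS = (
    "propulsion_duration",
    "propulsion_acceleration",
    "midstance_speed",
    "speed_norm",
    "toeoff_speed",
    "midswing_speed",
)

#: Units of the six gait parameters.
PARAMETER_UNITS = {
    "propulsion_duration": "s",
    "propulsion_acceleration": "deg/s^2",
    "midstance_speed": "deg/s",
    "speed_norm": "deg/s",
    "toeoff_speed": "deg/s",
    "midswing_speed": "deg/s",
}

# Gait-parameter summaries: {parameter: {stage: (mean, sd)}}.
RIGHT_SENSOR = {
    "propulsion_duration": {
        "non-frail": (0.70, 0.11),
        "pre-frail": (0.83, 0.23),
        "frail": (1.11, 0.46),
    },
    "propulsion_acceleration": {
        "non-frail": (366.6, 137.5),
        "pre-frail": (306.0, 125.4),
        "frail": (198.7, 109.8),
    },
    "midstance_speed": {
        "non-frail": (137.6, 42.2),
        "pre-frail": (122.1, 34.5),
        "frail": (98.2, 32.3),
    },
    "speed_norm": {
        "non-frail": (196.4, 53.5),
        "pre-frail": (170.6, 57.7),
        "frail": (129.2, 3.6),
    },
    "toeoff_speed": {
        "non-frail": (149.4, 48.2),
        "pre-frail": (118.6, 55.3),
        "frail": (82.7, 56.1),
    },
    "midswing_speed": {
        "non-frail": (336.9, 63.3),
        "pre-frail": (288.3, 69.0),
        "frail": (230.0, 74.8),
    },
}

LEFT_SENSOR = {
    "propulsion_duration": {
        "non-frail": (0.69, 0.10),
        "pre-frail": (0.83, 0.25),
        "frail": (1.07, 0.45),
    },
    "propulsion_acceleration": {
        "non-frail": (382.8, 115.3),
        "pre-frail": (314.4, 142.3),
        "frail": (220.3, 126.5),
    },
    "midstance_speed": {
        "non-frail": (144.1, 34.9),
        "pre-frail": (127.8, 40.8),
        "frail": (102.4, 35.8),
    },
    "speed_norm": {
        "non-frail": (198.8, 54.8),
        "pre-frail": (174.1, 60.5),
        "frail": (129.6, 48.9),
    },
    "toeoff_speed": {
        "non-frail": (154.2, 53.8),
        "pre-frail": (130.8, 64.4),
        "frail": (94.4, 51.8),
    },
    "midswing_speed": {
        "non-frail": (347.6, 58.9),
        "pre-frail": (291.6, 69.2),
        "frail": (223.2, 85.8),
    },
}

# Demographics: {characteristic: {stage: (mean, sd)}}.
DEMOGRAPHICS = {
    "age": {
        "non-frail": (71.2, 12.1),
        "pre-frail": (74.6, 10.3),
        "frail": (76.5, 14.3),
    },
    "height_m": {
        "non-frail": (1.66, 0.09),
        "pre-frail": (1.67, 0.12),
        "frail": (1.60, 0.12),
    },
    "weight_kg": {
        "non-frail": (73.5, 15.5),
        "pre-frail": (81.5, 21.2),
        "frail": (67.6, 14.3),
    },
    "bmi": {
        "non-frail": (26.5, 5.3),
        "pre-frail": (29.2, 6.5),
        "frail": (26.5, 5.4),
    },
}

#: Male / female counts per frailty stage.
SEX_COUNTS = {
    "non-frail": {"M": 17, "F": 32},
    "pre-frail": {"M": 41, "F": 51},
    "frail": {"M": 7, "F": 13},
}

#: Default stride durations (s) per stage, a generator-only control:
#: frailer gait is slower, so the stride lengthens with stage.
STRIDE_DURATION = {"non-frail": 1.20, "pre-frail": 1.30, "frail": 1.45}

#: Unintentional-weight-loss threshold (kg/year) for the shrinking
#: phenotype: 4.54 kg = 10 lbs.
SHRINKING_THRESHOLD_KG = 4.54

#: Walking-test distance in metres (15 ft) used for the slowness
#: phenotype and the single walking task.
WALK_DISTANCE_M = 4.57
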