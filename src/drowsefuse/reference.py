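"""Published reference numbers from the original 9-driver simulator study.

These constants are protocol- and arithmetic-level facts (printed scores,
optimized parameter values, dataset counts) used by
:func:`drowsefuse.pipeline.verify_paper_arithmetic` to desk-check that the
package's own operations reproduce every number that is arithmetically
determined.  The absolute classification scores depend on the unreleased
simulator recordings and are reference points only.

Each score row is (specificity, sensitivity, f) for all users and for the
spotlight subject U7.
"""

from __future__ import annotations

#: indicators without optimization — (spec, sens, f, spec_U7, sens_U7, f_U7)
UNOPTIMIZED_SCORES: dict[str, tuple[float, ...]] = {
    "Lateral Position": (0.89, 0.12, 0.50, 0.92, 0.18, 0.55),
    "STD_lp": (0.63, 0.58, 0.61, 0.74, 0.68, 0.71),
    "MSE_lp": (0.78, 0.50, 0.64, 0.84, 0.59, 0.72),
    "Lanex": (0.96, 0.08, 0.51, 0.99, 0.15, 0.57),
    "TLC_5s": (0.97, 0.23, 0.60, 0.99, 0.28, 0.63),
    "TLC_avg": (0.76, 0.62, 0.69, 0.86, 0.71, 0.79),
    "Steering Wheel": (0.09, 0.66, 0.37, 0.20, 0.75, 0.47),
    "STD_sw": (0.86, 0.01, 0.43, 0.98, 0.01, 0.49),
    "RSWM": (0.79, 0.03, 0.41, 0.84, 0.03, 0.44),
    "Heading error": (0.33, 0.47, 0.40, 0.45, 0.56, 0.50),
    "STD_he": (0.88, 0.53, 0.70, 0.98, 0.62, 0.80),
    "MSE_he": (0.94, 0.56, 0.75, 0.97, 0.68, 0.83),
    "PERCLOS": (0.90, 0.82, 0.86, 0.92, 0.89, 0.90),
}

#: GA-optimized indicators — same layout
OPTIMIZED_SCORES: dict[str, tuple[float, ...]] = {
    "MSE_lp_opti": (0.91, 0.47, 0.69, 0.99, 0.48, 0.73),
    "Lanex_opti": (0.90, 0.60, 0.75, 0.99, 0.65, 0.82),
    "TLC_opti": (0.77, 0.58, 0.68, 0.86, 0.59, 0.73),
    "MSE_he_opti": (0.85, 0.74, 0.80, 0.92, 0.81, 0.86),
    "RSWM_opti": (0.81, 0.49, 0.65, 0.84, 0.53, 0.69),
}

#: fused indicator combinations — same layout
FUSION_SCORES: dict[str, tuple[float, ...]] = {
    "PERCLOS + MSE_lp_opti": (0.98, 0.88, 0.93, 0.98, 0.89, 0.94),
    "PERCLOS + Lanex_opti": (0.98, 0.88, 0.93, 0.99, 0.89, 0.94),
    "PERCLOS + TLC_opti": (0.98, 0.82, 0.90, 0.99, 0.82, 0.90),
    "PERCLOS + MSE_he_opti": (0.98, 0.94, 0.96, 0.98, 0.96, 0.97),
    "TLC_avg + MSE_lp_opti": (0.98, 0.54, 0.76, 0.98, 0.55, 0.76),
    "TLC_avg + Lanex_opti": (0.96, 0.44, 0.70, 0.97, 0.46, 0.71),
    "TLC_avg + TLC_opti": (0.98, 0.57, 0.77, 0.98, 0.60, 0.79),
    "TLC_avg + MSE_he_opti": (0.87, 0.76, 0.81, 0.88, 0.78, 0.83),
    "PERCLOS + Lanex_opti + MSE_lp_opti": (0.94, 0.89, 0.91, 0.94, 0.90, 0.92),
}

#: reported optimized parameter values (units: m, m, m, s, deg/s, deg)
OPTIMIZED_PARAMS = {
    "MSE_lp": {"p": 1.865},
    "Lanex": {"x_L": 2.27, "x_R": 1.42},
    "TLC_5s": {"a": 6.4},
    "RSWM": {"d": 13.0},
    "MSE_he": {"p": -1.2},
}

#: dataset protocol counts
N_DRIVERS = 9
SESSIONS_PER_DRIVER = 3
INTERVALS_PER_HOUR = 12
RETAINED_INTERVALS = 314
DATA_POINTS = 3140
SPLIT_FRACTIONS = (0.60, 0.20, 0.20)
ALERT_SHARE = 0.709
DROWSY_SHARE = 0.291

#: road geometry (m)
LANE_WIDTH = 3.75
LANE_CENTER = 1.875
LEFT_BOUNDARY = 2.625
RIGHT_BOUNDARY = 1.125
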