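"""Reference outcome summaries for a 4-week AAN exoskeleton course (N=24).

Published summary statistics of a single-arm 4-week upper-limb
rehabilitation course with assistance-as-needed control: adaptive-control
trends (assist torque ratio, VR difficulty index, task success rate) and
clinical/functional outcomes (FMA-UE, ARAT, grip strength, normalized ROM,
SPARC smoothness) at baseline and week 4. These serve as the inputs of the
outcome-arithmetic module and as calibration context for the simulator; the
package recomputes all derived changes from the means, never stores them.
"""

from __future__ import annotations

import pandas as pd

#: Adaptive-control trends, week 1 -> week 4 (means +- sd where reported).
CONTROL_TRENDS = pd.DataFrame(
    [
        # metric, baseline mean, baseline sd, week-4 mean, week-4 sd, unit
        ("assist_torque", 62.0, 11.0, 45.0, 8.0, "% rated capacity"),
        ("vr_difficulty", 0.42, 0.09, 0.69, 0.10, "index 0-1"),
        ("success_rate", 61.3, 9.2, 82.1, 6.8, "%"),
    ],
    columns=["metric", "baseline_mean", "baseline_sd", "week4_mean",
             "week4_sd", "unit"],
).set_index("metric")

#: Clinical and functional outcomes, baseline -> week 4 (N=24).
CLINICAL_OUTCOMES = pd.DataFrame(
    [
        ("fma_ue", 34.2, 9.1, 43.3, 9.0, "points (0-66)"),
        ("arat", 22.8, 8.1, 30.4, 8.3, "points (0-57)"),
        ("grip_strength", 11.4, 5.8, 15.5, 6.2, "kg"),
        ("romn", 0.62, 0.18, 0.76, 0.15, "unitless"),
        ("sparc", 1.92, 0.31, 1.76, 0.28, "index"),
    ],
    columns=["metric", "baseline_mean", "baseline_sd", "week4_mean",
             "week4_sd", "unit"],
).set_index("metric")

#: Course adherence: sessions completed of sessions scheduled.
SESSIONS_DONE = 479
SESSIONS_SCHEDULED = 480

#: Closed-loop setpoint and reported tracking error of the smoothed score.
SCORE_TARGET = 0.75
REPORTED_TRACKING_ERROR = 0.045

#: Pre-specified multiplicity correction for the secondary outcomes.
N_SECONDARY_COMPARISONS = 5


def reference_outcome_table() -> pd.DataFrame:
    """Clinical + control reference rows in one frame (copy)."""
    return pd.concat([CONTROL_TRENDS, CLINICAL_OUTCOMES]).copy()
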