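"""Small built-in reference tables.

``example_factor_loadings`` is a published five-factor varimax loading
matrix for 18 cued-approach movement variables from a rat
discriminative-stimulus task, together with the rep scores printed alongside
it (NaN where the source marked the score not applicable).  It is used in
examples and as a worked input for the rep-score and regressor-selection
operations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_LOADING_ROWS: list[tuple[str, tuple[float, ...], float]] = [
    ("radial_velocity_max", (0.94, 0.25, 0.16, 0.01, -0.03), 0.55),
    ("radial_velocity_sd", (0.92, 0.14, 0.13, 0.30, 0.00), 0.36),
    ("speed_sd", (0.88, 0.10, 0.37, 0.22, 0.00), 0.18),
    ("speed_max", (0.88, 0.24, 0.39, -0.02, 0.02), 0.25),
    ("move_duration", (0.09, 0.95, 0.06, -0.07, 0.08), 0.78),
    ("path_length", (0.34, 0.82, 0.29, 0.33, 0.05), -0.18),
    ("latency_to_max_speed", (0.04, 0.77, 0.09, -0.08, -0.02), 0.73),
    ("latency_to_max_accel", (0.04, 0.75, 0.08, -0.09, 0.00), 0.72),
    ("max_path_deviation", (0.21, 0.66, 0.28, 0.58, 0.10), -0.50),
    ("angular_velocity_sd", (0.39, 0.12, 0.87, 0.17, 0.00), 0.19),
    ("angular_velocity_max", (0.45, 0.23, 0.82, -0.02, 0.19), -0.02),
    ("angular_velocity_mean", (0.18, 0.23, 0.74, 0.45, -0.38), 0.26),
    ("turn_efficiency", (0.01, 0.04, 0.04, -0.20, 0.02), np.nan),
    ("radial_velocity_mean", (0.54, 0.20, 0.14, 0.77, 0.20), -0.30),
    ("speed_mean", (0.49, 0.24, 0.37, 0.75, 0.01), -0.36),
    ("path_efficiency", (-0.03, -0.02, 0.11, 0.48, -0.02), 0.43),
    ("movement_onset_latency", (-0.12, 0.01, -0.04, -0.15, 0.01), np.nan),
    ("net_heading_change", (-0.01, -0.03, 0.00, -0.01, 0.01), np.nan),
]

#: rows whose printed (2-decimal) rep score is exactly reproduced by the
#: rep-score formula applied to the printed loadings
EXACT_REP_ROWS = (
    "radial_velocity_max",
    "latency_to_max_accel",
    "speed_mean",
    "angular_velocity_sd",
    "speed_max",
    "angular_velocity_mean",
)


def example_factor_loadings() -> pd.DataFrame:
    """Variable x factor loading matrix with a ``rep_score_printed`` column."""
    index = [name for name, _, _ in _LOADING_ROWS]
    loadings = pd.DataFrame(
        [vals for _, vals, _ in _LOADING_ROWS],
        index=index,
        columns=[f"factor{j + 1}" for j in range(5)],
    )
    loadings["rep_score_printed"] = [r for _, _, r in _LOADING_ROWS]
    return loadings
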