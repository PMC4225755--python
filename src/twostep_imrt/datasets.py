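"""Bundled worked-example data: achieved DVH metrics of a ten-case
prostate adaptation cohort (relocated / native / adapted plans).

Two fully worked single cases are included — the smallest volumetric
change between planning geometry and geometry of the day (about 5%,
``SMALL_CHANGE_CASE``) and the largest (about 25% Boost shrink,
``LARGE_CHANGE_CASE``) — together with the per-case S_D and rectum V_95%
values of the whole cohort.  They drive the worked examples, the
regression tests, and the ``repro-tables`` CLI command.
"""

from __future__ import annotations

# Achieved values (Gy) per requirement label, per plan group.  ``None``
# marks a metric not reported for that plan.
SMALL_CHANGE_CASE: dict[str, dict[str, float | None]] = {
    "relocated": {
        "Boost Dmean": 75.5, "Boost D99%": 64.3, "Boost D95%": 69.1,
        "Boost D1%": 79.6, "PTV-Boost D99%": 48.3, "PTV-Boost D95%": 56.5,
    },
    "native": {
        "Boost Dmean": None, "Boost D99%": 71.3, "Boost D95%": 73.0,
        "Boost D1%": 79.1, "PTV-Boost D99%": 58.9, "PTV-Boost D95%": 61.4,
    },
    "adapted": {
        "Boost Dmean": 76.1, "Boost D99%": 68.2, "Boost D95%": 71.3,
        "Boost D1%": 81.9, "PTV-Boost D99%": 53.6, "PTV-Boost D95%": 58.8,
    },
}

LARGE_CHANGE_CASE: dict[str, dict[str, float | None]] = {
    "relocated": {
        "Boost Dmean": 83.3, "Boost D99%": 78.7, "Boost D95%": 80.5,
        "Boost D1%": 86.1, "PTV-Boost D99%": 46.4, "PTV-Boost D95%": 54.4,
    },
    "native": {
        "Boost Dmean": None, "Boost D99%": 73.0, "Boost D95%": 74.2,
        "Boost D1%": 78.5, "PTV-Boost D99%": 58.0, "PTV-Boost D95%": 59.7,
    },
    "adapted": {
        "Boost Dmean": 82.5, "Boost D99%": 75.3, "Boost D95%": 77.2,
        "Boost D1%": 90.1, "PTV-Boost D99%": 44.0, "PTV-Boost D95%": 51.4,
    },
}

# Ten adaptation cases (five patients, forward and backward direction):
# S_D in Gy and rectum V_95% in cm^3 per plan group, same case order.
COHORT_S_D: dict[str, list[float]] = {
    "relocated": [74.1, 63.1, 19.2, 19.1, 45.2, 31.5, 67.8, 83.3, 23.5, 69.8],
    "native":    [17.8, 5.4, 5.7, 0.1, 0.0, 0.0, 1.0, 0.0, 0.5, 0.0],
    "adapted":   [41.1, 5.1, 13.4, 7.4, 5.3, 36.8, 9.6, 17.1, 11.5, 24.5],
}

COHORT_V95: dict[str, list[float]] = {
    "relocated": [2.8, 14.0, 4.4, 2.8, 0.0, 14.0, 2.0, 7.3, 17.7, 0.2],
    "native":    [0.2, 0.6, 2.4, 1.0, 1.4, 1.7, 2.7, 1.8, 6.0, 2.4],
    "adapted":   [0.1, 2.9, 4.5, 0.1, 3.0, 1.0, 0.1, 3.3, 4.3, 0.4],
}

__all__ = ["COHORT_S_D", "COHORT_V95", "LARGE_CHANGE_CASE", "SMALL_CHANGE_CASE"]
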