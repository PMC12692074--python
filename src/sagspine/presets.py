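"""Bundled cohort presets.

The ``table1`` preset encodes the published group summary statistics
(mean, SD, and observed min/max) of the normal-control and acute
low-back-pain (ALBP) cohorts for the generative variables, plus a
Pearson correlation matrix back-converted from the published Spearman
matrix (2*sin(pi*rho_s/6)) and projected to the nearest positive
semi-definite correlation matrix.  The PTS1-Cobb cell, not published,
is interpolated (see the methods note).

These presets let the simulate -> measure -> analyze pipeline run with
zero user input at the study's own conditions.
"""

from __future__ import annotations

import numpy as np

from .synthetic import (CohortSpec, GeometryParams, nearest_psd,
                        pearson_from_spearman)

__all__ = ["TABLE1_SUMMARY", "SPEARMAN_TABLE2", "preset_cohort_spec",
           "preset_names", "GROUP_SUMMARY_STATS"]

#: Published per-group (mean, sd) of the generative variables.  Cobb is
#: signed (negative = lordotic extension).
TABLE1_SUMMARY: dict[str, dict[str, tuple[float, float]]] = {
    "normal": {
        "SBA": (39.4, 7.2),
        "Cobb": (-65.4, 9.4),
        "PTS1": (50.3, 7.8),
        "API": (56.8, 11.0),
        "ba": (0.389, 0.147),
    },
    "albp": {
        "SBA": (44.5, 9.2),
        "Cobb": (-70.0, 10.1),
        "PTS1": (51.9, 7.8),
        "API": (57.4, 12.5),
        "ba": (0.389, 0.23),
    },
}

#: Published observed ranges (min, max) per group, available for opt-in
#: range clipping of the draws.
TABLE1_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "normal": {
        "SBA": (23.9, 53.4),
        "Cobb": (-83.4, -44.2),
        "PTS1": (29.7, 62.1),
        "API": (40.6, 82.2),
        "ba": (0.150, 0.874),
    },
    "albp": {
        "SBA": (22.0, 68.2),
        "Cobb": (-95.5, -51.4),
        "PTS1": (33.9, 67.9),
        "API": (35.0, 86.5),
        "ba": (0.027, 1.5),
    },
}

#: Full per-group, per-variable summaries (mean, sd, max, min) of every
#: reported radiographic variable, usable as direct inputs to the
#: effect-size and sample-size calculations (n = 50 per group).
GROUP_SUMMARY_STATS: dict[str, dict[str, dict[str, float]]] = {
    "normal": {
        "ARA_L1L5":   {"mean": -40.2, "sd": 9.5,  "max": -22.1, "min": -62.9, "n": 50},
        "ARA_T12S1":  {"mean": -76.3, "sd": 9.9,  "max": -47.8, "min": -97.3, "n": 50},
        "Cobb_T12S1": {"mean": -65.4, "sd": 9.4,  "max": -44.2, "min": -83.4, "n": 50},
        "SBA":        {"mean": 39.4,  "sd": 7.2,  "max": 53.4,  "min": 23.9,  "n": 50},
        "PT_S1":      {"mean": 50.3,  "sd": 7.8,  "max": 62.1,  "min": 29.7,  "n": 50},
        "API":        {"mean": 56.8,  "sd": 11.0, "max": 82.2,  "min": 40.6,  "n": 50},
        "PTPIA":      {"mean": 73.9,  "sd": 8.9,  "max": 92.9,  "min": 57.1,  "n": 50},
        "ba_ratio":   {"mean": 0.389, "sd": 0.147, "max": 0.874, "min": 0.150, "n": 50},
    },
    "albp": {
        "ARA_L1L5":   {"mean": -40.9, "sd": 9.1,  "max": -14.4, "min": -55.9, "n": 50},
        "ARA_T12S1":  {"mean": -77.5, "sd": 9.4,  "max": -51.4, "min": -91.8, "n": 50},
        "Cobb_T12S1": {"mean": -70.0, "sd": 10.1, "max": -51.4, "min": -95.5, "n": 50},
        "SBA":        {"mean": 44.5,  "sd": 9.2,  "max": 68.2,  "min": 22.0,  "n": 50},
        "PT_S1":      {"mean": 51.9,  "sd": 7.8,  "max": 67.9,  "min": 33.9,  "n": 50},
        "API":        {"mean": 57.4,  "sd": 12.5, "max": 86.5,  "min": 35.0,  "n": 50},
        "PTPIA":      {"mean": 70.6,  "sd": 9.5,  "max": 93.7,  "min": 55.8,  "n": 50},
        "ba_ratio":   {"mean": 0.389, "sd": 0.23, "max": 1.5,   "min": 0.027, "n": 50},
    },
}

#: Published Spearman correlations among the generative variables, per
#: group, over (SBA, Cobb, PTS1, API, ba).  The PTS1-Cobb entry is not
#: published and is interpolated from the SBA row.
_ORDER = ("SBA", "Cobb", "PTS1", "API", "ba")
SPEARMAN_TABLE2: dict[str, np.ndarray] = {
    #            SBA     Cobb    PTS1    API     ba
    "normal": np.array([
        [1.000, -0.731,  0.799,  0.492,  0.461],   # SBA
        [-0.731, 1.000, -0.600, -0.215, -0.596],   # Cobb (signed)
        [0.799, -0.600,  1.000,  0.248,  0.174],   # PTS1
        [0.492, -0.215,  0.248,  1.000,  0.195],   # API
        [0.461, -0.596,  0.174,  0.195,  1.000],   # ba
    ]),
    "albp": np.array([
        [1.000, -0.862,  0.329,  0.658,  0.143],
        [-0.862, 1.000, -0.300, -0.539, -0.307],
        [0.329, -0.300,  1.000,  0.102,  0.054],
        [0.658, -0.539,  0.102,  1.000,  0.001],
        [0.143, -0.307,  0.054,  0.001,  1.000],
    ]),
}


def _pearson_preset(group: str) -> np.ndarray:
    S = SPEARMAN_TABLE2[group]
    P = np.vectorize(pearson_from_spearman)(S)
    np.fill_diagonal(P, 1.0)
    return nearest_psd(P)


#: Pooled preset correlation (average of the two group matrices); a
#: single matrix is used for both groups when simulating.
def preset_correlation() -> np.ndarray:
    return nearest_psd((_pearson_preset("normal") + _pearson_preset("albp")) / 2.0)


_PRESETS = ("table1", "table1-normal", "table1-albp")


def preset_names() -> tuple[str, ...]:
    return _PRESETS


def preset_cohort_spec(name: str = "table1", n: int = 50, seed: int = 0,
                       noise_sd: float = 0.7, correlated: bool = True,
                       clip_to_ranges: bool = False) -> CohortSpec:
    """Build a :class:`CohortSpec` at the published study conditions.

    ``table1`` simulates both groups; ``table1-normal`` / ``table1-albp``
    one group only.  ``correlated`` applies the published-correlation
    preset (recommended: it also keeps the derived T12 tilt almost
    surely positive); ``clip_to_ranges`` additionally rejects draws
    outside the published observed ranges (off by default because range
    clipping biases the group means).
    """
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {_PRESETS}")
    if name == "table1":
        groups = {g: dict(d) for g, d in TABLE1_SUMMARY.items()}
    else:
        g = name.split("-", 1)[1]
        groups = {g: dict(TABLE1_SUMMARY[g])}
    return CohortSpec(
        groups=groups,
        n=n,
        seed=seed,
        noise_sd=noise_sd,
        correlation=preset_correlation() if correlated else None,
        corr_variables=_ORDER,
        bounds={g: dict(TABLE1_RANGES[g]) for g in groups} if clip_to_ranges else None,
        geometry=GeometryParams(),
    )
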