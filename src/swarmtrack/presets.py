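"""Named run configurations.

The trajectory-level presets pin the synthetic cohorts to the motility
regimes observed at *B. subtilis* colony edges: early-regime exponents of
about 1.4 (2 wt.% NaCl) and 1.27 (no NaCl), late-regime exponents of about
1.0 (NaCl) and 0.7 (control), and a super-diffusive-to-diffusive crossover
near 3 s.  Since the fBm exponent equals twice the Hurst index, the cohorts
use H = 0.70, 0.635, 0.50 and 0.35 respectively; the crossover cohort is a
persistent random walk with a 3 s velocity relaxation time.

The paired condition presets ("control" vs "nacl") add the population
structure of the two growth conditions: a large immobile subpopulation and
sub-diffusive mobile cells without NaCl, against a small immobile fraction
and diffusive mobile cells with 2 wt.% NaCl.
"""

from __future__ import annotations

import copy

_FBM_COHORT = {
    "model": "fbm",
    "sigma_step": 0.2,
    "n_cells": 200,
    "n_frames": 600,
    "frame_interval": 0.5,
    "loc_noise_sd": 0.0,
    "immobile_fraction": 0.0,
}

_CONDITION_COHORT = {
    "model": "fbm",
    "sigma_step": 1.0,
    "n_cells": 200,
    "n_frames": 600,
    "frame_interval": 0.5,
    "loc_noise_sd": 0.05,
}

_ANALYZE_DEFAULTS = {
    "t_c": 3.0,
    "t_max": None,
    "max_lag_fraction": 0.25,
    "factor": 3.5,
    "body_length_um": None,
    "noise_floor_um": None,
    "min_lags_per_regime": 3,
}

PRESETS: dict[str, dict] = {
    # exponent-recovery cohorts (trajectory level)
    "nacl-early": {
        "condition": "W_NaCl = 2%",
        "stages": ["simulate", "analyze"],
        "simulate": {**_FBM_COHORT, "hurst": 0.70},
        "analyze": {**_ANALYZE_DEFAULTS, "t_max": 30.0, "body_length_um": 4.0},
    },
    "control-early": {
        "condition": "W_NaCl = 0%",
        "stages": ["simulate", "analyze"],
        "simulate": {**_FBM_COHORT, "hurst": 0.635},
        "analyze": {**_ANALYZE_DEFAULTS, "t_max": 30.0, "body_length_um": 4.0},
    },
    "nacl-late": {
        "condition": "W_NaCl = 2%",
        "stages": ["simulate", "analyze"],
        "simulate": {**_FBM_COHORT, "hurst": 0.50},
        "analyze": {**_ANALYZE_DEFAULTS, "t_max": 30.0, "body_length_um": 4.0},
    },
    "control-late": {
        "condition": "W_NaCl = 0%",
        "stages": ["simulate", "analyze"],
        "simulate": {**_FBM_COHORT, "hurst": 0.35},
        "analyze": {**_ANALYZE_DEFAULTS, "t_max": 30.0, "body_length_um": 4.0},
    },
    # crossover-recovery cohort (persistent random walk)
    "crossover": {
        "condition": "crossover",
        "stages": ["simulate", "analyze"],
        "simulate": {
            "model": "prw",
            "speed_sd": 0.2,
            "persistence_time": 3.0,
            "n_cells": 300,
            "n_frames": 400,
            "frame_interval": 0.25,
            "loc_noise_sd": 0.0,
            "immobile_fraction": 0.0,
        },
        "analyze": {**_ANALYZE_DEFAULTS, "body_length_um": 4.0},
    },
    # paired growth-condition presets (population structure)
    "control": {
        "condition": "W_NaCl = 0%",
        "stages": ["simulate", "analyze"],
        "simulate": {**_CONDITION_COHORT, "hurst": 0.35, "immobile_fraction": 0.5},
        "analyze": {**_ANALYZE_DEFAULTS, "body_length_um": 4.0},
    },
    "nacl": {
        "condition": "W_NaCl = 2%",
        "stages": ["simulate", "analyze"],
        "simulate": {**_CONDITION_COHORT, "hurst": 0.50, "immobile_fraction": 0.1},
        "analyze": {**_ANALYZE_DEFAULTS, "body_length_um": 4.0},
    },
}


def get_preset(name: str) -> dict:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return copy.deepcopy(PRESETS[name])
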