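"""Published reference values for the Indonesian pubic-symphysis standard.

Holds the sex-specific age-at-transition parameters of the Indonesian
reference cohort (mean log age-at-transition per stage boundary plus the
common log-scale SD), the classical Suchey-Brooks phase age ranges, and the
reference cohort's age-distribution moments. These are treated as inputs:
the fitting, inversion and validation code never depends on them, but the
cohort presets and the worked examples do.
"""

from __future__ import annotations

import numpy as np

from .transition import TransitionModel

#: Support of the uniform age-at-death prior (years).
DEFAULT_SUPPORT = (17.0, 86.0)

#: Mean log age-at-transition (log-years) per stage boundary I-II .. V-VI,
#: and the common log-scale SD, for the Indonesian reference cohort.
INDONESIA_FEMALE = TransitionModel(
    sex="F",
    thresholds=np.array([2.98, 3.33, 3.64, 3.96, 4.42]),
    sigma=0.36,
    support=DEFAULT_SUPPORT,
)

INDONESIA_MALE = TransitionModel(
    sex="M",
    thresholds=np.array([2.84, 3.09, 3.58, 4.08, 4.62]),
    sigma=0.39,
    support=DEFAULT_SUPPORT,
)

REFERENCE_MODELS = {"F": INDONESIA_FEMALE, "M": INDONESIA_MALE}

#: Unmodified Suchey-Brooks age ranges (years) per phase, used for
#: classification accuracy.
SUCHEY_BROOKS_RANGES = {
    1: (15.0, 24.0),
    2: (19.0, 40.0),
    3: (21.0, 53.0),
    4: (26.0, 70.0),
    5: (25.0, 83.0),
    6: (42.0, 87.0),
}

#: Age-distribution moments of the Indonesian reference cohort
#: (truncated-normal mean/SD in years on the default support).
COHORT_AGE_MOMENTS = {
    "F": {"mean": 43.7, "sd": 12.8, "n": 213},
    "M": {"mean": 50.9, "sd": 13.3, "n": 165},
}

#: Default chronological-age brackets (closed integer bounds, years) for
#: bias/inaccuracy reporting.
DEFAULT_BRACKETS = ((17, 29), (30, 39), (40, 49), (50, 59), (60, 69), (70, 84))
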