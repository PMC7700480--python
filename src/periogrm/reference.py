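"""Published reference calibration for the six-variable reduced protocol.

A 2020 multicenter study of 254 treated chronic-periodontitis patients
reduced the 168 full-mouth probing sites to six bilaterally merged
variables at twelve sites by graded-response-model item information.  This
module freezes that study's published final-model item parameters and
cohort descriptive statistics.  They serve two roles here: the
``"paper-2020"`` synthetic-cohort preset plants its generating parameters
at the published winner sites, and the parameter values provide fixed,
externally published inputs for exercising the information machinery.
"""

from __future__ import annotations

from .chart import ToothSite
from .grm import GRMItemParams

__all__ = [
    "WINNER_SITES_RIGHT",
    "REFERENCE_MODEL4",
    "REFERENCE_FIT_STATS",
    "REFERENCE_DESCRIPTIVES",
]

#: The six winning (tooth type, surface, position) variables, given as the
#: right-side member of each mirrored pair.  Maxillary 2nd premolar
#: palatal-mesial, 1st premolar palatal-distal, canine palatal-mesial,
#: lateral incisor palatal-central, central incisor palatal-distal, and
#: mandibular 1st premolar lingual-mesial.
WINNER_SITES_RIGHT: tuple[ToothSite, ...] = (
    ToothSite(15, "lingual", "mesial"),
    ToothSite(14, "lingual", "distal"),
    ToothSite(13, "lingual", "mesial"),
    ToothSite(12, "lingual", "central"),
    ToothSite(11, "lingual", "distal"),
    ToothSite(44, "lingual", "mesial"),
)

_LABELS = [s.bilateral_label for s in WINNER_SITES_RIGHT]

#: Final-model (six bilaterally merged variables) item parameters per
#: clinical parameter, in winner order above.
REFERENCE_MODEL4: dict[str, list[tuple[str, GRMItemParams]]] = {
    "CAL": [
        (_LABELS[0], GRMItemParams(3.07, (0.28, 1.28))),
        (_LABELS[1], GRMItemParams(3.42, (0.45, 1.24))),
        (_LABELS[2], GRMItemParams(4.51, (0.65, 1.31))),
        (_LABELS[3], GRMItemParams(4.83, (1.13, 1.59))),
        (_LABELS[4], GRMItemParams(3.16, (0.75, 1.38))),
        (_LABELS[5], GRMItemParams(2.03, (0.53, 1.57))),
    ],
    "PD": [
        (_LABELS[0], GRMItemParams(3.89, (0.72, 1.46))),
        (_LABELS[1], GRMItemParams(3.38, (0.88, 1.48))),
        (_LABELS[2], GRMItemParams(4.89, (0.96, 1.39))),
        (_LABELS[3], GRMItemParams(4.63, (1.35, 1.79))),
        (_LABELS[4], GRMItemParams(3.90, (1.01, 1.45))),
        (_LABELS[5], GRMItemParams(3.39, (1.03, 1.63))),
    ],
    "BOP": [
        (_LABELS[0], GRMItemParams(3.70, (1.30,))),
        (_LABELS[1], GRMItemParams(7.71, (1.22,))),
        (_LABELS[2], GRMItemParams(2.93, (1.56,))),
        (_LABELS[3], GRMItemParams(16.96, (1.45,))),
        (_LABELS[4], GRMItemParams(2.48, (1.63,))),
        (_LABELS[5], GRMItemParams(2.09, (1.95,))),
    ],
    "PlI": [
        (_LABELS[0], GRMItemParams(2.78, (0.38, 1.85))),
        (_LABELS[1], GRMItemParams(3.85, (0.47, 1.70))),
        (_LABELS[2], GRMItemParams(3.86, (0.35, 1.65))),
        (_LABELS[3], GRMItemParams(2.66, (0.27, 1.81))),
        (_LABELS[4], GRMItemParams(2.14, (0.47, 1.96))),
        (_LABELS[5], GRMItemParams(2.19, (0.82, 2.03))),
    ],
    "mobility": [
        (_LABELS[0], GRMItemParams(2.41, (0.87, 1.90))),
        (_LABELS[1], GRMItemParams(2.53, (0.77, 1.85))),
        (_LABELS[2], GRMItemParams(2.98, (1.22, 2.21))),
        (_LABELS[3], GRMItemParams(3.81, (0.69, 1.79))),
        (_LABELS[4], GRMItemParams(3.23, (0.72, 1.99))),
        (_LABELS[5], GRMItemParams(2.07, (1.19, 2.56))),
    ],
}

#: Published per-parameter fit statistics of the final model (n = 254).
REFERENCE_FIT_STATS: dict[str, dict[str, float]] = {
    "CAL": {"aic": 1796.06, "bic": 1859.73, "n": 254, "p": 18},
    "PD": {"aic": 1198.73, "bic": 1262.41, "n": 254, "p": 18},
    "BOP": {"aic": 686.60, "bic": 729.04, "n": 254, "p": 12},
    "PlI": {"aic": 1965.74, "bic": 2029.41, "n": 254, "p": 18},
    "mobility": {"aic": 1445.90, "bic": 1509.57, "n": 254, "p": 18},
}

#: Published cohort descriptive statistics the synthetic preset targets.
REFERENCE_DESCRIPTIVES: dict[str, float] = {
    "mean_cal_mm": 3.1,
    "mean_pd_mm": 2.5,
    "bop_pct": 15.0,
    "mean_pli": 0.3,
    "n_subjects": 254,
}

#: Published item-information integrals of the final CAL/PD/BOP models,
#: used as spot checks of the information machinery.
REFERENCE_INFORMATION: dict[str, tuple[float, ...]] = {
    "CAL": (5.47, 5.92, 7.97, 7.93, 5.02, 3.27),
    "PD": (6.82, 5.37, 7.87, 7.41, 5.94, 5.40),
    "BOP": (3.70, 7.62, 2.93, 16.65, 2.48, 2.09),
    "PlI": (5.25, 7.44, 7.50, 5.03, 3.85, 3.76),
    "mobility": (4.06, 4.39, 5.28, 7.24, 6.11, 3.62),
}
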