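"""Synthetic full-mouth periodontal cohorts driven by one latent trait.

The generator emulates a cohort of treated chronic-periodontitis patients:
every subject carries a latent severity ``theta ~ N(0, 1)`` that drives all
five clinical parameters.  Per site, an ordinal CAL severity category is
drawn from a graded response model with site-specific discrimination and
thresholds; integer-mm CAL is emitted from per-category emission tables
(probes read in whole mm), probing depth is CAL minus a truncated-Poisson
recession, bleeding is a logistic function of theta with a deep-pocket
bonus, and plaque and mobility follow cumulative-logit models sharing
theta.

The ``"paper-2020"`` preset plants its highest-information CAL parameters
at the six published winner variables (see :mod:`periogrm.reference`) and
is calibrated so a 254-subject cohort reproduces the published descriptive
statistics: mean CAL 3.1 mm, mean PD 2.5 mm, BOP 15.0%, mean PlI 0.3.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from .chart import (
    OrdinalResponseMatrix,
    PeriodontalChart,
    SiteMeasurement,
    ToothSite,
    full_dentition_sites,
)
from .grm import GRMItemParams
from .reference import REFERENCE_MODEL4, WINNER_SITES_RIGHT

__all__ = [
    "SiteSusceptibilityProfile",
    "CohortConfig",
    "default_site_profiles",
    "generate_cohort",
    "generate_from_grm",
    "marginal_boundary_prob",
    "threshold_for_marginal",
]

# -- calibration constants of the "paper-2020" preset ----------------------

#: integer-mm CAL emitted per severity category: values and probabilities
CAL_EMISSION = {
    0: (np.array([1, 2, 3]), np.array([0.25, 0.40, 0.35])),
    1: (np.array([4, 5]), np.array([0.60, 0.40])),
}
#: category 2 emits 6 + min(Geometric(p) - 1, 6) mm (heavy right tail)
CAL_TAIL_GEOM_P = 0.6
CAL_TAIL_CAP = 6

#: marginal severity-category targets for non-winner sites:
#: P(cat >= 1) and P(cat >= 2) integrated over the theta prior
NONWINNER_P_GE1 = 0.34
NONWINNER_P_GE2 = 0.10

RECESSION_RATE = 0.8  # Poisson mean, truncated to [0, CAL-1]
DEEP_POCKET_BONUS = 0.8  # added to the BOP logit when PD >= 4 mm
# slope kept moderate so cohort-level BOP% sampling noise at n = 254 stays
# inside the preset's design band (15 +/- 2 points); intercept centres it
BOP_SLOPE = 0.8
BOP_INTERCEPT = -2.22

PLI_SLOPE = 1.0
PLI_CUTS = (-1.47, -3.19, -4.51)  # P(PlI >= 1, 2, 3) ~ 0.22 / 0.06 / 0.02
MOBILITY_SLOPE = 1.5
MOBILITY_CUTS = (-2.66, -4.64, -6.43)

#: tooth-loss model: Binomial(8, rate) missing teeth per subject (so at
#: least 20 of 28 teeth always remain), molars most likely to be absent
TOOTH_MISSING_RATE = 0.22
_TOOTH_LOSS_WEIGHT = {1: 1.0, 2: 1.0, 3: 0.7, 4: 1.5, 5: 1.5, 6: 3.0, 7: 3.0}


@dataclass(frozen=True)
class SiteSusceptibilityProfile:
    """Generating parameters of one probing site.

    ``a``/``b`` are the site's graded-model discrimination and two ordered
    CAL-severity thresholds on the latent scale; the remaining fields drive
    the downstream emission of BOP, recession (hence PD) and the ordinal
    plaque/mobility scores.
    """

    a: float
    b: tuple[float, float]
    bop_slope: float = BOP_SLOPE
    bop_intercept: float = BOP_INTERCEPT
    recession_rate: float = RECESSION_RATE
    pli_shift: float = 0.0
    mobility_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.recession_rate < 0:
            raise ValueError("discrimination and recession rate must be positive")
        if not self.b[0] < self.b[1]:
            raise ValueError("thresholds must be ordered")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort generation settings; the preset fixes all site profiles."""

    n_subjects: int
    seed: int = 0
    preset: str = "paper-2020"
    missing_rate: float = TOOTH_MISSING_RATE
    max_missing_teeth: int = 8
    asymmetry: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        if self.max_missing_teeth > 8:
            raise ValueError("more than 8 missing teeth would violate the >= 20 teeth rule")


def marginal_boundary_prob(a: float, b: float, n_grid: int = 801) -> float:
    """P(category >= k) integrated over the standard-normal trait prior."""
    grid = np.linspace(-8.0, 8.0, n_grid)
    w = norm.pdf(grid)
    return float(np.trapezoid(w * expit(a * (grid - b)), grid))


def threshold_for_marginal(a: float, target_p: float) -> float:
    """Threshold b at which the prior-marginal boundary probability hits
    ``target_p``; used to calibrate non-winner sites to the cohort-level
    category mix regardless of their discrimination."""
    return brentq(lambda b: marginal_boundary_prob(a, b) - target_p, -8.0, 8.0, xtol=1e-6)


def _winner_params() -> dict[ToothSite, GRMItemParams]:
    out = {}
    for site, (_, params) in zip(WINNER_SITES_RIGHT, REFERENCE_MODEL4["CAL"]):
        out[site] = params
        out[site.mirror()] = params
    return out


def default_site_profiles(
    preset: str = "paper-2020", asymmetry: float = 0.0
) -> dict[ToothSite, SiteSusceptibilityProfile]:
    """Generating profiles for all 168 sites of a preset.

    ``"paper-2020"`` plants the published final-model CAL parameters at the
    twelve winner sites and gives every other site a low, deterministically
    varying discrimination with thresholds solved so its prior-marginal
    category mix matches the cohort calibration.  ``"uniform"`` gives every
    site the same moderate profile.  Profiles are mirror-symmetric;
    ``asymmetry`` scales left-side discriminations by ``1 + asymmetry`` to
    stress the bilateral merge rule.
    """
    sites = full_dentition_sites()
    profiles: dict[ToothSite, SiteSusceptibilityProfile] = {}
    if preset == "uniform":
        for site in sites:
            profiles[site] = SiteSusceptibilityProfile(a=2.0, b=(0.5, 1.5))
    elif preset == "paper-2020":
        winners = _winner_params()
        right_sites = [s for s in sites if s.is_right]
        for i, site in enumerate(right_sites):
            if site in winners:
                p = winners[site]
                prof = SiteSusceptibilityProfile(a=p.a, b=(p.b[0], p.b[1]))
            else:
                a = 0.9 + 0.7 * ((7 * i) % 13) / 12.0
                b1 = threshold_for_marginal(a, NONWINNER_P_GE1)
                b2 = threshold_for_marginal(a, NONWINNER_P_GE2)
                prof = SiteSusceptibilityProfile(a=a, b=(b1, b2))
            profiles[site] = prof
            profiles[site.mirror()] = prof
    else:
        raise ValueError(f"unknown preset {preset!r}")

    if asymmetry:
        for site in sites:
            if not site.is_right:
                prof = profiles[site]
                profiles[site] = replace(prof, a=prof.a * (1.0 + asymmetry))
    return profiles


def _ordinal_draw(u: np.ndarray, cum_probs: list[np.ndarray]) -> np.ndarray:
    """Ordinal code from one uniform draw and descending cumulative probs."""
    code = np.zeros(u.shape, dtype=int)
    for p in cum_probs:
        code += (u < p).astype(int)
    return code


def generate_cohort(
    config: CohortConfig,
    profiles: dict[ToothSite, SiteSusceptibilityProfile] | None = None,
) -> list[PeriodontalChart]:
    """Draw a synthetic cohort of full-mouth charts.

    Deterministic given ``config.seed``: all randomness flows through one
    ``numpy.random.Generator`` with a fixed draw order (trait, tooth loss,
    mobility per tooth, then the site measurements in canonical site
    order).  Measurements at teeth later marked missing are drawn and
    discarded so the stream does not depend on the missingness pattern.
    """
    if profiles is None:
        profiles = default_site_profiles(config.preset, config.asymmetry)
    n = config.n_subjects
    if n == 0:
        return []
    rng = np.random.default_rng(config.seed)
    theta = rng.normal(size=n)

    # tooth loss: which of the 28 teeth each subject is missing
    all_teeth = sorted({s.tooth for s in full_dentition_sites()})
    loss_w = np.array([_TOOTH_LOSS_WEIGHT[t % 10] for t in all_teeth])
    loss_w = loss_w / loss_w.sum()
    n_missing = rng.binomial(config.max_missing_teeth, config.missing_rate, size=n)
    missing: list[set[int]] = []
    for i in range(n):
        if n_missing[i]:
            gone = rng.choice(len(all_teeth), size=n_missing[i], replace=False, p=loss_w)
            missing.append({all_teeth[g] for g in gone})
        else:
            missing.append(set())

    # tooth-level mobility (replicated across the tooth's six sites)
    mobility: dict[int, np.ndarray] = {}
    for tooth in all_teeth:
        u = rng.random(n)
        cps = [expit(MOBILITY_SLOPE * theta + c) for c in MOBILITY_CUTS]
        mobility[tooth] = _ordinal_draw(u, cps)

    sites = full_dentition_sites()
    measurements: dict[ToothSite, tuple[np.ndarray, ...]] = {}
    for site in sites:
        prof = profiles[site]
        # severity category from the site's graded model
        p1 = expit(prof.a * (theta - prof.b[0]))
        p2 = expit(prof.a * (theta - prof.b[1]))
        cat = _ordinal_draw(rng.random(n), [p1, p2])
        # integer-mm CAL from the per-category emission tables
        cal = np.empty(n, dtype=int)
        u = rng.random(n)
        for c, (vals, probs) in CAL_EMISSION.items():
            sel = cat == c
            cal[sel] = vals[np.searchsorted(np.cumsum(probs), u[sel])]
        tail = cat == 2
        geom = np.minimum(rng.geometric(CAL_TAIL_GEOM_P, size=n) - 1, CAL_TAIL_CAP)
        cal[tail] = 6 + geom[tail]
        # probing depth: CAL minus truncated-Poisson recession, floor 1 mm
        rec = np.minimum(rng.poisson(prof.recession_rate, size=n), cal - 1)
        pd_mm = np.maximum(cal - rec, 1)
        # bleeding: logistic in theta with a deep-pocket bonus
        logit = prof.bop_slope * theta + prof.bop_intercept + DEEP_POCKET_BONUS * (pd_mm >= 4)
        bop = rng.random(n) < expit(logit)
        # plaque: cumulative-logit sharing theta
        cps = [expit(PLI_SLOPE * theta + c + prof.pli_shift) for c in PLI_CUTS]
        pli = _ordinal_draw(rng.random(n), cps)
        measurements[site] = (cal, pd_mm, bop, pli)

    charts = []
    for i in range(n):
        chart_sites = {}
        for site in sites:
            if site.tooth in missing[i]:
                continue
            cal, pd_mm, bop, pli = measurements[site]
            chart_sites[site] = SiteMeasurement(
                cal_mm=int(cal[i]),
                pd_mm=int(pd_mm[i]),
                bop=bool(bop[i]),
                pli=int(pli[i]),
                mobility=int(mobility[site.tooth][i]),
            )
        charts.append(PeriodontalChart(patient_id=f"S{i:04d}", sites=chart_sites))
    return charts


def generate_from_grm(
    items: list[GRMItemParams],
    n: int,
    seed: int = 0,
    theta: np.ndarray | float | None = None,
) -> OrdinalResponseMatrix:
    """Pure graded-model response simulation (no mm/chart layer).

    ``theta`` fixes the latent trait (scalar or per-subject array) instead
    of drawing it from the standard-normal prior — a debugging hook.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if theta is None:
        th = rng.normal(size=n)
    else:
        th = np.broadcast_to(np.asarray(theta, float), (n,)).copy()
    resp = np.empty((n, len(items)), dtype=int)
    for j, params in enumerate(items):
        cps = [expit(params.a * (th - bk)) for bk in params.b]
        resp[:, j] = _ordinal_draw(rng.random(n), cps)
    return OrdinalResponseMatrix(
        subjects=[f"S{i:04d}" for i in range(n)],
        items=[f"item{j}" for j in range(len(items))],
        responses=resp,
        n_categories=np.array([p.n_categories for p in items]),
    )
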