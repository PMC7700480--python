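"""Downstream evaluation of a partial examination protocol.

Everything after the selection chain lives here: generalized-linear-model
regression of full-mouth summaries on latent ability (link chosen by AIC),
ROC analysis with the balanced cutoff rule (the threshold minimizing
|sensitivity - specificity|), CDC-AAP case classification, a community
periodontal index (CPI) comparator, and the partial-examination metrics —
sensitivity, prevalence and the relative biases of severity (mean CAL) and
extent (share of affected sites) against full-mouth examination.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .chart import PeriodontalChart, ToothSite

__all__ = [
    "ROCResult",
    "GLMResult",
    "PartialExamMetrics",
    "glm_link_selection",
    "roc_analysis",
    "cdc_aap_classify",
    "cpi_score",
    "partial_exam_metrics",
    "partial_mean_summary",
    "predict_full_mouth_summary",
    "CPI_INDEX_TEETH",
]


# ---------------------------------------------------------------------------
# ROC


@dataclass
class ROCResult:
    """ROC curve with the balanced operating point.

    ``chosen_cutoff`` minimizes |sensitivity - specificity| over all
    distinct score thresholds (ties broken toward higher sensitivity);
    scores at or above the cutoff are called positive.
    """

    auc: float
    chosen_cutoff: float
    sensitivity: float
    specificity: float
    lr_positive: float
    curve: pd.DataFrame

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC outside [0, 1]")


def roc_analysis(score: Sequence[float], outcome: Sequence[int]) -> ROCResult:
    """ROC analysis of a continuous score against a binary outcome.

    Higher scores indicate the positive class.  The AUC is the trapezoid
    area under the empirical curve, identical to the tie-corrected
    concordant-pair rank statistic.
    """
    score = np.asarray(score, float)
    outcome = np.asarray(outcome, int)
    if score.shape != outcome.shape:
        raise ValueError("score and outcome lengths differ")
    classes = np.unique(outcome)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("outcome must contain both classes (0 and 1)")

    fpr, tpr, thresholds = _sk_roc_curve(outcome, score, drop_intermediate=False)
    sens, spec = tpr, 1.0 - fpr
    curve = pd.DataFrame({"threshold": thresholds, "sensitivity": sens, "specificity": spec})

    gap = np.abs(sens - spec)
    # ties toward higher sensitivity
    best = max(range(len(gap)), key=lambda i: (-gap[i], sens[i]))
    chosen_sens, chosen_spec = float(sens[best]), float(spec[best])
    lr = chosen_sens / (1.0 - chosen_spec) if chosen_spec < 1.0 else np.inf
    return ROCResult(
        auc=float(_trapezoid_auc(fpr, tpr)),
        chosen_cutoff=float(thresholds[best]),
        sensitivity=chosen_sens,
        specificity=chosen_spec,
        lr_positive=float(lr),
        curve=curve,
    )


# ---------------------------------------------------------------------------
# GLM link selection


@dataclass
class GLMResult:
    """One fitted GLM candidate: family/link, coefficients and AIC."""

    family: str
    link: str
    intercept: float
    slope: float
    pvalues: tuple[float, float]
    aic: float
    result: object  # statsmodels results, kept for prediction

    def predict(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, float))
        return np.asarray(self.result.predict(sm.add_constant(x, has_constant="add")))


_GLM_CANDIDATES = [
    ("gaussian", "identity", lambda: sm.families.Gaussian(sm.families.links.Identity())),
    ("gaussian", "log", lambda: sm.families.Gaussian(sm.families.links.Log())),
    ("gamma", "log", lambda: sm.families.Gamma(sm.families.links.Log())),
    ("gamma", "inverse", lambda: sm.families.Gamma(sm.families.links.InversePower())),
]


def glm_link_selection(x: Sequence[float], y: Sequence[float]) -> GLMResult:
    """Fit the candidate family/link set and return the minimum-AIC model.

    Candidates: Gaussian-identity, Gaussian-log, Gamma-log, Gamma-inverse.
    Log and inverse links (and the Gamma family) require positive
    responses; inapplicable candidates are skipped and reported if all
    fail.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 10:
        raise ValueError("x and y must be equal-length with at least 10 points")
    X = sm.add_constant(x)
    fits: list[GLMResult] = []
    failures: list[str] = []
    for fam, link, make in _GLM_CANDIDATES:
        if (fam == "gamma" or link in ("log", "inverse")) and np.any(y <= 0):
            failures.append(f"{fam}-{link}: requires positive y")
            continue
        try:
            res = sm.GLM(y, X, family=make()).fit()
            if not np.isfinite(res.aic):
                raise ValueError("non-finite AIC")
            fits.append(
                GLMResult(
                    family=fam,
                    link=link,
                    intercept=float(res.params[0]),
                    slope=float(res.params[1]),
                    pvalues=(float(res.pvalues[0]), float(res.pvalues[1])),
                    aic=float(res.aic),
                    result=res,
                )
            )
        except Exception as exc:  # noqa: BLE001
            failures.append(f"{fam}-{link}: {exc}")
    if not fits:
        raise RuntimeError("all GLM candidates failed: " + "; ".join(failures))
    return min(fits, key=lambda f: f.aic)


# ---------------------------------------------------------------------------
# case definitions and comparator indices


def cdc_aap_classify(chart: PeriodontalChart) -> str:
    """CDC-AAP surveillance case definition: 'severe', 'moderate' or 'none'.

    Severe: >= 2 interproximal sites with CAL >= 6 mm on different teeth
    AND >= 1 interproximal site with PD >= 5 mm.  Moderate: >= 2
    interproximal sites with CAL >= 4 mm on different teeth, OR >= 2
    interproximal sites with PD >= 5 mm on different teeth.
    """
    cal6_teeth, cal4_teeth, pd5_teeth = set(), set(), set()
    any_pd5 = False
    for site, m in chart.sites.items():
        if not site.interproximal:
            continue
        if m.cal_mm >= 6:
            cal6_teeth.add(site.tooth)
        if m.cal_mm >= 4:
            cal4_teeth.add(site.tooth)
        if m.pd_mm >= 5:
            pd5_teeth.add(site.tooth)
            any_pd5 = True
    if len(cal6_teeth) >= 2 and any_pd5:
        return "severe"
    if len(cal4_teeth) >= 2 or len(pd5_teeth) >= 2:
        return "moderate"
    return "none"


#: the ten classic CPI index teeth (FDI)
CPI_INDEX_TEETH = (17, 16, 11, 26, 27, 37, 36, 31, 46, 47)


def cpi_score(chart: PeriodontalChart, index_teeth_only: bool = True) -> int:
    """Community periodontal index, PD+BOP variant, per person (0-4).

    Site codes: 4 for PD >= 6 mm, 3 for PD 4-5 mm, 1 for bleeding on
    probing, else 0; the person's score is the maximum.  Code 2 (calculus)
    is unreachable because no calculus data is charted, so this comparator
    is a "CPI (PD+BOP)".  With ``index_teeth_only`` only the ten classic
    index teeth are examined (all present teeth if none of them remain).
    """
    teeth = set(chart.teeth)
    if index_teeth_only:
        use = teeth & set(CPI_INDEX_TEETH) or teeth
    else:
        use = teeth
    code = 0
    for site, m in chart.sites.items():
        if site.tooth not in use:
            continue
        if m.pd_mm >= 6:
            site_code = 4
        elif m.pd_mm >= 4:
            site_code = 3
        elif m.bop:
            site_code = 1
        else:
            site_code = 0
        code = max(code, site_code)
    return code


# ---------------------------------------------------------------------------
# partial-examination metrics


@dataclass
class PartialExamMetrics:
    """Agreement of a partial protocol with full-mouth examination.

    ``sensitivity`` is the probability the partial exam finds at least one
    affected site given the full mouth has one; ``prevalence`` the share of
    subjects positive under the partial exam; the relative biases compare
    cohort severity (mean CAL) and extent (share of sites with CAL >= 4 mm)
    between the partial sites and all sites — negative values mean the
    partial protocol underestimates.
    """

    sensitivity: float
    prevalence: float
    relative_bias_severity: float
    relative_bias_extent: float
    sensitivity_defined: bool = True


def _chart_cal(chart: PeriodontalChart, sites: set[ToothSite] | None) -> np.ndarray:
    vals = [
        m.cal_mm
        for s, m in chart.sites.items()
        if sites is None or s in sites
    ]
    return np.asarray(vals, float)


def partial_exam_metrics(
    charts: Sequence[PeriodontalChart],
    partial_sites: Sequence[ToothSite],
    case_threshold_mm: float = 4,
    case_definition: str = "gt",
    per_subject: bool = False,
) -> PartialExamMetrics:
    """Sensitivity, prevalence and relative biases of a partial protocol.

    A subject is a case when at least one examined site has CAL above
    (``"gt"``) or at/above (``"ge"``) the threshold.  Biases use pooled
    cohort means by default; ``per_subject`` averages per-subject means
    first instead.  With no full-mouth cases sensitivity is undefined
    (NaN, flagged); the other metrics are still computed.
    """
    partial = set(partial_sites)
    if case_definition not in ("gt", "ge"):
        raise ValueError("case_definition must be 'gt' or 'ge'")

    def is_case(vals: np.ndarray) -> bool:
        if vals.size == 0:
            return False
        return bool((vals > case_threshold_mm).any() if case_definition == "gt"
                    else (vals >= case_threshold_mm).any())

    full_pos = np.array([is_case(_chart_cal(c, None)) for c in charts])
    part_pos = np.array([is_case(_chart_cal(c, partial)) for c in charts])

    prevalence = float(part_pos.mean()) if len(charts) else np.nan
    if full_pos.any():
        sensitivity = float(part_pos[full_pos].mean())
        defined = True
    else:
        sensitivity, defined = float("nan"), False

    if per_subject:
        sev_full = np.mean([_chart_cal(c, None).mean() for c in charts])
        sev_part = np.mean([
            m.mean() for c in charts if (m := _chart_cal(c, partial)).size
        ])
        ext_full = np.mean([(_chart_cal(c, None) >= 4).mean() for c in charts])
        ext_part = np.mean([
            (m >= 4).mean() for c in charts if (m := _chart_cal(c, partial)).size
        ])
    else:
        all_full = np.concatenate([_chart_cal(c, None) for c in charts])
        all_part = np.concatenate([_chart_cal(c, partial) for c in charts])
        sev_full, sev_part = all_full.mean(), all_part.mean()
        ext_full, ext_part = (all_full >= 4).mean(), (all_part >= 4).mean()

    bias_sev = float((sev_part - sev_full) / sev_full)
    bias_ext = float((ext_part - ext_full) / ext_full) if ext_full > 0 else 0.0
    return PartialExamMetrics(
        sensitivity=sensitivity,
        prevalence=prevalence,
        relative_bias_severity=bias_sev,
        relative_bias_extent=bias_ext,
        sensitivity_defined=defined,
    )


# ---------------------------------------------------------------------------
# prediction of full-mouth summaries


def partial_mean_summary(
    charts: Sequence[PeriodontalChart],
    sites: Sequence[ToothSite],
    parameter: str = "CAL",
) -> np.ndarray:
    """Per-subject simple mean of a clinical parameter over selected sites.

    CAL/PD in mm, BOP as a percentage, PlI/mobility on their 0-3 scales.
    Sites on missing teeth are skipped; a subject with none of the sites
    yields NaN.
    """
    site_set = set(sites)
    out = np.full(len(charts), np.nan)
    for i, chart in enumerate(charts):
        vals = []
        for s, m in chart.sites.items():
            if s not in site_set:
                continue
            if parameter == "CAL":
                vals.append(m.cal_mm)
            elif parameter == "PD":
                vals.append(m.pd_mm)
            elif parameter == "BOP":
                vals.append(100.0 * m.bop)
            elif parameter == "PlI":
                vals.append(m.pli)
            elif parameter == "mobility":
                vals.append(m.mobility)
            else:
                raise ValueError(f"unknown clinical parameter {parameter!r}")
        if vals:
            out[i] = float(np.mean(vals))
    return out


def predict_full_mouth_summary(
    model: GLMResult | None,
    inputs: np.ndarray,
) -> np.ndarray:
    """Predict a full-mouth summary per subject.

    With a fitted :class:`GLMResult`, ``inputs`` are final-model abilities
    and the prediction goes through the selected link.  With ``model=None``
    the twelve-site simple means in ``inputs`` are passed through unchanged
    (the mean-of-selected-sites rule).
    """
    inputs = np.atleast_1d(np.asarray(inputs, float))
    if model is None:
        return inputs
    if not isinstance(model, GLMResult):
        raise ValueError("model must be a fitted GLMResult or None")
    return model.predict(inputs)
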