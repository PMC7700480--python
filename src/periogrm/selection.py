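"""Stepwise item-information site reduction.

The full-mouth protocol is shortened in four stages, each a fresh
graded-model fit on the surviving sites:

* **Model 1** — all 168 unilateral sites.
* **Model 2** — for each of the 14 tooth types (jaw x position from the
  midline) keep the single (surface, position) slot whose left+right item
  information sums highest: 28 concrete sites.
* **Model 3** — keep the ``k`` (default 6) tooth types whose bilateral
  information sums highest in the 28-site refit: 12 concrete sites.
* **Model 4** — merge each mirrored pair into one variable via the
  bilateral worst-of rule: 6 variables, the deployable short protocol.

Selection is normally run on clinical attachment level; the same chain can
be built for any of the five clinical parameters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .chart import (
    CategorizationConfig,
    OrdinalResponseMatrix,
    PeriodontalChart,
    ToothSite,
    ToothType,
    chart_to_response_matrix,
    full_dentition_sites,
)
from .grm import GradedResponseModel, QuadratureSpec, fit_grm

__all__ = [
    "SiteInfoTable",
    "SelectionChain",
    "InformationSiteSelector",
    "bilateral_info_sum",
    "select_best_site_per_tooth_type",
    "select_top_tooth_types",
    "build_model_chain",
]

logger = logging.getLogger(__name__)

_SURFACE_ORDER = {"lingual": 0, "buccal": 1}
_POSITION_ORDER = {"mesial": 0, "central": 1, "distal": 2}


@dataclass
class SiteInfoTable:
    """Per (tooth type, surface, position) slot: left/right/summed item
    information and summed discrimination from a unilateral fit."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if (t["info_left"] < 0).any() or (t["info_right"] < 0).any():
            raise ValueError("item information cannot be negative")


def _fit_site_map(fit: GradedResponseModel) -> dict[ToothSite, int]:
    """Item column index per concrete site from a unilateral fit's labels."""
    out = {}
    for j, lab in enumerate(fit.item_labels_):
        try:
            out[ToothSite.from_label(lab)] = j
        except Exception as exc:  # noqa: BLE001
            raise ValueError(f"item label {lab!r} is not a tooth-site label") from exc
    return out


def bilateral_info_sum(fit: GradedResponseModel) -> SiteInfoTable:
    """Sum left- and right-side item information per anatomical slot.

    A side whose item was dropped before fitting contributes zero.  For a
    complete dentition the table has 84 rows (14 tooth types x 6 slots).
    """
    site_of = _fit_site_map(fit)
    infos = fit.information_integrals()
    rows: dict[tuple, dict] = {}
    for site, j in site_of.items():
        key = (site.tooth_type, site.surface, site.position)
        row = rows.setdefault(
            key,
            {
                "tooth_type": site.tooth_type.label,
                "jaw": site.jaw,
                "rank": site.rank,
                "surface": site.surface,
                "position": site.position,
                "info_left": 0.0,
                "info_right": 0.0,
                "disc_sum": 0.0,
            },
        )
        side = "info_right" if site.is_right else "info_left"
        row[side] += float(infos[j])
        row["disc_sum"] += float(fit.discrimination_[j])
    df = pd.DataFrame(sorted(rows.values(), key=lambda r: (r["jaw"], r["rank"], r["surface"], r["position"])))
    df["info_sum"] = df["info_left"] + df["info_right"]
    return SiteInfoTable(df.reset_index(drop=True))


def select_best_site_per_tooth_type(table: SiteInfoTable) -> list[ToothSite]:
    """The winning (surface, position) slot of every tooth type, expanded
    to concrete left+right sites.

    Ties on summed information break toward higher summed discrimination,
    then lingual before buccal, then mesial < central < distal.
    """
    df = table.table
    winners: list[ToothSite] = []
    for (_, _), group in df.groupby(["jaw", "rank"], sort=True):
        ranked = sorted(
            group.itertuples(),
            key=lambda r: (
                -r.info_sum,
                -r.disc_sum,
                _SURFACE_ORDER[r.surface],
                _POSITION_ORDER[r.position],
            ),
        )
        best = ranked[0]
        quadrants = (1, 2) if best.jaw == "maxilla" else (4, 3)
        for q in quadrants:
            winners.append(ToothSite(q * 10 + best.rank, best.surface, best.position))
    return sorted(winners)


def _tooth_type_info(fit: GradedResponseModel) -> pd.DataFrame:
    """Bilateral information sum per tooth type from a unilateral fit."""
    site_of = _fit_site_map(fit)
    infos = fit.information_integrals()
    acc: dict[ToothType, float] = {}
    sites_of_type: dict[ToothType, list[ToothSite]] = {}
    for site, j in site_of.items():
        acc[site.tooth_type] = acc.get(site.tooth_type, 0.0) + float(infos[j])
        sites_of_type.setdefault(site.tooth_type, []).append(site)
    df = pd.DataFrame(
        [
            {"tooth_type": tt, "label": tt.label, "info_sum": v,
             "sites": tuple(sorted(sites_of_type[tt]))}
            for tt, v in acc.items()
        ]
    )
    return df.sort_values("info_sum", ascending=False).reset_index(drop=True)


def select_top_tooth_types(fit: GradedResponseModel, k: int = 6) -> list[ToothSite]:
    """Keep the ``k`` tooth types with the highest bilateral information
    sums in a (28-site) fit; returns their concrete left+right sites."""
    ranked = _tooth_type_info(fit)
    if k > len(ranked):
        raise ValueError(f"k={k} exceeds the {len(ranked)} tooth types present")
    sites: list[ToothSite] = []
    for row in ranked.head(k).itertuples():
        sites.extend(row.sites)
    return sorted(sites)


@dataclass
class SelectionChain:
    """The four fitted models, the surviving site sets and an audit trail."""

    parameter: str
    model1: GradedResponseModel
    model2: GradedResponseModel
    model3: GradedResponseModel
    model4: GradedResponseModel
    sites1: list[ToothSite]
    sites2: list[ToothSite]
    selected_sites: list[ToothSite]  # the final 12 concrete sites
    info_table: SiteInfoTable
    audit: pd.DataFrame = field(default_factory=pd.DataFrame)
    #: per model-4 item: monotone raw-code -> fitted-code map (categories
    #: unseen at fit time fold into the nearest seen one)
    model4_category_maps: list[np.ndarray] | None = None
    model4_item_labels: list[str] | None = None

    @property
    def models(self) -> list[GradedResponseModel]:
        return [self.model1, self.model2, self.model3, self.model4]

    def validate_nesting(self) -> None:
        s1, s2, s3 = set(self.sites1), set(self.sites2), set(self.selected_sites)
        if not (s3 <= s2 <= s1):
            raise ValueError("selected site sets are not nested")
        if {s.mirror() for s in s3} != s3:
            raise ValueError("final sites are not closed under mirroring")

    def audit_frame(self) -> pd.DataFrame:
        return self.audit


def _audit_rows(stage: str, fit: GradedResponseModel) -> list[dict]:
    infos = fit.information_integrals()
    rows = []
    for (lab, p), info in zip(fit.items_, infos):
        rows.append(
            {
                "stage": stage,
                "item": lab,
                "info": float(info),
                "a": p.a,
                **{f"b{k + 1}": bk for k, bk in enumerate(p.b)},
                "n_items": len(fit.items_),
                "loglik": fit.loglik_,
                "aic": fit.aic_,
                "bic": fit.bic_,
            }
        )
    return rows


def _prepare(matrix: OrdinalResponseMatrix, stage: str, audit_notes: list[str]) -> OrdinalResponseMatrix:
    collapsed = matrix.collapse_sparse_categories()
    dropped = set(matrix.items) - set(collapsed.items)
    if dropped:
        audit_notes.append(f"{stage}: dropped degenerate items {sorted(dropped)}")
    changed = [
        lab
        for lab, old, new in zip(collapsed.items, matrix.n_categories, collapsed.n_categories)
        if old != new
    ]
    if changed:
        audit_notes.append(f"{stage}: collapsed sparse categories for {changed}")
    return collapsed


def build_model_chain(
    charts: list[PeriodontalChart],
    parameter: str = "CAL",
    config: CategorizationConfig | None = None,
    quad: QuadratureSpec | None = None,
    seed: int | None = None,
    k: int = 6,
    exclude_molars: bool = False,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> SelectionChain:
    """Run the full Models 1-4 reduction for one clinical parameter.

    Each stage refits from scratch on its reduced site set.  Items whose
    responses do not cover every category are renumbered or dropped before
    fitting (recorded in the audit).  ``exclude_molars`` restricts the
    starting universe to FDI positions 1-5 (premolars and anterior teeth).
    """
    if len(charts) < 50:
        warnings.warn(
            f"only {len(charts)} charts; selection is unstable below ~50 subjects",
            UserWarning,
        )
    notes: list[str] = []
    sites1 = full_dentition_sites(exclude_molars=exclude_molars)

    def _fit(matrix: OrdinalResponseMatrix, stage: str):
        prepared = _prepare(matrix, stage, notes)
        try:
            fit = fit_grm(prepared, quad=quad, tol=tol, max_iter=max_iter, seed=seed)
        except Exception as exc:
            raise RuntimeError(f"{stage} fit failed for parameter {parameter!r}") from exc
        logger.info(
            "%s (%s): %d items, loglik %.2f, %d EM iterations",
            stage, parameter, len(fit.items_), fit.loglik_, fit.n_iter_,
        )
        return fit, prepared

    m1, _ = _fit(chart_to_response_matrix(charts, sites1, parameter, config), "model1")
    info_table = bilateral_info_sum(m1)
    sites2 = select_best_site_per_tooth_type(info_table)

    m2, _ = _fit(chart_to_response_matrix(charts, sites2, parameter, config), "model2")
    sites3 = select_top_tooth_types(m2, k=k)

    m3, _ = _fit(chart_to_response_matrix(charts, sites3, parameter, config), "model3")
    m4, m4_prepared = _fit(
        chart_to_response_matrix(charts, sites3, parameter, config, bilateral=True),
        "model4",
    )

    audit = pd.DataFrame(
        _audit_rows("model1", m1)
        + _audit_rows("model2", m2)
        + _audit_rows("model3", m3)
        + _audit_rows("model4", m4)
    )
    audit.attrs["notes"] = notes
    chain = SelectionChain(
        parameter=parameter,
        model1=m1, model2=m2, model3=m3, model4=m4,
        sites1=sites1, sites2=sites2, selected_sites=sites3,
        info_table=info_table, audit=audit,
        model4_category_maps=m4_prepared.category_maps,
        model4_item_labels=list(m4_prepared.items),
    )
    chain.validate_nesting()
    return chain


class InformationSiteSelector(BaseEstimator):
    """Estimator wrapper around the Models 1-4 reduction chain.

    ``fit`` runs the chain on a list of charts; ``transform`` scores charts
    to the final-model EAP ability.  Fitted attributes: ``chain_``,
    ``selected_sites_`` (12 concrete sites), ``model4_``.
    """

    def __init__(
        self,
        parameter: str = "CAL",
        k: int = 6,
        exclude_molars: bool = False,
        lower_mm: int = 4,
        upper_mm: int = 5,
        tol: float = 1e-4,
        max_iter: int = 200,
        random_state: int | None = None,
    ):
        self.parameter = parameter
        self.k = k
        self.exclude_molars = exclude_molars
        self.lower_mm = lower_mm
        self.upper_mm = upper_mm
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X: list[PeriodontalChart], y=None):
        self.chain_ = build_model_chain(
            X,
            parameter=self.parameter,
            config=CategorizationConfig(self.lower_mm, self.upper_mm),
            seed=self.random_state,
            k=self.k,
            exclude_molars=self.exclude_molars,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        self.selected_sites_ = self.chain_.selected_sites
        self.model4_ = self.chain_.model4
        return self

    def transform(self, X: list[PeriodontalChart]) -> np.ndarray:
        """Final-model EAP ability per chart, as a column vector."""
        matrix = chart_to_response_matrix(
            X,
            self.selected_sites_,
            self.parameter,
            CategorizationConfig(self.lower_mm, self.upper_mm),
            bilateral=True,
        )
        cols = [matrix.items.index(lab) for lab in self.model4_.item_labels_]
        aligned = matrix.responses[:, cols]
        maps = self.chain_.model4_category_maps
        if maps is not None:
            for j, cmap in enumerate(maps):
                obs = aligned[:, j] != -1
                aligned[obs, j] = cmap[aligned[obs, j]]
        return self.model4_.transform(aligned)
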