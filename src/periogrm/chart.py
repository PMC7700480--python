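"""Full-mouth periodontal chart model.

A full dentition (third molars excluded) has 28 teeth in FDI two-digit
notation, each probed at six sites: mesial, central and distal positions on
the buccal and lingual surfaces ("lingual" covers palatal in the maxilla).
That gives 168 distinct examination sites per mouth.  This module holds the
domain types for charts, the ordinal categorization of mm readings, the
bilateral (left/right) merge rule, and per-patient summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SURFACES",
    "POSITIONS",
    "SITE_CODES",
    "ToothSite",
    "ToothType",
    "SiteMeasurement",
    "PeriodontalChart",
    "CategorizationConfig",
    "OrdinalResponseMatrix",
    "full_dentition_sites",
    "categorize_value",
    "merge_bilateral",
    "chart_to_response_matrix",
    "summary_stats",
    "InvalidMeasurementError",
    "EmptyItemError",
]

SURFACES = ("buccal", "lingual")
POSITIONS = ("mesial", "central", "distal")

#: CSV site codes -> (surface, position).  "Medial" readings in some charts
#: are the mesial position.
SITE_CODES = {
    "MB": ("buccal", "mesial"),
    "B": ("buccal", "central"),
    "DB": ("buccal", "distal"),
    "ML": ("lingual", "mesial"),
    "L": ("lingual", "central"),
    "DL": ("lingual", "distal"),
}
_CODE_OF = {v: k for k, v in SITE_CODES.items()}

_MIRROR_QUADRANT = {1: 2, 2: 1, 3: 4, 4: 3}

#: FDI position-from-midline -> tooth name (positions 1-7; no third molars).
TOOTH_NAMES = {
    1: "central incisor",
    2: "lateral incisor",
    3: "canine",
    4: "1st premolar",
    5: "2nd premolar",
    6: "1st molar",
    7: "2nd molar",
}


class InvalidMeasurementError(ValueError):
    """A clinical measurement is outside its valid range."""


class EmptyItemError(ValueError):
    """A requested site is absent from every chart in the cohort."""


def _check_tooth(tooth: int) -> None:
    q, r = divmod(int(tooth), 10)
    if q not in (1, 2, 3, 4) or r not in range(1, 8):
        raise ValueError(
            f"invalid FDI tooth code {tooth!r}; expected 11-17, 21-27, 31-37 or 41-47"
        )


@dataclass(frozen=True, order=True)
class ToothType:
    """A left/right-agnostic tooth identity: jaw plus position from midline."""

    jaw: str  # "maxilla" | "mandible"
    rank: int  # 1..7

    def __post_init__(self) -> None:
        if self.jaw not in ("maxilla", "mandible"):
            raise ValueError(f"invalid jaw {self.jaw!r}")
        if self.rank not in range(1, 8):
            raise ValueError(f"invalid tooth rank {self.rank}")

    @property
    def name(self) -> str:
        return f"{'maxillary' if self.jaw == 'maxilla' else 'mandibular'} {TOOTH_NAMES[self.rank]}"

    @property
    def label(self) -> str:
        return ("max" if self.jaw == "maxilla" else "man") + str(self.rank)


@dataclass(frozen=True, order=True)
class ToothSite:
    """One probing site: FDI tooth code, surface and mesio-distal position."""

    tooth: int
    surface: str
    position: str

    def __post_init__(self) -> None:
        _check_tooth(self.tooth)
        if self.surface not in SURFACES:
            raise ValueError(f"invalid surface {self.surface!r}")
        if self.position not in POSITIONS:
            raise ValueError(f"invalid position {self.position!r}")

    @property
    def quadrant(self) -> int:
        return self.tooth // 10

    @property
    def rank(self) -> int:
        """Position from the midline (1 = central incisor ... 7 = 2nd molar)."""
        return self.tooth % 10

    @property
    def jaw(self) -> str:
        return "maxilla" if self.quadrant in (1, 2) else "mandible"

    @property
    def is_right(self) -> bool:
        """Patient's right side (FDI quadrants 1 and 4)."""
        return self.quadrant in (1, 4)

    @property
    def tooth_type(self) -> ToothType:
        return ToothType(self.jaw, self.rank)

    @property
    def interproximal(self) -> bool:
        return self.position in ("mesial", "distal")

    def mirror(self) -> "ToothSite":
        """Contralateral site: same jaw, rank, surface and position."""
        q = _MIRROR_QUADRANT[self.quadrant]
        return ToothSite(q * 10 + self.rank, self.surface, self.position)

    @property
    def label(self) -> str:
        return f"{self.tooth}-{_CODE_OF[(self.surface, self.position)]}"

    @classmethod
    def from_label(cls, label: str) -> "ToothSite":
        tooth, code = label.split("-")
        surface, position = SITE_CODES[code]
        return cls(int(tooth), surface, position)

    @property
    def bilateral_label(self) -> str:
        """Label of the mirrored left+right pair this site belongs to."""
        return f"{self.tooth_type.label}-{_CODE_OF[(self.surface, self.position)]}"


def full_dentition_sites(exclude_molars: bool = False) -> list[ToothSite]:
    """All sites of a complete dentition in canonical order.

    168 sites, or 120 when first and second molars (FDI ranks 6-7) are
    excluded.
    """
    max_rank = 5 if exclude_molars else 7
    sites = []
    for quadrant in (1, 2, 3, 4):
        for rank in range(1, max_rank + 1):
            for surface in SURFACES:
                for position in POSITIONS:
                    sites.append(ToothSite(quadrant * 10 + rank, surface, position))
    return sites


@dataclass(frozen=True)
class SiteMeasurement:
    """Clinical readings at one probing site.

    CAL and PD are integer millimetres (periodontal probes read in 1-mm
    steps).  CAL may be smaller than PD - 1 (gingival hyperplasia) or much
    larger (recession); no coupling is enforced.  Mobility is a property of
    the tooth and is replicated across its six sites.
    """

    cal_mm: int
    pd_mm: int
    bop: bool
    pli: int
    mobility: int

    def __post_init__(self) -> None:
        if self.cal_mm < 0:
            raise InvalidMeasurementError(f"CAL must be >= 0 mm, got {self.cal_mm}")
        if self.pd_mm < 1:
            raise InvalidMeasurementError(f"PD must be >= 1 mm, got {self.pd_mm}")
        if self.pli not in range(4):
            raise InvalidMeasurementError(f"plaque index must be 0-3, got {self.pli}")
        if self.mobility not in range(4):
            raise InvalidMeasurementError(f"mobility must be 0-3, got {self.mobility}")


@dataclass
class PeriodontalChart:
    """One patient's full-mouth examination.

    Missing teeth are simply absent from ``sites``.  A tooth is either
    present with all six sites or absent entirely; at least 20 teeth must be
    present (the cohort inclusion criterion this package models).
    """

    patient_id: str
    sites: dict[ToothSite, SiteMeasurement]
    #: relax the >= 20 teeth inclusion criterion (e.g. toy charts); the
    #: per-tooth structural rules always apply
    enforce_min_teeth: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        by_tooth: dict[int, list[ToothSite]] = {}
        for site in self.sites:
            by_tooth.setdefault(site.tooth, []).append(site)
        if self.enforce_min_teeth and len(by_tooth) < 20:
            raise ValueError(
                f"chart {self.patient_id!r} has {len(by_tooth)} teeth; at least 20 required"
            )
        for tooth, tsites in by_tooth.items():
            if len(tsites) != 6:
                raise ValueError(
                    f"chart {self.patient_id!r}: tooth {tooth} has {len(tsites)} sites, expected 6"
                )
            mobilities = {self.sites[s].mobility for s in tsites}
            if len(mobilities) != 1:
                raise ValueError(
                    f"chart {self.patient_id!r}: tooth {tooth} has inconsistent mobility"
                )

    @property
    def teeth(self) -> list[int]:
        return sorted({s.tooth for s in self.sites})

    @property
    def n_teeth(self) -> int:
        return len(self.teeth)


@dataclass(frozen=True)
class CategorizationConfig:
    """Thresholds mapping mm readings to the three ordinal severity levels.

    With the default (4, 5) a reading is category 0 below 4 mm, category 1
    at 4-5 mm and category 2 above 5 mm.  A (4, 6) variant — category 1
    spanning 4-6 mm — is supported through the same fields.
    """

    lower_mm: int = 4
    upper_mm: int = 5

    def __post_init__(self) -> None:
        if not self.lower_mm < self.upper_mm:
            raise ValueError("lower_mm must be strictly below upper_mm")


def categorize_value(value_mm: int, config: CategorizationConfig | None = None) -> int:
    """Map a CAL or PD reading (mm) to ordinal category 0, 1 or 2."""
    if config is None:
        config = CategorizationConfig()
    if value_mm < 0:
        raise InvalidMeasurementError(f"measurement must be >= 0 mm, got {value_mm}")
    if value_mm < config.lower_mm:
        return 0
    if value_mm <= config.upper_mm:
        return 1
    return 2


MISSING = -1


def merge_bilateral(left: int | None, right: int | None) -> int | None:
    """Combine the categories of a mirrored site pair into one variable.

    The combined level is the worse (maximum) of the two sides: the pair is
    at the top level if at least one side is, at the middle level if at
    least one side is (and none higher), and at the bottom level only when
    both sides are.  A missing side is ignored; the result is missing only
    if both sides are missing.
    """
    vals = [v for v in (left, right) if v is not None and v != MISSING]
    if not vals:
        return None
    return max(vals)


@dataclass
class OrdinalResponseMatrix:
    """Subjects x items ordinal category codes, the graded-model input.

    ``responses`` uses integer codes ``0..n_categories[j]-1`` with ``-1``
    marking a missing response (absent tooth).  ``item_sites`` optionally
    records the concrete probing site(s) behind each column.
    """

    subjects: list[str]
    items: list[str]
    responses: np.ndarray
    n_categories: np.ndarray
    item_sites: list[tuple[ToothSite, ...]] | None = None
    #: monotone old-code -> new-code maps set by collapse_sparse_categories
    category_maps: list[np.ndarray] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=int)
        self.n_categories = np.asarray(self.n_categories, dtype=int)
        n, j = self.responses.shape
        if n != len(self.subjects) or j != len(self.items):
            raise ValueError("responses shape does not match subjects/items")
        if len(self.n_categories) != j:
            raise ValueError("n_categories length does not match items")
        for col in range(j):
            obs = self.responses[:, col]
            obs = obs[obs != MISSING]
            if obs.size and (obs.min() < 0 or obs.max() >= self.n_categories[col]):
                raise ValueError(f"item {self.items[col]!r} has out-of-range codes")

    @property
    def shape(self) -> tuple[int, int]:
        return self.responses.shape

    def observed_categories(self, col: int) -> np.ndarray:
        obs = self.responses[:, col]
        return np.unique(obs[obs != MISSING])

    def collapse_sparse_categories(self) -> "OrdinalResponseMatrix":
        """Renumber each item's codes so every category is observed.

        Unobserved categories are removed and the remaining ones renumbered
        contiguously; items left with fewer than two observed categories are
        dropped.  Used by pipelines before model fitting so that every
        retained item is estimable.
        """
        keep_cols: list[int] = []
        new_resp = self.responses.copy()
        new_ncat = self.n_categories.copy()
        maps: list[np.ndarray] = []
        for col in range(len(self.items)):
            obs = self.observed_categories(col)
            if obs.size < 2:
                continue
            # monotone map defined for every original code: an unobserved
            # code falls back to the nearest observed one below it
            full_map = np.clip(
                np.searchsorted(obs, np.arange(self.n_categories[col]), side="right") - 1,
                0,
                obs.size - 1,
            )
            mask = new_resp[:, col] != MISSING
            new_resp[mask, col] = full_map[new_resp[mask, col]]
            new_ncat[col] = obs.size
            keep_cols.append(col)
            maps.append(full_map)
        return OrdinalResponseMatrix(
            subjects=list(self.subjects),
            items=[self.items[c] for c in keep_cols],
            responses=new_resp[:, keep_cols],
            n_categories=new_ncat[keep_cols],
            item_sites=(
                [self.item_sites[c] for c in keep_cols] if self.item_sites else None
            ),
            category_maps=maps,
        )


PARAMETERS = ("CAL", "PD", "BOP", "PlI", "mobility")


def _site_code(m: SiteMeasurement, parameter: str, config: CategorizationConfig) -> int:
    if parameter == "CAL":
        return categorize_value(m.cal_mm, config)
    if parameter == "PD":
        return categorize_value(m.pd_mm, config)
    if parameter == "BOP":
        return int(m.bop)
    if parameter == "PlI":
        return min(m.pli, 2)  # 0 / 1 / >=2
    if parameter == "mobility":
        return min(m.mobility, 2)
    raise ValueError(f"unknown clinical parameter {parameter!r}")


def chart_to_response_matrix(
    charts: Sequence[PeriodontalChart],
    sites: Sequence[ToothSite],
    parameter: str = "CAL",
    config: CategorizationConfig | None = None,
    bilateral: bool = False,
) -> OrdinalResponseMatrix:
    """Build the ordinal item-response matrix for one clinical parameter.

    One column per site, or per mirrored left/right pair when ``bilateral``
    (the pair's code is :func:`merge_bilateral` of the two sides).  CAL and
    PD are categorized into three levels via ``config``; BOP is binary; the
    0-3 plaque-index and mobility scales are collapsed to three ordered
    levels (0, 1, >=2).  Missing teeth yield missing responses.
    """
    if not sites:
        raise ValueError("site list is empty")
    if parameter not in PARAMETERS:
        raise ValueError(f"unknown clinical parameter {parameter!r}")
    config = config or CategorizationConfig()
    n_cat = 2 if parameter == "BOP" else 3

    site_set = set(sites)
    if bilateral:
        if any(s.mirror() not in site_set for s in sites):
            raise ValueError("bilateral=True requires a site list closed under mirroring")
        # one column per pair, keyed by the right-side member, canonical order
        rights = sorted(s for s in sites if s.is_right)
        columns: list[tuple[ToothSite, ...]] = [(s, s.mirror()) for s in rights]
        labels = [s.bilateral_label for s in rights]
    else:
        columns = [(s,) for s in sites]
        labels = [s.label for s in sites]

    resp = np.full((len(charts), len(columns)), MISSING, dtype=int)
    for i, chart in enumerate(charts):
        for j, col_sites in enumerate(columns):
            codes = [
                _site_code(chart.sites[s], parameter, config)
                for s in col_sites
                if s in chart.sites
            ]
            if codes:
                resp[i, j] = max(codes) if len(col_sites) > 1 else codes[0]

    for j, lab in enumerate(labels):
        if np.all(resp[:, j] == MISSING):
            raise EmptyItemError(f"site {lab!r} is absent from every chart")

    return OrdinalResponseMatrix(
        subjects=[c.patient_id for c in charts],
        items=labels,
        responses=resp,
        n_categories=np.full(len(columns), n_cat),
        item_sites=columns,
    )


def summary_stats(chart: PeriodontalChart) -> dict[str, float]:
    """Whole-mouth summary statistics for one chart.

    Returns mean CAL and PD (mm), BOP% (0-100), mean plaque index, maximum
    CAL, and the extent (proportion of sites with CAL >= 4 mm).
    """
    if not chart.sites:
        raise ValueError("chart has no sites")
    cal = np.array([m.cal_mm for m in chart.sites.values()], dtype=float)
    pd_ = np.array([m.pd_mm for m in chart.sites.values()], dtype=float)
    bop = np.array([m.bop for m in chart.sites.values()], dtype=float)
    pli = np.array([m.pli for m in chart.sites.values()], dtype=float)
    return {
        "mean_cal": float(cal.mean()),
        "mean_pd": float(pd_.mean()),
        "bop_pct": float(100.0 * bop.mean()),
        "mean_pli": float(pli.mean()),
        "max_cal": float(cal.max()),
        "extent_cal_ge4": float((cal >= 4).mean()),
    }
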