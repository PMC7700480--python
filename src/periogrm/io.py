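"""Chart CSV reading/writing and run manifests.

The chart interchange format is a long CSV, one row per probing site::

    patient_id,tooth_fdi,site,cal_mm,pd_mm,bop,pli,mobility

with ``site`` one of MB, B, DB, ML, L, DL.  Missing teeth are absent rows.
Every artifact-producing run writes a JSON manifest capturing the command,
configuration hash, seed and package version, sufficient to reproduce the
outputs bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .chart import SITE_CODES, PeriodontalChart, SiteMeasurement, ToothSite

__all__ = [
    "CHART_COLUMNS",
    "ChartValidationError",
    "read_chart_csv",
    "write_chart_csv",
    "RunManifest",
    "write_manifest",
]

CHART_COLUMNS = ["patient_id", "tooth_fdi", "site", "cal_mm", "pd_mm", "bop", "pli", "mobility"]


class ChartValidationError(ValueError):
    """A chart CSV failed validation; the message names offending rows."""


def read_chart_csv(path: str | Path) -> list[PeriodontalChart]:
    """Read and validate a long-format chart CSV.

    Row order is irrelevant; charts are returned in order of first
    appearance.  Any malformed value raises :class:`ChartValidationError`
    naming the file row (1-based, excluding the header).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing_cols = [c for c in CHART_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ChartValidationError(f"{path}: missing columns {missing_cols}")

    records: dict[str, dict[ToothSite, SiteMeasurement]] = {}
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        try:
            code = str(row.site).strip()
            if code not in SITE_CODES:
                raise ValueError(f"unknown site code {code!r}")
            surface, position = SITE_CODES[code]
            site = ToothSite(int(row.tooth_fdi), surface, position)
            meas = SiteMeasurement(
                cal_mm=_as_int(row.cal_mm, "cal_mm"),
                pd_mm=_as_int(row.pd_mm, "pd_mm"),
                bop=bool(_as_int(row.bop, "bop")),
                pli=_as_int(row.pli, "pli"),
                mobility=_as_int(row.mobility, "mobility"),
            )
        except (ValueError, TypeError) as exc:
            raise ChartValidationError(f"{path}, data row {idx}: {exc}") from exc
        sites = records.setdefault(str(row.patient_id), {})
        if site in sites:
            raise ChartValidationError(
                f"{path}, data row {idx}: duplicate site {site.label} for patient {row.patient_id!r}"
            )
        sites[site] = meas

    charts = []
    for pid, sites in records.items():
        try:
            charts.append(PeriodontalChart(patient_id=pid, sites=sites))
        except ValueError as exc:
            raise ChartValidationError(f"{path}: patient {pid!r}: {exc}") from exc
    return charts


def _as_int(value, name: str) -> int:
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise ValueError(f"non-numeric {name}: {value!r}")
    if f != int(f):
        raise ValueError(f"non-integer {name}: {value!r} (probes read in whole mm)")
    return int(f)


_CODE_OF = {v: k for k, v in SITE_CODES.items()}


def write_chart_csv(charts: list[PeriodontalChart], path: str | Path) -> None:
    """Write charts in the long CSV format (canonical site order)."""
    rows = []
    for chart in charts:
        for site in sorted(chart.sites):
            m = chart.sites[site]
            rows.append(
                {
                    "patient_id": chart.patient_id,
                    "tooth_fdi": site.tooth,
                    "site": _CODE_OF[(site.surface, site.position)],
                    "cal_mm": m.cal_mm,
                    "pd_mm": m.pd_mm,
                    "bop": int(m.bop),
                    "pli": m.pli,
                    "mobility": m.mobility,
                }
            )
    pd.DataFrame(rows, columns=CHART_COLUMNS).to_csv(path, index=False)


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record of one artifact-producing run."""

    command: str
    config: dict
    config_hash: str
    seed: int | None
    inputs: list[str]
    outputs: list[str]
    package_version: str
    timestamp: str

    @classmethod
    def create(
        cls,
        command: str,
        config: dict,
        seed: int | None,
        inputs: list[str],
        outputs: list[str],
    ) -> "RunManifest":
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        return cls(
            command=command,
            config=config,
            config_hash=hashlib.sha256(blob).hexdigest()[:16],
            seed=seed,
            inputs=[str(p) for p in inputs],
            outputs=[str(p) for p in outputs],
            package_version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(),
        )


def write_manifest(manifest: RunManifest, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(dataclasses.asdict(manifest), indent=2, default=str))
    return path
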