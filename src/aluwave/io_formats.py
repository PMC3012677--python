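"""Peak-table ingest, size-standard calibration, and region reports.

Fragment analyzers export called peaks as delimited text with, at minimum,
the peak position in instrument datapoints, height and area (fluorescence
arbitrary units) and the dye label.  Column names vary by vendor, so the
reader takes a column-mapping dialect.  A co-electrophoresed size standard
(known fragment lengths at measured datapoints) calibrates datapoints to
base pairs; we interpolate piecewise-linearly between standard knots, the
simplest monotone choice.

Coordinates are 0-based continuous bp internally; region reports print
1-based inclusive intervals (a dyadic support [392, 396) prints "393-396").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .discriminant import COUPLES, ClassifyingRegion

logger = logging.getLogger(__name__)

#: default column names of the peak-table dialect
DEFAULT_DIALECT = {
    "position_dp": "position_dp",
    "height": "height",
    "area": "area",
    "channel": "channel",
    "sample": "sample",
    "replicate": "replicate",
}


@dataclass
class RawPeakRecord:
    """One called peak as exported by the instrument."""

    position_dp: float
    height: float
    area: float
    channel: str
    sample_id: str
    replicate_id: int
    position_bp: float | None = None
    in_calibration: bool = True

    @property
    def length(self) -> float:
        """Peak length, the area-to-height ratio (a reproducible shape index)."""
        return self.area / self.height


@dataclass
class SizeStandard:
    """Datapoint -> bp calibration knots, strictly increasing in both axes."""

    points: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("size standard needs at least 2 points")
        dp = np.array([p[0] for p in self.points], dtype=float)
        bp = np.array([p[1] for p in self.points], dtype=float)
        if np.any(np.diff(dp) <= 0) or np.any(np.diff(bp) <= 0):
            raise ValueError("size standard must be strictly increasing in dp and bp")
        self._dp, self._bp = dp, bp

    def to_bp(self, position_dp: np.ndarray) -> np.ndarray:
        return np.interp(position_dp, self._dp, self._bp)

    def to_dp(self, position_bp: np.ndarray) -> np.ndarray:
        return np.interp(position_bp, self._bp, self._dp)

    def in_range(self, position_dp: np.ndarray) -> np.ndarray:
        return (np.asarray(position_dp) >= self._dp[0]) & (
            np.asarray(position_dp) <= self._dp[-1]
        )

    @classmethod
    def read(cls, path: str | Path) -> "SizeStandard":
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError(f"size standard {path} must have 2 columns")
        return cls(points=list(zip(df.iloc[:, 0], df.iloc[:, 1])))

    def write(self, path: str | Path) -> None:
        pd.DataFrame(self.points, columns=["position_dp", "size_bp"]).to_csv(
            path, index=False
        )


def read_peak_table(
    path: str | Path, dialect: dict[str, str] | None = None
) -> list[RawPeakRecord]:
    """Read a delimited peak table into records, dropping non-positive peaks.

    ``dialect`` maps the canonical field names (keys of
    :data:`DEFAULT_DIALECT`) to the file's column names.  The delimiter is
    sniffed (comma or tab).  Rows with height <= 0 or area <= 0 are dropped
    and counted in the log.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cols = dict(DEFAULT_DIALECT, **(dialect or {}))
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: cannot resolve columns {missing} in {list(df.columns)}")
    if df.empty:
        raise ValueError(f"{path}: empty peak table")

    ok = (df[cols["height"]] > 0) & (df[cols["area"]] > 0)
    dropped = int((~ok).sum())
    if dropped:
        logger.info("%s: dropped %d rows with non-positive height/area", path, dropped)
    records = [
        RawPeakRecord(
            position_dp=float(row[cols["position_dp"]]),
            height=float(row[cols["height"]]),
            area=float(row[cols["area"]]),
            channel=str(row[cols["channel"]]),
            sample_id=str(row[cols["sample"]]),
            replicate_id=int(row[cols["replicate"]]),
        )
        for _, row in df[ok].iterrows()
    ]
    return records


def map_datapoints_to_bp(
    records: list[RawPeakRecord], standard: SizeStandard
) -> list[RawPeakRecord]:
    """Attach interpolated bp positions; flag records outside the standard.

    Out-of-range records keep ``position_bp=None`` and are marked
    ``in_calibration=False`` so downstream stages can exclude them.
    """
    dp = np.array([r.position_dp for r in records])
    if dp.size == 0:
        return records
    bp = standard.to_bp(dp)
    inside = standard.in_range(dp)
    for r, b, ok in zip(records, bp, inside):
        r.in_calibration = bool(ok)
        r.position_bp = float(b) if ok else None
    n_out = int((~inside).sum())
    if n_out:
        logger.info("%d peaks outside the size-standard range flagged", n_out)
    return records


def format_interval(interval_bp: tuple[float, float]) -> str:
    """Render a 0-based half-open bp interval as 1-based inclusive text."""
    lo, hi = interval_bp
    return f"{int(np.floor(lo)) + 1}-{int(np.ceil(hi))}"


def parse_interval(text: str) -> tuple[float, float]:
    lo, hi = text.split("-")
    return (float(int(lo) - 1), float(int(hi)))


def write_region_report(
    regions: list[ClassifyingRegion], path: str | Path
) -> None:
    """Write one CSV row per region per couple (long layout, round-trippable)."""
    rows = []
    for rid, reg in enumerate(regions):
        for couple in COUPLES:
            rows.append(
                {
                    "channel": reg.channel,
                    "region_id": rid,
                    "couple": couple,
                    "region_bp": format_interval(reg.couple_intervals[couple]),
                    "K": round(reg.couple_K[couple], 4),
                    "global": reg.is_global,
                }
            )
    pd.DataFrame(
        rows, columns=["channel", "region_id", "couple", "region_bp", "K", "global"]
    ).to_csv(path, index=False)


def read_region_report(path: str | Path) -> list[ClassifyingRegion]:
    df = pd.read_csv(path)
    regions = []
    if df.empty:
        return regions
    for (_, _), grp in df.groupby(["channel", "region_id"], sort=True):
        regions.append(
            ClassifyingRegion(
                channel=str(grp["channel"].iloc[0]),
                couple_intervals={
                    int(r["couple"]): parse_interval(r["region_bp"])
                    for _, r in grp.iterrows()
                },
                couple_K={int(r["couple"]): float(r["K"]) for _, r in grp.iterrows()},
                is_global=bool(grp["global"].iloc[0]),
            )
        )
    return regions
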