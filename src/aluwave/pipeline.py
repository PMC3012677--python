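"""End-to-end orchestration: peak tables -> union tracks -> regions.

Stages run per dye channel, fully independently: ingest and calibration,
noise reduction, replicate union, Gaussian reconstruction, Haar-Walsh WPT,
twin-contrast selection, global classifying regions.  Every run emits a
manifest (configuration snapshot, inputs, per-stage record counts) that
suffices to reproduce it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .discriminant import (
    COUPLES,
    TWINS,
    ClassifyingRegion,
    CohortCoefficients,
    DiscriminantConfig,
    global_classifying_regions,
)
from .io_formats import RawPeakRecord, SizeStandard, map_datapoints_to_bp, read_peak_table
from .preprocessing import (
    DEFAULT_CUTOFF_FRACTION,
    DEFAULT_MAX_BP,
    DEFAULT_MIN_BP,
    DEFAULT_UNION_TOLERANCE_BP,
    DEFAULT_WINDOW_BP,
    ReplicateTrack,
    UnionTrack,
    align_and_unite_replicates,
    filter_size_range,
    local_amplitude_cutoff,
)
from .reconstruction import reconstruct_signal
from .wpt import haar_wpt_forward

logger = logging.getLogger(__name__)

#: sample-id convention: couple 1..3, twin a/b
SAMPLE_IDS = tuple(f"c{k}{t}" for k in COUPLES for t in TWINS)


@dataclass
class PipelineConfig:
    min_bp: float = DEFAULT_MIN_BP
    max_bp: float = DEFAULT_MAX_BP
    window_bp: float = DEFAULT_WINDOW_BP
    cutoff_fraction: float = DEFAULT_CUTOFF_FRACTION
    cutoff_mode: str = "sliding"
    union_tolerance_bp: float = DEFAULT_UNION_TOLERANCE_BP
    delta: float = 1.0 / 3.0
    depth_min: int = 6
    depth_max: int = 11
    channels: tuple[str, ...] | None = None  # None = every channel present

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.min_bp >= self.max_bp:
            raise ValueError("min_bp must be < max_bp")
        if self.window_bp <= 0 or not 0 < self.cutoff_fraction < 1:
            raise ValueError("invalid cut-off configuration")
        if self.union_tolerance_bp <= 0:
            raise ValueError("union_tolerance_bp must be positive")
        if not 0 <= self.depth_min <= self.depth_max:
            raise ValueError("invalid depth band")

    def discriminant(self) -> DiscriminantConfig:
        return DiscriminantConfig(
            delta=self.delta, depth_min=self.depth_min, depth_max=self.depth_max
        )


def records_to_tracks(records: list[RawPeakRecord]) -> dict[tuple[str, str, int], ReplicateTrack]:
    """Group calibrated records into one track per (channel, sample, replicate)."""
    groups: dict[tuple[str, str, int], list[RawPeakRecord]] = {}
    for r in records:
        if not r.in_calibration or r.position_bp is None:
            continue
        groups.setdefault((r.channel, r.sample_id, r.replicate_id), []).append(r)
    return {
        key: ReplicateTrack(
            sample_id=key[1],
            replicate_id=key[2],
            channel=key[0],
            positions=np.array([r.position_bp for r in grp]),
            heights=np.array([r.height for r in grp]),
        )
        for key, grp in groups.items()
    }


def preprocess_tracks(
    tracks: dict[tuple[str, str, int], ReplicateTrack], config: PipelineConfig
) -> dict[tuple[str, str], UnionTrack]:
    """Size filter, local cut-off and replicate union, per channel x sample."""
    filtered: dict[tuple[str, str], list[ReplicateTrack]] = {}
    for (channel, sample, _rep), track in sorted(tracks.items()):
        t = filter_size_range(track, config.min_bp, config.max_bp)
        t = local_amplitude_cutoff(
            t, config.window_bp, config.cutoff_fraction, mode=config.cutoff_mode
        )
        filtered.setdefault((channel, sample), []).append(t)
    return {
        key: align_and_unite_replicates(reps, config.union_tolerance_bp)
        for key, reps in filtered.items()
    }


def unions_to_frame(unions: dict[tuple[str, str], UnionTrack]) -> pd.DataFrame:
    rows = [
        {
            "channel": channel,
            "sample": sample,
            "position_bp": float(p),
            "support_count": int(s),
        }
        for (channel, sample), u in sorted(unions.items())
        for p, s in zip(u.positions, u.support_counts)
    ]
    return pd.DataFrame(
        rows, columns=["channel", "sample", "position_bp", "support_count"]
    )


def frame_to_unions(df: pd.DataFrame) -> dict[tuple[str, str], UnionTrack]:
    unions = {}
    for (channel, sample), grp in df.groupby(["channel", "sample"], sort=True):
        unions[(str(channel), str(sample))] = UnionTrack(
            sample_id=str(sample),
            channel=str(channel),
            positions=grp["position_bp"].to_numpy(),
            support_counts=grp["support_count"].to_numpy(),
        )
    return unions


def _parse_sample_id(sample: str) -> tuple[int, str]:
    if len(sample) == 3 and sample[0] == "c" and sample[1] in "123" and sample[2] in "ab":
        return int(sample[1]), sample[2]
    raise ValueError(f"sample id {sample!r} does not follow the c<couple><twin> layout")


def analyze_unions(
    unions: dict[tuple[str, str], UnionTrack], config: PipelineConfig
) -> list[ClassifyingRegion]:
    """WPT + twin-contrast discriminant on the union tracks, per channel."""
    channels = sorted({ch for ch, _ in unions})
    if config.channels is not None:
        channels = [ch for ch in channels if ch in config.channels]
    disc = config.discriminant()
    regions: list[ClassifyingRegion] = []
    for channel in channels:
        tables = {}
        for sample in SAMPLE_IDS:
            if (channel, sample) not in unions:
                raise ValueError(f"cohort incomplete: no union track for {sample}/{channel}")
            signal = reconstruct_signal(unions[(channel, sample)])
            tables[_parse_sample_id(sample)] = haar_wpt_forward(
                signal.values, max_depth=config.depth_max
            )
        cohort = CohortCoefficients(tables=tables, channel=channel)
        regions.extend(global_classifying_regions(cohort, disc))
    return regions


def run_pipeline(
    peaks_path: str | Path,
    standard_path: str | Path,
    config: PipelineConfig | None = None,
) -> tuple[list[ClassifyingRegion], dict]:
    """Full analysis of one cohort; returns regions and the run manifest."""
    config = config or PipelineConfig()
    records = read_peak_table(peaks_path)
    standard = SizeStandard.read(standard_path)
    records = map_datapoints_to_bp(records, standard)
    tracks = records_to_tracks(records)
    unions = preprocess_tracks(tracks, config)
    regions = analyze_unions(unions, config)
    manifest = {
        "software": {"name": "aluwave", "version": __version__},
        "inputs": {"peaks": str(peaks_path), "size_standard": str(standard_path)},
        "config": asdict(config),
        "counts": {
            "peak_records": len(records),
            "calibrated_records": sum(r.in_calibration for r in records),
            "replicate_tracks": len(tracks),
            "union_tracks": len(unions),
            "union_peaks": int(sum(len(u) for u in unions.values())),
            "global_regions": len(regions),
        },
    }
    return regions, manifest


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
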