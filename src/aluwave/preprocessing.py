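"""Noise reduction for replicate peak tracks.

Three stages, applied per dye channel in this order:

1. size-range restriction (default 50-1000 bp; longer inter-Alu fragments
   separate poorly and short ones fall below the primer products);
2. a local amplitude cut-off that removes peaks smaller than a fraction
   (default 10%) of the largest peak within a sliding 250 bp window —
   amplification efficiency drifts with fragment length on a ~300 bp scale,
   so the reference amplitude must be local;
3. an OR-union of the (up to four) experimental replicates: peaks are
   clustered across replicates within a 5 bp alignment tolerance and each
   cluster becomes one consensus peak at the mean member position.

The union keeps a peak seen in a single replicate (logical OR); averaging the
member positions pushes the statistical error of the consensus position well
below the 5 bp single-measurement tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_MIN_BP = 50.0
DEFAULT_MAX_BP = 1000.0
DEFAULT_WINDOW_BP = 250.0
DEFAULT_CUTOFF_FRACTION = 0.10
DEFAULT_UNION_TOLERANCE_BP = 5.0


@dataclass
class ReplicateTrack:
    """Peak list of one sample x replicate x channel, sorted by position."""

    sample_id: str
    replicate_id: int
    channel: str
    positions: np.ndarray
    heights: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.positions.shape != self.heights.shape:
            raise ValueError("positions and heights must align")
        order = np.argsort(self.positions, kind="stable")
        self.positions = self.positions[order]
        self.heights = self.heights[order]

    def __len__(self) -> int:
        return self.positions.size

    def replace(self, keep: np.ndarray) -> "ReplicateTrack":
        return ReplicateTrack(
            self.sample_id,
            self.replicate_id,
            self.channel,
            self.positions[keep],
            self.heights[keep],
        )


@dataclass
class UnionTrack:
    """Consensus peak list of one sample x channel after the replicate OR-union.

    ``support_counts[i]`` is the number of replicates contributing to peak
    ``i`` (diagnostic only; downstream stages use positions alone).
    """

    sample_id: str
    channel: str
    positions: np.ndarray
    support_counts: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.support_counts = np.asarray(self.support_counts, dtype=int)
        order = np.argsort(self.positions, kind="stable")
        self.positions = self.positions[order]
        self.support_counts = self.support_counts[order]

    def __len__(self) -> int:
        return self.positions.size


def filter_size_range(
    track: ReplicateTrack,
    min_bp: float = DEFAULT_MIN_BP,
    max_bp: float = DEFAULT_MAX_BP,
) -> ReplicateTrack:
    """Keep peaks with ``min_bp <= position <= max_bp``."""
    if min_bp >= max_bp:
        raise ValueError(f"min_bp {min_bp} must be < max_bp {max_bp}")
    keep = (track.positions >= min_bp) & (track.positions <= max_bp)
    return track.replace(keep)


def local_amplitude_cutoff(
    track: ReplicateTrack,
    window_bp: float = DEFAULT_WINDOW_BP,
    fraction: float = DEFAULT_CUTOFF_FRACTION,
    mode: str = "sliding",
) -> ReplicateTrack:
    """Drop peaks below ``fraction`` of the local maximum height.

    ``mode='sliding'`` centres a window of width ``window_bp`` on each peak;
    ``mode='tiled'`` partitions the axis into fixed ``window_bp`` tiles.  The
    reference maximum is always computed on the *input* track, so removal of
    one small peak never changes another peak's threshold, and the retained
    set is invariant under rescaling all heights by a positive constant.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    if len(track) == 0:
        return track
    pos, h = track.positions, track.heights
    if mode == "sliding":
        half = window_bp / 2.0
        lo = np.searchsorted(pos, pos - half, side="left")
        hi = np.searchsorted(pos, pos + half, side="right")
        local_max = np.array([h[a:b].max() for a, b in zip(lo, hi)])
    elif mode == "tiled":
        tile = np.floor(pos / window_bp).astype(int)
        local_max = np.empty_like(h)
        for t in np.unique(tile):
            m = tile == t
            local_max[m] = h[m].max()
    else:
        raise ValueError(f"unknown cutoff mode {mode!r}")
    keep = h >= fraction * local_max
    return track.replace(keep)


def align_and_unite_replicates(
    tracks: list[ReplicateTrack],
    tolerance_bp: float = DEFAULT_UNION_TOLERANCE_BP,
) -> UnionTrack:
    """OR-union of replicate tracks with a local alignment tolerance.

    All peaks from all replicates are pooled and swept left to right,
    growing one cluster at a time: the next pooled peak joins the open
    cluster while it lies within ``tolerance_bp`` of the cluster's last
    (nearest) member and its replicate is not yet represented; otherwise it
    starts a new cluster.  Nearest-member linkage keeps the four jittered
    calls of one locus together even when they span more than the tolerance
    end to end, while the one-peak-per-replicate rule still resolves
    neighbouring loci.  Each cluster becomes one union peak at the
    arithmetic mean of its members' positions, with the number of
    contributing replicates as its support.  Deterministic and independent
    of the order in which the replicate tracks are given.
    """
    if not tracks:
        raise ValueError("at least one replicate track is required")
    sample_ids = {t.sample_id for t in tracks}
    channels = {t.channel for t in tracks}
    if len(sample_ids) != 1 or len(channels) != 1:
        raise ValueError(f"mixed sample/channel in union: {sample_ids}, {channels}")
    if tolerance_bp <= 0:
        raise ValueError("tolerance_bp must be positive")

    pos = np.concatenate([t.positions for t in tracks])
    rep = np.concatenate(
        [np.full(len(t), t.replicate_id, dtype=int) for t in tracks]
    )
    order = np.lexsort((rep, pos))  # position first; replicate id breaks ties
    pos, rep = pos[order], rep[order]

    centers: list[float] = []
    supports: list[int] = []
    members: list[float] = []
    member_reps: set[int] = set()

    def close_cluster() -> None:
        centers.append(float(np.mean(members)))
        supports.append(len(member_reps))
        members.clear()
        member_reps.clear()

    for p, r in zip(pos, rep):
        if members and (p - members[-1] > tolerance_bp or r in member_reps):
            close_cluster()
        members.append(float(p))
        member_reps.add(int(r))
    if members:
        close_cluster()

    return UnionTrack(
        sample_id=next(iter(sample_ids)),
        channel=next(iter(channels)),
        positions=np.array(centers),
        support_counts=np.array(supports, dtype=int),
    )
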