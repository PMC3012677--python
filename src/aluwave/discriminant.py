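"""Twin-contrast coefficient selection and global classifying regions.

The cohort is three couples of monozygotic twins; twins share a genome, so
any reproducible within-couple difference in their fingerprints measures pure
experimental variability.  A wavelet packet coefficient classifies the
reference couple ``r`` against the others when its smallest cross-couple
contrast exceeds the within-couple contrast by at least ``delta``:

    K(j, i) = [ min_{k != r; x, y in {a, b}} |c_rx(j,i) - c_ky(j,i)|
                - |c_ra(j,i) - c_rb(j,i)| ] / A(j, i)      select iff K >= delta

``A(j, i)`` expresses the score in *peak-area units*.  A depth-``j``
Haar-Walsh packet takes values ``+/- 2**(-j/2)``, so multiplying a
coefficient by ``2**(j/2)`` turns it into a signed area of the signal over
the packet's support; that signed-area contrast is then divided by the
signal area the support actually analyses — the cohort-mean signal
integrated over the support, floored at the sampled area of one standard
Gaussian peak (``32 * sqrt(2*pi)`` samples).  A single standard peak wholly
present in the reference couple and absent in both other couples therefore
scores exactly K = 1, while in a support holding n peaks the pattern
difference must exceed ``delta`` times the *total* signal area under it.

Selected coefficients are redundant across nested dyadic supports; the
refinement step keeps, per maximal nested chain, the most localised support
still passing the threshold.  A *global classifying region* is a maximal
stretch of the fingerprint covered — within the peak-alignment tolerance —
by passing coefficients of all three reference runs simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .reconstruction import PEAK_AREA_UNIT, SAMPLES_PER_BP
from .wpt import CoefficientIndex, WPTTable

COUPLES = (1, 2, 3)
TWINS = ("a", "b")

DEFAULT_DELTA = 1.0 / 3.0
DEFAULT_DEPTH_MIN = 6   # support 2 bp
DEFAULT_DEPTH_MAX = 11  # support 64 bp


@dataclass
class DiscriminantConfig:
    """Tunables of the selection criterion."""

    delta: float = DEFAULT_DELTA
    depth_min: int = DEFAULT_DEPTH_MIN
    depth_max: int = DEFAULT_DEPTH_MAX
    peak_area_unit: float = PEAK_AREA_UNIT
    #: optional specificity filter: if > 1, a support only counts toward a
    #: couple's classifying coverage when it sits in a nested chain of
    #: selected supports spanning at least this many distinct depths.
    #: Genuine whole-peak differences are usually scale-stable in area units,
    #: but borderline true effects can be depth-local too, so the filter
    #: trades sensitivity for specificity; off by default.
    min_chain_depths: int = 1
    #: when intersecting the three references' classifying coverage, each
    #: selected support is widened by this much on both sides.  Two supports
    #: closer than the peak-alignment tolerance refer to the same locus
    #: within measurement accuracy, so their references corroborate each
    #: other even when their dyadic intervals do not share a sample.
    coverage_dilation_bp: float = 5.0

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive (delta = 0 selects everything)")
        if self.depth_min > self.depth_max or self.depth_min < 0:
            raise ValueError("invalid depth band")

    def depth_band(self) -> range:
        return range(self.depth_min, self.depth_max + 1)

    def area_norm(self, depth: int) -> float:
        """Peak-area unit at depth ``depth`` (orthonormal-coefficient scale)."""
        return self.peak_area_unit / np.sqrt(float(1 << depth))

    def support_area_norm(self, cohort: "CohortCoefficients", depth: int) -> np.ndarray:
        """Per-coefficient normaliser: signal area inside each support.

        The contrast of a coefficient is measured against the amount of
        signal its support actually analyses: a support holding one peak is
        normalised to one peak-area (so a full single-peak gain/loss scores
        K = 1), while a support holding n peaks demands a pattern difference
        of delta x n peak-areas — a fraction delta of the *total* signal
        area under it.  The area is the cohort-mean signal integrated over
        the support, floored at one peak-area so sparse supports are never
        inflated.  Returned on the orthonormal-coefficient scale, one entry
        per flat coefficient index of the depth row.
        """
        mean_signal = np.mean(
            [cohort.row(k, x, 0) for k in COUPLES for x in TWINS], axis=0
        )
        support = 1 << depth
        area_per_translation = mean_signal.reshape(-1, support).sum(axis=1)
        area = np.maximum(area_per_translation, self.peak_area_unit)
        return np.tile(area, 1 << depth) / np.sqrt(float(support))


@dataclass
class CohortCoefficients:
    """WPT tables of the six union signals of one channel.

    Keyed by ``(couple, twin)`` with couple in 1..3 and twin 'a'/'b'.
    """

    tables: dict[tuple[int, str], WPTTable]
    channel: str = ""

    def __post_init__(self) -> None:
        missing = [key for key in product(COUPLES, TWINS) if key not in self.tables]
        if missing:
            raise ValueError(f"incomplete cohort, missing {missing}")
        Ms = {t.M for t in self.tables.values()}
        depths = {t.max_depth for t in self.tables.values()}
        if len(Ms) != 1 or len(depths) != 1:
            raise ValueError("cohort tables must share signal length and depth")

    @property
    def M(self) -> int:
        return next(iter(self.tables.values())).M

    @property
    def max_depth(self) -> int:
        return next(iter(self.tables.values())).max_depth

    def row(self, couple: int, twin: str, depth: int) -> np.ndarray:
        return self.tables[(couple, twin)].row(depth)


@dataclass
class CoefficientScore:
    reference_couple: int
    idx: CoefficientIndex
    K: float

    def support_samples(self) -> tuple[int, int]:
        size = 1 << self.idx.depth
        return (self.idx.translation * size, (self.idx.translation + 1) * size)

    def support_bp(self) -> tuple[float, float]:
        lo, hi = self.support_samples()
        return (lo / SAMPLES_PER_BP, hi / SAMPLES_PER_BP)


@dataclass
class ClassifyingRegion:
    """One output row: a signal interval with a per-couple score.

    ``couple_intervals[r]`` is reference couple ``r``'s own refined support
    (the three may differ, as in the published tables) and ``couple_K[r]`` the
    score of its surviving smallest-scale coefficient.
    """

    channel: str
    couple_intervals: dict[int, tuple[float, float]]
    couple_K: dict[int, float]
    #: maximal bp stretch covered by passing coefficients of all three
    #: reference runs; wide cores may span several variable loci
    core_interval: tuple[float, float] | None = None
    is_global: bool = True

    def merged_interval(self) -> tuple[float, float]:
        los, his = zip(*self.couple_intervals.values())
        if self.core_interval is not None:
            los += (self.core_interval[0],)
            his += (self.core_interval[1],)
        return (min(los), max(his))


def pair_variability(table_x: WPTTable, table_y: WPTTable) -> list[np.ndarray]:
    """Elementwise ``|c_x - c_y|`` per depth row (criterion numerator parts)."""
    if table_x.M != table_y.M or table_x.max_depth != table_y.max_depth:
        raise ValueError("tables are not conformable")
    return [
        np.abs(rx - ry) for rx, ry in zip(table_x.coeffs, table_y.coeffs)
    ]


def score_rows(
    cohort: CohortCoefficients,
    reference_couple: int,
    config: DiscriminantConfig | None = None,
) -> dict[int, np.ndarray]:
    """K score of every coefficient in the depth band, as one row per depth."""
    config = config or DiscriminantConfig()
    if reference_couple not in COUPLES:
        raise ValueError(f"reference couple must be one of {COUPLES}")
    others = [k for k in COUPLES if k != reference_couple]
    if config.depth_max > cohort.max_depth:
        raise ValueError("depth band exceeds the decomposition depth")

    out: dict[int, np.ndarray] = {}
    for j in config.depth_band():
        ref = {x: cohort.row(reference_couple, x, j) for x in TWINS}
        cross = None
        for k, x, y in product(others, TWINS, TWINS):
            d = np.abs(ref[x] - cohort.row(k, y, j))
            cross = d if cross is None else np.minimum(cross, d)
        within = np.abs(ref["a"] - ref["b"])
        out[j] = (cross - within) / config.support_area_norm(cohort, j)
    return out


def discriminant_score(
    cohort: CohortCoefficients,
    reference_couple: int,
    idx: CoefficientIndex,
    config: DiscriminantConfig | None = None,
) -> float:
    """K of a single coefficient (convenience wrapper over :func:`score_rows`)."""
    config = config or DiscriminantConfig()
    if not config.depth_min <= idx.depth <= config.depth_max:
        raise ValueError(f"depth {idx.depth} outside the configured band")
    rows = score_rows(cohort, reference_couple, config)
    return float(rows[idx.depth][idx.flat(cohort.M)])


def select_coefficients(
    cohort: CohortCoefficients,
    reference_couple: int,
    config: DiscriminantConfig | None = None,
) -> list[CoefficientScore]:
    """All coefficients in the depth band with ``K >= delta``, best first."""
    config = config or DiscriminantConfig()
    M = cohort.M
    rows = score_rows(cohort, reference_couple, config)
    scores: list[CoefficientScore] = []
    for j, K_row in rows.items():
        n_trans = 1 << (M - j)
        for i in np.flatnonzero(K_row >= config.delta):
            idx = CoefficientIndex(depth=j, block=int(i) // n_trans,
                                   translation=int(i) % n_trans)
            scores.append(CoefficientScore(reference_couple, idx, float(K_row[i])))
    scores.sort(key=lambda s: (-s.K, s.idx.depth, s.idx.block, s.idx.translation))
    return scores


def refine_to_smallest_scale(scores: list[CoefficientScore]) -> list[CoefficientScore]:
    """Keep one coefficient per maximal chain of nested supports.

    Dyadic supports are either nested or disjoint, so it suffices to keep the
    *minimal* supports (those containing no other selected support) and, for
    each, the best-scoring coefficient living on it; ties across frequency
    blocks break toward larger K, then lower block index.
    """
    if not scores:
        return []
    refs = {s.reference_couple for s in scores}
    if len(refs) != 1:
        raise ValueError("scores must come from a single reference couple")

    supports = {s.support_samples() for s in scores}
    minimal = {
        sup
        for sup in supports
        if not any(o != sup and sup[0] <= o[0] and o[1] <= sup[1] for o in supports)
    }
    best: dict[tuple[int, int], CoefficientScore] = {}
    for s in scores:
        sup = s.support_samples()
        if sup not in minimal:
            continue
        cur = best.get(sup)
        if cur is None or (s.K, -s.idx.block) > (cur.K, -cur.idx.block):
            best[sup] = s
    return sorted(best.values(), key=lambda s: s.support_samples())


def _chain_confirmed(
    scores: list[CoefficientScore], min_depths: int
) -> list[CoefficientScore]:
    """Scores whose support sits in a nested selected chain of >= min_depths depths.

    Dyadic supports are nested or disjoint, so the chain of a support is the
    set of selected supports containing it or contained in it; the chain's
    depth count is the number of distinct scales represented.
    """
    if min_depths <= 1:
        return scores
    supports = sorted({s.support_samples() for s in scores})
    keep: set[tuple[int, int]] = set()
    for lo, hi in supports:
        depths = {
            hi2 - lo2
            for lo2, hi2 in supports
            if (lo2 <= lo and hi <= hi2) or (lo <= lo2 and hi2 <= hi)
        }
        if len(depths) >= min_depths:
            keep.add((lo, hi))
    return [s for s in scores if s.support_samples() in keep]


def global_classifying_regions(
    cohort: CohortCoefficients,
    config: DiscriminantConfig | None = None,
) -> list[ClassifyingRegion]:
    """Regions that classify all three couples simultaneously.

    Selection runs once per reference couple; each run's selected supports
    (all scales) are merged into that couple's classifying *coverage* of the
    signal axis.  A global region is a maximal stretch covered by all three
    references at once — every point of it is analysed by a passing
    coefficient of every reference run, thanks to the multiscale redundancy
    of the packet table.  Within each such stretch every couple then reports
    its own smallest-scale selected support touching it (ties broken by
    larger K, then lower frequency block).  The three per-couple intervals
    may differ and even be mutually disjoint — couples can be told apart by
    neighbouring sub-intervals of the same variable stretch, as in the
    published-table rows.
    """
    config = config or DiscriminantConfig()
    per_ref = {r: select_coefficients(cohort, r, config) for r in COUPLES}

    n = 1 << cohort.M
    pad = int(round(config.coverage_dilation_bp * SAMPLES_PER_BP))
    covered = np.ones(n, dtype=bool)
    for r, scores in per_ref.items():
        confirmed = _chain_confirmed(scores, config.min_chain_depths)
        per_ref[r] = confirmed
        cover = np.zeros(n, dtype=bool)
        for s in confirmed:
            lo, hi = s.support_samples()
            cover[max(0, lo - pad):hi + pad] = True
        covered &= cover

    # maximal runs of simultaneous three-way coverage
    padded = np.concatenate([[0], covered.astype(np.int8), [0]])
    bounds = np.flatnonzero(np.diff(padded))
    cores = list(zip(bounds[::2].tolist(), bounds[1::2].tolist()))

    regions: list[ClassifyingRegion] = []
    for lo, hi in cores:
        by_ref: dict[int, CoefficientScore] = {}
        complete = True
        for r in COUPLES:
            touching = [
                s
                for s in per_ref[r]
                if s.support_samples()[0] < hi + pad and s.support_samples()[1] > lo - pad
            ]
            if not touching:
                complete = False
                break
            by_ref[r] = min(
                touching, key=lambda s: (s.idx.depth, -s.K, s.idx.block, s.idx.translation)
            )
        if not complete:
            continue
        spb = SAMPLES_PER_BP
        regions.append(
            ClassifyingRegion(
                channel=cohort.channel,
                couple_intervals={r: by_ref[r].support_bp() for r in COUPLES},
                couple_K={r: by_ref[r].K for r in COUPLES},
                core_interval=(lo / spb, hi / spb),
            )
        )
    regions.sort(key=lambda reg: reg.merged_interval())
    return regions
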