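"""Synthetic twin-cohort fingerprints with planted polymorphisms.

No public inter-Alu capillary-electrophoresis dataset exists, so every stage
of the pipeline is exercised on simulated cohorts: three couples of
monozygotic twins, two dye channels, four experimental replicates per sample.
Twins within a couple share identical *true* peak positions (their genomes
are identical); couples differ only at planted polymorphic loci, either by a
couple-specific position offset (length polymorphism) or by peak absence
(amplification-site polymorphism).  Replicate-level noise emulates PCR and
electrophoresis variability:

* position jitter — Gaussian, sd 2.5 bp truncated at +/-5 bp, consistent
  with the 5 bp alignment tolerance of the union procedure;
* peak dropout — each true peak missing from a replicate with small
  probability;
* spurious peaks — low-amplitude false calls, uniform in position, with
  heights a few percent of a typical true peak so the local amplitude
  cut-off can remove them;
* height variation — lognormal multiplicative noise on peak heights.

True locus positions are fixed by the locus list in the configuration; the
simulation seed drives only the noise, so different seeds replay the same
cohort under new experimental error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .discriminant import COUPLES, TWINS, ClassifyingRegion
from .io_formats import SizeStandard

DEFAULT_CHANNELS = ("Tet", "Fam")
#: calibration knots emulating a broad-range internal size standard
DEFAULT_STANDARD = SizeStandard(
    points=[
        (1000 + 15 * bp + 0.001 * bp**2, float(bp))
        for bp in (20, 50, 100, 200, 350, 500, 700, 1000, 1500, 2500)
    ]
)


@dataclass
class LocusSpec:
    """One true locus and its per-couple state.

    ``couple_offsets[k]`` is couple ``k+1``'s position offset from
    ``base_position_bp`` in bp, or ``None`` if the couple lacks the peak.
    All-zero offsets mean a monomorphic (shared) locus.
    """

    base_position_bp: float
    couple_offsets: tuple[float | None, float | None, float | None] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        for off in self.couple_offsets:
            if off is not None and off < 0:
                raise ValueError("offsets must be >= 0")
        if not any(off is not None for off in self.couple_offsets):
            raise ValueError("locus absent in every couple")

    def position_for(self, couple: int) -> float | None:
        off = self.couple_offsets[couple - 1]
        return None if off is None else self.base_position_bp + off

    @property
    def is_polymorphic(self) -> bool:
        return len(set(self.couple_offsets)) > 1

    @property
    def is_global_polymorphic(self) -> bool:
        """Pairwise-distinct states: the locus can separate all three couples."""
        return len(set(self.couple_offsets)) == 3


@dataclass
class NoiseModel:
    position_jitter_sd: float = 2.5
    jitter_truncation_bp: float = 5.0
    dropout_prob: float = 0.05
    spurious_rate_per_100bp: float = 0.2
    height_lognormal_sd: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must be a probability")
        if min(self.position_jitter_sd, self.spurious_rate_per_100bp,
               self.height_lognormal_sd) < 0:
            raise ValueError("noise magnitudes must be >= 0")

    def jitter(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.position_jitter_sd == 0 or n == 0:
            return np.zeros(n)
        a = self.jitter_truncation_bp / self.position_jitter_sd
        return stats.truncnorm.rvs(
            -a, a, scale=self.position_jitter_sd, size=n, random_state=rng
        )


@dataclass
class SimulationConfig:
    loci: list[LocusSpec]
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    replicates: int = 4
    noise: NoiseModel = field(default_factory=NoiseModel)
    standard: SizeStandard = field(default_factory=lambda: DEFAULT_STANDARD)
    typical_height: float = 1000.0
    position_range_bp: tuple[float, float] = (55.0, 995.0)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        lo, hi = self.position_range_bp
        for locus in self.loci:
            for k in COUPLES:
                pos = locus.position_for(k)
                if pos is not None and not lo <= pos <= hi:
                    raise ValueError(f"locus at {pos} bp outside [{lo}, {hi}]")


def random_loci(
    seed: int,
    n_loci: int = 50,
    n_polymorphic: int = 6,
    shift_bp: float = 8.0,
    mixed_fraction: float = 0.0,
    min_spacing_bp: float = 8.0,
    poly_clearance_bp: float = 26.0,
    position_range_bp: tuple[float, float] = (60.0, 985.0),
) -> list[LocusSpec]:
    """Draw a realistic locus set: ~50 loci per channel, a few polymorphic.

    The assay resolves on the order of a hundred fragments across its two dye
    channels, so ~50 loci per channel with a minimum spacing keeps neighbours
    resolvable against replicate position jitter.  Polymorphic loci get extra
    clearance — enough to hold the whole variant span plus the jitter range —
    and pairwise-distinct couple states: position shifts of ``shift_bp`` and
    ``2 * shift_bp`` (a short-repeat length polymorphism spanning a few
    repeat units), or, for a ``mixed_fraction`` of them, a shift combined
    with absence in one couple (an amplification-site polymorphism).
    """
    rng = np.random.default_rng(seed)
    lo, hi = position_range_bp
    if n_polymorphic > n_loci:
        raise ValueError("n_polymorphic exceeds n_loci")

    # polymorphic loci first, mutually separated by 2x the clearance
    poly_pos: list[float] = []
    for _ in range(200 * max(n_polymorphic, 1)):
        if len(poly_pos) == n_polymorphic:
            break
        cand = float(rng.uniform(lo, hi - 2 * shift_bp))
        if all(abs(cand - p) >= 2 * poly_clearance_bp for p in poly_pos):
            poly_pos.append(cand)
    if len(poly_pos) < n_polymorphic:
        raise ValueError("could not place polymorphic loci with enough clearance")

    # shared loci fill the rest of the range, avoiding the polymorphic zones
    shared_pos: list[float] = []
    n_shared = n_loci - n_polymorphic
    for _ in range(2000 * max(n_shared, 1)):
        if len(shared_pos) == n_shared:
            break
        cand = float(rng.uniform(lo, hi))
        if all(abs(cand - p) >= min_spacing_bp for p in shared_pos) and all(
            abs(cand - p) >= poly_clearance_bp for p in poly_pos
        ):
            shared_pos.append(cand)
    if len(shared_pos) < n_shared:
        raise ValueError("n_loci too large for the range at this spacing")

    loci = [
        LocusSpec(base_position_bp=pos, couple_offsets=(0.0, 0.0, 0.0))
        for pos in shared_pos
    ]
    for pos in poly_pos:
        perm = rng.permutation(3)
        if rng.random() < mixed_fraction:
            states: list[float | None] = [0.0, shift_bp, None]
        else:
            states = [0.0, shift_bp, 2 * shift_bp]
        loci.append(
            LocusSpec(
                base_position_bp=pos,
                couple_offsets=tuple(states[p] for p in perm),
            )
        )
    loci.sort(key=lambda l: l.base_position_bp)
    return loci


def simulate_cohort(
    config: SimulationConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate every peak table of the cohort.

    Returns ``(peaks, truth)``: ``peaks`` holds one row per called peak in
    the default io dialect (positions in instrument datapoints), over all
    samples x replicates x channels; ``truth`` lists every locus with its
    per-couple true position and polymorphism class.  The same locus list is
    used on every channel.  Deterministic given ``(config, seed)``.
    """
    rng = np.random.default_rng(seed)
    noise = config.noise
    lo, hi = config.position_range_bp
    span = hi - lo
    rows = []
    for channel in config.channels:
        for couple in COUPLES:
            true_pos = [
                p
                for locus in config.loci
                if (p := locus.position_for(couple)) is not None
            ]
            for twin in TWINS:
                sample = f"c{couple}{twin}"
                for rep in range(1, config.replicates + 1):
                    pos = np.array(true_pos)
                    keep = rng.random(pos.size) >= noise.dropout_prob
                    pos = pos[keep] + noise.jitter(rng, int(keep.sum()))
                    heights = config.typical_height * rng.lognormal(
                        mean=0.0, sigma=noise.height_lognormal_sd, size=pos.size
                    )
                    n_spur = rng.poisson(noise.spurious_rate_per_100bp * span / 100.0)
                    spur_pos = rng.uniform(lo, hi, size=n_spur)
                    spur_h = config.typical_height * rng.uniform(0.02, 0.06, size=n_spur)
                    all_pos = np.concatenate([pos, spur_pos])
                    all_h = np.concatenate([heights, spur_h])
                    lengths = rng.lognormal(mean=np.log(3.0), sigma=0.2, size=all_pos.size)
                    order = np.argsort(all_pos)
                    for p, h, ln in zip(all_pos[order], all_h[order], lengths[order]):
                        rows.append(
                            {
                                "position_dp": float(config.standard.to_dp(p)),
                                "height": float(h),
                                "area": float(h * ln),
                                "channel": channel,
                                "sample": sample,
                                "replicate": rep,
                            }
                        )
    peaks = pd.DataFrame(
        rows,
        columns=["position_dp", "height", "area", "channel", "sample", "replicate"],
    )

    truth_rows = []
    for i, locus in enumerate(config.loci):
        truth_rows.append(
            {
                "locus_id": i,
                "base_position_bp": locus.base_position_bp,
                **{
                    f"couple{k}_bp": locus.position_for(k) for k in COUPLES
                },
                "polymorphic": locus.is_polymorphic,
                "global_polymorphic": locus.is_global_polymorphic,
            }
        )
    truth = pd.DataFrame(truth_rows)
    return peaks, truth


def truth_match(
    regions: list[ClassifyingRegion],
    truth: pd.DataFrame,
    slack_bp: float = 5.0,
) -> tuple[float, int]:
    """Score detected global regions against the planted truth.

    A globally polymorphic locus counts as recovered when some region's
    merged interval, widened by ``slack_bp``, contains one of the locus's
    per-couple positions.  Regions matching no such locus are false
    positives.  Returns ``(sensitivity, n_false_positives)``; sensitivity is
    1.0 when nothing was planted.
    """
    planted = truth[truth["global_polymorphic"]]
    recovered = set()
    false_pos = 0
    for reg in regions:
        lo, hi = reg.merged_interval()
        hit = False
        for _, row in planted.iterrows():
            positions = [row[f"couple{k}_bp"] for k in COUPLES]
            if any(
                p is not None and not np.isnan(p) and lo - slack_bp <= p <= hi + slack_bp
                for p in positions
            ):
                recovered.add(int(row["locus_id"]))
                hit = True
        if not hit:
            false_pos += 1
    sensitivity = 1.0 if len(planted) == 0 else len(recovered) / len(planted)
    return sensitivity, false_pos
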