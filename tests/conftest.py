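import numpy as np
import pytest

from aluwave.discriminant import CohortCoefficients
from aluwave.preprocessing import UnionTrack
from aluwave.reconstruction import reconstruct_signal
from aluwave.wpt import haar_wpt_forward


def cohort_from_positions(positions, channel="x", max_depth=11):
    """Build a six-signal cohort from ``{(couple, twin): [bp, ...]}``."""
    tables = {}
    for couple in (1, 2, 3):
        for twin in "ab":
            pos = np.asarray(positions[(couple, twin)], dtype=float)
            track = UnionTrack(
                sample_id=f"c{couple}{twin}",
                channel=channel,
                positions=pos,
                support_counts=np.full(pos.size, 4, dtype=int),
            )
            tables[(couple, twin)] = haar_wpt_forward(
                reconstruct_signal(track).values, max_depth=max_depth
            )
    return CohortCoefficients(tables=tables, channel=channel)


def single_peak_cohort(ref_bp, other_bp):
    """Reference couple at ``ref_bp``, both other couples at ``other_bp``
    (``None`` = peak absent)."""
    pos = {}
    for twin in "ab":
        pos[(1, twin)] = [] if ref_bp is None else [ref_bp]
        for k in (2, 3):
            pos[(k, twin)] = [] if other_bp is None else [other_bp]
    return cohort_from_positions(pos)


@pytest.fixture(scope="session")
def identical_cohort():
    pos = {(k, t): [200.0, 500.5, 800.0] for k in (1, 2, 3) for t in "ab"}
    return cohort_from_positions(pos)
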