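"""Five-parameter binary scoring of paired left/right lymph nodes.

Each tumor-draining (left) node is scored against its internal-control
(right) node on five parameters, one point each:

=========  =====================================================
volume     left/right volume ratio >= 5
shape      left node round (length/width < 2)
hilum      no hilum detected on the left node
ttp        time-to-peak lengthened in the left node vs control
wir        wash-in rate reduced in the left node vs control
=========  =====================================================

The sum score is the count of positive parameters over the number of
*evaluable* parameters, reported as a percent: when the CEUS analysis of
either node is unusable, TTP and WiR drop out of the denominator instead
of being imputed (a 3/3 node scores 100%, like an all-positive 5/5 node).

Per-node "significantly increased/reduced" calls cannot be t-tests with a
single measurement per node; they are implemented as relative-margin
rules (default 20%), with the cohort-level paired t-test reported
separately via :func:`group_paired_ttest`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateTestError, InvalidInputError, PairingError
from .morphometry import LNMorphometry, ROUNDNESS_CUTOFF
from .perfusion import PerfusionParams

__all__ = [
    "LNRecord",
    "ScoreCard",
    "PARAMETER_NAMES",
    "score_volume",
    "score_shape",
    "score_hilum",
    "score_ttp",
    "score_wir",
    "build_scorecard",
    "group_paired_ttest",
    "round_half_away",
]

PARAMETER_NAMES = ("volume", "shape", "hilum", "ttp", "wir")

DEFAULT_VOLUME_RATIO_THRESHOLD = 5.0
DEFAULT_REL_MARGIN = 0.2


@dataclass
class LNRecord:
    """One node's measurements, paired with its contralateral node."""

    node_id: str
    subject_id: str
    side: str  # "left" | "right"
    morphometry: LNMorphometry
    perfusion: PerfusionParams | None
    hilum_visible: bool

    @property
    def perfusion_usable(self) -> bool:
        return self.perfusion is not None and self.perfusion.usable


@dataclass
class ScoreCard:
    """Five 0/1 parameter scores of one subject, with availability.

    ``scores`` maps parameter name to 0, 1 or None (unavailable).
    """

    subject_id: str
    scores: dict[str, int | None]
    available_count: int = field(init=False)
    sum_score: int = field(init=False)
    sum_percent: float = field(init=False)

    def __post_init__(self) -> None:
        vals = [self.scores[k] for k in PARAMETER_NAMES]
        avail = [v for v in vals if v is not None]
        if not avail:
            raise InvalidInputError(f"subject {self.subject_id!r}: no score available")
        self.available_count = len(avail)
        self.sum_score = int(sum(avail))
        self.sum_percent = 100.0 * self.sum_score / self.available_count

    @property
    def sum_percent_display(self) -> int:
        """Percent rounded to the nearest integer, half away from zero."""
        return round_half_away(self.sum_percent)


def round_half_away(x: float) -> int:
    """Round to the nearest integer with ties going away from zero."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def score_volume(
    left_vol: float,
    right_vol: float,
    ratio_threshold: float = DEFAULT_VOLUME_RATIO_THRESHOLD,
) -> int:
    """1 iff the left node is at least ``ratio_threshold`` times larger."""
    if left_vol <= 0 or right_vol <= 0:
        raise InvalidInputError(f"volumes must be positive, got {left_vol}, {right_vol}")
    return int(left_vol / right_vol >= ratio_threshold)


def score_shape(lw_ratio: float, cutoff: float = ROUNDNESS_CUTOFF) -> int:
    """1 iff the node is round (length/width strictly below the cutoff)."""
    return int(lw_ratio < cutoff)


def score_hilum(hilum_visible: bool) -> int:
    """1 iff no hilum was detected (hilar loss suggests infiltration)."""
    return int(not hilum_visible)


def score_ttp(
    left_ttp: float | None,
    right_ttp: float | None,
    rel_margin: float = DEFAULT_REL_MARGIN,
) -> int | None:
    """1 iff left TTP exceeds the control TTP by more than the margin."""
    if left_ttp is None or right_ttp is None:
        return None
    return int(left_ttp > right_ttp * (1.0 + rel_margin))


def score_wir(
    left_wir: float | None,
    right_wir: float | None,
    rel_margin: float = DEFAULT_REL_MARGIN,
) -> int | None:
    """1 iff left WiR falls below the control WiR by more than the margin."""
    if left_wir is None or right_wir is None:
        return None
    return int(left_wir < right_wir * (1.0 - rel_margin))


def build_scorecard(
    left: LNRecord,
    right: LNRecord,
    ratio_threshold: float = DEFAULT_VOLUME_RATIO_THRESHOLD,
    roundness_cutoff: float = ROUNDNESS_CUTOFF,
    ttp_rel_margin: float = DEFAULT_REL_MARGIN,
    wir_rel_margin: float = DEFAULT_REL_MARGIN,
) -> ScoreCard:
    """Score one subject from its paired left/right node records.

    TTP and WiR are unavailable together whenever either side's perfusion
    analysis is unusable (the study's motion-corrupted control node makes
    both comparisons impossible).
    """
    if left.subject_id != right.subject_id:
        raise PairingError(
            f"records from different subjects: {left.subject_id!r} / {right.subject_id!r}"
        )
    if left.side != "left" or right.side != "right":
        raise PairingError(
            f"subject {left.subject_id!r}: need one left and one right record"
        )
    ceus_ok = left.perfusion_usable and right.perfusion_usable
    scores: dict[str, int | None] = {
        "volume": score_volume(
            left.morphometry.volume_mm3, right.morphometry.volume_mm3, ratio_threshold
        ),
        "shape": score_shape(left.morphometry.lw_ratio, roundness_cutoff),
        "hilum": score_hilum(left.hilum_visible),
        "ttp": (
            score_ttp(left.perfusion.ttp_s, right.perfusion.ttp_s, ttp_rel_margin)
            if ceus_ok
            else None
        ),
        "wir": (
            score_wir(
                left.perfusion.wir_au_per_s, right.perfusion.wir_au_per_s, wir_rel_margin
            )
            if ceus_ok
            else None
        ),
    }
    return ScoreCard(subject_id=left.subject_id, scores=scores)


def group_paired_ttest(
    left_values: np.ndarray, right_values: np.ndarray
) -> tuple[float, float]:
    """Two-sided paired t-test of left vs right values across subjects.

    This is the cohort-level significance test reported alongside the
    scores; it never gates an individual subject's scorecard.
    """
    left_values = np.asarray(left_values, dtype=float)
    right_values = np.asarray(right_values, dtype=float)
    if left_values.shape != right_values.shape or left_values.ndim != 1:
        raise InvalidInputError("paired samples must be equal-length 1-D arrays")
    if left_values.size < 2:
        raise InvalidInputError("need at least two pairs")
    d = left_values - right_values
    if np.std(d, ddof=1) == 0:
        raise DegenerateTestError("zero variance of paired differences")
    res = stats.ttest_rel(left_values, right_values)
    return float(res.statistic), float(res.pvalue)
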